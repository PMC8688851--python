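"""Species × trait tables: loading, validation, transforms, subsetting.

The universal input for network construction is a :class:`TraitMatrix` —
observations (species-level records) in rows, trait values in columns,
with an explicit missingness mask and optional categorical group labels
(growth form, life form).  Mass-based traits can be converted to their
area-based counterparts via leaf mass per area (e.g. N_area = N_mass × LMA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MISSING_MARKERS = ("", "NA", "NaN")


class TraitTableError(ValueError):
    """Malformed trait table or an operation inconsistent with its schema."""


class EmptyGroupWarning(UserWarning):
    """A group subset matched no rows."""


@dataclass
class TraitMatrix:
    """Observations × traits with missingness mask and group labels.

    Parameters
    ----------
    values : ndarray of shape (n_obs, n_traits)
        Trait values as floats; entries flagged in ``missing_mask`` are NaN.
    trait_names : list of str
        Column labels, one per trait.
    group_labels : DataFrame or None
        Per-observation categorical labels (e.g. growth form); optional.
    missing_mask : ndarray of bool, same shape as ``values``
        True where a value is absent.
    meta : dict
        Free-form provenance (source file, transforms applied, units).
    """

    values: np.ndarray
    trait_names: list[str]
    group_labels: pd.DataFrame | None = None
    missing_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TraitTableError("trait values must form a 2-D matrix")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise TraitTableError("missing_mask shape differs from values shape")
        if len(self.trait_names) != self.values.shape[1]:
            raise TraitTableError(
                f"{len(self.trait_names)} trait names for "
                f"{self.values.shape[1]} columns"
            )
        # keep values and mask consistent: masked cells are NaN
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan
        present = ~self.missing_mask
        if not np.all(np.isfinite(self.values[present])):
            raise TraitTableError("non-missing trait values must be finite")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def trait_index(self, name: str) -> int:
        try:
            return self.trait_names.index(name)
        except ValueError:
            raise TraitTableError(f"unknown trait column {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Trait values (plus group labels, if any) as a DataFrame."""
        df = pd.DataFrame(self.values, columns=self.trait_names)
        if self.group_labels is not None:
            df = pd.concat(
                [self.group_labels.reset_index(drop=True), df], axis=1
            )
        return df

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(
            values=self.values.copy(),
            trait_names=list(self.trait_names),
            group_labels=None
            if self.group_labels is None
            else self.group_labels.copy(),
            missing_mask=self.missing_mask.copy(),
            meta=dict(self.meta),
        )

    def write(self, path: str | Path, sep: str = ",") -> None:
        """Write the table (labels + traits) as delimited text."""
        self.to_frame().to_csv(path, sep=sep, index=False)


def load_trait_table(
    path: str | Path,
    trait_columns: Sequence[str],
    group_columns: Sequence[str] = (),
    sep: str | None = None,
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> TraitMatrix:
    """Load a delimited species × trait table.

    Parameters
    ----------
    path : path to a CSV/TSV file with a header row (UTF-8).
    trait_columns : names of the numeric trait columns (≥ 2).
    group_columns : names of categorical grouping columns to preserve.
    sep : field delimiter; None auto-detects between comma and tab.
    missing_markers : cell contents treated as missing, besides blanks.

    Unparseable cells in trait columns become missing.  A trait column with
    no numeric values at all is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if len(trait_columns) < 2:
        raise TraitTableError("schema must name at least 2 trait columns")
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(
        path, sep=sep, na_values=list(missing_markers), keep_default_na=True,
        encoding="utf-8",
    )
    absent = [c for c in (*trait_columns, *group_columns) if c not in df.columns]
    if absent:
        raise TraitTableError(f"column(s) not present in {path.name}: {absent}")
    values = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
         for c in trait_columns]
    ) if len(df) else np.empty((0, len(trait_columns)))
    labels = df[list(group_columns)].astype("string") if group_columns else None
    if len(df):
        dead = [c for c, v in zip(trait_columns, values.T) if np.isnan(v).all()]
        if dead:
            raise TraitTableError(f"trait column(s) with zero numeric values: {dead}")
    return TraitMatrix(
        values=values,
        trait_names=list(trait_columns),
        group_labels=labels,
        meta={"source": str(path), "sep": sep, "transforms": []},
    )


def apply_transform(
    tm: TraitMatrix, transform: Mapping[str, str] | str
) -> TraitMatrix:
    """Apply per-trait value transforms ('identity' or 'log10').

    ``transform`` is either a single mode applied to every trait or a
    mapping trait name → mode (unnamed traits default to identity).
    log10 requires strictly positive non-missing values.
    """
    if isinstance(transform, str):
        transform = {t: transform for t in tm.trait_names}
    unknown = set(transform) - set(tm.trait_names)
    if unknown:
        raise TraitTableError(f"transform names unknown trait(s): {sorted(unknown)}")
    out = tm.copy()
    applied = {}
    for name, mode in transform.items():
        j = tm.trait_index(name)
        col = out.values[:, j]
        keep = ~out.missing_mask[:, j]
        if mode == "identity":
            applied[name] = "identity"
        elif mode == "log10":
            if keep.any() and np.nanmin(col[keep]) <= 0:
                raise TraitTableError(
                    f"log10 requested for {name!r} but it has values ≤ 0"
                )
            col[keep] = np.log10(col[keep])
            applied[name] = "log10"
        else:
            raise TraitTableError(f"unknown transform {mode!r} for {name!r}")
    out.meta.setdefault("transforms", [])
    out.meta["transforms"] = list(out.meta["transforms"]) + [applied]
    return out


def mass_to_area(
    tm: TraitMatrix,
    pairs: Mapping[str, str],
    lma_name: str = "LMA",
) -> TraitMatrix:
    """Append area-based trait columns: area value = mass value × LMA.

    ``pairs`` maps a mass-based source column to the new area-based column
    name (e.g. ``{"N_mass": "N_area"}``).  The product is taken on the
    original scale and in the source units (mg g⁻¹ × g m⁻² → mg m⁻²); no
    unit rescaling is performed.  A cell is missing if either factor is.
    """
    jl = tm.trait_index(lma_name)
    lma = tm.values[:, jl]
    lma_missing = tm.missing_mask[:, jl]
    new_cols, new_mask, new_names = [], [], []
    for src, dst in pairs.items():
        js = tm.trait_index(src)
        miss = tm.missing_mask[:, js] | lma_missing
        col = tm.values[:, js] * lma
        col[miss] = np.nan
        new_cols.append(col)
        new_mask.append(miss)
        new_names.append(dst)
    out = TraitMatrix(
        values=np.column_stack([tm.values] + new_cols)
        if new_cols else tm.values.copy(),
        trait_names=list(tm.trait_names) + new_names,
        group_labels=None if tm.group_labels is None else tm.group_labels.copy(),
        missing_mask=np.column_stack([tm.missing_mask] + new_mask)
        if new_mask else tm.missing_mask.copy(),
        meta=dict(tm.meta),
    )
    out.meta["area_conversion"] = {
        "lma": lma_name,
        "pairs": dict(pairs),
        "units": "area value = mass value × LMA, source units preserved",
    }
    return out


def subset_by_group(tm: TraitMatrix, column: str, value: str) -> TraitMatrix:
    """Rows whose label in ``column`` equals ``value``, order preserved.

    An empty result is legal but warns (`EmptyGroupWarning`): the caller
    asked for a category absent from the data.
    """
    if tm.group_labels is None or column not in tm.group_labels.columns:
        raise TraitTableError(f"unknown grouping column {column!r}")
    keep = (tm.group_labels[column] == value).fillna(False).to_numpy()
    if not keep.any():
        warnings.warn(
            f"no rows with {column} == {value!r}", EmptyGroupWarning,
            stacklevel=2,
        )
    out = TraitMatrix(
        values=tm.values[keep],
        trait_names=list(tm.trait_names),
        group_labels=tm.group_labels.loc[keep].reset_index(drop=True),
        missing_mask=tm.missing_mask[keep],
        meta=dict(tm.meta),
    ) if keep.any() else TraitMatrix(
        values=np.empty((0, tm.n_traits)),
        trait_names=list(tm.trait_names),
        group_labels=tm.group_labels.iloc[:0].reset_index(drop=True),
        missing_mask=np.empty((0, tm.n_traits), dtype=bool),
        meta=dict(tm.meta),
    )
    out.meta["subset"] = {"column": column, "value": value}
    return out
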