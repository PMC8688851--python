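"""Build a trait network from a species × trait matrix.

The network has one node per trait.  An edge joins two traits when their
pairwise Pearson correlation is significant (two-sided p < alpha, strict),
and carries weight |r|.  Independently, every node pair gets a distance:
the Euclidean separation of the two traits' coordinates in a
correlation-matrix PCA of the (standardised) traits,

    d_ij = sqrt( sum_m (j_m - i_m)^2 ),

where i_m is the coordinate of trait i on component m.  Distances live on
a dimension-free scale, so shortest paths over the significant edges are
comparable across trait sets and groups.

:class:`TraitNetworkBuilder` is the scikit-learn-style front end
(``fit`` on a TraitMatrix / DataFrame / array, fitted attributes with a
trailing underscore); the module functions wrap it step by step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .trait_data import TraitMatrix

MIN_PAIR_N = 3  # below this a pairwise correlation is undefined


@dataclass
class CorrelationResult:
    """Pairwise Pearson r, two-sided p, and pairwise-complete sample sizes.

    Undefined cells (n_pairs < 3 or a constant column on the
    pairwise-complete rows) hold r = NaN, p = NaN and are treated as
    non-significant downstream.
    """

    r: np.ndarray
    p: np.ndarray
    n_pairs: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        for m in (self.r, self.p):
            if m.shape != (len(self.trait_names),) * 2:
                raise ValueError("correlation matrices must be traits × traits")


@dataclass
class PCAEmbedding:
    """Per-trait coordinates across all principal components.

    ``scores[i, m]`` is the coordinate of trait i on component m.  With the
    default variance-scaled convention these are the standard variable-plot
    coordinates of a correlation PCA: loading × sqrt(component variance),
    so that scores @ scores.T reproduces the correlation matrix.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    trait_names: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class TraitNetwork:
    """Nodes = traits; |r|-weighted significant edges; PCA distances.

    ``adjacency[i, j]`` is |r_ij| if the correlation is significant at
    ``alpha`` else 0 (zero diagonal); ``distances[i, j]`` is the PCA-space
    Euclidean distance; ``r_signs`` keeps the sign of retained correlations
    for rendering and export.
    """

    trait_names: list[str]
    adjacency: np.ndarray
    distances: np.ndarray
    alpha: float
    r_signs: np.ndarray
    correlations: CorrelationResult | None = None
    embedding: PCAEmbedding | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.trait_names)
        if self.adjacency.shape != (n, n) or self.distances.shape != (n, n):
            raise ValueError("adjacency/distances must be traits × traits")

    @property
    def n_nodes(self) -> int:
        return len(self.trait_names)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def has_edges(self) -> bool:
        return self.n_edges > 0

    def edge_list(self) -> pd.DataFrame:
        """Tidy edge table: trait_i, trait_j, weight, sign, p, distance."""
        rows = []
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if self.adjacency[i, j] > 0:
                    rows.append(
                        {
                            "trait_i": self.trait_names[i],
                            "trait_j": self.trait_names[j],
                            "weight": self.adjacency[i, j],
                            "sign": int(self.r_signs[i, j]),
                            "p": float(self.correlations.p[i, j])
                            if self.correlations is not None
                            else np.nan,
                            "distance": self.distances[i, j],
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["trait_i", "trait_j", "weight", "sign", "p", "distance"],
        )

    def to_networkx(self):
        """Undirected networkx graph with weight/sign/p/distance edge attrs."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.trait_names)
        for row in self.edge_list().itertuples(index=False):
            g.add_edge(
                row.trait_i,
                row.trait_j,
                weight=float(row.weight),
                sign=int(row.sign),
                p=float(row.p),
                distance=float(row.distance),
            )
        return g

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Coerce TraitMatrix / DataFrame / array to (values, names)."""
    if isinstance(X, TraitMatrix):
        return X.values, list(X.trait_names)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D observations × traits matrix")
    return arr, [f"trait_{j}" for j in range(arr.shape[1])]


def _pearson_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Pearson r under the exact t transform (df = n − 2)."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)))
    return p


def correlate(X) -> CorrelationResult:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Each trait pair uses the rows where both traits are observed.  Pairs
    with fewer than 3 complete rows, or with a constant column on those
    rows, are undefined (NaN) and never become edges.
    """
    values, names = _as_matrix(X)
    n_traits = values.shape[1]
    if n_traits < 2:
        raise ValueError("need at least 2 traits to correlate")
    present = ~np.isnan(values)
    r = np.eye(n_traits)
    p = np.zeros((n_traits, n_traits))
    n_pairs = (present.T.astype(np.int64) @ present.astype(np.int64))

    if present.all():
        # fast path: no missing data, vectorised correlation
        with np.errstate(invalid="ignore", divide="ignore"):
            rfull = np.corrcoef(values, rowvar=False)
        rfull = np.asarray(rfull, dtype=float)
        np.fill_diagonal(rfull, 1.0)
        r = rfull
        p = _pearson_pvalue(r, n_pairs)
        np.fill_diagonal(p, 0.0)
        if values.shape[0] < MIN_PAIR_N:
            r, p = np.full_like(r, np.nan), np.full_like(p, np.nan)
            np.fill_diagonal(r, 1.0)
            np.fill_diagonal(p, 0.0)
        else:
            const = np.nanstd(values, axis=0) == 0
            for j in np.nonzero(const)[0]:
                r[j, :], r[:, j] = np.nan, np.nan
                p[j, :], p[:, j] = np.nan, np.nan
                r[j, j], p[j, j] = 1.0, 0.0
        return CorrelationResult(r, p, n_pairs, names)

    for i in range(n_traits):
        for j in range(i + 1, n_traits):
            keep = present[:, i] & present[:, j]
            nij = int(keep.sum())
            if nij < MIN_PAIR_N:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            xi, xj = values[keep, i], values[keep, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationResult(r, p, n_pairs, names)


def threshold_adjacency(
    cr: CorrelationResult, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Significance-gate the correlation matrix into a weighted adjacency.

    Returns ``(adjacency, signs)`` where a_ij = |r_ij| if p_ij < alpha
    (strict), else 0, with zero diagonal; signs carries sign(r_ij) for
    retained edges and 0 elsewhere.  Undefined correlations are non-edges.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    with np.errstate(invalid="ignore"):
        significant = cr.p < alpha
    adjacency = np.where(significant, np.abs(cr.r), 0.0)
    adjacency = np.nan_to_num(adjacency, nan=0.0)
    signs = np.where(adjacency > 0, np.sign(cr.r), 0.0)
    np.fill_diagonal(adjacency, 0.0)
    np.fill_diagonal(signs, 0.0)
    return adjacency, signs


def pca_embed(X, scale_scores: bool = True) -> PCAEmbedding:
    """Correlation-matrix PCA of the traits on complete-case rows.

    Rows with any missing trait are dropped (a PCA needs one common row
    space); at least n_traits + 1 complete rows are required.  With
    ``scale_scores`` (default) trait coordinates are loading × sqrt(λ_m)
    — the variable coordinates of a correlation biplot; otherwise raw
    eigenvector loadings.  Component sign is fixed so the
    largest-magnitude loading on each component is positive.
    """
    values, names = _as_matrix(X)
    n_traits = values.shape[1]
    complete = ~np.isnan(values).any(axis=1)
    cc = values[complete]
    if cc.shape[0] < n_traits + 1:
        raise ValueError(
            f"PCA needs ≥ {n_traits + 1} complete-case rows, have {cc.shape[0]}"
        )
    sd = cc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant trait(s) on complete-case rows: {bad}")
    z = (cc - cc.mean(axis=0)) / sd
    corr = (z.T @ z) / (cc.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for m in range(n_traits):
        k = np.argmax(np.abs(eigvec[:, m]))
        if eigvec[k, m] < 0:
            eigvec[:, m] = -eigvec[:, m]
    scores = eigvec * np.sqrt(eigval) if scale_scores else eigvec.copy()
    explained = eigval / eigval.sum()
    return PCAEmbedding(scores=scores, explained_variance=explained,
                        trait_names=names)


def trait_distances(emb: PCAEmbedding) -> np.ndarray:
    """Euclidean distance between trait score vectors over all components."""
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(emb.scores, metric="euclidean"))
    return d


class TraitNetworkBuilder(BaseEstimator):
    """Estimate a significance-thresholded, |r|-weighted trait network.

    scikit-learn-style estimator: ``fit(X)`` takes an observations × traits
    matrix (TraitMatrix, DataFrame, or ndarray; NaN = missing) and exposes
    the fitted network through trailing-underscore attributes.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level for edge inclusion (strict p < alpha).
    scale_scores : bool, default True
        PCA trait coordinates as loading × sqrt(component variance)
        (correlation-biplot variable coordinates); False uses raw
        eigenvector loadings.
    p_adjust : {None, "bonferroni", "fdr_bh"}, default None
        Optional multiple-testing correction of the pairwise p-values
        before thresholding.  Off by default: the method's convention is
        raw p < 0.05.

    Attributes
    ----------
    network_ : TraitNetwork
    adjacency_ : ndarray, |r| weights of significant edges (hollow).
    distances_ : ndarray, PCA-space Euclidean node-pair distances.
    correlations_ : CorrelationResult
    embedding_ : PCAEmbedding
    n_features_in_ : int
    feature_names_in_ : ndarray of trait names (when X carries names).
    """

    def __init__(self, alpha: float = 0.05, scale_scores: bool = True,
                 p_adjust: str | None = None):
        self.alpha = alpha
        self.scale_scores = scale_scores
        self.p_adjust = p_adjust

    def fit(self, X, y=None) -> "TraitNetworkBuilder":
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        values, names = _as_matrix(X)
        cr = correlate(X)
        if self.p_adjust is not None:
            cr = CorrelationResult(
                cr.r, _adjust_pvalues(cr.p, self.p_adjust), cr.n_pairs,
                cr.trait_names,
            )
        adjacency, signs = threshold_adjacency(cr, self.alpha)
        emb = pca_embed(X, scale_scores=self.scale_scores)
        dist = trait_distances(emb)
        self.correlations_ = cr
        self.embedding_ = emb
        self.adjacency_ = adjacency
        self.distances_ = dist
        self.n_features_in_ = values.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.network_ = TraitNetwork(
            trait_names=names,
            adjacency=adjacency,
            distances=dist,
            alpha=self.alpha,
            r_signs=signs,
            correlations=cr,
            embedding=emb,
            meta={
                "n_observations": int(values.shape[0]),
                "scale_scores": self.scale_scores,
                "p_adjust": self.p_adjust,
                "zero_edges": not bool((np.triu(adjacency, 1) > 0).any()),
            },
        )
        return self

    def fit_network(self, X) -> TraitNetwork:
        """Convenience: fit and return the TraitNetwork."""
        return self.fit(X).network_


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    """Adjust the upper-triangle p-values (Bonferroni or Benjamini-Hochberg)."""
    from statsmodels.stats.multitest import multipletests

    iu = np.triu_indices_from(p, k=1)
    raw = p[iu]
    ok = ~np.isnan(raw)
    adj = raw.copy()
    if ok.any():
        adj[ok] = multipletests(raw[ok], method=method)[1]
    out = p.copy()
    out[iu] = adj
    out.T[iu] = adj
    return out


def build_network(X, alpha: float = 0.05, **kwargs) -> TraitNetwork:
    """One-shot: correlations → thresholded adjacency, PCA → distances.

    Composes the full construction on a single trait matrix.  A network
    with zero significant edges is returned (flagged in ``meta``), not an
    error.
    """
    return TraitNetworkBuilder(alpha=alpha, **kwargs).fit_network(X)
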