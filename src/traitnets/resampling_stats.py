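"""Bootstrap uncertainty for network parameters and group comparisons.

Species (rows) are resampled; a full network — pairwise correlations,
significance threshold, PCA and distances — is rebuilt inside every
replicate, and all six parameters are recorded.  The replicate
distributions give each parameter a mean and a standard error (the
bootstrap standard deviation), and feed the between-group statistics:
Welch t-tests on the overall parameters, one-way ANOVA of node
parameters across traits, and paired mean differences of node
parameters between two networks with percentile bootstrap intervals.

Two resampling schemes are supported.  The classic scheme draws rows
with replacement at the full pool size.  The subgroup scheme draws
without replacement a subsample larger than three quarters of the pool
(ceil(0.75·N) + 1), which keeps small group pools dense enough that
every replicate can still form a network.

Replicates whose network has fewer than ``min_edges`` edges are counted
as degenerate and excluded from summaries — dropping them silently would
bias edge density upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .network_build import TraitNetworkBuilder, _as_matrix
from .network_metrics import NetworkSummary, summarize

OVERALL_PARAMS = ("edge_density", "diameter", "average_path_length")
NODE_PARAMS = ("degree", "closeness", "betweenness")


@dataclass
class BootstrapConfig:
    """Resampling configuration.

    n_replicates : number of bootstrap networks (field convention: 9999).
    sample_fraction : fraction of the species pool per replicate; None
        with replacement means the full pool size.
    with_replacement : classic bootstrap (True) or subsampling (False);
        without replacement the draw size is ceil(fraction·N) + 1 so the
        subsample always exceeds the stated fraction of the pool.
    seed : mandatory reproducibility seed.
    min_edges : replicates below this edge count are degenerate.
    """

    n_replicates: int = 9999
    sample_fraction: float | None = None
    with_replacement: bool = True
    seed: int = 0
    min_edges: int = 1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be ≥ 1")
        if self.sample_fraction is not None and not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def draw_size(self, n_rows: int) -> int:
        if self.with_replacement:
            if self.sample_fraction is None:
                return n_rows
            return max(1, round(self.sample_fraction * n_rows))
        frac = 0.75 if self.sample_fraction is None else self.sample_fraction
        return min(n_rows, math.ceil(frac * n_rows) + 1)


@dataclass
class BootstrapDistribution:
    """Per-replicate network parameters, with degeneracy bookkeeping.

    ``overall`` is a replicate × parameter frame; ``node[param]`` is a
    replicate × trait frame.  Degenerate replicates hold NaN rows and are
    excluded by ``valid`` but still counted.
    """

    overall: pd.DataFrame
    node: dict[str, pd.DataFrame]
    valid: np.ndarray
    trait_names: list[str]
    config: BootstrapConfig
    alpha: float
    length_mode: str

    @property
    def n_replicates(self) -> int:
        return len(self.overall)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def n_degenerate(self) -> int:
        return self.n_replicates - self.n_valid

    def values(self, parameter: str, trait: str | None = None) -> np.ndarray:
        """Valid-replicate values of an overall or per-trait parameter."""
        if parameter in OVERALL_PARAMS:
            v = self.overall.loc[self.valid, parameter].to_numpy()
        elif parameter in NODE_PARAMS:
            frame = self.node[parameter].loc[self.valid]
            if trait is None:
                raise ValueError(f"{parameter!r} is per-trait; name a trait")
            v = frame[trait].to_numpy()
        else:
            raise ValueError(f"unknown parameter {parameter!r}")
        return v[~np.isnan(v)]

    def node_matrix(self, parameter: str) -> pd.DataFrame:
        if parameter not in NODE_PARAMS:
            raise ValueError(f"unknown node parameter {parameter!r}")
        return self.node[parameter].loc[self.valid]


@dataclass
class GroupComparison:
    """Between-network comparison of one parameter.

    For overall parameters: Welch two-sample t-test on the replicate
    values.  For node parameters: the paired mean difference — the mean
    over traits of per-trait (a − b) differences of replicate means —
    with a percentile bootstrap confidence interval.
    """

    parameter: str
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    t: float | None = None
    df: float | None = None
    p: float | None = None
    paired_mean_difference: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    per_trait_difference: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, float):
                out[k] = None if np.isnan(v) else float(v)
            else:
                out[k] = v
        return out


class NetworkBootstrap(BaseEstimator):
    """Bootstrap distribution of trait-network parameters.

    scikit-learn-style estimator: ``fit(X)`` resamples the rows of X
    ``n_replicates`` times, rebuilds the full network per replicate
    (correlations, threshold, PCA, distances) and stores every
    parameter's replicate distribution in ``distribution_``.

    Parameters mirror :class:`BootstrapConfig` plus the network settings
    (``alpha``, ``length_mode``, ``betweenness_mode``, ``scale_scores``).
    Deterministic given ``seed``.
    """

    def __init__(
        self,
        n_replicates: int = 9999,
        sample_fraction: float | None = None,
        with_replacement: bool = True,
        seed: int = 0,
        min_edges: int = 1,
        alpha: float = 0.05,
        length_mode: str = "pca_distance",
        betweenness_mode: str = "count",
        scale_scores: bool = True,
    ):
        self.n_replicates = n_replicates
        self.sample_fraction = sample_fraction
        self.with_replacement = with_replacement
        self.seed = seed
        self.min_edges = min_edges
        self.alpha = alpha
        self.length_mode = length_mode
        self.betweenness_mode = betweenness_mode
        self.scale_scores = scale_scores

    def _config(self) -> BootstrapConfig:
        return BootstrapConfig(
            n_replicates=self.n_replicates,
            sample_fraction=self.sample_fraction,
            with_replacement=self.with_replacement,
            seed=self.seed,
            min_edges=self.min_edges,
        )

    def fit(self, X, y=None) -> "NetworkBootstrap":
        cfg = self._config()
        values, names = _as_matrix(X)
        n_rows = values.shape[0]
        if n_rows < 10:
            raise ValueError(f"need ≥ 10 rows to bootstrap, have {n_rows}")
        size = cfg.draw_size(n_rows)
        rng = np.random.default_rng(cfg.seed)
        builder = TraitNetworkBuilder(
            alpha=self.alpha, scale_scores=self.scale_scores
        )
        n_traits = len(names)
        overall = np.full((cfg.n_replicates, len(OVERALL_PARAMS)), np.nan)
        node = {
            p: np.full((cfg.n_replicates, n_traits), np.nan) for p in NODE_PARAMS
        }
        valid = np.zeros(cfg.n_replicates, dtype=bool)
        for b in range(cfg.n_replicates):
            idx = rng.choice(n_rows, size=size, replace=cfg.with_replacement)
            try:
                net = builder.fit_network(values[idx])
            except ValueError:
                continue  # unusable resample (e.g. constant trait) → degenerate
            if net.n_edges < cfg.min_edges:
                continue
            summ = summarize(
                net, self.length_mode, betweenness_mode=self.betweenness_mode
            )
            overall[b] = [
                summ.edge_density, summ.diameter, summ.average_path_length
            ]
            node["degree"][b] = summ.degree
            node["closeness"][b] = summ.closeness
            node["betweenness"][b] = summ.betweenness
            valid[b] = True
        if not valid.any():
            raise ValueError("all bootstrap replicates were degenerate")
        self.distribution_ = BootstrapDistribution(
            overall=pd.DataFrame(overall, columns=list(OVERALL_PARAMS)),
            node={p: pd.DataFrame(m, columns=names) for p, m in node.items()},
            valid=valid,
            trait_names=names,
            config=cfg,
            alpha=self.alpha,
            length_mode=self.length_mode,
        )
        return self


def bootstrap_networks(
    X, cfg: BootstrapConfig | None = None, alpha: float = 0.05, **kwargs
) -> BootstrapDistribution:
    """Resample rows, rebuild a network per replicate, collect parameters."""
    cfg = cfg or BootstrapConfig()
    est = NetworkBootstrap(
        n_replicates=cfg.n_replicates,
        sample_fraction=cfg.sample_fraction,
        with_replacement=cfg.with_replacement,
        seed=cfg.seed,
        min_edges=cfg.min_edges,
        alpha=alpha,
        **kwargs,
    )
    return est.fit(X).distribution_


def summarize_bootstrap(bd: BootstrapDistribution) -> pd.DataFrame:
    """Mean and SE per parameter (SE = bootstrap standard deviation).

    Returns a tidy frame with columns parameter, trait (empty for the
    overall parameters), mean, se, n.
    """
    if bd.n_valid < 2:
        raise ValueError("need ≥ 2 valid replicates to summarise")
    rows = []
    for p in OVERALL_PARAMS:
        v = bd.values(p)
        rows.append(
            {"parameter": p, "trait": "", "mean": v.mean(),
             "se": v.std(ddof=1), "n": len(v)}
        )
    for p in NODE_PARAMS:
        for t in bd.trait_names:
            v = bd.values(p, t)
            rows.append(
                {"parameter": p, "trait": t, "mean": v.mean(),
                 "se": v.std(ddof=1), "n": len(v)}
            )
    return pd.DataFrame(rows)


def compare_networks(
    a: BootstrapDistribution, b: BootstrapDistribution, parameter: str
) -> GroupComparison:
    """Welch t-test on the replicate values of one overall parameter.

    The test is run on bootstrap pseudo-replicates, mirroring the
    uncertainty layer it accompanies; with many replicates it is very
    powerful, so p-values should be read alongside the effect size.
    """
    if parameter not in OVERALL_PARAMS:
        raise ValueError(
            f"parameter must be one of {OVERALL_PARAMS}, got {parameter!r}"
        )
    va, vb = a.values(parameter), b.values(parameter)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need ≥ 2 valid replicates per group")
    res = stats.ttest_ind(va, vb, equal_var=False)
    return GroupComparison(
        parameter=parameter,
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
        se_a=float(va.std(ddof=1)),
        se_b=float(vb.std(ddof=1)),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def anova_node_parameter(bd: BootstrapDistribution, parameter: str):
    """One-way ANOVA of a node parameter's replicate values across traits.

    Returns ``(F, df_between, df_within, p, per-trait means)``; degenerate
    variance (all values identical) is signalled as a ValueError.
    """
    frame = bd.node_matrix(parameter)
    if len(frame) < 2:
        raise ValueError("need ≥ 2 valid replicates")
    groups = [frame[t].dropna().to_numpy() for t in bd.trait_names]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate variance: all replicate values identical")
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    means = pd.Series(
        {t: g.mean() for t, g in zip(bd.trait_names, groups)}, name=parameter
    ).sort_values(ascending=False)
    return float(F), k - 1, n - k, float(p), means


def paired_mean_difference(
    a: BootstrapDistribution,
    b: BootstrapDistribution,
    parameter: str,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> GroupComparison:
    """Paired mean difference of a node parameter between two networks.

    Per trait, the difference of replicate-mean values (a − b); the paired
    mean difference is the mean of these per-trait differences.  The
    percentile bootstrap CI resamples replicates (with replacement,
    independently in each group) ``n_boot`` times and recomputes the
    statistic.  Both distributions must cover the same trait set.
    """
    if parameter not in NODE_PARAMS:
        raise ValueError(f"parameter must be one of {NODE_PARAMS}")
    if list(a.trait_names) != list(b.trait_names):
        raise ValueError("trait sets differ between the two distributions")
    ma = a.node_matrix(parameter).to_numpy()
    mb = b.node_matrix(parameter).to_numpy()
    per_trait = np.nanmean(ma, axis=0) - np.nanmean(mb, axis=0)
    pmd = float(per_trait.mean())
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, ma.shape[0], ma.shape[0])
        ib = rng.integers(0, mb.shape[0], mb.shape[0])
        boot[i] = (np.nanmean(ma[ia], axis=0) - np.nanmean(mb[ib], axis=0)).mean()
    lo, hi = np.quantile(boot, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    va = np.nanmean(ma, axis=1)
    vb = np.nanmean(mb, axis=1)
    return GroupComparison(
        parameter=parameter,
        mean_a=float(np.nanmean(ma)),
        mean_b=float(np.nanmean(mb)),
        se_a=float(np.nanstd(va, ddof=1)),
        se_b=float(np.nanstd(vb, ddof=1)),
        paired_mean_difference=pmd,
        ci_low=float(lo),
        ci_high=float(hi),
        per_trait_difference={
            t: float(d) for t, d in zip(a.trait_names, per_trait)
        },
    )
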