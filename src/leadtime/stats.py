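"""Temporal cluster statistics with permutation reference and FDR control,
plus condition comparisons and behavioral tests.

Clusters are maximal runs of consecutive timebins whose |t| exceeds the
two-tailed critical value at the cluster-forming alpha; the cluster mass is
the signed sum of t within the run.  Observed masses are ranked (on |mass|)
against a reference distribution pooled from all clusters of all permutation
traces, and Benjamini-Hochberg FDR at q marks discoveries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .spectral import _pooled_t

__all__ = [
    "ClusterConfig",
    "Cluster",
    "ClusterResult",
    "find_clusters",
    "cluster_pvalues",
    "bh_fdr",
    "compare_traces_cluster",
    "compare_lead_counts",
    "chi2_vs_chance",
    "pooled_two_sample_t",
]


@dataclass(frozen=True)
class ClusterConfig:
    alpha: float = 0.05  # cluster-forming, two-tailed on t
    q_fdr: float = 0.10
    n_trace_shuffles: int = 500  # condition-comparison permutations
    n_subsamples: int = 10
    subsample_fraction: float = 0.5
    reference: str = "pooled"  # "pooled" (all clusters of all shuffles) or "max"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.q_fdr < 1:
            raise ValueError("alpha and q_fdr must lie in (0, 1)")
        if self.reference not in ("pooled", "max"):
            raise ValueError("reference must be 'pooled' or 'max'")


@dataclass
class Cluster:
    start: int  # first timebin index (inclusive)
    stop: int  # last timebin index (inclusive)
    mass: float  # signed sum of t within the run
    p: float = np.nan
    passes_fdr: bool = False


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    n_reference: int = 0
    reference_abs_quantiles: dict = field(default_factory=dict)


def find_clusters(trace: np.ndarray, df: int, config: ClusterConfig = ClusterConfig()) -> list[Cluster]:
    """Maximal supra-threshold runs of |t| with their signed masses."""
    if df < 1:
        raise ValueError("df must be at least 1")
    trace = np.asarray(trace, dtype=np.float64)
    t_crit = _st.t.ppf(1.0 - config.alpha / 2.0, df)
    above = np.abs(trace) > t_crit
    clusters: list[Cluster] = []
    i = 0
    n = len(trace)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            clusters.append(Cluster(start=i, stop=j, mass=float(trace[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return clusters


def _reference_masses(perm_traces: np.ndarray, df: int, config: ClusterConfig) -> np.ndarray:
    masses = []
    for trace in perm_traces:
        cl = [abs(c.mass) for c in find_clusters(trace, df, config)]
        if config.reference == "pooled":
            masses.extend(cl)
        else:
            masses.append(max(cl) if cl else 0.0)
    return np.asarray(masses, dtype=np.float64)


def cluster_pvalues(
    observed: list[Cluster],
    perm_traces: np.ndarray,
    df: int,
    config: ClusterConfig = ClusterConfig(),
) -> ClusterResult:
    """Rank-test p per observed cluster against the permutation reference.

    p = (1 + #{reference |mass| >= observed |mass|}) / (N_ref + 1); ties count
    against the observed cluster.  BH-FDR at ``config.q_fdr`` across this
    trace's clusters sets ``passes_fdr`` (pipeline-level FDR across leads is
    applied by the caller on the pooled p-values).
    """
    perm_traces = np.atleast_2d(np.asarray(perm_traces, dtype=np.float64))
    if perm_traces.shape[0] < 1:
        raise ValueError("need at least one permutation trace")
    reference = _reference_masses(perm_traces, df, config)
    n_ref = len(reference)
    result = ClusterResult(clusters=[Cluster(c.start, c.stop, c.mass) for c in observed])
    result.n_reference = n_ref
    if n_ref == 0:
        warnings.warn("empty cluster reference distribution; p set to 1", stacklevel=2)
        for c in result.clusters:
            c.p = 1.0
        return result
    result.reference_abs_quantiles = {
        q: float(np.quantile(reference, q)) for q in (0.5, 0.9, 0.95, 0.99)
    }
    for c in result.clusters:
        c.p = (1.0 + np.sum(reference >= abs(c.mass))) / (n_ref + 1.0)
    flags = bh_fdr([c.p for c in result.clusters], config.q_fdr)
    for c, flag in zip(result.clusters, flags):
        c.passes_fdr = bool(flag)
    return result


def bh_fdr(pvalues, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean discovery flags."""
    p = np.asarray(pvalues, dtype=np.float64)
    n = len(p)
    if n == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= q * (np.arange(1, n + 1) / n)
    flags = np.zeros(n, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        flags[order[: k + 1]] = True
    return flags


def compare_traces_cluster(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    config: ClusterConfig = ClusterConfig(),
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster-based comparison of two sets of per-lead traces.

    ``traces_a``/``traces_b`` are leads x timebins on a common grid.  A
    pointwise pooled two-sample t forms clusters; the null reshuffles
    condition membership ``config.n_trace_shuffles`` times; rank-test p per
    cluster with BH-FDR at q.
    """
    traces_a = np.atleast_2d(np.asarray(traces_a, dtype=np.float64))
    traces_b = np.atleast_2d(np.asarray(traces_b, dtype=np.float64))
    if traces_a.shape[1] != traces_b.shape[1]:
        raise ValueError("trace sets are on different time grids")
    na, nb = traces_a.shape[0], traces_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 traces per condition")
    if rng is None:
        rng = np.random.default_rng(0)
    df = na + nb - 2

    t_obs, _ = _pooled_t(traces_a, traces_b, axis=0)
    observed = find_clusters(t_obs, df, config)

    pooled = np.concatenate([traces_a, traces_b], axis=0)
    perm_traces = np.empty((config.n_trace_shuffles, traces_a.shape[1]))
    for k in range(config.n_trace_shuffles):
        idx = rng.permutation(na + nb)
        t_k, _ = _pooled_t(pooled[idx[:na]], pooled[idx[na:]], axis=0)
        perm_traces[k] = t_k
    return cluster_pvalues(observed, perm_traces, df, config)


def compare_lead_counts(
    count_a: dict[str, int],
    count_b: dict[str, int],
    subsample_counts: dict[str, np.ndarray],
    config: ClusterConfig = ClusterConfig(),
) -> dict[str, dict]:
    """Per-region rank test of a lead-count difference against subsample pairs.

    The reference per region is the |difference| over all C(n_subsamples, 2)
    pairs of subsampled lead counts (45 pairs for 10 subsamples);
    p = (1 + #{reference >= observed}) / (N_pairs + 1), one-tailed, ties
    counted as >=.  BH-FDR at q across regions adds a ``passes_fdr`` flag.
    """
    regions = sorted(set(count_a) & set(count_b) & set(subsample_counts))
    out: dict[str, dict] = {}
    pvals = []
    for region in regions:
        sub = np.asarray(subsample_counts[region], dtype=np.float64)
        if len(sub) < 2:
            raise ValueError(f"region {region!r}: need at least 2 subsample counts")
        i, j = np.triu_indices(len(sub), k=1)
        ref = np.abs(sub[i] - sub[j])
        obs = abs(count_a[region] - count_b[region])
        p = (1.0 + np.sum(ref >= obs)) / (len(ref) + 1.0)
        out[region] = {"observed_diff": obs, "n_pairs": len(ref), "p": p}
        pvals.append(p)
    flags = bh_fdr(pvals, config.q_fdr)
    for region, flag in zip(regions, flags):
        out[region]["passes_fdr"] = bool(flag)
    return out


def chi2_vs_chance(n_correct: int, n_total: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of a correct count against the 50% chance level.

    1 df, no continuity correction.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    expected = n_total / 2.0
    chi2 = (n_correct - expected) ** 2 / expected + ((n_total - n_correct) - expected) ** 2 / expected
    return float(chi2), float(_st.chi2.sf(chi2, df=1))


def pooled_two_sample_t(group_a, group_b) -> tuple[float, int]:
    """Pooled-variance two-sample t; df = n_a + n_b - 2.

    Zero pooled variance yields a capped t (+-1e6) with a warning.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 == 0:
        warnings.warn("zero pooled variance; t capped at +-1e6", stacklevel=2)
    t, df = _pooled_t(a, b, axis=0)
    return float(t), int(df)
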