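"""Pairwise area onset differences, leave-one-lead-out bootstraps, iterative
timeline reconstruction, and cross-method rank consensus.

Two routes build an area x area onset-difference matrix: pooling all trial
onsets per area and differencing the means ("average of onsets", complete
matrix, unit weights), or differencing lead pairs trial by trial within
subjects ("trial by trial", possibly incomplete, weighted by the SD of the
difference distribution).  A simplified one-dimensional MDS with
multiplicative-exponential updates embeds a matrix on a timeline; rank orders
across methods and bootstraps are pooled into a clustering score C tested
against label-shuffled null datasets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffMatrix",
    "Timeline",
    "RankConjunction",
    "diff_matrix_average_of_onsets",
    "diff_matrix_trial_by_trial",
    "bootstrap_leave_one_lead",
    "mds_reconstruct",
    "rank_conjunction",
]

log = logging.getLogger(__name__)

MIN_LEADS_PER_AREA = 3


@dataclass
class DiffMatrix:
    """Antisymmetric area x area onset differences (seconds); NaN = missing."""

    areas: list[str]
    delta: np.ndarray
    sigma: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        a = len(self.areas)
        if self.delta.shape != (a, a):
            raise ValueError("delta shape must be (areas, areas)")
        if not np.allclose(np.diag(self.delta), 0.0):
            raise ValueError("delta diagonal must be zero")
        present = np.isfinite(self.delta)
        if not np.allclose(
            np.where(present & present.T, self.delta + self.delta.T, 0.0), 0.0, atol=1e-12
        ):
            raise ValueError("delta must be antisymmetric where present")
        if np.any(self.sigma[np.isfinite(self.sigma)] <= 0):
            raise ValueError("sigma must be positive where present")


@dataclass
class Timeline:
    """Reconstructed 1-D coordinates (seconds); reference area pinned to 0."""

    coords: dict[str, float]
    reference: str
    iterations: int
    converged: bool

    def rank_order(self) -> list[str]:
        return sorted(self.coords, key=lambda a: (self.coords[a], a))

    def ranks(self) -> dict[str, int]:
        return {a: r + 1 for r, a in enumerate(self.rank_order())}


@dataclass
class RankConjunction:
    """Pooled ranks per area across methods x bootstraps, with clustering score C."""

    areas: list[str]
    ranks: dict[str, np.ndarray] = field(default_factory=dict)
    mean_rank: dict[str, float] = field(default_factory=dict)
    score: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)

    def consensus_order(self) -> list[str]:
        return sorted(self.areas, key=lambda a: (self.mean_rank[a], a))


def _onsets_2d(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    return arr[:, None] if arr.ndim == 1 else arr


def _included_areas(area_map: dict[str, str], lead_ids, min_leads: int) -> list[str]:
    counts: dict[str, int] = {}
    for lid in lead_ids:
        counts[area_map[lid]] = counts.get(area_map[lid], 0) + 1
    included = sorted(a for a, c in counts.items() if c >= min_leads)
    excluded = sorted(a for a, c in counts.items() if c < min_leads)
    if excluded:
        log.info("areas excluded (<%d leads): %s", min_leads, excluded)
    return included


def diff_matrix_average_of_onsets(
    onsets: dict[str, np.ndarray],
    area_map: dict[str, str],
    min_leads: int = MIN_LEADS_PER_AREA,
) -> DiffMatrix:
    """Complete difference matrix from pooled per-area onset means.

    ``onsets`` maps lead id to trial onsets (trials,) or (trials, scales);
    NaN entries are undetected trials.  Per area, all onsets of all its leads
    are pooled and averaged (per scale, then differences averaged across
    scales); sigma is 1 everywhere.  Areas with fewer than ``min_leads``
    leads are excluded (logged).
    """
    areas = _included_areas(area_map, onsets.keys(), min_leads)
    if not areas:
        raise ValueError("no area reaches the minimum lead count")
    n_scales = _onsets_2d(next(iter(onsets.values()))).shape[1]
    # per-area per-scale pooled means
    means = np.full((len(areas), n_scales), np.nan)
    counts = np.zeros(len(areas))
    for ai, area in enumerate(areas):
        pooled = [
            _onsets_2d(v) for lid, v in onsets.items() if area_map[lid] == area
        ]
        stack = np.concatenate(pooled, axis=0)  # (all trials of area, scales)
        with np.errstate(invalid="ignore"):
            means[ai] = np.nanmean(stack, axis=0)
        counts[ai] = np.isfinite(stack).sum()
    # pairwise differences per scale, then averaged across scales
    diff = means[:, None, :] - means[None, :, :]
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(diff, axis=2)
    np.fill_diagonal(delta, 0.0)
    sigma = np.ones_like(delta)
    return DiffMatrix(areas=areas, delta=delta, sigma=sigma,
                      counts=np.minimum.outer(counts, counts))


def diff_matrix_trial_by_trial(
    onsets: dict[str, np.ndarray],
    area_map: dict[str, str],
    subject_map: dict[str, str] | None = None,
    min_leads: int = MIN_LEADS_PER_AREA,
) -> DiffMatrix:
    """Difference matrix from per-trial lead-pair onset differences.

    Lead pairs are compared only within the same subject (simultaneous
    trials); a trial (and scale) contributes only when both onsets were
    detected.  Differences are averaged within subject per area pair, then
    across subjects; sigma is the SD of the pooled difference distribution.
    Entries with no co-recorded pair stay NaN.
    """
    if subject_map is None:
        subject_map = {lid: "S01" for lid in onsets}
    areas = _included_areas(area_map, onsets.keys(), min_leads)
    if not areas:
        raise ValueError("no area reaches the minimum lead count")
    a_idx = {a: i for i, a in enumerate(areas)}
    n = len(areas)
    # diffs[subject][(ai, aj)] -> list of per-trial differences
    per_subject: dict[str, dict[tuple[int, int], list[float]]] = {}
    pooled: dict[tuple[int, int], list[float]] = {}
    counts = np.zeros((n, n))
    for lid_i, lid_j in itertools.combinations(sorted(onsets), 2):
        if subject_map[lid_i] != subject_map[lid_j]:
            continue
        ai = a_idx.get(area_map[lid_i])
        aj = a_idx.get(area_map[lid_j])
        if ai is None or aj is None or ai == aj:
            continue
        oi = _onsets_2d(onsets[lid_i])
        oj = _onsets_2d(onsets[lid_j])
        both = np.isfinite(oi) & np.isfinite(oj)
        if not both.any():
            continue
        d = (oi - oj)[both]
        subj = subject_map[lid_i]
        per_subject.setdefault(subj, {}).setdefault((ai, aj), []).extend(d.tolist())
        pooled.setdefault((ai, aj), []).extend(d.tolist())
        counts[ai, aj] += both.sum()
        counts[aj, ai] += both.sum()

    delta = np.full((n, n), np.nan)
    sigma = np.full((n, n), np.nan)
    np.fill_diagonal(delta, 0.0)
    pairs = {key for subj_d in per_subject.values() for key in subj_d}
    for ai, aj in pairs:
        subj_means = [
            float(np.mean(subj_d[(ai, aj)]))
            for subj_d in per_subject.values()
            if (ai, aj) in subj_d
        ]
        val = float(np.mean(subj_means))
        delta[ai, aj] = val
        delta[aj, ai] = -val
        all_d = np.asarray(pooled[(ai, aj)])
        sd = float(np.std(all_d, ddof=1)) if len(all_d) > 1 else 1.0
        sigma[ai, aj] = sigma[aj, ai] = max(sd, 1e-6)
    return DiffMatrix(areas=areas, delta=delta, sigma=sigma, counts=counts)


def bootstrap_leave_one_lead(
    onsets: dict[str, np.ndarray],
    area_map: dict[str, str],
    method: str = "average",
    subject_map: dict[str, str] | None = None,
    min_leads: int = MIN_LEADS_PER_AREA,
) -> list[DiffMatrix]:
    """One difference matrix per left-out lead (N_leads bootstraps total).

    Areas dropping below the lead threshold in a bootstrap are excluded from
    that bootstrap's matrix (logged by the matrix builders).
    """
    if len(onsets) < 2:
        raise ValueError("need at least 2 leads to bootstrap")
    builders = {
        "average": lambda o: diff_matrix_average_of_onsets(o, area_map, min_leads),
        "trialwise": lambda o: diff_matrix_trial_by_trial(o, area_map, subject_map, min_leads),
    }
    if method not in builders:
        raise ValueError(f"unknown method {method!r}")
    out = []
    for left_out in sorted(onsets):
        subset = {lid: v for lid, v in onsets.items() if lid != left_out}
        try:
            out.append(builders[method](subset))
        except ValueError as exc:  # no area left above threshold
            log.info("bootstrap without %s skipped: %s", left_out, exc)
    return out


def _connected_components(present: np.ndarray) -> list[list[int]]:
    n = present.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(present[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def _rank_vector(labels: list[str], coords: np.ndarray) -> tuple[int, ...]:
    order = sorted(range(len(labels)), key=lambda i: (coords[i], labels[i]))
    ranks = [0] * len(labels)
    for r, i in enumerate(order):
        ranks[i] = r
    return tuple(ranks)


def mds_reconstruct(
    matrix: DiffMatrix,
    reference: str | None = None,
    beta: float = 0.9,
    init_range: float = 0.1,
    max_iter: int = 1000,
    stable_iters: int = 5,
    seed: int | np.random.Generator = 0,
) -> Timeline:
    """Embed a difference matrix on a 1-D timeline by iterative updates.

    Starting from uniform-random positions in [-init_range, +init_range], each
    sweep visits areas in fixed alphabetical order and moves area i by the
    mean of beta * sgn(D) * (exp(|D/sigma|) - 1) over partners j with a
    present entry, where D = (T_i - T_j) - delta_ij.  Stops once the rank
    order is unchanged for ``stable_iters`` consecutive sweeps (or at
    ``max_iter``).  Coordinates are translated so the reference area (default
    'BA4' when present, else the alphabetically first area) sits at 0.
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    areas = matrix.areas
    n = len(areas)
    if n < 2:
        if n == 1:
            return Timeline(coords={areas[0]: 0.0}, reference=areas[0], iterations=0, converged=True)
        raise ValueError("matrix must have at least 2 areas")
    present = np.isfinite(matrix.delta) & ~np.eye(n, dtype=bool)
    comps = _connected_components(present | present.T)
    if len(comps) > 1:
        names = [[areas[i] for i in c] for c in comps]
        raise ValueError(f"difference matrix is disconnected: components {names}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = sorted(range(n), key=lambda i: areas[i])
    T = rng.uniform(-init_range, init_range, size=n)
    sigma = np.where(np.isfinite(matrix.sigma), matrix.sigma, 1.0)

    prev_ranks = _rank_vector(areas, T)
    streak = 0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in order:
            js = np.flatnonzero(present[i])
            D = (T[i] - T[js]) - matrix.delta[i, js]
            arg = np.minimum(np.abs(D / sigma[i, js]), 50.0)  # overflow guard
            # cap the per-partner step at |D| so small sigma weights cannot
            # overshoot the consistent position (stability safeguard; the
            # fixed point is unchanged)
            dt = beta * np.sign(D) * np.minimum(np.expm1(arg), np.abs(D))
            T[i] -= dt.mean()
        ranks = _rank_vector(areas, T)
        if ranks == prev_ranks:
            streak += 1
            if streak >= stable_iters:
                break
        else:
            streak = 0
        prev_ranks = ranks
    converged = streak >= stable_iters

    if reference is None:
        reference = "BA4" if "BA4" in areas else areas[0]
    if reference not in areas:
        raise ValueError(f"reference area {reference!r} not in matrix")
    T = T - T[areas.index(reference)]
    return Timeline(
        coords={a: float(T[i]) for i, a in enumerate(areas)},
        reference=reference, iterations=iterations, converged=converged,
    )


def rank_conjunction(
    timelines: dict[str, list[Timeline]],
    n_null: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> RankConjunction:
    """Pool rank orders across methods and bootstraps; test rank clustering.

    ``timelines`` maps method name to its list of bootstrap timelines.  Per
    area, all ranks are pooled; the clustering score C is the mean absolute
    pairwise rank distance among that area's points.  The null shuffles the
    area labels within every timeline (preserving per-method/bootstrap
    structure) ``n_null`` times; one-sided p favors small C.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    all_tl = [tl for tls in timelines.values() for tl in tls]
    if not all_tl:
        raise ValueError("no timelines given")
    area_sets = [frozenset(tl.coords) for tl in all_tl]
    areas = sorted(set.union(*(set(s) for s in area_sets)))
    dropped = [a for a in areas if any(a not in s for s in area_sets)]
    if dropped:
        log.info("areas missing from some bootstraps (dropped pairwise): %s", dropped)

    rank_lists: list[dict[str, int]] = [tl.ranks() for tl in all_tl]
    pooled: dict[str, list[int]] = {a: [] for a in areas}
    for rl in rank_lists:
        for a, r in rl.items():
            pooled[a].append(r)
    for a in areas:
        if len(pooled[a]) < 2:
            raise ValueError(f"area {a!r} has fewer than 2 pooled rank points")

    def _score(points: np.ndarray) -> float:
        i, j = np.triu_indices(len(points), k=1)
        return float(np.mean(np.abs(points[i] - points[j])))

    out = RankConjunction(areas=areas)
    for a in areas:
        pts = np.asarray(pooled[a], dtype=np.float64)
        out.ranks[a] = pts
        out.mean_rank[a] = float(pts.mean())
        out.score[a] = _score(pts)

    null_scores = {a: np.empty(n_null) for a in areas}
    for k in range(n_null):
        shuffled: dict[str, list[int]] = {a: [] for a in areas}
        for rl in rank_lists:
            labels = list(rl)
            perm = rng.permutation(len(labels))
            for pos, a in enumerate(labels):
                shuffled[a].append(rl[labels[perm[pos]]])
        for a in areas:
            null_scores[a][k] = _score(np.asarray(shuffled[a], dtype=np.float64))
    for a in areas:
        out.p[a] = (1.0 + np.sum(null_scores[a] <= out.score[a])) / (n_null + 1.0)
        out.significant[a] = out.p[a] <= alpha
    return out
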