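"""Per-lead, per-timepoint linear decoding.

A shrinkage-regularized LDA classifier is trained independently at every
analysis time bin on the wavelet-power features of one lead.  Out-of-fold
decision values from repeated stratified k-fold cross-validation are combined
into a pooled two-sample t-statistic (df = N_trials - 2); balanced
label-shuffle permutations provide a lead-specific chance reference.  A
baseline (activity-vs-surrogate) classifier and leave-one-out single-trial
decision-value traces reuse the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import _pooled_t

__all__ = [
    "DecodeConfig",
    "ClassifierTrace",
    "DValueTraces",
    "fit_lda_shrinkage",
    "kfold_classifier_trace",
    "shuffle_labels_balanced",
    "baseline_classifier_trace",
    "loo_dvalue_traces",
]


@dataclass(frozen=True)
class DecodeConfig:
    n_folds: int = 5
    n_repeats: int = 10
    n_permutations: int = 100
    balance_min: float = 0.30
    max_shuffle_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not 0 <= self.balance_min <= 0.5:
            raise ValueError("balance_min must lie in [0, 0.5]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be nonnegative")


@dataclass
class ClassifierTrace:
    """Decoding t-statistic per timebin plus label-shuffled reference traces."""

    t_values: np.ndarray  # (timebin,)
    perm_t_values: np.ndarray  # (permutation, timebin)
    n_trials: int
    df: int
    lead_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.t_values)):
            raise ValueError("non-finite t-values in classifier trace")


@dataclass
class DValueTraces:
    """Leave-one-out decision values, trial x timebin, for one lead.

    Positive values fall on the positive-class (left) side of the hyperplane.
    """

    d: np.ndarray
    labels: np.ndarray
    positive_class: str
    lead_id: str = ""

    def class_aligned(self) -> np.ndarray:
        """D-values flipped so each trial's own class points positive.

        Decodable periods then show upward deflections for every trial, which
        is the convention the single-trial onset detector expects.
        """
        sign = np.where(self.labels == self.positive_class, 1.0, -1.0)
        return self.d * sign[:, None]


# --- shrinkage LDA ----------------------------------------------------------

def _lda_fit_batch(X: np.ndarray, mask_a: np.ndarray, shrinkage="auto"):
    """Fit LDA at every timebin at once.

    ``X`` is (trials, timebins, features); ``mask_a`` marks the positive
    class.  The pooled within-class covariance is shrunk toward a scaled
    identity with an analytic (Ledoit-Wolf) coefficient, so singular
    covariances never fail.  Returns weights (timebins, features) and biases
    (timebins,); the bias puts the boundary midway between projected means.
    """
    n, n_bins, p = X.shape
    na = int(mask_a.sum())
    nb = n - na
    if na == 0 or nb == 0:
        raise ValueError("both classes must be non-empty")
    mu_a = X[mask_a].mean(axis=0)  # (B, p)
    mu_b = X[~mask_a].mean(axis=0)
    Xc = np.where(mask_a[:, None, None], X - mu_a, X - mu_b)
    S = np.einsum("nbp,nbq->bpq", Xc, Xc) / n  # (B, p, p)

    m = np.trace(S, axis1=1, axis2=2) / p  # (B,)
    if shrinkage == "auto":
        d2 = (np.sum(S**2, axis=(1, 2)) - p * m**2) / p
        norms4 = np.sum(np.sum(Xc**2, axis=2) ** 2, axis=0)  # sum_k ||x_k||^4 per bin
        b_bar2 = (norms4 - n * np.sum(S**2, axis=(1, 2))) / (n**2 * p)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(d2 > 0, np.minimum(b_bar2, d2) / d2, 0.0)
        rho = np.clip(rho, 0.0, 1.0)
    else:
        rho = np.full(n_bins, float(shrinkage))
    eye = np.eye(p)
    target = np.where(m > 0, m, 1.0)  # all-zero bins fall back to identity
    sigma = (1.0 - rho)[:, None, None] * S + (rho * target)[:, None, None] * eye

    delta = (mu_a - mu_b)[..., None]  # (B, p, 1) stacked vectors
    try:
        w = np.linalg.solve(sigma, delta)[..., 0]
    except np.linalg.LinAlgError:
        w = np.linalg.solve(sigma + 1e-10 * target[:, None, None] * eye, delta)[..., 0]
    bias = -0.5 * np.einsum("bp,bp->b", w, mu_a + mu_b)
    return w, bias


def fit_lda_shrinkage(features: np.ndarray, labels: np.ndarray, shrinkage="auto",
                      positive_class=None):
    """Fit one shrinkage-LDA: returns ``(weights, bias)``.

    The discriminant direction is (regularized pooled covariance)^-1 applied
    to the difference of class means; decision value d(x) = w.x + bias is
    positive on the positive-class side.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError("features must be trials x features")
    mask_a = _positive_mask(np.asarray(labels), positive_class)[0]
    w, b = _lda_fit_batch(features[:, None, :], mask_a, shrinkage=shrinkage)
    return w[0], float(b[0])


def _positive_mask(labels: np.ndarray, positive_class=None):
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if positive_class is None:
        positive_class = "left" if "left" in classes else classes[0]
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among {list(classes)}")
    return labels == positive_class, positive_class


def _stratified_folds(mask_a: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Fold index per trial, stratified by class."""
    n = len(mask_a)
    folds = np.empty(n, dtype=int)
    for cls_mask in (mask_a, ~mask_a):
        idx = np.flatnonzero(cls_mask)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def _cv_dvalues(X: np.ndarray, mask_a: np.ndarray, config: DecodeConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Out-of-fold decision values averaged over fold repeats; (trials, timebins)."""
    n = X.shape[0]
    if n < config.n_folds:
        raise ValueError(f"fewer trials ({n}) than folds ({config.n_folds})")
    d = np.zeros(X.shape[:2])
    for _ in range(config.n_repeats):
        folds = _stratified_folds(mask_a, config.n_folds, rng)
        for k in range(config.n_folds):
            test = folds == k
            if not test.any():
                continue
            w, b = _lda_fit_batch(X[~test], mask_a[~test])
            d[test] += np.einsum("nbp,bp->nb", X[test], w) + b
    return d / config.n_repeats


def kfold_classifier_trace(
    features: np.ndarray,
    labels: np.ndarray,
    config: DecodeConfig = DecodeConfig(),
    aux_dims: dict[str, np.ndarray] | None = None,
    positive_class=None,
    lead_id: str = "",
    rng: np.random.Generator | None = None,
) -> ClassifierTrace:
    """Cross-validated decoding trace for one lead.

    ``features`` is trial x scale x timebin (a lead slice of TFPower).  At
    every timebin, stratified k-fold cross-validation (re-drawn
    ``config.n_repeats`` times) yields pooled out-of-fold decision values;
    the trace value is the pooled-variance two-sample t between the two
    classes' decision values, df = N - 2.  ``config.n_permutations`` balanced
    label shuffles produce the reference traces.
    """
    X = np.ascontiguousarray(np.moveaxis(np.asarray(features, dtype=np.float64), 2, 1))
    labels = np.asarray(labels)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mask_a, pos = _positive_mask(labels, positive_class)

    def trace_for(mask: np.ndarray) -> np.ndarray:
        d = _cv_dvalues(X, mask, config, rng)
        t, _ = _pooled_t(d[mask], d[~mask], axis=0)
        return t

    t_obs = trace_for(mask_a)
    perms = np.empty((config.n_permutations, X.shape[1]))
    for k in range(config.n_permutations):
        shuffled = shuffle_labels_balanced(labels, aux_dims, config, rng=rng)
        perms[k] = trace_for(shuffled == pos)
    n = len(labels)
    return ClassifierTrace(t_values=t_obs, perm_t_values=perms, n_trials=n,
                           df=n - 2, lead_id=lead_id)


def shuffle_labels_balanced(
    labels: np.ndarray,
    aux_dims: dict[str, np.ndarray] | None = None,
    config: DecodeConfig = DecodeConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform label permutation, resampled until balanced.

    Every shuffled class must contain at least ``config.balance_min`` of each
    level of every auxiliary task dimension (rule / color / orientation /
    congruency).  Dimensions with a single level are vacuous, as are
    dimensions whose own global level fractions fall below ``balance_min``
    (no permutation could balance those; the constraint presupposes a
    near-balanced dimension).  Raises after ``config.max_shuffle_attempts``
    failed draws.
    """
    labels = np.asarray(labels)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dims = {}
    for k, v in (aux_dims or {}).items():
        v = np.asarray(v)
        if len(v) != len(labels):
            raise ValueError(f"aux dimension {k!r} length mismatch")
        _, counts = np.unique(v, return_counts=True)
        if counts.min() / len(v) < config.balance_min:
            continue  # infeasible for any shuffle; treat as vacuous
        dims[k] = v
    classes = np.unique(labels)
    for _ in range(config.max_shuffle_attempts):
        perm = rng.permutation(labels)
        if _is_balanced(perm, classes, dims, config.balance_min):
            return perm
    composition = {k: dict(zip(*np.unique(v, return_counts=True))) for k, v in dims.items()}
    raise RuntimeError(
        f"no balanced shuffle found in {config.max_shuffle_attempts} attempts; "
        f"composition: {composition}"
    )


def _is_balanced(perm, classes, dims, balance_min) -> bool:
    for cls in classes:
        in_cls = perm == cls
        n_cls = in_cls.sum()
        for v in dims.values():
            levels = np.unique(v)
            if len(levels) < 2:
                continue
            for lev in levels:
                if (v[in_cls] == lev).sum() < balance_min * n_cls:
                    return False
    return True


def baseline_classifier_trace(
    features: np.ndarray,
    config: DecodeConfig = DecodeConfig(),
    lead_id: str = "",
    rng: np.random.Generator | None = None,
) -> ClassifierTrace:
    """Activity-vs-baseline decoding trace for one lead.

    A surrogate trial set is built by independently permuting the timebins
    within each trial and scale; the k-fold machinery then classifies intact
    vs surrogate trials (df = 2N - 2).  Label-shuffle references use the same
    balanced-shuffle permutation scheme (no auxiliary dimensions).
    """
    features = np.asarray(features, dtype=np.float64)
    n, n_scales, n_bins = features.shape
    if n < 2:
        raise ValueError("need at least 2 trials")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    surrogate = np.empty_like(features)
    for i in range(n):
        for s in range(n_scales):
            surrogate[i, s] = features[i, s, rng.permutation(n_bins)]
    combined = np.concatenate([features, surrogate], axis=0)
    labels = np.array(["intact"] * n + ["surrogate"] * n)
    return kfold_classifier_trace(combined, labels, config, positive_class="intact",
                                  lead_id=lead_id, rng=rng)


def loo_dvalue_traces(
    features: np.ndarray,
    labels: np.ndarray,
    config: DecodeConfig = DecodeConfig(),
    positive_class=None,
    lead_id: str = "",
) -> DValueTraces:
    """Leave-one-out decision-value trace per trial.

    For each trial and timebin, the signed distance to the hyperplane trained
    on all other trials at that timebin.  The closed-form LDA fit has no
    random initial conditions, so the repeat-and-average step of the original
    procedure collapses to a single deterministic pass.
    """
    X = np.ascontiguousarray(np.moveaxis(np.asarray(features, dtype=np.float64), 2, 1))
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials for leave-one-out")
    mask_a, pos = _positive_mask(labels, positive_class)
    d = np.empty(X.shape[:2])
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        w, b = _lda_fit_batch(X[keep], mask_a[keep])
        d[i] = np.einsum("bp,bp->b", X[i], w) + b
        keep[i] = True
    return DValueTraces(d=d, labels=labels, positive_class=str(pos), lead_id=lead_id)
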