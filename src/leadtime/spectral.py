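"""Morlet wavelet power, baseline z-scoring, contra/ipsi contrast, and
power-classifier correlation.

Spectral power is the magnitude (not squared magnitude) of a complex Morlet
convolution, four cycles wide, evaluated at 50 geometrically spaced
frequencies between 5 and 152 Hz and sampled on a 10-ms grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .prep import EpochSet

__all__ = [
    "SpectralConfig",
    "TFPower",
    "ContrastTrace",
    "wavelet_scales",
    "wavelet_power",
    "zscore_baseline",
    "contra_ipsi_contrast",
    "power_classifier_correlation",
]


@dataclass(frozen=True)
class SpectralConfig:
    f_min: float = 5.0
    f_max: float = 152.0
    n_scales: int = 50
    cycles: float = 4.0
    step: float = 0.010  # seconds between analysis time bins

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be below f_max")
        if self.n_scales < 2:
            raise ValueError("n_scales must be at least 2")
        if self.cycles <= 0:
            raise ValueError("cycles must be positive")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass
class TFPower:
    """Nonnegative spectral power, trial x lead x scale x timebin."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    leads: object = None  # lead metadata table (pd.DataFrame), optional
    trials: list = None  # TaskTrial list, optional

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.power.ndim != 4:
            raise ValueError("power must be trial x lead x scale x timebin")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("scale frequencies must be strictly increasing")
        if self.power.shape[2] != len(self.freqs) or self.power.shape[3] != len(self.times):
            raise ValueError("power shape inconsistent with freqs/times")

    def lead(self, index: int) -> np.ndarray:
        """Features for one lead: trial x scale x timebin view."""
        return self.power[:, index]


@dataclass
class ContrastTrace:
    """Two-sample t between contralateral and ipsilateral trials."""

    t: np.ndarray  # lead x scale x timebin
    freqs: np.ndarray
    times: np.ndarray
    contra_mask: np.ndarray  # lead x trial boolean, the grouping actually used


def wavelet_scales(config: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Geometrically spaced scale frequencies, endpoints inclusive."""
    return np.geomspace(config.f_min, config.f_max, config.n_scales)


def morlet_wavelet(freq: float, fs: float, cycles: float = 4.0) -> np.ndarray:
    """L2-normalized complex Morlet wavelet (Gaussian SD = cycles / (2 pi f))."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return w / np.linalg.norm(w)


def analysis_grid(times: np.ndarray, step: float = 0.010) -> np.ndarray:
    """Indices of the analysis time bins within a sample-resolution axis."""
    t0, t1 = times[0], times[-1]
    grid = np.arange(0, np.floor((t1 - t0) / step + 0.5) + 1) * step + t0
    idx = np.searchsorted(times, grid - 1e-9)
    return idx


def wavelet_power(epochs: EpochSet, config: SpectralConfig = SpectralConfig()) -> TFPower:
    """Morlet power of every trial and lead, sampled on the 10-ms grid.

    Epochs are reflect-padded before convolution so edge bins are usable
    (the cone of influence is not masked; the window is short).
    """
    freqs = wavelet_scales(config)
    if freqs[-1] > epochs.fs / 2:
        raise ValueError(f"scale frequency {freqs[-1]} Hz above Nyquist ({epochs.fs / 2} Hz)")
    data = epochs.data
    n_tr, n_ld, n_sa = data.shape
    idx = analysis_grid(epochs.times, config.step)
    grid_times = epochs.times[idx]

    max_half = int(np.ceil(5.0 * config.cycles / (2.0 * np.pi * freqs[0]) * epochs.fs))
    pad = min(max_half, n_sa - 1)
    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")

    power = np.empty((n_tr, n_ld, len(freqs), len(idx)))
    flat = padded.reshape(n_tr * n_ld, -1)
    for si, f in enumerate(freqs):
        w = morlet_wavelet(f, epochs.fs, config.cycles)
        conv = _sig.fftconvolve(flat, np.conj(w)[None, ::-1], mode="same", axes=-1)
        mag = np.abs(conv[:, pad : pad + n_sa])
        power[:, :, si, :] = mag.reshape(n_tr, n_ld, n_sa)[..., idx]
    return TFPower(power=power, freqs=freqs, times=grid_times,
                   leads=epochs.leads, trials=epochs.trials)


def zscore_baseline(power: TFPower, baseline: "TFPower | tuple[float, float]") -> TFPower:
    """Z-score power against a baseline, per lead and scale.

    ``baseline`` is either a separate :class:`TFPower` (e.g. computed on
    pre-cue epochs) or a ``(t0, t1)`` window on this object's own time grid.
    Mean and SD pool trials and baseline time bins.
    """
    if isinstance(baseline, TFPower):
        base = baseline.power
    else:
        t0, t1 = baseline
        mask = (power.times >= t0 - 1e-9) & (power.times <= t1 + 1e-9)
        if not mask.any():
            raise ValueError(f"baseline window {baseline} not on the time grid")
        base = power.power[..., mask]
    mean = base.mean(axis=(0, 3))
    sd = base.std(axis=(0, 3), ddof=1)
    bad = np.argwhere(sd == 0)
    if len(bad):
        lead, scale = bad[0]
        raise ValueError(f"zero baseline SD at lead {lead}, scale {scale}")
    z = (power.power - mean[None, :, :, None]) / sd[None, :, :, None]
    out = TFPower.__new__(TFPower)  # z-values may be negative; bypass power>=0 check
    out.power = z
    out.freqs = power.freqs.copy()
    out.times = power.times.copy()
    out.leads = power.leads
    out.trials = power.trials
    return out


def _pooled_t(a: np.ndarray, b: np.ndarray, axis: int = 0):
    """Pooled-variance two-sample t along ``axis`` (exactly antisymmetric)."""
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1) if na > 1 else np.zeros_like(ma)
    vb = b.var(axis=axis, ddof=1) if nb > 1 else np.zeros_like(mb)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    t = np.where(denom == 0, np.sign(ma - mb) * 1e6, t)
    return t, na + nb - 2


def contra_ipsi_contrast(power: TFPower, hemispheres: np.ndarray, response_sides: np.ndarray) -> ContrastTrace:
    """Contralateral-vs-ipsilateral pooled t per lead, scale and timebin.

    A trial is contralateral for a lead when the response hand is on the side
    opposite the recorded hemisphere (left press / right hemisphere and vice
    versa).  Requires at least two trials per group for every lead.
    """
    hemispheres = np.asarray(hemispheres)
    response_sides = np.asarray(response_sides)
    n_tr, n_ld = power.power.shape[:2]
    if len(hemispheres) != n_ld or len(response_sides) != n_tr:
        raise ValueError("hemisphere / response-side label lengths do not match power")
    t = np.empty(power.power.shape[1:])
    contra_mask = np.empty((n_ld, n_tr), dtype=bool)
    for li in range(n_ld):
        contra_side = "right" if hemispheres[li] == "left" else "left"
        contra = response_sides == contra_side
        contra_mask[li] = contra
        if contra.sum() < 2 or (~contra).sum() < 2:
            raise ValueError(f"lead {li}: need >=2 trials per contra/ipsi group")
        t[li], _ = _pooled_t(power.power[contra, li], power.power[~contra, li], axis=0)
    return ContrastTrace(t=t, freqs=power.freqs.copy(), times=power.times.copy(),
                         contra_mask=contra_mask)


def power_classifier_correlation(
    contrast: np.ndarray,
    classifier_t: np.ndarray,
    times: np.ndarray,
    window: float = 0.100,
) -> np.ndarray:
    """Sliding-window Pearson correlation between a classifier t-trace and a
    per-scale power-contrast trace.

    ``contrast`` is scale x timebin for one lead; ``classifier_t`` is the
    lead's decoding trace on the same grid.  The window (default 100 ms = 10
    bins on the 10-ms grid) is centered on each grid point and truncated at
    the epoch edges; zero-variance windows yield NaN.
    """
    contrast = np.asarray(contrast, dtype=np.float64)
    classifier_t = np.asarray(classifier_t, dtype=np.float64)
    if contrast.shape[-1] != len(times) or len(classifier_t) != len(times):
        raise ValueError("contrast and classifier traces must share the time grid")
    step = float(np.median(np.diff(times)))
    w = int(round(window / step))
    if w < 3:
        raise ValueError(f"window of {w} samples is shorter than 3 samples")
    half = w // 2
    n_scale, n_time = contrast.shape
    r = np.full((n_scale, n_time), np.nan)
    for c in range(n_time):
        lo = max(0, c - half)
        hi = min(n_time, lo + w)
        lo = max(0, hi - w)
        x = classifier_t[lo:hi]
        y = contrast[:, lo:hi]
        xv = x - x.mean()
        yv = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xv**2).sum() * (yv**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r[:, c] = np.where(denom > 0, yv @ xv / denom, np.nan)
    return r
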