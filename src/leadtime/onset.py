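"""Single-trial onset detection on 10-ms-grid traces.

The detector locates the highest peak of a trace (for power traces: the
largest-|value| peak or trough, subject to a minimum-height threshold of one
lead-level SD), smooths with a 50-ms block average, then scans backward from
the peak for the first point that is below half the peak height while the
derivative stays flat (below a 5-degree slope scaled by peak height) for at
least 3 consecutive bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["OnsetConfig", "OnsetSet", "detect_peak_onset", "onset_distributions"]


@dataclass(frozen=True)
class OnsetConfig:
    smooth_width: int = 5  # timebins (50 ms)
    half_height: float = 0.5
    angle_deg: float = 5.0  # flatness criterion; d_thres = tan(angle)/peak_height
    n_t: int = 3  # persistence, timebins (30 ms)
    p_thres_sd: float = 1.0  # power mode: minimum peak height in lead SDs
    detect_troughs: bool = True  # power mode
    backward_persistence: bool = True  # persistence window extends backward

    def __post_init__(self) -> None:
        if self.n_t < 1:
            raise ValueError("n_t must be at least 1")
        if not 0 < self.angle_deg < 90:
            raise ValueError("angle must lie in (0, 90) degrees")
        if self.smooth_width < 1:
            raise ValueError("smooth_width must be at least 1")


@dataclass
class OnsetSet:
    """Per-trial (and per-scale, power mode) onset times; NaN marks missing."""

    onsets: np.ndarray  # (trials,) or (trials, scales), seconds
    mode: str
    times: np.ndarray

    @property
    def detected_fraction(self) -> float:
        return float(np.mean(np.isfinite(self.onsets)))

    def detected(self) -> np.ndarray:
        return self.onsets[np.isfinite(self.onsets)]


def _block_smooth(trace: np.ndarray, width: int) -> np.ndarray:
    """Moving-average block smoothing with truncated (shrinking) edge windows."""
    n = len(trace)
    half = width // 2
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (width - half - 1), n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detect_peak_onset(
    trace: np.ndarray,
    times: np.ndarray,
    config: OnsetConfig = OnsetConfig(),
    mode: str = "dvalue",
    p_thres: float | None = None,
) -> float:
    """Onset time (seconds) of the highest peak in a single-trial trace.

    Returns NaN when no onset qualifies, or (power mode) when the extremum
    stays below ``p_thres``.  In power mode, peaks and troughs both count
    (when ``config.detect_troughs``); the extremum with the largest |value|
    is analyzed, troughs on the sign-flipped trace.  Half-height and the
    flatness threshold are evaluated on the smoothed trace; ties at the
    extremum resolve to the earliest time.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if mode not in ("dvalue", "power"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(trace) < config.smooth_width + config.n_t:
        raise ValueError(
            f"trace length {len(trace)} below minimum {config.smooth_width + config.n_t}"
        )
    if len(times) != len(trace):
        raise ValueError("times and trace lengths differ")

    if mode == "power":
        peak_idx = int(np.argmax(np.abs(trace)))
        height_raw = trace[peak_idx]
        if p_thres is not None and abs(height_raw) < p_thres:
            return math.nan
        if height_raw < 0:
            if not config.detect_troughs:
                return math.nan
            trace = -trace
    else:
        peak_idx = int(np.argmax(trace))

    smoothed = _block_smooth(trace, config.smooth_width)
    peak_height = smoothed[peak_idx]
    if peak_height <= 0:
        return math.nan
    # flatness: slope of the peak-normalized trace below the angle criterion,
    # i.e. |first difference| < peak_height * tan(angle) per bin.  This is the
    # scale-invariant reading of the "derivative below five degrees" rule
    # (the threshold scales with the peak, as the half-height criterion does).
    d_thres = peak_height * math.tan(math.radians(config.angle_deg))
    deriv = np.diff(smoothed)  # deriv[i] = s[i+1] - s[i], per bin

    half = config.half_height * peak_height
    for i in range(peak_idx - 1, -1, -1):
        if smoothed[i] >= half:
            continue
        if config.backward_persistence:
            window = range(i - config.n_t + 1, i + 1)  # candidate and n_t-1 earlier bins
        else:
            window = range(i, i + config.n_t)
        ok = True
        for j in window:
            if j - 1 < 0 or j - 1 >= len(deriv) or abs(deriv[j - 1]) >= d_thres:
                ok = False
                break
        if ok:
            return float(times[i])
    return math.nan


def onset_distributions(
    traces: np.ndarray,
    times: np.ndarray,
    config: OnsetConfig = OnsetConfig(),
    mode: str = "dvalue",
) -> OnsetSet:
    """Apply the onset detector to every trial of one lead.

    ``traces`` is (trials, timebins) for decision-value traces, or
    (trials, scales, timebins) for power traces.  Power traces are first
    expressed as deflections from the lead mean (per scale, across trials and
    time), and the inclusion threshold is ``config.p_thres_sd`` lead-level
    standard deviations; each frequency is analyzed independently.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if mode == "dvalue":
        if traces.ndim != 2:
            raise ValueError("dvalue mode expects trials x timebins")
        onsets = np.array(
            [detect_peak_onset(tr, times, config, mode="dvalue") for tr in traces]
        )
        return OnsetSet(onsets=onsets, mode=mode, times=np.asarray(times))
    if mode == "power":
        if traces.ndim != 3:
            raise ValueError("power mode expects trials x scales x timebins")
        n_tr, n_sc, _ = traces.shape
        mean = traces.mean(axis=(0, 2), keepdims=True)
        defl = traces - mean
        sd = defl.std(axis=(0, 2))  # per scale
        onsets = np.full((n_tr, n_sc), np.nan)
        for s in range(n_sc):
            thr = config.p_thres_sd * sd[s]
            for i in range(n_tr):
                onsets[i, s] = detect_peak_onset(
                    defl[i, s], times, config, mode="power", p_thres=thr
                )
        return OnsetSet(onsets=onsets, mode=mode, times=np.asarray(times))
    raise ValueError(f"unknown mode {mode!r}")
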