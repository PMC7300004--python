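"""Filtering, response-locked epoching, and serialization.

Signals are band-pass filtered (sixth-order Butterworth, 1.5-300 Hz) with
narrow notches at the line frequency and its harmonics, then cut into epochs
spanning 0.5 s before to 0.15 s after the button press.  Epoch containers are
single HDF5 files (arrays plus JSON-encoded metadata); trial tables and
result tables travel as TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .synth import TaskTrial, frame_to_trials, trials_to_frame

__all__ = [
    "EpochSet",
    "FilterSpec",
    "bandpass_notch",
    "epoch_response_locked",
    "save_epochs",
    "load_epochs",
    "save_table",
    "load_table",
    "make_lead_table",
]

_LEAD_COLUMNS = ["lead_id", "subject", "hemisphere", "area", "in_ez"]


def make_lead_table(
    lead_ids: list[str],
    subject: str | list[str],
    hemisphere: str | list[str],
    areas: list[str],
    in_ez: list[bool] | None = None,
) -> pd.DataFrame:
    n = len(lead_ids)
    if isinstance(subject, str):
        subject = [subject] * n
    if isinstance(hemisphere, str):
        hemisphere = [hemisphere] * n
    if in_ez is None:
        in_ez = [False] * n
    return pd.DataFrame(
        {"lead_id": lead_ids, "subject": subject, "hemisphere": hemisphere,
         "area": areas, "in_ez": in_ez}
    )


@dataclass
class EpochSet:
    """Response-locked trials x leads x samples with per-trial task labels.

    The time axis is seconds relative to the button press; by convention the
    analysis window is [-0.5, +0.15] s sampled at ``fs``, inclusive endpoints
    (651 samples at 1 kHz).  Only correct, non-timed-out trials are held.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    leads: pd.DataFrame
    trials: list[TaskTrial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trial x lead x sample")
        n_tr, n_ld, n_sa = self.data.shape
        if len(self.times) != n_sa:
            raise ValueError("time axis length does not match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not (self.times[0] - 1e-9 <= 0.0 <= self.times[-1] + 1e-9):
            raise ValueError("time axis must contain the response (t=0)")
        missing = [c for c in _LEAD_COLUMNS if c not in self.leads.columns]
        if missing:
            raise ValueError(f"lead table missing columns: {missing}")
        if len(self.leads) != n_ld:
            raise ValueError("lead table length does not match data")
        if self.trials and len(self.trials) != n_tr:
            raise ValueError("trial list length does not match data")
        for t in self.trials:
            if not t.correct or t.timed_out:
                raise ValueError("EpochSet may hold only correct, non-timed-out trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_leads(self) -> int:
        return self.data.shape[1]

    def response_sides(self) -> np.ndarray:
        return np.array([t.response_side for t in self.trials])

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(), fs=self.fs, times=self.times.copy(),
            leads=self.leads.copy(), trials=list(self.trials),
        )


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass plus line-noise notch settings.

    ``order`` is the effective Butterworth band-pass order (must be even;
    applied forward-backward, so zero phase).  ``notch_half_width`` is the
    -3 dB half-width of each notch in Hz.
    """

    band: tuple[float, float] = (1.5, 300.0)
    order: int = 6
    notch_base: float = 50.0
    notch_max: float = 300.0
    notch_half_width: float = 0.02

    def __post_init__(self) -> None:
        if self.band[0] <= 0 or self.band[1] <= self.band[0]:
            raise ValueError(f"invalid band {self.band}")
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be even and positive")
        if self.notch_half_width <= 0:
            raise ValueError("notch half-width must be positive")


def bandpass_notch(data: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase band-pass plus notch filtering along the last axis.

    The band-pass is a Butterworth of order ``spec.order`` (digital order
    ``order/2`` per pass direction times two passes of a band-pass section),
    applied with ``sosfiltfilt``; each notch is a second-order IIR notch at
    ``notch_base`` and its harmonics up to ``notch_max``.  Input is never
    mutated.
    """
    if fs <= 2 * spec.band[1]:
        raise ValueError(f"fs={fs} too low for band {spec.band} (need fs > 2*band_high)")
    data = np.asarray(data, dtype=np.float64)
    sos = _sig.butter(spec.order // 2, spec.band, btype="bandpass", fs=fs, output="sos")
    out = _sig.sosfiltfilt(sos, data, axis=-1)
    f0 = spec.notch_base
    while f0 <= min(spec.notch_max, fs / 2 - 1e-9):
        # Q from the -3 dB full width (2 * half-width)
        q = f0 / (2.0 * spec.notch_half_width)
        b, a = _sig.iirnotch(f0, q, fs=fs)
        out = _sig.filtfilt(b, a, out, axis=-1)
        f0 += spec.notch_base
    return out


def epoch_response_locked(
    signal: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    window: tuple[float, float] = (-0.5, 0.15),
    leads: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut response-locked epochs out of a continuous recording.

    ``signal`` is lead x sample (a 1-D array is treated as one lead);
    ``events`` needs a ``response_time_s`` column plus the trial-table columns
    understood by :func:`leadtime.synth.frame_to_trials`.  Incorrect and
    timed-out trials are dropped; the sample at time 0 is the signal at the
    response marker (inclusive endpoints).
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if "response_time_s" not in events.columns:
        raise ValueError("events table missing column 'response_time_s'")
    n_samp = int(round((window[1] - window[0]) * fs)) + 1
    offsets = np.arange(n_samp) + int(round(window[0] * fs))
    times = offsets / fs

    kept_rows = events[(events["correct"].astype(bool)) & (~events["timed_out"].astype(bool))]
    epochs = []
    for row in kept_rows.itertuples(index=False):
        center = int(round(row.response_time_s * fs))
        idx = center + offsets
        if idx[0] < 0 or idx[-1] >= signal.shape[-1]:
            raise ValueError(
                f"trial {row.trial_id}: window {window} falls outside the recording"
            )
        epochs.append(signal[:, idx])
    data = np.stack(epochs) if epochs else np.empty((0, signal.shape[0], n_samp))
    trials = frame_to_trials(kept_rows.drop(columns=["response_time_s"]))
    if leads is None:
        leads = make_lead_table(
            [f"L{i:03d}" for i in range(signal.shape[0])], "S01", "left",
            [f"A{i:02d}" for i in range(signal.shape[0])],
        )
    return EpochSet(data=data, fs=fs, times=times, leads=leads, trials=trials)


# --- serialization ----------------------------------------------------------

def save_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to a single HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.attrs["fs"] = epochs.fs
        # stdlib json round-trips doubles exactly (repr); pandas to_json does not
        f.attrs["leads_json"] = json.dumps(epochs.leads.to_dict(orient="records"))
        f.attrs["trials_json"] = json.dumps(trials_to_frame(epochs.trials).to_dict(orient="records"))


def load_epochs(path) -> EpochSet:
    """Load an epoch container written by :func:`save_epochs`."""
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"cannot open epoch container {path}: {exc}") from exc
    with f:
        for key in ("data", "times"):
            if key not in f:
                raise ValueError(f"epoch container missing dataset {key!r}")
        for key in ("fs", "leads_json", "trials_json"):
            if key not in f.attrs:
                raise ValueError(f"epoch container missing metadata field {key!r}")
        data = f["data"][()]
        times = f["times"][()]
        fs = float(f.attrs["fs"])
        leads = pd.DataFrame(json.loads(_as_str(f.attrs["leads_json"])))
        trials_frame = pd.DataFrame(json.loads(_as_str(f.attrs["trials_json"])))
    trials = frame_to_trials(trials_frame) if len(trials_frame) else []
    return EpochSet(data=data, fs=fs, times=times, leads=leads[_LEAD_COLUMNS], trials=trials)


def _as_str(value) -> str:
    if isinstance(value, bytes):
        return value.decode("utf-8")
    return str(value)


def save_table(frame: pd.DataFrame, path) -> None:
    """Write a result table as TSV (floats with full round-trip precision)."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except (pd.errors.ParserError, FileNotFoundError) as exc:
        raise ValueError(f"cannot parse table {path}: {exc}") from exc


def save_results(tables: dict[str, pd.DataFrame], meta: dict, outdir) -> None:
    """Write a dict of result tables plus a JSON provenance block."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        save_table(frame, outdir / f"{name}.tsv")
    (outdir / "provenance.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
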