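"""Synthetic task sequences and multi-lead recordings with planted effects.

The generator stands in for patient recordings: a rule-switching button-press
task (blocks of 10-46 trials, 18-step cue-duration grid over 300-600 ms,
1.5 s response deadline) and response-locked lead signals whose band-limited
spectral power differs between left- and right-hand responses from a known,
configurable onset time.  Every planted parameter is returned as ground truth
so downstream modules can be tested for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "TaskTrial",
    "AreaEffect",
    "NoiseSpec",
    "RTSpec",
    "SynthConfig",
    "GroundTruth",
    "CUE_GRID",
    "BLOCK_RANGE",
    "RESPONSE_DEADLINE_S",
    "generate_task_sequence",
    "generate_recording",
    "trials_to_frame",
    "frame_to_trials",
]

#: the 18-point uniform cue-duration grid, seconds
CUE_GRID = np.round(np.linspace(0.300, 0.600, 18), 10)
#: inclusive block-length bounds, trials
BLOCK_RANGE = (10, 46)
#: response deadline, seconds
RESPONSE_DEADLINE_S = 1.5

_RULES = ("color", "orientation")
_COLORS = ("red", "blue")
_ORIENTATIONS = ("horizontal", "vertical")
_SIDES = ("left", "right")


def decision_table(rule: str, stim_color: str, stim_orientation: str) -> str:
    """Correct response side for a rule/stimulus combination.

    Color rule: red -> right, blue -> left.  Orientation rule:
    horizontal -> right, vertical -> left.
    """
    if rule == "color":
        return "right" if stim_color == "red" else "left"
    if rule == "orientation":
        return "right" if stim_orientation == "horizontal" else "left"
    raise ValueError(f"unknown rule: {rule!r}")


def is_congruent(stim_color: str, stim_orientation: str) -> bool:
    """True iff both rules demand the same response (red-horizontal, blue-vertical)."""
    return (stim_color, stim_orientation) in (("red", "horizontal"), ("blue", "vertical"))


@dataclass(frozen=True)
class TaskTrial:
    """One trial of the rule-switching task."""

    trial_id: int
    block_id: int
    rule: str
    stim_color: str
    stim_orientation: str
    congruent: bool
    response_side: str
    correct: bool
    rt: float
    cue_duration: float
    timed_out: bool

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"invalid rule {self.rule!r}")
        if self.stim_color not in _COLORS:
            raise ValueError(f"invalid color {self.stim_color!r}")
        if self.stim_orientation not in _ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.stim_orientation!r}")
        if self.response_side not in _SIDES:
            raise ValueError(f"invalid response side {self.response_side!r}")
        if self.congruent != is_congruent(self.stim_color, self.stim_orientation):
            raise ValueError("congruency flag inconsistent with stimulus features")
        if self.correct and not self.timed_out:
            expected = decision_table(self.rule, self.stim_color, self.stim_orientation)
            if self.response_side != expected:
                raise ValueError("correct trial with response side off the decision table")
        if not self.timed_out and self.rt > RESPONSE_DEADLINE_S:
            raise ValueError("rt exceeds the response deadline on a non-timed-out trial")
        if not np.isclose(CUE_GRID, self.cue_duration, atol=1e-9).any():
            raise ValueError("cue duration off the 18-point grid")


@dataclass(frozen=True)
class AreaEffect:
    """Planted left/right band-power contrast for one area.

    ``onset`` is seconds relative to the button press.  ``amplitude`` is the
    fractional envelope modulation (0 <= amplitude < 1); positive sign means
    more band power on contralateral trials.  When ``biphasic`` is set, the
    contrast sign flips once between onset and ``flip_time`` (defaults to
    midway between onset and the response), emulating a decrease-then-increase
    gamma profile.
    """

    onset: float
    band: tuple[float, float] = (70.0, 90.0)
    amplitude: float = 0.5
    sign: int = 1
    biphasic: bool = False
    flip_time: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.band[0] <= 0 or self.band[1] <= self.band[0]:
            raise ValueError(f"invalid frequency band {self.band}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class NoiseSpec:
    """1/f^alpha Gaussian background plus a white-noise floor."""

    exponent: float = 1.0
    amplitude: float = 1.0
    white_amplitude: float = 0.1


@dataclass(frozen=True)
class RTSpec:
    """Shifted log-normal reaction-time model (seconds)."""

    shift: float = 0.25
    mu: float = -1.4
    sigma: float = 0.35


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of one synthetic recording."""

    n_trials: int
    n_leads: int
    fs: float = 1000.0
    area_assignment: tuple[str, ...] = ()
    effects: dict[str, AreaEffect] = field(default_factory=dict)
    noise: NoiseSpec = NoiseSpec()
    rt: RTSpec = RTSpec()
    p_correct: float = 0.95
    p_timeout: float = 0.02
    p_left: float = 0.5
    subject: str = "S01"
    hemisphere: str = "left"
    window: tuple[float, float] = (-0.5, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 0 or self.n_leads < 0:
            raise ValueError("n_trials and n_leads must be nonnegative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 <= self.p_timeout <= 1 or not 0 <= self.p_correct <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if not 0 < self.p_left < 1:
            raise ValueError("p_left must lie in (0, 1)")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.area_assignment and len(self.area_assignment) != self.n_leads:
            raise ValueError("area_assignment length must equal n_leads")
        for area, eff in self.effects.items():
            if not self.window[0] <= eff.onset <= self.window[1]:
                raise ValueError(f"effect onset for {area!r} outside the epoch window")
            if eff.band[1] >= self.fs / 2:
                raise ValueError(f"effect band for {area!r} outside (0, fs/2)")

    @property
    def areas(self) -> tuple[str, ...]:
        if self.area_assignment:
            return self.area_assignment
        return tuple(f"A{i:02d}" for i in range(self.n_leads))


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters, one record per lead (null leads listed explicitly)."""

    lead_id: str
    area: str
    onset: float | None
    band: tuple[float, float] | None
    sign: int | None
    biphasic: bool
    is_null: bool


def generate_task_sequence(config: SynthConfig, rng: np.random.Generator | None = None) -> list[TaskTrial]:
    """Draw a full task sequence.

    Block lengths are i.i.d. uniform integers in [10, 46]; the rule alternates
    by block; the response side is drawn with probability ``p_left`` and the
    rule-relevant stimulus feature set accordingly (the irrelevant feature is
    uniform), so at ``p_left = 0.5`` all stimulus features are i.i.d. uniform.
    Correctness and timeouts are drawn at the configured rates; incorrect
    trials press the side opposite the decision table; timed-out trials carry
    ``rt = inf``.
    """
    if config.n_trials <= 0:
        raise ValueError("n_trials must be positive to generate a sequence")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    lo, hi = BLOCK_RANGE
    trials: list[TaskTrial] = []
    block_id = 0
    rule_idx = int(rng.integers(2))
    while len(trials) < config.n_trials:
        block_len = int(rng.integers(lo, hi + 1))
        rule = _RULES[rule_idx]
        for _ in range(block_len):
            if len(trials) == config.n_trials:
                break
            side = "left" if rng.random() < config.p_left else "right"
            if rule == "color":
                color = "blue" if side == "left" else "red"
                orientation = _ORIENTATIONS[int(rng.integers(2))]
            else:
                orientation = "vertical" if side == "left" else "horizontal"
                color = _COLORS[int(rng.integers(2))]
            timed_out = bool(rng.random() < config.p_timeout)
            correct = (not timed_out) and bool(rng.random() < config.p_correct)
            pressed = side
            if not timed_out and not correct:
                pressed = "right" if side == "left" else "left"
            if timed_out:
                correct = False
                rt = math.inf
            else:
                rt = config.rt.shift + float(rng.lognormal(config.rt.mu, config.rt.sigma))
                while rt > RESPONSE_DEADLINE_S:
                    rt = config.rt.shift + float(rng.lognormal(config.rt.mu, config.rt.sigma))
            cue = float(CUE_GRID[int(rng.integers(len(CUE_GRID)))])
            trials.append(
                TaskTrial(
                    trial_id=len(trials),
                    block_id=block_id,
                    rule=rule,
                    stim_color=color,
                    stim_orientation=orientation,
                    congruent=is_congruent(color, orientation),
                    response_side=pressed,
                    correct=correct,
                    rt=rt,
                    cue_duration=cue,
                    timed_out=timed_out,
                )
            )
        block_id += 1
        rule_idx = 1 - rule_idx
    return trials


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float, spec: NoiseSpec) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum plus a white floor."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-spec.exponent / 2.0)
    scale[0] = 0.0  # no DC
    white = rng.standard_normal(shape)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n, axis=-1)
    # normalize the shaped component to unit variance before mixing
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    shaped /= sd
    return spec.amplitude * shaped + spec.white_amplitude * rng.standard_normal(shape)


def _band_carrier(rng: np.random.Generator, shape: tuple[int, ...], fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian carrier (filtered white noise)."""
    pad = int(round(0.25 * fs))
    n = shape[-1]
    raw = rng.standard_normal(shape[:-1] + (n + 2 * pad,))
    sos = _sig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = _sig.sosfiltfilt(sos, raw, axis=-1)[..., pad : pad + n]
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def _effect_envelope(times: np.ndarray, eff: AreaEffect, contra: bool, ramp_s: float = 0.02) -> np.ndarray:
    """Multiplicative envelope for the band carrier on one trial.

    Smooth (raised-cosine) ramp at the onset; for biphasic effects the
    contrast sign flips once at ``flip_time``.
    """

    def _ramp(t0: float) -> np.ndarray:
        x = np.clip((times - t0) / ramp_s, 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * x)

    c = eff.sign if contra else -eff.sign
    if eff.biphasic:
        flip = eff.flip_time if eff.flip_time is not None else eff.onset / 2.0
        profile = -_ramp(eff.onset) + 2.0 * _ramp(flip)
    else:
        profile = _ramp(eff.onset)
    return 1.0 + c * eff.amplitude * profile


def generate_recording(trials: list[TaskTrial], config: SynthConfig):
    """Synthesize a response-locked :class:`~leadtime.prep.EpochSet`.

    Only correct, non-timed-out trials receive epochs (the analysis uses
    correct trials only).  Each effect-carrying lead gets a multiplicative
    band-power contrast between contralateral and ipsilateral responses from
    its planted onset, riding on 1/f background noise; null leads are noise
    only.  Returns ``(EpochSet, list[GroundTruth])``.
    """
    from .prep import EpochSet, make_lead_table

    if not trials:
        raise ValueError("trials must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEC40]))

    kept = [t for t in trials if t.correct and not t.timed_out]
    if not kept:
        raise ValueError("no correct, non-timed-out trials to epoch")
    n_samp = int(round((config.window[1] - config.window[0]) * config.fs)) + 1
    times = config.window[0] + np.arange(n_samp) / config.fs

    areas = config.areas
    contra_side = "right" if config.hemisphere == "left" else "left"
    is_contra = np.array([t.response_side == contra_side for t in kept])

    data = np.empty((len(kept), config.n_leads, n_samp))
    truth: list[GroundTruth] = []
    for li in range(config.n_leads):
        area = areas[li]
        lead_id = f"L{li:03d}"
        noise = _pink_noise(rng, (len(kept), n_samp), config.fs, config.noise)
        eff = config.effects.get(area)
        if eff is None:
            data[:, li] = noise
            truth.append(GroundTruth(lead_id, area, None, None, None, False, True))
            continue
        carrier = _band_carrier(rng, (len(kept), n_samp), config.fs, eff.band)
        env = np.empty_like(carrier)
        for ti, contra in enumerate(is_contra):
            env[ti] = _effect_envelope(times, eff, bool(contra))
        # carrier at ~noise scale so the planted contrast is a band-power modulation
        data[:, li] = noise + 0.8 * config.noise.amplitude * env * carrier
        truth.append(GroundTruth(lead_id, area, eff.onset, eff.band, eff.sign, eff.biphasic, False))

    leads = make_lead_table(
        lead_ids=[f"L{i:03d}" for i in range(config.n_leads)],
        subject=config.subject,
        hemisphere=config.hemisphere,
        areas=list(areas),
    )
    epochs = EpochSet(data=data, fs=config.fs, times=times, leads=leads, trials=kept)
    return epochs, truth


# --- trial table (TSV) round-trip -------------------------------------------

_TRIAL_COLUMNS = [
    "trial_id", "block_id", "rule", "stim_color", "stim_orientation",
    "congruent", "response_side", "correct", "rt", "cue_duration", "timed_out",
]


def trials_to_frame(trials: list[TaskTrial]):
    import pandas as pd

    return pd.DataFrame([{c: getattr(t, c) for c in _TRIAL_COLUMNS} for t in trials])


def frame_to_trials(frame) -> list[TaskTrial]:
    missing = [c for c in _TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            TaskTrial(
                trial_id=int(row.trial_id),
                block_id=int(row.block_id),
                rule=str(row.rule),
                stim_color=str(row.stim_color),
                stim_orientation=str(row.stim_orientation),
                congruent=bool(row.congruent),
                response_side=str(row.response_side),
                correct=bool(row.correct),
                rt=float(row.rt),
                cue_duration=float(row.cue_duration),
                timed_out=bool(row.timed_out),
            )
        )
    return out
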