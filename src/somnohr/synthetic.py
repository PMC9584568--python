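"""Synthetic cohorts with known ground truth.

Every downstream stage of the pipeline — quality control, R-peak detection,
feature extraction, the classifier, and the covariate regressions — is
exercised on data from this module, so each generator is a pure, seeded
function of its configuration.

The physiological model is deliberately minimal but captures the structure
the staging problem relies on:

* hypnograms are first-order Markov chains over {W, N1, N2, N3, R};
* the RR tachogram within a stage is a baseline mean plus a low-frequency
  (~0.1 Hz) oscillation, a respiratory (high-frequency) oscillation, and
  white jitter, with the three variance contributions summing to the
  configured SDNN^2 — REM is expressed as elevated LF and reduced HF power
  relative to NREM;
* ECG is a train of Ricker (Mexican-hat) pulses at the beat times with
  optional baseline wander and segment-local Gaussian noise.  The staging
  pipeline is morphology-insensitive, so no PQST realism is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import EcgRecord, Hypnogram, STAGES_5

__all__ = [
    "HypnogramModelConfig",
    "StageDynamics",
    "StageDynamicsConfig",
    "EcgSynthConfig",
    "SubjectMeta",
    "CohortSubject",
    "default_transition_matrix",
    "stationary_distribution",
    "simulate_hypnogram",
    "simulate_rr_series",
    "synthesize_ecg",
    "simulate_cohort",
    "AGE_GROUPS",
    "AHI_GROUPS",
    "SEXES",
]

AGE_GROUPS = ("<=40", "40-60", ">60")
AHI_GROUPS = ("none/minimal", "mild", "severe")
SEXES = ("F", "M")


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Hypnogram model
# ---------------------------------------------------------------------------

def default_transition_matrix() -> np.ndarray:
    """A sticky, ergodic chain with adult-night flavor: long N2 runs,
    W->N1 entries, deep sleep reached through N2, REM episodes."""
    #              W      N1     N2     N3     R
    return np.array([
        [0.880, 0.100, 0.015, 0.000, 0.005],   # W
        [0.090, 0.600, 0.290, 0.000, 0.020],   # N1
        [0.020, 0.030, 0.870, 0.050, 0.030],   # N2
        [0.005, 0.005, 0.090, 0.890, 0.010],   # N3
        [0.030, 0.030, 0.040, 0.000, 0.900],   # R
    ])


@dataclass
class HypnogramModelConfig:
    transition: np.ndarray = field(default_factory=default_transition_matrix)
    initial: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0, 0.0]))
    n_epochs: int = 960
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (5, 5):
            raise ConfigError("transition matrix must be 5x5")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ConfigError("probabilities must be non-negative")
        if np.max(np.abs(self.transition.sum(axis=1) - 1.0)) > 1e-9:
            raise ConfigError("transition rows must sum to 1 within 1e-9")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ConfigError("initial distribution must sum to 1 within 1e-9")
        if self.n_epochs <= 0:
            raise ConfigError("n_epochs must be positive")


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary vector of an ergodic row-stochastic matrix (eigen-analysis)."""
    vals, vecs = np.linalg.eig(np.asarray(transition, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    return v / v.sum()


def simulate_hypnogram(cfg: HypnogramModelConfig, subject_id: str = "",
                       start_time: float = 0.0) -> Hypnogram:
    rng = np.random.default_rng(cfg.seed)
    cum = np.cumsum(cfg.transition, axis=1)
    labels = np.empty(cfg.n_epochs, dtype=np.int64)
    state = int(np.searchsorted(np.cumsum(cfg.initial), rng.random(), side="right"))
    labels[0] = state
    u = rng.random(cfg.n_epochs)
    for i in range(1, cfg.n_epochs):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        labels[i] = state
    return Hypnogram(labels=tuple(STAGES_5[s] for s in labels),
                     start_time=start_time, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Stage-conditioned RR dynamics
# ---------------------------------------------------------------------------

@dataclass
class StageDynamics:
    """HRV regime of one sleep stage.

    mean_rr and sdnn in ms; lf_power/hf_power in ms^2 (band power realized
    as seeded oscillations); resp_rate in Hz.  sdnn^2 must be >= lf+hf so
    the residual variance can be realized as white jitter.
    """

    mean_rr: float
    sdnn: float
    lf_power: float
    hf_power: float
    resp_rate: float

    def __post_init__(self) -> None:
        if not 300.0 <= self.mean_rr <= 1500.0:
            raise ConfigError(f"mean_rr {self.mean_rr} outside [300, 1500] ms")
        if self.lf_power < 0 or self.hf_power < 0 or self.sdnn < 0:
            raise ConfigError("powers and sdnn must be non-negative")
        if not 0.1 <= self.resp_rate <= 0.5:
            raise ConfigError(f"resp_rate {self.resp_rate} outside [0.1, 0.5] Hz")


def _default_stage_dynamics() -> dict:
    # Literature-plausible adult values; REM shows the LF-up / HF-down
    # contrast relative to NREM, N3 the slowest and least variable rhythm.
    return {
        "W":  StageDynamics(mean_rr=800.0,  sdnn=50.0, lf_power=1200.0, hf_power=400.0, resp_rate=0.25),
        "N1": StageDynamics(mean_rr=900.0,  sdnn=45.0, lf_power=900.0,  hf_power=500.0, resp_rate=0.24),
        "N2": StageDynamics(mean_rr=1000.0, sdnn=40.0, lf_power=600.0,  hf_power=800.0, resp_rate=0.22),
        "N3": StageDynamics(mean_rr=1080.0, sdnn=30.0, lf_power=100.0,  hf_power=400.0, resp_rate=0.20),
        "R":  StageDynamics(mean_rr=850.0,  sdnn=55.0, lf_power=1400.0, hf_power=300.0, resp_rate=0.28),
    }


@dataclass
class StageDynamicsConfig:
    stages: Mapping[str, StageDynamics] = field(default_factory=_default_stage_dynamics)
    transition_smoothing_s: float = 30.0
    lf_freq_range: tuple = (0.095, 0.105)

    def __post_init__(self) -> None:
        missing = set(STAGES_5) - set(self.stages)
        if missing:
            raise ConfigError(f"missing stage dynamics for {sorted(missing)}")


def _param_trace(h: Hypnogram, values: np.ndarray, grid_t: np.ndarray,
                 smoothing_s: float) -> np.ndarray:
    """Piecewise-constant per-epoch parameter, linearly cross-faded over
    ``smoothing_s`` around each stage boundary."""
    epoch_len = h.epoch_len_s
    n = len(h)
    step = np.repeat(values, 1)
    idx = np.clip((grid_t // epoch_len).astype(int), 0, n - 1)
    trace = step[idx].astype(float)
    if smoothing_s <= 0:
        return trace
    # moving-average smoothing with a boxcar of width smoothing_s implements
    # a linear cross-fade across each step discontinuity
    dt = grid_t[1] - grid_t[0] if grid_t.size > 1 else 1.0
    w = max(1, int(round(smoothing_s / dt)))
    kernel = np.ones(w) / w
    padded = np.pad(trace, (w, w), mode="edge")
    sm = np.convolve(padded, kernel, mode="same")[w:-w]
    return sm


def simulate_rr_series(h: Hypnogram, dyn: StageDynamicsConfig | None = None,
                       seed: int = 0):
    """Generate beat times whose RR dynamics follow the per-stage regimes.

    Returns an :class:`somnohr.rr_processing.RPeakSeries` with all beats
    flagged ``ok``.  RR(t) = baseline(t) + LF sinusoid + HF (respiratory)
    sinusoid + white jitter; sinusoid amplitudes are sqrt(2 * band power) so
    each contributes its configured variance; jitter carries the remainder
    of sdnn^2.  Beat times are generated by integrate-and-fire on RR(t) and
    are strictly increasing with a 300 ms floor.
    """
    from .rr_processing import RPeakSeries

    if len(h) == 0:
        raise ValueError("empty hypnogram")
    dyn = dyn or StageDynamicsConfig()
    rng = np.random.default_rng(seed)

    grid_hz = 4.0
    duration = len(h) * h.epoch_len_s
    t = np.arange(0.0, duration, 1.0 / grid_hz)

    def per_epoch(attr):
        return np.array([getattr(dyn.stages[lab], attr) for lab in h.labels])

    base = _param_trace(h, per_epoch("mean_rr"), t, dyn.transition_smoothing_s)
    lf_amp = _param_trace(h, np.sqrt(2.0 * per_epoch("lf_power")), t,
                          dyn.transition_smoothing_s)
    hf_amp = _param_trace(h, np.sqrt(2.0 * per_epoch("hf_power")), t,
                          dyn.transition_smoothing_s)
    resp = _param_trace(h, per_epoch("resp_rate"), t, dyn.transition_smoothing_s)
    jitter_var = np.maximum(
        _param_trace(h, per_epoch("sdnn") ** 2
                     - per_epoch("lf_power") - per_epoch("hf_power"), t,
                     dyn.transition_smoothing_s), 0.0)

    f_lf = rng.uniform(*dyn.lf_freq_range)
    phi_lf = rng.uniform(0, 2 * math.pi)
    phi_hf = rng.uniform(0, 2 * math.pi)
    dt = 1.0 / grid_hz
    resp_phase = 2 * math.pi * np.cumsum(resp) * dt  # phase-continuous HF
    rr_ms = (base
             + lf_amp * np.sin(2 * math.pi * f_lf * t + phi_lf)
             + hf_amp * np.sin(resp_phase + phi_hf)
             + rng.standard_normal(t.size) * np.sqrt(jitter_var))
    rr_ms = np.clip(rr_ms, 300.0, 2000.0)

    # integrate-and-fire: next beat follows the instantaneous RR
    beats = []
    tb = 0.0
    while tb < duration:
        beats.append(tb)
        i = min(int(tb * grid_hz), t.size - 1)
        tb += rr_ms[i] / 1000.0
    times = np.asarray(beats)
    return RPeakSeries(times_s=times,
                       quality=np.full(times.size, "ok", dtype="<U12"),
                       source_fs=grid_hz)


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

@dataclass
class EcgSynthConfig:
    fs: float = 256.0
    qrs_amplitude: float = 1.0          # mV
    qrs_width_ms: float = 80.0
    baseline_wander_amp: float = 0.05   # mV at ~0.3 Hz
    noise_segments: Sequence = ()       # (start_s, end_s, noise_sd_mV)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ConfigError(f"fs {self.fs} below the 100 Hz minimum")
        if not 40.0 <= self.qrs_width_ms <= 160.0:
            raise ConfigError(f"qrs_width_ms {self.qrs_width_ms} outside [40, 160]")
        if self.fs * self.qrs_width_ms / 1000.0 < 4:
            raise ConfigError("fs too low: fewer than 4 samples per QRS pulse")


def synthesize_ecg(r, cfg: EcgSynthConfig | None = None,
                   duration_s: float | None = None) -> EcgRecord:
    """Render a Ricker-pulse ECG from beat times.

    One pulse of width ``qrs_width_ms`` is centered at each beat time
    (sub-sample positions honored by evaluating the template analytically),
    so the waveform argmax near each beat sits within one sample of the true
    time on clean signal.
    """
    cfg = cfg or EcgSynthConfig()
    times = np.asarray(r.times_s, dtype=float)
    if duration_s is None:
        duration_s = float(times[-1]) + 1.0 if times.size else 1.0
    if times.size and times[-1] > duration_s:
        raise ValueError("beat times extend past the requested duration")
    n = int(round(duration_s * cfg.fs))
    x = np.zeros(n)
    t_axis = np.arange(n) / cfg.fs
    sigma = cfg.qrs_width_ms / 1000.0 / 4.0  # pulse support ~ +-2 sigma
    half = int(math.ceil(4 * sigma * cfg.fs))
    for tb in times:
        c = int(round(tb * cfg.fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        u = (t_axis[lo:hi] - tb) / sigma
        x[lo:hi] += cfg.qrs_amplitude * (1.0 - u ** 2) * np.exp(-0.5 * u ** 2)
    if cfg.baseline_wander_amp > 0:
        x += cfg.baseline_wander_amp * np.sin(2 * math.pi * 0.3 * t_axis)
    if cfg.noise_segments:
        rng = np.random.default_rng(cfg.seed)
        for start_s, end_s, sd in cfg.noise_segments:
            lo, hi = int(start_s * cfg.fs), min(n, int(end_s * cfg.fs))
            x[lo:hi] += rng.standard_normal(hi - lo) * sd
    return EcgRecord(samples=x, fs=cfg.fs, start_time=0.0, channel_label="ECG")


# ---------------------------------------------------------------------------
# Cohorts with plantable covariate effects
# ---------------------------------------------------------------------------

@dataclass
class SubjectMeta:
    subject_id: str
    age_group: str
    ahi_group: str
    sex: str

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ConfigError(f"age_group {self.age_group!r} not in {AGE_GROUPS}")
        if self.ahi_group not in AHI_GROUPS:
            raise ConfigError(f"ahi_group {self.ahi_group!r} not in {AHI_GROUPS}")
        if self.sex not in SEXES:
            raise ConfigError(f"sex {self.sex!r} not in {SEXES}")


@dataclass
class CohortSubject:
    meta: SubjectMeta
    hypnogram: Hypnogram
    rr: object | None = None          # RPeakSeries when signals were generated
    ecg: EcgRecord | None = None
    predicted4: tuple | None = None   # planted 4-level predictions


_FOUR_OF_FIVE = {"W": "W", "N1": "Light", "N2": "Light", "N3": "Deep", "R": "R"}
_FOUR = ("W", "Light", "Deep", "R")


def _plant_predictions(h: Hypnogram, flip_fraction: float,
                       rng: np.random.Generator) -> tuple:
    """4-level predictions at accuracy ~ 1 - flip_fraction: collapse the
    reference and flip a binomial fraction of epochs to a different class."""
    labels = [_FOUR_OF_FIVE[l] for l in h.labels]
    n = len(labels)
    flip = rng.random(n) < flip_fraction
    for i in np.flatnonzero(flip):
        others = [c for c in _FOUR if c != labels[i]]
        labels[i] = others[rng.integers(len(others))]
    return tuple(labels)


def simulate_cohort(n_subjects: int,
                    hyp_cfg: HypnogramModelConfig | None = None,
                    dyn: StageDynamicsConfig | None = None,
                    planted_effects: Mapping | None = None,
                    base_flip: float = 0.20,
                    subject_sd: float = 0.02,
                    signals: str = "none",
                    seed: int = 0) -> list:
    """Simulate ``n_subjects`` nights with balanced metadata strata.

    planted_effects
        Mapping ``(factor, level) -> accuracy degradation``, e.g.
        ``{("age", ">60"): 0.05}`` lowers planted prediction accuracy by
        0.05 for that group.  When not ``None`` (an empty mapping plants no
        group effect but still emits predictions), each subject receives a
        planted 4-level prediction whose flip fraction is
        ``base_flip + sum(effects) + N(0, subject_sd)``.
    signals
        ``"none"`` (hypnograms only — fast path for regression studies),
        ``"rr"`` (beat times), or ``"ecg"`` (beat times + waveform).
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    planted = dict(planted_effects) if planted_effects is not None else None
    if planted:
        for factor, level in planted:
            groups = {"age": AGE_GROUPS, "ahi": AHI_GROUPS, "sex": SEXES}.get(factor)
            if groups is None or level not in groups:
                raise ConfigError(f"unknown stratum {(factor, level)!r}")
    rng = np.random.default_rng(seed)
    hyp_cfg = hyp_cfg or HypnogramModelConfig()

    subjects = []
    for i in range(n_subjects):
        # round-robin over the three factors keeps every stratum populated
        meta = SubjectMeta(
            subject_id=f"S{i:03d}",
            age_group=AGE_GROUPS[i % 3],
            ahi_group=AHI_GROUPS[(i // 3) % 3],
            sex=SEXES[i % 2],
        )
        h = simulate_hypnogram(
            replace(hyp_cfg, seed=int(rng.integers(2 ** 31))),
            subject_id=meta.subject_id)
        subj = CohortSubject(meta=meta, hypnogram=h)
        if signals in ("rr", "ecg"):
            subj.rr = simulate_rr_series(h, dyn, seed=int(rng.integers(2 ** 31)))
            if signals == "ecg":
                subj.ecg = synthesize_ecg(
                    subj.rr, EcgSynthConfig(seed=int(rng.integers(2 ** 31))))
        elif signals != "none":
            raise ConfigError(f"unknown signals mode {signals!r}")
        if planted is not None:
            f = base_flip + rng.normal(0.0, subject_sd)
            for (factor, level), delta in planted.items():
                value = {"age": meta.age_group, "ahi": meta.ahi_group,
                         "sex": meta.sex}[factor]
                if value == level:
                    f += delta
            subj.predicted4 = _plant_predictions(
                h, float(np.clip(f, 0.0, 1.0)), rng)
        subjects.append(subj)

    if planted:
        # every targeted stratum must contain at least 2 subjects
        for factor, level in planted:
            count = sum(
                1 for s in subjects
                if {"age": s.meta.age_group, "ahi": s.meta.ahi_group,
                    "sex": s.meta.sex}[factor] == level)
            if count < 2:
                raise ConfigError(
                    f"stratum {(factor, level)!r} has {count} subjects; "
                    "need >= 2 when planting effects")
    return subjects
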