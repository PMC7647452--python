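"""Synthetic finger-PPG generator with exact ground truth.

Emulates a three-group stimulus-response design: each subject receives a
fixed analgesic effect-compartment concentration, a noxious stimulus is
applied at a known time, and the stimulus raises heart rate and steepens
the catacrotic limb by an amount attenuated by the drug through a Hill
sigmoid.  Every record carries the clean waveform, the true fiducials and
the true per-beat parameters, so each downstream stage is testable
without any recording.

Model
-----
* One pulse = two Gaussian bumps (systolic wave plus a diastolic
  shoulder); bump parameters are given in seconds for a 0.8 s reference
  cycle and scale proportionally with each cycle's length, so morphology
  is self-similar across heart rates.
* Beat boundaries come from a phase accumulator driven by the
  instantaneous heart rate: baseline, plus a drug-attenuated
  exponentially-recovering step after the stimulus, plus slow
  Ornstein-Uhlenbeck drift (spontaneous autonomic variability).
* The stimulus also deforms the waveform: a drug-attenuated steepening of
  the catacrotic limb (``slope_gain``) and a concentration-independent
  change of the diastolic shoulder (``shape_gain``), whose per-subject
  magnitude is randomized at the study level.
* Measurement noise: additive white Gaussian noise at a prescribed SNR,
  sinusoidal baseline wander, optional powerline interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import cycles as _cycles
from . import features as _features
from .fiducials import FiducialSet

__all__ = [
    "BeatShapeParams",
    "StimulusResponseParams",
    "NoiseParams",
    "GroundTruth",
    "PPGRecord",
    "render_beat",
    "effect_factor",
    "simulate_record",
    "simulate_study",
]

#: cycle length (s) at which BeatShapeParams are stated
REFERENCE_CYCLE_S = 0.8


@dataclass(frozen=True)
class BeatShapeParams:
    """Two-Gaussian pulse shape, stated for a 0.8 s reference cycle."""

    systolic_center: float = 0.18  # s
    systolic_width: float = 0.075  # s
    diastolic_center: float = 0.50  # s
    diastolic_width: float = 0.20  # s
    diastolic_rel_amplitude: float = 0.45  # in [0, 1)
    peak_amplitude: float = 1.0  # arbitrary units

    def __post_init__(self) -> None:
        if not (self.systolic_center < self.diastolic_center):
            raise ValueError("systolic_center must precede diastolic_center")
        if self.systolic_width <= 0 or self.diastolic_width <= 0:
            raise ValueError("widths must be positive")
        if not (0 <= self.diastolic_rel_amplitude < 1):
            raise ValueError("diastolic_rel_amplitude must lie in [0, 1)")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")


@dataclass(frozen=True)
class StimulusResponseParams:
    """Stimulus-evoked response and its drug attenuation.

    The heart-rate step and catacrotic steepening are multiplied by the
    Hill factor ``1 / (1 + (ce/ec50)^gamma)``; ``shape_gain`` (diastolic-
    shoulder deformation) is applied independently of the drug, with the
    same exponential recovery.
    """

    baseline_hr: float = 76.0  # bpm
    hr_step: float = 12.0  # bpm, maximal stimulus-induced increase
    recovery_tau: float = 60.0  # s
    drug_ec50: float = 1.5  # ng/ml
    drug_gamma: float = 4.5  # dimensionless
    slope_gain: float = 0.01  # drug-attenuated catacrotic steepening
    shape_gain: float = 0.0  # drug-independent shoulder deformation, mean
    shape_gain_sd: float = 0.22  # between-subject spread of shape_gain
    hr_drift_sd: float = 2.5  # bpm, Ornstein-Uhlenbeck drift amplitude
    hr_drift_tau: float = 30.0  # s, drift correlation time

    def __post_init__(self) -> None:
        if not (40.0 <= self.baseline_hr <= 140.0):
            raise ValueError("baseline_hr must lie in [40, 140] bpm")
        if self.hr_step < 0:
            raise ValueError("hr_step must be >= 0")
        if self.recovery_tau <= 0 or self.hr_drift_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.drug_ec50 <= 0 or self.drug_gamma <= 0:
            raise ValueError("drug_ec50 and drug_gamma must be positive")
        if self.hr_drift_sd < 0:
            raise ValueError("hr_drift_sd must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model; ``white_snr_db=None`` disables noise."""

    white_snr_db: float | None = 20.0  # dB relative to clean signal power
    wander_amplitude: float = 0.05  # fraction of peak amplitude
    wander_freq: float = 0.25  # Hz
    powerline_freq: float | None = None  # Hz
    powerline_amplitude: float = 0.0  # fraction of peak amplitude
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.wander_freq >= 1.0:
            raise ValueError("wander_freq must be < 1 Hz")
        if self.wander_amplitude < 0 or self.powerline_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    @classmethod
    def off(cls) -> "NoiseParams":
        return cls(white_snr_db=None, wander_amplitude=0.0, powerline_freq=None)


@dataclass
class GroundTruth:
    """True fiducials and per-beat parameters of the clean waveform."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    fs: float
    features: pd.DataFrame  # beat_time + the six per-beat parameters

    @property
    def peak_times(self) -> np.ndarray:
        return self.peak_indices / self.fs

    @property
    def trough_times(self) -> np.ndarray:
        return self.trough_indices / self.fs

    def fiducial_set(self) -> FiducialSet:
        return FiducialSet(self.peak_indices, self.trough_indices, self.fs)


@dataclass
class PPGRecord:
    """Single-channel PPG waveform with study metadata."""

    signal: np.ndarray
    fs: float
    stimulus_time: float
    subject_id: str = "S00"
    ce: float = 0.0  # ng/ml
    seed: int | None = None
    clean: np.ndarray | None = None  # noise-free waveform, when known

    @property
    def duration(self) -> float:
        return self.signal.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.fs


def _beat_waveform(t: np.ndarray, t0: float, shape: BeatShapeParams,
                   scale: float, steepen: float, shoulder: float) -> np.ndarray:
    """Two-Gaussian pulse starting at ``t0`` with cycle scale factor
    ``scale``; ``steepen`` compresses the diastolic component toward the
    peak, ``shoulder`` multiplies its relative amplitude."""
    c1 = shape.systolic_center * scale
    w1 = shape.systolic_width * scale
    off = (shape.diastolic_center - shape.systolic_center) * scale / steepen
    # the deformation axis raises-and-narrows the diastolic wave
    # (vasomotor-tone change); lowering leaves the width alone so the
    # inter-beat valley keeps its slope
    narrow = 1.0 + 0.7 * (shoulder - 1.0) if shoulder > 1.0 else 1.0
    w2 = shape.diastolic_width * scale / (steepen * narrow)
    r = shape.diastolic_rel_amplitude * shoulder
    u = t - t0
    g = np.exp(-0.5 * ((u - c1) / w1) ** 2)
    if r > 0:
        g = g + r * np.exp(-0.5 * ((u - c1 - off) / w2) ** 2)
    return shape.peak_amplitude * g


def render_beat(shape: BeatShapeParams, cycle_length: float, fs: float) -> np.ndarray:
    """Render one pulse cycle on a uniform grid.

    Returns ``round(cycle_length * fs)`` samples; the beat starts at the
    first sample, peaks at ``systolic_center`` and decays to near zero at
    the cycle boundaries.
    """
    if fs < 50.0:
        raise ValueError("fs must be >= 50 Hz")
    if cycle_length <= shape.systolic_center + 2.0 * shape.systolic_width:
        raise ValueError(
            "cycle too short to contain the systolic wave: "
            f"{cycle_length} s <= systolic_center + 2 widths"
        )
    n = int(round(cycle_length * fs))
    t = np.arange(n) / fs
    return _beat_waveform(t, 0.0, shape, scale=1.0, steepen=1.0, shoulder=1.0)


def effect_factor(ce: float, params: StimulusResponseParams) -> float:
    """Hill attenuation of the stimulus response by the analgesic:
    ``1 / (1 + (ce/ec50)^gamma)``; 1 at ce = 0, 0.5 at ce = ec50."""
    if ce < 0:
        raise ValueError("concentration must be >= 0")
    if ce == 0.0:
        return 1.0
    return float(1.0 / (1.0 + (ce / params.drug_ec50) ** params.drug_gamma))


def _ou_drift(n: int, fs: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck process, AR(1) discretization."""
    if sd == 0.0:
        return np.zeros(n)
    a = math.exp(-1.0 / (fs * tau))
    eps = rng.standard_normal(n) * sd * math.sqrt(1.0 - a * a)
    eps[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -a], eps)


def simulate_record(
    shape: BeatShapeParams | None = None,
    response: StimulusResponseParams | None = None,
    noise: NoiseParams | None = None,
    ce: float = 0.0,
    duration: float = 150.0,
    stimulus_time: float = 75.0,
    fs: float = 100.0,
    seed: int | None = None,
    subject_id: str = "S00",
) -> tuple[PPGRecord, GroundTruth]:
    """Simulate one subject's recording plus its ground truth.

    Requires both analysis windows to fit: ``stimulus_time >= 70`` and
    ``duration >= stimulus_time + 70``.  Identical seeds give identical
    output.
    """
    shape = shape or BeatShapeParams()
    response = response or StimulusResponseParams()
    noise = noise or NoiseParams()
    if stimulus_time < 70.0 or duration < stimulus_time + 70.0:
        raise ValueError(
            "analysis windows do not fit: need stimulus_time >= 70 s and "
            f"duration >= stimulus_time + 70 s (got stimulus_time={stimulus_time}, "
            f"duration={duration})"
        )
    rng = np.random.default_rng(noise.rng_seed if seed is None else seed)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    eff = effect_factor(ce, response)

    decay = np.where(t >= stimulus_time,
                     np.exp(-(t - stimulus_time) / response.recovery_tau), 0.0)
    hr = response.baseline_hr + eff * response.hr_step * decay
    hr = hr + _ou_drift(n, fs, response.hr_drift_sd, response.hr_drift_tau, rng)
    hr = np.clip(hr, 30.0, 200.0)

    # integrate the instantaneous rate; beat k starts where phase crosses k
    phase = np.cumsum(hr / 60.0) / fs
    n_beats = int(math.floor(phase[-1]))
    bounds = np.interp(np.arange(n_beats + 1, dtype=float), phase, t)

    clean = np.zeros(n)
    for k in range(n_beats):
        t0, t1 = bounds[k], bounds[k + 1]
        cycle = t1 - t0
        scale = cycle / REFERENCE_CYCLE_S
        if t0 >= stimulus_time:
            d = math.exp(-(t0 - stimulus_time) / response.recovery_tau)
        else:
            d = 0.0
        steepen = 1.0 + eff * response.slope_gain * d
        shoulder = 1.0 + response.shape_gain * d
        lo = max(0, int((t0 - 0.6 * cycle) * fs))
        hi = min(n, int((t0 + 1.8 * cycle) * fs) + 1)
        clean[lo:hi] += _beat_waveform(t[lo:hi], t0, shape, scale, steepen, max(0.0, shoulder))

    # true fiducials on the clean waveform: systolic argmax per beat,
    # argmin between adjacent peaks
    peaks = []
    for k in range(n_beats):
        lo = int(round(bounds[k] * fs))
        hi = min(n, int(round((bounds[k] + 0.6 * (bounds[k + 1] - bounds[k])) * fs)))
        if hi > lo:
            peaks.append(lo + int(np.argmax(clean[lo:hi])))
    peaks = np.asarray(peaks, dtype=np.int64)
    troughs = np.asarray(
        [p + 1 + int(np.argmin(clean[p + 1 : q])) for p, q in zip(peaks[:-1], peaks[1:])],
        dtype=np.int64,
    )

    truth_fid = FiducialSet(peaks, troughs, fs)
    true_cycles, _ = _cycles.normalize_cycles(clean, truth_fid)
    truth_features = _features.beat_features(true_cycles, fs)
    truth = GroundTruth(peaks, troughs, fs, truth_features)

    signal = clean.copy()
    if noise.wander_amplitude > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        signal = signal + (noise.wander_amplitude * shape.peak_amplitude
                           * np.sin(2 * np.pi * noise.wander_freq * t + phase0))
    if noise.powerline_freq is not None and noise.powerline_amplitude > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        signal = signal + (noise.powerline_amplitude * shape.peak_amplitude
                           * np.sin(2 * np.pi * noise.powerline_freq * t + phase0))
    if noise.white_snr_db is not None:
        sigma = float(np.std(clean)) * 10.0 ** (-noise.white_snr_db / 20.0)
        signal = signal + rng.standard_normal(n) * sigma

    record = PPGRecord(
        signal=signal, fs=fs, stimulus_time=stimulus_time,
        subject_id=subject_id, ce=ce, seed=seed, clean=clean,
    )
    return record, truth


def simulate_study(
    n_per_group: int = 15,
    groups: tuple[float, ...] = (0.0, 1.0, 3.0),
    shape: BeatShapeParams | None = None,
    response: StimulusResponseParams | None = None,
    noise: NoiseParams | None = None,
    duration: float = 150.0,
    stimulus_time: float = 75.0,
    fs: float = 100.0,
    seed: int = 0,
) -> list[tuple[PPGRecord, GroundTruth]]:
    """Simulate the full multi-group study with subject-level jitter.

    Each subject gets a jittered baseline heart rate and pulse shape, and
    a randomized (drug-independent) shoulder-deformation magnitude.  All
    randomness descends from ``seed`` through per-subject substreams
    keyed by subject index.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not groups:
        raise ValueError("groups must be non-empty")
    shape = shape or BeatShapeParams()
    response = response or StimulusResponseParams()
    noise = noise or NoiseParams()

    out: list[tuple[PPGRecord, GroundTruth]] = []
    idx = 0
    for ce in groups:
        for _ in range(n_per_group):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
            jitter = np.random.default_rng(child)
            subj_response = replace(
                response,
                baseline_hr=float(np.clip(
                    response.baseline_hr + jitter.normal(0.0, 5.0), 70.0, 95.0)),
                shape_gain=float(np.clip(
                    jitter.normal(response.shape_gain, response.shape_gain_sd),
                    -0.35, 0.35)),
            )
            subj_shape = replace(
                shape,
                systolic_width=shape.systolic_width * float(1 + jitter.normal(0, 0.05)),
                diastolic_width=shape.diastolic_width * float(1 + jitter.normal(0, 0.05)),
                diastolic_rel_amplitude=float(np.clip(
                    shape.diastolic_rel_amplitude * (1 + jitter.normal(0, 0.10)),
                    0.0, 0.9)),
                peak_amplitude=shape.peak_amplitude * float(max(0.3, 1 + jitter.normal(0, 0.2))),
            )
            rec_seed = int(child.generate_state(2)[1] % (2**31))
            record, truth = simulate_record(
                shape=subj_shape, response=subj_response, noise=noise, ce=ce,
                duration=duration, stimulus_time=stimulus_time, fs=fs,
                seed=rec_seed, subject_id=f"S{idx:02d}",
            )
            out.append((record, truth))
            idx += 1
    return out
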