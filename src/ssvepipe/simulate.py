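"""Synthetic SSVEP-EEG cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
phase-locked cortical source whose scalp topography is fixed across the
cohort, responding at harmonics 1F..nF of the flicker frequency with
group-dependent amplitude and phase delay; a subject-level random effect
shared (with configurable correlation) by the two eyes; additive 1/f
background noise; and transient blink/muscle artifacts large enough to trip
the amplitude-based rejection thresholds.

Every operation is deterministic under a fixed seed.  The generator returns,
alongside the data, a :class:`TruthTable` holding the planted topography and
per-eye complex response means so that parameter-recovery tests can compare
pipeline estimates against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .protocol import ProtocolConfig

__all__ = [
    "Montage",
    "SensorTrial",
    "SubjectDemographics",
    "EffectSpec",
    "EyeState",
    "TruthTable",
    "CohortDataset",
    "make_montage",
    "make_topography",
    "planted_coefficients",
    "simulate_trial",
    "simulate_cohort",
    "iter_cohort_trials",
    "noise_floor_amplitude",
]


# --------------------------------------------------------------------------
# montage
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Electrode positions on the upper unit hemisphere (x right, y anterior,
    z superior)."""

    positions: np.ndarray  # (n_channels, 3)
    names: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def nearest_neighbors(self, channel: int, k: int, candidates=None) -> np.ndarray:
        """Indices of the ``k`` nearest channels to ``channel`` (self excluded),
        optionally restricted to ``candidates``."""
        d = np.linalg.norm(self.positions - self.positions[channel], axis=1)
        idx = np.arange(self.n_channels) if candidates is None else np.asarray(candidates)
        idx = idx[idx != channel]
        if idx.size < k:
            raise ValueError(f"only {idx.size} candidate neighbors available, need {k}")
        order = np.argsort(d[idx], kind="stable")
        return idx[order[:k]]


def make_montage(n_channels: int, seed: int = 0) -> Montage:
    """Quasi-uniform electrode layout on the upper hemisphere.

    Golden-spiral placement plus a small seeded jitter (re-normalised to the
    sphere), which keeps layouts generic while remaining deterministic.
    """
    if n_channels < 8:
        raise ValueError("a montage needs at least 8 channels")
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    # z descends from near-vertex to just above the equator
    z = 1.0 - (i + 0.5) / n_channels * 0.95
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    pos = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    pos = pos + rng.normal(scale=0.01, size=pos.shape)
    pos[:, 2] = np.abs(pos[:, 2])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    names = tuple(f"E{k + 1}" for k in range(n_channels))
    return Montage(positions=pos, names=names)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SensorTrial:
    """One eye/condition/trial multichannel recording, in microvolts."""

    subject_id: str
    eye: str
    condition: str
    trial_index: int
    data: np.ndarray  # (n_channels, n_samples), µV
    sampling_rate: float
    montage: Montage | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be channels × samples")


@dataclass(frozen=True)
class SubjectDemographics:
    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "F" | "M" | "unknown"
    md_od: float | None = None
    md_os: float | None = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"unknown sex code {self.sex!r}")


@dataclass(frozen=True)
class EffectSpec:
    """Generative parameters for the cohort.

    Amplitudes are single-sided sinusoid amplitudes in µV of the component
    source; the measured per-channel amplitude is this times the (unit-norm)
    topography entry.  Group effects are a multiplicative amplitude scale and
    an additive phase delay per pathway, applied to patients.  Clinical
    reports characterize such effects only qualitatively (phase informative
    in both pathways; an OFF amplitude advantage in classification), so the
    default magnitudes are this package's calibration choices, documented in
    docs/methods.md.
    """

    base_amplitude_on: tuple[float, ...] = (1.2, 0.9, 0.5, 0.3)
    base_amplitude_off: tuple[float, ...] = (1.5, 1.1, 0.6, 0.35)
    base_phase_on: tuple[float, ...] = (0.8, 1.6, 2.4, 3.0)
    base_phase_off: tuple[float, ...] = (0.6, 1.4, 2.2, 2.8)
    patient_amp_scale_on: float = 0.90
    patient_amp_scale_off: float = 0.75
    patient_phase_delay_on: float = 0.40
    patient_phase_delay_off: float = 0.30
    eye_correlation: float = 0.7
    amp_sigma: float = 0.35  # sd of log-amplitude random effect
    phase_sigma: float = 0.30  # sd (rad) of phase random effect
    noise_exponent: float = 1.0
    noise_scale_uv: float = 2.0  # per-channel RMS of background noise
    blink_rate: float = 0.0  # expected blinks per trial
    muscle_rate: float = 0.0  # expected muscle bursts per trial
    bad_channel_rate: float = 0.0  # P(one continuously noisy channel) per trial
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.eye_correlation <= 1.0):
            raise ValueError("eye_correlation must lie in [0, 1]")
        for amps in (self.base_amplitude_on, self.base_amplitude_off):
            if any(a < 0 for a in amps):
                raise ValueError("amplitudes must be non-negative")

    def base_amplitude(self, condition: str, n_harmonics: int) -> np.ndarray:
        amps = self.base_amplitude_on if condition == "ON" else self.base_amplitude_off
        if len(amps) < n_harmonics:
            raise ValueError("EffectSpec defines fewer harmonics than the protocol")
        return np.asarray(amps[:n_harmonics], dtype=float)

    def base_phase(self, condition: str, n_harmonics: int) -> np.ndarray:
        ph = self.base_phase_on if condition == "ON" else self.base_phase_off
        return np.asarray(ph[:n_harmonics], dtype=float)

    def patient_amp_scale(self, condition: str) -> float:
        return self.patient_amp_scale_on if condition == "ON" else self.patient_amp_scale_off

    def patient_phase_delay(self, condition: str) -> float:
        return self.patient_phase_delay_on if condition == "ON" else self.patient_phase_delay_off


@dataclass(frozen=True)
class EyeState:
    """Per-eye realisation of the subject random effect.

    ``amp_factor`` and ``phase_offset`` may be scalars or per-harmonic arrays;
    per-harmonic effects make subject identity multidimensional, as in real
    recordings where each harmonic's amplitude and phase is idiosyncratic.
    """

    subject_id: str
    group: str
    eye: str
    amp_factor: float | np.ndarray  # multiplicative, lognormal
    phase_offset: float | np.ndarray  # additive, radians


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort (for recovery tests)."""

    topography: np.ndarray  # (n_channels,), zero-mean unit-norm
    # planted complex mean per (subject, eye, condition): dict -> (n_harmonics,)
    planted_means: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    eye_states: dict[tuple[str, str], EyeState] = field(default_factory=dict)
    demographics: dict[str, SubjectDemographics] = field(default_factory=dict)


@dataclass
class CohortDataset:
    """Materialised cohort: all trials in memory.

    For large protocols prefer :func:`iter_cohort_trials`, which yields trials
    one at a time.
    """

    protocol: ProtocolConfig
    montage: Montage
    demographics: list[SubjectDemographics]
    trials: dict[tuple[str, str, str], list[SensorTrial]]  # (subject, eye, condition)

    @property
    def subject_ids(self) -> list[str]:
        return [d.subject_id for d in self.demographics]

    def n_trials(self, subject_id: str) -> int:
        return sum(len(v) for (s, _, _), v in self.trials.items() if s == subject_id)


# --------------------------------------------------------------------------
# signal construction
# --------------------------------------------------------------------------

def make_topography(montage: Montage, center=(0.0, -0.95, 0.31), width: float = 0.5) -> np.ndarray:
    """Smooth posterior (occipital) scalp pattern, zero-mean and unit-norm.

    Zero mean across channels makes the planted signal invariant under
    common-average re-referencing, so noise-free recovery is exact.
    """
    c = np.asarray(center, dtype=float)
    c /= np.linalg.norm(c)
    d = np.linalg.norm(montage.positions - c, axis=1)
    topo = np.exp(-(d**2) / (2.0 * width**2))
    topo -= topo.mean()
    norm = np.linalg.norm(topo)
    if norm == 0:
        raise ValueError("degenerate topography")
    return topo / norm


def planted_coefficients(
    effect: EffectSpec, state: EyeState, condition: str, n_harmonics: int
) -> np.ndarray:
    """Complex harmonic means c_h = A_h·exp(iθ_h) for one eye/condition.

    Convention (shared with the spectral module): the time-domain source is
    Σ_h |c_h|·cos(2π f_h t − θ_h), i.e. θ is a phase *delay* — larger θ means
    a later response.
    """
    amp = effect.base_amplitude(condition, n_harmonics) * state.amp_factor
    phase = effect.base_phase(condition, n_harmonics) + state.phase_offset
    if state.group == "patient":
        amp = amp * effect.patient_amp_scale(condition)
        phase = phase + effect.patient_phase_delay(condition)
    return amp * np.exp(1j * phase)


def _draw_eye_states(
    effect: EffectSpec,
    subject_id: str,
    group: str,
    eyes: Sequence[str],
    rng: np.random.Generator,
    n_harmonics: int = 4,
) -> dict[str, EyeState]:
    """Correlated per-eye random effects: e = √ρ·z_subject + √(1−ρ)·z_eye.

    Effects are drawn independently per harmonic (log-amplitude and phase),
    so each subject occupies a distinctive point in the harmonic-response
    space shared, to degree ρ, by both eyes.
    """
    rho = effect.eye_correlation
    z_subj = rng.standard_normal((2, n_harmonics))  # (log-amp, phase) × harmonic
    states = {}
    for eye in eyes:
        z_eye = rng.standard_normal((2, n_harmonics))
        e = math.sqrt(rho) * z_subj + math.sqrt(1.0 - rho) * z_eye
        states[eye] = EyeState(
            subject_id=subject_id,
            group=group,
            eye=eye,
            amp_factor=np.exp(effect.amp_sigma * e[0]),
            phase_offset=effect.phase_sigma * e[1],
        )
    return states


def _noise_spectrum_scale(n_samples: int, exponent: float, rms: float) -> np.ndarray:
    """Per-rfft-bin amplitude s_k (with E|X_k|² = s_k²) giving the requested RMS."""
    k = np.arange(1, n_samples // 2 + 1, dtype=float)
    s = k ** (-exponent / 2.0)
    # Var(x_n) = (1/N²)(2·Σ_{k<N/2} s_k² + s_{N/2}²)
    var_unit = (2.0 * np.sum(s[:-1] ** 2) + s[-1] ** 2) / n_samples**2
    if rms == 0:
        return np.zeros(n_samples // 2 + 1)
    scale = rms / math.sqrt(var_unit)
    return np.concatenate([[0.0], scale * s])


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, exponent: float, rms: float) -> np.ndarray:
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    s = _noise_spectrum_scale(n_samples, exponent, rms)
    re = rng.standard_normal((n_channels, s.size))
    im = rng.standard_normal((n_channels, s.size))
    X = (re + 1j * im) / math.sqrt(2.0) * s
    X[:, 0] = 0.0
    return np.fft.irfft(X, n=n_samples, axis=1)

def noise_floor_amplitude(protocol: ProtocolConfig, effect: EffectSpec, frequency: float) -> float:
    """Analytic expected |c| of the bin-wise harmonic coefficient under pure
    background noise (no signal), for the amplitude-scaled estimator
    c = (2/M)·Σ x_m·e^{−iωm} on one bin.

    Derived from the exact discrete synthesis used by the generator, so it is
    a closed-form oracle for Monte-Carlo noise-floor tests.
    """
    N = protocol.samples_per_trial
    M = protocol.samples_per_bin
    s = _noise_spectrum_scale(N, effect.noise_exponent, effect.noise_scale_uv)
    omega = 2.0 * math.pi * frequency / protocol.sampling_rate_hz
    k = np.arange(1, N // 2 + 1, dtype=float)
    total = 0.0
    for sign in (+1.0, -1.0):
        theta = sign * 2.0 * math.pi * k / N - omega
        half = np.abs(theta) < 1e-12
        num = np.sin(M * theta / 2.0) ** 2
        den = np.sin(theta / 2.0) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            kern = np.where(half, float(M**2), num / np.maximum(den, 1e-300))
        total += np.sum(s[1:] ** 2 * kern)
    e_c2 = 4.0 / (M**2 * N**2) * total
    return math.sqrt(math.pi * e_c2 / 4.0)


def _inject_artifacts(
    data: np.ndarray, protocol: ProtocolConfig, effect: EffectSpec, montage: Montage, rng: np.random.Generator
) -> None:
    """Add blink / muscle transients (in place) large enough to trip the
    60-µV whole-bin and 30-µV channel-bin rejection thresholds."""
    n_ch, n_samp = data.shape
    fs = protocol.sampling_rate_hz
    # blink: slow frontal deflection on the most anterior ~10% of channels
    n_front = max(8, n_ch // 10)
    front = np.argsort(-montage.positions[:, 1])[:n_front]
    for _ in range(rng.poisson(effect.blink_rate)):
        dur = int(0.4 * fs)
        onset = rng.integers(0, n_samp - dur)
        pulse = 120.0 * np.hanning(dur)
        weights = 0.6 + 0.4 * rng.random(n_front)
        data[front, onset : onset + dur] += weights[:, None] * pulse[None, :]
    # muscle: broadband burst on a random contiguous-ish channel subset
    for _ in range(rng.poisson(effect.muscle_rate)):
        dur = int(0.25 * fs)
        onset = rng.integers(0, n_samp - dur)
        chans = rng.choice(n_ch, size=max(4, n_ch // 32), replace=False)
        data[chans, onset : onset + dur] += rng.normal(scale=50.0, size=(chans.size, dur))
    # continuously noisy channel (trips the bad-channel detector)
    if rng.random() < effect.bad_channel_rate:
        ch = rng.integers(0, n_ch)
        data[ch] += rng.normal(scale=45.0, size=n_samp)


def simulate_trial(
    protocol: ProtocolConfig,
    effect: EffectSpec,
    state: EyeState,
    condition: str,
    montage: Montage,
    seed: int,
    topography: np.ndarray | None = None,
    trial_index: int = 0,
) -> SensorTrial:
    """Simulate one multichannel trial.

    The noiseless part of every 1.1-s bin carries, at each harmonic h and
    channel j, exactly the complex coefficient topography[j]·c_h where c_h is
    :func:`planted_coefficients` for this eye/condition.
    """
    rng = np.random.default_rng(seed)
    if topography is None:
        topography = make_topography(montage)
    n = protocol.samples_per_trial
    t = np.arange(n) / protocol.sampling_rate_hz
    coeffs = planted_coefficients(effect, state, condition, protocol.n_harmonics)
    freqs = [float(f) for f in protocol.harmonics]
    source = np.zeros(n)
    for c_h, f_h in zip(coeffs, freqs):
        source += np.abs(c_h) * np.cos(2.0 * math.pi * f_h * t - np.angle(c_h))
    data = topography[:, None] * source[None, :]
    data += _pink_noise(rng, montage.n_channels, n, effect.noise_exponent, effect.noise_scale_uv)
    _inject_artifacts(data, protocol, effect, montage, rng)
    return SensorTrial(
        subject_id=state.subject_id,
        eye=state.eye,
        condition=condition,
        trial_index=trial_index,
        data=data,
        sampling_rate=float(protocol.sampling_rate_hz),
        montage=montage,
    )


# --------------------------------------------------------------------------
# cohort level
# --------------------------------------------------------------------------

def _draw_demographics(
    subject_id: str, group: str, rng: np.random.Generator,
    age_mean_patient: float, age_mean_control: float, age_sd: float,
) -> SubjectDemographics:
    mean = age_mean_patient if group == "patient" else age_mean_control
    age = float(np.clip(rng.normal(mean, age_sd), 30.0, 95.0))
    sex = str(rng.choice(["F", "M", "unknown"], p=[0.44, 0.49, 0.07]))
    md_od = md_os = None
    if group == "patient":
        md_od = float(np.clip(rng.normal(-6.0, 4.0), -30.0, 0.5))
        md_os = float(np.clip(rng.normal(-6.0, 4.0), -30.0, 0.5))
    return SubjectDemographics(subject_id, group, age, sex, md_od, md_os)


def _cohort_plan(
    protocol: ProtocolConfig,
    effect: EffectSpec,
    n_patients: int,
    n_controls: int,
    seed: int,
    age_mean_patient: float,
    age_mean_control: float,
    age_sd: float,
):
    """Deterministic cohort skeleton: demographics, eye states, truth, seeds."""
    if n_patients < 1 or n_controls < 1:
        raise ValueError("need at least one subject per group")
    root = np.random.default_rng(seed)
    montage = make_montage(protocol.n_channels, seed=int(root.integers(2**31)))
    topography = make_topography(montage)
    truth = TruthTable(topography=topography)
    groups = ["patient"] * n_patients + ["control"] * n_controls
    plan = []
    for i, group in enumerate(groups):
        sid = f"S{i + 1:03d}"
        demo = _draw_demographics(sid, group, root, age_mean_patient, age_mean_control, age_sd)
        truth.demographics[sid] = demo
        states = _draw_eye_states(effect, sid, group, protocol.eyes, root, protocol.n_harmonics)
        for eye in protocol.eyes:
            truth.eye_states[(sid, eye)] = states[eye]
            for cond in protocol.conditions:
                truth.planted_means[(sid, eye, cond)] = planted_coefficients(
                    effect, states[eye], cond, protocol.n_harmonics
                )
        trial_seeds = root.integers(
            2**31, size=(len(protocol.eyes), len(protocol.conditions), protocol.n_trials_per_condition)
        )
        plan.append((demo, states, trial_seeds))
    return montage, topography, truth, plan


def iter_cohort_trials(
    protocol: ProtocolConfig,
    effect: EffectSpec,
    n_patients: int,
    n_controls: int,
    seed: int,
    age_mean_patient: float = 59.3,
    age_mean_control: float = 61.7,
    age_sd: float = 10.0,
) -> tuple[Montage, TruthTable, Iterator[SensorTrial]]:
    """Streaming cohort generator: yields trials one at a time (constant memory)."""
    montage, topography, truth, plan = _cohort_plan(
        protocol, effect, n_patients, n_controls, seed, age_mean_patient, age_mean_control, age_sd
    )

    def gen() -> Iterator[SensorTrial]:
        for demo, states, trial_seeds in plan:
            for ei, eye in enumerate(protocol.eyes):
                for ci, cond in enumerate(protocol.conditions):
                    for k in range(protocol.n_trials_per_condition):
                        yield simulate_trial(
                            protocol, effect, states[eye], cond, montage,
                            seed=int(trial_seeds[ei, ci, k]),
                            topography=topography, trial_index=k,
                        )

    return montage, truth, gen()


def simulate_cohort(
    protocol: ProtocolConfig,
    effect: EffectSpec,
    n_patients: int,
    n_controls: int,
    seed: int | None = None,
    **kwargs,
) -> tuple[CohortDataset, TruthTable]:
    """Materialised cohort (all trials in memory); see :func:`iter_cohort_trials`
    for the constant-memory streaming variant."""
    if seed is None:
        seed = effect.seed if effect.seed is not None else 0
    montage, truth, gen = iter_cohort_trials(protocol, effect, n_patients, n_controls, seed, **kwargs)
    trials: dict[tuple[str, str, str], list[SensorTrial]] = {}
    for tr in gen:
        trials.setdefault((tr.subject_id, tr.eye, tr.condition), []).append(tr)
    demographics = [truth.demographics[sid] for sid in sorted(truth.demographics)]
    return CohortDataset(protocol=protocol, montage=montage, demographics=demographics, trials=trials), truth
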