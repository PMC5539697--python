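"""Synthetic-subject simulator.

Generates ground-truth hypnograms together with the baseband quadrature radar
channels and per-epoch snore features that the staging pipeline consumes.

The radar model works directly at baseband.  Chest-wall displacement
``x(t) = xm(t) + xb(t) + xh(t)`` (body movement, breathing, heartbeat, in
metres) phase-modulates the in-phase and quadrature channels of a
continuous-wave Doppler radar:

    I(t) = cos(theta + 4*pi*x(t)/lambda + dphi(t)) + noise
    Q(t) = sin(theta + 4*pi*x(t)/lambda + dphi(t)) + noise

where ``lambda`` is the carrier wavelength (~12.5 mm at 24 GHz), ``theta`` a
constant phase offset encoding target distance, and ``dphi`` a slow
random-walk phase noise.  Stage-dependent physiology (rates, regularity,
movement bursts, snoring) gives the classifier something to learn; absence
intervals (subject out of bed) zero all displacement and sound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InputError
from .hypnogram import WAKE, NREM, REM, Hypnogram

SAMPLE_RATE_HZ: int = 1000
EPOCH_LEN_S: int = 30
EPOCH_SAMPLES: int = SAMPLE_RATE_HZ * EPOCH_LEN_S

#: Default epoch-to-epoch stage transition matrix, rows/cols ordered
#: (WAKE, NREM, REM).  Chosen to give a realistic overnight architecture:
#: ~17% wake, ~58% NREM, ~25% REM at stationarity, mean bouts of 5 min
#: (wake), 10 min (NREM/REM).
DEFAULT_TRANSITIONS = np.array(
    [
        [0.90, 0.10, 0.00],
        [0.02, 0.95, 0.03],
        [0.02, 0.05, 0.93],
    ]
)

#: REM latency: no REM within this many epochs of sleep onset (50 min).
REM_LATENCY_EPOCHS: int = 100


@dataclass
class RadarModelParams:
    """Baseband CW Doppler radar model parameters.

    ``wavelength`` is the carrier wavelength in metres (24 GHz -> ~12.5 mm);
    ``phase_offset`` encodes the nominal target distance; ``phase_noise_sd``
    is the per-sample standard deviation of the Gaussian random-walk phase
    noise, in radians.  Residual phase noise in a CW radar is small because
    transmit and receive share one oscillator (range correlation), hence the
    small default.
    """

    wavelength: float = 3.0e8 / 24.0e9  # ~0.0125 m
    phase_offset: float = 0.7
    phase_noise_sd: float = 0.001
    sample_rate: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ConfigurationError("wavelength must be positive")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.phase_noise_sd < 0:
            raise ConfigurationError("phase_noise_sd must be non-negative")


def _default_breathing_rates() -> dict[int, float]:
    return {WAKE: 14.0, NREM: 12.0, REM: 15.0}  # breaths/min


def _default_breathing_jitter() -> dict[int, float]:
    # Fractional cycle-to-cycle rate jitter; REM breathing is irregular.
    return {WAKE: 0.10, NREM: 0.05, REM: 0.20}


def _default_heart_rates() -> dict[int, float]:
    return {WAKE: 70.0, NREM: 58.0, REM: 68.0}  # beats/min


def _default_snore_propensity() -> dict[int, float]:
    # Expected snore events per 30-s epoch; snoring concentrates in sleep.
    return {WAKE: 0.2, NREM: 3.0, REM: 1.5}


def _default_ci_mean() -> dict[int, float]:
    # Mean (pre-normalization) cycle-intensity per stage.
    return {WAKE: 0.1, NREM: 1.0, REM: 0.6}


@dataclass
class SubjectProfile:
    """Generative parameters for one synthetic subject.

    Rates are per minute, displacement amplitudes in metres (breathing ~4 mm,
    heartbeat ~0.3 mm, movement bursts ~20 mm).  ``absence_intervals`` are
    half-open ``(start_epoch, end_epoch)`` ranges during which the subject is
    out of bed: displacement and sound are zero and the ground-truth stage is
    WAKE (PSG scores absence as wake).
    """

    breathing_rate_by_stage: dict[int, float] = field(default_factory=_default_breathing_rates)
    breathing_amp: float = 4.0e-3
    breathing_jitter_by_stage: dict[int, float] = field(default_factory=_default_breathing_jitter)
    heart_rate_by_stage: dict[int, float] = field(default_factory=_default_heart_rates)
    heart_amp: float = 0.3e-3
    movement_rate_wake: float = 1.0  # bursts/min while awake
    movement_rate_sleep: float = 0.05
    movement_amp: float = 20.0e-3
    snore_propensity_by_stage: dict[int, float] = field(default_factory=_default_snore_propensity)
    ci_mean_by_stage: dict[int, float] = field(default_factory=_default_ci_mean)
    absence_intervals: tuple[tuple[int, int], ...] = ()
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self, n_epochs: int | None = None) -> None:
        for name in ("breathing_amp", "heart_amp", "movement_amp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for rates in (self.breathing_rate_by_stage, self.heart_rate_by_stage):
            if any(r <= 0 for r in rates.values()):
                raise ConfigurationError("physiological rates must be positive")
        if self.movement_rate_wake < 0 or self.movement_rate_sleep < 0:
            raise ConfigurationError("movement rates must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        prop = self.snore_propensity_by_stage
        if any(v < 0 for v in prop.values()):
            raise ConfigurationError("snore propensities must be non-negative")
        sleep_props = [prop.get(NREM, 0.0), prop.get(REM, 0.0)]
        if any(v > 0 for v in sleep_props) and prop.get(WAKE, 0.0) >= min(
            v for v in sleep_props if v > 0
        ):
            raise ConfigurationError(
                "snore propensity while awake must be strictly below sleep propensity"
            )
        ivs = sorted(self.absence_intervals)
        for (a, b) in ivs:
            if a < 0 or b <= a:
                raise ConfigurationError("absence intervals must satisfy 0 <= start < end")
            if n_epochs is not None and b > n_epochs:
                raise ConfigurationError("absence interval extends past the recording")
        for (_, b), (a2, _) in zip(ivs, ivs[1:]):
            if a2 < b:
                raise ConfigurationError("absence intervals must not overlap")

    def absence_mask(self, n_epochs: int) -> np.ndarray:
        mask = np.zeros(n_epochs, dtype=bool)
        for a, b in self.absence_intervals:
            mask[a:b] = True
        return mask


@dataclass
class QuadratureRecording:
    """Two-channel baseband radar trace with sample-rate metadata."""

    channel_I: np.ndarray
    channel_Q: np.ndarray
    sample_rate: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.channel_I = np.asarray(self.channel_I)
        self.channel_Q = np.asarray(self.channel_Q)
        if not np.issubdtype(self.channel_I.dtype, np.floating):
            self.channel_I = self.channel_I.astype(float)
        if not np.issubdtype(self.channel_Q.dtype, np.floating):
            self.channel_Q = self.channel_Q.astype(float)
        if self.channel_I.shape != self.channel_Q.shape:
            raise InputError("I and Q channels must have equal length")

    def __len__(self) -> int:
        return int(self.channel_I.size)


@dataclass
class SoundFeatureSeries:
    """Per-epoch snore-event counts (SE) and cycle-intensity values (CI)."""

    SE: np.ndarray
    CI: np.ndarray

    def __post_init__(self) -> None:
        self.SE = np.asarray(self.SE, dtype=int)
        self.CI = np.asarray(self.CI, dtype=float)
        if self.SE.shape != self.CI.shape:
            raise InputError("SE and CI must have equal length")
        if (self.SE < 0).any() or (self.CI < 0).any():
            raise InputError("SE and CI must be non-negative")

    def __len__(self) -> int:
        return int(self.SE.size)


@dataclass
class DisplacementTrace:
    """Chest-wall displacement and its components, sampled at 1000 Hz."""

    x: np.ndarray
    xm: np.ndarray
    xb: np.ndarray
    xh: np.ndarray
    sample_rate: int = SAMPLE_RATE_HZ


@dataclass
class SubjectRecord:
    """One simulated subject: radar, sound features and ground truth."""

    recording: QuadratureRecording
    sound: SoundFeatureSeries
    hypnogram: Hypnogram
    profile: SubjectProfile
    radar_params: RadarModelParams


# ---------------------------------------------------------------------------
# hypnogram simulation


def simulate_hypnogram(
    n_epochs: int,
    transition_params: np.ndarray | None = None,
    enforce_rem_latency: bool = True,
    seed: int = 0,
    rem_latency_epochs: int = REM_LATENCY_EPOCHS,
) -> Hypnogram:
    """Simulate a stage sequence from an epoch-level Markov chain.

    The sequence begins with two WAKE epochs (the subject is awake for the
    first minute).  With ``enforce_rem_latency`` set, REM draws within
    ``rem_latency_epochs`` (default 100 epochs = 50 min) of the first sleep
    epoch are redirected to NREM, reproducing the physiological REM latency.
    """
    if n_epochs < 2:
        raise ConfigurationError("n_epochs must be at least 2")
    P = np.asarray(
        DEFAULT_TRANSITIONS if transition_params is None else transition_params,
        dtype=float,
    )
    if P.shape != (3, 3) or (P < 0).any():
        raise ConfigurationError("transition matrix must be 3x3 and non-negative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ConfigurationError("transition matrix rows must sum to 1")

    rng = np.random.default_rng(seed)
    stages = np.empty(n_epochs, dtype=np.int8)
    stages[:2] = WAKE
    onset: int | None = None
    for i in range(2, n_epochs):
        s = int(rng.choice(3, p=P[stages[i - 1]]))
        if s != WAKE and onset is None:
            onset = i
        if (
            enforce_rem_latency
            and s == REM
            and (onset is None or i < onset + rem_latency_epochs)
        ):
            s = NREM
        stages[i] = s
    return Hypnogram(stages)


# ---------------------------------------------------------------------------
# displacement simulation


def _smooth_rate(
    base: float, jitter: float, n_seconds: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-second instantaneous rate: AR(1)-smoothed multiplicative jitter."""
    z = np.empty(n_seconds)
    z[0] = rng.standard_normal()
    rho = 0.8  # second-to-second correlation of the rate fluctuation
    innov = rng.standard_normal(n_seconds) * math.sqrt(1 - rho**2)
    for k in range(1, n_seconds):
        z[k] = rho * z[k - 1] + innov[k]
    rate = base * (1.0 + jitter * z)
    return np.clip(rate, 0.3 * base, 2.0 * base)


def _quasi_sinusoid(
    rates_per_min: np.ndarray, amp: float, sample_rate: int
) -> np.ndarray:
    """Constant-amplitude oscillation with per-second instantaneous rate.

    Computed in float32: sub-micrometre displacement resolution, far below
    the radar noise floor, at half the memory traffic of float64.
    """
    inst_hz = np.repeat((rates_per_min / 60.0).astype(np.float32), sample_rate)
    phase = 2.0 * np.pi * np.cumsum(inst_hz, dtype=np.float64) / sample_rate
    # wrap before the float32 cast so large accumulated phase keeps full
    # angular resolution
    return (amp * np.sin(np.mod(phase, 2.0 * np.pi).astype(np.float32))).astype(
        np.float32
    )


def simulate_displacement(
    hypnogram: Hypnogram, profile: SubjectProfile
) -> DisplacementTrace:
    """Generate ``x(t) = xm + xb + xh`` for a hypnogram.

    Breathing is a quasi-sinusoid at the stage's rate with stage-dependent
    rate jitter (REM irregular, NREM regular); heartbeat a smaller
    quasi-sinusoid; movement sparse large raised-cosine bursts concentrated
    in WAKE.  All components are zero during absence intervals.
    """
    profile.validate(hypnogram.n_epochs)
    n_epochs = hypnogram.n_epochs
    fs = SAMPLE_RATE_HZ
    rng = np.random.default_rng(profile.seed)
    n_seconds = n_epochs * EPOCH_LEN_S

    # per-second stage and rate traces (continuous phase across epochs)
    stage_sec = np.repeat(hypnogram.stages, EPOCH_LEN_S)
    b_rate = np.empty(n_seconds)
    h_rate = np.empty(n_seconds)
    for st in (WAKE, NREM, REM):
        m = stage_sec == st
        if not m.any():
            continue
        b = _smooth_rate(
            profile.breathing_rate_by_stage[st],
            profile.breathing_jitter_by_stage.get(st, 0.1),
            n_seconds,
            rng,
        )
        h = _smooth_rate(profile.heart_rate_by_stage[st], 0.05, n_seconds, rng)
        b_rate[m] = b[m]
        h_rate[m] = h[m]

    xb = _quasi_sinusoid(b_rate, profile.breathing_amp, fs)
    xh = _quasi_sinusoid(h_rate, profile.heart_amp, fs)

    # sparse movement bursts
    xm = np.zeros(n_epochs * EPOCH_SAMPLES, dtype=np.float32)
    for i in range(n_epochs):
        rate = (
            profile.movement_rate_wake
            if hypnogram.stages[i] == WAKE
            else profile.movement_rate_sleep
        )
        n_bursts = rng.poisson(rate * EPOCH_LEN_S / 60.0)
        for _ in range(n_bursts):
            dur = int(rng.uniform(1.0, 3.0) * fs)
            start = i * EPOCH_SAMPLES + int(rng.uniform(0, EPOCH_SAMPLES - dur))
            pulse = profile.movement_amp * 0.5 * (
                1 - np.cos(2 * np.pi * np.arange(dur) / dur)
            )
            xm[start : start + dur] += rng.choice([-1.0, 1.0]) * pulse

    absent = np.repeat(profile.absence_mask(n_epochs), EPOCH_SAMPLES)
    for comp in (xb, xh, xm):
        comp[absent] = 0.0
    x = xm + xb + xh
    return DisplacementTrace(x=x, xm=xm, xb=xb, xh=xh, sample_rate=fs)


# ---------------------------------------------------------------------------
# baseband synthesis and demodulation


def synthesize_baseband(
    displacement: DisplacementTrace | np.ndarray,
    params: RadarModelParams | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> QuadratureRecording:
    """Phase-modulate displacement into baseband I/Q channels.

    ``I = cos(theta + 4*pi*x/lambda + dphi) + e_I`` and ``Q`` the sine of the
    same argument; ``dphi`` is a seeded Gaussian random-walk phase noise and
    ``e`` additive white channel noise of standard deviation ``noise_sd``.
    """
    params = params or RadarModelParams()
    x = (
        displacement.x
        if isinstance(displacement, DisplacementTrace)
        else np.asarray(displacement, dtype=np.float32)
    )
    rng = np.random.default_rng(seed)
    phase = np.float32(params.phase_offset) + np.float32(
        4.0 * np.pi / params.wavelength
    ) * x.astype(np.float32)
    if params.phase_noise_sd > 0:
        walk = np.cumsum(
            rng.standard_normal(x.size, dtype=np.float32)
            * np.float32(params.phase_noise_sd),
            dtype=np.float64,
        )
        phase = phase + walk.astype(np.float32)
    channel_I = np.cos(phase)
    channel_Q = np.sin(phase)
    if noise_sd > 0:
        channel_I += rng.standard_normal(x.size, dtype=np.float32) * np.float32(noise_sd)
        channel_Q += rng.standard_normal(x.size, dtype=np.float32) * np.float32(noise_sd)
    return QuadratureRecording(channel_I, channel_Q, params.sample_rate)


def demodulate(
    rec: QuadratureRecording,
    params: RadarModelParams | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Arctangent-demodulate I/Q back to relative displacement (metres).

    Unwraps ``atan2(Q - cQ, I - cI)`` and scales by ``lambda / 4 pi``.  The
    returned displacement is relative to the first sample (the constant
    ``theta`` offset and any integer wrap at t=0 are unobservable).
    """
    params = params or RadarModelParams()
    phase = np.unwrap(
        np.arctan2(
            rec.channel_Q.astype(np.float64) - center[1],
            rec.channel_I.astype(np.float64) - center[0],
        )
    )
    x = phase * params.wavelength / (4.0 * np.pi)
    return x - x[0]


# ---------------------------------------------------------------------------
# sound features


def simulate_sound_features(
    hypnogram: Hypnogram, profile: SubjectProfile, seed: int = 0
) -> SoundFeatureSeries:
    """Per-epoch snore-event counts and cycle-intensity values.

    SE is Poisson with a stage-dependent mean (snoring concentrates in
    sleep); CI is gamma-distributed around a stage-dependent mean, standing
    in for per-breathing-cycle acoustic energy.  Both are zero while the
    subject is absent.
    """
    profile.validate(hypnogram.n_epochs)
    rng = np.random.default_rng(seed)
    n = hypnogram.n_epochs
    se = np.empty(n, dtype=int)
    ci = np.empty(n, dtype=float)
    for i, st in enumerate(hypnogram.stages):
        se[i] = rng.poisson(profile.snore_propensity_by_stage.get(int(st), 0.0))
        mean_ci = profile.ci_mean_by_stage.get(int(st), 0.0)
        ci[i] = rng.gamma(2.0, mean_ci / 2.0) if mean_ci > 0 else 0.0
    absent = profile.absence_mask(n)
    se[absent] = 0
    ci[absent] = 0.0
    return SoundFeatureSeries(se, ci)


# ---------------------------------------------------------------------------
# subjects and cohorts


def simulate_subject(
    n_epochs: int,
    profile: SubjectProfile | None = None,
    radar_params: RadarModelParams | None = None,
    transition_params: np.ndarray | None = None,
    seed: int = 0,
) -> SubjectRecord:
    """Simulate one full subject night.

    Ground-truth stages in absence intervals are forced to WAKE, matching
    how reference PSG scores an empty bed.
    """
    profile = profile if profile is not None else SubjectProfile(seed=seed)
    profile.validate(n_epochs)
    radar_params = radar_params or RadarModelParams()
    ss = np.random.SeedSequence(seed)
    s_hyp, s_radar, s_sound = (int(s) for s in ss.generate_state(3) % (2**31))

    hyp = simulate_hypnogram(n_epochs, transition_params, seed=s_hyp)
    stages = hyp.stages.copy()
    stages[profile.absence_mask(n_epochs)] = WAKE
    hyp = Hypnogram(stages)

    profile = replace(profile, seed=int(np.random.SeedSequence(seed).generate_state(4)[3] % (2**31)))
    disp = simulate_displacement(hyp, profile)
    rec = synthesize_baseband(disp, radar_params, seed=s_radar, noise_sd=profile.noise_sd)
    sound = simulate_sound_features(hyp, profile, seed=s_sound)
    return SubjectRecord(rec, sound, hyp, profile, radar_params)


def sample_profile(rng: np.random.Generator, n_epochs: int) -> SubjectProfile:
    """Default cohort profile sampler: physiology varies across subjects.

    Breathing 10-18 breaths/min, heart 50-90 bpm, amplitudes jittered around
    4 mm / 0.3 mm, and roughly one subject in three leaves the bed once for
    10-30 min mid-recording.
    """
    b_nrem = rng.uniform(10.0, 16.0)
    b_delta = rng.uniform(1.0, 3.0)
    h_nrem = rng.uniform(50.0, 70.0)
    h_delta = rng.uniform(8.0, 20.0)
    absence: tuple[tuple[int, int], ...] = ()
    if rng.random() < 1.0 / 3.0 and n_epochs > 200:
        length = int(rng.integers(20, 61))
        start = int(rng.integers(n_epochs // 4, n_epochs - length - 10))
        absence = ((start, start + length),)
    return SubjectProfile(
        breathing_rate_by_stage={
            WAKE: b_nrem + b_delta,
            NREM: b_nrem,
            REM: min(b_nrem + 1.5 * b_delta, 18.0),
        },
        breathing_amp=rng.uniform(3.0e-3, 5.0e-3),
        heart_rate_by_stage={
            WAKE: h_nrem + h_delta,
            NREM: h_nrem,
            REM: h_nrem + 0.8 * h_delta,
        },
        heart_amp=rng.uniform(0.2e-3, 0.4e-3),
        movement_rate_wake=rng.uniform(0.7, 1.5),
        movement_amp=rng.uniform(15.0e-3, 25.0e-3),
        absence_intervals=absence,
        noise_sd=0.02,
    )


def simulate_cohort(
    n_subjects: int,
    n_epochs: int,
    profile_sampler=sample_profile,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate ``n_subjects`` independent seeded subjects.

    Each subject draws its own profile (different rates, amplitudes, radar
    phase offset) so that personal-adjusted thresholds are exercised.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be at least 1")
    master = np.random.SeedSequence(seed)
    records = []
    for child in master.spawn(n_subjects):
        rng = np.random.default_rng(child)
        profile = profile_sampler(rng, n_epochs)
        params = RadarModelParams(phase_offset=float(rng.uniform(0, 2 * np.pi)))
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        records.append(
            simulate_subject(n_epochs, profile, params, seed=sub_seed)
        )
    return records
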