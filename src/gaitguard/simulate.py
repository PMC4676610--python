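"""Synthetic smartphone IMU streams for normal and deceptive sitting/walking.

No public dataset of raw deceptive-motion sensor logs exists, so this module
generates them: 50 Hz tri-axial accelerometer (m/s^2, gravity included) and
gyroscope (rad/s) sessions for a cohort of simulated subjects, together with
an adaptive adversary that probes a trained classifier and drifts its cheating
strategy between retraining rounds.

Deceptive strategies mirror the behaviours people actually use against
activity trackers: shaking the phone (linearly, in circles, or with
rotation-dominant wrist motion) or rocking the torso with the phone pocketed
while seated, and walking smoothly, off-pace, or with a damping hand grip to
fake sitting.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

SAMPLE_RATE = 50.0  # Hz, both sensors
GRAVITY = 9.81  # m/s^2

SITTING = "sitting"
WALKING = "walking"
ACTIVITIES = (SITTING, WALKING)

#: strategies performed while truly sitting (goal: be detected as walking)
FAKE_WALKING_KINDS = ("shake_linear", "shake_circular", "shake_rotational", "pocket_torso")
#: strategies performed while truly walking (goal: be detected as sitting)
FAKE_SITTING_KINDS = ("smooth_walk", "pace_shift", "hand_damped")
STRATEGY_KINDS = FAKE_WALKING_KINDS + FAKE_SITTING_KINDS


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce an int seed / None / Generator into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


@dataclass(frozen=True)
class StrategyParams:
    """Parameters of one cheating strategy.

    ``amplitude`` is in m/s^2, ``frequency`` in Hz, ``rotation_scale`` in
    rad/s; ``smoothing`` in [0, 1] low-pass-filters and attenuates a walking
    signal (0 = untouched, 1 = fully flattened); ``pace_factor`` multiplies
    the subject's natural step frequency.
    """

    kind: str
    amplitude: float = 0.0
    frequency: float = 0.0
    rotation_scale: float = 0.0
    smoothing: float = 0.0
    pace_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.amplitude < 0 or self.frequency < 0 or self.rotation_scale < 0:
            raise ValueError("amplitude, frequency, rotation_scale must be >= 0")
        if not 0.0 <= self.smoothing <= 1.0:
            raise ValueError("smoothing must lie in [0, 1]")
        if self.pace_factor <= 0:
            raise ValueError("pace_factor must be > 0")

    @property
    def true_activity(self) -> str:
        """The activity actually performed while executing this strategy."""
        return SITTING if self.kind in FAKE_WALKING_KINDS else WALKING

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "amplitude": self.amplitude,
            "frequency": self.frequency,
            "rotation_scale": self.rotation_scale,
            "smoothing": self.smoothing,
            "pace_factor": self.pace_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrategyParams":
        return cls(**d)


@dataclass
class SubjectProfile:
    """Per-subject motion parameters (stands in for a recruited participant).

    ``step_frequency`` is the gait fundamental in Hz (~1.4-2.2 across
    adults), ``gait_amplitude`` the vertical acceleration oscillation in
    m/s^2, ``gait_harmonic_weights`` the relative weights of harmonics
    k = 1, 2, ... of the step frequency, ``sit_noise_sd`` the resting
    accelerometer noise, ``gyro_gain`` couples the rotational channel to the
    gait pattern, and ``fidget_rate`` the expected number of small seated
    posture adjustments per second.
    """

    subject_id: str
    step_frequency: float
    gait_amplitude: float
    gait_harmonic_weights: tuple[float, ...]
    sit_noise_sd: float
    gyro_gain: float
    fidget_rate: float
    preferred_strategies: tuple[StrategyParams, ...]
    rng_seed: int
    #: habitual phone orientation (tilt and azimuth of the device Z axis,
    #: rad); a subject carries the phone roughly the same way in every
    #: session, with small per-session jitter on top
    base_tilt: float = 0.0
    base_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.step_frequency <= 0 or self.gait_amplitude <= 0:
            raise ValueError("step_frequency and gait_amplitude must be > 0")
        if self.sit_noise_sd < 0 or self.fidget_rate < 0:
            raise ValueError("sit_noise_sd and fidget_rate must be >= 0")

    def preferred_for(self, true_activity: str) -> StrategyParams | None:
        """First preferred strategy consistent with ``true_activity``."""
        for s in self.preferred_strategies:
            if s.true_activity == true_activity:
                return s
        return None


@dataclass
class SensorStream:
    """One uniformly sampled 6-channel motion recording.

    ``accel`` and ``gyro`` are (n, 3) arrays; the accelerometer includes the
    constant gravity component (|g| = 9.81 m/s^2, tilted by the session's
    random phone orientation).
    """

    subject_id: str
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    true_activity: str
    honesty: str
    strategy: StrategyParams | None = None
    sample_rate: float = SAMPLE_RATE
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must be (n, 3) arrays matching timestamps")
        if self.true_activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.true_activity!r}")
        if self.honesty not in ("normal", "deceptive"):
            raise ValueError(f"honesty must be 'normal' or 'deceptive', got {self.honesty!r}")
        if self.honesty == "deceptive" and self.strategy is None:
            raise ValueError("deceptive stream requires a strategy")
        if self.honesty == "normal" and self.strategy is not None:
            raise ValueError("normal stream must not carry a strategy")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class AdversaryConfig:
    """Search space and effort of the adaptive cheating adversary."""

    n_candidates: int = 20
    probe_s: float = 10.0
    fake_walk_kinds: tuple[str, ...] = FAKE_WALKING_KINDS
    fake_sit_kinds: tuple[str, ...] = FAKE_SITTING_KINDS
    amp_range: tuple[float, float] = (1.5, 4.5)
    freq_range: tuple[float, float] = (1.2, 2.6)
    rot_range: tuple[float, float] = (0.5, 2.5)
    smooth_range: tuple[float, float] = (0.55, 0.95)
    pace_range: tuple[float, float] = (0.6, 1.6)
    perturb_sd: float = 0.15


def make_cohort(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """Draw ``n_subjects`` reproducible subject profiles.

    The same ``seed`` always yields the identical cohort; different seeds
    differ in at least one parameter with probability 1.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    profiles = []
    for i in range(n_subjects):
        shake = StrategyParams(
            kind="shake_linear",
            amplitude=float(rng.uniform(2.5, 4.0)),
            frequency=float(rng.uniform(1.6, 2.4)),
            rotation_scale=float(rng.uniform(0.5, 1.5)),
        )
        smooth = StrategyParams(
            kind="smooth_walk",
            smoothing=float(rng.uniform(0.75, 0.92)),
            pace_factor=1.0,
        )
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:02d}",
                step_frequency=float(rng.uniform(1.4, 2.2)),
                gait_amplitude=float(rng.uniform(2.0, 4.0)),
                gait_harmonic_weights=(
                    1.0,
                    float(rng.uniform(0.3, 0.6)),
                    float(rng.uniform(0.1, 0.3)),
                ),
                sit_noise_sd=float(rng.uniform(0.05, 0.15)),
                gyro_gain=float(rng.uniform(0.25, 0.55)),
                fidget_rate=float(rng.uniform(0.05, 0.2)),
                preferred_strategies=(shake, smooth),
                rng_seed=_child_seed(rng),
                base_tilt=float(rng.normal(0.0, 0.05)),
                base_azimuth=float(rng.uniform(0.0, 2 * np.pi)),
            )
        )
    return profiles


def _smooth_wobble(n: int, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Slow orientation wobble: two random sub-Hz sinusoids of amplitude amp."""
    if amp <= 0 or n == 0:
        return np.zeros(n)
    t = np.arange(n) / SAMPLE_RATE
    out = np.zeros(n)
    for _ in range(2):
        f = rng.uniform(0.05, 0.2)
        out += 0.5 * amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _gravity_series(
    profile: SubjectProfile, n: int, rng: np.random.Generator, wobble_amp: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gravity in device coordinates: |g(t)| = 9.81 exactly.

    Orientation = the subject's habitual carry orientation, plus a small
    static per-session jitter, plus slow in-session wobble (a hand or pocket
    never holds the phone perfectly still).

    Returns the (n, 3) gravity series and the (n, 3) gyro signature of the
    wobble (zero when ``wobble_amp`` is zero).
    """
    alpha0 = profile.base_tilt + rng.normal(0.0, 0.02)
    phi0 = profile.base_azimuth + rng.normal(0.0, 0.05)
    alpha = alpha0 + _smooth_wobble(n, wobble_amp, rng)
    phi = phi0 + _smooth_wobble(n, 2.0 * wobble_amp, rng)
    G = GRAVITY * np.stack(
        [np.sin(alpha) * np.cos(phi), np.sin(alpha) * np.sin(phi), np.cos(alpha)], axis=1
    )
    gyro = np.zeros((n, 3))
    if wobble_amp > 0 and n > 1:
        gyro[:, 0] = np.gradient(alpha) * SAMPLE_RATE
        gyro[:, 1] = np.gradient(phi) * SAMPLE_RATE * np.sin(alpha)
    return G, gyro


def _sitting_parts(
    profile: SubjectProfile, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gravity series, dynamic accel, gyro for a seated session.

    Orientation wobble scales with the subject's resting noise so the
    noise-free limit (sit_noise_sd = 0, fidgets off) is exactly constant
    gravity and zero gyro.
    """
    g, gyro = _gravity_series(profile, n, rng, wobble_amp=0.3 * profile.sit_noise_sd)
    accel_dyn = rng.normal(0.0, profile.sit_noise_sd, (n, 3)) if profile.sit_noise_sd > 0 else np.zeros((n, 3))
    if profile.sit_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, 0.3 * profile.sit_noise_sd, (n, 3))
    # sparse fidget events: short Gaussian-windowed bumps on a random axis
    if profile.fidget_rate > 0 and n > 0:
        n_events = rng.poisson(profile.fidget_rate * n / SAMPLE_RATE)
        t = np.arange(n) / SAMPLE_RATE
        for _ in range(n_events):
            t0 = rng.uniform(0.0, n / SAMPLE_RATE)
            width = rng.uniform(0.2, 0.5)
            amp = rng.uniform(0.3, 0.8)
            axis = rng.integers(0, 3)
            bump = amp * np.exp(-0.5 * ((t - t0) / width) ** 2)
            accel_dyn[:, axis] += bump * np.sin(2 * np.pi * rng.uniform(0.5, 1.5) * (t - t0))
            gyro[:, axis] += 0.1 * bump
    return g, accel_dyn, gyro


def _walking_parts(
    profile: SubjectProfile,
    n: int,
    rng: np.random.Generator,
    pace_factor: float = 1.0,
    amplitude: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gravity vector, dynamic accel, gyro for a walking session.

    The vertical axis carries the harmonic stack at k * step_frequency; the
    lateral axes carry weaker components at the same fundamental so the
    dominant spectral line stays at the step frequency.
    """
    g, gyro_wobble = _gravity_series(profile, n, rng, wobble_amp=0.05)
    f = profile.step_frequency * pace_factor
    amp = profile.gait_amplitude if amplitude is None else amplitude
    t = np.arange(n) / SAMPLE_RATE
    phase = rng.uniform(0.0, 2 * np.pi)
    vert = np.zeros(n)
    gyro_osc = np.zeros(n)
    for k, w in enumerate(profile.gait_harmonic_weights, start=1):
        vert += w * amp * np.sin(2 * np.pi * k * f * t + k * phase)
        gyro_osc += w * np.sin(2 * np.pi * k * f * t + k * phase + np.pi / 2)
    noise_sd = 0.1 + 2.0 * profile.sit_noise_sd
    accel_dyn = rng.normal(0.0, noise_sd, (n, 3))
    accel_dyn[:, 2] += vert
    accel_dyn[:, 0] += 0.4 * amp * np.sin(2 * np.pi * f * t + phase + np.pi / 3)
    accel_dyn[:, 1] += 0.3 * amp * np.sin(2 * np.pi * f * t + phase + 2 * np.pi / 3)
    gyro = gyro_wobble + rng.normal(0.0, 0.05, (n, 3))
    for axis, scale in enumerate((1.0, 0.6, 0.4)):
        gyro[:, axis] += profile.gyro_gain * scale * gyro_osc
    return g, accel_dyn, gyro


def _make_stream(
    profile: SubjectProfile,
    g: np.ndarray,
    accel_dyn: np.ndarray,
    gyro: np.ndarray,
    true_activity: str,
    honesty: str,
    strategy: StrategyParams | None,
) -> SensorStream:
    n = accel_dyn.shape[0]
    return SensorStream(
        subject_id=profile.subject_id,
        timestamps=np.arange(n) / SAMPLE_RATE,
        accel=g + accel_dyn,
        gyro=gyro,
        true_activity=true_activity,
        honesty=honesty,
        strategy=strategy,
    )


def simulate_activity(
    profile: SubjectProfile,
    activity: str,
    duration_s: float,
    rng: np.random.Generator | int | None = None,
) -> SensorStream:
    """Simulate an honestly performed sitting or walking session."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}")
    rng = as_rng(rng)
    n = int(round(duration_s * SAMPLE_RATE))
    if activity == SITTING:
        g, dyn, gyro = _sitting_parts(profile, n, rng)
    else:
        g, dyn, gyro = _walking_parts(profile, n, rng)
    return _make_stream(profile, g, dyn, gyro, activity, "normal", None)


def _one_pole_lowpass(x: np.ndarray, s: float) -> np.ndarray:
    """y[t] = (1-s) x[t] + s y[t-1]; identity for s = 0."""
    if s <= 0:
        return x
    return _sig.lfilter([1.0 - s], [1.0, -s], x, axis=0)


def simulate_deceptive(
    profile: SubjectProfile,
    strategy: StrategyParams,
    duration_s: float,
    rng: np.random.Generator | int | None = None,
) -> SensorStream:
    """Simulate a deceptive session executing ``strategy``.

    Fake-walking kinds superimpose hand or torso motion on a seated base;
    fake-sitting kinds generate a walking base and smooth / re-pace / damp it.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = as_rng(rng)
    n = int(round(duration_s * SAMPLE_RATE))
    t = np.arange(n) / SAMPLE_RATE
    kind = strategy.kind

    if kind in FAKE_WALKING_KINDS:
        # hand or torso motion moves the whole phone: every accel axis and
        # the gyro are excited, as in a true walk, or the shake is trivially
        # exposed by any single quiet channel
        g, dyn, gyro = _sitting_parts(profile, n, rng)
        a, f, r = strategy.amplitude, strategy.frequency, strategy.rotation_scale
        w = 2 * np.pi * f
        phase = rng.uniform(0.0, 2 * np.pi)
        gyro_scale = (1.0, 0.6, 0.4)
        if kind == "shake_linear":
            # back-and-forth bounce along a mostly vertical direction,
            # with the hand adding a second harmonic
            # multiplicative jitter keeps every component away from zero: a
            # hand shake never leaves an axis still
            u = np.array([0.45, 0.35, 1.0]) * np.exp(0.15 * rng.normal(size=3))
            u /= np.linalg.norm(u)
            for i in range(3):
                dyn[:, i] += a * abs(u[i]) * (
                    np.sin(w * t + phase + 0.5 * i) + 0.4 * np.sin(2 * w * t + 2 * phase)
                )
                gyro[:, i] += 0.4 * r * gyro_scale[i] * np.sin(w * t + phase + np.pi / 2)
        elif kind == "shake_circular":
            # drawing circles: exact quadrature between X and Y
            dyn[:, 0] += a * np.sin(w * t + phase)
            dyn[:, 1] += a * np.cos(w * t + phase)
            dyn[:, 2] += 0.6 * a * np.sin(w * t + phase + np.pi / 5)
            for i in range(3):
                gyro[:, i] += 0.5 * r * gyro_scale[i] * np.sin(w * t + phase + i)
        elif kind == "shake_rotational":
            # wrist rotation: gyro-dominant, but rotating the case also
            # swings gravity across the accelerometer axes
            for i in range(3):
                gyro[:, i] += r * (1.0, 0.7, 0.5)[i] * np.sin(w * t + phase + i)
                dyn[:, i] += 0.5 * a * np.sin(w * t + phase + i + np.pi / 4)
        else:  # pocket_torso: rocking that mimics the gait template
            dyn[:, 2] += a * np.sin(w * t + phase) + 0.3 * a * np.sin(2 * w * t + 2 * phase)
            dyn[:, 0] += 0.4 * a * np.sin(w * t + phase + np.pi / 3)
            dyn[:, 1] += 0.3 * a * np.sin(w * t + phase + 2 * np.pi / 3)
            for i in range(3):
                gyro[:, i] += 0.5 * r * gyro_scale[i] * np.sin(w * t + phase + np.pi / 2)
        return _make_stream(profile, g, dyn, gyro, SITTING, "deceptive", strategy)

    # fake sitting: a modified walk
    s = strategy.smoothing
    if kind == "hand_damped":
        amp = strategy.amplitude if strategy.amplitude > 0 else 0.3 * profile.gait_amplitude
    else:
        amp = None
    g, dyn, gyro = _walking_parts(
        profile, n, rng, pace_factor=strategy.pace_factor, amplitude=amp
    )
    if s > 0:
        dyn = (1.0 - s) * _one_pole_lowpass(dyn, s)
        # rotation is harder to suppress by hand than linear impact
        gyro = (1.0 - 0.7 * s) * _one_pole_lowpass(gyro, 0.7 * s)
    return _make_stream(profile, g, dyn, gyro, WALKING, "deceptive", strategy)


def _sample_novel(
    kind: str, adv: AdversaryConfig, rng: np.random.Generator
) -> StrategyParams:
    u = rng.uniform
    return StrategyParams(
        kind=kind,
        amplitude=float(u(*adv.amp_range)),
        frequency=float(u(*adv.freq_range)),
        rotation_scale=float(u(*adv.rot_range)),
        smoothing=float(u(*adv.smooth_range)),
        pace_factor=float(u(*adv.pace_range)),
    )


def _perturb(
    base: StrategyParams, adv: AdversaryConfig, rng: np.random.Generator
) -> StrategyParams:
    def jig(v: float, lo: float, hi: float) -> float:
        out = v * float(np.exp(rng.normal(0.0, adv.perturb_sd)))
        return float(np.clip(out, lo, hi))

    return replace(
        base,
        amplitude=jig(base.amplitude, *adv.amp_range) if base.amplitude > 0 else base.amplitude,
        frequency=jig(base.frequency, *adv.freq_range) if base.frequency > 0 else base.frequency,
        rotation_scale=jig(base.rotation_scale, *adv.rot_range)
        if base.rotation_scale > 0
        else base.rotation_scale,
        smoothing=float(np.clip(base.smoothing + rng.normal(0.0, adv.perturb_sd / 2), 0.0, 1.0))
        if base.smoothing > 0
        else base.smoothing,
        pace_factor=jig(base.pace_factor, *adv.pace_range),
    )


def probe_success_rate(
    profile: SubjectProfile,
    classifier,
    strategy: StrategyParams,
    probe_s: float,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Fraction of probe frames on which ``strategy`` fools ``classifier``."""
    from .features import extract_dataset

    stream = simulate_deceptive(profile, strategy, probe_s, as_rng(rng))
    fs = extract_dataset([stream])
    if len(fs) == 0:
        return 0.0
    pred = classifier.predict(fs.X)
    return float(np.mean(pred != strategy.true_activity))


def adapt_strategy(
    profile: SubjectProfile,
    classifier,
    true_activity: str,
    n_candidates: int,
    probe_s: float,
    rng: np.random.Generator | int | None = None,
    adversary: AdversaryConfig | None = None,
) -> StrategyParams:
    """Search for the cheating strategy that best fools ``classifier``.

    Scores the current preferred strategy plus ``n_candidates`` sampled ones
    (perturbations of the current strategy and novel draws over the allowed
    kinds) by their success rate on a short probe stream, and returns the
    argmax; ties go to the earliest-sampled candidate, so the incumbent wins
    when nothing beats it. ``n_candidates = 0`` returns the preferred
    strategy unchanged.
    """
    if n_candidates < 0:
        raise ValueError("n_candidates must be >= 0")
    if not hasattr(classifier, "trees_") and not hasattr(classifier, "classes_"):
        raise ValueError("classifier must be trained before strategy adaptation")
    adv = adversary or AdversaryConfig()
    rng = as_rng(rng)
    kinds = adv.fake_walk_kinds if true_activity == SITTING else adv.fake_sit_kinds
    current = profile.preferred_for(true_activity)
    if current is None:
        current = _sample_novel(kinds[int(rng.integers(len(kinds)))], adv, rng)
    if n_candidates == 0:
        return current

    candidates = [current]
    for _ in range(n_candidates):
        if rng.random() < 0.5:
            candidates.append(_perturb(current, adv, rng))
        else:
            candidates.append(_sample_novel(kinds[int(rng.integers(len(kinds)))], adv, rng))

    best, best_rate = candidates[0], -1.0
    for cand in candidates:
        rate = probe_success_rate(profile, classifier, cand, probe_s, rng)
        if rate > best_rate:  # strict: ties keep the earliest
            best, best_rate = cand, rate
    return best


def with_preferred(
    profile: SubjectProfile, strategies: tuple[StrategyParams, ...]
) -> SubjectProfile:
    """Copy of ``profile`` with ``preferred_strategies`` replaced."""
    out = copy.deepcopy(profile)
    out.preferred_strategies = tuple(strategies)
    return out
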