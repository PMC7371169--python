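"""Synthetic multi-individual collar-IMU data generator.

Produces labelled 9-channel inertial streams (tri-axial acceleration in g,
tri-axial angular rate in rad/s, and roll/pitch/yaw attitude in rad) at a
fixed sampling rate for eight behaviour classes. The signal model is
deliberately simple — per-behaviour gravity baseline plus a sinusoidal
oscillation plus Gaussian noise, with transient bursts for feeding
behaviours — but it is parameterized so that:

* each individual carries a persistent signature (gait-frequency,
  amplitude and collar-orientation offsets) whose dispersion is controlled
  by a single ``individual_effect`` parameter (lambda); lambda = 0 makes
  individuals of a group statistically exchangeable;
* groups differ systematically through a body-size scale (larger bodies:
  lower stride frequency, higher amplitude) and an optional additive shift
  of the run-gait frequency.

These two knobs are what make downstream cross-validation and transfer
experiments meaningful on data that ships with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import UnknownBehaviourError, ValidationError
from .ethogram import BEHAVIOURS, PASSIVE

CHANNELS: tuple[str, ...] = (
    "ax", "ay", "az", "gx", "gy", "gz", "roll", "pitch", "yaw",
)

#: Passive behaviours must oscillate below this amplitude (g-units).
QUIESCENCE_BOUND = 0.05

# Per-unit-lambda dispersion of the individual signature draws.
FREQ_LOG_SPREAD = 0.08      # sd of log(freq_multiplier) at lambda = 1
AMP_LOG_SPREAD = 0.15       # sd of log(amplitude_multiplier) at lambda = 1
ORIENT_SPREAD = 0.25        # sd (rad) of each orientation offset at lambda = 1

_GYRO_GAIN = 2.0            # rad/s of angular rate per g of oscillation
_BURST_GAIN = 3.0           # amplitude multiplier inside a transient burst
_BURST_SLOT_S = 0.5         # burst bookkeeping granularity
_ATTITUDE_WOBBLE = 0.05     # rad, slow attitude oscillation amplitude
_ATTITUDE_RATE_HZ = 0.1     # slow attitude oscillation frequency
_ATTITUDE_NOISE = 0.01      # rad, attitude channel noise sd


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(a))
    if n == 0.0:
        raise ValidationError("gravity_orientation must be non-zero")
    a = a / n
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class BehaviourModel:
    """Signal parameters for one behaviour class."""

    behaviour_name: str
    gravity_orientation: tuple[float, float, float]
    osc_frequency: float
    osc_amplitude: tuple[float, float, float]
    noise_sd: float
    burstiness: float = 0.0

    def __post_init__(self):
        if self.behaviour_name not in BEHAVIOURS:
            raise UnknownBehaviourError(
                f"unknown behaviour {self.behaviour_name!r}; "
                f"expected one of {BEHAVIOURS}"
            )
        if abs(np.linalg.norm(self.gravity_orientation) - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.behaviour_name}: gravity_orientation must be a unit "
                f"vector (|v| = {np.linalg.norm(self.gravity_orientation)!r})"
            )
        if self.osc_frequency < 0:
            raise ValidationError("osc_frequency must be >= 0")
        if any(a < 0 for a in self.osc_amplitude):
            raise ValidationError("osc_amplitude components must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.burstiness <= 1.0:
            raise ValidationError("burstiness must lie in [0, 1]")


def default_behaviour_models() -> dict[str, BehaviourModel]:
    """The default eight-class signal registry.

    Passive postures differ mainly in collar attitude, gaits in oscillation
    frequency (walk < trot < run) and amplitude, feeding behaviours in a
    head-down attitude plus transient bursts.
    """
    return {
        "lay": BehaviourModel("lay", _unit((1.0, 0.0, 0.0)), 0.0,
                              (0.01, 0.01, 0.01), 0.02),
        "sit": BehaviourModel("sit", _unit((0.5, 0.0, math.sqrt(0.75))), 0.0,
                              (0.015, 0.015, 0.015), 0.02),
        "stand": BehaviourModel("stand", _unit((0.0, 0.0, 1.0)), 0.0,
                                (0.02, 0.02, 0.02), 0.025),
        "walk": BehaviourModel("walk", _unit((0.0, 0.0, 1.0)), 1.5,
                               (0.15, 0.10, 0.30), 0.05),
        "trot": BehaviourModel("trot", _unit((0.0, 0.0, 1.0)), 2.5,
                               (0.25, 0.15, 0.50), 0.06),
        "run": BehaviourModel("run", _unit((0.0, 0.0, 1.0)), 3.5,
                              (0.40, 0.25, 0.80), 0.08),
        "eat": BehaviourModel("eat", _unit((0.6, 0.0, 0.8)), 1.2,
                              (0.10, 0.08, 0.12), 0.05, burstiness=0.35),
        "drink": BehaviourModel("drink", _unit((0.8, 0.4, 0.45)),
                                4.0, (0.10, 0.08, 0.15), 0.03,
                                burstiness=0.20),
    }


def validate_registry(models: dict[str, BehaviourModel]) -> None:
    """Check the cross-behaviour invariants of a model registry."""
    missing = set(BEHAVIOURS) - set(models)
    if missing:
        raise ValidationError(f"registry missing behaviours: {sorted(missing)}")
    if not (models["walk"].osc_frequency
            < models["trot"].osc_frequency
            < models["run"].osc_frequency):
        raise ValidationError("gait frequencies must satisfy walk < trot < run")
    for name in PASSIVE:
        if max(models[name].osc_amplitude) >= QUIESCENCE_BOUND:
            raise ValidationError(
                f"passive behaviour {name!r} exceeds the quiescence bound "
                f"{QUIESCENCE_BOUND}"
            )


@dataclass(frozen=True)
class GroupProfile:
    """Group-level signal modifiers (body-size class)."""

    group_id: str
    size_scale: float = 1.0
    run_frequency_shift: float = 0.0

    def __post_init__(self):
        if self.size_scale <= 0:
            raise ValidationError("size_scale must be > 0")

    @property
    def frequency_factor(self) -> float:
        # larger bodies stride slower
        return self.size_scale ** -0.5

    @property
    def amplitude_factor(self) -> float:
        # ... but with larger excursions
        return self.size_scale ** 0.5


@dataclass(frozen=True)
class IndividualProfile:
    """One individual's persistent signal signature."""

    individual_id: str
    group_id: str
    freq_multiplier: float
    amplitude_multiplier: float
    orientation_offset: tuple[float, float, float]

    def __post_init__(self):
        if self.freq_multiplier <= 0 or self.amplitude_multiplier <= 0:
            raise ValidationError("profile multipliers must be > 0")


@dataclass(frozen=True)
class EthogramScript:
    """Ordered (behaviour, duration-in-seconds) schedule for one recording."""

    steps: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if not self.steps:
            raise ValidationError("script must contain at least one step")
        for name, dur in self.steps:
            if name not in BEHAVIOURS:
                raise UnknownBehaviourError(f"unknown behaviour {name!r}")
            if dur <= 0:
                raise ValidationError(f"step duration must be > 0, got {dur}")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.steps))

    @classmethod
    def uniform(cls, seconds_per_behaviour: float,
                behaviours: tuple[str, ...] = BEHAVIOURS,
                repeats: int = 1) -> "EthogramScript":
        """Equal-duration steps over the ethogram, optionally cycled.

        ``repeats > 1`` with short durations yields many short intervals,
        which decorrelates windows (at most one window per interval when
        the duration is near the clipped-window minimum).
        """
        return cls(tuple((b, float(seconds_per_behaviour))
                         for _ in range(repeats) for b in behaviours))


@dataclass(frozen=True)
class RecordingMeta:
    individual_id: str
    group_id: str
    sampling_rate: float = 50.0
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if len(self.channels) != 9:
            raise ValidationError(
                f"exactly 9 channels required, got {len(self.channels)}"
            )


@dataclass(frozen=True)
class LabelInterval:
    start_s: float
    end_s: float
    behaviour: str


@dataclass
class LabelTrack:
    """Ordered, non-overlapping half-open behaviour intervals [start, end)."""

    intervals: list[LabelInterval]

    def __post_init__(self):
        prev_end = -math.inf
        prev = None
        for iv in self.intervals:
            if iv.behaviour not in BEHAVIOURS:
                raise UnknownBehaviourError(f"unknown behaviour {iv.behaviour!r}")
            if iv.end_s <= iv.start_s:
                raise ValidationError(
                    f"empty or inverted interval [{iv.start_s}, {iv.end_s})"
                )
            if iv.start_s < prev_end - 1e-12:
                from .errors import OverlapError
                raise OverlapError(
                    f"intervals overlap: {prev} and {iv}"
                )
            prev_end = iv.end_s
            prev = iv

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def duration(self) -> float:
        return self.intervals[-1].end_s if self.intervals else 0.0


@dataclass
class InertialRecording:
    """One individual's fixed-rate 9-channel stream."""

    meta: RecordingMeta
    t: np.ndarray          # (n,) seconds
    samples: np.ndarray    # (n, 9) in CHANNELS order

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 9:
            raise ValidationError(
                f"samples must be (n, 9), got {self.samples.shape}"
            )
        if self.t.shape[0] != self.samples.shape[0]:
            raise ValidationError("t and samples lengths differ")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.meta.sampling_rate


def sample_individual_profile(
    group: GroupProfile,
    individual_effect: float,
    seed: int | np.random.SeedSequence,
    individual_id: str = "ind-00",
) -> IndividualProfile:
    """Draw an individual's signature around its group baseline.

    Multipliers are log-normal with log-scale sd proportional to
    ``individual_effect``; orientation offsets are normal with sd
    proportional to it. ``individual_effect = 0`` yields the exact group
    baseline (multipliers 1, zero offsets), making individuals exchangeable.
    """
    if individual_effect < 0:
        raise ValidationError(
            f"individual_effect must be >= 0, got {individual_effect}"
        )
    if individual_effect == 0:
        return IndividualProfile(individual_id, group.group_id, 1.0, 1.0,
                                 (0.0, 0.0, 0.0))
    rng = np.random.default_rng(seed)
    freq = float(np.exp(rng.normal(0.0, individual_effect * FREQ_LOG_SPREAD)))
    amp = float(np.exp(rng.normal(0.0, individual_effect * AMP_LOG_SPREAD)))
    off = rng.normal(0.0, individual_effect * ORIENT_SPREAD, size=3)
    return IndividualProfile(individual_id, group.group_id, freq, amp,
                             (float(off[0]), float(off[1]), float(off[2])))


def _interval_sample_bounds(start_s: float, end_s: float, rate: float,
                            n_total: int) -> tuple[int, int]:
    i0 = int(math.ceil(start_s * rate - 1e-9))
    i1 = min(int(math.ceil(end_s * rate - 1e-9)), n_total)
    return i0, i1


def _burst_envelope(n: int, rate: float, burstiness: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant amplitude envelope with random transient bursts."""
    if burstiness <= 0 or n == 0:
        return np.ones(n)
    slot = max(1, int(round(_BURST_SLOT_S * rate)))
    n_slots = int(math.ceil(n / slot))
    active = rng.random(n_slots) < burstiness
    env = np.where(np.repeat(active, slot)[:n], _BURST_GAIN, 1.0)
    return env


def generate_recording(
    profile: IndividualProfile,
    group: GroupProfile,
    script: EthogramScript,
    meta: RecordingMeta | None = None,
    seed: int | np.random.SeedSequence = 0,
    models: dict[str, BehaviourModel] | None = None,
) -> tuple[InertialRecording, LabelTrack]:
    """Synthesize one labelled recording following a behaviour script.

    Per scripted interval, acceleration = rotated gravity baseline +
    per-axis sinusoid (behaviour frequency and amplitude scaled by the
    individual and group profiles) + Gaussian noise; angular rate is the
    analogous oscillation without the gravity term; attitude channels are
    the slowly varying orientation angles plus noise. The label track tiles
    the scripted durations exactly.
    """
    if models is None:
        models = default_behaviour_models()
    validate_registry(models)
    if meta is None:
        meta = RecordingMeta(profile.individual_id, profile.group_id)
    rate = meta.sampling_rate
    n_total = int(math.floor(script.total_duration * rate + 1e-9))
    t = np.arange(n_total) / rate
    data = np.zeros((n_total, 9))
    rng = np.random.default_rng(seed)
    rot = Rotation.from_euler("xyz", profile.orientation_offset)

    intervals: list[LabelInterval] = []
    cursor = 0.0
    for name, dur in script.steps:
        start_s, end_s = cursor, cursor + dur
        cursor = end_s
        intervals.append(LabelInterval(start_s, end_s, name))
        bm = models[name]
        i0, i1 = _interval_sample_bounds(start_s, end_s, rate, n_total)
        m = i1 - i0
        if m <= 0:
            continue
        tt = t[i0:i1]

        f = bm.osc_frequency * profile.freq_multiplier * group.frequency_factor
        amp = (np.asarray(bm.osc_amplitude)
               * profile.amplitude_multiplier * group.amplitude_factor)
        if name == "run" and f > 0 and group.run_frequency_shift != 0.0:
            # the shift moves the gait along the speed continuum: dynamic
            # acceleration scales with stride frequency
            f_shifted = max(f + group.run_frequency_shift, 0.1)
            amp = amp * (f_shifted / f)
            f = f_shifted
        grav = rot.apply(np.asarray(bm.gravity_orientation))

        phases_a = rng.uniform(0.0, 2.0 * np.pi, 3)
        phases_g = rng.uniform(0.0, 2.0 * np.pi, 3)
        phase_att = rng.uniform(0.0, 2.0 * np.pi, 3)
        env = _burst_envelope(m, rate, bm.burstiness, rng)

        osc = np.sin(2.0 * np.pi * f * tt[:, None] + phases_a[None, :])
        acc = (grav[None, :]
               + amp[None, :] * osc * env[:, None]
               + rng.normal(0.0, bm.noise_sd, (m, 3)))

        osc_g = np.sin(2.0 * np.pi * f * tt[:, None] + phases_g[None, :])
        gyro = (_GYRO_GAIN * amp[None, :] * osc_g * env[:, None]
                + rng.normal(0.0, _GYRO_GAIN * bm.noise_sd, (m, 3)))

        # attitude: Euler angles of the collar baseline, slowly wobbling
        gx, gy, gz = grav
        roll = math.atan2(gy, gz)
        pitch = -math.asin(min(1.0, max(-1.0, gx)))
        yaw = float(profile.orientation_offset[2])
        base = np.array([roll, pitch, yaw])
        wobble = _ATTITUDE_WOBBLE * np.sin(
            2.0 * np.pi * _ATTITUDE_RATE_HZ * tt[:, None] + phase_att[None, :]
        )
        att = (base[None, :] + wobble
               + rng.normal(0.0, _ATTITUDE_NOISE, (m, 3)))

        data[i0:i1, 0:3] = acc
        data[i0:i1, 3:6] = gyro
        data[i0:i1, 6:9] = att

    return InertialRecording(meta, t, data), LabelTrack(intervals)


def generate_cohort(
    n_individuals: int,
    group: GroupProfile,
    script: EthogramScript,
    individual_effect: float = 0.5,
    seed: int = 0,
    models: dict[str, BehaviourModel] | None = None,
    sampling_rate: float = 50.0,
) -> list[tuple[InertialRecording, LabelTrack]]:
    """Generate one recording per individual for a group.

    Per-individual seeds are spawned hierarchically from the master seed, so
    the cohort is reproducible and profile draws are independent of signal
    noise draws.
    """
    if n_individuals < 2:
        raise ValidationError(
            "n_individuals must be >= 2 (per-individual cross-validation "
            f"needs at least two individuals), got {n_individuals}"
        )
    master = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(master.spawn(n_individuals)):
        profile_seed, signal_seed = child.spawn(2)
        ind_id = f"{group.group_id}-{i:02d}"
        profile = sample_individual_profile(group, individual_effect,
                                            profile_seed, ind_id)
        meta = RecordingMeta(ind_id, group.group_id, sampling_rate)
        out.append(generate_recording(profile, group, script, meta,
                                      signal_seed, models))
    return out
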