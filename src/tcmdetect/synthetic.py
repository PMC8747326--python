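"""Synthetic tri-axial accelerometer recordings of low-back-pain exercises.

The generator emulates the structure of the study recordings so the whole
analysis pipeline is testable without the (request-only) original dataset:
three spine-mounted sensors (L5/S1, Th1/C7, back of head), 200 Hz sampling,
12-bit quantization, a push-button marker channel, and for every exercise a
clinically prescribed execution (CPE) and one typical compensatory movement
(TCM).

Kinematics are deliberately simple: each sensor follows a parametric
tilt-angle trajectory (raised-cosine pulse per repetition) which is projected
onto the sensor axes through gravity, ``A_X = g sin(phi)``, ``A_Z = g
cos(phi)`` (tilt confined to the sagittal X-Z plane).  Small common-mode
oscillations, per-subject mounting offsets and sensor noise provide the
nuisance variability; the TCM category adds exercise-specific effect terms:

* Prone-Rocking TCM — twist around the longitudinal spine axis, expressed as
  a lateral oscillation on sensor 2's Y axis (raises ``var_Y2``).
* Bird-Dog TCM — upward head tilt with lumbar extension: stronger head-bob
  modulation on sensor 3's Z axis (raises ``var_Z3``) and a lumbar tilt
  offset on sensor 1 (shifts ``phiRMS_1``).
* Rowing TCM — rounding of the lower back via posterior pelvic tilt: a
  sensor-1 vs sensor-2 tilt divergence (raises ``maxdphi_1_2``) and extra
  head Z activity (raises ``aRMS_Z3``).

All randomness flows from explicit seeds; identical seeds give identical
recordings bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRAVITY",
    "TiltWaveform",
    "AxisEffect",
    "ExerciseSpec",
    "SensorModel",
    "SubjectProfile",
    "SessionRecording",
    "DEFAULT_EXERCISES",
    "default_exercise",
    "simulate_repetition",
    "generate_session",
    "generate_cohort",
]

GRAVITY = 9.81  # m s^-2

EXERCISE_NAMES = ("prone_rocking", "bird_dog", "rowing")
CATEGORIES = ("CPE", "TCM")
AXES = ("X", "Y", "Z")


@dataclass(frozen=True)
class TiltWaveform:
    """Parametric tilt trajectory of one sensor over a repetition.

    ``phi(u) = baseline + amplitude * (1 - cos(2*pi*u)) / 2`` for normalized
    repetition time ``u`` in [0, 1]: the sensor starts at its baseline tilt,
    peaks mid-repetition and returns.
    """

    baseline_deg: float
    amplitude_deg: float

    def angles(self, u: np.ndarray) -> np.ndarray:
        return self.baseline_deg + self.amplitude_deg * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


@dataclass(frozen=True)
class AxisEffect:
    """One additive effect term, applied to tilt or to a raw axis channel.

    kind:
      ``tilt_offset``  — constant tilt shift (deg) on ``sensor``;
      ``tilt_pulse``   — extra raised-cosine tilt excursion (deg);
      ``axis_osc``     — sinusoidal acceleration (m s^-2) on ``axis`` of
                         ``sensor``, ``cycles`` periods per repetition.
    """

    sensor: int  # 1..3
    kind: str  # tilt_offset | tilt_pulse | axis_osc
    amplitude: float
    axis: str | None = None  # for axis_osc
    cycles: float = 2.0
    #: oscillations get a fresh random phase and a frequency jitter factor
    #: drawn from U(1-cycle_jitter, 1+cycle_jitter) for every repetition, so
    #: repetition averaging attenuates them and their waveform shape varies
    #: between sets (shape statistics stay noisy within a category)
    cycle_jitter: float = 0.3

    def __post_init__(self):
        if self.sensor not in (1, 2, 3):
            raise ValueError(f"sensor must be 1..3, got {self.sensor}")
        if self.kind not in ("tilt_offset", "tilt_pulse", "axis_osc"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "axis_osc" and self.axis not in AXES:
            raise ValueError("axis_osc requires axis in X/Y/Z")

    def scaled(self, factor: float) -> "AxisEffect":
        return replace(self, amplitude=self.amplitude * factor)


@dataclass(frozen=True)
class ExerciseSpec:
    """Generative description of one exercise.

    ``tilt_waveforms`` has one entry per sensor (1..3).  ``common_effects``
    apply to both categories (baseline movement texture); ``tcm_effects``
    only to the TCM category.  With all TCM amplitudes zero, CPE and TCM are
    generatively identical.
    """

    name: str
    rep_duration_mean: float  # s
    rep_duration_cv: float
    tilt_waveforms: tuple[TiltWaveform, TiltWaveform, TiltWaveform]
    tcm_effects: tuple[AxisEffect, ...] = ()
    common_effects: tuple[AxisEffect, ...] = ()

    def __post_init__(self):
        if self.rep_duration_mean <= 0:
            raise ValueError("rep_duration_mean must be positive")
        if self.rep_duration_cv < 0:
            raise ValueError("rep_duration_cv must be non-negative")
        if len(self.tilt_waveforms) != 3:
            raise ValueError("exactly one tilt waveform per sensor is required")

    def with_effect_scale(self, scale: float) -> "ExerciseSpec":
        if scale < 0:
            raise ValueError("effect scale must be non-negative")
        return replace(self, tcm_effects=tuple(e.scaled(scale) for e in self.tcm_effects))


@dataclass(frozen=True)
class SensorModel:
    """Accelerometer front-end: sampling, quantization and noise."""

    sampling_rate: float = 200.0  # Hz
    resolution_bits: int = 12
    full_scale: float = 4.0 * GRAVITY  # m s^-2 (+-4 g default)
    noise_sd: float = 0.15  # m s^-2

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.full_scale <= 0:
            raise ValueError("sampling_rate and full_scale must be positive")
        if self.resolution_bits < 2:
            raise ValueError("resolution_bits must be at least 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def lsb(self) -> float:
        """Quantization step (m s^-2)."""
        return 2.0 * self.full_scale / (2**self.resolution_bits)

    def quantize(self, a: np.ndarray) -> np.ndarray:
        """Map to the 2^bits signed quantizer levels, clipping out of range."""
        half = 2 ** (self.resolution_bits - 1)
        idx = np.clip(np.round(a / self.lsb), -half, half - 1)
        return idx * self.lsb


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject nuisance parameters, shared across that subject's sets.

    ``tilt_offsets_deg`` — per-sensor constant tilt offsets (posture /
    mounting pitch); ``y_offsets`` — gravity leakage into Y from mounting
    roll (m s^-2); multipliers rescale movement amplitude, repetition
    tempo and TCM effect magnitude.
    """

    tilt_offsets_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    y_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amplitude_factor: float = 1.0
    speed_factor: float = 1.0
    tcm_factor: float = 1.0

    @classmethod
    def draw(cls, rng: np.random.Generator) -> "SubjectProfile":
        # the movement excursion (amplitude_factor) varies a lot between
        # subjects and is common to all sensors: the back moves as a unit,
        # so single-sensor amplitude statistics are subject-confounded while
        # between-sensor tilt differences are not
        # tilt offsets = shared postural part + smaller per-sensor mounting
        # part: posture shifts all sensors together and cancels in tilt
        # differences, mounting scatter does not
        common = rng.normal(0.0, 3.0)
        per_sensor = rng.normal(0.0, 1.5, size=3)
        return cls(
            tilt_offsets_deg=tuple(common + per_sensor),
            y_offsets=tuple(rng.normal(0.0, 0.6, size=3)),
            amplitude_factor=float(np.exp(rng.normal(0.0, 0.30))),
            speed_factor=float(np.exp(rng.normal(0.0, 0.10))),
            tcm_factor=float(np.exp(rng.normal(0.0, 0.20))),
        )


CHANNEL_NAMES = tuple(f"s{s}_a{ax.lower()}" for s in (1, 2, 3) for ax in AXES)


@dataclass
class SessionRecording:
    """One subject x exercise x category x set: 9 channels + markers.

    ``channels`` is a (9, n) array ordered sensor-major (s1_ax..s3_az);
    ``markers`` holds sample indices of the push-button events: set start
    plus one after each repetition (7 for a 6-repetition set).
    """

    subject_id: str
    exercise: str
    category: str
    set_index: int
    sampling_rate: float
    channels: np.ndarray
    markers: np.ndarray
    side: str | None = None  # bird-dog left/right when kept separate

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        self.markers = np.asarray(self.markers, dtype=np.int64)
        if self.channels.ndim != 2 or self.channels.shape[0] != 9:
            raise ValueError("channels must be a (9, n) array")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be CPE or TCM, got {self.category!r}")
        if np.any(np.diff(self.markers) <= 0):
            raise ValueError("markers must be strictly increasing")
        if self.markers.size and (self.markers[0] < 0 or self.markers[-1] > self.n_samples):
            raise ValueError("markers outside signal range")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    def sensor_block(self, sensor: int) -> np.ndarray:
        """(3, n) X/Y/Z block of one sensor (1..3)."""
        return self.channels[3 * (sensor - 1) : 3 * sensor]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.sampling_rate
        marker = np.zeros(self.n_samples, dtype=np.int64)
        marker[self.markers[self.markers < self.n_samples]] = 1
        data = {"time_s": t}
        data.update({name: self.channels[i] for i, name in enumerate(CHANNEL_NAMES)})
        data["marker"] = marker
        return pd.DataFrame(data)


def _pulse(u: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _default_exercises() -> dict[str, ExerciseSpec]:
    deg = TiltWaveform
    osc = AxisEffect
    return {
        "prone_rocking": ExerciseSpec(
            name="prone_rocking",
            rep_duration_mean=3.0,
            rep_duration_cv=0.15,
            tilt_waveforms=(deg(15.0, 35.0), deg(20.0, 25.0), deg(60.0, 20.0)),
            common_effects=(
                osc(1, "axis_osc", 0.3, axis="Y", cycles=1.0),
                osc(2, "axis_osc", 0.3, axis="Y", cycles=1.0),
                osc(3, "axis_osc", 0.3, axis="Y", cycles=1.0),
            ),
            tcm_effects=(
                # longitudinal-spine twist: lateral sway strongest mid-spine
                osc(2, "axis_osc", 1.6, axis="Y", cycles=2.0),
                osc(1, "axis_osc", 0.5, axis="Y", cycles=2.0),
            ),
        ),
        "bird_dog": ExerciseSpec(
            name="bird_dog",
            rep_duration_mean=4.0,
            rep_duration_cv=0.15,
            tilt_waveforms=(deg(20.0, 8.0), deg(15.0, 10.0), deg(70.0, 2.5)),
            common_effects=(
                osc(3, "axis_osc", 0.3, axis="Z", cycles=1.0),
                osc(1, "axis_osc", 0.2, axis="Y", cycles=1.0),
                osc(2, "axis_osc", 0.2, axis="Y", cycles=1.0),
            ),
            tcm_effects=(
                # head tilt-up: head-bob on sensor-3 Z plus a hollow-back
                # posture that tilts the whole spine (all sensors ride
                # along, so tilt differences cancel but phiRMS shifts)
                osc(3, "axis_osc", 2.8, axis="Z", cycles=2.0),
                osc(1, "tilt_offset", 8.0),
                osc(2, "tilt_offset", 8.0),
                osc(3, "tilt_offset", 8.0),
            ),
        ),
        "rowing": ExerciseSpec(
            name="rowing",
            rep_duration_mean=2.5,
            rep_duration_cv=0.15,
            tilt_waveforms=(deg(55.0, 10.0), deg(50.0, 12.0), deg(40.0, 8.0)),
            common_effects=(
                osc(3, "axis_osc", 0.3, axis="Z", cycles=1.0),
                osc(1, "axis_osc", 0.2, axis="Y", cycles=1.0),
                osc(2, "axis_osc", 0.2, axis="Y", cycles=1.0),
            ),
            tcm_effects=(
                # posterior pelvic tilt: lumbar sensor diverges from upper back
                osc(1, "tilt_pulse", 18.0),
                osc(3, "axis_osc", 1.0, axis="Z", cycles=2.0),
            ),
        ),
    }


DEFAULT_EXERCISES: dict[str, ExerciseSpec] = _default_exercises()


def default_exercise(name: str) -> ExerciseSpec:
    try:
        return DEFAULT_EXERCISES[name]
    except KeyError:
        raise ValueError(
            f"unknown exercise {name!r}; expected one of {sorted(DEFAULT_EXERCISES)}"
        ) from None


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_repetition(
    spec: ExerciseSpec,
    category: str,
    duration: float,
    sensor_model: SensorModel | None = None,
    rng_seed=0,
    profile: SubjectProfile | None = None,
    mirror: bool = False,
) -> np.ndarray:
    """Simulate one repetition; returns a (9, n) acceleration array.

    The tilt trajectory of each sensor is evaluated on normalized repetition
    time, projected through gravity onto the X/Z axes, effect terms and the
    subject's mounting offsets are added, then Gaussian noise and 12-bit
    quantization are applied.  ``mirror`` flips lateral (Y) components for
    the mirrored side of bird-dog.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if category not in CATEGORIES:
        raise ValueError(f"category must be CPE or TCM, got {category!r}")
    sensor_model = sensor_model or SensorModel()
    profile = profile or SubjectProfile()
    rng = _as_rng(rng_seed)

    n = max(int(round(duration * sensor_model.sampling_rate)), 2)
    u = (np.arange(n) + 0.5) / n

    # phase/frequency parameters are drawn for every effect in a fixed,
    # category-independent order so that CPE and TCM recordings with the
    # same seed differ only through the applied TCM effect terms (and are
    # bit-identical when all TCM amplitudes are zero)
    all_effects = list(spec.common_effects) + list(spec.tcm_effects)
    params = []
    for e in all_effects:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        jitter = rng.uniform(1.0 - e.cycle_jitter, 1.0 + e.cycle_jitter)
        params.append((phase, jitter))
    effects: list[tuple[AxisEffect, float, float]] = []
    for e, (phase, jitter) in zip(spec.common_effects, params):
        effects.append((e, phase, jitter))
    if category == "TCM":
        for e, (phase, jitter) in zip(spec.tcm_effects, params[len(spec.common_effects):]):
            scale = profile.tcm_factor
            if e.kind == "tilt_pulse":
                # a compensatory excursion scales with the subject's overall
                # movement excursion, like the prescribed movement does
                scale *= profile.amplitude_factor
            effects.append((e.scaled(scale), phase, jitter))

    channels = np.empty((9, n), dtype=float)
    for s in (1, 2, 3):
        wf = spec.tilt_waveforms[s - 1]
        phi = (
            wf.baseline_deg
            + profile.tilt_offsets_deg[s - 1]
            + profile.amplitude_factor * wf.amplitude_deg * _pulse(u)
        )
        for e, _phase, _jitter in effects:
            if e.sensor != s:
                continue
            if e.kind == "tilt_offset":
                phi = phi + e.amplitude
            elif e.kind == "tilt_pulse":
                phi = phi + e.amplitude * _pulse(u)
        phi_rad = np.deg2rad(phi)
        ax = GRAVITY * np.sin(phi_rad)
        ay = np.full(n, profile.y_offsets[s - 1])
        az = GRAVITY * np.cos(phi_rad)
        for e, phase, jitter in effects:
            if e.sensor == s and e.kind == "axis_osc":
                wave = e.amplitude * np.sin(2.0 * np.pi * e.cycles * jitter * u + phase)
                if e.axis == "X":
                    ax = ax + wave
                elif e.axis == "Y":
                    ay = ay + wave
                else:
                    az = az + wave
        if mirror:
            ay = -ay
        base = 3 * (s - 1)
        channels[base], channels[base + 1], channels[base + 2] = ax, ay, az

    if sensor_model.noise_sd > 0:
        channels = channels + rng.normal(0.0, sensor_model.noise_sd, size=channels.shape)
    else:
        # keep the stream position independent of noise_sd so that seeded
        # comparisons across settings stay aligned
        rng.normal(0.0, 1.0, size=channels.shape)
    return sensor_model.quantize(channels)


#: idle padding (s) before the first and after the last repetition, so the
#: final push-button event falls on a real sample row
_PAD_S = 0.25
_REPS_PER_SET = 6


def _rep_durations(spec: ExerciseSpec, n_reps: int, rng: np.random.Generator,
                   speed_factor: float = 1.0) -> np.ndarray:
    mean = spec.rep_duration_mean * speed_factor
    cv = spec.rep_duration_cv
    if cv == 0:
        return np.full(n_reps, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n_reps)


def generate_session(
    subject_id: str,
    spec: ExerciseSpec,
    category: str,
    set_index: int,
    sensor_model: SensorModel | None = None,
    rng_seed=0,
    profile: SubjectProfile | None = None,
    side: str | None = None,
) -> SessionRecording:
    """Generate one set: 6 repetitions with log-normal durations + markers.

    Markers are placed at the set start and after each repetition (7 events
    for 6 repetitions), exactly at the repetition boundaries.
    """
    if set_index < 1 or set_index > 3:
        raise ValueError("set_index must be in 1..3")
    sensor_model = sensor_model or SensorModel()
    profile = profile or SubjectProfile()
    rng = _as_rng(rng_seed)

    # day-to-day variation: the whole set is performed a little larger or
    # smaller than the subject's habitual excursion
    set_amp = float(np.exp(rng.normal(0.0, 0.15)))
    profile = replace(profile, amplitude_factor=profile.amplitude_factor * set_amp)
    durations = _rep_durations(spec, _REPS_PER_SET, rng, profile.speed_factor)
    mirror = side == "right"
    reps = [
        simulate_repetition(spec, category, d, sensor_model, rng, profile, mirror=mirror)
        for d in durations
    ]
    n_pad = int(round(_PAD_S * sensor_model.sampling_rate))
    # hold the start/end posture during the idle padding
    pre = np.repeat(reps[0][:, :1], n_pad, axis=1)
    post = np.repeat(reps[-1][:, -1:], n_pad, axis=1)
    channels = np.concatenate([pre] + reps + [post], axis=1)
    lengths = np.array([r.shape[1] for r in reps])
    markers = n_pad + np.concatenate([[0], np.cumsum(lengths)])
    return SessionRecording(
        subject_id=subject_id,
        exercise=spec.name,
        category=category,
        set_index=set_index,
        sampling_rate=sensor_model.sampling_rate,
        channels=channels,
        markers=markers,
        side=side,
    )


def generate_cohort(
    n_subjects: int = 30,
    exercises: Sequence[str | ExerciseSpec] | None = None,
    sensor_model: SensorModel | None = None,
    effect_scale: float = 1.0,
    master_seed: int = 0,
    keep_sides: bool = False,
) -> tuple[list[SessionRecording], pd.DataFrame]:
    """Generate a full cohort and its manifest.

    For every exercise each subject performs 3 sets of both categories, so a
    30-subject cohort yields 180 recordings per exercise.  Bird-dog is
    performed on both body sides; by default the sides are collapsed into
    the single ``bird_dog`` label with 3 sets per category (the mirrored
    side only flips lateral components, which the downstream features are
    insensitive to).  With ``keep_sides=True`` the sides become the separate
    exercises ``bird_dog_left``/``bird_dog_right`` — then a subject performs
    24 sets in total across the 4 counted exercises.

    Per-subject random offsets (posture, mounting, tempo, effect magnitude)
    induce between-subject variability; ``effect_scale`` multiplies every
    TCM effect amplitude (0 makes the categories generatively identical).

    Returns the recordings and a manifest DataFrame (file, subject,
    exercise, category, set, side).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    if exercises is None:
        exercises = list(EXERCISE_NAMES)
    if len(exercises) == 0:
        raise ValueError("exercise list must not be empty")
    specs: list[ExerciseSpec] = [
        e if isinstance(e, ExerciseSpec) else default_exercise(e) for e in exercises
    ]
    specs = [s.with_effect_scale(effect_scale) for s in specs]
    sensor_model = sensor_model or SensorModel()

    root_ss = np.random.SeedSequence(master_seed)
    subject_ss = root_ss.spawn(n_subjects)
    recordings: list[SessionRecording] = []
    rows = []
    for i in range(n_subjects):
        subject_id = f"S{i + 1:02d}"
        profile_ss, session_ss = subject_ss[i].spawn(2)
        profile = SubjectProfile.draw(np.random.default_rng(profile_ss))
        stream = np.random.default_rng(session_ss)
        for spec in specs:
            sides: list[str | None]
            if spec.name == "bird_dog" and keep_sides:
                sides = ["left", "right"]
            else:
                sides = [None]
            for side in sides:
                for category in CATEGORIES:
                    for set_index in (1, 2, 3):
                        seed = int(stream.integers(0, 2**31 - 1))
                        rec = generate_session(
                            subject_id, spec, category, set_index,
                            sensor_model, seed, profile, side=side,
                        )
                        if side is not None:
                            rec.exercise = f"{spec.name}_{side}"
                        recordings.append(rec)
                        rows.append(
                            {
                                "file": f"{subject_id}_{rec.exercise}_{category}_set{set_index}.csv",
                                "subject_id": subject_id,
                                "exercise": rec.exercise,
                                "category": category,
                                "set_index": set_index,
                                "side": side or "",
                            }
                        )
    manifest = pd.DataFrame(rows)
    return recordings, manifest
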