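"""Seeded synthetic sEMG generator for the six-channel forearm montage.

The signal model is the standard surrogate for surface EMG: amplitude-
modulated band-limited Gaussian noise.  Per channel, a zero-mean carrier
band-passed to ~20-450 Hz is multiplied by ``channel_gain * activation`` and
summed with an independent noise floor.  Activation traces come from commanded
(motion class, intensity) sequences via a per-profile synergy matrix, smoothed
by a 100 ms first-order lag that stands in for electromechanical low-pass
behaviour — fast enough to follow intent, slow enough that the 2 Hz envelope
filter sees realistic dynamics.

Two subject profiles are built in.  ``healthy`` has distinct, mostly
independent channel synergies.  ``dmd`` emulates the qualitative sEMG changes
reported in advanced Duchenne muscular dystrophy — much lower absolute
amplitude and less independent muscle activation — as channel gains scaled to
0.35x healthy and a crosstalk coefficient of 0.5 (vs 0.1), plus a seventh
``trigger`` channel (gastrocnemius switch electrode) driven only by discrete
switch commands.  The ratios are free parameters of the generator, not
estimates of any individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .mapping import MOTION_CLASSES, MotionClass
from .recording import FOREARM_ROLES, TRIGGER_ROLE, EmgRecording

# channel order used throughout the generator
CHANNEL_ORDER = ("fcu", "ecu", "mid1", "mid2", "mid3", "mid4")

# synergy matrix rows = channels (CHANNEL_ORDER), cols = MOTION_CLASSES
# (HAND_OPEN, HAND_CLOSE, WRIST_FLEXION, WRIST_EXTENSION, NO_MOTION)
_HEALTHY_SYNERGY = np.array(
    [
        # open  close  flex   ext    rest
        [0.15, 0.30, 0.95, 0.05, 0.0],  # fcu
        [0.30, 0.15, 0.05, 0.95, 0.0],  # ecu
        [0.85, 0.10, 0.30, 0.25, 0.0],  # mid1
        [0.70, 0.25, 0.10, 0.40, 0.0],  # mid2
        [0.10, 0.85, 0.35, 0.15, 0.0],  # mid3
        [0.25, 0.70, 0.45, 0.10, 0.0],  # mid4
    ]
)

# pseudo-commands the virtual user can issue besides motion classes
SWITCH_COMMAND = "cocontraction"
TRIGGER_COMMAND = "trigger"


@dataclass(frozen=True)
class SubjectProfile:
    """Statistical description of one simulated subject's sEMG."""

    cohort: str  # "healthy" | "dmd"
    channel_gain: np.ndarray = field(hash=False)  # mV at full activation, 6-vector
    synergy: np.ndarray = field(hash=False)  # [6 x 5] weights in [0, 1]
    noise_floor: float = 0.02  # mV RMS per channel
    crosstalk: float = 0.1
    trigger_gain: float = 0.0  # mV; > 0 adds a trigger channel
    carrier_band: tuple[float, float] = (20.0, 450.0)
    activation_lag_s: float = 0.100

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_gain", np.asarray(self.channel_gain, float))
        object.__setattr__(self, "synergy", np.asarray(self.synergy, float))
        if self.channel_gain.shape != (6,):
            raise ValueError("channel_gain must be a 6-vector")
        if self.synergy.shape != (6, len(MOTION_CLASSES)):
            raise ValueError("synergy must be [6 channels x 5 classes]")
        if np.any((self.synergy < 0) | (self.synergy > 1)):
            raise ValueError("synergy weights must lie in [0, 1]")
        if not 0 <= self.crosstalk < 1:
            raise ValueError("crosstalk must lie in [0, 1)")

    @property
    def has_trigger(self) -> bool:
        return self.trigger_gain > 0

    @property
    def channel_roles(self) -> tuple[str, ...]:
        roles = CHANNEL_ORDER
        return roles + (TRIGGER_ROLE,) if self.has_trigger else roles

    @property
    def n_channels(self) -> int:
        return 7 if self.has_trigger else 6

    def activation_for(self, command: MotionClass | str) -> np.ndarray:
        """Per-channel activation pattern (unit intensity) for a command.

        Motion classes mix their synergy column with crosstalk-scaled mean
        activity of the other moving classes; the co-contraction pseudo-command
        drives the flexion+extension columns together; the trigger
        pseudo-command drives only the trigger channel.
        """
        n = self.n_channels
        act = np.zeros(n)
        if command == TRIGGER_COMMAND:
            if not self.has_trigger:
                raise ValueError("profile has no trigger channel")
            act[-1] = 1.0
            return act
        if command == SWITCH_COMMAND:
            flex = self.synergy[:, MOTION_CLASSES.index(MotionClass.WRIST_FLEXION)]
            ext = self.synergy[:, MOTION_CLASSES.index(MotionClass.WRIST_EXTENSION)]
            act[:6] = np.clip(flex + ext, 0.0, 1.0)
            return act
        cls_idx = MOTION_CLASSES.index(command)
        if command is MotionClass.NO_MOTION:
            return act
        own = self.synergy[:, cls_idx]
        moving = [
            i
            for i, c in enumerate(MOTION_CLASSES)
            if c is not MotionClass.NO_MOTION and i != cls_idx
        ]
        other = self.synergy[:, moving].mean(axis=1)
        act[:6] = np.clip(own + self.crosstalk * other, 0.0, 1.0)
        return act


def healthy_profile() -> SubjectProfile:
    return SubjectProfile(
        cohort="healthy",
        channel_gain=np.array([1.0, 1.1, 0.9, 0.95, 1.05, 0.85]),
        synergy=_HEALTHY_SYNERGY,
        crosstalk=0.1,
        noise_floor=0.02,
    )


def dmd_profile() -> SubjectProfile:
    """Reduced-amplitude, high-crosstalk profile with a trigger channel."""
    h = healthy_profile()
    return replace(
        h,
        cohort="dmd",
        channel_gain=0.35 * h.channel_gain,
        crosstalk=0.5,
        trigger_gain=0.8,
    )


def get_profile(cohort: str) -> SubjectProfile:
    if cohort == "healthy":
        return healthy_profile()
    if cohort == "dmd":
        return dmd_profile()
    raise KeyError(f"unknown cohort '{cohort}'")


@dataclass
class ActivationTrace:
    """Per-channel activation in [0, 1] sampled at fs, with provenance."""

    values: np.ndarray  # [n_channels x n_samples]
    fs: float
    commands: list = field(default_factory=list)  # (t_start_s, command, intensity)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("activation must lie in [0, 1]")


def _lag_alpha(fs: float, lag_s: float) -> float:
    return 1.0 - np.exp(-1.0 / (fs * lag_s))


def activation_from_intent(
    commands: list[tuple[float, MotionClass | str, float]],
    profile: SubjectProfile,
    fs: float,
    duration_s: float,
) -> ActivationTrace:
    """Turn a timed (start_s, command, intensity) list into activation traces.

    Each command holds from its start time until the next command (or the end
    of the trace).  The raw piecewise-constant target is smoothed by the
    profile's first-order activation lag.
    """
    n = int(round(duration_s * fs))
    target = np.zeros((profile.n_channels, n))
    ordered = sorted(commands, key=lambda c: c[0])
    for i, (t0, command, intensity) in enumerate(ordered):
        if not 0.0 <= intensity <= 1.0:
            raise ValueError("command intensity must lie in [0, 1]")
        i0 = int(round(t0 * fs))
        i1 = n if i == len(ordered) - 1 else int(round(ordered[i + 1][0] * fs))
        if i0 >= i1:
            continue
        target[:, i0:i1] = (profile.activation_for(command) * intensity)[:, None]
    alpha = _lag_alpha(fs, profile.activation_lag_s)
    smoothed = np.empty_like(target)
    state = np.zeros(profile.n_channels)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    smoothed = sps.lfilter(b, a, target, axis=-1)
    return ActivationTrace(values=np.clip(smoothed, 0.0, 1.0), fs=fs, commands=ordered)


def _carrier_sos(profile: SubjectProfile, fs: float) -> np.ndarray:
    lo, hi = profile.carrier_band
    hi = min(hi, 0.475 * fs)  # keep below Nyquist for low-fs fixtures
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


class EmgSynthesizer:
    """Streaming renderer: activation chunks -> raw sEMG chunks.

    Keeps band-pass filter state and a seeded generator so that rendering in
    chunks of any size is reproducible and continuous.
    """

    def __init__(self, profile: SubjectProfile, fs: float, seed: int):
        self.profile = profile
        self.fs = fs
        self.rng = np.random.default_rng(seed)
        self._sos = _carrier_sos(profile, fs)
        n = profile.n_channels
        self._zi = np.zeros((self._sos.shape[0], n, 2))
        self._gains = np.concatenate(
            [profile.channel_gain, [profile.trigger_gain]]
            if profile.has_trigger
            else [profile.channel_gain]
        )

    def render(self, activation: np.ndarray) -> np.ndarray:
        """Render one [n_channels x n] activation chunk to raw sEMG (mV)."""
        activation = np.atleast_2d(activation)
        n_ch, n = activation.shape
        white = self.rng.standard_normal((n_ch, n))
        carrier, self._zi = sps.sosfilt(self._sos, white, axis=-1, zi=self._zi)
        floor = self.profile.noise_floor * self.rng.standard_normal((n_ch, n))
        return carrier * self._gains[:, None] * activation + floor


def render_emg(
    trace: ActivationTrace, profile: SubjectProfile, seed: int
) -> EmgRecording:
    """Render a full activation trace into a raw sEMG recording."""
    synth = EmgSynthesizer(profile, trace.fs, seed)
    samples = synth.render(trace.values)
    return EmgRecording(
        samples=samples,
        fs=trace.fs,
        channel_roles=profile.channel_roles,
        subject_profile_id=profile.cohort,
    )


# ------------------------------------------------------------- calibration


@dataclass
class CalibrationKit:
    """Everything needed to calibrate and train one simulated subject."""

    rest: EmgRecording
    mvc: EmgRecording
    training: dict[MotionClass, list[EmgRecording]]


def _mvc_commands(profile: SubjectProfile) -> list[tuple[float, str, float]]:
    return [(0.0, SWITCH_COMMAND, 1.0)]


def make_calibration_kit(
    profile: SubjectProfile,
    seed: int,
    fs: float = 1000.0,
    rest_s: float = 4.0,
    mvc_s: float = 4.0,
    rep_s: float = 2.0,
    n_reps: int = 5,
    training_intensities: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.6),
) -> CalibrationKit:
    """Generate rest, MVC and per-class training recordings.

    Rest is silence; MVC is full-intensity co-activation of the antagonist
    pair (with the trigger channel driven too, on profiles that have one) so
    every channel reaches a high envelope; training is five comfortable 2 s
    repetitions per motion class, at naturally varying effort (0.5-0.8) the
    way repeated "comfortable" contractions come out in practice — which also
    teaches the classifier some amplitude invariance.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 + n_reps * len(MOTION_CLASSES))

    rest_trace = activation_from_intent(
        [(0.0, MotionClass.NO_MOTION, 0.0)], profile, fs, rest_s
    )
    rest = render_emg(rest_trace, profile, int(seeds[0]))

    # MVC: co-contraction pattern, plus the trigger channel at full drive
    mvc_trace = activation_from_intent(_mvc_commands(profile), profile, fs, mvc_s)
    if profile.has_trigger:
        trig = activation_from_intent(
            [(0.0, TRIGGER_COMMAND, 1.0)], profile, fs, mvc_s
        )
        mvc_trace.values[-1] = trig.values[-1]
    mvc = render_emg(mvc_trace, profile, int(seeds[1]))

    training: dict[MotionClass, list[EmgRecording]] = {}
    k = 2
    for cls in MOTION_CLASSES:
        reps = []
        for r in range(n_reps):
            intensity = training_intensities[r % len(training_intensities)]
            trace = activation_from_intent(
                [(0.0, cls, intensity)], profile, fs, rep_s
            )
            reps.append(render_emg(trace, profile, int(seeds[k])))
            k += 1
        training[cls] = reps
    return CalibrationKit(rest=rest, mvc=mvc, training=training)
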