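"""Envelope extraction and MVC calibration for raw sEMG.

The pipeline is the standard proportional-myocontrol chain: a causal
second-order Butterworth high-pass at 20 Hz (movement-artifact removal),
full-wave rectification, and a causal fourth-order Butterworth low-pass at
2 Hz, which yields a slowly varying amplitude envelope.  Calibration reduces
a rest recording and a maximum-voluntary-contraction (MVC) recording to
per-channel baseline and MVC envelope levels; controllers normalise to these.

All filtering is forward-only (never zero-phase): the controllers this feeds
are real-time, so the offline path must be sample-for-sample identical to a
streaming one.  Both entry styles are provided — one-shot arrays and stateful
streaming via :class:`StreamingPipeline`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import EmgRecording, TRIGGER_ROLE

HP_CUTOFF_HZ = 20.0
HP_ORDER = 2
LP_CUTOFF_HZ = 2.0
LP_ORDER = 4

MVC_SEGMENT_S = 3.0
REST_SEGMENT_S = 3.0


@dataclass
class EnvelopeSeries:
    """Non-negative sEMG amplitude envelopes, same sampling rate as the source."""

    values: np.ndarray  # [n_channels x n_samples], mV, >= 0
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass
class CalibrationProfile:
    """Per-channel rest and MVC envelope levels, in mV.

    ``mvc_mean_env`` is the arithmetic mean of the six forearm channels' MVC
    envelopes and is the normaliser for the pattern-recognition proportional
    signal; the trigger channel (if any) is excluded from it.
    """

    rest_env: np.ndarray
    mvc_env: np.ndarray
    channel_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        self.rest_env = np.asarray(self.rest_env, dtype=float)
        self.mvc_env = np.asarray(self.mvc_env, dtype=float)
        self.channel_roles = tuple(self.channel_roles)
        if self.rest_env.shape != self.mvc_env.shape:
            raise ValueError("rest_env and mvc_env must have matching shapes")
        if len(self.channel_roles) != self.rest_env.size:
            raise ValueError("one role per channel required")
        if np.any(self.rest_env < 0):
            raise ValueError("rest envelope cannot be negative")
        for i, role in enumerate(self.channel_roles):
            if self.mvc_env[i] <= self.rest_env[i]:
                raise CalibrationError(
                    f"channel '{role}' (index {i}): MVC envelope "
                    f"{self.mvc_env[i]:.4g} mV does not exceed rest envelope "
                    f"{self.rest_env[i]:.4g} mV"
                )

    @property
    def forearm_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r != TRIGGER_ROLE])

    @property
    def mvc_mean_env(self) -> float:
        return float(self.mvc_env[self.forearm_indices].mean())

    def for_role(self, role: str) -> tuple[float, float]:
        """(rest, mvc) envelope pair for a channel role."""
        i = self.channel_roles.index(role)
        return float(self.rest_env[i]), float(self.mvc_env[i])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rest_env": self.rest_env.tolist(),
                    "mvc_env": self.mvc_env.tolist(),
                    "channel_roles": list(self.channel_roles),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            rest_env=np.asarray(d["rest_env"]),
            mvc_env=np.asarray(d["mvc_env"]),
            channel_roles=tuple(d["channel_roles"]),
        )


class CalibrationError(ValueError):
    """Degenerate calibration: MVC does not exceed rest on some channel."""


# ------------------------------------------------------------------ filters


def highpass_sos(fs: float) -> np.ndarray:
    """Second-order 20 Hz Butterworth high-pass, bilinear-discretised at fs."""
    return signal.butter(HP_ORDER, HP_CUTOFF_HZ, btype="highpass", fs=fs, output="sos")


def lowpass_sos(fs: float) -> np.ndarray:
    """Fourth-order 2 Hz Butterworth low-pass, bilinear-discretised at fs."""
    return signal.butter(LP_ORDER, LP_CUTOFF_HZ, btype="lowpass", fs=fs, output="sos")


def highpass(recording: EmgRecording) -> EmgRecording:
    """Causally high-pass filter a recording (20 Hz, 2nd order)."""
    sos = highpass_sos(recording.fs)
    return recording.replace_samples(signal.sosfilt(sos, recording.samples, axis=-1))


def envelope(recording: EmgRecording) -> EnvelopeSeries:
    """Rectify + causal 2 Hz low-pass; assumes input already high-passed.

    The low-pass step can ring slightly below zero; the output is clamped at
    zero because envelopes are amplitude estimates.
    """
    sos = lowpass_sos(recording.fs)
    env = signal.sosfilt(sos, np.abs(recording.samples), axis=-1)
    return EnvelopeSeries(values=np.clip(env, 0.0, None), fs=recording.fs)


def process(recording: EmgRecording) -> EnvelopeSeries:
    """Full pipeline: high-pass -> rectify -> low-pass."""
    return envelope(highpass(recording))


class StreamingPipeline:
    """Stateful chunked version of :func:`process`.

    Carries the Butterworth filter states across chunks so that feeding a
    signal in arbitrary chunk sizes reproduces the one-shot output exactly.
    Also exposes the high-passed raw signal of the latest chunk, which the
    pattern-recognition feature windows consume.
    """

    def __init__(self, n_channels: int, fs: float):
        self.fs = fs
        self._hp_sos = highpass_sos(fs)
        self._lp_sos = lowpass_sos(fs)
        self._hp_zi = np.zeros((self._hp_sos.shape[0], n_channels, 2))
        self._lp_zi = np.zeros((self._lp_sos.shape[0], n_channels, 2))

    def push(self, chunk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Process one [n_channels x n] chunk.

        Returns ``(filtered, envelope)`` for the chunk, both causal
        continuations of everything pushed so far.
        """
        chunk = np.atleast_2d(np.asarray(chunk, dtype=float))
        hp, self._hp_zi = signal.sosfilt(self._hp_sos, chunk, axis=-1, zi=self._hp_zi)
        env, self._lp_zi = signal.sosfilt(self._lp_sos, np.abs(hp), axis=-1, zi=self._lp_zi)
        return hp, np.clip(env, 0.0, None)


# -------------------------------------------------------------- calibration


def calibrate(
    mvc_recording: EmgRecording, rest_recording: EmgRecording
) -> CalibrationProfile:
    """Reduce MVC and rest recordings to a calibration profile.

    Rest level is the per-channel mean envelope over the final 3 s of the rest
    recording.  The MVC level is the mean envelope over the contiguous 3 s
    window of the MVC recording with maximal summed forearm envelope — robust
    to contraction ramp-up at the start of the recording.
    """
    for name, rec in (("MVC", mvc_recording), ("rest", rest_recording)):
        if rec.duration_s < MVC_SEGMENT_S:
            raise ValueError(f"{name} recording shorter than {MVC_SEGMENT_S} s")
    if mvc_recording.channel_roles != rest_recording.channel_roles:
        raise ValueError("MVC and rest recordings have mismatched channel roles")

    fs = mvc_recording.fs
    rest_env = process(rest_recording).values
    n_rest = int(round(REST_SEGMENT_S * fs))
    rest_levels = rest_env[:, -n_rest:].mean(axis=1)

    mvc_env = process(mvc_recording).values
    n_win = int(round(MVC_SEGMENT_S * fs))
    total = mvc_env[mvc_recording.forearm_indices].sum(axis=0)
    # best contiguous 3 s window by summed forearm envelope (cumsum trick)
    csum = np.concatenate([[0.0], np.cumsum(total)])
    window_sums = csum[n_win:] - csum[:-n_win]
    start = int(np.argmax(window_sums))
    mvc_levels = mvc_env[:, start : start + n_win].mean(axis=1)

    return CalibrationProfile(
        rest_env=rest_levels,
        mvc_env=mvc_levels,
        channel_roles=mvc_recording.channel_roles,
    )


def voluntary(env: EnvelopeSeries, calib: CalibrationProfile) -> EnvelopeSeries:
    """Rest-subtracted (voluntary) envelopes, clamped at zero."""
    if env.values.shape[0] != calib.rest_env.size:
        raise ValueError("channel count mismatch between envelopes and calibration")
    vol = env.values - calib.rest_env[:, None]
    return EnvelopeSeries(values=np.clip(vol, 0.0, None), fs=env.fs)
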