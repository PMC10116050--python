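"""Pattern-recognition myocontrol: time-domain features + MLP classifier.

Five time-domain features (the classic Hudgins set: root mean square, mean
absolute value, zero crossings, slope-sign changes, waveform length) are
extracted per forearm channel from 250 ms windows of high-pass-filtered raw
sEMG, sliding by 125 ms.  A multilayer perceptron with a single hidden layer
of ten logistic units classifies each window into one of five motion classes
(hand open/close, wrist flexion/extension, no motion).  The decoded class
selects a cursor direction; the magnitude is a proportional signal — the mean
voluntary envelope of all six forearm channels normalised to their mean MVC
envelope.

Features are z-scored with training-set statistics before the MLP: waveform
length and zero-crossing counts live on very different scales and raw features
make training erratic.  Training itself is delegated to scikit-learn; run-time
classification is a plain numpy forward pass from the stored weights, so a
serialized model needs no pickle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .mapping import MOTION_CLASSES, MotionClass, MotionMapping
from .processing import CalibrationProfile
from .recording import EmgRecording

FEATURE_NAMES = ("rms", "mav", "zc", "ssc", "wl")
WINDOW_S = 0.250
OVERLAP_S = 0.125
TRAINING_REP_S = 2.0
TRAINING_REPS = 5
HIDDEN_UNITS = 10


@dataclass
class PrConfig:
    """Windowing and training knobs for the pattern-recognition pipeline."""

    window_s: float = WINDOW_S
    overlap_s: float = OVERLAP_S
    zc_ssc_deadband_mv: float = 0.01  # noise-floor scale
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_s < self.window_s:
            raise ValueError("overlap must satisfy 0 < overlap_s < window_s")


def extract_features(window: np.ndarray, deadband: float = 0.01) -> np.ndarray:
    """Hudgins time-domain features for one [n_channels x n_samples] window.

    Returns a flat vector ordered channel-major: (rms, mav, zc, ssc, wl) for
    channel 0, then channel 1, ...  The deadband (mV) suppresses noise-floor
    zero crossings and slope-sign changes.
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    if x.shape[1] < 3:
        raise ValueError("window too short for feature extraction")
    rms = np.sqrt(np.mean(x**2, axis=1))
    mav = np.mean(np.abs(x), axis=1)
    d = np.diff(x, axis=1)
    # zero crossing: consecutive samples of opposite sign, step above deadband
    zc = np.sum((x[:, :-1] * x[:, 1:] < 0) & (np.abs(d) > deadband), axis=1)
    # slope-sign change: the slope flips sign and either step exceeds deadband
    d1, d2 = d[:, :-1], d[:, 1:]
    ssc = np.sum(
        (d1 * d2 < 0) & (np.maximum(np.abs(d1), np.abs(d2)) > deadband), axis=1
    )
    wl = np.sum(np.abs(d), axis=1)
    return np.column_stack([rms, mav, zc, ssc, wl]).ravel()


def sliding_windows(n_samples: int, window: int, step: int) -> list[slice]:
    """Start-aligned sliding-window slices fully inside [0, n_samples)."""
    if n_samples < window:
        return []
    starts = range(0, n_samples - window + 1, step)
    return [slice(s, s + window) for s in starts]


def build_training_set(
    recordings: dict[MotionClass, list[EmgRecording]],
    cfg: PrConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Window per-class training repetitions into a labelled feature set.

    Expects five repetitions of >= 2 s per motion class (the training
    protocol); every window lies fully inside its repetition, so for 2 s reps
    at 1 kHz each rep contributes 15 windows and the set totals 375 vectors.

    Returns (X, y) with y holding class indices into ``MOTION_CLASSES``.
    """
    cfg = cfg or PrConfig()
    missing = set(MOTION_CLASSES) - set(recordings)
    if missing:
        raise ValueError(f"missing training classes: {sorted(c.value for c in missing)}")
    X, y = [], []
    for cls_idx, cls in enumerate(MOTION_CLASSES):
        reps = recordings[cls]
        if len(reps) < TRAINING_REPS:
            raise ValueError(
                f"class {cls.value}: {len(reps)} repetitions, need {TRAINING_REPS}"
            )
        for rep in reps:
            if rep.duration_s < TRAINING_REP_S:
                raise ValueError(
                    f"class {cls.value}: repetition of {rep.duration_s:.2f} s "
                    f"is shorter than {TRAINING_REP_S} s"
                )
            fs = rep.fs
            window = int(round(cfg.window_s * fs))
            step = int(round(cfg.overlap_s * fs))
            forearm = rep.samples[rep.forearm_indices]
            for sl in sliding_windows(rep.n_samples, window, step):
                X.append(extract_features(forearm[:, sl], cfg.zc_ssc_deadband_mv))
                y.append(cls_idx)
    return np.asarray(X), np.asarray(y)


@dataclass
class PrModel:
    """Trained classifier: feature scaler + 30->10->5 MLP weights."""

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    hidden_weights: np.ndarray  # [n_features x 10]
    hidden_bias: np.ndarray
    output_weights: np.ndarray  # [10 x 5]
    output_bias: np.ndarray
    classes: tuple[int, ...]  # indices into MOTION_CLASSES
    metadata: dict = field(default_factory=dict)

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(features) - self.scaler_mean) / self.scaler_scale
        h = 1.0 / (1.0 + np.exp(-np.clip(z @ self.hidden_weights + self.hidden_bias, -500, 500)))
        return h @ self.output_weights + self.output_bias

    def classify(self, features: np.ndarray) -> MotionClass:
        """Decode one feature vector into a motion class."""
        scores = self.decision_values(features)[0]
        return MOTION_CLASSES[self.classes[int(np.argmax(scores))]]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scaler_mean": self.scaler_mean.tolist(),
                    "scaler_scale": self.scaler_scale.tolist(),
                    "hidden_weights": self.hidden_weights.tolist(),
                    "hidden_bias": self.hidden_bias.tolist(),
                    "output_weights": self.output_weights.tolist(),
                    "output_bias": self.output_bias.tolist(),
                    "classes": list(self.classes),
                    "metadata": self.metadata,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "PrModel":
        d = json.loads(Path(path).read_text())
        return cls(
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            hidden_weights=np.asarray(d["hidden_weights"]),
            hidden_bias=np.asarray(d["hidden_bias"]),
            output_weights=np.asarray(d["output_weights"]),
            output_bias=np.asarray(d["output_bias"]),
            classes=tuple(d["classes"]),
            metadata=d["metadata"],
        )


def train(X: np.ndarray, y: np.ndarray, seed: int = 0, max_iter: int = 500) -> PrModel:
    """Fit the one-hidden-layer (10 logistic units) MLP on a feature set.

    Deterministic for a fixed seed.  Non-convergence within ``max_iter`` is
    recorded in the model metadata rather than raised — a slightly
    under-trained classifier is still usable online.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.bincount(y, minlength=len(MOTION_CLASSES))
    if np.any(counts[np.unique(y)] < 2):
        raise ValueError("need at least two samples per class")
    scaler = StandardScaler().fit(X)
    clf = MLPClassifier(
        hidden_layer_sizes=(HIDDEN_UNITS,),
        activation="logistic",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(scaler.transform(X), y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf = MLPClassifier(
                    hidden_layer_sizes=(HIDDEN_UNITS,),
                    activation="logistic",
                    solver="lbfgs",
                    max_iter=max_iter,
                    random_state=seed,
                ).fit(scaler.transform(X), y)
    model = PrModel(
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        hidden_weights=clf.coefs_[0],
        hidden_bias=clf.intercepts_[0],
        output_weights=clf.coefs_[1],
        output_bias=clf.intercepts_[1],
        classes=tuple(int(c) for c in clf.classes_),
        metadata={"seed": int(seed), "max_iter": int(max_iter), "converged": converged},
    )
    preds = np.array([model.classify(x) for x in X])
    truth = np.array([MOTION_CLASSES[i] for i in y])
    model.metadata["training_accuracy"] = float(np.mean(preds == truth))
    return model


def pr_proportional(env_sample: np.ndarray, calib: CalibrationProfile) -> float:
    """Proportional signal: mean voluntary forearm envelope / mean MVC envelope.

    ``env_sample`` is the current per-channel envelope sample in mV (forearm
    channels at the calibration's forearm indices).  Clamped to [0, 1].
    """
    idx = calib.forearm_indices
    vol = np.clip(np.asarray(env_sample)[idx] - calib.rest_env[idx], 0.0, None)
    return float(np.clip(vol.mean() / calib.mvc_mean_env, 0.0, 1.0))


def pr_output(cls: MotionClass, u: float, mapping: MotionMapping) -> np.ndarray:
    """Route the proportional signal through the decoded class's direction.

    Internally the controller holds a five-element class vector with ``u`` at
    the decoded class and zeros elsewhere; projected on the cursor axes this
    is one signed nonzero component (or none for NO_MOTION).
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("proportional signal must lie in [0, 1]")
    return np.asarray(mapping.pr_vector(cls, u))


class PatternController:
    """Tick-wise PR controller over streaming high-passed sEMG + envelopes.

    Maintains a raw-signal ring buffer; every ``overlap_s`` it extracts
    features from the latest 250 ms window and re-decodes the motion class.
    The control output is recomputed every tick from the latest decoded class
    and the instantaneous proportional signal.
    """

    def __init__(
        self,
        model: PrModel,
        calib: CalibrationProfile,
        mapping: MotionMapping,
        fs: float,
        cfg: PrConfig | None = None,
    ):
        self.model = model
        self.calib = calib
        self.mapping = mapping
        self.cfg = cfg or PrConfig()
        self.fs = fs
        self._window = int(round(self.cfg.window_s * fs))
        self._step = int(round(self.cfg.overlap_s * fs))
        n_forearm = len(calib.forearm_indices)
        self._buffer = np.zeros((n_forearm, self._window))
        self._filled = 0
        self._since_decode = 0
        self.current_class = MotionClass.NO_MOTION

    def reset(self) -> None:
        self._buffer[:] = 0.0
        self._filled = 0
        self._since_decode = 0
        self.current_class = MotionClass.NO_MOTION

    def push_samples(self, hp_chunk: np.ndarray) -> None:
        """Append a chunk of high-passed raw samples (forearm channels)."""
        chunk = np.atleast_2d(hp_chunk)[self.calib.forearm_indices]
        n = chunk.shape[1]
        if n >= self._window:
            self._buffer = chunk[:, -self._window :].copy()
        else:
            self._buffer = np.roll(self._buffer, -n, axis=1)
            self._buffer[:, -n:] = chunk
        self._filled = min(self._filled + n, self._window)
        self._since_decode += n
        if self._filled >= self._window and self._since_decode >= self._step:
            feats = extract_features(self._buffer, self.cfg.zc_ssc_deadband_mv)
            self.current_class = self.model.classify(feats)
            self._since_decode = 0

    def tick(self, env_sample: np.ndarray, t: float) -> np.ndarray:
        """Control output from the latest decoded class + current envelope."""
        u = pr_proportional(env_sample, self.calib)
        return pr_output(self.current_class, u, self.mapping)
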