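"""Time-domain features, MLP training/decoding, proportional PR signal."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from myoreach.mapping import DMD, RIGHT_HANDED, MOTION_CLASSES, MotionClass
from myoreach.pattern_recognition import (
    FEATURE_NAMES,
    PrModel,
    build_training_set,
    extract_features,
    pr_output,
    pr_proportional,
    train,
)
from myoreach.processing import CalibrationProfile

ROLES6 = ("fcu", "ecu", "mid1", "mid2", "mid3", "mid4")


def feat(vec, name, channel=0):
    return vec[channel * len(FEATURE_NAMES) + FEATURE_NAMES.index(name)]


class TestFeatures:
    def test_constant_window(self):
        w = np.full((6, 250), 0.5)
        v = extract_features(w, deadband=0.01)
        for ch in range(6):
            assert feat(v, "rms", ch) == pytest.approx(0.5)
            assert feat(v, "mav", ch) == pytest.approx(0.5)
            assert feat(v, "zc", ch) == 0
            assert feat(v, "ssc", ch) == 0
            assert feat(v, "wl", ch) == pytest.approx(0.0)

    def test_sine_zero_crossings(self):
        # 40 Hz over 250 ms -> 10 cycles -> ~20 crossings (boundary +-1)
        t = np.arange(250) / 1000.0
        w = np.tile(np.sin(2 * np.pi * 40 * t), (6, 1))
        v = extract_features(w, deadband=0.0)
        assert 19 <= feat(v, "zc") <= 21

    def test_linear_ramp(self):
        w = np.tile(np.linspace(0.0, 1.0, 250), (6, 1))
        v = extract_features(w, deadband=0.0)
        assert feat(v, "ssc") == 0
        assert feat(v, "wl") == pytest.approx(1.0)

    def test_wrong_window_shape_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((6, 2)))

    @given(
        arrays(
            float,
            (6, 40),
            # 32-bit-representable values: squaring stays far from underflow
            elements=st.floats(
                -5.0, 5.0, width=32, allow_nan=False, allow_infinity=False
            ),
        )
    )
    @settings(deadline=None, max_examples=50,
              suppress_health_check=[HealthCheck.large_base_example])
    def test_invariants_on_random_windows(self, w):
        v = extract_features(w, deadband=0.01)
        for ch in range(6):
            mav = feat(v, "mav", ch)
            assert feat(v, "rms", ch) >= mav * (1 - 1e-12)  # Cauchy-Schwarz
            assert mav >= 0.0
            assert feat(v, "zc", ch) >= 0 and feat(v, "ssc", ch) >= 0
            assert feat(v, "wl", ch) >= 0.0


class TestTrainingSet:
    def test_protocol_yields_375_vectors(self, healthy_training_set):
        X, y = healthy_training_set
        # 15 windows/rep x 5 reps x 5 classes
        assert X.shape == (375, 30)
        assert np.bincount(y).tolist() == [75] * 5

    def test_short_repetition_rejected(self, healthy_kit):
        broken = dict(healthy_kit.training)
        cls = MotionClass.HAND_OPEN
        short = [r.replace_samples(r.samples[:, :1000]) for r in broken[cls]]
        broken[cls] = short
        with pytest.raises(ValueError, match="shorter"):
            build_training_set(broken)

    def test_missing_class_rejected(self, healthy_kit):
        broken = dict(healthy_kit.training)
        del broken[MotionClass.NO_MOTION]
        with pytest.raises(ValueError, match="missing"):
            build_training_set(broken)

    def test_windows_stay_inside_repetitions(self, healthy_kit):
        # 2.000 s reps at 1 kHz: last window starts at 1750, ends at 2000
        rep = healthy_kit.training[MotionClass.HAND_OPEN][0]
        n_windows = (rep.n_samples - 250) // 125 + 1
        assert n_windows == 15
        assert 125 * (n_windows - 1) + 250 <= rep.n_samples


class TestTraining:
    def test_seeded_accuracy_on_generator_defaults(self, healthy_model):
        assert healthy_model.metadata["training_accuracy"] >= 0.95

    def test_determinism(self, healthy_training_set):
        X, y = healthy_training_set
        m1 = train(X, y, seed=5)
        m2 = train(X, y, seed=5)
        np.testing.assert_array_equal(m1.hidden_weights, m2.hidden_weights)
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)

    def test_permuted_labels_near_chance(self, healthy_training_set):
        # holdout accuracy under label permutation ~ 0.20 for 5 classes
        X, y = healthy_training_set
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        train_idx = rng.random(len(y)) < 0.7
        model = train(X[train_idx], y_perm[train_idx], seed=1)
        preds = np.array([model.classify(x) for x in X[~train_idx]])
        truth = np.array([MOTION_CLASSES[i] for i in y_perm[~train_idx]])
        acc = float(np.mean(preds == truth))
        assert 0.10 <= acc <= 0.35

    def test_too_few_samples_per_class_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((5, 30)), np.arange(5))


class TestClassify:
    def test_class_centroids_decode_to_their_class(self, healthy_model, healthy_training_set):
        X, y = healthy_training_set
        for cls_idx in range(5):
            centroid = X[y == cls_idx].mean(axis=0)
            assert healthy_model.classify(centroid) == MOTION_CLASSES[cls_idx]

    def test_deterministic(self, healthy_model):
        x = np.linspace(0, 1, 30)
        assert healthy_model.classify(x) == healthy_model.classify(x)

    def test_json_round_trip_preserves_decisions(self, healthy_model, healthy_training_set, tmp_path):
        path = tmp_path / "model.json"
        healthy_model.save(path)
        loaded = PrModel.load(path)
        X, _ = healthy_training_set
        for x in X[::25]:
            assert loaded.classify(x) == healthy_model.classify(x)


class TestProportional:
    def _calib(self, rest=0.0, mvc=1.0):
        return CalibrationProfile(
            rest_env=np.full(6, rest), mvc_env=np.full(6, mvc), channel_roles=ROLES6
        )

    def test_half_activation(self):
        u = pr_proportional(np.full(6, 0.5), self._calib())
        assert u == pytest.approx(0.5)

    def test_rest_gives_zero(self):
        calib = self._calib(rest=0.1)
        assert pr_proportional(np.full(6, 0.1), calib) == 0.0

    def test_clamped_at_one(self):
        assert pr_proportional(np.full(6, 2.0), self._calib()) == 1.0


class TestPrOutput:
    @pytest.mark.parametrize(
        "mapping,cls,u,expected",
        [
            (RIGHT_HANDED, MotionClass.WRIST_EXTENSION, 0.8, (0.8, 0.0)),
            (RIGHT_HANDED, MotionClass.WRIST_FLEXION, 0.8, (-0.8, 0.0)),
            (RIGHT_HANDED, MotionClass.HAND_OPEN, 0.5, (0.0, 0.5)),
            (RIGHT_HANDED, MotionClass.HAND_CLOSE, 0.5, (0.0, -0.5)),
            (RIGHT_HANDED, MotionClass.NO_MOTION, 0.9, (0.0, 0.0)),
            (DMD, MotionClass.HAND_OPEN, 0.5, (0.5, 0.0)),  # DMD row: open -> right
            (DMD, MotionClass.WRIST_EXTENSION, 0.5, (0.0, 0.5)),
        ],
    )
    def test_mapping_rows(self, mapping, cls, u, expected):
        np.testing.assert_allclose(pr_output(cls, u, mapping), expected)

    def test_single_axis_and_magnitude_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            cls = MOTION_CLASSES[rng.integers(5)]
            u = float(rng.random())
            out = pr_output(cls, u, RIGHT_HANDED)
            assert np.count_nonzero(out) <= 1
            assert np.max(np.abs(out)) <= 1.0

    def test_rejects_out_of_range_signal(self):
        with pytest.raises(ValueError):
            pr_output(MotionClass.HAND_OPEN, 1.5, RIGHT_HANDED)
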