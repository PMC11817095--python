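"""CNN extractors: architecture contracts, training behaviour, extraction
purity, and gradient correctness of the underlying layers."""

import numpy as np
import pytest

from dentage import nn
from dentage.cnn_features import (
    ArchSpec1D,
    ArchSpec2D,
    TrainConfig,
    bin_ages,
    build_extractor,
    extract_features,
    train_extractor,
)

TINY_2D = ArchSpec2D(input_shape=(16, 16, 1), conv_blocks=((4, 3), (8, 3)),
                     dense_units=16, feature_units=8)
TINY_1D = ArchSpec1D(input_length=12, conv_blocks=((4, 5), (8, 3)),
                     dense_units=16, feature_units=8)


def _toy_images(n, rng, size=16):
    """Images whose bright-square area grows with age."""
    ages = rng.uniform(6, 15, size=n)
    X = np.zeros((n, size, size))
    for i, a in enumerate(ages):
        w = int((a - 6) / 9 * (size - 4)) + 2
        X[i, 2 : 2 + w, 2 : 2 + w] = 1.0
        X[i] += rng.normal(0, 0.05, size=(size, size))
    return X, ages


class TestGradients:
    """Finite-difference check of the full backward pass."""

    @pytest.mark.parametrize("modality", ["image", "record"])
    def test_backprop_matches_numerical_gradient(self, modality, rng):
        if modality == "image":
            net = nn.Sequential([
                nn.Conv2D(1, 3, 3, rng), nn.ReLU(), nn.MaxPool2D(2),
                nn.Flatten(), nn.Dense(3 * 4 * 4, 4, rng),
            ])
            x = rng.normal(size=(2, 1, 8, 8))
        else:
            net = nn.Sequential([
                nn.Conv1D(1, 3, 3, rng), nn.ReLU(), nn.GlobalMaxPool1D(),
                nn.Dense(3, 4, rng),
            ])
            x = rng.normal(size=(3, 1, 10))
        labels = np.arange(x.shape[0]) % 4
        _, grad = nn.softmax_cross_entropy(net.forward(x), labels)
        net.backward(grad)
        for p, g in net.params():
            for idx in (0, p.size // 2, p.size - 1):
                old = p.flat[idx]
                p.flat[idx] = old + 1e-6
                lp, _ = nn.softmax_cross_entropy(net.forward(x), labels)
                p.flat[idx] = old - 1e-6
                lm, _ = nn.softmax_cross_entropy(net.forward(x), labels)
                p.flat[idx] = old
                assert (lp - lm) / 2e-6 == pytest.approx(g.flat[idx], abs=1e-5)


class TestBuild:
    def test_default_2d_spec_yields_128_features(self, rng):
        model = build_extractor(ArchSpec2D(), seed=0)
        x = rng.uniform(0, 1, size=(1, 224, 224))
        assert extract_features(model, x).values.shape == (1, 128)

    def test_default_1d_spec_yields_128_features(self, rng):
        model = build_extractor(ArchSpec1D(input_length=16), seed=0)
        x = rng.normal(size=(1, 16))
        assert extract_features(model, x).values.shape == (1, 128)

    def test_same_seed_identical_initial_outputs(self, rng):
        x = rng.uniform(size=(3, 16, 16))
        out = [extract_features(build_extractor(TINY_2D, seed=4), x).values
               for _ in range(2)]
        assert np.array_equal(out[0], out[1])
        other = extract_features(build_extractor(TINY_2D, seed=5), x).values
        assert not np.array_equal(out[0], other)

    def test_too_small_input_for_poolings_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            ArchSpec2D(input_shape=(8, 8, 1),
                       conv_blocks=((4, 3),) * 4, dense_units=8, feature_units=4)


class TestTrain:
    def test_loss_decreases_on_learnable_signal(self, rng):
        X, ages = _toy_images(120, rng)
        model = build_extractor(TINY_2D, seed=0, n_age_bins=3)
        cfg = TrainConfig(n_age_bins=3, epochs=10, batch_size=16, rng_seed=0)
        train_extractor(model, X, ages, cfg)
        assert len(model.training_history) == 10
        assert model.training_history[-1] < model.training_history[0]

    def test_training_is_seed_deterministic(self, rng):
        X, ages = _toy_images(40, rng)
        finals = []
        for _ in range(2):
            model = build_extractor(TINY_2D, seed=1, n_age_bins=3)
            cfg = TrainConfig(n_age_bins=3, epochs=3, batch_size=16, rng_seed=7)
            train_extractor(model, X, ages, cfg)
            finals.append(model.training_history[-1])
        assert finals[0] == finals[1]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(n_age_bins=1)

    def test_bin_ages_covers_range(self):
        labels = bin_ages(np.array([6.0, 10.5, 15.0]), 9, (6.0, 15.0))
        assert labels.tolist() == [0, 4, 8]


class TestExtract:
    @pytest.fixture(scope="class")
    @classmethod
    def trained(cls):
        rng = np.random.default_rng(3)
        X, ages = _toy_images(60, rng)
        model = build_extractor(TINY_2D, seed=2, n_age_bins=3)
        train_extractor(model, X, ages, TrainConfig(n_age_bins=3, epochs=6,
                                                    batch_size=16, rng_seed=2))
        return model, X, ages

    def test_output_width_for_any_batch_size(self, trained, rng):
        model, X, _ = trained
        for n in (0, 1, 5):
            out = extract_features(model, X[:n])
            assert out.values.shape == (n, TINY_2D.feature_units)

    def test_pure_function_and_duplicates(self, trained):
        model, X, _ = trained
        batch = np.concatenate([X[:4], X[3:4]])  # row 3 duplicated
        f1 = extract_features(model, batch).values
        f2 = extract_features(model, batch).values
        assert np.array_equal(f1, f2)
        assert np.array_equal(f1[3], f1[4])

    def test_features_carry_age_signal_beyond_pixel_mean(self, trained):
        """Linear probe on extracted features beats one on raw pixel means."""
        model, X, ages = trained
        feats = extract_features(model, X).values

        def probe_r2(Z):
            Z1 = np.column_stack([Z, np.ones(len(Z))])
            coef, *_ = np.linalg.lstsq(Z1, ages, rcond=None)
            resid = ages - Z1 @ coef
            return 1 - resid @ resid / np.sum((ages - ages.mean()) ** 2)

        assert probe_r2(feats) > probe_r2(X.mean(axis=(1, 2))[:, None])

    def test_mismatched_shapes_raise(self, trained, rng):
        model, _, _ = trained
        with pytest.raises(ValueError):
            extract_features(model, rng.uniform(size=(2, 10, 10)))
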