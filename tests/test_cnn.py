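"""CNN demodulator: architecture contracts, training loop, persistence."""

import numpy as np
import pytest

from sonecg.cnn import (CNNArchitecture, TrainConfig, build_model, load_model,
                        predict, save_model, train)
from sonecg.records import AudioStream, CANONICAL_8


@pytest.fixture(scope="module")
def small_model():
    """Paper-layout network accepting short inputs (fully convolutional)."""
    return build_model(CNNArchitecture(input_len=4400), seed=0)


def _tiny_dataset(n=6, length=2200, seed=0):
    rng = np.random.default_rng(seed)
    audio = rng.standard_normal((n, length)).astype(np.float32)
    targets = rng.standard_normal((n, length // 44, 8)).astype(np.float32)
    return audio, targets


class TestArchitecture:
    def test_default_parameter_count(self):
        arch = CNNArchitecture()
        assert arch.n_params == 23_600
        assert arch.layer_param_counts() == [5304, 11544, 5784, 968]

    def test_rate_reduction_factor(self):
        arch = CNNArchitecture()
        assert arch.downsampling_factor == 44
        assert arch.input_len == 110_000
        assert arch.output_len == 2_500
        assert arch.n_leads == 8

    def test_model_matches_declared_count(self):
        model = build_model(seed=1)
        assert model.n_params == 23_600

    def test_forward_shape_on_zeros(self):
        model = build_model(seed=0)
        out = model.forward_array(np.zeros(110_000, dtype=np.float32))
        assert out.shape == (1, 2_500, 8)

    def test_indivisible_pooling_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            CNNArchitecture(input_len=110_001)

    def test_pool_count_must_match_convs(self):
        with pytest.raises(ValueError, match="pool"):
            CNNArchitecture(pool_windows=(11, 2))


def test_network_is_positively_homogeneous_before_training(small_model):
    """Linear activations + max pooling: predict(a*x) = a*predict(x), a>0."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal(4400).astype(np.float32)
    o1 = small_model.forward_array(x)
    o2 = small_model.forward_array(np.float32(3.0) * x)
    np.testing.assert_allclose(o2, 3.0 * o1, rtol=1e-4, atol=1e-4)


class TestTraining:
    def test_loss_decreases_on_tiny_problem(self):
        audio, targets = _tiny_dataset()
        model = build_model(CNNArchitecture(input_len=2200), seed=0)
        cfg = TrainConfig(batch_size=3, max_epochs=8, early_stop_patience=8,
                          seed=0)
        history = train(model, audio, targets, cfg)
        assert history["train_rmse"][-1] < history["train_rmse"][0]
        assert len(history["val_rmse"]) == len(history["train_rmse"])

    def test_zero_learning_rate_stops_after_patience(self):
        audio, targets = _tiny_dataset()
        model = build_model(CNNArchitecture(input_len=2200), seed=0)
        cfg = TrainConfig(learning_rate=0.0, batch_size=3, max_epochs=50,
                          early_stop_patience=4, seed=0)
        history = train(model, audio, targets, cfg)
        # epoch 1 sets the best loss; patience epochs without improvement
        assert len(history["val_rmse"]) == 5
        assert len(set(history["val_rmse"])) == 1

    def test_seeded_training_is_reproducible(self):
        audio, targets = _tiny_dataset()
        histories = []
        for _ in range(2):
            model = build_model(CNNArchitecture(input_len=2200), seed=0)
            cfg = TrainConfig(batch_size=3, max_epochs=3,
                              early_stop_patience=3, seed=7)
            histories.append(train(model, audio, targets, cfg))
        assert histories[0] == histories[1]

    def test_empty_dataset_rejected(self):
        model = build_model(CNNArchitecture(input_len=2200), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, np.zeros((0, 2200)), np.zeros((0, 50, 8)))

    def test_shape_mismatch_rejected(self):
        model = build_model(CNNArchitecture(input_len=2200), seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            train(model, np.zeros((4, 2200)), np.zeros((4, 49, 8)))


class TestPredict:
    def test_output_is_canonical_250_hz_record(self, small_model):
        stream = AudioStream(np.zeros(4400), 11_000.0)
        rec = predict(small_model, stream)
        assert rec.lead_names == CANONICAL_8
        assert rec.fs == pytest.approx(250.0)
        assert rec.units == "mV"
        assert rec.samples.shape == (8, 100)

    def test_short_audio_zero_padded_with_warning(self, small_model):
        stream = AudioStream(np.zeros(2000), 11_000.0)
        with pytest.warns(UserWarning, match="zero-padded"):
            rec = predict(small_model, stream)
        assert rec.samples.shape == (8, 100)

    def test_wrong_sample_rate_rejected(self, small_model):
        with pytest.raises(ValueError, match="Hz"):
            predict(small_model, AudioStream(np.zeros(4400), 44_100.0))


class TestPersistence:
    def test_save_load_round_trip_bit_identical(self, tmp_path, small_model):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4400).astype(np.float32)
        before = small_model.forward_array(x)
        path = tmp_path / "model.hdf5"
        save_model(small_model, path)
        loaded = load_model(path)
        after = loaded.forward_array(x)
        np.testing.assert_array_equal(before, after)

    def test_checkpoint_is_self_describing(self, tmp_path):
        arch = CNNArchitecture(input_len=8800, dropout_rate=0.05)
        model = build_model(arch, seed=3)
        path = tmp_path / "model.hdf5"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.arch == arch

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.hdf5"
        path.write_bytes(b"not an hdf5 file")
        with pytest.raises((OSError, ValueError)):
            load_model(path)
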