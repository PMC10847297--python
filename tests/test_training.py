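"""Training loop sanity, determinism, inference wrappers, multichannel contract."""

import numpy as np
import pytest

from dpae.contamination import build_pair_dataset
from dpae.metrics import evaluate_per_snr, rrmse_temporal
from dpae.model import Model, build_backbone_variant, canonical_mlp_table1
from dpae.signals import gen_clean_eeg, gen_emg
from dpae.training import (
    DivergenceError,
    TrainingConfig,
    denoise,
    denoise_multichannel,
    train,
)


@pytest.fixture(scope="module")
def tiny_spec():
    return build_backbone_variant(64, "mlp")


@pytest.fixture(scope="module")
def tiny_dataset():
    cleans = gen_clean_eeg(32, length=64, seed=9)
    arts = gen_emg(32, length=64, seed=10)
    return build_pair_dataset(cleans, arts, [0.0], count_per_level=32, seed=3)


class TestTrainBehavior:
    def test_identity_task_converges(self):
        """Reconstructing uncorrupted inputs: loss collapses well below start.

        The decoder bottleneck (half the input width) caps exact linear
        reconstruction of the band-limited surrogates, so the floor is not
        machine precision; the oracle-run bound is < 0.2 after 50 epochs.
        """
        cleans = gen_clean_eeg(200, seed=3)
        passthrough = gen_clean_eeg(200, seed=99)
        pairs = build_pair_dataset(cleans, passthrough, [200.0], 200, seed=0)
        model = Model(canonical_mlp_table1(), seed=0)
        _, hist = train(model, pairs, TrainingConfig(batch_size=16, epochs=50, seed=0))
        assert hist.train_loss[-1] < 0.2
        assert hist.train_loss[-1] < 0.15 * hist.train_loss[0]

    def test_single_batch_overfit(self):
        """128 pairs, one batch: 300 epochs cut the loss by >= 90%."""
        cleans = gen_clean_eeg(128, seed=3)
        arts = gen_emg(128, seed=4)
        ds = build_pair_dataset(cleans, arts, [0.0], 128, seed=0)
        model = Model(canonical_mlp_table1(), seed=0)
        _, hist = train(model, ds, TrainingConfig(batch_size=128, epochs=300, seed=0))
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]

    def test_loss_trend_non_increasing(self):
        cleans = gen_clean_eeg(128, seed=3)
        arts = gen_emg(128, seed=4)
        ds = build_pair_dataset(cleans, arts, [0.0], 128, seed=0)
        model = Model(canonical_mlp_table1(), seed=0)
        _, hist = train(model, ds, TrainingConfig(batch_size=64, epochs=30, seed=0))
        losses = np.array(hist.train_loss)
        block = losses.reshape(3, 10).mean(axis=1)
        assert all(a > b for a, b in zip(block, block[1:]))

    def test_same_seed_same_trace(self, tiny_spec, tiny_dataset):
        def run():
            model = Model(tiny_spec, seed=5)
            _, hist = train(model, tiny_dataset, TrainingConfig(batch_size=8, epochs=3, seed=5))
            return hist.train_loss

        assert run() == run()

    def test_validation_loss_recorded(self, tiny_spec, tiny_dataset):
        model = Model(tiny_spec, seed=5)
        _, hist = train(model, tiny_dataset,
                        TrainingConfig(batch_size=8, epochs=2, seed=5),
                        validation=tiny_dataset)
        assert len(hist.val_loss) == 2 and all(np.isfinite(hist.val_loss))

    def test_length_mismatch_rejected(self, tiny_dataset):
        model = Model(canonical_mlp_table1(), seed=0)
        with pytest.raises(ValueError):
            train(model, tiny_dataset, TrainingConfig(epochs=1))

    def test_divergence_reported_with_epoch(self):
        cleans = gen_clean_eeg(64, seed=3)
        arts = gen_emg(64, seed=4)
        ds = build_pair_dataset(cleans, arts, [0.0], 64, seed=0)
        model = Model(canonical_mlp_table1(), seed=0)
        with pytest.raises(DivergenceError) as err:
            with np.errstate(all="ignore"):
                train(model, ds, TrainingConfig(batch_size=64, epochs=20,
                                                learning_rate=1e8, seed=0))
        assert err.value.epoch >= 0

    def test_end_to_end_improvement_short_run(self):
        """A 20-epoch run already beats the untouched mixture at 0 dB."""
        tr = build_pair_dataset(gen_clean_eeg(300, seed=5), gen_emg(300, seed=6),
                                [0.0], 300, seed=1)
        te = build_pair_dataset(gen_clean_eeg(60, seed=7), gen_emg(60, seed=8),
                                [0.0], 60, seed=2)
        model = Model(canonical_mlp_table1(), seed=1)
        train(model, tr, TrainingConfig(batch_size=32, epochs=20, seed=1))
        curves, ref = evaluate_per_snr(model.predict, te)
        assert curves["rrmse_temporal"].values[0] < ref["rrmse_temporal"].values[0]


@pytest.fixture(scope="module")
def model():
    return Model(canonical_mlp_table1(), seed=2)


@pytest.fixture(scope="module")
def trial():
    return gen_clean_eeg(22, seed=21).to_matrix()  # 22 electrodes x 512 samples


class TestDenoiseWrappers:
    def test_denoise_contract(self, model, eeg100):
        subset = gen_clean_eeg(5, seed=13)
        out = denoise(model, subset)
        assert len(out) == 5 and out.length == 512
        assert out.source == "denoised"
        # inputs untouched
        np.testing.assert_array_equal(subset[0].samples, gen_clean_eeg(5, seed=13)[0].samples)

    def test_denoise_deterministic_at_inference(self, model):
        subset = gen_clean_eeg(3, seed=14)
        a = denoise(model, subset).to_matrix()
        b = denoise(model, subset).to_matrix()
        np.testing.assert_array_equal(a, b)

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            denoise(model, gen_clean_eeg(2, length=64, seed=0))


class TestMultichannel:
    def test_shape_preserved(self, model, trial):
        out = denoise_multichannel(model, trial)
        assert out.shape == (22, 512)

    def test_matches_per_channel_inference(self, model, trial):
        out = denoise_multichannel(model, trial)
        for ch in (0, 7, 21):
            np.testing.assert_array_equal(out[ch], model.predict(trial[ch]))

    def test_channel_permutation_equivariance(self, model, trial):
        perm = np.random.default_rng(0).permutation(22)
        np.testing.assert_array_equal(
            denoise_multichannel(model, trial[perm]),
            denoise_multichannel(model, trial)[perm],
        )

    def test_wrong_sample_count_rejected(self, model):
        with pytest.raises(ValueError):
            denoise_multichannel(model, np.zeros((22, 100)))
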