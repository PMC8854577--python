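"""Architecture arithmetic, autoencoder behavior, predictor training."""

import numpy as np
import pytest

from guidekit.genome import one_hot_batch
from guidekit.model import (ModelSpec, TrainConfig, KmerAutoencoder,
                            GuideActivityRegressor, CSNetwork,
                            encoder_flat_dim, build_predictor, pretrain_cae,
                            train_predictor, predict_cs, pack_X,
                            save_model, load_model, VARIANT_FCS)
from guidekit.synthetic import ActivityFunction


def random_kmers(rng, n, length):
    return ["".join(rng.choice(list("ACGT"), length)) for _ in range(n)]


class TestArchitecture:
    @pytest.mark.parametrize("n,expected", [(28, 280), (32, 320), (20, 200)])
    def test_flatten_dimension(self, n, expected):
        assert encoder_flat_dim(n) == expected

    @pytest.mark.parametrize("n", range(20, 41, 4))
    def test_encoder_output_law_by_forward_pass(self, n, rng):
        net = CSNetwork(n, [], False, 5, rng)
        h = net.encoder.forward(rng.normal(size=(2, 4, n)), train=False)
        assert h.shape == (2, 40, n // 4)
        assert net.flatten.forward(h).shape[1] == (n // 4) * 40 == \
            encoder_flat_dim(n)

    def test_fc_weight_matrix_sizes(self, rng):
        net = CSNetwork(28, [80, 40, 40], False, 5, rng)
        dense = [l for l in net.head if hasattr(l, "params") and "W" in l.params]
        sizes = [l.params["W"].size for l in dense]
        assert sizes == [280 * 80, 80 * 40, 40 * 40] == [22400, 3200, 1600]

    def test_occupancy_branch_width_matches_merged_layer(self, rng):
        cas9 = CSNetwork(28, [80], True, 5, rng)
        assert cas9.occ_branch[0].params["W"].shape == (1, 80)
        deep = CSNetwork(28, [80, 40, 40], True, 5, rng)
        assert deep.occ_branch[0].params["W"].shape == (1, 40)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ModelSpec(variant="fc99")

    def test_train_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrainConfig(split=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="patience"):
            TrainConfig(epochs=10, patience=10)


class TestAutoencoder:
    def test_training_reduces_reconstruction_loss(self, rng):
        X = pack_X(random_kmers(rng, 800, 28))
        cae = KmerAutoencoder(n=28, epochs=5, seed=0).fit(X)
        assert cae.loss_history_[-1] < cae.loss_history_[0]

    def test_seeded_determinism(self, rng):
        X = pack_X(random_kmers(rng, 300, 28))
        a = KmerAutoencoder(n=28, epochs=3, seed=4).fit(X)
        b = KmerAutoencoder(n=28, epochs=3, seed=4).fit(X)
        assert a.loss_history_ == b.loss_history_

    def test_degenerate_single_letter_genome_reconstructs(self):
        """k-mers from an all-A genome: reconstruction becomes near-perfect."""
        X = pack_X(["A" * 28] * 200)
        cae = KmerAutoencoder(n=28, epochs=120, seed=0).fit(X)
        assert cae.reconstruction_loss(X) < 0.05
        recon = cae.reconstruct(X[:5])
        assert (recon.argmax(axis=1) == 0).all()  # every column decodes to A

    def test_empty_kmer_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pretrain_cae([], ModelSpec(n=28), TrainConfig(cae_epochs=1))

    def test_length_not_divisible_by_four_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible by 4"):
            KmerAutoencoder(n=30).fit(pack_X(random_kmers(rng, 10, 30)))

    def test_transform_returns_flat_features(self, rng):
        X = pack_X(random_kmers(rng, 50, 28))
        cae = KmerAutoencoder(n=28, epochs=1, seed=0).fit(X)
        assert cae.transform(X).shape == (50, 280)


@pytest.fixture(scope="module")
def easy_dataset():
    """Sequence-determined CS with mild noise on 28 bp windows."""
    rng = np.random.default_rng(7)
    windows = random_kmers(rng, 1500, 28)
    act = ActivityFunction.random(28, sigma=0.15, seed=7)
    y = act.true_cs(windows, seed=8)
    return windows, np.asarray(y)


class TestPredictor:
    def test_learns_sequence_signal(self, easy_dataset):
        windows, y = easy_dataset
        X = pack_X(windows)
        est = GuideActivityRegressor(n=28, variant="fc8", epochs=25,
                                     patience=8, seed=0)
        est.fit(X[:1200], y[:1200])
        from guidekit.evaluation import correlations
        r, _ = correlations(est.predict(X[1200:]), y[1200:])
        assert r > 0.4

    def test_prediction_determinism_and_batch_consistency(self, easy_dataset):
        windows, y = easy_dataset
        X = pack_X(windows[:200])
        est = GuideActivityRegressor(n=28, variant="encoder_only", epochs=2,
                                     patience=1, seed=0).fit(X, y[:200])
        single = np.array([est.predict(X[i:i + 1])[0] for i in range(10)])
        batch = est.predict(X[:10])
        assert np.allclose(single, batch)
        dup = est.predict(np.repeat(X[:1], 10, axis=0))
        assert np.allclose(dup, dup[0])

    def test_random_encoder_only_uncorrelated(self, rng):
        """Untrained network: predictions carry no activity signal."""
        windows = random_kmers(rng, 3000, 28)
        act = ActivityFunction.random(28, sigma=0.1, seed=1)
        y = act.true_cs(windows, seed=2)
        est = GuideActivityRegressor(n=28, variant="encoder_only", epochs=0,
                                     seed=3)
        est.fit(pack_X(windows), y)
        from guidekit.evaluation import correlations
        r, _ = correlations(est.predict(pack_X(windows)), y)
        assert abs(r) < 0.1

    def test_occupancy_branch_is_live(self, easy_dataset):
        windows, y = easy_dataset
        occ = np.linspace(0, 1, 200)
        X = pack_X(windows[:200], occ)
        est = GuideActivityRegressor(n=28, variant="fc8", use_occupancy=True,
                                     epochs=3, patience=2, seed=0).fit(X, y[:200])
        w = windows[0]
        lo = predict_cs(est, [w], [0.2])[0]
        hi = predict_cs(est, [w], [0.9])[0]
        assert lo != hi

    def test_zero_occupancy_annihilates_merge_at_init(self, easy_dataset):
        """Zero-bias init: occupancy 0 multiplies the sequence path to zero,
        so every guide gets the same (bias-only) output."""
        windows, y = easy_dataset
        X = pack_X(windows[:50], np.zeros(50))
        est = GuideActivityRegressor(n=28, variant="fc8", use_occupancy=True,
                                     epochs=0, seed=0).fit(X, y[:50])
        preds = est.predict(X)
        assert np.allclose(preds, preds[0])

    def test_missing_occupancy_errors(self, easy_dataset):
        windows, y = easy_dataset
        est = GuideActivityRegressor(n=28, variant="fc8", use_occupancy=True,
                                     epochs=0, seed=0)
        est.fit(pack_X(windows[:120], np.zeros(120)), y[:120])
        with pytest.raises(ValueError, match="occupancy"):
            predict_cs(est, windows[:5])
        with pytest.raises(ValueError, match="occupancy"):
            est.fit(pack_X(windows[:120]), y[:120])

    def test_nonfinite_loss_aborts_with_diagnostics(self, easy_dataset):
        windows, y = easy_dataset
        bad = y[:200].copy()
        bad[0] = np.inf
        est = GuideActivityRegressor(n=28, variant="fc8", epochs=3,
                                     patience=1, batch_size=200, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            est.fit(pack_X(windows[:200]), bad)

    def test_sklearn_params_roundtrip(self):
        est = GuideActivityRegressor(n=32, variant="fc8+fc9")
        params = est.get_params()
        est2 = GuideActivityRegressor(**params)
        assert est2.get_params() == params

    def test_save_load_reproduces_predictions(self, easy_dataset, tmp_path):
        windows, y = easy_dataset
        X = pack_X(windows[:300])
        est = GuideActivityRegressor(n=28, variant="fc8", epochs=3,
                                     patience=2, seed=1).fit(X, y[:300])
        save_model(est, str(tmp_path / "m"))
        back = load_model(str(tmp_path / "m"))
        assert np.allclose(back.predict(X[:20]), est.predict(X[:20]))


class TestTrainPredictor:
    def test_split_and_heldout_predictions(self, easy_dataset):
        windows, y = easy_dataset
        spec = ModelSpec(nuclease="cas9", n=28, variant="fc8")
        cfg = TrainConfig(epochs=10, patience=5, seed=0)
        tm = train_predictor(spec, (windows, None, y), cfg)
        assert len(tm.test_targets) == len(tm.test_predictions) == \
            len(y) - int(round(0.6 * len(y))) - int(round(0.2 * len(y)))
        assert tm.provenance == {"pretrained": False, "frozen_encoder": False}

    def test_too_small_dataset_rejected(self):
        spec = ModelSpec(n=28, variant="fc8")
        with pytest.raises(ValueError, match="too small"):
            train_predictor(spec, (["A" * 28] * 50, None, np.zeros(50)),
                            TrainConfig(epochs=2, patience=1))

    def test_ranking_matches_sort_oracle(self, easy_dataset):
        """Top-5/bottom-5 selection by predicted CS equals a plain sort."""
        windows, y = easy_dataset
        spec = ModelSpec(nuclease="cas12a", n=28, variant="fc8")
        cfg = TrainConfig(epochs=12, patience=6, seed=0)
        tm = train_predictor(spec, (windows, None, y), cfg)
        preds = predict_cs(tm, windows[:40])
        order = np.argsort(preds)
        top5, bottom5 = set(order[-5:]), set(order[:5])
        srt = sorted(range(40), key=lambda i: preds[i])
        assert set(srt[-5:]) == top5 and set(srt[:5]) == bottom5
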