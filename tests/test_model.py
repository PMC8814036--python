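"""Submodel grid, network pieces, training contract, prediction, ensemble."""

import numpy as np
import pytest

import proteotrans as pt
from proteotrans.core import MultiOmicsDataset, OmicsMatrix
from proteotrans.model import (LatentDistribution, MERGE_SET_FULL,
                               MERGE_SET_MRNA, ModelError, SubmodelConfig,
                               TranslationNetwork, decode, encode,
                               ensemble_predict, enumerate_submodels, kl_term,
                               loss, lr_merge, predict, sample_latent,
                               train_submodel)


class TestEnumerateSubmodels:
    def test_default_grid_has_12_distinct_members(self):
        grid = enumerate_submodels()
        assert len(grid) == 12
        assert len(set(grid)) == 12
        sources = {c.encoder_source for c in grid}
        reps = {c.encoder_representation for c in grid}
        assert sources == {"mrna", "premrna", "utr"} and reps == {"hvg", "pc"}

    def test_pc_only_override_gives_6(self):
        grid = enumerate_submodels({"representations": ("pc",)})
        assert len(grid) == 6
        assert all(c.encoder_representation == "pc" for c in grid)

    def test_single_merge_set_gives_6(self):
        grid = enumerate_submodels({"merge_sets": (MERGE_SET_FULL,)})
        assert len(grid) == 6

    def test_duplicate_override_rejected(self):
        with pytest.raises(ModelError):
            enumerate_submodels({"merge_sets": (MERGE_SET_FULL, MERGE_SET_FULL)})

    def test_defaults_echo_training_protocol(self):
        c = SubmodelConfig()
        assert (c.lr_scgen, c.lr_merge) == (0.001, 0.01)
        assert (c.patience, c.max_epochs) == (30, 10000)
        assert c.validation_fraction == 0.10


class TestNetworkPieces:
    def _net(self, seed=0, merge=("mrna",)):
        rng = np.random.default_rng(seed)
        return TranslationNetwork(n_enc_in=5, n_proteins=4, merge_sources=merge,
                                  latent_dim=3, hidden_dims=(8,), rng=rng)

    def test_zero_weights_encode_to_bias(self):
        net = self._net()
        for p in net.trunk.params() + net.mu_head.params():
            p.value[...] = 0.0
        net.mu_head.b.value[...] = [1.0, 2.0, 3.0]
        dist = net.encode(np.random.default_rng(1).standard_normal((6, 5)))
        np.testing.assert_allclose(dist.mu, np.tile([1.0, 2.0, 3.0], (6, 1)))

    def test_identical_inputs_identical_latents(self):
        net = self._net(1)
        x = np.tile(np.arange(5.0), (3, 1))
        dist = net.encode(x)
        assert np.all(dist.mu == dist.mu[0]) and np.all(dist.logvar == dist.logvar[0])

    def test_logvar_within_clamp(self):
        net = self._net(2)
        for layer in [net.logvar_head]:
            layer.W.value *= 1e6
        dist = net.encode(np.random.default_rng(3).standard_normal((4, 5)) * 100)
        assert np.all(np.abs(dist.logvar) <= 15.0)

    def test_infer_mode_returns_mu_exactly(self):
        dist = LatentDistribution(np.arange(6.0).reshape(2, 3), np.zeros((2, 3)))
        np.testing.assert_array_equal(sample_latent(dist, "infer"), dist.mu)

    def test_degenerate_variance_draw_close_to_mu(self):
        dist = LatentDistribution(np.ones((2, 3)), np.full((2, 3), -15.0))
        z = sample_latent(dist, "train", seed=0)
        np.testing.assert_allclose(z, dist.mu, atol=1e-3)

    def test_reparameterization_moments(self):
        mu, logvar = 0.7, -0.4
        dist = LatentDistribution(np.full((10000, 1), mu),
                                  np.full((10000, 1), logvar))
        z = sample_latent(dist, "train", seed=42)
        sd = np.exp(logvar / 2)
        se = sd / np.sqrt(10000)
        assert abs(z.mean() - mu) < 3 * se
        assert abs(z.std() - sd) < 3 * sd / np.sqrt(2 * 10000)

    def test_decoder_directional_derivative(self):
        net = self._net(4)
        z = np.random.default_rng(5).standard_normal((1, 3))
        base = net.decoder.forward(z)
        eps = 1e-6
        zp = z.copy()
        zp[0, 1] += eps
        fd = (net.decoder.forward(zp) - base) / eps
        cache = net.forward(np.zeros((1, 5)), {"mrna": np.zeros((1, 4))},
                            mode="infer")
        # analytic gradient via one-hot backprop through the decoder
        net.decoder.forward(z)
        g = net.decoder.backward(np.eye(4)[[0]])
        assert abs(fd[0, 0] - g[0, 1]) < 1e-4


class TestLrMerge:
    def test_passthrough_when_a_is_one(self):
        d = np.array([[1.0, 2.0], [3.0, 4.0]])
        w = {"a": np.ones(2), "b0": np.zeros(2), "c": {}}
        np.testing.assert_array_equal(lr_merge(d, {}, w), d)

    def test_mrna_identity_baseline(self):
        d = np.zeros((2, 2))
        x = np.array([[5.0, 6.0], [7.0, 8.0]])
        w = {"a": np.zeros(2), "b0": np.zeros(2), "c": {"mrna": np.ones(2)}}
        np.testing.assert_array_equal(lr_merge(d, {"mrna": x}, w), x)

    def test_hand_arithmetic(self):
        w = {"a": np.array([0.5]), "b0": np.array([1.0]),
             "c": {"mrna": np.array([0.25])}}
        out = lr_merge(np.array([[2.0]]), {"mrna": np.array([[4.0]])}, w)
        assert out[0, 0] == pytest.approx(3.0)


class TestLoss:
    def test_perfect_prediction_standard_normal_latent_zero_loss(self):
        dist = LatentDistribution(np.zeros((2, 3)), np.zeros((2, 3)))
        y = np.ones((2, 4))
        assert loss(y, y, dist, kl_weight=0.005) == 0.0

    def test_kl_closed_form(self):
        dist = LatentDistribution(np.ones((1, 1)), np.zeros((1, 1)))
        assert kl_term(dist) == pytest.approx(0.5)
        pred = np.zeros((1, 1))
        target = np.full((1, 1), np.sqrt(0.2))
        assert loss(pred, target, dist, 0.005) == pytest.approx(0.2025)

    def test_fully_masked_batch_rejected(self):
        dist = LatentDistribution(np.zeros((1, 1)), np.zeros((1, 1)))
        with pytest.raises(ModelError):
            loss(np.ones((1, 2)), np.full((1, 2), np.nan), dist, 0.0)


class TestTraining:
    def test_constant_target_stops_within_patience(self, small_dataset):
        _, dataset, _ = small_dataset
        const = OmicsMatrix(dataset.protein.feature_ids, dataset.protein.sample_ids,
                            np.ones_like(dataset.protein.values))
        ds = MultiOmicsDataset(mrna=dataset.mrna, premrna=dataset.premrna,
                               utr=dataset.utr, protein=const,
                               metadata=dataset.metadata)
        cfg = SubmodelConfig(encoder_representation="pc", encoder_size=10,
                             latent_dim=4, hidden_dims=(16,), max_epochs=500,
                             patience=5, batch_size=32, seed=0)
        sub = train_submodel(ds, cfg)
        assert sub.history["stopped_epoch"] <= sub.history["best_epoch"] + 6

    def test_learns_linear_translation(self):
        # protein = 0.8 * mRNA + small noise is learnable by the merge layer
        rng = np.random.default_rng(8)
        n, g = 80, 40
        mrna = rng.standard_normal((g, n))
        prot = 0.8 * mrna[:20] + 0.05 * rng.standard_normal((20, n))
        samples = [f"S{i}" for i in range(n)]
        genes = [f"G{i}" for i in range(g)]
        ds = MultiOmicsDataset(
            mrna=OmicsMatrix(genes, samples, mrna),
            protein=OmicsMatrix(genes[:20], samples, prot))
        cfg = SubmodelConfig(encoder_representation="pc", encoder_size=5,
                             lr_inputs=MERGE_SET_MRNA, latent_dim=4,
                             hidden_dims=(16,), max_epochs=200, patience=200,
                             batch_size=32, seed=1)
        sub = train_submodel(ds, cfg)
        assert sub.history["val_loss"][-1] <= 0.5 * sub.history["val_loss"][0]

    def test_training_is_deterministic(self, small_dataset):
        _, dataset, _ = small_dataset
        cfg = SubmodelConfig(encoder_representation="pc", encoder_size=10,
                             latent_dim=4, hidden_dims=(16,), max_epochs=15,
                             patience=15, batch_size=32, seed=5)
        h1 = train_submodel(dataset, cfg).history
        h2 = train_submodel(dataset, cfg).history
        assert h1["val_loss"] == h2["val_loss"]
        assert h1["train_loss"] == h2["train_loss"]


class TestPrediction:
    def test_predict_is_deterministic(self, small_dataset, tiny_submodel):
        _, dataset, _ = small_dataset
        p1 = predict(tiny_submodel, dataset)
        p2 = predict(tiny_submodel, dataset)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_single_sample_matches_batch_row(self, small_dataset, tiny_submodel):
        _, dataset, _ = small_dataset
        batch = predict(tiny_submodel, dataset)
        one = predict(tiny_submodel, dataset.subset_samples([dataset.sample_ids[7]]))
        np.testing.assert_allclose(one.values[:, 0], batch.values[:, 7],
                                   atol=1e-10)

    def test_prediction_tracks_noiseless_truth_better_than_mrna(
            self, small_dataset, tiny_submodel):
        _, dataset, truth = small_dataset
        pred = predict(tiny_submodel, dataset)

        def row_r(a, b):
            aa = a - a.mean(1, keepdims=True)
            bb = b - b.mean(1, keepdims=True)
            return (aa * bb).sum(1) / np.sqrt((aa * aa).sum(1) * (bb * bb).sum(1))

        truth_vals = truth.noiseless_protein.values
        r_pred = np.nanmean(row_r(pred.values, truth_vals))
        r_mrna = np.nanmean(row_r(dataset.mrna.values[:truth_vals.shape[0]],
                                  truth_vals))
        assert r_pred > r_mrna


class TestEnsemble:
    def test_single_member_returns_zscored_prediction(self, small_dataset,
                                                      tiny_submodel):
        _, dataset, _ = small_dataset
        ens = pt.EnsembleModel([tiny_submodel])
        out = ensemble_predict(ens, dataset)
        raw = predict(tiny_submodel, dataset).values
        z = (raw - raw.mean(1, keepdims=True)) / raw.std(1, ddof=1, keepdims=True)
        np.testing.assert_allclose(out.values, z, atol=1e-12)

    def test_mean_of_members_matches_direct_average(self, small_dataset):
        _, dataset, _ = small_dataset
        subs = []
        for seed in (0, 1, 2):
            cfg = SubmodelConfig(encoder_representation="pc", encoder_size=8,
                                 latent_dim=4, hidden_dims=(16,), max_epochs=10,
                                 patience=10, batch_size=32, seed=seed)
            subs.append(train_submodel(dataset, cfg))
        out = ensemble_predict(pt.EnsembleModel(subs), dataset)
        mats = []
        for s in subs:
            raw = predict(s, dataset).values
            mats.append((raw - raw.mean(1, keepdims=True))
                        / raw.std(1, ddof=1, keepdims=True))
        np.testing.assert_allclose(out.values, np.mean(mats, axis=0), atol=1e-12)

    def test_mismatched_protein_sets_rejected(self, small_dataset, tiny_submodel):
        import copy
        other = copy.copy(tiny_submodel)
        other.protein_ids = list(tiny_submodel.protein_ids[:-1])
        with pytest.raises(ModelError):
            pt.EnsembleModel([tiny_submodel, other])


def test_checkpoint_round_trip(tmp_path, small_dataset, tiny_submodel):
    """A saved and reloaded submodel reproduces predictions bit for bit."""
    from proteotrans.model import load_submodel, save_submodel

    _, dataset, _ = small_dataset
    save_submodel(tiny_submodel, tmp_path / "ckpt")
    loaded = load_submodel(tmp_path / "ckpt")
    np.testing.assert_array_equal(predict(tiny_submodel, dataset).values,
                                  predict(loaded, dataset).values)
    assert loaded.config == tiny_submodel.config


class TestAblationHook:
    def test_layer_removal_expressible_via_config(self):
        grid = enumerate_submodels({"encoder_sources": ("mrna", "premrna"),
                                    "merge_sets": (("decoded", "mrna"),)})
        assert all(c.encoder_source != "utr" for c in grid)
        assert all("utr" not in c.lr_inputs for c in grid)

    def test_zeroing_a_merge_input_equals_removing_its_weight(self):
        # the merge is linear, so a zeroed input and a zeroed weight agree
        rng = np.random.default_rng(0)
        d = rng.standard_normal((5, 3))
        x = rng.standard_normal((5, 3))
        w = {"a": rng.standard_normal(3), "b0": rng.standard_normal(3),
             "c": {"utr": rng.standard_normal(3)}}
        zero_input = lr_merge(d, {"utr": np.zeros_like(x)}, w)
        w0 = {**w, "c": {"utr": np.zeros(3)}}
        zero_weight = lr_merge(d, {"utr": x}, w0)
        np.testing.assert_allclose(zero_input, zero_weight)
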