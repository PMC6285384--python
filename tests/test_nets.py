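"""Architecture audits, training contracts, and activation extraction."""

import numpy as np
import pytest

from cdrp.nets import (AETrainConfig, AutoencoderSpec, CDRPAutoencoder,
                       CDRPMultiTask, EmbeddingMatrix, MTTrainConfig,
                       MultiTaskSpec, TrainingConfig, autoencoder_input_dim,
                       encode, extract_activations, train_autoencoder)


def _toy_labels(rng, n, signal=None):
    if signal is None:
        y = rng.integers(0, 2, size=n)
    else:
        y = (signal > np.median(signal)).astype(int)
    return y


class TestArchitectureAudit:
    def test_autoencoder_widths_at_reference_scale(self):
        """Encoder 250→128→128→64, decoder the exact mirror."""
        assert autoencoder_input_dim(12464) == 250
        ae = CDRPAutoencoder(AutoencoderSpec(input_dim=250), seed=0)
        assert ae.layer_widths == [250, 128, 128, 64, 128, 128, 250]

    def test_multitask_widths(self):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=100), seed=0)
        w = m.layer_widths
        assert w["shared"] == [256, 128, 64]
        assert w["merge"] == 128
        assert w["efs_branch"] == [8, 2]
        assert w["os_branch"] == [32, 16, 2]

    def test_embedding_free_merge_is_shared_width(self):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=100, use_embedding=False))
        assert m.layer_widths["merge"] == 64

    @pytest.mark.parametrize("layer,width", [
        ("shared_64", 64), ("merge_128", 128),
        ("os_branch_32", 32), ("efs_branch_8", 8),
    ])
    def test_extraction_dimensions(self, rng, layer, width):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=20), seed=1)
        X = rng.normal(size=(7, 20))
        emb = rng.normal(size=(7, 64))
        e = extract_activations(m, X, layer, embedding=emb)
        assert e.values.shape == (7, width)

    def test_merge_requires_embedding_model(self, rng):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=10, use_embedding=False))
        with pytest.raises(ValueError, match="merge_128"):
            extract_activations(m, rng.normal(size=(5, 10)), "merge_128")

    def test_unknown_layer_rejected(self, rng):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=10, use_embedding=False))
        with pytest.raises(ValueError, match="unknown layer"):
            extract_activations(m, rng.normal(size=(5, 10)), "trunk_7")


class TestAutoencoder:
    def test_structure_learned_better_than_shuffled_control(self, rng):
        """Rank-1 data reconstructs below a structure-destroyed control.

        The cohort must exceed the 64-wide code so the bottleneck binds:
        column-shuffled data (identical marginals, no low-rank structure)
        then cannot be compressed, while the rank-1 signal can.
        """
        n, p = 256, 128
        u = rng.normal(size=(n, 1))
        v = rng.normal(size=(1, p))
        X = u @ v + 0.05 * rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        shuffled = X.copy()
        for j in range(p):  # break the rank-1 structure
            rng.shuffle(shuffled[:, j])
        cfg = TrainingConfig(ae=AETrainConfig(epochs=100), seed=0)
        res = train_autoencoder(X, cfg)
        res_ctl = train_autoencoder(shuffled, cfg)
        assert res.reconstruction_mse < 0.8 * res_ctl.reconstruction_mse

    def test_untrained_model_finite_on_zero_input(self):
        ae = CDRPAutoencoder(AutoencoderSpec(input_dim=12), seed=0)
        X = np.zeros((4, 12))
        assert np.all(np.isfinite(ae.encode_values(X)))
        assert np.all(np.isfinite(ae.reconstruct(X)))

    def test_same_seed_identical_history(self, rng):
        X = rng.normal(size=(32, 10))
        cfg = TrainingConfig(ae=AETrainConfig(epochs=20), seed=3)
        h1 = train_autoencoder(X, cfg).model.history
        h2 = train_autoencoder(X, cfg).model.history
        assert h1 == h2

    def test_encode_shape_permutation_and_duplicates(self, rng):
        X = rng.normal(size=(9, 15))
        ae = CDRPAutoencoder(AutoencoderSpec(input_dim=15), seed=0)
        res_type = encode(ae, X)
        assert isinstance(res_type, EmbeddingMatrix)
        assert res_type.values.shape == (9, 64)
        perm = rng.permutation(9)
        np.testing.assert_allclose(encode(ae, X[perm]).values,
                                   res_type.values[perm])
        dup = np.vstack([X[0], X[0]])
        e = encode(ae, dup).values
        np.testing.assert_allclose(e[0], e[1])

    def test_feature_count_mismatch_rejected(self, rng):
        ae = CDRPAutoencoder(AutoencoderSpec(input_dim=15), seed=0)
        with pytest.raises(ValueError, match="features"):
            encode(ae, rng.normal(size=(3, 8)))


class TestMultiTaskTraining:
    def test_loss_weight_identity_at_init(self, rng):
        """Combined loss is exactly ce_efs + 2 · ce_os (no class weights)."""
        from cdrp.nn import categorical_crossentropy
        m = CDRPMultiTask(MultiTaskSpec(input_dim=12, use_embedding=False),
                          seed=0)
        X = rng.normal(size=(16, 12))
        y_e = rng.integers(0, 2, 16)
        y_o = rng.integers(0, 2, 16)
        combined, acts = m.combined_loss(X, y_e, y_o)
        ce_e = categorical_crossentropy(acts["efs_probs"], m._onehot(y_e))
        ce_o = categorical_crossentropy(acts["os_probs"], m._onehot(y_o))
        assert combined == pytest.approx(ce_e + 2.0 * ce_o, abs=1e-6)

    def test_training_loss_decreases_on_separable_data(self, rng):
        n = 64
        signal = rng.normal(size=n)
        X = np.column_stack([signal + 0.1 * rng.normal(size=n)
                             for _ in range(10)])
        y = (signal > 0).astype(int)
        m = CDRPMultiTask(MultiTaskSpec(input_dim=10, use_embedding=False),
                          seed=1)
        m.fit(X, y, y, cfg=MTTrainConfig(max_epochs=6, patience=100,
                                         class_weights=False), seed=2)
        losses = m.history["loss"]
        assert losses[4] < losses[0]

    def test_memorizes_small_fixture(self, rng):
        """Driven to near-zero loss, hard labels equal training labels."""
        X = rng.normal(size=(20, 10))
        y_e = rng.integers(0, 2, 20)
        y_o = rng.integers(0, 2, 20)
        while len(np.unique(y_e)) < 2 or len(np.unique(y_o)) < 2:
            y_e = rng.integers(0, 2, 20)
            y_o = rng.integers(0, 2, 20)
        m = CDRPMultiTask(MultiTaskSpec(input_dim=10, use_embedding=False),
                          seed=3)
        m.fit(X, y_e, y_o,
              cfg=MTTrainConfig(max_epochs=400, patience=400,
                                min_delta=0.0, class_weights=False),
              seed=4, validation=(X, y_e, y_o, None))
        pred = m.predict(X)
        np.testing.assert_array_equal(pred["efs"], y_e)
        np.testing.assert_array_equal(pred["os"], y_o)

    def test_probabilities_normalized_and_replicable(self, rng):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=8, use_embedding=False))
        X = rng.normal(size=(6, 8))
        probs = m.predict_proba(X)
        for task in ("efs", "os"):
            np.testing.assert_allclose(probs[task].sum(axis=1), 1.0,
                                       atol=1e-6)
        dup = np.vstack([X, X[:1]])
        p2 = m.predict_proba(dup)
        np.testing.assert_allclose(p2["efs"][-1], p2["efs"][0])

    def test_single_class_labels_rejected(self, rng):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=5, use_embedding=False))
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="single-class"):
            m.fit(X, np.zeros(10, dtype=int), rng.integers(0, 2, 10))

    def test_misaligned_embedding_rejected(self, rng):
        m = CDRPMultiTask(MultiTaskSpec(input_dim=5))
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="misaligned"):
            m.forward(X, rng.normal(size=(7, 64)))

    def test_same_seed_identical_training(self, rng):
        X = rng.normal(size=(40, 8))
        y_e = (X[:, 0] > 0).astype(int)
        y_o = (X[:, 1] > 0).astype(int)
        hs = []
        for _ in range(2):
            m = CDRPMultiTask(MultiTaskSpec(input_dim=8,
                                            use_embedding=False), seed=9)
            m.fit(X, y_e, y_o, cfg=MTTrainConfig(max_epochs=10, patience=10),
                  seed=10)
            hs.append(m.history["loss"])
        assert hs[0] == hs[1]


class TestGradientIsolation:
    def test_branch_gradients_do_not_cross(self, rng):
        """The OS loss sends no gradient into EFS-branch weights and vice
        versa; both reach the shared trunk."""
        m = CDRPMultiTask(MultiTaskSpec(input_dim=6, use_embedding=False),
                          seed=0)
        X = rng.normal(size=(12, 6))
        y_e = rng.integers(0, 2, 12)
        y_o = rng.integers(0, 2, 12)
        # OS-only loss
        _, acts = m.combined_loss(X, y_e, y_o,
                                  loss_weights={"efs": 0.0, "os": 1.0})
        m._backward_batch(acts, y_e, y_o, None, None,
                          {"efs": 0.0, "os": 1.0})
        assert all(np.all(l.gW == 0.0) for l in m.efs_layers)
        assert any(np.any(l.gW != 0.0) for l in m.os_layers)
        assert any(np.any(l.gW != 0.0) for l in m.trunk)
        # EFS-only loss
        _, acts = m.combined_loss(X, y_e, y_o,
                                  loss_weights={"efs": 1.0, "os": 0.0})
        m._backward_batch(acts, y_e, y_o, None, None,
                          {"efs": 1.0, "os": 0.0})
        assert all(np.all(l.gW == 0.0) for l in m.os_layers)
        assert any(np.any(l.gW != 0.0) for l in m.efs_layers)

    def test_backprop_matches_finite_differences(self, rng):
        """Spot-check analytic gradients on a tiny model."""
        m = CDRPMultiTask(MultiTaskSpec(input_dim=4, use_embedding=False),
                          seed=5)
        X = rng.normal(size=(5, 4))
        y_e = np.array([0, 1, 0, 1, 1])
        y_o = np.array([1, 0, 0, 1, 0])
        lw = {"efs": 1.0, "os": 2.0}
        loss, acts = m.combined_loss(X, y_e, y_o, loss_weights=lw)
        m._backward_batch(acts, y_e, y_o, None, None, lw)
        layer = m.trunk[0]
        for (i, j) in [(0, 0), (2, 5), (3, 100)]:
            eps = 1e-6
            orig = layer.W[i, j]
            layer.W[i, j] = orig + eps
            up, _ = m.combined_loss(X, y_e, y_o, loss_weights=lw)
            layer.W[i, j] = orig - eps
            dn, _ = m.combined_loss(X, y_e, y_o, loss_weights=lw)
            layer.W[i, j] = orig
            fd = (up - dn) / (2 * eps)
            assert layer.gW[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestCheckpoints:
    def test_multitask_round_trip(self, rng, tmp_path):
        """Saved and reloaded nets produce identical predictions."""
        from cdrp.nets import load_checkpoint, save_checkpoint
        m = CDRPMultiTask(MultiTaskSpec(input_dim=12), seed=1)
        save_checkpoint(m, tmp_path / "mt")
        back = load_checkpoint(tmp_path / "mt")
        X = rng.normal(size=(5, 12))
        emb = rng.normal(size=(5, 64))
        for task in ("efs", "os"):
            np.testing.assert_array_equal(
                m.predict_proba(X, emb)[task],
                back.predict_proba(X, emb)[task])
        assert back.spec == m.spec

    def test_autoencoder_round_trip(self, rng, tmp_path):
        from cdrp.nets import load_checkpoint, save_checkpoint
        ae = CDRPAutoencoder(AutoencoderSpec(input_dim=9), seed=2)
        ae.feature_ids = [f"g{j}" for j in range(9)]
        save_checkpoint(ae, tmp_path / "ae")
        back = load_checkpoint(tmp_path / "ae")
        X = rng.normal(size=(4, 9))
        np.testing.assert_array_equal(ae.encode_values(X),
                                      back.encode_values(X))
        assert back.feature_ids == ae.feature_ids
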