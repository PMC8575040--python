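import numpy as np
import pytest

from pepstruct import featurize as fz
from pepstruct import model as md
from pepstruct import synthetic as sy

from conftest import TINY_HP


def _tiny_batch(property_matrix, n_items=3, seed=1):
    corpus = sy.make_training_corpus(10, length_range=(5, 8), seed=seed)
    items = [
        (fz.encode_peptide(rec, property_matrix, tt.offset), tt)
        for rec, tt, _ in corpus[:n_items]
    ]
    return md._sample_batch(items)


class TestBuildNetwork:
    def test_concatenated_input_width_is_77_for_default_embedding(self, property_matrix):
        net = md.build_network(md.NetworkHyperparams(conv_filters=4, dense_units=8))
        batch = _tiny_batch(property_matrix)
        net.forward(batch)
        assert net._in_width == 77  # 12 + 15 + 50

    def test_distance_heads_non_negative_trig_head_bounded(self, property_matrix):
        net = md.build_network(TINY_HP, seed=3)
        pred = net.forward(_tiny_batch(property_matrix))
        assert np.all(pred["dca"] >= 0)
        assert np.all(pred["dcb"] >= 0)
        assert np.all(np.abs(pred["trig"]) <= 1.0)

    def test_head_outputs_masked(self, property_matrix):
        net = md.build_network(TINY_HP, seed=3)
        batch = _tiny_batch(property_matrix)
        pred = net.forward(batch)
        assert np.all(pred["dca"][batch["M"] == 0] == 0)
        assert np.all(pred["trig"][batch["m"] == 0] == 0)

    def test_out_sizes_validated(self):
        with pytest.raises(ValueError, match="reshape"):
            md.NetworkHyperparams(out_sizes=(100, 100, 100))


class TestMaskedMse:
    def test_perfect_prediction_zero(self):
        y = np.arange(6.0).reshape(2, 3)
        assert md.masked_mse(y, y, np.ones_like(y)) == 0.0

    def test_hand_computed_example(self):
        y_true = np.array([1.0, 3.0])
        y_pred = np.array([1.0, 1.0])
        assert md.masked_mse(y_true, y_pred, np.array([1.0, 1.0])) == pytest.approx(2.0)

    def test_all_zero_mask_defined_as_zero(self):
        y = np.ones(4)
        assert md.masked_mse(y, y + 5.0, np.zeros(4)) == 0.0

    def test_zero_error_entry_does_not_increase_loss(self):
        y_true = np.array([1.0, 3.0, 7.0])
        y_pred = np.array([1.0, 1.0, 7.0])
        narrow = md.masked_mse(y_true, y_pred, np.array([1.0, 1.0, 0.0]))
        wide = md.masked_mse(y_true, y_pred, np.array([1.0, 1.0, 1.0]))
        assert wide <= narrow

    def test_loss_ignores_masked_out_entries(self, property_matrix):
        net = md.build_network(TINY_HP, seed=5)
        batch = _tiny_batch(property_matrix)
        pred = net.forward(batch)
        loss_a, _ = md._loss_and_grads(pred, batch)
        tampered = {k: v.copy() for k, v in pred.items()}
        tampered["dca"] = tampered["dca"] + 100.0 * (1.0 - batch["mask_ca"])
        loss_b, _ = md._loss_and_grads(tampered, batch)
        assert loss_b == pytest.approx(loss_a)


class TestBackprop:
    def test_gradients_match_finite_differences(self, property_matrix):
        hp = md.NetworkHyperparams(
            embed_dim=4, conv_filters=6, conv_window=3, n_res_blocks=1,
            dense_units=8, dropout_rate=0.0,
        )
        net = md.build_network(hp, seed=0)
        batch = _tiny_batch(property_matrix)
        pred = net.forward(batch, training=True)
        _, head_grads = md._loss_and_grads(pred, batch)
        net.backward(head_grads)
        grads = net.gradients()
        params = net.parameters()
        rng = np.random.default_rng(6)
        eps = 1e-2  # float32 arithmetic: central differences need a wide step
        checked = 0
        for key in ("stem.W", "block0_g1.a_W", "dense.W", "head_cb.W", "emb.W"):
            arr, g = params[key], grads[key]
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                old = arr[idx]
                arr[idx] = old + eps
                lp = md._loss_and_grads(net.forward(batch, training=True), batch)[0]
                arr[idx] = old - eps
                lm = md._loss_and_grads(net.forward(batch, training=True), batch)[0]
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                if abs(num) > 5e-3:
                    assert g[idx] == pytest.approx(num, rel=0.05)
                    checked += 1
        assert checked >= 5

    def test_inference_is_deterministic(self, property_matrix):
        net = md.build_network(TINY_HP, seed=1)
        batch = _tiny_batch(property_matrix)
        a = net.forward(batch, training=False)
        b = net.forward(batch, training=False)
        for k in a:
            assert np.array_equal(a[k], b[k])


class TestTrainCv:
    def test_fold_partition_is_disjoint_cover(self, tiny_bundle, tiny_corpus):
        assignment = tiny_bundle.fold_assignment
        assert set(assignment) == {rec.id for rec, _ in tiny_corpus}
        assert set(assignment.values()) == {0, 1}

    def test_each_fold_validates_once_with_equal_folds(self, property_matrix):
        corpus = [(rec, ens) for rec, _, ens in sy.make_training_corpus(10, length_range=(5, 7), seed=2)]
        bundle, _ = md.train_cv(corpus, property_matrix, TINY_HP, folds=10, seed=0, epochs=1)
        counts = [list(bundle.fold_assignment.values()).count(k) for k in range(10)]
        assert counts == [1] * 10

    def test_fewer_records_than_folds_rejected(self, property_matrix):
        corpus = [(rec, ens) for rec, _, ens in sy.make_training_corpus(10, length_range=(5, 7), seed=2)]
        with pytest.raises(ValueError, match="at least"):
            md.train_cv(corpus[:4], property_matrix, TINY_HP, folds=5, epochs=1)

    def test_retained_model_is_argmin_of_history(self, property_matrix, tiny_corpus):
        bundle, history = md.train_cv(
            tiny_corpus, property_matrix, TINY_HP, folds=2, seed=1, epochs=3
        )
        for fold, h in enumerate(history):
            assert bundle.best_epochs[fold] == int(np.argmin(h))
            assert bundle.best_val_losses[fold] == pytest.approx(min(h))


class TestPredictEnsemble:
    def test_output_shapes_and_symmetry(self, tiny_bundle):
        rec = sy.make_training_corpus(10, length_range=(8, 8), seed=5)[0][0]
        stats = md.predict_ensemble(rec, tiny_bundle)
        n = len(rec)
        assert stats.dca_mean.shape == (n, n)
        assert np.allclose(stats.dca_mean, stats.dca_mean.T)
        assert np.allclose(np.diag(stats.dca_mean), 0.0)
        assert stats.trig_mean.shape == (n, 4)

    def test_undefined_entries_are_nan(self, tiny_bundle):
        corpus = sy.make_training_corpus(30, length_range=(6, 12), seed=8)
        rec = next(r for r, _, _ in corpus if "G" in r.sequence)
        stats = md.predict_ensemble(rec, tiny_bundle)
        g = rec.sequence.index("G")
        assert np.isnan(stats.dcb_mean[g, :]).all()
        assert np.isnan(stats.trig_mean[0, 0])  # phi of residue 1
        assert np.isnan(stats.trig_mean[len(rec) - 1, 2])  # psi of last

    def test_out_of_range_length_rejected(self, tiny_bundle):
        from pepstruct.structures import PeptideRecord

        with pytest.raises(ValueError, match="5, 40"):
            md.predict_ensemble(PeptideRecord(id="x", sequence="AAAA"), tiny_bundle)

    def test_duplicate_fold_models_add_no_variance(self, tiny_bundle):
        rec = sy.make_training_corpus(10, length_range=(7, 7), seed=9)[0][0]
        single = md.ModelBundle(
            networks=[tiny_bundle.networks[0]],
            fold_assignment=tiny_bundle.fold_assignment,
            best_val_losses=tiny_bundle.best_val_losses[:1],
            best_epochs=tiny_bundle.best_epochs[:1],
            hyperparams=tiny_bundle.hyperparams,
            seed=tiny_bundle.seed,
            A=tiny_bundle.A,
        )
        dup = md.ModelBundle(
            networks=[tiny_bundle.networks[0]] * 3,
            fold_assignment=tiny_bundle.fold_assignment,
            best_val_losses=tiny_bundle.best_val_losses[:1] * 3,
            best_epochs=tiny_bundle.best_epochs[:1] * 3,
            hyperparams=tiny_bundle.hyperparams,
            seed=tiny_bundle.seed,
            A=tiny_bundle.A,
        )
        a = md.predict_ensemble(rec, single)
        b = md.predict_ensemble(rec, dup)
        assert np.allclose(np.nan_to_num(a.dca_sd), np.nan_to_num(b.dca_sd), atol=1e-6)


class TestSerialization:
    def test_save_load_round_trip(self, tiny_bundle, tmp_path):
        md.save_bundle(tiny_bundle, tmp_path / "bundle")
        back = md.load_bundle(tmp_path / "bundle")
        assert back.n_folds == tiny_bundle.n_folds
        assert back.fold_assignment == tiny_bundle.fold_assignment
        rec = sy.make_training_corpus(10, length_range=(6, 6), seed=4)[0][0]
        a = md.predict_ensemble(rec, tiny_bundle)
        b = md.predict_ensemble(rec, back)
        assert np.allclose(np.nan_to_num(a.dca_mean), np.nan_to_num(b.dca_mean), atol=1e-6)
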