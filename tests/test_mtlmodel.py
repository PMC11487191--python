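"""Masked-loss multitask ensemble: loss, gradients, training, prediction."""

import numpy as np
import pandas as pd
import pytest

import concshift as cs
from concshift.mtlmodel import _MLP, TrainConfig, masked_bce


class TestMaskedBce:
    def test_single_cell(self):
        out = np.array([[0.5]])
        lab = np.array([[1.0]])
        assert masked_bce(out, lab) == pytest.approx(np.log(2.0))

    def test_all_masked_is_zero_with_warning(self):
        out = np.array([[0.3, 0.7]])
        lab = np.full((1, 2), np.nan)
        with pytest.warns(UserWarning):
            assert masked_bce(out, lab) == 0.0

    def test_full_mask_equals_plain_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=(20, 4))
        y = rng.integers(0, 2, size=(20, 4)).astype(float)
        plain = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert masked_bce(p, y) == pytest.approx(plain, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            masked_bce(np.zeros((2, 2)) + 0.5, np.zeros((3, 2)))


class TestGradients:
    def test_masked_cells_have_zero_gradient(self):
        rng = np.random.default_rng(1)
        net = _MLP(n_features=6, n_tasks=3, hidden_sizes=(8,), dropout=0.0,
                   rng=rng)
        x = rng.normal(size=(5, 6))
        y = rng.integers(0, 2, size=(5, 3)).astype(float)
        mask = rng.random((5, 3)) < 0.5
        p, cache = net.forward(x)
        # gradient w.r.t. the logits is (p - y) * mask / n: exactly zero
        # wherever the mask is off
        n = max(int(mask.sum()), 1)
        delta = (p - y) * mask / n
        assert (delta[~mask] == 0.0).all()
        gw, gb = net.backward(p, y, mask, cache)
        # flipping a masked label changes nothing
        y2 = y.copy()
        y2[~mask] = 1.0 - y2[~mask]
        gw2, gb2 = net.backward(p, y2, mask, cache)
        for a, b in zip(gw + gb, gw2 + gb2):
            np.testing.assert_array_equal(a, b)

    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        net = _MLP(n_features=4, n_tasks=2, hidden_sizes=(5,), dropout=0.0,
                   rng=rng)
        x = rng.normal(size=(6, 4))
        y = rng.integers(0, 2, size=(6, 2)).astype(float)
        mask = rng.random((6, 2)) < 0.7

        def loss():
            p, _ = net.forward(x)
            return masked_bce(p, np.where(mask, y, np.nan))

        p, cache = net.forward(x)
        gw, _ = net.backward(p, y, mask, cache)
        eps = 1e-6
        for (i, j) in [(0, 0), (2, 3)]:
            w = net.weights[0]
            orig = w[i, j]
            w[i, j] = orig + eps
            up = loss()
            w[i, j] = orig - eps
            down = loss()
            w[i, j] = orig
            assert gw[0][i, j] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


def _separable_problem(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 10))
    w = rng.normal(size=(10, 2))
    y = (x @ w > 0).astype(float)
    return x, y


class TestTrainEnsemble:
    def test_training_reduces_loss(self):
        x, y = _separable_problem()
        cfg = TrainConfig(n_members=1, hidden_sizes=(16,), dropout=0.0,
                          n_iterations=800, seed=0)
        model = cs.train_ensemble(x, y, cfg)
        final = masked_bce(model.predict_proba(x), y)
        assert final < np.log(2.0) * 0.5  # well below chance-level BCE

    def test_seeded_determinism(self):
        x, y = _separable_problem(seed=3)
        cfg = TrainConfig(n_members=2, hidden_sizes=(8,), n_iterations=50, seed=9)
        a = cs.train_ensemble(x, y, cfg).predict_proba(x[:10])
        b = cs.train_ensemble(x, y, cfg).predict_proba(x[:10])
        np.testing.assert_array_equal(a, b)

    def test_row_mismatch_raises(self):
        x, y = _separable_problem()
        with pytest.raises(ValueError):
            cs.train_ensemble(x[:-1], y)

    def test_trains_well_on_default_screen(self, default_screen):
        """High-concentration features support strong moderate models."""
        ds = default_screen
        ids = ds.scaffolds.index
        labels = cs.binarize(cs.ActivityMatrix(ds.activity.wide.reindex(ids)), 5.0)
        x = ds.features(ids, 20.0)
        cfg = TrainConfig(n_members=2, hidden_sizes=(64, 32), dropout=0.1,
                          n_iterations=600, seed=0)
        model = cs.train_ensemble(x, labels, cfg)
        probs = model.predict_proba_frame(x, ids)
        aucs = []
        for assay in labels.wide.columns:
            y = labels.wide[assay].dropna()
            aucs.append(cs.auc_roc(probs.loc[y.index, assay], y))
        assert np.median(aucs) > 0.8
        assert np.mean(np.asarray(aucs) > 0.8) > 0.5

    def test_no_signal_gives_chance_auc(self):
        """With zero phenotype amplitude held-out AUC sits at 0.5."""
        cfg = cs.SimConfig(n_compounds=600, n_assays=4, n_features=40,
                           n_scaffolds=300, signature_scale=0.0, seed=2)
        ds = cs.generate_library(cfg)
        ids = ds.scaffolds.index
        half = ids[:300]
        rest = ids[300:]
        labels = cs.binarize(cs.ActivityMatrix(ds.activity.wide.reindex(half)), 5.0)
        x = ds.features(half, 20.0)
        model = cs.train_ensemble(
            x, labels, TrainConfig(n_members=2, hidden_sizes=(16,),
                                   n_iterations=200, seed=0))
        probs = model.predict_proba_frame(ds.features(rest, 20.0), rest)
        truth = cs.binarize(cs.ActivityMatrix(ds.latent.wide.reindex(rest)), 5.0)
        aucs = []
        for assay in truth.wide.columns:
            y = truth.wide[assay].dropna()
            aucs.append(cs.auc_roc(probs.loc[y.index, assay], y))
        se = 1.0 / np.sqrt(len(rest))  # coarse binomial-style scale
        assert abs(np.mean(aucs) - 0.5) < 4 * se


class TestPredictProba:
    def test_mean_aggregation(self):
        class Stub:
            def __init__(self, value):
                self.value = value

            def predict_proba(self, x):
                return np.full((x.shape[0], 1), self.value)

        model = cs.EnsembleModel(members=[Stub(0.2), Stub(0.4)], n_features=3,
                                 tasks=["a"], config=TrainConfig(n_members=2))
        out = model.predict_proba(np.zeros((4, 3)))
        np.testing.assert_allclose(out, 0.3)

    def test_single_member_identity(self):
        x, y = _separable_problem(seed=5)
        cfg = TrainConfig(n_members=1, hidden_sizes=(8,), n_iterations=30, seed=1)
        model = cs.train_ensemble(x, y, cfg)
        np.testing.assert_array_equal(model.predict_proba(x[:5]),
                                      model.members[0].predict_proba(x[:5]))

    def test_outputs_in_open_unit_interval(self):
        x, y = _separable_problem(seed=6)
        model = cs.train_ensemble(
            x, y, TrainConfig(n_members=1, hidden_sizes=(8,), n_iterations=30))
        p = model.predict_proba(np.full((3, 10), 1e3))
        assert ((p > 0) & (p < 1)).all()

    def test_dimension_mismatch(self):
        x, y = _separable_problem()
        model = cs.train_ensemble(
            x, y, TrainConfig(n_members=1, hidden_sizes=(4,), n_iterations=10))
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 7)))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        x, y = _separable_problem(seed=8)
        model = cs.train_ensemble(
            x, y, TrainConfig(n_members=2, hidden_sizes=(8,), n_iterations=40))
        model.save(tmp_path / "model")
        back = cs.EnsembleModel.load(tmp_path / "model")
        np.testing.assert_allclose(back.predict_proba(x[:7]),
                                   model.predict_proba(x[:7]))
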