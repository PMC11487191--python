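"""Conformal calibration: conformity scores, p-values, decisions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import concshift as cs
from concshift.datamodel import BinaryLabels, FoldAssignment
from concshift.mccp import CalibrationSet, MondrianCrossConformal
from concshift.mtlmodel import TrainConfig


def brute_force_pvalue(calibration, test):
    """Counting definition, written independently of the implementation."""
    count = 0
    for a in calibration:
        if a <= test:
            count += 1
    return count / len(calibration)


class TestConformityMeasure:
    @pytest.mark.parametrize("label, output, expected", [
        (1, 0.9, 0.9),
        (0, 0.9, 0.1),
        (0, 0.0, 1.0),
    ])
    def test_values(self, label, output, expected):
        assert cs.conformity_measure(label, output) == pytest.approx(expected)

    def test_rejects_non_binary_label(self):
        with pytest.raises(ValueError):
            cs.conformity_measure(2, 0.5)


class TestPvalue:
    def test_inclusive_count(self):
        assert cs.pvalue([0.2, 0.5, 0.8], 0.5) == pytest.approx(2 / 3)

    def test_extremes(self):
        assert cs.pvalue([0.2, 0.5, 0.8], 0.1) == 0.0
        assert cs.pvalue([0.2, 0.5, 0.8], 0.9) == 1.0

    def test_empty_calibration_raises(self):
        with pytest.raises(ValueError):
            cs.pvalue([], 0.5)

    def test_matches_counting_oracle_on_random_sets(self):
        """1000 random small calibration sets against brute-force counts."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            cal = np.round(rng.random(n), 3)  # rounding forces ties
            t = float(np.round(rng.random(), 3))
            assert cs.pvalue(cal, t) == pytest.approx(brute_force_pvalue(cal, t))

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_max_is_one(self, cal, t1, t2):
        lo, hi = sorted((t1, t2))
        assert cs.pvalue(cal, lo) <= cs.pvalue(cal, hi)
        assert cs.pvalue(cal, max(cal)) == 1.0

    def test_smoothed_variant(self):
        assert cs.pvalue([0.2, 0.5, 0.8], 0.5, smoothed=True) == pytest.approx(3 / 4)


class TestConformalDecision:
    @pytest.mark.parametrize("p0, p1, expected", [
        (0.01, 0.50, 1),
        (0.50, 0.01, -1),
        (0.05, 0.05, 0),    # neither strictly exceeds epsilon
        (0.50, 0.50, 0),    # both exceed: uncertain
        (float("nan"), 0.5, 0),
    ])
    def test_rule(self, p0, p1, expected):
        assert cs.conformal_decision(p0, p1, 0.05) == expected

    def test_exhaustive_on_dense_grid(self):
        """Decision regions partition the unit square at epsilon = 0.05."""
        eps = 0.05
        grid = np.linspace(0.0, 1.0, 101)
        p0, p1 = np.meshgrid(grid, grid)
        dec = cs.conformal_decision(p0.ravel(), p1.ravel(), eps)
        expected = np.zeros(p0.size, dtype=int)
        for i, (a, b) in enumerate(zip(p0.ravel(), p1.ravel())):
            if b > eps and a <= eps:
                expected[i] = 1
            elif a > eps and b <= eps:
                expected[i] = -1
        np.testing.assert_array_equal(dec, expected)
        assert set(np.unique(dec)) == {-1, 0, 1}

    def test_rejects_bad_epsilon(self):
        with pytest.raises(ValueError):
            cs.conformal_decision(0.5, 0.5, 0.0)


class _StubModel:
    """Deterministic 'ensemble' whose output is the first feature value."""

    def __init__(self, n_tasks):
        self.n_tasks = n_tasks

    def predict_proba(self, x):
        return np.tile(np.clip(x[:, :1], 0.0, 1.0), (1, self.n_tasks))

    def predict_proba_frame(self, x, index):
        return pd.DataFrame(self.predict_proba(x), index=index,
                            columns=[f"t{j}" for j in range(self.n_tasks)])


def _manual_mccp(calibration_folds, task="t0"):
    """Assemble a fitted MCCP object from handcrafted calibration folds.

    ``calibration_folds``: list of (outputs, labels) per fold where
    outputs is the stub-model probability per calibration compound.
    """
    mccp = MondrianCrossConformal(TrainConfig(n_members=1))
    mccp.tasks = [task]
    for outputs, labels in calibration_folds:
        idx = pd.Index([f"c{i}" for i in range(len(outputs))])
        out_frame = pd.DataFrame({task: outputs}, index=idx)
        lab_frame = BinaryLabels(pd.DataFrame({task: labels}, index=idx), 0.5)
        mccp.fold_models.append(_StubModel(1))
        mccp.calibration_sets.append(CalibrationSet.from_outputs(out_frame, lab_frame))
        mccp.fold_indices.append(idx)
    mccp.full_model = _StubModel(1)
    return mccp


class TestCrossConformal:
    def test_pvalues_average_over_folds(self):
        """Two handcrafted folds against a full brute-force enumeration."""
        fold_a = ([0.9, 0.8, 0.2, 0.1], [1.0, 1.0, 0.0, 0.0])
        fold_b = ([0.7, 0.3, 0.6, 0.4], [1.0, 0.0, 1.0, 0.0])
        mccp = _manual_mccp([fold_a, fold_b])
        x_test = np.array([[0.65]])
        res = mccp.predict(x_test, index=pd.Index(["q"]), epsilon=0.05)

        # brute force: alphas are active outputs, betas are 1 - inactive outputs
        p1_folds = []
        p0_folds = []
        for outputs, labels in (fold_a, fold_b):
            alphas = [o for o, l in zip(outputs, labels) if l == 1.0]
            betas = [1 - o for o, l in zip(outputs, labels) if l == 0.0]
            p1_folds.append(brute_force_pvalue(alphas, 0.65))
            p0_folds.append(brute_force_pvalue(betas, 1 - 0.65))
        assert res.loc[0, "p_active"] == pytest.approx(np.mean(p1_folds))
        assert res.loc[0, "p_inactive"] == pytest.approx(np.mean(p0_folds))

    def test_fold_with_empty_class_is_skipped(self):
        fold_a = ([0.9, 0.1], [1.0, 0.0])
        fold_b = ([0.8, 0.7], [1.0, 1.0])  # no inactives here
        mccp = _manual_mccp([fold_a, fold_b])
        res = mccp.predict(np.array([[0.5]]), epsilon=0.05)
        # p_active averages both folds; p_inactive only fold A
        assert res.loc[0, "p_active"] == pytest.approx(
            np.mean([brute_force_pvalue([0.9], 0.5),
                     brute_force_pvalue([0.8, 0.7], 0.5)]))
        assert res.loc[0, "p_inactive"] == pytest.approx(
            brute_force_pvalue([1 - 0.1], 0.5))

    def test_class_empty_in_all_folds_gives_uncertain(self):
        folds = [([0.9, 0.8], [1.0, 1.0]), ([0.7, 0.6], [1.0, 1.0])]
        mccp = _manual_mccp(folds)
        with pytest.warns(UserWarning):
            res = mccp.predict(np.array([[0.99]]), epsilon=0.05)
        assert np.isnan(res.loc[0, "p_inactive"])
        assert res.loc[0, "decision"] == 0

    def test_end_to_end_determinism(self, small_screen):
        ds = small_screen
        ids = ds.scaffolds.index
        labels = cs.binarize(cs.ActivityMatrix(ds.activity.wide.reindex(ids)), 5.0)
        folds = cs.assign_folds(ds.scaffolds, k=3, seed=0)
        x = ds.features(ids, 20.0)
        x_test = ds.features(ids[:20], 0.8)
        cfg = TrainConfig(n_members=1, hidden_sizes=(16,), n_iterations=60, seed=2)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cs.cross_conformal(x, labels, folds, x_test, train_config=cfg)
            b = cs.cross_conformal(x, labels, folds, x_test, train_config=cfg)
        pd.testing.assert_frame_equal(a, b)
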