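"""Mondrian cross-conformal prediction (MCCP).

Turns raw classifier probabilities into per-task, per-class p-values
with a finite-sample exchangeability guarantee, and into three-way
decisions (Active / Inactive / Uncertain). Mondrian here means the
calibration scores are pooled only within one (task, class) cell, so
validity holds per class even under heavy class imbalance.

Procedure: the training set is split into k scaffold-grouped folds.
For each fold, an ensemble is trained on the other k-1 folds; the held
-out fold provides calibration conformity scores, and the same fold
model scores the test compounds. Per-fold p-values are averaged over
folds. The conformity measure of a probability ``output`` under a
hypothesised ``label`` is ``|1 - label - output|`` — the probability
mass the model puts on that label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import BinaryLabels, FoldAssignment
from .mtlmodel import EnsembleModel, TrainConfig, train_ensemble


def conformity_measure(label, output):
    """Conformity of a probability output to a hypothesised label.

    ``|1 - label - output|``: for label 1 this is the output itself,
    for label 0 it is ``1 - output``. Labels must be 0 or 1.
    """
    lab = np.asarray(label, dtype=float)
    if not np.isin(lab, (0.0, 1.0)).all():
        raise ValueError("label must be 0 or 1")
    out = np.abs(1.0 - lab - np.asarray(output, dtype=float))
    if np.isscalar(label) and np.isscalar(output):
        return float(out)
    return out


def pvalue(calibration_scores, test_score, smoothed: bool = False):
    """Conformal p-value: fraction of calibration scores <= test score.

    Inclusive and unsmoothed by default, exactly the counting formula
    ``|{i: a_i <= a_t}| / n``. With ``smoothed=True`` the common
    ``(count + 1) / (n + 1)`` correction is applied instead. Raises on
    an empty calibration set (the p-value is undefined, not 0).
    """
    cal = np.sort(np.asarray(calibration_scores, dtype=float))
    if cal.size == 0:
        raise ValueError("empty calibration set: p-value undefined")
    t = np.asarray(test_score, dtype=float)
    count = np.searchsorted(cal, t, side="right")
    p = (count + 1.0) / (cal.size + 1.0) if smoothed else count / cal.size
    if np.isscalar(test_score):
        return float(p)
    return p


def conformal_decision(p0, p1, epsilon: float = 0.05):
    """Three-way decision from the two p-values at significance epsilon.

    1 (Active)    iff p1 > eps and p0 <= eps;
    -1 (Inactive) iff p0 > eps and p1 <= eps;
    0 (Uncertain) otherwise — both p-values above eps, both at or
    below, or either undefined (NaN).
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must be in (0, 1)")
    p0a = np.asarray(p0, dtype=float)
    p1a = np.asarray(p1, dtype=float)
    active = (p1a > epsilon) & (p0a <= epsilon)
    inactive = (p0a > epsilon) & (p1a <= epsilon)
    out = np.where(active, 1, np.where(inactive, -1, 0))
    out = np.where(np.isnan(p0a) | np.isnan(p1a), 0, out)
    if np.isscalar(p0) and np.isscalar(p1):
        return int(out)
    return out


@dataclass
class CalibrationSet:
    """Per-task conformity scores from one calibration fold.

    ``alphas[task]`` holds the sorted conformity scores of that fold's
    actives; ``betas[task]`` those of its inactives. Either may be
    empty when the fold lacks that class for the task.
    """

    alphas: dict
    betas: dict

    @classmethod
    def from_outputs(cls, outputs: pd.DataFrame, labels: BinaryLabels) -> "CalibrationSet":
        alphas: dict = {}
        betas: dict = {}
        y = labels.wide.reindex(index=outputs.index, columns=outputs.columns)
        for task in outputs.columns:
            p = outputs[task].to_numpy(dtype=float)
            lab = y[task].to_numpy(dtype=float)
            act = lab == 1.0
            inact = lab == 0.0
            alphas[task] = np.sort(conformity_measure(1.0, p[act])) if act.any() else np.array([])
            betas[task] = np.sort(conformity_measure(0.0, p[inact])) if inact.any() else np.array([])
        return cls(alphas=alphas, betas=betas)


class MondrianCrossConformal:
    """Fitted cross-conformal calibrator over scaffold folds.

    ``fit`` trains one ensemble per fold (on the other folds) and
    stores each fold's calibration scores; it also trains — or accepts
    — a full-data ensemble whose mean probability is kept as the
    auxiliary ranking score. ``predict`` can then be applied to feature
    matrices from *any* imaging concentration: this is what makes
    concentration-shift inference a pure inference-time change.
    """

    def __init__(self, train_config: TrainConfig, smoothed: bool = False):
        self.train_config = train_config
        self.smoothed = smoothed
        self.fold_models: list[EnsembleModel] = []
        self.calibration_sets: list[CalibrationSet] = []
        self.fold_indices: list[pd.Index] = []
        self.full_model: EnsembleModel | None = None
        self.tasks: list = []

    def fit(self, features: np.ndarray, labels: BinaryLabels,
            folds: FoldAssignment, full_model: EnsembleModel | None = None,
            ) -> "MondrianCrossConformal":
        """Train fold models and collect calibration scores.

        ``features`` rows must align with ``labels.wide.index`` (the
        training compounds). Ensembles see only the other k-1 folds'
        rows; each held-out fold is scored by its own fold model.
        """
        x = np.asarray(features, dtype=float)
        compounds = labels.wide.index
        if x.shape[0] != len(compounds):
            raise ValueError("features must be row-aligned with labels")
        self.tasks = list(labels.wide.columns)
        pos = pd.Series(np.arange(len(compounds)), index=compounds)
        member_seeds = np.random.SeedSequence(self.train_config.seed).spawn(folds.k)
        for fold in range(folds.k):
            cal_ids = folds.fold_compounds(fold).intersection(compounds)
            fit_ids = compounds.difference(cal_ids)
            fit_labels = labels.restrict(fit_ids)
            if not fit_labels.mask.to_numpy().any():
                warnings.warn(f"fold {fold}: no labels to train on; skipped", stacklevel=2)
                continue
            fold_seed = int(member_seeds[fold].generate_state(1)[0] % (2**31))
            cfg = replace(self.train_config, seed=fold_seed)
            model = train_ensemble(x[pos[fit_labels.wide.index].to_numpy()], fit_labels, cfg)
            cal_out = model.predict_proba_frame(x[pos[cal_ids].to_numpy()], cal_ids) if len(cal_ids) else \
                pd.DataFrame(columns=self.tasks)
            self.fold_models.append(model)
            self.calibration_sets.append(
                CalibrationSet.from_outputs(cal_out, labels)
            )
            self.fold_indices.append(cal_ids)
        if full_model is None:
            full_model = train_ensemble(x, labels, self.train_config)
        self.full_model = full_model
        return self

    def out_of_fold_scores(self, features: np.ndarray,
                           labels: BinaryLabels) -> pd.DataFrame:
        """Held-out probability per training compound (fold-model scores).

        Used downstream for the cross-validated model-quality gate.
        """
        x = np.asarray(features, dtype=float)
        compounds = labels.wide.index
        pos = pd.Series(np.arange(len(compounds)), index=compounds)
        parts = []
        for model, cal_ids in zip(self.fold_models, self.fold_indices):
            if len(cal_ids):
                parts.append(model.predict_proba_frame(x[pos[cal_ids].to_numpy()], cal_ids))
        if not parts:
            return pd.DataFrame(columns=self.tasks)
        return pd.concat(parts).reindex(compounds)

    def predict(self, features: np.ndarray, index=None,
                epsilon: float = 0.05) -> pd.DataFrame:
        """Conformal p-values, decisions and ranking scores per cell.

        Returns a long DataFrame with columns ``compound_id``,
        ``assay_id``, ``p_inactive``, ``p_active``, ``decision`` and
        ``probability`` (the full-model mean probability). A fold whose
        calibration set lacks a class for a task is skipped in that
        task's p-value average; if every fold is skipped the p-value is
        NaN and the decision is 0 (Uncertain).
        """
        if self.full_model is None:
            raise RuntimeError("predict() before fit()")
        x = np.asarray(features, dtype=float)
        n = x.shape[0]
        if index is None:
            index = pd.RangeIndex(n)
        t = len(self.tasks)
        p1_sum = np.zeros((n, t)); p1_cnt = np.zeros((n, t), dtype=int)
        p0_sum = np.zeros((n, t)); p0_cnt = np.zeros((n, t), dtype=int)
        for model, cal in zip(self.fold_models, self.calibration_sets):
            out = model.predict_proba(x)
            for j, task in enumerate(self.tasks):
                if cal.alphas[task].size:
                    p1_sum[:, j] += pvalue(cal.alphas[task], out[:, j], self.smoothed)
                    p1_cnt[:, j] += 1
                if cal.betas[task].size:
                    p0_sum[:, j] += pvalue(cal.betas[task], 1.0 - out[:, j], self.smoothed)
                    p0_cnt[:, j] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(p1_cnt > 0, p1_sum / np.maximum(p1_cnt, 1), np.nan)
            p0 = np.where(p0_cnt > 0, p0_sum / np.maximum(p0_cnt, 1), np.nan)
        for j, task in enumerate(self.tasks):
            if p1_cnt[:, j].max(initial=0) == 0 or p0_cnt[:, j].max(initial=0) == 0:
                warnings.warn(
                    f"task {task}: a calibration class is empty in all folds; "
                    "decisions are Uncertain", stacklevel=2)
        decision = conformal_decision(p0, p1, epsilon)
        prob = self.full_model.predict_proba(x)
        long = pd.DataFrame({
            "compound_id": np.repeat(np.asarray(index), t),
            "assay_id": np.tile(np.asarray(self.tasks, dtype=object), n),
            "p_inactive": p0.ravel(),
            "p_active": p1.ravel(),
            "decision": decision.ravel().astype(int),
            "probability": prob.ravel(),
        })
        return long


def cross_conformal(train_features, train_labels: BinaryLabels,
                    folds: FoldAssignment, test_features, test_index=None,
                    train_config: TrainConfig = TrainConfig(),
                    epsilon: float = 0.05,
                    full_model: EnsembleModel | None = None) -> pd.DataFrame:
    """One-shot cross-conformal run (fit + predict).

    Convenience wrapper around :class:`MondrianCrossConformal` for
    callers that do not need to reuse the fitted fold models across
    several inference feature sets.
    """
    mccp = MondrianCrossConformal(train_config)
    mccp.fit(train_features, train_labels, folds, full_model=full_model)
    return mccp.predict(test_features, index=test_index, epsilon=epsilon)
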