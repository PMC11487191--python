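"""Concentration-shift experiment orchestration.

The method under study: train a multitask activity model on profiles
imaged at a *high* concentration with labels binarized at a *moderate*
potency threshold (where positives are plentiful), calibrate it with
Mondrian cross-conformal prediction, then run inference on profiles of
the held-out compounds imaged at a *lower* concentration. Because
signal amplitude follows the dose-response curve, at low imaging
concentration only highly potent compounds still present the signal
the model was trained to recognise — so the moderate-potency model
selectively retrieves high-potency compounds without retraining.

The conventional alternative — training directly at the high potency
threshold and inferring at the training concentration — serves as the
comparison baseline. Models are named
``[train conc / inference conc / train threshold]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    ActivityMatrix,
    BinaryLabels,
    EligibilityCriteria,
    FoldAssignment,
    ScreenDataset,
    assign_folds,
    binarize,
    filter_assays,
    select_test_compounds,
)
from .evalmetrics import auc_roc, compare_models, evaluate_model
from .mccp import MondrianCrossConformal
from .mtlmodel import TrainConfig

logger = logging.getLogger(__name__)


def _fmt(v: float) -> str:
    return f"{v:g}"


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration in the naming convention of the study."""

    train_concentration: float
    infer_concentration: float
    train_threshold: float
    high_threshold: float = 7.0

    @property
    def name(self) -> str:
        return (f"[{_fmt(self.train_concentration)} μM / "
                f"{_fmt(self.infer_concentration)} μM / "
                f"{_fmt(self.train_threshold)}]")


@dataclass
class Split:
    """Frozen train/test compound partition plus scaffold folds."""

    train_ids: pd.Index
    test_ids: pd.Index
    folds: FoldAssignment


def make_split(dataset: ScreenDataset, max_test_fraction: float = 0.05,
               min_test_potency: float = 8.0, k: int = 5, seed: int = 0) -> Split:
    """Potency-selected, scaffold-disjoint test set and k-fold split."""
    activity = ActivityMatrix(dataset.activity.wide.reindex(dataset.scaffolds.index))
    test_ids = select_test_compounds(
        activity, dataset.scaffolds, max_test_fraction=max_test_fraction,
        min_potency=min_test_potency, seed=seed)
    train_ids = activity.compounds.difference(test_ids)
    folds = assign_folds(dataset.scaffolds[train_ids], k=k, seed=seed)
    return Split(train_ids=train_ids, test_ids=test_ids, folds=folds)


def make_random_split(dataset: ScreenDataset, test_fraction: float = 0.1,
                      k: int = 5, seed: int = 0) -> Split:
    """Random scaffold-disjoint split (no potency selection).

    Whole scaffold groups are moved to the test side until roughly
    ``test_fraction`` of compounds are held out. Unlike
    :func:`make_split` this keeps test compounds exchangeable with the
    training set, which is what conformal-validity checks and
    ranking-metric studies on a broad evaluation panel need.
    """
    rng = np.random.default_rng(seed)
    scaffolds = dataset.scaffolds
    groups = scaffolds.groupby(scaffolds).groups
    keys = sorted(groups)
    order = rng.permutation(len(keys))
    budget = int(round(test_fraction * len(scaffolds)))
    test: list = []
    for gi in order:
        members = list(groups[keys[gi]])
        if len(test) + len(members) <= budget:
            test.extend(members)
    test_ids = pd.Index(sorted(test), name="compound_id")
    train_ids = scaffolds.index.difference(test_ids)
    folds = assign_folds(scaffolds[train_ids], k=k, seed=seed)
    return Split(train_ids=train_ids, test_ids=test_ids, folds=folds)


class ConcentrationShiftExperiment:
    """One trained configuration, reusable across inference concentrations.

    Fitting is the expensive part (full ensemble + one ensemble per
    fold); inference at a new concentration is a pure prediction pass,
    so a fitted experiment serves the whole concentration grid.
    """

    def __init__(self, dataset: ScreenDataset, train_concentration: float,
                 train_threshold: float, high_threshold: float,
                 train_config: TrainConfig, epsilon: float = 0.05,
                 criteria: EligibilityCriteria = EligibilityCriteria(),
                 min_gate_auc: float = 0.7, split: Split | None = None,
                 seed: int = 0):
        self.dataset = dataset
        self.train_concentration = float(train_concentration)
        self.train_threshold = float(train_threshold)
        self.high_threshold = float(high_threshold)
        self.train_config = train_config
        self.epsilon = epsilon
        self.criteria = criteria
        self.min_gate_auc = min_gate_auc
        self.split = split if split is not None else make_split(dataset, seed=seed)
        self.mccp: MondrianCrossConformal | None = None
        self.gate_auc: pd.Series | None = None

        activity = ActivityMatrix(dataset.activity.wide.reindex(dataset.scaffolds.index))
        self.train_activity = activity.restrict(self.split.train_ids)
        truth_all = dataset.evaluation_truth()
        self.test_truth = ActivityMatrix(truth_all.wide.reindex(self.split.test_ids))
        self.train_labels = binarize(self.train_activity, self.train_threshold)
        thresholds = sorted({self.train_threshold, self.high_threshold})
        self.eligible_assays = filter_assays(
            [binarize(self.train_activity, t) for t in thresholds],
            [binarize(self.test_truth, t) for t in thresholds],
            criteria,
        )

    def fit(self) -> "ConcentrationShiftExperiment":
        """Train the full ensemble and the cross-conformal fold models.

        Also computes the per-assay cross-validated AUC-ROC gate from
        the out-of-fold probabilities: an assay qualifies only when the
        trained model itself validates (AUC-ROC >= ``min_gate_auc``).
        """
        x = self.dataset.features(self.split.train_ids, self.train_concentration)
        self.mccp = MondrianCrossConformal(self.train_config)
        self.mccp.fit(x, self.train_labels, self.split.folds)
        oof = self.mccp.out_of_fold_scores(x, self.train_labels)
        gate = {}
        for assay in self.train_labels.wide.columns:
            y = self.train_labels.wide[assay]
            keep = y.notna() & oof[assay].notna()
            gate[assay] = auc_roc(oof.loc[keep, assay], y[keep]) if keep.any() else float("nan")
        self.gate_auc = pd.Series(gate, name="cv_auc_roc")
        for assay in self.eligible_assays:
            if not (self.gate_auc[assay] >= self.min_gate_auc):
                logger.info("assay %s dropped by model-quality gate (cv AUC-ROC %.3f)",
                            assay, self.gate_auc[assay])
        return self

    @property
    def gated_assays(self) -> list:
        """Eligible assays whose trained model passed the CV gate."""
        if self.gate_auc is None:
            raise RuntimeError("fit() before reading gated_assays")
        return [a for a in self.eligible_assays
                if self.gate_auc[a] >= self.min_gate_auc]

    def predict(self, infer_concentration: float) -> pd.DataFrame:
        """Conformal decisions for test compounds at one concentration."""
        if self.mccp is None:
            raise RuntimeError("fit() before predict()")
        x = self.dataset.features(self.split.test_ids, infer_concentration)
        return self.mccp.predict(x, index=self.split.test_ids, epsilon=self.epsilon)

    def evaluate(self, decisions: pd.DataFrame, model_name: str,
                 assays: list | None = None) -> pd.DataFrame:
        """Per-assay retrieval metrics of one decision table.

        Truth is the evaluation potency of the test compounds at
        ``high_threshold``; compounds without a measured value for an
        assay are excluded from that assay's metrics.
        """
        if assays is None:
            assays = self.gated_assays
        rows = []
        wide_dec = decisions.pivot(index="compound_id", columns="assay_id",
                                   values="decision")
        wide_prob = decisions.pivot(index="compound_id", columns="assay_id",
                                    values="probability")
        for assay in assays:
            truth = self.test_truth.wide[assay].reindex(wide_dec.index)
            row = evaluate_model(wide_dec[assay], wide_prob[assay], truth,
                                 self.high_threshold)
            row["assay_id"] = assay
            row["model_name"] = model_name
            rows.append(row)
        cols = ["assay_id", "model_name", "high_potency_precision", "tp", "p_calls",
                "high_potency_recall", "n_positives", "n_evaluated",
                "auc_roc", "auc_pr", "baseline", "riptop_auc_pr"]
        return pd.DataFrame(rows, columns=cols)


def run_concshift(dataset: ScreenDataset, spec: ModelSpec,
                  train_config: TrainConfig = TrainConfig(),
                  epsilon: float = 0.05,
                  criteria: EligibilityCriteria = EligibilityCriteria(),
                  min_gate_auc: float = 0.7, split: Split | None = None,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train at ``spec.train_concentration`` / ``spec.train_threshold``,
    infer at ``spec.infer_concentration``, evaluate at ``spec.high_threshold``.

    Returns the per-(compound, assay) conformal decision table and the
    per-assay evaluation report labelled with the model name.
    """
    exp = ConcentrationShiftExperiment(
        dataset, spec.train_concentration, spec.train_threshold,
        spec.high_threshold, train_config, epsilon=epsilon, criteria=criteria,
        min_gate_auc=min_gate_auc, split=split, seed=seed)
    exp.fit()
    decisions = exp.predict(spec.infer_concentration)
    report = exp.evaluate(decisions, spec.name)
    return decisions, report


@dataclass
class ComparisonResult:
    """Full comparison of the method against the conventional model."""

    reports: pd.DataFrame                 # per (assay, model) metrics
    deltas: dict                          # model name -> per-assay delta table
    summary: pd.DataFrame                 # model name -> improved fractions
    decisions: dict                       # model name -> decision table
    assays: list
    test_ids: pd.Index
    moderate_gate_auc: pd.Series


def run_comparison(dataset: ScreenDataset, train_concentration: float = 20.0,
                   infer_concentrations: list | None = None,
                   moderate_threshold: float = 5.0, high_threshold: float = 7.0,
                   train_config: TrainConfig = TrainConfig(),
                   epsilon: float = 0.05,
                   criteria: EligibilityCriteria = EligibilityCriteria(),
                   min_gate_auc: float = 0.7, split: Split | None = None,
                   seed: int = 0) -> ComparisonResult:
    """The full experimental grid of the study, on one dataset.

    Fits the moderate-threshold model once and applies it at every
    inference concentration, fits the conventional model (train =
    inference concentration, high threshold) once, and evaluates all
    configurations at ``high_threshold`` on the identical test-compound
    and assay sets. The assay set is gated by the moderate model's
    cross-validated AUC-ROC, following the study's eligibility rule.
    """
    if infer_concentrations is None:
        infer_concentrations = dataset.concentrations
    if split is None:
        split = make_split(dataset, seed=seed)

    moderate = ConcentrationShiftExperiment(
        dataset, train_concentration, moderate_threshold, high_threshold,
        train_config, epsilon=epsilon, criteria=criteria,
        min_gate_auc=min_gate_auc, split=split, seed=seed)
    moderate.fit()
    assays = moderate.gated_assays

    conventional_spec = ModelSpec(train_concentration, train_concentration,
                                  high_threshold, high_threshold)
    conventional = ConcentrationShiftExperiment(
        dataset, train_concentration, high_threshold, high_threshold,
        train_config, epsilon=epsilon, criteria=criteria,
        min_gate_auc=min_gate_auc, split=split, seed=seed)
    conventional.fit()

    decisions: dict = {}
    reports = []
    for c in infer_concentrations:
        spec = ModelSpec(train_concentration, c, moderate_threshold, high_threshold)
        dec = moderate.predict(c)
        decisions[spec.name] = dec
        reports.append(moderate.evaluate(dec, spec.name, assays=assays))
    conv_dec = conventional.predict(train_concentration)
    decisions[conventional_spec.name] = conv_dec
    conv_report = conventional.evaluate(conv_dec, conventional_spec.name,
                                        assays=assays)
    reports.append(conv_report)
    report_df = pd.concat(reports, ignore_index=True)

    deltas = {}
    summary_rows = []
    for c in infer_concentrations:
        spec = ModelSpec(train_concentration, c, moderate_threshold, high_threshold)
        method_report = report_df[report_df["model_name"] == spec.name]
        d, s = compare_models(method_report, conv_report)
        deltas[spec.name] = d
        summary_rows.append({"model_name": spec.name, **s})
    summary = pd.DataFrame(summary_rows)

    return ComparisonResult(
        reports=report_df, deltas=deltas, summary=summary,
        decisions=decisions, assays=assays, test_ids=split.test_ids,
        moderate_gate_auc=moderate.gate_auc,
    )
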