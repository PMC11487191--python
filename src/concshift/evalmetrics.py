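"""Evaluation metrics for high-potency compound retrieval.

High-potency precision and recall are computed from the conformal
decisions (decision = 1 means the model calls the compound Active);
ranking metrics (AUC-ROC, AUC-PR) use the full-model probability
score. AUC-PR is additionally reported with the RIPtoP correction
(Relative Improvement of Proximity to Perfection),

    RIPtoP(AUC-PR) = (AUC-PR - BASELINE) / (1 - BASELINE),

where BASELINE is the assay's high-potency active fraction in the test
set — the expected AUC-PR of a random ranker — so that 0 means random
and 1 means perfect for every assay, making AUC-PR comparable across
assays with different imbalance.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def _aligned(decisions, true_values):
    d = np.asarray(decisions, dtype=float)
    v = np.asarray(true_values, dtype=float)
    if d.shape != v.shape:
        raise ValueError("decisions and true values must be aligned")
    keep = ~np.isnan(v)
    return d[keep], v[keep]


def high_potency_precision(decisions, true_values, high_threshold: float
                           ) -> tuple[float, int, int]:
    """Precision of Active calls against the high-potency threshold.

    Returns ``(precision, TP, P_calls)`` where TP counts Active calls
    whose measured value is at or above ``high_threshold`` and P_calls
    counts all Active calls. With no Active call the precision is
    reported as 0 with counts (0, 0), matching the ``0 (0/0)``
    convention of the result tables.
    """
    d, v = _aligned(decisions, true_values)
    calls = d == 1
    tp = int(np.sum(calls & (v >= high_threshold)))
    p_calls = int(np.sum(calls))
    precision = tp / p_calls if p_calls else 0.0
    return precision, tp, p_calls


def high_potency_recall(decisions, true_values, high_threshold: float
                        ) -> tuple[float, int, int]:
    """Recall of Active calls among truly high-potency compounds.

    Returns ``(recall, TP, n_positives)``; recall is NaN (undefined)
    when the assay has no high-potency compound in the test set.
    """
    d, v = _aligned(decisions, true_values)
    positives = v >= high_threshold
    tp = int(np.sum((d == 1) & positives))
    n_pos = int(np.sum(positives))
    recall = tp / n_pos if n_pos else float("nan")
    return recall, tp, n_pos


def auc_roc(scores, binary_truth) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative).

    Ties count one half. NaN when the truth is single-class.
    """
    y = np.asarray(binary_truth, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, s))


def auc_pr(scores, binary_truth) -> float:
    """Average precision (step-wise AUC-PR, no interpolation).

    NaN when there is no positive in the truth.
    """
    y = np.asarray(binary_truth, dtype=float)
    s = np.asarray(scores, dtype=float)
    if np.sum(y == 1) == 0:
        return float("nan")
    return float(average_precision_score(y, s))


def riptop(auc_pr_value: float, baseline: float) -> float:
    """RIPtoP correction of an AUC-PR value.

    Linear rescaling so the random baseline maps to 0 and a perfect
    model to 1; below-baseline models come out negative. The baseline
    must lie in [0, 1): an assay whose test positives are the entire
    set is degenerate.
    """
    if not (0.0 <= baseline < 1.0):
        raise ValueError("baseline must be in [0, 1)")
    return (auc_pr_value - baseline) / (1.0 - baseline)


def evaluate_model(decisions, scores, true_values, high_threshold: float) -> dict:
    """All retrieval metrics for one (assay, model) cell.

    ``decisions`` in {1, -1, 0}, ``scores`` the ranking probabilities,
    ``true_values`` the measured potency (NaN cells are excluded).
    """
    d = np.asarray(decisions, dtype=float)
    s = np.asarray(scores, dtype=float)
    v = np.asarray(true_values, dtype=float)
    keep = ~np.isnan(v)
    d, s, v = d[keep], s[keep], v[keep]
    truth = (v >= high_threshold).astype(float)
    precision, tp, p_calls = high_potency_precision(d, v, high_threshold)
    recall, _, n_pos = high_potency_recall(d, v, high_threshold)
    baseline = float(truth.mean()) if truth.size else float("nan")
    pr = auc_pr(s, truth)
    return {
        "high_potency_precision": precision,
        "tp": tp,
        "p_calls": p_calls,
        "high_potency_recall": recall,
        "n_positives": n_pos,
        "n_evaluated": int(truth.size),
        "auc_roc": auc_roc(s, truth),
        "auc_pr": pr,
        "baseline": baseline,
        "riptop_auc_pr": riptop(pr, baseline) if baseline < 1.0 and not np.isnan(pr) else float("nan"),
    }


def compare_models(method_report: pd.DataFrame, conventional_report: pd.DataFrame
                   ) -> tuple[pd.DataFrame, dict]:
    """Per-assay metric deltas of the method versus the conventional model.

    Both reports must be indexed by ``assay_id`` and cover identical
    assays. Deltas are on AUC-ROC and on RIPtoP-corrected AUC-PR (not
    raw AUC-PR). Returns the delta table and summary fractions of
    assays with a strictly positive delta.
    """
    a = method_report.set_index("assay_id") if "assay_id" in method_report else method_report
    b = conventional_report.set_index("assay_id") if "assay_id" in conventional_report else conventional_report
    if set(a.index) != set(b.index):
        diff = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"assay sets differ: {diff}")
    b = b.reindex(a.index)
    deltas = pd.DataFrame({
        "delta_auc_roc": a["auc_roc"] - b["auc_roc"],
        "delta_riptop_auc_pr": a["riptop_auc_pr"] - b["riptop_auc_pr"],
    })
    summary = {
        "frac_improved_auc_roc": float((deltas["delta_auc_roc"] > 0).mean()),
        "frac_improved_riptop_auc_pr": float((deltas["delta_riptop_auc_pr"] > 0).mean()),
    }
    return deltas, summary


def round_half_up(value: float, decimals: int = 3) -> float:
    """Round with ties away from zero, as the result tables format."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_precision(precision: float, tp: int, p_calls: int) -> str:
    """Render precision in the table style, e.g. ``0.243 (27/111)``."""
    if p_calls == 0:
        return "0 (0/0)"
    r = round_half_up(precision, 3)
    text = f"{r:g}"
    return f"{text} ({tp}/{p_calls})"


def plot_metric_heatmap(report: pd.DataFrame, metric: str, path=None):
    """Assay x model heatmap of one metric (precision/recall grids).

    ``report`` is the tidy per-(assay, model) table from the pipeline.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = report.pivot_table(index="model_name", columns="assay_id",
                              values=metric, aggfunc="mean")
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * grid.shape[1]), 0.6 * grid.shape[0] + 2))
    im = ax.imshow(grid.to_numpy(dtype=float), aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=1.0)
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90)
    ax.set_yticks(range(grid.shape[0]), grid.index)
    ax.set_title(metric)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
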