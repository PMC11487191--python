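"""Data containers and dataset operations.

Houses morphological profiles, the sparse potency matrix, label
binarization, potency-selected test-set construction, scaffold-grouped
fold assignment and the assay eligibility filter.

Conventions:

* profiles live in one long DataFrame with columns ``compound_id``,
  ``concentration_um``, ``f000`` ... ``f{N-1}``;
* potency matrices are wide DataFrames (compounds x assays) with NaN
  marking unobserved cells;
* scaffolds are a Series mapping ``compound_id`` to a group label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ActivityMatrix:
    """Sparse compound x assay potency values (pIC50 or ratio scale).

    Wraps a wide float DataFrame; NaN means unobserved. The observation
    mask is therefore implicit: ``mask`` is True exactly where a value
    exists, and all stored values are finite.
    """

    def __init__(self, wide: pd.DataFrame):
        wide = wide.astype(float)
        if not np.isfinite(wide.to_numpy(dtype=float, na_value=0.0)).all():
            raise ValueError("activity values must be finite where observed")
        self.wide = wide

    @classmethod
    def from_long(cls, df: pd.DataFrame, value_col: str = "pic50") -> "ActivityMatrix":
        wide = df.pivot_table(
            index="compound_id", columns="assay_id", values=value_col, aggfunc="mean"
        )
        return cls(wide)

    def to_long(self, value_col: str = "pic50") -> pd.DataFrame:
        long = self.wide.stack().rename(value_col).reset_index()
        long.columns = ["compound_id", "assay_id", value_col]
        return long

    @property
    def mask(self) -> pd.DataFrame:
        return self.wide.notna()

    @property
    def compounds(self) -> pd.Index:
        return self.wide.index

    @property
    def assays(self) -> pd.Index:
        return self.wide.columns

    def n_observed(self) -> pd.Series:
        return self.mask.sum(axis=0)

    def max_observed(self) -> pd.Series:
        """Per-compound maximum observed value (NaN if nothing observed)."""
        return self.wide.max(axis=1)

    def restrict(self, compounds: Iterable) -> "ActivityMatrix":
        idx = self.wide.index.intersection(pd.Index(compounds))
        return ActivityMatrix(self.wide.loc[idx])

    def __repr__(self) -> str:  # pragma: no cover
        fill = float(self.mask.to_numpy().mean()) if self.wide.size else 0.0
        return (
            f"ActivityMatrix({self.wide.shape[0]} compounds x "
            f"{self.wide.shape[1]} assays, fill={fill:.3f})"
        )


@dataclass
class BinaryLabels:
    """Binarized potency labels: wide {0, 1, NaN} frame plus threshold.

    Labelled cells are exactly the observed cells of the source matrix;
    NaN cells are excluded from loss, calibration and metrics.
    """

    wide: pd.DataFrame
    threshold: float

    @property
    def mask(self) -> pd.DataFrame:
        return self.wide.notna()

    def counts(self) -> pd.DataFrame:
        """Per-assay labelled / active / inactive counts."""
        return pd.DataFrame(
            {
                "labelled": self.mask.sum(axis=0),
                "actives": (self.wide == 1.0).sum(axis=0),
                "inactives": (self.wide == 0.0).sum(axis=0),
            }
        )

    def restrict(self, compounds: Iterable) -> "BinaryLabels":
        idx = self.wide.index.intersection(pd.Index(compounds))
        return BinaryLabels(self.wide.loc[idx], self.threshold)


def binarize(matrix: ActivityMatrix, threshold: float) -> BinaryLabels:
    """Binarize observed potency values at an inclusive threshold.

    value >= threshold -> 1, value < threshold -> 0, unobserved -> NaN.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    wide = (matrix.wide >= threshold).astype(float).where(matrix.mask)
    return BinaryLabels(wide, float(threshold))


@dataclass
class FoldAssignment:
    """Compound -> fold index mapping for k scaffold-grouped folds."""

    assignments: pd.Series  # compound_id -> fold in {0..k-1}
    k: int

    def fold_compounds(self, fold: int) -> pd.Index:
        return self.assignments.index[self.assignments == fold]

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(range(self.k), fill_value=0)


def select_test_compounds(
    matrix: ActivityMatrix,
    scaffolds: pd.Series,
    max_test_fraction: float = 0.05,
    min_potency: float = 8.0,
    seed: int = 0,
) -> pd.Index:
    """Select the held-out evaluation compounds.

    A compound qualifies when (1) its maximum observed potency is at
    least ``min_potency`` (pIC50 >= 8 by default: validated strong
    actives) and (2) its scaffold occurs in no compound that remains in
    the training set, so the evaluation chemistry is novel. Entire
    scaffold groups are trimmed by seeded sampling when the qualifying
    set exceeds ``max_test_fraction`` of the library, which preserves
    the scaffold-disjointness of the two sets.

    Returns a sorted Index of test compound ids (possibly empty, with a
    warning).
    """
    scaffolds = scaffolds.reindex(matrix.compounds)
    if scaffolds.isna().any():
        missing = scaffolds.index[scaffolds.isna()].tolist()[:5]
        raise ValueError(f"compounds missing scaffold labels, e.g. {missing}")

    potent = matrix.max_observed() >= min_potency
    candidate_ids = matrix.compounds[potent.to_numpy()]
    train_side_scaffolds = set(scaffolds[~scaffolds.index.isin(candidate_ids)])
    eligible = pd.Index(
        [c for c in candidate_ids if scaffolds[c] not in train_side_scaffolds]
    )
    if len(eligible) == 0:
        warnings.warn(
            "no compound satisfies the test-set criteria; test set is empty",
            stacklevel=2,
        )
        return pd.Index([], name="compound_id")

    budget = int(np.floor(max_test_fraction * len(matrix.compounds)))
    if len(eligible) <= budget:
        return pd.Index(sorted(eligible), name="compound_id")

    rng = np.random.default_rng(seed)
    groups = scaffolds[eligible].groupby(scaffolds[eligible]).groups
    group_keys = sorted(groups)
    order = rng.permutation(len(group_keys))
    chosen: list = []
    for gi in order:
        members = list(groups[group_keys[gi]])
        if len(chosen) + len(members) <= budget:
            chosen.extend(members)
    return pd.Index(sorted(chosen), name="compound_id")


def assign_folds(scaffolds: pd.Series, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Assign training compounds to k folds, keeping scaffolds whole.

    Greedy balanced allocation: scaffold groups are taken largest first
    (ties broken by a seeded shuffle) and each goes entirely to the
    currently smallest fold. Fold sizes therefore differ by at most the
    size of the largest group. Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    group_sizes = scaffolds.groupby(scaffolds).size()
    keys = sorted(group_sizes.index)
    shuffled = [keys[i] for i in rng.permutation(len(keys))]
    ordered = sorted(shuffled, key=lambda s: -int(group_sizes[s]))
    if len(ordered) < k:
        warnings.warn(
            f"only {len(ordered)} scaffold groups for {k} folds; "
            "some folds will be empty",
            stacklevel=2,
        )
    totals = np.zeros(k, dtype=int)
    fold_of_scaffold: dict = {}
    for s in ordered:
        target = int(np.argmin(totals))  # lowest index on ties
        fold_of_scaffold[s] = target
        totals[target] += int(group_sizes[s])
    assignments = scaffolds.map(fold_of_scaffold).astype(int)
    assignments.name = "fold"
    return FoldAssignment(assignments, k)


@dataclass(frozen=True)
class EligibilityCriteria:
    """Minimum label counts for an assay to enter the evaluation.

    Defaults are the production-scale values (train: >=100 labelled
    with >=25 actives and >=25 inactives at both potency thresholds;
    test: >=10 labelled with >=5 of each class). Desk-scale synthetic
    runs pass smaller counts.
    """

    min_train_labelled: int = 100
    min_train_class: int = 25
    min_test_labelled: int = 10
    min_test_class: int = 5


def _assays_passing(labels: BinaryLabels, min_labelled: int, min_class: int) -> set:
    c = labels.counts()
    ok = (
        (c["labelled"] >= min_labelled)
        & (c["actives"] >= min_class)
        & (c["inactives"] >= min_class)
    )
    return set(c.index[ok])


def filter_assays(
    train_labels: Sequence[BinaryLabels],
    test_labels: Sequence[BinaryLabels],
    criteria: EligibilityCriteria = EligibilityCriteria(),
) -> list:
    """Assays with enough labelled data at every potency threshold.

    ``train_labels`` / ``test_labels`` hold one BinaryLabels per
    threshold (typically the moderate and the high threshold). An assay
    is kept only if it passes the count criteria at *all* thresholds on
    both sides. The further gate — a validated moderate-potency model
    (cross-validated AUC-ROC >= 0.7) — is applied downstream by the
    pipeline, where models exist.
    """
    keep: set | None = None
    for labels in train_labels:
        ok = _assays_passing(labels, criteria.min_train_labelled, criteria.min_train_class)
        keep = ok if keep is None else keep & ok
    for labels in test_labels:
        ok = _assays_passing(labels, criteria.min_test_labelled, criteria.min_test_class)
        keep = ok if keep is None else keep & ok
    return sorted(keep or set())


@dataclass
class ScreenDataset:
    """One complete screen: profiles, labels, scaffolds, optional truth.

    ``latent`` carries the dense ground-truth potency matrix when the
    dataset is synthetic; real datasets leave it None and evaluation
    falls back to the observed matrix.
    """

    profiles: pd.DataFrame
    activity: ActivityMatrix
    scaffolds: pd.Series
    latent: ActivityMatrix | None = None

    def __post_init__(self) -> None:
        required = {"compound_id", "concentration_um"}
        if not required.issubset(self.profiles.columns):
            raise ValueError(f"profiles must have columns {sorted(required)}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.profiles.columns if c.startswith("f")]

    @property
    def concentrations(self) -> list[float]:
        return sorted(self.profiles["concentration_um"].unique())

    def features(self, compounds: Iterable, concentration: float) -> np.ndarray:
        """Feature matrix for given compounds at one concentration.

        Rows follow the order of ``compounds``. Raises if the
        concentration is absent, naming the available ones.
        """
        avail = self.concentrations
        match = [c for c in avail if np.isclose(c, concentration)]
        if not match:
            raise ValueError(
                f"no profiles at {concentration} uM; available: {avail}"
            )
        sub = self.profiles[np.isclose(self.profiles["concentration_um"], match[0])]
        sub = sub.set_index("compound_id")
        compounds = pd.Index(compounds)
        missing = compounds.difference(sub.index)
        if len(missing) > 0:
            raise ValueError(f"no profiles for compounds, e.g. {list(missing[:5])}")
        return sub.loc[compounds, self.feature_columns].to_numpy(dtype=float)

    def evaluation_truth(self) -> ActivityMatrix:
        """Ground truth used for evaluation: latent if present, else observed."""
        return self.latent if self.latent is not None else self.activity

    # --- persistence (plain text formats) ---------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(directory / "profiles.csv", index=False)
        self.activity.to_long().to_csv(directory / "activity.csv", index=False)
        self.scaffolds.rename("scaffold_id").rename_axis("compound_id").reset_index().to_csv(
            directory / "scaffolds.csv", index=False
        )
        if self.latent is not None:
            self.latent.to_long().to_csv(directory / "latent.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "ScreenDataset":
        directory = Path(directory)
        profiles = pd.read_csv(directory / "profiles.csv")
        activity = ActivityMatrix.from_long(pd.read_csv(directory / "activity.csv"))
        scaff_df = pd.read_csv(directory / "scaffolds.csv")
        scaffolds = scaff_df.set_index("compound_id")["scaffold_id"]
        latent_path = directory / "latent.csv"
        latent = (
            ActivityMatrix.from_long(pd.read_csv(latent_path))
            if latent_path.exists()
            else None
        )
        return cls(profiles=profiles, activity=activity, scaffolds=scaffolds, latent=latent)
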