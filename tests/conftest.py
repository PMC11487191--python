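"""Shared fixtures.

The end-to-end experiments are the expensive part of the suite, so each
is run once per session and shared by every test that inspects it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import concshift as cs
from concshift import presets
from concshift.pipeline import make_random_split


@pytest.fixture(scope="session")
def default_screen():
    """The frozen headline synthetic screen."""
    return cs.generate_library(presets.default_screen(seed=1))


@pytest.fixture(scope="session")
def small_screen():
    """A small screen for cheap structural tests."""
    return cs.generate_library(cs.SimConfig(n_compounds=400, n_assays=5,
                                            n_features=60, n_scaffolds=280,
                                            seed=7))


@pytest.fixture(scope="session")
def default_comparison(default_screen):
    """Full concentration grid + conventional model on the default screen."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.run_comparison(
            default_screen,
            train_config=presets.desk_train_config(seed=0),
            criteria=presets.desk_criteria(),
            moderate_threshold=presets.MODERATE_THRESHOLD,
            high_threshold=presets.HIGH_THRESHOLD,
            seed=0,
        )


@pytest.fixture(scope="session")
def imbalanced_comparisons():
    """Three seeded replicates of the rare-high-potency comparison."""
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in (1, 2, 3):
            dataset = cs.generate_library(presets.imbalanced_screen(seed=seed))
            split = make_random_split(dataset, test_fraction=0.12, seed=seed)
            results.append(cs.run_comparison(
                dataset,
                infer_concentrations=[0.16, 0.8, 4.0],
                train_config=presets.small_train_config(seed=seed),
                criteria=presets.imbalanced_criteria(),
                split=split,
                seed=seed,
            ))
    return results


@pytest.fixture(scope="session")
def validity_run(default_screen):
    """Calibrated predictions on an exchangeable random holdout.

    Train and inference both at 20 uM, random scaffold-disjoint split:
    the setting in which conformal class-conditional validity should
    hold empirically. Returns (decision table, observed test labels).
    """
    dataset = default_screen
    split = make_random_split(dataset, test_fraction=0.15, seed=11)
    activity = cs.ActivityMatrix(dataset.activity.wide.reindex(dataset.scaffolds.index))
    train_labels = cs.binarize(activity.restrict(split.train_ids),
                               presets.MODERATE_THRESHOLD)
    test_labels = cs.binarize(activity.restrict(split.test_ids),
                              presets.MODERATE_THRESHOLD)
    x_train = dataset.features(split.train_ids, 20.0)
    x_test = dataset.features(split.test_ids, 20.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mccp = cs.MondrianCrossConformal(presets.desk_train_config(seed=3))
        mccp.fit(x_train, train_labels, split.folds)
        decisions = mccp.predict(x_test, index=split.test_ids, epsilon=0.05)
    return decisions, test_labels
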