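"""Frozen study conditions for the desk-scale synthetic experiments.

These are the configurations the test-suite, the examples and the
reproduction script all run, kept in one place so every consumer sees
the same conditions.

Two screens are defined:

* the *default screen* — 2000 compounds, 10 assays, the standard
  right-skewed potency distribution with confirmatory-screening
  observation bias; used to demonstrate the concentration-shift
  mechanism (precision up, recall down as inference concentration
  falls);
* the *imbalanced screen* — a weaker high-potency tail and uniform
  observation, so that fewer than 5% of labelled cells exceed the
  high-potency threshold; used to demonstrate the advantage over the
  conventional high-threshold model when positives are scarce.

Training configurations are desk-scale (small ensembles, hundreds of
Adam steps): the synthetic signal is low-dimensional and clean, so
larger budgets change nothing but runtime.
"""

from __future__ import annotations

from .datamodel import EligibilityCriteria
from .mtlmodel import TrainConfig
from .simdata import PotencyModel, SimConfig

#: moderate / high potency thresholds used throughout the experiments
MODERATE_THRESHOLD = 5.0
HIGH_THRESHOLD = 7.0


def default_screen(seed: int = 1) -> SimConfig:
    """The headline synthetic screen (all SimConfig defaults)."""
    return SimConfig(seed=seed)


def imbalanced_screen(seed: int = 1) -> SimConfig:
    """A screen whose high-potency tail is rare (<5% of labelled cells).

    The potency mixture's upper component is down-weighted and the
    confirmatory-screening bias switched off, so labels above pIC50 7
    are scarce — the regime where training a high-threshold classifier
    directly is starved of positives.
    """
    return SimConfig(
        potency=PotencyModel(weights=(0.88, 0.12), means=(5.1, 6.8),
                             sds=(0.6, 0.8), compound_shift_sd=0.7),
        followup_boost=1.0,
        seed=seed,
    )


def desk_train_config(seed: int = 0) -> TrainConfig:
    """Ensemble budget for the default screen."""
    return TrainConfig(n_members=4, hidden_sizes=(64, 32), dropout=0.1,
                       n_iterations=800, batch_size=128, seed=seed)


def small_train_config(seed: int = 0) -> TrainConfig:
    """Smaller budget for multi-seed repeats."""
    return TrainConfig(n_members=3, hidden_sizes=(48, 24), dropout=0.1,
                       n_iterations=600, batch_size=128, seed=seed)


def desk_criteria() -> EligibilityCriteria:
    """Assay eligibility counts proportionate to the desk-scale screens.

    The production criteria (100 labelled / 25 per class in training)
    assume ~100k profiles; at ~100 labelled cells per assay they would
    reject every assay, so counts are scaled to the same ratios.
    """
    return EligibilityCriteria(min_train_labelled=50, min_train_class=10,
                               min_test_labelled=8, min_test_class=3)


def imbalanced_criteria() -> EligibilityCriteria:
    """Eligibility counts for the imbalanced screen.

    A high-threshold class minimum of 4 keeps assays whose conventional
    model is positive-starved — exactly the regime under study — while
    still requiring enough evaluation compounds for ranking metrics.
    """
    return EligibilityCriteria(min_train_labelled=50, min_train_class=4,
                               min_test_labelled=20, min_test_class=3)
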