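"""Synthetic Cell Painting-style screening data.

Emulates the statistical structure that concentration-shift inference
relies on, so the full pipeline can be exercised without proprietary
screening data:

* per-compound latent potency (pIC50) per assay, right-skewed so that
  highly potent compounds (pIC50 >= 7) are rare;
* morphological-profile feature vectors (Z-scores against vehicle
  control) whose assay-specific signal amplitude follows a Hill
  dose-response curve in the imaging concentration, so that at low
  concentration only highly potent compounds produce signal;
* a sparsely observed compound x assay label matrix (~5% fill);
* scaffold-style compound group labels for grouped splitting.

Nothing here renders images: profiles are generated directly in feature
space as ``signal + N(0, noise_sd)`` per feature, mirroring data that
has already been aggregated and DMSO-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ActivityMatrix, ScreenDataset

#: Imaging concentrations (uM) used throughout: a 125-fold range from a
#: dose at which only sub-100-nM-IC50 compounds act, up to a saturating
#: screening dose.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.16, 0.8, 4.0, 10.0, 20.0)


@dataclass(frozen=True)
class PotencyModel:
    """Latent potency distribution for compounds that engage an assay.

    A two-component Gaussian mixture on the pIC50 scale, truncated to
    ``[lower, upper]``: the bulk component sits near pIC50 5 (moderate
    potency) and a small upper component supplies the rare high-potency
    tail beyond 7. ``compound_shift_sd`` adds a per-compound offset
    shared across assays, so that broadly potent compounds exist (these
    are the compounds a potency-selected evaluation set is drawn from).
    Compounds that do not engage an assay get a latent value in
    ``[inactive_low, lower)`` — far enough below the moderate threshold
    that they produce essentially no signal at any tested dose.
    """

    weights: tuple[float, ...] = (0.7, 0.3)
    means: tuple[float, ...] = (5.2, 7.0)
    sds: tuple[float, ...] = (0.6, 0.9)
    lower: float = 4.0
    upper: float = 9.0
    inactive_low: float = 2.5
    compound_shift_sd: float = 0.7
    #: probability scale for a compound engaging any given assay; the
    #: realised per-compound rate is Beta-distributed (see engage_beta).
    engage_beta: tuple[float, float] = (2.0, 3.0)
    #: frequent-hitter coupling: the per-compound potency shift also
    #: raises the engagement rate, so broadly potent compounds hit more
    #: assays (as promiscuous screening actives do).
    promiscuity_coupling: float = 0.25

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if not (self.inactive_low < self.lower < self.upper):
            raise ValueError("require inactive_low < lower < upper")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic screen.

    Defaults describe the desk-scale study conditions used throughout
    the test-suite and the reproduction script: 2000 compounds, 10
    assays, 100 features (a stand-in for the ~800 real morphological
    features), five imaging concentrations spanning 0.16-20 uM, 5%
    label fill, and unit-variance baseline noise (profiles are
    Z-scores).
    """

    n_compounds: int = 2000
    n_assays: int = 10
    n_features: int = 100
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    fill_rate: float = 0.05
    potency: PotencyModel = field(default_factory=PotencyModel)
    #: fraction of features carrying each assay's phenotype
    signature_sparsity: float = 0.2
    #: per-feature signal amplitude (in noise SD units) of a saturating
    #: response in one assay, before the ±30% per-assay magnitude jitter
    signature_scale: float = 3.0
    noise_sd: float = 1.0
    n_scaffolds: int = 1400
    #: Zipf-like exponent of scaffold group sizes; smaller -> flatter,
    #: with many singleton scaffolds as in real screening libraries.
    scaffold_exponent: float = 0.7
    #: confirmatory-screening bias: cells whose latent potency reaches
    #: ``followup_threshold`` are observed at ``followup_boost`` times
    #: the base fill rate (potent compounds get dose-response follow-up
    #: more often; this is how sparse activity matrices arise in
    #: practice). Set the boost to 1 for uniform observation.
    followup_boost: float = 3.0
    followup_threshold: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_assays, self.n_features, self.n_scaffolds) < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 < self.fill_rate <= 1.0):
            raise ValueError("fill_rate must be in (0, 1]")
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 < self.signature_sparsity <= 1.0):
            raise ValueError("signature_sparsity must be in (0, 1]")


def dose_response_signal(pic50, concentration):
    """Fractional effect of a compound at an imaging concentration.

    Hill equation with unit slope: ``effect = c / (c + IC50)`` with
    ``IC50[uM] = 10**(6 - pIC50)``. Strictly increasing in both
    concentration and potency; equals 0.5 when the concentration matches
    the IC50. This is the mechanism the pipeline exploits: at 0.16 uM a
    pIC50 = 5 compound produces <2% of saturating signal while a
    pIC50 = 7 compound produces >60%.

    Accepts scalars or arrays (broadcast). ``concentration`` must be
    strictly positive.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be strictly positive (uM)")
    p = np.asarray(pic50, dtype=float)
    ic50_um = 10.0 ** (6.0 - p)
    out = c / (c + ic50_um)
    if np.isscalar(pic50) and np.isscalar(concentration):
        return float(out)
    return out


def _truncated_mixture(rng: np.random.Generator, model: PotencyModel,
                       shift: np.ndarray) -> np.ndarray:
    """Draw one potency per entry of ``shift`` from the active mixture."""
    n = shift.size
    comp = rng.choice(len(model.weights), size=n, p=np.asarray(model.weights))
    vals = rng.normal(np.asarray(model.means)[comp], np.asarray(model.sds)[comp])
    vals = vals + shift
    return np.clip(vals, model.lower, model.upper)


def generate_library(config: SimConfig) -> ScreenDataset:
    """Generate a complete synthetic screen.

    Returns a :class:`~concshift.datamodel.ScreenDataset` holding

    * ``profiles``: one feature vector per (compound, concentration),
      built as ``sum_t effect(pIC50_it, c) * signature_t + noise``;
    * ``activity``: the sparse observed label matrix (a uniform random
      subset of latent values at ``fill_rate``);
    * ``latent``: the dense ground-truth potency matrix (used only for
      evaluation, never for training);
    * ``scaffolds``: skew-sized integer group labels, assigned
      independently of potency.

    Identical config (including seed) gives bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, t, f = config.n_compounds, config.n_assays, config.n_features
    compound_ids = pd.Index([f"C{i:05d}" for i in range(n)], name="compound_id")
    assay_ids = pd.Index([f"assay_{j}" for j in range(t)], name="assay_id")
    feature_cols = [f"f{j:03d}" for j in range(f)]

    # scaffold sizes ~ rank^-exponent: a few large chemical series plus
    # a long tail of (near-)singleton scaffolds
    if config.n_scaffolds > 0 and n > 0:
        ranks = np.arange(1, config.n_scaffolds + 1, dtype=float)
        probs = ranks ** -config.scaffold_exponent
        probs /= probs.sum()
        scaffold_idx = rng.choice(config.n_scaffolds, size=n, p=probs)
    else:
        scaffold_idx = np.zeros(n, dtype=int)
    scaffolds = pd.Series(
        [f"S{j:04d}" for j in scaffold_idx], index=compound_ids, name="scaffold_id"
    )

    pot = config.potency
    shift = rng.normal(0.0, pot.compound_shift_sd, size=n)
    engage_rate = np.clip(
        rng.beta(*pot.engage_beta, size=n) + pot.promiscuity_coupling * shift,
        0.02, 0.98,
    )
    engaged = rng.random((n, t)) < engage_rate[:, None]

    latent = rng.uniform(pot.inactive_low, pot.lower, size=(n, t))
    if engaged.any():
        rows = np.nonzero(engaged)[0]
        latent[engaged] = _truncated_mixture(rng, pot, shift[rows])
    latent_df = pd.DataFrame(latent, index=compound_ids, columns=assay_ids)

    # assay phenotype signatures: sparse ±1 pattern x per-assay magnitude
    k = max(1, round(config.signature_sparsity * f)) if f > 0 else 0
    signatures = np.zeros((t, f))
    magnitudes = config.signature_scale * rng.uniform(0.7, 1.3, size=t)
    for j in range(t):
        idx = rng.choice(f, size=k, replace=False) if f > 0 else []
        signatures[j, idx] = rng.choice([-1.0, 1.0], size=k) * magnitudes[j]

    frames = []
    for c in config.concentrations:
        effect = dose_response_signal(latent, c)  # (n, t)
        signal = effect @ signatures  # (n, f)
        x = signal + rng.normal(0.0, config.noise_sd, size=(n, f))
        frame = pd.DataFrame(x, columns=feature_cols)
        frame.insert(0, "compound_id", compound_ids)
        frame.insert(1, "concentration_um", float(c))
        frames.append(frame)
    profiles = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["compound_id", "concentration_um", *feature_cols])
    )

    p_obs = np.where(latent >= config.followup_threshold,
                     min(config.fill_rate * config.followup_boost, 1.0),
                     config.fill_rate)
    observed_mask = rng.random((n, t)) < p_obs
    observed = pd.DataFrame(
        np.where(observed_mask, latent, np.nan), index=compound_ids, columns=assay_ids
    )

    return ScreenDataset(
        profiles=profiles,
        activity=ActivityMatrix(observed),
        scaffolds=scaffolds,
        latent=ActivityMatrix(latent_df),
    )


def summarize_potency(matrix: ActivityMatrix, threshold: float) -> pd.Series:
    """Per-assay fraction of observed labels at or above ``threshold``.

    Assays with no observed labels are omitted from the result (their
    active fraction is undefined, not zero).
    """
    wide = matrix.wide
    if wide.size == 0:
        return pd.Series(dtype=float, name="active_fraction")
    observed = wide.notna().sum(axis=0)
    active = (wide >= threshold).sum(axis=0)
    frac = (active / observed)[observed > 0]
    frac.name = "active_fraction"
    return frac.astype(float)
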