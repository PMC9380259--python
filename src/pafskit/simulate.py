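"""Synthetic-data generators with known ground truth for every pipeline stage.

Viability plates are drawn from known modified-Hill curves (11 doses in a
3-fold dilution series, four replicate wells per dose by default), drug
combination grids from an exactly Loewe-additive forward model with an
optional planted interaction, and phosphosite tables from a multi-batch
TMT-style log-normal intensity model with planted treatment effects and
batch offsets.  All generators take explicit integer seeds and hold no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import HillFit, ViabilityPlate, evaluate_hill
from .phospho_stats import PhosphoSiteTable
from .synergy import CombinationGrid, expected_response

__all__ = [
    "GroundTruthCurve",
    "gen_viability_plate",
    "gen_combination_grid",
    "gen_phospho_dataset",
    "gen_functional_scores",
    "gen_kinase_map",
    "gen_patient_cohort",
    "gen_cohort_plates",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: plate geometry used throughout: 11 doses, 3-fold dilution, 4 replicates
DEFAULT_N_DOSES = 11
DEFAULT_DILUTION = 3.0
DEFAULT_TOP_DOSE = 10_000.0
DEFAULT_N_REPLICATES = 4


@dataclass(frozen=True)
class GroundTruthCurve:
    """True modified-Hill parameters plus replicate noise for simulation.

    ``noise_sd`` is the SD of additive Gaussian noise on the relative
    response scale; evaluating the curve at dose 0 yields the intercept m.
    """

    k: float
    m: float
    n: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if self.n > 0:
            raise ValueError("n must be <= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def to_fit(self) -> HillFit:
        return HillFit(self.k, self.m, self.n)

    def response(self, dose):
        return evaluate_hill(self.to_fit(), dose)

    @property
    def ec50(self) -> float:
        if 2 * self.m - 1 <= 0 or self.n == 0:
            return float("nan")
        return self.k * (2 * self.m - 1) ** (-1.0 / self.n)


def gen_viability_plate(
    curve: GroundTruthCurve,
    n_doses: int = DEFAULT_N_DOSES,
    dilution_factor: float = DEFAULT_DILUTION,
    top_dose: float = DEFAULT_TOP_DOSE,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    sample_id: str = "sample",
    drug: str = "drug",
    reference_level: float = 10_000.0,
) -> ViabilityPlate:
    """Raw plate readings from a known curve: a zero-dose reference row plus
    ``n_doses`` serial dilutions (top_dose / dilution_factor^i).

    Each treated reading is ``reference_level * (R(dose) + eps)`` with
    ``eps ~ N(0, noise_sd)``; untreated wells read the full reference
    level (plus noise), since they define 100% viability — the curve's
    intercept m describes the extrapolated dose -> 0 limit of the
    *treated* response, which the fit may place away from 1.  Readings
    are clipped at 0 from below (a raw fluorescence count cannot be
    negative).
    """
    if top_dose <= 0:
        raise ValueError("top_dose must be positive")
    if n_doses < 4:
        raise ValueError("need at least 4 doses")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    rng = np.random.default_rng(seed)
    doses = np.concatenate(
        [[0.0], top_dose / dilution_factor ** np.arange(n_doses)[::-1]]
    )
    r = np.asarray(curve.response(doses), dtype=float)
    r[doses == 0] = 1.0  # untreated wells define the reference level
    eps = rng.normal(0.0, curve.noise_sd, size=(doses.size, n_replicates))
    readings = np.clip(reference_level * (r[:, None] + eps), 0.0, None)
    return ViabilityPlate(sample_id=sample_id, drug=drug, doses=doses, readings=readings)


def gen_combination_grid(
    curve_a: GroundTruthCurve,
    curve_b: GroundTruthCurve,
    doses_a,
    doses_b,
    interaction=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
) -> CombinationGrid:
    """Measured combination responses from the Loewe-additive forward model.

    measured(a, b) = R_expected(a, b) - interaction(a, b) + noise, where
    R_expected is the Loewe expectation of the two true curves.  A zero
    interaction yields an exactly additive grid; a positive interaction
    plants superadditivity of exactly that size (recovered as a positive
    synergy score downstream).  ``interaction`` may be None, a scalar
    (applied to interior pairs where both doses are positive), or a
    callable (a, b) -> perturbation.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if 0 not in doses_a or 0 not in doses_b:
        raise ValueError("dose lists must include 0")
    rng = np.random.default_rng(seed)
    fa, fb = curve_a.to_fit(), curve_b.to_fit()
    if interaction is None:
        inter = lambda a, b: 0.0
    elif callable(interaction):
        inter = interaction
    else:
        inter = lambda a, b, s=float(interaction): s if (a > 0 and b > 0) else 0.0
    measured = np.empty((doses_a.size, doses_b.size))
    for i, a in enumerate(np.sort(doses_a)):
        for j, b in enumerate(np.sort(doses_b)):
            measured[i, j] = expected_response(fa, fb, a, b) - inter(a, b)
    measured += rng.normal(0.0, noise_sd, size=measured.shape)
    return CombinationGrid(
        drug_a=drug_a,
        drug_b=drug_b,
        doses_a=np.sort(doses_a),
        doses_b=np.sort(doses_b),
        measured=measured,
    )


def _random_window(rng: np.random.Generator, residue: str) -> str:
    flank = rng.choice(AMINO_ACIDS, size=12)
    return "".join(flank[:6]) + residue + "".join(flank[6:])


def gen_phospho_dataset(
    n_sites: int = 1000,
    n_samples_per_group: int = 4,
    n_batches: int = 2,
    frac_regulated: float = 0.1,
    effect_size: float = 1.5,
    batch_sd: float = 0.5,
    residual_sd: float = 0.3,
    frac_below_class1: float = 0.25,
    frac_missing: float = 0.0,
    direction: str = "both",
    scale: str = "intensity",
    seed: int = 0,
) -> tuple[PhosphoSiteTable, pd.DataFrame]:
    """Multi-batch TMT-style phosphosite table with planted effects.

    log2 intensity = site baseline (~N(20, 2)) + per-(site, batch) offset
    (~N(0, batch_sd)) + planted condition effect on treated samples +
    residual (~N(0, residual_sd)).  Exactly
    ``round(frac_regulated * n_sites)`` sites carry a +-``effect_size``
    log2 effect (``direction``: 'both' random sign, 'up' or 'down' fixed).
    Localization probabilities: exactly ``round(frac_below_class1 *
    n_sites)`` sites drawn uniform below 0.75, the rest from a Beta
    concentrated near 1 rescaled to [0.75, 1] — exercising the class-I
    filter on both sides.  ``frac_missing`` > 0 masks cells completely at
    random.  ``scale`` is 'intensity' (raw, 2**log2) or 'log2'.

    Returns the table and the ground-truth frame (site_id, log2_effect,
    regulated).
    """
    if not 0 <= frac_regulated <= 1:
        raise ValueError("frac_regulated must be in [0, 1]")
    if n_batches < 1:
        raise ValueError("need at least one batch")
    if direction not in ("both", "up", "down"):
        raise ValueError("direction must be 'both', 'up' or 'down'")
    if scale not in ("intensity", "log2"):
        raise ValueError("scale must be 'intensity' or 'log2'")
    rng = np.random.default_rng(seed)

    residues = rng.choice(list("STY"), size=n_sites, p=[0.858, 0.125, 0.017])
    positions = rng.integers(5, 2000, size=n_sites)
    proteins = [f"PROT{i:05d}" for i in range(n_sites)]
    site_ids = [f"{p}:{r}{pos}" for p, r, pos in zip(proteins, residues, positions)]
    n_low = int(round(frac_below_class1 * n_sites))
    loc = np.empty(n_sites)
    low_idx = rng.choice(n_sites, size=n_low, replace=False)
    is_low = np.zeros(n_sites, dtype=bool)
    is_low[low_idx] = True
    loc[is_low] = rng.uniform(0.0, 0.7499, size=n_low)
    loc[~is_low] = 0.75 + 0.25 * rng.beta(5.0, 1.0, size=n_sites - n_low)
    windows = [_random_window(rng, r) for r in residues]
    sites = pd.DataFrame(
        {
            "protein": proteins,
            "position": positions,
            "residue": residues,
            "localization_prob": loc,
            "window": windows,
        },
        index=pd.Index(site_ids, name="site_id"),
    )

    n_reg = int(round(frac_regulated * n_sites))
    reg_idx = rng.choice(n_sites, size=n_reg, replace=False)
    effects = np.zeros(n_sites)
    if direction == "both":
        signs = rng.choice([-1.0, 1.0], size=n_reg)
    else:
        signs = np.full(n_reg, 1.0 if direction == "up" else -1.0)
    effects[reg_idx] = signs * effect_size
    truth = pd.DataFrame(
        {"site_id": site_ids, "log2_effect": effects, "regulated": effects != 0}
    ).set_index("site_id")

    # sample layout: treated/control pairs spread round-robin over batches
    conditions = ["treated"] * n_samples_per_group + ["control"] * n_samples_per_group
    sample_ids, batches = [], []
    for cond_i, cond in enumerate(conditions):
        rep = cond_i % n_samples_per_group
        sample_ids.append(f"{'T' if cond == 'treated' else 'C'}{rep + 1}")
        batches.append(f"B{rep % n_batches + 1}")
    samples = pd.DataFrame(
        {"batch": batches, "condition": conditions},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    baseline = rng.normal(20.0, 2.0, size=n_sites)
    batch_levels = sorted(set(batches))
    batch_offsets = {b: rng.normal(0.0, batch_sd, size=n_sites) for b in batch_levels}
    log2vals = np.empty((n_sites, len(sample_ids)))
    for s, (cond, b) in enumerate(zip(conditions, batches)):
        log2vals[:, s] = (
            baseline
            + batch_offsets[b]
            + (effects if cond == "treated" else 0.0)
            + rng.normal(0.0, residual_sd, size=n_sites)
        )
    if frac_missing > 0:
        mask = rng.random(log2vals.shape) < frac_missing
        log2vals[mask] = np.nan
    values = pd.DataFrame(log2vals, index=sites.index, columns=samples.index)
    if scale == "intensity":
        values = 2.0**values
    table = PhosphoSiteTable(
        values=values, sites=sites, samples=samples, log2=(scale == "log2")
    )
    return table, truth


def gen_functional_scores(
    sites: pd.DataFrame,
    truth: pd.DataFrame,
    high_score_fraction: float = 0.8,
    coverage: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site functional scores in [0, 1] covering a subset of sites.

    Of the planted-regulated sites that are covered, ``high_score_fraction``
    receive a score strictly above 0.6; everything else draws from a
    low-skewed Beta.  ``coverage`` < 1 leaves a fraction of sites unscored
    to exercise the unscored-site path downstream.
    """
    if not 0 <= high_score_fraction <= 1 or not 0 <= coverage <= 1:
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    covered = sites.index[rng.random(len(sites)) < coverage] if coverage < 1 else sites.index
    regulated = truth.index[truth["regulated"]]
    scores = pd.Series(rng.beta(1.2, 3.0, size=len(covered)), index=covered)
    reg_cov = covered.intersection(regulated)
    high = reg_cov[rng.random(len(reg_cov)) < high_score_fraction]
    scores.loc[high] = rng.uniform(0.62, 1.0, size=len(high))
    out = sites.loc[covered, ["protein", "position"]].copy()
    out["score"] = scores
    return out.reset_index(drop=True)


def gen_kinase_map(
    n_kinases: int,
    substrates_per_kinase: int,
    sites: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Random kinase -> substrate map over the given sites (may overlap)."""
    if substrates_per_kinase < 1:
        raise ValueError("substrates_per_kinase must be >= 1")
    if substrates_per_kinase > len(sites):
        raise ValueError("substrates_per_kinase exceeds the number of available sites")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_kinases):
        chosen = rng.choice(len(sites), size=substrates_per_kinase, replace=False)
        for c in chosen:
            rows.append(
                {
                    "kinase": f"KIN{i + 1:03d}",
                    "protein": sites["protein"].iloc[c],
                    "position": sites["position"].iloc[c],
                }
            )
    return pd.DataFrame(rows, columns=["kinase", "protein", "position"])


# --- synthetic patient cohort -------------------------------------------------

RISK_GROUPS = ("favorable", "intermediate", "high")


def gen_patient_cohort(seed: int = 0) -> pd.DataFrame:
    """Synthetic 44-patient cohort with ground-truth selinexor Hill curves.

    A stand-in for a per-patient clinical table that is not shipped with
    this package.  The cohort encodes the census structure of an AML
    ex vivo study: 18 responders (true EC50 log-uniform on [50, 600] nM)
    and 26 non-responders ([1800, 20000] nM), a 20-sample phosphoproteome
    subset containing 9 responders and 11 non-responders, and ELN-style
    risk groups with the subset split 9 favorable / 8 intermediate /
    3 high (45/40/15%).  True EC50s are kept well clear of the 1 uM
    responder cutoff, as the underlying per-patient values are.  Within
    each stratum the specific values are randomized under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_resp, n_nonresp = 18, 26
    ec50 = np.concatenate(
        [
            np.exp(rng.uniform(np.log(50.0), np.log(600.0), size=n_resp)),
            np.exp(rng.uniform(np.log(1800.0), np.log(20000.0), size=n_nonresp)),
        ]
    )
    m = rng.uniform(0.9, 1.1, size=ec50.size)
    n = rng.uniform(-2.2, -0.7, size=ec50.size)
    k = ec50 * (2 * m - 1) ** (1.0 / n)
    responder_truth = np.array([True] * n_resp + [False] * n_nonresp)

    in_subset = np.zeros(ec50.size, dtype=bool)
    in_subset[rng.choice(n_resp, size=9, replace=False)] = True
    in_subset[n_resp + rng.choice(n_nonresp, size=11, replace=False)] = True

    risk = np.empty(ec50.size, dtype=object)
    subset_idx = rng.permutation(np.flatnonzero(in_subset))
    for idx, grp in zip(subset_idx, ["favorable"] * 9 + ["intermediate"] * 8 + ["high"] * 3):
        risk[idx] = grp
    rest_idx = rng.permutation(np.flatnonzero(~in_subset))
    rest_groups = ["favorable"] * 5 + ["intermediate"] * 10 + ["high"] * 9
    for idx, grp in zip(rest_idx, rest_groups):
        risk[idx] = grp

    order = rng.permutation(ec50.size)
    return pd.DataFrame(
        {
            "patient_id": [f"AML{i + 1:02d}" for i in range(ec50.size)],
            "true_k": k[order],
            "true_m": m[order],
            "true_n": n[order],
            "true_ec50": ec50[order],
            "true_responder": responder_truth[order],
            "in_phospho_subset": in_subset[order],
            "risk_group": risk[order],
        }
    ).set_index("patient_id")


def gen_cohort_plates(
    cohort: pd.DataFrame, noise_sd: float = 0.02, seed: int = 0
) -> list[ViabilityPlate]:
    """One noisy 11-dose viability plate per cohort patient (drug selinexor)."""
    plates = []
    for i, (pid, row) in enumerate(cohort.iterrows()):
        curve = GroundTruthCurve(
            k=row["true_k"], m=row["true_m"], n=row["true_n"], noise_sd=noise_sd
        )
        plates.append(
            gen_viability_plate(curve, seed=seed + 7919 * (i + 1), sample_id=pid, drug="selinexor")
        )
    return plates
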