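"""Cohort, genotype and weight-table generation.

The generator emulates a population-based study of adults aged 30–95
(age ~ N(55.5, 14.0) truncated, 56.2% women, BMI ~ N(25.8, 4.4)
truncated above 14, 12.2% current smokers) with an additive genetic
architecture for leukocyte telomere length: latent LTL is a linear
function of the standardized primary polygenic score (default 0.14
SD/SD), chronological age (default −0.006 SD/year) and sex (default
+0.02 SD for women), with an independent Gaussian residual whose SD is
chosen to make the marginal SD of latent LTL ~1.

Variants are independent with minor allele frequency ~ U(0.05, 0.5) and
integer effect-allele dosages ~ Binomial(2, MAF); linkage disequilibrium
is deliberately not modeled (the PRS is a weighted sum, so recovery of
the regression contracts does not depend on it).  Panel structure: the
Mendelian-randomization panel nests inside the genome-wide-significant
panel of the primary GWAS; the two sensitivity panels from the second
GWAS are disjoint from them, with the sentinel panel nested in the
FDR panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..config import CELL_TYPES, ScenarioConfig
from ..ltl import compute_delta_ltl, compute_prs, standardize
from ..rng import substream

__all__ = ["TruthRecord", "generate_cohort"]

#: Dirichlet concentrations for the 12 leukocyte subtypes
#: (neutrophil-dominant, ~whole-blood composition).
_CELL_ALPHA = {
    "basophils": 0.6,
    "eosinophils": 2.5,
    "neutrophils": 55.0,
    "monocytes": 8.0,
    "b_naive": 2.5,
    "b_memory": 1.5,
    "cd4t_naive": 6.0,
    "cd4t_memory": 6.0,
    "t_regulatory": 1.5,
    "cd8t_naive": 3.5,
    "cd8t_memory": 3.0,
    "natural_killer": 4.0,
}

_EDUCATION_LEVELS = ("less_than_high_school", "high_school", "higher")
_EDUCATION_PROBS = (0.12, 0.43, 0.45)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    latent_ltl: np.ndarray
    #: z-scale exposure vectors actually used to plant outcome effects
    exposures: dict[str, np.ndarray]
    planted_effects: dict[tuple[str, str], float]
    causal_cpg_ids: list[str] = field(default_factory=list)
    causal_cpg_effects: dict[str, float] = field(default_factory=dict)


@lru_cache(maxsize=None)
def _matched_truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) such that the normal truncated to [lo, hi] has
    the requested mean and SD — published summaries describe the
    truncated data, not a latent parent."""

    def eqs(theta):
        mu, log_sigma = theta
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    mu, log_sigma = optimize.fsolve(eqs, [mean, np.log(sd)], xtol=1e-12)
    return float(mu), float(np.exp(log_sigma))


def _truncnorm(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    mu, sigma = _matched_truncnorm_params(float(mean), float(sd), float(lo), float(hi))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _variant_weight_table(config: ScenarioConfig, rng) -> pd.DataFrame:
    sizes = config.panel_sizes
    n_codd = sizes["gws_codd"]
    n_li = sizes["fdr_li"]
    n_total = n_codd + n_li
    alleles = np.array(list("ACGT"))
    eff = rng.integers(0, 4, n_total)
    other = (eff + rng.integers(1, 4, n_total)) % 4
    # per-allele effects on normalized LTL, magnitudes like published
    # GWAS betas (~0.01-0.12 SD per allele), oriented to the
    # longer-LTL allele (all positive)
    weight = np.abs(rng.normal(0.0, 0.035, n_total)) + 0.005
    tab = pd.DataFrame(
        {
            "variant_id": [f"rs{1_000_000 + i}" for i in range(n_total)],
            "effect_allele": alleles[eff],
            "other_allele": alleles[other],
            "weight": weight,
            "maf": rng.uniform(0.05, 0.5, n_total),
        }
    )
    is_codd = np.arange(n_total) < n_codd
    tab["gws_codd"] = is_codd.astype(int)
    mr_idx = rng.choice(n_codd, size=sizes["mr_codd"], replace=False)
    mr = np.zeros(n_total, dtype=int)
    mr[mr_idx] = 1
    tab["mr_codd"] = mr
    tab["fdr_li"] = (~is_codd).astype(int)
    gws_li = np.zeros(n_total, dtype=int)
    gws_li[n_codd + rng.choice(n_li, size=sizes["gws_li"], replace=False)] = 1
    tab["gws_li"] = gws_li
    return tab


def generate_cohort(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (cohort table, genotype dosage matrix, variant weight
    table, truth record) for one scenario."""
    config.validate()
    n = config.n_participants
    seed = config.seed

    woman = substream(seed, "sex").random(n) < config.frac_women
    pcs = substream(seed, "pcs").standard_normal((n, 10))
    alpha = np.array([_CELL_ALPHA[c] for c in CELL_TYPES])
    props = substream(seed, "cellprops").dirichlet(alpha, size=n)
    batch_labels = np.array([f"B{k + 1:02d}" for k in range(config.n_batches)])
    cols: dict[str, np.ndarray | list] = {
        "participant_id": [f"sub{i + 1:05d}" for i in range(n)],
        "age": _truncnorm(
            substream(seed, "age"), config.age_mean, config.age_sd, *config.age_range, size=n
        ),
        "sex": np.where(woman, "woman", "man"),
        "education": substream(seed, "education").choice(
            _EDUCATION_LEVELS, size=n, p=_EDUCATION_PROBS
        ),
        "smoking": np.where(
            substream(seed, "smoking").random(n) < config.frac_smoking, "current", "non-current"
        ),
        "bmi": _truncnorm(
            substream(seed, "bmi"), config.bmi_mean, config.bmi_sd, lo=config.bmi_floor, size=n
        ),
        "batch": batch_labels[substream(seed, "batch").integers(0, config.n_batches, n)],
    }
    for i in range(10):
        cols[f"pc{i + 1}"] = pcs[:, i]
    for i, cell in enumerate(CELL_TYPES):
        cols[f"cell_{cell}"] = props[:, i]
    cohort = pd.DataFrame(cols)

    weights = _variant_weight_table(config, substream(seed, "weights"))
    geno_rng = substream(seed, "genotypes")
    dosages = pd.DataFrame(
        geno_rng.binomial(2, weights["maf"].to_numpy(), size=(n, len(weights))).astype(float),
        columns=weights["variant_id"].tolist(),
    )

    # latent true LTL: genetic + demographic systematic part plus a
    # residual sized so the marginal SD is ~1
    prs_z = standardize(compute_prs(dosages, weights, config.primary_panel).to_numpy())
    systematic = (
        config.prs_to_ltl * prs_z
        + config.ltl_age_slope * (cohort["age"].to_numpy() - config.age_mean)
        + config.ltl_sex_effect * (woman.astype(float) - woman.mean())
    )
    var_sys = systematic.var(ddof=1)
    if var_sys >= 0.95:
        raise ValueError("systematic LTL variance >= 0.95; no room for a residual")
    latent = systematic + np.sqrt(1.0 - var_sys) * substream(seed, "ltl_noise").standard_normal(n)

    measured_z = standardize(latent)
    _, delta_z = compute_delta_ltl(
        measured_z, prs_z, cohort["batch"], pcs
    )
    truth = TruthRecord(
        latent_ltl=latent,
        exposures={"measured": measured_z, "prs": prs_z, "delta": delta_z},
        planted_effects=dict(config.planted_effects),
    )
    return cohort, dosages, weights.drop(columns=["maf"]), truth
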