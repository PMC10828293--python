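"""Linear-model battery for LTL exposures versus vascular phenotypes.

Three model families, one per exposure, each with exactly the covariate
set its design calls for (all continuous variables z-scored, categorical
covariates as indicator contrasts):

* measured LTL:  phenotype ~ measured LTL + age + sex + LTL batch + BMI
  + smoking status
* genetically predicted LTL:  phenotype ~ PRS + age + sex + first 10
  genetic PCs + BMI + smoking status
* ΔLTL:  phenotype ~ ΔLTL + age + sex + BMI + smoking status +
  matching-panel PRS

Outcomes are the nine composite phenotypes plus SBP, DBP and the
composite vascular health index.  Standardized effects are reported
with normal-approximation 95% CIs (β ± 1.96·SE; a t-quantile option is
available) and two-sided p-values from the t distribution.  No
multiple-testing adjustment is applied in this battery, by design: the
exposure–phenotype hypotheses are specified a priori, with significance
at P < 0.05.  A sensitivity variant further adjusts the measured-LTL
family for the 12 leukocyte subtype proportions (one dropped against
the simplex constraint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import ANALYSIS_OUTCOMES, CELL_TYPES
from .ltl import N_GENETIC_PCS, standardize

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "InteractionResult",
    "fit_linear_model",
    "build_analysis_frame",
    "run_battery",
    "test_interaction",
    "correlate_leukocytes",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ModelSpec:
    exposure: str
    outcome: str
    covariates: tuple[str, ...]


@dataclass
class AssociationResult:
    spec: ModelSpec
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "exposure": self.spec.exposure,
            "outcome": self.spec.outcome,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "covariate_set": ",".join(self.spec.covariates),
        }


def fit_linear_model(
    outcome_z,
    exposure_z,
    covariates: pd.DataFrame | None = None,
    ci_method: str = "normal",
    spec: ModelSpec | None = None,
) -> AssociationResult:
    """OLS of the standardized outcome on the standardized exposure plus
    covariates, with intercept; effect, SE, CI and two-sided p reported
    for the exposure term."""
    y = np.asarray(outcome_z, dtype=float)
    x = np.asarray(exposure_z, dtype=float)
    n = y.size
    cols = [np.ones(n), x]
    names = ["const", "exposure"]
    if covariates is not None and covariates.shape[1]:
        cols.extend(np.asarray(covariates[c], dtype=float) for c in covariates.columns)
        names.extend(map(str, covariates.columns))
    X = np.column_stack(cols)
    if n <= X.shape[1]:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    beta = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    if ci_method == "normal":
        q = 1.959963984540054  # N(0,1) 97.5% quantile
    elif ci_method == "t":
        q = float(stats.t.ppf(0.975, fit.df_resid))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    if spec is None:
        spec = ModelSpec("exposure", "outcome", tuple(names[2:]))
    return AssociationResult(
        spec=spec,
        beta=beta,
        se=se,
        ci_low=beta - q * se,
        ci_high=beta + q * se,
        p=float(fit.pvalues["exposure"]),
        n=n,
    )


def _encode_covariates(frame: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric design columns for named covariates: z-scores for
    continuous, indicators for sex/smoking, dummy contrasts for batch."""
    cols = {}
    for name in names:
        if name == "age":
            cols["age_z"] = standardize(frame["age"].to_numpy())
        elif name == "bmi":
            cols["bmi_z"] = standardize(frame["bmi"].to_numpy())
        elif name == "sex":
            cols["woman"] = (frame["sex"] == "woman").astype(float).to_numpy()
        elif name == "smoking":
            cols["smoker"] = (frame["smoking"] == "current").astype(float).to_numpy()
        elif name == "batch":
            dummies = pd.get_dummies(
                pd.Categorical(frame["batch"]), drop_first=True, dtype=float, prefix="batch"
            )
            for c in dummies.columns:
                cols[str(c)] = dummies[c].to_numpy()
        elif name == "pcs":
            for i in range(1, N_GENETIC_PCS + 1):
                cols[f"pc{i}"] = frame[f"pc{i}"].to_numpy(dtype=float)
        elif name == "cells":
            # drop neutrophils (largest mean) against the simplex constraint
            for cell in CELL_TYPES:
                if cell != "neutrophils":
                    cols[f"cell_{cell}"] = frame[f"cell_{cell}"].to_numpy(dtype=float)
        elif name.startswith("prs:"):
            cols[name.replace(":", "_")] = frame[f"prs_z_{name[4:]}"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return pd.DataFrame(cols)


def covariate_family(exposure: str, panel: str, cell_adjusted: bool = False) -> tuple[str, ...]:
    if exposure == "measured":
        base = ("age", "sex", "batch", "bmi", "smoking")
        return base + (("cells",) if cell_adjusted else ())
    if exposure == "prs":
        return ("age", "sex", "pcs", "bmi", "smoking")
    if exposure == "delta":
        return ("age", "sex", "bmi", "smoking", f"prs:{panel}")
    raise ValueError(f"unknown exposure family {exposure!r}")


def _exposure_column(exposure: str, panel: str) -> str:
    return {
        "measured": "measured_z",
        "prs": f"prs_z_{panel}",
        "delta": f"delta_{panel}",
    }[exposure]


def build_analysis_frame(
    cohort: pd.DataFrame, ltl_measures: pd.DataFrame, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Complete-case join of cohort covariates, exposures and raw-scale
    phenotypes on participant_id."""
    frame = cohort.merge(ltl_measures, on="participant_id").merge(
        phenotypes, on="participant_id"
    )
    return frame.dropna()


def run_battery(
    frame: pd.DataFrame,
    exposures=("measured", "prs", "delta"),
    outcomes=ANALYSIS_OUTCOMES,
    panels=("gws_codd",),
    cell_adjusted: bool = False,
    ci_method: str = "normal",
) -> pd.DataFrame:
    """One model per exposure family × outcome (× panel for the genetic
    families); returns the association table."""
    results = []
    for exposure in exposures:
        for panel in panels if exposure != "measured" else (panels[0],):
            family = covariate_family(exposure, panel, cell_adjusted and exposure == "measured")
            xcol = _exposure_column(exposure, panel)
            if xcol not in frame.columns:
                raise ValueError(f"missing exposure column {xcol!r}")
            covs = _encode_covariates(frame, family)
            x = frame[xcol].to_numpy(dtype=float)
            for outcome in outcomes:
                if outcome not in frame.columns:
                    raise ValueError(f"missing outcome column {outcome!r}")
                y = standardize(frame[outcome].to_numpy())
                label = exposure if exposure == "measured" else f"{exposure}_{panel}"
                spec = ModelSpec(label, outcome, family)
                results.append(fit_linear_model(y, x, covs, ci_method=ci_method, spec=spec))
    return pd.DataFrame([r.to_dict() for r in results])


@dataclass
class InteractionResult:
    exposure: str
    outcome: str
    modifier: str
    beta: float
    se: float
    p: float
    stratified: dict[str, AssociationResult] = field(default_factory=dict)


def test_interaction(
    frame: pd.DataFrame,
    exposure: str,
    outcome: str,
    modifier: str,
    panel: str = "gws_codd",
) -> InteractionResult:
    """Add an exposure×modifier term to the family's base model.

    ``modifier`` is ``age`` (z-scored) or ``sex`` (woman indicator).
    Sex-stratified fits are emitted only when the interaction is
    significant at P < 0.05.
    """
    if modifier not in ("age", "sex"):
        raise ValueError("modifier must be 'age' or 'sex'")
    family = covariate_family(exposure, panel)
    xcol = _exposure_column(exposure, panel)
    x = frame[xcol].to_numpy(dtype=float)
    y = standardize(frame[outcome].to_numpy())
    covs = _encode_covariates(frame, family)
    mod = covs["age_z" if modifier == "age" else "woman"].to_numpy()
    if np.unique(mod).size < 2:
        raise ValueError("modifier has a single level")
    design = covs.copy()
    design["exposure_x_modifier"] = x * mod
    n = len(y)
    X = sm.add_constant(pd.concat([pd.Series(x, name="exposure"), design], axis=1))
    fit = sm.OLS(y, X.astype(float)).fit()
    beta = float(fit.params["exposure_x_modifier"])
    se = float(fit.bse["exposure_x_modifier"])
    p = float(fit.pvalues["exposure_x_modifier"])
    stratified: dict[str, AssociationResult] = {}
    if p < ALPHA and modifier == "sex":
        for level in ("woman", "man"):
            sub = frame[frame["sex"] == level]
            sub_family = tuple(c for c in family if c != "sex")
            res = fit_linear_model(
                standardize(sub[outcome].to_numpy()),
                standardize(sub[xcol].to_numpy()),
                _encode_covariates(sub, sub_family),
                spec=ModelSpec(exposure, outcome, sub_family),
            )
            stratified[level] = res
    return InteractionResult(exposure, outcome, modifier, beta, se, p, stratified)


def correlate_leukocytes(measured_z, cell_props: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of measured LTL with each of the 12 leukocyte
    subtype proportions (two-sided p per subtype)."""
    x = np.asarray(measured_z, dtype=float)
    rows = []
    for col in cell_props.columns:
        y = cell_props[col].to_numpy(dtype=float)
        if not y.std(ddof=1) > 0:
            raise ValueError(f"zero-variance cell proportion column {col!r}")
        r, p = stats.pearsonr(x, y)
        rows.append({"subtype": str(col).removeprefix("cell_"), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
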