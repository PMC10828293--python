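"""Scenario configuration for the synthetic cohort generator.

A :class:`ScenarioConfig` fixes everything the simulator needs: cohort
size, the master seed, PRS panel sizes, the planted standardized
exposure→phenotype coefficients, covariate effects, the genetic and
demographic architecture of latent telomere length, and the methylation
architecture.  Preset scenarios (:func:`scenario_measured`,
:func:`scenario_prs`, :func:`scenario_delta`) carry the effect sizes the
study design is calibrated to, one exposure family per scenario so each
planted coefficient is identifiable by its own model family.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "ScenarioConfig",
    "PLANTABLE_OUTCOMES",
    "INDUCED_OUTCOMES",
    "COMPOSITE_PHENOTYPES",
    "ANALYSIS_OUTCOMES",
    "CELL_TYPES",
    "EXPOSURES",
    "scenario_null",
    "scenario_measured",
    "scenario_prs",
    "scenario_delta",
]

#: The seven derived phenotypes with a free dimension in the raw
#: back-construction.  MAP and PP are functional consequences
#: (MAP = SVRI*CI/80, PP = SI/TACI) and SBP/DBP follow from MAP and PP.
PLANTABLE_OUTCOMES = (
    "rsh",
    "cardiac_index",
    "svri",
    "stroke_index",
    "taci",
    "pwv",
    "abi",
)

INDUCED_OUTCOMES = ("map", "pp", "sbp", "dbp")

#: The nine phenotypes entering the composite vascular health index.
COMPOSITE_PHENOTYPES = (
    "rsh",
    "cardiac_index",
    "svri",
    "stroke_index",
    "taci",
    "pwv",
    "abi",
    "map",
    "pp",
)

#: Outcomes of the association battery: nine composite phenotypes
#: plus SBP, DBP and the composite index itself.
ANALYSIS_OUTCOMES = COMPOSITE_PHENOTYPES + ("sbp", "dbp", "composite")

EXPOSURES = ("measured", "prs", "delta")

#: Twelve leukocyte subtypes used as methylation covariates.
CELL_TYPES = (
    "basophils",
    "eosinophils",
    "neutrophils",
    "monocytes",
    "b_naive",
    "b_memory",
    "cd4t_naive",
    "cd4t_memory",
    "t_regulatory",
    "cd8t_naive",
    "cd8t_memory",
    "natural_killer",
)

#: Raw-scale anchors (mean, SD) for the plantable phenotypes.  Means match
#: the cohort summary this generator emulates; the RSH and PWV SDs are
#: narrowed so the affine z→raw map stays within physical support (see
#: docs/methods.md).
DEFAULT_RAW_SCALES: dict[str, tuple[float, float]] = {
    "rsh": (499.0, 150.0),
    "cardiac_index": (3.2, 0.5),
    "svri": (2120.0, 469.0),
    "stroke_index": (52.1, 8.7),
    "taci": (1.1, 0.15),
    "pwv": (6.8, 1.5),
    "abi": (1.2, 0.1),
}

_DEFAULT_PANELS = {"gws_codd": 150, "mr_codd": 130, "fdr_li": 47, "gws_li": 20}

_DEFAULT_COVARIATE_EFFECTS: dict[tuple[str, str], float] = {
    ("age", "rsh"): -0.15,
    ("age", "cardiac_index"): -0.25,
    ("age", "svri"): 0.20,
    ("age", "stroke_index"): -0.10,
    ("age", "taci"): -0.30,
    ("age", "pwv"): 0.45,
    ("age", "abi"): -0.05,
    ("sex", "cardiac_index"): -0.10,
    ("sex", "svri"): 0.10,
    ("sex", "stroke_index"): -0.05,
    ("sex", "pwv"): -0.10,
    ("bmi", "rsh"): -0.10,
    ("bmi", "cardiac_index"): -0.05,
    ("bmi", "svri"): 0.15,
    ("bmi", "taci"): -0.10,
    ("bmi", "pwv"): 0.15,
    ("smoking", "rsh"): -0.10,
    ("smoking", "pwv"): 0.05,
}

_DEFAULT_NOISE_SDS = {
    # extra multiplicative (log-scale) noise on the qPCR-implied T/S
    "ltl_measurement": 0.0,
    # per-well Ct noise for sample triplicates and standard-curve points
    "qpcr_ct": 0.05,
    "std_curve_ct": 0.02,
    # residual SD of the methylation latent (logit scale)
    "methylation": 1.0,
    # flux noise added to the skin-blood-flow trace (window means preserved)
    "trace": 2.0,
}


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic study scenario.

    Parameters mirror the population this simulator emulates: ~4180
    adults aged 30–95 (mean 55.5, SD 14.0), 56.2% women, BMI 25.8 (4.4),
    12.2% current smokers, with an additive genetic score explaining a
    0.14 SD/SD share of telomere length, an age slope of −0.006 SD/year
    and a +0.02 SD effect for women.
    """

    n_participants: int = 4180
    seed: int = 0
    panel_sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_PANELS))
    #: (exposure, outcome) → standardized coefficient (SD per SD).
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    #: (covariate, outcome) → SD of outcome per SD of covariate
    #: (continuous) or per category (sex=woman, smoking=current).
    covariate_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    ltl_age_slope: float = -0.006  # SD of LTL per year of age
    ltl_sex_effect: float = 0.02  # SD of LTL, women vs men
    prs_to_ltl: float = 0.14  # SD of LTL per SD of the primary PRS
    primary_panel: str = "gws_codd"
    n_cpgs: int = 5000
    n_causal_cpgs: int = 10
    cpg_effect_size: float = 0.5  # logit-latent units per SD of exposure
    noise_sds: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SDS))
    raw_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RAW_SCALES)
    )
    n_batches: int = 8
    frac_women: float = 0.562
    frac_smoking: float = 0.122
    age_mean: float = 55.5
    age_sd: float = 14.0
    age_range: tuple[float, float] = (30.0, 95.0)
    bmi_mean: float = 25.8
    bmi_sd: float = 4.4
    bmi_floor: float = 14.0
    qpcr_efficiency: dict[str, float] = field(
        default_factory=lambda: {"tel": 0.98, "alb": 1.00}
    )
    max_redraws: int = 50

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_cpgs < 0 or self.n_causal_cpgs < 0 or self.n_causal_cpgs > self.n_cpgs:
            raise ValueError("need 0 <= n_causal_cpgs <= n_cpgs")
        for panel, size in self.panel_sizes.items():
            if size < 1:
                raise ValueError(f"panel {panel!r} must have >= 1 variant")
        if self.panel_sizes.get("mr_codd", 0) > self.panel_sizes.get("gws_codd", 0):
            raise ValueError("mr_codd panel must nest inside gws_codd")
        if self.panel_sizes.get("gws_li", 0) > self.panel_sizes.get("fdr_li", 0):
            raise ValueError("gws_li panel must nest inside fdr_li")
        if self.primary_panel not in self.panel_sizes:
            raise ValueError(f"unknown primary panel {self.primary_panel!r}")
        for (exposure, outcome), coef in self.planted_effects.items():
            if exposure not in EXPOSURES:
                raise ValueError(f"unknown exposure {exposure!r}")
            if outcome not in PLANTABLE_OUTCOMES:
                raise ValueError(
                    f"cannot plant an effect on {outcome!r}; MAP/PP/SBP/DBP are "
                    "functionally induced by the seven free phenotypes"
                )
            if not (abs(coef) < 1.0):
                raise ValueError("planted standardized coefficients must satisfy |b| < 1")
        for (covariate, outcome), coef in self.covariate_effects.items():
            if covariate not in ("age", "sex", "bmi", "smoking"):
                raise ValueError(f"unknown covariate {covariate!r}")
            if outcome not in PLANTABLE_OUTCOMES:
                raise ValueError(f"cannot plant a covariate effect on {outcome!r}")
            if not (abs(coef) < 1.0):
                raise ValueError("covariate effects must satisfy |b| < 1")
        for p in (self.frac_women, self.frac_smoking):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must be probabilities")
        if not (abs(self.prs_to_ltl) < 1 and abs(self.ltl_sex_effect) < 1):
            raise ValueError("architecture coefficients must satisfy |b| < 1")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        for name, sd in self.noise_sds.items():
            if sd < 0:
                raise ValueError(f"noise SD {name!r} must be non-negative")

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_effects"] = {f"{e}:{o}": v for (e, o), v in self.planted_effects.items()}
        d["covariate_effects"] = {f"{c}:{o}": v for (c, o), v in self.covariate_effects.items()}
        d["raw_scales"] = {k: list(v) for k, v in self.raw_scales.items()}
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "planted_effects" in d:
            d["planted_effects"] = {
                tuple(k.split(":")): float(v) for k, v in d["planted_effects"].items()
            }
        if "covariate_effects" in d:
            d["covariate_effects"] = {
                tuple(k.split(":")): float(v) for k, v in d["covariate_effects"].items()
            }
        if "raw_scales" in d:
            d["raw_scales"] = {k: tuple(v) for k, v in d["raw_scales"].items()}
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# -- Preset scenarios ------------------------------------------------------
# One scenario per exposure family; each carries the standardized effect
# sizes its model family is calibrated to recover.


def scenario_null(n: int = 4180, seed: int = 0, **kwargs) -> ScenarioConfig:
    """All exposure→phenotype effects zero (type-I-error calibration)."""
    return ScenarioConfig(n_participants=n, seed=seed, planted_effects={}, **kwargs)


def scenario_measured(n: int = 1828, seed: int = 0, **kwargs) -> ScenarioConfig:
    """Measured-LTL exposure scenario (RSH +0.20, CI +0.19, SVRI −0.13)."""
    return ScenarioConfig(
        n_participants=n,
        seed=seed,
        planted_effects={
            ("measured", "rsh"): 0.20,
            ("measured", "cardiac_index"): 0.19,
            ("measured", "svri"): -0.13,
        },
        **kwargs,
    )


def scenario_prs(n: int = 4180, seed: int = 0, **kwargs) -> ScenarioConfig:
    """Genetically-predicted-LTL scenario (CI +0.04; PRS→LTL 0.14)."""
    return ScenarioConfig(
        n_participants=n,
        seed=seed,
        planted_effects={("prs", "cardiac_index"): 0.04},
        **kwargs,
    )


def scenario_delta(n: int = 1828, seed: int = 0, **kwargs) -> ScenarioConfig:
    """ΔLTL scenario (RSH +0.07, CI +0.08, SVRI −0.06)."""
    return ScenarioConfig(
        n_participants=n,
        seed=seed,
        planted_effects={
            ("delta", "rsh"): 0.07,
            ("delta", "cardiac_index"): 0.08,
            ("delta", "svri"): -0.06,
        },
        **kwargs,
    )
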