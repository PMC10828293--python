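"""Model/Results interface over the association battery.

``TeloVascModel`` binds the joined analysis data (cohort covariates,
LTL exposures, derived phenotypes); ``fit()`` runs the three
exposure-family model batteries and returns a ``TeloVascResults``
carrying the standardized effects with their uncertainties, interaction
tests, leukocyte-subtype correlations and a printable summary.

>>> model = TeloVascModel.from_tables(cohort, ltl_measures, phenotypes)
>>> results = model.fit()
>>> print(results.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association as assoc
from .config import ANALYSIS_OUTCOMES, CELL_TYPES, ScenarioConfig

__all__ = ["TeloVascModel", "TeloVascResults"]


class TeloVascModel:
    """Association model of LTL exposures against vascular phenotypes."""

    def __init__(self, frame: pd.DataFrame, panels=("gws_codd",)):
        self.frame = frame
        self.panels = tuple(panels)

    @classmethod
    def from_tables(
        cls,
        cohort: pd.DataFrame,
        ltl_measures: pd.DataFrame,
        phenotypes: pd.DataFrame,
        panels=("gws_codd",),
    ) -> "TeloVascModel":
        return cls(assoc.build_analysis_frame(cohort, ltl_measures, phenotypes), panels)

    @classmethod
    def from_simulation(cls, config: ScenarioConfig) -> "TeloVascModel":
        """Convenience constructor: simulate one scenario and bind it."""
        from .ltl import build_ltl_measures
        from .sim import simulate_analysis_dataset

        cohort, dosages, weights, phenotypes, truth = simulate_analysis_dataset(config)
        ltl = build_ltl_measures(
            cohort, dosages, weights, truth.latent_ltl, panels=(config.primary_panel,)
        )
        return cls.from_tables(cohort, ltl, phenotypes, panels=(config.primary_panel,))

    @property
    def nobs(self) -> int:
        return len(self.frame)

    def fit(
        self,
        exposures=("measured", "prs", "delta"),
        outcomes=ANALYSIS_OUTCOMES,
        cell_adjusted: bool = False,
        ci_method: str = "normal",
    ) -> "TeloVascResults":
        table = assoc.run_battery(
            self.frame,
            exposures=exposures,
            outcomes=outcomes,
            panels=self.panels,
            cell_adjusted=cell_adjusted,
            ci_method=ci_method,
        )
        return TeloVascResults(self, table)


class TeloVascResults:
    """Fitted association battery."""

    def __init__(self, model: TeloVascModel, associations: pd.DataFrame):
        self.model = model
        self.associations = associations

    def summary(self) -> str:
        tab = self.associations.copy()
        tab["95% CI"] = [
            f"({lo:+.3f}, {hi:+.3f})" for lo, hi in zip(tab["ci_low"], tab["ci_high"])
        ]
        tab["beta"] = tab["beta"].map("{:+.3f}".format)
        tab["se"] = tab["se"].map("{:.3f}".format)
        tab["p"] = tab["p"].map("{:.3g}".format)
        cols = ["exposure", "outcome", "beta", "se", "95% CI", "p", "n"]
        header = (
            "Leukocyte telomere length vs vascular phenotypes\n"
            f"n = {self.model.nobs} complete cases; standardized effects (SD per SD)\n"
        )
        return header + tab[cols].to_string(index=False)

    def interaction(self, exposure: str, outcome: str, modifier: str):
        return assoc.test_interaction(
            self.model.frame, exposure, outcome, modifier, panel=self.model.panels[0]
        )

    def leukocyte_correlations(self) -> pd.DataFrame:
        frame = self.model.frame
        cells = frame[[f"cell_{c}" for c in CELL_TYPES]]
        return assoc.correlate_leukocytes(frame["measured_z"].to_numpy(), cells)

    def significant(self, alpha: float = assoc.ALPHA) -> pd.DataFrame:
        return self.associations[self.associations["p"] < alpha]

    def plot_forest(self, ax=None):
        """Forest plot of standardized effects with 95% CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.35 * len(self.associations) + 1))
        tab = self.associations
        y = np.arange(len(tab))[::-1]
        ax.errorbar(
            tab["beta"], y,
            xerr=[tab["beta"] - tab["ci_low"], tab["ci_high"] - tab["beta"]],
            fmt="o", ms=4, capsize=2,
        )
        ax.axvline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(tab["exposure"] + " → " + tab["outcome"], fontsize=8)
        ax.set_xlabel("standardized effect (SD per SD), 95% CI")
        return ax
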