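"""Association battery: OLS engine, covariate families, interactions,
leukocyte correlations."""

import numpy as np
import pandas as pd
import pytest

from telovasc.association import (
    build_analysis_frame,
    correlate_leukocytes,
    fit_linear_model,
    run_battery,
    test_interaction as interaction_test,
)
from telovasc.config import ANALYSIS_OUTCOMES, scenario_measured, scenario_null
from telovasc.ltl import build_ltl_measures, standardize
from telovasc.rng import child_seed
from telovasc.sim import simulate_analysis_dataset


def normal_equations_oracle(y, X):
    """Closed-form OLS: beta = (X'X)^-1 X'y, se from sigma^2 (X'X)^-1."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se


@pytest.fixture(scope="module")
def measured_frame():
    cfg = scenario_measured(n=1000, seed=41)
    cohort, dosages, weights, phen, truth = simulate_analysis_dataset(cfg)
    ltl = build_ltl_measures(cohort, dosages, weights, truth.latent_ltl, panels=("gws_codd",))
    return build_analysis_frame(cohort, ltl, phen)


class TestFitLinearModel:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        x = standardize(rng.normal(size=60))
        res = fit_linear_model(0.5 * x, x)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 50
        covs = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        x = rng.normal(size=n)
        y = 0.3 * x + covs @ [0.2, -0.1, 0.4] + rng.normal(size=n)
        res = fit_linear_model(y.to_numpy(), x, covs)
        X = np.column_stack([np.ones(n), x, covs.to_numpy()])
        beta, se = normal_equations_oracle(y.to_numpy(), X)
        assert res.beta == pytest.approx(beta[1], abs=1e-8)
        assert res.se == pytest.approx(se[1], abs=1e-8)
        # normal-approximation CI
        assert res.ci_low == pytest.approx(res.beta - 1.96 * res.se, abs=1e-4)
        assert res.ci_high == pytest.approx(res.beta + 1.96 * res.se, abs=1e-4)

    def test_exposure_rescaling_leaves_standardized_beta_unchanged(self):
        rng = np.random.default_rng(2)
        raw = rng.gamma(3, 2, 200)
        y = standardize(0.4 * raw + rng.normal(size=200))
        a = fit_linear_model(y, standardize(raw))
        b = fit_linear_model(y, standardize(raw * 37.0))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_degenerate_designs_error(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            fit_linear_model(x, x, pd.DataFrame({"dup": x}))
        with pytest.raises(ValueError, match="parameters"):
            fit_linear_model(
                np.arange(4.0), np.array([1.0, 2.0, 1.5, 3.0]),
                pd.DataFrame(np.random.default_rng(3).normal(size=(4, 3))),
            )

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        n_reps, hits = 1000, 0
        for _ in range(n_reps):
            x = rng.normal(size=120)
            y = rng.normal(size=120)
            hits += int(fit_linear_model(y, x).p < 0.05)
        assert hits / n_reps == pytest.approx(0.05, abs=0.014)


class TestBattery:
    def test_one_row_per_exposure_outcome_pair(self, measured_frame):
        tab = run_battery(measured_frame)
        assert len(tab) == 3 * len(ANALYSIS_OUTCOMES) == 36

    def test_covariate_families_are_exact(self, measured_frame):
        tab = run_battery(measured_frame)
        by_exp = {e: set(g["covariate_set"]) for e, g in tab.groupby("exposure")}
        (measured_set,) = by_exp["measured"]
        (prs_set,) = by_exp["prs_gws_codd"]
        (delta_set,) = by_exp["delta_gws_codd"]
        assert measured_set == "age,sex,batch,bmi,smoking"
        assert prs_set == "age,sex,pcs,bmi,smoking"
        assert delta_set == "age,sex,bmi,smoking,prs:gws_codd"

    def test_cell_adjustment_runs_and_reports_both(self, measured_frame):
        plain = run_battery(measured_frame, exposures=("measured",), outcomes=("rsh",))
        adj = run_battery(
            measured_frame, exposures=("measured",), outcomes=("rsh",), cell_adjusted=True
        )
        assert "cells" in adj["covariate_set"].iloc[0]
        # cell proportions are generated independent of LTL, so the
        # sensitivity adjustment barely moves the estimate
        assert adj["beta"].iloc[0] == pytest.approx(plain["beta"].iloc[0], abs=0.05)

    def test_missing_outcome_column_errors(self, measured_frame):
        with pytest.raises(ValueError, match="missing outcome"):
            run_battery(measured_frame, outcomes=("nonexistent",))

    def test_planted_effect_recovered_across_replicates(self):
        betas = []
        for rep in range(40):
            cfg = scenario_measured(n=1828, seed=child_seed(42, rep))
            cohort, dosages, weights, phen, truth = simulate_analysis_dataset(cfg)
            ltl = build_ltl_measures(
                cohort, dosages, weights, truth.latent_ltl, panels=("gws_codd",)
            )
            frame = build_analysis_frame(cohort, ltl, phen)
            tab = run_battery(frame, exposures=("measured",), outcomes=("rsh",))
            betas.append(tab["beta"].iloc[0])
        betas = np.array(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - 0.20) < 4 * mc_se


class TestInteraction:
    def synth_frame(self, n, seed, effect_women, effect_men):
        rng = np.random.default_rng(seed)
        woman = rng.random(n) < 0.5
        x = rng.normal(size=n)
        y = np.where(woman, effect_women, effect_men) * x + rng.normal(size=n)
        return pd.DataFrame(
            {
                "age": rng.uniform(30, 95, n),
                "sex": np.where(woman, "woman", "man"),
                "bmi": rng.normal(26, 4, n),
                "smoking": np.where(rng.random(n) < 0.12, "current", "non-current"),
                "batch": rng.choice(["B1", "B2"], n),
                "measured_z": standardize(x),
                "rsh": y,
            }
        )

    def test_null_interaction_rarely_triggers_stratification(self):
        triggered = 0
        for rep in range(60):
            frame = self.synth_frame(800, 500 + rep, 0.3, 0.3)
            res = interaction_test(frame, "measured", "rsh", "sex")
            assert bool(res.stratified) == (res.p < 0.05)  # gating contract
            triggered += int(res.p < 0.05)
        assert triggered <= 9  # ~alpha * 60 plus slack

    def test_planted_sex_specific_effect_is_detected(self):
        detected = 0
        for rep in range(100):
            frame = self.synth_frame(4000, 600 + rep, 0.3, 0.0)
            res = interaction_test(frame, "measured", "rsh", "sex")
            detected += int(res.p < 0.05)
            if res.p < 0.05:
                assert set(res.stratified) == {"woman", "man"}
                assert res.stratified["woman"].beta > res.stratified["man"].beta
        assert detected >= 90

    def test_age_modifier_supported(self):
        frame = self.synth_frame(500, 7, 0.3, 0.3)
        res = interaction_test(frame, "measured", "rsh", "age")
        assert np.isfinite(res.p)

    def test_single_level_modifier_errors(self):
        frame = self.synth_frame(200, 8, 0.3, 0.3)
        frame["sex"] = "woman"
        with pytest.raises(ValueError):
            interaction_test(frame, "measured", "rsh", "sex")


class TestLeukocyteCorrelations:
    def test_independent_subtypes_give_null_correlations(self, measured_frame):
        cells = measured_frame[[c for c in measured_frame.columns if c.startswith("cell_")]]
        res = correlate_leukocytes(measured_frame["measured_z"].to_numpy(), cells)
        assert len(res) == 12
        assert (res["r"].abs() < 3 / np.sqrt(len(measured_frame))).all()

    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        cells = pd.DataFrame({"dup": x, "other": rng.normal(size=100)})
        res = correlate_leukocytes(x, cells).set_index("subtype")
        assert res.loc["dup", "r"] == pytest.approx(1.0)

    def test_weak_planted_correlation_stays_below_bound(self):
        """A true correlation of 0.2 at n=4180 stays below the 0.23
        reporting bound in at least 95% of replicates."""
        ok = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            n = 4180
            x = rng.normal(size=n)
            cells = pd.DataFrame(
                {"linked": 0.2 * x + np.sqrt(1 - 0.04) * rng.normal(size=n)}
                | {f"c{k}": rng.normal(size=n) for k in range(11)}
            )
            res = correlate_leukocytes(x, cells)
            ok += int((res["r"].abs() < 0.23).all())
        assert ok >= 95

    def test_zero_variance_column_errors(self):
        with pytest.raises(ValueError):
            correlate_leukocytes(
                np.arange(10.0), pd.DataFrame({"flat": np.ones(10)})
            )
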