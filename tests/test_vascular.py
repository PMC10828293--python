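"""Vascular phenotype derivations: formulas, ABI rule, composite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from telovasc.vascular import (
    compute_bp,
    compute_bsa,
    compute_composite,
    compute_hemodynamics,
    compute_rsh,
    compute_stiffness,
    reported_abi,
)


def flat_trace(baseline, plateau, n=1560):
    t = np.arange(n, dtype=float)
    flux = np.where(t < 120, baseline, plateau)
    return pd.DataFrame({"time_s": t, "flux": flux})


class TestBsa:
    def test_du_bois_reference_value(self):
        assert compute_bsa(1.75, 70.0) == pytest.approx(1.849, abs=2e-3)

    def test_weight_power_law(self):
        assert compute_bsa(1.75, 140.0) / compute_bsa(1.75, 70.0) == pytest.approx(2**0.425)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            compute_bsa(1.75, 0.0)

    def test_mosteller_close_to_du_bois(self):
        assert compute_bsa(1.75, 70.0, "mosteller") == pytest.approx(
            compute_bsa(1.75, 70.0), rel=0.03
        )


class TestRsh:
    def test_formula(self):
        assert compute_rsh(flat_trace(20.0, 120.0)) == pytest.approx(500.0)

    def test_no_hyperemia_is_zero(self):
        assert compute_rsh(flat_trace(30.0, 30.0)) == pytest.approx(0.0)

    def test_short_trace_errors(self):
        with pytest.raises(ValueError, match="26 minutes"):
            compute_rsh(flat_trace(20.0, 120.0, n=600))

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_rsh(flat_trace(-1.0, 120.0))


class TestHemodynamics:
    def test_arithmetic(self):
        h = compute_hemodynamics(80.0, 60.0, 2.0, 90.0)
        assert h.co == pytest.approx(4.8)
        assert h.cardiac_index == pytest.approx(2.4)
        assert h.stroke_index == pytest.approx(40.0)

    def test_svri_magnitude_uses_cardiac_index(self):
        # MAP 92.6, CI 3.2 -> 2315, the population-mean order of magnitude
        h = compute_hemodynamics(80.0, 60.0, 80.0 * 60 / 1000 / 3.2, 92.6)
        assert h.cardiac_index == pytest.approx(3.2)
        assert h.svri == pytest.approx(92.6 / 3.2 * 80, rel=1e-9)

    def test_svri_co_denominator_switch(self):
        h = compute_hemodynamics(80.0, 60.0, 2.0, 90.0, svri_denominator="co")
        assert h.svri == pytest.approx(90.0 / 4.8 * 80)

    def test_bsa_scaling(self):
        a = compute_hemodynamics(80.0, 60.0, 2.0, 90.0)
        b = compute_hemodynamics(80.0, 60.0, 1.0, 90.0)
        assert b.cardiac_index == pytest.approx(2 * a.cardiac_index)
        assert b.stroke_index == pytest.approx(2 * a.stroke_index)

    def test_doubling_sv_doubles_flow_indices(self):
        a = compute_hemodynamics(80.0, 60.0, 2.0, 90.0)
        b = compute_hemodynamics(160.0, 60.0, 2.0, 90.0)
        assert b.co == pytest.approx(2 * a.co)
        assert b.stroke_index == pytest.approx(2 * a.stroke_index)


class TestStiffness:
    def test_arithmetic(self):
        s = compute_stiffness(80.0, 50.0, 2.0, 0.6, 0.1, 132.0, 120.0, 132.0, 120.0)
        assert s.taci == pytest.approx(0.8)
        assert s.pwv == pytest.approx(6.0)
        assert s.abi == pytest.approx(1.1)

    @pytest.mark.parametrize(
        "left, right, expected",
        [(1.1, 1.2, 1.1), (1.45, 1.50, 1.50), (1.39, 1.41, 1.39), (1.40, 1.45, 1.45)],
    )
    def test_abi_side_selection_rule(self, left, right, expected):
        assert reported_abi(left, right) == pytest.approx(expected)

    @given(
        left=st.floats(0.3, 2.5, allow_nan=False),
        right=st.floats(0.3, 2.5, allow_nan=False),
    )
    def test_abi_rule_is_total(self, left, right):
        out = reported_abi(left, right)
        assert out in (left, right)

    def test_doubling_sv_doubles_taci_not_abi(self):
        a = compute_stiffness(80.0, 50.0, 2.0, 0.6, 0.1, 132.0, 120.0, 132.0, 120.0)
        b = compute_stiffness(160.0, 50.0, 2.0, 0.6, 0.1, 132.0, 120.0, 132.0, 120.0)
        assert b.taci == pytest.approx(2 * a.taci)
        assert b.abi == pytest.approx(a.abi)

    def test_zero_inputs_error(self):
        with pytest.raises(ValueError):
            compute_stiffness(80.0, 0.0, 2.0, 0.6, 0.1, 132.0, 120.0, 132.0, 120.0)


class TestBloodPressure:
    def test_mean_of_second_and_third(self):
        bp = compute_bp([(130, 80), (120, 75), (122, 77)])
        assert bp.sbp == pytest.approx(121.0)
        assert bp.dbp == pytest.approx(76.0)

    def test_map_and_pp(self):
        bp = compute_bp([(120, 75), (120, 75), (120, 75)])
        assert bp.map == pytest.approx(90.0)
        assert bp.pp == pytest.approx(45.0)
        assert bp.sbp == pytest.approx(120.0)

    def test_wrong_count_errors(self):
        with pytest.raises(ValueError):
            compute_bp([(120, 75), (118, 74)])


class TestComposite:
    def phen_table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        cols = ["rsh", "cardiac_index", "svri", "stroke_index", "taci", "pwv", "abi", "map", "pp"]
        return pd.DataFrame(rng.normal(10, 2, size=(n, 9)), columns=cols)

    def test_participant_at_sample_mean_scores_zero(self):
        tab = self.phen_table()
        # row 0 equal to the mean of the others is the full-sample mean
        tab.iloc[0] = tab.iloc[1:].mean()
        comp = compute_composite(tab)
        assert comp.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_unoriented_composite_matches_loop_oracle(self):
        tab = self.phen_table(seed=1)
        comp = compute_composite(tab, orient=False)
        oracle = np.zeros(len(tab))
        for col in tab.columns:
            z = (tab[col] - tab[col].mean()) / tab[col].std(ddof=1)
            oracle += z.to_numpy()
        np.testing.assert_allclose(comp.to_numpy(), oracle / 9, atol=1e-12)

    def test_orientation_negates_resistance_and_pressure_terms(self):
        tab = self.phen_table(seed=2)
        plain = compute_composite(tab, orient=False)
        oriented = compute_composite(tab)
        flipped = tab.copy()
        for col in ("svri", "pwv", "map", "pp"):
            flipped[col] = -flipped[col]
        np.testing.assert_allclose(
            oriented.to_numpy(), compute_composite(flipped, orient=False).to_numpy(), atol=1e-12
        )
        assert not np.allclose(plain, oriented)

    def test_zero_mean_by_construction(self):
        comp = compute_composite(self.phen_table(seed=3))
        assert comp.mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_column_errors(self):
        tab = self.phen_table()
        tab["pwv"] = 6.8
        with pytest.raises(ValueError, match="zero variance"):
            compute_composite(tab)
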