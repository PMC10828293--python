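"""qPCR quantification: standard curves, CV rule, T/S ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from telovasc.config import scenario_null
from telovasc.qpcr import (
    fit_standard_curve,
    qc_triplicate,
    quantify_plates,
    quantify_sample,
)
from telovasc.sim import generate_qpcr_plates

PERFECT_SLOPE = -3.3219280948873626  # -1/log10(2): exact twofold chemistry


def line_points(slope, intercept=35.0, concs=(230, 115, 57.5, 28.75, 14.375, 7.1875, 3.59375)):
    return [(c, intercept + slope * np.log10(c)) for c in concs]


class TestStandardCurve:
    def test_perfect_twofold_dilution_line(self):
        curve = fit_standard_curve(line_points(PERFECT_SLOPE))
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.qc_pass

    @pytest.mark.parametrize(
        "slope, expected_eff",
        [(-3.6, 10 ** (1 / 3.6) - 1), (-2.8, 10 ** (1 / 2.8) - 1)],  # ~89.6%, ~127.5%
    )
    def test_out_of_range_efficiency_fails(self, slope, expected_eff):
        curve = fit_standard_curve(line_points(slope))
        assert curve.efficiency == pytest.approx(expected_eff, rel=1e-9)
        assert not curve.qc_pass
        assert any("efficiency" in r for r in curve.qc_reasons)

    def test_low_r_squared_fails(self):
        pts = line_points(PERFECT_SLOPE)
        noisy = [(c, ct + d) for (c, ct), d in zip(pts, [2, -2, 2, -2, 2, -2, 2])]
        curve = fit_standard_curve(noisy)
        assert not curve.qc_pass

    @pytest.mark.parametrize(
        "points", [[(10, 30), (5, 31)], [(0.0, 30), (5, 31), (10, 32)]]
    )
    def test_degenerate_inputs_error(self, points):
        with pytest.raises(ValueError):
            fit_standard_curve(points)


class TestTriplicateCv:
    @pytest.mark.parametrize(
        "cts, cv, excluded",
        [
            ([20.0, 20.0, 20.0], 0.0, False),
            ([20.0, 20.0, 25.0], np.std([20, 20, 25], ddof=1) / np.mean([20, 20, 25]), True),
            ([20.0, 20.1, 20.05], 0.05 / 20.05, False),
        ],
    )
    def test_cv_rule(self, cts, cv, excluded):
        trip = qc_triplicate(cts)
        assert trip.cv == pytest.approx(cv, rel=1e-9)
        assert trip.excluded is excluded

    def test_errors(self):
        with pytest.raises(ValueError):
            qc_triplicate([20.0])
        with pytest.raises(ValueError):
            qc_triplicate([-30.0, 10.0])


class TestQuantifySample:
    def curves(self):
        tel = fit_standard_curve(line_points(PERFECT_SLOPE, intercept=28.0), "tel")
        alb = fit_standard_curve(line_points(PERFECT_SLOPE, intercept=33.0), "alb")
        return tel, alb

    def test_equal_quantities_give_unit_ratio(self):
        tel, alb = self.curves()
        # Cts implying 25 ng on each curve
        ct_t = 28.0 + PERFECT_SLOPE * np.log10(25)
        ct_a = 33.0 + PERFECT_SLOPE * np.log10(25)
        res = quantify_sample(qc_triplicate([ct_t] * 3), qc_triplicate([ct_a] * 3), tel, alb)
        assert res.qc_pass
        assert res.ts_ratio == pytest.approx(1.0, rel=1e-12)

    def test_one_cycle_is_one_doubling(self):
        tel, alb = self.curves()
        ct_t = 28.0 + PERFECT_SLOPE * np.log10(25) - 1.0
        ct_a = 33.0 + PERFECT_SLOPE * np.log10(25)
        res = quantify_sample(qc_triplicate([ct_t] * 3), qc_triplicate([ct_a] * 3), tel, alb)
        assert res.ts_ratio == pytest.approx(2.0, rel=1e-9)

    def test_excluded_triplicate_blocks_ratio(self):
        tel, alb = self.curves()
        bad = qc_triplicate([20.0, 20.0, 25.0])
        res = quantify_sample(bad, qc_triplicate([25.0] * 3), tel, alb)
        assert not res.qc_pass
        assert res.ts_ratio is None
        assert any("CV > 1%" in r for r in res.qc_reasons)

    @given(scale=st.floats(0.01, 100.0))
    def test_concentration_scale_equivariance(self, scale):
        """Multiplying all standard concentrations by a constant leaves
        the T/S ratio unchanged (relative quantification)."""
        concs = 230.0 / 2 ** np.arange(7)
        tel = fit_standard_curve(
            [(c * scale, 28.0 + PERFECT_SLOPE * np.log10(c)) for c in concs], "tel"
        )
        alb = fit_standard_curve(
            [(c * scale, 33.0 + PERFECT_SLOPE * np.log10(c)) for c in concs], "alb"
        )
        ct_t = 28.0 + PERFECT_SLOPE * np.log10(50)
        ct_a = 33.0 + PERFECT_SLOPE * np.log10(25)
        res = quantify_sample(qc_triplicate([ct_t] * 3), qc_triplicate([ct_a] * 3), tel, alb)
        assert res.ts_ratio == pytest.approx(2.0, rel=1e-9)

    @given(delta=st.floats(0.0, 5.0))
    def test_lower_telomere_ct_never_decreases_ratio(self, delta):
        tel, alb = self.curves()
        ct_a = 33.0 + PERFECT_SLOPE * np.log10(25)
        base = 28.0 + PERFECT_SLOPE * np.log10(25)
        hi = quantify_sample(
            qc_triplicate([base - delta] * 3), qc_triplicate([ct_a] * 3), tel, alb
        )
        lo = quantify_sample(qc_triplicate([base] * 3), qc_triplicate([ct_a] * 3), tel, alb)
        assert hi.ts_ratio >= lo.ts_ratio


class TestPlateChain:
    def test_noiseless_plates_reproduce_configured_ts(self):
        cfg = scenario_null(n=30, seed=2)
        cfg = cfg.replace(noise_sds={**cfg.noise_sds, "qpcr_ct": 0.0, "std_curve_ct": 0.0})
        latent = np.linspace(-2, 2, 30)
        plates, ts_true = generate_qpcr_plates(latent, cfg)
        res = quantify_plates(plates).set_index("sample_id")
        assert res["qc_pass"].all()
        np.testing.assert_allclose(
            res.loc[ts_true.index, "ts_ratio"], ts_true.to_numpy(), rtol=1e-9
        )

    def test_injected_faults_are_flagged(self):
        cfg = scenario_null(n=6, seed=3)
        sids = [f"s{i}" for i in range(6)]
        plate_of = {s: ("P1" if i < 3 else "P2") for i, s in enumerate(sids)}
        plates, _ = generate_qpcr_plates(
            np.zeros(6), cfg, sample_ids=sids, plate_of=plate_of,
            cv_fault_samples=["s0"], bad_curve_plates=["P2"],
        )
        res = quantify_plates(plates).set_index("sample_id")
        assert not res.loc["s0", "qc_pass"]
        assert "CV > 1%" in res.loc["s0", "qc_reasons"]
        for s in ("s3", "s4", "s5"):  # plate with the degraded telomere curve
            assert not res.loc[s, "qc_pass"]
            assert "standard curve" in res.loc[s, "qc_reasons"]
        for s in ("s1", "s2"):
            assert res.loc[s, "qc_pass"]

    def test_negative_control_amplification_gates_plate(self):
        cfg = scenario_null(n=3, seed=4)
        plates, _ = generate_qpcr_plates(np.zeros(3), cfg)
        plates.loc[plates["sample_id"] == "ntc", "ct"] = 35.0
        res = quantify_plates(plates)
        assert (~res["qc_pass"]).all()
        assert res["qc_reasons"].str.contains("negative control").all()
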