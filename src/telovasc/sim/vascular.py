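"""Planted vascular outcomes and raw-signal back-construction.

Outcomes are drawn on the z-scale: each of the seven free phenotypes
(RSH, CI, SVRI, SI, TACI, PWV, ABI) is a linear function of the
configured exposures and covariates plus Gaussian noise sized so the
marginal variance is ~1.  MAP, PP, SBP and DBP are then *induced* by
the hemodynamic identities (MAP = SVRI·CI/80, PP = SI/TACI,
SBP = MAP + 2/3·PP, DBP = MAP − PP/3) rather than planted — with a
shared stroke volume and a single MAP, they have no free dimension.

Raw fields are back-constructed to reproduce the derived values exactly
(choose height/weight → BSA; SV = SI·BSA; HR = 1000·CI/SI; baseline
skin blood flow drawn, plateau solved from the RSH target; three BP
readings whose 2nd/3rd mean equals the target SBP/DBP; per-side ankle
and arm pressures solving the ABI side-selection rule; cuff distance
drawn, transit time solved from PWV), so the vascular derivations
invert the generator to floating-point accuracy.  Draws implying
non-physical raw values (negative flows or pressures) are rejected and
the offending noise redrawn, with a hard failure after a bounded number
of attempts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import PLANTABLE_OUTCOMES, ScenarioConfig
from ..ltl import standardize
from ..rng import substream
from ..vascular import compute_bsa, compute_composite
from .cohort import TruthRecord

__all__ = ["plant_outcome_z", "derived_table", "generate_vascular_raw", "build_trace"]

TRACE_RATE_HZ = 1.0
TRACE_N = int(26 * 60 * TRACE_RATE_HZ)  # 26 min at 1 Hz


def _covariate_z(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    woman = (cohort["sex"] == "woman").to_numpy(dtype=float)
    smoking = (cohort["smoking"] == "current").to_numpy(dtype=float)
    return {
        "age": standardize(cohort["age"].to_numpy()),
        "bmi": standardize(cohort["bmi"].to_numpy()),
        "sex": woman - woman.mean(),
        "smoking": smoking - smoking.mean(),
    }


def plant_outcome_z(
    cohort: pd.DataFrame,
    truth: TruthRecord,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """z-scale draws of the seven plantable phenotypes.

    Noise SD per outcome is sqrt(1 − empirical var of the systematic
    part), so each column has marginal variance ~1 and the planted
    standardized coefficients are recovered by the corresponding
    adjusted models without rescaling.
    """
    if rng is None:
        rng = substream(config.seed, "vascular_noise")
    n = len(cohort)
    covs = _covariate_z(cohort)
    out = {}
    for outcome in PLANTABLE_OUTCOMES:
        s = np.zeros(n)
        for (exposure, target), coef in config.planted_effects.items():
            if target == outcome:
                s = s + coef * truth.exposures[exposure]
        for (cov, target), coef in config.covariate_effects.items():
            if target == outcome:
                s = s + coef * covs[cov]
        var_sys = s.var(ddof=1) if n > 1 else 0.0
        if var_sys >= 0.95:
            raise ValueError(f"systematic variance of {outcome!r} >= 0.95")
        out[outcome] = s + np.sqrt(1.0 - var_sys) * rng.standard_normal(n)
    return pd.DataFrame(out)


def _raw_from_z(z: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    raw = {}
    for outcome in PLANTABLE_OUTCOMES:
        mean, sd = config.raw_scales[outcome]
        raw[outcome] = mean + sd * z[outcome].to_numpy()
    return pd.DataFrame(raw)


def _physical(raw: pd.DataFrame) -> np.ndarray:
    """Row mask of physically admissible derived values."""
    pos = (
        (raw["cardiac_index"] > 0)
        & (raw["svri"] > 0)
        & (raw["stroke_index"] > 0)
        & (raw["taci"] > 0)
        & (raw["pwv"] > 0)
        & (raw["abi"] > 0)
        & (raw["rsh"] > -100.0)  # plateau flow must stay positive
    )
    map_ = raw["svri"] * raw["cardiac_index"] / 80.0
    pp = raw["stroke_index"] / raw["taci"]
    dbp = map_ - pp / 3.0
    return (pos & (dbp > 0)).to_numpy()


def derived_table(z: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Raw-scale derived phenotypes (the seven planted plus the induced
    MAP/PP/SBP/DBP and the composite index) from z-scale draws."""
    raw = _raw_from_z(z, config)
    if not _physical(raw).all():
        raise ValueError("non-physical derived values; redraw upstream")
    raw["map"] = raw["svri"] * raw["cardiac_index"] / 80.0
    raw["pp"] = raw["stroke_index"] / raw["taci"]
    raw["sbp"] = raw["map"] + 2.0 / 3.0 * raw["pp"]
    raw["dbp"] = raw["map"] - raw["pp"] / 3.0
    raw["composite"] = compute_composite(raw)
    return raw


def simulate_derived_phenotypes(
    cohort: pd.DataFrame, truth: TruthRecord, config: ScenarioConfig
) -> pd.DataFrame:
    """Planted z draws → physically admissible raw derived table,
    redrawing noise for non-physical rows (bounded attempts)."""
    rng = substream(config.seed, "vascular_noise")
    z = plant_outcome_z(cohort, truth, config, rng)
    raw = _raw_from_z(z, config)
    ok = _physical(raw)
    tries = 0
    while not ok.all():
        tries += 1
        if tries > config.max_redraws:
            raise RuntimeError(
                f"{(~ok).sum()} participants still non-physical after "
                f"{config.max_redraws} redraws; raw scales too wide"
            )
        bad = np.flatnonzero(~ok)
        z_bad = plant_outcome_z(cohort, truth, config, rng)
        z.iloc[bad] = z_bad.iloc[bad]
        raw = _raw_from_z(z, config)
        ok = _physical(raw)
    table = derived_table(z, config)
    table.insert(0, "participant_id", cohort["participant_id"].to_numpy())
    return table


def build_trace(
    baseline: float, plateau: float, rng: np.random.Generator, noise_sd: float = 2.0
) -> pd.DataFrame:
    """A 26-min, 1 Hz skin-blood-flow trace whose first-2-min and
    last-2-min window means equal ``baseline`` and ``plateau`` exactly.

    The mid-section follows the local-thermal-heating profile (initial
    peak, nadir, slow rise to plateau).  Window noise is recentered so
    the window means are preserved to floating point.
    """
    t = np.arange(TRACE_N, dtype=float)
    peak = max(baseline + 1.3 * (plateau - baseline), 1.5 * baseline)
    nadir = baseline + 0.6 * (plateau - baseline)
    knots_t = [0.0, 119.0, 300.0, 600.0, 1200.0, TRACE_N - 121.0, TRACE_N - 1.0]
    knots_f = [baseline, baseline, peak, nadir, plateau, plateau, plateau]
    flux = np.interp(t, knots_t, knots_f)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, TRACE_N)
        for window in (t < 120.0, t > t[-1] - 120.0):
            noise[window] -= noise[window].mean()
        mid = ~((t < 120.0) | (t > t[-1] - 120.0))
        flux = flux + noise
        flux[mid] = np.maximum(flux[mid], 0.05 * baseline)
    return pd.DataFrame({"time_s": t, "flux": flux})


def generate_vascular_raw(
    cohort: pd.DataFrame,
    truth: TruthRecord,
    config: ScenarioConfig,
    with_traces: bool = True,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Back-construct raw vascular measurements reproducing the planted
    derived values exactly.

    Returns ``(raw_table, traces, derived_table)``; ``traces`` maps
    participant_id to a time_s/flux table (empty when
    ``with_traces=False``).
    """
    derived = simulate_derived_phenotypes(cohort, truth, config)
    rng = substream(config.seed, "vascular_raw")
    n = len(cohort)

    height = np.clip(rng.normal(1.70, 0.09, n), 1.45, 2.05)
    weight = cohort["bmi"].to_numpy() * height**2
    bsa = compute_bsa(height, weight)

    si = derived["stroke_index"].to_numpy()
    ci = derived["cardiac_index"].to_numpy()
    sv = si * bsa
    hr = 1000.0 * ci / si

    sbp = derived["sbp"].to_numpy()
    dbp = derived["dbp"].to_numpy()
    d_s = rng.uniform(0.0, 3.0, n)
    d_d = rng.uniform(0.0, 2.0, n)
    first_s = sbp + rng.uniform(2.0, 8.0, n)  # white-coat first reading
    first_d = dbp + rng.uniform(1.0, 5.0, n)

    abi = derived["abi"].to_numpy()
    arm_l = sbp
    arm_r = sbp + rng.uniform(-2.0, 2.0, n)
    ankle_l = abi * arm_l
    # second side chosen so the side-selection rule returns the target:
    # below 1.40 the other side sits above the target (min wins);
    # at/above 1.40 it sits in [1.40, target] (max wins)
    u = rng.random(n)
    abi_r = np.where(abi < 1.40, abi + 0.04 * u, 1.40 + (abi - 1.40) * u)
    ankle_r = abi_r * arm_r

    distance = rng.uniform(0.50, 0.62, n)
    transit = distance / derived["pwv"].to_numpy()

    raw = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "sv": sv,
            "hr": hr,
            "height": height,
            "weight": weight,
            "sbp_1": first_s,
            "dbp_1": first_d,
            "sbp_2": sbp + d_s,
            "dbp_2": dbp + d_d,
            "sbp_3": sbp - d_s,
            "dbp_3": dbp - d_d,
            "ankle_sbp_left": ankle_l,
            "arm_sbp_left": arm_l,
            "ankle_sbp_right": ankle_r,
            "arm_sbp_right": arm_r,
            "pwv_distance": distance,
            "pwv_transit_time": transit,
        }
    )

    traces: dict[str, pd.DataFrame] = {}
    if with_traces:
        trace_rng = substream(config.seed, "traces")
        baseline = np.exp(trace_rng.normal(np.log(20.0), 0.3, n))
        plateau = baseline * (1.0 + derived["rsh"].to_numpy() / 100.0)
        noise_sd = config.noise_sds.get("trace", 0.0)
        for i, pid in enumerate(cohort["participant_id"]):
            traces[pid] = build_trace(baseline[i], plateau[i], trace_rng, noise_sd)
    return raw, traces, derived
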