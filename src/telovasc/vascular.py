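"""Derivation of vascular phenotypes from raw measurements.

Eleven phenotypes are derived per participant — reactive skin hyperemia
(RSH), cardiac index (CI), systemic vascular resistance index (SVRI),
stroke index (SI), total arterial compliance index (TACI), pulse wave
velocity (PWV), ankle-brachial index (ABI), systolic and diastolic blood
pressure, mean arterial pressure (MAP) and pulse pressure (PP) — plus a
composite vascular health index (the oriented average z-score of nine of
them).

All formulas follow standard clinical conventions:

* ``CO = SV * HR / 1000`` (L/min), ``CI = CO / BSA``, ``SI = SV / BSA``
* ``SVRI = MAP / CI * 80`` (dynes·sec/cm^5/m^2; see note below)
* ``TACI = SV / (PP * BSA)``, ``PWV = distance / transit time``
* ``ABI`` per side = ankle SBP / arm SBP; the lower side is reported when
  it is below 1.40, otherwise the higher side
* ``SBP``/``DBP`` = mean of the 2nd and 3rd of three seated readings;
  ``MAP = (SBP + 2*DBP)/3``; ``PP = SBP − DBP``
* ``RSH = 100 * (plateau SBF − baseline SBF) / baseline SBF`` with the
  baseline window the first 2 min and the plateau window the last 2 min
  of the 26-min local-thermal-heating protocol.

SVRI note: resistance formulas are sometimes written "MAP/CO × 80", but
the index units (per m² body surface) and the magnitude of population
means (~2100 with MAP ~93 mmHg and CI ~3.2) are only consistent with
division by cardiac *index*; division by CO is available via
``svri_denominator="co"``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import COMPOSITE_PHENOTYPES

__all__ = [
    "BASELINE_WINDOW_S",
    "PLATEAU_WINDOW_S",
    "TRACE_DURATION_S",
    "compute_bsa",
    "compute_rsh",
    "compute_hemodynamics",
    "compute_stiffness",
    "compute_bp",
    "compute_composite",
    "derive_phenotypes",
]

BASELINE_WINDOW_S = 120.0
PLATEAU_WINDOW_S = 120.0
TRACE_DURATION_S = 26.0 * 60.0

#: Phenotypes negated in the composite so that higher always means
#: better vascular health.
NEGATED_IN_COMPOSITE = frozenset({"svri", "pwv", "map", "pp"})


def compute_bsa(height_m, weight_kg, formula: str = "du_bois"):
    """Body surface area in m² from height (m) and weight (kg).

    Du Bois: ``0.007184 * W^0.425 * (100*H)^0.725`` (default);
    Mosteller: ``sqrt(H_cm * W / 3600)``.
    """
    height_m = np.asarray(height_m, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    if np.any(height_m <= 0) or np.any(weight_kg <= 0):
        raise ValueError("height and weight must be positive")
    if formula == "du_bois":
        bsa = 0.007184 * weight_kg**0.425 * (height_m * 100.0) ** 0.725
    elif formula == "mosteller":
        bsa = np.sqrt(height_m * 100.0 * weight_kg / 3600.0)
    else:
        raise ValueError(f"unknown BSA formula {formula!r}")
    return bsa if bsa.ndim else float(bsa)


def compute_rsh(trace: pd.DataFrame) -> float:
    """Reactive skin hyperemia (%) from a skin-blood-flow trace.

    ``trace`` must have columns ``time_s`` and ``flux`` and span the full
    26-minute protocol.  Baseline = mean flux over the first 2 minutes;
    plateau = mean flux over the last 2 minutes.
    """
    t = np.asarray(trace["time_s"], dtype=float)
    flux = np.asarray(trace["flux"], dtype=float)
    if t.size < 2:
        raise ValueError("trace too short")
    t0 = t.min()
    span = t.max() - t0
    # last sample of a 1 Hz, 26-min trace sits at 1559 s
    if span < TRACE_DURATION_S - (t[1] - t[0]) - 1e-9:
        raise ValueError(f"trace spans {span:.0f} s; 26 minutes required")
    baseline = flux[t - t0 < BASELINE_WINDOW_S].mean()
    plateau = flux[t > t.max() - PLATEAU_WINDOW_S].mean()
    if baseline <= 0:
        raise ValueError("baseline skin blood flow must be positive")
    return float(100.0 * (plateau - baseline) / baseline)


class Hemodynamics(NamedTuple):
    co: np.ndarray | float  # cardiac output, L/min
    cardiac_index: np.ndarray | float  # L/min/m²
    stroke_index: np.ndarray | float  # mL/m²
    svri: np.ndarray | float  # dynes·sec/cm⁵/m²


def compute_hemodynamics(sv, hr, bsa, map_, svri_denominator: str = "ci") -> Hemodynamics:
    """CO, CI, SI and SVRI from stroke volume (mL), heart rate (bpm),
    body surface area (m²) and mean arterial pressure (mmHg)."""
    sv, hr, bsa, map_ = (np.asarray(x, dtype=float) for x in (sv, hr, bsa, map_))
    if np.any(sv <= 0) or np.any(hr <= 0) or np.any(bsa <= 0) or np.any(map_ <= 0):
        raise ValueError("hemodynamic inputs must be positive")
    co = sv * hr / 1000.0
    ci = co / bsa
    si = sv / bsa
    if svri_denominator == "ci":
        svri = map_ / ci * 80.0
    elif svri_denominator == "co":
        svri = map_ / co * 80.0
    else:
        raise ValueError(f"unknown svri_denominator {svri_denominator!r}")
    scalar = co.ndim == 0
    out = (co, ci, si, svri)
    return Hemodynamics(*(float(x) if scalar else x for x in out))


class Stiffness(NamedTuple):
    taci: np.ndarray | float  # mL/mmHg/m²
    pwv: np.ndarray | float  # m/s
    abi: np.ndarray | float  # unitless


def reported_abi(abi_left, abi_right):
    """Side-selection rule: the lower side is used when it is < 1.40,
    otherwise the higher side."""
    abi_left = np.asarray(abi_left, dtype=float)
    abi_right = np.asarray(abi_right, dtype=float)
    lo = np.minimum(abi_left, abi_right)
    hi = np.maximum(abi_left, abi_right)
    out = np.where(lo < 1.40, lo, hi)
    return float(out) if out.ndim == 0 else out


def compute_stiffness(
    sv, pp, bsa, distance_m, transit_time_s, ankle_sbp_left, arm_sbp_left,
    ankle_sbp_right, arm_sbp_right,
) -> Stiffness:
    """TACI, PWV and reported ABI from raw stiffness measurements."""
    args = [sv, pp, bsa, distance_m, transit_time_s,
            ankle_sbp_left, arm_sbp_left, ankle_sbp_right, arm_sbp_right]
    args = [np.asarray(a, dtype=float) for a in args]
    if any(np.any(a <= 0) for a in args):
        raise ValueError("stiffness inputs must be positive")
    (sv, pp, bsa, distance_m, transit_time_s,
     ankle_l, arm_l, ankle_r, arm_r) = args
    taci = sv / (pp * bsa)
    pwv = distance_m / transit_time_s
    abi = reported_abi(ankle_l / arm_l, ankle_r / arm_r)
    scalar = taci.ndim == 0
    return Stiffness(
        float(taci) if scalar else taci,
        float(pwv) if scalar else pwv,
        abi,
    )


class BloodPressure(NamedTuple):
    sbp: float
    dbp: float
    map: float
    pp: float


def compute_bp(bp_readings) -> BloodPressure:
    """SBP/DBP as the mean of the 2nd and 3rd of three seated readings,
    with derived MAP and PP.

    ``bp_readings``: sequence of exactly three ``(sbp, dbp)`` pairs in
    measurement order.
    """
    readings = np.asarray(bp_readings, dtype=float)
    if readings.shape != (3, 2):
        raise ValueError("exactly three (SBP, DBP) reading pairs required")
    if np.any(readings <= 0):
        raise ValueError("pressures must be positive")
    sbp = readings[1:, 0].mean()
    dbp = readings[1:, 1].mean()
    return BloodPressure(float(sbp), float(dbp), float((sbp + 2 * dbp) / 3.0), float(sbp - dbp))


def compute_composite(phenotypes: pd.DataFrame, orient: bool = True) -> pd.Series:
    """Composite vascular health index: per-participant average of the
    z-scores of the nine phenotypes, oriented (unless ``orient=False``)
    so that higher always means better vascular health (SVRI, PWV, MAP
    and PP are negated)."""
    missing = [c for c in COMPOSITE_PHENOTYPES if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"missing phenotypes for composite: {missing}")
    zs = []
    for name in COMPOSITE_PHENOTYPES:
        col = phenotypes[name].astype(float)
        sd = col.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"phenotype {name!r} has zero variance")
        z = (col - col.mean()) / sd
        if orient and name in NEGATED_IN_COMPOSITE:
            z = -z
        zs.append(z)
    return sum(zs) / len(zs)


def derive_phenotypes(
    raw: pd.DataFrame,
    traces: dict[str, pd.DataFrame],
    svri_denominator: str = "ci",
    bsa_formula: str = "du_bois",
) -> pd.DataFrame:
    """Derive all phenotypes for a cohort.

    ``raw`` needs columns participant_id, sv, hr, height, weight,
    sbp_1..3, dbp_1..3, ankle_sbp_left/right, arm_sbp_left/right,
    pwv_distance, pwv_transit_time; ``traces`` maps participant_id to a
    skin-blood-flow trace table.
    """
    rows = []
    for rec in raw.itertuples(index=False):
        pid = rec.participant_id
        bp = compute_bp([(rec.sbp_1, rec.dbp_1), (rec.sbp_2, rec.dbp_2), (rec.sbp_3, rec.dbp_3)])
        bsa = compute_bsa(rec.height, rec.weight, formula=bsa_formula)
        hemo = compute_hemodynamics(rec.sv, rec.hr, bsa, bp.map, svri_denominator)
        stiff = compute_stiffness(
            rec.sv, bp.pp, bsa, rec.pwv_distance, rec.pwv_transit_time,
            rec.ankle_sbp_left, rec.arm_sbp_left, rec.ankle_sbp_right, rec.arm_sbp_right,
        )
        rows.append(
            {
                "participant_id": pid,
                "rsh": compute_rsh(traces[pid]),
                "cardiac_index": hemo.cardiac_index,
                "svri": hemo.svri,
                "stroke_index": hemo.stroke_index,
                "taci": stiff.taci,
                "pwv": stiff.pwv,
                "abi": stiff.abi,
                "sbp": bp.sbp,
                "dbp": bp.dbp,
                "map": bp.map,
                "pp": bp.pp,
                "bsa": bsa,
                "co": hemo.co,
            }
        )
    out = pd.DataFrame(rows)
    out["composite"] = compute_composite(out)
    return out
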