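"""Relative telomere length (T/S ratio) from qPCR plate data.

Telomere content is measured as the ratio of the relative quantity of
the telomeric repeat amplicon (T) to that of a single-copy gene,
albumin (S).  Each plate carries, per primer target, a seven-point
standard curve of a reference DNA sample in twofold dilution steps
(230 → 3.59 ng/µl, a 128-fold range), and each sample is run in
triplicate.  Quantification is by standard-curve interpolation per
target: ``Q = 10**((Ct − intercept)/slope)``; the per-well T/S ratio is
formed on paired wells and the triplicate mean is reported.  (At 100%
efficiency this coincides with the 2^−ΔΔCt shortcut.)

Quality control:

* a standard curve passes when reaction efficiency
  ``10**(−1/slope) − 1`` is within 90–110% and R² > 0.99;
* a triplicate is excluded when its coefficient of variation
  (sample SD / mean of the Ct values) exceeds 1%;
* any amplification in a negative control gates the whole plate.

Plate-table layout (TSV): columns ``plate_id, sample_id, target,
replicate, concentration, ct``.  ``target`` is ``tel`` or ``alb``;
standard-curve wells are rows with a non-null ``concentration`` (their
``sample_id`` is conventionally ``std``); negative-control wells carry
``sample_id == "ntc"`` with an empty ``ct`` when clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "TriplicateMeasurement",
    "TsResult",
    "fit_standard_curve",
    "qc_triplicate",
    "quantify_sample",
    "quantify_plates",
]

EFFICIENCY_RANGE = (0.90, 1.10)
R_SQUARED_MIN = 0.99
CV_MAX = 0.01


@dataclass(frozen=True)
class StandardCurve:
    target: str
    points: tuple[tuple[float, float], ...]  # (log10 concentration, Ct)
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    qc_pass: bool
    qc_reasons: tuple[str, ...]

    def quantity(self, ct):
        """Relative quantity interpolated from the curve."""
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


@dataclass(frozen=True)
class TriplicateMeasurement:
    sample_id: str
    target: str
    ct_values: tuple[float, ...]
    cv: float
    excluded: bool


@dataclass
class TsResult:
    sample_id: str
    t_quantity: float | None
    s_quantity: float | None
    ts_ratio: float | None
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)


def fit_standard_curve(points, target: str = "tel") -> StandardCurve:
    """Least-squares line of Ct on log10(concentration).

    ``points``: sequence of (concentration, Ct) pairs, ≥ 3, with distinct
    positive concentrations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("at least 3 standard points required")
    conc, ct = pts[:, 0], pts[:, 1]
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")
    logq = np.log10(conc)
    if np.unique(logq).size < 2:
        raise ValueError("standard concentrations must be distinct")
    fit = stats.linregress(logq, ct)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r_squared = float(fit.rvalue**2)
    if slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    efficiency = float(10.0 ** (-1.0 / slope) - 1.0)
    reasons = []
    if not EFFICIENCY_RANGE[0] <= efficiency <= EFFICIENCY_RANGE[1]:
        reasons.append(
            f"efficiency {efficiency * 100:.1f}% outside "
            f"{EFFICIENCY_RANGE[0] * 100:.0f}-{EFFICIENCY_RANGE[1] * 100:.0f}%"
        )
    if not r_squared > R_SQUARED_MIN:
        reasons.append(f"R^2 {r_squared:.4f} <= {R_SQUARED_MIN}")
    return StandardCurve(
        target=target,
        points=tuple(zip(logq.tolist(), ct.tolist())),
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        efficiency=efficiency,
        qc_pass=not reasons,
        qc_reasons=tuple(reasons),
    )


def qc_triplicate(ct_values, sample_id: str = "", target: str = "") -> TriplicateMeasurement:
    """Coefficient-of-variation rule: exclude when sd/mean > 1%.

    The CV uses the sample SD (n−1 denominator), the convention for
    triplicates.
    """
    ct = np.asarray(ct_values, dtype=float)
    ct = ct[np.isfinite(ct)]
    if ct.size < 2:
        raise ValueError("at least 2 finite Ct values required")
    mean = ct.mean()
    if mean <= 0:
        raise ValueError("mean Ct must be positive")
    cv = float(ct.std(ddof=1) / mean)
    return TriplicateMeasurement(
        sample_id=sample_id,
        target=target,
        ct_values=tuple(ct.tolist()),
        cv=cv,
        excluded=cv > CV_MAX,
    )


def quantify_sample(
    tel: TriplicateMeasurement,
    alb: TriplicateMeasurement,
    tel_curve: StandardCurve,
    alb_curve: StandardCurve,
) -> TsResult:
    """Per-well T/S ratios on paired wells, reported as the triplicate mean.

    QC gates: both triplicates must pass the CV rule and both standard
    curves must pass efficiency/R² QC; otherwise the ratio is withheld
    and the reasons recorded.
    """
    reasons: list[str] = []
    if tel.excluded:
        reasons.append("telomere triplicate CV > 1%")
    if alb.excluded:
        reasons.append("albumin triplicate CV > 1%")
    for curve in (tel_curve, alb_curve):
        if not curve.qc_pass:
            reasons.append(f"{curve.target} standard curve failed: " + "; ".join(curve.qc_reasons))
    if reasons:
        return TsResult(tel.sample_id, None, None, None, False, reasons)
    if len(tel.ct_values) != len(alb.ct_values):
        raise ValueError("mismatched replicate counts when pairing wells")
    t_q = tel_curve.quantity(np.array(tel.ct_values))
    s_q = alb_curve.quantity(np.array(alb.ct_values))
    per_well = t_q / s_q
    return TsResult(
        sample_id=tel.sample_id,
        t_quantity=float(t_q.mean()),
        s_quantity=float(s_q.mean()),
        ts_ratio=float(per_well.mean()),
        qc_pass=True,
    )


def quantify_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Quantify every sample on every plate of a plate table.

    Returns a table with columns ``plate_id, sample_id, ts_ratio,
    qc_pass, qc_reasons``.
    """
    required = {"plate_id", "sample_id", "target", "replicate", "ct"}
    missing = required - set(plates.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out = []
    for plate_id, plate in plates.groupby("plate_id", sort=False):
        has_conc = plate["concentration"].notna() if "concentration" in plate else pd.Series(
            False, index=plate.index
        )
        std = plate[has_conc]
        curves = {}
        for target in ("tel", "alb"):
            pts = std[std["target"] == target][["concentration", "ct"]].to_numpy(dtype=float)
            curves[target] = fit_standard_curve(pts, target=target)
        ntc = plate[(plate["sample_id"] == "ntc")]
        plate_gate = bool(np.isfinite(ntc["ct"].astype(float)).any())
        samples = plate[~has_conc & (plate["sample_id"] != "ntc")]
        for sample_id, grp in samples.groupby("sample_id", sort=False):
            trips = {}
            for target in ("tel", "alb"):
                cts = grp[grp["target"] == target].sort_values("replicate")["ct"]
                trips[target] = qc_triplicate(cts.to_numpy(dtype=float), sample_id, target)
            res = quantify_sample(trips["tel"], trips["alb"], curves["tel"], curves["alb"])
            if plate_gate:
                res = TsResult(
                    res.sample_id, None, None, None, False,
                    res.qc_reasons + ["amplification in negative control"],
                )
            out.append(
                {
                    "plate_id": plate_id,
                    "sample_id": sample_id,
                    "ts_ratio": res.ts_ratio,
                    "qc_pass": res.qc_pass,
                    "qc_reasons": "; ".join(res.qc_reasons),
                }
            )
    return pd.DataFrame(out, columns=["plate_id", "sample_id", "ts_ratio", "qc_pass", "qc_reasons"])
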