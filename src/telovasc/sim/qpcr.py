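"""Synthetic qPCR plates for telomere (T) and albumin (S) assays.

Each participant's true T/S ratio is a monotone (log-linear) transform
of latent telomere length, ``T/S = exp(0.25 * latent)``, so raw ratios
sit near 1.  Per plate, both targets carry a seven-point standard curve
of a reference DNA sample spanning a 128-fold range (230 → 3.59 ng/µl
in twofold dilutions) with the configured reaction efficiency, plus
clean negative controls; samples are run in triplicate with Gaussian Ct
noise.  With zero noise the downstream standard-curve quantification
reproduces the configured T/S exactly.

Deterministic faults can be injected for QC-rule testing: a displaced
replicate (forces triplicate CV > 1%) and a degraded standard curve
(efficiency below 90%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import ScenarioConfig
from ..rng import substream

__all__ = ["generate_qpcr_plates", "true_ts_ratio"]

STD_CONCENTRATIONS = 230.0 / 2.0 ** np.arange(7)  # ng/µl, 128-fold range
_TS_LOG_SCALE = 0.25
_INTERCEPTS = {"tel": 28.0, "alb": 33.0}  # Ct at 1 ng/µl
_DNA_INPUT_NG = 25.0


def true_ts_ratio(latent_ltl, config: ScenarioConfig | None = None) -> np.ndarray:
    """The monotone transform mapping latent LTL to a raw T/S ratio."""
    return np.exp(_TS_LOG_SCALE * np.asarray(latent_ltl, dtype=float))


def _slope(efficiency: float) -> float:
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    return -1.0 / np.log10(1.0 + efficiency)


def generate_qpcr_plates(
    true_ltl,
    config: ScenarioConfig,
    sample_ids=None,
    plate_of=None,
    cv_fault_samples=(),
    bad_curve_plates=(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit a plate table and the configured per-sample T/S ratios.

    ``plate_of`` optionally maps each sample to a plate label (defaults
    to a single plate).  ``cv_fault_samples``: sample ids whose first
    telomere replicate is displaced by +3 cycles; ``bad_curve_plates``:
    plates whose telomere standard curve is generated with slope −3.6
    (efficiency ≈ 89.6%, below the 90% QC floor).
    """
    latent = np.asarray(true_ltl, dtype=float)
    if not np.isfinite(latent).all():
        raise ValueError("true LTL must be finite")
    n = latent.size
    if sample_ids is None:
        sample_ids = [f"sub{i + 1:05d}" for i in range(n)]
    if plate_of is None:
        plate_of = {s: "P01" for s in sample_ids}
    rng = substream(config.seed, "qpcr")
    ct_sd = config.noise_sds.get("qpcr_ct", 0.0)
    std_sd = config.noise_sds.get("std_curve_ct", 0.0)

    ts = true_ts_ratio(latent)
    if config.noise_sds.get("ltl_measurement", 0.0) > 0:
        ts = ts * np.exp(rng.normal(0.0, config.noise_sds["ltl_measurement"], n))
    ts_series = pd.Series(ts, index=pd.Index(sample_ids, name="sample_id"), name="ts_true")

    slopes = {t: _slope(config.qpcr_efficiency[t]) for t in ("tel", "alb")}
    rows = []
    for plate in dict.fromkeys(plate_of.values()):
        plate_slopes = dict(slopes)
        if plate in set(bad_curve_plates):
            plate_slopes["tel"] = -3.6
        for target in ("tel", "alb"):
            for conc in STD_CONCENTRATIONS:
                ct0 = _INTERCEPTS[target] + plate_slopes[target] * np.log10(conc)
                for rep in (1, 2, 3):
                    rows.append(
                        {
                            "plate_id": plate,
                            "sample_id": "std",
                            "target": target,
                            "replicate": rep,
                            "concentration": conc,
                            "ct": ct0 + (rng.normal(0.0, std_sd) if std_sd else 0.0),
                        }
                    )
        for target in ("tel", "alb"):
            rows.append(
                {
                    "plate_id": plate,
                    "sample_id": "ntc",
                    "target": target,
                    "replicate": 1,
                    "concentration": np.nan,
                    "ct": np.nan,
                }
            )
    # standard curves are averaged per (plate, target, concentration) by
    # the quantifier via least squares over all replicate points
    for i, sid in enumerate(sample_ids):
        plate = plate_of[sid]
        tel_slope = -3.6 if plate in set(bad_curve_plates) else slopes["tel"]
        q_alb = _DNA_INPUT_NG
        q_tel = ts[i] * _DNA_INPUT_NG
        for target, q, slope in (("tel", q_tel, tel_slope), ("alb", q_alb, slopes["alb"])):
            ct0 = _INTERCEPTS[target] + slope * np.log10(q)
            for rep in (1, 2, 3):
                ct = ct0 + (rng.normal(0.0, ct_sd) if ct_sd else 0.0)
                if target == "tel" and rep == 1 and sid in set(cv_fault_samples):
                    ct += 3.0
                rows.append(
                    {
                        "plate_id": plate,
                        "sample_id": sid,
                        "target": target,
                        "replicate": rep,
                        "concentration": np.nan,
                        "ct": ct,
                    }
                )
    plates = pd.DataFrame(
        rows, columns=["plate_id", "sample_id", "target", "replicate", "concentration", "ct"]
    )
    return plates, ts_series
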