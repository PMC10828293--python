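"""The three telomere-length exposures.

* **Measured LTL** — the z-standardized qPCR T/S ratio.
* **Genetically predicted LTL** — weighted polygenic risk scores (PRS):
  per-participant sums of effect-allele dosage × published per-allele
  effect on normalized LTL, over four instrument panels (genome-wide
  significant and Mendelian-randomization panels from a UK Biobank GWAS;
  FDR-significant and sentinel panels from an independent European
  GWAS), each z-standardized.
* **ΔLTL** — telomere length not explained by genetic predisposition:
  the residual of measured LTL regressed on the PRS, adjusting for the
  measurement batch and the first 10 genetic principal components.  The
  raw residual is retained for diagnostics; a z-standardized copy enters
  all downstream models, per the global convention that continuous
  analysis variables are z-scored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PANELS",
    "compute_prs",
    "standardize",
    "compute_delta_ltl",
    "build_ltl_measures",
]

PANELS = ("gws_codd", "mr_codd", "fdr_li", "gws_li")
N_GENETIC_PCS = 10


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame, panel: str) -> pd.Series:
    """Raw polygenic score: ``score_i = sum_j w_j * dosage_ij`` over the
    panel's variants.

    ``dosages``: participants × variants, entries in [0, 2] (effect-allele
    dosage, allele orientation already harmonized).  ``weights``: table
    with ``variant_id``, ``weight`` and 0/1 panel-membership flags.
    """
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; expected one of {PANELS}")
    if panel not in weights.columns:
        raise ValueError(f"weight table lacks panel flag column {panel!r}")
    sel = weights[weights[panel].astype(bool)]
    missing = set(sel["variant_id"]) - set(dosages.columns)
    if missing:
        raise ValueError(f"{len(missing)} panel variants absent from dosage matrix")
    mat = dosages[sel["variant_id"].tolist()].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("missing dosages are not allowed")
    if mat.min() < 0 or mat.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    score = mat @ sel["weight"].to_numpy(dtype=float)
    return pd.Series(score, index=dosages.index, name=f"prs_{panel}")


def standardize(values) -> np.ndarray:
    """z-scores: (x − mean) / sample SD.  Errors on zero variance."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("at least 2 values required to standardize")
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def _delta_design(prs_z, batch, pcs) -> np.ndarray:
    n = len(prs_z)
    batch_d = pd.get_dummies(pd.Categorical(batch), drop_first=True, dtype=float)
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2 or pcs.shape[0] != n:
        raise ValueError("pcs must be an (n, k) array")
    return np.column_stack([np.ones(n), np.asarray(prs_z, float), batch_d.to_numpy(), pcs])


def compute_delta_ltl(measured_z, prs_z, batch, pcs) -> tuple[np.ndarray, np.ndarray]:
    """ΔLTL: OLS residual of measured LTL on [intercept, PRS, batch
    dummies, genetic PCs].

    Returns ``(raw_residual, z_standardized_residual)``.  The residual is
    orthogonal to the PRS and every PC by construction.
    """
    y = np.asarray(measured_z, dtype=float)
    X = _delta_design(prs_z, batch, pcs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design in delta-LTL residualization")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return resid, standardize(resid)


def build_ltl_measures(
    cohort: pd.DataFrame,
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    measured: pd.Series | np.ndarray,
    panels=PANELS,
) -> pd.DataFrame:
    """Assemble the per-participant exposure table.

    Columns: ``participant_id``, ``measured_z``, and per panel
    ``prs_z_<panel>``, ``delta_<panel>`` (z-scored residual) and
    ``delta_raw_<panel>``.
    """
    pcs = cohort[[f"pc{i}" for i in range(1, N_GENETIC_PCS + 1)]].to_numpy()
    out = pd.DataFrame({"participant_id": cohort["participant_id"].to_numpy()})
    out["measured_z"] = standardize(np.asarray(measured, dtype=float))
    for panel in panels:
        prs_z = standardize(compute_prs(dosages, weights, panel).to_numpy())
        raw, z = compute_delta_ltl(out["measured_z"], prs_z, cohort["batch"], pcs)
        out[f"prs_z_{panel}"] = prs_z
        out[f"delta_raw_{panel}"] = raw
        out[f"delta_{panel}"] = z
    return out
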