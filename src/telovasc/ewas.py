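"""Epigenome-wide association of methylation with LTL measures.

One linear regression per CpG with methylation level (beta scale) as
the outcome and the LTL measure as the exposure, adjusting for age,
sex, batch, the leukocyte subtype proportions (one dropped against the
simplex constraint) and the first 10 genetic principal components.
False-discovery-rate control is by Benjamini–Hochberg step-up over all
CpGs tested for an exposure (one BH family per exposure); q < 0.05 is
treated as epigenome-wide significant and p < 1e-05 as suggestive.

Per-CpG OLS is computed in closed form after projecting the covariates
out of the exposure and every CpG column (Frisch–Waugh–Lovell), which
is algebraically identical to fitting each full model separately but
runs as three matrix products for the whole matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import CELL_TYPES
from .ltl import N_GENETIC_PCS, standardize

__all__ = [
    "Q_GENOME_WIDE",
    "P_SUGGESTIVE",
    "adjust_bh",
    "run_ewas",
    "classify_hits",
    "manhattan_table",
]

Q_GENOME_WIDE = 0.05
P_SUGGESTIVE = 1e-05


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    ``q_(i) = min_{j>=i}(p_(j) * m / j)`` on the sorted p-values, capped
    at 1 and mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ewas_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Design columns: age (z), sex, batch dummies, 11 cell proportions
    (neutrophils dropped), PC1–10."""
    cols = {
        "age_z": standardize(cohort["age"].to_numpy()),
        "woman": (cohort["sex"] == "woman").astype(float).to_numpy(),
    }
    dummies = pd.get_dummies(
        pd.Categorical(cohort["batch"]), drop_first=True, dtype=float, prefix="batch"
    )
    for c in dummies.columns:
        cols[str(c)] = dummies[c].to_numpy()
    for cell in CELL_TYPES:
        if cell != "neutrophils":
            cols[f"cell_{cell}"] = cohort[f"cell_{cell}"].to_numpy(dtype=float)
    for i in range(1, N_GENETIC_PCS + 1):
        cols[f"pc{i}"] = cohort[f"pc{i}"].to_numpy(dtype=float)
    return pd.DataFrame(cols)


def run_ewas(
    beta_matrix: pd.DataFrame,
    exposure_z,
    cohort: pd.DataFrame,
    cpg_map: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
) -> pd.DataFrame:
    """Per-CpG regression of methylation on the LTL exposure.

    ``beta_matrix``: CpG × participant (columns must match the cohort's
    participant order).  The regression direction is fixed —
    methylation is the dependent variable — so swapping outcome and
    exposure is *not* equivalent and not supported.

    Returns one row per CpG: beta (methylation units per SD exposure),
    se, p, q (BH within this call), plus chr/pos when a map is given.
    """
    x = np.asarray(exposure_z, dtype=float)
    n = x.size
    if list(beta_matrix.columns) != list(cohort["participant_id"]):
        beta_matrix = beta_matrix[cohort["participant_id"].tolist()]
    Y = beta_matrix.to_numpy(dtype=float).T  # n × m
    if Y.shape[0] != n:
        raise ValueError("beta matrix and exposure have different sample counts")

    keep = Y.std(axis=0, ddof=1) > 0
    if not keep.all():
        warnings.warn(f"skipping {(~keep).sum()} constant CpG columns", stacklevel=2)
    cpg_ids = beta_matrix.index.to_numpy()[keep]
    Y = Y[:, keep]

    C = np.column_stack([np.ones(n), ewas_covariates(cohort).to_numpy(dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate design")
    Q, _ = np.linalg.qr(C)
    x_t = x - Q @ (Q.T @ x)
    Y_t = Y - Q @ (Q.T @ Y)
    xtx = float(x_t @ x_t)
    if xtx <= 0:
        raise ValueError("exposure is collinear with the covariates")
    beta = (x_t @ Y_t) / xtx
    df = n - C.shape[1] - 1
    rss = np.einsum("ij,ij->j", Y_t, Y_t) - beta**2 * xtx
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / df / xtx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    out = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "exposure": exposure_name,
            "beta": beta,
            "se": se,
            "p": p,
            "q": adjust_bh(p),
            "n": n,
        }
    )
    if cpg_map is not None:
        out = out.merge(
            cpg_map.rename(columns={"cpg": "cpg_id"})[["cpg_id", "chr", "pos"]],
            on="cpg_id",
            how="left",
        )
    return classify_hits(out)


def classify_hits(results: pd.DataFrame) -> pd.DataFrame:
    """Tier per CpG: genome-wide (q < 0.05), suggestive (p < 1e-05),
    else null."""
    res = results.copy()
    res["tier"] = np.select(
        [res["q"] < Q_GENOME_WIDE, res["p"] < P_SUGGESTIVE],
        ["genome-wide", "suggestive"],
        default="null",
    )
    return res


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """chr, pos, −log10(p) ordered by chromosomal position."""
    if "chr" not in results.columns or results["chr"].isna().any():
        raise ValueError("results lack chromosomal positions")
    out = results[["cpg_id", "chr", "pos", "p"]].copy()
    out["neg_log10_p"] = -np.log10(np.maximum(out["p"].to_numpy(dtype=float), 1e-300))
    return out.sort_values(["chr", "pos"], kind="mergesort").reset_index(drop=True)
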