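"""Synthetic methylation beta matrix with planted causal CpGs.

Beta values are the logistic transform of a Gaussian latent on the
logit (M-value-like) scale::

    latent_ij = intercept_j + cell-type loading_j · props_i
                + effect_j * exposure_i  (causal CpGs only)
                + noise_ij

which keeps every beta strictly inside (0, 1) without asserting a named
marginal distribution.  Cell-type loadings give the matrix the
cell-composition-driven covariance structure that makes the downstream
cell-proportion covariates matter.  CpG positions are assigned
uniformly over the 22 autosomes for Manhattan-style output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import CELL_TYPES, ScenarioConfig
from ..rng import substream
from .cohort import TruthRecord

__all__ = ["generate_methylation"]


def generate_methylation(
    cohort: pd.DataFrame,
    exposure_values: np.ndarray,
    config: ScenarioConfig,
    truth: TruthRecord | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (beta matrix, CpG map).

    ``exposure_values`` is the standardized exposure the causal CpGs
    respond to.  Returns the beta matrix as a CpG × participant
    DataFrame and a map with columns ``cpg, chr, pos``.  Causal CpG ids
    and their latent-scale effects are recorded on ``truth`` when given.
    """
    x = np.asarray(exposure_values, dtype=float)
    n = len(cohort)
    if x.shape != (n,):
        raise ValueError(f"exposure length {x.shape} does not match cohort size {n}")
    m = config.n_cpgs
    rng = substream(config.seed, "methylation")

    cpg_ids = [f"cg{i:08d}" for i in range(1, m + 1)]
    cpg_map = pd.DataFrame(
        {
            "cpg": cpg_ids,
            "chr": rng.integers(1, 23, m),
            "pos": rng.integers(1, 250_000_000, m),
        }
    )

    intercept = rng.normal(0.0, 1.5, m)
    # sparse cell-type loadings: each CpG loads on two random subtypes
    props = cohort[[f"cell_{c}" for c in CELL_TYPES]].to_numpy()
    props_z = (props - props.mean(axis=0)) / np.maximum(props.std(axis=0, ddof=1), 1e-12)
    load_idx = rng.integers(0, len(CELL_TYPES), size=(m, 2))
    load_coef = rng.normal(0.0, 0.3, size=(m, 2))
    cell_part = (
        props_z[:, load_idx[:, 0]] * load_coef[:, 0]
        + props_z[:, load_idx[:, 1]] * load_coef[:, 1]
    )  # n × m

    latent = intercept[None, :] + cell_part
    causal = rng.choice(m, size=config.n_causal_cpgs, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_causal_cpgs)
    effects = signs * config.cpg_effect_size
    latent[:, causal] += np.outer(x, effects)
    latent += rng.normal(0.0, config.noise_sds.get("methylation", 1.0), size=(n, m))

    beta = 1.0 / (1.0 + np.exp(-latent))
    betas = pd.DataFrame(beta.T, index=pd.Index(cpg_ids, name="cpg"),
                         columns=cohort["participant_id"].tolist())
    if truth is not None:
        truth.causal_cpg_ids = [cpg_ids[i] for i in causal]
        truth.causal_cpg_effects = {cpg_ids[i]: float(e) for i, e in zip(causal, effects)}
    return betas, cpg_map
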