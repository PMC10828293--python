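"""Plot helpers: Manhattan plot for EWAS results."""

from __future__ import annotations

import numpy as np

from .ewas import P_SUGGESTIVE, manhattan_table

__all__ = ["plot_manhattan"]


def plot_manhattan(results, ax=None, suggestive_line: float = P_SUGGESTIVE):
    """Manhattan plot: CpGs ordered by chromosomal position, −log10(p)
    on the y axis, with the suggestive-significance line dashed in red."""
    import matplotlib.pyplot as plt

    tab = manhattan_table(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for chrom, grp in tab.groupby("chr", sort=True):
        x = offset + grp["pos"].to_numpy(dtype=float)
        ax.scatter(x, grp["neg_log10_p"], s=4,
                   color="#3b6aa0" if int(chrom) % 2 else "#9bb7d4")
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max() + 1e6
    ax.axhline(-np.log10(suggestive_line), color="red", ls="--", lw=0.9)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    return ax
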