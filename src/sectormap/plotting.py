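"""Variant-density figures (one panel per chromosome, one row per pool)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .bsa import BinCounts, MappingInterval

__all__ = ["plot_variant_density"]


def plot_variant_density(
    bins_per_pool: list[list[BinCounts]],
    path: str | Path,
    pool_names: list[str] | None = None,
    intervals: list[MappingInterval | None] | None = None,
) -> None:
    """Per-1-Mbp homozygous-variant density across all chromosomes.

    Each row is one mutant pool; each column one chromosome.  The detected
    mapping interval, when present, is shaded on its chromosome's panel.
    """
    n_pools = len(bins_per_pool)
    n_chrom = len(bins_per_pool[0])
    fig, axes = plt.subplots(
        n_pools,
        n_chrom,
        figsize=(2.2 * n_chrom, 2.0 * n_pools),
        sharey="row",
        squeeze=False,
    )
    for row, pool_bins in enumerate(bins_per_pool):
        for col, bc in enumerate(pool_bins):
            ax = axes[row][col]
            mb = [start / 1e6 for start, _ in bc.counts]
            counts = [n for _, n in bc.counts]
            ax.bar(mb, counts, width=bc.bin_size / 1e6, align="edge", color="#2c6e91")
            iv = intervals[row] if intervals else None
            if iv is not None and iv.chrom == bc.chrom:
                ax.axvspan((iv.start - 1) / 1e6, iv.end / 1e6, color="orange", alpha=0.25)
            if row == 0:
                ax.set_title(bc.chrom, fontsize=9)
            if row == n_pools - 1:
                ax.set_xlabel("Mbp", fontsize=8)
            if col == 0:
                name = pool_names[row] if pool_names else f"pool{row + 1}"
                ax.set_ylabel(f"{name}\nhom. variants / bin", fontsize=8)
            ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
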