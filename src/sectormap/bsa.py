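"""Bulked-segregant mapping from pooled variant calls.

The mutant pool of a recessive screen is homozygous for the causal allele
and, by linkage, enriched for homozygous causal-parent alleles around it.
The stages here reproduce that logic: call homozygous variants
(frequency >= 0.99 at >= 2 reads), subtract sites shared with the fertile
sibling pool and known error-prone sites, keep the canonical EMS spectrum
(G>A / C>T), bin the survivors per megabase, and walk outward from the
density peak until counts return to background to define the mapping
interval.  With two independent pools the candidate region is refined to the
span of the shared variants inside both intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import PoolVariantSet, ReferenceGenome, SiteBlacklist, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "BinCounts",
    "MappingInterval",
    "NoConsensusError",
    "call_homozygous",
    "subtract_shared",
    "apply_blacklist",
    "filter_ems_spectrum",
    "bin_variant_counts",
    "detect_mapping_interval",
    "shared_variants",
    "refine_interval",
    "intersect_pools",
]


@dataclass(frozen=True)
class BinCounts:
    """Homozygous-variant counts per fixed-size bin on one chromosome."""

    chrom: str
    bin_size: int
    counts: tuple[tuple[int, int], ...]  # (bin_start 1-based, n variants)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)


@dataclass(frozen=True)
class MappingInterval:
    """A candidate region around the genome-wide variant-density peak."""

    chrom: str
    start: int
    end: int
    peak_bin: int
    peak_count: int
    background_level: float

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class NoConsensusError(ValueError):
    """Raised when two pools yield no consensus candidate region."""


def call_homozygous(
    pool: PoolVariantSet, min_depth: int = 2, freq_threshold: float = 0.99
) -> set[VariantCall]:
    """Nonreference homozygous calls: depth >= min_depth and frequency >= 0.99."""
    return {
        c
        for c in pool.calls.values()
        if c.depth >= min_depth and c.allele_frequency >= freq_threshold
    }


def subtract_shared(
    mutant_set: set[VariantCall],
    sibling_pool: PoolVariantSet,
    min_depth: int = 2,
    freq_threshold: float = 0.99,
) -> set[VariantCall]:
    """Drop variants whose exact allele is also homozygous in the sibling pool.

    The sibling's homozygous set is computed with the same thresholds; a
    site merely heterozygous in the sibling is retained.
    """
    sibling_hom = {
        c.key for c in call_homozygous(sibling_pool, min_depth, freq_threshold)
    }
    return {c for c in mutant_set if c.key not in sibling_hom}


def apply_blacklist(
    variants: set[VariantCall], blacklist: SiteBlacklist
) -> set[VariantCall]:
    """Remove calls at experimentally determined error-prone sites."""
    return {c for c in variants if c.site not in blacklist}


def filter_ems_spectrum(variants: set[VariantCall]) -> set[VariantCall]:
    """Keep only canonical EMS transitions (G>A or C>T on the reference strand)."""
    return {c for c in variants if c.is_ems_transition()}


def bin_variant_counts(
    variants: set[VariantCall],
    genome: ReferenceGenome,
    bin_size: int = 1_000_000,
) -> list[BinCounts]:
    """Count variants per bin; bins tile each chromosome from position 1.

    A position maps to bin floor((pos - 1) / bin_size); the per-chromosome
    totals conserve the size of the input set.
    """
    for c in variants:
        if c.chrom not in genome:
            raise ValueError(f"variant on unknown chromosome {c.chrom!r}")
    per_chrom: dict[str, dict[int, int]] = {n: {} for n in genome.names}
    for c in variants:
        b = (c.pos - 1) // bin_size
        per_chrom[c.chrom][b] = per_chrom[c.chrom].get(b, 0) + 1
    out = []
    for name, length in genome.lengths.items():
        n_bins = max(1, -(-length // bin_size))
        counts = tuple(
            (b * bin_size + 1, per_chrom[name].get(b, 0)) for b in range(n_bins)
        )
        out.append(BinCounts(chrom=name, bin_size=bin_size, counts=counts))
    return out


def _median(values: list[int]) -> float:
    vs = sorted(values)
    n = len(vs)
    mid = n // 2
    return float(vs[mid]) if n % 2 else (vs[mid - 1] + vs[mid]) / 2.0


def detect_mapping_interval(
    bins: list[BinCounts],
    consecutive_background: int = 2,
    min_peak_excess: int = 3,
) -> MappingInterval | None:
    """Find the density peak and extend until counts return to background.

    Background is the median bin count genome-wide.  From the genome-wide
    maximum bin the interval grows in each direction until
    ``consecutive_background`` successive bins sit at or below background;
    bins at/below background inside an unfinished run stay in the interval.
    Returns None when the peak does not exceed background by more than
    ``min_peak_excess``.  Ties between equal peaks go to the lower
    (chromosome order, bin start) and are logged.
    """
    if not bins:
        return None
    all_counts = [n for bc in bins for _, n in bc.counts]
    background = _median(all_counts)
    # Genome-wide maximum; tie -> first in chromosome order, lowest bin_start.
    peak_chrom_idx, peak_bin_idx, peak_count = None, None, -1
    n_ties = 0
    for ci, bc in enumerate(bins):
        for bi, (_, n) in enumerate(bc.counts):
            if n > peak_count:
                peak_chrom_idx, peak_bin_idx, peak_count = ci, bi, n
                n_ties = 0
            elif n == peak_count:
                n_ties += 1
    if peak_count <= background + min_peak_excess:
        return None
    if n_ties:
        logger.info(
            "peak count %d tied at %d other bin(s); keeping lowest coordinates",
            peak_count,
            n_ties,
        )
    bc = bins[peak_chrom_idx]
    counts = [n for _, n in bc.counts]

    def _edge(step: int) -> int:
        """Last above-background bin index before a full background run."""
        edge = peak_bin_idx
        run = 0
        i = peak_bin_idx + step
        while 0 <= i < len(counts):
            if counts[i] <= background:
                run += 1
                if run >= consecutive_background:
                    break
            else:
                run = 0
                edge = i
            i += step
        return edge

    left, right = _edge(-1), _edge(+1)
    bin_size = bc.bin_size
    return MappingInterval(
        chrom=bc.chrom,
        start=left * bin_size + 1,
        end=(right + 1) * bin_size,
        peak_bin=peak_bin_idx * bin_size + 1,
        peak_count=peak_count,
        background_level=background,
    )


def shared_variants(
    set_a: set[VariantCall], set_b: set[VariantCall]
) -> set[VariantCall]:
    """Variants with identical (chrom, pos, ref, alt) in both pools.

    The returned calls carry pool-A depths; allele identity is what matters
    downstream.
    """
    keys_b = {c.key for c in set_b}
    return {c for c in set_a if c.key in keys_b}


def refine_interval(
    shared: set[VariantCall],
    interval_a: MappingInterval,
    interval_b: MappingInterval,
) -> MappingInterval:
    """Narrow the candidate region to the span of shared variants within both
    single-pool intervals."""
    if interval_a.chrom != interval_b.chrom:
        raise NoConsensusError(
            f"pool intervals on different chromosomes "
            f"({interval_a.chrom} vs {interval_b.chrom})"
        )
    chrom = interval_a.chrom
    lo = max(interval_a.start, interval_b.start)
    hi = min(interval_a.end, interval_b.end)
    positions = [c.pos for c in shared if c.chrom == chrom and lo <= c.pos <= hi]
    if not positions:
        raise NoConsensusError("no shared variants inside the consensus region")
    start, end = max(lo, min(positions)), min(hi, max(positions))
    peak = interval_a if interval_a.peak_count >= interval_b.peak_count else interval_b
    return MappingInterval(
        chrom=chrom,
        start=start,
        end=end,
        peak_bin=min(max(peak.peak_bin, start), end),
        peak_count=peak.peak_count,
        background_level=max(interval_a.background_level, interval_b.background_level),
    )


def intersect_pools(
    set_a: set[VariantCall],
    set_b: set[VariantCall],
    interval_a: MappingInterval,
    interval_b: MappingInterval,
) -> tuple[set[VariantCall], MappingInterval]:
    """Two-pool intersection: shared variant set plus the refined interval."""
    shared = shared_variants(set_a, set_b)
    return shared, refine_interval(shared, interval_a, interval_b)
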