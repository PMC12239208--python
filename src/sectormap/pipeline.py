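"""End-to-end workflows tying the stages together, with run logging.

``run_bsa`` executes the pooled-mapping chain
(homozygous call -> sibling subtraction -> blacklist -> EMS spectrum ->
binning -> interval detection -> two-pool intersection -> candidate
ranking); ``run_sector`` executes the sector chain (heterozygous call ->
sterile-unique differencing -> prior-allele confirmation -> phasing ->
nomination).  Both consume in-memory objects; the CLI wraps them with file
I/O.  Every filter step's input/output counts are recorded so a run log can
show the non-increasing filter chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import bsa, effects, sectors
from .bsa import BinCounts, MappingInterval
from .effects import EffectAnnotation
from .model import (
    GeneModel,
    PoolVariantSet,
    ReadObservation,
    ReferenceGenome,
    SiteBlacklist,
    ValidationError,
    VariantCall,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "BsaResult", "SectorResult", "run_bsa", "run_sector"]


_PARAM_RANGES = {
    "min_depth": (1, 10_000),
    "freq_threshold": (0.5, 1.0),
    "bin_size": (1_000, 100_000_000),
    "consecutive_background": (1, 100),
    "min_peak_excess": (0, 10_000),
    "het_min_depth": (1, 10_000),
    "freq_window_low": (0.0, 0.5),
    "freq_window_high": (0.5, 1.0),
    "err_max": (0.0, 0.5),
    "min_informative": (1, 10_000),
    "max_discord_frac": (0.0, 0.5),
}


@dataclass
class PipelineParams:
    """All stage thresholds in one validated bundle."""

    min_depth: int = 2
    freq_threshold: float = 0.99
    bin_size: int = 1_000_000
    consecutive_background: int = 2
    min_peak_excess: int = 3
    het_min_depth: int = 10
    freq_window_low: float = 0.25
    freq_window_high: float = 0.75
    err_max: float = 0.02
    min_informative: int = 3
    max_discord_frac: float = 0.05

    def __post_init__(self):
        for name, (lo, hi) in _PARAM_RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValidationError(
                    f"parameter {name}={value} outside its range [{lo}, {hi}]"
                )

    @property
    def freq_window(self) -> tuple[float, float]:
        return (self.freq_window_low, self.freq_window_high)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PoolFilterTrace:
    """Variant counts after each filter step for one mutant pool."""

    sample_id: str
    n_input: int
    n_homozygous: int
    n_after_sibling: int
    n_after_blacklist: int
    n_after_spectrum: int


@dataclass
class BsaResult:
    """Everything the pooled-mapping workflow produced."""

    filtered_sets: list[set[VariantCall]]
    traces: list[PoolFilterTrace]
    bins: list[list[BinCounts]]
    intervals: list[MappingInterval | None]
    shared_set: set[VariantCall] | None
    refined_interval: MappingInterval | None
    annotations: dict[tuple[str, int, str, str], EffectAnnotation]
    candidates: pd.DataFrame

    def summary(self) -> str:
        lines = ["BSA mapping run"]
        for t in self.traces:
            lines.append(
                f"  {t.sample_id}: {t.n_input} calls -> {t.n_homozygous} homozygous "
                f"-> {t.n_after_sibling} after sibling subtraction "
                f"-> {t.n_after_blacklist} after blacklist "
                f"-> {t.n_after_spectrum} after EMS-spectrum filter"
            )
        for i, iv in enumerate(self.intervals, 1):
            if iv is None:
                lines.append(f"  pool{i}: no mapping interval detected")
            else:
                lines.append(
                    f"  pool{i}: interval {iv.chrom}:{iv.start}-{iv.end} "
                    f"(peak {iv.peak_count} at {iv.peak_bin}, "
                    f"background {iv.background_level:g})"
                )
        if self.shared_set is not None:
            lines.append(f"  shared variants: {len(self.shared_set)}")
        if self.refined_interval is not None:
            iv = self.refined_interval
            lines.append(f"  refined interval: {iv.chrom}:{iv.start}-{iv.end}")
        lines.append(f"  protein-altering candidates: {len(self.candidates)}")
        return "\n".join(lines)


def _filter_chain(
    mutant: PoolVariantSet,
    sibling: PoolVariantSet,
    blacklist: SiteBlacklist,
    params: PipelineParams,
) -> tuple[set[VariantCall], PoolFilterTrace]:
    hom = bsa.call_homozygous(mutant, params.min_depth, params.freq_threshold)
    after_sib = bsa.subtract_shared(hom, sibling, params.min_depth, params.freq_threshold)
    after_bl = bsa.apply_blacklist(after_sib, blacklist)
    after_ems = bsa.filter_ems_spectrum(after_bl)
    trace = PoolFilterTrace(
        sample_id=mutant.sample_id,
        n_input=len(mutant),
        n_homozygous=len(hom),
        n_after_sibling=len(after_sib),
        n_after_blacklist=len(after_bl),
        n_after_spectrum=len(after_ems),
    )
    logger.info(
        "%s: %d -> hom %d -> -sibling %d -> -blacklist %d -> EMS %d",
        trace.sample_id,
        trace.n_input,
        trace.n_homozygous,
        trace.n_after_sibling,
        trace.n_after_blacklist,
        trace.n_after_spectrum,
    )
    return after_ems, trace


def run_bsa(
    mutant_pools: list[PoolVariantSet],
    sibling_pools: list[PoolVariantSet],
    blacklist: SiteBlacklist,
    genome: ReferenceGenome,
    genes: list[GeneModel],
    params: PipelineParams | None = None,
) -> BsaResult:
    """Map the causal region from >= 1 mutant pool with matched sibling pools.

    With two or more pools the first two are intersected and the candidate
    table is built from the shared set; with a single pool intersection is
    skipped (logged) and candidates come from that pool's filtered set
    restricted to its interval.
    """
    params = params or PipelineParams()
    if not mutant_pools or len(mutant_pools) != len(sibling_pools):
        raise ValidationError("need >= 1 mutant pool, each with a matched sibling pool")
    for pool in (*mutant_pools, *sibling_pools):
        pool.validate_against(genome)

    filtered, traces, all_bins, intervals = [], [], [], []
    for mutant, sibling in zip(mutant_pools, sibling_pools):
        fset, trace = _filter_chain(mutant, sibling, blacklist, params)
        filtered.append(fset)
        traces.append(trace)
        bins = bsa.bin_variant_counts(fset, genome, params.bin_size)
        all_bins.append(bins)
        intervals.append(
            bsa.detect_mapping_interval(
                bins, params.consecutive_background, params.min_peak_excess
            )
        )

    shared_set: set[VariantCall] | None = None
    refined: MappingInterval | None = None
    if len(mutant_pools) >= 2:
        if intervals[0] is None or intervals[1] is None:
            raise bsa.NoConsensusError(
                "no mapping interval detected in "
                + " and ".join(
                    t.sample_id for t, iv in zip(traces, intervals) if iv is None
                )
            )
        shared_set, refined = bsa.intersect_pools(
            filtered[0], filtered[1], intervals[0], intervals[1]
        )
        candidate_set = shared_set
    else:
        logger.info("single pool supplied; skipping two-pool intersection")
        refined = intervals[0]
        candidate_set = (
            {
                c
                for c in filtered[0]
                if refined is not None and refined.contains(c.chrom, c.pos)
            }
            if refined is not None
            else set()
        )

    annotations = {
        c.key: effects.classify_variant(c, genes, genome) for c in candidate_set
    }
    candidates = effects.rank_candidates(candidate_set, annotations)
    return BsaResult(
        filtered_sets=filtered,
        traces=traces,
        bins=all_bins,
        intervals=intervals,
        shared_set=shared_set,
        refined_interval=refined,
        annotations=annotations,
        candidates=candidates,
    )


@dataclass
class SectorResult:
    """Everything the sector workflow produced."""

    sterile_het: set[VariantCall]
    differential: sectors.DifferentialResult
    genome_wide_unique: int
    prior_report: sectors.PriorAlleleReport | None
    annotations: dict[tuple[str, int, str, str], EffectAnnotation]
    pair_verdicts: dict[frozenset, sectors.PhaseVerdict]
    prior_verdicts: dict[tuple[str, int, str, str], sectors.PhaseVerdict]
    nomination: sectors.AlleleNomination

    def summary(self) -> str:
        lines = [
            "Sector analysis run",
            f"  sterile heterozygous EMS calls: {len(self.sterile_het)}",
            f"  within interval: {self.differential.n_considered} "
            f"({len(self.differential.unique)} sterile-unique, "
            f"{len(self.differential.shared)} shared with fertile)",
            f"  sterile-unique genome-wide: {self.genome_wide_unique}",
        ]
        if self.prior_report:
            r = self.prior_report
            lines.append(
                f"  prior allele at {r.site[0]}:{r.site[1]}: "
                f"sterile {r.freq_sterile:.2f}, fertile {r.freq_fertile:.2f} "
                f"({'confirmed heterozygous' if r.confirmed else 'NOT confirmed'})"
            )
        for g in self.nomination.genes:
            verdicts = ", ".join(
                f"{v.site_a[1]}x{v.site_b[1]}:{v.verdict}" for v in g.pair_verdicts
            )
            priors = ", ".join(f"{v.site_a[1]}vs-prior:{v.verdict}" for v in g.prior_verdicts)
            lines.append(
                f"  gene {g.gene_id}: {len(g.variants)} unique coding variant(s); "
                f"pairs [{verdicts}]; prior [{priors}]"
                + (" -> NOMINATED" if g.nominated else "")
            )
        lines.append(f"  nominated allele: {self.nomination.nominated_gene or 'none'}")
        return "\n".join(lines)


def run_sector(
    sterile: PoolVariantSet,
    fertile: PoolVariantSet,
    reads: list[ReadObservation],
    interval: MappingInterval,
    genome: ReferenceGenome,
    genes: list[GeneModel],
    prior_site: tuple[str, int] | None = None,
    params: PipelineParams | None = None,
) -> SectorResult:
    """Identify and phase a novel noncomplementing allele from a sector pair.

    ``prior_site`` is the known pre-existing lesion (e.g. the top candidate
    from pooled mapping); when given, the heterozygote control and
    novel-versus-prior phasing are computed against it.
    """
    params = params or PipelineParams()
    if interval is None:
        raise ValidationError(
            "no mapping interval supplied; run the pooled-mapping workflow first"
        )
    sterile.validate_against(genome)
    fertile.validate_against(genome)

    het = sectors.call_heterozygous(sterile, params.het_min_depth, params.freq_window)
    diff = sectors.differential_sterile_unique(het, fertile, interval, params.err_max)
    genome_wide = sectors.differential_sterile_unique(het, fertile, None, params.err_max)
    logger.info(
        "sterile het %d; interval: %d unique / %d shared; genome-wide unique %d",
        len(het),
        len(diff.unique),
        len(diff.shared),
        len(genome_wide.unique),
    )

    prior_report = None
    if prior_site is not None:
        prior_report = sectors.confirm_prior_allele(
            prior_site, sterile, fertile, params.freq_window
        )

    # Exclude the prior allele itself from the novel-variant set: it is
    # heterozygous in both sectors, so it lands in the shared partition
    # anyway, but guard against an unconfirmed borderline call.
    novel = {v for v in diff.unique if prior_site is None or v.site != tuple(prior_site)}
    annotations = {c.key: effects.classify_variant(c, genes, genome) for c in novel}

    coding = sorted(
        (v for v in novel if annotations[v.key].is_coding
         and annotations[v.key].impact in {"HIGH", "MODERATE"}),
        key=lambda v: (v.chrom, v.pos),
    )
    pair_verdicts: dict[frozenset, sectors.PhaseVerdict] = {}
    for i, a in enumerate(coding):
        for b in coding[i + 1 :]:
            pair_verdicts[frozenset({a.key, b.key})] = sectors.phase_variant_pair(
                reads, a, b, params.min_informative, params.max_discord_frac
            )
    prior_verdicts: dict[tuple[str, int, str, str], sectors.PhaseVerdict] = {}
    if prior_site is not None:
        prior_call = sterile.get(*prior_site)
        if prior_call is not None:
            for v in coding:
                prior_verdicts[v.key] = sectors.phase_relative_to_prior(
                    reads, v, prior_call, params.min_informative, params.max_discord_frac
                )

    nomination = sectors.nominate_allele(novel, annotations, pair_verdicts, prior_verdicts)
    return SectorResult(
        sterile_het=het,
        differential=diff,
        genome_wide_unique=len(genome_wide.unique),
        prior_report=prior_report,
        annotations=annotations,
        pair_verdicts=pair_verdicts,
        prior_verdicts=prior_verdicts,
        nomination=nomination,
    )
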