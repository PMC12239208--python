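"""Identification and phasing of a novel noncomplementing allele from paired
sterile/fertile sector sequencing.

An M1 plant heterozygous for a known recessive allele can show a sterile
sector when a new lesion knocks out the remaining wild-type copy.  Both
sectors stay heterozygous at the prior allele (~50% reads), while the novel
lesion is heterozygous in the sterile sector only and must lie *in trans* to
the prior allele (on the wild-type-derived homolog).  The routines here call
heterozygous EMS transitions, partition them into sterile-unique versus
shared within the mapped interval, confirm the prior genotype, and decide
cis/trans for variant pairs from alleles co-observed on single reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .bsa import MappingInterval
from .effects import EffectAnnotation
from .model import PoolVariantSet, ReadObservation, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseVerdict",
    "DifferentialResult",
    "PriorAlleleReport",
    "AlleleNomination",
    "call_heterozygous",
    "differential_sterile_unique",
    "confirm_prior_allele",
    "phase_variant_pair",
    "phase_relative_to_prior",
    "nominate_allele",
]

Site = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


def _as_site(v) -> Site:
    return v.key if isinstance(v, VariantCall) else tuple(v)


@dataclass(frozen=True)
class PhaseVerdict:
    """Read-backed linkage decision for a pair of heterozygous variants."""

    site_a: Site
    site_b: Site
    n_both_alt: int
    n_both_ref: int
    n_discordant: int  # alt at exactly one of the two sites
    verdict: str  # cis | trans | ambiguous

    @property
    def n_informative(self) -> int:
        return self.n_both_alt + self.n_both_ref + self.n_discordant


def call_heterozygous(
    sector: PoolVariantSet,
    min_depth: int = 10,
    freq_window: tuple[float, float] = (0.25, 0.75),
) -> set[VariantCall]:
    """Heterozygous EMS transitions: adequate depth, ~50% frequency, G>A/C>T.

    The frequency window operationalises the expected heterozygote allele
    frequency under binomial read sampling; non-EMS changes are dropped as in
    the pooled-mapping spectrum filter.
    """
    lo, hi = freq_window
    return {
        c
        for c in sector.calls.values()
        if c.depth >= min_depth
        and lo <= c.allele_frequency <= hi
        and c.is_ems_transition()
    }


@dataclass
class DifferentialResult:
    """Partition of sterile-sector heterozygous calls within the interval."""

    unique: set[VariantCall] = field(default_factory=set)
    shared: set[VariantCall] = field(default_factory=set)

    @property
    def n_considered(self) -> int:
        return len(self.unique) + len(self.shared)


def differential_sterile_unique(
    sterile_set: set[VariantCall],
    fertile_sector: PoolVariantSet,
    interval: MappingInterval | None,
    err_max: float = 0.02,
) -> DifferentialResult:
    """Split sterile het calls into fertile-shared vs sterile-unique.

    A variant is *unique* when the fertile sector shows no alternate-allele
    evidence above an error floor (alt fraction <= ``err_max``); absence of
    any fertile call, or a fertile call for a different alternate allele,
    counts as no evidence.  When ``interval`` is given only variants inside
    it are considered (the candidate region from pooled mapping).
    """
    result = DifferentialResult()
    for v in sterile_set:
        if interval is not None and not interval.contains(v.chrom, v.pos):
            continue
        f = fertile_sector.get(v.chrom, v.pos)
        if f is None or f.alt != v.alt or f.allele_frequency <= err_max:
            result.unique.add(v)
        else:
            result.shared.add(v)
    return result


@dataclass(frozen=True)
class PriorAlleleReport:
    """Allele frequencies of the known prior allele in both sectors."""

    site: tuple[str, int]
    freq_sterile: float
    freq_fertile: float
    confirmed: bool


def confirm_prior_allele(
    known_site: tuple[str, int],
    sterile: PoolVariantSet,
    fertile: PoolVariantSet,
    freq_window: tuple[float, float] = (0.25, 0.75),
) -> PriorAlleleReport:
    """Check that the pre-existing allele is heterozygous in both sectors.

    Both sectors of a chimeric head derived from a heterozygote must carry
    the prior allele at ~50%; this is the control demonstrating the plant's
    pre-mutagenesis genotype.  A missing call in either sector is an error —
    the prior genotype cannot be confirmed.
    """
    chrom, pos = known_site
    s, f = sterile.get(chrom, pos), fertile.get(chrom, pos)
    if s is None or f is None:
        missing = "sterile" if s is None else "fertile"
        raise ValueError(
            f"prior allele site {chrom}:{pos} has no call in the {missing} sector"
        )
    lo, hi = freq_window
    confirmed = lo <= s.allele_frequency <= hi and lo <= f.allele_frequency <= hi
    return PriorAlleleReport(
        site=known_site,
        freq_sterile=s.allele_frequency,
        freq_fertile=f.allele_frequency,
        confirmed=confirmed,
    )


def _classify_reads(
    reads: list[ReadObservation], site_a: Site, site_b: Site
) -> tuple[int, int, int, int]:
    """Counts (both_alt, both_ref, alt_a_only, alt_b_only) over informative reads.

    A read is informative when it observes both sites and each observed base
    is that site's reference or alternate allele; third-base observations
    (sequencing error to a non-allele) drop the read from consideration.
    """
    ca, pa, ra, aa = site_a
    cb, pb, rb, ab = site_b
    both_alt = both_ref = alt_a = alt_b = 0
    for read in reads:
        oa = read.allele_at(ca, pa)
        ob = read.allele_at(cb, pb)
        if oa not in (ra, aa) or ob not in (rb, ab):
            continue
        is_alt_a, is_alt_b = oa == aa, ob == ab
        if is_alt_a and is_alt_b:
            both_alt += 1
        elif not is_alt_a and not is_alt_b:
            both_ref += 1
        elif is_alt_a:
            alt_a += 1
        else:
            alt_b += 1
    return both_alt, both_ref, alt_a, alt_b


def verdict_from_counts(
    both_alt: int,
    both_ref: int,
    alt_a_only: int,
    alt_b_only: int,
    min_informative: int = 3,
    max_discord_frac: float = 0.05,
) -> str:
    """Decision rule mapping informative-read counts to cis/trans/ambiguous.

    cis: concordant reads (both-alt or both-ref) make up at least
    (1 - max_discord_frac) of informative reads.  trans: single-alt reads do,
    with both orientations represented.  Anything else — too few reads or too
    much discordance — is ambiguous.
    """
    n = both_alt + both_ref + alt_a_only + alt_b_only
    if n < min_informative:
        return "ambiguous"
    need = (1.0 - max_discord_frac) * n
    if both_alt + both_ref >= need:
        return "cis"
    if alt_a_only + alt_b_only >= need and alt_a_only > 0 and alt_b_only > 0:
        return "trans"
    return "ambiguous"


def phase_variant_pair(
    reads: list[ReadObservation],
    site_a,
    site_b,
    min_informative: int = 3,
    max_discord_frac: float = 0.05,
) -> PhaseVerdict:
    """Decide whether two heterozygous variants lie on the same homolog.

    Only reads observing ref/alt alleles at *both* sites are informative.  An
    all-or-none pattern (reads carry both alternate alleles or neither) is
    cis; complementary single-alt patterns are trans; low counts or excess
    discordance yield ambiguous.  Symmetric in its two sites.
    """
    a, b = _as_site(site_a), _as_site(site_b)
    if (a[0], a[1]) == (b[0], b[1]):
        raise ValueError(f"cannot phase a site against itself: {a[0]}:{a[1]}")
    both_alt, both_ref, alt_a, alt_b = _classify_reads(reads, a, b)
    verdict = verdict_from_counts(
        both_alt, both_ref, alt_a, alt_b, min_informative, max_discord_frac
    )
    return PhaseVerdict(
        site_a=a,
        site_b=b,
        n_both_alt=both_alt,
        n_both_ref=both_ref,
        n_discordant=alt_a + alt_b,
        verdict=verdict,
    )


def phase_relative_to_prior(
    reads: list[ReadObservation],
    novel_site,
    prior_site,
    min_informative: int = 3,
    max_discord_frac: float = 0.05,
) -> PhaseVerdict:
    """Phase a novel lesion against the pre-existing allele.

    Same decision rule as :func:`phase_variant_pair`; a novel lesion that
    knocked out the wild-type copy is expected *trans* to the prior allele.
    """
    return phase_variant_pair(
        reads, novel_site, prior_site, min_informative, max_discord_frac
    )


@dataclass
class GeneEvidence:
    """Phasing evidence for one gene's sterile-unique coding variants."""

    gene_id: str
    variants: list[VariantCall]
    pair_verdicts: list[PhaseVerdict]
    prior_verdicts: list[PhaseVerdict]
    nominated: bool = False


@dataclass
class AlleleNomination:
    """Outcome of the sector screen: candidate genes and the nominated allele."""

    genes: list[GeneEvidence]
    nominated_gene: str | None


def nominate_allele(
    unique_set: set[VariantCall],
    annotations: dict[Site, EffectAnnotation],
    pair_verdicts: dict[frozenset[Site], PhaseVerdict],
    prior_verdicts: dict[Site, PhaseVerdict],
) -> AlleleNomination:
    """Nominate the gene carrying the novel noncomplementing allele.

    Candidate genes are those with sterile-unique MODERATE/HIGH coding
    variants.  A gene is nominated when its novel variants are cis among
    themselves (every informative pairwise verdict cis, none trans) and at
    least one shows a definite trans verdict against the prior allele with
    none cis to it.  Genes lacking phasing support are listed but not
    nominated; more than one qualifying gene leaves the nomination empty
    with a warning.
    """
    by_gene: dict[str, list[VariantCall]] = {}
    for v in sorted(unique_set, key=lambda c: (c.chrom, c.pos)):
        ann = annotations.get(v.key)
        if ann is not None and ann.is_coding and ann.impact in {"HIGH", "MODERATE"}:
            by_gene.setdefault(ann.gene_id, []).append(v)

    evidence: list[GeneEvidence] = []
    for gene_id, variants in sorted(by_gene.items()):
        pairs = [
            pair_verdicts[frozenset({a.key, b.key})]
            for i, a in enumerate(variants)
            for b in variants[i + 1 :]
            if frozenset({a.key, b.key}) in pair_verdicts
        ]
        priors = [prior_verdicts[v.key] for v in variants if v.key in prior_verdicts]
        # Cis among themselves: at least one definite cis pair and no trans
        # pair.  An ambiguous pair (no spanning reads) is absence of
        # evidence, not evidence against cis.  A singleton is vacuously cis
        # with itself but then needs its own definite trans-to-prior verdict.
        if len(variants) > 1:
            cis_ok = any(p.verdict == "cis" for p in pairs) and not any(
                p.verdict == "trans" for p in pairs
            )
        else:
            cis_ok = True
        trans_ok = (
            any(p.verdict == "trans" for p in priors)
            and not any(p.verdict == "cis" for p in priors)
        )
        evidence.append(
            GeneEvidence(
                gene_id=gene_id,
                variants=variants,
                pair_verdicts=pairs,
                prior_verdicts=priors,
                nominated=bool(cis_ok and trans_ok),
            )
        )

    nominated = [e.gene_id for e in evidence if e.nominated]
    if len(nominated) > 1:
        logger.warning(
            "multiple genes with phasing-supported novel alleles: %s; "
            "no single nomination made",
            nominated,
        )
        for e in evidence:
            e.nominated = False
        nominated = []
    if len(by_gene) > 1 and not nominated:
        logger.warning(
            "unique coding variants found in %d genes without decisive phasing",
            len(by_gene),
        )
    return AlleleNomination(
        genes=evidence, nominated_gene=nominated[0] if nominated else None
    )
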