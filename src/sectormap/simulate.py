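"""Synthetic EMS-screen generator with known ground truth.

Generates a complete, deterministic dataset for the pipeline: a random
reference genome with planted gene models, a causal stop-gain lesion, the
causal parent's background EMS load, two independent F2 pool pairs
(mutant + fertile sibling) with Haldane linkage decay and binomial read
sampling, planted sibling-shared and error-prone (blacklist) sites, and a
chimeric sterile/fertile sector pair carrying a prior heterozygous allele
plus a cis-linked novel lesion pair with per-read allele observations.

Genetic model
-------------
F2 individuals selected for the recessive phenotype are homozygous for the
causal allele.  A causal-parent variant at genetic distance d Morgans from
the causal site rides on each selected chromosome with probability
1 - r, where r = (1 - exp(-2 d)) / 2 (Haldane map function, uniform
Morgans/Mbp).  Unlinked causal-parent variants segregate at expected pool
frequency 1/2.  Fertile siblings are 1/3 homozygous wild type and 2/3
heterozygous at the causal locus, so the causal allele sits at frequency
1/3 among their chromosomes.

Read sampling draws site depth from Poisson(mean_depth) and applies a
symmetric per-base substitution error: a read reports its true base with
probability 1 - e and each of the other three bases with probability e / 3.
Reads reporting a base that is neither the reference nor the alternate
allele count toward neither allelic depth.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import (
    GeneModel,
    PoolVariantSet,
    ReadObservation,
    ReferenceGenome,
    SiteBlacklist,
    ValidationError,
    VariantCall,
    revcomp,
)

__all__ = [
    "ScreenSimConfig",
    "SimTruth",
    "SectorTruth",
    "ScreenDataset",
    "generate_reference",
    "simulate_ems_mutations",
    "simulate_f2_pools",
    "simulate_sector_pair",
    "simulate_screen",
    "write_dataset",
    "haldane_r",
]

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)
_EMS_ALT = {"G": "A", "C": "T"}


def haldane_r(d_morgans: float) -> float:
    """Recombination fraction for a genetic distance under the Haldane map."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))


@dataclass
class ScreenSimConfig:
    """Parameters of a synthetic EMS screen.

    The defaults describe the scaled-down screen every stage is exercised
    on: a 5 x 10-Mbp genome, pools of 40 phenotyped F2 individuals at 12x
    with 1% sequencing error, a hot genetic map (0.5 Morgans/Mbp) so linkage
    decays within a chromosome, 200 causal-parent background EMS variants,
    and 50 planted sibling-shared plus 50 error-prone sites.  Sector
    sequencing runs at 60x with 150-bp reads.
    """

    seed: int = 0
    n_chrom: int = 5
    chrom_length: int = 10_000_000
    ems_rate: float = 8e-6  # per G/C site, for the rate-based generator
    causal_site: tuple[str, int] | str = "auto"
    n_mutant_individuals: int = 40
    n_wildtype_individuals: int = 40
    mean_depth: float = 12.0
    seq_error_rate: float = 0.01
    recomb_rate: float = 0.5  # Morgans per Mbp
    n_shared_background: int = 50
    n_blacklist: int = 50
    n_background: int = 200  # causal-parent EMS load, planted as an exact count
    second_parent_background: bool = False
    n_second_parent: int = 200
    # Sector-pair parameters (chimeric-head sequencing).
    sector_mean_depth: float = 60.0
    read_length: int = 150
    n_sector_shared: int = 40
    n_sector_unique: int = 20
    sector_margin: int = 1000

    def __post_init__(self):
        counts = (
            self.n_chrom,
            self.n_mutant_individuals,
            self.n_wildtype_individuals,
            self.n_shared_background,
            self.n_blacklist,
            self.n_background,
            self.n_sector_shared,
            self.n_sector_unique,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("all counts must be >= 0")
        for rate in (self.ems_rate, self.seq_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        if self.mean_depth <= 0 or self.sector_mean_depth <= 0:
            raise ValidationError("mean depth must be positive")
        if self.recomb_rate < 0:
            raise ValidationError("recombination rate must be >= 0")


Mutation = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


@dataclass
class SectorTruth:
    """Ground truth of the chimeric sector pair."""

    prior_het_site: Mutation
    novel_cis_pair: tuple[Mutation, Mutation]
    # Haplotype 0 carries the prior allele; the novel pair sits on haplotype 1.
    novel_haplotype: int
    gene_id: str
    shared_het_sites: list[Mutation] = field(default_factory=list)
    sterile_unique_sites: list[Mutation] = field(default_factory=list)
    fertile_unique_sites: list[Mutation] = field(default_factory=list)


@dataclass
class SimTruth:
    """Everything the generator planted, for closing the loop in tests."""

    causal_site: Mutation
    linked_sites: list[tuple[Mutation, float]] = field(default_factory=list)
    blacklist_sites: list[Mutation] = field(default_factory=list)
    sibling_shared_sites: list[Mutation] = field(default_factory=list)
    sector_truth: SectorTruth | None = None


def _rng(config_or_seed, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    seed = config_or_seed.seed if isinstance(config_or_seed, ScreenSimConfig) else config_or_seed
    return np.random.default_rng(seed)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_reference(
    config: ScreenSimConfig, rng: np.random.Generator | None = None
) -> ReferenceGenome:
    """Random uniform-composition reference; deterministic for a given seed."""
    rng = _rng(config, rng)
    chroms = []
    for i in range(config.n_chrom):
        arr = rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        chroms.append((f"Chr{i + 1}", _BASE_BYTES[arr].tobytes().decode("ascii")))
    return ReferenceGenome(chroms)


def _draw_gc_sites(
    genome: ReferenceGenome,
    n: int,
    rng: np.random.Generator,
    exclude: set[tuple[str, int]],
) -> list[Mutation]:
    """Draw n distinct G/C positions uniformly over the genome (rejection)."""
    names = genome.names
    lengths = genome.lengths
    total = sum(lengths.values())
    if total == 0 and n > 0:
        raise ValidationError("cannot draw sites from an empty genome")
    weights = np.array([lengths[c] / total for c in names])
    out: list[Mutation] = []
    taken = set(exclude)
    while len(out) < n:
        k = max(4 * (n - len(out)), 16)
        chrom_idx = rng.choice(len(names), size=k, p=weights)
        positions = rng.integers(1, np.array([lengths[names[i]] for i in chrom_idx]) + 1)
        for ci, pos in zip(chrom_idx, positions):
            chrom = names[ci]
            base = genome.base(chrom, int(pos))
            if base in _EMS_ALT and (chrom, int(pos)) not in taken:
                taken.add((chrom, int(pos)))
                out.append((chrom, int(pos), base, _EMS_ALT[base]))
                if len(out) == n:
                    break
    return out


def simulate_ems_mutations(
    genome: ReferenceGenome,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Mutation]:
    """Draw EMS lesions: per-G/C-site Bernoulli(rate), always G>A or C>T.

    The count per chromosome is Binomial(number of G/C positions, rate); the
    positions are uniform over G/C sites.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError("rate must lie in [0, 1]")
    rng = _rng(seed if seed is not None else 0, rng)
    out: list[Mutation] = []
    for name, seq in genome:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n_gc = int(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))))
        if n_gc == 0:
            continue
        count = int(rng.binomial(n_gc, rate))
        sub = ReferenceGenome([(name, seq)])
        out.extend(_draw_gc_sites(sub, count, rng, set()))
    return sorted(out)


# ---------------------------------------------------------------------------
# Gene planting

_CAUSAL_CODONS = {98: "CCA", 111: "CAA", 150: "CAG"}  # P, Q, Q
_CAUSAL_N_CODONS = 300
_CAUSAL_EXON1_CODONS = 200
_CAUSAL_INTRON_LEN = 200


def _coding_sequence(
    n_codons: int, rng: np.random.Generator, forced: dict[int, str] | None = None
) -> str:
    codons = ["ATG"]
    codons += list(rng.choice(_SENSE_CODONS, size=n_codons - 2))
    codons.append("TGA")
    for idx, codon in (forced or {}).items():
        codons[idx - 1] = codon
    return "".join(codons)


def plant_genes(
    genome: ReferenceGenome,
    config: ScreenSimConfig,
    rng: np.random.Generator,
) -> tuple[ReferenceGenome, list[GeneModel], str]:
    """Embed designed genes into the reference.

    The causal gene sits at the centre of the middle chromosome on the plus
    strand with two CDS exons; codons 98/111/150 are forced to CCA/CAA/CAG so
    that C>T at their first bases yields P98S, Q111* and Q150*.  Two decoy
    genes (random strand, single exon) are planted per chromosome.
    """
    edits: dict[str, list[tuple[int, str]]] = {n: [] for n in genome.names}
    genes: list[GeneModel] = []

    causal_chrom = genome.names[len(genome.names) // 2]
    cds = _coding_sequence(_CAUSAL_N_CODONS, rng, _CAUSAL_CODONS)
    exon1 = cds[: 3 * _CAUSAL_EXON1_CODONS]
    exon2 = cds[3 * _CAUSAL_EXON1_CODONS :]
    intron = "GT" + "".join(rng.choice(list("ACGT"), size=_CAUSAL_INTRON_LEN - 4)) + "AG"
    genomic = exon1 + intron + exon2
    start = genome.lengths[causal_chrom] // 2 - len(genomic) // 2
    causal_gene = GeneModel(
        gene_id="GeneC.causal",
        chrom=causal_chrom,
        strand="+",
        cds_segments=(
            (start, start + len(exon1) - 1),
            (start + len(exon1) + len(intron), start + len(genomic) - 1),
        ),
        start=start,
        end=start + len(genomic) - 1,
    )
    edits[causal_chrom].append((start, genomic))
    genes.append(causal_gene)

    for ci, name in enumerate(genome.names):
        length = genome.lengths[name]
        for k, frac in enumerate((0.25, 0.75)):
            n_codons = 300
            decoy_cds = _coding_sequence(n_codons, rng)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            seq = decoy_cds if strand == "+" else revcomp(decoy_cds)
            jitter = int(rng.integers(-length // 20, length // 20 + 1))
            gstart = max(1, min(length - len(seq), int(length * frac) + jitter))
            genes.append(
                GeneModel(
                    gene_id=f"Gene{ci + 1}.{k + 1}",
                    chrom=name,
                    strand=strand,
                    cds_segments=((gstart, gstart + len(seq) - 1),),
                )
            )
            edits[name].append((gstart, seq))

    new_chroms = []
    for name, seq in genome:
        for estart, payload in sorted(edits[name]):
            seq = seq[: estart - 1] + payload + seq[estart - 1 + len(payload) :]
        new_chroms.append((name, seq))
    return ReferenceGenome(new_chroms), genes, causal_gene.gene_id


def causal_stop_site(gene: GeneModel) -> Mutation:
    """Genomic site whose C>T creates the premature stop at codon 150."""
    pos = gene.cds_segments[0][0] + 3 * (150 - 1)
    return (gene.chrom, pos, "C", "T")


# ---------------------------------------------------------------------------
# Pool simulation

def _sample_read_counts(
    rng: np.random.Generator, p_true: float, mean_depth: float, err: float
) -> tuple[int, int]:
    """(ref_depth, alt_depth) after Poisson depth and substitution error."""
    d = int(rng.poisson(mean_depth))
    if d == 0:
        return 0, 0
    n_alt_true = int(rng.binomial(d, p_true))
    n_ref_true = d - n_alt_true
    alt_as = rng.multinomial(n_alt_true, [1 - err, err / 3, 2 * err / 3])
    ref_as = rng.multinomial(n_ref_true, [1 - err, err / 3, 2 * err / 3])
    alt_depth = int(alt_as[0] + ref_as[1])
    ref_depth = int(ref_as[0] + alt_as[1])
    return ref_depth, alt_depth


def _emit_call(
    pool: PoolVariantSet,
    rng: np.random.Generator,
    site: Mutation,
    p_true: float,
    mean_depth: float,
    err: float,
) -> None:
    chrom, pos, ref, alt = site
    ref_d, alt_d = _sample_read_counts(rng, p_true, mean_depth, err)
    if alt_d >= 1 and ref_d + alt_d >= 1:
        pool.add(VariantCall(chrom, pos, ref, alt, depth=ref_d + alt_d, alt_depth=alt_d))


def _linked_mutant_freq(
    site: Mutation, causal: Mutation, recomb_rate: float
) -> float:
    """Expected mutant-pool frequency of a causal-parent variant (1 - r)."""
    if site[0] != causal[0]:
        return 0.5
    d = abs(site[1] - causal[1]) / 1e6 * recomb_rate
    return 1.0 - haldane_r(d)


def simulate_f2_pools(
    genome: ReferenceGenome,
    config: ScreenSimConfig,
    rng: np.random.Generator | None = None,
    causal_site: Mutation | None = None,
    background: Sequence[Mutation] | None = None,
    shared_sites: Sequence[Mutation] | None = None,
    blacklist_sites: Sequence[Mutation] | None = None,
    pool_name: str = "pool1",
) -> tuple[PoolVariantSet, PoolVariantSet, SimTruth]:
    """Simulate one mutant/sibling pool pair from an F2 mapping population.

    Selection forces mutant-pool homozygosity at the causal site; linked
    causal-parent variants follow Haldane linkage decay, unlinked ones
    segregate at 1/2.  Sibling-shared sites are homozygous in both pools and
    error-prone (blacklist) sites carry inflated nonreference frequency in
    every sample.  When the optional site lists are omitted they are drawn
    from the config (``causal_site='auto'`` resolves to the central G/C
    position of the middle chromosome).
    """
    rng = _rng(config, rng)
    if causal_site is None:
        causal_site = _resolve_causal(genome, config)
    exclude = {(causal_site[0], causal_site[1])}
    if background is None:
        background = _draw_gc_sites(genome, config.n_background, rng, exclude)
    exclude |= {(c, p) for c, p, _, _ in background}
    if shared_sites is None:
        shared_sites = _draw_gc_sites(genome, config.n_shared_background, rng, exclude)
    exclude |= {(c, p) for c, p, _, _ in shared_sites}
    if blacklist_sites is None:
        blacklist_sites = _draw_gc_sites(genome, config.n_blacklist, rng, exclude)

    n_mut = config.n_mutant_individuals
    n_wt = config.n_wildtype_individuals
    mutant = PoolVariantSet(f"ms-{pool_name}", "mutant_pool")
    sibling = PoolVariantSet(f"wt-{pool_name}", "wildtype_pool")
    md, err = config.mean_depth, config.seq_error_rate

    truth = SimTruth(
        causal_site=causal_site,
        blacklist_sites=list(blacklist_sites),
        sibling_shared_sites=list(shared_sites),
    )

    # Causal site: homozygous in the mutant pool, 1/3 among sibling chromosomes.
    _emit_call(mutant, rng, causal_site, 1.0, md, err)
    n_het = int(rng.binomial(n_wt, 2.0 / 3.0)) if n_wt else 0
    sib_p = n_het / (2 * n_wt) if n_wt else 0.0
    _emit_call(sibling, rng, causal_site, sib_p, md, err)

    for site in background:
        exp_freq = _linked_mutant_freq(site, causal_site, config.recomb_rate)
        truth.linked_sites.append((site, exp_freq))
        if site[0] == causal_site[0]:
            one_minus_r = exp_freq
            k_mut = int(rng.binomial(2 * n_mut, one_minus_r)) if n_mut else 0
            p_mut = k_mut / (2 * n_mut) if n_mut else 0.0
            # Sibling chromosomes: n_het carry the causal allele, the rest do not.
            k_sib = 0
            if n_wt:
                k_sib = int(rng.binomial(n_het, one_minus_r)) + int(
                    rng.binomial(2 * n_wt - n_het, 1.0 - one_minus_r)
                )
            p_sib = k_sib / (2 * n_wt) if n_wt else 0.0
        else:
            p_mut = rng.binomial(2 * n_mut, 0.5) / (2 * n_mut) if n_mut else 0.0
            p_sib = rng.binomial(2 * n_wt, 0.5) / (2 * n_wt) if n_wt else 0.0
        _emit_call(mutant, rng, site, p_mut, md, err)
        _emit_call(sibling, rng, site, p_sib, md, err)

    if config.second_parent_background:
        second = _draw_gc_sites(
            genome,
            config.n_second_parent,
            rng,
            exclude | {(c, p) for c, p, _, _ in blacklist_sites},
        )
        for site in second:
            # The other parent's variants are unselected in both pools.
            for pool, n_ind in ((mutant, n_mut), (sibling, n_wt)):
                p = rng.binomial(2 * n_ind, 0.5) / (2 * n_ind) if n_ind else 0.0
                _emit_call(pool, rng, site, p, md, err)

    for site in shared_sites:
        _emit_call(mutant, rng, site, 1.0, md, err)
        _emit_call(sibling, rng, site, 1.0, md, err)
    for site in blacklist_sites:
        _emit_call(mutant, rng, site, 1.0, md, err)
        _emit_call(sibling, rng, site, 1.0, md, err)

    return mutant, sibling, truth


def _resolve_causal(genome: ReferenceGenome, config: ScreenSimConfig) -> Mutation:
    if isinstance(config.causal_site, tuple):
        chrom, pos = config.causal_site
        base = genome.base(chrom, pos)
        if base not in _EMS_ALT:
            raise ValidationError(
                f"causal site {chrom}:{pos} is {base}, not a G/C position"
            )
        return (chrom, pos, base, _EMS_ALT[base])
    chrom = genome.names[len(genome.names) // 2]
    centre = genome.lengths[chrom] // 2
    for offset in range(genome.lengths[chrom]):
        for pos in (centre + offset, centre - offset):
            if 1 <= pos <= genome.lengths[chrom]:
                base = genome.base(chrom, pos)
                if base in _EMS_ALT:
                    return (chrom, pos, base, _EMS_ALT[base])
    raise ValidationError("no G/C position available for an automatic causal site")


# ---------------------------------------------------------------------------
# Sector-pair simulation

def novel_pair_sites(gene: GeneModel) -> tuple[Mutation, Mutation]:
    """The two C>T lesions of the novel allele (codons 98 and 111)."""
    base = gene.cds_segments[0][0]
    return (
        (gene.chrom, base + 3 * (98 - 1), "C", "T"),
        (gene.chrom, base + 3 * (111 - 1), "C", "T"),
    )


def simulate_sector_pair(
    genome: ReferenceGenome,
    config: ScreenSimConfig,
    gene: GeneModel,
    rng: np.random.Generator | None = None,
    prior_site: Mutation | None = None,
) -> tuple[PoolVariantSet, PoolVariantSet, list[ReadObservation], SectorTruth]:
    """Simulate sterile/fertile sector sequencing of one chimeric head.

    Both sectors are heterozygous at the prior site (the lesion carried on
    haplotype 0); the sterile sector additionally carries two novel C>T
    lesions in cis on haplotype 1 — the homolog *not* carrying the prior
    allele.  Read observations over the gene neighbourhood record per-read
    alleles so that some reads span both novel sites and some span a novel
    site together with the prior site.  Shared somatic heterozygous EMS
    variants are planted in both sectors, sector-unique ones in each.
    """
    rng = _rng(config, rng)
    if prior_site is None:
        prior_site = causal_stop_site(gene)
    novel_a, novel_b = novel_pair_sites(gene)
    if novel_b[1] - novel_a[1] >= config.read_length:
        import logging

        logging.getLogger(__name__).warning(
            "novel pair separation %d bp exceeds the read span %d bp; "
            "phasing will be ambiguous by construction",
            novel_b[1] - novel_a[1],
            config.read_length,
        )

    exclude = {
        (s[0], s[1]) for s in (prior_site, novel_a, novel_b)
    }
    shared = _draw_gc_sites(genome, config.n_sector_shared, rng, exclude)
    exclude |= {(c, p) for c, p, _, _ in shared}
    sterile_unique = _draw_gc_sites(genome, config.n_sector_unique, rng, exclude)
    exclude |= {(c, p) for c, p, _, _ in sterile_unique}
    fertile_unique = _draw_gc_sites(genome, config.n_sector_unique, rng, exclude)

    # Haplotype of every heterozygous site.  0 = homolog carrying the prior
    # allele; 1 = the wild-type-derived homolog carrying the novel pair.
    hap_of: dict[tuple[str, int], int] = {
        (prior_site[0], prior_site[1]): 0,
        (novel_a[0], novel_a[1]): 1,
        (novel_b[0], novel_b[1]): 1,
    }
    for site in shared + sterile_unique + fertile_unique:
        hap_of[(site[0], site[1])] = int(rng.integers(0, 2))

    margin = config.sector_margin
    region = (max(1, gene.start - margin), min(genome.lengths[gene.chrom], gene.end + margin))

    def region_sites(sector: str) -> list[Mutation]:
        sites = [prior_site] + list(shared)
        if sector == "sterile":
            sites += [novel_a, novel_b] + list(sterile_unique)
        else:
            sites += list(fertile_unique)
        return [
            s
            for s in sites
            if s[0] == gene.chrom and region[0] <= s[1] <= region[1]
        ]

    def make_reads(sector: str, tracked: list[Mutation]) -> list[ReadObservation]:
        region_len = region[1] - region[0] + 1
        n_reads = int(round(config.sector_mean_depth * region_len / config.read_length))
        tracked_sorted = sorted(tracked, key=lambda s: s[1])
        reads = []
        starts = rng.integers(
            region[0] - config.read_length + 1, region[1] + 1, size=n_reads
        )
        haps = rng.integers(0, 2, size=n_reads)
        err = config.seq_error_rate
        for i, (start, hap) in enumerate(zip(starts, haps)):
            end = start + config.read_length - 1
            obs = []
            for chrom, pos, ref, alt in tracked_sorted:
                if not start <= pos <= end:
                    continue
                carries = hap_of[(chrom, pos)] == hap
                if sector == "fertile" and (chrom, pos) in {
                    (novel_a[0], novel_a[1]),
                    (novel_b[0], novel_b[1]),
                }:
                    carries = False  # the fertile sector never has the novel pair
                base = alt if carries else ref
                if err > 0 and rng.random() < err:
                    others = [b for b in "ACGT" if b != base]
                    base = others[int(rng.integers(0, 3))]
                obs.append((chrom, pos, base))
            if obs:
                reads.append(
                    ReadObservation(
                        read_id=f"{sector}-{i:06d}", observations=tuple(obs)
                    )
                )
        return reads

    def calls_from_reads(
        pool: PoolVariantSet, reads: list[ReadObservation], tracked: list[Mutation]
    ) -> None:
        for chrom, pos, ref, alt in tracked:
            ref_d = alt_d = 0
            for r in reads:
                a = r.allele_at(chrom, pos)
                if a == ref:
                    ref_d += 1
                elif a == alt:
                    alt_d += 1
            if alt_d >= 1:
                pool.add(VariantCall(chrom, pos, ref, alt, ref_d + alt_d, alt_d))

    sterile = PoolVariantSet("sector-sterile", "sterile_sector")
    fertile = PoolVariantSet("sector-fertile", "fertile_sector")

    sterile_tracked = region_sites("sterile")
    fertile_tracked = region_sites("fertile")
    # Fertile reads must still cover the novel sites (showing reference
    # alleles) so the differential step sees explicit absence of evidence.
    fertile_tracked_reads = sorted(set(fertile_tracked + [novel_a, novel_b]), key=lambda s: s[1])

    sterile_reads = make_reads("sterile", sterile_tracked)
    fertile_reads = make_reads("fertile", fertile_tracked_reads)
    calls_from_reads(sterile, sterile_reads, sterile_tracked)
    calls_from_reads(fertile, fertile_reads, fertile_tracked_reads)

    # Heterozygous background outside the read region: direct binomial sampling.
    def emit_het(pool: PoolVariantSet, sites: list[Mutation]) -> None:
        for site in sites:
            if site[0] == gene.chrom and region[0] <= site[1] <= region[1]:
                continue  # already covered by reads
            _emit_call(
                pool, rng, site, 0.5, config.sector_mean_depth, config.seq_error_rate
            )

    for site_list, pools in (
        ([prior_site] + shared, (sterile, fertile)),
        (sterile_unique, (sterile,)),
        (fertile_unique, (fertile,)),
    ):
        for pool in pools:
            emit_het(pool, list(site_list))

    truth = SectorTruth(
        prior_het_site=prior_site,
        novel_cis_pair=(novel_a, novel_b),
        novel_haplotype=1,
        gene_id=gene.gene_id,
        shared_het_sites=list(shared),
        sterile_unique_sites=list(sterile_unique) + [novel_a, novel_b],
        fertile_unique_sites=list(fertile_unique),
    )
    return sterile, fertile, sterile_reads, truth


# ---------------------------------------------------------------------------
# Full-screen orchestration

@dataclass
class ScreenDataset:
    """A complete synthetic screen: reference, annotation, pools, sectors."""

    config: ScreenSimConfig
    genome: ReferenceGenome
    genes: list[GeneModel]
    causal_gene_id: str
    blacklist: SiteBlacklist
    mutant_pools: list[PoolVariantSet]
    sibling_pools: list[PoolVariantSet]
    sterile: PoolVariantSet
    fertile: PoolVariantSet
    sector_reads: list[ReadObservation]
    truth: SimTruth

    @property
    def causal_gene(self) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == self.causal_gene_id)


def simulate_screen(config: ScreenSimConfig) -> ScreenDataset:
    """Generate the full synthetic screen: two F2 pool pairs (sharing the
    causal parent's background, as two crosses of the same mutant line) plus
    one chimeric sector pair.  Fully deterministic for a given config."""
    root = np.random.default_rng(config.seed)
    streams = root.spawn(6)
    genome = generate_reference(config, rng=streams[0])
    genome, genes, causal_gene_id = plant_genes(genome, config, streams[1])
    causal_gene = next(g for g in genes if g.gene_id == causal_gene_id)
    causal = causal_stop_site(causal_gene)

    exclude = {(causal[0], causal[1])}
    background = _draw_gc_sites(genome, config.n_background, streams[2], exclude)
    exclude |= {(c, p) for c, p, _, _ in background}
    shared = _draw_gc_sites(genome, config.n_shared_background, streams[2], exclude)
    exclude |= {(c, p) for c, p, _, _ in shared}
    bl_sites = _draw_gc_sites(genome, config.n_blacklist, streams[2], exclude)

    mutants, siblings = [], []
    truth = None
    for i, stream in enumerate((streams[3], streams[4]), start=1):
        m, s, t = simulate_f2_pools(
            genome,
            config,
            rng=stream,
            causal_site=causal,
            background=background,
            shared_sites=shared,
            blacklist_sites=bl_sites,
            pool_name=f"pool{i}",
        )
        mutants.append(m)
        siblings.append(s)
        truth = truth or t

    sterile, fertile, reads, sector_truth = simulate_sector_pair(
        genome, config, causal_gene, rng=streams[5], prior_site=causal
    )
    truth.sector_truth = sector_truth

    blacklist = SiteBlacklist(frozenset((c, p) for c, p, _, _ in bl_sites))
    return ScreenDataset(
        config=config,
        genome=genome,
        genes=genes,
        causal_gene_id=causal_gene_id,
        blacklist=blacklist,
        mutant_pools=mutants,
        sibling_pools=siblings,
        sterile=sterile,
        fertile=fertile,
        sector_reads=reads,
        truth=truth,
    )


def write_dataset(dataset: ScreenDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset to disk: FASTA, GFF3, VCFs, BED, reads TSV, truth JSON."""
    from . import io as smio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fasta"
    smio.write_fasta(dataset.genome, paths["genome"])
    paths["genes"] = outdir / "genes.gff3"
    smio.write_gff3(dataset.genes, paths["genes"])
    paths["blacklist"] = outdir / "blacklist.bed"
    smio.write_blacklist_bed(dataset.blacklist, paths["blacklist"])
    for i, (m, s) in enumerate(zip(dataset.mutant_pools, dataset.sibling_pools), 1):
        paths[f"mutant{i}"] = outdir / f"mutant_pool{i}.vcf"
        smio.write_vcf(m, paths[f"mutant{i}"], dataset.genome)
        paths[f"sibling{i}"] = outdir / f"sibling_pool{i}.vcf"
        smio.write_vcf(s, paths[f"sibling{i}"], dataset.genome)
    paths["sterile"] = outdir / "sector_sterile.vcf"
    smio.write_vcf(dataset.sterile, paths["sterile"], dataset.genome)
    paths["fertile"] = outdir / "sector_fertile.vcf"
    smio.write_vcf(dataset.fertile, paths["fertile"], dataset.genome)
    paths["reads"] = outdir / "sector_reads.tsv"
    smio.write_observations_tsv(dataset.sector_reads, paths["reads"])

    paths["truth"] = outdir / "truth.json"
    truth_dict = asdict(dataset.truth)
    truth_dict["causal_gene_id"] = dataset.causal_gene_id
    with open(paths["truth"], "w") as fh:
        json.dump(truth_dict, fh, indent=1, default=list)
    return paths
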