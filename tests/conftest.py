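"""Shared fixtures: tiny deterministic genomes and designed gene models."""

from __future__ import annotations

import numpy as np
import pytest

from sectormap.model import GeneModel, ReferenceGenome, VariantCall, revcomp

# Sense codons chosen so the designed CDS has no internal stops.
_FILLER = "GCT"  # Ala


def make_cds(n_codons: int, forced: dict[int, str]) -> str:
    codons = ["ATG"] + [_FILLER] * (n_codons - 2) + ["TGA"]
    for idx, codon in forced.items():
        codons[idx - 1] = codon
    return "".join(codons)


@pytest.fixture(scope="session")
def worked_gene_genome():
    """A genome with one plus-strand gene whose codons reproduce the
    worked consequence examples: Q150*, P98S, D209N, L478F, plus a
    synonymous site (codon 30 CTG -> TTG? no: CTG first base C>T gives TTG,
    Leu->Leu at position 1)."""
    n_codons = 500
    forced = {
        30: "CTG",   # C>T at first base: CTG->TTG, both Leu (synonymous)
        98: "CCA",   # C>T at first base: P98S
        111: "CAA",  # C>T at first base: Q111*
        150: "CAG",  # C>T at first base: Q150*
        209: "GAT",  # G>A at first base: D209N
        478: "CTT",  # C>T at first base: L478F
    }
    cds = make_cds(n_codons, forced)
    gene_start = 101
    flank = "A" * (gene_start - 1)
    seq = flank + cds + "A" * 100
    genome = ReferenceGenome([("Chr4", seq)])
    gene = GeneModel(
        gene_id="GeneT1",
        chrom="Chr4",
        strand="+",
        cds_segments=((gene_start, gene_start + len(cds) - 1),),
    )
    return genome, gene


def codon_first_base_pos(gene: GeneModel, codon_index: int) -> int:
    """Genomic position of a codon's first base in a single-exon + gene."""
    return gene.cds_segments[0][0] + 3 * (codon_index - 1)


def call_at(genome: ReferenceGenome, chrom: str, pos: int, alt: str,
            depth: int = 30, alt_depth: int = 30) -> VariantCall:
    return VariantCall(
        chrom=chrom, pos=pos, ref=genome.base(chrom, pos), alt=alt,
        depth=depth, alt_depth=alt_depth,
    )


@pytest.fixture(scope="session")
def small_random_genome():
    """A 2 x 50 kb random genome for binning/annotation oracle tests."""
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms = [
        (name, bases[rng.integers(0, 4, 50_000)].tobytes().decode())
        for name in ("Chr1", "Chr2")
    ]
    return ReferenceGenome(chroms)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
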