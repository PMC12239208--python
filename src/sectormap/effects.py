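"""Codon-level consequence classification of candidate SNPs.

A SNP inside a gene's spliced CDS is classified by translating its reference
and alternate codons with the standard nuclear genetic code: stop_gained
(HIGH), stop_lost (HIGH), missense_variant (MODERATE) or synonymous_variant
(LOW).  Positions inside a gene but outside every CDS segment are
intron_or_utr, anything else intergenic (both MODIFIER).  Protein changes
use single-letter HGVS-style notation, e.g. ``p.Q150*``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .model import COMPLEMENT, GeneModel, ReferenceGenome, VariantCall, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "EffectAnnotation",
    "IMPACT_OF_TYPE",
    "classify_variant",
    "format_hgvs_p",
    "rank_candidates",
    "spliced_cds",
]

IMPACT_OF_TYPE = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "intron_or_utr": "MODIFIER",
    "intergenic": "MODIFIER",
}

_IMPACT_RANK = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "MODIFIER": 3}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY*")


@dataclass(frozen=True)
class EffectAnnotation:
    """Consequence of one SNP against one gene model (or none)."""

    gene_id: str
    variant_type: str
    impact: str
    hgvs_p: str = ""
    codon_index: int | None = None

    def __post_init__(self):
        if self.variant_type not in IMPACT_OF_TYPE:
            raise ValueError(f"unknown variant type {self.variant_type!r}")
        if IMPACT_OF_TYPE[self.variant_type] != self.impact:
            raise ValueError(
                f"impact {self.impact} inconsistent with type {self.variant_type}"
            )

    @property
    def is_coding(self) -> bool:
        return self.variant_type in {
            "stop_gained",
            "stop_lost",
            "missense_variant",
            "synonymous_variant",
        }


def format_hgvs_p(ref_aa: str, codon_index: int, alt_aa: str) -> str:
    """HGVS-style protein change, e.g. (Q, 150, *) -> ``p.Q150*``."""
    for aa in (ref_aa, alt_aa):
        if aa not in _VALID_AA:
            raise ValueError(f"invalid amino-acid code {aa!r}")
    if codon_index < 1:
        raise ValueError("codon index must be >= 1")
    return f"p.{ref_aa}{codon_index}{alt_aa}"


def spliced_cds(gene: GeneModel, genome: ReferenceGenome) -> str:
    """Coding sequence of a gene, 5'->3' (reverse-complemented on '-')."""
    seq = genome.sequence(gene.chrom)
    joined = "".join(seq[s - 1 : e] for s, e in gene.cds_segments)
    return revcomp(joined) if gene.strand == "-" else joined


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced, stranded CDS."""
    before = 0
    plus_offset = None
    for s, e in gene.cds_segments:
        if s <= pos <= e:
            plus_offset = before + (pos - s)
            break
        before += e - s + 1
    if plus_offset is None:
        return None
    if gene.strand == "+":
        return plus_offset
    return gene.cds_length - 1 - plus_offset


def _classify_in_gene(
    variant: VariantCall, gene: GeneModel, genome: ReferenceGenome
) -> EffectAnnotation:
    offset = _cds_offset(gene, variant.pos)
    if offset is None:
        return EffectAnnotation(gene.gene_id, "intron_or_utr", "MODIFIER")
    cds = spliced_cds(gene, genome)
    codon_index = offset // 3 + 1
    within = offset % 3
    ref_codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    alt_base = variant.alt if gene.strand == "+" else COMPLEMENT[variant.alt]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate(table=standard_dna_table))
    alt_aa = str(Seq(alt_codon).translate(table=standard_dna_table))
    if ref_aa == alt_aa:
        vtype = "synonymous_variant"
    elif alt_aa == "*":
        vtype = "stop_gained"
    elif ref_aa == "*":
        vtype = "stop_lost"
    else:
        vtype = "missense_variant"
    return EffectAnnotation(
        gene_id=gene.gene_id,
        variant_type=vtype,
        impact=IMPACT_OF_TYPE[vtype],
        hgvs_p=format_hgvs_p(ref_aa, codon_index, alt_aa),
        codon_index=codon_index,
    )


def classify_variant(
    variant: VariantCall,
    gene_models: list[GeneModel],
    genome: ReferenceGenome,
) -> EffectAnnotation:
    """Classify one SNP against all overlapping genes, keeping the
    highest-impact annotation (ties broken by lowest gene id).

    The variant's reference allele must match the genome at its position;
    a mismatch is a data-integrity error naming the site.
    """
    genome_base = genome.base(variant.chrom, variant.pos)
    if genome_base != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"call says {variant.ref}, genome has {genome_base}"
        )
    hits = [
        g
        for g in gene_models
        if g.chrom == variant.chrom and g.contains(variant.pos)
    ]
    if not hits:
        return EffectAnnotation("", "intergenic", "MODIFIER")
    annotations = [_classify_in_gene(variant, g, genome) for g in hits]
    annotations.sort(key=lambda a: (_IMPACT_RANK[a.impact], a.gene_id))
    return annotations[0]


def rank_candidates(
    shared_set: set[VariantCall],
    annotations: dict[tuple[str, int, str, str], EffectAnnotation],
) -> pd.DataFrame:
    """Protein-altering candidates as a table, HIGH impact first then position.

    Columns mirror the candidate-variant table of a mapping-by-sequencing
    report: Chr, Position, Ref, Alt, Variant type, Impact, Effect, Gene ID.
    """
    rows = []
    for call in sorted(shared_set, key=lambda c: (c.chrom, c.pos)):
        ann = annotations[call.key]
        if ann.impact not in {"HIGH", "MODERATE"}:
            continue
        rows.append(
            {
                "Chr": call.chrom,
                "Position": call.pos,
                "Ref": call.ref,
                "Alt": call.alt,
                "Variant type": ann.variant_type,
                "Impact": ann.impact,
                "Effect": ann.hgvs_p,
                "Gene ID": ann.gene_id,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["Chr", "Position", "Ref", "Alt", "Variant type", "Impact", "Effect", "Gene ID"],
    )
    if len(df):
        df["_rank"] = df["Impact"].map(_IMPACT_RANK)
        df = (
            df.sort_values(["_rank", "Chr", "Position"])
            .drop(columns="_rank")
            .reset_index(drop=True)
        )
    return df
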