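"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO, VCF through pysam.VariantFile, GFF3 through
gffutils; the blacklist and read-observation tables are plain TSV/BED read
with pandas.  All coordinates are converted to the package's internal
1-based inclusive convention on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

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

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_blacklist",
    "read_gff3",
    "read_observations_tsv",
    "write_observations_tsv",
    "VcfReadStats",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a reference genome; one chromosome per record, order preserved.

    Lowercase bases are normalised to uppercase.  An empty file yields an
    empty genome with a logged warning.
    """
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    except (ValueError, AssertionError) as exc:  # biopython parse failures
        raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    if not records:
        # Distinguish truly empty from garbage that SeqIO silently skips.
        text = path.read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            first_line = text.strip().splitlines()[0]
            raise FormatError(f"{path}: not FASTA, first line {first_line!r}")
        logger.warning("%s: empty FASTA, returning empty genome", path)
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass
class VcfReadStats:
    """Counts of records accepted and skipped while reading a VCF."""

    n_snp: int = 0
    n_skipped_indel: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_other: int = 0


def read_vcf(
    path: str | Path,
    role: str,
    sample_id: str | None = None,
    stats: VcfReadStats | None = None,
) -> PoolVariantSet:
    """Read per-sample SNP calls from a VCF with FORMAT/AD allelic depths.

    Biallelic SNP records become :class:`VariantCall`; indel and
    multi-allelic records are skipped with a counted warning.  Depth and
    allele frequency are recomputed from the AD field (ref + alt depths); a
    record without AD is a format error.
    """
    path = Path(path)
    stats = stats if stats is not None else VcfReadStats()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pysam warns on index absence
        vf = pysam.VariantFile(str(path))
    if sample_id is None:
        sample_id = list(vf.header.samples)[0] if list(vf.header.samples) else path.stem
    pool = PoolVariantSet(sample_id, role)
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            stats.n_skipped_multiallelic += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1:
            stats.n_skipped_indel += 1
            continue
        if ref not in "ACGT" or alt not in "ACGT":
            stats.n_skipped_other += 1
            continue
        ad = None
        if rec.samples:
            sample = rec.samples[0]
            ad = sample.get("AD")
        if ad is None or any(a is None for a in ad):
            raise FormatError(
                f"{path}: record {rec.chrom}:{rec.pos} lacks the AD allelic-depth field"
            )
        ref_depth, alt_depth = int(ad[0]), int(ad[1])
        depth = ref_depth + alt_depth
        if depth < 1:
            stats.n_skipped_other += 1
            continue
        pool.add(
            VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                depth=depth,
                alt_depth=alt_depth,
            )
        )
        stats.n_snp += 1
    n_skip = stats.n_skipped_indel + stats.n_skipped_multiallelic + stats.n_skipped_other
    if n_skip:
        logger.warning("%s: skipped %d non-SNP/multi-allelic records", path, n_skip)
    return pool


def write_vcf(
    pool: PoolVariantSet,
    path: str | Path,
    genome: ReferenceGenome | None = None,
) -> None:
    """Write a single-sample VCF v4.2 with FORMAT AD/DP, sorted by (chrom, pos).

    Round-trip contract: ``read_vcf(write_vcf(p))`` reproduces the call set
    exactly.  Contig lengths come from ``genome`` when supplied.
    """
    header = pysam.VariantHeader()
    contigs: list[str] = []
    if genome is not None:
        for name, seq in genome:
            contigs.append(name)
            header.contigs.add(name, length=len(seq))
    else:
        seen = set()
        for call in pool:  # genome order unknown: fall back to sorted call order
            if call.chrom not in seen:
                seen.add(call.chrom)
                contigs.append(call.chrom)
                header.contigs.add(call.chrom)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Read depth (ref + alt)")
    header.add_sample(pool.sample_id)
    order = {c: i for i, c in enumerate(contigs)}
    calls = sorted(pool.calls.values(), key=lambda c: (order.get(c.chrom, 1 << 30), c.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos,
                alleles=(call.ref, call.alt),
            )
            rec.samples[0]["AD"] = (call.depth - call.alt_depth, call.alt_depth)
            rec.samples[0]["DP"] = call.depth
            out.write(rec)


def read_blacklist(path: str | Path) -> SiteBlacklist:
    """Read error-prone sites from BED (0-based half-open) or 2-column TSV.

    A file whose lines have >= 3 columns with integer second and third fields
    is treated as BED and every base in each interval becomes a site
    (``Chr1 9 10`` -> (Chr1, 10)).  Two-column files are (chrom, 1-based pos).
    """
    path = Path(path)
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 3:
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{i}: bad BED interval") from exc
                if end <= start:
                    raise FormatError(f"{path}:{i}: empty/negative BED interval")
                sites.update((fields[0], p) for p in range(start + 1, end + 1))
            elif len(fields) == 2:
                try:
                    sites.add((fields[0], int(fields[1])))
                except ValueError as exc:
                    raise FormatError(f"{path}:{i}: bad TSV position") from exc
            else:
                raise FormatError(f"{path}:{i}: expected 2 (TSV) or >=3 (BED) columns")
    return SiteBlacklist(frozenset(sites))


def write_blacklist_bed(blacklist: SiteBlacklist, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in sorted(blacklist.sites):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Assemble gene models (strand + sorted CDS segments) from a GFF3 file.

    CDS features are grouped by their parent gene (through mRNA parents when
    present).  A gene whose total CDS length is not divisible by 3 raises a
    validation error naming the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        segs = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="CDS")
        )
        if not segs:
            continue
        try:
            genes.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    cds_segments=tuple(segs),
                    start=gene.start,
                    end=gene.end,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/CDS features for the simulator's planted genes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            # Phase of each CDS segment follows from the bases already used.
            used = 0
            segs = g.cds_segments if g.strand == "+" else g.cds_segments[::-1]
            phased = {}
            for s, e in segs:
                phased[(s, e)] = (3 - used % 3) % 3
                used += e - s + 1
            for s, e in g.cds_segments:
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phased[(s, e)]}\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )


def read_observations_tsv(path: str | Path) -> list[ReadObservation]:
    """Read the per-read allele table (read_id, chrom, pos, allele)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "chrom": str})
    expected = ["read_id", "chrom", "pos", "allele"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    reads = []
    for read_id, grp in df.groupby("read_id", sort=True):
        obs = tuple(
            (row.chrom, int(row.pos), row.allele) for row in grp.itertuples()
        )
        reads.append(ReadObservation(read_id=read_id, observations=obs))
    return reads


def write_observations_tsv(reads: Iterable[ReadObservation], path: str | Path) -> None:
    rows = [
        {"read_id": r.read_id, "chrom": c, "pos": p, "allele": a}
        for r in reads
        for c, p, a in r.observations
    ]
    pd.DataFrame(rows, columns=["read_id", "chrom", "pos", "allele"]).to_csv(
        path, sep="\t", index=False
    )
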