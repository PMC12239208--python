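"""Shared domain types for the EMS-screen mapping pipeline.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention); BED input
is converted on read.  Only single-nucleotide variants are modelled: the
analysis targets EMS-induced point mutations, which are overwhelmingly
G:C -> A:T transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ReferenceGenome",
    "GeneModel",
    "VariantCall",
    "PoolVariantSet",
    "SiteBlacklist",
    "ReadObservation",
    "ValidationError",
    "DNA_ALPHABET",
    "COMPLEMENT",
    "revcomp",
]

DNA_ALPHABET = frozenset("ACGTN")
_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ValidationError(ValueError):
    """Raised when an input object violates a data-model invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class ReferenceGenome:
    """Ordered, named chromosome sequences.

    Sequences are upper-case over {A, C, G, T, N}; other IUPAC ambiguity
    codes are rejected so that foreign data fails fast.
    """

    def __init__(self, chromosomes: Iterable[tuple[str, str]]):
        self._names: list[str] = []
        self._seqs: dict[str, str] = {}
        for name, seq in chromosomes:
            if name in self._seqs:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            self._names.append(name)
            self._seqs[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self._seqs[n]) for n in self._names}

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for n in self._names:
            yield n, self._seqs[n]

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self._seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise ValidationError(f"position {chrom}:{pos} outside chromosome bounds")
        return seq[pos - 1]

    def chrom_index(self, chrom: str) -> int:
        """Rank of a chromosome in genome order (used for tie-breaking)."""
        return self._names.index(chrom)

    def with_sequence(self, chrom: str, seq: str) -> "ReferenceGenome":
        """Return a copy with one chromosome's sequence replaced."""
        return ReferenceGenome(
            (n, seq if n == chrom else s) for n, s in self
        )


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: strand plus ordered, disjoint CDS segments.

    ``start``/``end`` give the full gene extent (UTRs included when the
    source annotation provides them); positions inside the extent but outside
    every CDS segment are intronic/UTR for annotation purposes.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    start: int = 0
    end: int = 0

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.cds_segments:
            raise ValidationError(f"gene {self.gene_id}: no CDS segments")
        prev_end = 0
        for s, e in self.cds_segments:
            if s < 1 or e < s:
                raise ValidationError(f"gene {self.gene_id}: bad CDS segment ({s}, {e})")
            if s <= prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: CDS segments overlap or are unsorted"
                )
            prev_end = e
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if self.start == 0:
            object.__setattr__(self, "start", self.cds_segments[0][0])
        if self.end == 0:
            object.__setattr__(self, "end", self.cds_segments[-1][1])
        if self.start > self.cds_segments[0][0] or self.end < self.cds_segments[-1][1]:
            raise ValidationError(f"gene {self.gene_id}: CDS outside gene extent")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)


@dataclass(frozen=True)
class VariantCall:
    """A biallelic SNP observation in one pooled or sector sample.

    ``depth`` is the number of reads supporting either allele (the sum of the
    VCF AD field); ``allele_frequency`` is always recomputed as
    alt_depth/depth, never trusted from an INFO annotation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_depth: int

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: alleles must be single bases, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref == alt")
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.depth < 1 or not 0 <= self.alt_depth <= self.depth:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: bad depths {self.alt_depth}/{self.depth}"
            )

    @property
    def allele_frequency(self) -> float:
        return self.alt_depth / self.depth

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Full allele identity, used for exact-match set operations."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def is_ems_transition(self) -> bool:
        """Canonical EMS spectrum: G>A or C>T on the reference strand."""
        return (self.ref, self.alt) in {("G", "A"), ("C", "T")}


# Valid sample roles for a PoolVariantSet.
POOL_ROLES = frozenset(
    {"mutant_pool", "wildtype_pool", "sterile_sector", "fertile_sector"}
)


class PoolVariantSet:
    """All SNP calls for one pooled (or sector) sample, keyed by site."""

    def __init__(self, sample_id: str, role: str, calls: Iterable[VariantCall] = ()):
        if role not in POOL_ROLES:
            raise ValidationError(f"unknown sample role {role!r}")
        self.sample_id = sample_id
        self.role = role
        self._calls: dict[tuple[str, int], VariantCall] = {}
        for c in calls:
            self.add(c)

    def add(self, call: VariantCall) -> None:
        if call.site in self._calls:
            raise ValidationError(
                f"{self.sample_id}: duplicate call at {call.chrom}:{call.pos}"
            )
        self._calls[call.site] = call

    @property
    def calls(self) -> Mapping[tuple[str, int], VariantCall]:
        return self._calls

    def get(self, chrom: str, pos: int) -> VariantCall | None:
        return self._calls.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(sorted(self._calls.values(), key=lambda c: c.site))

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Reject calls on chromosomes absent from the reference."""
        for c in self._calls.values():
            if c.chrom not in genome:
                raise ValidationError(
                    f"{self.sample_id}: call on unknown chromosome {c.chrom!r}"
                )


@dataclass(frozen=True)
class SiteBlacklist:
    """Experimentally determined error-prone sites to exclude outright."""

    sites: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        for chrom, pos in self.sites:
            if pos < 1:
                raise ValidationError(f"blacklist site {chrom}:{pos} has position < 1")

    def __contains__(self, site: tuple[str, int]) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class ReadObservation:
    """Alleles observed on a single sequencing read at covered variant sites."""

    read_id: str
    observations: tuple[tuple[str, int, str], ...]

    def __post_init__(self):
        seen = set()
        for chrom, pos, allele in self.observations:
            if allele not in _BASES:
                raise ValidationError(
                    f"read {self.read_id}: allele {allele!r} at {chrom}:{pos}"
                )
            if (chrom, pos) in seen:
                raise ValidationError(
                    f"read {self.read_id}: duplicate observation at {chrom}:{pos}"
                )
            seen.add((chrom, pos))

    def allele_at(self, chrom: str, pos: int) -> str | None:
        for c, p, a in self.observations:
            if c == chrom and p == pos:
                return a
        return None
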