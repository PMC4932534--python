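"""Core in-memory records shared by every pipeline stage.

Coordinate conventions
----------------------
GFF and VCF positions are 1-based closed, as in the formats themselves.
Depth intervals and all mask arithmetic are 0-based half-open (BED).
Conversion happens only at read/write boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class StructureError(ValueError):
    """Structurally invalid annotation (e.g. a CDS row with no parent gene)."""


class ConsistencyError(ValueError):
    """Inputs disagree with each other (e.g. VCF REF vs. reference genome)."""


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence (a linkage group or the pooled 'Un' scaffold)."""

    sequence_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CdsSegment:
    """One CDS piece, 1-based closed genome coordinates, with a GFF phase."""

    start: int
    end: int
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A stranded, spliced protein-coding gene in genome coordinates.

    ``exons`` and ``cds_segments`` are kept in ascending genome order
    regardless of strand; translation order for minus-strand genes is the
    reverse. ``flags`` collects repair warnings (e.g. a CDS whose total
    length is not a multiple of three).
    """

    gene_id: str
    sequence_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[CdsSegment]
    gene_span: tuple[int, int]
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments, key=lambda s: s.start)

    @property
    def cds_length(self) -> int:
        return sum(s.length for s in self.cds_segments)

    def segments_in_translation_order(self) -> list[CdsSegment]:
        return self.cds_segments if self.strand == "+" else self.cds_segments[::-1]


@dataclass(frozen=True)
class GenotypeCall:
    """Alleles observed in one accession's pool (four haploid genomes)."""

    present: bool
    observed_alleles: frozenset[str] = frozenset()

    @property
    def n_alleles(self) -> int:
        return len(self.observed_alleles)


@dataclass
class VariantRecord:
    """One called locus with per-accession pooled genotypes."""

    sequence_id: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    quality: float
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError("a variant needs at least one alternate allele")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("alternate alleles must differ from the reference")
        if self.quality < 0:
            raise ValueError("Phred quality must be non-negative")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.sequence_id, self.position)

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)


@dataclass(frozen=True)
class DepthInterval:
    """Per-base read depth summarised over a 0-based half-open interval."""

    sequence_id: str
    start: int
    end: int
    depth: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"depth interval {self.sequence_id}:{self.start}-{self.end} is empty"
            )
        if self.depth < 0:
            raise FormatError("read depth cannot be negative")


def genome_lookup(sequences: list[GenomeSequence]) -> dict[str, GenomeSequence]:
    """Index sequences by id, rejecting duplicates."""
    out: dict[str, GenomeSequence] = {}
    for seq in sequences:
        if seq.sequence_id in out:
            raise FormatError(f"duplicate sequence id {seq.sequence_id!r}")
        out[seq.sequence_id] = seq
    return out


def reference_base(
    sequences: Mapping[str, GenomeSequence], sequence_id: str, position: int, length: int = 1
) -> Optional[str]:
    """Reference residues at a 1-based position, or None if out of range."""
    seq = sequences.get(sequence_id)
    if seq is None:
        return None
    if position < 1 or position + length - 1 > seq.length:
        return None
    return seq.residues[position - 1 : position - 1 + length]
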