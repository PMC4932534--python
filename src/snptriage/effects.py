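"""Miniature variant-effect predictor over repaired gene models.

Each variant is classified against every gene model within a configurable
flank (5 kb by default) by translating through the spliced CDS with the
standard genetic code. Categories follow the snpEff-style taxonomy used
throughout downstream triage:

HIGH      frameshift, start_lost, stop_gained, stop_lost, splice_site
MODERATE  missense, inframe_indel
LOW       synonymous
MODIFIER  upstream_5kb, downstream_5kb, intron, intergenic
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .records import ConsistencyError, GeneModel, GenomeSequence, VariantRecord

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a nucleotide CDS (length divisible by 3) incl. terminal *."""
    return "".join(CODON_TO_AA.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3))


CATEGORIES = (
    "frameshift",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_site",
    "missense",
    "inframe_indel",
    "synonymous",
    "intron",
    "upstream_5kb",
    "downstream_5kb",
    "intergenic",
)

IMPACT_OF_CATEGORY: dict[str, str] = {
    "frameshift": "HIGH",
    "start_lost": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "splice_site": "HIGH",
    "missense": "MODERATE",
    "inframe_indel": "MODERATE",
    "synonymous": "LOW",
    "upstream_5kb": "MODIFIER",
    "downstream_5kb": "MODIFIER",
    "intron": "MODIFIER",
    "intergenic": "MODIFIER",
}

_IMPACT_RANK = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}


def severity_key(category: str) -> tuple[int, int]:
    """Sort key: higher = more severe (impact first, then category order)."""
    return (_IMPACT_RANK[IMPACT_OF_CATEGORY[category]], -_CATEGORY_RANK[category])


@dataclass(frozen=True)
class AnnotationConfig:
    flank: int = 5000  # bp from the gene span still annotated as up/downstream
    splice_window: int = 2  # bp into the intron counted as splice site

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.splice_window <= 0:
            raise ValueError("flank and splice_window must be positive")


@dataclass(frozen=True)
class EffectAnnotation:
    sequence_id: str
    position: int
    gene_id: Optional[str]  # None for intergenic
    category: str
    alt_allele: Optional[str] = None
    aa_change: Optional[tuple[str, int, str]] = None  # (ref res, protein pos, alt res)

    @property
    def impact(self) -> str:
        return IMPACT_OF_CATEGORY[self.category]

    def aa_change_str(self) -> Optional[str]:
        if self.aa_change is None:
            return None
        ref, pos, alt = self.aa_change
        return f"{ref}{pos}{alt}"


# ---------------------------------------------------------------------------
# coordinate helpers on gene models


def cds_offset(model: GeneModel, position: int) -> Optional[int]:
    """0-based offset of a genome position within the spliced CDS, in
    translation order; None when the position is not coding."""
    offset = 0
    for seg in model.segments_in_translation_order():
        if seg.start <= position <= seg.end:
            if model.strand == "+":
                return offset + (position - seg.start)
            return offset + (seg.end - position)
        offset += seg.length
    return None


def genome_position_at_cds_offset(model: GeneModel, offset: int) -> int:
    """Inverse of :func:`cds_offset` (1-based genome position)."""
    for seg in model.segments_in_translation_order():
        if offset < seg.length:
            if model.strand == "+":
                return seg.start + offset
            return seg.end - offset
        offset -= seg.length
    raise IndexError("CDS offset beyond coding length")


def spliced_cds(model: GeneModel, genome: Mapping[str, GenomeSequence]) -> str:
    """The CDS nucleotide sequence in translation order (revcomp on -)."""
    chrom = genome[model.sequence_id].residues
    parts = [chrom[seg.start - 1 : seg.end] for seg in model.cds_segments]
    if model.strand == "+":
        return "".join(parts)
    return "".join(reverse_complement(p) for p in reversed(parts))


# ---------------------------------------------------------------------------
# classification


def locate_variant(
    v: VariantRecord, model: GeneModel, config: AnnotationConfig = AnnotationConfig()
) -> str:
    """Positional class of a variant relative to one gene model.

    Returns one of coding / splice_site / intron / upstream_5kb /
    downstream_5kb / intergenic. The splice window counts bases on the
    intron side of each exon-intron boundary.
    """
    pos = v.position
    span_s, span_e = model.gene_span
    if pos < span_s or pos > span_e:
        if span_s - config.flank <= pos < span_s:
            left_side = True
        elif span_e < pos <= span_e + config.flank:
            left_side = False
        else:
            return "intergenic"
        upstream_is_left = model.strand == "+"
        return "upstream_5kb" if left_side == upstream_is_left else "downstream_5kb"

    for seg in model.cds_segments:
        if seg.start <= pos <= seg.end:
            return "coding"

    # intron side of each exon boundary
    for (xs, xe) in model.exons:
        if xs <= pos <= xe:
            # inside an exon but outside the CDS (UTR); treated at
            # intron/gene-body level — UTR subclasses are not modelled
            return "intron"
    for (_, prev_end), (next_start, _) in zip(model.exons, model.exons[1:]):
        if prev_end < pos < next_start:
            if pos - prev_end <= config.splice_window:
                return "splice_site"
            if next_start - pos <= config.splice_window:
                return "splice_site"
            return "intron"
    return "intron"


def translate_effect(
    v: VariantRecord,
    model: GeneModel,
    genome: Mapping[str, GenomeSequence],
    config: AnnotationConfig = AnnotationConfig(),
    alt_allele: Optional[str] = None,
) -> EffectAnnotation:
    """Coding-effect call for one variant x gene pair via codon comparison.

    SNPs are resolved by mutating the affected codon of the spliced CDS;
    indels by length arithmetic (frameshift iff length change mod 3 != 0).
    """
    alt = alt_allele if alt_allele is not None else v.alt_alleles[0]
    chrom = genome[model.sequence_id].residues
    ref_here = chrom[v.position - 1 : v.position - 1 + len(v.ref_allele)]
    if ref_here != v.ref_allele:
        raise ConsistencyError(
            f"{v.sequence_id}:{v.position}: REF {v.ref_allele!r} does not match "
            f"genome {ref_here!r}"
        )

    offset = cds_offset(model, v.position)
    if offset is None:
        raise ValueError("translate_effect requires a coding position")

    if len(v.ref_allele) != len(alt):
        # indel: frame arithmetic only
        delta = abs(len(alt) - len(v.ref_allele))
        codon_i = offset // 3
        cds = spliced_cds(model, genome)
        ref_aa = CODON_TO_AA.get(cds[codon_i * 3 : codon_i * 3 + 3], "X")
        if delta % 3 != 0:
            return EffectAnnotation(
                v.sequence_id, v.position, model.gene_id, "frameshift", alt,
                aa_change=(ref_aa, codon_i + 1, "fs"),
            )
        return EffectAnnotation(
            v.sequence_id, v.position, model.gene_id, "inframe_indel", alt,
            aa_change=(ref_aa, codon_i + 1, "del" if len(alt) < len(v.ref_allele) else "ins"),
        )

    cds = spliced_cds(model, genome)
    codon_i, within = divmod(offset, 3)
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_base = alt if model.strand == "+" else reverse_complement(alt)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = CODON_TO_AA.get(ref_codon, "X")
    alt_aa = CODON_TO_AA.get(alt_codon, "X")

    if codon_i == 0 and cds[:3] == "ATG" and alt_codon != "ATG":
        category = "start_lost"
    elif ref_aa == "*" and alt_aa != "*":
        category = "stop_lost"
    elif alt_aa == "*" and ref_aa != "*":
        category = "stop_gained"
    elif ref_aa == alt_aa:
        category = "synonymous"
    else:
        category = "missense"
    return EffectAnnotation(
        v.sequence_id, v.position, model.gene_id, category, alt,
        aa_change=(ref_aa, codon_i + 1, alt_aa),
    )


class _GeneIndex:
    """Per-sequence gene lookup by span with flank expansion."""

    def __init__(self, models: Sequence[GeneModel], flank: int):
        self.flank = flank
        self.by_seq: dict[str, list[GeneModel]] = {}
        for m in models:
            self.by_seq.setdefault(m.sequence_id, []).append(m)
        self.starts: dict[str, list[int]] = {}
        self.max_span: dict[str, int] = {}
        for seq, ms in self.by_seq.items():
            ms.sort(key=lambda m: m.gene_span[0])
            self.starts[seq] = [m.gene_span[0] for m in ms]
            self.max_span[seq] = max(m.gene_span[1] - m.gene_span[0] + 1 for m in ms)

    def near(self, sequence_id: str, position: int) -> list[GeneModel]:
        ms = self.by_seq.get(sequence_id)
        if not ms:
            return []
        lo = position - self.flank - self.max_span[sequence_id]
        i = bisect_left(self.starts[sequence_id], lo)
        out = []
        for m in ms[i:]:
            if m.gene_span[0] > position + self.flank:
                break
            if m.gene_span[0] - self.flank <= position <= m.gene_span[1] + self.flank:
                out.append(m)
        return out


def annotate_variant(
    v: VariantRecord,
    models: Iterable[GeneModel],
    genome: Mapping[str, GenomeSequence],
    config: AnnotationConfig = AnnotationConfig(),
) -> list[EffectAnnotation]:
    """All annotations for one variant (one per nearby gene per alt allele,
    or a single intergenic annotation)."""
    out: list[EffectAnnotation] = []
    for model in models:
        where = locate_variant(v, model, config)
        if where == "intergenic":
            continue
        for alt in v.alt_alleles:
            if where == "coding":
                out.append(translate_effect(v, model, genome, config, alt_allele=alt))
            else:
                out.append(
                    EffectAnnotation(v.sequence_id, v.position, model.gene_id, where, alt)
                )
    if not out:
        out.append(
            EffectAnnotation(
                v.sequence_id, v.position, None, "intergenic", v.alt_alleles[0]
            )
        )
    return out


def annotate_all(
    records: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence],
    config: AnnotationConfig = AnnotationConfig(),
) -> list[EffectAnnotation]:
    """Annotate every variant against every gene within the flank."""
    index = _GeneIndex(models, config.flank) if models else None
    out: list[EffectAnnotation] = []
    for v in records:
        near = index.near(v.sequence_id, v.position) if index else []
        out.extend(annotate_variant(v, near, genome, config))
    return out


def representative_category(annotations: Iterable[EffectAnnotation]) -> str:
    """The severest category among a variant's annotations."""
    return max((a.category for a in annotations), key=severity_key)


def group_by_locus(
    annotations: Iterable[EffectAnnotation],
) -> dict[tuple[str, int], list[EffectAnnotation]]:
    grouped: dict[tuple[str, int], list[EffectAnnotation]] = {}
    for a in annotations:
        grouped.setdefault((a.sequence_id, a.position), []).append(a)
    return grouped


def summarize_impacts(annotations: Iterable[EffectAnnotation]) -> pd.DataFrame:
    """Per-variant category counts under severity precedence.

    Each variant contributes exactly one row-count, for its severest
    category (HIGH > MODERATE > LOW > MODIFIER); the table therefore sums
    to the number of distinct variant loci.
    """
    grouped = group_by_locus(annotations)
    counts: dict[str, int] = {}
    for anns in grouped.values():
        cat = representative_category(anns)
        counts[cat] = counts.get(cat, 0) + 1
    rows = [
        {"category": c, "impact": IMPACT_OF_CATEGORY[c], "n_variants": counts[c]}
        for c in CATEGORIES
        if c in counts
    ]
    return pd.DataFrame(rows, columns=["category", "impact", "n_variants"])
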