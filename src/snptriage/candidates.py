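"""Candidate-SNP prioritization funnel.

Given classified loci and effect annotations, the funnel keeps loci that
are (i) unique to a target accession, (ii) homozygous for the alternate
allele there (and homozygous reference in the others), (iii) of HIGH or
MODERATE coding impact, and (iv) inside a gene on a user-supplied
candidate list (e.g. anthocyanin biosynthesis and its MYB regulators).
Survivors are then ranked by whether the substitution crosses amino-acid
property classes and whether it hits a conserved alignment column.

The amino-acid property table ships with the pipeline's house convention:
glycine is grouped with the polar residues. Pass a custom ``table`` to any
classifier to override it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .classify import AccessionProfile
from .effects import EffectAnnotation

# one fixed table covering all 20 standard residues
AA_CLASS_TABLE: dict[str, str] = {
    **{aa: "nonpolar" for aa in "AVLIPFMW"},
    **{aa: "polar" for aa in "GSTCYNQ"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "acidic" for aa in "DE"},
}


@dataclass(frozen=True)
class AASubstitution:
    ref_residue: str
    protein_position: int
    alt_residue: str
    ref_class: str
    alt_class: str

    @property
    def class_changing(self) -> bool:
        return self.ref_class != self.alt_class

    def __str__(self) -> str:
        return f"{self.ref_residue}{self.protein_position}{self.alt_residue}"


def classify_substitution(
    ref_residue: str,
    protein_position: int,
    alt_residue: str,
    table: Optional[Mapping[str, str]] = None,
) -> AASubstitution:
    """Property-class call for a single-residue substitution."""
    table = AA_CLASS_TABLE if table is None else table
    for res in (ref_residue, alt_residue):
        if res not in table:
            raise ValueError(f"nonstandard amino-acid residue {res!r}")
    return AASubstitution(
        ref_residue=ref_residue,
        protein_position=protein_position,
        alt_residue=alt_residue,
        ref_class=table[ref_residue],
        alt_class=table[alt_residue],
    )


@dataclass(frozen=True)
class ConservationScore:
    column_index: int  # 1-based alignment column
    query_residue: str
    identity_fraction: float  # non-query rows matching, gaps excluded
    threshold: float

    @property
    def conserved(self) -> bool:
        return self.identity_fraction >= self.threshold


Alignment = Sequence[tuple[str, str]]  # (sequence id, aligned residues)


def conservation_score(
    alignment: Alignment,
    query_id: str,
    query_position: int,
    threshold: float = 0.9,
) -> ConservationScore:
    """Identity of homolog residues at the column holding a query position.

    ``query_position`` is 1-based in the *ungapped* query; it is mapped
    through the query's gaps to an alignment column. The fraction counts
    homolog rows (the query itself is excluded) carrying the query residue,
    over homolog rows without a gap in that column.
    """
    rows = dict(alignment)
    if query_id not in rows:
        raise ValueError(f"query {query_id!r} not in alignment")
    query = rows[query_id]
    seen = 0
    column = None
    for col, res in enumerate(query):
        if res != "-":
            seen += 1
            if seen == query_position:
                column = col
                break
    if column is None:
        raise ValueError(
            f"query position {query_position} beyond ungapped query length {seen}"
        )
    query_res = query[column]
    matches = 0
    non_gap = 0
    for sid, seq in alignment:
        if sid == query_id:
            continue
        res = seq[column]
        if res == "-":
            continue
        non_gap += 1
        if res == query_res:
            matches += 1
    fraction = matches / non_gap if non_gap else 0.0
    return ConservationScore(
        column_index=column + 1,
        query_residue=query_res,
        identity_fraction=fraction,
        threshold=threshold,
    )


def read_alignment_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


@dataclass
class CandidateReport:
    gene_id: str
    sequence_id: str
    position: int
    substitution: Optional[AASubstitution]
    conservation: Optional[ConservationScore]
    flags: dict[str, Optional[bool]]  # filter name -> passed (None = not scored)

    @property
    def passes_all(self) -> bool:
        return all(v for v in self.flags.values())


FUNNEL_IMPACTS = frozenset({"HIGH", "MODERATE"})


def funnel(
    profiles: Sequence[AccessionProfile],
    annotations: Iterable[EffectAnnotation],
    gene_list: Sequence[str],
    target_accession: str,
    alignments: Optional[Mapping[str, Alignment]] = None,
    conservation_threshold: float = 0.9,
    table: Optional[Mapping[str, str]] = None,
) -> list[CandidateReport]:
    """Run the candidate funnel for one target accession.

    Emits one report per locus x listed gene passing the first three
    filters (unique+homozygous in target; HIGH/MODERATE; listed gene),
    ordered by sequence then position, with property-change and
    conservation flags for downstream ranking. ``alignments`` maps gene id
    to an aligned homolog set whose first row is the query protein; when a
    gene has no alignment its conservation flag is left unscored (None).
    The funnel is a pure conjunction: the order the filters are applied in
    cannot change the result.
    """
    if not gene_list:
        raise ValueError("the candidate gene list is empty")
    listed = set(gene_list)

    other_hom_ref = lambda p: all(  # noqa: E731
        z == "hom_ref" for a, z in p.zygosity.items() if a != target_accession
    )
    ann_by_locus: dict[tuple[str, int], list[EffectAnnotation]] = {}
    for a in annotations:
        ann_by_locus.setdefault((a.sequence_id, a.position), []).append(a)

    reports: list[CandidateReport] = []
    for p in sorted(profiles, key=lambda p: (p.sequence_id, p.position)):
        if p.uniqueness != target_accession:
            continue
        if p.zygosity.get(target_accession) != "hom_alt" or not other_hom_ref(p):
            continue
        for ann in ann_by_locus.get(p.locus, []):
            if ann.impact not in FUNNEL_IMPACTS:
                continue
            if ann.gene_id not in listed:
                continue
            substitution = None
            class_flag: Optional[bool] = None
            if ann.aa_change is not None:
                ref_res, pos, alt_res = ann.aa_change
                if len(ref_res) == 1 and len(alt_res) == 1 and alt_res != "*":
                    substitution = classify_substitution(ref_res, pos, alt_res, table)
                    class_flag = substitution.class_changing
                else:
                    # truncating / frame-changing: property class not applicable,
                    # treat as passing (a knockout is at least as disruptive)
                    class_flag = True
            conservation = None
            cons_flag: Optional[bool] = None
            if (
                alignments is not None
                and ann.gene_id in alignments
                and substitution is not None
            ):
                aln = alignments[ann.gene_id]
                query_id = aln[0][0]
                conservation = conservation_score(
                    aln, query_id, substitution.protein_position, conservation_threshold
                )
                cons_flag = conservation.conserved
            reports.append(
                CandidateReport(
                    gene_id=ann.gene_id,
                    sequence_id=p.sequence_id,
                    position=p.position,
                    substitution=substitution,
                    conservation=conservation,
                    flags={
                        "unique_homozygous": True,
                        "impact": True,
                        "in_gene_list": True,
                        "class_changing": class_flag,
                        "conserved": cons_flag,
                    },
                )
            )
    return reports


def isolate_candidates(reports: Iterable[CandidateReport]) -> list[CandidateReport]:
    """Reports passing every funnel flag, including property change and
    conservation."""
    return [r for r in reports if r.passes_all]


def predict_f1(parent1_genotype: str, parent2_genotype: str) -> str:
    """Fruit-colour phenotype of the F1 of a cross at the colour locus.

    Alleles are G (functional, red, dominant) and C (loss-of-function
    substitution, yellow, recessive). Red requires at least one G allele.
    Returns "red", "yellow", or "segregating" when heterozygous parents
    make both outcomes possible.
    """
    for geno in (parent1_genotype, parent2_genotype):
        if len(geno) != 2 or any(a not in "GC" for a in geno):
            raise ValueError(f"unknown allele symbol in genotype {geno!r}")
    phenos = {
        "red" if "G" in (a + b) else "yellow"
        for a in set(parent1_genotype)
        for b in set(parent2_genotype)
    }
    return phenos.pop() if len(phenos) == 1 else "segregating"
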