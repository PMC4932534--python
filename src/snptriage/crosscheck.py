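"""Brute-force re-translation cross-check for coding SNP effect calls.

This module classifies a coding SNP by the most literal route available:
apply the substitution to a copy of the whole chromosome, re-extract the
spliced CDS from the mutated copy by coordinates, translate both proteins
in full, and diff them. It shares no codon-offset arithmetic with
:mod:`snptriage.effects`, so agreement between the two routes is a real
end-to-end check of the annotator's coordinate and strand handling.
"""

from __future__ import annotations

from typing import Mapping

from .records import GeneModel, GenomeSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TABLE = {}


def _codon_table() -> dict[str, str]:
    global _TABLE
    if not _TABLE:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        t = unambiguous_dna_by_id[1]
        _TABLE = dict(t.forward_table)
        _TABLE.update({c: "*" for c in t.stop_codons})
    return _TABLE


def _extract_and_translate(chrom: str, model: GeneModel) -> str:
    pieces = [chrom[seg.start - 1 : seg.end] for seg in model.cds_segments]
    cds = "".join(pieces)
    if model.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    table = _codon_table()
    return "".join(
        table.get(cds[i : i + 3], "X") for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def classify_coding_snp_by_retranslation(
    sequence_id: str,
    position: int,
    ref: str,
    alt: str,
    model: GeneModel,
    genome: Mapping[str, GenomeSequence],
) -> str:
    """Category of a coding SNP from full mutate-translate-diff.

    Returns one of synonymous / missense / start_lost / stop_gained /
    stop_lost (the only categories a single coding substitution can give).
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("re-translation cross-check handles single-base SNPs only")
    chrom = genome[sequence_id].residues
    if chrom[position - 1] != ref:
        raise ValueError(f"reference mismatch at {sequence_id}:{position}")
    mutated = chrom[: position - 1] + alt + chrom[position:]

    p_ref = _extract_and_translate(chrom, model)
    p_alt = _extract_and_translate(mutated, model)

    if p_ref and p_ref[0] == "M" and (not p_alt or p_alt[0] != "M"):
        return "start_lost"
    if p_ref == p_alt:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
    i = diffs[0]
    if p_ref[i] == "*":
        return "stop_lost"
    if p_alt[i] == "*":
        return "stop_gained"
    return "missense"
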