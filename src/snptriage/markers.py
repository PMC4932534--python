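"""Accession-discriminating indel marker selection.

From a table of called insertion/deletion polymorphisms, keep those whose
alternate allele is carried by exactly one accession and whose length
difference is resolvable on a gel (>= 20 bp by default, suitable for 1%
agarose), then report the expected PCR amplicon length per accession for
a primer window spanning the indel. An F1 hybrid shows both parental
bands (heterozygous) at the marker discriminating either parent, so a set
with one marker per accession assigns every accession a unique
band-pattern triple and flags hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

ALLELE_STATES = ("ref", "alt", "het", "missing")

DEFAULT_MIN_SIZE_DIFF = 20
DEFAULT_WINDOW_PAD = 150  # bp either side of the indel


@dataclass(frozen=True)
class IndelRecord:
    sequence_id: str
    position: int  # 1-based anchor
    ref_length: int
    alt_length: int
    alleles: Mapping[str, str]  # accession -> one of ALLELE_STATES

    def __post_init__(self) -> None:
        if self.ref_length < 0 or self.alt_length < 0:
            raise ValueError("allele lengths cannot be negative")
        if abs(self.ref_length - self.alt_length) < 1:
            raise ValueError("an indel must change the allele length")
        for state in self.alleles.values():
            if state not in ALLELE_STATES:
                raise ValueError(f"unknown allele state {state!r}")

    @property
    def size_diff(self) -> int:
        return abs(self.alt_length - self.ref_length)

    @property
    def length_shift(self) -> int:
        return self.alt_length - self.ref_length


def _carriers(indel: IndelRecord) -> list[str]:
    return [a for a, s in indel.alleles.items() if s in ("alt", "het")]


def select_discriminating_indels(
    indels: Iterable[IndelRecord],
    accession_ids: Sequence[str],
    min_size_diff: int = DEFAULT_MIN_SIZE_DIFF,
) -> list[IndelRecord]:
    """Indels where exactly one accession carries the alternate allele and
    the length difference is at least ``min_size_diff``; loci with any
    missing call are excluded."""
    out = []
    for indel in indels:
        states = [indel.alleles.get(a, "missing") for a in accession_ids]
        if "missing" in states:
            continue
        if indel.size_diff < min_size_diff:
            continue
        if len(_carriers(indel)) == 1:
            out.append(indel)
    return out


def discriminated_accession(indel: IndelRecord) -> str:
    carriers = _carriers(indel)
    if len(carriers) != 1:
        raise ValueError("indel does not discriminate a single accession")
    return carriers[0]


def amplicon_lengths(
    indel: IndelRecord, primer_window: tuple[int, int]
) -> dict[str, tuple[int, ...]]:
    """Expected amplicon length(s) per accession for a 1-based closed
    primer window containing the indel.

    Reference-allele carriers amplify the raw window span; alternate
    carriers shift by (alt_length - ref_length); heterozygous carriers
    produce both bands.
    """
    w_start, w_end = primer_window
    span = w_end - w_start + 1
    if not (w_start <= indel.position <= w_end):
        raise ValueError(
            f"indel at {indel.position} outside primer window {primer_window}"
        )
    out: dict[str, tuple[int, ...]] = {}
    for acc, state in indel.alleles.items():
        if state == "ref":
            out[acc] = (span,)
        elif state == "alt":
            out[acc] = (span + indel.length_shift,)
        elif state == "het":
            out[acc] = tuple(sorted({span, span + indel.length_shift}))
        else:
            out[acc] = ()
    return out


@dataclass
class MarkerDesign:
    indel: IndelRecord
    discriminates: str
    primer_window: tuple[int, int]
    amplicons: dict[str, tuple[int, ...]]
    resolvable: bool


def design_markers(
    indels: Iterable[IndelRecord],
    accession_ids: Sequence[str],
    min_size_diff: int = DEFAULT_MIN_SIZE_DIFF,
    window_pad: int = DEFAULT_WINDOW_PAD,
) -> list[MarkerDesign]:
    """Select discriminating indels and lay out default primer windows."""
    designs = []
    for indel in select_discriminating_indels(indels, accession_ids, min_size_diff):
        window = (max(1, indel.position - window_pad), indel.position + window_pad)
        designs.append(
            MarkerDesign(
                indel=indel,
                discriminates=discriminated_accession(indel),
                primer_window=window,
                amplicons=amplicon_lengths(indel, window),
                resolvable=indel.size_diff >= min_size_diff,
            )
        )
    return designs


def band_pattern(
    designs: Sequence[MarkerDesign], genotype: Mapping[str, str]
) -> tuple[tuple[int, ...], ...]:
    """Band sizes at each marker for an individual described by per-marker
    allele states (keys "{sequence_id}:{position}")."""
    pattern = []
    for d in designs:
        key = f"{d.indel.sequence_id}:{d.indel.position}"
        state = genotype[key]
        span = d.primer_window[1] - d.primer_window[0] + 1
        if state == "ref":
            pattern.append((span,))
        elif state == "alt":
            pattern.append((span + d.indel.length_shift,))
        elif state == "het":
            pattern.append(tuple(sorted({span, span + d.indel.length_shift})))
        else:
            pattern.append(())
    return tuple(pattern)


def accession_band_patterns(
    designs: Sequence[MarkerDesign], accession_ids: Sequence[str]
) -> dict[str, tuple[tuple[int, ...], ...]]:
    """Band-pattern triple per accession over the selected marker set."""
    out = {}
    for acc in accession_ids:
        genotype = {
            f"{d.indel.sequence_id}:{d.indel.position}": d.indel.alleles[acc]
            for d in designs
        }
        out[acc] = band_pattern(designs, genotype)
    return out


def f1_band_pattern(
    designs: Sequence[MarkerDesign], parent1: str, parent2: str
) -> tuple[tuple[int, ...], ...]:
    """Expected band pattern of an F1 between two (homozygous) accessions:
    heterozygous, hence two bands, wherever the parents differ."""
    genotype = {}
    for d in designs:
        key = f"{d.indel.sequence_id}:{d.indel.position}"
        s1, s2 = d.indel.alleles[parent1], d.indel.alleles[parent2]
        genotype[key] = s1 if s1 == s2 else "het"
    return band_pattern(designs, genotype)


INDEL_TABLE_COLUMNS = ["sequence_id", "position", "ref_length", "alt_length"]


def read_indel_table(path: str | Path, accession_ids: Sequence[str]) -> list[IndelRecord]:
    """TSV with columns sequence_id, position, ref_length, alt_length and
    one allele-state column per accession."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            IndelRecord(
                sequence_id=row["sequence_id"],
                position=int(row["position"]),
                ref_length=int(row["ref_length"]),
                alt_length=int(row["alt_length"]),
                alleles={a: row[a] for a in accession_ids},
            )
        )
    return records


def write_indel_table(
    indels: Iterable[IndelRecord], accession_ids: Sequence[str], path: str | Path
) -> None:
    rows = []
    for indel in indels:
        row = {
            "sequence_id": indel.sequence_id,
            "position": indel.position,
            "ref_length": indel.ref_length,
            "alt_length": indel.alt_length,
        }
        row.update({a: indel.alleles[a] for a in accession_ids})
        rows.append(row)
    pd.DataFrame(rows, columns=INDEL_TABLE_COLUMNS + list(accession_ids)).to_csv(
        path, sep="\t", index=False
    )
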