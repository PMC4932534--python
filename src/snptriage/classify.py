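"""Accession-level classification of variant loci.

A locus is *unique* to an accession when that accession carries an
alternate allele and both other accessions were explicitly called
homozygous reference there; a missing call in any accession disqualifies
the locus (labelled "none") rather than counting as absence, so coverage
gaps cannot inflate uniqueness. A locus is *heterozygous* in an accession
when more than one distinct allele was observed in its sequencing pool.

Also houses the closed-form inbreeding expectation: each generation of
selfing halves heterozygosity, so after g generations the progenitor's
heterozygous-site density is the observed density times 2^g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .effects import EffectAnnotation, group_by_locus, representative_category
from .records import GenotypeCall, VariantRecord

logger = logging.getLogger(__name__)

ZYGOSITY = ("hom_ref", "hom_alt", "het", "missing")


def zygosity_of_call(call: GenotypeCall, ref_allele: str) -> str:
    """het iff >1 distinct allele observed in the pool; else hom ref/alt."""
    if not call.present:
        return "missing"
    if call.n_alleles > 1:
        return "het"
    (allele,) = call.observed_alleles
    return "hom_ref" if allele == ref_allele else "hom_alt"


def _carries_alt(call: GenotypeCall, ref_allele: str) -> bool:
    return call.present and any(a != ref_allele for a in call.observed_alleles)


@dataclass
class AccessionProfile:
    sequence_id: str
    position: int
    zygosity: dict[str, str]  # accession -> zygosity label
    carries_alt: dict[str, bool]
    uniqueness: str  # accession id, "shared", or "none"

    @property
    def locus(self) -> tuple[str, int]:
        return (self.sequence_id, self.position)


def classify_zygosity(
    records: Iterable[VariantRecord], accession_ids: Sequence[str]
) -> list[dict[str, str]]:
    """Per-accession zygosity labels, one dict per record."""
    return [
        {acc: zygosity_of_call(r.genotypes[acc], r.ref_allele) for acc in accession_ids}
        for r in records
    ]


def classify_uniqueness(
    records: Iterable[VariantRecord], accession_ids: Sequence[str]
) -> list[AccessionProfile]:
    """Label every locus unique-to-one-accession / shared / none.

    A unique locus may be homozygous or heterozygous within its accession;
    both count, because uniqueness is about presence of the alternate
    allele, not about zygosity.
    """
    profiles: list[AccessionProfile] = []
    n_missing = 0
    for rec in records:
        for acc in accession_ids:
            if acc not in rec.genotypes:
                raise KeyError(f"accession {acc!r} has no genotype call column")
        zyg = {
            acc: zygosity_of_call(rec.genotypes[acc], rec.ref_allele)
            for acc in accession_ids
        }
        carries = {
            acc: _carries_alt(rec.genotypes[acc], rec.ref_allele)
            for acc in accession_ids
        }
        if any(z == "missing" for z in zyg.values()):
            uniqueness = "none"
            n_missing += 1
        else:
            carriers = [acc for acc in accession_ids if carries[acc]]
            if len(carriers) == 1:
                uniqueness = carriers[0]
            elif len(carriers) >= 2:
                uniqueness = "shared"
            else:
                uniqueness = "none"
        profiles.append(
            AccessionProfile(rec.sequence_id, rec.position, zyg, carries, uniqueness)
        )
    if n_missing:
        logger.info(
            "classify_uniqueness: %d loci with missing calls labelled 'none'", n_missing
        )
    return profiles


def pairwise_sharing(profiles: Sequence[AccessionProfile]) -> pd.DataFrame:
    """Symmetric matrix of loci where both accessions carry an alt allele."""
    accessions = list(profiles[0].carries_alt) if profiles else []
    mat = pd.DataFrame(0, index=accessions, columns=accessions, dtype=int)
    for p in profiles:
        carriers = [a for a, c in p.carries_alt.items() if c]
        for i, a in enumerate(carriers):
            for b in carriers[i:]:
                mat.loc[a, b] += 1
                if a != b:
                    mat.loc[b, a] += 1
    return mat


def intersect_labels(
    profiles: Sequence[AccessionProfile],
    annotations: Iterable[EffectAnnotation],
    accession: Optional[str] = None,
    want_unique: bool = False,
    want_het: bool = False,
    want_impacts: Optional[set[str]] = None,
) -> list[AccessionProfile]:
    """Conjunction of uniqueness / zygosity / impact predicates on loci.

    ``want_unique`` keeps loci unique to ``accession``; ``want_het`` keeps
    loci heterozygous in ``accession``; ``want_impacts`` keeps loci whose
    severest annotation impact is in the given set. With no predicates the
    input is returned unchanged (order preserved).
    """
    impact_by_locus: dict[tuple[str, int], str] = {}
    if want_impacts is not None:
        from .effects import IMPACT_OF_CATEGORY

        for locus, anns in group_by_locus(annotations).items():
            impact_by_locus[locus] = IMPACT_OF_CATEGORY[representative_category(anns)]

    out: list[AccessionProfile] = []
    for p in profiles:
        if want_unique and p.uniqueness != accession:
            continue
        if want_het and p.zygosity.get(accession) != "het":
            continue
        if want_impacts is not None and impact_by_locus.get(p.locus) not in want_impacts:
            continue
        out.append(p)
    return out


def high_impact_fraction(
    profiles: Sequence[AccessionProfile], annotations: Iterable[EffectAnnotation]
) -> dict[str, Optional[float]]:
    """Fraction of HIGH-impact loci overall and within each accession's
    heterozygous stratum (None where a stratum is empty).

    Comparable strata address whether heterozygosity shelters deleterious
    alleles: enrichment of HIGH calls among het loci would support it.
    """
    from .effects import IMPACT_OF_CATEGORY

    impact_by_locus = {
        locus: IMPACT_OF_CATEGORY[representative_category(anns)]
        for locus, anns in group_by_locus(annotations).items()
    }
    accessions = list(profiles[0].zygosity) if profiles else []
    n_all = len(profiles)
    n_high = sum(1 for p in profiles if impact_by_locus.get(p.locus) == "HIGH")
    out: dict[str, Optional[float]] = {
        "all": (n_high / n_all) if n_all else None
    }
    for acc in accessions:
        het = [p for p in profiles if p.zygosity[acc] == "het"]
        if not het:
            out[f"het_{acc}"] = None
            continue
        h = sum(1 for p in het if impact_by_locus.get(p.locus) == "HIGH")
        out[f"het_{acc}"] = h / len(het)
    return out


@dataclass(frozen=True)
class InbreedingExpectation:
    generations: int
    reduction_factor: int
    observed_locus_count: int
    genome_length: int
    mean_spacing: float  # bp between heterozygous loci today
    inferred_ancestral_spacing: int  # bp, rounded half away from zero


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def inbreeding_expectation(
    generations: int, observed_locus_count: int, genome_length: int
) -> InbreedingExpectation:
    """Project observed heterozygosity back through g generations of selfing.

    reduction_factor = 2^g; mean_spacing = genome_length / observed loci;
    the progenitor's expected spacing is mean_spacing / 2^g, rounded to
    whole base pairs.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if observed_locus_count <= 0 or genome_length <= 0:
        raise ValueError("locus count and genome length must be positive")
    factor = 2**generations
    spacing = genome_length / observed_locus_count
    return InbreedingExpectation(
        generations=generations,
        reduction_factor=factor,
        observed_locus_count=observed_locus_count,
        genome_length=genome_length,
        mean_spacing=spacing,
        inferred_ancestral_spacing=_round_half_away(spacing / factor),
    )
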