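"""Readers/writers for the standard formats the pipeline touches.

FASTA parsing goes through Biopython, GFF3 through gffutils, VCF through
cyvcf2; this module wraps them into the pipeline's own records and adds the
annotation repair step (CDS phase recomputation) that the upstream gene
annotation required before effect prediction.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .records import (
    CdsSegment,
    ConsistencyError,
    DepthInterval,
    FormatError,
    GeneModel,
    GenomeSequence,
    GenotypeCall,
    StructureError,
    VariantRecord,
    reference_base,
)

logger = logging.getLogger(__name__)

_IUPAC_DNA = set("ACGTNacgtn")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a DNA FASTA into :class:`GenomeSequence` records, in file order.

    Raises :class:`FormatError` naming the offending line for a malformed
    header or a residue outside {A,C,G,T,N}.
    """
    path = Path(path)
    with open(path) as fh:
        in_record = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if not line[1:].strip():
                    raise FormatError(f"{path}:{lineno}: FASTA header has no id")
                in_record = True
            else:
                if not in_record:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any FASTA header"
                    )
                bad = set(line) - _IUPAC_DNA
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC DNA residue(s) {sorted(bad)}"
                    )
    return [
        GenomeSequence(sequence_id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: Iterable[GenomeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.sequence_id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


_CONSUMED_FEATURES = {"gene", "mRNA", "exon", "CDS"}


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS rows of a GFF3 into :class:`GeneModel`s.

    Only the first mRNA of each gene is used (one isoform per gene is the
    working assumption of the whole pipeline). Other feature types are
    ignored with a logged count. A CDS row whose Parent chain does not reach
    a gene raises :class:`StructureError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    ignored = sum(
        1 for f in db.all_features() if f.featuretype not in _CONSUMED_FEATURES
    )
    if ignored:
        logger.info("read_gff: ignored %d rows of unconsumed feature types", ignored)

    gene_ids = {f.id for f in db.features_of_type("gene")}

    # every CDS must trace to a gene through its Parent chain
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds))
        if not any(p.featuretype == "gene" or p.id in gene_ids for p in parents):
            raise StructureError(
                f"CDS at {cds.seqid}:{cds.start}-{cds.end} has no parent gene"
            )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise FormatError(
                f"gene {gene.id}: unknown strand symbol {gene.strand!r}"
            )
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        carriers = mrnas[:1] if mrnas else [gene]
        exons: list[tuple[int, int]] = []
        cds: list[CdsSegment] = []
        for carrier in carriers:
            for ex in db.children(carrier, featuretype="exon", order_by="start"):
                exons.append((ex.start, ex.end))
            for c in db.children(carrier, featuretype="CDS", order_by="start"):
                phase = 0 if c.frame in (None, ".") else int(c.frame)
                cds.append(CdsSegment(start=c.start, end=c.end, phase=phase))
        if not exons:
            exons = [(s.start, s.end) for s in cds]
        models.append(
            GeneModel(
                gene_id=gene.id,
                sequence_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_segments=cds,
                gene_span=(gene.start, gene.end),
            )
        )
    return models


def write_gff(models: Iterable[GeneModel], path: str | Path, source: str = "snptriage") -> None:
    """Emit gene/mRNA/exon/CDS rows (the repaired copy of the annotation)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.gene_span
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.sequence_id}\t{source}\tgene\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{m.gene_id}.1"
            fh.write(
                f"{m.sequence_id}\t{source}\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for (xs, xe) in m.exons:
                fh.write(
                    f"{m.sequence_id}\t{source}\texon\t{xs}\t{xe}\t.\t{m.strand}\t.\t"
                    f"Parent={mrna_id}\n"
                )
            for seg in m.cds_segments:
                fh.write(
                    f"{m.sequence_id}\t{source}\tCDS\t{seg.start}\t{seg.end}\t.\t"
                    f"{m.strand}\t{seg.phase}\tParent={mrna_id}\n"
                )


FRAME_FLAG = "cds_length_not_multiple_of_3"


def repair_gff_phases(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Recompute CDS phases from segment lengths in translation order.

    The first segment (5' end of the transcript) gets phase 0; each later
    segment gets ``(3 - cumulative_length % 3) % 3``. Models whose total CDS
    length is not a multiple of three are flagged, never dropped. The
    operation is idempotent.
    """
    repaired: list[GeneModel] = []
    for m in models:
        segs = m.segments_in_translation_order()
        cum = 0
        new: list[CdsSegment] = []
        for seg in segs:
            phase = 0 if cum == 0 else (3 - cum % 3) % 3
            new.append(CdsSegment(start=seg.start, end=seg.end, phase=phase))
            cum += seg.length
        flags = set(m.flags)
        if cum % 3 != 0:
            flags.add(FRAME_FLAG)
        else:
            flags.discard(FRAME_FLAG)
        repaired.append(
            GeneModel(
                gene_id=m.gene_id,
                sequence_id=m.sequence_id,
                strand=m.strand,
                exons=list(m.exons),
                cds_segments=new,
                gene_span=m.gene_span,
                flags=flags,
            )
        )
    return repaired


def _calls_from_gt(
    gt_indices: Sequence[int], ref: str, alts: Sequence[str]
) -> GenotypeCall:
    alleles = set()
    for idx in gt_indices:
        if idx < 0:
            continue
        alleles.add(ref if idx == 0 else alts[idx - 1])
    if not alleles:
        return GenotypeCall(present=False)
    return GenotypeCall(present=True, observed_alleles=frozenset(alleles))


def read_vcf(
    path: str | Path,
    accession_ids: Optional[Sequence[str]] = None,
    genome: Optional[Mapping[str, GenomeSequence]] = None,
) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord`s.

    ``accession_ids`` maps the VCF sample columns, in order, onto accession
    names; by default the sample names in the header are used. With a loaded
    ``genome``, REF alleles are checked against it and a mismatch raises
    :class:`ConsistencyError` listing the locus.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if accession_ids is None:
        accession_ids = samples
    elif len(accession_ids) != len(samples):
        raise FormatError(
            f"{path}: {len(samples)} sample columns but {len(accession_ids)} accession ids"
        )
    records: list[VariantRecord] = []
    for v in vcf:
        ref = v.REF
        alts = tuple(v.ALT)
        if genome is not None:
            expect = reference_base(genome, v.CHROM, v.POS, len(ref))
            if expect is not None and expect != ref:
                raise ConsistencyError(
                    f"{v.CHROM}:{v.POS}: VCF REF {ref!r} does not match genome {expect!r}"
                )
        genotypes = {
            acc: _calls_from_gt(v.genotypes[i][:-1], ref, alts)
            for i, acc in enumerate(accession_ids)
        }
        records.append(
            VariantRecord(
                sequence_id=v.CHROM,
                position=v.POS,
                ref_allele=ref,
                alt_alleles=alts,
                quality=float(v.QUAL) if v.QUAL is not None else 0.0,
                genotypes=genotypes,
            )
        )
    return records


def read_accession_vcfs(
    paths: Mapping[str, str | Path],
    genome: Optional[Mapping[str, GenomeSequence]] = None,
) -> list[VariantRecord]:
    """Merge per-accession single-sample VCFs into pooled records.

    Records are merged by (sequence, position, REF); ALT alleles are the
    union in first-seen order. An accession with no row at a locus gets an
    absent call, matching how a caller omits uncovered sites.
    """
    merged: dict[tuple[str, int, str], VariantRecord] = {}
    for acc, path in paths.items():
        for rec in read_vcf(path, accession_ids=[acc], genome=genome):
            key = (rec.sequence_id, rec.position, rec.ref_allele)
            if key not in merged:
                merged[key] = VariantRecord(
                    sequence_id=rec.sequence_id,
                    position=rec.position,
                    ref_allele=rec.ref_allele,
                    alt_alleles=rec.alt_alleles,
                    quality=rec.quality,
                    genotypes={},
                )
            tgt = merged[key]
            for alt in rec.alt_alleles:
                if alt not in tgt.alt_alleles:
                    tgt.alt_alleles = tgt.alt_alleles + (alt,)
            tgt.quality = max(tgt.quality, rec.quality)
            tgt.genotypes = {**tgt.genotypes, acc: rec.genotypes[acc]}
    accessions = list(paths)
    records = []
    for rec in sorted(merged.values(), key=lambda r: (r.sequence_id, r.position)):
        rec.genotypes = {
            acc: rec.genotypes.get(acc, GenotypeCall(present=False))
            for acc in accessions
        }
        records.append(rec)
    return records


def write_vcf(
    records: Iterable[VariantRecord],
    accession_ids: Sequence[str],
    path: str | Path,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write records as a minimal multi-sample VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snptriage\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(accession_ids)
            + "\n"
        )
        for rec in records:
            allele_index = {rec.ref_allele: 0}
            for i, alt in enumerate(rec.alt_alleles, start=1):
                allele_index[alt] = i
            gts = []
            for acc in accession_ids:
                call = rec.genotypes.get(acc, GenotypeCall(present=False))
                if not call.present:
                    gts.append("./.")
                    continue
                idx = sorted(allele_index[a] for a in call.observed_alleles)
                if len(idx) == 1:
                    idx = idx * 2
                gts.append("/".join(str(i) for i in idx[:2]))
            qual = f"{rec.quality:g}"
            fh.write(
                f"{rec.sequence_id}\t{rec.position}\t.\t{rec.ref_allele}\t"
                f"{','.join(rec.alt_alleles)}\t{qual}\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_depth_bed(path: str | Path) -> list[DepthInterval]:
    """Read a BED4 depth map: sequence, 0-based start, end, read depth."""
    out: list[DepthInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            seq, start, end, depth = fields[:4]
            try:
                start_i, end_i, depth_i = int(start), int(end), int(depth)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start_i >= end_i:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval {start_i}-{end_i}"
                )
            out.append(DepthInterval(seq, start_i, end_i, depth_i))
    return out


def write_depth_bed(intervals: Iterable[DepthInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{iv.depth}\n")


VARIANT_TABLE_COLUMNS = [
    "sequence_id",
    "position",
    "ref",
    "alt",
    "quality",
    "gene_id",
    "category",
    "impact",
    "aa_change",
]


def write_variant_table(records, annotations, path: str | Path) -> None:
    """Write the annotated variant list: one row per variant x gene effect.

    ``annotations`` is the output of :func:`snptriage.effects.annotate_all`;
    per-accession zygosity columns are derived from the records' pooled
    genotype calls.
    """
    from .classify import zygosity_of_call  # local import to avoid a cycle

    by_locus: dict[tuple[str, int], VariantRecord] = {r.locus: r for r in records}
    accessions: list[str] = []
    for r in records:
        accessions = list(r.genotypes)
        break
    rows = []
    for ann in annotations:
        rec = by_locus[(ann.sequence_id, ann.position)]
        row = {
            "sequence_id": ann.sequence_id,
            "position": ann.position,
            "ref": rec.ref_allele,
            "alt": ",".join(rec.alt_alleles),
            "quality": rec.quality,
            "gene_id": ann.gene_id if ann.gene_id is not None else ".",
            "category": ann.category,
            "impact": ann.impact,
            "aa_change": ann.aa_change_str() or ".",
        }
        for acc in accessions:
            row[f"zygosity_{acc}"] = zygosity_of_call(
                rec.genotypes[acc], rec.ref_allele
            )
        rows.append(row)
    cols = VARIANT_TABLE_COLUMNS + [f"zygosity_{a}" for a in accessions]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
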