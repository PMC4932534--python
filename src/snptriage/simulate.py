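"""Synthetic three-accession resequencing panels with planted ground truth.

The generator emulates the downstream products of a pooled resequencing
study of three inbred accessions: a reference genome of seven linkage
groups plus an unanchored-scaffold pseudo-sequence ("Un"), spliced gene
models, per-accession pooled genotype calls with Phred qualities, a
read-depth map with deep repeat blocks, a candidate gene list, protein
alignments, and an indel table. Every planted variant carries complete
truth labels (uniqueness, per-accession zygosity, effect category,
masking), so each pipeline stage can be scored exactly.

Defaults mirror the structure of the study conditions: three accessions
pooled two plants (four haploid genomes) each, a second/third accession
pair ("Ru"/"YW") sharing more variants with each other than with the
first, extensive residual heterozygosity after seven inbred generations,
a strict-quality tail below Phred 30, and repeat blocks deeper than 50
reads. Scale defaults (8 sequences of ~1 Mb, 200 genes, 5,000 variants)
are a desk-size panel with the same statistical shape.

All randomness flows from ``GeneratorConfig.seed`` through named
``numpy`` child generators, so every output is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .effects import (
    CODON_TO_AA,
    genome_position_at_cds_offset,
    spliced_cds,
)
from .io_formats import (
    repair_gff_phases,
    write_depth_bed,
    write_fasta,
    write_gff,
    write_vcf,
)
from .markers import IndelRecord, write_indel_table
from .records import (
    CdsSegment,
    DepthInterval,
    GeneModel,
    GenomeSequence,
    GenotypeCall,
    VariantRecord,
    genome_lookup,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(sorted(set(CODON_TO_AA) - set(_STOPS)))

CODING_CATEGORIES = (
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe_indel",
)


def _default_category_mix() -> dict[str, float]:
    # roughly the positional composition of a genome-wide call set:
    # most variants are near-gene or intronic modifiers, a few percent
    # are coding, and well under 1% are gene-breaking
    return {
        "intergenic": 0.15,
        "upstream_5kb": 0.22,
        "downstream_5kb": 0.22,
        "intron": 0.26,
        "splice_site": 0.004,
        "synonymous": 0.040,
        "missense": 0.065,
        "stop_gained": 0.004,
        "stop_lost": 0.001,
        "start_lost": 0.001,
        "frameshift": 0.004,
        "inframe_indel": 0.002,
    }


def _default_unique_fraction() -> dict[str, float]:
    # first accession clearly more divergent than the other two
    return {"H4": 0.27, "Ru": 0.105, "YW": 0.115}


def _default_pair_fraction() -> dict[tuple[str, str], float]:
    # the Ru/YW pair shares far more than either does with H4
    return {("Ru", "YW"): 0.22, ("H4", "Ru"): 0.05, ("H4", "YW"): 0.05}


@dataclass
class GeneratorConfig:
    seed: int = 1
    accessions: tuple[str, ...] = ("H4", "Ru", "YW")
    n_linkage_groups: int = 7
    sequence_length: int = 1_000_000
    un_length: int = 500_000
    n_genes: int = 200
    n_variants: int = 5000
    unique_fraction: dict[str, float] = field(default_factory=_default_unique_fraction)
    pair_shared_fraction: dict[tuple[str, str], float] = field(
        default_factory=_default_pair_fraction
    )
    missing_fraction: float = 0.01
    het_fraction: float = 0.30
    category_mix: dict[str, float] = field(default_factory=_default_category_mix)
    low_quality_fraction: float = 0.05
    n_repeat_regions: int = 24
    repeat_length: int = 4000
    masked_variant_fraction: float = 0.02
    depth_tile: int = 2000
    base_depth_range: tuple[int, int] = (8, 45)
    repeat_depth_range: tuple[int, int] = (60, 200)
    inbreeding_generations: int = 7
    plant_causal: bool = True
    causal_accession: str = "Ru"
    n_gene_list: int = 10
    flank: int = 5000
    splice_window: int = 2

    def sequence_names(self) -> list[str]:
        return [f"LG{i}" for i in range(1, self.n_linkage_groups + 1)] + ["Un"]

    def sequence_lengths(self) -> dict[str, int]:
        out = {f"LG{i}": self.sequence_length for i in range(1, self.n_linkage_groups + 1)}
        out["Un"] = self.un_length
        return out

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


# stream ids for the named child generators
_STREAM_GENOME = 1
_STREAM_REPEATS = 2
_STREAM_VARIANTS = 3
_STREAM_DEPTH = 4
_STREAM_ALIGNMENT = 5
_STREAM_INDELS = 6

# roles of the deliberately constructed funnel genes, in planting order
_SPECIAL_ROLES = (
    "causal",  # class-changing missense at a conserved column, unique+hom
    "decoy_het",  # class-changing missense but heterozygous in the target
    "decoy_same_class",  # missense within one property class
    "decoy_not_conserved",  # class-changing missense at a variable column
    "decoy_synonymous",  # silent change in a listed gene
    "decoy_unlisted",  # qualifying missense in a gene off the list
)

# forced codons so each special gene offers the substitution its role needs:
# codon 12 TGG (Trp) hosts the causal Trp->Ser analog; codon 21 hosts the
# decoy substitutions
_CAUSAL_CODON_INDEX = 11  # protein position 12
_DECOY_CODON_INDEX = 20  # protein position 21


# ---------------------------------------------------------------------------
# genome and gene models


def generate_genome(
    config: GeneratorConfig,
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Random genome plus spliced gene models.

    Genes have 1-4 exons on either strand, an ATG...stop CDS whose length
    is a multiple of three and which translates without internal stops,
    and are spaced so that no base is within the annotation flank of more
    than one gene.
    """
    rng = config.rng(_STREAM_GENOME)
    lengths = config.sequence_lengths()
    total_len = sum(lengths.values())
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)

    # distribute genes proportionally to sequence length
    names = config.sequence_names()
    genes_per_seq: dict[str, int] = {}
    assigned = 0
    for i, name in enumerate(names):
        if i == len(names) - 1:
            genes_per_seq[name] = config.n_genes - assigned
        else:
            k = int(round(config.n_genes * lengths[name] / total_len))
            genes_per_seq[name] = k
            assigned += k

    sequences: list[GenomeSequence] = []
    models: list[GeneModel] = []
    gene_counter = 0
    special_assigned = 0
    special_gene_ids: list[str] = []

    for name in names:
        L = lengths[name]
        arr = base_bytes[rng.integers(0, 4, size=L)].copy()
        k = genes_per_seq[name]
        if k > 0:
            pitch = L // (k + 1)
            min_room = 2 * config.flank + 12_000
            if pitch < min_room:
                raise ValueError(
                    f"sequence {name} too short for {k} genes "
                    f"(pitch {pitch} < {min_room})"
                )
        for i in range(k):
            gene_counter += 1
            gene_id = f"gene{gene_counter:05d}"
            role = None
            if config.plant_causal and special_assigned < len(_SPECIAL_ROLES):
                role = _SPECIAL_ROLES[special_assigned]
                special_assigned += 1
                special_gene_ids.append(gene_id)

            protein_len = int(rng.integers(60, 300))  # aa, excluding stop
            codons = ["ATG"]
            idx = rng.integers(0, len(_SENSE_CODONS), size=protein_len - 1)
            codons += [_SENSE_CODONS[j] for j in idx]
            codons.append(_STOPS[int(rng.integers(0, 3))])
            if role == "causal":
                codons[_CAUSAL_CODON_INDEX] = "TGG"  # Trp
            elif role in ("decoy_het", "decoy_not_conserved", "decoy_unlisted"):
                codons[_DECOY_CODON_INDEX] = "AAT"  # Asn -> Lys via third base
            elif role == "decoy_same_class":
                codons[_DECOY_CODON_INDEX] = "CTT"  # Leu -> Ile via first base
            elif role == "decoy_synonymous":
                codons[_DECOY_CODON_INDEX] = "CTG"  # Leu, silent via third base
            cds = "".join(codons)

            n_exons = int(rng.integers(1, 5))
            cuts = []
            if n_exons > 1:
                base = len(cds) // n_exons
                cuts = [base * j + int(rng.integers(-9, 10)) for j in range(1, n_exons)]
            bounds = [0] + cuts + [len(cds)]
            seg_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
            introns = [int(rng.integers(150, 1200)) for _ in range(n_exons - 1)]
            strand = "+" if rng.integers(0, 2) == 0 else "-"

            # genome-order exon sequences
            if strand == "+":
                genome_exons = seg_seqs
            else:
                genome_exons = [
                    "".join(_COMP[b] for b in reversed(s)) for s in reversed(seg_seqs)
                ]
            span_len = len(cds) + sum(introns)
            center = pitch * (i + 1) + int(rng.integers(-2000, 2001))
            start = max(1, center - span_len // 2)

            exon_coords: list[tuple[int, int]] = []
            pos = start
            for j, es in enumerate(genome_exons):
                exon_coords.append((pos, pos + len(es) - 1))
                arr[pos - 1 : pos - 1 + len(es)] = np.frombuffer(
                    es.encode(), dtype=np.uint8
                )
                pos += len(es)
                if j < len(introns):
                    pos += introns[j]
            span = (exon_coords[0][0], exon_coords[-1][1])
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    sequence_id=name,
                    strand=strand,
                    exons=exon_coords,
                    cds_segments=[CdsSegment(s, e) for s, e in exon_coords],
                    gene_span=span,
                )
            )
        sequences.append(GenomeSequence(sequence_id=name, residues=arr.tobytes().decode()))

    models = repair_gff_phases(models)
    if config.plant_causal and special_assigned < len(_SPECIAL_ROLES):
        raise ValueError("not enough genes to host the causal/decoy constructs")
    return sequences, models


def special_gene_roles(config: GeneratorConfig, models: Sequence[GeneModel]) -> dict[str, str]:
    """role -> gene_id mapping (the first six generated genes, in order)."""
    if not config.plant_causal:
        return {}
    return {role: models[i].gene_id for i, role in enumerate(_SPECIAL_ROLES)}


# ---------------------------------------------------------------------------
# repeat regions (shared by depth simulation and variant planting)


def plan_repeats(
    config: GeneratorConfig,
    sequences: Sequence[GenomeSequence],
    models: Sequence[GeneModel],
) -> dict[str, list[tuple[int, int]]]:
    """Deterministic 0-based half-open repeat blocks placed in intergenic
    zones well clear of every gene flank."""
    rng = config.rng(_STREAM_REPEATS)
    margin = config.flank + 500
    zones: list[tuple[str, int, int]] = []
    spans_by_seq: dict[str, list[tuple[int, int]]] = {s.sequence_id: [] for s in sequences}
    for m in models:
        spans_by_seq[m.sequence_id].append(m.gene_span)
    for seq in sequences:
        spans = sorted(spans_by_seq[seq.sequence_id])
        edges = [(0, 0)] + spans + [(seq.length + 1, seq.length + 1)]
        for (_, prev_e), (next_s, _) in zip(edges, edges[1:]):
            lo = prev_e + margin + 1
            hi = next_s - margin - 1
            if hi - lo >= config.repeat_length + 1000:
                zones.append((seq.sequence_id, lo, hi))
    n = min(config.n_repeat_regions, len(zones))
    chosen = rng.choice(len(zones), size=n, replace=False)
    repeats: dict[str, list[tuple[int, int]]] = {}
    for zi in sorted(chosen):
        seq_id, lo, hi = zones[zi]
        start1 = int(rng.integers(lo, hi - config.repeat_length + 1))
        repeats.setdefault(seq_id, []).append((start1 - 1, start1 - 1 + config.repeat_length))
    for ivs in repeats.values():
        ivs.sort()
    return repeats


# ---------------------------------------------------------------------------
# variant planting


def _codon_category(codon_i: int, ref_codon: str, within: int, new_base: str) -> str:
    alt_codon = ref_codon[:within] + new_base + ref_codon[within + 1 :]
    ref_aa = CODON_TO_AA[ref_codon]
    alt_aa = CODON_TO_AA[alt_codon]
    if codon_i == 0 and alt_codon != "ATG":
        return "start_lost"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


class _Planter:
    """Stateful placement of variants with collision avoidance."""

    def __init__(
        self,
        config: GeneratorConfig,
        sequences: Sequence[GenomeSequence],
        models: Sequence[GeneModel],
        repeats: Mapping[str, list[tuple[int, int]]],
        rng: np.random.Generator,
    ):
        self.config = config
        self.rng = rng
        self.genome = genome_lookup(list(sequences))
        self.models = list(models)
        self.repeats = repeats
        self.used: dict[str, set[int]] = {s.sequence_id: set() for s in sequences}
        self.cds_cache: dict[str, str] = {}
        # intergenic zones excluding repeats
        margin = config.flank + 1
        self.zones: list[tuple[str, int, int]] = []
        spans: dict[str, list[tuple[int, int]]] = {s.sequence_id: [] for s in sequences}
        for m in models:
            spans[m.sequence_id].append(m.gene_span)
        for s in sequences:
            ss = sorted(spans[s.sequence_id])
            edges = [(0, 0)] + ss + [(s.length + 1, s.length + 1)]
            for (_, prev_e), (next_s, _) in zip(edges, edges[1:]):
                lo, hi = prev_e + margin, next_s - margin
                if hi - lo > 200:
                    self.zones.append((s.sequence_id, lo, hi))

    def cds_of(self, model: GeneModel) -> str:
        if model.gene_id not in self.cds_cache:
            self.cds_cache[model.gene_id] = spliced_cds(model, self.genome)
        return self.cds_cache[model.gene_id]

    def _reserve(self, seq: str, positions: Sequence[int]) -> bool:
        if any(p in self.used[seq] for p in positions):
            return False
        self.used[seq].update(positions)
        return True

    def _in_repeat(self, seq: str, pos: int) -> bool:
        for s0, e0 in self.repeats.get(seq, ()):
            if s0 <= pos - 1 < e0:
                return True
        return False

    # -- coding SNPs --------------------------------------------------------

    def plant_coding_snp(
        self,
        model: GeneModel,
        want: str,
        codon_index: Optional[int] = None,
        within: Optional[int] = None,
        new_base: Optional[str] = None,
    ) -> tuple[int, str, str, tuple[str, int, str]]:
        """Place a SNP of the wanted category in a gene; returns
        (genome position, ref allele, alt allele, aa_change)."""
        cds = self.cds_of(model)
        n_codons = len(cds) // 3
        if codon_index is not None:
            codon_order = [codon_index]
        else:
            codon_order = list(self.rng.permutation(n_codons))
        for ci in codon_order:
            ref_codon = cds[ci * 3 : ci * 3 + 3]
            withins = [within] if within is not None else list(self.rng.permutation(3))
            for w in withins:
                bases = (
                    [new_base]
                    if new_base is not None
                    else [b for b in "ACGT" if b != ref_codon[w]]
                )
                for nb in bases:
                    if nb == ref_codon[w]:
                        continue
                    if _codon_category(ci, ref_codon, w, nb) != want:
                        continue
                    pos = genome_position_at_cds_offset(model, ci * 3 + w)
                    chrom = self.genome[model.sequence_id].residues
                    ref_g = chrom[pos - 1]
                    alt_g = nb if model.strand == "+" else _COMP[nb]
                    if alt_g == ref_g:
                        continue
                    if not self._reserve(model.sequence_id, [pos]):
                        continue
                    alt_codon = ref_codon[:w] + nb + ref_codon[w + 1 :]
                    aa = (CODON_TO_AA[ref_codon], ci + 1, CODON_TO_AA[alt_codon])
                    return pos, ref_g, alt_g, aa
        raise RuntimeError(
            f"could not place a {want} SNP in gene {model.gene_id}"
        )

    # -- coding indels ------------------------------------------------------

    def plant_coding_deletion(
        self, model: GeneModel, n_deleted: int
    ) -> tuple[int, str, str]:
        """Anchor-base deletion of ``n_deleted`` bases inside one CDS
        segment; returns (position, ref, alt)."""
        chrom = self.genome[model.sequence_id].residues
        segs = [s for s in model.cds_segments if s.length >= n_deleted + 4]
        for si in self.rng.permutation(len(segs)):
            seg = segs[int(si)]
            lo, hi = seg.start + 1, seg.end - n_deleted - 1
            if hi <= lo:
                continue
            for _ in range(20):
                pos = int(self.rng.integers(lo, hi + 1))
                span = list(range(pos, pos + n_deleted + 1))
                if self._reserve(model.sequence_id, span):
                    ref = chrom[pos - 1 : pos + n_deleted]
                    return pos, ref, ref[0]
        raise RuntimeError(f"no room for a deletion in gene {model.gene_id}")

    # -- non-coding positions -----------------------------------------------

    def plant_positional(self, model: GeneModel, category: str) -> tuple[int, str, str]:
        """Place a SNP at a position whose locational class is ``category``
        relative to ``model``; returns (position, ref, alt)."""
        cfg = self.config
        chrom = self.genome[model.sequence_id].residues
        span_s, span_e = model.gene_span
        for _ in range(200):
            if category in ("upstream_5kb", "downstream_5kb"):
                left = (category == "upstream_5kb") == (model.strand == "+")
                if left:
                    pos = int(self.rng.integers(span_s - cfg.flank, span_s))
                else:
                    pos = int(self.rng.integers(span_e + 1, span_e + cfg.flank + 1))
            elif category == "intron":
                pairs = list(zip(model.exons, model.exons[1:]))
                if not pairs:
                    raise RuntimeError("intron variant needs a multi-exon gene")
                (_, pe), (ns, _) = pairs[int(self.rng.integers(0, len(pairs)))]
                lo, hi = pe + cfg.splice_window + 1, ns - cfg.splice_window - 1
                if hi <= lo:
                    continue
                pos = int(self.rng.integers(lo, hi + 1))
            elif category == "splice_site":
                pairs = list(zip(model.exons, model.exons[1:]))
                if not pairs:
                    raise RuntimeError("splice variant needs a multi-exon gene")
                (_, pe), (ns, _) = pairs[int(self.rng.integers(0, len(pairs)))]
                d = int(self.rng.integers(1, cfg.splice_window + 1))
                pos = pe + d if self.rng.integers(0, 2) == 0 else ns - d
            else:
                raise ValueError(category)
            if pos < 1 or pos > len(chrom):
                continue
            if not self._reserve(model.sequence_id, [pos]):
                continue
            ref = chrom[pos - 1]
            alt = "ACGT"[int(self.rng.integers(0, 4))]
            while alt == ref:
                alt = "ACGT"[int(self.rng.integers(0, 4))]
            return pos, ref, alt
        raise RuntimeError(f"could not place {category} variant near {model.gene_id}")

    def plant_intergenic(self, masked: bool) -> tuple[str, int, str, str]:
        """A SNP >flank away from every gene; inside a repeat iff masked."""
        if masked:
            flat = [
                (seq, s0, e0) for seq, ivs in self.repeats.items() for s0, e0 in ivs
            ]
            if not flat:
                raise RuntimeError("no repeat regions to host masked variants")
            for _ in range(200):
                seq, s0, e0 = flat[int(self.rng.integers(0, len(flat)))]
                pos = int(self.rng.integers(s0 + 2, e0))  # 1-based, inside
                if self._reserve(seq, [pos]):
                    break
            else:
                raise RuntimeError("could not place masked variant")
        else:
            for _ in range(200):
                seq, lo, hi = self.zones[int(self.rng.integers(0, len(self.zones)))]
                pos = int(self.rng.integers(lo, hi + 1))
                if not self._in_repeat(seq, pos) and self._reserve(seq, [pos]):
                    break
            else:
                raise RuntimeError("could not place intergenic variant")
        chrom = self.genome[seq].residues
        ref = chrom[pos - 1]
        alt = "ACGT"[int(self.rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(self.rng.integers(0, 4))]
        return seq, pos, ref, alt


def _genotypes_for_class(
    config: GeneratorConfig,
    uniqueness: str,
    carriers: Sequence[str],
    ref: str,
    alt: str,
    rng: np.random.Generator,
    force_hom: bool = False,
    force_het_in: Optional[str] = None,
    missing_in: Optional[str] = None,
) -> tuple[dict[str, GenotypeCall], dict[str, str]]:
    calls: dict[str, GenotypeCall] = {}
    zyg: dict[str, str] = {}
    for acc in config.accessions:
        if acc == missing_in:
            calls[acc] = GenotypeCall(present=False)
            zyg[acc] = "missing"
        elif acc in carriers:
            het = rng.random() < config.het_fraction
            if force_hom:
                het = False
            if acc == force_het_in:
                het = True
            if het:
                calls[acc] = GenotypeCall(True, frozenset({ref, alt}))
                zyg[acc] = "het"
            else:
                calls[acc] = GenotypeCall(True, frozenset({alt}))
                zyg[acc] = "hom_alt"
        else:
            calls[acc] = GenotypeCall(True, frozenset({ref}))
            zyg[acc] = "hom_ref"
    return calls, zyg


TRUTH_COLUMNS = [
    "sequence_id",
    "position",
    "ref",
    "alt",
    "quality",
    "category",
    "gene_id",
    "uniqueness",
    "masked",
    "passes_quality",
    "role",
]


def plant_variants(
    config: GeneratorConfig,
    sequences: Sequence[GenomeSequence],
    models: Sequence[GeneModel],
    repeats: Optional[Mapping[str, list[tuple[int, int]]]] = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Plant the full variant panel; returns (records, truth table).

    The truth table has one row per planted variant with its uniqueness
    class, per-accession zygosity, effect category, target gene, repeat
    masking, and quality-filter fate. When the causal construct is on,
    exactly one row has role "causal": a Trp->Ser missense at protein
    position 12, unique and homozygous in the target accession.
    """
    if repeats is None:
        repeats = plan_repeats(config, sequences, models)
    rng = config.rng(_STREAM_VARIANTS)
    planter = _Planter(config, sequences, models, repeats, rng)
    specials = special_gene_roles(config, models)
    model_by_id = {m.gene_id: m for m in models}

    protected = set(specials.values())
    # reserve a few more genes as inert gene-list fillers
    fillers = [m.gene_id for m in models if m.gene_id not in protected][
        : max(0, config.n_gene_list - 5)
    ]
    protected.update(fillers)
    open_models = [m for m in models if m.gene_id not in protected]
    multi_exon = [m for m in open_models if len(m.exons) > 1]

    n_special = 6 if config.plant_causal else 0
    n_masked = int(round(config.masked_variant_fraction * config.n_variants))
    if not repeats:
        n_masked = 0
    n_main = config.n_variants - n_masked - n_special
    if n_main < 0:
        raise ValueError("n_variants too small for the requested special variants")

    # uniqueness class sequence
    classes: list[tuple] = []
    for acc, f in config.unique_fraction.items():
        classes += [("unique", acc)] * int(round(f * n_main))
    for pair, f in config.pair_shared_fraction.items():
        classes += [("pair", pair)] * int(round(f * n_main))
    classes += [("missing", None)] * int(round(config.missing_fraction * n_main))
    if len(classes) > n_main:
        classes = classes[:n_main]
    classes += [("all", None)] * (n_main - len(classes))
    classes = [classes[i] for i in rng.permutation(len(classes))]

    names = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in names], dtype=float)
    probs /= probs.sum()
    cats = [names[i] for i in rng.choice(len(names), size=n_main, p=probs)]

    records: list[VariantRecord] = []
    rows: list[dict] = []

    def add(seq, pos, ref, alt, category, gene_id, uniqueness, zyg, calls, masked,
            quality, role):
        records.append(
            VariantRecord(
                sequence_id=seq,
                position=pos,
                ref_allele=ref,
                alt_alleles=(alt,),
                quality=quality,
                genotypes=calls,
            )
        )
        row = {
            "sequence_id": seq,
            "position": pos,
            "ref": ref,
            "alt": alt,
            "quality": quality,
            "category": category,
            "gene_id": gene_id or ".",
            "uniqueness": uniqueness,
            "masked": masked,
            "passes_quality": quality > 30.0,
            "role": role,
        }
        for acc in config.accessions:
            row[f"zygosity_{acc}"] = zyg[acc]
        rows.append(row)

    def draw_quality(force_high: bool = False) -> float:
        if not force_high and rng.random() < config.low_quality_fraction:
            return round(5.0 + 24.0 * rng.random(), 2)
        return round(31.0 + 300.0 * rng.random(), 2)

    # -- special funnel constructs first (fixed codons must stay free) -----
    if config.plant_causal:
        target = config.causal_accession
        others = [a for a in config.accessions if a != target]

        def plant_special(role, want, codon_index, force_hom, force_het, **kw):
            model = model_by_id[specials[role]]
            pos, ref, alt, aa = planter.plant_coding_snp(
                model, want, codon_index=codon_index, **kw
            )
            calls, zyg = _genotypes_for_class(
                config, target, [target], ref, alt, rng,
                force_hom=force_hom, force_het_in=target if force_het else None,
            )
            add(model.sequence_id, pos, ref, alt, want, model.gene_id, target,
                zyg, calls, False, draw_quality(force_high=True), role)

        # causal: TGG -> TCG, Trp12Ser, unique + homozygous in target
        plant_special("causal", "missense", _CAUSAL_CODON_INDEX, True, False,
                      within=1, new_base="C")
        # heterozygous decoy: Asn21Lys but het in target
        plant_special("decoy_het", "missense", _DECOY_CODON_INDEX, False, True,
                      within=2, new_base="A")
        # same-class decoy: Leu21Ile (nonpolar -> nonpolar)
        plant_special("decoy_same_class", "missense", _DECOY_CODON_INDEX, True, False,
                      within=0, new_base="A")
        # non-conserved decoy: Asn21Lys at a variable alignment column
        plant_special("decoy_not_conserved", "missense", _DECOY_CODON_INDEX, True, False,
                      within=2, new_base="A")
        # silent decoy: CTG -> CTA
        plant_special("decoy_synonymous", "synonymous", _DECOY_CODON_INDEX, True, False,
                      within=2, new_base="A")
        # unlisted decoy: qualifying substitution in a gene off the list
        plant_special("decoy_unlisted", "missense", _DECOY_CODON_INDEX, True, False,
                      within=2, new_base="A")

    # -- masked variants (always high quality; removed only by the mask) ---
    for _ in range(n_masked):
        seq, pos, ref, alt = planter.plant_intergenic(masked=True)
        cls = ("unique", config.accessions[int(rng.integers(0, len(config.accessions)))])
        calls, zyg = _genotypes_for_class(config, cls[1], [cls[1]], ref, alt, rng)
        add(seq, pos, ref, alt, "intergenic", None, cls[1], zyg, calls, True,
            draw_quality(force_high=True), "masked")

    # -- the main panel -----------------------------------------------------
    def plant_in_some_gene(category):
        pool = multi_exon if category in ("intron", "splice_site") else open_models
        last_err = None
        for _ in range(20):  # a full gene may run out of free positions
            model = pool[int(rng.integers(0, len(pool)))]
            try:
                if category in ("upstream_5kb", "downstream_5kb",
                                "intron", "splice_site"):
                    pos, ref, alt = planter.plant_positional(model, category)
                elif category == "frameshift":
                    pos, ref, alt = planter.plant_coding_deletion(model, 1)
                elif category == "inframe_indel":
                    pos, ref, alt = planter.plant_coding_deletion(model, 3)
                else:
                    pos, ref, alt, _aa = planter.plant_coding_snp(model, category)
                return model.sequence_id, pos, ref, alt, model.gene_id
            except RuntimeError as err:
                last_err = err
        raise RuntimeError(f"could not place a {category} variant: {last_err}")

    for cls, category in zip(classes, cats):
        kind, detail = cls
        if category == "intergenic":
            seq, pos, ref, alt = planter.plant_intergenic(masked=False)
            gene_id = None
        else:
            seq, pos, ref, alt, gene_id = plant_in_some_gene(category)

        if kind == "unique":
            uniq, carriers, missing = detail, [detail], None
        elif kind == "pair":
            uniq, carriers, missing = "shared", list(detail), None
        elif kind == "all":
            uniq, carriers, missing = "shared", list(config.accessions), None
        else:  # missing call in one accession
            missing = config.accessions[int(rng.integers(0, len(config.accessions)))]
            rest = [a for a in config.accessions if a != missing]
            carriers = [rest[int(rng.integers(0, len(rest)))]]
            uniq = "none"
        calls, zyg = _genotypes_for_class(
            config, uniq, carriers, ref, alt, rng, missing_in=missing
        )
        add(seq, pos, ref, alt, category, gene_id, uniq, zyg, calls, False,
            draw_quality(), "main")

    order = sorted(
        range(len(records)), key=lambda i: (records[i].sequence_id, records[i].position)
    )
    records = [records[i] for i in order]
    rows = [rows[i] for i in order]
    truth = pd.DataFrame(
        rows, columns=TRUTH_COLUMNS + [f"zygosity_{a}" for a in config.accessions]
    )
    return records, truth


# ---------------------------------------------------------------------------
# depth map


def simulate_depth(
    config: GeneratorConfig,
    sequences: Sequence[GenomeSequence],
    models: Sequence[GeneModel],
) -> list[DepthInterval]:
    """Tiled read-depth map: baseline below the mask cutoff everywhere
    except the planned repeat blocks, which exceed it."""
    repeats = plan_repeats(config, sequences, models)
    rng = config.rng(_STREAM_DEPTH)
    lo, hi = config.base_depth_range
    rlo, rhi = config.repeat_depth_range
    out: list[DepthInterval] = []
    for seq in sequences:
        breaks = set(range(0, seq.length, config.depth_tile))
        breaks.add(seq.length)
        for s0, e0 in repeats.get(seq.sequence_id, ()):
            breaks.update((s0, e0))
        pts = sorted(b for b in breaks if 0 <= b <= seq.length)
        rep = repeats.get(seq.sequence_id, ())
        for a, b in zip(pts, pts[1:]):
            in_repeat = any(s0 <= a and b <= e0 for s0, e0 in rep)
            depth = int(rng.integers(rlo, rhi + 1)) if in_repeat else int(
                rng.integers(lo, hi + 1)
            )
            out.append(DepthInterval(seq.sequence_id, a, b, depth))
    return out


# ---------------------------------------------------------------------------
# alignment fixture


def make_alignment_fixture(
    config: GeneratorConfig,
    sequences: Sequence[GenomeSequence],
    models: Sequence[GeneModel],
) -> dict[str, list[tuple[str, str]]]:
    """Aligned homolog sets (query + 10 homologs) for the funnel genes.

    The causal gene's column 12 is invariant across homologs; the decoy
    genes' scored column 21 is made variable; one homolog carries a gap
    run so gap handling is always exercised.
    """
    rng = config.rng(_STREAM_ALIGNMENT)
    genome = genome_lookup(list(sequences))
    specials = special_gene_roles(config, models)
    model_by_id = {m.gene_id: m for m in models}
    aa_pool = "ACDEFGHIKLMNPQRSTVWY"

    out: dict[str, list[tuple[str, str]]] = {}
    for role in ("causal", "decoy_het", "decoy_same_class", "decoy_not_conserved"):
        gene_id = specials.get(role)
        if gene_id is None:
            continue
        model = model_by_id[gene_id]
        query = spliced_cds(model, genome)
        protein = "".join(
            CODON_TO_AA[query[i : i + 3]] for i in range(0, len(query) - 3, 3)
        )
        keep_col = _CAUSAL_CODON_INDEX if role == "causal" else None
        vary_col = _DECOY_CODON_INDEX if role != "causal" else None
        rows: list[tuple[str, str]] = [(gene_id, protein)]
        for h in range(10):
            res = list(protein)
            for i in range(len(res)):
                if i == keep_col:
                    continue
                if rng.random() < 0.25:
                    alt = aa_pool[int(rng.integers(0, len(aa_pool)))]
                    while alt == protein[i]:
                        alt = aa_pool[int(rng.integers(0, len(aa_pool)))]
                    res[i] = alt
            if vary_col is not None:
                # force a clearly non-conserved column: most homologs differ
                if h < 7:
                    alt = aa_pool[int(rng.integers(0, len(aa_pool)))]
                    while alt == protein[vary_col]:
                        alt = aa_pool[int(rng.integers(0, len(aa_pool)))]
                    res[vary_col] = alt
                else:
                    res[vary_col] = protein[vary_col]
            if h == 9:
                # one gapped homolog, away from the scored columns
                for i in range(1, 4):
                    res[i] = "-"
            rows.append((f"homolog{h + 1:02d}", "".join(res)))
        out[gene_id] = rows
    return out


def candidate_gene_list(config: GeneratorConfig, models: Sequence[GeneModel]) -> list[str]:
    """The pigment-pathway analog list: the causal gene, the listed decoys,
    and inert fillers; the 'unlisted' decoy gene is deliberately absent."""
    specials = special_gene_roles(config, models)
    listed = [
        specials[r]
        for r in ("causal", "decoy_het", "decoy_same_class",
                  "decoy_not_conserved", "decoy_synonymous")
        if r in specials
    ]
    excluded = set(specials.values())
    fillers = [m.gene_id for m in models if m.gene_id not in excluded]
    return listed + fillers[: max(0, config.n_gene_list - len(listed))]


# ---------------------------------------------------------------------------
# indel marker panel


def make_indel_panel(config: GeneratorConfig) -> tuple[list[IndelRecord], pd.DataFrame]:
    """Synthetic large-indel table with planted marker truth.

    Two gel-resolvable discriminating indels per accession, plus decoys
    that fail selection: small size differences, multi-accession carriers,
    and loci with missing calls.
    """
    rng = config.rng(_STREAM_INDELS)
    accs = config.accessions
    records: list[IndelRecord] = []
    rows = []
    pos = 10_000

    def alleles(states):
        return dict(zip(accs, states))

    for acc in accs:
        for _ in range(2):
            diff = int(rng.integers(20, 61))
            ins = rng.integers(0, 2) == 0
            ref_len, alt_len = (1, 1 + diff) if ins else (1 + diff, 1)
            states = ["alt" if a == acc else "ref" for a in accs]
            records.append(
                IndelRecord(f"LG{int(rng.integers(1, config.n_linkage_groups + 1))}",
                            pos, ref_len, alt_len, alleles(states))
            )
            rows.append({"position": pos, "kind": "marker", "discriminates": acc})
            pos += 7919
    for _ in range(3):  # too small for a gel
        diff = int(rng.integers(2, 16))
        records.append(
            IndelRecord("LG1", pos, 1 + diff, 1,
                        alleles(["alt", "ref", "ref"]))
        )
        rows.append({"position": pos, "kind": "too_small", "discriminates": ""})
        pos += 7919
    for _ in range(2):  # carried by two accessions
        diff = int(rng.integers(20, 61))
        records.append(
            IndelRecord("LG2", pos, 1 + diff, 1,
                        alleles(["ref", "alt", "alt"]))
        )
        rows.append({"position": pos, "kind": "multi_carrier", "discriminates": ""})
        pos += 7919
    for _ in range(2):  # a missing call disqualifies the locus
        diff = int(rng.integers(20, 61))
        records.append(
            IndelRecord("LG3", pos, 1, 1 + diff,
                        alleles(["missing", "alt", "ref"]))
        )
        rows.append({"position": pos, "kind": "missing_call", "discriminates": ""})
        pos += 7919
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestrator


@dataclass
class SyntheticPanel:
    config: GeneratorConfig
    sequences: list[GenomeSequence]
    models: list[GeneModel]
    records: list[VariantRecord]
    truth: pd.DataFrame
    depth: list[DepthInterval]
    repeats: dict[str, list[tuple[int, int]]]
    gene_list: list[str]
    alignments: dict[str, list[tuple[str, str]]]
    indels: list[IndelRecord]
    indel_truth: pd.DataFrame

    @property
    def genome(self) -> dict[str, GenomeSequence]:
        return genome_lookup(self.sequences)


def generate_panel(
    config: GeneratorConfig, out_dir: Optional[str | Path] = None
) -> SyntheticPanel:
    """Run every generator stage; optionally write the full file set
    (FASTA, GFF3, per-accession + pooled VCFs, depth BED, gene list,
    alignments, indel table, truth TSV) into ``out_dir``."""
    sequences, models = generate_genome(config)
    repeats = plan_repeats(config, sequences, models)
    records, truth = plant_variants(config, sequences, models, repeats)
    depth = simulate_depth(config, sequences, models)
    gene_list = candidate_gene_list(config, models) if config.plant_causal else []
    alignments = (
        make_alignment_fixture(config, sequences, models) if config.plant_causal else {}
    )
    indels, indel_truth = make_indel_panel(config)
    panel = SyntheticPanel(
        config=config,
        sequences=sequences,
        models=models,
        records=records,
        truth=truth,
        depth=depth,
        repeats=repeats,
        gene_list=gene_list,
        alignments=alignments,
        indels=indels,
        indel_truth=indel_truth,
    )
    if out_dir is not None:
        write_panel(panel, out_dir)
    return panel


def write_panel(panel: SyntheticPanel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = panel.config
    contigs = {s.sequence_id: s.length for s in panel.sequences}
    write_fasta(panel.sequences, out / "genome.fasta")
    write_gff(panel.models, out / "genes.gff3")
    write_vcf(panel.records, list(config.accessions), out / "panel.vcf", contigs)
    for acc in config.accessions:
        present = [r for r in panel.records if r.genotypes[acc].present]
        write_vcf(present, [acc], out / f"{acc}.vcf", contigs)
    write_depth_bed(panel.depth, out / "depth.bed")
    panel.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if panel.gene_list:
        (out / "gene_list.txt").write_text("\n".join(panel.gene_list) + "\n")
    for gene_id, rows in panel.alignments.items():
        with open(out / f"{gene_id}.aln.fasta", "w") as fh:
            for sid, seq in rows:
                fh.write(f">{sid}\n{seq}\n")
    write_indel_table(panel.indels, list(config.accessions), out / "indels.tsv")


# ---------------------------------------------------------------------------
# random coding SNP sampler (for effect-caller cross-validation)


def sample_coding_snps(
    models: Sequence[GeneModel],
    genome: Mapping[str, GenomeSequence],
    n: int,
    seed: int,
) -> list[tuple[GeneModel, int, str, str]]:
    """Uniformly random coding SNPs: (model, position, ref, alt) tuples
    drawn over genes, codons and substituted bases, with no category
    targeting — raw material for annotator cross-checks."""
    rng = np.random.default_rng(seed)
    out = []
    models = [m for m in models if m.cds_length >= 6]
    while len(out) < n:
        model = models[int(rng.integers(0, len(models)))]
        chrom = genome[model.sequence_id].residues
        offset = int(rng.integers(0, model.cds_length))
        pos = genome_position_at_cds_offset(model, offset)
        ref = chrom[pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        out.append((model, pos, ref, alt))
    return out
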