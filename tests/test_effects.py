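from __future__ import annotations

import pytest

from snptriage import effects
from snptriage.crosscheck import classify_coding_snp_by_retranslation
from snptriage.effects import (
    AnnotationConfig,
    annotate_all,
    locate_variant,
    representative_category,
    reverse_complement,
    summarize_impacts,
    translate_effect,
)
from snptriage.records import (
    CdsSegment,
    ConsistencyError,
    GeneModel,
    GenomeSequence,
    VariantRecord,
)
from snptriage.simulate import GeneratorConfig, generate_genome, sample_coding_snps
from snptriage.records import genome_lookup


def _variant(pos, ref, alt, seq="chr1", qual=100.0):
    return VariantRecord(seq, pos, ref, (alt,), qual, {})


class TestTranslateEffect:
    def test_trp_to_ser_missense(self, toy_gene):
        """Middle-base G->C in a TGG codon yields the Trp->Ser call."""
        genome, model = toy_gene
        # codon 3 (TGG) spans exon2 positions 207..209; middle base at 208
        ann = translate_effect(_variant(208, "G", "C"), model, genome)
        assert ann.category == "missense"
        assert ann.impact == "MODERATE"
        assert ann.aa_change == ("W", 3, "S")

    def test_synonymous_leucine(self):
        cds = "ATGCTGTAA"  # M-L-stop
        chrom = "A" * 50 + cds + "A" * 50
        genome = {"c": GenomeSequence("c", chrom)}
        model = GeneModel("g", "c", "+", [(51, 59)], [CdsSegment(51, 59, 0)], (51, 59))
        # third base of codon 2 (CTG) at position 56: G->A keeps Leu
        ann = translate_effect(_variant(56, "G", "A", seq="c"), model, genome)
        assert ann.category == "synonymous"
        assert ann.impact == "LOW"

    def test_one_bp_deletion_is_frameshift(self, toy_gene):
        genome, model = toy_gene
        ann = translate_effect(_variant(103, "GG", "G"), model, genome)
        assert ann.category == "frameshift"
        assert ann.impact == "HIGH"

    def test_three_bp_deletion_is_inframe(self, toy_gene):
        genome, model = toy_gene
        ann = translate_effect(_variant(102, "TGGC", "T"), model, genome)
        assert ann.category == "inframe_indel"
        assert ann.impact == "MODERATE"

    def test_start_lost(self, toy_gene):
        genome, model = toy_gene
        ann = translate_effect(_variant(101, "A", "G"), model, genome)
        assert ann.category == "start_lost"

    def test_stop_gained(self, toy_gene):
        genome, model = toy_gene
        # codon 3 TGG -> TGA (stop) via last base 209 G->A
        ann = translate_effect(_variant(209, "G", "A"), model, genome)
        assert ann.category == "stop_gained"
        assert ann.aa_change == ("W", 3, "*")

    def test_stop_lost(self, toy_gene):
        genome, model = toy_gene
        # stop codon TAA at 210..212; 211 A->C gives TCA = Ser
        ann = translate_effect(_variant(211, "A", "C"), model, genome)
        assert ann.category == "stop_lost"

    def test_ref_mismatch_raises(self, toy_gene):
        genome, model = toy_gene
        with pytest.raises(ConsistencyError):
            translate_effect(_variant(208, "T", "C"), model, genome)


class TestLocate:
    # the toy gene shifted deep into a chromosome: exon1 10101..10106,
    # intron 10107..10206, exon2 10207..10212
    @pytest.fixture()
    def deep_gene(self):
        shift = 10_000
        return GeneModel(
            "deep", "chr1", "+",
            [(10101, 10106), (10207, 10212)],
            [CdsSegment(10101, 10106, 0), CdsSegment(10207, 10212, 0)],
            (10101, 10212),
        )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (10101 - 4999, "upstream_5kb"),  # inside the 5 kb flank
            (10101 - 5000, "upstream_5kb"),  # boundary base
            (10101 - 5001, "intergenic"),  # one base beyond
            (10212 + 5000, "downstream_5kb"),
            (10212 + 5001, "intergenic"),
            (10107, "splice_site"),  # 1 bp into the intron (donor side)
            (10108, "splice_site"),  # 2 bp in: window edge
            (10109, "intron"),  # 3 bp in: past the window
            (10205, "splice_site"),  # 2 bp before the acceptor exon
            (10150, "intron"),
            (10104, "coding"),
        ],
    )
    def test_positional_classes(self, deep_gene, pos, expected):
        v = _variant(pos, "N", "A")
        assert locate_variant(v, deep_gene, AnnotationConfig()) == expected

    def test_strand_flips_up_and_downstream(self, toy_gene):
        genome, model = toy_gene
        minus = GeneModel(
            "toy1", "chr1", "-", model.exons, model.cds_segments, model.gene_span
        )
        v = _variant(50, "N", "A")  # left of the gene
        assert locate_variant(v, model) == "upstream_5kb"
        assert locate_variant(v, minus) == "downstream_5kb"


class TestAnnotateAll:
    def test_intergenic_fallback(self, toy_gene):
        genome, model = toy_gene
        # chromosome is only 312 bp, use a variant outside the flank on a
        # bigger virtual genome: no gene nearby -> intergenic
        genome2 = {"chr2": GenomeSequence("chr2", "A" * 100)}
        anns = annotate_all(
            [_variant(50, "A", "G", seq="chr2")], [model], {**genome, **genome2}
        )
        assert len(anns) == 1
        assert anns[0].category == "intergenic"
        assert anns[0].gene_id is None

    def test_one_annotation_per_gene_and_alt(self, toy_gene):
        genome, model = toy_gene
        other = GeneModel(
            "toy2", "chr1", "+", [(250, 290)], [CdsSegment(250, 290, 0)], (250, 290)
        )
        rec = VariantRecord("chr1", 220, "C", ("A", "T"), 50.0, {})
        anns = annotate_all([rec], [model, other], genome)
        # within 5 kb of both genes, two alts each -> 4 annotations
        assert len(anns) == 4
        assert {a.gene_id for a in anns} == {"toy1", "toy2"}

    def test_empty_input(self, toy_gene):
        genome, model = toy_gene
        assert annotate_all([], [model], genome) == []


class TestSummarize:
    def test_severity_precedence_counts_variants_once(self, toy_gene):
        genome, model = toy_gene
        mk = effects.EffectAnnotation
        anns = [
            mk("chr1", 208, "toy1", "missense", "C"),
            mk("chr1", 208, "toy2", "upstream_5kb", "C"),  # same variant
            mk("chr1", 150, "toy1", "intron", "A"),
            mk("chr2", 10, None, "intergenic", "G"),
        ]
        df = summarize_impacts(anns)
        counts = dict(zip(df["category"], df["n_variants"]))
        assert counts == {"missense": 1, "intron": 1, "intergenic": 1}
        assert df["n_variants"].sum() == 3

    def test_representative_prefers_high(self):
        mk = effects.EffectAnnotation
        anns = [
            mk("c", 1, "a", "synonymous", "A"),
            mk("c", 1, "b", "frameshift", "A"),
            mk("c", 1, "d", "intron", "A"),
        ]
        assert representative_category(anns) == "frameshift"


@pytest.fixture(scope="module")
def small_genome():
    config = GeneratorConfig(
        seed=3, n_variants=0, plant_causal=False, n_genes=50,
        sequence_length=300_000, un_length=150_000,
    )
    seqs, models = generate_genome(config)
    return genome_lookup(seqs), models


class TestOracleEquivalence:
    """Codon-offset logic vs. whole-genome mutate-retranslate-diff."""

    def test_random_coding_snps_agree(self, small_genome):
        genome, models = small_genome
        snps = sample_coding_snps(models, genome, 300, seed=42)
        strands = set()
        for model, pos, ref, alt in snps:
            v = _variant(pos, ref, alt, seq=model.sequence_id)
            fast = translate_effect(v, model, genome).category
            slow = classify_coding_snp_by_retranslation(
                model.sequence_id, pos, ref, alt, model, genome
            )
            assert fast == slow, f"{model.gene_id} {pos} {ref}>{alt}"
            strands.add(model.strand)
        assert strands == {"+", "-"}  # both strands exercised


def test_strand_symmetry(toy_gene):
    """Reverse-complementing the chromosome and flipping coordinates and
    strand leaves every category and amino-acid change unchanged."""
    genome, model = toy_gene
    L = genome["chr1"].length
    rc = {"chr1": GenomeSequence("chr1", reverse_complement(genome["chr1"].residues))}

    def flip(pos):
        return L - pos + 1

    flipped = GeneModel(
        "toy1",
        "chr1",
        "-",
        [(flip(e), flip(s)) for s, e in model.exons],
        [CdsSegment(flip(seg.end), flip(seg.start)) for seg in model.cds_segments],
        (flip(model.gene_span[1]), flip(model.gene_span[0])),
    )
    from snptriage.io_formats import repair_gff_phases

    (flipped,) = repair_gff_phases([flipped])
    cases = [(208, "G", "C"), (209, "G", "A"), (101, "A", "G"), (56 + 48, "C", "A")]
    for pos, ref, alt in cases:
        if genome["chr1"].residues[pos - 1] != ref:
            continue
        fwd = translate_effect(_variant(pos, ref, alt), model, genome)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rev = translate_effect(
            _variant(flip(pos), comp[ref], comp[alt]), flipped, rc
        )
        assert fwd.category == rev.category
        assert fwd.aa_change == rev.aa_change
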