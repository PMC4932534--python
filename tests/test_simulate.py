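from __future__ import annotations

import hashlib
from pathlib import Path

import pytest

from snptriage.effects import CODON_TO_AA, spliced_cds
from snptriage.io_formats import (
    read_depth_bed,
    read_fasta,
    read_gff,
    read_vcf,
    repair_gff_phases,
)
from snptriage.records import genome_lookup
from snptriage.simulate import (
    GeneratorConfig,
    generate_genome,
    generate_panel,
    plan_repeats,
    simulate_depth,
    write_panel,
)

SMALL = dict(n_variants=300, n_genes=40, sequence_length=300_000, un_length=150_000,
             n_repeat_regions=8)


def _dir_digest(d: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(d.iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_panel(GeneratorConfig(seed=5, **SMALL), out_dir=d1)
        generate_panel(GeneratorConfig(seed=5, **SMALL), out_dir=d2)
        assert _dir_digest(d1) == _dir_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_panel(GeneratorConfig(seed=5, **SMALL), out_dir=d1)
        generate_panel(GeneratorConfig(seed=6, **SMALL), out_dir=d2)
        assert _dir_digest(d1) != _dir_digest(d2)


@pytest.fixture(scope="module")
def genome_models():
    seqs, models = generate_genome(GeneratorConfig(seed=9, **SMALL))
    return genome_lookup(seqs), models


class TestGenome:
    def test_sequence_panel_shape(self, genome_models):
        genome, models = genome_models
        assert set(genome) == {f"LG{i}" for i in range(1, 8)} | {"Un"}
        assert len(models) == 40

    def test_every_cds_is_clean_orf(self, genome_models):
        """Each emitted CDS starts with ATG, ends with a stop, has length
        divisible by 3 and no internal stop codons."""
        genome, models = genome_models
        for m in models:
            cds = spliced_cds(m, genome)
            assert len(cds) % 3 == 0
            assert cds[:3] == "ATG"
            aas = [CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3)]
            assert aas[-1] == "*"
            assert "*" not in aas[:-1]

    def test_both_strands_and_exon_counts(self, genome_models):
        _, models = genome_models
        assert {m.strand for m in models} == {"+", "-"}
        assert {len(m.exons) for m in models} <= {1, 2, 3, 4}

    def test_no_genes_mode(self):
        seqs, models = generate_genome(
            GeneratorConfig(seed=9, n_genes=0, plant_causal=False,
                            sequence_length=100_000, un_length=50_000)
        )
        assert models == []
        assert len(seqs) == 8


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    out = tmp_path_factory.mktemp("panel")
    panel = generate_panel(GeneratorConfig(seed=21, **SMALL), out_dir=out)
    return out, panel


class TestEmittedFiles:
    def test_fasta_round_trip(self, written):
        out, panel = written
        seqs = read_fasta(out / "genome.fasta")
        assert seqs == panel.sequences

    def test_gff_round_trip(self, written):
        out, panel = written
        models = repair_gff_phases(read_gff(out / "genes.gff3"))
        assert len(models) == len(panel.models)
        by_id = {m.gene_id: m for m in models}
        for m in panel.models:
            back = by_id[m.gene_id]
            assert back.exons == m.exons
            assert back.strand == m.strand
            assert [(s.start, s.end, s.phase) for s in back.cds_segments] == [
                (s.start, s.end, s.phase) for s in m.cds_segments
            ]

    def test_vcf_round_trip(self, written):
        out, panel = written
        records = read_vcf(out / "panel.vcf", genome=panel.genome)
        assert len(records) == len(panel.records)
        for a, b in zip(records, panel.records):
            assert a.locus == b.locus
            assert a.ref_allele == b.ref_allele
            assert a.alt_alleles == b.alt_alleles
            for acc in panel.config.accessions:
                assert (
                    a.genotypes[acc].observed_alleles
                    == b.genotypes[acc].observed_alleles
                )

    def test_depth_bed_round_trip(self, written):
        out, panel = written
        assert read_depth_bed(out / "depth.bed") == panel.depth

    def test_truth_consistent_with_vcf(self, written):
        out, panel = written
        truth = panel.truth
        assert len(truth) == len(panel.records)
        for rec, (_, row) in zip(panel.records, truth.iterrows()):
            assert rec.locus == (row["sequence_id"], row["position"])
            assert rec.ref_allele == row["ref"]


class TestDepthAndRepeats:
    def test_repeats_exceed_threshold_elsewhere_below(self, small_config):
        seqs, models = generate_genome(small_config)
        repeats = plan_repeats(small_config, seqs, models)
        depth = simulate_depth(small_config, seqs, models)
        assert sum(len(v) for v in repeats.values()) > 0
        for iv in depth:
            in_repeat = any(
                s0 <= iv.start and iv.end <= e0
                for s0, e0 in repeats.get(iv.sequence_id, ())
            )
            if in_repeat:
                assert iv.depth > 50
            else:
                assert iv.depth <= 50

    def test_no_repeats_mode(self):
        config = GeneratorConfig(seed=9, n_repeat_regions=0, **{
            k: v for k, v in SMALL.items() if k != "n_repeat_regions"})
        seqs, models = generate_genome(config)
        assert plan_repeats(config, seqs, models) == {}

    def test_depth_tiles_cover_each_sequence(self, small_panel):
        by_seq = {}
        for iv in small_panel.depth:
            by_seq.setdefault(iv.sequence_id, []).append(iv)
        for seq in small_panel.sequences:
            ivs = sorted(by_seq[seq.sequence_id], key=lambda i: i.start)
            assert ivs[0].start == 0
            assert ivs[-1].end == seq.length
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start


class TestAlignmentFixture:
    def test_causal_column_invariant(self, small_panel):
        from snptriage.candidates import conservation_score

        truth = small_panel.truth.set_index("role")
        causal_gene = truth.loc["causal", "gene_id"]
        aln = small_panel.alignments[causal_gene]
        assert len(aln) == 11
        score = conservation_score(aln, causal_gene, 12)
        assert score.identity_fraction == 1.0
        assert score.query_residue == "W"

    def test_decoy_column_variable(self, small_panel):
        from snptriage.candidates import conservation_score

        truth = small_panel.truth.set_index("role")
        decoy_gene = truth.loc["decoy_not_conserved", "gene_id"]
        aln = small_panel.alignments[decoy_gene]
        score = conservation_score(aln, decoy_gene, 21)
        assert score.identity_fraction < 0.9

    def test_a_gapped_homolog_exists(self, small_panel):
        for aln in small_panel.alignments.values():
            assert any("-" in seq for _, seq in aln[1:])


class TestPlantedComposition:
    def test_requested_counts_materialize(self, small_panel):
        truth = small_panel.truth
        config = small_panel.config
        assert len(truth) == config.n_variants
        assert (truth.role == "causal").sum() == 1
        n_masked = int(round(config.masked_variant_fraction * config.n_variants))
        assert truth.masked.sum() == n_masked

    def test_quality_tail_straddles_cutoff(self, small_panel):
        truth = small_panel.truth
        assert (~truth.passes_quality).sum() > 0
        assert truth.passes_quality.sum() > 0
        assert (truth.quality == 30.0).sum() == 0  # never ambiguous
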