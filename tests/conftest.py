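from __future__ import annotations

import pytest

from snptriage.records import CdsSegment, GeneModel, GenomeSequence
from snptriage.simulate import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def panel():
    """The default-scale synthetic panel (8 sequences, 200 genes, 5,000
    variants) with the causal construct planted."""
    return generate_panel(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        seed=11,
        n_variants=400,
        n_genes=40,
        sequence_length=300_000,
        un_length=150_000,
        n_repeat_regions=8,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture
def toy_gene():
    """A two-exon plus-strand gene on a hand-built chromosome.

    CDS: ATG GCT TGG TAA split 6|6 across the exons, i.e. protein M-A-W.
    Exon1 = 101..106, intron = 107..206, exon2 = 207..212.
    """
    cds = "ATGGCTTGGTAA"
    chrom = "T" * 100 + cds[:6] + "C" * 100 + cds[6:] + "G" * 100
    seq = GenomeSequence("chr1", chrom)
    model = GeneModel(
        gene_id="toy1",
        sequence_id="chr1",
        strand="+",
        exons=[(101, 106), (207, 212)],
        cds_segments=[CdsSegment(101, 106, 0), CdsSegment(207, 212, 0)],
        gene_span=(101, 212),
    )
    return {"chr1": seq}, model
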