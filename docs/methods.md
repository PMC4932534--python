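# Methods

This note documents the models, conventions and design decisions behind
`snptriage`, in the order the pipeline runs.

## Coordinates and formats

GFF3 and VCF positions are 1-based closed, as the formats define them;
depth intervals, masks and binned tracks are 0-based half-open (BED).
Conversion happens only at read/write boundaries, so all internal
arithmetic is uniform. A variant at 1-based position p is tested against
masks at 0-based p−1; a locus falls in bin ⌊(p−1)/bin_size⌋. FASTA parsing
goes through Biopython, GFF3 through gffutils (only gene/mRNA/exon/CDS
rows are consumed; the first mRNA per gene is used — one isoform per gene
is the pipeline-wide assumption), VCF through cyvcf2.

## Gene-model repair

Upstream annotations can carry inconsistent CDS phases. Phases are
recomputed from segment lengths in translation order: the 5′-most segment
gets phase 0, each later segment gets (3 − cumulative_length mod 3) mod 3.
Models whose total CDS length is not a multiple of three are flagged
(`cds_length_not_multiple_of_3`) and retained, never dropped: downstream
stages can then decide to skip or inspect them. The repair is idempotent.

## Filtering

Two filters, both strict inequalities:

| parameter | default | meaning |
|---|---|---|
| `min_quality` | 30 (Phred) | keep calls with quality **> 30** |
| `max_depth` | 50 (reads) | mask bases with depth **> 50** |

High-coverage intervals are interpreted as repetitive or collapsed
sequence where calls are unreliable, and the whole interval is excluded.
Adjacent qualifying depth intervals are merged; overlapping input
intervals are a consistency error (a depth map must tile). Indels are
masked by their 1-based start position only, not their span — the
simplest consistent extension of a filter designed for SNP lists. Masks
are built per depth map; when per-accession maps exist their masks can be
built separately and variants removed against the union.

## Effect annotation

Each variant is annotated against every gene whose span lies within
`flank` (default 5,000 bp) of it; a variant near two genes gets two
annotations, and one with no gene in range gets a single intergenic
annotation. Positional classes: coding (inside a CDS segment);
splice_site (within `splice_window` = 2 bp of an exon boundary on the
intron side — the canonical donor/acceptor dinucleotides); intron;
upstream/downstream (resolved by strand). Exonic but non-CDS positions
(UTRs) are classed at intron level; UTR subclassification is out of
scope, and the synthetic generator emits exon = CDS models so this path
is a fallback for real annotations only.

Coding SNPs are resolved by mutating the affected codon of the spliced
CDS (reverse-complemented on the minus strand) under the standard genetic
code: start_lost when codon 1 of an ATG-initiated model is changed;
stop_lost / stop_gained by comparing the translated residues; synonymous
/ missense otherwise. Models not starting with ATG never receive
start_lost calls. Indels are classified by length arithmetic alone:
frameshift iff |len(ref) − len(alt)| mod 3 ≠ 0, else inframe_indel.
Multi-allelic records are annotated per alternate allele and represented
by their severest category.

Impact is a function of category — HIGH: frameshift, start_lost,
stop_gained, stop_lost, splice_site; MODERATE: missense, inframe_indel;
LOW: synonymous; MODIFIER: upstream, downstream, intron, intergenic.
Summary tables count variants once, under HIGH > MODERATE > LOW >
MODIFIER precedence, with a fixed category order breaking ties inside an
impact class, so every variant maps to exactly one cell.

An independent cross-check (`snptriage.crosscheck`) classifies a coding
SNP by applying it to a copy of the whole chromosome, re-extracting the
spliced CDS by coordinates, translating both proteins in full and
diffing them. It shares no offset arithmetic with the annotator; the test
suite and the acceptance script require 100% agreement between the two
routes on 1,000 random coding SNPs spanning both strands. For the
aa_change field of indels the substituted residue is ill-defined, so the
affected codon is reported with "fs"/"del"/"ins" in place of an alternate
residue.

## Accession classification

Genotypes are pooled observed-allele sets (two plants, i.e. four haploid
genomes, per accession): heterozygous iff the set holds more than one
distinct allele; homozygous alt iff a single non-reference allele;
homozygous ref iff only the reference allele. A locus is unique to
accession X iff X carries an alternate allele and both other accessions
have explicit homozygous-reference calls; a missing call anywhere
disqualifies the locus ("none") rather than counting as absence, so
coverage gaps cannot inflate uniqueness. Sharing matrices use
carries-alt (dominant) coding, matching the unique/shared dichotomy
rather than exact-genotype identity.

The inbreeding expectation is deterministic: g selfing generations give a
2^g reduction factor; mean spacing = genome_length / observed het loci;
ancestral spacing = mean spacing / 2^g, rounded half away from zero to
whole base pairs (2000/128 = 15.625 → 16). Inefficient selfing, sib
outcrossing or balancing selection — the plausible reasons observed
panels exceed the expectation — are deliberately not modelled.

## Density tracks

Default bin size 500 kb; the last partial bin keeps its natural shorter
span and raw count (the tracks plot counts, not per-bp densities).
Unanchored scaffolds are pooled as one pseudo-sequence "Un". Track files
are BED-style text, ordered by sequence then bin, so halving the bin size
and re-summing adjacent pairs reproduces the coarser track exactly.

## Candidate funnel

A pure conjunction, so filter order cannot change the result: unique to
the target accession ∧ homozygous alt there (and hom-ref in both others)
∧ HIGH or MODERATE ∧ gene on the candidate list. Survivors are scored for
amino-acid property change and alignment-column conservation; reports
keep per-filter flags rather than silently discarding, mirroring how a
human curator works down a short list.

The amino-acid property table (nonpolar A V L I P F M W; polar G S T C Y
N Q; basic K R H; acidic D E) is the pipeline's house convention — note
glycine sits with the polar residues — and is overridable via the
`table` argument wherever it is used. Conservation of a substituted
residue is the fraction of homolog rows (query excluded, gaps excluded
from the denominator) matching the query residue at the column its
ungapped position maps to; default threshold 0.9 over an alignment of 10
homologs. Truncating changes (frameshift, stop-gain) pass the
property-change filter by construction: a knockout is at least as
disruptive as a class change. Homolog retrieval is not performed; the
alignment is an input. The Mendelian predictor for the colour locus takes
two-allele parent genotypes over {G functional/dominant, C
loss-of-function} and returns red / yellow / segregating.

## Indel markers

A marker is an indel carried by exactly one accession (loci with missing
calls are excluded) with allele-length difference ≥ 20 bp — resolvable on
a 1% agarose gel. Default primer window is ±150 bp around the indel;
expected amplicon length is the window span, shifted by (alt − ref)
length for alternate carriers, with heterozygotes showing both bands.
Thermodynamic primer design is out of scope; the windows are coordinates
for external primer tools.

## Synthetic panels

The generator emulates the downstream products of a three-accession
pooled resequencing study, with planted truth for every variant.
Defaults, chosen once to mirror the study conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| sequences | 7 LGs × 1 Mb + "Un" × 0.5 Mb | seven linkage groups plus unanchored scaffolds |
| genes / variants | 200 / 5,000 | minutes on one CPU at genome-like density |
| unique fractions | H4 0.27, Ru 0.105, YW 0.115 | the first accession is the divergent one, ≈ the 99,722 / 38,404 / 42,483 proportions of a 366k-variant panel |
| pair sharing | Ru∩YW 0.22 vs 0.05 each with H4 | the Ru/YW excess similarity |
| het fraction | 0.30 per carrier | extensive residual heterozygosity after 7 generations |
| category mix | ~0.85 near-gene, ~0.04 silent, ~0.01 gene-breaking | genome-scale impact composition |
| low-quality tail | 5% below Phred 30 | exercises the strict quality cutoff |
| repeats | 24 × 4 kb blocks, depth 60–200 vs baseline 8–45 | exercises the strict depth cutoff |
| missing calls | 1% of loci | exercises the uniqueness disqualification rule |

Gene models are ATG…stop ORFs (60–300 codons, no internal stops, 1–4
exons, both strands) spaced so no base lies within the 5 kb flank of more
than one gene — which makes planted positional categories unambiguous.
Quality scores are drawn from two bands (5–29 and 31–331) so no call sits
on the cutoff. Repeat blocks are placed in intergenic zones clear of all
gene flanks; the masked-variant quota is planted inside them and nothing
else is, so the depth filter's removal set is exactly known. All
randomness flows from one seed through named child generators
(`numpy` PCG64), making every emitted file byte-reproducible.

When the causal construct is enabled the generator designates six genes:
one causal (reference codon TGG at protein position 12, alternate allele
giving a Trp→Ser change, unique and homozygous in the target accession,
at an alignment column invariant across all 10 homologs) and five decoys
that each fail exactly one funnel filter: heterozygous in the target;
same-class substitution (Leu→Ile); class-changing but at a variable
column; synonymous; and off the gene list. The emitted candidate list
holds the causal gene, the four listed decoys, and inert fillers.

What the generator does **not** emulate: read-level errors and mapping
artifacts (qualities are drawn, not computed from reads), linkage
disequilibrium and recombination structure, indels longer than a few bp
in the variant panel, transcript isoforms, UTRs, and non-ATG initiation.
Passing the planted-truth tests therefore demonstrates the correctness of
the set logic, coordinate handling and codon arithmetic — not robustness
to caller-specific artifacts in real data.

## Problem sizes used in checks

The test suite and the acceptance script run the generator at its default
scale (5,000 variants) for recovery, funnel, binning and marker checks,
and at a reduced scale (2.25 Mb genome, 60 genes) for the 1,000-SNP
annotator/oracle agreement check; both complete in seconds.

## Known limitations

- One transcript per gene; alternative isoforms would need an isoform
  ranking rule the pipeline does not define.
- An indel anchored in an intron but extending into an exon is classified
  by its anchor position.
- Compound heterozygous codons (two SNPs in one codon) are annotated per
  variant against the reference, as variant callers report them.
- The funnel's conservation flag stays unscored (and the candidate cannot
  pass) for genes without a supplied alignment.
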