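# snptriage

Post-variant-calling triage for multi-accession resequencing panels of
inbred plants.

When several accessions (named lines) of a selfing species are resequenced
against one reference, the called SNPs and indels must be turned into
biology: which variants are trustworthy, what each does to a gene, which
are private to one accession, how much residual heterozygosity each line
carries, and — ultimately — which single variant is the best candidate for
a phenotype segregating between the lines. `snptriage` implements that
whole downstream path for a three-accession panel (the canonical use case
is a diploid woodland-strawberry panel: one reference-like line and two
others, one of which carries a dominant fruit-colour allele), plus a
seeded synthetic-data generator so every stage is testable with planted
ground truth and no downloads.

## What the pipeline computes

1. **Filtering** — keep calls with Phred-scaled quality strictly above 30;
   build a mask of genomic intervals whose read depth is strictly above 50
   (likely repeats) and drop variants inside it.
2. **Effect annotation** — a miniature variant-effect predictor: each
   variant is located against every repaired gene model within 5 kb and,
   for coding positions, resolved by codon translation of the spliced CDS
   (reverse-complemented for minus-strand genes). Categories map to
   impacts the usual way: frameshift / start-loss / stop-gain / stop-loss /
   splice-site are HIGH, missense and in-frame indels MODERATE, synonymous
   LOW, near-gene / intronic / intergenic MODIFIER.
3. **Accession classification** — a locus is *unique* to accession X when
   X carries an alternate allele and the other two are explicitly
   homozygous reference; it is *heterozygous* in an accession when its
   sequencing pool (two plants, four haploid genomes) shows more than one
   allele. Pairwise sharing matrices quantify which accessions are closest.
4. **Inbreeding arithmetic** — each selfing generation halves
   heterozygosity, so g generations imply a 2^g reduction: observed spacing
   s of het loci projects back to an ancestral spacing s / 2^g.
5. **Density tracks** — 500-kb binned per-linkage-group variant counts in
   plain-text histogram (Circos-style) files.
6. **Candidate funnel** — loci that are unique *and* homozygous in the
   target accession, of HIGH/MODERATE impact, and inside a listed candidate
   gene, then ranked by amino-acid property change (nonpolar / polar /
   basic / acidic classes) and by conservation of the affected alignment
   column among homologs.
7. **Marker design** — indels carried by exactly one accession with a
   gel-resolvable length difference (≥ 20 bp), with expected per-accession
   amplicon lengths; each accession gets a unique band-pattern triple and
   F1 hybrids show two bands.

## Worked example

```python
from snptriage import (GeneratorConfig, generate_panel, apply_filters,
                       annotate_all, summarize_impacts, classify_uniqueness,
                       pairwise_sharing, funnel, isolate_candidates,
                       inbreeding_expectation)

panel = generate_panel(GeneratorConfig(seed=1))     # 8 sequences, 200 genes,
kept, removed, mask = apply_filters(panel.records, panel.depth)  # 5,000 variants
print(f"kept {len(kept)} of {len(panel.records)} variants")
# kept 4672 of 5000 variants (328 removed; 96,000 bases masked)

anns = annotate_all(kept, panel.models, panel.genome)
print(summarize_impacts(anns))
#       category   impact  n_variants
#     frameshift     HIGH          19
#    stop_gained     HIGH          19
#       missense MODERATE         292
#     synonymous      LOW         158
#         intron MODIFIER        1207
#   ... (one row per category; rows sum to the number of kept loci)

profiles = classify_uniqueness(kept, panel.config.accessions)
print(pairwise_sharing(profiles))
#       H4    Ru    YW
# H4  2598  1084  1089
# Ru  1084  2618  1869     <- Ru and YW share far more with each other
# YW  1089  1869  2646        than either does with H4

reports = funnel(profiles, anns, panel.gene_list, "Ru",
                 alignments=panel.alignments)
for r in isolate_candidates(reports):
    print(r.gene_id, f"{r.sequence_id}:{r.position}", r.substitution)
# gene00001 LG1:37191 W12S   (nonpolar -> polar, column identity 1.00)
```

The funnel returns three reports (candidates that are unique+homozygous,
HIGH/MODERATE, and in a listed gene) but exactly one survives the
property-change and conservation filters: the planted tryptophan-to-serine
substitution at protein position 12 — the analog of a loss-of-function
change in an R2R3-MYB DNA-binding domain that turns fruit yellow.

The inbreeding expectation is closed-form:

```python
inbreeding_expectation(7, 100_000, 200_000_000)
# reduction_factor=128, mean_spacing=2000.0, inferred_ancestral_spacing=16
```

i.e. 100,000 heterozygous loci over a 200 Mb genome (one per 2 kb) after
seven inbred generations would require an implausible ancestral het site
every 16 bp — evidence that inbreeding did not halve heterozygosity each
generation.

A `triage` command-line tool wraps the same stages
(`triage simulate | filter | annotate | classify | bins | candidates |
markers`); run `triage --help`.

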