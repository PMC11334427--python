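# markerlens

Tooling for assessing alternative phylogenetic marker genes in microbiome
studies and for relating marker-resolved diversity to a continuous host
phenotype (BMI). The package covers five analysis stages, each usable as a
library module and as a CLI subcommand:

- **marker_survey** — locate marker genes on genome assemblies (nucleotide
  or protein queries, both strands), compute pairwise Kimura-1980 distances
  and p-identities over aligned, ungapped columns, regress one marker's
  identities on another's, and report single-copy fractions.
- **insilico_pcr** — degenerate-primer matching with IUPAC subset
  semantics, amplicon calling under per-primer mismatch and product-length
  constraints, per-family taxonomic coverage, and inner-region extraction.
- **primer_design** — codon-aware back-translation of protein orthologue
  alignments, minimal-covering degenerate consensus windows, and pairing of
  forward/reverse candidates under product-length, Tm and %GC constraints.
- **amplicon_diversity** — count filtering, rarefaction, taxon-subset
  Shannon indices, greedy identity clustering, a two-part hurdle GLM
  (binomial/logit presence + Gamma/log positive part) of diversity against
  BMI with a city covariate, and Benjamini–Hochberg FDR.
- **abundance** — median-of-ratios size factors and per-ASV negative
  binomial Wald tests across BMI categories (plain NB, no dispersion or
  fold-change shrinkage).

A **synthetic_data** module generates every fixture the pipeline needs:
genomes carrying marker loci evolved under K80 at per-marker rates with
controlled primer-site mismatches, hurdle-structured diversity cohorts, and
negative-binomial count cohorts — each with a truth table sufficient to
score the downstream stage.

## CLI

```sh
markerlens simulate       --out fixtures --seed 1 [--config cfg.yaml]
markerlens survey         --genomes g.fasta --taxonomy t.tsv --queries q.fasta --out out/
markerlens pcr-coverage   --genomes g.fasta --taxonomy t.tsv \
                          --fwd YGTNGCNGTNATGGARGGCGG --rev NGCCTGNCKYTTTGCVACCTG \
                          --min-len 75 --max-len 150 --max-mismatch 6 --out out/
markerlens design-primers --protein-msa msa.fasta --cds cds.fasta --out out/
markerlens diversity      --counts c.tsv --taxonomy t.tsv --metadata m.tsv \
                          --taxa family:Oscillospiraceae,genus:Vescimonas \
                          --thresholds 1.0,0.97,0.90,0.85 --fdr-alpha 0.20 --out out/
markerlens diffabund      --counts c.tsv --metadata m.tsv --out out/
markerlens pipeline       --out demo --seed 1   # end-to-end on synthetic fixtures
```

Exit codes: 0 ok, 1 data error, 2 usage error. Outputs carry a provenance
header (version, seed, parameters); identical config + seed gives
byte-identical artifacts.

## Conventions

- Coordinates are 0-based, half-open, forward strand; reverse-strand
  features carry a strand flag.
- Sequences are upper-cased on input; `U` maps to `T`.
- Taxonomy uses 7-rank GTDB-style labels (`d__…;s__…`).
- BMI categories: lean [18.5, 25), overweight [25, 30), obese ≥ 30 kg/m²;
  samples under 18.5 are excluded on metadata load.
- Amplicon product length is the outer 5'→5' span including both primer
  footprints (`inner_span=True` switches to the insert-only convention).
- Every stochastic operation takes an explicit seed.
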