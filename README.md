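# strainpop

Strain-level population genomics for metagenome-derived microbial
populations, built around the kind of question posed by co-occurring
complete ammonia oxidizer (comammox *Nitrospira*) populations in
groundwater-fed rapid sand filters: how much sequence microdiversity do the
populations carry, how much homologous recombination do they experience,
how strong is selection on their genes, and how differentiated are the
populations between isolated filter plants (waterworks)?

The package is aimed at researchers who have mapped metagenomic reads to
reference genomes (MAGs) and want reproducible, tested strain-level
statistics from per-site allele counts, plus a community-level
co-occurrence layer on species abundance tables.

## What it computes

Working from pooled per-site base counts (a simple TSV "sitecounts" format,
optionally produced from filtered SAM/BAM), the pipeline applies the
standard gates — MAPQ ≥ 30, percent identity ≥ 96%, uniquely-best read
pairs, and a sample × genome cutoff of ≥ 50% of the genome covered at ≥ 5×
— pools samples by population, and then computes:

- **SNPs** — biallelic sites where the pooled minor allele reaches a count
  and frequency threshold (defaults: coverage ≥ 5, minor count ≥ 4, minor
  frequency ≥ 0.05), with codon-aware synonymous/nonsynonymous annotation.
- **Nucleotide diversity** — per site, the unbiased mean pairwise
  difference among reads, π = n/(n−1)·(1 − Σ p²); aggregated over *all*
  gated positions (variant and invariant) per gene and genome.
- **Linkage disequilibrium** — D′ = |D|/D_max from haplotype counts
  observed on single reads or read pairs covering both sites; D′ < 1 only
  when all four allele combinations of a site pair are observed, so clonal
  populations sit at 1 and recombination pulls the aggregate down.
- **Selection** — pN/pS with equal-weight Nei–Gojobori potential-site
  counting, per gene and genome-wide; Fisher + Benjamini–Hochberg scan for
  genes under positive selection (pN/pS > 1 and significantly above the
  genomic background); Kruskal–Wallis + Dunn (Holm) comparisons of gene
  classes such as the nitrification genes *amoA/amoB/haoA/haoB/nxrA/nxrB*.
- **Differentiation and sweeps** — Hudson F_ST per site (coverage ≥ 20× in
  both populations) and ratio-of-averages per gene; runs of consecutive
  high-F_ST genes as candidate loci, tested against the genomic background
  (Wilcoxon on site D′, t-test on site π, both BH-corrected); loci with low
  diversity *and* high linkage flagged as recent selective sweeps; Jaccard
  allele-profile dissimilarities and Mantel tests.
- **Compositional ecology** — count-zero-multiplicative replacement,
  centered log-ratio transform, proportionality ρ = 1 − var(xᵢ−xⱼ)/(var xᵢ
  + var xⱼ), co-occurrence edges at ρ > 0.56 with a permutation FDR
  estimate, and species richness summaries.

A synthetic-community simulator with full ground truth (haplotype pool at a
target π, tunable nonsynonymous fraction, segment-reassortment
recombination, Dirichlet population structure, Poisson read depth with
sequencing error) stands in for raw metagenome data and backs the test
suite end to end.

## Worked example

Simulate a 3-population community (30 kb coding genome, 20 haplotypes,
target π = 0.01, 50× coverage) and run every stage:

```python
from strainpop.pipeline import RunConfig, run_pipeline

cfg = RunConfig(outdir="demo", seed=42,
                simulate=dict(genome_length=30_000, n_genes=30, n_populations=3))
run_pipeline(cfg)
```

`demo/genome_stats.tsv` then contains (rounded):

```
species population     pi  dprime   pnps  snp_count  snps_per_mbp
    sim        ALL 0.0113  0.9954 0.1692       1025       34166.7
    sim        WW1 0.0099  0.9980 0.1728        661       22033.3
    sim        WW2 0.0109  0.9976 0.1717        728       24266.7
    sim        WW3 0.0105  0.9970 0.1620        727       24233.3
```

Reading: each population carries about 1% sequence microdiversity
(tens of thousands of SNPs/Mbp); D′ near 1 means essentially clonal
evolution (the default simulation has no recombination); pN/pS ≈ 0.17
signals strong purifying selection (the simulator's default nonsynonymous
mutation fraction is 0.2).  The manifest additionally reports the mean gene
F_ST between population pairs (≈ 0.14 here — sizeable allopatric
differentiation induced by the Dirichlet α = 0.5 population structure).

The same stages are available as subcommands of the `strainpop` CLI
(`simulate`, `filter`, `pool`, `call`, `diversity`, `linkage`, `selection`,
`fst`, `mantel`, `ecology`, `run-all`).

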