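# Methods

This note documents the statistical models implemented in `strainpop`, the
design choices made where several defensible options existed, and what the
synthetic-data tests do and do not demonstrate about real metagenomes.

## Input model and gating

The unit of analysis is a species reference genome (contigs + CDS models)
together with per-sample, per-site counts of A/C/G/T from mapped reads
("sitecounts").  Coordinates are 1-based inclusive throughout; only CDS
features are consumed from GFF3; reference `N` positions are excluded from
every statistic.  Minus-strand genes are stored with their coding-strand
sequence at load time, so all codon logic downstream is strand-agnostic,
while nucleotide-level statistics (π, D′, F_ST) never consult strand.

Read-level filters keep alignments with mapping quality ≥ 30, percent
identity ≥ 96 computed as (aligned columns − edit distance)/aligned columns
(soft clips excluded), and a uniquely best mapping pair (alignment score
strictly above the suboptimal score).  When the pipeline starts from a
sitecounts table these filters are assumed pre-applied and the manifest
records which entry point was used.  A sample × genome combination enters
the analysis only when ≥ 50% of the genome is covered at ≥ 5×; both
boundaries are inclusive.  Retained samples are summed per population
(waterworks), and a synthetic `ALL` population sums every retained sample.
For gene-level statistics, genes whose mean coverage in a population lies
outside 2 standard deviations of that population's per-gene coverage
distribution are excluded, independently per population.

## Diversity

Per-site diversity is the unbiased average pairwise difference among
sampled reads, π = n/(n−1)·(1 − Σ_b p_b²), undefined below 2 reads.  Gene
and genome aggregates divide the summed site values by the number of *all*
gated positions (variant plus invariant) in scope.  This denominator choice
is deliberate: it is what makes genome-scale π magnitudes (∼10⁻³–10⁻²)
comparable across populations and species; using variant sites only would
conflate diversity with SNP density.  SNP density is reported separately as
SNPs/Mbp over the same denominator.

SNP calling operates on the pooled `ALL` population: a site is a SNP when
coverage ≥ 5 and the second most common base reaches 4 reads and 5%
frequency.  These thresholds follow common strain-metagenomics practice and
are exposed in configuration; lowering the frequency threshold can only add
calls (tested as a superset property).  Sites where a third allele also
passes the minor thresholds are retained with class `multi`: they
contribute to π through the full Σ p² but are excluded from the biallelic
pN/pS and D′ machinery.  For effect classification the substituted allele
is the called allele that differs from the reference (the major allele when
it differs, otherwise the minor).

"Common SNPs" for the major-allele matrix are calls covered strictly above
5× in every retained population; entries are the frequency of the
`ALL`-major allele.  A local population is flagged as a candidate clonal
expansion when its mean coverage is ≥ 10× but its genome π is ≤ 10% of the
species-wide (`ALL`) value — high abundance with almost no microdiversity.

## Linkage disequilibrium

Haplotype counts at a SNP pair come only from physically linked
observations: single reads or read pairs covering both sites, restricted to
each site's top-2 alleles.  With p_A, p_B the joint marginal frequencies,
D = p_AB − p_A·p_B and D′ = |D|/D_max with the usual frequency-dependent
maximum.  D′ = 1 exactly whenever at most three of the four combinations
are observed (verified exhaustively in the tests); values a few ulp above 1
from floating point are snapped to 1.  Defaults: pairs within 500 bp
(roughly the span of 2×150 bp reads with short inserts) and ≥ 10 joint
observations.  The headline aggregate is the unweighted mean D′ over
qualifying pairs — the aggregation weighting is genuinely open, and the
unweighted mean was chosen and documented; a per-distance decay table is
emitted for diagnostics only.  Pairs with a site monomorphic among the
joint observations are skipped.

## Selection

Synonymous/nonsynonymous classification compares the reference codon with
the substituted codon under the bacterial code (translation table 11);
stop read-through counts as nonsynonymous, stop-to-stop as synonymous.
Codons carrying several SNPs classify each SNP against the reference codon
independently — polymorphism counting, not substitution-path counting.
Potential sites use equal-weight Nei–Gojobori counting (no
transition/transversion bias): per codon position, the synonymous fraction
of the three possible substitutions; S + N = 3 × codons exactly.

pN/pS = (nN/NN)/(nS/NS) per gene; the genome level sums the raw counts over
retained genes before taking the ratio.  Genes with pS = 0 and pN > 0 are
undefined ("infinity" flagged), excluded from population means with the
number of exclusions logged, but they do satisfy the "above 1" condition of
the outlier scan.  Positive selection is scanned with a one-sided Fisher
exact test of each gene's (nN, nS) against the rest of the genome,
Benjamini–Hochberg corrected; outliers need adjusted p < 0.05 *and*
pN/pS > 1.  The choice of Fisher + BH is a package decision — the
requirement is "significantly above the genomic average" with no canonical
test — and is isolated behind one function so it can be swapped.

Gene classes (e.g. nitrification genes vs the rest) are compared with
Kruskal–Wallis followed by pairwise Dunn z-tests (joint-rank, tie-corrected)
with Holm adjustment; a compact letter display (maximal cliques of the
not-significantly-different graph) summarises the result, classes sharing a
letter being statistically indistinguishable.

## Differentiation and sweeps

The site estimator is Hudson's two-population F_ST, 1 − H_w/H_b, with the
small-sample within-population heterozygosity correction n/(n−1); it is the
standard recommendation for sequence data with unequal depth.  A Nei G_ST
alternative is available by configuration.  Only sites covered ≥ 20× in
both populations are used; sites with H_b = 0 are skipped.  Gene values are
ratio-of-averages (Σ H_w / Σ H_b), the variance-stabilising convention,
clamped to [0, 1] with clamp events logged.  Because the field is ambiguous
about averaging, the genome summary reports both the mean over all
gene × pair values and the mean of per-pair means.

High-F_ST loci are runs of ≥ 3 consecutive genes (genome order within a
contig) with gene-F_ST z-score ≥ 2 against the genome's gene-F_ST
distribution; the scan refuses to run with fewer than 30 background genes.
Both the window length and z cutoff are configuration.  Per locus, site D′
inside vs outside is compared with a two-sample Wilcoxon rank-sum test and
site π with a two-sample t-test, each family BH-corrected across loci.  A
locus is a sweep candidate only when both tests are significant *in the
sweep direction*: diversity below and linkage above the genomic mean.

Allele-profile dissimilarity between populations is the Jaccard distance on
binarized profiles, an entry being "present" when the population's major
allele equals the species-wide major allele (frequency ≥ 0.5) — the exact
binarization is not canonical and this convention is documented here.  The
Mantel test correlates off-diagonal entries (Pearson) with significance
from row/column permutations, two-sided, observed value included in the
null set so p ≥ 1/(n_perm + 1); default 100,000 permutations, seedable.

## Compositional ecology

Abundance tables are compositions: zeros are replaced by the
count-zero-multiplicative convention (δ = 0.65 × the sample's smallest
nonzero proportion — the conventional default of that method family,
configurable — with multiplicative rescaling of the nonzero part), then
centered log-ratio transformed.  Proportionality is
ρ = 1 − var(clrᵢ − clrⱼ)/(var clrᵢ + var clrⱼ) with sample variances;
co-occurrence edges keep pairs with ρ > 0.56, and the false-discovery rate
at a grid of cutoffs is estimated by permuting each species' sample labels
independently (mean permuted exceedances / observed exceedances).  The
field's sources waver between cutoffs 0.55 and 0.56 for this network; 0.56
is the default here and the cutoff is configurable.  Richness is the count
of species strictly above 0.5% relative abundance.

## The simulator

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

- **Reference**: a random single-contig coding genome; n non-overlapping
  CDS (ATG start, stop-free interior, stop codon) covering ≥ 60% of the
  genome, random strands, optionally labelled with the six nitrification
  gene classes.
- **Haplotypes**: mutations are placed under an infinite-sites
  approximation (collisions resampled), which keeps the mapping between
  mutation count and expected diversity analytic.  Each mutation attaches
  to a uniformly chosen clade of a random bifurcating relatedness tree over
  the haplotypes, so derived alleles are nested as in a clonal genealogy:
  without recombination every site pair shows at most three haplotype
  combinations (D′ = 1), and segment-reassortment events (expected
  `recomb_rate` per haplotype; random intervals swapped between random
  haplotype pairs) are what erode linkage.  This is a relatedness structure
  only — no coalescent times are simulated.  The mutation count is
  calibrated as target_π × genome length / E[het per mutation], the
  expectation computed exactly from the realized clade sizes.
- **Mutation classes**: within CDS a mutation is nonsynonymous with
  probability `ns_fraction`, realized by choosing an admissible
  substitution given the codon (sites with no admissible option are
  resampled and logged); intergenic mutations are class-free.
- **Population structure**: per-population haplotype frequency vectors from
  a symmetric Dirichlet(α); smaller α ⇒ stronger differentiation; α = ∞ is
  the no-differentiation limit.  The truth object stores realized π and
  per-site Hudson F_ST recomputable exactly from haplotypes + frequencies.
- **Observation model**: per sample and site, depth ∼ Poisson(coverage)
  (negative binomial via an overdispersion switch), each read drawn from a
  haplotype by the population's frequencies and miscalled uniformly to
  another base with probability `error_rate`.  Counts-level emission is the
  contract; read-pair emission (150 bp pairs, ∼350 bp inserts) exists for
  the physical-linkage D′ stage.

Defaults mirror the study conditions the package is aimed at: π = 0.01
(mid-range microdiversity), ns_fraction = 0.2 (strong purifying selection,
genome pN/pS well below 1), recomb_rate = 0 (near-clonal populations),
coverage 50×, error 10⁻³, 4 populations × 2 samples with Dirichlet α = 0.5
(sizeable allopatric differentiation).  Twelve waterworks are desk-scaled
to 4 populations and genomes of tens of kb; every stage is deterministic
given the root seed (each stage derives its own stream).

What the simulator does *not* model — and what passing tests therefore do
not establish about real data: indels and structural variation, gene
content differences between strains (pangenomes), mapping artefacts and
reference bias, within-sample relatedness between reads beyond the
haplotype frequencies, GC- or position-dependent coverage, and realistic
site-frequency spectra (clade sizes of a random merge tree are not a
neutral coalescent SFS).

## Numerical conventions and degenerate inputs

Undefined values are NaN with logged context rather than errors wherever
the definition of the statistic allows it: π below 2 reads, D′ with a
monomorphic site, F_ST with H_b = 0 or coverage below the gate, pN/pS with
pS = 0.  F_ST and D′ are clamped/snapped into their theoretical ranges with
events logged.  The gene coverage gate applies no exclusion below 3 genes;
the locus scan refuses below 30 genes; the positive-selection scan refuses
below 20 genes; proportionality needs ≥ 3 samples.  BH/Holm corrections
are applied within the test family they belong to.

## Problem sizes in the test suite

The suite exercises the full loop at desk scale by choice: 10–60 kb
genomes, 10–50 genes, 20 haplotypes, 30–50× coverage, 2–4 populations.
Recovery checks compare estimates against simulator truth: genome π within
15% of target over 10 seeds (at error 0, since sequencing error adds ≈ 2e
to π and the recovery check isolates the diversity parameter); mean F_ST
monotone in Dirichlet α (3 levels × 5 seeds); aggregate D′ strictly lower
at recombination rate 20 than in the clonal case (5 seeds); genome pN/pS
below 1 in every replicate at ns_fraction 0.2.  Exact laws (π vs read-pair
enumeration, the S/N classifier vs translation over all 576 codon
substitutions, the D′ three-class law over all tables with total ≤ 8, site
F_ST vs the closed form) are verified exhaustively or over large random
samples.
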