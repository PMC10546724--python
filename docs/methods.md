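# Methods

This note documents the models implemented in `cistrans`, the assumptions
behind them, the defaults that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open. Every empirical number quoted here is computed by the
test suite or by `scripts/acceptance.py`.

## Study design assumed throughout

A two-group donor cohort (disease "LOAD" vs. "Normal"), paired snRNA-seq and
snATAC-seq per donor, nuclei pre-assigned to cell-subtype clusters, and
per-nucleus label-transfer prediction scores consumed as input (the package
does not perform normalization, batch integration or label transfer).
Default synthetic sizes: 24 donors split 12/12, 200 RNA and 800 ATAC nuclei
per donor, 3 clusters, 60 genes, 120 peaks on two 10-Mb chromosomes. These
are desk-scale analogues of the motivating study design, chosen so the full
suite runs in minutes; the ATAC side is deeper than the RNA side because
k-nearest-neighbor aggregation (k = 50) needs the number of effectively
independent aggregated groups per cluster (≈ n/k) to be large enough for
partial-correlation estimation.

## Per-nucleus QC and cluster linking

RNA nuclei pass when 200 ≤ features ≤ 10,000, mitochondrial fraction
≤ 17.4 % (a data-driven threshold in the motivating study; configurable),
top prediction score x₁ ≥ 0.5 and hybrid score (x₁−x₂)/x₁ ≥ 0.2. ATAC
nuclei additionally need nucleosome signal ≤ 4 (mononucleosome 147–294 bp
over nucleosome-free < 147 bp counts), TSS enrichment ≥ 2, ≥ 15 % of
fragments in peaks, 1000 ≤ peak-region fragments ≤ the per-sample 99th
percentile, and blacklist ratio ≤ 5 %. TSS enrichment compares per-bp
fragment-midpoint density in ±100 bp of a TSS against two 100-bp flanks at
±1900–2000 bp; the window sizes are a common-practice choice (the metric's
definition does not fix them) and are configurable. Every removed nucleus
carries the full list of failed rules, and filtering is idempotent.

ATAC→RNA cluster links take the argmax of prediction scores summed over the
ATAC cluster's nuclei; ties break deterministically to the lowest cluster id
and are flagged. The cluster-level hybrid score reuses the (s₁−s₂)/s₁ form
on the summed scores. When a multiome-style fixture provides both
assignments per barcode, links are validated by the Jaccard index of
barcode compositions.

## Cohort statistics

Demographics: Shapiro–Wilk gates (p > 0.05 in both groups) a pooled-variance
two-sample t-test (with a Bartlett equal-variance check) versus a two-sided
Mann–Whitney U. From printed summaries, the pooled t is computed directly
from (mean, SD, n). Cell-type proportions: per-donor proportions are
recomputed on 30 random 20 % subsamples of nuclei and compared between
groups by two-sided Wilcoxon rank-sum per unit; the 30 p-values are
combined by their arithmetic mean by default (median and Fisher's method
are options — how the motivating analysis collapsed the 30 iterations is
not stated, so the choice is exposed rather than silently fixed), then
BH-adjusted across units with significance tiers at FDR < 0.05/0.01/0.001.

## Peak calling and consensus

A windowed approximation of dynamic-λ Poisson calling: 200-bp windows at
100-bp steps; the local rate is the maximum of the genome-wide fragment
rate and the rates in centered 1/5/10-kb spans, rescaled to the window;
windows with upper-tail Poisson p ≤ 1e-5 are merged when they touch (the
motivating text prints "10e-5", read here as the conventional 1e-5;
configurable). Consensus across samples groups peaks by single-linkage
interval overlap and combines member p-values with Fisher's method
(X² = −2Σln pᵢ, df = 2k), keeping groups supported by ≥ 2 samples at BH
FDR ≤ 0.05, with union-span coordinates.

## Covariate selection

Counts are summed per donor ("pseudobulk"), features zero in > 20 % of
donors are dropped, and the matrix is centered/scaled. Per round: PCA; all
PCs with variance fraction > 0.10 are each regressed on every remaining
metadata variable one at a time (categoricals by one-way F-test); the
Bonferroni family is (#PCs × #variables); among significant hits the
selection anchors on the top retained PC, falling back to the
highest-variance PC with any significant variable (the source description
is ambiguous between "PC1" and "the PC explaining the most variability";
both readings are logged per round so either can be audited). All features
are residualized on the selection and the loop repeats until nothing is
significant, with a hard cap at the number of variables.

## Differential expression: the mixed two-part hurdle

For one gene in one cluster, with y the raw count and z = log₂(y+1):

- detection: logit P(y > 0) = Xβ_d + a·u_donor
- magnitude: z | y > 0 ~ N(Xβ_c + b·u_donor, σ²), u_donor ~ N(0, 1)

X contains intercept, diagnosis, the selected covariates, centered/scaled
cellular detection rate, and the donor's cluster proportion. The two parts
share **one** donor random intercept with separate loadings (a ≥ 0, b
free). This is deliberate: fitting the parts separately and summing their
LRTs double-counts the common donor-level contrast — the summed statistic
approaches 2·χ²₁ when donor variation dominates, giving a measured null
level of 0.083 at nominal 0.05 — whereas the shared-intercept model makes
the 2-df LRT (diagnosis dropped from both parts at once) a true likelihood
ratio. The marginal likelihood integrates u per donor by adaptive
Gauss–Hermite quadrature (9 nodes, re-centered at the per-donor posterior
mode found by a vectorized Newton iteration); warm starts come from a
GH-quadrature logistic mixed fit and a profiled-likelihood linear mixed fit
(ψ = τ²/σ² profiled to a 1-D search with closed-form GLS).

Genes expressed in < 10 % of nuclei in both groups are skipped. The
reported log₂FC is the empirical difference of mean log₂(y+1)
(disease − control) — reproducible and auditable; the model coefficient is
a secondary column. BH adjustment is per cluster.

Measured operating characteristics (negative binomial counts, dispersion 2,
24 donors × 200 nuclei): power for a +0.5 log₂ planted effect at donor SD
0.2 is 96/100 seeds at BH FDR < 0.05 in a 5-gene family; null level at
donor SD 0.3 is ≈ 0.073–0.09 against the nominal 0.05 while a
donor-ignorant hurdle rejects ≈ 0.3–0.4 of nulls. The residual
anti-conservatism is the χ² reference itself at 24 donors — with the same
generator it falls to 0.060 at 48 donors and 0.047 at 96 — a known
small-sample property of likelihood-ratio tests for donor-level contrasts,
shared by the standard tooling this model mirrors; it is documented rather
than patched with a nonstandard reference distribution.

## Differential accessibility

Logistic regression of diagnosis on nucleus covariates (peak-region
fragments, fraction of fragments in target regions, cluster proportion,
age, sex, PMI) with versus without the peak's per-nucleus fragment count
(raw by default; log1p available), 1-df LRT, BH per cluster. Peaks detected
in < 2.5 % of nuclei are skipped (no filter is stated in the motivating
text; configurable). Separated fits are ridge-stabilized and flagged. This
test has **no donor random effect** (faithful to the method it mirrors);
its calibration is therefore assessed on data without donor-level peak
heterogeneity, and pseudoreplication sensitivity is a known limitation.

## Co-accessibility and CCANs

Disease-group nuclei of one cluster are aggregated by summing counts over
groups of k = 50 nearest neighbors in the embedding (greedy seed selection
rejecting groups sharing > 80 % of members with an accepted group), each
group divided by its total fragments × 10⁴. Per chromosome, in overlapping
1-Mb windows (50 % overlap), the correlation matrix of aggregated profiles
enters a graphical lasso whose elementwise penalty is
ρ_ij = ρ₀·(d_ij/500 kb)^γ with ρ₀ = 0.1, γ = 0.5 — the reference method
states only that the penalty grows with genomic distance; this form is
smooth, bounded, and recovers planted blocks at mixed distances — and pairs
beyond 500 kb are excluded from the precision support outright. The block
coordinate-descent solver accepts an arbitrary penalty matrix (the
scikit-learn implementation only takes a scalar). Scores are partial
correlations from the precision matrix; window-boundary duplicates are
averaged. CCANs are Louvain communities (weight = score, resolution 1,
fixed seed) of the score ≥ 0.2 graph with ≥ 3 peaks (a 2-peak community is
just an edge; configurable).

On well-separated planted blocks (5-peak equicorrelated precision at
partial correlation 0.24, 500 Gaussian samples) the in-block vs.
out-of-block edge AUROC is 1.0 and the Louvain partition matches the blocks
at adjusted Rand index 1.0. On count-level data at the default synthetic
depth the anchor–cCRE edge estimate has a standard deviation of roughly
0.1 around ≈ 0.3, so a ~10 % minority of planted edges fall under the 0.2
score threshold in any one run; the candidate screen is therefore asserted
as the deterministic filter it is (everything satisfying the criteria is
emitted), with planted-module recall reported as a measured quantity.

## CCAN classification, cCREs, GO

Promoters are [TSS−2000, TSS+200) strand-oriented; first introns come from
the exon structure (single-exon genes anchor by promoter only, logged).
All (DAP, DEG-anchor) sign pairs classify a CCAN as unidirectional (all
concordant), bidirectional (none), or mixed; CCANs lacking a DAP or a DEG
anchor are unclassified and excluded. cCRE links require, within
unidirectional/mixed CCANs: co-accessibility ≥ 0.2 between the DAP and a
DEG promoter/intron-1 anchor peak; the anchor itself a DAP; sign
concordance of DAP, anchor and DEG; |DEG log₂FC| ≥ 0.15; and the cCRE
noncoding — defined here (the source leaves "noncoding" undefined) as
overlapping no annotated exon and no promoter of any gene. GO enrichment is
a one-sided hypergeometric test per term against a background of genes
expressed in ≥ 10 % of the cluster's cells, reporting terms with p ≤ 0.05
and ≥ 3 mapped test genes. GWAS windows are ±500 kb of a tag SNP,
inclusive at the boundary.

## Motifs and regulatory SNPs

PWM entries are log₂[(count + 0.8)/(total + 3.2) ÷ background stationary
probability] (pseudocount 0.8 per column, standard JASPAR practice). The
null score distribution of an L-window under the first-order Markov
background is computed exactly by dynamic programming over (position,
previous base, score discretized to 1e-3-bit bins); the match threshold s*
is the smallest achievable score with tail ≤ 5e-5, and p(s) is exposed for
arbitrary scores. Scores computed from the unrounded matrix can differ from
binned sums by at most L·(bin width), and every threshold comparison uses
that tolerance. Against exhaustive 4^L enumeration (L ≤ 6) the DP tail is
exact to < 1e-10. Scanning covers both strands; overlapping same-TF hits
collapse to the best score (ties: leftmost, then '+').

Motif enrichment resamples background peaks to the target GC histogram in
5 % bins, then tests the count of target peaks with ≥ 1 hit against the
background hit fraction with a one-sided binomial upper tail; retained
motifs need fold ≥ 1.2, BH FDR ≤ 0.05, and TF expression in ≥ 10 % of the
cluster's cells. The GC-stratified background is a deliberate, auditable
replacement for the reference tool's n-mer autonormalization.

The affinity-change test: for a SNP centered in its 2L−1 context, the
observed statistic is the difference of best L-window scores (windows
covering the SNP, both strands) between reference and alternate alleles.
Its null is the same statistic on background-Markov sequences; the tail is
estimated by importance sampling — proposals place a motif-sampled
L-subsequence at a uniform offset with background flanks, and each draw is
weighted by the null/proposal density ratio; the weighted exceedance
indicator averaged over N = 100·L draws is one run's unbiased p estimate
("N determined by the motif length" is not further specified; 100·L keeps
the per-run Monte-Carlo error roughly length-independent). 1000 runs give
the mean/variance/min/max summary. Where the sampling scheme's description
is ambiguous, the implementation is pinned by agreement with the
exhaustive-enumeration oracle at small L (within 3 Monte-Carlo SEs at
L = 3, 4^(2L−1) contexts), which is the normative definition here. The
per-run variance scales as 1/N (verified at N vs. 4N).

Candidate SNP×TFBS pairs must satisfy all of: (a) inside a DAP; (b) in a
unidirectional/mixed CCAN; (c) CCAN within 500 kb of a GWAS tag SNP;
(d) the DAP co-accessible (≥ 0.2) with a DEG promoter/intron-1 anchor;
(e) DAP and DEG sign-concordant; (f) exact motif p ≤ 5e-5 for the major or
minor allele (evaluated against the shared background); (g) TFBS overlaps
the SNP; (h) MAF ≥ 1 % (multiallelic sites contribute only alleles ≥ 1 %).
Flagship rows additionally need BH FDR ≤ 0.01 on the mean Monte-Carlo p,
TF expression ≥ 10 %, and |target DEG log₂FC| ≥ 0.15.

## The synthetic-data generator

The generator is deterministic given (config, seed): every random stream is
a named child of the config seed, and regenerating produces byte-identical
files. It emulates: cluster structure with donor multinomial sampling;
negative-binomial gene counts (dispersion 2) with per-(gene, donor)
log₂-scale random intercepts (SD 0.2) so donor pseudoreplication is real;
Bernoulli-thinned-Poisson peak fragment counts; planted cluster-specific
differential effects (multiplicative 2^log₂FC in disease nuclei — the
log₂(x+1)-scale effect is therefore attenuated relative to the latent
value, and only the sign is a construction guarantee); within-block
co-accessibility via per-nucleus latent Gaussian vectors with a chain
(tridiagonal) precision, because a single shared factor per block spreads
the dependence so thin that pairwise partial correlations cannot clear the
0.2 score threshold by construction; QC-violating and hybrid nuclei at
configured fractions; peak sequences from a first-order Markov background
(uniform by default) with motif instances sampled from the PWM columns and
retried against the exact 5e-5 threshold (consensus fallback for very sharp
motifs); loss SNPs as consensus→weakest-base substitutions and gain SNPs as
planted-weak-base→consensus substitutions, verified at generation to move
the best-window score by ≥ 1 bit in the intended direction; rare-allele and
GWAS-window decoys; and coherent causal modules (anchor gene at +0.75
log₂FC — a flagship-scale effect, while the +0.5 power analyses use their
own single-purpose fixtures — distal noncoding cCRE peak, motif, common
SNP, tag SNP within 500 kb).

It does **not** emulate: read-level data (FASTQ/BAM), ambient RNA, barcode
collisions, doublet expression profiles (hybrids are planted directly in
the prediction scores), realistic LD between SNPs, genome sequence
composition, or batch effects. Passing tests therefore demonstrate the
correctness and calibration of the statistical chain under its stated
assumptions, not robustness to artifacts the generator omits.

## Problem sizes used by the tests and acceptance script

Chosen so one serial run of the suite takes well under half an hour: hurdle
power at 100 seeds × 5-gene families and null calibration at 200 seeds
(the type-I comparison is definitive at this size because the
donor-ignorant level is ~6 standard errors above nominal); the end-to-end
run at the default synthetic sizes with 300 Monte-Carlo affinity runs (the
run count only tightens the variance summary; each run is unbiased); motif
DP oracle over 20 random PWMs with L ≤ 6; co-accessibility recovery at 500
aggregated samples. The acceptance script mirrors these sizes with 50/150
seeds for the hurdle study and 1000 affinity runs.

## Known limitations

- The 2-df hurdle LRT is mildly anti-conservative at 24 donors (see above);
  with ~50+ donors it is nominal.
- The binomial DA test inherits the pseudoreplication sensitivity of the
  method it mirrors.
- Partial-correlation edge estimates at desk-scale aggregation depths are
  noisy near the 0.2 threshold; CCAN membership is stable but individual
  borderline edges are not.
- The affinity-change null treats flanking sequence as background Markov;
  contexts inside strong repeats would violate this.
- Windowed co-accessibility estimation (1 Mb, 50 % overlap) averages
  boundary duplicates; extremely long-range (> 500 kb) interactions are out
  of scope by definition.
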