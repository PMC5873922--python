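# Methods

This note records the models, conventions and numerical choices behind
`inbredpanel`, in the order the pipeline runs them.

## Genotype representation and filtering

Genotypes are allele-count codes 0/1/2 for a "counted" allele
(reference by default, per-site sample minor allele on request) with −1
for missing; heterozygotes are 1 under either policy and the policy
flip x → 2−x is involutive. VCF (v4.x) parsing goes through cyvcf2;
writing produces plain VCF v4.2 with GT/DP/GQ. Genotype confidence is
taken from GP directly or from GQ as 1 − 10^(−GQ/10); calls strictly
below the 99% default are masked to missing, and a matrix without
confidence fields passes through unchanged with a logged warning.

Site filters apply in a fixed order so removal reports are
reproducible: biallelic SNP → depth summary in [5, 60] reads → call
rate ≥ 80% → MAF ≥ 5%. All thresholds are inclusive; MAF inclusivity is
a deliberate choice where "above 5%" and "minimum of 5%" both appear in
common usage. The depth summary is the across-line mean by default with
a median option, since panels are described both ways in practice. MAF
is computed on diploid allele counts over called lines only
(heterozygotes contribute one copy). Coordinates are 1-based inclusive
at the VCF/GFF boundary and 0-based half-open internally. Whether call
rate should be applied before MAF is not fixed by any external
constraint; the order above is this package's convention.

Site classification against a GFF3 (gffutils, in-memory) is
exon > intron > intergenic by priority: inside any exon → exonic, else
inside a gene body → intronic, else intergenic; contigs missing from
the annotation classify as intergenic with a warning.

## Full-sib inbreeding theory

The inbreeding coefficient follows the classical recurrence
F_t = (1 + 2F_{t−1} + F_{t−2})/4, initialized F_0 = F_{−1} = 0
(wild-caught founders treated as unrelated and non-inbred). Expected
residual heterozygosity is 100·(1 − F_t) percent of founder
heterozygosity: 1.4% at t = 20. 1 − F_t shrinks asymptotically by the
largest root of the recurrence, (1 + √5)/4 ≈ 0.809, per generation.
Generation counting: t is the number of brother–sister matings; the
founder pair's brood is generation 1 and the emitted individual is an
offspring of the t-th sib mating, which carries exactly F_t. A
Monte-Carlo gene-dropping oracle in the test suite checks this
convention independently.

Heterozygosity summaries intentionally use the unfiltered (no MAF/depth)
site set. Per-line values use only non-missing calls in the
denominator; lines or sites with zero calls are flagged undefined and
excluded from panel means. The heterozygosity–depth Spearman
correlation (midrank ties, large-sample p) is the diagnostic for
collapsed duplications: paralogous reads mapping to one locus inflate
both apparent heterozygosity and depth.

## Relatedness and the eigenvalue substructure test

The GRM is the standardized allele-sharing average over SNPs; missing
genotypes are mean-imputed to 2p_i, which contributes zero to the
centered cross-product and keeps the SNP count N constant across pairs
(the imputation rule is a package choice, matching common GRM
practice). Sites monomorphic after imputation are skipped with a
warning. Under "standard" scaling identical fully-inbred lines score
≈ 2 because their allele-count variance is twice the outbred binomial
variance; the default "inbred" scaling divides by two so duplicates
score ≈ 1, which is the scale on which a relatedness cutoff of 0.1 and
the reduction of related pairs operate. Panel reduction removes the
lexicographically last line id of each connected component of the
flagged-pair graph — one line per component, deterministic.

The substructure test works on the uncentered, unnormalized
minor-allele count matrix C (M lines × N complete-data SNPs). The
scaling, isolated in `rmt_scale_gram`, is

    X = C C′ / ( 2 · Σ_i 2 p_i (1 − p_i)(1 + F) · (1 + √(M/N))² ).

Rationale: the count variance of an individual at inbreeding F is
2p(1−p)(1+F), so dividing the Gram matrix by twice the summed variance
sends the noise-bulk eigenvalues to 1/2 as N/M → ∞, and the
(1 + √(M/N))² factor absorbs the finite-sample Marchenko–Pastur edge.
Each distinct subpopulation mean contributes one eigenvalue separated
from the bulk — including the single Perron eigenvalue of a homogeneous
panel, carried by the positive mean of the uncentered counts — so the
number of eigenvalues above t = (1 + F)/2 (0.993 at F_20 = 0.986,
strictly above the bulk since t ∈ (0.5, 1]) estimates the number of
subpopulations. A duplicated line doubles one noise direction and
produces a spike near 2·(1/2) = 1, which is why contaminated duplicate
pairs can masquerade as a second subpopulation until removed. Ties at
the threshold count as not significant. The test consumes either a raw
count matrix or an already-scaled square matrix (as distributed in
published relatedness-matrix text files); symmetric input is required
to 1e-8.

## Diversity, neutrality, LD

Per site with j alternate copies among n called alleles the mean
pairwise difference is 2j(n−j)/(n(n−1)); windowed π sums these over a
0-based half-open tile and divides by the tile length in bp (trailing
partial windows use their true length when scaffold lengths are
supplied). Missing calls reduce n per site; nothing is imputed, unlike
the GRM. Tajima's D uses the 1989 constants with the sample size taken
as the window's mean diploid called-allele count rounded (a
"lines-as-haploid" option exists for fully-inbred treatments, where
within-line allele pairs are not independent draws). D is undefined
(NaN, never 0) for S = 0 or n < 3; at n = 3 every segregating site is a
singleton, both θ estimators coincide and the 0/0 limit resolves to
D = 0. LD r² is the squared Pearson correlation of allele-count vectors
over lines with both sites called (≥ 3 co-called lines required),
restricted to pairs within the same non-overlapping 500 bp tile — a
fidelity choice to the windowed estimation method, not a claim that
cross-tile pairs are uninformative. Decay curves bin distance half-open
([k·b, (k+1)·b)) and report the first bin midpoint at which pooled mean
r² drops below 0.1.

## Mixed-model association scan

The model for replicate j of line i is y_ij = μ + β·snp_i + g_i + e_ij
with g ~ N(0, σ²_A A) and e ~ N(0, σ²_ε I). Fitting is REML through a
spectral rotation: the individual-level polygenic covariance
K = A[lines, lines] is eigendecomposed once, the model rotated, and the
profile REML criterion optimized over γ = σ²_A/σ²_ε by a coarse
log-grid (25 points over e^±12, plus γ = 0) followed by bounded scalar
refinement to 1e-8 on log γ. The grid step guards against local optima;
non-negativity is enforced by the parametrization and boundary hits are
flagged rather than errored. A GRM that is not positive semidefinite
beyond tolerance raises with advice to clip negative eigenvalues at 0
(small negatives are clipped automatically). With A = I and no
replication the two components enter only through their sum; the fit is
flagged non-identifiable and the fixed effects collapse exactly to OLS
— the test suite asserts Wald = t² to 1e-6 in that limit.

The scan re-estimates σ²_A and σ²_ε for every SNP with the SNP effect
included, so the Wald statistic (β̂/se(β̂))² is exact; p-values are
χ²₁ (no small-sample t correction — the replicate-level n of a
~100-line × 4-replicate design makes the difference negligible, and the
asymptotic form keeps the statistic exactly the squared effect/se
ratio). Individuals from lines missing the SNP genotype are dropped for
that test only; the spectral rotation is recomputed per line subset and
cached by subset. The SNP fixed effect is the minor-allele dosage
(0/1/2, additive heterozygotes). SNPs monomorphic among phenotyped
lines or below the MAF floor are reported with an exclusion reason. The
phenotype enters as log(trait/divisor) — the compositional log-contrast
that cancels shared multiplicative variation such as body size — with
strictly positive inputs enforced. Thresholds are Bonferroni
−log10(α/n_tests) and a fixed suggestive −log10 p = 5; at the scale of
~3.3 million tests the Bonferroni line is 7.8. Significant SNPs are
annotated within-gene / near-gene (≤ 3 kb) / intergenic with nearest
gene and distance. A vial/batch random effect is intentionally absent
from the model. Heritability is reported as σ²_A/(σ²_A + σ²_ε), which
presumes the GRM diagonal ≈ 1 (true under inbred scaling); line-mean
analyses can be run by passing per-line means as single replicates.

## Synthetic panel generator

The generator emulates the statistical structure the pipeline assumes,
at desk scale.

*Base variation.* A stationary coalescent (msprime) supplies the
neutral haplotype pool; this replaces a forward Wright–Fisher burn-in,
which at equilibrium it reproduces exactly and instantly. Demography:
one population of size N_e = 200 that expanded 12-fold 100 generations
ago (defaults), producing the rare-allele-skewed SFS and negative
Tajima's D of a large expanding natural population; with K > 1
subpopulations, a split `divergence_generations` ago replaces the
expansion. Mutations are biallelic at discrete positions (duplicate
positions collapsed); zero segregating sites raises an explicit
monomorphic-simulation error. `n_generations_base` is retained in the
config for interface stability but the coalescent pool is already
stationary, so it is unused.

*Defaults as study conditions.* 110 lines, 20 generations of sib
mating, 23.5× mean depth. Mutation rate 3.6e-5 and recombination rate
6e-5 per bp per generation on a 100 kb region are rescaled desk values
calibrated once so the emitted panel shows π ≈ 0.008, window-mean
Tajima's D ≈ −1.25, and LD r² dropping below 0.1 within ~100 bp —
matching the regime of a real inbred fly panel at ~1/30 the genome
size. Per-line residual heterozygosity of the clean simulation
(~0.2% of panel variants) sits near the pedigree expectation given the
founders' heterozygosity at ascertained sites; real panels report
several-fold more because collapsed duplications add apparent
heterozygosity, which the generator reproduces only when
`duplication_artifact` intervals are enabled.

*Lines.* Each line is founded from one mated female: 4 founder
haplotypes drawn from the (sub)population pool. Each generation one
sister and one brother are bred (Poisson crossovers at the configured
rate, uniform positions, Mendelian segregation) and mated; after t sib
matings one female is emitted. All loci are autosomal — X transmission
and sex linkage are not modeled, a known divergence from real fly
panels where X-linked sites fix faster. Sites monomorphic across the
emitted panel are dropped by default (a joint genotyper only reports
variants); theory checks disable this to keep denominators comparable.

*Depth, artifacts, missingness.* Per-genotype depths are negative
binomial (mean 23.5, shape 8 — overdispersion matching shotgun
coverage). Within duplication-artifact intervals depths are multiplied
and a configurable fraction (default 0.3) of homozygous calls becomes
spurious heterozygotes, reproducing the co-elevated depth/het signal.
Genotypes with zero reads plus a 1% random fraction are missing, so the
call-rate filter and the complete-data restriction of the structure
test are exercised.

*Phenotypes.* Line genetic values are Σ β·dosage over planted causal
SNPs plus a polygenic draw with covariance σ²_A·A (A the realized
inbred-scaled GRM, eigenvalues clipped at 0); polygenic + residual
variance is normalized to 1 with polygenic share `h2_polygenic`.
Each line yields 4 replicate individuals. Two positive traits are
emitted — focal = divisor·exp(y) with a shared lognormal nuisance
factor — so the log-contrast transform recovers y exactly and its
common-factor invariance is exercisable. Requesting a causal SNP below
the 5% MAF floor errors with the eligible site list.

Everything is deterministic under (config, seed): msprime seeds and the
numpy generator are derived from the config seed via SeedSequence with
distinct salts per stage.

## What passing tests do and do not show

The simulator provides exchangeable lines, a single scaffold, no
selection, no inversions, no X chromosome, genotype-error-free calls
(outside artifact intervals) and independent residuals. Passing the
suite therefore demonstrates correctness of the estimators and the
statistical calibration of the scan under the model's own assumptions —
type-I error at nominal level over ≥ 2000 null SNPs, ≥ 95% top-hit
recovery for a 50%-variance SNP, heritability recovery with |mean bias|
< 0.05, heterozygosity retention at 1 − F_t, and exact one/two
supra-threshold eigenvalues for one/two simulated subpopulations. It
does not validate robustness to genotyping error models, reference
bias, segregating inversions, or X-linked architecture in real data.

## Problem sizes in the shipped suite

Simulation-backed checks run at 20–120 lines on 8–60 kb regions with
seeds fixed in the tests: 50 replicates for power, 3 panels (> 5000
SNPs pooled) for type-I calibration, 20 replicates for heritability,
20 + 20 seeds for structure detection. These sizes were chosen so
Monte-Carlo intervals are decisive for the asserted properties.
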