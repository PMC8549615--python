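# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, in the spirit of a statistical supplement.

## Study design being modelled

A *translocation system* is a wild source population together with the
refuge populations founded from it.  The default synthetic design has
two systems: system A with one source, two old (≈10 generations,
5–6 founder families) and two young (≈3 generations, 15–18 families)
refuges; system B with one source and two young refuges founded from
25–30 families.  Populations are sampled at 12–30 individuals.  These
sizes put the simulated contrasts in the same qualitative regime as a
real multi-decade translocation programme — small founder bottlenecks,
a handful of generations of drift, and modest sample sizes — while
keeping every test fast on one CPU.

## Synthetic-data generator

**Genotypes.**  Ancestral allele frequencies are i.i.d. Beta(0.8, 0.8)
(a mildly U-shaped spectrum typical of RAD SNP panels before MAF
filtering).  Each system's source pool is one binomial resampling of the
ancestral pool (2 × 500 gene copies), giving the small between-system
divergence that dominates PC1 in the combined data.  A refuge is founded
by drawing 2 × n_families parental diploids binomially from the source
frequencies, then drifting for G Wright–Fisher generations with 2 Ne
gene copies.  Selected loci receive a deterministic frequency shift of
±s per generation (sign chosen to push away from the source frequency
consistently in every refuge, creating shared outliers); fixed loci are
absorbing since there is no mutation.  Sampled genotypes are
Hardy–Weinberg draws from the final frequencies; 3% of calls are masked
as missing.  No linkage, migration, or family structure beyond the
founder draw is modelled — LD enters the pipeline only as a filtering
concern, which is also why LD-based imputation is replaced by genotype
distance (below).

The expected drift differentiation is F = 1 − (1 − 1/(2Ne))^G; the
generator reproduces it within Monte-Carlo error (tested at Ne = 50,
G = 10, where F ≈ 0.0956), measured as the mean of (p′ − p)²/(p(1 − p))
over replicate loci.

**epiRAD counts.**  count_{il} ~ NB(mean = s_i · μ_l · 2^{β_l·refuge_i}
· b_{l,batch(i)}, dispersion φ) with log-normal locus means (CV ≈ 0.8
around a mean of 80 reads), log-normal library-size factors, φ = 0.2 by
default.  Planted differentially methylated loci carry β = ±dm_log2fc
with alternating signs (epiRAD semantics: a methylated cut site yields
*fewer* reads, so β < 0 reads as methylation gain in refuges); 2% of
loci get a 2-fold multiplier in one library to emulate batch effects.
NB draws use the gamma–Poisson mixture; φ < 1e-7 falls back to Poisson.

**Morphology.**  A fixed 14-landmark fish-body template is deformed
along three orthonormal directions, each orthogonalized against the
similarity group (translation, rotation, scaling of the template) so the
planted signal survives Procrustes superimposition: an allometric
direction scaled by log centroid size, and one direction each for the
latent genomic and epigenomic scores.  The weights are chosen so the
planted variance fractions (f_gen, f_epi, f_resid) of a total shape
variance (4e-4 squared-template units) are realized exactly in
expectation, with the residual spread isotropically over all 28
coordinates.  In the full study bundle the latent scores are the first
PC of the realized genotype matrix and the first PC of the log counts
orthogonalized against it, so the downstream variance partitioning has a
well-defined target.  Note that when morphology is reduced to its first
3 PCs (as the integration stage does), noise is filtered and the
*apparent* explained fractions exceed the planted full-space fractions;
recovery tests therefore check fractions in the full Procrustes space.

**Isotopes.**  Stomach (δ13C, δ15N) values are bivariate normal per
population with refuge niches 1.8× wider than source (ecological
release); muscle = 0.8 × stomach + N(0, 0.3) per axis, emulating the
slower isotopic turnover of muscle.

**Determinism.**  One master seed; each component draws from an
independent stream derived by a fixed offset, so any layer can be
regenerated alone.  Identical configs give bit-identical bundles.

## Estimators and tests

**GPA.**  Translate to centroid, scale to unit centroid size, rotate to
the evolving consensus by SVD with the rotation determinant forced +1
(fish are photographed on one side; reflections would be artefacts).
Convergence at consensus change < 1e-10 or 100 iterations.  Tangent-
space projection is omitted: shape variation in this setting is small
(Procrustes distances ≪ 1), where the approximation error is far below
the quantities of interest.

**RRPP.**  Sequential (Type I) multivariate SS; for each term the
residuals of the reduced model (all preceding terms) are permuted, added
back to the reduced fit, and the term's F recomputed; p = (#{F* ≥ F} +
1)/(n_perm + 1).  Permutation p-values are therefore discrete in steps
of 1/(n_perm + 1); calibration checks compare at p ≤ α.

**Trajectory analysis.**  Per system, the trajectory is (mean refuge −
mean source) in the full flattened Procrustes space (equivalent to PC
space with all axes retained).  Refuge populations are pooled per
system; ΔL_P = | ‖v_A‖ − ‖v_B‖ |, θ_P = arccos of the normalized dot
product, permutation by shuffling source/refuge labels within systems.

**Allometric standardization.**  The common slope b per trait is the
pooled within-group slope (Sxx-weighted average of group slopes) of
log10 trait on log10 length; L_st is the arithmetic mean of the raw
measured lengths.

**IDiv.**  Functional-divergence analogue with equal weights: with G
the centroid of the hull vertices, d_i the point distances to G, d̄
their mean, and Δ|d| the mean absolute deviation, IDiv = d̄/(Δ|d| + d̄)
(the signed-deviation term of the general abundance-weighted formula
vanishes at equal weights).  All points on a circle around G give 1.
Scaling is min–max over all populations jointly so hull areas are
comparable.

**QC chain.**  Order: global missingness (33%) → MAF (0.05) → max
observed heterozygosity (0.6) → individual missingness (30%) →
per-population exact HWE (drop if p < 0.001 in > 50% of populations,
full enumeration over heterozygote counts) → per-population missingness
(33%) → one SNP per RAD locus (first by position; configurable).  The
filter report logs counts at every step.

**LD pruning** is a greedy left-to-right scan per chromosome dropping a
SNP whose dosage r² with any retained SNP within 1 Mb reaches 0.2
(composite LD on dosages — phase is unknown for RAD data).

**kNN imputation** replaces the LD-kNNi algorithm of the original
toolchain with plain genotype-distance kNN over shared sites (k = 10,
distance-weighted modal dosage, neighbours restricted to the same
system partition).  This is simpler and deterministic but ignores
site-specific LD, so its accuracy ceiling is the within-neighbourhood
Hardy–Weinberg entropy: recovery is ≥ 90% only when within-population
frequencies are concentrated near fixation (strong bottlenecks), and
lower for mid-frequency loci.  Observed genotypes are never altered.

**Batch blacklisting (genotypes)** picks the PCA axis most correlated
with library batch and flags SNPs with |genotype–score correlation| or
|correlation-scaled loading| > 0.3.  If no axis correlates with batch
beyond the threshold, nothing is blacklisted — a few percent of SNPs
always correlate strongly with *some* PC, so flagging without a genuine
batch axis would only discard information.

**F_H** uses expected homozygosity from the designated outbred source
frequencies without a small-sample correction (the reference-population
requirement is the point of the estimator; the N/(N−1) variant of the
original tool differs by O(1/N) and is documented here rather than
toggled on).  **R_xy** is the genomic-relationship form, averaging
(x_i − 2p)(x_j − 2p)/(2pq) over SNPs with pairwise-complete data; full
sibs average 0.5, unrelated pairs 0.  **θ (F_ST)** uses the two-sample
Weir–Cockerham variance components with the ratio-of-sums estimator as
primary (the mean of per-locus ratios is also reported but is not the
same quantity); negative estimates are retained.  π is computed over
variant sites only and is therefore proportional to, not identical
with, per-nucleotide diversity from all-site denominators.

**RDA.**  Y column-centred; X centred (both residualized on the
condition block for partial RDA); fit by least squares, constrained
axes from the SVD of the fitted values, R² = SS(fit)/SS(total) with the
Ezekiel adjustment 1 − (1 − R²)(n − 1)/(n − k − 1); global test by free
row permutation of the (residualized) response with a pseudo-F.
Rank-deficient designs are handled by the pseudo-inverse with the
effective rank reported.  Outlier calling z-scores the loadings within
the chosen axis across variables; |z| > 2.5 corresponds to a two-tailed
normal p of 0.01.

**Allele-frequency-change z.**  Major allele defined in the pooled
sample; group frequencies average population frequencies with equal
weight (pooled-count weighting available), Δ = mean(source) −
mean(refuge), z = (|Δ| − mean|Δ|)/SD(|Δ|).  The shared outlier set is
the intersection of the RDA and AF-change callers — a deliberate
substitution of the second evidence line (a Bayesian
covariance-matrix model in some workflows) by a calibration-free
statistic that preserves the intersect-two-callers design.

**NB GLMs.**  Per-locus log-link IRLS, vectorized across loci, with
offsets log(library size × TMM factor).  TMM: reference is the sample
whose upper-quartile count/library ratio is closest to the mean;
per-locus log-ratios trimmed 30% per tail on M and 5% per tail on A,
precision-weighted mean, factors rescaled to geometric mean 1.  Common
dispersion maximizes the Cox–Reid-adjusted profile likelihood on an
18-point log grid (1e-4 to 5) with quadratic interpolation; tagwise
dispersions maximize the per-locus APL plus 10 (prior df) times the
average APL, shrinking noisy estimates toward the common value.  DM
testing is a 1-df LRT of the group term against intercept-only with
chi-square p and BH FDR at 0.05; non-converged loci get p = NaN and are
excluded from FDR.  The variance-stabilizing log transform of the
original workflow is replaced by log2(normalized count + 1) — its only
role here is as input to PCA/RDA/heatmaps, where the simpler transform
behaves equivalently at these depths.

**Variance partitioning.**  Unique fractions are adjusted-R²
differences ([gen|epi] = R²adj(gen+epi) − R²adj(epi)); the overlap has
no permutation test and may be negative (suppression) — it is reported
unclipped.  Three PCs per block by default; cohorts with n ≤ k + 4 rows
are refused (too few residual df).

## Problem sizes used in tests and the acceptance script

Null calibrations run 200–1000 simulations per machinery (RRPP
interaction, KW, NB-GLM locus-level p, FST permutation, RDA
permutation), chosen to put the Monte-Carlo SE of a 5% rate near half a
percentage point.  Recovery experiments use the sizes the corresponding
analyses see in practice: drift FST at 500 loci; sib relatedness at 500
SNPs; DM power at 1000 loci, 15/group; RDA outlier power at 2020 SNPs,
120 individuals; variance-fraction recovery at n = 200.  The acceptance
script's study bundle uses 1000 SNPs and 4000 count loci with 199
permutations per test — large enough for stable estimates, small enough
to finish in minutes.

## Known limitations

* Unlinked loci: no LD structure, so LD pruning and the imputation
  accuracy ceiling behave differently from real RAD data.
* Selection is a deterministic frequency shift, not fitness-based;
  planted outliers are exchangeable across refuges by construction.
* Methylation is encoded only through count means; no CpG-level state,
  no region-level smoothing.
* π lacks invariant-site denominators; values are comparable within a
  run, not with published per-nucleotide estimates.
* The permutation engine permutes rows freely; no restricted
  (block/strata) schemes beyond the within-system shuffling used by the
  trajectory analysis.
* Passing tests demonstrate internal consistency and recovery under the
  generator's assumptions (independent loci, NB counts, isotropic
  landmark noise); they do not certify behaviour under real-data
  pathologies such as allele dropout, batch-confounded sampling or
  digitization error.
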