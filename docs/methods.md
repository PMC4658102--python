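# Methods

This note documents the models, numerical choices and limitations of
`popadapt`, in the order the pipeline runs.

## Synthetic data: what it emulates and what it does not

The generators reproduce the study design the pipeline assumes: a
range-wide collection of ~400 genotypes in four climate-defined
subpopulations with very low marker differentiation (mean F_ST ≈ 0.01),
continuous isolation by distance, array-like biallelic SNPs, correlated
temperature/precipitation surfaces, a minority of clinal loci, and
clonally replicated common-garden phenotypes with an additive
architecture.

* **Island genotypes.** Deme allele frequencies follow the
  Balding–Nichols model: ancestral `p ~ Uniform(0.05, 0.95)` (bounded away
  from fixation so MAF filtering does not empty simulated panels), deme
  frequencies Beta-distributed with strength `F = target_fst`, dosages
  `Binomial(2, p_deme)`.  A closed-form F_ST target makes calibration
  tests exact; the cost is the absence of genealogical noise shared
  between loci (no LD, no shared drift history).  `target_fst = 0`
  short-circuits the Beta draw and yields one panmictic pool.
* **Isolation by distance.** Individuals are uniform on the landscape;
  per-locus logit frequencies are a Gaussian random field with
  squared-exponential correlation of range `dispersal_sigma` (default
  50 km on a 1000 km landscape) and logit-scale variance 0.5.  As
  `dispersal_sigma → ∞` the field becomes constant and the panel
  panmictic.
* **Clinal loci.** `n_clinal_loci` random loci are overwritten with
  `p = logistic(logit(p0) + slope · centred predictor)`; the predictor is
  a km-scaled landscape axis (slope in logit/km) or a climate variable.
  A zero slope plants nothing detectable and is warned about.
* **Climate.** Zones are spatially coherent (k-means on coordinates,
  relabelled along the dominant axis); zone means follow a
  coastal-to-interior gradient — MAT 4.2→9.5 °C, NFFD 175→287 d, MAP
  744→2806 mm — with within-zone noise of 0.5 °C, 8 d and 100 mm and a
  0.7 correlation between the MAT and NFFD noise.  The zone means are the
  study's published cluster averages; the within-zone spreads are free
  choices (nothing constrains them) picked so zones overlap mildly in any
  single variable but separate in the joint space.
* **Phenotypes.** With the within-population scale fixed at one,
  `σ²_a = h²`, `σ²_e = 1 − h²` and `σ²_p = 2σ²_a·Q_ST/(1−Q_ST)` (the Q_ST
  definition inverted).  Additive values are `a ~ N(0, σ²_a G)` drawn
  through the eigendecomposition of G; each genotype contributes
  `n_ramets` records (default 3) sharing its genetic value with i.i.d.
  residuals — the common-garden clonal design.  By default the d ≈ 4
  cluster effects are rescaled to carry *exactly* the planted
  among-cluster variance: with so few groups the χ²_{d−1} scatter of
  unconditioned draws would dominate any recovery study.  Calibration
  studies of the neutrality test switch this off
  (`exact_cluster_variance=False`) because there the natural χ² scatter
  *is* the quantity under test.
* **RNG discipline.** Every generator call derives its own stream from
  `SimConfig.seed` via a fixed numpy spawn key, so generators are
  individually reproducible and mutually independent.

Passing tests on these data demonstrate the estimators' correctness and
calibration under the assumed design; they do not speak to LD structure,
genotyping error, non-additive architectures or real climate topography.

## Relatedness

The realized relationship matrix is `G = ZZ′ / 2Σp(1−p)` over polymorphic
loci, with allele frequencies taken from the observed sample (no base
population is specified for this design) and missing dosages mean-imputed
per locus (unbiased under missing-at-random).  A ridge of
`1e−6 · mean(diag) · I` is added only when the smallest eigenvalue is
negative, and is recorded.  QC retention is boundary-inclusive (MAF ≥
0.05, missingness ≤ 0.10, quality ≥ 0.5) since the removal criteria are
strict inequalities; the quality score generalizes an array's GenTrain
score so non-array inputs can supply any [0, 1] per-locus quality.

## REML

All three model forms are cases of `y = Xβ + Σ Z_i u_i + e` with
`u_i ~ N(0, σ²_i K_i)`.  The fitter runs a short EM-flavoured fixed-point
warm-up (multiplicative updates, positivity preserved) followed by
average-information steps with step-halving; convergence requires a
relative restricted-log-likelihood change below 1e−8 *and* a scaled
gradient norm below 1e−6.  Components whose update crosses zero are
pinned at the boundary (reported as exact zeros, SE undefined there) and
released only if the gradient later pulls them inward; when an AI step
hits the boundary the remaining components are re-solved against the
reduced AI matrix, which avoids the step-halving deadlock near boundary
optima.  The asymptotic covariance is the inverse AI matrix over interior
components.

Clonal replication is absorbed exactly: records collapse to genotype
means with per-row residual multipliers `1/r_i`, and the within-genotype
contrasts contribute `−(df·log 2πσ²_e + SS/σ²_e)/2` analytically.  This
keeps the replicated animal model at genotype-level cost and is
likelihood-exact (verified against the dense fit in the tests).

Confounded covariance structures (e.g. `G = I` without clonal
replication, where the additive and residual terms coincide) are detected
by pairwise proportionality of the covariance parts and flagged as
non-identifiable rather than silently resolved.

Q_ST, h² and P_ST standard errors use the delta method on the AI
covariance.  P_ST deliberately combines h² from the cluster-fixed model
with σ²_p and σ²_e from the cluster-random model, exactly as the
estimator is defined, even though the two residual variances refer to
different models; the tests cover its algebraic limits (h² = 1 reduces to
the narrow form, h² = 0 degenerates to 1 and is flagged).

## Q_ST–F_ST neutrality test

A neutral trait drifts like a single neutral locus, so its Q_ST is
compared to the distribution of marker F_ST.  Each null replicate draws a
marker F from the trimmed neutral per-locus F_ST vector, sets the neutral
among-group variance `σ²_B = 2σ̂²_a F/(1−F)` (the Q_ST definition with
Q_ST := F), then injects estimation noise using balanced normal theory:
the among-cluster mean square is `(σ²_B + v_m)·χ²_{d−1}/(d−1)` with `v_m`
the sampling-variance floor of one cluster mean, and the estimated
among-group variance is that mean square minus `v_m`, truncated at zero
exactly as REML truncates.  The floor is computed from the fitted
components and the G blocks (within-cluster relatedness inflates
cluster-mean variance noticeably at F_ST ≈ 0.01 and cannot be ignored).
The within-group additive variance is drawn as `σ̂²_a·χ²_ν/ν` with
Satterthwaite `ν = 2(σ̂²_a/se)²`.  The p-value is one-sided toward
divergent selection with +1 smoothing, `p = (1 + #{draws ≥ Q̂_ST −
mean F̄})/(n_reps + 1)`; a two-sided option exists but is off by default
since traits are classified as adaptive when Q_ST exceeds the neutral
expectation.  Type-I calibration is demonstrated by simulation (rejection
rate of neutral traits inside the 95% binomial band around α = 0.05).

## F_ST outliers

Weir & Cockerham's (1984) θ is used for observed and simulated loci alike
— consistency of estimator between data and null is what makes the
envelope valid.  Loci not covered by at least two genotypes in every
population are skipped; loci monomorphic across populations have
undefined θ (NaN).  The multi-locus estimate is the ratio of summed
variance components.

The neutral (He, F_ST) null represents an exchangeable island model
through its equilibrium allele-frequency law: deme frequencies
Beta-distributed around a uniform ancestral frequency at strength F, with
each of d demes sampled as 25 HWE diploids (50 genes, matching the
subsample convention of Fdist-style scans) and loci with He < 0.02
discarded as array-unlike.  A closed-form frequency null was chosen over
an explicit structured coalescent: at mean F_ST ≈ 0.01 the island model
sits in the very-high-migration regime where per-locus genealogy
simulation is orders of magnitude too slow for the 10⁴–10⁵ loci the
envelope needs, while the frequency law it converges to is simulated in
milliseconds and matches the estimator's sampling layer exactly.  Because
the sampled multi-locus θ is not identical to the model's F parameter,
F is calibrated by a 5000-locus pilot plus secant refinement until the
realized mean is within 5% of target.

The envelope partitions He into 20 equal-count bins and takes per-bin
empirical quantiles at (1±ci)/2, linearly interpolated between bin
centres and flat beyond.  Outlier detection iterates simulate → envelope
→ flag → recompute the mean over unflagged loci, until the flag set
repeats (max 5 rounds; non-convergence returns the last round with a
warning).  High-side flags are candidates for diversifying selection.
The chromosome hotspot test combines a chi-square goodness of fit against
a uniform per-chromosome expectation (df = chromosomes − 1) with a
randomization rule: scatter the same outlier total uniformly 1000 times,
record each replicate's maximum per-chromosome count, and flag
chromosomes whose observed count reaches the maximum across replicates.
A SNP-density-weighted expectation is exposed through the counts the
caller supplies but the uniform rule is the default.

## Spatial structure

Coordinates are projected azimuthal-equidistant about the sample centroid
(one well-defined chart, great-circle-faithful at sampling scale; UTM
would need multiple zones for a 1500-km range).  One genotype per unique
(lat, lon) is retained, seed-deterministically, before any network is
built.  KNN networks (default K = 10) are symmetrised by union with ties
broken by node order; distance-band networks use `lo < d ≤ hi`.

Moran's I uses binary 0/1 weights for the 200-km lag tests and
row-standardised weights inside sPCA; its permutation test shuffles
values over nodes, one-sided toward the observed deviation from
`−1/(n−1)`, with the (1+k)/(1+n_perm) convention.

Spatial PCA diagonalises `(1/2n)·Xᵀ(W+Wᵀ)X` for the node-centred dosage
matrix; each signed eigenvalue equals var(score)·I(score), so large
positive eigenvalues indicate global (IBD-like) structure and negative
ones local clusters.  The global and local significance tests permute
genotype rows over network nodes and compare the sum of positive
(respectively |negative|) eigenvalues with the permutation distribution —
a permutation construction chosen because it is simple, exact in level,
and testable by simulation (calibration and power are both exercised in
the suite).  The computation works in the row space of X (SVD once,
r × r eigenproblems thereafter) so permutations are cheap.

SPA-style cline scores fit, per locus, allele presence on standardized
predictors by binomial IRLS (two Bernoulli draws per diploid); the score
is the slope norm ‖b‖, invariant to allele relabelling.  Perfect
separation caps ‖b‖ at 25 on standardized predictors and flags the
locus.  Flags are drawn at the 95th and 99th percentiles of the score
distribution.  The "unsupervised" variant of this scan simply receives
latent genotype-PC surrogates as predictors; the pipeline's default runs
use geographic coordinates and climate variables.

## Climate clustering and association

K-medoids is classic PAM (greedy build + first-improvement swap,
deterministic with index-order tie-breaking) on Euclidean distances of
standardized MAT/NFFD/MAP.  The Calinski–Harabasz criterion is computed
with the *medoids* as cluster centres (PAM-consistent, slightly more
conservative than the centroid version); K maximizing CH wins, with the
smaller K preferred on exact ties.

The SAM-style scan fits one logistic model per (allele, variable).  The
three required statistics are the likelihood-ratio test, the Wald test on
the slope, and the score (Lagrange-multiplier) test — three
asymptotically equivalent tests with identical pass semantics (all must
clear `α/(n_alleles · n_variables)`).  Under separation the Wald p is
withheld and the decision falls to LR + score (logged).  Environment
values default to cluster means ("subpopulation averages"); per-individual
values are available.  Cluster-level frequency regressions use the
variance-stabilizing `arcsin(√f)` transform; boundary frequencies map to
0 or π/2 and are flagged rather than dropped.

## Integration

The adaptive-SNP report keeps SNPs flagged by ≥ 1 outlier method and
associated with ≥ 1 trait whose Q_ST rejected neutrality; rows carry the
method set, shared/unique status and pleiotropy degree (count of distinct
adaptive traits).  Because "percent overlap among methods" admits two
denominators, both are emitted explicitly: shared SNPs over the union of
flagged SNPs, and shared method–SNP pairs over all method–SNP pairs.

## Problem sizes and numerical defaults

The test suite and acceptance script run the studies at: recovery, 4 × 100
genotypes × 5000 loci × 3 ramets, 10 seeds per setting; neutrality
calibration, 200 neutral traits on a 400-genotype, 2000-locus background
with 2000 null draws each; envelope calibration, 20k simulated loci for
the envelope and 10k fresh loci for the exceedance check, with
planted-outlier recovery over 20 seeds at 8k simulations per trimming
round; sPCA, 110 individuals × 300 loci with 199 permutations over 20
seeds.  These sizes were chosen so each study's Monte-Carlo error is
small relative to the tolerance it is checked against.  The envelope
default for production use remains 200k simulations.

## Known limitations

* The neutral F_ST null ignores LD between loci; with tag-SNP arrays the
  effective number of independent loci is smaller than the nominal count.
* The neutrality test's χ²/Satterthwaite noise model is an approximation
  to the REML sampling distribution; it is validated by calibration
  simulation at the design sizes above, not derived exactly.
* P_ST mixes components from two model fits by construction and should be
  read as the phenotypic approximation it is.
* The Balding–Nichols generators share no genealogy across loci, so
  multi-locus sampling variance of mean F_ST is mildly understated
  relative to coalescent expectations.
* Non-additive genetic variance appears only implicitly (clone models);
  no dominance or epistatic relationship matrices are built.
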