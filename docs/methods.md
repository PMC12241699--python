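# Methods

This note documents the models, the numerical choices, and what the
synthetic data generator does and does not emulate. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic metapopulation and soil generator

**Genotypes.** Allele frequencies follow the hierarchical
Balding–Nichols model. Per locus an ancestral frequency
p₀ ~ Uniform(0.05, 0.95) is drawn; each genetic cluster receives a
frequency Beta(p₀(1−f_c)/f_c, (1−p₀)(1−f_c)/f_c) with cluster-level
drift f_c (`f_cluster`), and each population repeats the draw around
its cluster frequency with `f_pop`. Under this model E[F_ST] equals
the drift parameter, which gives the simulator a closed-form
calibration target: the test suite checks that multi-locus
Weir–Cockerham θ on neutral 2-population draws recovers `f_pop`
to ±0.02 at 5,000 loci. Genotypes are Binomial(2, p) per individual;
no linkage disequilibrium, no coalescent history — the downstream
inference uses only allele-frequency information, so haplotype
structure would add cost without adding testable signal.

**Selection.** A fraction `prop_adaptive` of loci is "adaptive": the
population frequency is shifted on the logit scale by
`beta` × (standardised driver value at that population) before
genotypes are drawn. Selection therefore acts on population allele
frequencies, which is exactly the estimand of every GEA detector here;
individual-level fitness is not modelled.

**Soil.** Each chemical variable is a Gaussian random field with
exponential spatial covariance exp(−d/`soil_range`) over great-circle
distances, cross-mixed through the Cholesky factor of `soil_corr` and
affinely mapped to plausible field ranges (pH ≈ 6.0 ± 0.6,
EC ≈ 0.8 ± 0.3 dS/m, OC ≈ 6 ± 2 kg/m², cations in cmol⁺/kg, each with
a positive floor). The default correlation length is 50 km: soil
chemistry over a volcanic mountain belt turns over at scales much
finer than the ~300 km separation of genetic clusters, and a driver
that varies *within* clusters is what makes soil-driven selection
statistically separable from cluster-level drift. Site coordinates are
drawn in a box spanning roughly −104…−97° E, 18.9…21° N purely so that
distances are realistic.

**Missingness** is completely at random (`missing_rate`, default 5%);
no mechanism for genotype-quality-dependent missingness is claimed.

**What passing tests show.** Recovery results on these data show the
estimators are correct and calibrated under drift + logit selection
with independent loci and MCAR missingness. They do not certify
behaviour under LD, batch effects, unmodelled relatedness, or
informative missingness.

## QC

Filters run in a fixed order — monomorphic, missing call rate > 20%,
MAF < 5%, exact Hardy–Weinberg p < 10⁻⁶ in any population with ≥ 5
non-missing genotypes — and per-locus statistics are computed before
imputation. The HWE test is the exact conditional test (probability of
the observed heterozygote count given allele counts; the p-value sums
all configurations no more probable than the observed one) and is
verified against an exact-rational enumeration oracle to 10⁻¹².

KNN imputation is LD-guided: for a missing call, the `n_ld_sites`
most-correlated loci (squared Pearson on pairwise-complete dosages)
define a similarity 1 − mean|dosage difference| between the focal
sample and every sample observed at the target locus; the imputed
value is the similarity-weighted modal dosage among the `k` nearest,
ties broken toward the lower dosage (deterministic). With no LD in the
panel, the information ceiling is the modal genotype given the
population frequency — ≈ 0.59 exact recovery under the generator's
frequency prior — so the recovery test builds LD explicitly (four
near-duplicate SNPs per tag, as multi-SNP RAD tags have) and requires
≥ 85% there.

Diversity: Ho is the mean observed heterozygote fraction; He uses the
small-sample factor (2n/(2n−1))·2p̂(1−p̂); π divides the He sum by
(number of tags × tag length, default 82 bp) — the per-nucleotide
scaling that reconciles SNP-panel heterozygosities near 0.2 with
π values near 0.05 on reduced-representation data.

## Population structure

**PCA** uses Patterson scaling ((g − 2p̂)/√(2p̂(1−p̂))); constant loci
are dropped with a warning.

**Admixture** maximises the binomial likelihood
g ~ Binomial(2, (QF)) by EM (the classical allele-assignment E-step),
which guarantees a monotone log-likelihood — a property the tests
assert. K is chosen by entry-masking cross-validation: 5% of observed
dosage entries are hidden per replicate, the model is fit on the rest,
and CV error is the masked-entry MSE of the predicted dosage 2·(QF);
chosen_K minimises the mean CV error over replicates. Entry masking
(matrix-completion style) replaces fold-based CV because the sample
sizes here (tens per population) make sample-level folds unstable.

**DAPC**: k-means over the PCs explaining 95% of variance (default),
BIC(K) = n·ln(W_K/n) + K·ln(n) averaged over random starts, chosen_K
at the global minimum of mean BIC, then LDA axes on the chosen
clustering. The BIC constant differs across published implementations;
this form is monotone-equivalent and fixed here.

**F_ST**: multi-locus Weir–Cockerham θ as the ratio of summed
variance components a/(a+b+c); per-locus components verified against
an independent scalar implementation to 10⁻¹⁰. Pair significance comes
from shuffling individuals between the two populations with +1
smoothing; negative θ estimates are reported as computed.

## Soil predictors

Pairwise pruning removes one member of every |r| ≥ 0.75 pair (the
member with the larger mean |r| to all others — the more redundant
one); zero-variance variables drop first. Univariate normality is
Anderson–Darling with estimated parameters; joint normality is
Royston's H: each variable's Shapiro–Wilk statistic is normalised
(the AS R94 transformation behind the Shapiro–Wilk p-value),
folded to r_j = [Φ⁻¹(p_j/2)]², and H = e·mean(r) is referred to χ²
with equivalent degrees of freedom e = p/(1 + (p−1)·c̄), where c̄
discounts for inter-variable correlation (Royston's 1992 constants).
With fewer than 8 sites the joint test is flagged "not computed"
rather than returning a number. VIF screening iteratively drops the
largest-VIF variable until all VIF < 3; the environmental PCA
(z-scored) exposes EPC1/EPC2 for the cline regressions.

## GEA detectors

**Latent-factor scan.** Factors U are the top-K left singular vectors
of the centred dosage matrix, estimated once and shared across soil
variables. An earlier design estimated U from the matrix residualised
on each covariate; under the package's own null simulations this
systematically misses the structure component aligned with the
covariate and inflates λ (median ≈ 1.14 with excursions past 1.6),
so the raw-matrix basis — which calibrates at λ ≈ 1.0 — is used, with
genomic control mopping up residual confounding. K defaults to
(number of clusters − 1): with an explicit intercept, K clusters span
a rank-(K−1) subspace, and adding the K-th factor absorbs the
selection signal itself (power collapses to ~0 in truth-labeled
simulations). λ = median(z²)/0.45494; calibrated p from χ²₁ of z²/λ;
BH at FDR 0.05.

**Logistic scan.** Response is minor-allele presence (the
minor-encoding collapses 0/1/2 to carrier status); covariates are K−1
admixture columns (drop-one avoids the simplex collinearity);
G = 2(ℓ₁−ℓ₀) against χ²₁ via batched Newton/IRLS with a small ridge
(10⁻⁶) so quasi-separated fits stay finite (they are flagged).
Bonferroni over the full locus × variable family. Calibration runs use
panels of a few hundred loci and ~140 samples so that the χ² tail is
accurate at the Bonferroni threshold being probed.

**F_ST–environment scan.** Environmental distance per population is
|x_j − x̄| normalised to max 1 (a signed variant is available via
`signed=True`; absolute is the default because the concept — locus
differentiation tracking environmental displacement — is direction-
free). Locus statistic: Pearson correlation of the per-population
differentiation contributions with the distances; null from
permutations of the distance vector shared across loci; one-sided
(upper) p with +1 smoothing; Storey q (π₀ estimated at λ = 0.5) flags
candidates. Loci with degenerate mean frequency (0 or 1) or zero
differentiation spread are skipped with a reason, as is every locus
when the distances are identical across populations.

**Combination** is the union of flagged (locus, variable) pairs over
methods, with per-method membership kept for Venn counts. A locus
associated with several variables appears once per variable.

## Polygenic dbRDA

Gower centring G = −½·C·D²·C of the Bray–Curtis matrix (dosages are
the abundances; an all-zero pair has distance 0 by convention).
Conditional inertia is the trace claimed by the conditioners' hat
matrix beyond the intercept; constrained inertia is the trace claimed
by the predictors residualised on the conditioners; the residual is
the remainder, so the partition closes identically. Negative
eigenvalues of G stay inside the traces (no Lingoes/Cailliez
correction), matching the McArdle–Anderson treatment of non-Euclidean
dissimilarities. Adjusted R² is Ezekiel's 1 − (1−R²)(n−1)/(n−m−1)
applied to the conditioned fraction. Significance permutes the
reduced-model residual structure (rows/columns of the conditioner-
residualised G) — the statistically standard choice where the
published phrasing ("permutations of the genotype matrix") is
ambiguous. The number of conditioning PCs defaults to (clusters − 1).

Forward selection admits, at each step, the predictor with the largest
adjusted-R² gain, only if its marginal permutation p ≤ 0.05 and the
cumulative adjusted R² does not exceed the all-predictor value (the
double stopping rule). MAF-matched nulls bin candidate MAFs at width
0.05 and draw non-candidate loci matching the per-bin counts without
replacement within a set; a short bin widens by one step with a
warning, and fails loudly if still short. The exceedance rank places
the candidate constrained proportion within {candidate} ∪ nulls
(rank 1 = candidate beats every null). Cross-scale transfer evaluates
the other scale's candidate loci on this scale's genotypes and reports
the result against the same-scale model and the null range.

## Spatial PCA and clines

The connection network is a symmetrised k-nearest-neighbour graph
(k = 3 by default) with inverse great-circle-distance weights, built
on site coordinates; samples inherit their site's row, with weights to
a site split evenly among its samples so rows still sum to one.
Duplicate coordinates are refused rather than jittered — callers must
aggregate to sites. The eigenproblem is (1/2n)·Xᵀ(W̄+W̄ᵀ)X on
column-centred dosages; by construction each eigenvalue equals
var(score) × Moran's I(score), an identity the tests verify to 10⁻⁶
by independent recomputation. Positive eigenvalues are global
(cline-like) axes, negative ones local; lagged scores are W̄·scores.

Cline regressions treat individuals as replicates with site-level
predictors broadcast (the pseudo-replication this induces is the
published design of this analysis and is reproduced deliberately);
per axis the package reports every univariate OLS fit and a
bidirectional AIC-stepwise model from the null model. With a single
predictor the procedure reduces exactly to OLS. The AIC criterion has
a per-candidate false-entry rate of P(χ²₁ > 2) ≈ 0.16 under the null;
the calibration test asserts exactly that behaviour rather than a
stricter one the criterion does not deliver. IDW interpolation
(power 2, exact at sites) is provided as a minimal surface utility;
cartography is out of scope.

## Problem sizes and determinism

Simulation-based checks use panels of 300–1,000 loci and 70–190
samples with 10–20 seeds per property — sizes at which every asserted
rate (θ within ±0.02, λ within [0.8, 1.2], power ≥ 0.5 at β = 1.5,
K-recovery ≥ 8/10, exceedance rank 1 in ≥ 9/10) holds with margin in
repeated runs. Monte-Carlo estimates of error *rates* (the Bonferroni
FWER) are judged by a one-sided binomial consistency test at the
nominal level, since a 20-replicate point estimate of a 5% rate sits
at its own acceptance boundary in expectation. Every stochastic
component takes an explicit seed; the pipeline writes a manifest with
a config hash and per-file checksums, and two runs with the same
config and seed are byte-identical (asserted in the tests).

## Known limitations

* No LD, demographic history, or individual fitness in the generator;
  the spec's inference chain never consumes them, but transferability
  claims to real data carry the usual caveats.
* The latent-factor scan is a least-squares analogue of the Bayesian
  LFMM: same estimand, no MCMC; "median z across runs" is a no-op for
  a deterministic estimator.
* The F_ST–environment scan keeps the concept of a differentiation-
  environment coupling but replaces the reversible-jump machinery of
  the Bayesian original (locus-effect decomposition, convergence
  diagnostics) with a permutation test.
* Royston's equivalent-degrees constants are the published
  approximations; they are accurate for the 5–9 variable, n ≥ 50
  regimes used here.
* `idw_interpolate` is a deliberately minimal stand-in for map
  rendering; grid resolution is a parameter with no fidelity claim.
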