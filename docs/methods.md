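# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `diallelpred`.

## Population model

The simulator emulates a two-founder diallel panel. Every segregating site
is biallelic by construction, coded 0 for one founder's allele (WA) and 1
for the other's (NA), so allele frequencies are close to one half
everywhere and diploid dosages lie in {0, 1, 2}.

**Genetic map.** `simulate_genetic_map` places sites uniformly at random on
each chromosome (positions in centimorgans, strictly increasing within a
chromosome). Defaults: 16 chromosomes, 100 cM each.

**Segregant mosaics.** An F12-style haploid segregant is represented only by
its marginal mosaic structure: `n_meioses` (default 12) independent rounds
of Poisson crossovers (rate = chromosome length / 100 expected crossovers
per chromosome per round, uniform positions, no interference) applied to a
random founder-phase start. Superimposing rounds is equivalent to
alternating founder origin across the union of all breakpoints, so the
effective map length scales with `n_meioses`. An explicit pedigree of
selfings is deliberately not simulated: only the marginal mosaic matters
for relatedness and prediction, not the identity of intermediate
generations.

**Mating.** `mate_diallel` crosses every MatA segregant with every MatAlpha
segregant; a hybrid's dosage vector is the elementwise sum of its two
parental haplotypes. Consequences used throughout: hybrids sharing one
haploid parent share one complete haplotype (expected genotype-identity
fraction f = 0.5); hybrids sharing none are independent draws at every site
(f = 0.25² + 0.5² + 0.25² = 0.375). `remove_founders` reproduces the
filtering of whole parental families (e.g. contaminated or aneuploid
founders) from the grid.

## Trait architectures

`TraitSpec` holds, per trait: sparse additive effects on dosages, dominance
effects on the heterozygote indicator 1{dosage = 1}, pairwise epistatic
coefficients on dosage products, a loading on one population-wide latent
factor shared by all traits, an individual residual SD and a replicate
noise SD. A replicate measurement is the sum of these terms; the latent
factor and residual are drawn once per individual, replicate noise per
measurement.

The dominance generator acts on the heterozygote *indicator* while the QTL
models encode dominance as squared-dosage (self-interaction) columns; the
two parameterizations span the same per-locus space but are not the same
basis, so recovery tests are not circular.

`sample_architecture` calibrates effect sizes against the realized
genotypes: each component's score is rescaled so its population variance
equals the requested fraction exactly (additive after combining a shared
polygenic score — fraction `shared_add_frac` of additive variance — with a
private one; this final rescaling matters because independently drawn
scores are sample-correlated in small related populations). Dominance and
epistasis are scaled separately, so their sum can deviate from the target
by a small sampling covariance. Replicate noise is set from the target
repeatability of the n_rep-average, H² = V_ind / (V_ind + sigma_rep²/n_rep).

`study_architecture` is the nine-trait default: additive fractions chosen
so h² of the four-replicate mean spans 0.66–0.88 with median 0.80, small
dominance/epistasis on a subset of traits, shared-factor and shared-additive
loadings that give pairwise trait r² from ~0 to ~0.45, and repeatability
0.94 with four replicates.

**What the generator does not emulate:** sequence-level variation and rare
alleles (every site segregates at ~50%), crossover interference, mating-type
or selection effects, aneuploidy, batch/plate structure in phenotyping, and
non-Gaussian noise. Passing tests therefore show that the estimators and
experimental designs behave correctly under the idealized population
structure, not that they are robust to those real-data complications.

## Relatedness

`compute_grm` builds K = XXᵀ/c with c the mean diagonal of XXᵀ, so
mean(diag K) = 1. Columns of X are mean-centred by default: the raw-dosage
product contains a near-rank-one common component (every dosage has mean
~1) that is not genetic covariance; in variance-component fits it is
absorbed into sigma_g² and inflates heritability estimates by ~0.1 on
purely additive simulations. Centring removes it exactly; `center=False`
restores the raw product. No allele-frequency standardization is applied —
frequencies are ~0.5 by design, so column scales are already homogeneous.

IBS between two hybrids is the fraction of sites with equal (unordered)
diploid genotype. Pedigree classification: *self*, *close* (exactly one
shared haploid parent), *distant* (none); sharing both parents is
impossible in a diallel and raises an error.

## Prediction models

All models are fit on training individuals only; accuracy is the
coefficient of determination R² = 1 − SS_res/SS_tot computed on the test
set against the test mean (negative values possible). Pearson's r² is used
only where model agreement (not accuracy) is measured.

**P.** OLS of the focal trait on the other trait means plus intercept;
rank-deficient designs fall back to the minimum-norm solution with a
warning. No imputation: missing covariates are an error.

**BLUP.** y ~ N(mu 1, sigma_g² K + sigma_e² I). The mean is fitted
explicitly (equivalent to centring by the training mean) because synthetic
phenotypes are not centred. Components are estimated by full maximum
likelihood (not REML): after eigendecomposition of the training block of K,
mu and the scale have closed forms given the ratio delta =
sigma_e²/sigma_g², leaving a bounded 1-D Brent search over log delta in
[1e-6, 1e6] (tolerance 1e-8). ML matches the stated Gaussian likelihood
directly; with an intercept-only mean the REML correction is one degree of
freedom and is negligible at the sample sizes used. Prediction conditions
the joint Gaussian of test on training phenotypes (Cholesky of the training
block; jitter 1e-8·mean-diagonal is added only if factorization fails).
Predictive SD includes sigma_e² by default — it describes a *measured*
phenotype, which is what calibration against realized residuals requires —
with `include_residual=False` giving the genetic-only SD.

**QTL.** Greedy forward selection over dosage columns by residual-sum-of-
squares reduction (incremental orthogonalization makes each step O(nM)),
up to 50 terms by default, no p-value entry threshold; ties resolve to the
earliest candidate. Model size is chosen by inner fourfold CV on the
training data (size 0, the intercept-only model, is always a candidate, so
the chosen size never scores below the empty model), smallest size on ties;
inside the outer CV this is a double cross-validation. Weights are refit by
OLS on the full training set. OLS predictive SDs use
sigma² (1 + x(XᵀX)⁻¹xᵀ).

**LMM.** Fixed effects: the additive forward path, sized by inner CV; then
interaction candidates — all pairs (i, j) with i among the selected
additive sites and j any site, self-pairs giving squared-dosage (dominance)
columns — appended by continued forward selection, with the concatenated
path re-sized by inner CV. Variance components are then re-fit on the
fixed-effect residuals against K, and prediction adds the fixed-effect mean
to the conditional (BLUP) mean of the residual. With no fixed effects this
reduces exactly to BLUP.

**LMM+P.** Stage 1 regresses y on the other traits; stage 2 fits the full
LMM (QTL selection included) on the stage-1 residuals. Test predictions add
the stage-1 prediction from the test individuals' other traits to the
stage-2 genomic prediction.

**Midparent.** y_ij = (P¹_i + P²_j)/2 + noise, parental values estimated by
least squares on the additive two-way layout. The layout is deficient by
the usual additive shift; the minimum-norm solution is used (predictions
are invariant). Hybrids with a parent unseen in training get NaN with a
warning rather than an imputed value.

**MT-LMM.** Residuals R = Y − F (F = per-trait LMM fixed-effect
predictions, reused rather than refit jointly) follow
vec(R) ~ N(0, C⊗K + Σ⊗I). After rotating by the eigenvectors of the
training K, rows are independent with covariance s_i C + Σ, evaluated by
batched Cholesky. C and Σ are parameterized by Cholesky factors with
log-diagonals (PSD by construction) and optimized by L-BFGS-B, initialized
from single-trait fits and empirical residual correlations. Prediction
conditions the dense joint Gaussian over (individual, trait) pairs on all
training phenotypes plus the test individuals' other traits; this is the
multi-trait counterpart of LMM+P. Dense Kronecker covariance limits the
implementation to ~12 traits.

**Heritability and repeatability.** h² = sigma_g²/(sigma_g² + sigma_e²)
from the full-data BLUP fit. Repeatability uses the fixed-effects model
r_ij = y_i + eps: sigma² is the population-denominator variance of the
within-individual residuals and H²_single = 1 − sigma²/Var(r); H²_mean
rescales the noise by 1/n_rep. The population denominator understates
sigma² by (1 − 1/n_rep), so the estimator's null value is 1/n_rep and
designed H² = 0.94 is recovered at ~0.957 with four replicates; the bias
vanishes as replicates grow and is small near the high repeatabilities this
design targets.

## Evaluation designs

**Folds.** Each parental panel is split into two near-equal groups (odd
sizes ⌈n/2⌉/⌊n/2⌋, seeded); the four row-group × column-group blocks are
the folds, so fold membership is a function of parents, not individuals.

**Scenarios** for a test block: *random* = all non-test hybrids; *distant*
= the opposite block (provably no shared parent with any test individual);
*close* = a seeded uniform sample, of the distant set's size, from the two
off-blocks (every member shares exactly one parent with some test
individual). The close downsample is redrawn per fold with a fold-indexed
seed offset. Per-trait accuracy is reported as R² over the pooled test
predictions of the four folds, with per-fold values retained as ranges.

**Experiments.** `learning_curve` grows the training set through one
shuffled relative class then the other. `replacement_experiment` swaps
⌈fraction·n⌉ (default 1%) distant-training individuals for close relatives
without replacement, training size constant, reporting in- and
out-of-sample R² before and after. `cross_fit_experiment` decouples QTL
mapping (term selection on set A) from weight estimation (OLS refit, fixed
terms, on set B) for all four close/distant combinations.
`calibration_summary` pairs each (trait, scenario)'s mean predictive SD
with its realized residual SD and reports the regression slope of residual
variance on predictive variance and the squared correlation across points;
fewer than three points, or constant predictive SDs, are an error.

## Problem sizes in the test suite

The suite exercises the designs at desk scale, chosen so each effect is
statistically resolvable: combinatorial checks on the full 86 × 86 pedigree
(no genotypes needed); IBS expectations on 20 + 20-segregant diallels with
512 sites; heritability recovery on a 45 × 45 diallel (n = 2025, 800
sites); the model-accuracy ordering and close/distant contrasts on 20 × 20
diallels (400 hybrids, 320 sites) over five seeds; predictive-SD
calibration and QTL/weight cross-fitting on 24 × 24 diallels, where
variance-component estimates from small distant-only training sets are
stable enough for the comparisons; and the 1%-replacement experiment on a
40 × 40 diallel with a dense 800-site map, because the effect operates
through linkage — close relatives steer selection away from non-transferable
proxy markers, which requires markers correlated enough to act as proxies —
and is summarized, like the accuracy experiments, as the median over nine
simulated traits.

## Known limitations

* ML (not REML) variance components are slightly biased downward in small
  samples; immaterial at the suite's sizes but worth noting for n < 100.
* The repeatability estimator's population-denominator bias (above).
* MT-LMM likelihood optimization is quasi-Newton on a non-convex surface;
  initialization from single-trait fits makes it reliable in the regimes
  tested (≤ 3 traits in the suite) but global optimality is not guaranteed.
* The QTL/LMM interaction search only considers pairs anchored at an
  already-selected additive site; purely epistatic pairs with no marginal
  effect are invisible to it by design.
* Close/distant contrasts at 20–40 parent panels are noisier than in a full
  86 + 86 panel; the suite asserts medians over five seeds with margins
  rather than point values.
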