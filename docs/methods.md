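# Methods

This note records the modelling choices behind `raresdm`: the generative
model of the synthetic surveys, the five predictive models and their
defaults, the two enhancement procedures, the evaluation design, and what
the synthetic benchmarks do and do not demonstrate.

## Synthetic survey generator

The generator (`raresdm.synthetic`) emulates the structure of an
effort-standardized trawl survey: a site-by-species abundance table with
many exact zeros, a few smooth environmental gradients, and residual
correlation among species beyond what the environment explains.

**Environment.** Each covariate is a monotone function of a shared
latitudinal site index plus independent noise, then standardized per
column. This makes covariates mutually correlated (as temperature,
salinity and depth are along a coastal gradient) while leaving units
arbitrary; no downstream formula uses the original scales.

**Latent abundance.** Species `j` at site `i` has

    z_ij = a_j + f_j(x_i) + (Λ η_i)_j + ε_ij

with factor scores `η_i ~ N(0, I_K)` (default `K = 2`), loadings drawn
`N(0, loading_scale²)` (default 1.0), and noise `ε ~ N(0, residual_sd²)`
(default 1.0). `f_j` is quadratic in the covariates by default — linear
coefficients `N(0, 0.6²)`, concave curvature `−|N(0, 0.35²)|`, giving
unimodal niches; a linear option exists for closed-form checks. The
default observation mechanism is Tobit censoring, `y = max(0, z)`, which
matches the latent-Gaussian assumption of the joint model and so supports
exact parameter-recovery tests; a hurdle-lognormal variant (occurrence
from `z > 0`, positive abundance lognormal) is provided to probe
misspecification.

**Prevalence calibration.** Occurrence frequency is controlled through the
intercepts: `a_j` is the negated empirical `(1 − p)`-quantile of
`f_j + (Λη)_j + ε` over a 20,000-draw Monte-Carlo pool with the same
distribution as the sites. Defaults place the six rare targets at
3.5/4.3/6.1/8.8/9.6/12.3% occurrence — all under the 15% rarity cutoff —
and spread the 31 ancillary species evenly over 23–87%. At 10,000 sites
realized prevalences sit within ±0.005 of target; at the default 118
sites binomial noise of a few percentage points remains, as in a real
survey.

**What the generator does not emulate**: spatial autocorrelation beyond
the shared gradient, gear selectivity, detection error, temporal
structure, and abundance distributions heavier-tailed than the censored
Gaussian / lognormal. Benchmarks passed on this data therefore show that
the pipeline's machinery behaves as designed under its own assumptions —
not that any model ranking generalizes to a particular real survey.

## Predictive models

**RF** — `sklearn` regression forest; 500 trees, minimum leaf 5,
square-root feature sampling. Predictions are leaf means of non-negative
responses, hence non-negative without clipping.

**ANN / MANN** — one tanh hidden layer (default 8 units), linear outputs,
squared-error loss summed over output columns, L2 weight decay 0.01 on
connection weights, trained by L-BFGS (500 iterations) with 5 random
restarts keeping the lowest training loss. Inputs and responses are
standardized by training statistics; predictions are de-standardized and
floored at 0 because abundance is non-negative. The implementation is
written directly over `scipy.optimize` so that output weights can start at
exactly zero: every response column is then treated symmetrically, and
permuting species columns permutes predictions identically — a property
the cross-validation pipeline relies on having no hidden order dependence.
MANN is the same network with one output neuron per species; the shared
input-to-hidden weights are where community information enters.

**MRF** — multivariate random forest: per-species standardized responses
fed to a multi-output forest whose split criterion is the summed
within-node squared deviation across species (a Euclidean multivariate
impurity; the common multi-output criterion, well-defined for zero-heavy
rare columns since a constant column simply contributes zero).
A Mahalanobis impurity with the fixed training covariance is available:
whitening the responses by the inverse Cholesky factor of their covariance
makes the Euclidean criterion equal the Mahalanobis one, so both options
run through the same forest. With a single response column standardization
is scale-free and is skipped, making a one-column MRF coincide exactly
with RF under the same seed.

**Latent-factor censored JSDM** — the explicit-covariance model:

    y_ij = max(0, z_ij),  z_i ~ N(B x_i + Λ η_i, diag(σ²))

Gibbs updates: (1) censored cells imputed from their truncated-normal
conditional by inverse-CDF sampling (probabilities clipped away from 0/1
for numerical safety); (2) factor scores, coefficient rows and loading
rows by conjugate normal updates; (3) variances by inverse-gamma. Priors
are weakly informative — `N(0, 10²)` on coefficients, `N(0, 1)` on
loadings, `IG(2, 1)` on variances. Loadings are identified by a
lower-triangular constraint with the diagonal kept non-negative via
per-iteration sign flips; the rotation is immaterial to `Σ = ΛΛᵀ +
diag(σ²)` and to prediction. Default chain: 4000 iterations, 2000 burn-in,
thinning 2; a split-chain R-hat above 1.1 on the coefficients triggers a
warning. Marginal prediction samples `z ~ N(Bx, Σ)` per retained draw and
averages `max(0, z)`; the one-species, zero-mean, unit-variance case
reproduces the half-normal mean `1/√(2π)` to within Monte-Carlo error.

Covariates are standardized inside the fit (constants stored with the
posterior); an exactly collinear design raises an error naming the
dependent columns rather than sampling from an improper conditional.

## Enhancements

**Species filtering** ranks ancillary species by correlation with the
target and keeps all (LV1), the top two-thirds (LV2, `ceil(2n/3)`), or
the top third (LV3, `ceil(n/3)`); for 31 ancillaries that is 31/21/11.
Spearman on abundance is the default measure — robust to the zero-heavy,
skewed catch distributions; Pearson and presence-absence phi are options.
Ranking uses |correlation| so strong negative associates can inform
predictions (signed ranking is an option); ties break toward the lower
species index; a constant ancillary gets correlation 0 with a warning.
Ceiling (rather than floor) resolves the fractional cardinalities in
favour of inclusion.

**Conditional prediction** appends PCA scores of the ancillary abundances
to the covariates of a single-species model. The PCA is computed on the
correlation matrix (variables centered and scaled to unit variance)
because the eigenvalue-above-one retention rule is the Kaiser criterion,
which presumes unit-variance variables. Scores at prediction sites come
either from observed ancillary abundances or from the marginal predictions
of a JSDM trained on the same training fold; the PCA constants themselves
always come from the training fold.

## Evaluation design

Presence-stratified k-fold CV (default k = 4): presences and absences are
permuted separately and dealt round-robin, so per-fold presence counts
differ by at most one and every training set holds ~75% of sites and ~3/4
of the presences. 118 sites is not divisible by 4; fold sizes are
(30, 30, 29, 29) — "equal sized" as near-equal. Every data-derived
statistic used in fitting (correlation ranks, PCA constants, JSDM
posteriors) is recomputed on training folds only, and an audit hook lets
tests assert that test-site indices never reach fitting code. One
deliberate exception: the occurrence-binarization threshold is each
species' mean abundance over the *whole* study area, computed once on the
full dataset — it is part of the evaluation definition (the threshold a
manager would use over the survey region), not a fitted quantity, but it
is flagged here because it technically sees all sites. Correlation ranks
and PCA are refit within each fold; refitting once on the full data would
be the leakier alternative and is not offered.

Failed fits on a fold (possible when k approaches the presence count)
produce a flagged NaN record and the run continues.

Metrics: AUC uses the continuous predicted abundance as score
(Mann-Whitney midrank form, ties count ½) — it is threshold-free, while
κ and TSS use the binarized predictions; observed occurrence is always
observed abundance > 0. PRB averages the per-site ratio
`(P_p − O_p)/O_p` within a fold (the ratio-of-sums aggregate is an
option). Undefined cases (no presences in a fold's test set for PRB,
single-class occurrence for AUC/TSS, degenerate marginals for κ) return
NaN with a warning. The all-zero baseline `sqrt(mean(O²))` anchors RMSE:
a model worse than this baseline is worse than predicting the species
absent everywhere.

## Benchmark experiments and problem sizes

The reference experiments (`raresdm.experiments`, also run by
`scripts/acceptance.py`) use these sizes, chosen to give stable directions
at desk scale:

* Random-guess references and independence checks: 10,000 sites.
* JSDM recovery: 500 sites, 10 species, 2 factors, 2000-iteration chain —
  posterior-mean coefficient RMSE ≈ 0.06 against true coefficients of
  magnitude ≤ 1, and full sign agreement for residual correlations with
  |r| > 0.3.
* Conditional-RF gain: 20 replicate communities (default design,
  loading scale 2.0 — strong shared-factor structure), 25 CV repetitions
  each, 50-tree forests, two mid-prevalence targets. Positive mean ΔRMSE.
* MANN filtering: 20 replicate communities in which only the targets and
  10 of 31 ancillaries share a latent factor and an environmental niche
  while the rest respond strongly and unrelatedly, with a 3-unit hidden
  layer. This is the regime where unrelated community responses compete
  with the target's niche for shared hidden features, and LV3 filtering
  recovers the loss. With generous capacity (8+ units, here 6 quadratic
  basis functions suffice for every niche) the competition disappears and
  extra species act as benign multi-task regularization — filtering is
  then neutral-to-harmful. The experiment documents the mechanism, not a
  universal ordering.

## Known limitations

* The joint model is one unified Tobit-factor regression standing in for
  the broader family of hierarchical JSDMs; it has no traits, phylogeny,
  spatial random effects, or non-Gaussian response families.
* Abundance is modelled untransformed by default (a `log1p` option exists
  on the ML models); heavy-tailed catches may deserve the transform.
* Network restarts make ANN/MANN deterministic given the seed but only
  locally optimal; the permutation-equivariance guarantee is exact in
  arithmetic but realized to ~1e-3 numerically because summation order
  perturbs L-BFGS trajectories.
* The MRF "compositional similarity" split criterion is realized as the
  standardized Euclidean impurity (optionally Mahalanobis); other
  dissimilarity-based criteria (e.g. Bray-Curtis-like) are not offered.
* CV repetition defaults (500) match survey-scale practice; desk runs and
  the reference experiments use far fewer repetitions, which widens
  Monte-Carlo error on per-species means but not the direction of the
  aggregate comparisons reported.
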