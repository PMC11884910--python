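# Methods

## The model

`netoutcome` estimates a mixed graphical model (MGM) over p = 17 ordinal
depression symptom items (HRSD-17 style: thirteen items scored 0–4, four
scored 0–2) plus one binary remission outcome. Following common practice
when n is far too small to treat 5-category items as categorical, symptom
items enter as continuous variables; the outcome is categorical. Each node
is regressed on all other nodes:

* symptom node *i*: least squares of x_i on all x_j (j ≠ i) and the outcome,
* outcome node: logistic regression of y on all symptoms,

each with an L1 (LASSO) penalty so that weak conditional associations are
set exactly to zero. An edge (i, j) of the network represents the
conditional dependence of the two variables given all others; under the
default **AND rule** the edge exists only when regression *i* retains term
*j* **and** regression *j* retains term *i*, with weight equal to the mean
of the two standardized coefficient magnitudes carrying their shared sign
(conflicting signs are kept with mean magnitude and flagged
`sign_undefined`). The **OR rule** (available, not default) keeps an edge if
either side retains it, with weight averaged over both positions (zeros
included).

The penalty λ is selected per node by 10-fold cross-validation over a
log-spaced grid of 50 values from the node's λ_max (the smallest penalty
that zeroes every coefficient) down to 0.01·λ_max, minimizing mean
out-of-fold squared error (gaussian) or log-loss (binomial). Folds for the
outcome node are stratified by outcome so both classes appear in every fold;
if the minority class is smaller than the fold count, the fold count is
capped at the minority size. Exact ties in the CV curve resolve to the
larger (sparser) λ. We deliberately use the CV-error *minimum*, not the
one-standard-error rule.

Predictors are standardized before penalization. Coefficients are kept on
both scales: the standardized scale defines edge weights, while raw item
units feed the odds-ratio translation (per 1-point item increase).

**Predictability** is reported per node: for symptom nodes the in-sample
proportion of variance explained by the nodewise prediction (floored at 0);
for the outcome node the accuracy of the fitted classifier beyond the modal
class frequency, normalized to [0, 1]. A zero-variance node has
predictability 0 by definition.

## Odds ratios and their bootstrap

For each symptom with a retained outcome edge, the per-point odds ratio is
exp(raw-unit coefficient of that symptom in the outcome node's regression);
symptoms without a retained edge get OR = 1 exactly. A k-point score
difference compounds multiplicatively, OR^k, reported as a "times
more/less likely" magnitude (the reciprocal when below 1) rounded to one
decimal. Note the rounding order matters: fold changes computed from an OR
already rounded to two decimals can differ in the last digit from those
computed from the unrounded coefficient (e.g. 1.31⁴ = 2.94 while a
coefficient of log 1.316 gives 3.0).

Edge stability uses nonparametric **case resampling**: patients are drawn
with replacement (same n), and the *entire* pipeline — including fresh,
deterministically re-seeded CV folds — is refit per resample (default 500;
the bundled studies use 200). Per edge we report the inclusion proportion
(fraction of resamples with a nonzero edge) and 2.5/97.5 percentile
intervals of the weight, and of the OR for outcome edges with absent edges
contributing OR = 1 — which is why OR intervals of moderately stable edges
touch 1.00 exactly. Resamples in which only one outcome class survives are
skipped and excluded from `n_effective` (at realistic remission rates this
is vanishingly rare). Because the LASSO biases every estimate toward zero,
these percentile intervals are **bootstrapped confidence intervals (bCI)**
in name only: they are descriptive and not coverage-valid, and every output
labels them accordingly.

## Moderation

To test whether a binary grouping variable (e.g. study membership) changes
any pairwise relation, each nodewise regression is augmented with the
moderator main effect and all (standardized predictor × moderator) product
terms, jointly penalized with the same shared λ selected by the same CV. A
pair counts as *moderated* when its interaction term survives the edge rule
in both directions. The moderator stays on its 0/1 coding so an interaction
weight reads directly as the between-group difference in that pairwise
weight. An empty moderated-pair set is a non-detection — never evidence
that the groups share the network.

## The synthetic-data generator

Cohorts with known ground truth come from the estimation model class run
forward: latent continuous symptoms follow a conditional-Gaussian pairwise
model (x_i | rest ∼ N(intercept_i + Σ_j w_ij x_j, σ²) with shared residual
σ), sampled by Gibbs with burn-in 200 and thinning 5 (lag-1 autocorrelation
of retained sweeps is < 0.2 on the independence model). Properness —
positive definiteness of I − W, for both moderator levels when edge shifts
are present — is checked at construction so an improper model fails
immediately rather than diverging mid-chain. Latent values are discretized
by an affine map of [μ_i − 2.5 s_i, μ_i + 2.5 s_i] (model-implied marginal
moments) onto the item's score range, rounded and clipped, which keeps all
response categories populated. The binary outcome is then Bernoulli with
logit = b₀ + Σ β_i · score_i on the *recorded* scores, so β_i is exactly a
per-point log-odds contribution on the scale an analyst sees. An optional
moderator is Bernoulli(0.5) per patient — mimicking two roughly equal-size
trials — and additively shifts selected pairwise weights and/or outcome
coefficients for its upper level, with each level sampled from its own
chain.

The default fixture (`default_study_model`) plants a sparse,
clinically-shaped symptom network (mood/guilt/suicidality cluster,
anxiety/somatic chain, insomnia chain, retardation–work coupling; weights
0.10–0.25 with a small seed-dependent jitter) and exactly three outcome
coefficients: log 0.75 on suicidality, log 1.21 on retardation, log 1.31 on
hypochondriasis. The outcome intercept 0.15 targets a ≈62% marginal
remission rate. Edge weights are free parameters of the test fixtures —
chosen once for realism, with row sums below 1 so properness is guaranteed —
not empirical claims.

What the generator does **not** emulate: genuinely ordinal response
processes (thresholded-latent rather than rounded-Gaussian categories),
item-level missingness, per-item residual variances, floor effects of
severely skewed items, or longitudinal change under treatment. Passing
recovery tests therefore shows the estimator works when its model class is
correct; it does not certify behavior under ordinal misspecification, which
is a known limitation of treating Likert items as continuous.

## Numerical choices

* Gaussian nodewise CV uses scikit-learn's `lasso_path` per fold
  (fold-centered responses); the final refit is a full-data `Lasso` at the
  selected λ (tol 1e-8).
* Binomial fits use an in-package IRLS + coordinate-descent path
  (glmnet-style: quadratic approximation, soft-thresholding, unpenalized
  intercept, warm starts along the descending λ grid; numba-compiled).
  CV paths run at tol 1e-5, final refits at 1e-9; the solution matches
  scikit-learn's saga solver to ~1e-6 and unpenalized ML fits to ~1e-6
  (tested). A relative slack of 1e-12 at the soft-threshold boundary keeps
  coefficients exactly zero at λ = λ_max despite floating-point rounding
  of the KKT bound.
* IRLS working weights are floored at 1e-5; fitted probabilities are
  clipped at 1e-12 when computing out-of-fold log-loss.
* Edge retention uses a 1e-10 magnitude threshold on otherwise exact
  coordinate-descent zeros.
* All randomness (Gibbs chains, CV folds, bootstrap resampling, moderator
  draws) derives from explicit integer seeds via `numpy.random.SeedSequence`;
  identical seeds give bit-identical cohorts, fits and bootstrap summaries.

## Selection behavior under the null, honestly

Minimum-CV LASSO is a prediction-oriented selector and is known to admit
weak spurious terms. In the package's own calibration studies (computed by
the test suite), pure-noise cohorts at n = 2000 leave the outcome node
isolated in only about two thirds of fits even under the AND rule, and
zero-shift moderated fits almost always flag at least one spurious
interaction among the 153 candidate pairs. We cross-checked this against an
independent reference pipeline (R `cv.glmnet`, deviance loss, `lambda.min`,
10-fold, AND rule) on identical cohorts and obtained statistically
indistinguishable behavior, so this is a property of the design, not of the
implementation. Consequently edge *presence* should be read together with
bootstrap inclusion proportions and the smallest retained weight — not as a
significance test. Planted effects of the default fixture's size are
essentially always recovered with correct signs at n = 2000, and a +0.5
between-study edge shift is detected in every one of 50 power-study
replicates at n = 4000.

## Problem sizes used by the bundled studies

Recovery and null studies run at n = 2000 (20 and 100 replicates), the
moderation power study at n = 4000 (50 replicates), and bootstrap stability
with 200 resamples of one n = 2000 cohort — sizes chosen so each study
gives stable Monte-Carlo proportions on a single CPU. The acceptance script
(`scripts/acceptance.py`) reruns the full synthetic study at the same sizes
from a single command-line seed.
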