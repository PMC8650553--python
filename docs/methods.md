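# Methods

## Model

The analysis object is a discrete Bayesian network over dichotomous
questionnaire-derived variables. Two granularities are used:

* **Core network** (3 nodes): job stress (JS) → safety climate (SC),
  JS → accident, SC → accident. Its parameters are calibrated to
  published values: the accident CPT P(yes | SC, JS) = 0.91 / 0.93 /
  0.32 / 0.95 over (SC, JS) = (low,low), (low,high), (high,low),
  (high,high); P(JS = high) = 0.50; P(SC = high | JS = high) = 0.37. The
  remaining entry P(SC = high | JS = low) is not printed anywhere and is
  solved from the SC marginal: 0.53 = 0.50·0.37 + 0.50·x ⇒ x = 0.69.
  The accident CPT is reproduced as printed, including its
  non-monotonicity (P(yes | SC=high, JS=high) = 0.95 exceeds the
  SC=low, JS=high entry); no "correction" is applied.
* **Full network** (26 nodes): 16 GJSQ stress-scale nodes → JS; JS → each
  of the 7 NOSACQ-50 climate dimensions; the 7 dimensions → SC; JS and SC
  → accident. Its parameters are learned from data.

All inference is exact sum-product variable elimination with a min-degree
elimination order. Exactness does not depend on the order, only cost,
which is negligible at this scale (the largest factor is the 17-variable
family of the 16-parent JS node, ~131k entries). Evidence whose
probability falls below 1e-300 is treated as zero and rejected as
inconsistent. Probabilities are stored in linear space; likelihood
computations use the log-space joint.

## Structure elicitation

Expert opinions per candidate pair are basic probability assignments over
nonempty subsets of {forward, backward, none}; composite subsets are
allowed, so an expert can express partial ignorance. Opinions are fused
with Dempster's rule (conflict mass K renormalized away; K = 1 raises).
The decision rule is configurable because no canonical choice exists:
default is the pignistic maximum (each subset's mass split equally among
its atoms), with max-belief and max-plausibility available. Exact ties
break conservatively toward "no edge", then "forward". Experts are
equally credible by default; Shafer discounting per expert is available.
Accepted directed verdicts are admitted in descending support order and
an edge whose addition would create a cycle is skipped and reported.

## Preprocessing

* **Dichotomization** uses the uniform-width method: the variable's range
  is split into two equal bins and the midpoint is the boundary; values
  at the boundary are "high" (deterministic, documented tie rule).
  The range is the observed min/max by default; the instrument's
  theoretical range (1–5 GJSQ, 1–4 NOSACQ-50) is available. Observed
  range is the default because mid-scale boundaries from theoretical
  ranges can leave a nearly empty bin when responses cluster.
* **Composites**: the overall job-stress and safety-climate variables are
  the row means of the scale (dimension) mean-scores, mirroring how
  instrument total scores are formed; they are then dichotomized like any
  other variable.
* **Imputation** runs on the continuous scores *before* discretization
  (the alternative — discrete EM inside the network — lives in the
  learning module). It is multivariate-normal EM: E-step replaces missing
  cells by conditional expectations given the observed cells (with the
  conditional-covariance correction for second moments); M-step updates
  mean and covariance; iteration stops when the observed-data
  log-likelihood improves by < 1e-6 (cap 200 iterations). The
  log-likelihood is asserted non-decreasing every iteration. Singular
  covariance blocks are ridge-regularized by 1e-8·trace/p. Missingness
  above 30% per variable (configurable) is refused.
* **Reliability**: Cronbach's α with unbiased variances, and ICC from the
  two-way ANOVA decomposition in the *consistency* form (ICC(3,1),
  ICC(3,k)); the agreement/consistency choice is flagged because the
  source method description ("two-way mixed") does not make it, and
  consistency is the common default for internal-reliability use.

## Parameter learning

CPT entries are (expected count + λ) / (expected parent count + λ·states)
with pseudocount λ = 1 by default (λ = 0 gives plain MLE; unobserved
configurations then yield uniform rows and a warning). EM handles missing
cells exactly: per record, the posterior over each family's missing
members given all observed cells is computed by variable elimination;
expected counts accumulate over records (grouped by observed-value
pattern, with fully observed families counted directly). Initialization
is uniform CPTs with symmetric Dirichlet jitter; 3 restarts keep the best
final objective; convergence is an absolute objective change < 1e-6
(cap 500 iterations). With λ > 0 the ascended objective is the penalized
likelihood (likelihood × Dirichlet prior); it is asserted non-decreasing
at every iteration, and with λ = 0 this is the plain log-likelihood.
Fully observed data short-circuits to closed-form estimation in one
iteration.

The 16-parent JS node is unestimable as a full table from ~1530 records
(2^16 rows). Nodes with ≥ 9 binary parents therefore default to a
noisy-OR parameterization — P(child = high | parents) = 1 − (1 − leak)
∏_{active j} (1 − w_j) — fitted by weighted maximum likelihood (L-BFGS on
logit-scale parameters) and expanded to a dense table for inference. A
full-table-with-smoothing path is available; the two choices do not
affect accident prediction when JS is observed, since the accident node's
Markov blanket is then fully observed.

## Sensitivity

Delta-p is defined as the *relative* percent change of the target-state
probability under point evidence:
change(s) = 100·(P(target | factor = s) − P(target)) / P(target).
This definition is adopted because it reproduces the published
job-stress sensitivity row to within 0.4 points from the printed CPT
(+77.6 / −77.6 vs the published 78.01 / −77.72; the residual is the
source's unrounded internal CPT). Factors are ranked by
Variation = |Low%| + |High%|, ties broken alphabetically.

Edge influence measures the distance between the child's conditional
distributions as the parent switches states, aggregated over the other
parents' configurations. Four metrics are exposed — unweighted average
total variation (default), probability-weighted average TV, average
Euclidean, maximum TV — because the source's "influence value" formula is
unstated; none of the standard variants reproduces its printed
magnitudes, so only the ordering (JS→accident above SC→accident) is
treated as reproducible.

## Validation

Folds are a uniform random permutation assigned round-robin (sizes differ
by ≤ 1), deterministic given the seed; stratification by outcome is
available but off by default. Per fold, CPTs are learned on the other
k−1 folds and each held-out record is scored by the exact posterior
P(accident = yes | all its other variables); when the accident node is a
sink with fully observed parents this reduces exactly to a CPT-row
lookup, used as a fast path. Classification threshold is 0.5 (score ≥
threshold predicts "yes"). AUC uses the Mann–Whitney rank formulation
with midranks, which equals the trapezoidal area under the ROC points at
every distinct threshold. Note that with an uninformative model,
per-fold marginal estimates anticorrelate with held-out labels and bias
CV-AUC slightly below 0.5; chance level is exactly recovered under
stratified folds.

## Synthetic cohorts

Each subject draws a latent JS state ~ Bernoulli(0.50), a latent SC state
from P(high | JS) = 0.37 / 0.69, and the accident outcome from the
published CPT, giving an accident marginal of 0.7202 analytically. The
16 stress scores (range 1–5) and 7 climate scores (range 1–4) are
truncated normals with sd 0.6 whose means shift by scale_effect·sd
(default 1.0 sd) with the corresponding latent state; the two group means
sit symmetrically about the instrument midpoint so truncation compresses
both groups equally and the designed effect size survives
discretization. Missingness can be injected MCAR (default) or MAR with
deletion probability depending on the accident state; the outcome is
never deleted. Cohorts are bit-reproducible given parameters and seed.

What the generator does *not* emulate: item-level response structure
(only scale mean-scores are modeled), demographic covariate effects on
risk, correlated residuals between scales, non-normal response styles,
and MNAR missingness. Passing recovery tests therefore show that the
pipeline recovers the generating mechanism it assumes — not that the
model is correct for any particular real cohort.

A deliberate consequence of the design: the pipeline observes the latent
states only through discretized composite scores, which misclassify the
latent JS state ~3% and the latent SC state ~10% of the time under the
default effect size. This attenuates the learned accident CPT contrast
(the recovery report carries both the latent-conditioned error, which
vanishes as n grows, and the learned-CPT error, which plateaus around
0.10–0.15) and caps cross-validated accuracy near 81% and AUC near 0.80
— close to, but by construction not identical to, the performance
reported for the real cohort (85%, 0.8353).

## Problem sizes used in the test suite

Consistency checks run at n = 200k records sampled directly from the
three-node network (MLE recovery to ±0.01); EM-with-missingness recovery
at n = 5k with 10% MCAR; end-to-end pipeline recovery at n = 20k; the
validation bracket at the study size n = 1530 over 10 seeds and the
ranking-stability check over 20 regenerated cohorts. These sizes were
chosen so each check's sampling error is comfortably below its assertion
tolerance while the whole suite stays quick to run.

## Known limitations

* Exact inference only; no sampling or loopy approximations (fine at 26
  binary nodes, not intended for hundreds).
* Point estimates only (maximum likelihood / MAP with pseudocounts); no
  Bayesian posterior over parameters.
* Structure comes from expert elicitation; no score- or constraint-based
  structure learning.
* One published posterior (accident given low safety climate) computes to
  92.34% from the printed rounded inputs while the source prints 93%; the
  package reports the computed value and documents the residual rather
  than matching the print.
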