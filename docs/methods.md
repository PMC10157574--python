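# Methods

`dwkit` estimates disability weights (DWs) for a catalog of health
states from two kinds of survey responses and attaches uncertainty to
them. This note describes the statistical model, the synthetic-data
generator used to validate it, and the numerical and design choices
behind the implementation.

## The estimation model

**Paired comparisons (PC).** Each respondent answers 16 forced choices
"which of these two people is healthier?". With an indicator coding of
+1 for the state shown first, −1 for the state shown second and 0
otherwise, the choice of the first state as healthier is modeled with a
Thurstonian probit,

    P(Y = 1 | X) = Φ(X′β),

so each state receives a latent healthiness index β_s and the choice
probability for a pair depends only on the difference β_first −
β_second. Because only differences are identified, the location of β is
pinned by a constraint — sum-to-zero over the included states by
default, or a designated reference state fixed at zero. The likelihood
is maximized by a damped Newton iteration with analytic gradient and
observed-information Hessian, started at β = 0; a small ridge penalty
(10⁻⁶, configurable) keeps estimates finite when a state wins or loses
every one of its comparisons (quasi-complete separation, warned and
reported). The covariance of β̂ is the inverse observed information on
the free parameters, mapped back to the full vector.

**Population health equivalence (PHE).** Web respondents additionally
answer three questions opposing a program that prevents 1000 rapid
deaths to one preventing M ∈ {1500, 2000, 3000, 5000, 10000} lifelong
nonfatal cases of a specific state. Preferring the nonfatal program
reveals DW > 1000/M, the fatal program DW < 1000/M, so each response is
a one-sided censored observation of the state's DW at a known threshold.
A censored-normal (interval) regression on a transformed scale places a
location γ_s per anchor state with a common residual σ; the inverse
transform of γ̂_s is the state's PHE disability weight. Locations are
box-constrained to the transform of [10⁻⁴, 1 − 10⁻⁴]; a state whose
responses are all one-sided pins at the box and is flagged — such a
state carries no usable PHE information (see below).

**Anchoring.** The probit index is unitless; the PHE DWs anchor it to
the 0–1 scale through an ordinary least-squares line fitted over the
anchor states,

    logit(DW_PHE,s) = a + b · r(s) + ε_s,

after which every state receives DW_s = expit(a + b · r(s)), guaranteed
inside (0, 1). The regressor r is configurable: the latent index β_s
itself (pipeline default) or the predicted probability Φ(β_s). Anchor
states flagged at the interval-regression boundary are excluded from
the line: a pinned location is an artifact of one-sided data, and a
single such point, being far outside the range of the others on the
logit scale, can tilt the whole line.

**Uncertainty.** Two complementary mechanisms:

* *Monte Carlo means*: β vectors are drawn from N(β̂, V̂), pushed
  through the anchoring prediction and averaged per state (1000 draws
  by default), giving a mean that accounts for the nonlinearity of the
  expit link.
* *Bootstrap 95% uncertainty intervals*: respondents — the exchangeable
  unit — are resampled with replacement, stratified by survey mode so
  household/web counts (and the web-only PHE structure) are preserved;
  the entire probit → interval → anchoring → prediction chain is re-run
  per replicate (1000 by default) and the 2.5th/97.5th percentiles
  taken per state. Replicates in which a state drops out are excluded
  for that state; states absent from more than 10% of replicates are
  flagged unreliable. If percentile noise places the Monte Carlo mean
  outside its interval, the interval is widened to include it (warned).

## Default estimation configuration

The module-level functions default to the literal description of the
method: interval regression on the logit scale and the predicted
probability Φ(β) as the anchoring regressor. The *pipeline* defaults
(`RunConfig`) differ deliberately:

* `interval_scale="log"` — PHE misperception of severity is
  multiplicative in nature, and a log-scale censored-normal model is
  exactly the instrument's noise model under that assumption;
* `regressor="index"` — regressing logit(DW) on β itself makes the
  anchoring line absorb the probit location entirely, so final DWs are
  invariant (to numerical precision) to the identifiability constraint;
  with the Φ(β) regressor that invariance fails because Φ is nonlinear.

Under the synthetic generator below, the matched (log/index) chain is
correctly specified; simulation shows its bootstrap intervals are
calibrated (~0.9 empirical coverage at nominal 0.95 at the reduced
study scale), while the logit/probability alternative recovers the DW
ordering equally well but exhibits small systematic curvature biases
that push interval coverage down to ~0.6. Both alternatives remain one
configuration flag away.

## The synthetic-data generator

The generator exists so that the whole pipeline can be exercised and
scored against a known truth without any external data. It emulates the
modeled survey design: 2610 household + 3140 web respondents by
default, 16 PC questions each with one pair repeated at positions 3, 10
and 16 (same presentation order, for test–retest diagnostics), 3 PHE
questions per web respondent over the anchor subset, and
minimum-selection balancing for both pair and anchor assignment (each
fresh draw is uniform over the currently least-used items, keeping
selection counts within a spread of one and guaranteeing coverage of
all unordered pairs once the draw count suffices).

Ground truth: one DW per state from Beta(1.2, 6) — right-skewed, ~90%
of mass below 0.4, matching the skew such surveys observe. The latent
index is the exact inverse of the anchoring model, h = (logit(dw) −
a\*)/b\* with defaults a\* = −2.0, b\* = −1.7, which centers h near
zero and gives a median PC choice accuracy of about 0.75 — a realistic
discrimination level for lay respondents comparing health-state
descriptions. PC choices are Bernoulli with P(first) = Φ(h₁ − h₂). PHE
choices use multiplicative log-normal perception noise (sd 0.5 on the
log scale): the nonfatal program is preferred iff M·dw·exp(ε) > 1000;
exact indifference at zero noise resolves to the fatal program
(documented tie-break). Completion times are sampled above the QC
threshold so clean cohorts pass filtering; an `invalid_fraction` knob
injects respondents violating specific QC rules, tagged so tests can
check the filter catches exactly them.

Synthetic anchor subsets (`select_anchors`) are placed at evenly spaced
severity ranks, restricted to true DWs in [0.05, 0.95]: the PHE
thresholds 1000/M span only 0.1 to 2/3, so a state far outside that
band draws the same answer from essentially every respondent at every
multiplier and contributes an unstable, uninformative anchor — real
survey designs likewise choose anchor states of graded, measurable
severity.

What the generator does **not** emulate: demographic heterogeneity in
valuations, respondent-level consistency differences, order or fatigue
effects, and any cultural structure in which states are judged severe.
Passing recovery tests therefore show that the estimation chain inverts
its own generative assumptions at survey scale — not that those
assumptions hold for any particular human population.

## Quality control

Respondents are excluded, in order of precedence: duplicate IDs beyond
the first occurrence; incomplete PC sets (≠16 answers or repeated
question indices); web respondents faster than 180 s (household
interviews are interviewer-administered and exempt); all-A or all-B
straightlining; and strict alternation over all 16 answers starting
with either option (a single break defeats the pattern). The filter is
idempotent and reports every exclusion with its rule. Test–retest
consistency — the fraction of successive repeated-pair showings picking
the same state — is a reported diagnostic, never a filter.

## Numerical choices

* Probit Newton iteration: convergence at free-gradient max-norm
  < 10⁻⁸; step capped at max-norm 2 (under separation the penalized
  ridge direction is nearly flat and raw steps can be enormous); line
  search accepts with slack relative to |loglik| so float-level noise
  cannot stall the final iterations; log-CDF evaluations via
  `scipy.special.log_ndtr` throughout.
* Interval regression: L-BFGS-B on (γ, log σ) with analytic gradients,
  deterministic start (per-state mean of finite bounds; σ = 1);
  boundary hits flagged at 10⁻⁸ of the box.
* Binning: half-open [k/10, (k+1)/10) with the top bin closed at 1;
  distribution percentages are computed against the full catalog size
  by convention, even when some states carry no estimable DW.
* Determinism: every stochastic stage derives its stream from the run
  seed and a CRC-32 hash of the stage name; identical inputs, config
  and seed give byte-identical output files.
* Exports round DW means and interval bounds to 3 decimals; full
  precision is kept internally.

## Problem sizes used in validation

The recovery study (`dwkit.recovery_study`, also run by
`scripts/acceptance.py`) uses a reduced universe: 30 states, 10
anchors, 1000 household + 1000 web respondents, 200 bootstrap
replicates, three independent replicate datasets, pooling all scored
states. These sizes keep a full study under about a minute while
leaving every estimator in its asymptotic regime (≈900 comparisons per
state, ≈600 PHE responses per anchor).

## Known limitations

* The bootstrap treats the pair-assignment mechanism as fixed;
  balancing-induced dependence between respondents is ignored (it is
  negligible at survey scale).
* Monte Carlo means propagate probit uncertainty only; anchoring-line
  and interval-regression uncertainty enter through the bootstrap
  intervals instead (each replicate refits both).
* The shipped 206-state catalog carries the real published state
  labels, but its lay descriptions, symptom flags and 28-state anchor
  subset are synthetic stand-ins (seeded; per-category flag counts
  matched to published category totals), because the survey's per-state
  annotations are not publicly deposited. Analyses that depend on which
  specific states carry which flags are therefore only meaningful on
  real annotations supplied by the user.
* Cross-survey comparisons (proportional differences, the
  eleven-category regression, Pearson correlation) require an external
  reference DW table; without one the pipeline skips them gracefully.
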