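# Methods

## The valuation problem

CALY-SWE describes a life situation by six attributes on three agreement
levels; a value set assigns each of the 729 states a capability weight on
[0, 1] for computing capability-adjusted life years. Two preference
sources are combined: time trade-off (TTO) answers, which locate single
states on the unit interval (an answer of x years against a 10-year
horizon gives weight w = x/10, so answers live on the grid 0.1, …, 1.0,
narrowed to 0.2–0.9 for the guided learning task), and discrete choice
experiment (DCE) answers, which carry relative information about
attributes and levels without a scale of their own.

## Coding

States are coded cumulatively: per attribute one indicator for reaching
level 2 and one for reaching level 3, so the level-2 coefficient is the
gain over the base level and the level-3 coefficient the further gain over
level 2. With all 12 increments constrained nonnegative, predicted weights
automatically respect dominance: improving any attribute can never lower a
weight. The *discapability* coding flips this into cumulative decrements
(indicators for falling short of level 3 and for sitting at level 1),
modeling `1 - y` without a constant so the best state 333333 is pinned to
weight 1 structurally.

## Model family

All members share the additive TTO mean `mu + X beta` (attainment) or
`1 - X' beta` (discapability). Feature flags add:

- **Censoring.** Answers at the grid boundary are treated as Tobit
  observations: the lower-tail mass at 0.1 (0.2 for the learning state),
  the upper-tail mass at 1.0 (0.9). Boundary status is detected by
  equality with the bound, matching how grid data present; interior
  answers contribute the normal density.
- **Hybrid DCE component.** `P(choose A) = logistic(theta (X_A - X_B)
  beta)` with the increments shared between components and a free logit
  scale factor `theta > 0`. The anchor scale never enters the DCE side.
- **Heteroskedasticity.** `log sd_i = mu_H + X_i beta_H` with `beta_H >=
  0`, the same parametrization as the mean; `beta_H = 0` recovers the
  constant-sd model exactly.
- **Varying intercept.** A per-participant normal offset, non-centered
  (`offset = omega * b_raw`, `b_raw ~ N(0,1)`), capturing individual
  response-scale shifts.
- **Anchoring.** The anchor-scale model multiplies only the level part of
  the TTO mean by `s > 0` and adds a pseudo-observation of 1 at
  `mu + sum(beta)` with SD 0.01. The reported tariff uses the anchored
  coefficients without `s` (the unit scale); `s` absorbs the compression
  of raw TTO answers and is applied when predicting answers (e.g. in
  cross-validation, which scores predictions on the answer scale).

## Priors and fitting

Priors are weakly informative and positivity-respecting: half-normal(1) on
the increments, `sigma`, `omega`, `s` and `beta_H`; normal(0,1) truncated
at zero on `mu`; half-normal(10) on `theta`; normal(0,1) on `mu_H`. The
anchor SD (0.01) is part of the model, not a tunable prior.

Positive parameters are sampled on the log scale (with the Jacobian).
The reference fit is ensemble MCMC (64 walkers by default, 80%
differential-evolution and 20% snooker moves, initialized at the MAP with
small jitter; 12 000 burn-in and 10 000 retained steps). The
anchor pseudo-observation creates a narrow ridge between `mu` and the
increments — DE moves traverse it far better than the stretch move, which
is why they are the default. Convergence is gated: split-chain R-hat ≤
1.01 and bulk ESS ≥ 400 for every sampled parameter, otherwise the fit is
flagged (never silently accepted). Identical seeds and settings reproduce
identical summaries.

The MAP path (L-BFGS-B in the unconstrained space, box-bounded to avoid
degenerate plateaus) with a finite-difference Laplace approximation serves
cross-validation, sensitivity refits and quick exploration. Its credible
bands match the MCMC reference closely at moderate n, but the summed
posterior-mean weight of 333333 can overshoot 1 by a few hundredths
because means of exp-transformed Gaussian draws are biased upward; the
anchor holds exactly at the mode (`map_params_`). Varying-intercept specs
add one dimension per participant, so the MAP path is the practical
default for them; the methods-grade posterior for the reported tariff
comes from the MCMC path on specs without varying intercepts.

## Experimental designs

The TTO design maximizes the D-criterion of the 13-parameter main-effects
linear model by coordinate exchange (20 random restarts by default;
efficiency improves monotonically within each sweep). Efficiency is
reported against the continuous D-optimum over all 729 candidate states,
computed by a Fedorov–Wynn multiplicative algorithm; determinant ratios
are invariant to recoding, so the choice of coding does not affect the
percentage. The pit state 111111 and 333333 are excluded from the search:
the pit is appended to every block, and the learning state (three
attributes at level 2, three at level 3; default 222333, configurable
because the fielded state is not public) always opens the TTO block.

The DCE design takes the 18 rows of the classic L18 orthogonal array as
first alternatives and adds the generator (1,1,1,1,1,1) modulo 3, so every
attribute differs in every pair and each level change occurs equally
often. Its multinomial-logit main-effects information matrix equals the
continuous optimum — the uniform design on all-attributes-differing pairs,
whose optimality is certified by checking the Kiefer–Wolfowitz equivalence
theorem over every candidate pair — hence D-efficiency is exactly 100%.
Participants see five randomly drawn choice sets plus the fixed dominated
consistency pair (222332 vs 232332) at a random position.

## Synthetic surveys

The generator emulates the structure the analysis assumes: latent TTO
values are the additive truth plus normal noise (SD 0.302 by default), then
mapped to the answer grid by half-up rounding with boundary clamping — a
step-by-step bisection emulator of the year-trading task is provided and
provably agrees with the rounding engine. DCE choices are Bernoulli draws
from the logistic model. The default truth is the final published
anchored model (constant 0.114; increments summing with it to ≈1; logit
scale 5.952), so the default conditions mirror the study the pipeline
emulates; 20% of participants are careless by default (uniform grid
answers, coin-flip choices), in line with the observed ~17–20%
inconsistency rates. Each participant owns an RNG stream derived from
(survey seed, participant id), making tables bit-identical across runs.

What the generator does **not** emulate: demographic covariates and
quota sampling, panel attrition, response times, order effects between
the DCE and TTO blocks, and genuinely heteroskedastic or individually
shifted engaged respondents (unless configured). Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
assumed response model, not behavioural validity of real survey data.

One deliberate mismatch is worth naming: rounding assigns the boundary
answer 0.1 to every latent value below 0.15, while the Tobit likelihood
attributes boundary mass to latents below 0.10. At noise SD 0.3 this
shifts the recovered constant downward by roughly 0.03–0.05 (states near
the floor carry the most half-cell excess), which is visible in
recovery experiments as a small negative bias of `w(111111)` and keeps
coefficient coverage slightly below nominal. This is a property of
grid-censored data generation, not of the fitting code; the bias shrinks
with the noise SD.

## Quality control

Within each participant's five answered states, every ordered dominated
pair is classified: weak inconsistency if the dominating state's weight is
≤ the dominated one's, strict if <. The CIS score sums the violation
sizes of weak records plus a penalty of 0.05 per exact tie — zero iff the
participant is consistent, monotone in number and severity of violations.
The exact severity kernel used in the original study is not public; the
implemented kernel satisfies the same contract and is pluggable. The 20%
of participants with the highest CIS lose their TTO data
(`ceil(fraction * n)`, ties broken by participant id, highest removed
first, for determinism); DCE data are never excluded.

## Model comparison

Cross-validation folds are drawn at the participant level (all of a
participant's answers are held out together), preventing leakage of
individual response styles. DCE accuracy counts a held-out choice correct
when the predicted probability sides with it; an exact 0.5 counts half.
TTO errors are measured on the answer scale (anchor scale applied).
Logit fidelity normalizes each 12-vector of increments to shares summing
to 100% and adds up absolute share differences — zero for proportional
vectors, reported in percentage points. Five metrics enter the ranking
(accuracy up; MAE, distance of `w(333333)` from 1, fidelity, and mean 95%
CI width relative to the spanned weight range, all down); percentile
scores use average ranks for ties. The CI-width metric divides the mean
interval width by (max − min) of the posterior-mean weights — the "range
covered" is not defined more precisely in the source material, and this
reading is fixed here. The Breusch–Pagan screen is the standard n·R²
auxiliary regression of squared OLS residuals on the 12 indicators
(chi-squared, 12 df). The sensitivity analysis refits the selected spec
retaining the best 50–100% of participants by ascending CIS.

## Numerical choices and scales used in tests

- Boundary detection uses `np.isclose` against the grid bounds.
- The continuous linear optimum iterates the multiplicative weight update
  until the maximal normalized prediction variance is within 1e-9 of the
  parameter count.
- Exact-midpoint latents round up in both answer engines, phrased through
  the same floating-point expression so they cannot disagree.
- Test problem sizes are chosen for precision per check: designs and
  likelihood oracles run at ≤ 24 states; recovery uses one 500-participant
  engaged survey (2 500 TTO, 3 000 DCE answers) with the full MCMC
  reference; calibration of the Breusch–Pagan test uses 1 000 replicates
  of n = 200; quality-control checks use 500–1 000 simulated participants.

## Known limitations

- Main effects only; no attribute interactions.
- No worse-than-dead valuations: answers are bounded below at 0.1.
- The MAP/Laplace path's posterior-mean summaries carry the
  log-transform bias described above; use the MCMC path for reported
  tariffs.
- Varying-intercept specs are fit by MAP by default; their full-posterior
  treatment is supported but slow in high dimensions.
- The published 43-set DCE design and the original blocked design are not
  reconstructable from public information; the constructions here match
  them in method and in the efficiency metric, not row for row.
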