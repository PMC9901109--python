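# Methods

## Estimator

For subject i with events at times t_{i1} < ... and severity weights
w ∈ (0, 1], the weighted survival path is the right-continuous step function
Ŝ_i(t) = ∏_{j: t_j ≤ t}(1 − w_ij). The pooled curve is the mean of the n
subject paths, evaluated on the union of all subjects' event times plus
t = 0. Conventions:

* **Right continuity.** Ŝ(t) "at t" includes events occurring at exactly t.
* **Simultaneous events** of one subject at one time multiply into a single
  step; order within the time is irrelevant.
* **Terminal events** (death, weight 1) drive the path to exactly 0.0 —
  floating multiplication by (1 − 1.0) is exact — and the subject
  contributes zero to every later grid point. Events after a terminal event
  are rejected at validation, as are right-censoring markers: the method
  requires every subject observed to τ or to death.
* **Event-free subjects** stay at 1 for the whole window and must be counted
  in n; the trial-table format keeps them recoverable through `NONE` roster
  rows at time τ.

The mean form equals the product-limit recursion
Ŝ(t_j) = Ŝ(t_{j−1})(1 − d_j/n_j) with weighted increments
d_j = Σ_i[Ŝ_i(t_{j−1}) − Ŝ_i(t_j)] and weighted risk set
n_j = Σ_i Ŝ_i(t_{j−1}); the implementation computes the mean form in a
single event-driven sweep (O(events + grid)) and the test suite verifies
the identity to 1e−12 absolute on every dataset — the natural tolerance for
pure products and sums of unit-scale values. With all weights forced to 1
and subjects truncated at the first event, the estimator reproduces the
classical no-censoring Kaplan–Meier exactly (checked against lifelines at
1e−12), so the traditional analysis is implemented as that special case.

## Variance

At each grid time the event-type indicator of a surviving subject is
modelled as one multinomial draw over the K types plus a no-event category,
with type probabilities P_j estimated by E_.j/n_j (event counts at exactly
t_j over the risk set). The per-event weight ω = WᵀE then has mean WᵀP_j and
variance Wᵀ[diag(P_j) − P_jP_jᵀ]W, and a delta-method expansion of the
product path gives

Var(Ŝ(t)) ≈ (1/n²) Σ_i Ŝ_i²(t) Σ_{j: t_j ≤ t} Wᵀ[diag(P_j) − P_jP_jᵀ]W / (1 − WᵀP_j)².

Choices made where the formulation left room:

* **Risk-set definition.** n_j in P̂_j = E_.j/n_j is the *weighted* risk set
  Σ_i Ŝ_i(t_{j−1}) — the same n_j as in the product-limit recursion — so
  that with weights 1 the quantity WᵀP̂_j reduces exactly to the
  Kaplan–Meier hazard d_j/n_j. A raw head count of subjects with positive
  path value is available (`risk_set="raw"`) for sensitivity analysis.
* **Zero-event times** contribute nothing (skipping the 0/0 in P̂_j).
* **Simultaneous same-subject events** sit outside the one-draw multinomial
  model; they are counted and tolerated up to 1% of event rows (they cannot
  occur under the continuous-time simulator) and rejected beyond that.
* **Degenerate hazards.** WᵀP̂_j ≥ 1 (the whole remaining risk set removed
  at one time) makes the accumulation factor undefined and raises an error.
* **Bands** are pointwise normal, Ŝ ± z_{α/2}·sd (default α = 0.05). They
  are clipped to [0, 1] in reports and exports; the unclipped values stay on
  the curve object because the overshoot near the boundaries is informative
  about the quality of the normal approximation. No log–log or arcsine
  transforms and no simultaneous bands are provided.

Validation: the delta-method Var(Ŝ(30)) on simulated 1500-subject arms sits
within a few percent of the empirical variance of Ŝ(30) across 1000
simulation replicates (the acceptance suite enforces 15%); the moment
formulas are checked against brute-force multinomial sampling; in the
death-only, weight-1 reduction the variance agrees with the Greenwood
binomial form at the hazard level (within 10% at moderate cumulative
mortality — the two forms genuinely diverge as cumulative mortality grows,
by a factor −log Ŝ/(1 − Ŝ)).

## Simulator

Each subject is a renewal process: at every cycle a category is drawn from
a multinomial over the K event types and "no event", the category's sojourn
is added to the clock, the event is recorded if the cumulative time is
within the τ = 30-day window, and the loop stops at death or when the clock
passes τ. Per-draw incident probabilities are the target 30-day event rates
divided by a single scalar C ≥ 1 — repeated exposure inflates realized
rates, so incident rates must be deflated to hit the targets.

* **Sojourn distributions.** Event categories draw exponential times
  parameterized by the mean time-to-event (3.0, 2.4, 2.3, 5.5 days at the
  packaged defaults). The no-event category consumes a *fixed* block of
  μ_no-event days: only its mean is ever specified, and making it
  deterministic keeps a subject's event exposure at about two draws per
  30-day window. (With an exponential no-event sojourn, short random
  event-free gaps let event-prone trajectories pack in many more draws;
  the calibrated C then lands near 2.55 and the realized-rate pattern
  becomes strongly type-dependent — inconsistent with a coefficient near 2.1
  and a near-uniform realized-to-target pattern, which the deterministic
  block reproduces.)
* **Event rate** means the proportion of subjects with ≥ 1 event of the
  type within the window — matching how trial event rates are tabulated.
* **μ_no-event calibration.** The time-accounting identity
  Σ_k μ_k + μ_no-event = τ − μ_after-death bounds the mean event-free
  sojourn between τ − Σμ_k − (death rate)·τ (all deaths at t = 0; 15.9 days
  at treatment defaults) and τ − Σμ_k (all deaths on the last day;
  16.8 days). The calibration iterates the fixed point
  μ ← τ − Σμ_k − (realized mean time after death), measuring the realized
  mean over m simulated samples of n subjects, clipping proposals to the
  analytic bounds (so every iterate after the first is inside them) and
  stopping when successive values differ by < 0.05 days; a damped update is
  engaged if the raw iteration oscillates without shrinking. From a start
  of 1 the treatment arm converges in three to four iterations to ≈ 16.29.
* **C calibration** minimizes the sum of squared differences between
  realized and target per-type proportions over C ∈ [1, 5], by a 0.1-step
  grid refined once to 0.01, with a common seed across candidates (common
  random numbers make the objective deterministic in C). A minimizer on the
  interval boundary triggers a mis-specification warning. The two
  calibrations are interdependent; `calibrate_arm` alternates them twice.
  At the packaged treatment parameters C ≈ 2.05 and the realized
  proportions land within ~1% relative of the 6/5/4/3% targets.
* **Randomness.** Trial-level simulation derives one substream per
  (arm position, subject index), so enlarging an arm never reshuffles
  earlier subjects and a fixed seed gives byte-identical trial tables. The
  vectorized batch path (`simulate_batch`) — used by the calibrations and
  Monte-Carlo checks, where only per-subject summaries matter — draws from
  a single stream and is statistically identical but orders of magnitude
  faster (~10⁶ subjects/s), which is what lets the calibrations run at
  their full m = 1000 × n = 1500 scale in seconds.

What the generator emulates: a fixed-follow-up two-arm RCT with independent
multiple recurrent events, type-specific exponential timing, and no
censoring. What it does not: correlated events or frailty, non-exponential
event timing, event-rate time trends, loss to follow-up, or covariates —
so green tests say the estimator behaves correctly under independence and
complete follow-up, not that those assumptions hold in any real trial.

## Treatment contrast

"Mean survival" is the restricted mean over [0, τ]: the area under the step
curve, reported in days and τ-normalized (the headline, on the probability
scale). Because the pooled curve is the mean of subject paths, the pooled
restricted mean equals the mean of per-subject restricted means; the
difference between arms therefore gets its CI from a subject-level
bootstrap (default, 1000 resamples of the per-subject values) or from the
normal approximation with the per-subject sample variance
(`ci_method="analytic"`). The variance-vs-sample-size experiment simulates
`replicates` trials per size, runs both analyses on each, and averages the
analytic day-by-day variances into a (method, n, day) table; the packaged
checks run sizes 250–1000 with 25 replicates, where the weighted analysis'
mean variance stays below the traditional one in every cell.

## Known limitations

* No censoring, truncation, covariates, or hazard-ratio/Cox-style output —
  the estimator is defined only for complete fixed-window follow-up.
* The delta-method variance ignores the sampling variability of P̂_j itself
  and the Greenwood comparison degrades at high cumulative mortality.
* Severity weights are inputs; nothing in the package derives or validates
  them.
* The normal band can overshoot [0, 1] near the boundaries; clipping is a
  reporting convention, not a distributional fix.
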