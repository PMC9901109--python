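# wcesurv

Weighted composite endpoint (WCE) survival analysis for fixed-follow-up
randomized trials with multiple recurrent events of unequal clinical
severity.

## The problem

Cardiovascular trials routinely use a composite MACE endpoint — e.g.
recurrent myocardial infarction (REMI), congestive heart failure (CHF),
cardiogenic shock (SHK) and all-cause death (DTH) — analyzed as time to the
*first* event. That analysis weights a first re-infarction the same as a
death, discards everything that happens after the first event, and is
dominated by the clinically mildest (and usually earliest) event types.

The weighted composite endpoint keeps every event and weights it by its
severity. Each event type k carries a stakeholder-elicited weight
w_k ∈ (0, 1] (here: REMI 0.2, CHF 0.3, SHK 0.5, DTH 1.0; death is the
terminal type). A subject's weighted survival is the product over their
events,

    Ŝᵢ(t) = ∏_{j: tⱼ ≤ t} (1 − w_ij),

and the pooled estimate over n subjects is the mean of the individual paths,

    Ŝ(t) = (1/n) Σᵢ Ŝᵢ(t),

which is identical to a product-limit recursion Ŝ(tⱼ) = Ŝ(tⱼ₋₁)(1 − dⱼ/nⱼ)
with weighted increments dⱼ = Σᵢ[Ŝᵢ(tⱼ₋₁) − Ŝᵢ(tⱼ)] and weighted risk set
nⱼ = Σᵢ Ŝᵢ(tⱼ₋₁). With all weights set to 1 and each subject truncated at
the first event this collapses to the classical no-censoring Kaplan–Meier.
Modelling the per-time event-type indicator as a single multinomial draw
with probability vector Pⱼ (estimated by E₊ⱼ/nⱼ) gives a delta-method
variance

    Var(Ŝ(t)) ≈ (1/n²) Σᵢ Ŝᵢ²(t) · Σ_{j: tⱼ ≤ t} Wᵀ[diag(Pⱼ) − PⱼPⱼᵀ]W / (1 − WᵀPⱼ)²,

and a pointwise normal band Ŝ(t) ± z_{α/2}·sd(Ŝ(t)). The method assumes
complete follow-up (everyone observed to τ or to death) and rejects
right-censored input.

The package also ships the calibrated renewal-process simulator used to
study the estimator: multinomial event-type draws with exponential
times-to-event, clock restart after each non-fatal event, a fixed no-event
sojourn of μ_no-event days, and two simulation-based calibrations — the
fixed point of μ_no-event from a time-accounting identity, and the
incident-rate coefficient C that deflates target 30-day event rates into
per-draw incident probabilities.

## Worked example

Simulate a 1500-per-arm trial at the packaged trial-derived parameters
(treatment 30-day rates 6/5/4/3% for REMI/CHF/SHK/DTH, control 3/4/5/6%,
calibrated C = 2.05 and μ_no-event = 16.29) and contrast the two analyses:

```python
import numpy as np
from wcesurv import ArmParams, EventTypeCatalog, compare_arms, simulate_arm

catalog = EventTypeCatalog.mace_default()
treatment = ArmParams((0.06, 0.05, 0.04, 0.03), no_event_mean=16.29, rate_coefficient=2.05)
control = ArmParams((0.03, 0.04, 0.05, 0.06), no_event_mean=16.29, rate_coefficient=2.05)
arms = {
    "treatment": simulate_arm(treatment, catalog, "treatment", 1500, base_seed=11, arm_position=0),
    "control": simulate_arm(control, catalog, "control", 1500, base_seed=11, arm_position=1),
}
result = compare_arms(arms, catalog, followup=30.0, rng=np.random.default_rng(11))
```

This run prints:

```
treatment  WCE mean survival 0.9554   traditional 0.8958
control    WCE mean survival 0.9402   traditional 0.8946
WCE difference 0.0152  95% CI [0.0041, 0.0257]
traditional difference 0.0011  95% CI [-0.0174, 0.0198]
treatment S(30): WCE 0.9315 (sd 0.0050), traditional 0.8393 (sd 0.0099)
```

Mean survival is the τ-normalized restricted mean (area under the step
curve over the 30-day follow-up). The weighted analysis gives each arm a
higher survival (non-fatal events only discount a subject, not remove
them), roughly halves the standard error at day 30, and detects the
treatment benefit (CI excludes 0) where the time-to-first-event contrast —
blind to the fact that the treatment trades deaths for re-infarctions —
does not.

The same is available from the shell:

```bash
wcesurv simulate --seed 11 --n 1500 --outdir out      # calibrates, writes out/trial.csv
wcesurv estimate out/trial.csv --outdir out           # curve CSVs + two-panel plot
wcesurv compare out/trial.csv --seed 11 --outdir out  # comparison JSON
wcesurv calibrate --seed 11 --outdir out              # C and no-event mean with trace
wcesurv experiment --sizes 250,500,1000 --seed 11 --outdir out
```

Input format: a long CSV `subject_id,arm,time,event_type` with one row per
event and a `NONE` roster row at time τ for event-free subjects (see
`examples/trial_mini.csv`); the catalog is `event_type,weight,terminal`
(`examples/catalog_mace.csv`).

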