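# Methods

## Model structure

Four mutually exclusive health states — Event-free, Event/Post-event,
Cured, Death — with 1-month cycles. Event-free and Event/Post-event are
time-expanded: the Event-free clock counts months since diagnosis (0–17)
and the Event/Post-event tunnel counts months since the first event
(0–17). Cured and Death are absorbing. After 18 months in Event-free
without event or death, and after 18 post-event months without death,
patients enter Cured with probability 1; consequently no occupancy
remains in a non-absorbing state after cycle 36 (latest tunnel entry at
month 18 plus 18 tunnel months). No general-population background
mortality is applied: the cohort is pediatric and the horizon short.

## Transition probabilities

All transitions are time-varying and Kaplan–Meier-derived. For a KM
curve S the probability attached to the cycle ending at month k is
`p_k = 1 − S(k)/S(k−1)`, clamped to [0, 1]; by telescoping, the product
`∏_{k≤K}(1 − p_k)` equals S(K) exactly at integer months, which the test
suite asserts to 1e−12. Inputs:

* Event-free → Event/Post-event: KM of time to first event, deaths
  censored, estimated in the control (chemotherapy) arm. The rituximab
  arm's probabilities are `1 − (1 − p_k)^HR` with HR = 0.317.
* Event-free → Death: KM of time to death censoring events, per arm in
  the base case (pooled variant available).
* Event/Post-event → Death: KM of time from event onset to death, pooled
  across arms in the base case because post-event deaths are few
  (per-arm variant available).

KM fitting is delegated to `lifelines.KaplanMeierFitter`; the module
adds risk-set/event counts per month and Greenwood standard errors.
Ties between events and censorings at the same time follow the KM
convention (events first). If a risk set is exhausted before the
horizon, the conditional probability is undefined; the schedule builder
treats subsequent months as structural zeros (no occupants remain in the
data to inform them, and by 18 months the model's cure rule takes over).

## Within-cycle ordering and the tunnel clock

Death and the event compete within an Event-free cycle. The order is
fixed: death first, then the event among survivors, i.e.
`P(event in cycle) = (1 − p_death) · p_event`, which keeps each marginal
at or below its KM input. Tunnel age 0 is the cycle of event entry;
entrants face their first post-event death risk (`p_death_pe[1]`) in the
following cycle — a patient cannot enter and exit the tunnel in the same
month. Cure at month 18 is applied after that cycle's death/event risks,
so the whole 18th month is at risk. The microsimulation oracle
(`microsim_oracle`) replays exactly these rules patient by patient and
is required (in tests and in the acceptance script) to agree with the
deterministic trace within binomial Monte Carlo error (< 0.005 at
n = 200,000).

## Accrual, discounting, costs

State membership is counted at cycle boundaries, with no half-cycle
correction: the occupancy at the start of cycle k (end of cycle k−1)
earns that cycle's 1/12 year of life, its utility-weighted QALY fraction
and its per-cycle cost, discounted by `(1 + r)^(−k/12)` (geometric
sub-annual compounding of the annual rate r, base 2.5%, range 0–5%).
With an all-zero schedule and no discounting this yields exactly 3.0 LY
and 1.5·0.8 + 1.5·0.9 = 2.55 QALY over 36 cycles, which the tests pin.

Cost components (2020 €):

* Event-free: €3,238/month (control), €2,864/month (rituximab arm,
  excluding rituximab itself).
* Rituximab: €4,108 per patient (€1.44/mg), spread uniformly over the
  rituximab arm's first six event-free cycles (the six administrations),
  weighted by occupancy. Spreading instead of charging at entry changes
  discounted totals by < 0.5% but must be fixed for reproducibility.
* Event/Post-event: €5,276/month for tunnel months 1–18 only.
* Immunoglobulin (IG), one-time: €311 (control) / €388 (rituximab) at
  model entry, €412 per entrant into Cured discounted at the entry
  cycle. The point values are the published expected costs; they differ
  from rate × per-user mean (e.g. 0.08 × 3,924 = 313.9) by rounding in
  the published rates, and the printed values are kept as the base
  case.
* Cured and Death accrue no per-cycle cost; Death no utility.

Utilities: Event-free 0.8, Event/Post-event 0.4, Cured 0.9, Death 0.

## Probabilistic sensitivity analysis

Each of the n simulations draws, independently:

* every monthly transition probability from a beta distribution with
  shapes `(d_k + ½, n_k − d_k + ½)` built from that month's risk set —
  the Jeffreys ½ adjustment keeps zero-event months uncertain instead of
  degenerate;
* one HR per simulation from log-normal(−1.14938, 0.38759), applied to
  all sampled control event probabilities;
* each cost from its gamma; the one-time IG entry costs are resampled as
  uptake rate × a gamma draw of the per-user cost;
* each utility from a beta moment-matched to SE = 20% of the mean
  (feasibility `SE² < μ(1−μ)` is checked at run time; an infeasible SE
  would be clamped to the bound and logged — with the default utilities
  all three are feasible, the Cured state's beta being heavily
  left-skewed, α ≈ 1.6, β ≈ 0.18).

Draws producing an invalid schedule are dropped and logged, never
silently resampled, so the effective n is reproducible. The CEAC is the
fraction of draws with λ·ΔE − ΔC > 0 over a €0–100,000 grid in €1,000
steps, and is re-computable from the persisted draw table.

A known property of the Jeffreys parameterization: adding ½ pseudo-event
per month to every monthly risk shifts the PSA's per-arm survival
distribution slightly below the deterministic point (≈ 0.1 LY per arm at
n = 164 per arm with 36 monthly betas). The incremental results, which
drive all conclusions, are much less affected because the shift largely
cancels between arms. The summary table therefore reports PSA means with
percentile CIs (the convention of trial-based PSA reporting), with the
dominance classification taken from the deterministic point analysis.
Whether the original analysis sampled per-cycle probabilities or
perturbed whole curves is not documented; per-cycle independent betas
are the simplest reproducible choice.

## Deterministic sensitivity analysis

One parameter at a time is set to each end of its uncertainty range
(rituximab cost ±30%: 2,876–5,340; discount 0–5%; monthly event-free
costs at their 95% CI limits, control 2,793–3,685 and rituximab
2,298–3,533; post-event 1,870–9,015; one-time IG costs at CI limits;
HR 0.148–0.677; for the QALY variant also the three utilities' CI
ranges), the model is re-run deterministically, and entries are sorted
by INMB bar width. The HR entry rebuilds the rituximab event schedule
from the bound.

## Synthetic-trial generator

The generator defines the study conditions under which everything is
tested. Event times follow a mixture-cure law: with probability 0.82 (the
control cure fraction, matching ~82% control 3-year EFS) no event ever
occurs; otherwise the event time is exponential (rate 0.15/month)
truncated to (0, 18] months — the simplest law consistent with a cured
majority and the structural assumption that all first events occur
within 18 months. The rituximab arm is generated by raising the control
arm's event-free survival function to the power HR = 0.317, so the
marginal hazard ratio is exactly the target and large-sample KM/Cox
estimation recovers it (the acceptance run checks ±0.03 at 5,000 per
arm). Note the cured fraction then scales as 0.82^0.317 ≈ 0.94,
mirroring the event counts seen in a real two-arm trial of this size.
Event-free death (0.002/month) competes with the event; post-event death
is exponential (0.045/month) from event onset; administrative censoring
at 36 months (the trial's median follow-up exceeded the horizon, so a
single administrative cut suffices for testing).

The 69-patient cost subgroup receives monthly gamma cost draws
(dispersion shape 2, CV ≈ 0.7 — a realistic patient-month spread for
hospital costs) around the per-state means, attributed by the costing
rule: event-free months end 7 days (7/30.4375 months) before an event,
post-event months run from event onset for at most 18 months. IG use is
Bernoulli at 8%/15% (entry, per arm) and 3% (post-cure) with gamma
per-user costs.

What the generator does not emulate: covariate structure (histology,
stage, country), uniform accrual censoring, toxicity-specific
hospitalization patterns, or any particular parametric shape of the real
event-time distribution — the source analysis never states one, so
passing tests demonstrate parameter recovery and pipeline correctness,
not distributional fidelity to the trial.

## Problem sizes and numerics

Default test/acceptance sizes: 328-patient synthetic trial for the
cost-effectiveness runs; 10,000 patients for parameter recovery; 200,000
microsimulated patients for the engine cross-check; 5,000 PSA draws in
the acceptance run (the CLI default is 10,000). Occupancy conservation
is asserted to 1e−12 per cycle. Probabilities from `1 − S(k)/S(k−1)` are
clamped to [0, 1] against floating-point undershoot. All randomness
flows through `numpy.random.default_rng` seeds; identical seeds give
byte-identical datasets, draws and output files.

## Known limitations

* The registry's published gamma for the rituximab per-patient cost
  (α = 7421.9, λ = 1.81) has mean €4,100.5 against the printed point
  €4,108 — a rounding inconsistency in the source parameters; the tests
  compare distribution means to points at 1% relative tolerance for this
  reason.
* The INMB definition λ·ΔE − ΔC is the standard form; the source's
  supplementary definition was not available, but all printed numbers
  are consistent with it.
* Per-cycle beta independence and the Jeffreys adjustment are modelling
  choices where the source is silent (see PSA section).
* The cohort model, like the source analysis, treats the HR as constant
  over the 18 event months and applies no covariate adjustment.
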