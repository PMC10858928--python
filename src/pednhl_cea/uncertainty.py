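"""Probabilistic and deterministic sensitivity analysis.

The probabilistic analysis (PSA) draws, per Monte Carlo simulation, one
joint realization of all uncertain parameters — hazard ratio (log-normal
on the log scale), per-state costs (gamma), utilities (beta,
moment-matched to SE = 20% of the mean) and every monthly transition
probability (beta from its month's risk-set counts) — rebuilds the
intervention schedule through the hazard-ratio transform, runs both
cohorts and records incremental effects, costs and net monetary benefit.
All draws are independent.  The cost-effectiveness acceptability curve is
the fraction of simulations with positive INMB across a willingness-to-pay
grid.

The deterministic analysis (tornado) reruns the base-case model with one
parameter at a time set to each bound of its uncertainty range.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic_trial import CONTROL, INTERVENTION, CURE_MONTHS
from .survival_transitions import TransitionSchedule, apply_hazard_ratio
from .cohort_engine import run_cohort
from .economics import ModelParams, ArmOutcome, CEAResult, accumulate, compare

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistributionSpec:
    """A marginal PSA distribution.

    families: 'gamma' (alpha, lambda; mean alpha/lambda), 'log-normal'
    (mu, sigma on the log scale; median exp(mu)), 'beta' (alpha, beta),
    'fixed' (no parameters — the base value is returned unchanged).
    """

    family: str
    params: tuple[float, ...] = ()

    def __post_init__(self):
        if self.family not in ("beta", "gamma", "log-normal", "fixed"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("beta", "gamma") and any(p <= 0 for p in self.params):
            raise ValueError("shape parameters must be positive")
        if self.family == "log-normal" and self.params[1] <= 0:
            raise ValueError("log-normal sigma must be positive")

    def sample(self, rng: np.random.Generator, base: float) -> float:
        if self.family == "fixed":
            return base
        if self.family == "gamma":
            alpha, lam = self.params
            return float(rng.gamma(alpha, 1.0 / lam))
        if self.family == "log-normal":
            mu, sigma = self.params
            return float(rng.lognormal(mu, sigma))
        alpha, beta = self.params
        return float(rng.beta(alpha, beta))


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shapes for a given mean and SE.

    Infeasible when se**2 >= mean * (1 - mean); callers may clamp the SE
    to the feasibility bound first.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly inside (0, 1)")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError("beta moment matching infeasible: variance too large")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _utility_beta(mean: float, se_frac: float) -> tuple[float, float]:
    """Beta shapes for a utility with SE = se_frac x mean, clamping the SE
    just inside the feasibility bound if needed (logged)."""
    se = se_frac * mean
    bound = np.sqrt(mean * (1.0 - mean))
    if se >= bound:
        clamped = 0.999 * bound
        logger.warning("utility SE %.4f infeasible for mean %.3f; clamped to %.4f",
                       se, mean, clamped)
        se = clamped
    return beta_from_moments(mean, se)


def default_specs(params: ModelParams) -> dict[str, DistributionSpec]:
    """The published marginal distributions keyed by ModelParams field.

    The ``transition_probs`` entry is a marker: 'beta' means each monthly
    probability is drawn from its risk-set beta stored on the schedule;
    'fixed' keeps the point schedule (the intervention arm is still
    rebuilt from the sampled hazard ratio).
    """
    return {
        "transition_probs": DistributionSpec("beta", (1.0, 1.0)),
        "hr": DistributionSpec("log-normal", params.hr_lognormal),
        "monthly_cost_ef_control": DistributionSpec("gamma", params.gamma_ef_control),
        "monthly_cost_ef_intervention": DistributionSpec("gamma", params.gamma_ef_intervention),
        "monthly_cost_pe": DistributionSpec("gamma", params.gamma_pe),
        "rituximab_cost_per_patient": DistributionSpec("gamma", params.gamma_rituximab),
        "ig_peruser_control": DistributionSpec("gamma", params.gamma_ig_control),
        "ig_peruser_intervention": DistributionSpec("gamma", params.gamma_ig_intervention),
        "ig_peruser_cured": DistributionSpec("gamma", params.gamma_ig_cured),
        "u_event_free": DistributionSpec("beta", _utility_beta(params.u_event_free, params.utility_se_frac)),
        "u_post_event": DistributionSpec("beta", _utility_beta(params.u_post_event, params.utility_se_frac)),
        "u_cured": DistributionSpec("beta", _utility_beta(params.u_cured, params.utility_se_frac)),
    }


def fixed_specs() -> dict[str, DistributionSpec]:
    """All-degenerate specs: sampling returns the base parameters."""
    keys = ("transition_probs", "hr",
            "monthly_cost_ef_control", "monthly_cost_ef_intervention",
            "monthly_cost_pe", "rituximab_cost_per_patient",
            "ig_peruser_control", "ig_peruser_intervention", "ig_peruser_cured",
            "u_event_free", "u_post_event", "u_cured")
    return {k: DistributionSpec("fixed") for k in keys}


def sample_params(base: ModelParams, specs: dict[str, DistributionSpec],
                  rng: np.random.Generator) -> ModelParams:
    """One joint parameter draw (marginals independent).

    One-time IG entry costs are resampled as uptake rate x a gamma draw
    of the per-user cost; with 'fixed' specs the published expected
    values are kept as-is.
    """
    updates: dict[str, float] = {}
    for key in ("hr", "monthly_cost_ef_control", "monthly_cost_ef_intervention",
                "monthly_cost_pe", "rituximab_cost_per_patient",
                "u_event_free", "u_post_event", "u_cured"):
        updates[key] = specs[key].sample(rng, getattr(base, key))
    for spec_key, field_name, rate, base_mean in (
            ("ig_peruser_control", "ig_onetime_ef_control",
             base.ig_rate_control, base.ig_peruser_mean_control),
            ("ig_peruser_intervention", "ig_onetime_ef_intervention",
             base.ig_rate_intervention, base.ig_peruser_mean_intervention),
            ("ig_peruser_cured", "ig_onetime_cured",
             base.ig_rate_cured, base.ig_peruser_mean_cured)):
        spec = specs[spec_key]
        if spec.family == "fixed":
            updates[field_name] = getattr(base, field_name)
        else:
            updates[field_name] = rate * spec.sample(rng, base_mean)
    return replace(base, **updates)


def sample_schedule(schedule: TransitionSchedule, hr: float,
                    rng: np.random.Generator) -> TransitionSchedule:
    """One beta draw of every monthly transition probability.

    Control event and per-arm event-free death probabilities (months
    1..18) and pooled post-event death probabilities (tunnel months
    1..18) are drawn from their per-month betas; the intervention event
    probabilities are rebuilt from the sampled control ones with the
    sampled hazard ratio.  Months without a risk set keep their point
    value (structurally 0).
    """
    out = copy.deepcopy(schedule)

    def draw(alpha: np.ndarray, beta: np.ndarray, point: np.ndarray) -> np.ndarray:
        p = point.copy()
        for k in range(1, min(CURE_MONTHS, len(alpha) - 1) + 1):
            if alpha[k] > 0 and beta[k] > 0:
                p[k] = rng.beta(alpha[k], beta[k])
        return p

    a, b = schedule.event_beta
    p_event_c = draw(a, b, schedule.p_event[CONTROL])
    out.p_event[CONTROL] = p_event_c
    p_event_i = np.zeros_like(p_event_c)
    for k in range(1, CURE_MONTHS + 1):
        p_event_i[k] = apply_hazard_ratio(p_event_c[k], hr)
    out.p_event[INTERVENTION] = p_event_i

    for arm in (CONTROL, INTERVENTION):
        a, b = schedule.death_ef_beta[arm]
        out.p_death_ef[arm] = draw(a, b, schedule.p_death_ef[arm])

    # pooled tunnel probabilities: one draw shared by both arms when the
    # stored beta arrays are identical
    drawn: dict[int, np.ndarray] = {}
    for arm in (CONTROL, INTERVENTION):
        a, b = schedule.death_pe_beta[arm]
        key = hash((a.tobytes(), b.tobytes()))
        if key not in drawn:
            drawn[key] = draw(a, b, schedule.p_death_pe[arm])
        out.p_death_pe[arm] = drawn[key]
    return out


def deterministic_result(schedule: TransitionSchedule, params: ModelParams,
                         effect: str = "ly", wtp: float | None = None
                         ) -> tuple[ArmOutcome, ArmOutcome, CEAResult]:
    """Run both cohorts and compare at the given willingness-to-pay."""
    wtp = params.wtp_reference if wtp is None else wtp
    control = accumulate(run_cohort(schedule, CONTROL), params, CONTROL)
    intervention = accumulate(run_cohort(schedule, INTERVENTION), params, INTERVENTION)
    return control, intervention, compare(control, intervention, wtp=wtp, effect=effect)


@dataclass
class PSAResult:
    """Draw table, acceptability curve and summary of a PSA run."""

    draws: pd.DataFrame  # sim, delta_ly, delta_qaly, delta_c, inmb
    ceac: pd.DataFrame  # lambda_, probability
    summary: dict
    effect: str
    n_skipped: int = 0


def _percentile_ci(x: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))


def run_psa(schedule: TransitionSchedule, base: ModelParams, n_sims: int,
            seed: int, specs: dict[str, DistributionSpec] | None = None,
            effect: str = "ly", wtp_grid=None) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Deterministic given ``seed``.  Simulations whose sampled schedule is
    invalid are dropped and logged (never silently resampled); the count
    is reported in the result.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    specs = default_specs(base) if specs is None else specs
    wtp_grid = np.asarray(base.wtp_grid if wtp_grid is None else wtp_grid, dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    per_arm = {CONTROL: [], INTERVENTION: []}
    n_skipped = 0
    sample_transitions = specs.get(
        "transition_probs", DistributionSpec("beta", (1.0, 1.0))).family != "fixed"
    for sim in range(n_sims):
        params_i = sample_params(base, specs, rng)
        if sample_transitions:
            sched_i = sample_schedule(schedule, params_i.hr, rng)
        elif params_i.hr != base.hr:
            sched_i = _rebuild_intervention_events(schedule, params_i.hr)
        else:
            sched_i = schedule
        try:
            sched_i.validate()
            control, intervention, res = deterministic_result(
                sched_i, params_i, effect=effect, wtp=base.wtp_reference)
        except ValueError as exc:
            n_skipped += 1
            logger.warning("simulation %d skipped: %s", sim, exc)
            continue
        rows.append((sim, intervention.ly - control.ly,
                     intervention.qaly - control.qaly, res.delta_c, res.inmb))
        per_arm[CONTROL].append(control)
        per_arm[INTERVENTION].append(intervention)

    draws = pd.DataFrame(rows, columns=["sim", "delta_ly", "delta_qaly",
                                        "delta_c", "inmb"])
    delta_e = draws["delta_ly" if effect == "ly" else "delta_qaly"].to_numpy()
    delta_c = draws["delta_c"].to_numpy()
    ceac = pd.DataFrame({
        "lambda_": wtp_grid,
        "probability": [float(np.mean(lam * delta_e - delta_c > 0))
                        for lam in wtp_grid],
    })
    summary = {
        "n_effective": len(draws),
        "effect": effect,
        "delta_e_mean": float(delta_e.mean()),
        "delta_e_ci": _percentile_ci(delta_e),
        "delta_c_mean": float(delta_c.mean()),
        "delta_c_ci": _percentile_ci(delta_c),
        "inmb_mean": float(draws["inmb"].mean()),
        "inmb_ci": _percentile_ci(draws["inmb"].to_numpy()),
        "prob_cost_effective_at_reference": float(
            np.mean(base.wtp_reference * delta_e - delta_c > 0)),
    }
    for arm in (CONTROL, INTERVENTION):
        outs = per_arm[arm]
        for attr in ("ly", "qaly", "cost"):
            vals = np.array([getattr(o, attr) for o in outs])
            summary[f"{arm}_{attr}_mean"] = float(vals.mean())
            summary[f"{arm}_{attr}_ci"] = _percentile_ci(vals)
    return PSAResult(draws=draws, ceac=ceac, summary=summary, effect=effect,
                     n_skipped=n_skipped)


def _rebuild_intervention_events(schedule: TransitionSchedule, hr: float
                                 ) -> TransitionSchedule:
    out = copy.deepcopy(schedule)
    p_c = out.p_event[CONTROL]
    p_i = np.zeros_like(p_c)
    for k in range(1, CURE_MONTHS + 1):
        p_i[k] = apply_hazard_ratio(p_c[k], hr)
    out.p_event[INTERVENTION] = p_i
    return out


def tornado(schedule: TransitionSchedule, base: ModelParams,
            wtp: float | None = None, effect: str = "ly") -> pd.DataFrame:
    """One-way deterministic sensitivity analysis.

    Each parameter is set in turn to the low and high bound of its
    uncertainty range (others at base); the INMB is recomputed.  The
    hazard-ratio entry rebuilds the intervention event schedule.  Entries
    are sorted by bar width descending.  For the QALY variant the three
    utilities are varied as well.
    """
    wtp = base.wtp_reference if wtp is None else wtp
    ranges = dict(base.dsa_ranges)
    if effect == "qaly":
        ranges.update(base.dsa_ranges_utilities)

    _, _, base_res = deterministic_result(schedule, base, effect=effect, wtp=wtp)
    rows = []
    for name, (low, high) in ranges.items():
        inmbs = []
        for bound in (low, high):
            params_b = replace(base, **{name: bound})
            params_b.validate()
            sched_b = (_rebuild_intervention_events(schedule, bound)
                       if name == "hr" else schedule)
            _, _, res = deterministic_result(sched_b, params_b, effect=effect, wtp=wtp)
            inmbs.append(res.inmb)
        rows.append((name, low, high, inmbs[0], inmbs[1],
                     abs(inmbs[1] - inmbs[0])))
    table = pd.DataFrame(rows, columns=["parameter", "low", "high",
                                        "inmb_low", "inmb_high", "bar_width"])
    table["inmb_base"] = base_res.inmb
    return table.sort_values("bar_width", ascending=False, ignore_index=True)
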