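"""Costs, utilities, discounting and incremental cost-effectiveness.

The parameter registry holds the model's point estimates together with
the distribution shapes used by the probabilistic sensitivity analysis
(gamma for costs, log-normal for the hazard ratio, beta for utilities and
transition probabilities) and the bounds used by the deterministic
one-way analysis.  All costs are 2020 euros; costs and health outcomes
are discounted at the same annual rate (base case 2.5%) with geometric
monthly compounding.

Accrual convention: life-years, QALYs and per-cycle costs for cycle k are
earned by the occupancy at the start of the cycle (the end of cycle k-1)
and discounted with the factor of cycle k; state membership is counted at
cycle boundaries and no half-cycle correction is applied.  One-time costs
(immunoglobulin at model entry; immunoglobulin on entering Cured) are
discounted at their entry cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_trial import CONTROL, INTERVENTION, TrialDataset
from .cohort_engine import CohortTrace, CURE_MONTHS

#: number of event-free cycles over which the rituximab per-patient total
#: is spread (the regimen's six administrations)
RITUXIMAB_CYCLES = 6


@dataclass(frozen=True)
class ModelParams:
    """Registry of model parameters (point values, PSA shapes, DSA ranges).

    Gamma parameters are (shape, rate) with mean shape/rate.  The one-time
    immunoglobulin (IG) entry costs are the published expected values
    (per-user mean cost x uptake rate, as printed); the PSA perturbs the
    per-user cost and holds the rate fixed.
    """

    hr: float = 0.317
    hr_lognormal: tuple[float, float] = (-1.14938, 0.38759)  # (mu, sigma)

    u_event_free: float = 0.8
    u_post_event: float = 0.4
    u_cured: float = 0.9
    u_dead: float = 0.0
    utility_se_frac: float = 0.2  # PSA: SE = 20% of the mean

    monthly_cost_ef_control: float = 3238.0
    monthly_cost_ef_intervention: float = 2864.0  # excludes rituximab
    monthly_cost_pe: float = 5276.0
    rituximab_cost_per_patient: float = 4108.0
    rituximab_price_per_mg: float = 1.44

    ig_onetime_ef_control: float = 311.0  # 8% x mean 3,924
    ig_onetime_ef_intervention: float = 388.0  # 15% x mean 2,545
    ig_onetime_cured: float = 412.0  # 3% x mean 15,020
    ig_rate_control: float = 0.08
    ig_rate_intervention: float = 0.15
    ig_rate_cured: float = 0.03
    ig_peruser_mean_control: float = 3924.0
    ig_peruser_mean_intervention: float = 2545.0
    ig_peruser_mean_cured: float = 15020.0

    gamma_ef_control: tuple[float, float] = (198.06, 0.06116)
    gamma_ef_intervention: tuple[float, float] = (83.83, 0.02927)
    gamma_pe: tuple[float, float] = (7.65, 0.001451)
    gamma_rituximab: tuple[float, float] = (7421.9, 1.81)
    gamma_ig_control: tuple[float, float] = (9.53, 0.002429)
    gamma_ig_intervention: tuple[float, float] = (23.48, 0.009227)
    gamma_ig_cured: tuple[float, float] = (7.21, 0.0004799)

    discount_annual: float = 0.025
    horizon_years: float = 3.0
    wtp_reference: float = 50_000.0
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 101_000, 1_000))

    #: one-way sensitivity bounds (low, high) per parameter
    dsa_ranges: dict = field(default_factory=lambda: {
        "rituximab_cost_per_patient": (2876.0, 5340.0),  # -/+ 30%
        "discount_annual": (0.0, 0.05),
        "monthly_cost_ef_control": (2793.0, 3685.0),
        "monthly_cost_ef_intervention": (2298.0, 3533.0),
        "monthly_cost_pe": (1870.0, 9015.0),
        "ig_onetime_ef_control": (163.0, 539.0),
        "ig_onetime_ef_intervention": (243.0, 549.0),
        "ig_onetime_cured": (146.0, 735.0),
        "hr": (0.148, 0.677),
    })
    #: additional bounds for the QALY variant of the tornado
    dsa_ranges_utilities: dict = field(default_factory=lambda: {
        "u_event_free": (0.41, 0.99),
        "u_post_event": (0.25, 0.56),
        "u_cured": (0.33, 1.00),
    })

    @property
    def horizon_cycles(self) -> int:
        return int(round(self.horizon_years * 12))

    def validate(self) -> None:
        for u in (self.u_event_free, self.u_post_event, self.u_cured, self.u_dead):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")
        for name in ("monthly_cost_ef_control", "monthly_cost_ef_intervention",
                     "monthly_cost_pe", "rituximab_cost_per_patient",
                     "ig_onetime_ef_control", "ig_onetime_ef_intervention",
                     "ig_onetime_cured"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.discount_annual <= 0.05:
            raise ValueError("discount_annual must lie in [0, 0.05]")
        if self.hr <= 0:
            raise ValueError("hr must be positive")

    def monthly_cost_ef(self, arm: str) -> float:
        return (self.monthly_cost_ef_control if arm == CONTROL
                else self.monthly_cost_ef_intervention)

    def ig_onetime_entry(self, arm: str) -> float:
        return (self.ig_onetime_ef_control if arm == CONTROL
                else self.ig_onetime_ef_intervention)

    def utility(self, state: str) -> float:
        return {"event_free": self.u_event_free, "post_event": self.u_post_event,
                "cured": self.u_cured, "dead": self.u_dead}[state]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["hr_lognormal"] = list(self.hr_lognormal)
        for key in list(data):
            if key.startswith("gamma_"):
                data[key] = list(data[key])
        data["wtp_grid"] = list(self.wtp_grid)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        for key in list(data):
            if key.startswith("gamma_") or key in ("hr_lognormal",):
                data[key] = tuple(data[key])
        if "wtp_grid" in data:
            data["wtp_grid"] = tuple(float(x) for x in data["wtp_grid"])
        for key in ("dsa_ranges", "dsa_ranges_utilities"):
            if key in data:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        params = cls(**data)
        params.validate()
        return params


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted per-patient results for one strategy."""

    ly: float
    qaly: float
    cost: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of intervention vs control."""

    delta_e: float
    delta_c: float
    dominance: str  # 'intervention dominant' | 'comparator dominant' | 'trade-off'
    icer: float | None
    wtp: float
    inmb: float


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Monthly discount factor (1 + r)**(-cycle/12)."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return float((1.0 + annual_rate) ** (-cycle / 12.0))


def accumulate(trace: CohortTrace, params: ModelParams, arm: str) -> ArmOutcome:
    """Discounted life-years, QALYs and cost for one arm's cohort trace.

    Per-cycle cost: event-free occupancy x the arm's monthly event-free
    cost (plus the rituximab total spread over the intervention arm's
    first six event-free cycles), tunnel occupancy x the monthly
    post-event cost.  One-time costs: the arm's expected IG entry cost at
    model start, and the cured-state IG expectation for every new entrant
    into Cured at the entry cycle.  Cured and Dead carry no per-cycle
    cost; Dead carries no utility.
    """
    T = params.horizon_cycles
    if trace.horizon_cycles != T:
        raise ValueError("trace horizon does not match params.horizon_years")
    r = params.discount_annual

    ly = qaly = 0.0
    cost = params.ig_onetime_entry(arm)  # model-entry one-time IG, cycle 0
    ritux_per_cycle = (params.rituximab_cost_per_patient / RITUXIMAB_CYCLES
                       if arm == INTERVENTION else 0.0)
    entrants = trace.cured_entrants()

    for t in range(1, T + 1):
        df = discount_factor(t, r)
        ef = float(trace.event_free[t - 1].sum())
        pe = float(trace.post_event[t - 1].sum())
        cured = float(trace.cured[t - 1])
        alive = ef + pe + cured

        ly += alive / 12.0 * df
        qaly += (ef * params.u_event_free + pe * params.u_post_event
                 + cured * params.u_cured) / 12.0 * df

        cycle_cost = ef * params.monthly_cost_ef(arm) + pe * params.monthly_cost_pe
        if t <= RITUXIMAB_CYCLES:
            cycle_cost += ef * ritux_per_cycle
        cycle_cost += entrants[t] * params.ig_onetime_cured
        cost += cycle_cost * df

    return ArmOutcome(ly=ly, qaly=qaly, cost=cost)


def compare(control: ArmOutcome, intervention: ArmOutcome,
            wtp: float = 50_000.0, effect: str = "ly") -> CEAResult:
    """Incremental effect, cost, dominance classification and INMB.

    INMB = wtp * dE - dC; the intervention dominates iff dE > 0 and
    dC < 0; the ICER dC/dE is reported only for trade-offs.
    """
    e_c = getattr(control, effect)
    e_i = getattr(intervention, effect)
    delta_e = e_i - e_c
    delta_c = intervention.cost - control.cost
    if delta_e > 0 and delta_c < 0:
        dominance = "intervention dominant"
        icer = None
    elif delta_e < 0 and delta_c > 0:
        dominance = "comparator dominant"
        icer = None
    else:
        dominance = "trade-off"
        icer = delta_c / delta_e if delta_e != 0 else None
    return CEAResult(delta_e=delta_e, delta_c=delta_c, dominance=dominance,
                     icer=icer, wtp=wtp, inmb=wtp * delta_e - delta_c)


def estimate_state_costs(dataset: TrialDataset) -> pd.DataFrame:
    """Re-derive monthly state cost means from the cost-record table.

    Means are per patient-month at risk in the state (event-free window
    months for 'event_free', tunnel months for 'post_event'), per arm and
    pooled, mirroring how the published per-state monthly costs were
    estimated from the cost-observed subgroup.
    """
    costs = dataset.costs.merge(dataset.patients[["id", "arm"]],
                                left_on="patient_id", right_on="id")
    rows = []
    for state in ("event_free", "post_event"):
        sub = costs[costs["state_label"] == state]
        for arm, grp in sub.groupby("arm"):
            rows.append((state, arm, grp["amount_eur"].mean(), len(grp)))
        rows.append((state, "pooled", sub["amount_eur"].mean(), len(sub)))
    return pd.DataFrame(rows, columns=["state", "arm", "monthly_mean_eur",
                                       "n_patient_months"])


def with_pooled_ef_cost(params: ModelParams, dataset: TrialDataset) -> ModelParams:
    """Variant: event-free monthly hospital cost estimated combining arms."""
    table = estimate_state_costs(dataset)
    pooled = float(table.query("state == 'event_free' and arm == 'pooled'")
                   ["monthly_mean_eur"].iloc[0])
    return replace(params, monthly_cost_ef_control=pooled,
                   monthly_cost_ef_intervention=pooled)
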