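"""Kaplan-Meier estimation and conversion to monthly transition probabilities.

The cohort model runs in 1-month cycles.  For a Kaplan-Meier curve S, the
probability of the modelled transition during cycle k (the month ending at
time k) is

    p_k = 1 - S(k) / S(k - u),   u = 1 month,

so that the compounded cycle probabilities reproduce the curve exactly at
its step points.  The intervention arm's event probabilities are obtained
from the control arm's via the proportional-hazards transform
1 - (1 - p)**HR.  For probabilistic sensitivity analysis each monthly
probability carries a beta distribution parameterized from the month's
risk set (events + 1/2, non-events + 1/2; a Jeffreys continuity adjustment
so that event-free months still carry uncertainty).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .synthetic_trial import CONTROL, INTERVENTION, CURE_MONTHS, TrialDataset

ARMS = (CONTROL, INTERVENTION)


@dataclass
class KMCurve:
    """Product-limit estimate with risk-set counts and Greenwood errors."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function (S = 1 before the
        first observed time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, status) -> KMCurve:
    """Product-limit estimator (ties: events precede censoring).

    Thin wrapper over :class:`lifelines.KaplanMeierFitter`; exposes the
    survival curve together with risk-set and event counts and the
    Greenwood standard error.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("negative times")
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be binary")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=status)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        kmf.event_table["observed"].iloc[0] == 0 and kmf.event_table["censored"].iloc[0] == 0 \
        else kmf.event_table
    t = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy(dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    se = surv * np.sqrt(np.cumsum(terms))
    return KMCurve(times=t, survival=surv, at_risk=n,
                   events=d, greenwood_se=se)


def cycle_probability(curve: KMCurve, t: float, u: float = 1.0) -> float:
    """Transition probability for the cycle ending at t: 1 - S(t)/S(t-u)."""
    s_prev = curve.survival_at(t - u)
    if s_prev == 0.0:
        raise ZeroDivisionError(
            f"S({t - u}) = 0: risk set exhausted, conditional probability undefined")
    p = 1.0 - curve.survival_at(t) / s_prev
    return float(min(max(p, 0.0), 1.0))


def apply_hazard_ratio(p_control: float, hr: float) -> float:
    """Proportional-hazards transform of a cycle probability:
    1 - (1 - p)**hr.  Returns 1.0 when p_control == 1 for any hr."""
    if hr <= 0:
        raise ValueError("hr must be positive")
    if not 0.0 <= p_control <= 1.0:
        raise ValueError("p_control must be a probability")
    return float(1.0 - (1.0 - p_control) ** hr)


def monthly_counts(times, status, n_months: int) -> tuple[np.ndarray, np.ndarray]:
    """Events d_k in month k (interval (k-1, k]) and risk set n_k at the
    start of the month, for k = 1..n_months (index 0 unused)."""
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    d = np.zeros(n_months + 1)
    n = np.zeros(n_months + 1)
    for k in range(1, n_months + 1):
        in_month = (times > k - 1) & (times <= k)
        d[k] = np.sum(status[in_month])
        n[k] = np.sum(times > k - 1)
    return d, n


def beta_uncertainty(d: float, n: float) -> tuple[float, float]:
    """Beta shape pair for a monthly probability from risk-set counts,
    with a Jeffreys 1/2 continuity adjustment: (d + 1/2, n - d + 1/2)."""
    if n < 1:
        raise ValueError("risk set empty")
    return (float(d) + 0.5, float(n - d) + 0.5)


@dataclass(frozen=True)
class ScheduleVariant:
    """Estimation variants of the base case.

    pool_ef_death: estimate Event-free -> Death combining both arms.
    split_pe_death: estimate Event/Post-event -> Death separately per arm
    (the base case pools arms because post-event deaths are few).
    """

    pool_ef_death: bool = False
    split_pe_death: bool = False
    horizon_cycles: int = 36


@dataclass
class TransitionSchedule:
    """Monthly transition probabilities over the horizon.

    Arrays are cycle-indexed from 1 (index 0 unused).  ``p_event`` and
    ``p_death_ef`` are keyed by arm and cover cycles 1..horizon with
    structural zeros beyond cycle 18.  ``p_death_pe`` is keyed by arm
    (identical arrays when pooled) and indexed by tunnel month 1..18
    (months since event onset).  Parallel alpha/beta arrays parameterize
    the per-month beta distributions for probabilistic sensitivity
    analysis; intervention event probabilities have no betas of their own
    — they derive from the control arm's via the hazard-ratio transform.
    """

    horizon_cycles: int
    cycle_length_months: float = 1.0
    cure_cycle: int = CURE_MONTHS
    p_event: dict[str, np.ndarray] = field(default_factory=dict)
    p_death_ef: dict[str, np.ndarray] = field(default_factory=dict)
    p_death_pe: dict[str, np.ndarray] = field(default_factory=dict)
    event_beta: tuple[np.ndarray, np.ndarray] | None = None
    death_ef_beta: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    death_pe_beta: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def validate(self) -> None:
        T = self.horizon_cycles
        for arm in ARMS:
            for name, arr in (("p_event", self.p_event[arm]),
                              ("p_death_ef", self.p_death_ef[arm])):
                if arr.shape[0] != T + 1:
                    raise ValueError(f"{name}[{arm}] does not cover the horizon")
                if np.any((arr < 0) | (arr > 1)):
                    raise ValueError(f"{name}[{arm}] outside [0, 1]")
            if np.any(self.p_event[arm][CURE_MONTHS + 1:] != 0):
                raise ValueError("event probabilities after month 18 must be 0")
            pe = self.p_death_pe[arm]
            if np.any((pe < 0) | (pe > 1)):
                raise ValueError("p_death_pe outside [0, 1]")
            # competing exits from Event-free: death applied first, then
            # events among survivors, so the combined exit never exceeds 1
            exit_p = self.p_death_ef[arm][1:] + (1 - self.p_death_ef[arm][1:]) * self.p_event[arm][1:]
            if np.any(exit_p > 1 + 1e-12):
                raise ValueError("exit probabilities exceed 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in ARMS:
            for k in range(1, self.horizon_cycles + 1):
                a = b = np.nan
                if arm == CONTROL and self.event_beta is not None and k <= CURE_MONTHS:
                    a, b = self.event_beta[0][k], self.event_beta[1][k]
                rows.append((k, arm, "event_free->post_event",
                             self.p_event[arm][k], a, b))
                a = b = np.nan
                if arm in self.death_ef_beta and k <= CURE_MONTHS:
                    a, b = self.death_ef_beta[arm][0][k], self.death_ef_beta[arm][1][k]
                rows.append((k, arm, "event_free->death",
                             self.p_death_ef[arm][k], a, b))
            for j in range(1, CURE_MONTHS + 1):
                a = b = np.nan
                if arm in self.death_pe_beta:
                    a, b = self.death_pe_beta[arm][0][j], self.death_pe_beta[arm][1][j]
                rows.append((j, arm, "post_event->death",
                             self.p_death_pe[arm][j], a, b))
        return pd.DataFrame(rows, columns=["cycle", "arm", "transition",
                                           "probability", "beta_alpha", "beta_beta"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _event_inputs(patients: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Time to first event, censoring deaths and administrative censoring."""
    t = np.where(patients["event"] == 1, patients["t_event"],
                 np.where(patients["death"] == 1, patients["t_death"],
                          patients["t_censor"]))
    return t.astype(float), patients["event"].to_numpy(dtype=int)


def _death_ef_inputs(patients: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Time to event-free death, censoring events."""
    event = patients["event"].to_numpy(dtype=int)
    death = patients["death"].to_numpy(dtype=int)
    t = np.where(event == 1, patients["t_event"],
                 np.where(death == 1, patients["t_death"], patients["t_censor"]))
    status = ((event == 0) & (death == 1)).astype(int)
    return t.astype(float), status


def _death_pe_inputs(patients: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Time from event onset to death among patients with an event."""
    ev = patients[patients["event"] == 1]
    t = np.where(ev["death"] == 1, ev["t_death"], ev["t_censor"]) - ev["t_event"]
    return t.to_numpy(dtype=float), ev["death"].to_numpy(dtype=int)


def _monthly_probs(times, status, n_months: int) -> np.ndarray:
    """Cycle probabilities 1..n_months from a KM fit (0 once the risk set
    is exhausted — no occupants remain to transition)."""
    curve = kaplan_meier(times, status)
    p = np.zeros(n_months + 1)
    for k in range(1, n_months + 1):
        try:
            p[k] = cycle_probability(curve, float(k))
        except ZeroDivisionError:
            p[k] = 0.0
    return p


def _beta_arrays(times, status, n_months: int) -> tuple[np.ndarray, np.ndarray]:
    d, n = monthly_counts(times, status, n_months)
    alpha = np.zeros(n_months + 1)
    beta = np.zeros(n_months + 1)
    for k in range(1, n_months + 1):
        if n[k] >= 1:
            alpha[k], beta[k] = beta_uncertainty(d[k], n[k])
    return alpha, beta


def build_schedule(dataset: TrialDataset, params, variant: ScheduleVariant | None = None
                   ) -> TransitionSchedule:
    """Estimate the full transition schedule from patient-level data.

    Control-arm event probabilities come from the control arm's
    event-free-survival KM curve (deaths censored); the intervention
    arm's are the hazard-ratio transform of the control probabilities
    with ``params.hr``.  Event-free death probabilities are KM-estimated
    per arm (pooled under ``variant.pool_ef_death``); post-event death
    probabilities are measured from event onset and pooled across arms
    (split under ``variant.split_pe_death``).  Cure at 18 months is
    structural and handled by the cohort engine, not the schedule.
    """
    variant = variant or ScheduleVariant()
    patients = dataset.patients
    T = variant.horizon_cycles
    if T < CURE_MONTHS:
        raise ValueError("horizon shorter than the 18-month cure point")
    for arm in ARMS:
        if (patients["arm"] == arm).sum() == 0:
            raise ValueError(f"dataset is missing the {arm} arm")

    sched = TransitionSchedule(horizon_cycles=T)

    ctrl = patients[patients["arm"] == CONTROL]
    t_ev, s_ev = _event_inputs(ctrl)
    if s_ev.sum() == 0:
        warnings.warn("no events in the control arm: the event schedule is "
                      "degenerate (all zeros)", stacklevel=2)
        p_event_c = np.zeros(T + 1)
    else:
        p_event_c = np.zeros(T + 1)
        p_event_c[:CURE_MONTHS + 1] = _monthly_probs(t_ev, s_ev, CURE_MONTHS)
    sched.p_event[CONTROL] = p_event_c
    p_event_i = np.zeros(T + 1)
    for k in range(1, CURE_MONTHS + 1):
        p_event_i[k] = apply_hazard_ratio(p_event_c[k], params.hr)
    sched.p_event[INTERVENTION] = p_event_i
    sched.event_beta = _beta_arrays(t_ev, s_ev, CURE_MONTHS)

    for arm in ARMS:
        src = patients if variant.pool_ef_death else patients[patients["arm"] == arm]
        t_d, s_d = _death_ef_inputs(src)
        p = np.zeros(T + 1)
        p[:CURE_MONTHS + 1] = _monthly_probs(t_d, s_d, CURE_MONTHS)
        sched.p_death_ef[arm] = p
        sched.death_ef_beta[arm] = _beta_arrays(t_d, s_d, CURE_MONTHS)

    for arm in ARMS:
        src = patients[patients["arm"] == arm] if variant.split_pe_death else patients
        t_pe, s_pe = _death_pe_inputs(src)
        p = np.zeros(CURE_MONTHS + 1)
        if len(t_pe) > 0:
            p = _monthly_probs(t_pe, s_pe, CURE_MONTHS)
            alpha, beta = _beta_arrays(t_pe, s_pe, CURE_MONTHS)
        else:
            alpha = np.zeros(CURE_MONTHS + 1)
            beta = np.zeros(CURE_MONTHS + 1)
        sched.p_death_pe[arm] = p
        sched.death_pe_beta[arm] = (alpha, beta)

    sched.validate()
    return sched
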