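"""Discrete-time cohort simulation of the four-state semi-Markov model.

States: Event-free (clock 0..17 months in state), Event/Post-event (a
tunnel indexed by months since event onset, 0..17), Cured, Death.  The
cohort starts entirely event-free.  Within a cycle the Event-free exits
compete with a fixed precedence: death is applied first, then the event
among survivors, so P(event this cycle) = (1 - p_death) * p_event and each
marginal stays at or below its Kaplan-Meier input.  Survivors completing
18 event-free months — or 18 tunnel months — move to Cured with
probability 1.  No background mortality is applied (pediatric cohort).

``microsim_oracle`` replays the identical rules patient-by-patient and is
used in tests to validate the deterministic cohort trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .survival_transitions import TransitionSchedule, CURE_MONTHS


@dataclass
class CohortTrace:
    """State occupancancies at the end of each cycle (row 0 = start).

    ``event_free`` and ``post_event`` have one column per in-state month
    0..17; ``cured`` and ``dead`` are absorbing totals.
    """

    arm: str
    horizon_cycles: int
    event_free: np.ndarray  # (T+1, 18)
    post_event: np.ndarray  # (T+1, 18)
    cured: np.ndarray  # (T+1,)
    dead: np.ndarray  # (T+1,)

    def alive(self, t: int) -> float:
        return float(self.event_free[t].sum() + self.post_event[t].sum()
                     + self.cured[t])

    def total(self, t: int) -> float:
        return self.alive(t) + float(self.dead[t])

    def cured_entrants(self) -> np.ndarray:
        """New arrivals into Cured per cycle (index = entry cycle)."""
        entrants = np.zeros(self.horizon_cycles + 1)
        entrants[1:] = np.diff(self.cured)
        return entrants

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.horizon_cycles + 1):
            for k in range(CURE_MONTHS):
                if self.event_free[t, k] > 0:
                    rows.append((t, "event_free", k, self.event_free[t, k], self.arm))
                if self.post_event[t, k] > 0:
                    rows.append((t, "post_event", k, self.post_event[t, k], self.arm))
            rows.append((t, "cured", -1, self.cured[t], self.arm))
            rows.append((t, "dead", -1, self.dead[t], self.arm))
        return pd.DataFrame(rows, columns=["cycle", "state", "substate_clock",
                                           "occupancy", "arm"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_exits(p_death: float, p_event: float) -> None:
    if p_death + (1 - p_death) * p_event > 1 + 1e-12:
        raise ValueError("exit probabilities sum above 1")


def run_cohort(schedule: TransitionSchedule, arm: str) -> CohortTrace:
    """Propagate cohort occupancy over the horizon for one arm."""
    T = schedule.horizon_cycles
    p_event = schedule.p_event[arm]
    p_death_ef = schedule.p_death_ef[arm]
    p_death_pe = schedule.p_death_pe[arm]

    ef = np.zeros((T + 1, CURE_MONTHS))
    pe = np.zeros((T + 1, CURE_MONTHS))
    cured = np.zeros(T + 1)
    dead = np.zeros(T + 1)
    ef[0, 0] = 1.0

    for t in range(1, T + 1):
        ef_new = np.zeros(CURE_MONTHS)
        pe_new = np.zeros(CURE_MONTHS)
        cured_t = cured[t - 1]
        dead_t = dead[t - 1]

        pd_ef = p_death_ef[t]
        pv = p_event[t]
        _check_exits(pd_ef, pv)
        for k in range(CURE_MONTHS):
            occ = ef[t - 1, k]
            if occ == 0.0:
                continue
            dead_t += occ * pd_ef
            pe_new[0] += occ * (1 - pd_ef) * pv
            surv = occ * (1 - pd_ef) * (1 - pv)
            if k + 1 == CURE_MONTHS:
                cured_t += surv  # cure applied after this cycle's risks
            else:
                ef_new[k + 1] = surv

        for j in range(CURE_MONTHS):
            occ = pe[t - 1, j]
            if occ == 0.0:
                continue
            p = p_death_pe[j + 1]  # tunnel age j faces the (j+1)-th month's risk
            dead_t += occ * p
            surv = occ * (1 - p)
            if j + 1 == CURE_MONTHS:
                cured_t += surv
            else:
                pe_new[j + 1] = surv

        ef[t] = ef_new
        pe[t] = pe_new
        cured[t] = cured_t
        dead[t] = dead_t

    return CohortTrace(arm=arm, horizon_cycles=T, event_free=ef,
                       post_event=pe, cured=cured, dead=dead)


# patient state codes for the microsimulation
_EF, _PE, _CURED, _DEAD = 0, 1, 2, 3


def microsim_oracle(schedule: TransitionSchedule, arm: str, n_patients: int,
                    seed: int) -> CohortTrace:
    """Individual-level replay of the cohort rules (validation oracle).

    Simulates ``n_patients`` monthly trajectories with the identical
    precedence (death before event, cure after the cycle's risks) and
    averages state occupancy.  Intended for tests only: occupancies carry
    binomial Monte Carlo error of order (p(1-p)/n)**0.5.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    T = schedule.horizon_cycles
    p_event = schedule.p_event[arm]
    p_death_ef = schedule.p_death_ef[arm]
    p_death_pe = schedule.p_death_pe[arm]
    rng = np.random.default_rng(seed)

    state = np.full(n_patients, _EF, dtype=np.int8)
    clock = np.zeros(n_patients, dtype=np.int8)

    ef = np.zeros((T + 1, CURE_MONTHS))
    pe = np.zeros((T + 1, CURE_MONTHS))
    cured = np.zeros(T + 1)
    dead = np.zeros(T + 1)
    ef[0, 0] = 1.0

    for t in range(1, T + 1):
        in_ef = state == _EF
        if in_ef.any():
            _check_exits(p_death_ef[t], p_event[t])
            n_ef = int(in_ef.sum())
            dies = rng.uniform(size=n_ef) < p_death_ef[t]
            events = rng.uniform(size=n_ef) < p_event[t]
            idx = np.flatnonzero(in_ef)
            state[idx[dies]] = _DEAD
            ev_idx = idx[~dies & events]
            state[ev_idx] = _PE
            clock[ev_idx] = 0
            surv_idx = idx[~dies & ~events]
            clock[surv_idx] += 1
            cured_idx = surv_idx[clock[surv_idx] == CURE_MONTHS]
            state[cured_idx] = _CURED

        in_pe = (state == _PE) & (clock < CURE_MONTHS)
        # exclude this cycle's fresh entrants: they face risk next cycle
        fresh = np.zeros_like(in_pe)
        if in_ef.any():
            fresh[ev_idx] = True
        at_risk = in_pe & ~fresh
        if at_risk.any():
            idx = np.flatnonzero(at_risk)
            probs = p_death_pe[clock[idx] + 1]
            dies = rng.uniform(size=len(idx)) < probs
            state[idx[dies]] = _DEAD
            surv_idx = idx[~dies]
            clock[surv_idx] += 1
            cured_idx = surv_idx[clock[surv_idx] == CURE_MONTHS]
            state[cured_idx] = _CURED

        for k in range(CURE_MONTHS):
            ef[t, k] = np.mean((state == _EF) & (clock == k))
            pe[t, k] = np.mean((state == _PE) & (clock == k))
        cured[t] = np.mean(state == _CURED)
        dead[t] = np.mean(state == _DEAD)

    return CohortTrace(arm=arm, horizon_cycles=T, event_free=ef,
                       post_event=pe, cured=cured, dead=dead)
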