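"""Synthetic two-arm trial generator.

Produces patient-level data with the statistical structure the downstream
model assumes: a mixture-cure event process in which every first event
occurs within 18 months of diagnosis, proportional hazards between arms on
event-free survival, exponential event-free and post-event death hazards,
administrative censoring, and a cost-observed subgroup with monthly
hospitalization cost records attributed to health states.

The event-time law is a two-point mixture: with probability
``cure_fraction`` the patient never has an event; otherwise the event time
is exponential truncated to (0, 18] months.  The intervention arm is
generated by raising the control arm's all-in event-free survival function
to the power ``hr_event``, so the marginal hazard ratio between arms equals
``hr_event`` exactly and Kaplan-Meier / Cox estimation on large generated
samples recovers it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

CONTROL = "control"
INTERVENTION = "intervention"

#: days-per-month convention used to convert the 7-day pre-event
#: cost-attribution window into months
DAYS_PER_MONTH = 30.4375
PRE_EVENT_WINDOW_MONTHS = 7.0 / DAYS_PER_MONTH

#: months after which event-free (resp. post-event) survivors are cured
CURE_MONTHS = 18


@dataclass(frozen=True)
class CostConfig:
    """Per-state cost generators for the cost-observed subgroup.

    Monthly hospital costs are gamma draws around the configured state
    means; ``monthly_shape`` controls patient-month dispersion
    (CV = shape**-0.5).  Immunoglobulin (IG) use is Bernoulli per patient
    with per-arm rates; the per-user IG cost is gamma with the configured
    shape around the configured mean.  Rituximab totals (intervention arm
    only) are gamma around the per-patient mean cost, converted to mg at
    the unit price.
    """

    monthly_mean_ef_control: float = 3238.0
    monthly_mean_ef_intervention: float = 2864.0
    monthly_mean_pe: float = 5276.0
    monthly_shape: float = 2.0

    ig_rate_control: float = 0.08
    ig_rate_intervention: float = 0.15
    ig_rate_cured: float = 0.03
    ig_mean_control: float = 3924.0
    ig_mean_intervention: float = 2545.0
    ig_mean_cured: float = 15020.0
    ig_shape_control: float = 9.53
    ig_shape_intervention: float = 23.48
    ig_shape_cured: float = 7.21
    ig_price_per_g: float = 40.4

    rituximab_mean_cost: float = 4108.0
    rituximab_shape: float = 7421.9
    rituximab_price_per_mg: float = 1.44


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of the synthetic trial.

    Defaults emulate the study conditions of the source trial: 164
    patients per arm, an EFS hazard ratio of 0.317, a cured majority
    (control 3-year event-free proportion ~0.82), all first events within
    18 months, administrative censoring at 36 months, and a 69-patient
    cost-observed subgroup.
    """

    n_per_arm: int = 164
    hr_event: float = 0.317
    cure_fraction_control: float = 0.82
    event_rate_control: float = 0.15  # per-month hazard among the non-cured
    death_after_event_rate: float = 0.045  # per-month, from event onset
    death_event_free_rate: float = 0.002  # per-month, event-free death
    admin_censor_months: float = 36.0
    cost_subgroup_size: int = 69
    cost_params: CostConfig = field(default_factory=CostConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if self.hr_event <= 0:
            raise ValueError("hr_event must be positive")
        if not 0.0 <= self.cure_fraction_control <= 1.0:
            raise ValueError("cure_fraction_control must be a probability")
        for name in ("event_rate_control", "death_after_event_rate",
                     "death_event_free_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cost_subgroup_size > 2 * self.n_per_arm:
            raise ValueError("cost_subgroup_size exceeds trial size")
        if self.event_rate_control > 0 and self.event_rate_control * CURE_MONTHS < 0.05:
            warnings.warn(
                "event_rate_control is so small that truncation to 18 months "
                "dominates the event-time law", stacklevel=2)


@dataclass
class TrialDataset:
    """Patient table plus long-format cost records.

    ``patients`` columns: id, arm, t_event, event, t_death, death,
    t_censor, in_cost_subgroup, rituximab_mg, ig_grams, ig_cost,
    ig_cured_grams, ig_cured_cost.
    ``costs`` columns: patient_id, month_index, state_label, amount_eur.
    """

    patients: pd.DataFrame
    costs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["patient_id", "month_index", "state_label", "amount_eur"]))

    def arm(self, label: str) -> pd.DataFrame:
        return self.patients[self.patients["arm"] == label]

    def to_csv(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ppath = outdir / "patients.csv"
        cpath = outdir / "cost_records.csv"
        self.patients.to_csv(ppath, index=False)
        self.costs.to_csv(cpath, index=False)
        return ppath, cpath

    @classmethod
    def from_csv(cls, outdir: str | Path) -> "TrialDataset":
        outdir = Path(outdir)
        patients = pd.read_csv(outdir / "patients.csv")
        cpath = outdir / "cost_records.csv"
        costs = pd.read_csv(cpath) if cpath.exists() else pd.DataFrame(
            columns=["patient_id", "month_index", "state_label", "amount_eur"])
        return cls(patients=patients, costs=costs)


def _mixture_cure_event_times(u: np.ndarray, pi: float, rate: float,
                              hr: float) -> np.ndarray:
    """Invert S(t)**hr for the mixture-cure / truncated-exponential law.

    S(t) = pi + (1 - pi) * (exp(-rate t) - E) / (1 - E) on [0, 18],
    E = exp(-18 rate).  Returns +inf for cured draws (u <= pi**hr).
    """
    t = np.full(u.shape, np.inf)
    if pi >= 1.0 or rate == 0.0:
        return t
    cured_mass = pi ** hr
    has_event = u > cured_mass
    v = u[has_event] ** (1.0 / hr)  # value of the control survival function
    w = (v - pi) / (1.0 - pi)  # conditional truncated-exponential survival
    e18 = np.exp(-rate * CURE_MONTHS)
    t[has_event] = -np.log(e18 + w * (1.0 - e18)) / rate
    return t


def generate_trial(config: TrialConfig) -> TrialDataset:
    """Generate the patient table (no cost records yet).

    Deterministic given ``config.seed``.  Event times are drawn from the
    mixture-cure law; the intervention arm shares the control cure/rate
    parameters but its event-free survival is the control curve raised to
    ``hr_event``.  Event-free death competes with the event; post-event
    death is exponential from event onset.  Administrative censoring is
    applied at ``admin_censor_months``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_arm
    c = config.admin_censor_months

    frames = []
    for arm, hr in ((CONTROL, 1.0), (INTERVENTION, config.hr_event)):
        u = rng.uniform(size=n)
        t_event_latent = _mixture_cure_event_times(
            u, config.cure_fraction_control, config.event_rate_control, hr)
        if config.death_event_free_rate > 0:
            t_death_ef = rng.exponential(1.0 / config.death_event_free_rate, size=n)
        else:
            t_death_ef = np.full(n, np.inf)
        if config.death_after_event_rate > 0:
            post_event_gap = rng.exponential(1.0 / config.death_after_event_rate, size=n)
        else:
            post_event_gap = np.full(n, np.inf)

        # competing structure: event-free death pre-empts the event
        event_obs = (t_event_latent < t_death_ef) & (t_event_latent < c)
        t_event = np.where(event_obs, t_event_latent, np.nan)
        t_death_latent = np.where(event_obs, t_event_latent + post_event_gap,
                                  t_death_ef)
        death_obs = t_death_latent < c
        t_death = np.where(death_obs, t_death_latent, np.nan)

        frames.append(pd.DataFrame({
            "arm": arm,
            "t_event": t_event,
            "event": event_obs.astype(int),
            "t_death": t_death,
            "death": death_obs.astype(int),
            "t_censor": c,
        }))

    patients = pd.concat(frames, ignore_index=True)
    patients.insert(0, "id", np.arange(len(patients)))
    subgroup = rng.choice(len(patients), size=config.cost_subgroup_size,
                          replace=False)
    patients["in_cost_subgroup"] = 0
    patients.loc[subgroup, "in_cost_subgroup"] = 1

    cp = config.cost_params
    ritux_cost = np.where(
        patients["arm"] == INTERVENTION,
        rng.gamma(cp.rituximab_shape,
                  cp.rituximab_mean_cost / cp.rituximab_shape,
                  size=len(patients)),
        0.0)
    patients["rituximab_mg"] = ritux_cost / cp.rituximab_price_per_mg
    return TrialDataset(patients=patients)


def _event_free_end(row: pd.Series) -> float:
    """End of the event-free costing window, in months from diagnosis.

    Ends 7 days before the event when one occurs, at death or censoring,
    and never after the 18-month cure point.
    """
    end = float(CURE_MONTHS)
    if row["event"]:
        end = min(end, max(0.0, row["t_event"] - PRE_EVENT_WINDOW_MONTHS))
    if row["death"]:
        end = min(end, row["t_death"])
    return min(end, row["t_censor"])


def generate_cost_records(dataset: TrialDataset, config: TrialConfig) -> TrialDataset:
    """Attach monthly hospital cost records and one-time drug amounts.

    For every cost-subgroup patient, a gamma cost is drawn for each whole
    month inside the event-free window (diagnosis to 7 days before the
    event, capped at 18 months) and, for event patients, for each month of
    the post-event window (event onset to 18 months later, censored by
    death / follow-up end).  Records carry the state label used by the
    costing stage to re-derive per-state monthly means.  Immunoglobulin
    use is drawn per patient at the per-arm (and post-cure) rates.
    """
    cp = config.cost_params
    patients = dataset.patients.copy()
    sub = patients[patients["in_cost_subgroup"] == 1]
    if len(sub) == 0:
        raise ValueError("cost subgroup is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    records: list[tuple[int, int, str, float]] = []
    for _, row in sub.iterrows():
        mean_ef = (cp.monthly_mean_ef_control if row["arm"] == CONTROL
                   else cp.monthly_mean_ef_intervention)
        ef_end = _event_free_end(row)
        for m in range(int(np.ceil(ef_end))):
            if m < ef_end:
                amount = rng.gamma(cp.monthly_shape, mean_ef / cp.monthly_shape)
                records.append((int(row["id"]), m, "event_free", amount))
        if row["event"]:
            start = int(np.floor(row["t_event"]))
            pe_end = row["t_event"] + CURE_MONTHS
            if row["death"]:
                pe_end = min(pe_end, row["t_death"])
            pe_end = min(pe_end, row["t_censor"])
            for j in range(CURE_MONTHS):
                m = start + j
                if row["t_event"] + j < pe_end:
                    amount = rng.gamma(cp.monthly_shape, cp.monthly_mean_pe / cp.monthly_shape)
                    records.append((int(row["id"]), m, "post_event", amount))

    costs = pd.DataFrame(records, columns=["patient_id", "month_index",
                                           "state_label", "amount_eur"])

    # one-time immunoglobulin amounts, all patients
    n = len(patients)
    is_int = (patients["arm"] == INTERVENTION).to_numpy()
    rate = np.where(is_int, cp.ig_rate_intervention, cp.ig_rate_control)
    uses_ig = rng.uniform(size=n) < rate
    ig_cost = np.where(
        uses_ig,
        np.where(is_int,
                 rng.gamma(cp.ig_shape_intervention,
                           cp.ig_mean_intervention / cp.ig_shape_intervention, n),
                 rng.gamma(cp.ig_shape_control,
                           cp.ig_mean_control / cp.ig_shape_control, n)),
        0.0)
    patients["ig_cost"] = ig_cost
    patients["ig_grams"] = ig_cost / cp.ig_price_per_g

    # post-cure IG among patients who reach the cured state
    ef_cured = (patients["event"] == 0) & (
        patients["t_death"].fillna(np.inf) > CURE_MONTHS)
    pe_cured = (patients["event"] == 1) & (
        patients["t_death"].fillna(np.inf) > patients["t_event"] + CURE_MONTHS)
    cured = (ef_cured | pe_cured).to_numpy()
    uses_cured_ig = cured & (rng.uniform(size=n) < cp.ig_rate_cured)
    ig_cured_cost = np.where(
        uses_cured_ig,
        rng.gamma(cp.ig_shape_cured, cp.ig_mean_cured / cp.ig_shape_cured, n),
        0.0)
    patients["ig_cured_cost"] = ig_cured_cost
    patients["ig_cured_grams"] = ig_cured_cost / cp.ig_price_per_g

    return TrialDataset(patients=patients, costs=costs)


def config_to_dict(config: TrialConfig) -> dict:
    return asdict(config)
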