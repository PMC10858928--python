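"""Sensitivity-analysis tests: sampling distributions, PSA, tornado."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pednhl_cea import (
    DistributionSpec,
    ModelParams,
    run_psa,
    sample_params,
    sample_schedule,
    tornado,
    deterministic_result,
)
from pednhl_cea.survival_transitions import CURE_MONTHS
from pednhl_cea.synthetic_trial import CONTROL, INTERVENTION
from pednhl_cea.uncertainty import beta_from_moments, default_specs, fixed_specs


class TestDistributionSpec:
    def test_hr_lognormal_median(self, params):
        spec = DistributionSpec("log-normal", params.hr_lognormal)
        rng = np.random.default_rng(0)
        draws = np.array([spec.sample(rng, params.hr) for _ in range(100_000)])
        assert np.median(draws) == pytest.approx(np.exp(-1.14938), rel=0.01)
        assert np.median(draws) == pytest.approx(0.317, rel=0.01)

    def test_gamma_cost_mean(self, params):
        spec = DistributionSpec("gamma", params.gamma_ef_control)
        rng = np.random.default_rng(1)
        draws = np.array([spec.sample(rng, 0.0) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(198.06 / 0.06116, rel=0.01)

    def test_fixed_returns_base(self):
        assert DistributionSpec("fixed").sample(np.random.default_rng(0), 3.5) == 3.5

    @pytest.mark.parametrize("family,p", [
        ("gamma", (-1.0, 2.0)), ("beta", (0.0, 1.0)), ("log-normal", (0.0, 0.0)),
        ("cauchy", (0.0, 1.0)),
    ])
    def test_invalid_specs_rejected(self, family, p):
        with pytest.raises(ValueError):
            DistributionSpec(family, p)


class TestBetaMomentMatching:
    def test_mean_and_se_recovered(self):
        a, b = beta_from_moments(0.8, 0.16)
        assert a / (a + b) == pytest.approx(0.8)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert np.sqrt(var) == pytest.approx(0.16)

    def test_cured_utility_is_feasible_but_heavily_skewed(self):
        # mean 0.9 with SE 0.18 -> alpha ~ 1.6, beta ~ 0.18
        a, b = beta_from_moments(0.9, 0.18)
        assert a == pytest.approx(1.6, rel=1e-6)
        assert b < 0.2

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_moments(0.5, 0.6)


class TestSampleParams:
    def test_fixed_specs_return_base_exactly(self, params):
        rng = np.random.default_rng(0)
        assert sample_params(params, fixed_specs(), rng) == params

    def test_utility_draws_stay_in_unit_interval(self, params):
        rng = np.random.default_rng(2)
        specs = default_specs(params)
        for _ in range(200):
            drawn = sample_params(params, specs, rng)
            for u in (drawn.u_event_free, drawn.u_post_event, drawn.u_cured):
                assert 0.0 <= u <= 1.0

    def test_ig_onetime_resampled_as_rate_times_peruser_cost(self, params):
        rng = np.random.default_rng(3)
        specs = default_specs(params)
        draws = [sample_params(params, specs, rng).ig_onetime_ef_control
                 for _ in range(4000)]
        # expectation = rate x per-user gamma mean
        assert np.mean(draws) == pytest.approx(
            params.ig_rate_control * 3924.0, rel=0.05)


class TestSampleSchedule:
    def test_intervention_events_follow_sampled_hr(self, schedule):
        rng = np.random.default_rng(4)
        drawn = sample_schedule(schedule, hr=0.5, rng=rng)
        for k in range(1, CURE_MONTHS + 1):
            p_c = drawn.p_event[CONTROL][k]
            assert drawn.p_event[INTERVENTION][k] == pytest.approx(
                1 - (1 - p_c) ** 0.5)

    def test_pooled_tunnel_draw_is_shared(self, schedule):
        rng = np.random.default_rng(5)
        drawn = sample_schedule(schedule, hr=0.3, rng=rng)
        np.testing.assert_array_equal(drawn.p_death_pe[CONTROL],
                                      drawn.p_death_pe[INTERVENTION])

    def test_sampled_mean_tracks_beta_mean(self, schedule):
        rng = np.random.default_rng(6)
        a, b = schedule.event_beta
        k = int(np.argmax(a[1:]) + 1)  # month with most events
        draws = [sample_schedule(schedule, 0.317, rng).p_event[CONTROL][k]
                 for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(a[k] / (a[k] + b[k]), rel=0.05)


class TestRunPSA:
    def test_single_sim_with_fixed_specs_equals_base_case(self, schedule, params):
        psa = run_psa(schedule, params, n_sims=1, seed=0, specs=fixed_specs())
        _, _, base = deterministic_result(schedule, params)
        assert psa.summary["delta_e_mean"] == pytest.approx(base.delta_e)
        assert psa.summary["delta_c_mean"] == pytest.approx(base.delta_c)
        assert psa.summary["inmb_mean"] == pytest.approx(base.inmb)

    def test_same_seed_identical_draws(self, schedule, params):
        a = run_psa(schedule, params, n_sims=50, seed=11)
        b = run_psa(schedule, params, n_sims=50, seed=11)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.ceac, b.ceac)

    def test_ceac_definition_and_monotonicity(self, schedule, params):
        psa = run_psa(schedule, params, n_sims=200, seed=12)
        de = psa.draws["delta_ly"].to_numpy()
        dc = psa.draws["delta_c"].to_numpy()
        for _, row in psa.ceac.iloc[::20].iterrows():
            expected = np.mean(row["lambda_"] * de - dc > 0)
            assert row["probability"] == pytest.approx(expected)
        if de.min() >= 0:
            assert (np.diff(psa.ceac["probability"]) >= -1e-12).all()

    def test_dominant_in_every_draw_gives_ceac_one(self, schedule, params):
        psa = run_psa(schedule, params, n_sims=100, seed=13)
        mask = (psa.draws["delta_ly"] > 0) & (psa.draws["delta_c"] < 0)
        sub = psa.draws[mask]
        de, dc = sub["delta_ly"].to_numpy(), sub["delta_c"].to_numpy()
        for lam in (0.0, 50_000.0):
            assert np.all(lam * de - dc > 0)

    def test_fixed_specs_reproduce_base_in_every_draw(self, schedule, params):
        psa = run_psa(schedule, params, n_sims=20, seed=14, specs=fixed_specs())
        _, _, base = deterministic_result(schedule, params)
        np.testing.assert_allclose(psa.draws["inmb"], base.inmb)

    def test_inmb_ci_narrows_as_cost_precision_grows(self, schedule, params):
        """Scaling every gamma's (shape, rate) by a common factor keeps
        the means but shrinks the SEs, so the INMB percentile CI narrows."""
        scale = 16.0
        precise = default_specs(params)
        for key, spec in list(precise.items()):
            if spec.family == "gamma":
                precise[key] = DistributionSpec(
                    "gamma", (spec.params[0] * scale, spec.params[1] * scale))
        wide = run_psa(schedule, params, n_sims=300, seed=16)
        narrow = run_psa(schedule, params, n_sims=300, seed=16, specs=precise)
        width = lambda s: s.summary["inmb_ci"][1] - s.summary["inmb_ci"][0]
        assert width(narrow) < width(wide)

    def test_qaly_effect_changes_inmb_scale(self, schedule, params):
        psa = run_psa(schedule, params, n_sims=30, seed=15, effect="qaly")
        de = psa.draws["delta_qaly"].to_numpy()
        dc = psa.draws["delta_c"].to_numpy()
        np.testing.assert_allclose(psa.draws["inmb"],
                                   params.wtp_reference * de - dc)


class TestTornado:
    def test_base_inmb_between_endpoints_for_monotone_params(self, schedule, params):
        table = tornado(schedule, params)
        base = table["inmb_base"].iloc[0]
        for _, row in table.iterrows():
            lo, hi = sorted([row["inmb_low"], row["inmb_high"]])
            assert lo - 1e-6 <= base <= hi + 1e-6

    def test_hr_entry_direction(self, schedule, params):
        table = tornado(schedule, params).set_index("parameter")
        row = table.loc["hr"]
        # hr low bound (0.148) -> fewer events -> higher INMB
        assert row["inmb_low"] > row["inmb_high"]

    def test_sorted_by_bar_width(self, schedule, params):
        table = tornado(schedule, params)
        assert (table["bar_width"].diff().dropna() <= 1e-9).all()

    def test_discount_direction_when_dominant(self, schedule, params):
        """INMB decreases with the discount rate when the undiscounted
        incremental effect is positive and incremental cost negative."""
        _, _, base = deterministic_result(
            schedule, dataclasses.replace(params, discount_annual=0.0))
        table = tornado(schedule, params).set_index("parameter")
        row = table.loc["discount_annual"]
        if base.delta_e > 0 and base.delta_c < 0:
            assert row["inmb_low"] > row["inmb_high"]

    def test_qaly_variant_adds_utility_entries(self, schedule, params):
        table = tornado(schedule, params, effect="qaly")
        assert {"u_event_free", "u_post_event", "u_cured"} <= set(table["parameter"])

    def test_degenerate_range_gives_zero_width(self, schedule, params):
        p = dataclasses.replace(params, dsa_ranges={
            "monthly_cost_pe": (params.monthly_cost_pe, params.monthly_cost_pe)})
        table = tornado(schedule, p)
        assert table["bar_width"].iloc[0] == pytest.approx(0.0, abs=1e-9)
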