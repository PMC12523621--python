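"""Expected costs, win-win price bounds, and sensitivity sweeps."""

import numpy as np
import pytest

from followup_pricing import (
    BaselineHazard,
    ConfigurationError,
    Policy,
    cumulative_hazard,
    expected_costs,
    identity_profile,
    price_bounds,
    sweep,
)

from conftest import make_spec

POLICIES = [Policy.I, Policy.II, Policy.III]


@pytest.fixture(scope="module")
def near_zero_baseline():
    # negligible hazard over the horizon: Lambda0(36) ~ 1e-21
    return BaselineHazard("weibull", {"shape": 2.0, "scale": 1e12})


class TestExpectedCosts:
    def test_degenerate_hazard_leaves_fixed_terms(self, near_zero_baseline, gamma_stratum):
        spec = make_spec(Policy.I)
        costs = expected_costs(spec, gamma_stratum, near_zero_baseline, P_k=500.0)
        assert costs[("patient", False)].expected_cost == pytest.approx(0.0, abs=1e-6)
        assert costs[("hospital", True)].expected_cost == pytest.approx(
            spec.n1 * spec.cf - 500.0, abs=1e-6
        )

    def test_no_followup_patient_cost(self, weibull_months, gamma_stratum):
        spec = make_spec(Policy.NONE)
        costs = expected_costs(spec, gamma_stratum, weibull_months, P_k=0.0)
        none = identity_profile(weibull_months, spec.L)
        expected = (
            gamma_stratum.treatment_cost
            * gamma_stratum.phi
            * cumulative_hazard(none, spec.W, spec.L)
        )
        assert costs[("patient", False)].expected_cost == pytest.approx(expected)

    def test_linear_in_treatment_cost(self, weibull_months, gamma_stratum):
        from dataclasses import replace

        spec = make_spec(Policy.NONE)
        c1 = expected_costs(spec, gamma_stratum, weibull_months, 0.0)
        doubled = replace(gamma_stratum, treatment_cost=2 * gamma_stratum.treatment_cost)
        c2 = expected_costs(spec, doubled, weibull_months, 0.0)
        assert c2[("patient", False)].expected_cost == pytest.approx(
            2 * c1[("patient", False)].expected_cost
        )

    def test_components_sum_to_expected_cost(self, weibull_months, gamma_stratum):
        spec = make_spec(Policy.III)
        for summary in expected_costs(spec, gamma_stratum, weibull_months, 321.0).values():
            assert summary.expected_cost == pytest.approx(
                summary.treatment + summary.checkup + summary.price_transfer
            )


class TestPriceBounds:
    def test_policy_two_hospital_minimum_is_checkup_bill(self, weibull_months, gamma_stratum):
        """P_h for policy II is n2*cf: the warranty-window hazard is untouched."""
        spec = make_spec(Policy.II, tau=3.0)
        iv = price_bounds(spec, gamma_stratum, weibull_months)
        assert iv.P_h == pytest.approx(8 * 428.0, abs=1e-9)

    @pytest.mark.parametrize("policy", POLICIES)
    def test_theta_one_kills_patient_value(self, weibull_months, gamma_stratum, policy):
        iv = price_bounds(make_spec(policy, theta=1.0), gamma_stratum, weibull_months)
        assert iv.P_p == pytest.approx(0.0, abs=1e-9)
        assert not iv.exists

    @pytest.mark.parametrize("policy", POLICIES)
    def test_patient_bound_linear_in_treatment_cost(
        self, weibull_months, gamma_stratum, policy
    ):
        from dataclasses import replace

        spec = make_spec(policy)
        iv1 = price_bounds(spec, gamma_stratum, weibull_months)
        doubled = replace(gamma_stratum, treatment_cost=2 * gamma_stratum.treatment_cost)
        iv2 = price_bounds(spec, doubled, weibull_months)
        assert iv2.P_p == pytest.approx(2 * iv1.P_p, rel=1e-12)

    @pytest.mark.parametrize("policy", POLICIES)
    def test_bounds_consistent_with_cost_functions(
        self, weibull_months, gamma_stratum, policy
    ):
        """At P = P_p the patient is indifferent; at raw P_h the hospital is."""
        spec = make_spec(policy, theta=0.2)
        iv = price_bounds(spec, gamma_stratum, weibull_months)
        at_pp = expected_costs(spec, gamma_stratum, weibull_months, iv.P_p)
        assert at_pp[("patient", True)].expected_cost == pytest.approx(
            at_pp[("patient", False)].expected_cost, abs=1e-8
        )
        at_ph = expected_costs(spec, gamma_stratum, weibull_months, iv.P_h_raw)
        assert at_ph[("hospital", True)].expected_cost == pytest.approx(
            at_ph[("hospital", False)].expected_cost, abs=1e-8
        )

    def test_hospital_bound_clamped_at_zero(self, weibull_months, gamma_stratum):
        # effective checkups + expensive AOs can push the raw bound negative
        spec = make_spec(Policy.I, theta=0.0, cf=1.0)
        iv = price_bounds(spec, gamma_stratum, weibull_months)
        assert iv.P_h == 0.0
        assert iv.P_h_raw < 0.0

    def test_none_policy_has_empty_interval(self, weibull_months, gamma_stratum):
        iv = price_bounds(make_spec(Policy.NONE), gamma_stratum, weibull_months)
        assert (iv.P_h, iv.P_p, iv.exists) == (0.0, 0.0, False)

    def test_reset_integral_bounded(self, weibull_months, gamma_stratum):
        """Full resets at vanishing intervals pin the post-warranty hazard near
        the reset age, bounding the subtracted integral by lambda0(L-W)*(L-W)."""
        spec = make_spec(Policy.I, tau=0.05, theta=0.0)
        from followup_pricing import build_profile

        profile = build_profile(spec, weibull_months)
        sub = cumulative_hazard(profile, spec.W, spec.L)
        cap = float(weibull_months.rate(spec.L - spec.W)) * (spec.L - spec.W)
        assert 0.0 <= sub <= cap


class TestStructuralIdentities:
    def test_ph2_invariant_to_theta_and_ckr(self, weibull_months, gamma_stratum):
        from dataclasses import replace

        for theta in np.linspace(0.0, 1.0, 5):
            for factor in np.linspace(0.5, 2.0, 5):
                spec = make_spec(Policy.II, theta=theta)
                stratum = replace(
                    gamma_stratum,
                    treatment_cost=gamma_stratum.treatment_cost * factor,
                )
                iv = price_bounds(spec, stratum, weibull_months)
                assert iv.P_h == pytest.approx(spec.n2 * spec.cf, abs=1e-9)

    @pytest.mark.parametrize("policy", POLICIES)
    def test_pp_invariant_to_cf_and_ph_monotone_in_cf(
        self, weibull_months, gamma_stratum, policy
    ):
        cfs = [200.0, 428.0, 600.0, 900.0]
        ivs = [
            price_bounds(make_spec(policy, cf=cf), gamma_stratum, weibull_months)
            for cf in cfs
        ]
        pps = [iv.P_p for iv in ivs]
        assert all(p == pytest.approx(pps[0], rel=1e-12) for p in pps)
        phs = [iv.P_h for iv in ivs]
        assert all(b >= a - 1e-12 for a, b in zip(phs, phs[1:]))

    @pytest.mark.parametrize("policy", POLICIES)
    def test_width_nondecreasing_in_ckr(self, weibull_months, gamma_stratum, policy):
        from dataclasses import replace

        spec = make_spec(policy, theta=0.2)
        widths = []
        for factor in [0.5, 0.75, 1.0, 1.5, 2.0]:
            stratum = replace(
                gamma_stratum, treatment_cost=gamma_stratum.treatment_cost * factor
            )
            iv = price_bounds(spec, stratum, weibull_months)
            widths.append(max(0.0, iv.P_p - iv.P_h_raw))
        assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))


class TestSweep:
    def test_cf_grid_reproduces_policy_two_minimum(self, case_config):
        """Hospital minimum under policy II tracks the checkup bill exactly."""
        spec = case_config.policy_spec(Policy.II)
        grid = [428.0 * (1 + p / 100) for p in (-30, -20, -10, 0, 10, 20, 30)]
        df = sweep(spec, case_config.strata, case_config.baseline, "cf", grid)
        got = df[(df.policy == "II") & (df.stratum == 2)]["P_h"].tolist()
        assert got == pytest.approx(
            [2396.80, 2739.20, 3081.60, 3424.0, 3766.40, 4108.80, 4451.20], abs=1e-9
        )

    def test_horizon_grid_reproduces_policy_two_minimum(self, case_config):
        spec = case_config.policy_spec(Policy.II)
        df = sweep(
            spec, case_config.strata, case_config.baseline, "L", [24.0, 36.0, 48.0, 60.0]
        )
        got = df[(df.policy == "II") & (df.stratum == 1)]["P_h"].tolist()
        assert got == pytest.approx([1712.0, 3424.0, 5136.0, 6848.0], abs=1e-9)

    def test_ckr_sweep_leaves_policy_two_minimum_constant(self, case_config):
        spec = case_config.policy_spec(Policy.II)
        df = sweep(
            spec,
            case_config.strata,
            case_config.baseline,
            "ckr",
            [0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3],
        )
        assert df[df.policy == "II"]["P_h"].tolist() == pytest.approx(
            [3424.0] * 21, abs=1e-9
        )

    def test_tau_beyond_window_gives_zero_checkups(self, case_config):
        spec = case_config.policy_spec(Policy.II)
        df = sweep(spec, case_config.strata, case_config.baseline, "tau", [25.0])
        rows = df[df.policy == "II"]
        assert (rows["P_h"] == 0.0).all()

    def test_invalid_grid_value_recorded_not_fatal(self, case_config):
        spec = case_config.policy_spec(Policy.I)
        df = sweep(spec, case_config.strata, case_config.baseline, "theta", [0.2, 1.7])
        bad = df[df.value == 1.7]
        assert (bad["error"] != "").all()
        good = df[df.value == 0.2]
        assert (good["error"] == "").all()

    def test_unknown_parameter_rejected(self, case_config):
        spec = case_config.policy_spec(Policy.I)
        with pytest.raises(ConfigurationError):
            sweep(spec, case_config.strata, case_config.baseline, "W", [6.0])
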