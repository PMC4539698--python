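"""One-way DSA mechanics and PSA sampling/propagation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from copdce import engine, sensitivity
from copdce.economics import incremental_analysis
from copdce.sensitivity import (
    ParameterDistribution,
    ScenarioOverride,
    apply_scenario,
    default_psa_distributions,
    lognormal_sigma_from_ci,
    run_one_way_dsa,
    run_psa,
    sample_psa_parameters,
    standard_scenarios,
)


class TestOneWayDSA:
    def test_empty_patch_reproduces_base_case_exactly(
        self, calibrated_params, calibrated_schedule
    ):
        res = {
            arm: engine.run_cohort(arm, calibrated_params, calibrated_schedule)
            for arm in ("UC", "TIO")
        }
        base_icer = incremental_analysis(res["UC"], res["TIO"]).icer
        df = run_one_way_dsa(
            calibrated_params,
            [ScenarioOverride("base_case")],
            comparisons=[("UC", "TIO")],
        )
        assert df.loc[0, "icer"] == base_icer

    def test_invalid_patch_fails_alone(self, calibrated_params):
        scenarios = [
            ScenarioOverride("broken", {"settings.discount_rate_annual": -2.0}),
            ScenarioOverride("discount_0", {"settings.discount_rate_annual": 0.0}),
        ]
        df = run_one_way_dsa(calibrated_params, scenarios, comparisons=[("UC", "TIO")])
        assert df.loc[df.scenario == "broken", "error"].notna().all()
        assert df.loc[df.scenario == "discount_0", "error"].isna().all()
        assert np.isfinite(df.loc[df.scenario == "discount_0", "icer"].astype(float)).all()

    def test_unknown_patch_path_rejected(self, calibrated_params):
        with pytest.raises(KeyError):
            apply_scenario(
                calibrated_params, ScenarioOverride("typo", {"settings.discuont": 0})
            )

    def test_rr_scenario_rederives_comparator_table(self, calibrated_params):
        sc = ScenarioOverride(
            "rr_low",
            {"relative_risk_severe_gly_vs_tio.point": 1.05},
            rederive_gly_events=True,
        )
        p = apply_scenario(calibrated_params, sc)
        tio_sev = calibrated_params.exacerbations["TIO"].probabilities[:, 2]
        np.testing.assert_allclose(
            p.exacerbations["GLY"].probabilities[:, 2], tio_sev * 1.05
        )

    def test_standard_set_runs_clean(self, calibrated_params):
        df = run_one_way_dsa(calibrated_params, standard_scenarios(calibrated_params))
        assert df.error.isna().all()
        assert len(df) == 25 * 2
        # direction checks: a higher severe-exacerbation cost must improve
        # (lower) the comparator-side ICER, and vice versa
        gly = df[df.comparison == "TIO vs GLY"].set_index("scenario").icer
        base = gly["base_case"]
        assert gly["sevex_cost_+20pct"] < base < gly["sevex_cost_-20pct"]


class TestPSASampling:
    def test_lognormal_sigma_closed_form(self):
        sigma = lognormal_sigma_from_ci(1.05, 1.97)
        assert sigma == pytest.approx(
            (math.log(1.97) - math.log(1.05)) / 3.919928, rel=1e-5
        )
        assert sigma == pytest.approx(0.16055, abs=5e-5)

    def test_lognormal_median_at_point_estimate(self, base_params):
        dists = [
            ParameterDistribution(
                "rr_severe_gly_vs_tio", "lognormal-from-CI",
                point=1.43, ci_low=1.05, ci_high=1.97,
            )
        ]
        draws = [
            sample_psa_parameters(base_params, dists, 11, i)
            .exacerbations["GLY"].probabilities[2, 2]
            for i in range(400)
        ]
        tio_sev = base_params.exacerbations["TIO"].probabilities[2, 2]
        med_rr = np.median(draws) / tio_sev
        assert med_rr == pytest.approx(1.43, rel=0.03)

    def test_uniform_draws_stay_in_band(self, base_params):
        dists = [
            ParameterDistribution("costs", "uniform-pm-fraction", fraction=0.2),
            ParameterDistribution("utilities", "uniform-pm-fraction", fraction=0.2),
        ]
        base_c = base_params.costs.direct_cost
        base_u = base_params.utilities.annual_weight
        for i in range(50):
            p = sample_psa_parameters(base_params, dists, 3, i)
            assert np.all(p.costs.direct_cost >= base_c * 0.8 - 1e-9)
            assert np.all(p.costs.direct_cost <= base_c * 1.2 + 1e-9)
            assert np.all(p.utilities.annual_weight <= 1.0)
            assert np.all(p.utilities.annual_weight >= base_u * 0.8 - 1e-9)

    def test_zero_fraction_degenerates_to_point(self, base_params):
        dists = [ParameterDistribution("costs", "uniform-pm-fraction", fraction=0.0)]
        p = sample_psa_parameters(base_params, dists, 5, 17)
        np.testing.assert_array_equal(p.costs.direct_cost, base_params.costs.direct_cost)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ParameterDistribution("costs", "beta", fraction=0.2)


@pytest.fixture(scope="module")
def small_psa(calibrated_params, calibrated_schedule):
    return run_psa(
        calibrated_params, n_iterations=400, seed=123, schedule=calibrated_schedule
    )


class TestPSARun:

    def test_seed_reproducibility_bitwise(self, calibrated_params, calibrated_schedule):
        a = run_psa(calibrated_params, n_iterations=50, seed=9,
                    schedule=calibrated_schedule)
        b = run_psa(calibrated_params, n_iterations=50, seed=9,
                    schedule=calibrated_schedule)
        assert (a.ce_points == b.ce_points).all().all()
        np.testing.assert_array_equal(
            a.ceac.prob_cost_effective, b.ceac.prob_cost_effective
        )

    def test_ceac_at_zero_wtp_is_cost_saving_fraction(self, small_psa):
        frac_saving = (small_psa.ce_points.delta_cost < 0).mean()
        assert small_psa.probability_cost_effective(0.0) == pytest.approx(frac_saving)

    def test_ceac_limit_is_qaly_gain_fraction(self, small_psa):
        frac_gain = (small_psa.ce_points.delta_qalys > 0).mean()
        assert small_psa.probability_cost_effective(1e12) == pytest.approx(frac_gain)

    def test_ceac_monotone_for_effect_dominant_comparison(self, small_psa):
        """When nearly all iterations gain QALYs, the acceptability curve is
        non-decreasing in willingness-to-pay (asserted, not assumed)."""
        assert (small_psa.ce_points.delta_qalys > 0).mean() > 0.9
        probs = small_psa.ceac.prob_cost_effective
        assert np.all(np.diff(probs) >= -1e-12)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_batch_matches_scalar_engine(self, calibrated_params, calibrated_schedule):
        """The vectorised PSA propagation must agree with per-iteration runs
        of the scalar engine on the reconstructed parameter draws."""
        seed, n = 42, 5
        res = run_psa(
            calibrated_params, n_iterations=n, seed=seed,
            schedule=calibrated_schedule,
        )
        dists = default_psa_distributions(calibrated_params)
        for i in range(n):
            p_i = sample_psa_parameters(calibrated_params, dists, seed, i)
            runs = {
                arm: engine.run_cohort(arm, p_i, calibrated_schedule)
                for arm in ("GLY", "TIO")
            }
            dc = runs["TIO"].total_cost - runs["GLY"].total_cost
            dq = runs["TIO"].qalys - runs["GLY"].qalys
            assert res.ce_points.delta_cost[i] == pytest.approx(dc, abs=1e-6)
            assert res.ce_points.delta_qalys[i] == pytest.approx(dq, abs=1e-10)

    def test_symmetric_distributions_centre_on_base_case(
        self, calibrated_params, calibrated_schedule
    ):
        """With only the symmetric uniform cost/utility distributions (no
        skewed RR), the PSA mean deltas converge on the deterministic base
        case within Monte Carlo error."""
        dists = [
            ParameterDistribution("costs", "uniform-pm-fraction", fraction=0.2),
            ParameterDistribution("utilities", "uniform-pm-fraction", fraction=0.2),
        ]
        res = run_psa(
            calibrated_params, distributions=dists, n_iterations=600, seed=7,
            schedule=calibrated_schedule,
        )
        runs = {
            arm: engine.run_cohort(arm, calibrated_params, calibrated_schedule)
            for arm in ("GLY", "TIO")
        }
        inc = incremental_analysis(runs["GLY"], runs["TIO"])
        dc_se = res.ce_points.delta_cost.std() / math.sqrt(len(res.ce_points))
        assert res.ce_points.delta_cost.mean() == pytest.approx(
            inc.delta_cost, abs=4 * dc_se
        )
        dq_se = res.ce_points.delta_qalys.std() / math.sqrt(len(res.ce_points))
        assert res.ce_points.delta_qalys.mean() == pytest.approx(
            inc.delta_qalys, abs=max(4 * dq_se, 1e-6)
        )
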