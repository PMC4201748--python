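"""Deterministic scenarios, triangular sampling, and the probabilistic SA."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from adcea import (
    PSADistributions,
    ScenarioSpec,
    apply_scenario,
    build_paper_scenarios,
    ceac,
    compare,
    evaluate_arm,
    run_dsa,
    run_psa,
    sample_triangular,
)

# The published scenario cells were computed from unrounded base values and
# printed at 4 decimals, while the bundled base values are themselves the
# 4-decimal printed ones: a cell scaled by m can differ from m x (rounded
# base) by up to (m + 1) x 5e-5.
PROB_TOL = 3 * 5e-5 + 1e-9
EUR_TOL = 1.0  # published scenario costs are printed to the euro


def _scenario(scenarios, sid):
    return next(s for s in scenarios if s.id == sid)


@pytest.fixture(scope="module")
def scenarios():
    return build_paper_scenarios()


@pytest.fixture(scope="module")
def dsa(base_spec):
    return run_dsa(base_spec)


@pytest.fixture(scope="module")
def psa_small(base_spec):
    return run_psa(base_spec, n=1_000, seed=17)


class TestScenarioTableRoundTrip:
    """Applying the scenario set reproduces every published scenario cell."""

    def test_eighteen_unique_scenarios(self, scenarios):
        assert len(scenarios) == 18
        assert len({s.id for s in scenarios}) == 18
        assert scenarios[0].target == "base"

    @pytest.mark.parametrize(
        "sid,field,expected",
        [
            (2, "community_direct_other", 10_900),
            (3, "community_direct_other", 16_350),
            (4, "community_indirect", 4_106),
            (5, "community_indirect", 6_159),
            (6, "institution_direct_other", 23_074),
            (7, "institution_direct_other", 34_611),
        ],
    )
    def test_cost_scenarios(self, base_spec, scenarios, sid, field, expected):
        spec = apply_scenario(base_spec, _scenario(scenarios, sid))
        assert getattr(spec.costs, field) == pytest.approx(expected, abs=EUR_TOL)

    @pytest.mark.parametrize(
        "sid,field,expected",
        [
            (8, "u_community", 0.48),
            (9, "u_community", 0.72),
            (10, "u_institution", 0.27),
            (11, "u_institution", 0.41),
        ],
    )
    def test_utility_scenarios(self, base_spec, scenarios, sid, field, expected):
        spec = apply_scenario(base_spec, _scenario(scenarios, sid))
        assert getattr(spec.utilities, field) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "sid,ref_series,alt_series",
        [
            # 50 % / 200 % of both arms
            (12, (0.0084, 0.0516, 0.0474, 0.0404, 0.0446, 0, 0),
                 (0, 0, 0, 0.0084, 0.0209, 0, 0)),
            (13, (0.0334, 0.2062, 0.1894, 0.1616, 0.1782, 0, 0),
                 (0, 0, 0, 0.0334, 0.0836, 0, 0)),
            # worst case: reference halved, alternative doubled
            (14, (0.0084, 0.0516, 0.0474, 0.0404, 0.0446, 0, 0),
                 (0, 0, 0, 0.0334, 0.0836, 0, 0)),
            # best case: reference doubled, alternative halved
            (15, (0.0334, 0.2062, 0.1894, 0.1616, 0.1782, 0, 0),
                 (0, 0, 0, 0.0084, 0.0209, 0, 0)),
            # constant-hazard smoothed
            (16, (0.0559,) * 7, (0.0085,) * 7),
        ],
    )
    def test_institutionalisation_scenarios(
        self, base_spec, scenarios, sid, ref_series, alt_series
    ):
        spec = apply_scenario(base_spec, _scenario(scenarios, sid))
        assert spec.strategies[0].p_institutionalisation == pytest.approx(
            ref_series, abs=PROB_TOL
        )
        assert spec.strategies[1].p_institutionalisation == pytest.approx(
            alt_series, abs=PROB_TOL
        )

    @pytest.mark.parametrize(
        "sid,series",
        [
            (17, (0.0150, 0.0167, 0.0187, 0.0210, 0.0238, 0.0269, 0.0306)),
            (18, (0.0600, 0.0670, 0.0749, 0.0842, 0.0951, 0.1078, 0.1225)),
        ],
    )
    def test_death_scenarios(self, base_spec, scenarios, sid, series):
        spec = apply_scenario(base_spec, _scenario(scenarios, sid))
        assert spec.mortality.p_death == pytest.approx(series, abs=PROB_TOL)


class TestApplyScenario:
    def test_base_scenario_is_identity(self, base_spec):
        assert apply_scenario(base_spec, ScenarioSpec(1, "base", "base")) == base_spec

    def test_input_spec_untouched(self, base_spec):
        before = base_spec.costs.community_direct_other
        apply_scenario(base_spec, ScenarioSpec(3, "x", "community_direct", 1.2))
        assert base_spec.costs.community_direct_other == before

    def test_one_way_discipline(self, base_spec):
        """Each scenario perturbs exactly one parameter group."""
        from adcea.parameters import spec_to_dict

        base = spec_to_dict(base_spec)
        groups = {
            "community_direct": lambda d: d["costs"]["community_direct_other"],
            "community_indirect": lambda d: d["costs"]["community_indirect"],
            "institution_direct": lambda d: d["costs"]["institution_direct_other"],
            "u_community": lambda d: d["utilities"]["u_community"],
            "u_institution": lambda d: d["utilities"]["u_institution"],
            "p_inst": lambda d: [s["p_institutionalisation"] for s in d["strategies"]],
            "p_death": lambda d: d["mortality"]["p_death"],
        }
        for scen in build_paper_scenarios():
            changed = spec_to_dict(apply_scenario(base_spec, scen))
            diff = [g for g, get in groups.items() if get(changed) != get(base)]
            assert len(diff) == (0 if scen.target == "base" else 1), scen.label

    def test_invalid_transform_rejected(self, base_spec):
        huge = ScenarioSpec(99, "p_inst x12", "p_inst_both_arms", 12.0)
        with pytest.raises(ValueError, match="invalid spec"):
            apply_scenario(base_spec, huge)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown target"):
            ScenarioSpec(99, "bad", "medication_cost", 1.1)


class TestRunDsa:
    def test_shape(self, dsa):
        assert len(dsa) == 36
        assert set(dsa["perspective"]) == {"healthcare", "societal"}

    def test_all_scenarios_gain_qalys(self, dsa):
        assert (dsa["delta_qalys"] > 0).all()

    def test_healthcare_dominance_pattern(self, dsa):
        hc = dsa[dsa["perspective"] == "healthcare"]
        assert (hc["classification"] == "dominant").sum() >= 17
        worst = hc[hc["scenario_id"] == 14].iloc[0]
        assert worst["classification"] == "icer"
        assert 0 < worst["icer"] < 23_065  # cost-effective at the lower threshold

    def test_societal_nondominant_scenarios_still_gain_qalys(self, dsa):
        soc = dsa[dsa["perspective"] == "societal"]
        nondom = soc[soc["classification"] != "dominant"]
        assert (nondom["delta_qalys"] > 0).all()
        # every scenario is cost-effective at the upper threshold
        assert dsa["ce_at_34598"].all()


class TestTriangularSampling:
    def test_degenerate_width(self):
        rng = np.random.default_rng(0)
        assert sample_triangular(1.0, 1.0, 1.0, rng) == 1.0

    def test_mean_and_cdf_at_mode(self):
        rng = np.random.default_rng(42)
        draws = np.array([sample_triangular(0.0, 1.0, 2.0, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.01)
        rng = np.random.default_rng(42)
        draws = np.array([sample_triangular(0.5, 1.0, 2.0, rng) for _ in range(100_000)])
        # F(mode) = (mode - low) / (high - low)
        assert np.mean(draws <= 1.0) == pytest.approx(1 / 3, abs=0.01)
        assert draws.min() >= 0.5 and draws.max() <= 2.0

    def test_ordering_violation(self):
        with pytest.raises(ValueError):
            sample_triangular(2.0, 1.0, 3.0, np.random.default_rng(0))


class TestRunPsa:
    def test_degenerate_distributions_collapse_to_base_case(self, base_spec):
        psa = run_psa(base_spec, PSADistributions.degenerate(), n=20, seed=5)
        base = compare(evaluate_arm(base_spec, 0), evaluate_arm(base_spec, 1), "healthcare")
        assert np.allclose(psa.draws["delta_qalys"], base.delta_qalys)
        assert np.allclose(psa.draws["delta_cost_healthcare"], base.delta_cost)
        assert psa.proportion_dominant == {"healthcare": 1.0, "societal": 1.0}

    def test_seed_determinism(self, base_spec):
        a = run_psa(base_spec, n=200, seed=11)
        b = run_psa(base_spec, n=200, seed=11)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.proportion_cost_effective == b.proportion_cost_effective

    def test_single_draw_proportions_are_binary(self, base_spec):
        psa = run_psa(base_spec, n=1, seed=3)
        for p in psa.proportion_dominant.values():
            assert p in (0.0, 1.0)

    def test_cost_effective_at_least_dominant(self, base_spec):
        psa = run_psa(base_spec, n=500, seed=9)
        for persp, dom in psa.proportion_dominant.items():
            for prop in psa.proportion_cost_effective[persp].values():
                assert prop >= dom

    def test_rejects_nothing_on_the_base_model(self, base_spec):
        assert run_psa(base_spec, n=300, seed=2).n_rejected == 0

    def test_invalid_draws_are_resampled(self, base_spec):
        # force frequent joint-probability violations: high mortality + wide bounds
        spec = dataclasses.replace(
            base_spec,
            mortality=dataclasses.replace(
                base_spec.mortality, p_death=(0.8,) * 7
            ),
        )
        dists = PSADistributions(p_inst_rel=(0.5, 1.0, 2.0), vary_death=True,
                                 death_rel=(0.5, 1.0, 1.2))
        psa = run_psa(spec, dists, n=100, seed=13)
        assert psa.n_rejected > 0
        assert len(psa.draws) == 100

    def test_n_zero_rejected(self, base_spec):
        with pytest.raises(ValueError):
            run_psa(base_spec, n=0)


class TestCeac:
    def test_matches_summary_at_thresholds(self, psa_small, base_spec):
        curve = ceac(psa_small, base_spec.wtp_thresholds, "societal")
        for wtp, prob in zip(curve["wtp"], curve["probability_cost_effective"]):
            assert prob == psa_small.proportion_cost_effective["societal"][wtp]

    def test_zero_wtp_is_cost_saving_fraction(self, psa_small):
        curve = ceac(psa_small, [0.0], "healthcare")
        frac_saving = float((psa_small.draws["delta_cost_healthcare"] < 0).mean())
        assert curve["probability_cost_effective"][0] == frac_saving

    def test_monotone_when_all_draws_gain_qalys(self, psa_small):
        assert (psa_small.draws["delta_qalys"] > 0).all()
        curve = ceac(psa_small, np.linspace(0, 60_000, 25), "societal")
        assert (np.diff(curve["probability_cost_effective"]) >= 0).all()

    def test_empty_grid_rejected(self, psa_small):
        with pytest.raises(ValueError):
            ceac(psa_small, [])
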