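"""Generative-parameter chain and design-planning arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abilitysim.generative import (
    DesignConfig,
    InfeasibleScenarioError,
    Scenario,
    ancova_adjusted_n,
    band_weights,
    build_generative_params,
    mixture_variance,
    required_total_n,
    scenario_mean_gsv,
    scenario_sigma,
    sd_from_sem,
    treatment_delta,
)
from abilitysim.score_tables import (
    AgeBand,
    SEMReliabilityTable,
    TableSet,
)
from conftest import make_alpha_tableset


class TestSdFromSem:
    @pytest.mark.parametrize(
        "sem,rel,expected",
        [(3.0, 0.75, 6.0), (2.0, 0.0, 2.0), (2.5, 0.84, 6.25)],
    )
    def test_values(self, sem, rel, expected):
        assert sd_from_sem(sem, rel) == pytest.approx(expected)

    @pytest.mark.parametrize("sem,rel", [(0.0, 0.5), (-1.0, 0.5), (2.0, 1.0), (2.0, 1.5)])
    def test_invalid_inputs(self, sem, rel):
        with pytest.raises(ValueError):
            sd_from_sem(sem, rel)


class TestMixtureVariance:
    def test_equal_means_reduce_to_weighted_variance(self):
        w, s2 = [0.3, 0.7], [4.0, 9.0]
        assert mixture_variance(w, [5.0, 5.0], s2) == pytest.approx(
            0.3 * 4 + 0.7 * 9
        )

    def test_dispersion_term(self):
        # two components at 0 and 2, unit variances: 1 + (2 - 1) = 2
        assert mixture_variance([0.5, 0.5], [0.0, 2.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_single_component_identity(self):
        assert mixture_variance([1.0], [3.0], [7.0]) == pytest.approx(7.0)

    def test_matches_pooled_sample_oracle(self):
        # empirical variance of a large pooled two-component normal sample
        rng = np.random.default_rng(42)
        w, mu, sd = [0.4, 0.6], [12.0, 20.0], [3.0, 5.0]
        n = 10**6
        comp = rng.choice(2, size=n, p=w)
        draws = rng.normal(np.array(mu)[comp], np.array(sd)[comp])
        expected = mixture_variance(w, mu, [9.0, 25.0])
        assert draws.var() == pytest.approx(expected, rel=5e-3)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.05, 1.0),
                st.floats(-50, 50),
                st.floats(0.1, 100.0),
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_dispersion_term_nonnegative(self, components):
        w = np.array([c[0] for c in components])
        w = w / w.sum()
        mu = [c[1] for c in components]
        var = [c[2] for c in components]
        assert mixture_variance(w, mu, var) >= float(w @ np.array(var)) - 1e-9

    def test_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            mixture_variance([0.5, 0.5], [1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="sum to 1"):
            mixture_variance([0.5, 0.4], [0.0, 0.0], [1.0, 1.0])


class TestBandWeights:
    def test_single_band(self):
        bw = band_weights((36, 60), [AgeBand(36, 60)])
        assert bw.weights.tolist() == [1.0]

    def test_even_split(self):
        bw = band_weights((36, 84), [AgeBand(36, 60), AgeBand(60, 84)])
        assert bw.weights.tolist() == [0.5, 0.5]

    def test_partial_overlap(self):
        bw = band_weights((48, 84), [AgeBand(36, 60), AgeBand(60, 84)])
        assert bw.weights.tolist() == pytest.approx([1 / 3, 2 / 3])

    @settings(max_examples=30, deadline=None)
    @given(lo=st.integers(0, 50), span=st.integers(1, 100), width=st.integers(1, 30))
    def test_weights_sum_to_one(self, lo, span, width):
        bands = [AgeBand(m, m + width) for m in range(0, 200, width)]
        bw = band_weights((lo, lo + span), bands)
        assert bw.weights.sum() == pytest.approx(1.0)

    def test_uncovered_range_rejected(self):
        with pytest.raises(Exception, match="cover"):
            band_weights((36, 96), [AgeBand(36, 60), AgeBand(60, 84)])


class TestScenarioChain:
    def test_mean_traces_table_chain(self, alpha_tables):
        # midpoint age 60 -> band [60,84); impairment 3 -> vscale 6 -> raw
        # band 10-14 -> mean raw 12 -> gsv table value at raw 12
        scenario = Scenario((3, 6), 3, "alpha")
        assert scenario_mean_gsv(alpha_tables, scenario) == 55.0

    def test_extreme_impairment_lands_on_gsv_floor(self, default_tables):
        # "written" at 174 months: v-scale 1 band is raw 0-0, gsv(0) = 10
        from abilitysim.score_tables import gsv_from_raw, mean_raw_for_vscale

        raw = mean_raw_for_vscale(default_tables.vscale_tables["written"], 174, 1)
        assert raw == 0
        assert gsv_from_raw(default_tables.gsv_tables["written"], raw) == 10

    def test_absent_band_is_infeasible(self, alpha_tables):
        with pytest.raises(InfeasibleScenarioError):
            scenario_mean_gsv(alpha_tables, Scenario((3, 6), 2, "alpha"))

    def test_sigma_single_band_equals_sem_formula(self, alpha_tables):
        # restrict the SEM table to one band covering the whole range
        single = TableSet(
            alpha_tables.gsv_tables,
            alpha_tables.vscale_tables,
            {
                sd: SEMReliabilityTable(
                    sd,
                    pd.DataFrame(
                        {
                            "age_min_months": [36],
                            "age_max_months": [84],
                            "sem_gsv": [3.0],
                            "reliability": [0.75],
                        }
                    ),
                )
                for sd in alpha_tables.subdomains
            },
        )
        scenario = Scenario((3, 6), 3, "alpha")
        assert scenario_sigma(single, scenario) == pytest.approx(6.0)

    def test_sigma_two_band_mixture(self, alpha_tables):
        # equal per-band SDs but band-specific chain means: the dispersion
        # of the means across bands must enter the pooled variance
        tables = make_alpha_tableset()
        for sd in tables.subdomains:
            tables.sem_tables[sd].frame["sem_gsv"] = [3.0, 3.0]
            tables.sem_tables[sd].frame["reliability"] = [0.75, 0.75]
        scenario = Scenario((3, 6), 5, "alpha")  # vscale 1 differs per band
        mu1 = 12.0  # band [36,60): raw 0-0 -> gsv 10; band [60,84): raw 0-2 -> 1 -> 12
        sigma = scenario_sigma(tables, scenario)
        expected = np.sqrt(
            mixture_variance([0.5, 0.5], [10.0, mu1], [36.0, 36.0])
        )
        assert sigma == pytest.approx(expected)

    def test_sigma_matches_pooled_monte_carlo(self, default_tables):
        scenario = Scenario((3, 6), 1, "receptive")
        sigma = scenario_sigma(default_tables, scenario)
        # brute-force oracle: draw ages uniformly, then a GSV from the
        # age-band-specific normal; pooled SD must match the mixture formula
        from abilitysim.generative import band_weights as bw_fn
        from abilitysim.generative import _chain_mean_gsv

        sem_table = default_tables.sem_tables["receptive"]
        bw = bw_fn(scenario.months_range, sem_table.age_bands)
        rng = np.random.default_rng(7)
        n = 10**6
        idx = rng.choice(len(bw.bands), size=n, p=bw.weights)
        mus = np.array(
            [
                _chain_mean_gsv(
                    default_tables, "receptive", int(b.midpoint),
                    scenario.target_vscale,
                )
                for b in bw.bands
            ]
        )
        sds = np.array(
            [sd_from_sem(*sem_table.row_for_band(b)) for b in bw.bands]
        )
        draws = rng.normal(mus[idx], sds[idx])
        assert sigma == pytest.approx(draws.std(), rel=5e-3)

    def test_sigma_invariant_to_band_split(self, alpha_tables):
        # splitting a SEM band into two identical halves leaves sigma
        # unchanged when the v-scale chain agrees at both half-midpoints
        tables = make_alpha_tableset()
        split = TableSet(
            tables.gsv_tables,
            tables.vscale_tables,
            {
                sd: SEMReliabilityTable(
                    sd,
                    pd.DataFrame(
                        {
                            "age_min_months": [36, 48, 60, 72],
                            "age_max_months": [48, 60, 72, 84],
                            "sem_gsv": [3.0, 3.0, 2.5, 2.5],
                            "reliability": [0.75, 0.75, 0.84, 0.84],
                        }
                    ),
                )
                for sd in tables.subdomains
            },
        )
        scenario = Scenario((3, 6), 3, "alpha")
        assert scenario_sigma(split, scenario) == pytest.approx(
            scenario_sigma(tables, scenario)
        )


class TestTreatmentDelta:
    def test_large_and_zero(self):
        assert treatment_delta(10.0, "large") == pytest.approx(8.0)
        assert treatment_delta(10.0, "zero") == 0.0

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 1e3))
    def test_standardized_effect_is_constant(self, sigma):
        assert treatment_delta(sigma, "large") / sigma == pytest.approx(0.8)

    def test_invalid(self):
        with pytest.raises(ValueError):
            treatment_delta(0.0, "large")
        with pytest.raises(ValueError):
            treatment_delta(1.0, "huge")


class TestPlanningArithmetic:
    def test_planned_design_numbers(self):
        assert required_total_n(0.8, 0.05, 0.90) == 66
        assert ancova_adjusted_n(66, 0.8) == 24

    def test_half_power_case(self):
        # 4 * 1.95996**2 / 0.64 = 24.01 -> even ceiling
        assert required_total_n(0.8, 0.05, 0.50) == 26

    def test_monotone_in_power(self):
        ns = [required_total_n(0.8, 0.05, p) for p in (0.2, 0.5, 0.8, 0.9, 0.99)]
        assert ns == sorted(ns)

    def test_agrees_with_independent_power_solver(self):
        # statsmodels' t-test solver gives the exact-t answer; the normal
        # approximation must land within one participant pair of it
        from statsmodels.stats.power import TTestIndPower

        n_per_arm = TTestIndPower().solve_power(
            effect_size=0.8, alpha=0.05, power=0.90, ratio=1.0
        )
        assert abs(required_total_n(0.8, 0.05, 0.90) - 2 * n_per_arm) <= 2

    def test_adjusted_n_identity_and_rounding(self):
        assert ancova_adjusted_n(66, 0.0) == 66
        assert ancova_adjusted_n(100, 0.5) == 76  # 75 -> even ceiling

    def test_design_config_derives_n24(self, design):
        assert design.n_total == 24
        assert design.followup_months == 6


def test_build_generative_params_bundles_chain(default_tables, design):
    scenario = Scenario((12, 16), 3, "receptive")
    params = build_generative_params(default_tables, scenario, design)
    assert params.mu_gsv == scenario_mean_gsv(default_tables, scenario)
    assert params.sigma_gsv == pytest.approx(
        scenario_sigma(default_tables, scenario)
    )
    assert params.delta == pytest.approx(0.8 * params.sigma_gsv)
    assert params.rho == 0.8
    null = build_generative_params(
        default_tables, Scenario((12, 16), 3, "receptive", "zero"), design
    )
    assert null.delta == 0.0
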