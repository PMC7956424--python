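"""Markov cohort engine: transitions, conservation, accrual and oracles."""
import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from hcc_cea import (
    LifeTable,
    ModelSettings,
    ParametricSurvival,
    StrategySpec,
    ae_burden,
    bev_cost,
    build_strategies,
    build_transitions,
    evaluate_arms,
    run_cohort,
)

CYCLE = 21 / (365.25 / 12)


def _zero_mortality_table():
    ages = np.arange(18, 121)
    return LifeTable(ages=ages, annual_mortality=np.zeros_like(ages, dtype=float))


class TestBuildTransitions:
    def test_rows_sum_to_one(self, arms, settings, life_table):
        for strat in arms:
            T = build_transitions(strat, settings, life_table)
            assert np.abs(T.sum(axis=2) - 1).max() < 1e-12

    def test_dead_absorbing(self, arms, settings, life_table):
        T = build_transitions(arms[0], settings, life_table)
        np.testing.assert_array_equal(T[:, 2], np.tile([0, 0, 1.0], (len(T), 1)))

    def test_first_cycle_death_prob_closed_form(self, arms, settings, life_table):
        """Hazard-additive construction from the sorafenib Weibull OS."""
        sor = arms[1]
        T = build_transitions(sor, settings, life_table)
        H_dis = 0.027 * CYCLE**1.286
        H_bg = -np.log(1 - life_table.qx(settings.start_age)) * (21 / 365.25)
        assert T[0, 0, 2] == pytest.approx(1 - np.exp(-(H_dis + H_bg)), rel=1e-10)

    def test_zero_hazards_identity(self, settings):
        tiny = ParametricSurvival("weibull", (1e-12, 1.0))
        strat = StrategySpec(name="null", os_model=tiny, pfs_model=tiny,
                             drug_components=())
        T = build_transitions(strat, settings, _zero_mortality_table())
        assert np.abs(T - np.eye(3)).max() < 1e-10

    def test_life_table_range_error(self, arms, life_table):
        settings = ModelSettings(start_age=108.0, horizon_years=5)
        with pytest.raises(ValueError, match="age"):
            build_transitions(arms[0], settings, life_table)


class TestRunCohort:
    def test_conservation(self, base_traces):
        for trace, _ in base_traces.values():
            sums = trace.occupancy.sum(axis=1)
            assert np.abs(sums - 1).max() < 1e-12
            assert np.all(np.diff(trace.occupancy[:, 2]) >= 0)

    def test_immortal_cohort_with_unit_utility(self, settings):
        tiny = ParametricSurvival("weibull", (1e-12, 1.0))
        strat = StrategySpec(name="null", os_model=tiny, pfs_model=tiny,
                             drug_components=(), utility_first_line=1.0,
                             utility_progressed=1.0)
        st0 = ModelSettings(discount_rate=0.0)
        _, out = run_cohort(strat, st0, _zero_mortality_table())
        expected = st0.n_cycles * st0.cycle_years
        assert out.life_years == pytest.approx(expected, rel=1e-9)
        assert out.qalys == pytest.approx(expected, rel=1e-9)

    def test_discounting_reduces_accruals(self, base_traces):
        for _, out in base_traces.values():
            assert out.qalys < out.qalys_undiscounted
            assert out.total_cost < out.total_cost_undiscounted
            assert out.life_years < out.life_years_undiscounted

    def test_qalys_bounded_by_life_years(self, base_traces):
        for _, out in base_traces.values():
            assert 0 < out.qalys <= out.life_years

    def test_transitions_argument_equivalent(self, arms, settings, life_table):
        strat = arms[0]
        T = build_transitions(strat, settings, life_table)
        _, direct = run_cohort(strat, settings, life_table)
        _, via_T = run_cohort(strat, settings, life_table, transitions=T)
        assert direct.qalys == via_T.qalys
        assert direct.total_cost == via_T.total_cost

    def test_half_cycle_toggle_bounded_by_one_cycle(self, arms, life_table):
        on = ModelSettings(half_cycle_correction=True)
        off = ModelSettings(half_cycle_correction=False)
        for strat in arms:
            _, a = run_cohort(strat, on, life_table)
            _, b = run_cohort(strat, off, life_table)
            assert abs(a.life_years - b.life_years) < on.cycle_years

    def test_lower_os_hazard_increases_life_years(self, life_table):
        lys = []
        for hr in (0.9, 0.7, 0.5, 0.3):
            out_ab, _, _ = evaluate_arms({"hr_os": hr}, life_table=life_table)
            lys.append(float(out_ab.life_years))
        assert all(np.diff(lys) > 0)

    def test_higher_unit_cost_increases_total_cost(self, life_table):
        costs = []
        for c in (8000.0, 9419.16, 12000.0):
            out_ab, _, _ = evaluate_arms({"cost_atezolizumab": c},
                                         life_table=life_table)
            costs.append(float(out_ab.total_cost))
        assert all(np.diff(costs) > 0)

    def test_longer_horizon_non_decreasing(self, arms, life_table):
        prev = None
        for hy in (5, 10, 40):
            _, out = run_cohort(arms[0], ModelSettings(horizon_years=hy),
                                life_table)
            if prev is not None:
                assert out.life_years >= prev.life_years
                assert out.total_cost >= prev.total_cost
            prev = out

    @hsettings(derandomize=True, max_examples=15, deadline=None)
    @given(hr_os=st.floats(0.3, 1.5), hr_pfs=st.floats(0.3, 1.5))
    def test_conservation_under_random_hazard_ratios(self, settings, life_table,
                                                     hr_os, hr_pfs):
        ab, _ = build_strategies({"hr_os": hr_os, "hr_pfs": hr_pfs})
        trace, _ = run_cohort(ab, settings, life_table)
        assert np.abs(trace.occupancy.sum(axis=1) - 1).max() < 1e-12

    def test_vectorized_matches_scalar(self, settings, life_table):
        """Array-parameter broadcasting reproduces scalar runs elementwise."""
        hrs = np.array([0.42, 0.58, 0.79])
        ab, _ = build_strategies({"hr_os": hrs})
        _, vec = run_cohort(ab, settings, life_table, collect_trace=False)
        for i, hr in enumerate(hrs):
            ab_i, _ = build_strategies({"hr_os": float(hr)})
            _, sc = run_cohort(ab_i, settings, life_table)
            assert vec.qalys[i] == pytest.approx(sc.qalys, rel=1e-12)
            assert vec.total_cost[i] == pytest.approx(sc.total_cost, rel=1e-12)

    def test_microsimulation_oracle(self, arms, settings, life_table):
        """A 100k-subject microsimulation on the same per-cycle transition
        probabilities reproduces cohort life-years and QALYs within
        Monte-Carlo error."""
        from helpers import microsim_ly_qaly

        strat = arms[1]
        _, cohort = run_cohort(strat, settings, life_table)
        ly, qaly = microsim_ly_qaly(strat, settings, life_table,
                                    n=100_000, seed=12345)
        assert ly == pytest.approx(float(cohort.life_years), rel=0.007)
        assert qaly == pytest.approx(float(cohort.qalys), rel=0.007)


class TestCostPieces:
    def test_ae_burden_sorafenib_arithmetic(self, arms):
        cost, dec = ae_burden(arms[1])
        # 0.051*88.38 + 0.083*145.65 + 0.122*64.01 + 0.064*0
        assert cost == pytest.approx(24.41, abs=0.01)
        # 0.051*0.103 + 0.083*0.116
        assert dec == pytest.approx(0.0149, abs=0.0001)

    def test_ae_burden_zero_profile(self):
        tiny = ParametricSurvival("weibull", (0.01, 1.0))
        strat = StrategySpec(name="x", os_model=tiny, pfs_model=tiny,
                             drug_components=())
        assert ae_burden(strat) == (0.0, 0.0)

    @pytest.mark.parametrize(
        "weight, dose, expected",
        [(70, 15, 117.60), (140, 15, 235.20), (70, 0, 0.0)],
    )
    def test_bev_cost_scaling(self, weight, dose, expected):
        assert bev_cost(weight, dose) == pytest.approx(expected)

    def test_bev_cost_domain_errors(self):
        with pytest.raises(ValueError):
            bev_cost(-70, 15)
        with pytest.raises(ValueError):
            bev_cost(70, -1)

    def test_trace_csv_export(self, base_traces, tmp_path):
        trace, _ = base_traces["atezo-bev"]
        trace.to_csv(tmp_path / "trace.csv")
        lines = (tmp_path / "trace.csv").read_text().strip().splitlines()
        assert len(lines) == 1 + len(trace.time_months)
        assert lines[0].startswith("cycle,time_months,pf,progressed,dead")
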