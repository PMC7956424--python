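"""Parametric survival laws, censored fitting and AIC selection."""
import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from hcc_cea import (
    ParametricSurvival,
    apply_hazard_ratio,
    cycle_transition_prob,
    fit_parametric,
    select_model,
    simulate_survival,
    survival_at,
)

WEIBULL_OS_SOR = ParametricSurvival("weibull", (0.027, 1.286))
WEIBULL_PFS_SOR = ParametricSurvival("weibull", (0.093, 1.312))
CYCLE = 21 / (365.25 / 12)


@st.composite
def survival_laws(draw):
    family = draw(st.sampled_from(["weibull", "exponential", "log_logistic",
                                   "log_normal"]))
    if family == "exponential":
        params = (draw(st.floats(1e-3, 0.5)),)
    elif family == "weibull":
        params = (draw(st.floats(1e-3, 0.5)), draw(st.floats(0.5, 3.0)))
    else:
        params = (draw(st.floats(0.5, 30.0)), draw(st.floats(0.3, 3.0)))
    return ParametricSurvival(family, params)


class TestSurvivalFunction:
    def test_survival_at_zero_is_one_and_median_consistent(self):
        for dist in (WEIBULL_OS_SOR, WEIBULL_PFS_SOR):
            assert survival_at(dist, 0.0) == pytest.approx(1.0)
            assert survival_at(dist, dist.median()) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "dist, t, expected",
        [
            # medians implied by the fitted sorafenib models
            (WEIBULL_PFS_SOR, 4.62, 0.50),
            (WEIBULL_OS_SOR, 12.47, 0.50),
        ],
    )
    def test_fitted_model_medians(self, dist, t, expected):
        assert survival_at(dist, t) == pytest.approx(expected, abs=0.005)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            WEIBULL_OS_SOR.sf(-1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParametricSurvival("weibull", (-0.1, 1.0))
        with pytest.raises(ValueError):
            ParametricSurvival("nonsense", (1.0,))

    @hsettings(derandomize=True, max_examples=40, deadline=None)
    @given(survival_laws())
    def test_survival_monotone_from_one(self, dist):
        t = np.linspace(0, 80, 200)
        s = dist.sf(t)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)


class TestCycleTransitionProb:
    def test_exponential_is_memoryless(self):
        dist = ParametricSurvival("exponential", (0.08,))
        expected = 1 - np.exp(-0.08 * CYCLE)
        for t in (0.0, 3.0, 17.0, 44.0):
            assert cycle_transition_prob(dist, t, CYCLE) == pytest.approx(expected)

    def test_increasing_hazard_weibull_gives_increasing_probs(self):
        t = np.arange(0, 40, CYCLE)
        p = cycle_transition_prob(WEIBULL_OS_SOR, t, CYCLE)
        assert np.all(np.diff(p) > 0)

    def test_first_cycle_matches_direct_evaluation(self):
        p = cycle_transition_prob(WEIBULL_OS_SOR, 0.0, CYCLE)
        assert p == pytest.approx(1 - np.exp(-0.027 * CYCLE**1.286))

    @hsettings(derandomize=True, max_examples=30, deadline=None)
    @given(survival_laws(), st.floats(5.0, 60.0))
    def test_compounding_reproduces_survival(self, dist, horizon):
        """prod(1 - p_k) over a grid equals S(T) exactly."""
        edges = np.linspace(0, horizon, 41)
        p = cycle_transition_prob(dist, edges[:-1], edges[1] - edges[0])
        assert np.prod(1 - p) == pytest.approx(float(dist.sf(horizon)), rel=1e-9)


class TestHazardRatio:
    def test_identity_hr(self):
        scaled = apply_hazard_ratio(WEIBULL_PFS_SOR, 1.0)
        assert scaled.params == WEIBULL_PFS_SOR.params

    @pytest.mark.parametrize(
        "dist, hr, expected_median",
        [
            (WEIBULL_PFS_SOR, 0.59, 6.91),   # trial PFS HR
            (WEIBULL_OS_SOR, 0.58, 19.05),   # trial OS HR
        ],
    )
    def test_hr_scaled_medians(self, dist, hr, expected_median):
        assert apply_hazard_ratio(dist, hr).median() == pytest.approx(
            expected_median, rel=0.005
        )

    def test_survival_power_identity(self):
        """Under proportional hazards S_hr(t) = S(t)**hr for Weibull."""
        t = np.linspace(0, 60, 50)
        for hr in (0.3, 0.58, 1.7):
            scaled = apply_hazard_ratio(WEIBULL_OS_SOR, hr)
            np.testing.assert_allclose(scaled.sf(t), WEIBULL_OS_SOR.sf(t) ** hr)

    def test_invalid_hr_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(WEIBULL_OS_SOR, -0.5)


class TestFitting:
    def test_exponential_mle_matches_closed_form(self):
        coh = simulate_survival(
            ParametricSurvival("exponential", (0.05,)), 2000,
            censor_rate=0.01, seed=5,
        )
        fit = fit_parametric(coh.times, coh.events, "exponential")
        closed_form = coh.events.sum() / coh.times.sum()
        assert float(fit.model.params[0]) == pytest.approx(closed_form, rel=1e-5)
        assert fit.aic == pytest.approx(2 - 2 * fit.log_likelihood)

    @pytest.mark.parametrize(
        "family, truth, censor_rate, follow_up",
        [
            ("weibull", (0.027, 1.286), 0.014, 60.0),
            ("exponential", (0.05,), 0.012, 80.0),
            ("log_logistic", (10.0, 2.0), 0.012, 80.0),
            ("log_normal", (9.0, 0.8), 0.012, 80.0),
        ],
    )
    def test_parameter_recovery(self, family, truth, censor_rate, follow_up):
        """Each family refits its own simulations within 5% at n=5000."""
        coh = simulate_survival(
            ParametricSurvival(family, truth), 5000,
            censor_rate=censor_rate, max_follow_up=follow_up, seed=0,
        )
        fit = fit_parametric(coh.times, coh.events, family)
        assert fit.converged
        for est, true in zip(fit.model.params, truth):
            assert float(est) == pytest.approx(true, rel=0.05)

    def test_optimum_beats_truth(self):
        truth = ParametricSurvival("weibull", (0.027, 1.286))
        coh = simulate_survival(truth, 3000, censor_rate=0.02, seed=2)
        fit = fit_parametric(coh.times, coh.events, "weibull")
        ll_truth = float(
            np.sum(truth.logpdf(coh.times[coh.events == 1]))
            + np.sum(truth.logsf(coh.times[coh.events == 0]))
        )
        assert fit.log_likelihood >= ll_truth - 1e-6

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric([1.0, 2.0, 3.0], [0, 0, 0], "weibull")


class TestModelSelection:
    def test_weibull_data_ranks_weibull_above_exponential(self):
        coh = simulate_survival(
            ParametricSurvival("weibull", (0.093, 1.312)), 5000,
            censor_rate=0.02, seed=4,
        )
        ranked = select_model(coh.times, coh.events)
        families = [f.model.family for f in ranked]
        assert families.index("weibull") < families.index("exponential")
        aics = [f.aic for f in ranked]
        assert aics == sorted(aics)

    def test_exponential_data_within_two_aic_of_weibull(self):
        """Nested models, one extra df: AIC gap bounded for true-exponential data."""
        coh = simulate_survival(
            ParametricSurvival("exponential", (0.07,)), 5000,
            censor_rate=0.01, seed=6,
        )
        fits = {f.model.family: f for f in select_model(coh.times, coh.events)}
        assert abs(fits["exponential"].aic - fits["weibull"].aic) <= 2.0 + 1e-6

    def test_ranking_invariant_to_subject_order(self):
        coh = simulate_survival(WEIBULL_OS_SOR, 500, censor_rate=0.02, seed=8)
        perm = np.random.default_rng(1).permutation(len(coh.times))
        r1 = select_model(coh.times, coh.events)
        r2 = select_model(coh.times[perm], coh.events[perm])
        assert [f.model.family for f in r1] == [f.model.family for f in r2]

    def test_fit_result_json_roundtrip(self):
        coh = simulate_survival(WEIBULL_OS_SOR, 300, seed=9)
        fit = fit_parametric(coh.times, coh.events, "weibull")
        import json

        blob = json.loads(fit.to_json())
        assert blob["family"] == "weibull"
        assert blob["aic"] == pytest.approx(fit.aic)
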