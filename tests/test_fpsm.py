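"""Spline hazard models: basis properties, Weibull nesting, constraints."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import rxmsm
from rxmsm import (
    FPSMFit,
    ModelSpec,
    SplineBasisSpec,
    evaluate,
    fit_constrained,
    fit_transition,
    place_knots,
    rcs_basis,
)
from rxmsm.structures import ClockSpec, episodes_to_transition_data, make_structure
from rxmsm.synthetic import GeneratorConfig, TransitionHazard, zero_hazard
from rxmsm.cycles import DAYS_PER_YEAR


def weibull_rows(rng, n=5000, shape=1.5, scale=1.71, loghr_case=None, censor=5.0):
    """Weibull H(t) = (t/scale)^shape with optional case-status effect."""
    case = rng.integers(0, 2, size=n) if loghr_case is not None else np.zeros(n, int)
    lp = (loghr_case or 0.0) * case
    t = scale * (-np.log(rng.uniform(size=n)) * np.exp(-lp)) ** (1 / shape)
    obs = np.minimum(t, censor)
    return pd.DataFrame({
        "t_entry": 0.0, "t_exit": obs, "event": (t <= censor).astype(int),
        "case_status": np.where(case == 1, "case", "comparator"),
        "age_group": "<50",
    })


def direct_weibull_mle(rows):
    """Independent Weibull MLE (log lam, log k parameterization)."""
    t = rows["t_exit"].to_numpy()
    d = rows["event"].to_numpy()

    def nll(p):
        lam, k = np.exp(p)
        return -(np.sum(d * (np.log(lam) + np.log(k) + (k - 1) * np.log(t)))
                 - np.sum(lam * t ** k))

    res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    lam, k = np.exp(res.x)
    return np.log(lam), k, -res.fun


class TestSplineBasis:
    def test_derivative_matches_central_difference(self):
        rng = np.random.default_rng(0)
        spec = SplineBasisSpec((-2.0, -0.5, 0.3, 1.1, 2.0))
        x = rng.uniform(-3, 3, size=100)
        h = 1e-6
        _, dB = rcs_basis(x, spec)
        num = (rcs_basis(x + h, spec)[0] - rcs_basis(x - h, spec)[0]) / (2 * h)
        assert np.max(np.abs(dB - num)) < 1e-6

    def test_linear_beyond_boundary_knots(self):
        spec = SplineBasisSpec((0.0, 0.5, 1.0, 1.5, 2.0))
        xs = np.array([-3.0, -2.0, 3.0, 4.0])
        B, dB = rcs_basis(xs, spec)
        # equal slopes at two points on the same side of the boundary
        assert np.allclose(dB[0], dB[1])
        assert np.allclose(dB[2], dB[3])
        assert np.allclose(B[1] - B[0], dB[0] * (xs[1] - xs[0]))

    def test_df1_is_log_time_identity(self):
        spec = SplineBasisSpec((0.0, 1.0))
        x = np.linspace(-2, 2, 7)
        B, dB = rcs_basis(x, spec)
        assert B.shape == (7, 1)
        assert np.allclose(B[:, 0], x)
        assert np.allclose(dB[:, 0], 1.0)

    def test_knot_placement_centiles(self):
        times = np.arange(1, 101, dtype=float)
        spec = place_knots(times, df=4)
        interior = np.exp(spec.knots[1:-1])
        assert interior == pytest.approx(
            np.percentile(times, [25, 50, 75]), rel=0.05)
        assert spec.knots[0] == pytest.approx(np.log(1.0))
        assert spec.knots[-1] == pytest.approx(np.log(100.0))

    def test_too_few_events_is_explicit_error(self):
        with pytest.raises(ValueError, match="lower df"):
            place_knots([1.0, 2.0, 3.0], df=4)


class TestWeibullNesting:
    def test_df1_fit_equals_direct_weibull_mle(self):
        rng = np.random.default_rng(10)
        rows = weibull_rows(rng, n=5000)
        fit = fit_transition(rows, ModelSpec(baseline_df=1, include_case=False,
                                             include_age=False), "x")
        loglam, k, ll = direct_weibull_mle(rows)
        assert fit.converged and fit.grad_norm < 1e-5
        assert fit.coef[0] == pytest.approx(loglam, rel=1e-4, abs=1e-6)
        assert fit.coef[1] == pytest.approx(k, rel=1e-4)
        assert fit.loglik == pytest.approx(ll, rel=1e-6)

    def test_df1_matches_lifelines_weibull(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        rows = weibull_rows(rng, n=2000)
        fit = fit_transition(rows, ModelSpec(baseline_df=1, include_case=False,
                                             include_age=False), "x")
        wf = lifelines.WeibullFitter().fit(rows["t_exit"], rows["event"])
        # lifelines: H(t) = (t/lambda_)^rho_
        assert fit.coef[1] == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.coef[0] == pytest.approx(-wf.rho_ * np.log(wf.lambda_), rel=1e-3)

    def test_exponential_data_recovers_unit_shape(self):
        rng = np.random.default_rng(12)
        rows = weibull_rows(rng, n=4000, shape=1.0, scale=2.0)
        fit = fit_transition(rows, ModelSpec(baseline_df=1, include_case=False,
                                             include_age=False), "x")
        se = np.sqrt(fit.vcov[1, 1])
        assert abs(fit.coef[1] - 1.0) < 3 * se

    def test_case_log_hazard_ratio_recovered(self):
        rng = np.random.default_rng(13)
        rows = weibull_rows(rng, n=5000, loghr_case=0.7)
        fit = fit_transition(rows, ModelSpec(baseline_df=1, include_age=False), "x")
        j = fit.coef_names.index("case")
        se = np.sqrt(fit.vcov[j, j])
        assert abs(fit.coef[j] - 0.7) < 3 * se
        # proportional model: HR constant in t and equal to exp(beta)
        hr = fit.hazard(np.array([0.5, 1, 2]), "case") / fit.hazard(
            np.array([0.5, 1, 2]), "comparator")
        assert np.allclose(hr, np.exp(fit.coef[j]))


class TestEvaluate:
    def test_closed_form_df1(self):
        fit = FPSMFit.from_weibull("x", shape=1.0, scale=10.0)  # H = 0.1 t
        h, H, S = evaluate(fit, 2.0)
        assert H == pytest.approx(0.2)
        assert S == pytest.approx(np.exp(-0.2))
        assert h == pytest.approx(0.1)

    def test_conditional_survival_uses_entry_time(self):
        fit = FPSMFit.from_constant("x", rate=0.3)
        _, _, S = evaluate(fit, 2.0, t_entry=1.0)
        assert S == pytest.approx(np.exp(-0.3))  # exp(-(H(2)-H(1)))

    def test_cumhaz_nondecreasing_over_data_range(self):
        rng = np.random.default_rng(14)
        rows = weibull_rows(rng, n=3000, shape=0.8)
        fit = fit_transition(rows, ModelSpec(baseline_df=4, include_case=False,
                                             include_age=False), "x")
        grid = np.linspace(rows.t_exit.min(), rows.t_exit.max(), 1000)
        H = fit.cumhaz(grid)
        assert np.all(np.diff(H) >= 0)

    def test_nonpositive_time_rejected(self):
        fit = FPSMFit.from_constant("x", rate=0.1)
        with pytest.raises(ValueError):
            fit.cumhaz(0.0)


class TestDelayedEntry:
    def test_forward_clock_markov_rates_recovered(self):
        """Left truncation: clock-forward rows from a constant-hazard
        process refit to the true rates."""
        cfg = GeneratorConfig(
            n_cases=500, comparator_ratio=3, seed=20,
            admin_horizon_days=6 * DAYS_PER_YEAR,
            transition_params={
                "start-cycle": TransitionHazard(1.0, DAYS_PER_YEAR / 0.3),
                "start-death": TransitionHazard(1.0, DAYS_PER_YEAR / 0.05),
                "cycle-disc": TransitionHazard(1.0, DAYS_PER_YEAR / 1.2),
                "cycle-death": TransitionHazard(1.0, DAYS_PER_YEAR / 0.05),
                "disc-cycle": TransitionHazard(1.0, DAYS_PER_YEAR / 0.4),
                "disc-death": TransitionHazard(1.0, DAYS_PER_YEAR / 0.05),
            },
        )
        subjects, timelines = rxmsm.simulate_cohort(cfg)
        E = make_structure("E")
        rows = episodes_to_transition_data(timelines, subjects, E, ClockSpec("forward"))
        for tid, true_rate in [("cycle-disc", 1.2), ("disc-cycle", 0.4)]:
            sub = rows[rows.transition_id == tid]
            assert (sub.t_entry > 0).any()  # genuinely left-truncated rows
            fit = fit_transition(sub, ModelSpec(baseline_df=1, include_case=False,
                                                include_age=False), tid)
            # rate parameter: H(t) = exp(g0) t^g1; evaluate log-rate SE at g1~1
            se0 = np.sqrt(fit.vcov[0, 0])
            assert abs(fit.coef[0] - np.log(true_rate)) < 3.5 * (se0 + 0.02)


@pytest.fixture(scope="module")
def g_truth_registry():
    """Cohort generated under the emulated-bidirectional constraints
    with known proportionality offsets."""
    offs = [0.0, 0.3, 0.6, 0.9, 1.2]
    tp = rxmsm.synthetic.default_transition_params()
    base = tp["cycle-disc"]
    for k, delta in enumerate(offs, start=1):
        tp[f"cycle{k}-disc{k}"] = TransitionHazard(
            shape=base.shape, scale_days=base.scale_days * np.exp(-delta / base.shape),
            loghr_case=base.loghr_case)
    cfg = GeneratorConfig(n_cases=900, seed=21, transition_params=tp)
    subjects, timelines = rxmsm.simulate_cohort(cfg)
    G = make_structure("G")
    rows = episodes_to_transition_data(timelines, subjects, G, ClockSpec("reset"))
    return rows, G, offs


class TestConstrainedFit:
    def test_proportionality_offsets_recovered(self, g_truth_registry):
        rows, G, offs = g_truth_registry
        jf = fit_constrained(rows, G,
                             ModelSpec(baseline_df=1, include_age=False,
                                       include_interactions=False, td_df=0),
                             td_transitions=())
        assert jf.converged and jf.grad_norm < 1e-5
        for k, true_off in enumerate(offs[1:], start=2):
            tid = f"cycle{k}-disc{k}"
            se = jf.offset_se(tid)
            assert abs(jf.offsets[tid] - true_off) < 3 * se

    def test_shared_death_rates_recovered(self, g_truth_registry):
        rows, G, _ = g_truth_registry
        jf = fit_constrained(rows, G,
                             ModelSpec(baseline_df=1, include_age=False,
                                       include_interactions=False, td_df=0),
                             td_transitions=())
        # cycle-death truth: exponential with rate 365.25/150000 per day
        j = jf.param_names.index("cycle-death:intercept")
        se = np.sqrt(jf.vcov[j, j])
        true_lograte = np.log(DAYS_PER_YEAR / 150_000.0)
        assert abs(jf.theta[j] - true_lograte) < 3 * (se + 0.05)

    def test_vacuous_constraints_reduce_to_per_transition_fits(self, g_truth_registry):
        rows, G, _ = g_truth_registry
        F = make_structure("F")  # same graph, no constraint groups
        spec = ModelSpec(baseline_df=1, include_age=False,
                         include_interactions=False, td_df=0)
        jf = fit_constrained(rows, F, spec, td_transitions=())
        # transitions too sparse to fit (fewer than two distinct event
        # times) are excluded from the likelihood on both sides
        total = 0.0
        for tid in F.transition_ids:
            sub = rows[rows.transition_id == tid]
            ev = sub.loc[sub.event == 1, "t_exit"].nunique()
            if ev < 2:
                continue
            total += fit_transition(sub, spec, tid).loglik
        assert jf.loglik == pytest.approx(total, abs=1e-6)


def test_no_events_is_explicit_error():
    rows = pd.DataFrame({
        "t_entry": 0.0, "t_exit": [1.0, 2.0], "event": [0, 0],
        "case_status": "case", "age_group": "<50",
    })
    with pytest.raises(ValueError, match="no events"):
        fit_transition(rows, ModelSpec(baseline_df=1, include_case=False,
                                       include_age=False), "x")
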