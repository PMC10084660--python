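"""Microsimulation prediction: inverse draws, oracles, invariants."""

import numpy as np
import pytest
from scipy.linalg import expm

from rxmsm import (
    ClockSpec,
    FPSMFit,
    PredictionRequest,
    aalen_johansen_oracle,
    draw_transition_time,
    make_structure,
    parameter_uncertainty,
    simulate_msm,
)


def constant_fits_B(lam1=0.2, lam2=0.05):
    return {"start-cycle1": FPSMFit.from_constant("start-cycle1", lam1),
            "start-death": FPSMFit.from_constant("start-death", lam2)}


def constant_fits_C(lam01=0.2, lam02=0.05, lam13=0.3):
    fits = constant_fits_B(lam01, lam02)
    fits["cycle1-death"] = FPSMFit.from_constant("cycle1-death", lam13)
    return fits


class TestDrawTransitionTime:
    def test_constant_hazard_inverse_transform(self):
        fit = FPSMFit.from_constant("x", rate=0.1)
        t = draw_transition_time(fit, "comparator", "<50", t0=0.0, horizon=100.0,
                                 u=np.array([0.5]))
        assert t[0] == pytest.approx(np.log(2) / 0.1, rel=1e-8)  # 6.9315

    def test_weibull_quadratic_cumhaz(self):
        fit = FPSMFit.from_weibull("x", shape=2.0, scale=1.0)  # H(t) = t^2
        t = draw_transition_time(fit, "comparator", "<50", t0=0.0, horizon=100.0,
                                 u=np.array([np.exp(-1.0)]))
        assert t[0] == pytest.approx(1.0, rel=1e-8)

    def test_forward_clock_shifts_by_entry_cumhaz(self):
        fit = FPSMFit.from_constant("x", rate=0.1)
        t = draw_transition_time(fit, "comparator", "<50", t0=np.array([5.0]),
                                 horizon=100.0, u=np.array([0.5]))
        assert t[0] == pytest.approx(5.0 + np.log(2) / 0.1, rel=1e-8)  # 11.9315

    def test_insufficient_hazard_returns_inf(self):
        fit = FPSMFit.from_constant("x", rate=1e-9)
        t = draw_transition_time(fit, "comparator", "<50", t0=0.0, horizon=10.0,
                                 u=np.array([0.5]))
        assert np.isinf(t[0])

    def test_invalid_u_rejected(self):
        fit = FPSMFit.from_constant("x", rate=0.1)
        with pytest.raises(ValueError):
            draw_transition_time(fit, "comparator", "<50", 0.0, 10.0, np.array([0.0]))


class TestClosedFormOccupancy:
    def test_competing_risks_cumulative_incidence(self):
        """P(cycle1 at 2) = (lam1/lam)(1 - e^(-lam t)) = 0.3148."""
        req = PredictionRequest(time_grid=np.linspace(0.2, 2.0, 10),
                                n_sim=50_000, seed=101)
        res = simulate_msm(constant_fits_B(), make_structure("B"),
                           ClockSpec("reset"), req)
        i = res.states.index("cycle1")
        p, se = res.occupancy[i, -1], res.occupancy_se[i, -1]
        assert abs(p - 0.3148) < 3 * se

    def test_illness_death_transient_occupancy(self):
        """P(in cycle1 at 2) = lam01 (e^(-.25 t*) - e^(-.3 t*))/(0.05) = 0.2313."""
        req = PredictionRequest(time_grid=np.linspace(0.2, 2.0, 10),
                                n_sim=50_000, seed=102)
        res = simulate_msm(constant_fits_C(), make_structure("C"),
                           ClockSpec("reset"), req)
        i = res.states.index("cycle1")
        p, se = res.occupancy[i, -1], res.occupancy_se[i, -1]
        assert abs(p - 0.2313) < 3 * se

    def test_zero_hazards_stay_in_start(self):
        fits = constant_fits_B(1e-12, 1e-12)
        grid = np.linspace(0.5, 4.0, 8)
        res = simulate_msm(fits, make_structure("B"), ClockSpec("reset"),
                           PredictionRequest(time_grid=grid, n_sim=2000, seed=1))
        i = res.states.index("start")
        assert np.all(res.occupancy[i] == 1.0)
        assert res.length_of_stay[i] == pytest.approx(grid, abs=1e-9)


@pytest.fixture(scope="module")
def f_result():
    rates = {"start-cycle1": 0.5, "start-death": 0.05}
    F = make_structure("F", k_cap=3)
    fits = {}
    for frm, to, tid in F.transitions:
        if tid in rates:
            fits[tid] = FPSMFit.from_constant(tid, rates[tid])
        elif to == "death":
            fits[tid] = FPSMFit.from_constant(tid, 0.08)
        elif to.startswith("disc"):
            fits[tid] = FPSMFit.from_constant(tid, 2.5)
        else:
            fits[tid] = FPSMFit.from_constant(tid, 0.6)
    req = PredictionRequest(time_grid=np.linspace(0.25, 5.0, 20),
                            n_sim=20_000, seed=55)
    return F, fits, simulate_msm(fits, F, ClockSpec("reset"), req)


class TestStructuralInvariants:
    def test_occupancy_partitions_cohort(self, f_result):
        _, _, res = f_result
        assert np.allclose(res.occupancy.sum(axis=0), 1.0, atol=1e-12)

    def test_death_and_ever_visit_monotone(self, f_result):
        F, _, res = f_result
        d = res.states.index("death")
        assert np.all(np.diff(res.occupancy[d]) >= 0)
        assert np.all(np.diff(res.ever_visit, axis=1) >= -1e-12)

    def test_length_of_stay_slope_at_most_one(self, f_result):
        _, _, res = f_result
        dt = np.diff(res.time_grid)
        for i in range(len(res.states)):
            slopes = np.diff(res.length_of_stay[i]) / dt
            assert np.all(slopes <= 1.0 + 1e-9)
        assert np.all(np.diff(res.in_cycle_los) >= -1e-12)

    def test_mc_se_scales_with_sqrt_n(self, f_result):
        F, fits, res = f_result
        req2 = PredictionRequest(time_grid=res.time_grid, n_sim=2 * res.n_sim,
                                 seed=56)
        res2 = simulate_msm(fits, F, ClockSpec("reset"), req2)
        i = res.states.index("cycle1")
        j = len(res.time_grid) // 2
        ratio = res.occupancy_se[i, j] / res2.occupancy_se[i, j]
        assert ratio == pytest.approx(np.sqrt(2), rel=0.2)


class TestAalenJohansenOracle:
    def test_matches_closed_form_competing_risks(self):
        B = make_structure("B")
        haz = {"start-cycle1": lambda t: 0.2, "start-death": lambda t: 0.05}
        grid = np.array([0.5, 1.0, 2.0])
        aj = aalen_johansen_oracle(haz, B, grid, step=1e-4)
        lam = 0.25
        expected = (0.2 / lam) * (1 - np.exp(-lam * grid))
        assert np.max(np.abs(aj[1] - expected)) < 1e-6

    def test_matches_matrix_exponential_recurrent_chain(self):
        F = make_structure("F", k_cap=3)
        rng = np.random.default_rng(3)
        rates = {tid: float(rng.uniform(0.05, 1.5)) for _, _, tid in F.transitions}
        haz = {tid: (lambda t, r=r: r) for tid, r in rates.items()}
        grid = np.array([0.5, 1.5, 3.0])
        aj = aalen_johansen_oracle(haz, F, grid, step=1e-3)
        states = list(F.states)
        Q = np.zeros((len(states), len(states)))
        for (a, b, tid) in F.transitions:
            i, j = states.index(a), states.index(b)
            Q[i, j] += rates[tid]
            Q[i, i] -= rates[tid]
        ex = np.array([expm(Q * t)[0] for t in grid]).T
        assert np.max(np.abs(aj - ex)) < 1e-6

    def test_zero_hazards_identity(self):
        B = make_structure("B")
        haz = {"start-cycle1": lambda t: 0.0, "start-death": lambda t: 0.0}
        aj = aalen_johansen_oracle(haz, B, np.array([1.0, 5.0]), step=1e-2)
        assert np.allclose(aj[0], 1.0)
        assert np.allclose(aj[1:], 0.0)


class TestMicrosimAgainstOracle:
    @pytest.mark.parametrize("sid", ["B", "C", "D"])
    def test_forward_clock_weibull_occupancy(self, sid):
        structure = make_structure(sid)
        rng = np.random.default_rng(17)
        fits, haz = {}, {}
        for _, _, tid in structure.transitions:
            shape = float(rng.uniform(0.8, 1.6))
            scale = float(rng.uniform(1.0, 8.0))
            fits[tid] = FPSMFit.from_weibull(tid, shape, scale)
            haz[tid] = (lambda t, p=shape, s=scale: (p / s) * (t / s) ** (p - 1))
        grid = np.linspace(0.25, 3.0, 12)
        res = simulate_msm(fits, structure, ClockSpec("forward"),
                           PredictionRequest(time_grid=grid, n_sim=30_000, seed=18))
        aj = aalen_johansen_oracle(haz, structure, grid, step=1e-3)
        gap = np.abs(res.occupancy - aj)
        tol = 3 * np.maximum(res.occupancy_se, 1e-3)
        assert np.all(gap < tol)

    def test_reset_equals_forward_under_constant_hazards(self):
        """Memorylessness: the two clocks give the same occupancy."""
        C = make_structure("C")
        fits = constant_fits_C()
        grid = np.linspace(0.25, 3.0, 12)
        res_r = simulate_msm(fits, C, ClockSpec("reset"),
                             PredictionRequest(time_grid=grid, n_sim=40_000, seed=19))
        res_f = simulate_msm(fits, C, ClockSpec("forward"),
                             PredictionRequest(time_grid=grid, n_sim=40_000, seed=20))
        se = np.sqrt(res_r.occupancy_se ** 2 + res_f.occupancy_se ** 2)
        assert np.all(np.abs(res_r.occupancy - res_f.occupancy)
                      < 3 * np.maximum(se, 1e-3))


class TestConditionalAndUncertainty:
    def test_conditional_start_in_cycle_state(self):
        fits = constant_fits_C()
        C = make_structure("C")
        grid = np.linspace(0.25, 3.0, 12)
        res = simulate_msm(fits, C, ClockSpec("reset"),
                           PredictionRequest(time_grid=grid, n_sim=10_000,
                                             seed=30, start_state="cycle1"))
        i = res.states.index("cycle1")
        # pure death exit at rate 0.3: occupancy = exp(-0.3 t)
        expected = np.exp(-0.3 * grid)
        assert np.max(np.abs(res.occupancy[i] - expected)) \
            < 3 * max(res.occupancy_se[i].max(), 1e-3)

    def test_seed_reproducibility(self):
        fits = constant_fits_B()
        B = make_structure("B")
        req = PredictionRequest(time_grid=np.linspace(0.5, 2, 4), n_sim=5000, seed=77)
        r1 = simulate_msm(fits, B, ClockSpec("reset"), req)
        r2 = simulate_msm(fits, B, ClockSpec("reset"), req)
        assert np.array_equal(r1.occupancy, r2.occupancy)

    def test_no_ci_draws_means_no_bands(self):
        fits = constant_fits_B()
        B = make_structure("B")
        req = PredictionRequest(time_grid=np.linspace(0.5, 2, 4), n_sim=2000,
                                seed=5, ci_draws=0)
        res = parameter_uncertainty(fits, B, ClockSpec("reset"), req)
        assert res.ci_lower is None and res.ci_upper is None

    def test_bands_contain_point_estimate(self):
        rng = np.random.default_rng(40)
        fits = constant_fits_B()
        for f in fits.values():  # attach a plausible sampling covariance
            f.vcov = np.diag([0.01, 0.01])
        B = make_structure("B")
        req = PredictionRequest(time_grid=np.linspace(0.5, 2, 4), n_sim=2000,
                                seed=6, ci_draws=100)
        res = parameter_uncertainty(fits, B, ClockSpec("reset"), req)
        assert np.all(res.ci_lower <= res.occupancy + 1e-12)
        assert np.all(res.ci_upper >= res.occupancy - 1e-12)
        assert np.any(res.ci_upper > res.ci_lower)

    def test_occupancy_plot_written(self, tmp_path, f_result):
        from rxmsm import plot_occupancy
        _, _, res = f_result
        out = tmp_path / "occ.png"
        fig = plot_occupancy({"comparator": res}, path=out, states=["cycle1", "death"])
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt
        plt.close(fig)

    def test_missing_transition_fit_is_an_error(self):
        with pytest.raises(KeyError):
            simulate_msm({"start-cycle1": FPSMFit.from_constant("start-cycle1", 0.1)},
                         make_structure("B"), ClockSpec("reset"),
                         PredictionRequest(time_grid=np.array([1.0]), n_sim=1000, seed=1))
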