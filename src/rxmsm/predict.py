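"""Simulation-based prediction of multi-state measures.

Given one fitted transition-intensity model per allowed transition of a
structure, a large cohort of individuals with a fixed covariate pattern
is simulated forward through the state graph: in each occupied state,
candidate times to every allowed exit are drawn independently by inverse
transform on the fitted cumulative hazards (cause-specific hazards define
the joint exit law, so the minimum wins), until absorption or the
prediction horizon.  The simulated trajectories are aggregated into
state-occupation probabilities, the aggregate probability of being in any
medication cycle, restricted expected length of stay, and
probability-of-ever-visit curves, with Monte-Carlo standard errors and
optional parameter-uncertainty bands.

An independent product-integral (Aalen–Johansen) oracle for clock-forward
(Markov) hazards is included for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fpsm import FPSMFit
from .structures import DEATH, START, ClockSpec, StructureSpec


@dataclass
class PredictionRequest:
    """What to predict and under which simulated conditions.

    Times are in years.  ``start_state``/``start_time`` support
    conditional predictions (e.g. since entry into the 2nd cycle);
    under forward or mixed clocks a positive ``start_time`` acts as the
    left-truncation entry time of the conditioning state.
    """

    time_grid: np.ndarray
    case_status: str = "comparator"
    age_group: str = "60-69"
    start_state: str = START
    start_time: float = 0.0
    n_sim: int = 100_000
    seed: int = 12345
    ci_draws: int = 0

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.time_grid.ndim != 1 or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.n_sim < 1000:
            raise ValueError("n_sim must be >= 1000")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")


@dataclass
class PredictionResult:
    """Occupation probabilities and derived measures on the time grid."""

    time_grid: np.ndarray
    states: list[str]
    occupancy: np.ndarray            # (n_states, n_grid) proportions
    occupancy_se: np.ndarray
    in_cycle: np.ndarray             # aggregate P(in any medication cycle)
    in_cycle_se: np.ndarray
    length_of_stay: np.ndarray       # (n_states, n_grid) integral of occupancy
    in_cycle_los: np.ndarray
    ever_visit: np.ndarray           # (n_states, n_grid)
    n_sim: int = 0
    ci_lower: np.ndarray | None = None   # (n_states, n_grid) parameter bands
    ci_upper: np.ndarray | None = None
    in_cycle_ci: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.states):
            for j, t in enumerate(self.time_grid):
                rows.append((
                    t, s, self.occupancy[i, j], self.occupancy_se[i, j],
                    self.length_of_stay[i, j], self.ever_visit[i, j],
                    self.ci_lower[i, j] if self.ci_lower is not None else np.nan,
                    self.ci_upper[i, j] if self.ci_upper is not None else np.nan,
                ))
        return pd.DataFrame(
            rows, columns=["time", "state", "probability", "se",
                           "length_of_stay", "ever_visit", "lci", "uci"],
        )


def _is_cycle_state(state: str) -> bool:
    return state.startswith("cycle")


# ---------------------------------------------------------------------------
# Inverse-transform event-time draws


def draw_transition_time(fit: FPSMFit, case_status: str, age_group: str,
                         t0, horizon: float, u, tol: float = 1e-10) -> np.ndarray:
    """Solve H(t) - H(t0) = -log(u) on the fit's own timescale.

    Vectorized bisection on log time over (t0, horizon]; entries whose
    total hazard over the horizon falls short of the target are returned
    as ``inf`` (no event before the horizon).  ``t0 = 0`` means no
    conditioning (H(0) = 0).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    t0 = np.broadcast_to(np.atleast_1d(np.asarray(t0, dtype=float)), u.shape).copy()
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in (0, 1)")
    target = -np.log(u)
    H = lambda t: fit.cumhaz(t, case_status, age_group)
    H0 = np.where(t0 > 0, H(np.clip(t0, 1e-12, None)), 0.0)
    if not np.all(np.isfinite(H0)):
        raise FloatingPointError("non-finite cumulative hazard at entry times")
    need = H0 + target
    Hh = H(np.full(u.shape, horizon))
    if not np.all(np.isfinite(Hh)):
        raise FloatingPointError("non-finite cumulative hazard at the horizon")
    out = np.full(u.shape, np.inf)
    solvable = Hh >= need
    if not solvable.any():
        return out
    lo = np.log(np.clip(t0[solvable], 1e-12, None))
    hi = np.full(lo.shape, np.log(horizon))
    tgt = need[solvable]
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        above = H(np.exp(mid)) >= tgt
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
        if np.max(hi - lo) < 1e-14:
            break
    out[solvable] = np.exp(hi)
    return out


# ---------------------------------------------------------------------------
# Microsimulation engine


def simulate_msm(fits: dict[str, FPSMFit], structure: StructureSpec,
                 clock: ClockSpec, request: PredictionRequest,
                 max_transitions: int = 1000) -> PredictionResult:
    """Microsimulate trajectories through the structure and aggregate.

    ``fits`` maps every non-absorbing transition id of the structure to a
    hazard model.  Occupation probabilities sum to one exactly at every
    grid time (they are proportions of the same simulated individuals).
    """
    for _, _, tid in structure.transitions:
        if tid not in fits:
            raise KeyError(f"missing fitted model for transition {tid}")
    grid = request.time_grid
    horizon = float(grid[-1])
    n = request.n_sim
    states = list(structure.states)
    s_index = {s: i for i, s in enumerate(states)}
    n_states, n_grid = len(states), grid.size
    rng = np.random.default_rng(request.seed)

    if request.start_state in structure.absorbing:
        import warnings
        warnings.warn("absorbing start state: trivial prediction")
    start_idx = s_index[request.start_state]

    # difference-array accumulation of occupancy counts on the grid
    diff = np.zeros((n_states, n_grid + 1), dtype=np.int64)
    first_entry = np.full((n_states, n), np.inf)

    state = np.full(n, start_idx)
    # absolute clock time; under pure reset predictions the grid is time
    # since the conditioning entry, so simulation starts at 0 there
    t_abs = np.full(n, float(request.start_time))
    entry_abs = t_abs.copy()
    active = np.ones(n, dtype=bool)
    first_entry[start_idx, :] = t_abs

    def record(sl, a, b):
        """Occupancy of state sl over [a, b) for a vector of individuals."""
        i0 = np.searchsorted(grid, a, side="left")
        i1 = np.searchsorted(grid, b, side="left")
        np.add.at(diff[sl], i0, 1)
        np.add.at(diff[sl], i1, -1)

    for _ in range(max_transitions):
        if not active.any():
            break
        for si in np.unique(state[active]):
            s = states[si]
            mask = active & (state == si)
            idx = np.flatnonzero(mask)
            outs = structure.out_transitions(s)
            if not outs:
                # absorbing or dead-end non-death state: occupy to horizon
                record(si, t_abs[idx], np.full(idx.size, np.inf))
                active[idx] = False
                continue
            cand = np.full((len(outs), idx.size), np.inf)
            for j, (frm, to, tid) in enumerate(outs):
                u = rng.uniform(size=idx.size)
                if clock.is_forward(to):
                    t_draw = draw_transition_time(
                        fits[tid], request.case_status, request.age_group,
                        t0=t_abs[idx], horizon=horizon, u=u)
                    cand[j] = t_draw  # already absolute
                else:
                    d_draw = draw_transition_time(
                        fits[tid], request.case_status, request.age_group,
                        t0=0.0, horizon=horizon, u=u)
                    cand[j] = t_abs[idx] + d_draw
            winner = np.argmin(cand, axis=0)
            t_next = cand[winner, np.arange(idx.size)]
            censored = ~np.isfinite(t_next) | (t_next > horizon)
            # censored-in-state until the horizon
            record(si, t_abs[idx[censored]], np.full(censored.sum(), np.inf))
            active[idx[censored]] = False
            moved = ~censored
            if moved.any():
                im = idx[moved]
                record(si, t_abs[im], t_next[moved])
                dest = np.array([s_index[outs[w][1]] for w in winner[moved]])
                t_abs[im] = t_next[moved]
                entry_abs[im] = t_next[moved]
                state[im] = dest
                for dsts in np.unique(dest):
                    sel = im[dest == dsts]
                    first_entry[dsts, sel] = np.minimum(first_entry[dsts, sel], t_abs[sel])
                # absorbing destinations occupy to the horizon immediately
                for dsts in np.unique(dest):
                    if states[dsts] in structure.absorbing:
                        sel = im[dest == dsts]
                        record(dsts, t_abs[sel], np.full(sel.size, np.inf))
                        active[sel] = False
    else:
        import warnings
        n_left = int(active.sum())
        warnings.warn(f"{n_left} trajectories exceeded {max_transitions} transitions; "
                      "censored in current state")
        for si in np.unique(state[active]):
            idx = np.flatnonzero(active & (state == si))
            record(si, t_abs[idx], np.full(idx.size, np.inf))
        active[:] = False

    counts = np.cumsum(diff[:, :-1], axis=1)
    occ = counts / n
    occ_se = np.sqrt(occ * (1 - occ) / n)
    cyc_states = [i for i, s in enumerate(states) if _is_cycle_state(s)]
    in_cycle = occ[cyc_states].sum(axis=0)
    in_cycle_se = np.sqrt(in_cycle * (1 - in_cycle) / n)

    from scipy.integrate import cumulative_trapezoid
    los = np.concatenate(
        [np.zeros((n_states, 1)), cumulative_trapezoid(occ, grid, axis=1)], axis=1
    )
    # grids that do not start at the origin still measure LOS from the start
    if grid[0] > request.start_time:
        los += occ[:, :1] * (grid[0] - request.start_time)
    in_cycle_los = los[cyc_states].sum(axis=0)

    ever = np.empty((n_states, n_grid))
    for i in range(n_states):
        ever[i] = np.searchsorted(np.sort(first_entry[i]), grid, side="right") / n

    return PredictionResult(
        time_grid=grid, states=states, occupancy=occ, occupancy_se=occ_se,
        in_cycle=in_cycle, in_cycle_se=in_cycle_se,
        length_of_stay=los, in_cycle_los=in_cycle_los, ever_visit=ever, n_sim=n,
    )


def plot_occupancy(results: dict[str, PredictionResult], path=None,
                   states: list[str] | None = None):
    """Plot state-occupancy curves, one panel per state, one line per
    covariate pattern (the keys of ``results``); the aggregate in-cycle
    probability gets its own panel.  Returns the figure; saves to
    ``path`` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = next(iter(results.values()))
    states = states or [s for s in first.states if s != "start"]
    panels = states + ["any medication cycle"]
    ncol = min(3, len(panels))
    nrow = -(-len(panels) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharex=True)
    for ax, panel in zip(axes.flat, panels):
        for label, res in results.items():
            if panel == "any medication cycle":
                y, se = res.in_cycle, res.in_cycle_se
            else:
                i = res.states.index(panel)
                y, se = res.occupancy[i], res.occupancy_se[i]
            ax.plot(res.time_grid, y, label=label)
            ax.fill_between(res.time_grid, y - 1.96 * se, y + 1.96 * se, alpha=0.2)
        ax.set_title(panel)
        ax.set_xlabel("years")
        ax.set_ylabel("probability")
    axes.flat[0].legend(frameon=False)
    for ax in axes.flat[len(panels):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


# ---------------------------------------------------------------------------
# Aalen–Johansen product-integral oracle (clock-forward hazards)


def aalen_johansen_oracle(hazards: dict[str, callable], structure: StructureSpec,
                          grid, start_state: str = START, step: float = 1e-3,
                          max_refine: int = 6) -> np.ndarray:
    """State-occupation probabilities by product integration.

    ``hazards`` maps transition ids to callables h(t) on the common
    forward timescale.  Uses a second-order (midpoint exponential-free)
    scheme P(t+h) = P(t) (I + Q h + (Q h)^2 / 2) with Q evaluated at the
    interval midpoint, refining the step when a diagonal overshoots.
    Returns an array (n_states, n_grid) for a start in ``start_state``.
    """
    grid = np.asarray(grid, dtype=float)
    states = list(structure.states)
    s_index = {s: i for i, s in enumerate(states)}
    m = len(states)
    trans = [(s_index[a], s_index[b], tid) for a, b, tid in structure.transitions]

    def Q_at(t):
        Q = np.zeros((m, m))
        for ia, ib, tid in trans:
            h = float(hazards[tid](t))
            Q[ia, ib] += h
            Q[ia, ia] -= h
        return Q

    for attempt in range(max_refine):
        h = step / (2 ** attempt)
        p = np.zeros(m)
        p[s_index[start_state]] = 1.0
        out = np.empty((m, grid.size))
        t = 0.0
        ok = True
        for j, tg in enumerate(grid):
            while t < tg - 1e-12:
                dt = min(h, tg - t)
                Q = Q_at(t + dt / 2)
                if np.any(1.0 + np.diag(Q) * dt < 0):
                    ok = False
                    break
                A = np.eye(m) + Q * dt + (Q @ Q) * (dt * dt / 2)
                p = p @ A
                t += dt
            if not ok:
                break
            out[:, j] = p
        if ok:
            # guard against accumulated drift
            out = np.clip(out, 0.0, None)
            out /= out.sum(axis=0, keepdims=True)
            return out
    raise RuntimeError("product integration failed to stabilize; step too coarse")


# ---------------------------------------------------------------------------
# Parameter uncertainty by redrawing coefficients


def _perturbed_fit(fit: FPSMFit, rng: np.random.Generator) -> FPSMFit:
    if fit.vcov is None:
        return fit
    V = np.asarray(fit.vcov)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        # nearest-PD repair: floor the eigenvalues
        w, U = np.linalg.eigh((V + V.T) / 2)
        import warnings
        warnings.warn(f"{fit.transition_id}: vcov not positive definite; repaired")
        L = U @ np.diag(np.sqrt(np.clip(w, 1e-12, None)))
    coef = fit.coef + L @ rng.standard_normal(fit.coef.size)
    out = FPSMFit(
        transition_id=fit.transition_id, basis=fit.basis, td_basis=fit.td_basis,
        coef=coef, coef_names=fit.coef_names, covariate_names=fit.covariate_names,
    )
    return out


def parameter_uncertainty(fits: dict[str, FPSMFit], structure: StructureSpec,
                          clock: ClockSpec, request: PredictionRequest,
                          alpha: float = 0.05) -> PredictionResult:
    """Percentile CI bands from redrawn coefficient vectors.

    Each draw perturbs every transition's coefficients from its estimated
    sampling distribution N(theta_hat, vcov) independently across
    transitions, re-simulates, and the pointwise percentile band across
    draws is attached to the point-estimate result.  ``ci_draws = 0``
    returns the plain point estimates.
    """
    point = simulate_msm(fits, structure, clock, request)
    if request.ci_draws == 0:
        return point
    if request.ci_draws < 100:
        raise ValueError("ci_draws must be 0 or >= 100")
    rng = np.random.default_rng([request.seed, 0xC1])
    occ_draws = np.empty((request.ci_draws, len(point.states), point.time_grid.size))
    cyc_draws = np.empty((request.ci_draws, point.time_grid.size))
    for b in range(request.ci_draws):
        pfits = {tid: _perturbed_fit(f, rng) for tid, f in fits.items()}
        req_b = PredictionRequest(
            time_grid=request.time_grid, case_status=request.case_status,
            age_group=request.age_group, start_state=request.start_state,
            start_time=request.start_time, n_sim=request.n_sim,
            seed=int(rng.integers(2 ** 31)), ci_draws=0,
        )
        res_b = simulate_msm(pfits, structure, clock, req_b)
        occ_draws[b] = res_b.occupancy
        cyc_draws[b] = res_b.in_cycle
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    point.ci_lower = np.percentile(occ_draws, lo, axis=0)
    point.ci_upper = np.percentile(occ_draws, hi, axis=0)
    point.in_cycle_ci = (
        np.percentile(cyc_draws, lo, axis=0),
        np.percentile(cyc_draws, hi, axis=0),
    )
    # bands should contain the point estimate; widen by MC jitter if needed
    point.ci_lower = np.minimum(point.ci_lower, point.occupancy)
    point.ci_upper = np.maximum(point.ci_upper, point.occupancy)
    return point
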