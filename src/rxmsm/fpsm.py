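"""Flexible parametric survival models for transition intensities.

Royston–Parmar models on the log cumulative-hazard scale:

    log H(t | x) = s(ln t; gamma) + x' beta + case * s_td(ln t; delta)

where ``s`` is a restricted cubic spline (linear beyond its boundary
knots) with ``df`` basis columns plus an intercept, ``x`` collects the
case-status and age-group covariates (optionally with interactions) and
``s_td`` is a lower-dimensional spline carrying a time-dependent
(non-proportional) effect of case status.  The hazard follows by
differentiation,

    h(t) = H(t) * ds/d(ln t) / t,

and the log-likelihood with delayed entry (left truncation at t0) is

    sum_i  d_i * ln h(t_i) - H(t_i) + H(t0_i).

With ``df = 1`` and no time-dependent effect the model is exactly a
Weibull proportional-hazards model, which the tests exploit as an
independent oracle.  Joint estimation across transitions with shared or
proportional parameter blocks (the "emulated bidirectional" restrictions)
is provided by :func:`fit_constrained`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

AGE_GROUPS = ("<50", "50-59", "60-69", "70+")

_LOG_EPS = 1e-10  # floor for the spline slope inside the log-hazard


# ---------------------------------------------------------------------------
# Restricted cubic splines on log time


@dataclass(frozen=True)
class SplineBasisSpec:
    """Knots on the log-time scale; ``df`` basis columns (no intercept).

    ``df = 1`` keeps only the linear term ln t (two boundary knots, no
    interior); ``df = m`` adds ``m - 1`` interior knots and cubic terms
    restricted to be linear beyond the boundaries.
    """

    knots: tuple[float, ...]

    def __post_init__(self):
        k = np.asarray(self.knots)
        if k.size < 2 or np.any(np.diff(k) <= 0):
            raise ValueError("knots must be >= 2 strictly increasing values")

    @property
    def df(self) -> int:
        return len(self.knots) - 1


def place_knots(event_times, df: int) -> SplineBasisSpec:
    """Boundary knots at the extreme log event times; interior knots at
    equally spaced centiles of the log uncensored event times
    (df = 4 -> 25/50/75th)."""
    t = np.asarray(event_times, dtype=float)
    t = t[t > 0]
    distinct = np.unique(t)
    if distinct.size < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct uncensored event times for "
            f"df={df} (got {distinct.size}); consider a lower df"
        )
    x = np.log(t)
    lo, hi = float(x.min()), float(x.max())
    if df == 1:
        return SplineBasisSpec((lo, hi))
    qs = np.linspace(0, 100, df + 1)[1:-1]
    interior = np.percentile(x, qs)
    knots = np.concatenate([[lo], interior, [hi]])
    knots = np.unique(knots)
    if knots.size != df + 1:
        raise ValueError("tied centile knots; consider a lower df")
    return SplineBasisSpec(tuple(knots))


def rcs_basis(x, spec: SplineBasisSpec):
    """Evaluate the restricted cubic spline basis and its derivative.

    Returns (B, dB), each of shape (n, df).  The first column is ``x``
    itself; column j >= 2 is the restricted cubic term for interior knot
    j-1, which is linear in ``x`` beyond the boundary knots.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(spec.knots)
    kmin, kmax = knots[0], knots[-1]
    df = spec.df
    B = np.empty((x.size, df))
    dB = np.empty((x.size, df))
    B[:, 0] = x
    dB[:, 0] = 1.0
    span = kmax - kmin
    for j, kj in enumerate(knots[1:-1], start=1):
        lam = (kmax - kj) / span
        p = np.clip(x - kj, 0, None)
        pmin = np.clip(x - kmin, 0, None)
        pmax = np.clip(x - kmax, 0, None)
        B[:, j] = p ** 3 - lam * pmin ** 3 - (1 - lam) * pmax ** 3
        dB[:, j] = 3 * (p ** 2 - lam * pmin ** 2 - (1 - lam) * pmax ** 2)
    return B, dB


# ---------------------------------------------------------------------------
# Model specification and design construction


@dataclass(frozen=True)
class ModelSpec:
    """What enters the linear predictor of one transition model.

    baseline_df : spline df of the baseline log cumulative hazard
    td_df : df of the time-dependent case-status effect (0 = proportional)
    include_case / include_age / include_interactions : covariate blocks
    """

    baseline_df: int = 4
    td_df: int = 0
    include_case: bool = True
    include_age: bool = True
    include_interactions: bool = True

    def __post_init__(self):
        if self.baseline_df < 1:
            raise ValueError("baseline_df must be >= 1")
        if self.td_df < 0:
            raise ValueError("td_df must be >= 0")


def build_covariates(rows: pd.DataFrame, spec: ModelSpec, force_names=None):
    """Covariate matrix (n, p) and names; constant columns are dropped
    unless ``force_names`` pins the column set (used by joint fits so that
    every member of a constrained group shares one design)."""
    n = len(rows)
    cols, names = [], []
    case = (rows["case_status"].to_numpy() == "case").astype(float)
    if spec.include_case:
        cols.append(case)
        names.append("case")
    if spec.include_age:
        age = rows["age_group"].to_numpy()
        for g in AGE_GROUPS[1:]:
            dummy = (age == g).astype(float)
            cols.append(dummy)
            names.append(f"age[{g}]")
            if spec.include_interactions and spec.include_case:
                cols.append(case * dummy)
                names.append(f"case:age[{g}]")
    if not cols:
        return np.empty((n, 0)), [], case
    X = np.column_stack(cols)
    if force_names is not None:
        keep = [names.index(nm) for nm in force_names]
    else:
        keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        if dropped:
            logger.info("dropping constant covariate columns: %s", dropped)
    return X[:, keep], [names[i] for i in keep], case


def covariate_vector(names: list[str], case_status: str, age_group: str) -> np.ndarray:
    """Covariate vector for one pattern, in the fit's column order."""
    case = 1.0 if case_status == "case" else 0.0
    vals = []
    for nm in names:
        if nm == "case":
            vals.append(case)
        elif nm.startswith("age["):
            vals.append(1.0 if nm == f"age[{age_group}]" else 0.0)
        elif nm.startswith("case:age["):
            vals.append(case if nm == f"case:age[{age_group}]" else 0.0)
        else:
            raise ValueError(f"unknown covariate name {nm!r}")
    return np.asarray(vals)


# ---------------------------------------------------------------------------
# Fitted model container


@dataclass
class FPSMFit:
    """One fitted (or analytically constructed) transition model."""

    transition_id: str
    basis: SplineBasisSpec
    td_basis: SplineBasisSpec | None
    coef: np.ndarray  # [intercept, gamma(df), beta(p), delta(td_df)]
    coef_names: list[str]
    covariate_names: list[str]
    loglik: float = np.nan
    vcov: np.ndarray | None = None
    converged: bool = True
    grad_norm: float = np.nan
    n: int = 0
    n_events: int = 0

    # -- linear-predictor pieces -------------------------------------------
    def _split(self):
        df = self.basis.df
        p = len(self.covariate_names)
        g0 = self.coef[0]
        gamma = self.coef[1:1 + df]
        beta = self.coef[1 + df:1 + df + p]
        delta = self.coef[1 + df + p:]
        return g0, gamma, beta, delta

    def linear_predictor(self, t, case_status="comparator", age_group="<50"):
        """eta(ln t) and its derivative d eta / d ln t for one pattern."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t <= 0):
            raise ValueError("t must be positive")
        g0, gamma, beta, delta = self._split()
        x = np.log(t)
        B, dB = rcs_basis(x, self.basis)
        xb = covariate_vector(self.covariate_names, case_status, age_group)
        eta = g0 + B @ gamma + float(xb @ beta)
        etap = dB @ gamma
        if self.td_basis is not None and delta.size:
            case = 1.0 if case_status == "case" else 0.0
            C, dC = rcs_basis(x, self.td_basis)
            eta = eta + case * (C @ delta)
            etap = etap + case * (dC @ delta)
        return eta, etap

    def cumhaz(self, t, case_status="comparator", age_group="<50"):
        eta, _ = self.linear_predictor(t, case_status, age_group)
        return np.exp(np.clip(eta, -700, 700))

    def hazard(self, t, case_status="comparator", age_group="<50"):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        eta, etap = self.linear_predictor(t, case_status, age_group)
        return np.exp(eta) * etap / t

    def survival(self, t, case_status="comparator", age_group="<50", t_entry=0.0):
        S = np.exp(-self.cumhaz(t, case_status, age_group))
        if t_entry > 0:
            S0 = np.exp(-self.cumhaz(t_entry, case_status, age_group))
            S = S / S0
        return S

    # -- analytic constructors (oracle plumbing and microsimulation tests) --
    @classmethod
    def from_weibull(cls, transition_id: str, shape: float, scale: float,
                     loghr_case: float = 0.0) -> "FPSMFit":
        """Exact Weibull model H(t) = (t/scale)^shape * exp(loghr*case)."""
        basis = SplineBasisSpec((np.log(1e-8), np.log(1e8)))
        names = ["case"] if loghr_case != 0.0 else []
        coef = [-shape * np.log(scale), shape] + ([loghr_case] if names else [])
        return cls(
            transition_id=transition_id, basis=basis, td_basis=None,
            coef=np.asarray(coef, dtype=float),
            coef_names=["intercept", "rcs1"] + names,
            covariate_names=names,
        )

    @classmethod
    def from_constant(cls, transition_id: str, rate: float,
                      loghr_case: float = 0.0) -> "FPSMFit":
        """Exact exponential model with constant hazard ``rate`` (per year)."""
        return cls.from_weibull(transition_id, 1.0, 1.0 / rate, loghr_case)

    def to_dict(self) -> dict:
        return {
            "transition_id": self.transition_id,
            "knots": list(self.basis.knots),
            "td_knots": list(self.td_basis.knots) if self.td_basis else None,
            "coef": {n: float(c) for n, c in zip(self.coef_names, self.coef)},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "n": self.n,
            "n_events": self.n_events,
            "vcov": self.vcov.tolist() if self.vcov is not None else None,
        }


def evaluate(fit: FPSMFit, t, case_status="comparator", age_group="<50",
             t_entry: float = 0.0):
    """(hazard, cumulative hazard, survival) at times ``t`` for one pattern."""
    h = fit.hazard(t, case_status, age_group)
    H = fit.cumhaz(t, case_status, age_group)
    S = fit.survival(t, case_status, age_group, t_entry=t_entry)
    return h, H, S


# ---------------------------------------------------------------------------
# Likelihood machinery


def _safe_log(v):
    """log with a linear extension below _LOG_EPS (keeps gradients finite
    while pushing the optimizer back to positive spline slopes)."""
    v = np.asarray(v, dtype=float)
    out = np.where(v > _LOG_EPS, np.log(np.clip(v, _LOG_EPS, None)),
                   np.log(_LOG_EPS) + (v - _LOG_EPS) / _LOG_EPS)
    return out


def _safe_log_grad(v):
    v = np.asarray(v, dtype=float)
    return np.where(v > _LOG_EPS, 1.0 / np.clip(v, _LOG_EPS, None), 1.0 / _LOG_EPS)


class _TransitionBlock:
    """Design matrices of one transition mapped into a global parameter vector."""

    def __init__(self, rows: pd.DataFrame, model_spec: ModelSpec,
                 basis: SplineBasisSpec, td_basis: SplineBasisSpec | None,
                 idx: np.ndarray, force_names=None):
        t1 = rows["t_exit"].to_numpy(dtype=float)
        t0 = rows["t_entry"].to_numpy(dtype=float)
        d = rows["event"].to_numpy(dtype=float)
        if np.any(t1 <= t0) or np.any(t0 < 0):
            raise ValueError("require t_exit > t_entry >= 0")
        X, names, case = build_covariates(rows, model_spec, force_names=force_names)
        self.covariate_names = names
        self.basis, self.td_basis = basis, td_basis

        def design(tv, mask=None):
            sel = slice(None) if mask is None else mask
            x = np.log(tv[sel])
            B, dB = rcs_basis(x, basis)
            parts = [np.ones((B.shape[0], 1)), B, X[sel]]
            dparts = [np.zeros((B.shape[0], 1)), dB, np.zeros_like(X[sel])]
            if td_basis is not None:
                C, dC = rcs_basis(x, td_basis)
                cs = case[sel][:, None]
                parts.append(cs * C)
                dparts.append(cs * dC)
            return np.hstack(parts), np.hstack(dparts)

        self.Z, self.Zx = design(t1)
        self.d = d
        self.logt = np.log(t1)
        delayed = t0 > 0
        self.Z0, _ = design(t0, mask=delayed) if delayed.any() else (np.empty((0, self.Z.shape[1])), None)
        self.idx = idx  # global column index per local column (plus offsets appended)
        self.offset_col: int | None = None  # global index of an additive intercept offset

    @property
    def n_params(self) -> int:
        return self.Z.shape[1]

    def nll_grad(self, theta_global: np.ndarray):
        th = theta_global[self.idx]
        off = theta_global[self.offset_col] if self.offset_col is not None else 0.0
        eta = np.clip(self.Z @ th + off, -300, 300)  # overflow guard in line search
        etap = self.Zx @ th
        H = np.exp(eta)
        ev = self.d > 0
        ll = np.sum(self.d * (eta + _safe_log(etap) - self.logt)) - np.sum(H)
        grad = np.zeros_like(theta_global)
        w = self.d * _safe_log_grad(etap)
        gl = self.Z.T @ self.d + self.Zx.T @ w - self.Z.T @ H
        g_off = float(np.sum(self.d) - np.sum(H))
        if len(self.Z0):
            th0 = theta_global[self.idx]
            eta0 = np.clip(self.Z0 @ th0 + off, -300, 300)
            H0 = np.exp(eta0)
            ll += np.sum(H0)
            gl += self.Z0.T @ H0
            g_off += float(np.sum(H0))
        np.add.at(grad, self.idx, gl)
        if self.offset_col is not None:
            grad[self.offset_col] += g_off
        return -ll, -grad


def _start_values(blocks: list[_TransitionBlock], n_params: int) -> np.ndarray:
    """Exponential-fit starting values per block: intercept = log crude rate,
    unit coefficient on the linear log-time column, zeros elsewhere."""
    theta = np.zeros(n_params)
    for b in blocks:
        # delayed entry only shortens exposure; total exit time is close
        # enough for a starting value
        exposure = max(np.sum(np.exp(b.logt)), 1e-12)
        rate = max(np.sum(b.d), 0.5) / exposure
        theta[b.idx[0]] = np.log(rate)
        theta[b.idx[1]] = 1.0
    return theta


def _optimize(nll_grad, theta0: np.ndarray):
    res = optimize.minimize(nll_grad, theta0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 1000})
    x, (f, g) = res.x, nll_grad(res.x)
    gn = float(np.max(np.abs(g)))
    # Newton polish with the numeric Hessian: BFGS routinely stalls a few
    # orders of magnitude above the score tolerance
    for _ in range(8):
        if gn < 1e-7:
            break
        H = _numeric_hessian(nll_grad, x)
        try:
            step = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(H, g, rcond=None)[0]
        scale = 1.0
        improved = False
        for _ in range(20):
            x_new = x + scale * step
            f_new, g_new = nll_grad(x_new)
            gn_new = float(np.max(np.abs(g_new)))
            if np.isfinite(f_new) and (f_new < f or gn_new < gn):
                x, f, g, gn = x_new, f_new, g_new, gn_new
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
    res.x, res.fun, res.jac = x, f, g
    return res, gn


def _numeric_hessian(nll_grad, theta: np.ndarray) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = nll_grad(tp)
        _, gm = nll_grad(tm)
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def _vcov_from_hessian(H: np.ndarray):
    try:
        return np.linalg.inv(H), True
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian; using pseudo-inverse for vcov")
        return np.linalg.pinv(H), False


# ---------------------------------------------------------------------------
# Single-transition fit


def fit_transition(rows: pd.DataFrame, model_spec: ModelSpec = ModelSpec(),
                   transition_id: str | None = None,
                   basis: SplineBasisSpec | None = None) -> FPSMFit:
    """Maximum likelihood fit of one transition's Royston–Parmar model.

    ``rows`` must carry t_entry, t_exit, event, case_status, age_group.
    Knots default to centile placement on the uncensored exit times.
    Raises if no events are present or the optimizer fails to reach a
    small gradient norm.
    """
    if transition_id is None:
        tids = rows["transition_id"].unique() if "transition_id" in rows else ["?"]
        if len(tids) != 1:
            raise ValueError("rows contain multiple transitions; pass them separately")
        transition_id = str(tids[0])
    d = rows["event"].to_numpy()
    if d.sum() < 1:
        raise ValueError(f"{transition_id}: no events; cannot fit")
    events = rows.loc[rows["event"] == 1, "t_exit"].to_numpy(dtype=float)
    if basis is None:
        basis = place_knots(events, model_spec.baseline_df)
    td_basis = place_knots(events, model_spec.td_df) if model_spec.td_df else None

    block = _TransitionBlock(rows, model_spec, basis, td_basis, idx=None)
    p = block.n_params
    block.idx = np.arange(p)
    nll_grad = lambda th: block.nll_grad(th)
    theta0 = _start_values([block], p)
    res, gn = _optimize(nll_grad, theta0)
    converged = gn < 1e-5
    if not converged:
        logger.warning("%s: optimizer gradient norm %.2e", transition_id, gn)
    Hess = _numeric_hessian(nll_grad, res.x)
    vcov, _ = _vcov_from_hessian(Hess)

    names = (["intercept"] + [f"rcs{j}" for j in range(1, basis.df + 1)]
             + block.covariate_names
             + [f"td{j}" for j in range(1, (td_basis.df if td_basis else 0) + 1)])
    fit = FPSMFit(
        transition_id=transition_id, basis=basis, td_basis=td_basis,
        coef=res.x, coef_names=names, covariate_names=block.covariate_names,
        loglik=-res.fun, vcov=vcov, converged=converged, grad_norm=gn,
        n=len(rows), n_events=int(d.sum()),
    )
    _check_fitted_hazard(fit, rows)
    return fit


def _check_fitted_hazard(fit: FPSMFit, rows: pd.DataFrame) -> None:
    """Reject fits with a negative hazard at observed event times."""
    ev = rows[rows["event"] == 1]
    if not len(ev):
        return
    for (cs, ag), grp in ev.groupby(["case_status", "age_group"]):
        _, etap = fit.linear_predictor(grp["t_exit"].to_numpy(), cs, ag)
        if np.any(etap <= 0):
            fit.converged = False
            logger.warning(
                "%s: non-monotone cumulative hazard at %d event time(s)",
                fit.transition_id, int(np.sum(etap <= 0)),
            )
            return


# ---------------------------------------------------------------------------
# Constrained joint fit (structure G)


@dataclass
class JointFitResult:
    """Joint constrained fit across the transitions of one structure."""

    fits: dict[str, FPSMFit]
    loglik: float
    theta: np.ndarray
    param_names: list[str]
    vcov: np.ndarray
    converged: bool
    grad_norm: float
    offsets: dict[str, float] = field(default_factory=dict)

    def offset_se(self, transition_id: str) -> float:
        j = self.param_names.index(f"offset[{transition_id}]")
        return float(np.sqrt(self.vcov[j, j]))


def fit_constrained(rows: pd.DataFrame, structure, model_spec: ModelSpec = ModelSpec(),
                    td_transitions: tuple[str, ...] = ("start-cycle1", "start-death"),
                    ) -> JointFitResult:
    """Jointly fit all transitions of a structure under its constraint tags.

    Transitions in a ``shared`` group use one common parameter vector;
    transitions in a ``proportional`` group share the baseline spline and
    covariate effects, with additive log-scale intercept offsets for every
    member after the first.  Ungrouped transitions get their own block.
    Time-dependent case effects are restricted to ``td_transitions``
    (start-of-follow-up exits, per the emulated-bidirectional convention).
    An empty ``constraint_groups`` reproduces per-transition fits.
    """
    tids = list(structure.transition_ids)
    group_of = {}
    for gname, g in structure.constraint_groups.items():
        for tid in g["transitions"]:
            group_of[tid] = (gname, g["kind"])

    # estimation units: (unit_name, kind, member tids in order)
    units, seen = [], set()
    for tid in tids:
        if tid in seen:
            continue
        if tid in group_of:
            gname, kind = group_of[tid]
            members = [m for m in structure.constraint_groups[gname]["transitions"] if m in tids]
            units.append((gname, kind, members))
            seen.update(members)
        else:
            units.append((tid, "own", [tid]))
            seen.add(tid)

    blocks: list[_TransitionBlock] = []
    block_tids: list[str] = []
    param_names: list[str] = []
    offsets_index: dict[str, int] = {}
    cursor = 0

    def spec_for(tid: str) -> ModelSpec:
        td = model_spec.td_df if tid in td_transitions else 0
        return replace(model_spec, td_df=td)

    placeholder_fits: dict[str, FPSMFit] = {}
    for unit_name, kind, members in units:
        sub_all = rows[rows["transition_id"].isin(members)]
        events = sub_all.loc[sub_all["event"] == 1, "t_exit"].to_numpy(dtype=float)
        if events.size == 0:
            # no events anywhere in the unit: the likelihood is maximized in
            # the limit of a vanishing hazard (zero contribution); exclude
            # the unit and return a near-zero placeholder hazard
            logger.warning("unit %s: no events; substituting near-zero hazard",
                           unit_name)
            for tid in members:
                placeholder_fits[tid] = FPSMFit.from_constant(tid, rate=1e-10)
            continue
        if np.unique(events).size < 2:
            # a single event time cannot identify even the two-parameter
            # df=1 model; substitute the crude-rate exponential MLE
            exposure = float((sub_all["t_exit"] - sub_all["t_entry"]).sum())
            rate = events.size / max(exposure, 1e-12)
            logger.warning("unit %s: single event time; substituting crude "
                           "exponential rate %.3g", unit_name, rate)
            for tid in members:
                placeholder_fits[tid] = FPSMFit.from_constant(tid, rate=rate)
            continue
        mspec = spec_for(members[0])
        basis = place_knots(events, mspec.baseline_df)
        td_basis = place_knots(events, mspec.td_df) if mspec.td_df else None

        # pin the covariate column set on the pooled rows of the unit
        _, unit_covnames, _ = build_covariates(sub_all, mspec)

        if kind == "shared":
            blk = _TransitionBlock(sub_all, mspec, basis, td_basis, idx=None,
                                   force_names=unit_covnames)
            blk.idx = np.arange(cursor, cursor + blk.n_params)
            blocks.append(blk)
            block_tids.append(unit_name)
            param_names += [f"{unit_name}:{nm}" for nm in _block_names(blk, basis, td_basis)]
            cursor += blk.n_params
        elif kind == "proportional":
            core_idx = None
            for j, tid in enumerate(members):
                sub = rows[rows["transition_id"] == tid]
                if not len(sub):
                    continue
                blk = _TransitionBlock(sub, mspec, basis, td_basis, idx=None,
                                       force_names=unit_covnames)
                if core_idx is None:
                    core_idx = np.arange(cursor, cursor + blk.n_params)
                    param_names += [f"{unit_name}:{nm}" for nm in _block_names(blk, basis, td_basis)]
                    cursor += blk.n_params
                blk.idx = core_idx
                if j > 0:
                    blk.offset_col = cursor
                    offsets_index[tid] = cursor
                    param_names.append(f"offset[{tid}]")
                    cursor += 1
                blocks.append(blk)
                block_tids.append(tid)
        else:  # own
            tid = members[0]
            sub = rows[rows["transition_id"] == tid]
            blk = _TransitionBlock(sub, mspec, basis, td_basis, idx=None)
            blk.idx = np.arange(cursor, cursor + blk.n_params)
            blocks.append(blk)
            block_tids.append(tid)
            param_names += [f"{tid}:{nm}" for nm in _block_names(blk, basis, td_basis)]
            cursor += blk.n_params

    n_params = cursor

    def joint_nll_grad(theta):
        tot, grad = 0.0, np.zeros(n_params)
        for blk in blocks:
            nll, g = blk.nll_grad(theta)
            tot += nll
            grad += g
        return tot, grad

    theta0 = np.zeros(n_params)
    # exponential start per block core (first block of each unit sets it)
    initialized = set()
    for blk in blocks:
        key = int(blk.idx[0])
        if key in initialized:
            continue
        initialized.add(key)
        exposure = max(np.sum(np.exp(blk.logt)), 1e-12)
        rate = max(np.sum(blk.d), 0.5) / exposure
        theta0[blk.idx[0]] = np.log(rate)
        theta0[blk.idx[1]] = 1.0

    res, gn = _optimize(joint_nll_grad, theta0)
    converged = gn < 1e-5
    if not converged:
        logger.warning("constrained fit: gradient norm %.2e", gn)
    Hess = _numeric_hessian(joint_nll_grad, res.x)
    vcov, pd_ok = _vcov_from_hessian(Hess)
    if not pd_ok:
        raise ValueError("rank-deficient constraint map: joint Hessian is singular")

    # per-transition fit views (offset folded into the intercept)
    fits: dict[str, FPSMFit] = {}
    for blk, name in zip(blocks, block_tids):
        member_tids = [name] if name in tids else structure.constraint_groups[name]["transitions"]
        th = res.x[blk.idx].copy()
        off = res.x[blk.offset_col] if blk.offset_col is not None else 0.0
        coef = th.copy()
        coef[0] += off
        names = _block_names(blk, blk.basis, blk.td_basis)
        for tid in member_tids:
            if tid in fits:
                continue
            fits[tid] = FPSMFit(
                transition_id=tid, basis=blk.basis, td_basis=blk.td_basis,
                coef=coef, coef_names=names, covariate_names=blk.covariate_names,
                loglik=-res.fun, vcov=None, converged=converged, grad_norm=gn,
                n=len(blk.d), n_events=int(blk.d.sum()),
            )

    fits.update(placeholder_fits)
    offsets = {tid: float(res.x[j]) for tid, j in offsets_index.items()}
    return JointFitResult(
        fits=fits, loglik=-res.fun, theta=res.x, param_names=param_names,
        vcov=vcov, converged=converged, grad_norm=gn, offsets=offsets,
    )


def _block_names(blk: _TransitionBlock, basis, td_basis) -> list[str]:
    return (["intercept"] + [f"rcs{j}" for j in range(1, basis.df + 1)]
            + blk.covariate_names
            + [f"td{j}" for j in range(1, (td_basis.df if td_basis else 0) + 1)])
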