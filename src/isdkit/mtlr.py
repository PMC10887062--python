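"""Multi-task logistic regression (MTLR) individual survival distributions.

MTLR places a logistic predictor theta_j(x) = w_j . x + b_j at each of m
discretized time points tau_1 < ... < tau_m and models the joint
distribution over the m+1 monotone death-status sequences.  The
unnormalized score of death occurring in interval k (intervals
(tau_{k-1}, tau_k] with tau_0 = 0, tau_{m+1} = inf) is

    u_k(x) = exp( sum_{j=k}^{m} theta_j(x) ),      u_{m+1}(x) = 1,

with partition function Z(x) = sum_k u_k(x).  An uncensored patient dying
in interval k contributes -ln(u_k / Z); a censored patient contributes the
log-probability of the union of all death intervals not contradicted by
survival to the censoring time.  Because each covariate gets its own weight
*per time point*, the model is free of the proportional-hazards
assumption and predicted curves of two patients may cross.

The discretization uses m = ceil(sqrt(#uncensored)) quantile-placed time
points, the square-root-of-events convention of the model's reference
implementations.  The fit is a ridge-penalized convex problem solved by
L-BFGS from the zero start with log-sum-exp stabilization throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .cohort import CohortTable, CovariateDesign, stratified_kfold_split
from .curves import SurvivalCurve
from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "TimeGrid",
    "MTLRParams",
    "MTLRModel",
    "build_time_grid",
    "mtlr_objective",
    "mtlr_neg_log_likelihood",
    "fit_mtlr",
    "select_lambda",
    "predict_survival_curve",
    "DEFAULT_LAMBDA_GRID",
]

#: 2^-6 ... 2^6 by powers of 4
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(float(4.0**k) for k in range(-3, 4))


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing discretization points tau_1 < ... < tau_m (months)."""

    tau: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or tau.size < 1:
            raise ValidationError("time grid needs at least one point")
        if tau[0] <= 0 or np.any(np.diff(tau) <= 0):
            raise ValidationError("time grid must be strictly increasing and positive")
        object.__setattr__(self, "tau", tau)

    @property
    def m(self) -> int:
        return int(self.tau.size)

    def interval_index(self, t) -> np.ndarray:
        """1-based index of the interval (tau_{k-1}, tau_k] containing t.

        A time exactly at tau_k belongs to interval k; times beyond tau_m
        fall in the open interval m+1.
        """
        t = np.asarray(t, dtype=float)
        return np.searchsorted(self.tau, t, side="left") + 1


def build_time_grid(times, events) -> TimeGrid:
    """Quantile time grid from uncensored training times.

    m = ceil(sqrt(n_uncensored)); tau_j is the j/(m+1) empirical quantile
    of the uncensored event times (linear interpolation convention).
    Duplicate quantiles collapse, shrinking m.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    unc = times[events == 1]
    if unc.size == 0:
        raise ValidationError("time grid requires at least one uncensored record")
    m = math.ceil(math.sqrt(unc.size))
    qs = np.arange(1, m + 1) / (m + 1)
    tau = np.unique(np.quantile(unc, qs))
    return TimeGrid(tau)


@dataclass
class MTLRParams:
    """Per-time-point weights W (m x p) and biases b (m), ridge weight lam."""

    W: np.ndarray
    b: np.ndarray
    lam: float = 1.0

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.ndim != 1 or self.W.shape[0] != self.b.size:
            raise ValidationError("W must be m x p and b length m")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValidationError("MTLR parameters must be finite")

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[1]

    def ravel(self) -> np.ndarray:
        return np.concatenate([self.W.ravel(), self.b])

    @classmethod
    def unravel(cls, theta: np.ndarray, m: int, p: int, lam: float) -> "MTLRParams":
        return cls(theta[: m * p].reshape(m, p), theta[m * p:], lam)

    @classmethod
    def zeros(cls, m: int, p: int, lam: float = 1.0) -> "MTLRParams":
        return cls(np.zeros((m, p)), np.zeros(m), lam)


def _sequence_scores(params: MTLRParams, X: np.ndarray) -> np.ndarray:
    """n x (m+1) matrix of log u_k(x_i) = sum_{j>=k} theta_j(x_i); column m is 0."""
    theta = X @ params.W.T + params.b  # n x m
    S = np.zeros((X.shape[0], params.m + 1))
    S[:, :-1] = np.cumsum(theta[:, ::-1], axis=1)[:, ::-1]
    return S


def _interval_targets(grid: TimeGrid, times, events,
                      censored_includes_current: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(k_event, k_lo) 1-based interval indices for each record.

    For uncensored records k_event is the death interval; for censored
    records k_lo is the first death interval consistent with survival to
    the censoring time (by default including the interval the censoring
    time falls in, since death later in that interval is not excluded).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    k = grid.interval_index(times)
    k_lo = k.copy()
    if not censored_includes_current:
        inside = (events == 0) & (k <= grid.m)
        k_lo = np.where(inside, k + 1, k_lo)
    return k, k_lo


def mtlr_objective(params: MTLRParams, X: np.ndarray, times, events, grid: TimeGrid,
                   censored_includes_current: bool = True) -> tuple[float, MTLRParams]:
    """Penalized negative log-likelihood and its exact gradient.

    value = sum_i -ln P(data_i) + (lam/2) ||W||_F^2 with biases unpenalized.
    The gradient is returned as an :class:`MTLRParams` of matching shape.
    """
    events = np.asarray(events)
    S = _sequence_scores(params, X)  # n x (m+1)
    logZ = logsumexp(S, axis=1)
    k_event, k_lo = _interval_targets(grid, times, events, censored_includes_current)

    n, m1 = S.shape
    P = softmax(S, axis=1)
    Q = np.zeros_like(P)
    unc = events == 1
    rows_u = np.flatnonzero(unc)
    if rows_u.size:
        Q[rows_u, k_event[rows_u] - 1] = 1.0
    rows_c = np.flatnonzero(~unc)
    log_target = np.empty(n)
    if rows_u.size:
        log_target[rows_u] = S[rows_u, k_event[rows_u] - 1]
    if rows_c.size:
        # suffix log-sum-exp over the admissible death intervals, vectorized
        Sc = S[rows_c]
        suffix = np.logaddexp.accumulate(Sc[:, ::-1], axis=1)[:, ::-1]
        lo = k_lo[rows_c] - 1
        lt = suffix[np.arange(rows_c.size), lo]
        log_target[rows_c] = lt
        admissible = np.arange(m1)[None, :] >= lo[:, None]
        Q[rows_c] = np.where(admissible, np.exp(Sc - lt[:, None]), 0.0)

    nll = float(np.sum(logZ - log_target))
    value = nll + 0.5 * params.lam * float(np.sum(params.W**2))

    # dNLL/dtheta_ij = sum_{k<=j} (P_ik - Q_ik), j = 1..m
    D = np.cumsum(P - Q, axis=1)[:, : m1 - 1]
    grad_W = D.T @ X + params.lam * params.W
    grad_b = D.sum(axis=0)
    return value, MTLRParams(grad_W, grad_b, params.lam)


def mtlr_neg_log_likelihood(params: MTLRParams, X, times, events, grid,
                            censored_includes_current: bool = True) -> float:
    """Unpenalized negative log-likelihood (used for out-of-fold scoring)."""
    bare = MTLRParams(params.W.copy(), params.b.copy(), 0.0)
    value, _ = mtlr_objective(bare, X, times, events, grid, censored_includes_current)
    return value


@dataclass
class MTLRModel:
    """A fitted MTLR model bound to its design metadata."""

    params: MTLRParams
    grid: TimeGrid
    column_names: list[str] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def predict_curve(self, x: np.ndarray) -> SurvivalCurve:
        return predict_survival_curve(self, x)

    def predict_curves(self, X: np.ndarray) -> list[SurvivalCurve]:
        S = predict_survival_matrix(self, np.atleast_2d(X))
        times = np.concatenate([[0.0], self.grid.tau])
        return [SurvivalCurve(times, np.concatenate([[1.0], S[i]])) for i in range(S.shape[0])]


def fit_mtlr(design: CovariateDesign | np.ndarray, times, events, grid: TimeGrid,
             lam: float = 1.0, max_iter: int = 2000, gtol: float = 1e-6,
             smoothness: float = 0.0,
             censored_includes_current: bool = True) -> MTLRModel:
    """Fit MTLR by L-BFGS from the zero start.

    The objective is convex (a ridge-penalized log-linear model), so the
    optimum is unique for lam > 0 and the fit is deterministic.  An optional
    temporal-smoothness penalty (smoothness/2) * sum_j ||w_{j+1}-w_j||^2 is
    available but off by default.  Raises :class:`ConvergenceError` with the
    final gradient norm if the tolerance (gtol * max(1, |value|)) is not met.
    """
    if isinstance(design, CovariateDesign):
        X = design.matrix
        meta = dict(column_names=list(design.column_names), center=design.center.copy(),
                    scale=design.scale.copy())
    else:
        X = np.asarray(design, dtype=float)
        meta = dict(column_names=[f"x{j}" for j in range(X.shape[1])], center=None, scale=None)
    m, p = grid.m, X.shape[1]
    n = X.shape[0]
    # precondition the weight block: the data curvature scales with n while
    # the penalty curvature scales with lam (+ up to 4*smoothness for the
    # second-difference operator), so optimize over V = s * W
    s = float(np.sqrt(1.0 + (lam + 4.0 * smoothness) / max(1.0, n)))

    def fun(theta):
        theta_w = theta[: m * p] / s
        params = MTLRParams(theta_w.reshape(m, p), theta[m * p:], lam)
        value, grad = mtlr_objective(params, X, times, events, grid, censored_includes_current)
        gW, gb = grad.W, grad.b
        if smoothness > 0 and m > 1:
            dW = np.diff(params.W, axis=0)
            value += 0.5 * smoothness * float(np.sum(dW**2))
            gW = gW.copy()
            gW[:-1] -= smoothness * dW
            gW[1:] += smoothness * dW
        return value, np.concatenate([(gW / s).ravel(), gb])

    theta = np.zeros(m * p + m)
    total_iter = 0
    for _ in range(4):  # restarts clear stale L-BFGS curvature memory
        res = minimize(fun, theta, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                                "maxcor": 20, "ftol": 1e-14, "gtol": 1e-10})
        theta = res.x
        total_iter += res.nit
        value, grad = fun(theta)
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= gtol * max(1.0, abs(value)):
            break
    if gnorm > gtol * max(1.0, abs(value)):
        raise ConvergenceError(
            f"MTLR fit did not converge: |grad| = {gnorm:.3e} after {total_iter} iterations",
            gradient_norm=gnorm,
        )
    res.x = theta
    params = MTLRParams(res.x[: m * p].reshape(m, p) / s, res.x[m * p:], lam)
    return MTLRModel(params=params, grid=grid, **meta)


def select_lambda(design, times, events, grid: TimeGrid,
                  lambda_grid=DEFAULT_LAMBDA_GRID, k_inner: int = 5, seed: int = 0,
                  censored_includes_current: bool = True) -> float:
    """Choose the ridge weight by inner k-fold out-of-fold log-likelihood.

    Returns the grid value with the highest mean held-out log-likelihood,
    ties broken toward the larger (more regularized) value.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValidationError("lambda grid must be non-empty")
    if len(lambda_grid) == 1:
        return float(lambda_grid[0])
    X = design.matrix if isinstance(design, CovariateDesign) else np.asarray(design, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    import pandas as pd

    from .cohort import EVENT_COL, TIME_COL

    holder = CohortTable(pd.DataFrame({TIME_COL: times, EVENT_COL: events}), schema=())
    folds = stratified_kfold_split(holder, k_inner, seed)
    scores = {lam: [] for lam in lambda_grid}
    for tr, te in folds:
        inner_grid = build_time_grid(times[tr], events[tr])
        for lam in lambda_grid:
            model = fit_mtlr(X[tr], times[tr], events[tr], inner_grid, lam=lam,
                             censored_includes_current=censored_includes_current)
            nll = mtlr_neg_log_likelihood(model.params, X[te], times[te], events[te],
                                          inner_grid, censored_includes_current)
            scores[lam].append(-nll / te.size)
    means = {lam: float(np.mean(v)) for lam, v in scores.items()}
    best = max(means.values())
    return float(max(lam for lam, s in means.items() if s >= best - 1e-12))


def predict_survival_matrix(model: MTLRModel, X: np.ndarray) -> np.ndarray:
    """n x m matrix of S(tau_j | x_i) = sum_{k>j} u_k / Z."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.params.p:
        raise ValidationError(
            f"covariate vector length {X.shape[1]} does not match design p = {model.params.p}"
        )
    S = _sequence_scores(model.params, X)
    P = softmax(S, axis=1)
    # survival past tau_j = probability of dying in an interval k > j
    surv = 1.0 - np.cumsum(P[:, :-1], axis=1)
    return np.clip(surv, 0.0, 1.0)


def predict_survival_curve(model: MTLRModel, x: np.ndarray) -> SurvivalCurve:
    """Individual survival distribution for one encoded covariate vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("predict_survival_curve expects a single covariate vector")
    surv = predict_survival_matrix(model, x[None, :])[0]
    times = np.concatenate([[0.0], model.grid.tau])
    return SurvivalCurve(times, np.concatenate([[1.0], surv]))
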