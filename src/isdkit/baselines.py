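"""Classical ISD baselines: Cox-KP, elastic-net Cox, and Weibull AFT.

The Cox model supplies a relative risk exp(beta . x); to turn it into an
individual survival distribution the Kalbfleisch–Prentice (KP) estimator
supplies a baseline survival function, solved from its self-consistency
equation at each distinct event time.  With beta = 0 the KP estimator
reduces exactly to Kaplan–Meier.  CoxEN adds elastic-net regularization of
the negative log partial likelihood (proximal-gradient / FISTA solver).
The accelerated failure time (AFT) model is the Weibull log-linear model
ln T = mu + gamma . x + sigma W with W standard minimum extreme value.

Ties are handled with the Breslow approximation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

from .curves import SurvivalCurve
from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "CoxModel",
    "AFTModel",
    "cox_neg_log_partial_likelihood",
    "fit_cox",
    "kp_baseline",
    "predict_cox_curve",
    "fit_coxen",
    "select_coxen_alpha",
    "fit_weibull_aft",
    "predict_aft_curve",
]


@dataclass
class CoxModel:
    """Cox coefficients plus a KP baseline survival estimate."""

    beta: np.ndarray
    baseline_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_surv: np.ndarray = field(default_factory=lambda: np.empty(0))
    penalty: tuple[float, float] | None = None  # (alpha_en, l1_ratio)

    def predict_curve(self, x: np.ndarray) -> SurvivalCurve:
        return predict_cox_curve(self, x)

    def predict_curves(self, X: np.ndarray) -> list[SurvivalCurve]:
        return [predict_cox_curve(self, x) for x in np.atleast_2d(X)]


@dataclass
class AFTModel:
    """Weibull AFT: ln T = mu + gamma . x + sigma W."""

    mu: float
    gamma: np.ndarray
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("AFT scale sigma must be positive")

    def predict_curve(self, x: np.ndarray, grid: np.ndarray | None = None) -> SurvivalCurve:
        return predict_aft_curve(self, x, grid)

    def predict_curves(self, X: np.ndarray, grid: np.ndarray | None = None) -> list[SurvivalCurve]:
        return [predict_aft_curve(self, x, grid) for x in np.atleast_2d(X)]


def _risk_order(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    order = np.argsort(times, kind="stable")
    return times[order], events[order], order


def _partial_likelihood_parts(beta, X, times, events, need_hess: bool = True):
    """Breslow negative log partial likelihood, gradient and (optionally) Hessian."""
    t, d, order = _risk_order(times, events)
    Xs = X[order]
    p = X.shape[1]
    eta = Xs @ beta
    eta = eta - eta.max()  # the partial likelihood is shift-invariant in eta
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        r = np.exp(eta)
        # suffix sums over the risk set {i : t_i >= t}
        s0 = np.cumsum(r[::-1])[::-1]
        s1 = np.cumsum((r[:, None] * Xs)[::-1], axis=0)[::-1]
        # first index of each tie group (Breslow: tied deaths share the risk set)
        first = np.searchsorted(t, t, side="left")
        ev = np.flatnonzero(d == 1)
        f = ev if ev.size == 0 else first[ev]
        nll = -float(np.sum(eta[ev])) + float(np.sum(np.log(s0[f])))
        xbar = s1[f] / s0[f][:, None]
        grad = -Xs[ev].sum(axis=0) + xbar.sum(axis=0)
        if not (np.isfinite(nll) and np.all(np.isfinite(grad))):
            # degenerate linear predictor (under/overflowed risk sums); report
            # +inf so that line searches and backtracking reject the point
            return np.inf, np.zeros(p), (np.zeros((p, p)) if need_hess else None)
        if not need_hess:
            return nll, grad, None
        s2 = np.cumsum((r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]
        hess = np.einsum("ijk->jk", s2[f] / s0[f][:, None, None]) - np.einsum("ij,ik->jk", xbar, xbar)
    return nll, grad, hess


def cox_neg_log_partial_likelihood(beta, X, times, events) -> float:
    """Breslow negative log partial likelihood at ``beta``."""
    return _partial_likelihood_parts(np.asarray(beta, dtype=float), np.asarray(X, dtype=float),
                                     times, events, need_hess=False)[0]


def fit_cox(X, times, events, max_iter: int = 100, gtol: float = 1e-8) -> CoxModel:
    """Newton–Raphson fit of the Cox model (Breslow ties) with KP baseline.

    Raises :class:`ConvergenceError` when the likelihood is monotone
    (separation), with a hint to use penalization.
    """
    X = np.asarray(X, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")
    if np.any(np.std(X, axis=0) == 0):
        raise ValidationError("Cox fit requires non-constant covariate columns")
    beta = np.zeros(X.shape[1])
    nll, grad, hess = _partial_likelihood_parts(beta, X, times, events)
    for _ in range(max_iter):
        if np.linalg.norm(grad) <= gtol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving line search
        scale = 1.0
        for _ in range(40):
            cand = beta - scale * step
            new_nll = cox_neg_log_partial_likelihood(cand, X, times, events)
            if new_nll <= nll + 1e-12:
                break
            scale /= 2
        beta = beta - scale * step
        nll, grad, hess = _partial_likelihood_parts(beta, X, times, events)
        if np.linalg.norm(beta) > 50:
            raise ConvergenceError(
                "Cox partial likelihood appears monotone (separation); "
                "consider elastic-net penalization (fit_coxen)",
                gradient_norm=float(np.linalg.norm(grad)),
            )
    gnorm = float(np.linalg.norm(grad))
    if gnorm > gtol:
        raise ConvergenceError(f"Cox fit did not converge: |grad| = {gnorm:.2e}",
                               gradient_norm=gnorm)
    bt, bs = kp_baseline(beta, X, times, events)
    return CoxModel(beta=beta, baseline_times=bt, baseline_surv=bs)


def kp_baseline(beta, X, times, events) -> tuple[np.ndarray, np.ndarray]:
    """Kalbfleisch–Prentice baseline survival.

    At each distinct event time the survival factor alpha solves the
    self-consistency equation sum_{l in D} r_l / (1 - alpha^{r_l}) =
    sum_{l in R} r_l (risk set R, death set D, r = exp(beta . x)).  For a
    single death this has the closed form alpha = (1 - r_i / sum_R r_l)^{1/r_i};
    tied deaths are solved numerically.  S0(t) is the product of factors at
    event times <= t.  At beta = 0 this is exactly Kaplan–Meier.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    t, d, order = _risk_order(times, events)
    r = np.exp(X[order] @ beta)
    s0 = np.cumsum(r[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    event_times, alphas = [], []
    i = 0
    n = t.size
    while i < n:
        j = i
        deaths = []
        while j < n and t[j] == t[i]:
            if d[j] == 1:
                deaths.append(j)
            j += 1
        if deaths:
            risk_total = s0[first[i]]
            rd = r[deaths]
            if len(deaths) == 1:
                ri = rd[0]
                inner = 1.0 - ri / risk_total
                alpha = 0.0 if inner <= 0 else inner ** (1.0 / ri)
            else:
                def f(a):
                    return float(np.sum(rd / (1.0 - a**rd)) - risk_total)
                # f is increasing in a with f(0+) = sum(rd) - risk_total <= 0,
                # with equality when the whole risk set dies (alpha = 0)
                lo, hi = 1e-12, 1.0 - 1e-12
                if f(lo) >= 0:
                    alpha = 0.0
                else:
                    alpha = brentq(f, lo, hi, xtol=1e-14)
            event_times.append(t[i])
            alphas.append(alpha)
        i = j
    et = np.asarray(event_times)
    surv = np.cumprod(np.asarray(alphas))
    return et, surv


def predict_cox_curve(model: CoxModel, x) -> SurvivalCurve:
    """ISD from the Cox-KP model: S(t|x) = S0(t)^{exp(beta . x)}."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.beta.size:
        raise ValidationError("covariate vector length does not match Cox coefficients")
    hr = float(np.exp(model.beta @ x))
    times = np.concatenate([[0.0], model.baseline_times])
    probs = np.concatenate([[1.0], model.baseline_surv**hr])
    return SurvivalCurve(times, probs)


def _soft_threshold(z, thresh):
    return np.sign(z) * np.maximum(np.abs(z) - thresh, 0.0)


def fit_coxen(X, times, events, alpha_en: float, l1_ratio: float = 0.5,
              max_iter: int = 2000, kkt_tol: float = 1e-6) -> CoxModel:
    """Elastic-net-penalized Cox fit: proximal gradient plus active-set
    Newton polish.

    Minimizes NLL(beta) + alpha_en * (l1_ratio ||beta||_1 +
    (1 - l1_ratio)/2 ||beta||_2^2).  FISTA with backtracking identifies the
    support; Newton steps restricted to the active coordinates (with
    sign-crossing projection) drive the KKT residual of the subgradient
    conditions below ``kkt_tol``.
    """
    if alpha_en < 0 or not (0.0 <= l1_ratio <= 1.0):
        raise ValidationError("need alpha_en >= 0 and l1_ratio in [0, 1]")
    X = np.asarray(X, dtype=float)
    lam1 = alpha_en * l1_ratio
    lam2 = alpha_en * (1.0 - l1_ratio)

    def smooth(beta, need_hess=False):
        nll, grad, hess = _partial_likelihood_parts(beta, X, times, events, need_hess)
        val = nll + 0.5 * lam2 * float(beta @ beta)
        grad = grad + lam2 * beta
        if need_hess:
            hess = hess + lam2 * np.eye(beta.size)
        return val, grad, hess

    def objective(beta):
        return smooth(beta)[0] + lam1 * float(np.sum(np.abs(beta)))

    def kkt_residual(grad, beta):
        res = np.where(
            beta != 0.0,
            np.abs(grad + lam1 * np.sign(beta)),
            np.maximum(np.abs(grad) - lam1, 0.0),
        )
        return float(np.max(res)) if res.size else 0.0

    # phase 1: FISTA to locate the support
    beta = np.zeros(X.shape[1])
    y = beta.copy()
    t_mom = 1.0
    L = 1.0
    f_y, g_y, _ = smooth(y)
    for _ in range(max_iter):
        for _ in range(60):
            cand = _soft_threshold(y - g_y / L, lam1 / L)
            diff = cand - y
            f_c = smooth(cand)[0]
            if f_c <= f_y + g_y @ diff + 0.5 * L * float(diff @ diff) + 1e-12:
                break
            L *= 2.0
        if np.max(np.abs(cand - beta)) < 1e-9:
            beta = cand
            break
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        y = cand + ((t_mom - 1.0) / t_new) * (cand - beta)
        beta, t_mom = cand, t_new
        f_y, g_y, _ = smooth(y)
        L = max(L / 2.0, 1e-6)

    # phase 2: active-set Newton with sign-crossing projection
    for _ in range(100):
        val, grad, hess = smooth(beta, need_hess=True)
        if kkt_residual(grad, beta) <= kkt_tol:
            bt, bs = kp_baseline(beta, X, times, events)
            return CoxModel(beta=beta, baseline_times=bt, baseline_surv=bs,
                            penalty=(alpha_en, l1_ratio))
        active = beta != 0.0
        viol = (~active) & (np.abs(grad) > lam1 + 1e-15)
        work = active | viol
        signs = np.where(active, np.sign(beta), -np.sign(grad))
        idx = np.flatnonzero(work)
        g_w = grad[idx] + lam1 * signs[idx]
        H_w = hess[np.ix_(idx, idx)]
        try:
            step = np.linalg.solve(H_w + 1e-10 * np.eye(idx.size), g_w)
        except np.linalg.LinAlgError:
            step = g_w
        f0 = val + lam1 * float(np.sum(np.abs(beta)))
        scale = 1.0
        accepted = False
        for _ in range(40):
            cand = beta.copy()
            cand[idx] = beta[idx] - scale * step
            # project sign crossings of previously-active coords to zero
            crossed = active[idx] & (np.sign(cand[idx]) * signs[idx] < 0)
            cand[idx[crossed]] = 0.0
            # near the optimum the decrement underflows; accept non-increase
            if objective(cand) <= f0 + 1e-12:
                accepted = True
                break
            scale /= 2
        if not accepted or np.max(np.abs(cand - beta)) < 1e-15:
            break
        beta = cand
    _, grad, _ = smooth(beta, need_hess=False)
    res = kkt_residual(grad, beta)
    if res <= kkt_tol:
        bt, bs = kp_baseline(beta, X, times, events)
        return CoxModel(beta=beta, baseline_times=bt, baseline_surv=bs,
                        penalty=(alpha_en, l1_ratio))
    raise ConvergenceError(f"CoxEN did not converge: KKT residual = {res:.2e}",
                           gradient_norm=res)


def select_coxen_alpha(X, times, events, alpha_grid=(0.01, 0.1, 1.0, 10.0),
                       l1_ratio: float = 0.5, k_inner: int = 5, seed: int = 0) -> float:
    """Pick alpha_en by inner CV on the held-out partial likelihood."""
    import pandas as pd

    from .cohort import EVENT_COL, TIME_COL, CohortTable, stratified_kfold_split

    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    holder = CohortTable(pd.DataFrame({TIME_COL: times, EVENT_COL: events}), schema=())
    folds = stratified_kfold_split(holder, k_inner, seed)
    scores = {}
    for alpha in alpha_grid:
        vals = []
        for tr, te in folds:
            model = fit_coxen(X[tr], times[tr], events[tr], alpha, l1_ratio)
            vals.append(-cox_neg_log_partial_likelihood(model.beta, X[te], times[te], events[te]))
        scores[alpha] = float(np.mean(vals))
    best = max(scores.values())
    return float(max(a for a, s in scores.items() if s >= best - 1e-12))


def _aft_nll_grad(theta, X, logt, events):
    p = X.shape[1]
    mu, gamma, log_sigma = theta[0], theta[1 : 1 + p], theta[-1]
    sigma = np.exp(log_sigma)
    z = (logt - mu - X @ gamma) / sigma
    ez = np.exp(z)
    d = events
    # log f = z - e^z - log sigma - log t (log t constant in theta, dropped)
    nll = -float(np.sum(d * (z - log_sigma) - ez))
    dz = (d - ez) / sigma  # d loglik / dz * dz/d(-linear)...
    # d loglik / dmu = -sum dz ; d/dgamma = -X^T dz ; d/dlog_sigma = -sum(d + z*(d - ez))... careful:
    dl_dmu = float(np.sum(dz))
    dl_dgamma = X.T @ dz
    dl_dlogs = float(np.sum(z * (d - ez) + d))
    return nll, np.concatenate([[dl_dmu], dl_dgamma, [dl_dlogs]])


def fit_weibull_aft(X, times, events, gtol: float = 1e-8) -> AFTModel:
    """Maximum-likelihood Weibull AFT fit.

    ln T = mu + gamma . x + sigma W, W ~ standard minimum extreme value;
    censored records contribute log S = -exp(z).  Optimized over
    (mu, gamma, ln sigma) by L-BFGS with the analytic gradient; the fit
    must reach gradient norm <= gtol * max(1, |nll|).
    """
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(float)
    if events.sum() < 1:
        raise ValidationError("AFT fit requires at least one event")
    logt = np.log(times)
    theta0 = np.concatenate([[float(np.mean(logt))], np.zeros(X.shape[1]), [0.0]])
    res = minimize(lambda th: _aft_nll_grad(th, X, logt, events), theta0, jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12})
    theta = res.x
    nll, grad = _aft_nll_grad(theta, X, logt, events)
    # Newton polish (finite-difference Hessian; the parameter space is tiny)
    for _ in range(25):
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= gtol * max(1.0, abs(nll)):
            break
        h = 1e-6 * np.maximum(1.0, np.abs(theta))
        H = np.empty((theta.size, theta.size))
        for j in range(theta.size):
            e = np.zeros_like(theta)
            e[j] = h[j]
            gp = _aft_nll_grad(theta + e, X, logt, events)[1]
            gm = _aft_nll_grad(theta - e, X, logt, events)[1]
            H[:, j] = (gp - gm) / (2 * h[j])
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = theta - scale * step
            cand_nll = _aft_nll_grad(cand, X, logt, events)[0]
            if cand_nll <= nll + 1e-12:
                break
            scale /= 2
        theta = theta - scale * step
        nll, grad = _aft_nll_grad(theta, X, logt, events)
    res.x = theta
    gnorm = float(np.linalg.norm(grad))
    if gnorm > gtol * max(1.0, abs(nll)):
        raise ConvergenceError(f"Weibull AFT did not converge: |grad| = {gnorm:.2e}",
                               gradient_norm=gnorm)
    p = X.shape[1]
    return AFTModel(mu=float(res.x[0]), gamma=res.x[1 : 1 + p], sigma=float(np.exp(res.x[-1])))


def predict_aft_curve(model: AFTModel, x, grid: np.ndarray | None = None) -> SurvivalCurve:
    """ISD from the Weibull AFT: S(t|x) = exp(-(t / exp(mu + gamma.x))^{1/sigma})."""
    x = np.asarray(x, dtype=float)
    scale = np.exp(model.mu + float(model.gamma @ x))
    if grid is None:
        # a grid dense enough for spline queries, out to the 99th percentile
        t99 = scale * (-np.log(0.01)) ** model.sigma
        grid = np.linspace(0.0, t99, 101)[1:]
    grid = np.asarray(grid, dtype=float)
    surv = np.exp(-((grid / scale) ** (1.0 / model.sigma)))
    return SurvivalCurve(np.concatenate([[0.0], grid]), np.concatenate([[1.0], surv]))
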