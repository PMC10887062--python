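"""ISD evaluation: concordance, 1-calibration, D-calibration, integrated
Brier score, and the 5-fold cross-validation harness.

Discrimination is Harrell's concordance on an ISD-native risk score (the
negative predicted median survival time).  Calibration is assessed two
ways: 1-calibration is a Hosmer–Lemeshow goodness-of-fit test at a single
anchor time with censoring-adjusted (Kaplan–Meier) observed rates per risk
decile, and D-calibration tests whether predicted survival probabilities
evaluated at observed times are uniform over probability deciles, censored
patients contributing conditional-uniform fractional mass.  The integrated
Brier score uses inverse-probability-of-censoring weights.  The CV harness
reports concordance and IBS as fold mean +/- sd and the calibration tests
on pooled out-of-fold predictions, one p-value per model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .baselines import fit_cox, fit_coxen, fit_weibull_aft, select_coxen_alpha
from .cohort import CohortTable, encode_design, stratified_kfold_split
from .curves import NOT_REACHED, SurvivalCurve
from .exceptions import ValidationError
from .mtlr import DEFAULT_LAMBDA_GRID, build_time_grid, fit_mtlr, select_lambda

logger = logging.getLogger(__name__)

__all__ = [
    "concordance_index",
    "one_calibration",
    "d_calibration",
    "integrated_brier",
    "cross_validated_evaluation",
    "EvaluationReport",
    "MTLRStrategy",
    "CoxKPStrategy",
    "CoxENStrategy",
    "AFTStrategy",
    "default_model_suite",
    "risk_from_curves",
]

ANCHOR_PERCENTILES = (10, 25, 50, 75, 90)


# ---------------------------------------------------------------------------
# Kaplan-Meier step function (internal utility; needed with explicit
# left-limit evaluation for the IPCW weights)

def _km_steps(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - first
    deaths = np.array([d[t == u].sum() for u in uniq])
    keep = deaths > 0
    factors = 1.0 - deaths[keep] / at_risk[keep]
    return uniq[keep], np.cumprod(factors)


def _km_eval(step_times, step_surv, t, left_limit: bool = False) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    side = "left" if left_limit else "right"
    idx = np.searchsorted(step_times, t, side=side)
    out = np.ones_like(t)
    nz = idx > 0
    out[nz] = step_surv[idx[nz] - 1]
    return out


# ---------------------------------------------------------------------------
# metrics

def risk_from_curves(curves) -> np.ndarray:
    """ISD-native risk score: negative predicted median survival time.

    Curves whose extended median is never reached get risk -inf (lowest
    possible risk); ties are handled by the concordance convention.
    """
    med = np.array([c.median() for c in curves])
    risk = -med
    risk[np.isinf(med)] = -np.inf
    return risk


def concordance_index(predicted_risk, times, events) -> float:
    """Harrell's C: (concordant + 0.5 * tied risk) / comparable pairs.

    Comparable pairs are (i, j) with t_i < t_j and event_i = 1; higher risk
    should go with the earlier event.
    """
    risk = np.asarray(predicted_risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    conc = tied = comp = 0
    for i in np.flatnonzero(events == 1):
        later = times > times[i]
        comp += int(later.sum())
        conc += int(np.sum(risk[i] > risk[later]))
        tied += int(np.sum(risk[i] == risk[later]))
    if comp == 0:
        raise ValidationError("no comparable pairs for concordance")
    return (conc + 0.5 * tied) / comp


def _survival_at(curves, t) -> np.ndarray:
    if isinstance(curves, np.ndarray) and curves.ndim == 1:
        return curves
    return np.array([c.survival_at(t) for c in curves])


def _km_at_with_variance(times, events, t_star) -> tuple[float, float]:
    """Kaplan-Meier survival at t_star with its Greenwood variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order]
    uniq, first = np.unique(t, return_index=True)
    at_risk = t.size - first
    deaths = np.array([d[t == u].sum() for u in uniq])
    keep = (deaths > 0) & (uniq <= t_star)
    surv = float(np.prod(1.0 - deaths[keep] / at_risk[keep]))
    denom = at_risk[keep] * (at_risk[keep] - deaths[keep])
    if np.any(denom <= 0):
        return surv, np.inf if surv > 0 else 0.0
    var = surv**2 * float(np.sum(deaths[keep] / denom))
    return surv, var


def one_calibration(curves, times, events, t_star: float, n_groups: int = 10):
    """Hosmer-Lemeshow 1-calibration test at anchor time ``t_star``.

    Patients are grouped into deciles of predicted event probability
    1 - S_i(t_star); the observed event rate per group is the within-group
    Kaplan-Meier estimate at t_star, so censoring before the anchor is
    accounted for.  Each group contributes (O_g - E_g)^2 / Var_g with
    Var_g the Greenwood variance of the group's KM estimate (the binomial
    E(1-E)/n denominator understates the variance under censoring and
    makes the test anti-conservative); the statistic is referenced to
    chi2 with (groups - 2) df.  Degenerate groups (no observable events
    before t_star, or expected rate 0/1) are merged with a neighbour
    (logged).  Returns (statistic, p_value).
    """
    from scipy.stats import chi2

    if t_star <= 0:
        raise ValidationError("anchor time must be positive")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    p_event = 1.0 - _survival_at(curves, t_star)
    order = np.argsort(p_event, kind="stable")
    raw_groups = [g for g in np.array_split(order, n_groups) if g.size > 0]

    def summarize(idx):
        e_g = float(np.mean(p_event[idx]))
        surv, var = _km_at_with_variance(times[idx], events[idx], t_star)
        return e_g, 1.0 - surv, var

    groups: list[np.ndarray] = []
    carry = np.empty(0, dtype=int)
    for g in raw_groups:
        g = np.concatenate([carry, g])
        e_g, _, var = summarize(g)
        degenerate = var <= 0 or not np.isfinite(var) or e_g <= 1e-12 or e_g >= 1 - 1e-12
        if degenerate:
            logger.info("1-calibration: merging degenerate group (E = %.3g)", e_g)
            carry = g
        else:
            groups.append(g)
            carry = np.empty(0, dtype=int)
    if carry.size and groups:
        groups[-1] = np.concatenate([groups[-1], carry])
    if len(groups) < 3:
        raise ValidationError("too few non-degenerate groups for 1-calibration")

    stat = 0.0
    for g in groups:
        e_g, o_g, var = summarize(g)
        stat += (o_g - e_g) ** 2 / var
    df = len(groups) - 2
    return float(stat), float(chi2.sf(stat, df))


def d_calibration(curves, times, events, n_bins: int = 10):
    """Distribution calibration test.

    Each uncensored patient contributes mass 1 to the probability decile
    containing S_i(t_i); a censored patient with p = S_i(c_i) spreads mass
    (min(hi, p) - lo)+ / p over the bins below p (conditional-uniform
    allocation).  The chi-square statistic against the uniform expectation
    n / n_bins is referenced to (n_bins - 1) df.  Returns
    (statistic, p_value, bin_masses) with bins ordered [0, 1/n_bins), ...
    """
    from scipy.stats import chi2

    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    n = times.size
    if isinstance(curves, np.ndarray) and curves.ndim == 1:
        s_obs = curves  # precomputed S_i at each patient's own time
    else:
        s_obs = np.array([c.survival_at(t) for c, t in zip(curves, times)])
    masses = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) / n_bins
    for s, ev in zip(s_obs, events):
        if ev == 1:
            masses[min(int(s * n_bins), n_bins - 1)] += 1.0
        elif s <= 0.0:
            logger.info("D-calibration: censored patient with S(c) = 0; mass to lowest bin")
            masses[0] += 1.0
        else:
            lo = edges[:-1]
            hi = edges[1:]
            masses += np.clip(np.minimum(hi, s) - lo, 0.0, None) / s
    expected = n / n_bins
    stat = float(np.sum((masses - expected) ** 2 / expected))
    return stat, float(chi2.sf(stat, n_bins - 1)), masses


def integrated_brier(curves, times, events, t_max: float) -> float:
    """IPCW integrated Brier score over [0, t_max], normalized by the horizon.

    BS(t) = n^-1 sum_i [ S_i(t)^2 1(t_i <= t, ev_i) / G(t_i-) +
    (1 - S_i(t))^2 1(t_i > t) / G(t) ] with G the Kaplan-Meier estimate of
    the censoring distribution; integrated by trapezoid over the pooled
    event-time grid.  If G reaches 0 before t_max the integration is
    truncated at the last usable time (logged) and normalized accordingly.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if t_max <= 0:
        raise ValidationError("t_max must be positive")
    gt, gs = _km_steps(times, 1 - events)
    g_at_minus = _km_eval(gt, gs, times, left_limit=True)

    grid = np.unique(np.concatenate([[0.0], times[(events == 1) & (times <= t_max)], [t_max]]))
    g_grid = _km_eval(gt, gs, grid)
    usable = g_grid > 0
    if not np.all(usable):
        t_limit = float(grid[usable][-1])
        logger.info("IBS: censoring KM hits 0; truncating integration at %.3g", t_limit)
        grid = grid[grid <= t_limit]
        g_grid = g_grid[: grid.size]
    horizon = float(grid[-1])
    if horizon <= 0:
        raise ValidationError("no usable integration range for IBS")

    S = np.array([c.survival_at(grid) for c in curves])  # n x T
    bs = np.zeros(grid.size)
    for j, t in enumerate(grid):
        died = (times <= t) & (events == 1)
        alive = times > t
        terms = np.zeros(times.size)
        terms[died] = S[died, j] ** 2 / g_at_minus[died]
        terms[alive] = (1.0 - S[alive, j]) ** 2 / g_grid[j]
        bs[j] = terms.mean()
    return float(np.trapezoid(bs, grid) / horizon)


# ---------------------------------------------------------------------------
# model strategies for the CV harness

@dataclass
class MTLRStrategy:
    """MTLR with ridge weight fixed or chosen by inner CV."""

    lam: float | None = None
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    k_inner: int = 5
    smoothness: float = 0.0

    name: str = "MTLR"
    chosen_lam: float | None = None

    def fit(self, X, times, events, seed: int = 0):
        grid = build_time_grid(times, events)
        if self.lam is not None:
            lam = float(self.lam)
        else:
            lam = select_lambda(X, times, events, grid, self.lambda_grid,
                                self.k_inner, seed)
        self.chosen_lam = lam
        logger.info("MTLR: m = %d, lambda = %g", grid.m, lam)
        return fit_mtlr(X, times, events, grid, lam=lam, smoothness=self.smoothness)


@dataclass
class CoxKPStrategy:
    name: str = "CoxKP"

    def fit(self, X, times, events, seed: int = 0):
        return fit_cox(X, times, events)


@dataclass
class CoxENStrategy:
    alpha_en: float | None = None
    alpha_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    l1_ratio: float = 0.5
    k_inner: int = 5
    name: str = "CoxENKP"
    chosen_alpha: float | None = None

    def fit(self, X, times, events, seed: int = 0):
        if self.alpha_en is not None:
            alpha = float(self.alpha_en)
        else:
            alpha = select_coxen_alpha(X, times, events, self.alpha_grid,
                                       self.l1_ratio, self.k_inner, seed)
        self.chosen_alpha = alpha
        logger.info("CoxEN: alpha = %g, l1_ratio = %g", alpha, self.l1_ratio)
        return fit_coxen(X, times, events, alpha, self.l1_ratio)


class _AFTFitted:
    def __init__(self, model, grid):
        self.model = model
        self.grid = grid

    def predict_curves(self, X):
        return self.model.predict_curves(X, self.grid)


@dataclass
class AFTStrategy:
    name: str = "AFT"

    def fit(self, X, times, events, seed: int = 0):
        model = fit_weibull_aft(X, times, events)
        grid = np.linspace(0.0, 1.05 * float(np.max(times)), 101)[1:]
        return _AFTFitted(model, grid)


def default_model_suite(**mtlr_kwargs) -> dict:
    return {
        "AFT": AFTStrategy(),
        "CoxKP": CoxKPStrategy(),
        "CoxENKP": CoxENStrategy(),
        "MTLR": MTLRStrategy(**mtlr_kwargs),
    }


# ---------------------------------------------------------------------------
# report + harness

_METRIC_ROWS = ["Concordance", "D-Calibration"] + [
    f"1-Calibration {p}th" for p in ANCHOR_PERCENTILES
] + ["Integrated Brier"]


@dataclass
class EvaluationReport:
    """Per-model discrimination and calibration summary over k folds."""

    models: dict[str, dict]
    anchors: dict[str, float]
    k: int
    seed: int
    n: int
    n_events: int

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "anchors": self.anchors,
            "k": self.k,
            "seed": self.seed,
            "n": self.n,
            "n_events": self.n_events,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["models"], d["anchors"], d["k"], d["seed"], d["n"], d["n_events"])

    def to_table(self):
        """Models-by-metrics table in the conventional report shape."""
        import pandas as pd

        cols = {}
        for name, m in self.models.items():
            cols[name] = [
                f"{m['concordance_mean']:.3f} ± {m['concordance_sd']:.3f}",
                f"{m['d_calibration_p']:.3f}",
                *[f"{m['one_calibration_p'][str(p)]:.3f}" for p in ANCHOR_PERCENTILES],
                f"{m['ibs_mean']:.3f} ± {m['ibs_sd']:.3f}",
            ]
        return pd.DataFrame(cols, index=_METRIC_ROWS)


def cross_validated_evaluation(cohort: CohortTable, models: dict | None = None,
                               k: int = 5, seed: int = 0,
                               standardize: bool = True) -> EvaluationReport:
    """Event-stratified k-fold evaluation producing an EvaluationReport.

    For each fold every model is fitted on the training part (including any
    internal hyper-parameter selection), ISDs are predicted for the test
    part, and concordance / IBS are computed per fold.  Calibration tests
    run once per model on the pooled out-of-fold predictions.  Anchor times
    for 1-calibration are the 10/25/50/75/90th percentiles of the observed
    (uncensored) event times.
    """
    if models is None:
        models = default_model_suite()
    if cohort.n_events == 0:
        raise ValidationError("cohort has no events; cannot evaluate survival models")
    folds = stratified_kfold_split(cohort, k, seed)
    times, events = cohort.times, cohort.events
    event_times = times[events == 1]
    anchors = {str(p): float(np.percentile(event_times, p)) for p in ANCHOR_PERCENTILES}

    per_model_curves: dict[str, list] = {name: [None] * cohort.n for name in models}
    fold_conc: dict[str, list] = {name: [] for name in models}
    fold_ibs: dict[str, list] = {name: [] for name in models}

    for fold_idx, (tr, te) in enumerate(folds):
        if events[te].sum() == 0 or events[tr].sum() == 0:
            raise ValidationError(
                f"fold {fold_idx} has no events; stratify or use a larger cohort"
            )
        train = cohort.subset(tr)
        design = encode_design(train, standardize=standardize)
        X_test = design.transform(cohort.df.iloc[te])
        for name, strat in models.items():
            fitted = strat.fit(design.matrix, train.times, train.events,
                               seed=seed + fold_idx)
            curves = fitted.predict_curves(X_test)
            for local, global_i in enumerate(te):
                per_model_curves[name][global_i] = curves[local]
            risk = risk_from_curves(curves)
            fold_conc[name].append(concordance_index(risk, times[te], events[te]))
            t_max = float(np.max(times[te][events[te] == 1]))
            fold_ibs[name].append(integrated_brier(curves, times[te], events[te], t_max))
        logger.info("fold %d: n_train = %d, n_test = %d done", fold_idx, tr.size, te.size)

    out: dict[str, dict] = {}
    for name in models:
        curves = per_model_curves[name]
        d_stat, d_p, _ = d_calibration(curves, times, events)
        one_p = {}
        for p_label, t_star in anchors.items():
            _, pval = one_calibration(curves, times, events, t_star)
            one_p[p_label] = pval
        out[name] = {
            "concordance_mean": float(np.mean(fold_conc[name])),
            "concordance_sd": float(np.std(fold_conc[name], ddof=1)),
            "ibs_mean": float(np.mean(fold_ibs[name])),
            "ibs_sd": float(np.std(fold_ibs[name], ddof=1)),
            "d_calibration_stat": d_stat,
            "d_calibration_p": d_p,
            "one_calibration_p": one_p,
        }
    return EvaluationReport(models=out, anchors=anchors, k=k, seed=seed,
                            n=cohort.n, n_events=cohort.n_events)
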