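"""Interpretation layer: time-varying weight profiles, forest-plot
summaries, Cox-coefficient concordance, and counterfactual curve pairs.

Because MTLR attaches one weight per covariate *per time point*, the
weights collected across cross-validation fits form a time profile
W_jc(tau_j) per covariate: the covariate's log-odds push toward death
around time tau_j.  Negative weights favour survival.  Averaging over all
time points and folds yields a Cox-like per-covariate effect summary with
bootstrap confidence intervals and one-sample significance tests, and the
mean weights can be correlated against coefficients of a conventional Cox
model fitted on the full data.  "Counterfactual" curves are model
predictions for the same patient with one input toggled — a prediction
contrast, not a causal estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, CovariateDesign, encode_design, stratified_kfold_split
from .curves import SurvivalCurve
from .exceptions import SchemaError, ValidationError
from .mtlr import MTLRModel

__all__ = [
    "WeightProfiles",
    "WeightSummary",
    "collect_out_of_fold_weights",
    "cv_mtlr_fits",
    "rank_influential",
    "bootstrap_mean_weight_ci",
    "weight_significance",
    "weight_summary",
    "correlate_with_cox",
    "counterfactual_curves",
]


@dataclass
class WeightProfiles:
    """Long-format table of (covariate, fold, tau, weight) across CV fits.

    Weights are on the standardized-covariate scale of the training design;
    folds may have different grid sizes m, so profiles are pooled as
    (tau, value) pairs rather than aligned by index.
    """

    data: pd.DataFrame  # columns: covariate, fold, tau, weight
    column_names: list[str]

    def values_for(self, covariate: str) -> np.ndarray:
        if covariate not in self.column_names:
            raise ValidationError(f"unknown covariate {covariate!r}")
        return self.data.loc[self.data["covariate"] == covariate, "weight"].to_numpy()

    def mean_weights(self) -> pd.Series:
        return self.data.groupby("covariate")["weight"].mean().reindex(self.column_names)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def collect_out_of_fold_weights(cv_fits: list[MTLRModel]) -> WeightProfiles:
    """Pool the per-time-point weights of k cross-validation MTLR fits."""
    if len(cv_fits) < 2:
        raise ValidationError("need at least 2 CV fits to pool weights")
    names = cv_fits[0].column_names
    for fit in cv_fits[1:]:
        if fit.column_names != names:
            raise SchemaError("CV fits do not share a covariate schema")
    rows = []
    for fold, fit in enumerate(cv_fits):
        for j, tau in enumerate(fit.grid.tau):
            for c, name in enumerate(names):
                rows.append((name, fold, float(tau), float(fit.params.W[j, c])))
    data = pd.DataFrame(rows, columns=["covariate", "fold", "tau", "weight"])
    return WeightProfiles(data=data, column_names=list(names))


def cv_mtlr_fits(cohort: CohortTable, k: int = 5, seed: int = 0, lam: float | None = None,
                 lambda_grid=None, standardize: bool = True,
                 smoothness: float = 0.0) -> list[MTLRModel]:
    """Fit MTLR on each training fold of an event-stratified k-fold split."""
    from .mtlr import DEFAULT_LAMBDA_GRID, build_time_grid, fit_mtlr, select_lambda

    folds = stratified_kfold_split(cohort, k, seed)
    fits = []
    for fold_idx, (tr, _) in enumerate(folds):
        train = cohort.subset(tr)
        design = encode_design(train, standardize=standardize)
        grid = build_time_grid(train.times, train.events)
        if lam is None:
            chosen = select_lambda(design.matrix, train.times, train.events, grid,
                                   lambda_grid or DEFAULT_LAMBDA_GRID, seed=seed + fold_idx)
        else:
            chosen = float(lam)
        fits.append(fit_mtlr(design, train.times, train.events, grid, lam=chosen,
                             smoothness=smoothness))
    return fits


def rank_influential(profiles: WeightProfiles) -> list[str]:
    """Covariates ordered by influence: |mean weight| descending, ties
    broken alphabetically."""
    means = profiles.mean_weights()
    return sorted(means.index, key=lambda c: (-abs(means[c]), c))


def bootstrap_mean_weight_ci(values, n_boot: int = 1000, seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap 95% CI of the mean of pooled weight values.

    The resampling unit is the individual (fold, tau) weight value.
    Returns (mean, lo, hi); reproducible under ``seed``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 weight values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return float(values.mean()), float(lo), float(hi)


def weight_significance(profiles: WeightProfiles, method: str = "wilcoxon") -> pd.DataFrame:
    """Per-covariate one-sample test of mean weight zero, BH-adjusted.

    ``method`` is "wilcoxon" (signed-rank, default) or "ttest".  All-zero
    weight vectors get p = 1 by convention.  Returns a DataFrame with
    columns p_raw, p_adj indexed by covariate.
    """
    from statsmodels.stats.multitest import multipletests

    raw = {}
    for cov in profiles.column_names:
        vals = profiles.values_for(cov)
        if np.all(vals == 0):
            raw[cov] = 1.0
        elif method == "wilcoxon":
            raw[cov] = float(stats.wilcoxon(vals).pvalue)
        elif method == "ttest":
            raw[cov] = float(stats.ttest_1samp(vals, 0.0).pvalue)
        else:
            raise ValidationError(f"unknown test method {method!r}")
    covs = list(raw)
    _, p_adj, _, _ = multipletests([raw[c] for c in covs], method="fdr_bh")
    return pd.DataFrame({"p_raw": [raw[c] for c in covs], "p_adj": p_adj}, index=covs)


def weight_summary(profiles: WeightProfiles, n_boot: int = 1000, seed: int = 0,
                   method: str = "wilcoxon") -> pd.DataFrame:
    """Forest-plot table: mean weight, bootstrap 95% CI, raw/BH-adjusted
    p-values and influence rank per covariate."""
    sig = weight_significance(profiles, method=method)
    order = rank_influential(profiles)
    rows = []
    for i, cov in enumerate(order):
        mean, lo, hi = bootstrap_mean_weight_ci(profiles.values_for(cov), n_boot,
                                                seed=seed + i)
        rows.append({
            "covariate": cov,
            "mean_weight": mean,
            "ci_lo": lo,
            "ci_hi": hi,
            "p_raw": sig.loc[cov, "p_raw"],
            "p_adj": sig.loc[cov, "p_adj"],
            "rank": i + 1,
        })
    return pd.DataFrame(rows).set_index("covariate")


def correlate_with_cox(mean_weights: pd.Series, cox_beta: pd.Series) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation between MTLR mean weights and Cox coefficients.

    Both inputs are indexed by encoded covariate name; the correlation runs
    over the shared covariates (at least 3 required).  Returns
    (r, p_value, scatter) where scatter is the per-covariate data behind
    the comparison plot.
    """
    shared = [c for c in mean_weights.index if c in cox_beta.index]
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared covariates for correlation")
    w = mean_weights[shared].to_numpy(dtype=float)
    b = cox_beta[shared].to_numpy(dtype=float)
    r, p = stats.pearsonr(w, b)
    scatter = pd.DataFrame({"mtlr_mean_weight": w, "cox_coefficient": b}, index=shared)
    return float(r), float(p), scatter


def counterfactual_curves(model: MTLRModel, design: CovariateDesign, patient: pd.Series | dict,
                          toggle: dict, query_times=(24.0, 48.0)):
    """Predicted ISD pair for a patient with and without a covariate toggle.

    ``toggle`` maps schema covariate names to replacement values (e.g.
    ``{"treatment": "Yes"}``).  Returns a dict with both curves, survival
    differences (toggled - base) at the query times, and both medians.
    """
    base = pd.DataFrame([dict(patient)])
    schema_names = {c.name for c in design.schema}
    unknown = sorted(set(toggle) - schema_names)
    if unknown:
        raise ValidationError(f"toggle refers to unknown covariate(s): {unknown}")
    alt = base.copy()
    for name, value in toggle.items():
        alt[name] = value
    x_base = design.transform(base)[0]
    x_alt = design.transform(alt)[0]
    curve_base = model.predict_curve(x_base)
    curve_alt = model.predict_curve(x_alt)
    diffs = {
        float(t): float(curve_alt.survival_at(t) - curve_base.survival_at(t))
        for t in query_times
    }
    return {
        "base": curve_base,
        "toggled": curve_alt,
        "diff_at": diffs,
        "median_base": curve_base.median(),
        "median_toggled": curve_alt.median(),
    }
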