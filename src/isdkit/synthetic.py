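"""Synthetic gastric-adenocarcinoma cohorts with known ground truth.

The generator emulates the structure of a pooled gastric-cancer cohort:
covariate marginals matching the published demographics table (stage mix,
sex, Lauren class, tumour location, adjuvant chemotherapy exposure, age with
median 59, continuous molecular-subtype probability scores), an event
process with a piecewise-constant baseline hazard and per-covariate
log-hazard effects that may themselves be step functions of time, and
administrative-plus-uniform censoring.

The time-varying defaults encode the qualitative picture reported for the
real cohort: chemotherapy is protective early and its effect tapers off
after 24 months, Stage IV is constantly harmful, Stage III becomes harmful
only after the first year, and a high tumour-microenvironment (TME) score is
protective mainly late.  Covariates are drawn independently; correlation
structure of real registries is deliberately not emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import Categorical, CohortTable, Continuous, cohort_from_frame
from .exceptions import ValidationError

__all__ = [
    "StepEffect",
    "constant_effect",
    "BaselineHazard",
    "CensoringSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_schema",
    "default_config",
    "generate_cohort",
    "sample_event_times",
    "apply_censoring",
]

_N_STUDY = 1043  # size of the pooled cohort whose marginals are emulated


@dataclass(frozen=True)
class StepEffect:
    """A log-hazard effect that is a step function of time.

    ``values[i]`` applies on ``[breaks[i-1], breaks[i])`` with breaks
    padded by 0 and infinity, so ``len(values) == len(breaks) + 1``.
    """

    breaks: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != len(self.breaks) + 1:
            raise ValidationError("StepEffect needs len(values) == len(breaks) + 1")
        if any(b <= a for a, b in zip(self.breaks, self.breaks[1:])):
            raise ValidationError("StepEffect breaks must be increasing")

    def at(self, t: float) -> float:
        return self.values[int(np.searchsorted(self.breaks, t, side="right"))]


def constant_effect(beta: float) -> StepEffect:
    return StepEffect((), (float(beta),))


@dataclass(frozen=True)
class BaselineHazard:
    """Piecewise-constant baseline hazard: ``rates[i]`` on ``[starts[i], starts[i+1])``."""

    starts: tuple[float, ...] = (0.0, 12.0, 36.0, 72.0)
    rates: tuple[float, ...] = (0.018, 0.022, 0.012, 0.006)

    def __post_init__(self):
        if self.starts[0] != 0.0 or any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValidationError("baseline segments must start at 0 and be ordered")
        if len(self.rates) != len(self.starts):
            raise ValidationError("one rate per segment required")
        if any(r <= 0 for r in self.rates):
            raise ValidationError("baseline hazard rates must be positive")


@dataclass(frozen=True)
class CensoringSpec:
    """Administrative horizon plus independent uniform early censoring.

    Each patient is administratively censored at ``horizon``; with
    probability ``uniform_prob`` an additional Uniform(0, uniform_upper)
    censoring time applies (loss to follow-up).  The default targets
    roughly half of patients censored overall under the default hazard.
    """

    horizon: float = 120.0
    uniform_prob: float = 0.85
    uniform_upper: float = 60.0

    def __post_init__(self):
        if not (self.horizon > 0) or not (0.0 < self.uniform_upper <= self.horizon):
            raise ValidationError("need horizon > 0 and 0 < uniform_upper <= horizon")
        if not (0.0 <= self.uniform_prob <= 1.0):
            raise ValidationError("uniform censoring probability must lie in [0, 1]")


def _default_effects() -> dict[str, StepEffect]:
    return {
        "treatment=Yes": StepEffect((24.0,), (math.log(0.5), 0.0)),
        "stage=II": constant_effect(0.3),
        "stage=III": StepEffect((12.0,), (0.0, 0.7)),
        "stage=IV": constant_effect(0.9),
        "sex=Male": constant_effect(0.1),
        "tme_score": StepEffect((24.0,), (0.0, -0.8)),
        "acrg_emt": constant_effect(0.5),
        "tcga_msi": constant_effect(-0.3),
        "age_z": constant_effect(0.25),
        "lauren=Diffuse": constant_effect(0.15),
        "location=Proximal": constant_effect(0.1),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 1000
    seed: int = 0
    # covariate marginals (fractions of the emulated 1043-patient table)
    stage_probs: tuple[float, ...] = (170 / _N_STUDY, 330 / _N_STUDY, 339 / _N_STUDY, 204 / _N_STUDY)
    sex_probs: tuple[float, ...] = (359 / _N_STUDY, 684 / _N_STUDY)  # Female, Male
    lauren_probs: tuple[float, ...] = (504 / _N_STUDY, 495 / _N_STUDY, 44 / _N_STUDY)  # Int, Dif, Mix
    location_probs: tuple[float, ...] = (537 / _N_STUDY, 482 / _N_STUDY, 24 / _N_STUDY)  # Dis, Pro, Whl
    treatment_probs: tuple[float, ...] = (299 / _N_STUDY, 744 / _N_STUDY)  # No, Yes
    age_median: float = 59.0
    age_sd: float = 13.3  # normal sd matching the reported IQR width (49, 67)
    age_bounds: tuple[float, float] = (18.0, 95.0)
    # Dirichlet concentrations for per-classifier probability scores
    tcga_alpha: tuple[float, ...] = tuple(2.0 * np.array([824, 43, 66, 110]) / _N_STUDY)  # CIN,EBV,GS,MSI
    acrg_alpha: tuple[float, ...] = tuple(2.0 * np.array([118, 162, 412, 351]) / _N_STUDY)  # EMT,MSI,TP53-,TP53+
    tme_beta: tuple[float, float] = (1.83, 2.17)  # mean ~ 0.46, the TME-high fraction
    baseline: BaselineHazard = field(default_factory=BaselineHazard)
    effects: dict[str, StepEffect] = field(default_factory=_default_effects)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)

    def __post_init__(self):
        for name, probs in [
            ("stage", self.stage_probs),
            ("sex", self.sex_probs),
            ("lauren", self.lauren_probs),
            ("location", self.location_probs),
            ("treatment", self.treatment_probs),
        ]:
            p = np.asarray(probs)
            if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-6:
                raise ValidationError(f"{name} probabilities must lie in [0,1] and sum to 1")

    def with_effects(self, effects: dict[str, StepEffect]) -> "SyntheticConfig":
        return replace(self, effects=dict(effects))


def default_config(**overrides) -> SyntheticConfig:
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def default_schema() -> tuple:
    """Covariate schema of the generated cohort (reference levels dropped
    from the one-hot expansion: Stage I, Female, Intestinal, Distal,
    untreated; one probability score per classifier is omitted to avoid
    the sum-to-one collinearity)."""
    return (
        Continuous("age"),
        Categorical("stage", ("I", "II", "III", "IV"), "I"),
        Categorical("sex", ("Female", "Male"), "Female"),
        Categorical("lauren", ("Intestinal", "Diffuse", "Mixed"), "Intestinal"),
        Categorical("location", ("Distal", "Proximal", "Whole"), "Distal"),
        Categorical("treatment", ("No", "Yes"), "No"),
        Continuous("tcga_ebv"),
        Continuous("tcga_gs"),
        Continuous("tcga_msi"),
        Continuous("acrg_emt"),
        Continuous("acrg_msi"),
        Continuous("acrg_mss_tp53neg"),
        Continuous("tme_score"),
    )


_TRUTH_ONEHOT = {
    "stage": ("I", ("II", "III", "IV")),
    "sex": ("Female", ("Male",)),
    "lauren": ("Intestinal", ("Diffuse", "Mixed")),
    "location": ("Distal", ("Proximal", "Whole")),
    "treatment": ("No", ("Yes",)),
}


def truth_design(df: pd.DataFrame, age_center: float = 59.0, age_scale: float = 13.3) -> pd.DataFrame:
    """Design matrix on which the generating effects are defined.

    Categorical covariates one-hot against the same reference levels as the
    default schema; age enters as ``age_z = (age - 59) / 13.3``; the
    molecular scores enter untransformed.
    """
    out = pd.DataFrame(index=df.index)
    out["age_z"] = (df["age"] - age_center) / age_scale
    for name, (_, levels) in _TRUTH_ONEHOT.items():
        for level in levels:
            out[f"{name}={level}"] = (df[name].astype(str) == level).astype(float)
    for col in ("tcga_cin", "tcga_ebv", "tcga_gs", "tcga_msi",
                "acrg_emt", "acrg_msi", "acrg_mss_tp53neg", "acrg_mss_tp53pos",
                "tme_score"):
        if col in df.columns:
            out[col] = df[col].astype(float)
    return out


def _segment_table(baseline: BaselineHazard, effects: dict[str, StepEffect]) -> np.ndarray:
    starts = set(baseline.starts)
    for eff in effects.values():
        starts.update(eff.breaks)
    return np.array(sorted(starts), dtype=float)


def _log_rate_matrix(X: pd.DataFrame, baseline: BaselineHazard,
                     effects: dict[str, StepEffect], starts: np.ndarray) -> np.ndarray:
    """n x S matrix of per-patient log hazard rates on the global segments."""
    unknown = sorted(set(effects) - set(X.columns))
    if unknown:
        raise ValidationError(f"effects refer to unknown design columns: {unknown}")
    base_idx = np.searchsorted(np.asarray(baseline.starts), starts, side="right") - 1
    log_h0 = np.log(np.asarray(baseline.rates))[base_idx]
    log_rate = np.tile(log_h0, (len(X), 1))
    for col, eff in effects.items():
        beta_s = np.array([eff.at(t) for t in starts])
        log_rate += np.outer(X[col].to_numpy(dtype=float), beta_s)
    return log_rate


def sample_event_times(X: pd.DataFrame, baseline: BaselineHazard,
                       effects: dict[str, StepEffect], rng: np.random.Generator) -> np.ndarray:
    """Draw event times from h(t|x) = h0(t) * exp(sum_c beta_c(t) x_c).

    The cumulative hazard of a piecewise-constant hazard is piecewise
    linear, so H(T) = -ln U inverts segment-by-segment in closed form.
    """
    starts = _segment_table(baseline, effects)
    rates = np.exp(_log_rate_matrix(X, baseline, effects, starts))
    if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
        raise ValidationError("degenerate hazard: non-finite or non-positive segment rate")
    durations = np.diff(starts)  # last segment is open-ended
    target = rng.exponential(size=len(X))
    cum_edges = np.concatenate(
        [np.zeros((len(X), 1)), np.cumsum(rates[:, :-1] * durations, axis=1)], axis=1
    )
    seg = (target[:, None] >= cum_edges).sum(axis=1) - 1
    rows = np.arange(len(X))
    return starts[seg] + (target - cum_edges[rows, seg]) / rates[rows, seg]


def apply_censoring(true_times: np.ndarray, spec: CensoringSpec,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply administrative + uniform censoring.

    Returns (observed_time, event, censor_time); observed = min(T, C) and
    event = 1(T <= C).
    """
    true_times = np.asarray(true_times, dtype=float)
    n = true_times.size
    censor = np.full(n, spec.horizon)
    if spec.uniform_prob > 0:
        drawn = rng.random(n) < spec.uniform_prob
        censor[drawn] = rng.uniform(0.0, spec.uniform_upper, size=int(drawn.sum()))
    observed = np.minimum(true_times, censor)
    event = (true_times <= censor).astype(int)
    return observed, event, censor


@dataclass
class GroundTruth:
    """Everything the generator knew: true covariate design, effect
    functions, per-patient segment rates, and uncensored event times.

    Enables closed-form evaluation of the *true* survival function for any
    patient — the oracle model against which calibration tests and
    discrimination metrics are themselves validated.
    """

    design: pd.DataFrame
    true_time: np.ndarray
    censor_time: np.ndarray
    observed_time: np.ndarray
    event: np.ndarray
    segment_starts: np.ndarray
    rates: np.ndarray  # n x S
    effects: dict[str, StepEffect]
    config: SyntheticConfig

    def cumulative_hazard(self, times) -> np.ndarray:
        """n x len(times) matrix of true cumulative hazards H_i(t)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        starts = self.segment_starts
        ends = np.append(starts[1:], np.inf)
        H = np.zeros((self.rates.shape[0], times.size))
        for s in range(starts.size):
            overlap = np.clip(np.minimum(times, ends[s]) - starts[s], 0.0, None)
            H += np.outer(self.rates[:, s], overlap)
        return H

    def survival(self, times) -> np.ndarray:
        """n x len(times) matrix of true survival probabilities S_i(t)."""
        return np.exp(-self.cumulative_hazard(times))

    def survival_at_own_time(self, times=None) -> np.ndarray:
        """S_i evaluated at each patient's own (observed) time."""
        t = self.observed_time if times is None else np.asarray(times, dtype=float)
        starts = self.segment_starts
        ends = np.append(starts[1:], np.inf)
        H = np.zeros(self.rates.shape[0])
        for s in range(starts.size):
            H += self.rates[:, s] * np.clip(np.minimum(t, ends[s]) - starts[s], 0.0, None)
        return np.exp(-H)

    def true_median(self) -> np.ndarray:
        """Per-patient true median survival time (H_i(t) = ln 2)."""
        target = math.log(2.0)
        starts = self.segment_starts
        durations = np.diff(starts)
        n = self.rates.shape[0]
        cum_edges = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(self.rates[:, :-1] * durations, axis=1)], axis=1
        )
        seg = (target >= cum_edges).sum(axis=1) - 1
        rows = np.arange(n)
        return starts[seg] + (target - cum_edges[rows, seg]) / self.rates[rows, seg]

    def true_curves(self, grid: np.ndarray):
        """True SurvivalCurve per patient on the given positive time grid."""
        from .curves import SurvivalCurve

        grid = np.asarray(grid, dtype=float)
        surv = self.survival(grid)
        times = np.concatenate([[0.0], grid])
        return [SurvivalCurve(times, np.concatenate([[1.0], surv[i]])) for i in range(surv.shape[0])]

    @property
    def censored_fraction(self) -> float:
        return float(1.0 - self.event.mean())


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n
    a, b = (np.array(cfg.age_bounds) - cfg.age_median) / cfg.age_sd
    age = truncnorm.rvs(a, b, loc=cfg.age_median, scale=cfg.age_sd, size=n, random_state=rng)
    df = pd.DataFrame(
        {
            "age": age,
            "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=cfg.stage_probs),
            "sex": rng.choice(["Female", "Male"], size=n, p=cfg.sex_probs),
            "lauren": rng.choice(["Intestinal", "Diffuse", "Mixed"], size=n, p=cfg.lauren_probs),
            "location": rng.choice(["Distal", "Proximal", "Whole"], size=n, p=cfg.location_probs),
            "treatment": rng.choice(["No", "Yes"], size=n, p=cfg.treatment_probs),
        }
    )
    tcga = rng.dirichlet(cfg.tcga_alpha, size=n)
    acrg = rng.dirichlet(cfg.acrg_alpha, size=n)
    for j, name in enumerate(["tcga_cin", "tcga_ebv", "tcga_gs", "tcga_msi"]):
        df[name] = tcga[:, j]
    for j, name in enumerate(["acrg_emt", "acrg_msi", "acrg_mss_tp53neg", "acrg_mss_tp53pos"]):
        df[name] = acrg[:, j]
    df["tme_score"] = rng.beta(*cfg.tme_beta, size=n)
    return df


def generate_cohort(config: SyntheticConfig | None = None, **overrides) -> tuple[CohortTable, GroundTruth]:
    """Generate a synthetic cohort plus its ground truth.

    Fully reproducible under ``config.seed``; covariates are drawn
    independently from the configured marginals, event times from the
    piecewise-exponential hazard, and censoring per the censoring spec.
    """
    cfg = config if config is not None else SyntheticConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    raw = _draw_covariates(cfg, rng)
    X = truth_design(raw, cfg.age_median, cfg.age_sd)
    starts = _segment_table(cfg.baseline, cfg.effects)
    rates = np.exp(_log_rate_matrix(X, cfg.baseline, cfg.effects, starts))
    if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
        raise ValidationError("degenerate hazard: non-finite or non-positive segment rate")
    durations = np.diff(starts)
    target = rng.exponential(size=cfg.n)
    cum_edges = np.concatenate(
        [np.zeros((cfg.n, 1)), np.cumsum(rates[:, :-1] * durations, axis=1)], axis=1
    )
    seg = (target[:, None] >= cum_edges).sum(axis=1) - 1
    rows = np.arange(cfg.n)
    true_time = starts[seg] + (target - cum_edges[rows, seg]) / rates[rows, seg]
    observed, event, censor = apply_censoring(true_time, cfg.censoring, rng)

    table = raw.copy()
    table.insert(0, "event", event)
    table.insert(0, "time_months", observed)
    cohort = cohort_from_frame(table, default_schema())
    truth = GroundTruth(
        design=X,
        true_time=true_time,
        censor_time=censor,
        observed_time=observed,
        event=event,
        segment_starts=starts,
        rates=rates,
        effects=dict(cfg.effects),
        config=cfg,
    )
    return cohort, truth


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    out = truth.design.copy()
    out.insert(0, "event", truth.event)
    out.insert(0, "censor_time", truth.censor_time)
    out.insert(0, "true_time", truth.true_time)
    out.insert(0, "observed_time", truth.observed_time)
    return out
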