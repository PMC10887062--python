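"""Patient-level survival tables: schema, validation, design encoding, CV splits.

The cohort layer turns a CSV of overall-survival times, event indicators and
raw covariates into the numeric design matrix shared by every survival model
in the package.  Records with missing values for any declared covariate are
excluded (the pooled gastric-cancer study did the same), categorical
covariates are one-hot encoded against a declared reference level, and
continuous covariates may be standardized with constants learned on the
training fold only so cross-validation never leaks scale information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import SchemaError, ValidationError

__all__ = [
    "Continuous",
    "Categorical",
    "CohortTable",
    "CovariateDesign",
    "read_cohort_csv",
    "encode_design",
    "stratified_kfold_split",
    "TIME_COL",
    "EVENT_COL",
]

TIME_COL = "time_months"
EVENT_COL = "event"


@dataclass(frozen=True)
class Continuous:
    """A continuous covariate (age in years, subtype probability score, ...)."""

    name: str


@dataclass(frozen=True)
class Categorical:
    """A categorical covariate with declared levels and a reference level.

    One-hot encoding drops the reference level, so a patient at reference
    encodes all-zero for this covariate.
    """

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if self.reference not in self.levels:
            raise SchemaError(
                f"reference level {self.reference!r} of {self.name!r} not among levels {self.levels}"
            )


Schema = Sequence[Continuous | Categorical]


def schema_from_dict(spec: dict) -> tuple:
    """Build a schema from a plain mapping (as loaded from a YAML config).

    ``{"age": {"type": "continuous"}, "stage": {"type": "categorical",
    "levels": [...], "reference": "I"}}``
    """
    out = []
    for name, entry in spec.items():
        kind = entry.get("type", "continuous")
        if kind == "continuous":
            out.append(Continuous(name))
        elif kind == "categorical":
            out.append(Categorical(name, tuple(entry["levels"]), entry["reference"]))
        else:
            raise SchemaError(f"unknown covariate type {kind!r} for {name!r}")
    return tuple(out)


def schema_to_dict(schema: Schema) -> dict:
    out: dict = {}
    for cov in schema:
        if isinstance(cov, Continuous):
            out[cov.name] = {"type": "continuous"}
        else:
            out[cov.name] = {
                "type": "categorical",
                "levels": list(cov.levels),
                "reference": cov.reference,
            }
    return out


@dataclass
class CohortTable:
    """Validated patient-level table with survival outcome and covariates."""

    df: pd.DataFrame
    schema: tuple
    dropped_count: int = 0

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        self.schema = tuple(self.schema)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df[TIME_COL].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.df[EVENT_COL].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def covariate_names(self) -> list[str]:
        return [c.name for c in self.schema]

    def subset(self, idx) -> "CohortTable":
        return CohortTable(self.df.iloc[np.asarray(idx)].copy(), self.schema, 0)

    def write_csv(self, path) -> None:
        cols = [TIME_COL, EVENT_COL] + self.covariate_names()
        extra = [c for c in self.df.columns if c not in cols]
        self.df[cols + extra].to_csv(path, index=False)


def _validate_rows(df: pd.DataFrame, schema: Schema, strict: bool) -> tuple[pd.DataFrame, int]:
    cov_names = [c.name for c in schema]
    needed = [TIME_COL, EVENT_COL] + cov_names
    keep = pd.Series(True, index=df.index)

    missing = df[needed].isna().any(axis=1)
    keep &= ~missing

    times = pd.to_numeric(df[TIME_COL], errors="coerce")
    bad_time = times.isna() | (times <= 0) | ~np.isfinite(times)
    bad_time &= ~missing  # rows already dropped for missingness are not "bad"
    if strict and bad_time.any():
        row = int(df.index[bad_time][0])
        raise ValidationError(f"row {row}: non-positive or non-numeric {TIME_COL}")
    keep &= ~bad_time

    events = pd.to_numeric(df[EVENT_COL], errors="coerce")
    bad_event = ~events.isin([0, 1])
    bad_event &= ~missing
    if strict and bad_event.any():
        row = int(df.index[bad_event][0])
        raise ValidationError(f"row {row}: event indicator must be 0 or 1")
    keep &= ~bad_event

    for cov in schema:
        if isinstance(cov, Categorical):
            col = df[cov.name].astype(str)
            bad = ~col.isin(cov.levels) & ~df[cov.name].isna()
            if strict and bad.any():
                row = int(df.index[bad][0])
                raise ValidationError(
                    f"row {row}: level {col[bad].iloc[0]!r} of {cov.name!r} not in schema"
                )
            keep &= ~bad

    out = df.loc[keep].copy()
    out[TIME_COL] = pd.to_numeric(out[TIME_COL])
    out[EVENT_COL] = pd.to_numeric(out[EVENT_COL]).astype(int)
    return out, int((~keep).sum())


def read_cohort_csv(path, schema: Schema, strict: bool = False) -> CohortTable:
    """Read and validate a cohort CSV.

    The file must have a header with ``time_months``, ``event`` and one
    column per schema covariate.  Rows with missing schema fields are
    dropped and counted; invalid times/events/levels are dropped under
    ``strict=False`` and fatal under ``strict=True``.
    """
    df = pd.read_csv(path)
    cov_names = [c.name for c in schema]
    missing_cols = [c for c in [TIME_COL, EVENT_COL] + cov_names if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort CSV is missing columns: {missing_cols}")
    clean, dropped = _validate_rows(df, schema, strict)
    return CohortTable(clean, tuple(schema), dropped)


def cohort_from_frame(df: pd.DataFrame, schema: Schema, strict: bool = False) -> CohortTable:
    """Validate an in-memory DataFrame the same way as :func:`read_cohort_csv`."""
    clean, dropped = _validate_rows(df, schema, strict)
    return CohortTable(clean, tuple(schema), dropped)


@dataclass
class CovariateDesign:
    """Numeric design matrix plus the constants needed to rebuild it.

    ``matrix`` is the encoded design of the cohort the design was fitted
    on; :meth:`transform` applies the identical encoding (and the stored
    centering/scaling constants) to new records.
    """

    schema: tuple
    column_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    standardize: bool
    matrix: np.ndarray
    zero_variance: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.column_names)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        raw, names = _raw_matrix(df, self.schema)
        if names != self.column_names:
            raise SchemaError("column layout of new data does not match the design")
        return (raw - self.center) / self.scale

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.center


def _raw_matrix(df: pd.DataFrame, schema: Schema) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in schema:
        if isinstance(cov, Continuous):
            cols.append(pd.to_numeric(df[cov.name]).to_numpy(dtype=float))
            names.append(cov.name)
        else:
            vals = df[cov.name].astype(str)
            unseen = sorted(set(vals) - set(cov.levels))
            if unseen:
                raise SchemaError(f"unseen level(s) {unseen} for covariate {cov.name!r}")
            for level in cov.levels:
                if level == cov.reference:
                    continue
                cols.append((vals == level).to_numpy(dtype=float))
                names.append(f"{cov.name}={level}")
    return np.column_stack(cols) if cols else np.empty((len(df), 0)), names


def encode_design(cohort: CohortTable, standardize: bool = True) -> CovariateDesign:
    """Encode a cohort into a numeric design.

    Categorical covariates expand to one-hot columns against their reference
    level, in schema order then level order.  Continuous covariates are
    centered and scaled to unit sample variance (n-1 denominator) when
    ``standardize`` is true; constant columns are flagged and left
    untouched rather than divided by zero.
    """
    raw, names = _raw_matrix(cohort.df, cohort.schema)
    center = np.zeros(raw.shape[1])
    scale = np.ones(raw.shape[1])
    zero_var: list[str] = []
    if standardize:
        cont = {c.name for c in cohort.schema if isinstance(c, Continuous)}
        for j, name in enumerate(names):
            if name not in cont:
                continue
            sd = float(np.std(raw[:, j], ddof=1)) if raw.shape[0] > 1 else 0.0
            if sd == 0.0:
                zero_var.append(name)
                continue
            center[j] = float(np.mean(raw[:, j]))
            scale[j] = sd
    return CovariateDesign(
        schema=cohort.schema,
        column_names=names,
        center=center,
        scale=scale,
        standardize=standardize,
        matrix=(raw - center) / scale,
        zero_variance=zero_var,
    )


def stratified_kfold_split(cohort: CohortTable, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Event-stratified k-fold partition of cohort indices.

    Every index lands in exactly one test fold, and the number of events per
    fold differs by at most one from perfect proportionality.  Reproducible
    under ``seed``.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > cohort.n:
        raise ValidationError(f"k = {k} exceeds cohort size n = {cohort.n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dummy = np.zeros(cohort.n)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(dummy, cohort.events)]
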