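"""Individual survival curves and monotone spline utilities.

A :class:`SurvivalCurve` is the package's exchange format for an individual
survival distribution (ISD): a non-increasing step of probabilities
``S(t)`` anchored at ``S(0) = 1``.  Between knots the curve is interpolated
with a monotonicity-preserving cubic Hermite spline (Fritsch–Carlson slope
filter, the same family as Hyman-filtered Hermite interpolation), so the
interpolant never overshoots neighbouring knot values.  Beyond the last
knot the curve is extended linearly with the final segment's slope and
floored at zero — MTLR grids frequently end while the curve is still above
0.5, and the median would otherwise be undefined.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .exceptions import ValidationError

__all__ = ["SurvivalCurve", "monotone_spline", "NOT_REACHED"]

#: Marker returned by :meth:`SurvivalCurve.median` when the (extended)
#: curve never crosses 0.5.
NOT_REACHED = math.inf

_MONOTONE_TOL = 1e-9


class SurvivalCurve:
    """A per-patient survival probability curve.

    Parameters
    ----------
    times:
        Increasing time points (months), starting at 0.
    probs:
        Survival probabilities in ``[0, 1]``, starting at 1, non-increasing.
        Violations of monotonicity larger than 1e-9 raise; smaller ones
        (floating-point noise from model prediction) are clamped.
    """

    def __init__(self, times, probs):
        times = np.asarray(times, dtype=float)
        probs = np.asarray(probs, dtype=float)
        if times.ndim != 1 or times.shape != probs.shape or times.size < 2:
            raise ValidationError("curve needs matching 1-d times/probs with >= 2 knots")
        if times[0] != 0.0:
            raise ValidationError("curve must start at t = 0")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("curve times must be strictly increasing")
        if abs(probs[0] - 1.0) > _MONOTONE_TOL:
            raise ValidationError("curve must start at S(0) = 1")
        if np.any(probs < -_MONOTONE_TOL) or np.any(probs > 1 + _MONOTONE_TOL):
            raise ValidationError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(probs) > _MONOTONE_TOL):
            raise ValidationError("survival probabilities must be non-increasing")
        probs = np.clip(probs, 0.0, 1.0)
        probs[0] = 1.0
        # clamp sub-tolerance wiggles so downstream interpolation is monotone
        probs = np.minimum.accumulate(probs)
        self.times = times
        self.probs = probs
        self._spline = None

    def __len__(self) -> int:
        return self.times.size

    def __repr__(self) -> str:
        return f"SurvivalCurve({len(self)} knots, last S({self.times[-1]:g}) = {self.probs[-1]:.3f})"

    @property
    def spline(self):
        if self._spline is None:
            self._spline = monotone_spline(self)
        return self._spline

    def _tail_slope(self) -> float:
        return (self.probs[-1] - self.probs[-2]) / (self.times[-1] - self.times[-2])

    def survival_at(self, t):
        """Survival probability at time ``t`` (scalar or array), ``t >= 0``.

        Uses the monotone spline within the knot range and the linear
        tail extension (floored at zero) beyond it.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValidationError("survival queried at negative time")
        inside = t_arr <= self.times[-1]
        out = np.empty_like(t_arr, dtype=float)
        if np.any(inside):
            out[inside] = np.clip(self.spline(t_arr[inside]), 0.0, 1.0)
        if np.any(~inside):
            ext = self.probs[-1] + self._tail_slope() * (t_arr[~inside] - self.times[-1])
            out[~inside] = np.clip(ext, 0.0, 1.0)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def median(self) -> float:
        """Median survival time: the crossing of the interpolant at S = 0.5.

        Returns :data:`NOT_REACHED` (``inf``) when the extended curve never
        reaches 0.5.
        """
        return self.time_at_probability(0.5)

    def time_at_probability(self, p: float) -> float:
        """First time at which the (extended) curve reaches probability ``p``."""
        if not 0.0 < p < 1.0:
            raise ValidationError("probability threshold must lie in (0, 1)")
        if self.probs[-1] > p:
            slope = self._tail_slope()
            if slope >= 0.0:
                return NOT_REACHED
            return self.times[-1] + (p - self.probs[-1]) / slope
        # bracket the first knot interval where the curve crosses p
        idx = int(np.argmax(self.probs <= p))  # first knot at or below p
        if self.probs[idx] == p:
            return float(self.times[idx])
        lo, hi = self.times[idx - 1], self.times[idx]
        f = lambda t: float(self.spline(t)) - p
        return float(brentq(f, lo, hi, xtol=1e-6))

    def restricted_mean(self, t_max: float) -> float:
        """Restricted mean survival time: integral of the interpolant on [0, t_max]."""
        if t_max <= 0:
            raise ValidationError("t_max must be positive")
        t_end = min(t_max, self.times[-1])
        area = float(self.spline.antiderivative()(t_end) - self.spline.antiderivative()(0.0))
        if t_max > self.times[-1]:
            # integrate the linear tail, clipped at zero
            grid = np.linspace(self.times[-1], t_max, 257)
            area += float(np.trapezoid(self.survival_at(grid), grid))
        return area

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_months": self.times, "survival_prob": self.probs})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["survival_prob"].to_numpy())


def monotone_spline(curve: SurvivalCurve) -> PchipInterpolator:
    """Monotone-preserving C1 cubic Hermite interpolant through the knots.

    The Fritsch–Carlson filter limits the Hermite slopes so the interpolant
    is monotone wherever the knots are, and exactly flat across equal
    adjacent knot values.
    """
    if curve.times.size < 2:
        raise ValidationError("spline needs at least 2 knots")
    return PchipInterpolator(curve.times, curve.probs, extrapolate=False)


def survival_at_time(curve: SurvivalCurve, t) -> float:
    """Functional alias for :meth:`SurvivalCurve.survival_at`."""
    return curve.survival_at(t)


def median_survival_time(curve: SurvivalCurve) -> float:
    """Functional alias for :meth:`SurvivalCurve.median`."""
    return curve.median()
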