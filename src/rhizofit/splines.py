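"""Non-parametric cubic smoothing splines and finite-difference rates.

The spline path exists to check that rate estimates are not artifacts of the
parametric growth-model choice: the same colonization/proliferation series
are smoothed with cubic splines, differentiated by finite differences, and
the resulting rates compared with the parametric ones.

Replicated (duplicate-time) observations are reduced to per-time means with
weights equal to replicate counts before smoothing; when no smoothing value
is supplied the penalty is chosen by generalized cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .data import NormalizedSeries
from .exceptions import DomainError, ValidationError

__all__ = ["SplineCurve", "FiniteDifferenceRates", "fit_spline", "spline_rate"]


@dataclass(frozen=True)
class FiniteDifferenceRates:
    """Rates from finite differences plus evaluation metadata.

    ``one_sided`` flags grid points within one step of the domain boundary
    where a one-sided difference replaced the central one.
    """

    grid: np.ndarray
    values: np.ndarray
    step: float
    one_sided: np.ndarray


@dataclass(frozen=True)
class SplineCurve:
    """A fitted cubic smoothing spline with its evaluation domain."""

    spline: object  # scipy BSpline
    smoothing: float | None
    t_min: float
    t_max: float

    def __call__(self, t):
        tt = np.asarray(t, dtype=float)
        out = self.spline(tt)
        return float(out) if tt.ndim == 0 else out


def fit_spline(series, values=None, smoothing: float | None = None) -> SplineCurve:
    """Cubic smoothing spline through a pooled series.

    Parameters
    ----------
    series
        A :class:`~rhizofit.data.NormalizedSeries`, or a times array when
        ``values`` is also given.
    smoothing
        Penalty weight ``lam`` of the penalized least-squares problem;
        ``None`` selects it by generalized cross-validation, ``0`` yields the
        natural interpolating cubic spline.
    """
    if isinstance(series, NormalizedSeries):
        t, y = series.times, series.values
    else:
        if values is None:
            raise ValidationError("pass a NormalizedSeries or both times and values")
        t = np.asarray(series, dtype=float)
        y = np.asarray(values, dtype=float)
    # collapse replicate measurements to weighted per-time means
    ut, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if ut.size < 5:
        raise ValidationError(f"spline fitting needs >= 5 distinct timepoints, got {ut.size}")
    ym = np.bincount(inverse, weights=y) / counts
    spl = make_smoothing_spline(ut, ym, w=counts.astype(float), lam=smoothing)
    return SplineCurve(spline=spl, smoothing=smoothing, t_min=float(ut[0]), t_max=float(ut[-1]))


def spline_rate(curve: SplineCurve, grid, step: float = 1.0) -> FiniteDifferenceRates:
    """Finite-difference derivative of a spline on a grid (rate per hour).

    Central differences with the given step; grid points within one step of
    the domain boundary fall back to one-sided differences (flagged in the
    returned metadata).  Grid points outside the fitted domain raise.
    """
    if step <= 0:
        raise ValidationError("step must be > 0")
    g = np.asarray(grid, dtype=float)
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    if np.any(g < curve.t_min) or np.any(g > curve.t_max):
        raise DomainError(
            f"grid must lie within the spline domain [{curve.t_min}, {curve.t_max}]"
        )
    lo_ok = g - step >= curve.t_min
    hi_ok = g + step <= curve.t_max
    central = lo_ok & hi_ok
    values = np.empty_like(g)
    values[central] = (curve(g[central] + step) - curve(g[central] - step)) / (2 * step)
    fwd = ~central & hi_ok
    values[fwd] = (curve(g[fwd] + step) - curve(g[fwd])) / step
    bwd = ~central & ~hi_ok
    values[bwd] = (curve(g[bwd]) - curve(g[bwd] - step)) / step
    rates = FiniteDifferenceRates(grid=g, values=values, step=step, one_sided=~central)
    return rates
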