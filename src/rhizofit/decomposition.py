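"""Decomposition of total colonization rate into attachment and proliferation.

The root-surface density from the total-colonization experiment follows a
logistic curve ``y_c(t)`` with parameters ``(K_c, y_c0, mu_c)``.  Bacteria on
the root also proliferate in place with the smaller rate constant ``mu_p``
estimated from the proliferation-only experiment (plants moved to sterile
microcosms 2 h after inoculation, so attachment cannot continue).  The total
colonization rate then splits as

    R_c(t) = dy_c/dt = mu_c y_c (1 - y_c/K_c)          total
    R_p(t) = mu_p y_c (1 - y_c/K_c)                    proliferation in place
    R_a(t) = R_c(t) - R_p(t)                           attachment (recruitment)

so attachment — which no destructive assay can observe directly — is the
difference of two measurable rates.  Integrating ``R_a`` gives the cumulative
density recruited from the medium, and the contribution proportion

    p(t) = R_a(t) / ( K_c * \\int_t^T mu_p y_c (1 - y_c/K_c) dt )

weighs attachment at time ``t`` against all future proliferation up to the
experiment horizon ``T`` (96 h by default).  The denominator vanishes at the
horizon, so ``p`` is undefined there; it is also dimensionally a rate over a
density (h^-1) although the source framework names it a proportion — the
formula is implemented literally.

For logistic inputs ``R_a`` is an exact quadratic in ``y_c``:
``R_a = (mu_c - mu_p)(y_c - y_c^2/K_c)``, which the quadratic-relation fit
recovers from gridded (y_c, R_a) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, InvalidParameterError, SingularDesignError, ValidationError
from .models import LogisticParams, logistic_density
from .splines import SplineCurve, fit_spline, spline_rate

__all__ = [
    "AttachmentDecomposition",
    "RateCurves",
    "QuadraticRelation",
    "CrossCheckReport",
    "colonization_rate",
    "proliferation_rate",
    "attachment_rate",
    "attached_cumulative",
    "contribution_proportion",
    "fit_quadratic_relation",
    "spline_cross_check",
]


def colonization_rate(p: LogisticParams, t):
    """Total colonization rate ``R_c(t)``: the exact time-derivative of the
    logistic curve, ``mu K (K/y0 - 1) e^{-mu t} / (1 + (K/y0 - 1) e^{-mu t})^2``,
    identically equal to ``mu y_c(t) (1 - y_c(t)/K)``."""
    if p.y0 >= p.K:
        raise InvalidParameterError("colonization rate requires y0 < K")
    tt = np.asarray(t, dtype=float)
    q = (p.K / p.y0 - 1.0) * np.exp(-p.mu * tt)
    r = p.mu * p.K * q / (1.0 + q) ** 2
    return float(r) if tt.ndim == 0 else r


def proliferation_rate(mu_p: float, y_c, K_c: float):
    """On-root proliferation rate ``R_p = mu_p y_c (K_c - y_c) / K_c`` at
    colonization density ``y_c`` (zero at ``y_c = 0`` and ``y_c = K_c``)."""
    y = np.asarray(y_c, dtype=float)
    r = mu_p * y * (K_c - y) / K_c
    return float(r) if y.ndim == 0 else r


@dataclass(frozen=True)
class QuadraticRelation:
    """Least-squares quadratic ``R_a = c0 + c1 y_c + c2 y_c^2``."""

    c0: float
    c1: float
    c2: float

    @property
    def vertex_yc(self) -> float:
        """Density at which attachment peaks, ``-c1 / (2 c2)``."""
        return -self.c1 / (2.0 * self.c2)

    @property
    def peak_rate(self) -> float:
        return self.c0 + self.c1 * self.vertex_yc + self.c2 * self.vertex_yc**2

    def __call__(self, y_c):
        y = np.asarray(y_c, dtype=float)
        out = self.c0 + self.c1 * y + self.c2 * y**2
        return float(out) if y.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"c0": self.c0, "c1": self.c1, "c2": self.c2,
              "vertex_yc": self.vertex_yc, "peak_Ra": self.peak_rate}]
        )


def fit_quadratic_relation(y_c_grid, r_a_grid) -> QuadraticRelation:
    """OLS of attachment rate on ``(1, y_c, y_c^2)``.

    Exact for logistic inputs: ``c1 -> mu_c - mu_p``,
    ``c2 -> -(mu_c - mu_p)/K_c``, ``c0 -> 0``.
    """
    y = np.asarray(y_c_grid, dtype=float)
    r = np.asarray(r_a_grid, dtype=float)
    if y.size != r.size or np.unique(y).size < 3:
        raise ValidationError("quadratic fit needs >= 3 distinct y_c values")
    design = np.column_stack([np.ones_like(y), y, y**2])
    if np.linalg.matrix_rank(design) < 3:
        raise SingularDesignError("collinear (y_c, y_c^2) design; quadratic unidentifiable")
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    rel = QuadraticRelation(*map(float, coef))
    # a (near-)linear relation leaves the curvature unidentified and the
    # vertex -c1/(2 c2) undefined
    scale = max(abs(rel.c1) / max(np.ptp(y), 1e-300), abs(rel.c2), 1e-300)
    if abs(rel.c2) < 1e-9 * scale:
        raise SingularDesignError(
            "attachment rate is (numerically) linear in y_c: curvature c2 ~ 0, "
            "quadratic vertex undefined"
        )
    return rel


@dataclass(frozen=True)
class RateCurves:
    """Gridded decomposition output.

    ``attached_cumulative`` is the trapezoidal integral of ``R_a`` from the
    first grid point; ``p`` is the contribution proportion, NaN at any grid
    point at or beyond the horizon where its denominator vanishes.
    """

    grid: np.ndarray
    y_c: np.ndarray
    R_c: np.ndarray
    R_p: np.ndarray
    R_a: np.ndarray
    attached_cumulative: np.ndarray
    p: np.ndarray
    colonization: LogisticParams
    mu_p: float
    horizon_h: float

    @property
    def peak_attachment_rate(self) -> float:
        return float(self.R_a.max())

    @property
    def peak_attachment_time(self) -> float:
        return float(self.grid[np.argmax(self.R_a)])

    @property
    def attached_fraction(self) -> float:
        """Share of the density gained over the grid that came from attachment."""
        gained = self.y_c[-1] - self.y_c[0]
        return float(self.attached_cumulative[-1] / gained)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.grid,
                "y_c": self.y_c,
                "R_c": self.R_c,
                "R_p": self.R_p,
                "R_a": self.R_a,
                "attached_cumulative": self.attached_cumulative,
                "p_t": self.p,
            }
        )

    def summary(self) -> str:
        lines = [
            "Attachment decomposition",
            "=" * 58,
            f"colonization: K_c={self.colonization.K:.6g}, y_c0={self.colonization.y0:.6g}, "
            f"mu_c={self.colonization.mu:.6g} h^-1",
            f"proliferation rate constant mu_p={self.mu_p:.6g} h^-1",
            f"grid: {self.grid[0]:g}..{self.grid[-1]:g} h "
            f"({self.grid.size} points), horizon {self.horizon_h:g} h",
            "-" * 58,
            f"peak attachment rate : {self.peak_attachment_rate:.4g} g^-1 h^-1 "
            f"at t = {self.peak_attachment_time:g} h",
            f"attachment at t={self.grid[0]:g} h : {self.R_a[0]:.4g} g^-1 h^-1",
            f"attachment at t={self.grid[-1]:g} h : {self.R_a[-1]:.4g} g^-1 h^-1",
            f"cumulative attached density : {self.attached_cumulative[-1]:.4g} g^-1",
            f"attached fraction of density gain : {self.attached_fraction:.4f} "
            f"(closed form 1 - mu_p/mu_c = {1 - self.mu_p / self.colonization.mu:.4f})",
            "=" * 58,
        ]
        return "\n".join(lines)


class AttachmentDecomposition:
    """Rate decomposition for one colonization/proliferation experiment pair.

    Parameters
    ----------
    colonization
        Logistic parameters of the *total colonization* fit (``K_c``,
        ``y_c0``, ``mu_c``); requires ``y_c0 < K_c``.
    mu_p
        Proliferation rate constant (h^-1) from the proliferation-only fit.
    horizon_h
        Experiment end ``T`` used by the contribution proportion (default 96).
    grid_step_h
        Default grid spacing in hours.

    ``mu_p > mu_c`` makes the attachment rate negative everywhere; it is
    allowed (net loss of bacteria from the root) but warned about loudly.
    """

    def __init__(self, colonization: LogisticParams, mu_p: float,
                 horizon_h: float = 96.0, grid_step_h: float = 1.0):
        if colonization.y0 >= colonization.K:
            raise InvalidParameterError("decomposition requires y_c0 < K_c")
        if horizon_h <= 0 or grid_step_h <= 0:
            raise ValidationError("horizon_h and grid_step_h must be > 0")
        if mu_p < 0:
            raise InvalidParameterError("mu_p must be >= 0")
        if mu_p > colonization.mu:
            warnings.warn(
                f"mu_p ({mu_p:.4g}) exceeds mu_c ({colonization.mu:.4g}): attachment "
                "rates will be negative (net loss from the root surface)",
                UserWarning, stacklevel=2,
            )
        self.colonization = colonization
        self.mu_p = float(mu_p)
        self.horizon_h = float(horizon_h)
        self.grid_step_h = float(grid_step_h)

    # -- pointwise rates ---------------------------------------------------
    def density(self, t):
        return logistic_density(self.colonization, t)

    def colonization_rate(self, t):
        return colonization_rate(self.colonization, t)

    def proliferation_rate(self, t):
        return proliferation_rate(self.mu_p, self.density(t), self.colonization.K)

    def attachment_rate(self, t):
        """``R_a(t) = R_c(t) - R_p(t) = (mu_c - mu_p) y_c (1 - y_c/K_c)``."""
        return self.colonization_rate(t) - self.proliferation_rate(t)

    # -- gridded quantities ------------------------------------------------
    def default_grid(self) -> np.ndarray:
        """Hourly-style grid from t = grid step to the horizon."""
        return np.arange(self.grid_step_h, self.horizon_h + 0.5 * self.grid_step_h,
                         self.grid_step_h)

    def attached_cumulative(self, grid) -> np.ndarray:
        """Trapezoidal cumulative integral of ``R_a`` along a sorted grid."""
        g = np.asarray(grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if g[0] < 0 or g[-1] > self.horizon_h:
            raise ValidationError(f"grid must lie within [0, {self.horizon_h}]")
        ra = np.asarray(self.attachment_rate(g), dtype=float)
        out = np.zeros_like(g)
        if g.size > 1:
            out[1:] = np.cumsum(0.5 * (ra[1:] + ra[:-1]) * np.diff(g))
        return out

    def contribution_proportion(self, t: float, grid_step: float | None = None) -> float:
        """Contribution proportion ``p(t)`` by trapezoidal quadrature of the
        future-proliferation denominator on a grid from ``t`` to the horizon.

        Undefined at the horizon itself (the denominator integral vanishes
        there), hence ``t`` must not reach it.
        """
        step = self.grid_step_h if grid_step is None else float(grid_step)
        if not 0.0 <= t <= self.horizon_h - step:
            raise DomainError(
                f"p(t) requires 0 <= t <= horizon - grid_step = {self.horizon_h - step}; the "
                f"denominator integral vanishes at the horizon t = {self.horizon_h}"
            )
        g = np.arange(t, self.horizon_h + 0.5 * step, step)
        if g[-1] < self.horizon_h:
            g = np.append(g, self.horizon_h)
        integrand = self.proliferation_rate(g)
        denom = self.colonization.K * np.trapezoid(integrand, g)
        return float(self.attachment_rate(t) / denom)

    def rates(self, grid=None) -> RateCurves:
        """Evaluate the full decomposition on a grid (default hourly 1..horizon)."""
        g = self.default_grid() if grid is None else np.asarray(grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValidationError("grid must be strictly increasing")
        y_c = np.asarray(self.density(g), dtype=float)
        r_c = np.asarray(self.colonization_rate(g), dtype=float)
        r_p = np.asarray(proliferation_rate(self.mu_p, y_c, self.colonization.K), dtype=float)
        r_a = r_c - r_p
        cum = self.attached_cumulative(g)
        # shared reverse cumulative quadrature of the p(t) denominator
        tail = np.zeros_like(g)
        seg = 0.5 * (r_p[1:] + r_p[:-1]) * np.diff(g)
        tail[:-1] = np.cumsum(seg[::-1])[::-1]
        if g[-1] < self.horizon_h:
            gg = np.linspace(g[-1], self.horizon_h,
                             max(2, int(np.ceil((self.horizon_h - g[-1]) / self.grid_step_h)) + 1))
            tail += np.trapezoid(self.proliferation_rate(gg), gg)
        denom = self.colonization.K * tail
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, r_a / denom, np.nan)
        return RateCurves(
            grid=g, y_c=y_c, R_c=r_c, R_p=r_p, R_a=r_a,
            attached_cumulative=cum, p=p,
            colonization=self.colonization, mu_p=self.mu_p, horizon_h=self.horizon_h,
        )

    def quadratic_relation(self, grid=None) -> QuadraticRelation:
        rc = self.rates(grid)
        return fit_quadratic_relation(rc.y_c, rc.R_a)


# ---------------------------------------------------------------------------
# module-level functional forms mirroring the object API


def attachment_rate(decomposition: AttachmentDecomposition, t):
    return decomposition.attachment_rate(t)


def attached_cumulative(decomposition: AttachmentDecomposition, grid):
    return decomposition.attached_cumulative(grid)


def contribution_proportion(decomposition: AttachmentDecomposition, t,
                            grid_step: float | None = None):
    return decomposition.contribution_proportion(t, grid_step)


@dataclass(frozen=True)
class CrossCheckReport:
    """Agreement between the parametric and spline-based attachment rates."""

    grid: np.ndarray
    ra_parametric: np.ndarray
    ra_spline: np.ndarray
    max_abs_deviation: float
    max_rel_deviation: float
    rel_threshold: float
    peak_time_parametric: float
    peak_time_spline: float
    mu_p: float


def spline_cross_check(colonization_series, proliferation_series,
                       parametric: RateCurves, mu_p: float | None = None,
                       smoothing: float | None = None,
                       rel_threshold: float = 0.01) -> CrossCheckReport:
    """Recompute the attachment rate non-parametrically and compare.

    The colonization series is smoothed with a cubic spline; ``R_c`` is its
    finite-difference derivative, ``R_p`` uses the proliferation relation with
    the spline's own ``y_c``, and their difference is compared with the
    parametric ``R_a`` on the shared part of the grid.  ``mu_p`` defaults to
    the parametric decomposition's value; if the parametric object carries
    none, it is estimated by a logistic fit of the proliferation series.
    Relative deviations are summarized only where the parametric rate exceeds
    ``rel_threshold`` (the ratio is meaningless near the zero crossings).
    """
    from .fitting import fit_model

    c_spline = fit_spline(colonization_series, smoothing=smoothing)
    if mu_p is None:
        mu_p = parametric.mu_p
        if mu_p is None:
            mu_p = fit_model(proliferation_series, "logistic").params.mu
    lo = max(parametric.grid[0], c_spline.t_min)
    hi = min(parametric.grid[-1], c_spline.t_max)
    if hi <= lo:
        raise ValidationError("parametric grid and spline domain do not overlap")
    keep = (parametric.grid >= lo) & (parametric.grid <= hi)
    g = parametric.grid[keep]
    r_c = spline_rate(c_spline, g).values
    y_c = c_spline(g)
    r_p = proliferation_rate(mu_p, y_c, parametric.colonization.K)
    ra_spline = r_c - r_p
    ra_param = parametric.R_a[keep]
    dev = np.abs(ra_spline - ra_param)
    big = ra_param > rel_threshold
    max_rel = float(np.max(dev[big] / ra_param[big])) if np.any(big) else np.nan
    return CrossCheckReport(
        grid=g,
        ra_parametric=ra_param,
        ra_spline=ra_spline,
        max_abs_deviation=float(dev.max()),
        max_rel_deviation=max_rel,
        rel_threshold=rel_threshold,
        peak_time_parametric=float(g[np.argmax(ra_param)]),
        peak_time_spline=float(g[np.argmax(ra_spline)]),
        mu_p=float(mu_p),
    )
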