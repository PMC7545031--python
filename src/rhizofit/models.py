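"""Parametric growth and decline curves for microbial density time courses.

Each model is a pure function of a frozen parameter record and time (hours).
Densities are carried in opaque "response units" — normalized root-surface
density (g^-1) or Log10(CFU ml^-1) for suspension data — and the module never
converts between the two; the caller chooses the response scale.

Every sigmoid is parameterized so that ``y(0) = y0`` and ``y -> K`` as
``t -> inf``, and each curve ships with its analytic time-derivative so rate
calculations never rely on finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InvalidParameterError

__all__ = [
    "LogisticParams",
    "GompertzParams",
    "DeclineParams",
    "RichardsParams",
    "BaranyiParams",
    "logistic_density",
    "logistic_rate",
    "gompertz_density",
    "gompertz_rate",
    "decline_density",
    "decline_rate",
    "decline_initial_level",
    "richards_density",
    "richards_rate",
    "baranyi_density",
    "baranyi_rate",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


def _finite(*values: float) -> bool:
    return all(math.isfinite(v) for v in values)


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth: carrying capacity ``K``, initial density ``y0``,
    intrinsic growth rate ``mu`` (h^-1).

    ``y0 > K`` is permitted: suspension series may start above the medium's
    carrying capacity, in which case the curve declines toward ``K``.
    """

    K: float
    y0: float
    mu: float

    def __post_init__(self) -> None:
        _require(_finite(self.K, self.y0, self.mu), "logistic parameters must be finite")
        _require(self.K > 0, f"carrying capacity K must be > 0, got {self.K}")
        _require(self.y0 > 0, f"initial density y0 must be > 0, got {self.y0}")


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth: asymptote ``K``, initial density ``y0`` (0 < y0 < K),
    rate constant ``mu`` (h^-1)."""

    K: float
    y0: float
    mu: float

    def __post_init__(self) -> None:
        _require(_finite(self.K, self.y0, self.mu), "Gompertz parameters must be finite")
        _require(self.K > 0, f"asymptote K must be > 0, got {self.K}")
        _require(0 < self.y0 < self.K, f"Gompertz requires 0 < y0 < K, got y0={self.y0}, K={self.K}")


@dataclass(frozen=True)
class DeclineParams:
    """Logistic decline ``y = a + b (1 - exp(-c / t))`` for suspensions with
    no root input: late-time asymptote ``a``, amplitude ``b``, timescale ``c``
    (hours).  The early-time level is the limit ``a + b`` as ``t -> 0+``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        _require(_finite(self.a, self.b, self.c), "decline parameters must be finite")
        _require(self.c > 0, f"timescale c must be > 0, got {self.c}")


@dataclass(frozen=True)
class RichardsParams:
    """Generalized logistic with shape exponent ``nu > 0``; ``nu = 1``
    recovers the logistic exactly."""

    K: float
    y0: float
    mu: float
    nu: float

    def __post_init__(self) -> None:
        _require(_finite(self.K, self.y0, self.mu, self.nu), "Richards parameters must be finite")
        _require(self.K > 0, f"K must be > 0, got {self.K}")
        _require(self.y0 > 0, f"y0 must be > 0, got {self.y0}")
        _require(self.nu > 0, f"shape exponent nu must be > 0, got {self.nu}")


@dataclass(frozen=True)
class BaranyiParams:
    """Baranyi–Roberts growth with lag: ``h0`` is the dimensionless product
    of lag time and ``mu``; ``h0 = 0`` recovers lag-free logistic growth."""

    y0: float
    mu: float
    K: float
    h0: float

    def __post_init__(self) -> None:
        _require(_finite(self.y0, self.mu, self.K, self.h0), "Baranyi parameters must be finite")
        _require(self.y0 > 0, f"y0 must be > 0, got {self.y0}")
        _require(self.mu > 0, f"mu must be > 0, got {self.mu}")
        _require(self.K > 0, f"K must be > 0, got {self.K}")
        _require(self.h0 >= 0, f"lag parameter h0 must be >= 0, got {self.h0}")


def _astime(t, minimum: float = 0.0, strict: bool = False):
    arr = np.asarray(t, dtype=float)
    bad = (arr < minimum) if not strict else (arr <= minimum)
    if np.any(bad):
        op = ">" if strict else ">="
        raise DomainError(f"time must be {op} {minimum} h, got {arr[bad].min()}")
    return arr


def _maybe_scalar(value, t):
    return float(value) if np.isscalar(t) or np.ndim(t) == 0 else value


def logistic_density(p: LogisticParams, t):
    """Logistic density ``K y0 / (y0 + (K - y0) exp(-mu t))`` at time ``t`` (h)."""
    tt = _astime(t)
    y = p.K * p.y0 / (p.y0 + (p.K - p.y0) * np.exp(-p.mu * tt))
    return _maybe_scalar(y, t)


def logistic_rate(p: LogisticParams, y):
    """Logistic growth rate ``mu y (K - y) / K`` as a function of density.

    Zero at ``y = 0`` and ``y = K``; maximal ``mu K / 4`` at ``y = K / 2``.
    """
    yy = np.asarray(y, dtype=float)
    r = p.mu * yy * (p.K - yy) / p.K
    return _maybe_scalar(r, y)


def gompertz_density(p: GompertzParams, t):
    """Gompertz density ``K exp(ln(y0/K) exp(-mu t))`` (natural log)."""
    tt = _astime(t)
    y = p.K * np.exp(math.log(p.y0 / p.K) * np.exp(-p.mu * tt))
    return _maybe_scalar(y, t)


def gompertz_rate(p: GompertzParams, t):
    """Analytic time-derivative of the Gompertz curve: ``mu y ln(K / y)``."""
    y = np.asarray(gompertz_density(p, t), dtype=float)
    r = p.mu * y * np.log(p.K / y)
    return _maybe_scalar(r, t)


def decline_initial_level(p: DeclineParams) -> float:
    """Analytic early-time limit ``a + b`` of the decline curve as t -> 0+."""
    return p.a + p.b


def decline_density(p: DeclineParams, t):
    """Decline curve ``a + b (1 - exp(-c / t))`` for ``t > 0``.

    ``t = 0`` is outside the formula's domain; use
    :func:`decline_initial_level` for the analytic limit ``a + b``.
    """
    tt = _astime(t, minimum=0.0, strict=True)
    y = p.a + p.b * (1.0 - np.exp(-p.c / tt))
    return _maybe_scalar(y, t)


def decline_rate(p: DeclineParams, t):
    """Time-derivative ``-b c exp(-c / t) / t^2`` of the decline curve."""
    tt = _astime(t, minimum=0.0, strict=True)
    r = -p.b * p.c * np.exp(-p.c / tt) / tt**2
    return _maybe_scalar(r, t)


def richards_density(p: RichardsParams, t):
    """Richards generalized logistic
    ``K (1 + ((K/y0)^nu - 1) exp(-mu nu t))^(-1/nu)``."""
    tt = _astime(t)
    q = (p.K / p.y0) ** p.nu - 1.0
    y = p.K * (1.0 + q * np.exp(-p.mu * p.nu * tt)) ** (-1.0 / p.nu)
    return _maybe_scalar(y, t)


def richards_rate(p: RichardsParams, t):
    """Analytic Richards rate ``mu y (1 - (y/K)^nu)``."""
    y = np.asarray(richards_density(p, t), dtype=float)
    r = p.mu * y * (1.0 - (y / p.K) ** p.nu)
    return _maybe_scalar(r, t)


def _baranyi_adjusted_time(p: BaranyiParams, tt: np.ndarray) -> np.ndarray:
    # A(t) = t + (1/mu) ln(e^{-mu t} + e^{-h0} - e^{-mu t - h0})
    emt = np.exp(-p.mu * tt)
    eh = math.exp(-p.h0)
    return tt + np.log(emt + eh - emt * eh) / p.mu


def baranyi_density(p: BaranyiParams, t):
    """Baranyi–Roberts explicit solution (natural-log scale internally).

    ``ln y = ln y0 + mu A(t) - ln(1 + (e^{mu A(t)} - 1) y0 / K)`` with the
    adjusted time ``A(t)`` encoding the lag; ``h0 = 0`` gives ``A(t) = t``
    and the solution collapses to the logistic curve.
    """
    tt = _astime(t)
    a = _baranyi_adjusted_time(p, tt)
    mu_a = p.mu * a
    ln_y = math.log(p.y0) + mu_a - np.log1p(np.expm1(mu_a) * (p.y0 / p.K))
    y = np.exp(ln_y)
    return _maybe_scalar(y, t)


def baranyi_rate(p: BaranyiParams, t):
    """Analytic Baranyi rate ``mu alpha(t) y (1 - y/K)`` with adjustment
    function ``alpha(t) = 1 / (1 + (e^{h0} - 1) e^{-mu t})``."""
    tt = _astime(t)
    y = np.asarray(baranyi_density(p, tt), dtype=float)
    alpha = 1.0 / (1.0 + math.expm1(p.h0) * np.exp(-p.mu * tt))
    r = p.mu * alpha * y * (1.0 - y / p.K)
    return _maybe_scalar(r, t)
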