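"""Nonlinear least-squares fitting of growth models, AIC model selection and
case-resampling bootstrap uncertainty.

The central objects follow the Model/Results convention:

>>> model = GrowthCurveModel(series, model="logistic")
>>> res = model.fit()
>>> res.bootstrap(reps=1000, seed=1)
>>> print(res.summary())

Fits minimize the residual sum of squares on the series' own response scale
(normalized density or Log10 CFU/ml; the two are never mixed or compared).
AIC uses the Gaussian profile-likelihood form ``n ln(rss/n) + 2 (k + 1)``,
counting the residual variance as a fitted parameter; only AIC differences
within one series matter for selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import NormalizedSeries
from .exceptions import (
    AllFitsFailedError,
    DomainError,
    FitFailure,
    InvalidParameterError,
    ValidationError,
)
from .models import (
    BaranyiParams,
    DeclineParams,
    GompertzParams,
    LogisticParams,
    RichardsParams,
)

__all__ = [
    "MODEL_NAMES",
    "GrowthCurveModel",
    "GrowthCurveResults",
    "BootstrapResult",
    "fit_model",
    "select_model",
    "bootstrap_fit",
    "aic",
    "write_fit_report",
    "write_comparison",
]


def aic(rss: float, n: int, k: int) -> float:
    """Gaussian least-squares AIC, ``n ln(rss/n) + 2 (k + 1)``."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)


# ---------------------------------------------------------------------------
# raw curve evaluations on unvalidated theta vectors (used inside the solver,
# where iterates may wander through regions a parameter record would reject)

def _logistic(theta, t):
    K, y0, mu = theta
    return K * y0 / (y0 + (K - y0) * np.exp(-mu * t))


def _gompertz(theta, t):
    K, y0, mu = theta
    return K * np.exp(np.log(y0 / K) * np.exp(-mu * t))


def _decline(theta, t):
    a, b, c = theta
    return a + b * (1.0 - np.exp(-c / t))


def _richards(theta, t):
    K, y0, mu, nu = theta
    q = (K / y0) ** nu - 1.0
    return K * (1.0 + q * np.exp(-mu * nu * t)) ** (-1.0 / nu)


def _baranyi(theta, t):
    y0, mu, K, h0 = theta
    emt = np.exp(-mu * t)
    eh = np.exp(-h0)
    a = t + np.log(emt + eh - emt * eh) / mu
    mu_a = mu * a
    return np.exp(np.log(y0) + mu_a - np.log1p(np.expm1(mu_a) * (y0 / K)))


def _time_means(t: np.ndarray, y: np.ndarray):
    ut, inverse = np.unique(t, return_inverse=True)
    means = np.bincount(inverse, weights=y) / np.bincount(inverse)
    return ut, means


def _initial_mu(t: np.ndarray, y: np.ndarray) -> float:
    """Default growth-rate start: 4x the log-response slope over the first
    rising interval of the per-time means; clipped to [1e-3, 5]."""
    ut, ym = _time_means(t, y)
    for i in range(len(ut) - 1):
        if ym[i] > 0 and ym[i + 1] > ym[i]:
            slope = (np.log(ym[i + 1]) - np.log(ym[i])) / (ut[i + 1] - ut[i])
            return float(np.clip(4.0 * slope, 1e-3, 5.0))
    return 0.1


def _first_positive(t: np.ndarray, y: np.ndarray) -> float:
    ut, ym = _time_means(t, y)
    pos = ym[ym > 0]
    return float(pos[0]) if pos.size else 1e-6


def _init_logistic(t, y):
    return np.array([1.05 * y.max(), max(_first_positive(t, y), 1e-6), _initial_mu(t, y)])


def _init_gompertz(t, y):
    K0 = 1.05 * y.max()
    y00 = np.clip(max(_first_positive(t, y), 1e-6), 1e-6, 0.9 * K0)
    return np.array([K0, y00, _initial_mu(t, y)])


def _init_decline(t, y):
    ut, ym = _time_means(t, y)
    a0 = ym[-1]
    b0 = ym[0] - ym[-1]
    if b0 <= 0:
        b0 = max(np.ptp(y), 0.1)
    return np.array([a0, b0, 2.0 * t.max()])


def _init_richards(t, y):
    return np.append(_init_logistic(t, y), 1.0)


def _init_baranyi(t, y):
    K0, y00, mu0 = _init_logistic(t, y)
    return np.array([y00, mu0, K0, 0.5])


_TINY = 1e-12


@dataclass(frozen=True)
class _ModelSpec:
    name: str
    param_cls: type
    param_names: tuple
    curve: Callable
    init: Callable
    lower: tuple
    upper: tuple

    @property
    def k(self) -> int:
        return len(self.param_names)


_SPECS = {
    "logistic": _ModelSpec(
        "logistic", LogisticParams, ("K", "y0", "mu"), _logistic, _init_logistic,
        (_TINY, _TINY, 1e-6), (np.inf, np.inf, 10.0),
    ),
    "gompertz": _ModelSpec(
        "gompertz", GompertzParams, ("K", "y0", "mu"), _gompertz, _init_gompertz,
        (_TINY, _TINY, 1e-6), (np.inf, np.inf, 10.0),
    ),
    "decline": _ModelSpec(
        "decline", DeclineParams, ("a", "b", "c"), _decline, _init_decline,
        (-np.inf, -np.inf, _TINY), (np.inf, np.inf, np.inf),
    ),
    "richards": _ModelSpec(
        "richards", RichardsParams, ("K", "y0", "mu", "nu"), _richards, _init_richards,
        (_TINY, _TINY, 1e-6, 1e-3), (np.inf, np.inf, 10.0, 20.0),
    ),
    "baranyi": _ModelSpec(
        "baranyi", BaranyiParams, ("y0", "mu", "K", "h0"), _baranyi, _init_baranyi,
        (_TINY, 1e-6, _TINY, 0.0), (np.inf, 10.0, np.inf, 50.0),
    ),
}

MODEL_NAMES = tuple(_SPECS)


def _fit_arrays(spec: _ModelSpec, t: np.ndarray, y: np.ndarray, x0: np.ndarray):
    """Solve the least-squares problem; returns (theta, rss) or raises FitFailure."""

    def residuals(theta):
        with np.errstate(all="ignore"):
            r = spec.curve(theta, t) - y
        return np.where(np.isfinite(r), r, 1e6)

    try:
        sol = optimize.least_squares(
            residuals, x0, bounds=(spec.lower, spec.upper), method="trf",
            x_scale="jac", max_nfev=5000,
        )
    except Exception as exc:  # singular Jacobian, overflow in solver, ...
        raise FitFailure(f"{spec.name}: solver error: {exc}") from exc
    if not sol.success:
        raise FitFailure(
            f"{spec.name}: no convergence (status {sol.status}: {sol.message})",
            best_theta=sol.x,
            diagnostics={"status": sol.status, "cost": sol.cost, "nfev": sol.nfev},
        )
    rss = float(np.sum(sol.fun**2))
    return sol.x, rss, sol


class GrowthCurveModel:
    """A growth model bound to one pooled response series.

    Parameters
    ----------
    series
        A :class:`~rhizofit.data.NormalizedSeries`; alternatively pass raw
        ``times=`` / ``values=`` arrays.
    model
        One of ``logistic``, ``gompertz``, ``decline``, ``richards``,
        ``baranyi``.
    """

    def __init__(self, series: NormalizedSeries | None = None, model: str = "logistic",
                 *, times=None, values=None):
        if model not in _SPECS:
            raise ValidationError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
        if series is None:
            if times is None or values is None:
                raise ValidationError("provide a NormalizedSeries or times= and values=")
            series = NormalizedSeries(np.asarray(times, float), np.asarray(values, float), "raw")
        self.series = series
        self.spec = _SPECS[model]
        self.model_name = model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, treatment: str, model: str = "logistic",
                       sampled_volume_ml: float | None = None) -> "GrowthCurveModel":
        """Build from a validated observation table, pooling all replicates."""
        from .data import DEFAULT_SAMPLED_VOLUME_ML, build_series

        vol = DEFAULT_SAMPLED_VOLUME_ML if sampled_volume_ml is None else sampled_volume_ml
        return cls(build_series(df, treatment, vol), model)

    def fit(self, init: Sequence[float] | None = None) -> "GrowthCurveResults":
        """Least-squares fit; deterministic given the data and start values.

        Raises
        ------
        ValidationError
            If there are fewer than ``k + 2`` observations.
        FitFailure
            On non-convergence, an unidentifiable (constant) response, or
            convergence to a parameter region the model record rejects;
            carries the best iterate and solver diagnostics.
        """
        t, y = self.series.times, self.series.values
        spec = self.spec
        n, k = t.size, spec.k
        if n < k + 2:
            raise ValidationError(f"{spec.name}: need at least {k + 2} observations, got {n}")
        if np.ptp(y) == 0:
            raise FitFailure(f"{spec.name}: constant response, parameters unidentifiable")
        x0 = np.asarray(init, float) if init is not None else spec.init(t, y)
        if x0.size != k:
            raise ValidationError(f"{spec.name}: init must have {k} entries, got {x0.size}")
        x0 = np.clip(x0, spec.lower, spec.upper)
        theta, rss, sol = _fit_arrays(spec, t, y, x0)
        try:
            params = spec.param_cls(*theta)
        except InvalidParameterError as exc:
            raise FitFailure(
                f"{spec.name}: converged on the boundary of the valid region ({exc})",
                best_theta=theta,
                diagnostics={"cost": sol.cost, "nfev": sol.nfev},
            ) from exc
        tss = float(np.sum((y - y.mean()) ** 2))
        return GrowthCurveResults(
            model=self,
            model_name=spec.name,
            params=params,
            theta=np.asarray(theta, float),
            param_names=spec.param_names,
            rss=rss,
            n=n,
            k=k,
            aic=float(aic(rss, n, k)),
            r_squared=1.0 - rss / tss,
        )


@dataclass
class BootstrapResult:
    """Case-resampling bootstrap summary for one fitted model."""

    reps: int
    n_failures: int
    param_se: np.ndarray
    conf_int: np.ndarray  # (k, 2) percentile 95% interval
    thetas: np.ndarray  # (successful reps, k)
    grid: np.ndarray
    prediction_sd: np.ndarray
    seed: int | None


@dataclass
class GrowthCurveResults:
    """Estimates and diagnostics of one growth-model fit.

    ``param_se`` / ``param_p`` are populated by :meth:`bootstrap`.
    """

    model: GrowthCurveModel
    model_name: str
    params: object
    theta: np.ndarray
    param_names: tuple
    rss: float
    n: int
    k: int
    aic: float
    r_squared: float
    param_se: np.ndarray | None = None
    param_p: np.ndarray | None = None
    bootstrap_reps: int = 0
    bootstrap_result: BootstrapResult | None = field(default=None, repr=False)

    def predict(self, t):
        """Evaluate the fitted curve at times ``t`` (hours)."""
        tt = np.asarray(t, dtype=float)
        out = self.model.spec.curve(self.theta, tt)
        return float(out) if tt.ndim == 0 else out

    def bootstrap(self, reps: int = 1000, seed: int | None = None,
                  grid: np.ndarray | None = None) -> BootstrapResult:
        """Case-resampling bootstrap: resample observation rows with
        replacement (destructive samples are independent), refit, and report
        parameter standard errors, 95% percentile intervals and the
        prediction-curve sd on an hourly grid.

        Replicates that fail to refit are dropped; a failure fraction above
        20% triggers a warning, total failure raises.  Per-parameter p-values
        are two-sided normal Wald tests on the bootstrap SEs.
        """
        if reps < 1:
            raise ValidationError("bootstrap needs reps >= 1")
        t, y = self.model.series.times, self.model.series.values
        spec = self.model.spec
        if grid is None:
            lo = max(np.floor(t.min()), 1e-6 if spec.name == "decline" else 0.0)
            grid = np.arange(lo, np.floor(t.max()) + 1.0)
        grid = np.asarray(grid, dtype=float)
        rng = np.random.default_rng(seed)
        thetas, preds = [], []
        failures = 0
        for _ in range(reps):
            idx = rng.integers(0, t.size, t.size)
            try:
                th, _, _ = _fit_arrays(spec, t[idx], y[idx], self.theta)
            except FitFailure:
                failures += 1
                continue
            thetas.append(th)
            with np.errstate(all="ignore"):
                preds.append(spec.curve(th, grid))
        if not thetas:
            raise AllFitsFailedError(f"all {reps} bootstrap replicates failed to refit")
        if failures > 0.2 * reps:
            warnings.warn(
                f"{failures}/{reps} bootstrap replicates failed to refit and were dropped",
                UserWarning, stacklevel=2,
            )
        thetas = np.asarray(thetas)
        preds = np.asarray(preds)
        if thetas.shape[0] < 2:
            warnings.warn(
                "bootstrap with a single successful replicate has no spread; SEs are degenerate zeros",
                UserWarning, stacklevel=2,
            )
            se = np.zeros(self.k)
            ci = np.column_stack([thetas[0], thetas[0]])
            band = np.zeros(grid.size)
        else:
            se = thetas.std(axis=0, ddof=1)
            ci = np.percentile(thetas, [2.5, 97.5], axis=0).T
            band = preds.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(self.theta) / se
        pvals = np.where(se > 0, 2.0 * stats.norm.sf(z), 0.0)
        result = BootstrapResult(
            reps=reps, n_failures=failures, param_se=se, conf_int=ci,
            thetas=thetas, grid=grid, prediction_sd=band, seed=seed,
        )
        self.param_se = se
        self.param_p = pvals
        self.bootstrap_reps = reps
        self.bootstrap_result = result
        return result

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Growth curve fit",
            "=" * 58,
            f"model:        {self.model_name}",
            f"response:     {self.model.series.response_kind}"
            + (f" ({self.model.series.treatment})" if self.model.series.treatment else ""),
            f"observations: {self.n}    parameters: {self.k}",
            f"rss: {self.rss:.6g}    r2: {self.r_squared:.4f}    AIC: {self.aic:.2f}",
        ]
        if self.bootstrap_reps:
            lines.append(f"bootstrap:    {self.bootstrap_reps} case-resampling replicates")
        lines.append("-" * 58)
        lines.append(f"{'param':>8} {'estimate':>14} {'boot SE':>12} {'p value':>10}")
        for i, name in enumerate(self.param_names):
            se = f"{self.param_se[i]:.4g}" if self.param_se is not None else "-"
            pv = f"{self.param_p[i]:.4g}" if self.param_p is not None else "-"
            lines.append(f"{name:>8} {self.theta[i]:>14.7g} {se:>12} {pv:>10}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_report_frame(self) -> pd.DataFrame:
        """Tidy fit-report table: model, parameter, estimate, bootstrap_se, p_value."""
        return pd.DataFrame(
            {
                "model": self.model_name,
                "parameter": list(self.param_names),
                "estimate": self.theta,
                "bootstrap_se": self.param_se if self.param_se is not None else np.nan,
                "p_value": self.param_p if self.param_p is not None else np.nan,
            }
        )


def fit_model(series: NormalizedSeries, model_name: str,
              init: Sequence[float] | None = None) -> GrowthCurveResults:
    """Functional wrapper: fit one named model to a series."""
    return GrowthCurveModel(series, model_name).fit(init=init)


def select_model(series: NormalizedSeries,
                 candidates: Sequence[str] = MODEL_NAMES,
                 inits: dict | None = None):
    """Fit all candidate models and select the lowest AIC.

    Ties (within 1e-9) are broken toward fewer parameters, then
    lexicographically by model name.

    Returns
    -------
    (best, comparison)
        The winning :class:`GrowthCurveResults` and a ranked DataFrame with
        columns model, k, rss, aic, delta_aic, selected.
    """
    fits: dict[str, GrowthCurveResults] = {}
    errors: dict[str, str] = {}
    for name in candidates:
        try:
            fits[name] = fit_model(series, name, init=(inits or {}).get(name))
        except (FitFailure, DomainError, ValidationError) as exc:
            errors[name] = str(exc)
    if not fits:
        raise AllFitsFailedError(
            f"no candidate model could be fitted: {errors}", failures=errors
        )
    ranked = sorted(fits.values(), key=lambda r: (round(r.aic / 1e-9) * 1e-9, r.k, r.model_name))
    best = ranked[0]
    comparison = pd.DataFrame(
        {
            "model": [r.model_name for r in ranked],
            "k": [r.k for r in ranked],
            "rss": [r.rss for r in ranked],
            "aic": [r.aic for r in ranked],
            "delta_aic": [r.aic - best.aic for r in ranked],
            "selected": [r is best for r in ranked],
        }
    )
    if errors:
        comparison.attrs["fit_errors"] = errors
    return best, comparison


def bootstrap_fit(series: NormalizedSeries, model_name: str, reps: int = 1000,
                  seed: int | None = None) -> GrowthCurveResults:
    """Fit one model and attach bootstrap uncertainty in a single call."""
    res = fit_model(series, model_name)
    res.bootstrap(reps=reps, seed=seed)
    return res


def write_fit_report(results: GrowthCurveResults, path) -> None:
    results.to_report_frame().to_csv(path, index=False)


def write_comparison(comparison: pd.DataFrame, path) -> None:
    comparison.to_csv(path, index=False)
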