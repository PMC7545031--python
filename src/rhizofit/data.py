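"""Data model, validation and normalization for destructive microcosm counts.

One row = one destroyed plant (or one suspension draw): time post inoculation,
raw CFU count, fresh root weight (root treatments only), inoculant density,
treatment label, replicate and experimental run.  Because sampling is
destructive the series are cross-sectional; replicates from different runs are
pooled before any fitting.

Root-surface responses are normalized by inoculant density and root weight
(``y = CFU / (CFU0 * Wt)``, reported in g^-1 following the field's convention
even though the ratio dimensionally carries ml g^-1).  Suspension responses
are expressed as Log10(CFU ml^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SingularDesignError, ValidationError

__all__ = [
    "TREATMENTS",
    "ROOT_TREATMENTS",
    "SUSPENSION_TREATMENTS",
    "OBSERVATION_COLUMNS",
    "DEFAULT_SAMPLED_VOLUME_ML",
    "NormalizedSeries",
    "WeightRegression",
    "read_observations",
    "write_observations",
    "validate_observations",
    "normalize_density",
    "to_log10_per_ml",
    "build_series",
    "normalize_table",
    "write_series",
    "weight_regression",
]

TREATMENTS = ("total", "proliferation", "suspension_root", "suspension_blank", "exudate")
#: treatments measured on the root surface (require a root weight)
ROOT_TREATMENTS = frozenset({"total", "proliferation"})
#: treatments measured in the liquid phase (no root weight; Log10 CFU/ml response)
SUSPENSION_TREATMENTS = frozenset({"suspension_root", "suspension_blank", "exudate"})

OBSERVATION_COLUMNS = [
    "time_h",
    "cfu",
    "root_weight_g",
    "inoculant_cfu_per_ml",
    "treatment",
    "replicate",
    "run",
]

#: volume of the suspension draw (100 ul), used to express counts per ml
DEFAULT_SAMPLED_VOLUME_ML = 0.1


@dataclass(frozen=True)
class NormalizedSeries:
    """A pooled response series ready for fitting.

    ``response_kind`` is ``"normalized_density"`` (g^-1) for root treatments
    and ``"log10_cfu_per_ml"`` for suspension treatments.
    """

    times: np.ndarray
    values: np.ndarray
    response_kind: str
    treatment: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("times and values must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValidationError("series times and values must be finite")
        order = np.argsort(t, kind="stable")
        object.__setattr__(self, "times", t[order])
        object.__setattr__(self, "values", v[order])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class WeightRegression:
    """OLS of log10 per-root count on fresh root weight."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an observation table in place and return it.

    Checks the exact column set, treatment labels, non-negative counts,
    positive inoculant densities, and that a root weight is present iff the
    treatment is a root treatment.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"observation table is missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError("observation table is empty")
    bad_treat = set(df["treatment"].unique()) - set(TREATMENTS)
    if bad_treat:
        raise ValidationError(f"unknown treatment labels: {sorted(bad_treat)}; expected one of {TREATMENTS}")
    if (df["time_h"] < 0).any():
        raise ValidationError("time_h must be >= 0")
    if (df["cfu"] < 0).any():
        raise ValidationError("cfu must be >= 0")
    if (df["inoculant_cfu_per_ml"] <= 0).any():
        raise ValidationError("inoculant_cfu_per_ml must be > 0")
    is_root = df["treatment"].isin(ROOT_TREATMENTS)
    wt = df["root_weight_g"]
    if wt[is_root].isna().any():
        raise ValidationError("root treatments require root_weight_g")
    if (wt[is_root] <= 0).any():
        raise ValidationError("root_weight_g must be > 0 for root treatments")
    if wt[~is_root].notna().any():
        raise ValidationError("suspension treatments must leave root_weight_g empty")
    return df


def read_observations(path) -> pd.DataFrame:
    """Read and validate a destructive-observation CSV (UTF-8, '.' decimals)."""
    try:
        df = pd.read_csv(path, dtype={"replicate": str, "run": str}, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file, expected header {OBSERVATION_COLUMNS}") from exc
    return validate_observations(df)


def write_observations(df: pd.DataFrame, path) -> None:
    """Write an observation table in the CSV dialect :func:`read_observations` reads."""
    validate_observations(df)
    df.to_csv(path, index=False, columns=OBSERVATION_COLUMNS)


def normalize_density(cfu, inoculant_cfu_per_ml, root_weight_g):
    """Inoculant- and weight-normalized density ``y = CFU / (CFU0 * Wt)``.

    Linear in ``cfu`` and inversely linear in each of the inoculant density
    and the root weight; halving the inoculant density doubles ``y``.
    """
    cfu = np.asarray(cfu, dtype=float)
    c0 = np.asarray(inoculant_cfu_per_ml, dtype=float)
    wt = np.asarray(root_weight_g, dtype=float)
    if np.any(~np.isfinite(wt)) or np.any(wt <= 0):
        raise ValidationError("root_weight_g must be present and > 0 for normalization")
    if np.any(c0 <= 0):
        raise ValidationError("inoculant_cfu_per_ml must be > 0")
    y = cfu / (c0 * wt)
    return float(y) if y.ndim == 0 else y


def to_log10_per_ml(cfu, sampled_volume_ml: float = DEFAULT_SAMPLED_VOLUME_ML):
    """Log10 of counts per ml for a suspension draw of ``sampled_volume_ml``.

    Zero counts are below the detection limit of plating and have no
    log-scale value; scalar input raises :class:`ValidationError`, array
    input returns NaN for the affected entries (callers drop them with a
    warning when building series).
    """
    if sampled_volume_ml <= 0:
        raise ValidationError("sampled_volume_ml must be > 0")
    cfu = np.asarray(cfu, dtype=float)
    if cfu.ndim == 0:
        if cfu <= 0:
            raise ValidationError("cfu must be > 0 on the log scale (below detection)")
        return float(np.log10(cfu / sampled_volume_ml))
    out = np.full(cfu.shape, np.nan)
    pos = cfu > 0
    out[pos] = np.log10(cfu[pos] / sampled_volume_ml)
    return out


def build_series(
    df: pd.DataFrame,
    treatment: str,
    sampled_volume_ml: float = DEFAULT_SAMPLED_VOLUME_ML,
) -> NormalizedSeries:
    """Pool all replicates/runs of one treatment into a fit-ready series.

    Root treatments are normalized per the inoculant/weight rule (zero counts
    stay 0 on the linear scale); suspension treatments become Log10(CFU/ml),
    with zero counts excluded under a warning.
    """
    validate_observations(df)
    sub = df[df["treatment"] == treatment]
    if len(sub) == 0:
        raise ValidationError(f"no observations for treatment {treatment!r}")
    if treatment in ROOT_TREATMENTS:
        values = normalize_density(sub["cfu"], sub["inoculant_cfu_per_ml"], sub["root_weight_g"])
        return NormalizedSeries(
            sub["time_h"].to_numpy(float), np.asarray(values), "normalized_density", treatment
        )
    values = to_log10_per_ml(sub["cfu"].to_numpy(float), sampled_volume_ml)
    keep = np.isfinite(values)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{treatment}: excluded {n_dropped} zero-count observation(s) below detection "
            "from the log-scale series",
            UserWarning,
            stacklevel=2,
        )
    return NormalizedSeries(
        sub["time_h"].to_numpy(float)[keep], values[keep], "log10_cfu_per_ml", treatment
    )


def normalize_table(df: pd.DataFrame, sampled_volume_ml: float = DEFAULT_SAMPLED_VOLUME_ML) -> pd.DataFrame:
    """Tidy long table of all treatments' normalized series:
    columns treatment, time_h, response_kind, value."""
    frames = []
    for treatment in df["treatment"].unique():
        s = build_series(df, treatment, sampled_volume_ml)
        frames.append(
            pd.DataFrame(
                {
                    "treatment": treatment,
                    "time_h": s.times,
                    "response_kind": s.response_kind,
                    "value": s.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_series(df: pd.DataFrame, path, sampled_volume_ml: float = DEFAULT_SAMPLED_VOLUME_ML) -> None:
    normalize_table(df, sampled_volume_ml).to_csv(path, index=False)


def weight_regression(root_weight_g, log10_cfu_per_root) -> WeightRegression:
    """OLS of log10 per-root CFU on fresh root weight at one timepoint.

    Mirrors the check that plant size drives raw counts (hence the need for
    weight normalization): significant for total colonization, expected null
    for proliferation-only roots.
    """
    x = np.asarray(root_weight_g, dtype=float)
    y = np.asarray(log10_cfu_per_root, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("weight regression needs >= 3 paired observations")
    if np.ptp(x) == 0:
        raise SingularDesignError("root weights are constant: slope is unidentifiable")
    res = stats.linregress(x, y)
    return WeightRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=int(x.size),
    )
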