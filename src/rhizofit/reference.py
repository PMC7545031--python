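"""Published parameter estimates for the lettuce / *Pseudomonas fluorescens*
SBW25 hydroponic microcosm system.

These are the AIC-selected fits reported for each treatment of the original
colonization study (inoculation at ~2e7 CFU/ml, destructive sampling to 96 h,
suspension-without-root monitored to 192 h).  They serve as defaults for the
synthetic-data generator and as ready-made inputs to the attachment
decomposition when raw data are unavailable.

Root-surface responses (total colonization, proliferation-only) are
inoculant/weight-normalized densities (g^-1); suspension responses are
Log10(CFU ml^-1).
"""

from __future__ import annotations

from .models import DeclineParams, GompertzParams, LogisticParams

__all__ = [
    "TOTAL_COLONIZATION",
    "PROLIFERATION",
    "SUSPENSION_ROOT",
    "SUSPENSION_BLANK",
    "EXUDATE",
    "REFERENCE_FITS",
    "QUADRATIC_COEFFICIENTS",
    "WEIGHT_REGRESSION_SLOPE",
    "WEIGHT_REGRESSION_INTERCEPT",
]

#: total root-surface colonization (attachment + proliferation), logistic, g^-1
TOTAL_COLONIZATION = LogisticParams(K=8.855974, y0=0.007333, mu=0.184677)

#: proliferation-only roots (transferred to sterile microcosms at 2 h), logistic, g^-1
PROLIFERATION = LogisticParams(K=9.04029218, y0=0.02508862, mu=0.09949397)

#: suspension around a live root, Gompertz, Log10(CFU/ml)
SUSPENSION_ROOT = GompertzParams(K=7.4503415, y0=4.6670427, mu=0.1240495)

#: suspension with no root input, logistic decline, Log10(CFU/ml)
SUSPENSION_BLANK = DeclineParams(a=-5.151, b=12.272, c=633.798)

#: suspension in harvested root exudate, logistic, Log10(CFU/ml)
EXUDATE = LogisticParams(K=8.109634, y0=7.814389, mu=0.017965)

#: treatment label -> (selected model name, parameter record)
REFERENCE_FITS = {
    "total": ("logistic", TOTAL_COLONIZATION),
    "proliferation": ("logistic", PROLIFERATION),
    "suspension_root": ("gompertz", SUSPENSION_ROOT),
    "suspension_blank": ("decline", SUSPENSION_BLANK),
    "exudate": ("logistic", EXUDATE),
}

#: reported quadratic R_a(y_c) = c0 + c1 y_c + c2 y_c^2
QUADRATIC_COEFFICIENTS = (-1.19e-11, 8.52e-2, -9.98e-3)

#: reported regression of Log10 per-root CFU on root weight at 96 h (total colonization)
WEIGHT_REGRESSION_SLOPE = 214.55
WEIGHT_REGRESSION_INTERCEPT = 5.29
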