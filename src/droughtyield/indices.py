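"""Standardized drought and yield indices.

The Standardized Precipitation Evapotranspiration Index (SPEI) is computed
from a monthly climatic water balance (precipitation minus potential
evapotranspiration, P−PET, mm/month): the series is linearly detrended once,
accumulated over a duration of ``d`` consecutive months (d = 1..14), and the
resulting one-value-per-year sample for each calendar ending month is fitted
with a three-parameter log-logistic distribution by unbiased probability
weighted moments; fitted cumulative probabilities are mapped to
standard-normal quantiles. The Standardized Yield Index (SYI) applies the
identical detrend → fit → standardize path to yearly crop yields (one
implicit annual duration).

Values are classified into seven magnitude classes per index and three
macro-classes (Dry/Normal/Wet for SPEI, Lower/Normal/Higher yield for SYI)
with the dry/low tail closed at −1.0 and the wet/high tail closed at +1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.special import gamma as _gamma
from scipy.stats import norm

__all__ = [
    "SPEI_CLASSES",
    "SYI_CLASSES",
    "MACRO_SPEI",
    "MACRO_SYI",
    "MAX_DURATION",
    "detrend_linear",
    "accumulate",
    "fit_standardize",
    "compute_spei",
    "compute_syi",
    "classify",
    "classify_array",
]

#: SPEI magnitude classes, driest to wettest.
SPEI_CLASSES = ("ED", "SD", "MD", "N", "MW", "SW", "EW")
#: SYI magnitude classes, lowest to highest yield.
SYI_CLASSES = ("ELY", "SLY", "MLY", "NY", "MHY", "SHY", "EHY")
#: Macro-class of each magnitude class, in the same order.
MACRO_SPEI = ("D", "D", "D", "N", "W", "W", "W")
MACRO_SYI = ("LY", "LY", "LY", "NY", "HY", "HY", "HY")

#: Longest accumulation duration (months): the longest cropping season found
#: is 12 months and two pre-planting months are added.
MAX_DURATION = 14

#: Standard-normal scores are clipped to this magnitude to avoid infinities
#: at extreme fitted probabilities.
SCORE_CLIP = 4.0


def detrend_linear(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Remove an ordinary-least-squares linear trend (slope and mean).

    Parameters
    ----------
    series
        Ordered numeric values; NaNs are preserved in the output and
        excluded from the fit. At least 3 finite values are required.

    Returns
    -------
    residuals, degenerate
        OLS residuals (summing to ~0, orthogonal to the time index) and a
        flag that is True when all finite values are identical, in which
        case the residuals are exactly zero.
    """
    y = np.asarray(series, dtype=float)
    finite = np.isfinite(y)
    if finite.sum() < 3:
        raise ValueError("detrend_linear needs at least 3 finite values")
    t = np.arange(y.size, dtype=float)
    yf = y[finite]
    if np.all(yf == yf[0]):
        out = np.where(finite, 0.0, np.nan)
        return out, True
    slope, intercept = np.polyfit(t[finite], yf, 1)
    resid = y - (slope * t + intercept)
    # a perfect line leaves only float cancellation noise: degenerate too
    degenerate = bool(np.std(resid[finite]) <= 1e-9 * max(1.0, float(np.std(yf))))
    if degenerate:
        resid = np.where(finite, 0.0, np.nan)
    return resid, degenerate


def accumulate(series: np.ndarray, d: int) -> np.ndarray:
    """Rolling ``d``-month sum dated by the ending month.

    Element ``t`` of the result is the sum of months ``t-d+1 .. t``; the
    first ``d-1`` elements are NaN (no partial windows). ``d=1`` returns a
    copy of the input.
    """
    if not 1 <= d <= MAX_DURATION:
        raise ValueError(f"duration must be in 1..{MAX_DURATION}, got {d}")
    x = np.asarray(series, dtype=float)
    if d == 1:
        return x.copy()
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.full(x.size, np.nan)
    out[d - 1:] = c[d:] - c[:-d]
    return out


def _pwm_loglogistic(x: np.ndarray) -> tuple[float, float, float]:
    """Fit a 3-parameter log-logistic by unbiased probability weighted
    moments. Returns (shape, scale, location)."""
    xs = np.sort(x)
    n = xs.size
    j = np.arange(1, n + 1, dtype=float)
    # unbiased PWMs in (1 - F)^r form: a_r = E[X (1 - F(X))^r]
    a0 = xs.mean()
    a1 = np.sum((n - j) / (n - 1) * xs) / n
    a2 = np.sum((n - j) * (n - j - 1) / ((n - 1) * (n - 2)) * xs) / n
    denom = 6.0 * a1 - a0 - 6.0 * a2
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = (2.0 * a1 - a0) / denom
    if not np.isfinite(shape) or shape <= 1.0:
        # gamma(1 - 1/shape) is undefined/inf for shape <= 1
        return np.nan, np.nan, np.nan
    g = _gamma(1.0 + 1.0 / shape) * _gamma(1.0 - 1.0 / shape)
    scale = (a0 - 2.0 * a1) * shape / g
    loc = a0 - scale * g
    return shape, scale, loc


def fit_standardize(values: np.ndarray, min_n: int = 30) -> tuple[np.ndarray, str]:
    """Map one-value-per-year samples to standard-normal scores.

    A three-parameter log-logistic distribution is fitted by unbiased PWMs
    (the SPEIbase convention); the score of each value is the
    standard-normal quantile of its fitted CDF probability. When the fit is
    invalid (non-finite shape, shape ≤ 1, or fitted location at/above the
    sample minimum, so that some datum would fall outside the support) the
    function falls back to Weibull plotting-position (rank/(n+1)) empirical
    standardization.

    Returns
    -------
    scores, method
        Scores (NaNs preserved, clipped to ±4) and one of
        ``"pwm"``, ``"plotting-position"``, ``"undefined"``.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    finite = np.isfinite(v)
    x = v[finite]
    if x.size < min_n or np.all(x == x[0] if x.size else True):
        return out, "undefined"
    if np.std(x) == 0.0:
        return out, "undefined"

    shape, scale, loc = _pwm_loglogistic(x)
    if np.isfinite(shape) and loc < x.min() and scale != 0.0:
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            cdf = 1.0 / (1.0 + (scale / (x - loc)) ** shape)
        if np.all(np.isfinite(cdf)) and np.all((cdf > 0) & (cdf < 1)):
            out[finite] = np.clip(norm.ppf(cdf), -SCORE_CLIP, SCORE_CLIP)
            return out, "pwm"

    # graceful degradation at small n: empirical plotting positions
    ranks = np.argsort(np.argsort(x)) + 1.0
    p = ranks / (x.size + 1.0)
    out[finite] = np.clip(norm.ppf(p), -SCORE_CLIP, SCORE_CLIP)
    return out, "plotting-position"


def compute_spei(
    ppet: np.ndarray,
    n_years: int | None = None,
    durations: range | None = None,
) -> xr.Dataset:
    """Multiscale SPEI cube from per-cell monthly P−PET series.

    Parameters
    ----------
    ppet
        Array (n_cells, 12 * n_years) of monthly P−PET (mm/month), complete
        consecutive calendar months starting in January of year 0.
    n_years
        Number of years (inferred from the time axis when omitted).
    durations
        Accumulation durations; defaults to 1..14.

    Returns
    -------
    xarray.Dataset with
        ``spei``   (cell, duration, month, year) — standard-normal scores;
        NaN where the accumulation window precedes the first data month or
        the fit is undefined;
        ``method`` (cell, duration, month) — 0 PWM fit, 1 plotting-position
        fallback, 2 undefined.

    Each cell's full monthly series is detrended once; for every
    (duration d, calendar ending month m) the n_years accumulated values
    ending in m are standardized independently. Values are dated by the
    ending month of the accumulation.
    """
    ppet = np.atleast_2d(np.asarray(ppet, dtype=float))
    n_cells, n_months = ppet.shape
    if n_years is None:
        n_years = n_months // 12
    if n_months != 12 * n_years:
        raise ValueError("time axis must hold exactly 12 * n_years months")
    if durations is None:
        durations = range(1, MAX_DURATION + 1)
    durations = list(durations)

    method_codes = {"pwm": 0, "plotting-position": 1, "undefined": 2}
    cube = np.full((n_cells, len(durations), 12, n_years), np.nan)
    meth = np.full((n_cells, len(durations), 12), 2, dtype=np.int8)

    for c in range(n_cells):
        resid, _ = detrend_linear(ppet[c])
        for di, d in enumerate(durations):
            acc = accumulate(resid, d)
            for m in range(12):
                vals = acc[m::12]
                scores, how = fit_standardize(vals)
                cube[c, di, m, :] = scores
                meth[c, di, m] = method_codes[how]

    return xr.Dataset(
        {
            "spei": (("cell", "duration", "month", "year"), cube),
            "method": (("cell", "duration", "month"), meth),
        },
        coords={
            "cell": np.arange(n_cells),
            "duration": durations,
            "month": np.arange(1, 13),
            "year": np.arange(n_years),
        },
    )


def compute_syi(yields: np.ndarray) -> xr.Dataset:
    """Standardized Yield Index per location from yearly yields.

    Applies the same detrend → log-logistic fit → normal-quantile path as
    the SPEI, with the single implicit annual duration. Input shape
    (n_cells, n_years); returns a Dataset with ``syi`` (cell, year) and
    ``method`` (cell).
    """
    y = np.atleast_2d(np.asarray(yields, dtype=float))
    n_cells, n_years = y.shape
    scores = np.full_like(y, np.nan, dtype=float)
    method_codes = {"pwm": 0, "plotting-position": 1, "undefined": 2}
    meth = np.full(n_cells, 2, dtype=np.int8)
    for c in range(n_cells):
        resid, degenerate = detrend_linear(y[c])
        if degenerate:
            continue
        s, how = fit_standardize(resid)
        scores[c] = s
        meth[c] = method_codes[how]
    return xr.Dataset(
        {"syi": (("cell", "year"), scores), "method": (("cell",), meth)},
        coords={"cell": np.arange(n_cells), "year": np.arange(n_years)},
    )


def classify_array(values: np.ndarray) -> np.ndarray:
    """Class index 0..6 (driest/lowest to wettest/highest); −1 for NaN.

    Boundaries (identical for SPEI and SYI): the dry/low side is
    upper-inclusive (x ≤ −2 extreme, −2 < x ≤ −1.5 severe,
    −1.5 < x ≤ −1 moderate) and the wet/high side lower-inclusive
    (1 ≤ x < 1.5 moderate, 1.5 ≤ x < 2 severe, x ≥ 2 extreme);
    −1 < x < 1 is normal.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, -1, dtype=np.int8)
    finite = np.isfinite(v)
    out[finite & (v <= -2.0)] = 0
    out[finite & (v > -2.0) & (v <= -1.5)] = 1
    out[finite & (v > -1.5) & (v <= -1.0)] = 2
    out[finite & (v > -1.0) & (v < 1.0)] = 3
    out[finite & (v >= 1.0) & (v < 1.5)] = 4
    out[finite & (v >= 1.5) & (v < 2.0)] = 5
    out[finite & (v >= 2.0)] = 6
    return out


@dataclass(frozen=True)
class Classification:
    """Magnitude class and macro-class of a single index value."""

    label: str
    macro: str
    index: int


def classify(value: float, kind: str = "spei") -> Classification | None:
    """Classify one SPEI or SYI value; returns None for undefined input."""
    if kind not in ("spei", "syi"):
        raise ValueError("kind must be 'spei' or 'syi'")
    idx = int(classify_array(np.array([value]))[0])
    if idx < 0:
        return None
    labels = SPEI_CLASSES if kind == "spei" else SYI_CLASSES
    macros = MACRO_SPEI if kind == "spei" else MACRO_SYI
    return Classification(labels[idx], macros[idx], idx)
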