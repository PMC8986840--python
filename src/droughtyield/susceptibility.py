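"""Country and year susceptibility to multiscale drought in low-yield years.

For every year with country SYI ≤ −1, the number of admissible (duration,
ending-month) combinations with country SPEI ≤ −1 is counted; the
across-years average per (country, cropping system) measures how complex a
drought pattern typically accompanies a low yield there. Averages pooled
over all cropping systems are split into five quintile classes (zero kept
as its own class); the yearly global view summarizes the per-country counts
year by year with box-plot statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import pair_series
from .spatial import SeasonWindow

__all__ = [
    "SusceptibilityRecord",
    "count_drought_combos",
    "classify_susceptibility",
    "yearly_global",
    "SUSCEPTIBILITY_LABELS",
]

SUSCEPTIBILITY_LABELS = ("Very Low", "Low", "Medium", "High", "Very High")


@dataclass(frozen=True)
class SusceptibilityRecord:
    """Drought-combination counts of one (country, cropping system)."""

    country: int | str
    cropping_system: str
    counts: dict[int, int] = field(default_factory=dict)  # low-yield year -> count
    average: float | None = None


def count_drought_combos(
    spei_cube,
    syi_series: np.ndarray,
    window: SeasonWindow,
    country: int | str = 0,
    cropping_system: str = "crop",
    drought_threshold: float = -1.0,
    syi_threshold: float = -1.0,
) -> SusceptibilityRecord:
    """Count drought window combinations in each low-yield year.

    ``spei_cube`` is a country-level DataArray (duration, month, year).
    For every harvest year with SYI ≤ ``syi_threshold`` the (duration,
    ending month) pairs of the window with a defined SPEI ≤
    ``drought_threshold`` are counted; undefined SPEI values never count
    as drought. The average is None when no low-yield year exists.
    """
    syi = np.asarray(syi_series, dtype=float)
    low_years = np.flatnonzero(np.isfinite(syi) & (syi <= syi_threshold))
    aligned = {}
    for pair in window.pairs:
        raw = np.asarray(
            spei_cube.sel(duration=pair.duration, month=pair.month).values,
            dtype=float,
        )
        aligned[pair] = pair_series(raw, pair.year_offset)
    counts = {}
    for y in low_years:
        n = 0
        for pair, series in aligned.items():
            v = series[y]
            if np.isfinite(v) and v <= drought_threshold:
                n += 1
        counts[int(y)] = n
    avg = float(np.mean(list(counts.values()))) if counts else None
    return SusceptibilityRecord(
        country=country, cropping_system=cropping_system,
        counts=counts, average=avg,
    )


def classify_susceptibility(
    averages: dict, n_classes: int = 5
) -> tuple[dict, np.ndarray]:
    """Five-quantile susceptibility classes on pooled positive averages.

    ``averages`` maps a key (e.g. (country, system)) to an average count;
    None entries (no low-yield year) are dropped; exact zeros form their
    own "Zero" class. Positive values, pooled across all cropping
    systems, are split by quintiles (linear-interpolation quantile
    estimator) into lower-open/upper-closed bins labelled Very Low .. Very
    High. With fewer than ``n_classes`` positive values every positive key
    is labelled "Positive" (single-class fallback).

    Returns (labels per key, quintile bin edges).
    """
    defined = {k: v for k, v in averages.items() if v is not None}
    positive = np.array([v for v in defined.values() if v > 0], dtype=float)
    labels: dict = {}
    if positive.size >= n_classes:
        edges = np.quantile(positive, np.linspace(0, 1, n_classes + 1)[1:-1])
        for k, v in defined.items():
            if v <= 0:
                labels[k] = "Zero"
            else:
                labels[k] = SUSCEPTIBILITY_LABELS[
                    int(np.searchsorted(edges, v, side="left"))
                ]
    else:
        edges = np.array([])
        for k, v in defined.items():
            labels[k] = "Zero" if v <= 0 else "Positive"
    return labels, edges


def yearly_global(
    records: list[SusceptibilityRecord],
    low_medium_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-(year, cropping system) distribution of country counts.

    For each year, the counts contributed by every country whose SYI was
    low that year are summarized with median, quartiles and Tukey whiskers
    (the most extreme values within 1.5 × IQR of the quartiles).
    ``low_medium_threshold`` — the upper bound of the second quintile bin
    from :func:`classify_susceptibility` — is echoed into every row as the
    low/medium susceptibility boundary.
    """
    pooled: dict[tuple[int, str], list[int]] = {}
    for rec in records:
        for year, n in rec.counts.items():
            pooled.setdefault((year, rec.cropping_system), []).append(n)
    rows = []
    for (year, system), counts in sorted(pooled.items()):
        c = np.asarray(counts, dtype=float)
        q25, med, q75 = np.percentile(c, [25, 50, 75])
        iqr = q75 - q25
        inside = c[(c >= q25 - 1.5 * iqr) & (c <= q75 + 1.5 * iqr)]
        rows.append(
            {
                "year": year,
                "cropping_system": system,
                "n_countries": c.size,
                "median": med,
                "q25": q25,
                "q75": q75,
                "whisker_low": inside.min(),
                "whisker_high": inside.max(),
                "low_medium_threshold": low_medium_threshold,
            }
        )
    return pd.DataFrame(rows)
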