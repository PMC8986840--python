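"""Zonal bookkeeping: crop-fraction resampling, country weights, country
aggregation of index cubes, calendar month conversion, and the admissible
duration × timing window of a cropping season.

Conventions: months are 1-based; grid cells are indexed row-major from the
north-west corner; flat cell ids are ``row * n_cols + col``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "block_average",
    "country_weights",
    "aggregate_spei",
    "aggregate_syi",
    "doy_to_month",
    "calendar_to_months",
    "WindowPair",
    "SeasonWindow",
    "build_window",
]

# cumulative days at the end of each month, 365-day (non-leap) calendar
_MONTH_END_DOY = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


def block_average(fine: np.ndarray, factor: int = 6) -> np.ndarray:
    """Coarsen a grid by arithmetic block means.

    Each coarse cell is the mean of its ``factor × factor`` fine cells
    (e.g. 36 cells when aggregating a 1/12° fraction-cover grid to 0.5°).
    """
    fine = np.asarray(fine, dtype=float)
    rows, cols = fine.shape
    if rows % factor or cols % factor:
        raise ValueError(
            f"grid shape {fine.shape} not divisible by factor {factor}"
        )
    return fine.reshape(rows // factor, factor, cols // factor, factor).mean(
        axis=(1, 3)
    )


def country_weights(
    fractions: np.ndarray, country_grid: np.ndarray
) -> tuple[dict[int, np.ndarray], list[int]]:
    """Within-country weights proportional to crop fraction cover.

    For each country, W_cell = FC_cell / Sum_FC where Sum_FC is the sum of
    the fraction cover over the country's cells; weights sum to 1.
    Countries whose total fraction is zero are excluded.

    Returns
    -------
    weights, excluded
        ``weights`` maps country id → weight grid (same shape as the
        coarse grid, zero outside the country); ``excluded`` lists country
        ids with no cultivated surface.
    """
    fractions = np.asarray(fractions, dtype=float)
    country_grid = np.asarray(country_grid)
    if fractions.shape != country_grid.shape:
        raise ValueError("fraction and country grids must be aligned")
    weights: dict[int, np.ndarray] = {}
    excluded: list[int] = []
    for cid in np.unique(country_grid):
        mask = country_grid == cid
        total = fractions[mask].sum()
        if total <= 0.0:
            excluded.append(int(cid))
            continue
        w = np.zeros_like(fractions)
        w[mask] = fractions[mask] / total
        weights[int(cid)] = w
    return weights, excluded


def aggregate_spei(
    spei: xr.Dataset | xr.DataArray, weights: dict[int, np.ndarray]
) -> xr.DataArray:
    """Fraction-weighted country average of a cell-level SPEI cube.

    ``spei`` has dims (cell, duration, month, year), cell ids row-major
    over the coarse grid. An undefined cell value with positive weight
    makes the country value undefined for that (duration, month, year):
    silent renormalization would bias dry/wet frequencies.
    """
    da = spei["spei"] if isinstance(spei, xr.Dataset) else spei
    countries = sorted(weights)
    if not countries:
        raise ValueError("no countries with positive weights")
    vals = da.transpose("cell", "duration", "month", "year").values
    n_cells = vals.shape[0]
    out = np.full((len(countries),) + vals.shape[1:], np.nan)
    for i, cid in enumerate(countries):
        w = np.asarray(weights[cid], dtype=float).ravel()
        if w.size != n_cells:
            raise ValueError("weight grid does not match the index cube cells")
        sel = np.flatnonzero(w > 0)
        if sel.size == 0:
            continue
        # dot propagates NaN from any positively weighted cell
        out[i] = np.tensordot(w[sel], vals[sel], axes=(0, 0))
    return xr.DataArray(
        out,
        dims=("country", "duration", "month", "year"),
        coords={
            "country": countries,
            "duration": da["duration"].values,
            "month": da["month"].values,
            "year": da["year"].values,
        },
        name="spei",
    )


def aggregate_syi(
    syi: xr.Dataset | xr.DataArray,
    country_grid: np.ndarray,
    crop_mask: np.ndarray,
) -> xr.DataArray:
    """Plain (unweighted) country mean of cell-level SYI series.

    Deliberately contrasts with :func:`aggregate_spei`: gridded yields are
    already fraction-weighted in their source dataset, so the country SYI
    is the simple mean over cells carrying the cropping system
    (``crop_mask``). Countries with no such cell are excluded.
    """
    da = syi["syi"] if isinstance(syi, xr.Dataset) else syi
    country_flat = np.asarray(country_grid).ravel()
    mask_flat = np.asarray(crop_mask).ravel().astype(bool)
    vals = da.transpose("cell", "year").values
    rows = []
    countries = []
    for cid in np.unique(country_flat):
        sel = np.flatnonzero((country_flat == cid) & mask_flat)
        if sel.size == 0:
            continue
        countries.append(int(cid))
        rows.append(vals[sel].mean(axis=0))
    if not countries:
        raise ValueError("no country has cells carrying the cropping system")
    return xr.DataArray(
        np.vstack(rows),
        dims=("country", "year"),
        coords={"country": countries, "year": da["year"].values},
        name="syi",
    )


def doy_to_month(doy: np.ndarray) -> np.ndarray:
    """Day of year (1..365/366) → containing calendar month, non-leap
    calendar; day 366 maps to December."""
    d = np.asarray(doy)
    if np.any((d < 1) | (d > 366)):
        raise ValueError("day of year must be in 1..366")
    return np.minimum(np.searchsorted(_MONTH_END_DOY, d, side="left"), 11) + 1


def calendar_to_months(
    planting_doy: np.ndarray,
    harvest_doy: np.ndarray,
    country_grid: np.ndarray,
) -> pd.DataFrame:
    """Per-country planting/harvesting months from cell-level average dates.

    Cell day-of-year values are converted to calendar months; the country
    month is the half-up rounded arithmetic mean of the cell months (4.5
    rounds to 5). Plain, non-circular averaging is used; a country whose
    cell months span more than half the year is flagged
    (``boundary_flag``) as a possible December/January straddle where the
    plain average is questionable. Cells with NaN dates are ignored;
    countries with no valid cell are excluded.
    """
    pg = np.asarray(planting_doy, dtype=float).ravel()
    hg = np.asarray(harvest_doy, dtype=float).ravel()
    cg = np.asarray(country_grid).ravel()
    rows = []
    for cid in np.unique(cg):
        sel = (cg == cid) & np.isfinite(pg) & np.isfinite(hg)
        if not sel.any():
            continue
        pm_cells = doy_to_month(pg[sel].astype(int))
        hm_cells = doy_to_month(hg[sel].astype(int))
        flag = bool(
            (pm_cells.max() - pm_cells.min() > 6)
            or (hm_cells.max() - hm_cells.min() > 6)
        )
        rows.append(
            {
                "country": int(cid),
                "planting_month": _round_half_up(pm_cells.mean()),
                "harvesting_month": _round_half_up(hm_cells.mean()),
                "boundary_flag": flag,
            }
        )
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class WindowPair:
    """One admissible (duration, ending month) combination.

    ``month`` is the calendar ending month of the accumulation;
    ``year_offset`` places that month relative to the harvest calendar
    year (0 same year, −1/−2 prior years for seasons wrapping the year
    boundary); ``mbh`` is the timing as months before the harvesting
    month.
    """

    duration: int
    month: int
    year_offset: int
    mbh: int


@dataclass(frozen=True)
class SeasonWindow:
    """Admissible duration × timing combinations for one calendar.

    The window spans the months from two months before planting (soil
    workability and antecedent moisture) through the harvesting month:
    W = L + 2 months for a season of length L, giving W·(W+1)/2
    combinations — every duration d = 1..W at each ending month such that
    the accumulation lies fully inside the window.
    """

    planting_month: int
    harvesting_month: int
    season_length: int
    pairs: tuple[WindowPair, ...] = field(repr=False)

    @property
    def width(self) -> int:
        return self.season_length + 2

    @property
    def months(self) -> tuple[tuple[int, int], ...]:
        """Window (calendar month, year offset) from earliest to harvest."""
        w = self.width
        out = []
        for j in range(w - 1, -1, -1):  # j = months before harvest
            q, r = divmod(self.harvesting_month - 1 - j, 12)
            out.append((r + 1, q))
        return tuple(out)


def build_window(pm: int, hm: int) -> SeasonWindow:
    """Enumerate the admissible SPEI duration × timing pairs.

    Season length L = ((HM − PM) mod 12) + 1 (planting and harvesting
    months inclusive, wrapping allowed); the window runs from PM−2 to HM.
    E.g. harvest in August with a 5-month season (planting April) gives a
    7-month window and 28 pairs with durations 1..7.
    """
    if not (1 <= pm <= 12 and 1 <= hm <= 12):
        raise ValueError("planting and harvesting months must be in 1..12")
    length = ((hm - pm) % 12) + 1
    w = length + 2
    pairs = []
    for d in range(1, w + 1):
        # ending position i within the window (0 = earliest month)
        for i in range(d - 1, w):
            j = w - 1 - i  # months before harvest
            q, r = divmod(hm - 1 - j, 12)
            pairs.append(WindowPair(duration=d, month=r + 1, year_offset=q, mbh=j))
    return SeasonWindow(
        planting_month=pm,
        harvesting_month=hm,
        season_length=length,
        pairs=tuple(pairs),
    )
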