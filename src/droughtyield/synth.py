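"""Synthetic geography, climate and yield worlds.

The generator emulates the statistical structure the association analysis
assumes — not any real dataset's magnitudes or spatial covariance:

* a coarse country grid of contiguous rectangular blocks with a fine
  (block-factor finer) crop fraction-cover grid containing exact zeros;
* per-country cropping-season calendars (planting month PM, harvesting
  month HM), including seasons wrapping the calendar year;
* per-cell monthly P−PET series = intercept + linear trend + sinusoidal
  seasonality + AR(1) noise, with optional injected multi-month dry spells
  (additive before any detrending, so interannual events survive the
  pipeline's linear trend removal);
* yearly yields = base + technology trend + an optional coupling to the
  standardized rolling P−PET sum over a configurable window ending a fixed
  number of months before harvest + white noise. ``coupling_beta = 0``
  gives a null world.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .indices import accumulate

__all__ = ["DrySpell", "SynthConfig", "Geography", "MonthlyGrid", "SynthWorld",
           "generate_geography", "generate_climate", "generate_yield",
           "generate_world", "load_world"]


class ConfigError(ValueError):
    """Invalid synthetic-world configuration."""


@dataclass(frozen=True)
class DrySpell:
    """An injected dry event: a negative P−PET offset (mm/month) applied
    over ``length`` months starting at ``start_month`` of ``year``, on the
    given flat coarse-cell ids (None = all cells)."""

    year: int
    start_month: int
    length: int
    offset: float
    cells: tuple[int, ...] | None = None


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the stated synthetic world.

    Defaults mirror the analysed setting: 36 years (the study period
    1981–2016 is 36 years long and the standardization needs ≥ 30), a 0.5°
    -style coarse grid built from a 6× finer fraction grid, and mid-
    latitude monthly water-balance magnitudes (≈ ±40 mm/month seasonal
    cycle, 30 mm/month interannual noise, a mild drying trend). The yield
    coupling window defaults to a 3-month accumulation ending 2 months
    before harvest; ``coupling_beta = 0`` keeps the world null.
    """

    n_years: int = 36
    fine_shape: tuple[int, int] = (36, 36)
    coarse_factor: int = 6
    n_countries: int = 6
    cropping_systems: tuple[str, ...] = ("maize_main",)
    seed: int = 0
    # climate (P-PET, mm/month)
    base_ppet: float = 10.0
    trend_ppet: float = -0.2  # mm/month per year
    ar1_rho: float = 0.3
    season_amp: float = 40.0
    noise_sd: float = 30.0
    dry_spells: tuple[DrySpell, ...] = ()
    # yields
    yield_base: float = 5.0
    yield_trend: float = 0.05  # units per year
    yield_noise_sd: float = 0.5
    coupling_beta: float = 0.0  # yield units per standardized anomaly
    coupling_duration: int = 3
    coupling_ending_mbh: int = 2
    coupling_kind: str = "linear"  # "linear" (beta*z) or "deficit" (beta*min(z,0))
    coupled_countries: tuple[int, ...] | None = None  # None = all
    # geography knobs
    zero_fraction_prob: float = 0.1
    zero_countries: tuple[int, ...] = ()
    fixed_calendar: tuple[int, int] | None = None  # (PM, HM) for all
    force_wrap_case: bool = True

    def __post_init__(self):
        # normalize list-valued fields (e.g. parsed from YAML) to tuples
        for name in ("fine_shape", "cropping_systems", "dry_spells",
                     "coupled_countries", "zero_countries", "fixed_calendar"):
            v = getattr(self, name)
            if isinstance(v, list):
                object.__setattr__(self, name, tuple(v))
        if any(isinstance(d, dict) for d in self.dry_spells):
            object.__setattr__(
                self,
                "dry_spells",
                tuple(
                    DrySpell(**{**d, "cells": tuple(d["cells"]) if d.get("cells") else None})
                    if isinstance(d, dict) else d
                    for d in self.dry_spells
                ),
            )
        if self.n_years < 30:
            raise ConfigError("n_years must be >= 30 for standardization")
        r, c = self.fine_shape
        f = self.coarse_factor
        if r % f or c % f:
            raise ConfigError("fine grid dimensions must be divisible by coarse_factor")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho must be in [0, 1)")
        if self.n_countries < 1 or self.n_countries > (r // f) * (c // f):
            raise ConfigError("n_countries must fit on the coarse grid")
        if self.coupling_kind not in ("linear", "deficit"):
            raise ConfigError("coupling_kind must be 'linear' or 'deficit'")

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.fine_shape[0] // self.coarse_factor,
                self.fine_shape[1] // self.coarse_factor)

    @property
    def n_cells(self) -> int:
        r, c = self.coarse_shape
        return r * c

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("fine_shape", "cropping_systems", "coupled_countries",
                    "zero_countries", "fixed_calendar"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "dry_spells" in raw:
            raw["dry_spells"] = tuple(
                DrySpell(**{**d, "cells": tuple(d["cells"]) if d.get("cells") else None})
                for d in raw["dry_spells"]
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        def _plain(obj):
            if isinstance(obj, tuple):
                return [_plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            return obj

        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))


@dataclass(frozen=True)
class Geography:
    country_grid: np.ndarray          # coarse (rows, cols) int ids
    crop_fraction_fine: np.ndarray    # fine (rows, cols) in [0, 1]
    calendars: pd.DataFrame           # country, cropping_system, PM, HM


@dataclass(frozen=True)
class MonthlyGrid:
    """Per-cell monthly P−PET series with grid/country metadata."""

    values: np.ndarray                # (n_cells, 12 * n_years)
    coarse_shape: tuple[int, int]
    cell_country: np.ndarray          # (n_cells,) flat, row-major
    n_years: int

    def __post_init__(self):
        if self.values.shape[1] != 12 * self.n_years:
            raise ValueError("time axis must be 12 * n_years complete months")


@dataclass(frozen=True)
class SynthWorld:
    config: SynthConfig
    geography: Geography
    ppet: MonthlyGrid
    yields: dict[str, np.ndarray] = field(repr=False)  # system -> (cells, years)

    @property
    def crop_fraction_coarse(self) -> np.ndarray:
        from .spatial import block_average

        return block_average(self.geography.crop_fraction_fine,
                             self.config.coarse_factor)

    def to_dir(self, path: str | Path) -> None:
        """Serialize as NetCDF3 grids + a CSV calendar table + YAML config."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        nc = dict(engine="scipy")
        g = self.geography
        xr.Dataset(
            {
                "country": (("row", "col"), g.country_grid.astype(np.int32)),
                "fraction_fine": (("frow", "fcol"), g.crop_fraction_fine),
            }
        ).to_netcdf(path / "geography.nc", **nc)
        xr.Dataset(
            {"ppet": (("cell", "time"), self.ppet.values)}
        ).to_netcdf(path / "ppet.nc", **nc)
        xr.Dataset(
            {s: (("cell", "year"), v) for s, v in self.yields.items()}
        ).to_netcdf(path / "yields.nc", **nc)
        g.calendars.to_csv(path / "calendars.csv", index=False)
        self.config.to_yaml(path / "config.yaml")


def _country_blocks(coarse_shape: tuple[int, int], n_countries: int) -> np.ndarray:
    """Contiguous rectangular country blocks: horizontal row strips when
    possible, else equal contiguous row-major runs."""
    rows, cols = coarse_shape
    grid = np.empty((rows, cols), dtype=np.int32)
    if rows >= n_countries:
        for cid, strip in enumerate(np.array_split(np.arange(rows), n_countries)):
            grid[strip, :] = cid
    else:
        flat = np.empty(rows * cols, dtype=np.int32)
        for cid, run in enumerate(np.array_split(np.arange(rows * cols), n_countries)):
            flat[run] = cid
        grid = flat.reshape(rows, cols)
    return grid


def generate_geography(cfg: SynthConfig, rng: np.random.Generator | None = None) -> Geography:
    """Country map, fine crop-fraction grid and per-country calendars."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    country_grid = _country_blocks(cfg.coarse_shape, cfg.n_countries)
    frac = rng.uniform(0.0, 1.0, size=cfg.fine_shape)
    frac[rng.uniform(size=cfg.fine_shape) < cfg.zero_fraction_prob] = 0.0
    if cfg.zero_countries:
        fine_country = np.kron(
            country_grid, np.ones((cfg.coarse_factor, cfg.coarse_factor), dtype=int)
        )
        frac[np.isin(fine_country, cfg.zero_countries)] = 0.0

    rows = []
    for system in cfg.cropping_systems:
        for cid in range(cfg.n_countries):
            if cfg.fixed_calendar is not None:
                pm, hm = cfg.fixed_calendar
            else:
                hm = int(rng.integers(1, 13))
                length = int(rng.integers(3, 9))
                pm = ((hm - length) % 12) + 1
            rows.append(
                {"country": cid, "cropping_system": system,
                 "planting_month": pm, "harvesting_month": hm}
            )
    cal = pd.DataFrame(rows)
    if cfg.fixed_calendar is None and cfg.force_wrap_case:
        wraps = cal["planting_month"] > cal["harvesting_month"]
        if not wraps.any():
            # season spanning the year boundary: plant October, harvest March
            cal.loc[cal.index[0], ["planting_month", "harvesting_month"]] = (10, 3)
    return Geography(country_grid=country_grid, crop_fraction_fine=frac, calendars=cal)


def generate_climate(
    cfg: SynthConfig,
    geography: Geography,
    rng: np.random.Generator | None = None,
) -> MonthlyGrid:
    """Monthly P−PET per coarse cell: trend + seasonality + AR(1) noise.

    The AR(1) noise is initialized at its stationary distribution so the
    marginal standard deviation equals ``noise_sd`` at every month; the
    seasonal phase is drawn once per cell. Dry spells are added last.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n_cells = cfg.n_cells
    n_months = 12 * cfg.n_years
    t = np.arange(n_months, dtype=float)
    month = (np.arange(n_months) % 12) + 1

    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_cells)
    det = (
        cfg.base_ppet
        + cfg.trend_ppet * t[None, :] / 12.0
        + cfg.season_amp * np.sin(2.0 * np.pi * month[None, :] / 12.0 + phase[:, None])
    )
    rho = cfg.ar1_rho
    eps = rng.standard_normal((n_cells, n_months))
    noise = np.empty((n_cells, n_months))
    noise[:, 0] = cfg.noise_sd * eps[:, 0]
    innov_sd = cfg.noise_sd * np.sqrt(1.0 - rho**2)
    for k in range(1, n_months):
        noise[:, k] = rho * noise[:, k - 1] + innov_sd * eps[:, k]
    values = det + noise

    for spell in cfg.dry_spells:
        t0 = 12 * spell.year + (spell.start_month - 1)
        if t0 < 0 or t0 + spell.length > n_months:
            raise ConfigError("dry spell outside the simulated period")
        cells = np.arange(n_cells) if spell.cells is None else np.asarray(spell.cells)
        values[np.ix_(cells, np.arange(t0, t0 + spell.length))] += spell.offset

    return MonthlyGrid(
        values=values,
        coarse_shape=cfg.coarse_shape,
        cell_country=geography.country_grid.ravel(),
        n_years=cfg.n_years,
    )


def _coupling_z(
    ppet_cell: np.ndarray, hm: int, duration: int, mbh: int, n_years: int
) -> np.ndarray:
    """Standardized rolling P−PET sum of ``duration`` months ending ``mbh``
    months before the harvesting month, one value per year."""
    acc = accumulate(ppet_cell, duration)
    ends = 12 * np.arange(n_years) + (hm - 1) - mbh
    if ends[0] - duration + 1 < 0 or ends[0] < 0:
        raise ConfigError(
            "coupling window extends before the first available month"
        )
    s = acc[ends]
    return (s - s.mean()) / s.std()


def generate_yield(
    cfg: SynthConfig,
    geography: Geography,
    climate: MonthlyGrid,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Yearly yields per cell and cropping system.

    yield(y) = base + trend·y + β·g(z(y)) + noise, with z the standardized
    water-balance anomaly of the configured window (per cell, using its
    country's harvesting month). ``coupling_kind`` sets the response
    g: "linear" is the identity (wet surplus helps as much as deficit
    hurts); "deficit" responds to water deficit only, g(z) = min(z, 0),
    emulating the asymmetric drought → yield-loss relation the analysis is
    designed to detect. β applies only to coupled countries; elsewhere
    (and when β = 0) yields are a pure trend + noise null.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    n_cells, n_years = cfg.n_cells, cfg.n_years
    years = np.arange(n_years, dtype=float)
    cal = geography.calendars.set_index(["cropping_system", "country"])
    out: dict[str, np.ndarray] = {}
    for system in cfg.cropping_systems:
        y = (
            cfg.yield_base
            + cfg.yield_trend * years[None, :]
            + cfg.yield_noise_sd * rng.standard_normal((n_cells, n_years))
        )
        if cfg.coupling_beta != 0.0:
            coupled = (
                set(range(cfg.n_countries))
                if cfg.coupled_countries is None
                else set(cfg.coupled_countries)
            )
            for cell in range(n_cells):
                cid = int(climate.cell_country[cell])
                if cid not in coupled:
                    continue
                hm = int(cal.loc[(system, cid), "harvesting_month"])
                z = _coupling_z(
                    climate.values[cell], hm, cfg.coupling_duration,
                    cfg.coupling_ending_mbh, n_years,
                )
                if cfg.coupling_kind == "deficit":
                    z = np.minimum(z, 0.0)
                y[cell] += cfg.coupling_beta * z
        out[system] = y
    return out


def generate_world(cfg: SynthConfig) -> SynthWorld:
    """Generate the full world deterministically from ``cfg.seed``."""
    geo = generate_geography(cfg)
    climate = generate_climate(cfg, geo)
    yields = generate_yield(cfg, geo, climate)
    return SynthWorld(config=cfg, geography=geo, ppet=climate, yields=yields)


def load_world(path: str | Path) -> SynthWorld:
    """Load a world serialized by :meth:`SynthWorld.to_dir`."""
    path = Path(path)
    cfg = SynthConfig.from_yaml(path / "config.yaml")
    with xr.open_dataset(path / "geography.nc", engine="scipy") as g:
        country = g["country"].values.astype(np.int32)
        frac = g["fraction_fine"].values
    with xr.open_dataset(path / "ppet.nc", engine="scipy") as p:
        ppet = p["ppet"].values
    with xr.open_dataset(path / "yields.nc", engine="scipy") as yds:
        yields = {name: yds[name].values for name in yds.data_vars}
    cal = pd.read_csv(path / "calendars.csv")
    geo = Geography(country_grid=country, crop_fraction_fine=frac, calendars=cal)
    grid = MonthlyGrid(
        values=ppet, coarse_shape=cfg.coarse_shape,
        cell_country=country.ravel(), n_years=cfg.n_years,
    )
    return SynthWorld(config=cfg, geography=geo, ppet=grid, yields=yields)
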