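"""End-to-end orchestration: synthetic world → indices → country
aggregation → association statistics → susceptibility, from one config,
with CSV outputs and a machine-readable run manifest.

Each stage is an importable function over in-memory objects; ``run``
chains them and serializes every stage product so any stage can be re-run
or audited independently. All randomness flows from the single seed in the
config, so a repeated run writes identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .association import (
    AssocResult,
    associate_pairs,
    asymmetry,
    build_table,
    dominance,
    dominance_summary,
    fisher_macro,
    merge_pvalues,
    classify_p,
    wilcoxon_split,
    pair_series,
)
from .indices import compute_spei, compute_syi
from .spatial import aggregate_spei, aggregate_syi, block_average, build_window, country_weights
from .susceptibility import classify_susceptibility, count_drought_combos, yearly_global
from .synth import ConfigError, SynthConfig, SynthWorld, generate_world

__all__ = ["RunConfig", "run"]

log = logging.getLogger("droughtyield")


@dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds plus the synthetic-world parameters."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    min_table_n: int = 36
    wilcoxon_min_group: int = 5
    dominance_thr_ge: float = 66.7
    dominance_thr_gt: float = 50.0
    drought_threshold: float = -1.0
    syi_threshold: float = -1.0

    def __post_init__(self):
        if self.min_table_n <= 0 or self.wilcoxon_min_group <= 0:
            raise ConfigError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synth", {})
        if isinstance(synth, dict):
            for key in ("fine_shape", "cropping_systems", "coupled_countries",
                        "zero_countries", "fixed_calendar"):
                if key in synth and isinstance(synth[key], list):
                    synth[key] = tuple(synth[key])
            synth = SynthConfig(**synth)
        return cls(synth=synth, **raw)

    def hash(self) -> str:
        def _plain(obj):
            if isinstance(obj, tuple):
                return [_plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            return obj

        blob = json.dumps(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _assoc_row(r: AssocResult) -> dict:
    row = {
        "country": r.country,
        "cropping_system": r.cropping_system,
        "duration": r.duration,
        "month": r.month,
        "year_offset": r.year_offset,
        "mbh": r.mbh,
        "n": r.n,
        "asym_mean": np.nan if r.asym_mean is None else r.asym_mean,
        "fisher_p": r.fisher_p,
        "wilcoxon_syi_p": r.wilcoxon_syi_p,
        "wilcoxon_syi_lower": r.wilcoxon_syi_lower,
        "wilcoxon_spei_p": r.wilcoxon_spei_p,
        "wilcoxon_spei_lower": r.wilcoxon_spei_lower,
        "merged_p": r.merged_p,
        "sig_class": r.sig_class,
        "dominance_ge": r.dominance_ge,
        "dominance_gt": r.dominance_gt,
    }
    for name, v in r.asym_components.items():
        row[f"asym_vs_{name}"] = v
    return row


def pooled_association(
    country_spei: xr.DataArray,
    country_syi: dict[int, np.ndarray],
    windows: dict[int, "object"],
    cropping_system: str,
    min_table_n: int = 36,
    min_group: int = 5,
) -> list[AssocResult]:
    """Association statistics on tables pooled across countries.

    Countries share the duration × months-before-harvest (MBH)
    coordinates even though their calendar months differ, so for each
    (d, mbh) cell the paired yearly values of every country whose window
    contains that cell are concatenated into one sample before the
    contingency table and the three tests are computed. This is the
    aggregation behind the per-crop significance matrix and the
    per-cropping-system dominance summary.
    """
    cells: dict[tuple[int, int], tuple[list, list]] = {}
    for cid, window in windows.items():
        if cid not in country_syi:
            continue
        syi = country_syi[cid]
        for pair in window.pairs:
            raw = np.asarray(
                country_spei.sel(
                    country=cid, duration=pair.duration, month=pair.month
                ).values,
                dtype=float,
            )
            spei = pair_series(raw, pair.year_offset)
            bucket = cells.setdefault((pair.duration, pair.mbh), ([], []))
            bucket[0].append(spei)
            bucket[1].append(syi)
    results = []
    for (d, mbh), (spei_parts, syi_parts) in sorted(cells.items()):
        spei = np.concatenate(spei_parts)
        syi = np.concatenate(syi_parts)
        table = build_table(spei, syi)
        asym = asymmetry(table, min_n=min_table_n)
        fisher = fisher_macro(table) if asym.computed else np.nan
        w1, w1_lower, w1_ok = wilcoxon_split(syi, spei, min_group=min_group)
        w2, w2_lower, w2_ok = wilcoxon_split(spei, syi, min_group=min_group)
        gate = asym.computed and asym.mean is not None
        if gate and w1_ok and w2_ok and np.isfinite(fisher):
            merged = merge_pvalues(fisher, w1, w2)
            if classify_p(merged) != "ns" and not (w1_lower and w2_lower):
                sig = "reversed"
            else:
                sig = classify_p(merged)
        else:
            merged, sig = np.nan, "not_computed"
        dom_ge, dom_gt = dominance(table)
        results.append(
            AssocResult(
                country="pooled",
                cropping_system=cropping_system,
                duration=d,
                month=-1,
                year_offset=0,
                mbh=mbh,
                n=table.n,
                asym_components=asym.components,
                asym_mean=asym.mean,
                fisher_p=fisher,
                wilcoxon_syi_p=w1,
                wilcoxon_syi_lower=w1_lower,
                wilcoxon_spei_p=w2,
                wilcoxon_spei_lower=w2_lower,
                merged_p=merged,
                sig_class=sig,
                dominance_ge=dom_ge,
                dominance_gt=dom_gt,
            )
        )
    return results


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and write the result bundle to ``outdir``.

    Returns a dict of the in-memory stage products (world, index cubes,
    per-country and pooled association results, susceptibility records,
    manifest). Files written: country weights and windows CSVs, the
    per-country association CSV, one significance-matrix CSV per cropping
    system (duration × MBH), a dominance summary CSV, susceptibility
    count/class CSVs, the yearly global summary, and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.synth

    log.info("stage synth: generating world (seed=%d)", cfg.seed)
    world = generate_world(cfg)
    world.to_dir(outdir / "world")
    n_cells = cfg.n_cells
    systems = list(cfg.cropping_systems)
    unknown = [s for s in systems
               if s not in set(world.geography.calendars["cropping_system"])]
    if unknown:
        raise ConfigError(f"unknown cropping systems: {unknown}")

    log.info("stage indices: SPEI on %d cells, SYI on %d systems", n_cells, len(systems))
    spei_cells = compute_spei(world.ppet.values, cfg.n_years)
    syi_cells = {s: compute_syi(world.yields[s]) for s in systems}

    log.info("stage aggregate: weights, windows, country cubes")
    frac_coarse = block_average(world.geography.crop_fraction_fine, cfg.coarse_factor)
    weights, excluded = country_weights(frac_coarse, world.geography.country_grid)
    log.info("countries with weights: %d (excluded: %s)", len(weights), excluded)
    wrows = [
        {"country": cid, "cell": i, "weight": w}
        for cid, grid in weights.items()
        for i, w in enumerate(grid.ravel())
        if w > 0
    ]
    pd.DataFrame(wrows).to_csv(outdir / "country_weights.csv", index=False)

    country_spei = aggregate_spei(spei_cells, weights)
    crop_mask = frac_coarse > 0
    country_syi: dict[str, dict[int, np.ndarray]] = {}
    for s in systems:
        agg = aggregate_syi(syi_cells[s], world.geography.country_grid, crop_mask)
        country_syi[s] = {
            int(c): agg.sel(country=c).values
            for c in agg["country"].values
            if int(c) in weights
        }

    cal = world.geography.calendars.set_index(["cropping_system", "country"])
    windows: dict[str, dict[int, object]] = {}
    wrows = []
    for s in systems:
        windows[s] = {}
        for cid in weights:
            pm = int(cal.loc[(s, cid), "planting_month"])
            hm = int(cal.loc[(s, cid), "harvesting_month"])
            win = build_window(pm, hm)
            windows[s][cid] = win
            for pair in win.pairs:
                wrows.append(
                    {"country": cid, "cropping_system": s,
                     "duration": pair.duration, "month": pair.month,
                     "mbh": pair.mbh, "year_offset": pair.year_offset}
                )
    pd.DataFrame(wrows).to_csv(outdir / "windows.csv", index=False)

    log.info("stage associate: per-country and pooled tables")
    assoc_rows = []
    per_country_results = []
    for s in systems:
        for cid, win in windows[s].items():
            if cid not in country_syi[s]:
                continue
            res = associate_pairs(
                country_spei.sel(country=cid),
                country_syi[s][cid],
                win,
                country=cid,
                cropping_system=s,
                min_table_n=config.min_table_n,
                min_group=config.wilcoxon_min_group,
            )
            per_country_results.extend(res)
            assoc_rows.extend(_assoc_row(r) for r in res)
    pd.DataFrame(assoc_rows).to_csv(outdir / "association_by_country.csv", index=False)

    pooled_results: dict[str, list[AssocResult]] = {}
    dominances: dict[str, list[tuple[float, float]]] = {}
    tables_analysed: dict[str, int] = {}
    for s in systems:
        pooled = pooled_association(
            country_spei, country_syi[s], windows[s], s,
            min_table_n=config.min_table_n, min_group=config.wilcoxon_min_group,
        )
        pooled_results[s] = pooled
        analysed = [r for r in pooled if r.n >= config.min_table_n
                    and np.isfinite(r.dominance_ge)]
        tables_analysed[s] = len(analysed)
        dominances[s] = [(r.dominance_ge, r.dominance_gt) for r in analysed]
        mat = (
            pd.DataFrame(
                [{"duration": r.duration, "mbh": r.mbh, "sig_class": r.sig_class}
                 for r in pooled]
            )
            .pivot(index="duration", columns="mbh", values="sig_class")
            .sort_index()
        )
        mat.to_csv(outdir / f"significance_matrix_{s}.csv")
        log.info("system %s: %d pooled tables analysed", s, tables_analysed[s])
    dom = dominance_summary(
        dominances, thr_ge=config.dominance_thr_ge, thr_gt=config.dominance_thr_gt
    )
    dom.to_csv(outdir / "dominance_summary.csv", index=False)

    log.info("stage susceptibility")
    records = []
    count_rows = []
    for s in systems:
        for cid, win in windows[s].items():
            if cid not in country_syi[s]:
                continue
            rec = count_drought_combos(
                country_spei.sel(country=cid),
                country_syi[s][cid],
                win,
                country=cid,
                cropping_system=s,
                drought_threshold=config.drought_threshold,
                syi_threshold=config.syi_threshold,
            )
            records.append(rec)
            for year, n in rec.counts.items():
                count_rows.append(
                    {"country": cid, "cropping_system": s, "year": year, "count": n}
                )
    pd.DataFrame(count_rows).to_csv(outdir / "susceptibility_counts.csv", index=False)
    averages = {(r.country, r.cropping_system): r.average for r in records}
    labels, edges = classify_susceptibility(averages)
    pd.DataFrame(
        [
            {"country": k[0], "cropping_system": k[1],
             "average": averages[k], "susceptibility_class": v}
            for k, v in labels.items()
        ]
    ).to_csv(outdir / "susceptibility_classes.csv", index=False)
    low_medium = float(edges[1]) if edges.size >= 2 else None
    yearly = yearly_global(records, low_medium_threshold=low_medium)
    yearly.to_csv(outdir / "yearly_susceptibility.csv", index=False)

    manifest = {
        "config_hash": config.hash(),
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "n_cells": n_cells,
        "n_countries_weighted": len(weights),
        "countries_excluded": excluded,
        "tables_analysed": tables_analysed,
        "n_records": len(records),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", outdir)

    return {
        "world": world,
        "spei_cells": spei_cells,
        "syi_cells": syi_cells,
        "country_spei": country_spei,
        "country_syi": country_syi,
        "windows": windows,
        "per_country": per_country_results,
        "pooled": pooled_results,
        "dominance_summary": dom,
        "susceptibility": records,
        "susceptibility_labels": labels,
        "yearly": yearly,
        "manifest": manifest,
    }
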