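"""Country aggregation and season windows.

Crop fraction cover is block-averaged to the analysis grid, turned into
within-country weights, and used to average cell SPEI to country level
(weighted) while country SYI is a plain mean. The cropping calendar
defines the admissible duration x timing window: from two months before
planting through the harvesting month.
"""

import numpy as np

import droughtyield as dy

cfg = dy.SynthConfig(fine_shape=(24, 24), n_countries=4, seed=3)
world = dy.generate_world(cfg)

frac = dy.block_average(world.geography.crop_fraction_fine, 6)
weights, excluded = dy.country_weights(frac, world.geography.country_grid)
print("within-country crop-fraction weights (sum to 1 per country):")
for cid, grid in weights.items():
    print(f"  country {cid}: weights {np.round(grid[grid > 0], 3)}")
if excluded:
    print(f"  excluded (no cultivated surface): {excluded}")

spei = dy.compute_spei(world.ppet.values, cfg.n_years)
country_spei = dy.aggregate_spei(spei, weights)
print(f"\ncountry SPEI cube: {dict(country_spei.sizes)}")

syi = dy.compute_syi(world.yields["maize_main"])
country_syi = dy.aggregate_syi(syi, world.geography.country_grid, frac > 0)
print(f"country SYI: {dict(country_syi.sizes)}")

# season windows from the calendars
print("\nduration x timing windows per country:")
for _, row in world.geography.calendars.iterrows():
    win = dy.build_window(row["planting_month"], row["harvesting_month"])
    wrap = " (wraps the year boundary)" if row["planting_month"] > row["harvesting_month"] else ""
    print(f"  country {row['country']}: PM={row['planting_month']} "
          f"HM={row['harvesting_month']} -> season {win.season_length} months, "
          f"{len(win.pairs)} (duration, ending month) pairs{wrap}")

# cell-level calendar averaging (day-of-year -> month, half-up country mean)
planting_doy = np.array([91.0, 95.0, 121.0, 100.0])  # early Apr .. early May
harvest_doy = np.array([213.0, 220.0, 230.0, 244.0])
months = dy.calendar_to_months(planting_doy, harvest_doy, np.zeros(4, int))
print("\ncell day-of-year calendars averaged to one country month:")
print(months.to_string(index=False))
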