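"""Driver regressions: what predicts alien richness across the landscape?

Fits OLS models of alien richness on climate (BIO6, BIO12), human footprint
and native richness over grid cells, screens collinearity with VIFs, and
regresses the alien proportion of each belt on native richness (a negative
slope would suggest biotic resistance).
"""

import montinv as mv

cfg = mv.SimulationConfig(seed=42)
records = mv.simulate_pool(cfg)
landscape = mv.simulate_landscape(cfg, 30, 10)

grid = mv.assign_grid(records, landscape)
table = mv.drivers_from_grid(grid)

fit = mv.fit_linear(table, "alien_richness",
                    ["bio6", "bio12", "footprint", "native_richness"],
                    interactions=True)
print("alien richness ~ climate + footprint + natives (z-scored, "
      "with interactions):")
print(fit.summary().round(3).to_string())
print(f"R^2 = {fit.rsquared:.3f}  (n = {fit.nobs} cells)\n")

vif = mv.collinearity_check(table, ["bio6", "bio12", "footprint", "elevation"])
print("variance inflation factors:", {k: round(v, 1) for k, v in vif.items()})
print("(bio6 and elevation are near-duplicates by construction -- the "
      "temperature lapse -- so elevation absorbs the climate signal)\n")

bands = mv.band_richness(records)
prop = mv.proportion_vs_native(bands.dropna(subset=["alien_proportion"]))
print(f"alien proportion vs native richness per belt: slope "
      f"{prop.slope:.5f} +/- {prop.se:.5f} (p = {prop.p:.3g})")
if prop.slope < 0:
    print("(negative slope here: with floor-anchored introductions the alien "
          "share falls exactly where natives get richer -- directional "
          "filtering can mimic biotic resistance at this grain)")
else:
    print("(no negative slope = no sign that native richness blocks aliens)")
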