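# montinv

Elevational-gradient analysis of alien vs. native montane floras:
band-wise richness, phylogenetic clustering, nestedness, and driver
regressions — with a synthetic-data generator that reproduces the
directional-filtering structure the analyses are designed to detect.

## The problem

Mountain floras accumulate alien plant species mostly from below:
introductions happen at low elevations and species expand upslope slowly.
If that *directional filtering* operates, high-elevation alien assemblages
should be nested subsets of low-elevation ones, and more strongly so than
native assemblages. Distinguishing that signature from ordinary climatic
control (warm, wet elevations simply hold more species of any origin)
requires comparing aliens and natives on richness, phylogenetic structure
and nestedness simultaneously — which is what this package implements, for
anyone working with elevational range tables (species, status, range
limits, regions), a genus/family backbone phylogeny, and gridded
climate/disturbance layers.

## What it computes

* **Richness**: species counted in every 200 m band their range overlaps;
  per-group tables and band-wise Pearson correlations; per-cell richness on
  a 0.2° grid (region × elevation intersection rule) and inverse-distance-
  weighted surfaces, `value(t) = Σ d_i^-p z_i / Σ d_i^-p`.
* **Community phylogenetics**: grafting of unsampled species onto a
  backbone (congeners at the genus basal node, placed half-way from the
  family node to the tip when the genus has a single exemplar); MPD and
  MNTD; the Net Relatedness Index and Nearest Taxon Index
  `NRI = −(MPD_obs − mean MPD_null)/SD(MPD_null)` against uniform
  tip-subset nulls (positive = clustering, |NRI| > 1.96 significant);
  species:genus ratios with natives rarefied to the alien genus count.
* **Nestedness**: NODF over rows and columns; the maximum NODF at the same
  dimensions and fill (exhaustive ≤ 16 cells, staircase optimum +
  hill-climb above); `NODFc = (NODF/NODF_max)/(C·ln S)`; branch-length
  treeNODF with its shared-species (S) and shared-topology (T) fractions;
  and a band-wise resampling test drawing equal-sized samples from the
  native and alien pools and comparing NODFc distributions (|Δ| > 0.05
  decisive).
* **Drivers**: OLS of alien richness on climate (BIO6, BIO12), human
  footprint and native richness with interactions and VIF screening, and
  the alien-proportion-vs-native-richness regression.

See `docs/methods.md` for the formulas, conventions and design choices.

## Worked example

```python
import montinv as mv

cfg = mv.SimulationConfig(seed=42)          # 600 natives, 300 aliens,
records = mv.simulate_pool(cfg)             # aliens floor-anchored w.p. 0.9,
backbone = mv.simulate_backbone(cfg)        # mean upward spread 800 m
tree = mv.graft_tips(backbone, [r for r in records
                                if r.name not in set(backbone.tip_labels)])

alien = mv.elevational_nestedness(records, group="alien", tree=tree)
native = mv.elevational_nestedness(records, group="native", tree=tree)
```

`examples/04_nestedness.py` runs exactly this and formats the two result
objects; at seed 42 it prints:

```
 alien: NODF  74.6  NODFmax  88.5  C 0.17  NODFc 1.087  treeNODF 82.5 (S 65.4 + T 17.1)
native: NODF  35.9  NODFmax  92.9  C 0.27  NODFc 0.303  treeNODF 59.4 (S 51.3 + T 8.1)
```

The alien matrix is far closer to its size-and-fill-matched maximum
nestedness than the native one (NODFc 1.09 vs 0.30): high-elevation alien
assemblages are near-subsets of low-elevation ones, exactly the
directional-filtering signature the generator planted. The resampling test
agrees decisively:

```
mean NODFc difference (alien - native) across bands: 0.710 (threshold 0.05)
```

The `examples/` directory holds five short narrative scripts — flora
generation, band richness + IDW, phylogenetic clustering, nestedness, and
driver regressions — each building a small input, running the method and
printing what the numbers mean.

## Reading real data

`read_species_table` ingests a UTF-8 CSV (one row per species: name,
genus, family, status, alien class, invasive flag, semicolon-separated
continents and regions, elev_min, elev_max), validates every record,
reports bad rows with line numbers, and counts range-less records excluded
from elevational analyses. A `dialect` mapping adapts externally curated
column headers. Trees are standard Newick; landscapes are CSV with
`lon,lat,region,mean_elev,bio6,bio12,footprint`.

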