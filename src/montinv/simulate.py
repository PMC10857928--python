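"""Synthetic species pools, backbone phylogenies and landscapes.

The generator emulates the statistical structure the elevational analysis
assumes, so every downstream stage can be exercised without external data:

* **Aliens** follow directional filtering: lower range limits anchored at the
  domain floor (the point of introduction) with probability
  ``introduction_mix``, and upper limits extended by an exponential spread
  with mean ``spread_rate`` metres.  This construction makes high-elevation
  alien assemblages nested subsets of low-elevation ones.
* **Natives** get ranges without low-elevation anchoring (uniform midpoints
  or a spreading-dye growth model).
* The **backbone tree** is a pure-birth (Yule) hierarchy — families, genera
  within families, one sequenced exemplar species per genus — normalised to
  a fixed crown height so all tips are contemporaneous; the remaining
  species in the pool are left for grafting.
* The **landscape** is a 0.2-degree grid with a smooth elevational ridge, a
  temperature lapse (BIO6), a west-to-east precipitation gradient (BIO12)
  and a human footprint that declines with elevation and is higher in the
  west.

All draws flow from a single integer seed, so identical configurations give
bit-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .core import (
    REGIONS,
    ElevationalBands,
    LandscapeGrid,
    SpeciesRecord,
    write_landscape,
    write_species_table,
)
from .trees import Phylogeny, write_newick

import pandas as pd

__all__ = ["SimulationConfig", "simulate_pool", "simulate_backbone",
           "simulate_landscape", "simulate_dataset"]

_CONTINENT_CHOICES = ("Africa", "Australia", "Europe", "NorthAmerica", "SouthAmerica")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study system (defaults are the study
    conditions used throughout the tests).

    Units: elevations in metres, temperatures in deg C, precipitation in mm,
    lapse rate in deg C per km, footprint in score units per km.
    """

    n_native: int = 600
    n_alien: int = 300
    domain: tuple[float, float] = (0.0, 5000.0)
    #: probability an alien's lower limit sits at the domain floor
    introduction_mix: float = 0.9
    #: mean of the exponential upper-range extension for aliens (m)
    spread_rate: float = 800.0
    native_range_model: str = "uniform_midpoint"
    #: mean native range extent (m)
    native_spread: float = 1400.0
    n_genera: int = 120
    n_families: int = 30
    #: per-lineage speciation rate of the pure-birth backbone (shapes
    #: topology only; heights are normalised to a fixed crown age)
    birth_rate: float = 1.0
    #: elevation at which P(tropical affinity) = 0.5
    tropical_cutoff: float = 2000.0
    lapse_rate: float = 6.5
    temp_at_floor: float = 12.0
    precip_west: float = 800.0
    precip_east: float = 3000.0
    footprint_slope: float = 6.0
    footprint_base: float = 28.0
    footprint_west_bonus: float = 8.0
    elev_noise_sd: float = 150.0
    temp_noise_sd: float = 0.8
    precip_noise_sd: float = 80.0
    footprint_noise_sd: float = 1.5
    #: > 0 tilts un-anchored alien midpoints towards native-rich elevations
    #: (sampling probability proportional to native richness ** exponent)
    coupling_exponent: float = 0.0
    #: fraction of species whose elevational range is withheld (missing data)
    missing_range_rate: float = 0.0
    p_cultivated: float = 0.52
    p_invasive_naturalised: float = 0.38
    p_invasive_cultivated: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        floor, ceiling = self.domain
        if ceiling <= floor:
            raise ValueError("domain ceiling must exceed floor")
        if self.spread_rate <= 0 or self.native_spread <= 0 or self.birth_rate <= 0:
            raise ValueError("rates must be positive")
        for p in (self.introduction_mix, self.missing_range_rate,
                  self.p_cultivated, self.p_invasive_naturalised,
                  self.p_invasive_cultivated):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_genera > self.n_native + self.n_alien:
            raise ValueError("more genera than species")
        if self.n_families > self.n_genera:
            raise ValueError("more families than genera")
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if self.native_range_model not in {"uniform_midpoint", "spreading_dye"}:
            raise ValueError(f"unknown native range model {self.native_range_model!r}")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams, all derived from the one config seed
    return np.random.default_rng([config.seed, stream])


def _long_tailed_partition(n_items: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Assign items to groups with Zipf-like weights; every group non-empty."""
    w = 1.0 / (1.0 + np.arange(n_groups))
    w /= w.sum()
    assign = np.empty(n_items, dtype=np.intp)
    assign[:n_groups] = np.arange(n_groups)  # guarantee occupancy
    if n_items > n_groups:
        assign[n_groups:] = rng.choice(n_groups, size=n_items - n_groups, p=w)
    return assign


@dataclass(frozen=True)
class _Taxonomy:
    species: list[str]
    genus_of_species: list[str]
    family_of_genus: dict[str, str]
    species_by_genus: dict[str, list[str]]
    genera_by_family: dict[str, list[str]]


def _taxonomy(config: SimulationConfig) -> _Taxonomy:
    """Deterministic genus/family scaffold shared by the pool and the
    backbone simulators (so exemplar tips match pool species names)."""
    rng = _rng(config, 0)
    n_species = config.n_native + config.n_alien
    genus_idx = _long_tailed_partition(n_species, config.n_genera, rng)
    family_idx = _long_tailed_partition(config.n_genera, config.n_families, rng)
    genera = [f"Genus{i:03d}" for i in range(config.n_genera)]
    families = [f"Family{i:02d}" for i in range(config.n_families)]
    family_of_genus = {genera[g]: families[family_idx[g]] for g in range(config.n_genera)}
    species: list[str] = []
    genus_of_species: list[str] = []
    counters = {g: 0 for g in genera}
    for gi in genus_idx:
        g = genera[gi]
        counters[g] += 1
        # underscore binomials round-trip through Newick untouched
        species.append(f"{g}_sp{counters[g]:03d}")
        genus_of_species.append(g)
    species_by_genus: dict[str, list[str]] = {g: [] for g in genera}
    for s, g in zip(species, genus_of_species):
        species_by_genus[g].append(s)
    genera_by_family: dict[str, list[str]] = {f: [] for f in families}
    for g in genera:
        genera_by_family[family_of_genus[g]].append(g)
    return _Taxonomy(species, genus_of_species, family_of_genus,
                     species_by_genus, genera_by_family)


# ---------------------------------------------------------------------------
# species pool

def _native_band_richness(emin: np.ndarray, emax: np.ndarray,
                          bands: ElevationalBands) -> np.ndarray:
    counts = np.zeros(bands.n_bands)
    for lo, hi in zip(emin, emax):
        counts += bands.occupancy(lo, hi)
    return counts


def simulate_pool(config: SimulationConfig) -> list[SpeciesRecord]:
    """Draw a full species pool (natives + aliens) under the configured
    range models, affinity rule and taxonomy.

    Alien ranges: ``elev_min`` is the domain floor with probability
    ``introduction_mix`` (a point mass at the introduction elevation), else
    uniform over the domain; ``elev_max = elev_min + Exp(spread_rate)``
    truncated at the ceiling.  Affinity is tropical with probability
    declining logistically in the range midpoint around ``tropical_cutoff``.
    """
    tax = _taxonomy(config)
    rng = _rng(config, 1)
    floor, ceiling = config.domain
    n_nat, n_ali = config.n_native, config.n_alien

    # natives first (alien coupling may depend on their richness profile)
    if config.native_range_model == "uniform_midpoint":
        mid = rng.uniform(floor, ceiling, size=n_nat)
        half = rng.exponential(config.native_spread, size=n_nat) / 2.0
        nat_min = np.maximum(floor, mid - half)
        nat_max = np.minimum(ceiling, mid + half)
    else:  # spreading_dye: grow independently in both directions from a seed point
        start = rng.uniform(floor, ceiling, size=n_nat)
        down = rng.exponential(config.native_spread / 2.0, size=n_nat)
        up = rng.exponential(config.native_spread / 2.0, size=n_nat)
        nat_min = np.maximum(floor, start - down)
        nat_max = np.minimum(ceiling, start + up)

    anchored = rng.random(n_ali) < config.introduction_mix
    ali_min = np.empty(n_ali)
    ali_min[anchored] = floor
    n_free = int((~anchored).sum())
    if config.coupling_exponent > 0 and n_free:
        bands = ElevationalBands(200.0, floor, ceiling)
        richness = _native_band_richness(nat_min, nat_max, bands)
        w = richness ** config.coupling_exponent
        if w.sum() == 0:
            w = np.ones_like(w)
        band_idx = rng.choice(bands.n_bands, size=n_free, p=w / w.sum())
        edges = bands.edges
        ali_min[~anchored] = rng.uniform(edges[band_idx], edges[band_idx + 1])
    elif n_free:
        ali_min[~anchored] = rng.uniform(floor, ceiling, size=n_free)
    if math.isinf(config.spread_rate):
        ali_max = np.full(n_ali, ceiling)
    else:
        ali_max = np.minimum(ceiling, ali_min + rng.exponential(config.spread_rate, size=n_ali))

    emin = np.concatenate([nat_min, ali_min])
    emax = np.concatenate([nat_max, ali_max])
    status = ["native"] * n_nat + ["alien"] * n_ali

    # affinity: logistic decline of P(tropical) with range midpoint
    mids = (emin + emax) / 2.0
    p_trop = 1.0 / (1.0 + np.exp((mids - config.tropical_cutoff) / 400.0))
    u = rng.random(n_nat + n_ali)
    tropical = u < p_trop
    cosmo = (~tropical) & (rng.random(n_nat + n_ali) < 0.15)
    affinity = np.where(tropical, "tropical", np.where(cosmo, "cosmopolitan", "temperate"))

    # contiguous runs of regions; aliens tend to be more widespread
    n_reg = len(REGIONS)
    width = 1 + rng.binomial(n_reg - 1, np.where(np.array(status) == "alien", 0.55, 0.35))
    start = rng.integers(0, n_reg, size=n_nat + n_ali)
    start = np.minimum(start, n_reg - width)

    klass_u = rng.random(n_ali)
    inv_u = rng.random(n_ali)
    cont_counts = 1 + rng.binomial(2, 0.4, size=n_ali)
    missing = rng.random(n_nat + n_ali) < config.missing_range_rate

    records: list[SpeciesRecord] = []
    for i in range(n_nat + n_ali):
        name = tax.species[i]
        genus = tax.genus_of_species[i]
        if status[i] == "alien":
            j = i - n_nat
            klass = "cultivated" if klass_u[j] < config.p_cultivated else "naturalised"
            p_inv = (config.p_invasive_cultivated if klass == "cultivated"
                     else config.p_invasive_naturalised)
            invasive = bool(inv_u[j] < p_inv)
            conts = frozenset(
                rng.choice(_CONTINENT_CHOICES, size=cont_counts[j], replace=False)
            )
        else:
            klass, invasive, conts = "none", False, frozenset({"Asia"})
        records.append(
            SpeciesRecord(
                name=name,
                genus=genus,
                family=tax.family_of_genus[genus],
                status=status[i],
                alien_class=klass,
                invasive=invasive,
                continents=conts,
                affinity=str(affinity[i]),
                regions=frozenset(REGIONS[start[i]: start[i] + width[i]]),
                elev_min=None if missing[i] else float(emin[i]),
                elev_max=None if missing[i] else float(emax[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# backbone tree

def _yule_tree(tip_labels: list[str], rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree over the given tips; ultrametric, unit-normalised height."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    if len(tip_labels) == 1:
        only = tree.seed_node.new_child(edge_length=1.0)
        only.taxon = taxa.new_taxon(label=tip_labels[0])
        return tree
    active = [tree.seed_node.new_child(edge_length=0.0),
              tree.seed_node.new_child(edge_length=0.0)]
    while len(active) < len(tip_labels):
        dt = rng.exponential(1.0 / (rate * len(active)))
        for node in active:
            node.edge.length += dt
        node = active.pop(int(rng.integers(len(active))))
        active.append(node.new_child(edge_length=0.0))
        active.append(node.new_child(edge_length=0.0))
    dt = rng.exponential(1.0 / (rate * len(active)))
    for node in active:
        node.edge.length += dt
    # randomise label order, then normalise crown height to 1
    order = rng.permutation(len(tip_labels))
    for node, k in zip(active, order):
        node.taxon = taxa.new_taxon(label=tip_labels[k])
    height = max(l.distance_from_root() for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length /= height
    return tree


def simulate_backbone(config: SimulationConfig, height: float = 100.0) -> Phylogeny:
    """Pure-birth backbone with one sequenced exemplar tip per genus.

    Construction: a family-level Yule tree occupies the deepest 60% of the
    crown depth; within each family a genus-level Yule subtree occupies the
    remaining 40%, its tips being the first species of each genus (the
    exemplars).  Heights are normalised so the crown age equals ``height``
    exactly regardless of ``birth_rate`` (the rate shapes topology and
    relative node depths only), which keeps the tree ultrametric with all
    families and genera of the pool represented.
    """
    tax = _taxonomy(config)
    rng = _rng(config, 2)
    fam_frac = 0.6
    families = list(tax.genera_by_family)
    fam_tree = _yule_tree(families, config.birth_rate, rng)
    # rescale family tree to the deep portion
    for edge in fam_tree.preorder_edge_iter():
        if edge.length:
            edge.length *= fam_frac * height
    for leaf in list(fam_tree.leaf_node_iter()):
        fam = leaf.taxon.label
        genera = tax.genera_by_family[fam]
        exemplars = [tax.species_by_genus[g][0] for g in genera]
        if len(exemplars) == 1:
            leaf.taxon.label = exemplars[0]
            leaf.edge.length += (1.0 - fam_frac) * height
            continue
        sub = _yule_tree(exemplars, config.birth_rate, rng)
        for edge in sub.preorder_edge_iter():
            if edge.length:
                edge.length *= (1.0 - fam_frac) * height
        # the family tip becomes the family crown node
        leaf.taxon = None
        for child in sub.seed_node.child_nodes():
            sub.seed_node.remove_child(child)
            leaf.add_child(child)
    # rebuild under a single taxon namespace
    tree = dendropy.Tree.get(
        data=fam_tree.as_string(schema="newick", suppress_rooting=True,
                                real_value_format_specifier=".12g"),
        schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return Phylogeny(tree, genus_to_family=tax.family_of_genus)


# ---------------------------------------------------------------------------
# landscape

def simulate_landscape(
    config: SimulationConfig, n_cells_x: int = 24, n_cells_y: int = 8,
    lon0: float = 74.0, lat0: float = 27.0,
) -> LandscapeGrid:
    """0.2-degree landscape grid with ridge topography, a temperature lapse,
    a west-to-east precipitation gradient and west-heavy disturbance.

    ``bio6 = temp_at_floor - lapse_rate * elev / 1000 + noise``;
    ``bio12`` is linear in longitude from ``precip_west`` to ``precip_east``;
    footprint decreases with elevation and carries a western offset.
    Regions are longitudinal slabs ordered west to east.
    """
    if n_cells_x < 2 or n_cells_y < 2:
        raise ValueError("grid must be at least 2 x 2")
    rng = _rng(config, 3)
    floor, ceiling = config.domain
    lon = lon0 + 0.2 * np.arange(n_cells_x)
    lat = lat0 + 0.2 * np.arange(n_cells_y)
    LON, LAT = np.meshgrid(lon, lat, indexing="ij")
    lon_f = (LON - lon.min()) / max(lon.max() - lon.min(), 1e-12)
    lat_f = (LAT - lat.min()) / max(lat.max() - lat.min(), 1e-12)
    # smooth ridge: elevation rises towards the high-latitude edge
    ridge = np.exp(-((lat_f - 0.85) ** 2) / (2 * 0.35**2))
    elev = floor + (ceiling - floor) * ridge
    elev = elev + rng.normal(0.0, config.elev_noise_sd, size=elev.shape)
    elev = np.clip(elev, floor, ceiling)
    bio6 = (config.temp_at_floor - config.lapse_rate * (elev - floor) / 1000.0
            + rng.normal(0.0, config.temp_noise_sd, size=elev.shape))
    bio12 = (config.precip_west + (config.precip_east - config.precip_west) * lon_f
             + rng.normal(0.0, config.precip_noise_sd, size=elev.shape))
    foot = (config.footprint_base
            - config.footprint_slope * (elev - floor) / 1000.0
            + config.footprint_west_bonus * (1.0 - lon_f)
            + rng.normal(0.0, config.footprint_noise_sd, size=elev.shape))
    foot = np.maximum(foot, 0.0)
    region_idx = np.minimum((lon_f * len(REGIONS)).astype(int), len(REGIONS) - 1)
    df = pd.DataFrame(
        {
            "lon": LON.ravel(),
            "lat": LAT.ravel(),
            "region": [REGIONS[i] for i in region_idx.ravel()],
            "mean_elev": elev.ravel(),
            "bio6": bio6.ravel(),
            "bio12": bio12.ravel(),
            "footprint": foot.ravel(),
        }
    )
    return LandscapeGrid(df)


def simulate_dataset(config: SimulationConfig, out_dir: str | Path,
                     n_cells_x: int = 24, n_cells_y: int = 8) -> None:
    """Write species.csv, tree.nwk, landscape.csv and meta.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = simulate_pool(config)
    write_species_table(records, out / "species.csv")
    write_newick(simulate_backbone(config), out / "tree.nwk")
    write_landscape(simulate_landscape(config, n_cells_x, n_cells_y),
                    out / "landscape.csv")
    import json

    (out / "meta.json").write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
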