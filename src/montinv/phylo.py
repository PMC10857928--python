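"""Community phylogenetics: tip grafting, MPD/MNTD, NRI/NTI, genus ratios.

Unsampled species are grafted onto a backbone of sequenced exemplars using
the basal-node approach: a new species of an existing genus joins at the
genus basal node; if the genus has a single sequenced exemplar, a genus node
is first created half-way along the path from the family basal node to that
tip; a species of a genus absent from the backbone joins at the family basal
node.  Grafted tips are made contemporaneous with their sister clade's tips,
so ultrametric backbones stay ultrametric.

Clustering is quantified by the Net Relatedness Index and Nearest Taxon
Index: negated standardised effect sizes of MPD and MNTD against a null of
uniformly drawn equal-sized tip subsets, so positive values mean clustering
and |index| > 1.96 is nominally significant.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import ElevationalBands, SpeciesRecord
from .richness import GROUP_FILTERS
from .trees import Phylogeny

__all__ = [
    "graft_tips",
    "mpd",
    "mntd",
    "StandardizedIndex",
    "standardized_index",
    "band_phylo_indices",
    "GenusRatioResult",
    "genus_ratio_rarefied",
    "band_genus_ratios",
]


# ---------------------------------------------------------------------------
# grafting

def _mean_tip_depth_below(node) -> float:
    return float(np.mean([l.distance_from_root() for l in node.leaf_iter()]))


def _attach_tip(tree_phylo: Phylogeny, node, label: str):
    """Attach a new tip at ``node``; pendant length makes it contemporaneous
    with the mean root-to-tip depth of the clade below (exact equality for
    ultrametric trees).  Returns the new leaf node."""
    target_depth = _mean_tip_depth_below(node)
    pendant = max(target_depth - node.distance_from_root(), 0.0)
    taxon = tree_phylo.tree.taxon_namespace.new_taxon(label=label)
    return node.new_child(taxon=taxon, edge_length=pendant)


def _split_edge_at_depth(child, depth_from_root: float):
    """Insert a node on ``child``'s stem edge at the given absolute depth;
    returns the new node.  Path lengths through the edge are preserved
    exactly."""
    parent = child.parent_node
    child_depth = child.distance_from_root()
    assert parent is not None
    new_below = child_depth - depth_from_root  # new node -> child
    old_len = child.edge.length
    mid = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(mid)
    mid.edge.length = old_len - new_below
    mid.add_child(child)
    child.edge.length = new_below
    return mid


def graft_tips(backbone: Phylogeny, records: Sequence[SpeciesRecord]) -> Phylogeny:
    """Graft pool species missing from the backbone; returns a new tree.

    Rules, applied sequentially (earlier grafts count as genus members for
    later ones):

    * genus already has >= 2 tips: attach at the genus basal node (the MRCA
      of its tips);
    * genus has exactly 1 tip: create the genus basal node half-way from the
      family basal node to that tip (splitting whichever edge the midpoint
      falls on), then attach there;
    * genus absent: attach at the family basal node.

    Raises if a record's family is absent from the backbone or a tip name
    already exists.  Patristic distances among pre-existing tips are
    unchanged.
    """
    phylo = backbone.clone()
    tree = phylo.tree
    g2f = phylo.genus_to_family
    for r in records:
        if r.family and r.genus not in g2f:
            g2f[r.genus] = r.family
    phylo.annotate_families(g2f)

    genus_tips: dict[str, list] = defaultdict(list)
    family_tips: dict[str, list] = defaultdict(list)
    existing: set[str] = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        existing.add(label)
        g = Phylogeny.genus_of(label)
        genus_tips[g].append(leaf)
        fam = g2f.get(g)
        if fam:
            family_tips[fam].append(leaf)

    def mrca(nodes: list):
        if len(nodes) == 1:
            return nodes[0]
        paths = []
        for n in nodes:
            path = []
            while n is not None:
                path.append(n)
                n = n.parent_node
            paths.append(path[::-1])
        k = 0
        while all(len(p) > k for p in paths) and all(p[k] is paths[0][k] for p in paths):
            k += 1
        return paths[0][k - 1]

    for r in records:
        if r.name in existing:
            raise ValueError(f"duplicate tip name {r.name!r}")
        fam = g2f.get(r.genus)
        if not fam or fam not in family_tips:
            raise ValueError(f"{r.name}: family {r.family or fam!r} absent from backbone")
        def graft_half_stem(leaf):
            # degenerate one-tip clade: its "basal node" is the leaf itself;
            # mirror the half-distance rule on the leaf's stem edge
            parent_depth = leaf.parent_node.distance_from_root()
            node = _split_edge_at_depth(leaf, (parent_depth + leaf.distance_from_root()) / 2.0)
            return _attach_tip(phylo, node, r.name)

        tips = genus_tips.get(r.genus, [])
        if len(tips) >= 2:
            new_leaf = _attach_tip(phylo, mrca(tips), r.name)
        elif len(tips) == 1:
            exemplar = tips[0]
            fam_node = mrca(family_tips[fam])
            fam_depth = fam_node.distance_from_root()
            tip_depth = exemplar.distance_from_root()
            if fam_node is exemplar or tip_depth <= fam_depth:
                new_leaf = graft_half_stem(exemplar)
            else:
                target = fam_depth + (tip_depth - fam_depth) / 2.0
                # walk rootward from the exemplar to the edge containing target
                child = exemplar
                while child.parent_node is not None and \
                        child.parent_node.distance_from_root() > target + 1e-12:
                    child = child.parent_node
                node = _split_edge_at_depth(child, target)
                new_leaf = _attach_tip(phylo, node, r.name)
        else:
            fam_node = mrca(family_tips[fam])
            if fam_node.is_leaf():
                new_leaf = graft_half_stem(fam_node)
            else:
                new_leaf = _attach_tip(phylo, fam_node, r.name)
        existing.add(r.name)
        genus_tips[r.genus].append(new_leaf)
        family_tips[fam].append(new_leaf)
    phylo.invalidate_cache()
    return phylo


# ---------------------------------------------------------------------------
# MPD / MNTD

def _community_submatrix(community: Iterable[str], tree: Phylogeny) -> np.ndarray:
    _, D = tree.distance_matrix()
    index = tree.tip_index()
    try:
        idx = [index[s] for s in community]
    except KeyError as err:
        raise ValueError(f"community member {err} is not a tip of the tree") from None
    return D[np.ix_(idx, idx)]


def mpd(community: Iterable[str], tree: Phylogeny) -> float:
    """Mean patristic distance over unordered pairs of community tips."""
    sub = _community_submatrix(list(community), tree)
    k = sub.shape[0]
    if k < 2:
        raise ValueError("MPD needs at least 2 species")
    return float(sub.sum() / (k * (k - 1)))


def mntd(community: Iterable[str], tree: Phylogeny) -> float:
    """Mean distance from each community tip to its nearest other member."""
    sub = _community_submatrix(list(community), tree)
    k = sub.shape[0]
    if k < 2:
        raise ValueError("MNTD needs at least 2 species")
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _null_metric(D: np.ndarray, k: int, iterations: int,
                 rng: np.random.Generator, metric: str,
                 chunk: int = 200) -> np.ndarray:
    """Vectorised null distribution: MPD/MNTD of uniform random k-subsets."""
    n = D.shape[0]
    vals = np.empty(iterations)
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :k]
        sub = D[idx[:, :, None], idx[:, None, :]]
        if metric == "mpd":
            vals[done:done + m] = sub.sum(axis=(1, 2)) / (k * (k - 1))
        else:
            ii = np.arange(k)
            sub[:, ii, ii] = np.inf
            vals[done:done + m] = sub.min(axis=2).mean(axis=1)
        done += m
    return vals


@dataclass(frozen=True)
class StandardizedIndex:
    """NRI or NTI with its null summary.  ``value = -(obs - mean) / sd``;
    positive values indicate phylogenetic clustering."""

    value: float
    observed: float
    null_mean: float
    null_sd: float
    metric: str
    iterations: int

    @property
    def significant(self) -> bool:
        return abs(self.value) > 1.96


def standardized_index(
    community: Iterable[str],
    pool_tree: Phylogeny,
    metric: str = "mpd",
    iterations: int = 999,
    seed: int | np.random.Generator | None = None,
    pool: Iterable[str] | None = None,
) -> StandardizedIndex:
    """NRI (``metric="mpd"``) or NTI (``metric="mntd"``) of a community
    against uniform random tip subsets of the pool.

    The null draws equal-sized subsets of the pool (all tips of
    ``pool_tree`` unless ``pool`` narrows it) without replacement.  If the
    community equals the pool the index is exactly 0.  A degenerate null
    (SD = 0) with a proper sub-community raises ``ValueError``.
    """
    if metric not in {"mpd", "mntd"}:
        raise ValueError("metric must be 'mpd' or 'mntd'")
    if iterations < 99:
        raise ValueError("use at least 99 null iterations")
    community = list(community)
    labels, D = pool_tree.distance_matrix()
    if pool is not None:
        index = pool_tree.tip_index()
        pool = list(pool)
        try:
            pidx = np.array([index[s] for s in pool])
        except KeyError as err:
            raise ValueError(f"pool member {err} is not a tip of the tree") from None
        if not set(community) <= set(pool):
            raise ValueError("community must be a subset of the pool")
        D = D[np.ix_(pidx, pidx)]
        pool_size = len(pool)
    else:
        pool_size = len(labels)
    k = len(community)
    if k < 2:
        raise ValueError("community must have at least 2 species")
    if k > pool_size:
        raise ValueError("community larger than pool")
    obs = mpd(community, pool_tree) if metric == "mpd" else mntd(community, pool_tree)
    if k == pool_size:
        return StandardizedIndex(0.0, obs, obs, 0.0, metric, iterations)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nulls = _null_metric(D, k, iterations, rng, metric)
    mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd == 0.0:
        raise ValueError("null distribution has zero SD; index undefined")
    return StandardizedIndex(-(obs - mu) / sd, obs, mu, sd, metric, iterations)


def band_phylo_indices(
    records: Sequence[SpeciesRecord],
    tree: Phylogeny,
    bands: ElevationalBands | None = None,
    groups: tuple[str, ...] = ("all", "native", "alien"),
    iterations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """MPD, MNTD, NRI and NTI per elevational band per group.

    For each group the null pool is restricted to the group's own species
    (so e.g. alien indices are standardised against random alien subsets)
    and each band's community is the group members whose range overlaps the
    band.  Bands with fewer than 2 members give NaN.
    """
    bands = bands or ElevationalBands()
    rng = np.random.default_rng(seed)
    rows = []
    tip_set = set(tree.tip_labels)
    for g in groups:
        pred = GROUP_FILTERS[g]
        members = [r for r in records if pred(r) and r.has_range and r.name in tip_set]
        occ_rows = {r.name: bands.occupancy(r.elev_min, r.elev_max) for r in members}
        for b, ((lo, hi), label) in enumerate(zip(bands.intervals, bands.labels)):
            occ = [r.name for r in members if occ_rows[r.name][b]]
            row = {"group": g, "band": label, "band_mid": (lo + hi) / 2,
                   "n_species": len(occ), "mpd": np.nan, "mntd": np.nan,
                   "nri": np.nan, "nti": np.nan}
            if len(occ) >= 2:
                pool = [r.name for r in members]
                row["mpd"] = mpd(occ, tree)
                row["mntd"] = mntd(occ, tree)
                row["nri"] = standardized_index(
                    occ, tree, "mpd", iterations, rng, pool=pool).value
                row["nti"] = standardized_index(
                    occ, tree, "mntd", iterations, rng, pool=pool).value
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species:genus ratios

@dataclass(frozen=True)
class GenusRatioResult:
    """Species:genus ratio with a rarefied comparison.

    ``rarefied_*`` summarise draws in which ``n_target_genera`` genera are
    sampled without replacement and the ratio is recomputed over the sampled
    genera's species (used to compare natives with the alien genus count on
    an equal footing)."""

    n_species: int
    n_genera: int
    ratio: float
    rarefied_mean: float
    rarefied_lo: float
    rarefied_hi: float
    draws: int


def genus_ratio_rarefied(
    records: Sequence[SpeciesRecord],
    n_target_genera: int,
    draws: int = 100,
    seed: int | np.random.Generator | None = None,
) -> GenusRatioResult:
    """Rarefied species:genus ratio of a record set.

    Each draw samples ``n_target_genera`` genera without replacement and
    computes (species in sampled genera) / (genera sampled); the mean and
    2.5/97.5 percentiles over draws are reported.  With the full genus count
    every draw equals the plain ratio."""
    if n_target_genera == 0:
        raise ValueError("n_target_genera must be >= 1")
    sizes = defaultdict(int)
    for r in records:
        sizes[r.genus] += 1
    genera = sorted(sizes)
    if n_target_genera > len(genera):
        raise ValueError("fewer genera available than n_target_genera")
    counts = np.array([sizes[g] for g in genera], dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = np.empty(draws)
    for d in range(draws):
        pick = rng.choice(len(genera), size=n_target_genera, replace=False)
        vals[d] = counts[pick].sum() / n_target_genera
    return GenusRatioResult(
        n_species=int(counts.sum()),
        n_genera=len(genera),
        ratio=float(counts.sum() / len(genera)),
        rarefied_mean=float(vals.mean()),
        rarefied_lo=float(np.percentile(vals, 2.5)),
        rarefied_hi=float(np.percentile(vals, 97.5)),
        draws=draws,
    )


def band_genus_ratios(
    records: Sequence[SpeciesRecord],
    bands: ElevationalBands | None = None,
    draws: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-band native and alien species:genus ratios, natives additionally
    rarefied to the alien genus count of the band (NaN where undefined)."""
    bands = bands or ElevationalBands()
    rng = np.random.default_rng(seed)
    rows = []
    for (lo, hi), label in zip(bands.intervals, bands.labels):
        idx = bands.labels.index(label)
        in_band = [r for r in records if r.has_range
                   and bands.occupancy(r.elev_min, r.elev_max)[idx]]
        nat = [r for r in in_band if r.status == "native"]
        ali = [r for r in in_band if r.status == "alien"]
        row = {"band": label, "band_mid": (lo + hi) / 2,
               "native_species": len(nat), "alien_species": len(ali)}
        for name, grp in (("native", nat), ("alien", ali)):
            genera = {r.genus for r in grp}
            row[f"{name}_genera"] = len(genera)
            row[f"{name}_ratio"] = len(grp) / len(genera) if genera else np.nan
        n_target = row["alien_genera"]
        if nat and 1 <= n_target <= row["native_genera"]:
            res = genus_ratio_rarefied(nat, n_target, draws=draws, seed=rng)
            row["native_rarefied_mean"] = res.rarefied_mean
            row["native_rarefied_lo"] = res.rarefied_lo
            row["native_rarefied_hi"] = res.rarefied_hi
        else:
            row["native_rarefied_mean"] = np.nan
            row["native_rarefied_lo"] = np.nan
            row["native_rarefied_hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
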