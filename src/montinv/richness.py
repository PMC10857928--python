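"""Band-wise richness, richness correlations, grid assignment and IDW surfaces.

Richness along the gradient is computed by range interpolation: a species is
counted in every 200 m band its elevational range overlaps, so band counts
are "species with overlapping ranges", not point records.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .core import ElevationalBands, LandscapeGrid, SpeciesRecord

__all__ = [
    "GROUP_FILTERS",
    "band_richness",
    "richness_correlation",
    "assign_grid",
    "idw_interpolate",
]

#: Named record filters used for the standard richness table columns.
GROUP_FILTERS: dict[str, Callable[[SpeciesRecord], bool]] = {
    "all": lambda r: True,
    "native": lambda r: r.status == "native",
    "alien": lambda r: r.status == "alien",
    "naturalised": lambda r: r.alien_class == "naturalised",
    "cultivated": lambda r: r.alien_class == "cultivated",
    "invasive": lambda r: r.invasive,
    "tropical": lambda r: r.affinity == "tropical",
    "temperate": lambda r: r.affinity == "temperate",
}


def band_richness(
    records: Sequence[SpeciesRecord],
    bands: ElevationalBands | None = None,
    groups: dict[str, Callable[[SpeciesRecord], bool]] | None = None,
) -> pd.DataFrame:
    """Per-band species counts for each group, plus the alien proportion.

    Returns a DataFrame indexed by band label with columns ``band_low``,
    ``band_mid``, one count column per group, and ``alien_proportion`` =
    alien / (alien + native) (NaN where the denominator is zero).  Records
    without an elevational range are excluded.
    """
    if not records:
        raise ValueError("empty record list")
    bands = bands or ElevationalBands()
    groups = groups or GROUP_FILTERS
    counts = {g: np.zeros(bands.n_bands, dtype=int) for g in groups}
    for r in records:
        if not r.has_range:
            continue
        occ = bands.occupancy(r.elev_min, r.elev_max)
        for g, pred in groups.items():
            if pred(r):
                counts[g] += occ
    table = pd.DataFrame(counts, index=bands.labels)
    table.insert(0, "band_low", bands.edges[:-1])
    table.insert(1, "band_mid", bands.midpoints)
    if "alien" in table.columns and "native" in table.columns:
        denom = table["alien"] + table["native"]
        table["alien_proportion"] = np.where(
            denom > 0, table["alien"] / denom.replace(0, np.nan), np.nan
        )
    return table


def richness_correlation(
    table: pd.DataFrame,
    group_a: str = "native",
    group_b: str = "alien",
    drop_zero: bool = False,
) -> float:
    """Pearson correlation of two groups' richness across bands.

    ``drop_zero`` removes bands where both groups are empty before
    correlating (kept by default).  Raises if either series has zero
    variance or fewer than 3 bands remain.
    """
    a = table[group_a].to_numpy(dtype=float)
    b = table[group_b].to_numpy(dtype=float)
    if drop_zero:
        keep = (a + b) > 0
        a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 bands with data")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a richness series")
    return float(stats.pearsonr(a, b).statistic)


def assign_grid(
    records: Sequence[SpeciesRecord],
    grid: LandscapeGrid,
    groups: tuple[str, ...] = ("native", "alien"),
) -> LandscapeGrid:
    """Fill per-cell richness columns on a landscape grid.

    A species is present in a cell iff the cell's region is among the
    species' regions of occurrence **and** its elevational range contains
    the cell's mean elevation (closed interval:
    ``elev_min <= mean_elev <= elev_max``).  Adds ``<group>_richness``
    columns and returns a new grid.
    """
    df = grid.df.copy()
    elev = df["mean_elev"].to_numpy(dtype=float)
    region_arr = df["region"].to_numpy()
    for g in groups:
        pred = GROUP_FILTERS[g]
        total = np.zeros(len(df), dtype=int)
        for r in records:
            if not (pred(r) and r.has_range):
                continue
            in_reg = np.isin(region_arr, list(r.regions))
            total += in_reg & (elev >= r.elev_min) & (elev <= r.elev_max)
        df[f"{g}_richness"] = total
    return LandscapeGrid(df)


def _haversine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance in km between (lon, lat) degree arrays."""
    R = 6371.0088
    a = np.radians(a)
    b = np.radians(b)
    dlon = a[:, None, 0] - b[None, :, 0]
    dlat = a[:, None, 1] - b[None, :, 1]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(a[:, None, 1]) * np.cos(b[None, :, 1]) * np.sin(dlon / 2) ** 2)
    return 2 * R * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def idw_interpolate(
    known_xy: np.ndarray,
    known_values: np.ndarray,
    target_xy: np.ndarray,
    power: float = 2.0,
    metric: str = "euclidean",
) -> np.ndarray:
    """Inverse-distance-weighted interpolation.

    ``value(t) = sum_i d_i^-power * z_i / sum_i d_i^-power`` over **all**
    known points (no neighbour cutoff).  A target coinciding with a known
    point returns that point's value exactly.  ``metric`` is ``"euclidean"``
    (degrees) or ``"haversine"`` (great-circle km).  Output is a convex
    combination, hence bounded by the known-value range.
    """
    known_xy = np.atleast_2d(np.asarray(known_xy, dtype=float))
    target_xy = np.atleast_2d(np.asarray(target_xy, dtype=float))
    z = np.asarray(known_values, dtype=float)
    if known_xy.shape[0] == 0:
        raise ValueError("need at least one known point")
    if known_xy.shape[0] != z.shape[0]:
        raise ValueError("known_xy and known_values length mismatch")
    if power <= 0:
        raise ValueError("power must be positive")
    # duplicate known points must agree in value
    order = np.lexsort(known_xy.T)
    kxy = known_xy[order]
    kz = z[order]
    dup = np.all(np.diff(kxy, axis=0) == 0, axis=1)
    if np.any(dup & (np.diff(kz) != 0)):
        raise ValueError("duplicate known points with conflicting values")
    if metric == "euclidean":
        D = cdist(target_xy, known_xy)
    elif metric == "haversine":
        D = _haversine(target_xy, known_xy)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = np.empty(len(target_xy))
    hits = D <= 0.0
    any_hit = hits.any(axis=1)
    with np.errstate(divide="ignore"):
        w = D ** (-power)
    for i in range(len(target_xy)):
        if any_hit[i]:
            out[i] = z[np.argmax(hits[i])]
        else:
            wi = w[i]
            out[i] = float(np.dot(wi, z) / wi.sum())
    return out
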