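"""Core domain types and CSV readers/writers.

The analysis revolves around three inputs: a species attribute table (one row
per taxon with status, biogeographic affinity, regional occurrence and an
elevational range), a backbone phylogeny (see :mod:`montinv.trees`), and a
gridded landscape table of 0.2-degree cells carrying climate and disturbance
covariates.  This module holds the validated in-memory forms of the tabular
inputs and the incidence-matrix container shared by the richness and
nestedness analyses.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "CONTINENTS",
    "STATUSES",
    "ALIEN_CLASSES",
    "AFFINITIES",
    "SpeciesRecord",
    "ValidationIssue",
    "SpeciesTable",
    "ElevationalBands",
    "IncidenceMatrix",
    "LandscapeGrid",
    "read_species_table",
    "write_species_table",
    "read_landscape",
    "write_landscape",
    "write_metadata_sidecar",
]

#: The six study regions, fixed west-to-east: Jammu & Kashmir, Himachal
#: Pradesh, Uttarakhand, Nepal, Bhutan region (Bhutan + Sikkim + north
#: Bengal), Arunachal Pradesh.
REGIONS: tuple[str, ...] = ("JK", "HP", "UK", "NP", "BR", "AP")

CONTINENTS: frozenset[str] = frozenset(
    {"Africa", "Australia", "Europe", "NorthAmerica", "SouthAmerica", "Asia"}
)
STATUSES: frozenset[str] = frozenset({"native", "alien"})
ALIEN_CLASSES: frozenset[str] = frozenset({"cultivated", "naturalised", "none"})
AFFINITIES: frozenset[str] = frozenset(
    {"tropical", "temperate", "cosmopolitan", "unknown"}
)

_LANDSCAPE_COLUMNS = ("lon", "lat", "region", "mean_elev", "bio6", "bio12", "footprint")


@dataclass(frozen=True)
class SpeciesRecord:
    """One taxon: identity, origin status and distribution attributes.

    ``elev_min``/``elev_max`` are metres above sea level; both ``None`` means
    the elevational range is unknown and the record is excluded from band
    and nestedness analyses (but still counted in pool tallies).
    """

    name: str
    genus: str = ""
    family: str = ""
    status: str = "native"
    alien_class: str = "none"
    invasive: bool = False
    continents: frozenset[str] = frozenset()
    affinity: str = "unknown"
    regions: frozenset[str] = frozenset()
    elev_min: float | None = None
    elev_max: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.alien_class not in ALIEN_CLASSES:
            raise ValueError(f"unknown alien class {self.alien_class!r}")
        if self.status == "native" and self.alien_class != "none":
            raise ValueError(f"{self.name}: native record cannot carry an alien class")
        if self.status == "alien" and self.alien_class == "none":
            raise ValueError(f"{self.name}: alien record needs an alien class")
        if self.affinity not in AFFINITIES:
            raise ValueError(f"unknown affinity {self.affinity!r}")
        bad = set(self.continents) - CONTINENTS
        if bad:
            raise ValueError(f"{self.name}: unknown continents {sorted(bad)}")
        bad = set(self.regions) - set(REGIONS)
        if bad:
            raise ValueError(f"{self.name}: unknown regions {sorted(bad)}")
        if (self.elev_min is None) != (self.elev_max is None):
            raise ValueError(f"{self.name}: elevational range must be both-or-neither")
        if self.elev_min is not None and self.elev_min > self.elev_max:
            raise ValueError(f"{self.name}: elev_min > elev_max")
        if not self.genus:
            # first token of the binomial; space- or underscore-separated
            object.__setattr__(self, "genus", self.name.replace("_", " ").split()[0])

    @property
    def has_range(self) -> bool:
        return self.elev_min is not None

    def in_region(self, region: str) -> bool:
        return region in self.regions


@dataclass(frozen=True)
class ValidationIssue:
    """A rejected or suspicious input row; ``row`` is the 1-based file line."""

    row: int
    message: str


@dataclass
class SpeciesTable:
    """Validated records plus the per-row validation report."""

    records: list[SpeciesRecord]
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_missing_range(self) -> int:
        """Records excluded from elevational analyses for lack of a range."""
        return sum(not r.has_range for r in self.records)

    def subset(self, *, status: str | None = None, region: str | None = None) -> list[SpeciesRecord]:
        out = self.records
        if status is not None:
            out = [r for r in out if r.status == status]
        if region is not None:
            out = [r for r in out if r.in_region(region)]
        return list(out)

    def continent_tally(self, status: str | None = None) -> dict[str, int]:
        """Species per source continent; a multi-continent species counts once
        per continent, so the tally can sum past the species total."""
        counts: dict[str, int] = {c: 0 for c in sorted(CONTINENTS)}
        for r in self.records:
            if status is not None and r.status != status:
                continue
            for c in r.continents:
                counts[c] += 1
        return counts


@dataclass(frozen=True)
class ElevationalBands:
    """Contiguous half-open elevational bands ``[lower, upper)``.

    The default slices 0–5000 m into 200 m bands.  The topmost band is closed
    above so a range ending exactly at the ceiling is still counted.
    """

    width: float = 200.0
    floor: float = 0.0
    ceiling: float = 5000.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.ceiling <= self.floor:
            raise ValueError("ceiling must exceed floor")
        n = (self.ceiling - self.floor) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("ceiling - floor must be divisible by width")

    @property
    def n_bands(self) -> int:
        return int(round((self.ceiling - self.floor) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.floor + self.width * np.arange(self.n_bands + 1)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        e = self.edges
        return [(float(e[i]), float(e[i + 1])) for i in range(self.n_bands)]

    @property
    def midpoints(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2.0

    @property
    def labels(self) -> list[str]:
        return [f"{int(lo)}-{int(hi)}" for lo, hi in self.intervals]

    def occupancy(self, elev_min: float, elev_max: float) -> np.ndarray:
        """Boolean vector: which bands the range ``[elev_min, elev_max]`` occupies.

        A range occupies band ``[L, U)`` iff ``elev_min < U`` and
        ``elev_max >= L``; for the top band the upper edge is closed
        (``elev_min <= U``).
        """
        e = self.edges
        lo, hi = e[:-1], e[1:]
        below_upper = elev_min < hi
        below_upper[-1] = elev_min <= hi[-1]
        return below_upper & (elev_max >= lo)


@dataclass
class IncidenceMatrix:
    """Binary species x ordered-site occurrence matrix.

    Sites are elevational bands ordered low to high, or regions ordered west
    to east.  ``values`` is an int8/bool array; rows are species.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("incidence matrix must be 2-D")
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def fill(self) -> int:
        return int(self.values.sum())

    @property
    def connectance(self) -> float:
        r, c = self.values.shape
        return self.fill / (r * c)

    def empty_rows(self) -> list[str]:
        return [l for l, s in zip(self.row_labels, self.values.sum(1)) if s == 0]

    def empty_cols(self) -> list[str]:
        return [l for l, s in zip(self.col_labels, self.values.sum(0)) if s == 0]

    def prune_empty(self) -> "IncidenceMatrix":
        """Drop all-zero rows and columns (returns a new matrix)."""
        rmask = self.values.sum(1) > 0
        cmask = self.values.sum(0) > 0
        return IncidenceMatrix(
            [l for l, m in zip(self.row_labels, rmask) if m],
            [l for l, m in zip(self.col_labels, cmask) if m],
            self.values[np.ix_(rmask, cmask)],
        )

    @staticmethod
    def from_ranges(
        records: Sequence[SpeciesRecord], bands: ElevationalBands
    ) -> "IncidenceMatrix":
        """Species x band matrix from elevational ranges (range interpolation:
        a species is present in every band its range overlaps).  Records
        without a range are skipped."""
        with_range = [r for r in records if r.has_range]
        rows = np.zeros((len(with_range), bands.n_bands), dtype=np.int8)
        for i, r in enumerate(with_range):
            rows[i] = bands.occupancy(r.elev_min, r.elev_max)
        return IncidenceMatrix([r.name for r in with_range], bands.labels, rows)

    @staticmethod
    def from_regions(records: Sequence[SpeciesRecord]) -> "IncidenceMatrix":
        """Species x region matrix, regions ordered west to east."""
        rows = np.zeros((len(records), len(REGIONS)), dtype=np.int8)
        for i, r in enumerate(records):
            for j, reg in enumerate(REGIONS):
                rows[i, j] = reg in r.regions
        return IncidenceMatrix([r.name for r in records], list(REGIONS), rows)


class LandscapeGrid:
    """0.2-degree landscape cells with climate and disturbance covariates.

    Wraps a DataFrame with columns ``lon, lat, region, mean_elev, bio6,
    bio12, footprint`` (BIO6 = minimum temperature of the coldest month in
    deg C, BIO12 = annual precipitation in mm, footprint = human-footprint
    disturbance score).  Richness columns (``native_richness`` etc.) are
    added downstream by :func:`montinv.richness.assign_grid`.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _LANDSCAPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"landscape table missing columns {missing}")
        if df.duplicated(subset=["lon", "lat"]).any():
            raise ValueError("duplicate (lon, lat) cells")
        bad = set(df["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"cells with unassigned/unknown region: {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def cells_in_region(self, region: str) -> pd.DataFrame:
        return self.df[self.df["region"] == region]


# ---------------------------------------------------------------------------
# CSV I/O

_CANONICAL_FIELDS = (
    "name", "genus", "family", "status", "alien_class", "invasive",
    "continents", "affinity", "regions", "elev_min", "elev_max",
)

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", ""}


def _parse_bool(tok: str, row: int) -> bool:
    t = tok.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"row {row}: cannot parse boolean {tok!r}")


def _parse_elev(tok: str) -> float | None:
    t = tok.strip()
    if t == "" or t.lower() in {"na", "nan", "none"}:
        return None
    return float(t)


def read_species_table(
    path: str | Path, dialect: dict[str, str] | None = None
) -> SpeciesTable:
    """Read and validate a species attribute CSV.

    Parameters
    ----------
    path
        UTF-8 CSV with a header row.  Set-valued fields (``continents``,
        ``regions``) are semicolon-separated tokens.
    dialect
        Optional mapping from canonical field names to the file's column
        names, for ingesting externally curated tables whose headers differ.

    Rows violating record invariants (e.g. ``elev_min > elev_max``) are
    excluded and reported in :attr:`SpeciesTable.issues` with their 1-based
    file line number.  Unknown status/affinity tokens abort the read.
    Missing elevations are permitted (both empty); the count of records
    excluded from elevational analyses is ``SpeciesTable.n_missing_range``.
    """
    colmap = {f: f for f in _CANONICAL_FIELDS}
    if dialect:
        colmap.update(dialect)
    records: list[SpeciesRecord] = []
    issues: list[ValidationIssue] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty or unreadable CSV")
        for f in ("name", "status"):
            if colmap[f] not in reader.fieldnames:
                raise ValueError(f"{path}: required column {colmap[f]!r} missing")

        def get(row: dict, f: str) -> str:
            return (row.get(colmap[f]) or "").strip()

        for lineno, row in enumerate(reader, start=2):
            status = get(row, "status").lower()
            if status not in STATUSES:
                raise ValueError(f"row {lineno}: unknown status token {get(row, 'status')!r}")
            affinity = get(row, "affinity").lower() or "unknown"
            if affinity not in AFFINITIES:
                raise ValueError(f"row {lineno}: unknown affinity token {get(row, 'affinity')!r}")
            klass_toks = [t.strip().lower() for t in get(row, "alien_class").split(";") if t.strip()]
            if status == "native":
                klass = "none"
            elif "cultivated" in klass_toks:
                # cultivated takes priority when a species is both
                klass = "cultivated"
            elif "naturalised" in klass_toks or "naturalized" in klass_toks:
                klass = "naturalised"
            elif not klass_toks or klass_toks == ["none"]:
                klass = "naturalised" if status == "alien" else "none"
            else:
                raise ValueError(f"row {lineno}: unknown alien class {get(row, 'alien_class')!r}")
            try:
                rec = SpeciesRecord(
                    name=get(row, "name"),
                    genus=get(row, "genus"),
                    family=get(row, "family"),
                    status=status,
                    alien_class=klass,
                    invasive=_parse_bool(get(row, "invasive"), lineno),
                    continents=frozenset(
                        t.strip() for t in get(row, "continents").split(";") if t.strip()
                    ),
                    affinity=affinity,
                    regions=frozenset(
                        t.strip() for t in get(row, "regions").split(";") if t.strip()
                    ),
                    elev_min=_parse_elev(get(row, "elev_min")),
                    elev_max=_parse_elev(get(row, "elev_max")),
                )
            except ValueError as err:
                issues.append(ValidationIssue(lineno, str(err)))
                continue
            if not rec.regions:
                issues.append(
                    ValidationIssue(lineno, f"{rec.name}: no regions; unusable in distributional analyses")
                )
            records.append(rec)
    return SpeciesTable(records, issues)


def write_species_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column schema (lossless round-trip)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CANONICAL_FIELDS)
        for r in records:
            writer.writerow(
                [
                    r.name, r.genus, r.family, r.status, r.alien_class,
                    int(r.invasive),
                    ";".join(sorted(r.continents)),
                    r.affinity,
                    ";".join(sorted(r.regions, key=REGIONS.index)),
                    "" if r.elev_min is None else repr(float(r.elev_min)),
                    "" if r.elev_max is None else repr(float(r.elev_max)),
                ]
            )


def read_landscape(path: str | Path) -> LandscapeGrid:
    return LandscapeGrid(pd.read_csv(path))


def write_landscape(grid: LandscapeGrid, path: str | Path) -> None:
    grid.df.to_csv(path, index=False, float_format="%.6g")


def write_metadata_sidecar(path: str | Path, **params) -> None:
    """Record run parameters (seed included) next to a CSV output."""
    with open(Path(path).with_suffix(".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _record_with(rec: SpeciesRecord, **kw) -> SpeciesRecord:
    """Convenience for tests: a modified copy of a record."""
    return replace(rec, **kw)
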