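"""Gridded landscape environment: data model, CSV readers/writers, availability.

The environment mirrors the structure of the Long House Valley inputs of the
Artificial Anasazi lineage of models: a rectangular grid of cells carrying a
zone id, a relative soil quality in [0, 1] and a water-body mask; a per-zone,
per-year baseline maize yield table (the drought signal is folded into these
yields); point water sources with active year ranges; and an annual target
household-count series the simulation is scored against.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, origin top-left.
All CSV files written by this module state this in a leading comment line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeError",
    "LandscapeCell",
    "WaterSource",
    "Occupancy",
    "Landscape",
    "read_landscape",
    "write_landscape",
    "available_plots",
]

_COORD_COMMENT = "# coordinates: 0-based, x=column, y=row, origin top-left\n"

_FILES = {
    "cells": "cells.csv",
    "yields": "yields.csv",
    "water": "water.csv",
    "target": "target.csv",
}


class LandscapeError(ValueError):
    """Raised for malformed or mutually inconsistent environment files."""


@dataclass(frozen=True)
class LandscapeCell:
    """One grid cell of the environment."""

    x: int
    y: int
    zone: int
    quality: float
    water_body: bool


@dataclass(frozen=True)
class WaterSource:
    """A point water source active over an inclusive range of calendar years."""

    x: int
    y: int
    start_year: int
    end_year: int


@dataclass
class Occupancy:
    """Boolean masks (shape ``(height, width)``) of farmed and dwelt cells."""

    farm: np.ndarray
    dwelling: np.ndarray

    @classmethod
    def empty(cls, height: int, width: int) -> "Occupancy":
        return cls(
            farm=np.zeros((height, width), dtype=bool),
            dwelling=np.zeros((height, width), dtype=bool),
        )


@dataclass
class Landscape:
    """Immutable environment consumed by the household simulator.

    Attributes
    ----------
    quality, zone, water_body
        ``(height, width)`` arrays indexed ``[y, x]``.
    yield_table
        ``(n_zones, n_years)`` array of baseline yields (kg maize per cell per
        year); row = zone id, column = year offset from ``start_year``.
    target_series
        ``(n_years,)`` integer household counts, year ``start_year`` first.
    """

    width: int
    height: int
    quality: np.ndarray
    zone: np.ndarray
    water_body: np.ndarray
    yield_table: np.ndarray
    water_sources: list[WaterSource]
    target_series: np.ndarray
    start_year: int
    end_year: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=float)
        self.zone = np.asarray(self.zone, dtype=np.int64)
        self.water_body = np.asarray(self.water_body, dtype=bool)
        self.yield_table = np.asarray(self.yield_table, dtype=float)
        self.target_series = np.asarray(self.target_series, dtype=np.int64)
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def n_zones(self) -> int:
        return self.yield_table.shape[0]

    def baseline_yield(self, zone: int | np.ndarray, year: int):
        """Baseline yield (kg/cell) for ``zone`` in calendar ``year``."""
        return self.yield_table[zone, year - self.start_year]

    def cell(self, x: int, y: int) -> LandscapeCell:
        return LandscapeCell(
            x=x,
            y=y,
            zone=int(self.zone[y, x]),
            quality=float(self.quality[y, x]),
            water_body=bool(self.water_body[y, x]),
        )

    def cells(self):
        """Iterate all cells in row-major (y, x) order."""
        for y in range(self.height):
            for x in range(self.width):
                yield self.cell(x, y)

    def active_water_sources(self, year: int) -> list[WaterSource]:
        return [w for w in self.water_sources if w.start_year <= year <= w.end_year]

    def target(self, year: int) -> int:
        return int(self.target_series[year - self.start_year])

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        h, w = self.height, self.width
        for name, arr in (("quality", self.quality), ("zone", self.zone), ("water_body", self.water_body)):
            if arr.shape != (h, w):
                raise LandscapeError(f"{name} grid has shape {arr.shape}, expected {(h, w)}")
        if np.any((self.quality < 0) | (self.quality > 1)):
            raise LandscapeError("quality values must lie in [0, 1]")
        if self.start_year > self.end_year:
            raise LandscapeError("start_year must not exceed end_year")
        if self.zone.min() < 0 or self.zone.max() >= self.yield_table.shape[0]:
            raise LandscapeError(
                f"zone ids span [{self.zone.min()}, {self.zone.max()}] but the "
                f"yield table covers {self.yield_table.shape[0]} zones"
            )
        if self.yield_table.shape[1] != self.n_years:
            raise LandscapeError(
                f"yield table covers {self.yield_table.shape[1]} years, "
                f"simulation span has {self.n_years}"
            )
        if np.any(self.yield_table < 0):
            raise LandscapeError("baseline yields must be non-negative")
        if self.target_series.shape != (self.n_years,):
            raise LandscapeError(
                f"target series has {self.target_series.shape[0]} entries, "
                f"simulation span has {self.n_years}"
            )
        for s in self.water_sources:
            if not (0 <= s.x < w and 0 <= s.y < h):
                raise LandscapeError(f"water source at ({s.x}, {s.y}) lies outside the {w}x{h} grid")
            if s.start_year > s.end_year:
                raise LandscapeError(
                    f"water source at ({s.x}, {s.y}) has start_year {s.start_year} > end_year {s.end_year}"
                )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv(path: str, required: list[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise LandscapeError(f"missing environment file: {path}")
    # round_trip float parsing keeps write->read->write byte-stable
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise LandscapeError(f"{path}: missing required column '{col}'")
    return df


def read_landscape(path: str) -> Landscape:
    """Read an environment directory (cells/yields/water/target CSVs).

    Raises :class:`LandscapeError` naming the offending file and row for any
    missing column, out-of-grid coordinate or gap in the year span.
    """
    p = {k: os.path.join(path, v) for k, v in _FILES.items()}

    cells = _read_csv(p["cells"], ["x", "y", "zone", "quality", "water_body"])
    yields = _read_csv(p["yields"], ["zone", "year", "baseline_yield"])
    water = _read_csv(p["water"], ["x", "y", "start_year", "end_year"])
    target = _read_csv(p["target"], ["year", "households"])

    width = int(cells["x"].max()) + 1
    height = int(cells["y"].max()) + 1
    if len(cells) != width * height:
        raise LandscapeError(
            f"{p['cells']}: {len(cells)} rows do not tile a {width}x{height} grid "
            "(duplicate or missing (x, y))"
        )
    if cells.duplicated(subset=["x", "y"]).any():
        row = int(cells.index[cells.duplicated(subset=["x", "y"])][0])
        raise LandscapeError(f"{p['cells']}: duplicate (x, y) at data row {row}")

    quality = np.zeros((height, width))
    zone = np.zeros((height, width), dtype=np.int64)
    water_body = np.zeros((height, width), dtype=bool)
    xs = cells["x"].to_numpy()
    ys = cells["y"].to_numpy()
    quality[ys, xs] = cells["quality"].to_numpy()
    zone[ys, xs] = cells["zone"].to_numpy()
    water_body[ys, xs] = cells["water_body"].to_numpy().astype(bool)

    t_years = target["year"].to_numpy()
    start_year, end_year = int(t_years.min()), int(t_years.max())
    expected = np.arange(start_year, end_year + 1)
    missing = np.setdiff1d(expected, t_years)
    if missing.size:
        raise LandscapeError(f"{p['target']}: target series missing year {int(missing[0])}")
    target = target.sort_values("year")

    n_zones = int(yields["zone"].max()) + 1
    yield_table = np.full((n_zones, expected.size), np.nan)
    in_span = yields[(yields["year"] >= start_year) & (yields["year"] <= end_year)]
    yield_table[
        in_span["zone"].to_numpy(),
        in_span["year"].to_numpy() - start_year,
    ] = in_span["baseline_yield"].to_numpy()
    if np.isnan(yield_table).any():
        z, t = np.argwhere(np.isnan(yield_table))[0]
        raise LandscapeError(
            f"{p['yields']}: no baseline yield for zone {int(z)} in year {int(start_year + t)}"
        )

    sources = [
        WaterSource(int(r.x), int(r.y), int(r.start_year), int(r.end_year))
        for r in water.itertuples()
    ]
    for i, s in enumerate(sources):
        if not (0 <= s.x < width and 0 <= s.y < height):
            raise LandscapeError(f"{p['water']}: data row {i}: coordinate ({s.x}, {s.y}) outside grid")

    return Landscape(
        width=width,
        height=height,
        quality=quality,
        zone=zone,
        water_body=water_body,
        yield_table=yield_table,
        water_sources=sources,
        target_series=target["households"].to_numpy(),
        start_year=start_year,
        end_year=end_year,
    )


def write_landscape(landscape: Landscape, path: str) -> None:
    """Write an environment directory in canonical form.

    Canonical row orders (cells by (y, x); yields by (zone, year); water
    sources by (x, y, start_year); target by year) make
    ``write(read(F)) == F`` byte-for-byte for directories produced here.
    """
    os.makedirs(path, exist_ok=True)
    ls = landscape

    ys, xs = np.mgrid[0 : ls.height, 0 : ls.width]
    cells = pd.DataFrame(
        {
            "x": xs.ravel(),
            "y": ys.ravel(),
            "zone": ls.zone.ravel(),
            "quality": ls.quality.ravel(),
            "water_body": ls.water_body.ravel().astype(int),
        }
    )
    zz, tt = np.mgrid[0 : ls.n_zones, 0 : ls.n_years]
    yields = pd.DataFrame(
        {
            "zone": zz.ravel(),
            "year": tt.ravel() + ls.start_year,
            "baseline_yield": ls.yield_table.ravel(),
        }
    )
    water = pd.DataFrame(
        [
            (s.x, s.y, s.start_year, s.end_year)
            for s in sorted(ls.water_sources, key=lambda s: (s.x, s.y, s.start_year))
        ],
        columns=["x", "y", "start_year", "end_year"],
    )
    target = pd.DataFrame({"year": ls.years, "households": ls.target_series})

    for name, df in (("cells", cells), ("yields", yields), ("water", water), ("target", target)):
        fp = os.path.join(path, _FILES[name])
        with open(fp, "w", newline="") as fh:
            fh.write(_COORD_COMMENT)
            df.to_csv(fh, index=False, lineterminator="\n")


def available_plots(landscape: Landscape, occupancy: Occupancy, year: int) -> set[tuple[int, int]]:
    """Cells free of farms and dwellings and not inside a water body.

    ``year`` is accepted for interface symmetry with time-varying layers; the
    availability predicate itself is time-invariant.
    """
    free = ~(landscape.water_body | occupancy.farm | occupancy.dwelling)
    ys, xs = np.nonzero(free)
    return {(int(x), int(y)) for x, y in zip(xs, ys)}


def available_mask(landscape: Landscape, occupancy: Occupancy) -> np.ndarray:
    """Vectorized form of :func:`available_plots` (``(height, width)`` bool)."""
    return ~(landscape.water_body | occupancy.farm | occupancy.dwelling)
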