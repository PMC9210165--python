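"""Quadrat grid construction, terrain attributes and substrate typing.

The plot is tiled by square quadrats (10 x 10 m by default). Each
quadrat carries the elevation of its four corner stakes and its centre,
from which four topographic attributes are derived:

* elevation — arithmetic mean of the four vertex elevations;
* convexity — centre elevation minus that mean (positive = locally
  raised);
* slope — mean dip angle of the four planes through each triple of
  vertices;
* aspect — circular mean of the downslope azimuths of those planes,
  degrees clockwise from north; undefined (NaN) when every plane is
  flat.

Quadrats are typed *rock* when rock outcrop covers at least half of the
cell, *soil* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

__all__ = [
    "Quadrat",
    "QuadratGrid",
    "SubstrateMap",
    "build_quadrat_grid",
    "quadrat_elevation",
    "quadrat_convexity",
    "quadrat_slope",
    "quadrat_aspect",
    "rock_fraction",
    "classify_site_type",
    "set_elevations",
    "compute_terrain",
    "terrain_table",
]

FLAT_DIP_DEG = 1e-9


class GeometryError(ValueError):
    pass


@dataclass
class Quadrat:
    row: int
    col: int
    x0: float
    y0: float
    size: float
    vertex_z: Optional[np.ndarray] = None  # order: (x0,y0),(x1,y0),(x1,y1),(x0,y1)
    center_z: Optional[float] = None
    center_interpolated: bool = False
    elevation: float = math.nan
    convexity: float = math.nan
    slope: float = math.nan
    aspect: float = math.nan
    rock_fraction: float = math.nan
    site_type: Optional[str] = None

    @property
    def x1(self) -> float:
        return self.x0 + self.size

    @property
    def y1(self) -> float:
        return self.y0 + self.size

    @property
    def center_xy(self) -> tuple[float, float]:
        return (self.x0 + self.size / 2.0, self.y0 + self.size / 2.0)

    @property
    def area(self) -> float:
        return self.size * self.size

    def polygon(self) -> Polygon:
        return box(self.x0, self.y0, self.x1, self.y1)

    def vertices_xyz(self) -> np.ndarray:
        """4 x 3 array of corner coordinates with elevations."""
        if self.vertex_z is None:
            raise GeometryError(f"quadrat {(self.row, self.col)} has no elevations")
        xy = [
            (self.x0, self.y0),
            (self.x1, self.y0),
            (self.x1, self.y1),
            (self.x0, self.y1),
        ]
        return np.array([(x, y, z) for (x, y), z in zip(xy, self.vertex_z)])


@dataclass
class QuadratGrid:
    plot_width: float
    plot_height: float
    cell_size: float
    nrows: int
    ncols: int
    cells: list[Quadrat] = field(default_factory=list)

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, row: int, col: int) -> Quadrat:
        return self.cells[row * self.ncols + col]

    def cell_index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point.

        Membership is half-open [lo, hi); points on the top or right
        plot boundary belong to the last row/column. Points outside the
        plot raise.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = (x < 0) | (x > self.plot_width) | (y < 0) | (y > self.plot_height)
        if np.any(out):
            bad = np.nonzero(np.atleast_1d(out))[0]
            raise GeometryError(f"points outside plot at positions {bad.tolist()}")
        col = np.minimum((x / self.cell_size).astype(int), self.ncols - 1)
        row = np.minimum((y / self.cell_size).astype(int), self.nrows - 1)
        return row, col


def build_quadrat_grid(
    plot_width: float, plot_height: float, cell_size: float = 10.0
) -> QuadratGrid:
    """Tile the plot rectangle with square quadrats, row-major order."""
    if plot_width <= 0 or plot_height <= 0 or cell_size <= 0:
        raise GeometryError("plot dimensions and cell size must be positive")
    for dim, name in ((plot_width, "plot_width"), (plot_height, "plot_height")):
        ratio = dim / cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            rem = dim - math.floor(ratio) * cell_size
            raise GeometryError(
                f"{name}={dim} is not a multiple of cell_size={cell_size} "
                f"(remainder {rem:g} m)"
            )
    ncols = round(plot_width / cell_size)
    nrows = round(plot_height / cell_size)
    cells = [
        Quadrat(row=r, col=c, x0=c * cell_size, y0=r * cell_size, size=cell_size)
        for r in range(nrows)
        for c in range(ncols)
    ]
    return QuadratGrid(plot_width, plot_height, cell_size, nrows, ncols, cells)


# ---------------------------------------------------------------------------
# Substrate


class SubstrateMap:
    """Rock-outcrop polygons clipped to the plot rectangle."""

    def __init__(self, polygons: Iterable, plot_width: float, plot_height: float):
        self.plot_width = float(plot_width)
        self.plot_height = float(plot_height)
        window = box(0.0, 0.0, self.plot_width, self.plot_height)
        clipped = []
        for i, poly in enumerate(polygons):
            if not poly.is_valid:
                raise GeometryError(f"invalid (self-intersecting?) polygon at feature {i}")
            inter = poly.intersection(window)
            if not inter.is_empty:
                clipped.append(inter)
        self.polygons = clipped
        self._union = unary_union(clipped) if clipped else Polygon()

    @property
    def union(self):
        return self._union

    @property
    def plot_area(self) -> float:
        return self.plot_width * self.plot_height

    @property
    def total_rock_area(self) -> float:
        return self._union.area

    @property
    def total_soil_area(self) -> float:
        return self.plot_area - self.total_rock_area

    @property
    def rock_fraction(self) -> float:
        return self.total_rock_area / self.plot_area

    def __len__(self) -> int:
        return len(self.polygons)


# ---------------------------------------------------------------------------
# Per-quadrat attributes


def quadrat_elevation(vertex_z) -> float:
    """Mean of the four vertex elevations."""
    z = np.asarray(vertex_z, dtype=float)
    if z.shape != (4,) or not np.all(np.isfinite(z)):
        raise GeometryError("quadrat elevation needs 4 finite vertex values")
    return float(z.mean())


def quadrat_convexity(center_z: float, vertex_z) -> float:
    """Centre elevation minus mean vertex elevation."""
    if center_z is None or not np.isfinite(center_z):
        raise GeometryError("centre elevation missing (enable bilinear fallback?)")
    return float(center_z) - quadrat_elevation(vertex_z)


def _triple_plane(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-ish normal (nz >= 0) and dip angle (deg) of the plane through 3 points."""
    v1 = p[1] - p[0]
    v2 = p[2] - p[0]
    n = np.cross(v1, v2)
    if abs(v1[0] * v2[1] - v1[1] * v2[0]) < 1e-12:
        raise GeometryError("degenerate vertex triple (collinear in xy)")
    if n[2] < 0:
        n = -n
    dip = math.degrees(math.acos(min(1.0, abs(n[2]) / np.linalg.norm(n))))
    return n, dip


def quadrat_slope(vertices) -> float:
    """Mean dip angle of the four planes through each triple of vertices."""
    p = np.asarray(vertices, dtype=float)
    if p.shape != (4, 3):
        raise GeometryError("quadrat_slope needs 4 (x, y, z) vertices")
    dips = [_triple_plane(p[list(tri)])[1] for tri in combinations(range(4), 3)]
    return float(np.mean(dips))


def _plane_aspect(n: np.ndarray) -> float:
    """Azimuth (deg clockwise from north) of steepest descent for normal n."""
    # gradient of z(x, y) is (-nx/nz, -ny/nz); downslope is its negation
    dx, dy = n[0] / n[2], n[1] / n[2]
    return math.degrees(math.atan2(dx, dy)) % 360.0


def quadrat_aspect(vertices) -> float:
    """Circular mean of the downslope azimuths of the four vertex-triple planes.

    Flat planes (dip below 1e-9 degrees) carry no direction and are
    excluded; a fully flat quadrat returns NaN.
    """
    p = np.asarray(vertices, dtype=float)
    if p.shape != (4, 3):
        raise GeometryError("quadrat_aspect needs 4 (x, y, z) vertices")
    azimuths = []
    for tri in combinations(range(4), 3):
        n, dip = _triple_plane(p[list(tri)])
        if dip < FLAT_DIP_DEG:
            continue
        azimuths.append(_plane_aspect(n))
    if not azimuths:
        return math.nan
    ang = np.radians(azimuths)
    return math.degrees(math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))) % 360.0


def rock_fraction(quadrat: Quadrat, substrate: SubstrateMap) -> float:
    """Fraction of the quadrat covered by rock, by exact polygon clipping."""
    if substrate.union.is_empty:
        return 0.0
    return quadrat.polygon().intersection(substrate.union).area / quadrat.area


def classify_site_type(
    grid: QuadratGrid, substrate: SubstrateMap, threshold: float = 0.5
) -> dict:
    """Type every quadrat rock/soil and return count and area totals.

    A quadrat is *rock* when its rock cover fraction is >= ``threshold``
    (default one half), *soil* otherwise.
    """
    n_rock = 0
    for q in grid:
        q.rock_fraction = rock_fraction(q, substrate)
        q.site_type = "rock" if q.rock_fraction >= threshold else "soil"
        n_rock += q.site_type == "rock"
    n_soil = len(grid) - n_rock
    cell_area = grid.cell_size**2
    return {
        "n_rock_quadrats": n_rock,
        "n_soil_quadrats": n_soil,
        "rock_quadrat_area": n_rock * cell_area,
        "soil_quadrat_area": n_soil * cell_area,
    }


# ---------------------------------------------------------------------------
# Elevation attachment and the terrain table


def set_elevations(
    grid: QuadratGrid,
    elevations: pd.DataFrame,
    center_fallback_bilinear: bool = False,
) -> None:
    """Attach vertex/centre elevations from a long-format table.

    ``elevations`` columns: kind in {vertex, center}, i (column index),
    j (row index), x, y, z. Vertex (i, j) sits at (i*s, j*s). With
    ``center_fallback_bilinear`` a missing centre is replaced by the
    bilinear interpolant of the four corners (their mean), which forces
    convexity to zero and is flagged on the quadrat.
    """
    vz = {
        (int(r.i), int(r.j)): float(r.z)
        for r in elevations[elevations["kind"] == "vertex"].itertuples()
    }
    cz = {
        (int(r.i), int(r.j)): float(r.z)
        for r in elevations[elevations["kind"] == "center"].itertuples()
    }
    for q in grid:
        try:
            q.vertex_z = np.array(
                [
                    vz[(q.col, q.row)],
                    vz[(q.col + 1, q.row)],
                    vz[(q.col + 1, q.row + 1)],
                    vz[(q.col, q.row + 1)],
                ]
            )
        except KeyError as e:
            raise GeometryError(
                f"missing vertex elevation {e} for quadrat {(q.row, q.col)}"
            ) from None
        if (q.col, q.row) in cz:
            q.center_z = cz[(q.col, q.row)]
        elif center_fallback_bilinear:
            q.center_z = float(np.mean(q.vertex_z))
            q.center_interpolated = True
        else:
            raise GeometryError(
                f"missing centre elevation for quadrat {(q.row, q.col)} "
                "(pass center_fallback_bilinear=True to interpolate)"
            )


def compute_terrain(grid: QuadratGrid) -> None:
    """Fill elevation, convexity, slope and aspect for every quadrat."""
    for q in grid:
        verts = q.vertices_xyz()
        q.elevation = quadrat_elevation(q.vertex_z)
        q.convexity = quadrat_convexity(q.center_z, q.vertex_z)
        q.slope = quadrat_slope(verts)
        q.aspect = quadrat_aspect(verts)


def terrain_table(grid: QuadratGrid) -> pd.DataFrame:
    """Per-quadrat terrain attributes as a tidy table."""
    rows = []
    for q in grid:
        rows.append(
            {
                "row": q.row,
                "col": q.col,
                "elevation": q.elevation,
                "convexity": q.convexity,
                "slope": q.slope,
                "aspect": q.aspect,
                "rock_fraction": q.rock_fraction,
                "site_type": q.site_type,
                "center_interpolated": q.center_interpolated,
            }
        )
    return pd.DataFrame(rows)
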