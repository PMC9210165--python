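"""Species diversity indices at plot, site-type and quadrat scales.

Richness R, abundance N, the Shannon–Wiener index H' = -sum p_i ln p_i
and the Pielou evenness E_H = H'/ln S (natural logarithms throughout,
so a perfectly even community has E_H = 1). Evenness is undefined for
single-species groups and reported as NaN.

Stem densities are expressed per hectare under two area conventions:
the actual substrate area of each site type, and the area implied by
the quadrat count (quadrats x cell area); mapped-plot studies report
either, and they differ whenever rock cover is not an exact multiple
of the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .terrain import QuadratGrid, SubstrateMap


class DiversityError(ValueError):
    pass


@dataclass
class CommunityCounts:
    group: object
    counts: dict
    N: int
    S: int


def _make_counts(group, labels) -> CommunityCounts:
    vals, cnts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    counts = {str(v): int(c) for v, c in zip(vals, cnts)}
    return CommunityCounts(group, counts, int(cnts.sum()), int((cnts > 0).sum()))


def community_counts(
    stems: pd.DataFrame,
    grouping: str = "plot",
    grid: QuadratGrid | None = None,
    substrate: SubstrateMap | None = None,
    convention: str = "quadrat",
) -> list[CommunityCounts]:
    """Species abundance tallies per plot, site type or quadrat.

    Site-type membership of a stem follows its containing quadrat by
    default; with ``convention="substrate"`` (requires a substrate map)
    it follows the substrate directly under the stem.
    """
    if grouping == "plot":
        return [_make_counts("plot", stems["species"])]
    if grid is None:
        raise DiversityError(f"grouping={grouping!r} needs a classified grid")
    row, col = grid.cell_index_of(stems["x"].to_numpy(), stems["y"].to_numpy())
    if grouping == "quadrat":
        out = []
        key = row * grid.ncols + col
        for cell_id in np.unique(key):
            q = grid.cells[cell_id]
            out.append(_make_counts((q.row, q.col), stems["species"].to_numpy()[key == cell_id]))
        return out
    if grouping == "site_type":
        if convention == "substrate":
            if substrate is None:
                raise DiversityError("substrate convention needs a substrate map")
            on_rock = shapely.contains_xy(
                substrate.union, stems["x"].to_numpy(), stems["y"].to_numpy()
            )
            site = np.where(on_rock, "rock", "soil")
        else:
            types = np.array([q.site_type for q in grid.cells], dtype=object)
            if (types == None).any():  # noqa: E711
                raise DiversityError("grid is not classified (run classify_site_type)")
            site = types[row * grid.ncols + col]
        return [
            _make_counts(st, stems["species"].to_numpy()[site == st])
            for st in ("rock", "soil")
            if (site == st).any()
        ]
    raise DiversityError(f"unknown grouping {grouping!r}")


def shannon_index(counts: CommunityCounts) -> float:
    """Shannon–Wiener index H' = -sum p_i ln p_i (nats)."""
    n = np.array([c for c in counts.counts.values() if c > 0], dtype=float)
    if counts.N <= 0 or n.size == 0:
        raise DiversityError("Shannon index undefined for an empty community")
    p = n / n.sum()
    return float(-(p * np.log(p)).sum())


def pielou_evenness(counts: CommunityCounts) -> float:
    """Pielou evenness E_H = H'/ln S; NaN (undefined) when S < 2."""
    if counts.S < 2:
        return math.nan
    return shannon_index(counts) / math.log(counts.S)


def density_per_hectare(count: int, area_m2: float) -> float:
    """Stems per hectare; callers truncate toward zero for integer reports."""
    if area_m2 <= 0:
        raise DiversityError("area must be positive")
    return count * 10_000.0 / area_m2


def diversity_table(
    stems: pd.DataFrame,
    grid: QuadratGrid,
    substrate: SubstrateMap | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-quadrat and per-site-type diversity summaries.

    Returns ``(quadrat_table, site_table)``. The site table carries both
    per-hectare density conventions: actual substrate area (when a
    substrate map is given) and quadrat-count area.
    """
    quad_counts = community_counts(stems, "quadrat", grid)
    by_cell = {cc.group: cc for cc in quad_counts}
    qrows = []
    for q in grid:
        cc = by_cell.get((q.row, q.col))
        qrows.append(
            {
                "row": q.row,
                "col": q.col,
                "site_type": q.site_type,
                "R": cc.S if cc else 0,
                "N": cc.N if cc else 0,
                "shannon": shannon_index(cc) if cc else math.nan,
                "evenness": pielou_evenness(cc) if cc else math.nan,
            }
        )
    quadrat_table = pd.DataFrame(qrows)

    site_counts = community_counts(stems, "site_type", grid)
    cell_area = grid.cell_size**2
    n_cells = {
        st: sum(q.site_type == st for q in grid) for st in ("rock", "soil")
    }
    srows = []
    for cc in site_counts:
        st = cc.group
        quad_area = n_cells[st] * cell_area
        row = {
            "site_type": st,
            "R": cc.S,
            "N": cc.N,
            "shannon": shannon_index(cc),
            "evenness": pielou_evenness(cc),
            "n_quadrats": n_cells[st],
            "quadrat_area_m2": quad_area,
            "density_quadrat_ha": density_per_hectare(cc.N, quad_area),
        }
        if substrate is not None:
            sub_area = (
                substrate.total_rock_area if st == "rock" else substrate.total_soil_area
            )
            row["substrate_area_m2"] = sub_area
            row["density_substrate_ha"] = density_per_hectare(cc.N, sub_area)
        srows.append(row)
    return quadrat_table, pd.DataFrame(srows)
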