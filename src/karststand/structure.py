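"""Nearest-neighbour stand spatial structure parameters.

For every reference tree i and its four nearest neighbours the module
computes three structural indices, each quantized to quarters:

* uniform angle index W_i — the fraction of the four angular gaps
  between consecutive neighbour directions that are smaller than the
  standard angle alpha0 = 360/(k+1) = 72 degrees. W ~ 0.5 under
  complete spatial randomness, lower under regularity, higher under
  clustering.
* dominance U_i — the fraction of neighbours strictly larger than the
  reference (ties count as not larger); U_i = 1 means the reference is
  suppressed by all four neighbours.
* mingling M_i — the fraction of neighbours of a different species.

Neighbour search spans the whole stand (not quadrat-bounded). Edge
effects are handled by flagging references within a buffer of the plot
boundary; flagged stems can be excluded from summary means while still
serving as neighbours of interior stems.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .terrain import QuadratGrid

ALPHA0_DEFAULT = 72.0
QUARTERS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


class StructureError(ValueError):
    pass


def knn_neighborhoods(
    stems: pd.DataFrame, k: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices, distances and azimuths of each stem's k nearest others.

    Distance ties are broken by (distance, stem id) lexicographic
    order, so results are deterministic and match a brute-force scan.
    Returns ``(neighbor_idx, distances, azimuths)``, each (n, k);
    azimuths are degrees clockwise from north. Indices are positional
    row indices into ``stems``.
    """
    n = len(stems)
    if n <= k:
        raise StructureError(f"need more than k={k} stems, got {n}")
    xy = stems[["x", "y"]].to_numpy(dtype=float)
    ids = stems["id"].to_numpy()
    tree = cKDTree(xy)
    # query extra candidates so ties can be re-ordered by stem id
    kq = min(n, k + 4)
    dist, idx = tree.query(xy, k=kq)
    nb_idx = np.empty((n, k), dtype=int)
    nb_dist = np.empty((n, k))
    for i in range(n):
        cand = [(d, ids[j], j) for d, j in zip(dist[i], idx[i]) if j != i]
        cand.sort(key=lambda t: (t[0], t[1]))
        chosen = cand[:k]
        # guard: if the k-th and (k+1)-th candidate distances tie, the
        # id order inside the tie is already respected by the sort
        nb_dist[i] = [t[0] for t in chosen]
        nb_idx[i] = [t[2] for t in chosen]
    dx = xy[nb_idx, 0] - xy[:, None, 0]
    dy = xy[nb_idx, 1] - xy[:, None, 1]
    azimuth = np.degrees(np.arctan2(dx, dy)) % 360.0
    return nb_idx, nb_dist, azimuth


def uniform_angle_index(azimuths, alpha0: float = ALPHA0_DEFAULT) -> float:
    """W_i from the four neighbour azimuths (degrees clockwise from north).

    The four circular gaps between consecutive sorted directions sum to
    360 degrees; each gap strictly smaller than alpha0 scores 1.
    """
    az = np.sort(np.asarray(azimuths, dtype=float) % 360.0)
    if az.shape != (4,):
        raise StructureError("uniform_angle_index needs exactly 4 azimuths")
    gaps = np.diff(az, append=az[0] + 360.0)
    return float(np.sum(gaps < alpha0) / 4.0)


def dominance(reference_dbh: float, neighbour_dbhs) -> float:
    """U_i: fraction of neighbours strictly larger than the reference."""
    nb = np.asarray(neighbour_dbhs, dtype=float)
    return float(np.sum(reference_dbh < nb) / nb.size)


def mingling(reference_species, neighbour_species) -> float:
    """M_i: fraction of neighbours of a different species."""
    nb = np.asarray(neighbour_species, dtype=object)
    return float(np.sum(nb != reference_species) / nb.size)


def edge_flags(stems: pd.DataFrame, plot_width: float, plot_height: float, buffer_m: float) -> np.ndarray:
    """True for stems within buffer_m of any plot boundary."""
    x = stems["x"].to_numpy(dtype=float)
    y = stems["y"].to_numpy(dtype=float)
    return (
        (x < buffer_m)
        | (x > plot_width - buffer_m)
        | (y < buffer_m)
        | (y > plot_height - buffer_m)
    )


def sssp_table(
    stems: pd.DataFrame,
    grid: QuadratGrid | None = None,
    buffer_m: float = 5.0,
    alpha0: float = ALPHA0_DEFAULT,
    size_var: str = "dbh_cm",
    plot_width: float | None = None,
    plot_height: float | None = None,
) -> pd.DataFrame:
    """Per-tree W, U, M with neighbour bookkeeping and an edge flag.

    The neighbour search always uses the full stem map; the edge flag
    marks references within ``buffer_m`` of the plot boundary so that
    summaries can exclude them. ``size_var`` selects the dominance size
    variable (DBH by default; height or basal area column names work
    too). When a grid is given, each stem also carries its quadrat
    index and site type.
    """
    if grid is not None:
        plot_width = grid.plot_width
        plot_height = grid.plot_height
    if plot_width is None or plot_height is None:
        raise StructureError("need a grid or explicit plot dimensions")
    nb_idx, nb_dist, nb_az = knn_neighborhoods(stems, k=4)
    n = len(stems)
    size = stems[size_var].to_numpy(dtype=float)
    sp = stems["species"].to_numpy(dtype=object)
    ids = stems["id"].to_numpy()

    w = np.array([uniform_angle_index(nb_az[i], alpha0) for i in range(n)])
    u = np.array([dominance(size[i], size[nb_idx[i]]) for i in range(n)])
    m = np.array([mingling(sp[i], sp[nb_idx[i]]) for i in range(n)])

    out = pd.DataFrame(
        {
            "id": ids,
            "x": stems["x"].to_numpy(),
            "y": stems["y"].to_numpy(),
            "species": sp,
            "dbh_cm": stems["dbh_cm"].to_numpy() if "dbh_cm" in stems else np.nan,
            "lifeform": stems["lifeform"].to_numpy()
            if "lifeform" in stems
            else "tree",
            "W": w,
            "U": u,
            "M": m,
            "edge_flag": edge_flags(stems, plot_width, plot_height, buffer_m),
        }
    )
    for j in range(4):
        out[f"n{j + 1}_id"] = ids[nb_idx[:, j]]
        out[f"n{j + 1}_dist"] = nb_dist[:, j]
    if grid is not None:
        row, col = grid.cell_index_of(out["x"].to_numpy(), out["y"].to_numpy())
        out["q_row"] = row
        out["q_col"] = col
        types = np.array([q.site_type for q in grid.cells], dtype=object)
        out["site_type"] = types[row * grid.ncols + col]
    return out


def univariate_distribution(values) -> np.ndarray:
    """Relative frequencies of quarter-quantized values at {0, .25, .5, .75, 1}."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StructureError("empty input")
    if not np.all(np.isclose(v[:, None], QUARTERS[None, :], atol=1e-9).any(axis=1)):
        raise StructureError("values are not quantized to quarters")
    freqs = np.array([np.isclose(v, q).sum() for q in QUARTERS], dtype=float)
    return freqs / v.size


def group_summaries(
    records: pd.DataFrame,
    grid: QuadratGrid | None = None,
    edge_policy: str = "exclude_buffer",
) -> dict[str, pd.DataFrame]:
    """Mean W, U, M by site type and life form, plus per-quadrat means.

    Under ``exclude_buffer`` (default), edge-flagged stems are dropped
    from every summary; under ``include`` all stems contribute.
    Returns ``{"groups": ..., "quadrats": ..., "distributions": ...}``.
    """
    if edge_policy not in {"include", "exclude_buffer"}:
        raise StructureError(f"unknown edge_policy {edge_policy!r}")
    df = records if edge_policy == "include" else records[~records["edge_flag"]]

    sites = ["all"]
    if "site_type" in records.columns:
        sites += sorted(records["site_type"].dropna().unique())
    lifeforms = ["all", "tree", "shrub"]

    grows, drows = [], []
    for st in sites:
        d1 = df if st == "all" else df[df["site_type"] == st]
        for lf in lifeforms:
            d2 = d1 if lf == "all" else d1[d1["lifeform"] == lf]
            base = {"site_type": st, "lifeform": lf, "n": len(d2)}
            if len(d2) == 0:
                grows.append({**base, "mean_W": np.nan, "mean_U": np.nan, "mean_M": np.nan})
                continue
            grows.append(
                {
                    **base,
                    "mean_W": d2["W"].mean(),
                    "mean_U": d2["U"].mean(),
                    "mean_M": d2["M"].mean(),
                }
            )
            for param in ("W", "U", "M"):
                freqs = univariate_distribution(d2[param].to_numpy())
                drows.append(
                    {
                        "site_type": st,
                        "lifeform": lf,
                        "parameter": param,
                        **{f"f_{q:g}": f for q, f in zip(QUARTERS, freqs)},
                    }
                )
    out = {"groups": pd.DataFrame(grows), "distributions": pd.DataFrame(drows)}
    if "q_row" in records.columns:
        out["quadrats"] = (
            df.groupby(["q_row", "q_col"])[["W", "U", "M"]]
            .mean()
            .reset_index()
            .rename(columns={"W": "mean_W", "U": "mean_U", "M": "mean_M"})
        )
    return out


def csr_mean_w(
    n_stems: int = 2000,
    plot_width: float = 200.0,
    plot_height: float = 110.0,
    n_replicates: int = 20,
    seed: int = 0,
    buffer_m: float = 5.0,
    alpha0: float = ALPHA0_DEFAULT,
) -> tuple[float, np.ndarray]:
    """Grand mean W of replicated complete-spatial-randomness stands.

    Simulates homogeneous Poisson stands at the given density, averages
    W over interior stems (outside the edge buffer) within each
    replicate, then across replicates. Returns ``(grand_mean,
    replicate_means)``. Used as the random-pattern reference band for
    the uniform angle index.
    """
    from .config import StandConfig
    from .synthetic import generate_point_pattern

    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    means = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = StandConfig(
            plot_width=plot_width,
            plot_height=plot_height,
            n_stems=n_stems,
            pattern="poisson",
            species_abundances=[1.0],
            seed=0,
        )
        pts = generate_point_pattern(cfg, np.random.default_rng(seeds[r]))
        stems = pd.DataFrame(
            {
                "id": np.arange(1, n_stems + 1),
                "x": pts[:, 0],
                "y": pts[:, 1],
                "species": "X",
                "dbh_cm": 10.0,
                "th_m": 10.0,
                "lifeform": "tree",
            }
        )
        tab = sssp_table(
            stems,
            buffer_m=buffer_m,
            alpha0=alpha0,
            plot_width=plot_width,
            plot_height=plot_height,
        )
        means[r] = tab.loc[~tab["edge_flag"], "W"].mean()
    return float(means.mean()), means
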