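"""Tree-size metrics and rock-vs-soil statistical comparisons.

Basal area is computed from DBH as BA = pi * (DBH/200)^2 (DBH in cm,
BA in m^2). Per-quadrat means of DBH, TH and BA feed three kinds of
comparison between site types: Kruskal–Wallis rank tests on quadrat
values, two-sample Kolmogorov–Smirnov tests on the quarter-quantized
structure indices, and ordinary least-squares trends of metrics against
topographic attributes fitted separately per site type. Significance
bands follow the common figure convention: p >= 0.05 non-significant,
0.01 <= p < 0.05 significant, p < 0.01 highly significant (boundary p
assigned to the less significant band). No multiple-testing correction
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .terrain import QuadratGrid


class CompareError(ValueError):
    pass


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple
    band: str


def significance_band(p: float) -> str:
    if not 0.0 <= p <= 1.0:
        raise CompareError(f"p-value {p} outside [0, 1]")
    if p < 0.01:
        return "highly_significant"
    if p < 0.05:
        return "significant"
    return "ns"


def basal_area(dbh_cm):
    """Basal area in m^2 from DBH in cm: pi * (dbh/200)^2."""
    d = np.asarray(dbh_cm, dtype=float)
    if np.any(d < 1.0):
        raise CompareError("DBH below the 1 cm census threshold")
    out = math.pi * (d / 200.0) ** 2
    return float(out) if np.isscalar(dbh_cm) else out


def quadrat_size_metrics(
    stems: pd.DataFrame, grid: QuadratGrid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-quadrat mean DBH, TH, per-tree BA and total BA; site aggregates.

    Empty quadrats appear as sentinel rows (NaN means, n = 0) and are
    excluded from site aggregates and downstream tests.
    """
    row, col = grid.cell_index_of(stems["x"].to_numpy(), stems["y"].to_numpy())
    df = stems.copy()
    df["q_row"], df["q_col"] = row, col
    df["ba_m2"] = basal_area(df["dbh_cm"].to_numpy())
    agg = (
        df.groupby(["q_row", "q_col"])
        .agg(
            n=("id", "size"),
            mean_dbh=("dbh_cm", "mean"),
            mean_th=("th_m", "mean"),
            mean_ba=("ba_m2", "mean"),
            total_ba=("ba_m2", "sum"),
        )
        .reset_index()
    )
    full = pd.DataFrame(
        [(q.row, q.col, q.site_type) for q in grid],
        columns=["q_row", "q_col", "site_type"],
    )
    table = full.merge(agg, on=["q_row", "q_col"], how="left")
    table["n"] = table["n"].fillna(0).astype(int)

    occupied = table[table["n"] > 0]
    site = (
        occupied.groupby("site_type")[["mean_dbh", "mean_th", "mean_ba"]]
        .mean()
        .reset_index()
    )
    return table, site


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal–Wallis rank test (tie-corrected H, chi-square p).

    Degenerate input in which every observation is identical yields
    H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise CompareError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise CompareError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return TestResult(
        "kruskal_wallis", float(h), float(p), tuple(a.size for a in arrays),
        significance_band(float(p)),
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test with asymptotic p.

    D is the supremum distance between the two empirical CDFs. The
    asymptotic p is conservative on heavily tied (quarter-quantized)
    inputs; with such data D remains exact while p is approximate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CompareError("empty sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(
        "ks_two_sample",
        float(res.statistic),
        float(min(1.0, res.pvalue)),
        (x.size, y.size),
        significance_band(float(min(1.0, res.pvalue))),
    )


def linear_trend(x, y) -> dict:
    """OLS fit y = slope * x + intercept with R^2 and slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CompareError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise CompareError("zero variance in x")
    if np.ptp(y) == 0:
        # flat response: zero slope, no explained variance, p undefined
        return {
            "slope": 0.0,
            "intercept": float(y[0]),
            "r2": 0.0,
            "p_value": math.nan,
            "n": int(x.size),
        }
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(x.size),
    }


def linear_trends_by_group(
    table: pd.DataFrame, xcol: str, ycol: str, group_col: str = "site_type"
) -> pd.DataFrame:
    """Per-group OLS trends of a metric against a topographic variable.

    Rows with missing values (e.g. undefined aspect on flat quadrats)
    are dropped per group before fitting.
    """
    rows = []
    for g, d in table.groupby(group_col):
        d = d[[xcol, ycol]].dropna()
        if len(d) < 3:
            continue
        fit = linear_trend(d[xcol], d[ycol])
        # a degenerate fit (e.g. constant response) has no defined p
        band = (
            significance_band(fit["p_value"])
            if math.isfinite(fit["p_value"])
            else "undefined"
        )
        rows.append({group_col: g, "x": xcol, "y": ycol, **fit, "band": band})
    return pd.DataFrame(rows)


def ordination_export(
    quadrat_diversity: pd.DataFrame,
    quadrat_structure: pd.DataFrame,
    quadrat_size: pd.DataFrame,
    terrain: pd.DataFrame,
    stems: pd.DataFrame,
    grid: QuadratGrid,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assemble ordination-ready matrices (RDA/NMDS inputs, not fits).

    Returns ``(response, explanatory, abundance)`` aligned on quadrat
    index. Response: R, N, H', E_H, mean W/U/M, mean DBH/TH/BA per
    quadrat. Explanatory: per-quadrat rock and soil area, elevation,
    convexity, aspect, slope. Abundance: species-by-quadrat counts.
    Quadrats missing any response or explanatory value (empty cells,
    flat-aspect cells) are dropped from all three with a notice.
    """
    key = ["row", "col"]
    struct = quadrat_structure.rename(columns={"q_row": "row", "q_col": "col"})
    size = quadrat_size.rename(columns={"q_row": "row", "q_col": "col"})
    resp = (
        quadrat_diversity[key + ["R", "N", "shannon", "evenness"]]
        .merge(struct[key + ["mean_W", "mean_U", "mean_M"]], on=key, how="left")
        .merge(size[key + ["mean_dbh", "mean_th", "mean_ba"]], on=key, how="left")
    )
    cell_area = grid.cell_size**2
    expl = terrain[key + ["elevation", "convexity", "aspect", "slope", "rock_fraction"]].copy()
    expl["rock_area"] = expl.pop("rock_fraction") * cell_area
    expl["soil_area"] = cell_area - expl["rock_area"]
    expl = expl[key + ["rock_area", "soil_area", "elevation", "convexity", "aspect", "slope"]]

    merged = resp.merge(expl, on=key, how="inner", suffixes=("", "_e"))
    complete = merged.dropna()
    dropped = len(merged) - len(complete)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "ordination export: dropped %d incomplete quadrat rows", dropped
        )
    keep = complete[key]
    resp = keep.merge(resp, on=key).sort_values(key).reset_index(drop=True)
    expl = keep.merge(expl, on=key).sort_values(key).reset_index(drop=True)

    row, col = grid.cell_index_of(stems["x"].to_numpy(), stems["y"].to_numpy())
    ab = (
        pd.DataFrame({"row": row, "col": col, "species": stems["species"].to_numpy()})
        .pivot_table(index=key, columns="species", aggfunc="size", fill_value=0)
    )
    ab = ab.reindex(pd.MultiIndex.from_frame(keep[key]), fill_value=0)
    ab.columns.name = None
    ab = ab.reset_index()
    return resp, expl, ab
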