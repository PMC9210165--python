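"""End-to-end pipeline: scenario/inputs -> terrain -> diversity ->
spatial structure -> size metrics and comparisons -> ordination export.

Every run is deterministic given the configuration and seed, and every
output table is stamped with a provenance string (config hash + seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as kio
from .config import PipelineConfig, StandConfig
from .diversity import diversity_table
from .sizecomp import (
    kruskal_wallis,
    ks_two_sample,
    linear_trends_by_group,
    ordination_export,
    quadrat_size_metrics,
)
from .structure import group_summaries, sssp_table
from .synthetic import generate_scenario
from .terrain import (
    build_quadrat_grid,
    classify_site_type,
    compute_terrain,
    set_elevations,
    terrain_table,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _provenance(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {k: v for k, v in vars(cfg).items() if not k.startswith("_")},
        sort_keys=True,
        default=str,
    )
    return f"config_sha1={hashlib.sha1(blob.encode()).hexdigest()[:12]} seed={cfg.seed}"


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Run every analysis stage; write tables when out_dir is given.

    Returns a dict of in-memory results: grid, substrate, stems plus
    all metric tables. Stage failures abort with the stage name.
    """
    cfg.validate()
    prov = _provenance(cfg)
    out = Path(out_dir if out_dir is not None else cfg.out_dir)

    stage = "inputs"
    try:
        if cfg.simulate is not None:
            stand = StandConfig(
                **{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)}
            )
            scenario = generate_scenario(stand)
            stems, substrate, elev = scenario.stems, scenario.substrate, scenario.elevations
            cfg.plot_width, cfg.plot_height = stand.plot_width, stand.plot_height
        else:
            stems = kio.read_stem_map(cfg.stems_path)
            substrate = kio.read_substrate(cfg.substrate_path, cfg.plot_width, cfg.plot_height)
            elev = kio.read_elevations(cfg.elevations_path)

        stage = "terrain"
        grid = build_quadrat_grid(cfg.plot_width, cfg.plot_height, cfg.cell_size)
        set_elevations(grid, elev)
        compute_terrain(grid)
        totals = classify_site_type(grid, substrate, cfg.rock_threshold)
        terr = terrain_table(grid)
        log.info(
            "terrain: %d quadrats (%d rock / %d soil); threshold=%g; "
            "edge_policy=%s buffer=%gm alpha0=%g",
            len(grid), totals["n_rock_quadrats"], totals["n_soil_quadrats"],
            cfg.rock_threshold, cfg.edge_policy, cfg.buffer_m, cfg.alpha0,
        )

        stage = "diversity"
        div_quadrat, div_site = diversity_table(stems, grid, substrate)

        stage = "structure"
        records = sssp_table(stems, grid, buffer_m=cfg.buffer_m, alpha0=cfg.alpha0)
        summaries = group_summaries(records, grid, edge_policy=cfg.edge_policy)

        stage = "size_compare"
        size_quadrat, size_site = quadrat_size_metrics(stems, grid)
        tests = _site_tests(div_quadrat, size_quadrat, summaries)
        trends = _trend_tables(div_quadrat, size_quadrat, summaries, terr)

        stage = "ordination_export"
        resp, expl, abund = ordination_export(
            div_quadrat, summaries["quadrats"], size_quadrat, terr, stems, grid
        )
    except Exception as e:
        raise PipelineError(f"pipeline stage '{stage}' failed: {e}") from e

    results = {
        "grid": grid,
        "substrate": substrate,
        "stems": stems,
        "elevations": elev,
        "site_totals": totals,
        "terrain": terr,
        "diversity_quadrat": div_quadrat,
        "diversity_site": div_site,
        "sssp_records": records,
        "sssp_groups": summaries["groups"],
        "sssp_distributions": summaries["distributions"],
        "sssp_quadrats": summaries["quadrats"],
        "size_quadrat": size_quadrat,
        "size_site": size_site,
        "tests": tests,
        "trends": trends,
        "ordination_response": resp,
        "ordination_explanatory": expl,
        "ordination_abundance": abund,
    }

    if out_dir is not None or cfg.out_dir:
        out.mkdir(parents=True, exist_ok=True)
        kio.write_stem_map(stems, out / "stems.csv", prov)
        kio.write_substrate_geojson(substrate, out / "substrate.geojson")
        kio.write_elevations(elev, out / "elevations.csv", prov)
        for name in (
            "terrain", "diversity_quadrat", "diversity_site", "sssp_records",
            "sssp_groups", "sssp_distributions", "sssp_quadrats",
            "size_quadrat", "size_site", "tests", "trends",
            "ordination_response", "ordination_explanatory", "ordination_abundance",
        ):
            kio.write_table(results[name], out / f"{name}.csv", prov)
        (out / "run_info.json").write_text(
            json.dumps({"provenance": prov, "site_totals": totals}, indent=1)
        )
    return results


def _site_tests(div_quadrat, size_quadrat, summaries) -> pd.DataFrame:
    """Kruskal–Wallis rock-vs-soil tests on quadrat metrics and KS tests
    on the per-tree structure index distributions."""
    rows = []
    dq = div_quadrat[div_quadrat["N"] > 0]
    for metric in ("R", "N", "shannon", "evenness"):
        groups = [
            dq.loc[dq["site_type"] == st, metric].dropna().to_numpy()
            for st in ("rock", "soil")
        ]
        if all(len(g) for g in groups):
            t = kruskal_wallis(*groups)
            rows.append({"comparison": f"kw_{metric}", **vars(t)})
    sq = size_quadrat[size_quadrat["n"] > 0]
    for metric in ("mean_dbh", "mean_th", "mean_ba"):
        groups = [
            sq.loc[sq["site_type"] == st, metric].dropna().to_numpy()
            for st in ("rock", "soil")
        ]
        if all(len(g) for g in groups):
            t = kruskal_wallis(*groups)
            rows.append({"comparison": f"kw_{metric}", **vars(t)})
    return pd.DataFrame(rows)


def _trend_tables(div_quadrat, size_quadrat, summaries, terr) -> pd.DataFrame:
    key = ["row", "col"]
    t = terr[key + ["elevation", "convexity", "aspect", "slope"]]
    dq = div_quadrat.merge(t, on=key)
    sq = size_quadrat.rename(columns={"q_row": "row", "q_col": "col"}).merge(t, on=key)
    st = summaries["quadrats"].rename(columns={"q_row": "row", "q_col": "col"}).merge(
        div_quadrat[key + ["site_type"]], on=key
    ).merge(t, on=key)
    frames = []
    for table, metrics in (
        (dq[dq["N"] > 0], ["R", "N", "shannon", "evenness"]),
        (sq[sq["n"] > 0], ["mean_dbh", "mean_th", "mean_ba"]),
        (st, ["mean_W", "mean_U", "mean_M"]),
    ):
        for x in ("elevation", "convexity", "aspect", "slope"):
            for y in metrics:
                frames.append(linear_trends_by_group(table, x, y))
    frames = [f for f in frames if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
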