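# karststand

Quadrat-based stand structure, diversity and terrain analysis for
stem-mapped forest plots on karst terrain.

Karst landscapes interleave exposed rock outcrops with pockets of soil,
and the two substrates can support quite different woody communities.
`karststand` implements the complete analysis workflow used to compare
them within a single mapped plot: it tiles the plot into quadrats,
derives topographic attributes from surveyed corner elevations, types
each quadrat *rock* or *soil* from an outcrop polygon map, and then
quantifies taxonomic diversity, neighbourhood spatial structure and
tree size per quadrat and per site type — with the statistical
comparisons between the two. Because stem-mapped census data are rarely
public, the package ships a first-class synthetic stand generator whose
defaults emulate a 2.2 ha (200 × 110 m) old-growth oak forest on a
karst slope: 4,596 stems of 62 species with a strongly skewed abundance
distribution, ~28 % rock cover, mean elevation ~1,293 m, mean slope
~25°.

## The statistics at its core

For a reference tree *i* and its four nearest neighbours *j* = 1…4:

- **Uniform angle index** `W_i = ¼ Σ z_ij`, where `z_ij = 1` if the
  *j*-th angular gap between consecutive neighbour directions is
  smaller than the standard angle α₀ = 360°/5 = 72°. `W ≈ 0.5` under
  complete spatial randomness (reference interval 0.475–0.517), lower
  under regularity, higher under clustering.
- **Dominance** `U_i = ¼ Σ k_ij`, where `k_ij = 1` if neighbour *j* is
  strictly larger (DBH by default) than the reference.
- **Mingling** `M_i = ¼ Σ v_ij`, where `v_ij = 1` if neighbour *j* is a
  different species.

Per community the package computes richness *R*, abundance *N*, the
Shannon–Wiener index `H′ = −Σ pᵢ ln pᵢ` and Pielou evenness
`E_H = H′ / ln S`, plus mean DBH, tree height and basal area
`BA = π (DBH/200)²` m². Quadrat topography comes from the four corner
stakes: elevation (vertex mean), convexity (centre minus vertex mean),
slope (mean dip of the four vertex-triple planes) and aspect (circular
mean of their downslope azimuths). Site types are compared with
Kruskal–Wallis rank tests, Kolmogorov–Smirnov tests on the structure
index distributions, and per-site ordinary least-squares trends against
topography; ordination-ready matrices (response, environment, species ×
quadrat abundance) are exported for RDA/NMDS in external software.

## Worked example

```python
import karststand as ks

cfg = ks.yachang_like(seed=1)          # census-abundance preset
sc = ks.generate_scenario(cfg)         # stems + rock map + elevations

grid = ks.build_quadrat_grid(200, 110, 10)
ks.set_elevations(grid, sc.elevations)
ks.compute_terrain(grid)
totals = ks.classify_site_type(grid, sc.substrate)

qt, site = ks.diversity_table(sc.stems, grid, sc.substrate)
records = ks.sssp_table(sc.stems, grid)           # per-tree W, U, M
groups = ks.group_summaries(records, grid)["groups"]
```

With seed 1 this prints (220 quadrats, 61 rock / 159 soil, 29.2 % rock
cover):

```
site_type  R    N  shannon  evenness  density_substrate_ha
     rock 43 1384    2.225     0.592              2154.290
     soil 57 3212    2.216     0.548              2062.198

site_type lifeform    n  mean_W  mean_U  mean_M
      all      all 4020   0.491   0.504   0.830
     rock      all 1206   0.495   0.502   0.834
     soil      all 2814   0.490   0.505   0.828
```

Reading: the two site types hold similar diversity per hectare; the
mean uniform angle index near 0.49 sits in the random-pattern band, as
expected for a Poisson-free cluster process at this density once edge
trees (n = 4,596 → 4,020 interior) are excluded; mingling is high
because species labels are unassociated with location in this scenario.

The same pipeline runs from the shell:

```sh
karststand simulate --config cfg.yaml --seed 1 --out data/
karststand all --config cfg.yaml --seed 1 --out results/
```

## Layout

- `karststand.synthetic` — point processes (Poisson, Thomas cluster,
  hard-core), species/size marks, rock-blob substrate, elevation field
- `karststand.terrain` — quadrat grid, topographic attributes, rock/soil
  classification
- `karststand.diversity` — R, N, H′, E_H, per-hectare densities
- `karststand.structure` — W/U/M neighbourhoods, distributions, group
  summaries, CSR reference simulation
- `karststand.sizecomp` — size metrics, Kruskal–Wallis/KS/OLS
  comparisons, ordination export
- `karststand.io` / `karststand.pipeline` / `karststand.cli` — formats,
  end-to-end runs, command line

See `docs/methods.md` for the full methodological account.
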