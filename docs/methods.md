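# Methods

This note records the models, conventions and numerical choices behind
`karststand`, in the package's own terms.

## Scope and data model

The unit of analysis is a rectangular stem-mapped plot in plot-local
Cartesian metres (x east, y north, origin at the lower-left corner;
azimuths in degrees clockwise from north). Three inputs describe it:

1. a **stem map** — one row per standing live tree: coordinates,
   species, DBH (cm, census threshold ≥ 1 cm), total height (m), life
   form (tree/shrub);
2. a **substrate map** — rock-outcrop polygons in the same frame;
3. an **elevation table** — survey elevations at every quadrat corner
   stake and quadrat centre.

The plot is tiled by square quadrats (default 10 m) in row-major order
with half-open membership `[lo, hi)`; points on the top/right plot
boundary belong to the last row/column, so every stem lives in exactly
one quadrat.

## Terrain attributes

Per quadrat: **elevation** is the mean of the four vertex elevations;
**convexity** is centre minus that mean (positive = locally raised);
**slope** is the mean dip angle `arccos(|n_z|/‖n‖)` of the four exact
planes through each triple of vertices; **aspect** is the downslope
(steepest-descent) azimuth of those planes combined by the *circular*
mean. An arithmetic mean of azimuths is wrong across the 0°/360° wrap
(350° and 10° would average to 180°), so the vector mean is used.
Planes flatter than 1e-9° carry no direction and are excluded; a fully
flat quadrat has undefined aspect, reported as NaN and dropped from
aspect regressions rather than raised as an error. Centre elevations
are expected as survey input; an explicit opt-in fallback interpolates
the bilinear (mean-of-corners) value, which forces convexity to zero
and is flagged in the output.

A quadrat is typed **rock** when the exactly clipped polygon
intersection covers ≥ 50 % of the cell (the threshold is
configurable); otherwise **soil**. Site-type areas are reported both as
actual substrate area and as quadrat count × cell area, because the
two conventions disagree whenever outcrop boundaries cross cells, and
per-hectare densities are derived under both.

## Neighbourhood structure indices

Each reference tree is paired with its four nearest neighbours by
Euclidean distance, searched stand-wide (never quadrat-bounded).
Distance ties are broken by stem id so results are deterministic and
reproducible against a brute-force scan. The indices are

- uniform angle index `W`: fraction of the four circular gaps between
  consecutive neighbour azimuths smaller than α₀ = 72°. The value
  360°/(k+1) with k = 4 is the standard-angle convention of the
  uniform-angle-index literature and is configurable. The comparison is
  strict (`gap < α₀`); a zero gap (two neighbours at the same bearing)
  counts as below the standard angle.
- dominance `U`: fraction of neighbours strictly larger than the
  reference; ties score zero. DBH is the default size variable; height
  or basal area columns can be selected.
- mingling `M`: fraction of neighbours of a different species.

All three are quantized to {0, ¼, ½, ¾, 1}. Under complete spatial
randomness the replicate-mean `W` of simulated stands falls in the
published random-pattern interval [0.475, 0.517]; the package's CSR
reference simulation (20 replicates of 2,000 stems in 200 × 110 m)
reproduces this, landing near 0.49.

**Edge handling.** Plot-boundary trees lack neighbours outside the
window, which biases their angular configuration. The package computes
indices for every tree but flags references within a buffer (default
5 m) of any boundary; group summaries exclude flagged trees by default
(`exclude_buffer`) while still letting them serve as neighbours of
interior trees. An `include` policy is available since field studies do
not always state their choice. No toroidal wrapping is applied.

## Diversity and size

`H′ = −Σ pᵢ ln pᵢ` uses natural logarithms throughout, making
`E_H = H′/ln S` exactly; `E_H` is undefined (NaN, excluded from
summaries) for single-species groups rather than forced to 0 or 1.
Site-type membership of a stem follows its containing quadrat by
default, with a point-in-substrate alternative exposed, matching the
two area conventions above. Basal area is `π (DBH/200)²` m² per stem;
per-quadrat "BA" is the mean per-tree basal area, with total BA per
quadrat also emitted.

## Statistical comparisons

Rock-vs-soil differences in quadrat-level metrics use the
Kruskal–Wallis rank test (tie-corrected H, chi-square p). The fully
degenerate case — every observation identical — is defined as H = 0,
p = 1. Distributions of the quantized structure indices are compared
with the two-sample Kolmogorov–Smirnov test using the asymptotic
p-value; on heavily tied quarter-quantized data D remains exact while
the p-value is approximate (conservative), which is documented rather
than corrected. Trends of metrics against topographic attributes are
ordinary least-squares fits per site type; aspect enters in raw degrees
(with the wrap-around caveat; a sine/cosine decomposition can be
applied by the caller on the exported tables), and a constant response
is reported as slope 0, R² = 0 with an undefined p. Significance
bands follow the common figure convention — p ≥ 0.05 non-significant,
0.01 ≤ p < 0.05 significant, p < 0.01 highly significant, boundary
values assigned to the less significant band. No multiple-testing
correction is applied, matching standard practice in single-plot
descriptive studies; the test tables carry raw p-values so users can
adjust. Redundancy analysis and non-metric multidimensional scaling are
out of scope: the package only assembles their aligned input matrices
(per-quadrat responses, six environmental columns — rock area, soil
area, elevation, convexity, aspect, slope — and the species × quadrat
abundance matrix), dropping incomplete quadrats with a log notice.

## Synthetic stand generator

The generator is the canonical test input, since stem-mapped census
data of this kind are typically available only on request. Defaults
describe the reference conditions: 200 × 110 m, 4,596 stems, the
62-species census abundance table (the 22 rare species are expanded to
pseudo-species apportioned 2 × 6 + 1 × 16 = 28 individuals; their life
form is not itemised in the source table and is taken as tree), rock
fraction 0.283, elevation base 1,293 m, slope 25°, dip azimuth 200°.

- **Point patterns.** Poisson (uniform iid), Thomas cluster (parents
  uniform at 0.003 m⁻², isotropic Gaussian offspring with 8 m sd,
  reflected at the window boundary) and hard-core (simple sequential
  inhibition). Cluster and hard-core patterns are conditioned on the
  exact stem count by thinning/topping-up so density-based metrics are
  comparable across patterns; infeasible hard-core packings fail with
  an explicit error naming radius, count and area. All patterns enforce
  a 1 cm minimum separation because neighbour azimuths are undefined at
  zero distance.
- **Marks.** Species iid from the abundance vector, or exact
  largest-remainder apportionment (which reproduces the census integer
  counts when n matches). DBH ~ Weibull(shape 1.2, scale 6 cm by
  default, a realistic right-skewed small-stem census) truncated at
  1 cm by inverse-CDF sampling; height TH = 1.3 + 1.5·DBH^0.6 m with
  optional lognormal noise, calibrated to the census mean-height/
  mean-DBH pairs of the dominant species. An optional multiplier
  shrinks the DBH scale on rock (off by default) to emulate
  substrate-limited growth, and an optional rock-affinity multiplier
  biases stem placement toward or away from rock (default none, since
  association strengths are not part of the reference conditions).
- **Substrate.** Rock cover is a union of smoothed random blobs
  (log-normal radii, low-order Fourier boundary wiggle) whose global
  radius scale is iterated until the clipped rock fraction is within
  0.02 of target (promise: ± 0.03, verified against a 0.1 m
  rasterization oracle).
- **Elevation.** A planar trend — elevation falls at tan(slope) along
  the dip azimuth — plus smooth correlated relief built from eight
  random long-wavelength (20–80 m) cosines scaled to the requested
  standard deviation (default 2 m). With zero noise the field is
  exactly planar, giving sharp identities: convexity ≡ 0, slope ≡ dip
  angle, aspect ≡ dip azimuth.
- **Reproducibility.** One master seed spawns independent sub-streams
  (points, marks, substrate, elevation), so components regenerate
  independently and serialized outputs are byte-identical across runs.

**What the generator does not emulate.** Real stands couple species
identity, size and location through competition, dispersal and habitat
filtering; the generator's marks are independent of location unless the
rock-bias options are enabled. Real karst microtopography is rougher
than a cosine relief; deadwood, snags and temporal dynamics are absent.
Passing tests therefore demonstrate the correctness of the *measures*
and the pipeline on data with known truth — not ecological conclusions
about any real forest.

## Numerical and interface choices

CSV output uses 9 significant digits for reproducible diffs; each table
carries a `# provenance:` comment line (config hash + seed) that pandas
readers skip, with a `run_info.json` sidecar per pipeline run. GeoJSON
coordinates are written in the plot-local metric frame (explicitly
non-geographic) rounded to 1 µm for byte-stable output. The CLI is a
thin layer over the library; its stage subcommands run the shared
pipeline (stages are interdependent and cheap) and report the tables
relevant to that stage.

## Problem sizes used in the shipped checks

The test suite and the reproduction script are sized to run on a single
CPU in well under their nominal budgets: CSR reference bands use 20
replicates of 2,000 stems; pattern-ordering checks 20 replicates per
process; distributional recovery checks 10⁵ draws; raster-oracle
equivalence 5 random substrate scenarios at 0.1 m resolution plus the
full-plot scenario; the Monte-Carlo mingling null 99 relabellings of
600 stems; the Kruskal–Wallis oracle enumerates all 252 5/5 splits of
a 10-point dataset.

## Known limitations

- The asymptotic KS p-value on quantized indices is conservative; an
  exact or permutation variant is not provided.
- Aspect regressions on raw degrees are discontinuous at north;
  interpret slopes near the wrap with care.
- The hard-core generator is sequential inhibition, not an equilibrium
  Gibbs process; very dense packings approach jamming slowly and may
  error out.
- Rock blobs are star-shaped around their seed; extremely elongated or
  perforated outcrops are not represented.
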