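"""Synthetic stand generator.

Builds complete, self-consistent study scenarios — a stem map, a rock
outcrop map and an elevation field — with the statistical structure a
karst stand analysis assumes: a chosen spatial point process (complete
spatial randomness, Thomas cluster, or hard-core inhibition), a skewed
species abundance distribution, Weibull diameters with an allometric
height model, blob-shaped rock cover at a target fraction, and a planar
terrain trend with smooth correlated relief.

One master seed drives independent sub-streams for points, marks,
substrate and elevation, so each component can be regenerated on its
own and every output is bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .config import StandConfig
from .terrain import QuadratGrid, SubstrateMap, build_quadrat_grid

MIN_SEPARATION = 0.01  # m; neighbour azimuths are undefined at zero distance


class SimulationError(RuntimeError):
    pass


@dataclass
class SyntheticScenario:
    stems: pd.DataFrame
    substrate: SubstrateMap
    elevations: pd.DataFrame
    config: StandConfig


# ---------------------------------------------------------------------------
# Point patterns


def _enforce_separation(pts: np.ndarray, min_sep: float = MIN_SEPARATION) -> np.ndarray:
    """Greedily drop points closer than min_sep to an earlier point."""
    if len(pts) < 2:
        return pts
    tree = cKDTree(pts)
    pairs = tree.query_pairs(min_sep, output_type="ndarray")
    if len(pairs) == 0:
        return pts
    drop = set(pairs[:, 1].tolist())
    keep = [i for i in range(len(pts)) if i not in drop]
    return pts[keep]


def _reflect(v: np.ndarray, hi: float) -> np.ndarray:
    """Reflect coordinates into [0, hi] (billiard boundary)."""
    v = np.mod(v, 2 * hi)
    return np.where(v > hi, 2 * hi - v, v)


def _poisson(n: int, w: float, h: float, rng: np.random.Generator) -> np.ndarray:
    pts = np.empty((0, 2))
    while len(pts) < n:
        extra = rng.uniform([0, 0], [w, h], size=(n - len(pts), 2))
        pts = _enforce_separation(np.vstack([pts, extra]))
    return pts[:n]


def _thomas(
    n: int, w: float, h: float, params: dict, rng: np.random.Generator
) -> np.ndarray:
    intensity = params.get("parent_intensity", 0.003)
    sd = params.get("cluster_sd", 8.0)
    if intensity <= 0 or sd <= 0:
        raise SimulationError("thomas_cluster needs positive parent_intensity and cluster_sd")
    n_parents = max(1, rng.poisson(intensity * w * h))
    parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = n - len(pts)
        idx = rng.integers(0, n_parents, size=m)
        off = parents[idx] + rng.normal(0.0, sd, size=(m, 2))
        off[:, 0] = _reflect(off[:, 0], w)
        off[:, 1] = _reflect(off[:, 1], h)
        pts = _enforce_separation(np.vstack([pts, off]))
    return pts[:n]


def _hardcore(
    n: int, w: float, h: float, params: dict, rng: np.random.Generator
) -> np.ndarray:
    r = params.get("radius")
    if r is None or r <= 0:
        raise SimulationError("hardcore pattern needs a positive 'radius'")
    accepted = np.empty((n, 2))
    count = 0
    max_attempts = 500 * n
    attempts = 0
    while count < n:
        if attempts >= max_attempts:
            raise SimulationError(
                f"could not place {n} points with hard-core radius {r} m in a "
                f"{w} x {h} m window ({w * h:g} m^2) after {max_attempts} attempts"
            )
        m = min(256, n - count)
        props = rng.uniform([0, 0], [w, h], size=(m, 2))
        attempts += m
        for p in props:
            if count:
                d2 = np.sum((accepted[:count] - p) ** 2, axis=1)
                if d2.min() < r * r:
                    continue
            accepted[count] = p
            count += 1
            if count == n:
                break
    return accepted


def generate_point_pattern(
    config: StandConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Stem locations as an (n, 2) array under the configured process.

    All patterns enforce a 1 cm minimum pairwise separation, and the
    cluster and hard-core processes are conditioned on the exact stem
    count so density-based metrics stay comparable across patterns.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    n, w, h = config.n_stems, config.plot_width, config.plot_height
    if n < 5:
        raise SimulationError("n_stems must be >= 5")
    if config.pattern == "poisson":
        return _poisson(n, w, h, rng)
    if config.pattern == "thomas_cluster":
        return _thomas(n, w, h, config.pattern_params, rng)
    if config.pattern == "hardcore":
        return _hardcore(n, w, h, config.pattern_params, rng)
    raise SimulationError(f"unknown pattern {config.pattern!r}")


# ---------------------------------------------------------------------------
# Marks: species, DBH, height, life form


def largest_remainder_counts(n: int, p: np.ndarray) -> np.ndarray:
    """Apportion n individuals to classes proportional to p, exactly."""
    quota = n * np.asarray(p, dtype=float)
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _truncated_weibull(
    shape: float, scale: np.ndarray, n: int, rng: np.random.Generator, lo: float = 1.0
) -> np.ndarray:
    """Weibull(shape, scale) conditioned on X >= lo, by inverse CDF."""
    f_lo = 1.0 - np.exp(-((lo / scale) ** shape))
    u = rng.uniform(f_lo, 1.0, size=n)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def assign_species_and_sizes(
    points: np.ndarray,
    config: StandConfig,
    rng: np.random.Generator | None = None,
    substrate: SubstrateMap | None = None,
) -> pd.DataFrame:
    """Attach species, DBH, height and life form to stem locations.

    Species are sampled iid from the abundance vector, or apportioned
    exactly (largest-remainder) when ``exact_counts`` is set. DBH is
    Weibull, truncated at the 1 cm census threshold; when a substrate
    map is supplied the Weibull scale of stems rooted on rock is
    multiplied by ``rock_dbh_factor``. Height follows
    TH = 1.3 + a * DBH**b with optional lognormal noise.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    names, p = config.abundance_vector()
    if len(names) == 0:
        raise SimulationError("species abundance vector is empty")
    n = len(points)
    if config.exact_counts:
        counts = largest_remainder_counts(n, p)
        labels = np.repeat(np.array(names, dtype=object), counts)
        rng.shuffle(labels)
    else:
        labels = rng.choice(np.array(names, dtype=object), size=n, p=p)

    shape, scale = config.dbh_weibull
    scales = np.full(n, float(scale))
    if substrate is not None and config.rock_dbh_factor != 1.0 and len(substrate):
        on_rock = shapely.contains_xy(substrate.union, points[:, 0], points[:, 1])
        scales[on_rock] *= config.rock_dbh_factor
    dbh = _truncated_weibull(shape, scales, n, rng)

    a, b = config.height_allometry
    th = 1.3 + a * dbh**b
    if config.height_noise_sd > 0:
        th = 1.3 + (th - 1.3) * np.exp(rng.normal(0.0, config.height_noise_sd, size=n))

    lf_map = config.lifeforms()
    lifeform = np.array([lf_map.get(s, "tree") for s in labels], dtype=object)
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x": points[:, 0],
            "y": points[:, 1],
            "species": labels,
            "dbh_cm": dbh,
            "th_m": th,
            "lifeform": lifeform,
        }
    )


# ---------------------------------------------------------------------------
# Substrate


def _blob(center, radius, wiggle, n_vertices: int = 36) -> Polygon:
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    eps = np.zeros_like(theta)
    for m, (am, bm) in enumerate(wiggle, start=1):
        eps += am * np.cos(m * theta) + bm * np.sin(m * theta)
    r = radius * np.exp(eps)
    pts = np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def generate_substrate(
    config: StandConfig, rng: np.random.Generator | None = None
) -> SubstrateMap:
    """Rock cover as a union of smoothed random blobs at a target fraction.

    Blob shapes are drawn once; a global radius scale is then iterated
    until the achieved rock fraction (union clipped to the plot) is
    within 0.02 of the target, comfortably inside the promised 0.03.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    target = config.rock_target_fraction
    if not 0.0 <= target < 0.95 + 1e-12:
        raise SimulationError("rock_target_fraction must lie in [0, 0.95]")
    w, h = config.plot_width, config.plot_height
    if target == 0.0:
        return SubstrateMap([], w, h)
    n_seeds, mean_radius = config.rock_blob_params
    centers = rng.uniform([0, 0], [w, h], size=(int(n_seeds), 2))
    radii = mean_radius * rng.lognormal(0.0, 0.35, size=int(n_seeds))
    wiggles = [
        [(rng.normal(0, 0.15), rng.normal(0, 0.15)) for _ in range(3)]
        for _ in range(int(n_seeds))
    ]
    scale = 1.0
    substrate = None
    for _ in range(80):
        polys = [
            _blob(c, r * scale, wg) for c, r, wg in zip(centers, radii, wiggles)
        ]
        substrate = SubstrateMap(polys, w, h)
        achieved = substrate.rock_fraction
        if abs(achieved - target) <= 0.02:
            return substrate
        if achieved <= 1e-6:
            scale *= 2.0
        else:
            scale *= (target / achieved) ** 0.5
    raise SimulationError(
        f"substrate generator failed to reach rock fraction {target:g} "
        f"(achieved {substrate.rock_fraction:.3f})"
    )


# ---------------------------------------------------------------------------
# Elevation


class _CosineRelief:
    """Smooth correlated noise: a sum of random long-wavelength cosines."""

    def __init__(self, sd: float, rng: np.random.Generator, k: int = 8):
        self.sd = sd
        self.k = k
        wavelengths = rng.uniform(20.0, 80.0, size=k)
        theta = rng.uniform(0.0, 2.0 * math.pi, size=k)
        self.freq = np.column_stack(
            [np.cos(theta) / wavelengths, np.sin(theta) / wavelengths]
        )
        self.phase = rng.uniform(0.0, 2.0 * math.pi, size=k)
        self.amp = sd * math.sqrt(2.0 / k)

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(np.broadcast(x, y).shape)
        for i in range(self.k):
            z += self.amp * np.cos(
                2.0 * math.pi * (self.freq[i, 0] * x + self.freq[i, 1] * y)
                + self.phase[i]
            )
        return z


def generate_elevation_field(
    config: StandConfig,
    grid: QuadratGrid | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Elevations at every quadrat vertex and centre.

    The field is a planar trend — elevation falls at tan(slope) along
    the dip azimuth — plus smooth correlated relief of the configured
    standard deviation. With zero noise the field is exactly planar, so
    every quadrat recovers the trend slope and azimuth and has zero
    convexity.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    if grid is None:
        grid = build_quadrat_grid(config.plot_width, config.plot_height, 10.0)
    base, slope_deg, dip_az = config.elevation_trend
    u = np.array([math.sin(math.radians(dip_az)), math.cos(math.radians(dip_az))])
    tan_s = math.tan(math.radians(slope_deg))
    noise = (
        _CosineRelief(config.elevation_noise_sd, rng)
        if config.elevation_noise_sd > 0
        else (lambda x, y: np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape))
    )

    def z(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return base - tan_s * (x * u[0] + y * u[1]) + noise(x, y)

    s = grid.cell_size
    rows = []
    for j in range(grid.nrows + 1):
        for i in range(grid.ncols + 1):
            rows.append(("vertex", i, j, i * s, j * s))
    for j in range(grid.nrows):
        for i in range(grid.ncols):
            rows.append(("center", i, j, (i + 0.5) * s, (j + 0.5) * s))
    df = pd.DataFrame(rows, columns=["kind", "i", "j", "x", "y"])
    df["z"] = z(df["x"].to_numpy(), df["y"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Whole scenarios


def generate_scenario(config: StandConfig) -> SyntheticScenario:
    """Generate a full stand scenario (stems, substrate, elevations).

    Sub-streams for points, marks, substrate and elevation are spawned
    independently from the master seed. An optional rock-affinity
    multiplier biases stem retention toward (or away from) rock by
    thinning and topping up the point pattern.
    """
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    substrate = generate_substrate(config, streams[2])
    points = generate_point_pattern(config, streams[0])
    if config.rock_affinity != 1.0 and len(substrate):
        points = _apply_rock_affinity(points, config, substrate, streams[0])
    stems = assign_species_and_sizes(points, config, streams[1], substrate=substrate)
    grid = build_quadrat_grid(config.plot_width, config.plot_height, 10.0)
    elevations = generate_elevation_field(config, grid, streams[3])
    _check_scenario(stems, config)
    return SyntheticScenario(stems, substrate, elevations, config)


def _apply_rock_affinity(
    points: np.ndarray,
    config: StandConfig,
    substrate: SubstrateMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thin stems against the disfavoured substrate, topping up to n."""
    a = config.rock_affinity
    kept = points
    for _ in range(200):
        on_rock = shapely.contains_xy(substrate.union, kept[:, 0], kept[:, 1])
        w = np.where(on_rock, min(a, 1.0), min(1.0 / a, 1.0))
        keep = rng.uniform(size=len(kept)) < w
        kept = kept[keep]
        if len(kept) >= config.n_stems:
            return kept[: config.n_stems]
        extra = generate_point_pattern(config, rng)
        kept = _enforce_separation(np.vstack([kept, extra]))
    raise SimulationError("rock-affinity thinning failed to reach n_stems")


def _check_scenario(stems: pd.DataFrame, config: StandConfig) -> None:
    x, y = stems["x"].to_numpy(), stems["y"].to_numpy()
    if len(stems) != config.n_stems:
        raise SimulationError("scenario stem count differs from n_stems")
    if (
        (x < 0).any()
        or (x > config.plot_width).any()
        or (y < 0).any()
        or (y > config.plot_height).any()
    ):
        raise SimulationError("stem outside the plot rectangle")
    tree = cKDTree(np.column_stack([x, y]))
    if len(tree.query_pairs(MIN_SEPARATION)) > 0:
        raise SimulationError("coincident stem coordinates")
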