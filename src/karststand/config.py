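"""Configuration objects for synthetic stands and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import species as census


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class StandConfig:
    """Parameters of a synthetic karst stand.

    The defaults describe a plot like the old-growth oak forest the
    package was written around: a 200 x 110 m rectangle holding 4,596
    stems of 62 species with census abundances, ~28% exposed rock, a
    mean elevation near 1,293 m and a mean slope of 25 degrees dipping
    roughly south-southwest.

    Parameters
    ----------
    plot_width, plot_height : float
        Plot dimensions in metres.
    n_stems : int
        Number of stems to place (>= 5).
    pattern : {"poisson", "thomas_cluster", "hardcore"}
        Point process for stem locations. ``poisson`` is complete
        spatial randomness; ``thomas_cluster`` scatters offspring
        isotropically around uniform parents; ``hardcore`` is simple
        sequential inhibition with a minimum pairwise distance.
    pattern_params : dict
        ``thomas_cluster``: ``parent_intensity`` (parents/m^2) and
        ``cluster_sd`` (m). ``hardcore``: ``radius`` (m).
    species_abundances : "census" or sequence of float
        Relative abundances; the string preset uses the census table.
    species_names : list of str, optional
        Labels matching ``species_abundances`` when given as a vector.
    lifeform_of_species : dict, optional
        Species label -> {"tree", "shrub"}; defaults to "tree".
    exact_counts : bool
        Draw species by largest-remainder apportionment of n * p
        instead of iid sampling.
    dbh_weibull : (shape, scale)
        DBH distribution in cm, truncated below 1 cm (census threshold).
    height_allometry : (a, b)
        TH = 1.3 + a * DBH**b metres.
    height_noise_sd : float
        Lognormal sigma multiplying the allometric height above breast
        height; 0 disables noise.
    rock_target_fraction : float in [0, 0.95]
        Proportion of the plot covered by rock outcrop.
    rock_blob_params : (n_seeds, mean_radius_m)
        Number and size of the random rock blobs.
    rock_dbh_factor : float
        Multiplier on the DBH Weibull scale for stems rooted on rock
        (1.0 = no substrate effect).
    rock_affinity : float
        Optional multiplier on the retention probability of stems
        falling on rock (1.0 = no species-substrate association).
    elevation_trend : (base_m, slope_deg, dip_azimuth_deg)
        Planar terrain trend: elevation decreases at tan(slope) along
        the dip azimuth (degrees clockwise from north).
    elevation_noise_sd : float
        Standard deviation (m) of the smooth correlated relief added to
        the planar trend.
    seed : int
        Master seed; independent sub-streams are spawned for points,
        marks, substrate and elevation.
    """

    plot_width: float = 200.0
    plot_height: float = 110.0
    n_stems: int = 4596
    pattern: str = "thomas_cluster"
    pattern_params: dict = field(
        default_factory=lambda: {"parent_intensity": 0.003, "cluster_sd": 8.0}
    )
    species_abundances: object = "census"
    species_names: Optional[Sequence[str]] = None
    lifeform_of_species: Optional[dict] = None
    exact_counts: bool = False
    dbh_weibull: tuple = (1.2, 6.0)
    height_allometry: tuple = (1.5, 0.6)
    height_noise_sd: float = 0.0
    rock_target_fraction: float = 0.283
    rock_blob_params: tuple = (25, 12.0)
    rock_dbh_factor: float = 1.0
    rock_affinity: float = 1.0
    elevation_trend: tuple = (1293.0, 25.0, 200.0)
    elevation_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived accessors -------------------------------------------------

    def abundance_vector(self) -> tuple[list[str], np.ndarray]:
        """Species labels and relative abundances (sums to 1)."""
        if isinstance(self.species_abundances, str):
            if self.species_abundances != "census":
                raise ConfigError(
                    f"unknown abundance preset {self.species_abundances!r}"
                )
            names, counts = census.census_abundances()
            p = counts / counts.sum()
            return names, p
        p = np.asarray(self.species_abundances, dtype=float)
        if self.species_names is not None:
            names = list(self.species_names)
        else:
            names = [f"S{i + 1:02d}" for i in range(p.size)]
        return names, p

    def lifeforms(self) -> dict[str, str]:
        if isinstance(self.species_abundances, str):
            lf = census.census_lifeforms()
        else:
            lf = {}
        if self.lifeform_of_species:
            lf = {**lf, **self.lifeform_of_species}
        return lf

    @property
    def plot_area(self) -> float:
        return self.plot_width * self.plot_height

    def validate(self) -> None:
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ConfigError("plot dimensions must be positive")
        if self.n_stems < 5:
            raise ConfigError("n_stems must be >= 5")
        if self.pattern not in {"poisson", "thomas_cluster", "hardcore"}:
            raise ConfigError(f"unknown pattern {self.pattern!r}")
        names, p = self.abundance_vector()
        if p.size == 0:
            raise ConfigError("species abundance vector is empty")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("abundances must be >= 0 and sum to 1 (1e-9)")
        if len(names) != p.size:
            raise ConfigError("species_names length does not match abundances")
        if not (0.0 <= self.rock_target_fraction <= 0.95):
            raise ConfigError("rock_target_fraction must lie in [0, 0.95]")
        shape, scale = self.dbh_weibull
        if shape <= 0 or scale <= 0:
            raise ConfigError("dbh_weibull shape and scale must be positive")
        if self.elevation_noise_sd < 0:
            raise ConfigError("elevation_noise_sd must be >= 0")
        if self.rock_affinity <= 0 or self.rock_dbh_factor <= 0:
            raise ConfigError("rock multipliers must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["species_abundances"], str):
            d["species_abundances"] = list(np.asarray(d["species_abundances"], float))
        return d


def yachang_like(seed: int = 0, **overrides) -> StandConfig:
    """The default preset: census abundances on a 200 x 110 m karst slope."""
    return StandConfig(seed=seed, exact_counts=True, **overrides)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Either the three input paths (stems, substrate, elevations) or a
    ``simulate`` block (StandConfig fields) must be present.
    """

    stems_path: Optional[str] = None
    substrate_path: Optional[str] = None
    elevations_path: Optional[str] = None
    simulate: Optional[dict] = None
    plot_width: float = 200.0
    plot_height: float = 110.0
    cell_size: float = 10.0
    rock_threshold: float = 0.5
    buffer_m: float = 5.0
    alpha0: float = 72.0
    edge_policy: str = "exclude_buffer"
    site_convention: str = "quadrat"
    seed: int = 0
    out_dir: str = "karststand_out"

    def validate(self) -> None:
        has_paths = self.stems_path is not None
        if not has_paths and self.simulate is None:
            raise ConfigError(
                "config needs either input paths (stems/substrate/elevations) "
                "or a simulate block"
            )
        if self.cell_size <= 0:
            raise ConfigError("cell_size must be positive")
        if self.edge_policy not in {"include", "exclude_buffer"}:
            raise ConfigError(f"unknown edge_policy {self.edge_policy!r}")
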