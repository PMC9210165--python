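"""Census species table for the old-growth oak forest preset.

The preset describes a 2.2 ha karst plot holding 4,596 live stems of 62
woody species with a strongly right-skewed abundance distribution: the
40 taxa listed individually below plus 22 rare species (abundance at or
below one stem per hectare) that together contribute 28 individuals.
Each entry carries the species abbreviation, abundance, mean tree height
(m), mean DBH (cm) and life form.
"""

from __future__ import annotations

import numpy as np

# (abbreviation, abundance, mean TH m, mean DBH cm, life form)
CENSUS_SPECIES: list[tuple[str, int, float, float, str]] = [
    ("PS", 1369, 4.50, 2.94, "tree"),
    ("LOV", 832, 3.29, 2.14, "shrub"),
    ("QF", 698, 14.72, 24.83, "tree"),
    ("QV", 638, 6.85, 8.48, "tree"),
    ("RC", 203, 5.04, 3.53, "shrub"),
    ("CMV", 140, 4.10, 2.23, "shrub"),
    ("KD", 139, 5.99, 7.34, "tree"),
    ("TG", 126, 4.19, 3.33, "tree"),
    ("CS", 66, 4.28, 3.96, "tree"),
    ("VM", 53, 2.81, 2.21, "tree"),
    ("BA", 42, 5.85, 4.50, "tree"),
    ("MR", 30, 4.44, 5.59, "shrub"),
    ("AK", 23, 3.97, 2.69, "shrub"),
    ("LV", 21, 3.01, 1.79, "shrub"),
    ("PL", 18, 3.91, 2.35, "tree"),
    ("AA", 17, 11.80, 12.01, "tree"),
    ("LF", 15, 9.12, 7.87, "tree"),
    ("LP", 14, 5.14, 5.12, "tree"),
    ("CA", 13, 5.73, 3.86, "tree"),
    ("MF", 11, 2.84, 1.78, "shrub"),
    ("BK", 10, 4.45, 3.23, "shrub"),
    ("PT", 6, 4.03, 3.89, "shrub"),
    ("LN", 6, 5.52, 4.09, "shrub"),
    ("PY", 5, 9.24, 19.69, "tree"),
    ("CN", 5, 4.20, 4.59, "shrub"),
    ("KS", 5, 8.58, 9.83, "tree"),
    ("GP", 5, 5.14, 2.68, "shrub"),
    ("CM", 5, 5.20, 4.85, "shrub"),
    ("FI", 5, 4.26, 2.21, "tree"),
    ("LO", 4, 2.28, 2.01, "shrub"),
    ("CR", 4, 4.70, 4.53, "shrub"),
    ("CC", 3, 6.80, 6.53, "tree"),
    ("CG", 3, 4.30, 2.56, "tree"),
    ("EJ", 3, 2.27, 1.21, "tree"),
    ("IF", 3, 2.83, 1.53, "tree"),
    ("CP", 3, 3.77, 1.95, "tree"),
    ("AD", 3, 4.83, 3.00, "tree"),
    ("IM", 9, 5.37, 3.38, "shrub"),
    ("H", 7, 7.39, 6.91, "tree"),
    ("SR", 6, 10.18, 5.77, "tree"),
]

# 22 rare species pooled in the census to 28 individuals (mean TH 5.8 m,
# mean DBH 5.1 cm, life form not itemised -> treated as trees). The 28
# stems are apportioned 2 each to the first six pseudo-species and 1 each
# to the remaining sixteen.
N_RARE_SPECIES = 22
N_RARE_INDIVIDUALS = 28

RARE_SPECIES: list[tuple[str, int, float, float, str]] = [
    (f"R{i + 1:02d}", 2 if i < 6 else 1, 5.8, 5.1, "tree")
    for i in range(N_RARE_SPECIES)
]


def census_table() -> list[tuple[str, int, float, float, str]]:
    """Full species list: the 40 itemised taxa plus the 22 rare species."""
    return CENSUS_SPECIES + RARE_SPECIES


def census_abundances() -> tuple[list[str], np.ndarray]:
    """Species labels and integer abundances of the census preset."""
    table = census_table()
    names = [row[0] for row in table]
    counts = np.array([row[1] for row in table], dtype=int)
    return names, counts


def census_lifeforms() -> dict[str, str]:
    return {row[0]: row[4] for row in census_table()}


def census_total() -> int:
    """Total number of live stems in the census preset."""
    _, counts = census_abundances()
    return int(counts.sum())


def census_richness() -> int:
    """Number of woody species in the census preset."""
    return len(census_table())
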