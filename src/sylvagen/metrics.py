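"""Evolutionary-rate and dendrometric summary statistics."""

from __future__ import annotations

import numpy as np


def evolutionary_rate_H0(mean_start: float, mean_end: float,
                         var_start: float, var_end: float,
                         n_gen: int) -> float:
    """Average evolutionary rate in haldanes.

    Absolute change of the trait mean between the start and the end of the
    interval, divided by the pooled within-population phenotypic standard
    deviation (square root of the mean of the two variances) and by the
    number of generations elapsed.
    """
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    pooled = 0.5 * (var_start + var_end)
    if pooled <= 0:
        raise ValueError("pooled phenotypic variance must be positive")
    return abs(mean_end - mean_start) / np.sqrt(pooled) / n_gen


def quadratic_mean_diameter(dbh: np.ndarray) -> float:
    """Diameter of the tree of mean squared diameter (cm)."""
    dbh = np.asarray(dbh, dtype=np.float64)
    if dbh.size == 0:
        raise ValueError("no alive trees")
    return float(np.sqrt(np.mean(dbh ** 2)))


def selection_differential(seed_tree_mean: float,
                           cycle_start_mean: float) -> float:
    """Genetic mean of the seed trees minus that of the cycle-start
    population (cm/yr)."""
    return seed_tree_mean - cycle_start_mean


def cumulative_production(standing_volume_m3: float,
                          dead_removed_volume_m3: float,
                          area_ha: float) -> float:
    """Cumulative timber volume produced per hectare within a cycle:
    standing volume plus the volume of trees that died or were removed
    since the cycle start."""
    return (standing_volume_m3 + dead_removed_volume_m3) / area_ha
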