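"""Mortality processes: selective self-thinning and random disturbance.

Self-thinning is density-dependent soft selection: whenever a pixel's
relative density index (stems per hectare over the Reineke maximum density
for the current mean tree size) exceeds its ceiling, the smallest trees die
one by one until the pixel drops back below the ceiling.  Disturbance is a
stand-level stochastic mortality rate, locally damped in pixels with little
cumulated crown height, that kills trees irrespective of size or genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SelfThinningParams:
    """Reineke-type maximum density line Nmax(Cg) = k * Cg^(-b) (stems/ha,
    Cg the quadratic mean circumference in cm) and the RDI ceiling."""

    k: float = 1.26e6
    b: float = 1.6
    rdi_max: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.b <= 0 or not 0 < self.rdi_max <= 1:
            raise ValueError("invalid self-thinning parameters")

    def nmax(self, cg_cm):
        return self.k * np.asarray(cg_cm, dtype=np.float64) ** (-self.b)

    def rdi(self, n_ha, cg_cm):
        n_ha = np.asarray(n_ha, dtype=np.float64)
        return np.where(n_ha > 0, n_ha / self.nmax(np.maximum(cg_cm, 1e-12)),
                        0.0)


def self_thinning(dbh: np.ndarray, tree_ids: np.ndarray,
                  pixel_area_ha: float, params: SelfThinningParams
                  ) -> np.ndarray:
    """Tree ids removed from one pixel by self-thinning.

    Implements the sequential rule "remove the smallest tree, recompute Cg
    and RDI, repeat while RDI > RDImax" in closed form: after removing the
    j smallest trees the remaining count and sum of squared circumferences
    are prefix sums, so the stopping index is the first j whose RDI falls
    below the ceiling.  Ties in dbh are broken by tree id.
    """
    dbh = np.asarray(dbh, dtype=np.float64)
    tree_ids = np.asarray(tree_ids)
    n = dbh.size
    if n == 0:
        return tree_ids[:0]
    order = np.lexsort((tree_ids, dbh))
    c2 = (np.pi * dbh[order]) ** 2
    total = c2.sum()
    j = np.arange(n)                       # number of trees already removed
    n_left = n - j
    s2_left = total - np.concatenate([[0.0], np.cumsum(c2)[:-1]])
    cg_left = np.sqrt(s2_left / n_left)
    rdi = (n_left / pixel_area_ha) / params.nmax(np.maximum(cg_left, 1e-12))
    ok = rdi <= params.rdi_max
    stop = int(np.argmax(ok)) if ok.any() else n - 1
    return tree_ids[order[:stop]]


@dataclass
class DisturbanceRegime:
    """Annual potential stand mortality-rate distribution.

    ``none`` draws 0; ``medium`` draws one Weibull clipped to [0, 1] with a
    long-run mean around 2%/yr; ``severe`` is a two-component Weibull
    mixture of frequent low-mortality events and five-times rarer
    high-mortality events with a long-run mean around 12%/yr.  The crown
    modifier exponent controls the local damping of the potential rate.
    """

    kind: str = "none"
    medium_shape: float = 1.5
    medium_scale: float = 0.0222
    severe_low_shape: float = 1.5
    severe_low_scale: float = 0.0443
    severe_high_shape: float = 3.0
    severe_high_scale: float = 0.582
    high_event_odds: float = 5.0   # low events are this many times more frequent
    crown_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "medium", "severe"):
            raise ValueError(f"unknown disturbance kind {self.kind!r}")


def draw_potential_mortality_rate(regime: DisturbanceRegime,
                                  rng: np.random.Generator) -> float:
    """One annual whole-stand potential mortality rate in [0, 1]."""
    if regime.kind == "none":
        return 0.0
    if regime.kind == "medium":
        rate = regime.medium_scale * rng.weibull(regime.medium_shape)
    else:
        p_low = regime.high_event_odds / (regime.high_event_odds + 1.0)
        if rng.random() < p_low:
            rate = regime.severe_low_scale * rng.weibull(regime.severe_low_shape)
        else:
            rate = regime.severe_high_scale * rng.weibull(regime.severe_high_shape)
    return float(np.clip(rate, 0.0, 1.0))


def disturbance_death_mask(pixel_of_tree: np.ndarray,
                           crown_height: np.ndarray, n_pixels: int,
                           potential_rate: float,
                           regime: DisturbanceRegime,
                           rng: np.random.Generator) -> np.ndarray:
    """Bernoulli death mask for the alive trees passed in.

    The per-pixel effective rate is the potential rate scaled by
    (S_p / S_ref)^theta where S_p is the summed crown height of the pixel's
    trees and S_ref the maximum S_p across pixels this year, capped at the
    potential rate, so a fully stocked pixel feels the full potential rate
    and sparse pixels are damped.  Death is independent of size and
    genotype within a pixel.
    """
    if not 0.0 <= potential_rate <= 1.0:
        raise ValueError("potential rate must lie in [0, 1]")
    if potential_rate == 0.0 or pixel_of_tree.size == 0:
        return np.zeros(pixel_of_tree.size, dtype=bool)
    s_p = np.bincount(pixel_of_tree, weights=crown_height, minlength=n_pixels)
    s_ref = s_p.max()
    if s_ref <= 0:
        eff = np.full(n_pixels, potential_rate)
    else:
        eff = potential_rate * np.minimum(
            (s_p / s_ref) ** regime.crown_exponent, 1.0)
    return rng.random(pixel_of_tree.size) < eff[pixel_of_tree]
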