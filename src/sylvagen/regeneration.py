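"""Regeneration: fecundity, dispersal to pixel centers, mating, seedlings.

Seeds and pollen grains are not simulated individually.  Each regeneration
year, every pixel receives an expected seed-rain density at its center from
all fertile mothers (female fecundity times a fat-tailed dispersal kernel
evaluated at the mother-to-center distance).  The number of seedlings
established in the pixel is proportional to that density over one square
meter; each seedling draws its mother proportionally to her contribution
and its father among all fertile trees proportionally to male fertility
(dbh squared), selfing allowed.  Genotypes are built from one recombinant
gamete per parent, so every pedigree is exactly replayable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma as gamma_fn
from typing import Tuple

import numpy as np

from . import genetics


@dataclass
class FecundityParams:
    """Ordinal cone-production model and seed scaling.

    Cone production is an ordinal class (0..4) from a latent score linear in
    dbh and crown height plus a lifetime tree effect (inter-individual) and
    an annual draw (inter-annual), both Normal.  Classes map to midpoint
    cone counts; viable seeds are cones times ``seeds_per_cone``.  A tree is
    fertile only when strictly older than the recruitment age and with dbh
    strictly above the fertility threshold.
    """

    fertility_dbh_cm: float = 15.0
    recruitment_age: int = 25
    latent_intercept: float = 0.0
    latent_dbh_coef: float = 0.25       # per cm above the fertility threshold
    latent_crown_coef: float = 0.05     # per m of crown height
    sd_individual: float = 0.5
    sd_annual: float = 0.5
    class_thresholds: Tuple[float, ...] = (0.5, 1.5, 2.5, 3.5)
    class_cones: Tuple[float, ...] = (0.0, 10.0, 50.0, 200.0, 500.0)
    seeds_per_cone: float = 10.0
    seedling_multiplier: float = 6.0
    selfing_allowed: bool = True

    def __post_init__(self) -> None:
        if self.fertility_dbh_cm <= 0 or self.seeds_per_cone <= 0:
            raise ValueError("invalid fecundity parameters")
        if len(self.class_cones) != len(self.class_thresholds) + 1:
            raise ValueError("need one cone midpoint per ordinal class")


def is_fertile(age, dbh, params: FecundityParams) -> np.ndarray:
    return (np.asarray(age) > params.recruitment_age) & \
           (np.asarray(dbh) > params.fertility_dbh_cm)


def female_fecundity(dbh, crown_height, age, indiv_effect,
                     rng: np.random.Generator, params: FecundityParams
                     ) -> np.ndarray:
    """Viable seed count per tree for one year (0 for non-fertile trees)."""
    dbh = np.atleast_1d(np.asarray(dbh, dtype=np.float64))
    crown = np.broadcast_to(np.asarray(crown_height, dtype=np.float64),
                            dbh.shape)
    age = np.broadcast_to(np.asarray(age), dbh.shape)
    indiv = np.broadcast_to(np.asarray(indiv_effect, dtype=np.float64),
                            dbh.shape)
    latent = (params.latent_intercept
              + params.latent_dbh_coef * (dbh - params.fertility_dbh_cm)
              + params.latent_crown_coef * crown
              + indiv
              + rng.normal(0.0, params.sd_annual, dbh.shape))
    cls = np.searchsorted(np.asarray(params.class_thresholds), latent)
    seeds = np.asarray(params.class_cones)[cls] * params.seeds_per_cone
    return np.where(is_fertile(age, dbh, params), seeds, 0.0)


def male_fertility(dbh, age, params: FecundityParams) -> np.ndarray:
    """Relative pollen-production index: dbh^2, 0 for non-fertile trees."""
    dbh = np.asarray(dbh, dtype=np.float64)
    return np.where(is_fertile(age, dbh, params), dbh ** 2, 0.0)


@dataclass
class DispersalKernel:
    """2D exponential-power seed dispersal kernel.

    f(r) = s / (2 pi a^2 Gamma(2/s)) * exp(-(r/a)^s); with shape s < 1 the
    kernel is fat-tailed.  The scale a is set from the mean dispersal
    distance through mean = a Gamma(3/s) / Gamma(2/s).
    """

    shape: float = 0.5
    mean_distance_m: float = 240.0

    def __post_init__(self) -> None:
        if not 0 < self.shape < 2:
            raise ValueError("kernel shape must lie in (0, 2)")
        if self.mean_distance_m <= 0:
            raise ValueError("mean dispersal distance must be positive")
        s = self.shape
        self.scale = self.mean_distance_m * gamma_fn(2.0 / s) / gamma_fn(3.0 / s)
        self._norm = s / (2.0 * np.pi * self.scale ** 2 * gamma_fn(2.0 / s))

    def density(self, r) -> np.ndarray:
        """Planar density (per m2) at distance r from the source."""
        r = np.asarray(r, dtype=np.float64)
        return self._norm * np.exp(-(r / self.scale) ** self.shape)

    def sample_distances(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Radial distances of dispersed seeds (for diagnostics/tests)."""
        u = rng.gamma(2.0 / self.shape, 1.0, n)
        return self.scale * u ** (1.0 / self.shape)


def seed_rain_contributions(mother_xy: np.ndarray, mother_seeds: np.ndarray,
                            pixel_centers: np.ndarray,
                            kernel: DispersalKernel) -> np.ndarray:
    """(n_mothers, n_pixels) expected seed density (seeds/m2) at each pixel
    center contributed by each mother."""
    mother_xy = np.atleast_2d(mother_xy)
    d = np.hypot(mother_xy[:, 0:1] - pixel_centers[None, :, 0],
                 mother_xy[:, 1:2] - pixel_centers[None, :, 1])
    return np.asarray(mother_seeds, dtype=np.float64)[:, None] * kernel.density(d)


def sample_seedling_parents(contrib: np.ndarray, n_per_pixel: np.ndarray,
                            father_weights: np.ndarray,
                            rng: np.random.Generator):
    """Draw (pixel, mother, father) index triples for new seedlings.

    ``contrib`` is the mothers-by-pixels contribution matrix; mothers are
    drawn per pixel proportionally to their contribution, fathers stand-wide
    proportionally to ``father_weights``.  Returns (pixel_idx, mother_idx,
    father_idx) arrays over all seedlings (mother/father indices refer to
    the rows of ``contrib`` / entries of ``father_weights``).
    """
    n_total = int(n_per_pixel.sum())
    pixel_idx = np.repeat(np.arange(n_per_pixel.size), n_per_pixel)
    mother_idx = np.empty(n_total, dtype=np.int64)
    pos = 0
    for p in np.nonzero(n_per_pixel)[0]:
        w = contrib[:, p]
        tot = w.sum()
        k = int(n_per_pixel[p])
        if tot <= 0:
            raise ValueError("pixel received seedlings with no seed rain")
        mother_idx[pos:pos + k] = rng.choice(w.size, size=k, p=w / tot)
        pos += k
    fw = np.asarray(father_weights, dtype=np.float64)
    if fw.sum() <= 0:
        raise ValueError("no fertile father available")
    father_idx = rng.choice(fw.size, size=n_total, p=fw / fw.sum())
    return pixel_idx, mother_idx, father_idx


def offspring_genotypes(mother_geno: np.ndarray, father_geno: np.ndarray,
                        qmap: genetics.QTLMap, rng: np.random.Generator
                        ) -> np.ndarray:
    """(n, L, 2) seedling genotypes: one recombinant gamete per parent."""
    g_m = genetics.make_gametes(mother_geno, qmap, rng)
    g_f = genetics.make_gametes(father_geno, qmap, rng)
    return np.stack([g_m, g_f], axis=2).astype(np.uint8)
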