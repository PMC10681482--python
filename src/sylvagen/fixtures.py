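"""Deterministic miniature worlds for tests and documentation examples.

These fixtures never read external files; every value is inline and every
stochastic element takes an explicit generator so replays are bit-identical.
They are deliberately unrealistic: their purpose is hand-checkable
arithmetic, not calibration.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core_state import Stand, TreePopulation
from .genetics import GeneticSetup, QTLMap, environmental_variance


def mini_stand(n_pixels_x: int = 2, n_pixels_y: int = 2,
               trees_per_pixel: int = 5,
               dbh_pattern: Sequence[float] = (10.0, 20.0, 30.0, 40.0, 50.0),
               age: int = 30, pixel_size: float = 15.0,
               site_index: float = 20.0):
    """A toy stand with a staircase of diameters repeated in every pixel.

    Trees sit on a regular sub-grid inside each pixel, so positions, pixel
    membership and dendrometrics are all exactly predictable.
    """
    if n_pixels_x < 1 or n_pixels_y < 1 or trees_per_pixel < 1:
        raise ValueError("fixture dimensions must be >= 1")
    stand = Stand(width_m=n_pixels_x * pixel_size,
                  depth_m=n_pixels_y * pixel_size,
                  site_index=site_index, pixel_size=pixel_size)
    pattern = np.resize(np.asarray(dbh_pattern, dtype=float), trees_per_pixel)
    xs, ys, dbhs = [], [], []
    for row in range(n_pixels_y):
        for col in range(n_pixels_x):
            offs = (np.arange(trees_per_pixel) + 0.5) / trees_per_pixel
            xs.append(col * pixel_size + offs * pixel_size)
            ys.append(np.full(trees_per_pixel,
                              (row + 0.5) * pixel_size))
            dbhs.append(pattern)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    pop = TreePopulation(n_loci=0)
    pop.append(x=x, y=y, pixel=stand.pixel_of(x, y), age=age,
               dbh=np.concatenate(dbhs), cohort=1, recruited=True)
    return stand, pop


def two_locus_setup(effects: Sequence[float] = (0.05, 0.03),
                    freqs: Sequence[float] = (0.5, 0.5),
                    h2: float = 0.3,
                    linkage_groups: Sequence[int] = (0, 1),
                    positions: Sequence[float] = (0.0, 0.0)) -> GeneticSetup:
    """A hand-specified map bypassing the optimizer, for exact arithmetic."""
    qmap = QTLMap(np.asarray(effects, float), np.asarray(freqs, float),
                  np.asarray(linkage_groups, int),
                  np.asarray(positions, float))
    va = qmap.expected_additive_variance()
    return GeneticSetup(
        qmap=qmap, va_target=va, mean_target=0.0, h2=h2,
        ve_fixed=environmental_variance(va, h2), ve_step=0.0,
        realized_va=va, realized_mean=0.0, n_iter=0, converged=True)


def enumerate_genotypes(n_loci: int) -> np.ndarray:
    """All 3^L dosage combinations as phased genotypes (one heterozygote
    phase each), for brute-force enumeration oracles at tiny L."""
    if n_loci > 8:
        raise ValueError("enumeration fixture limited to 8 loci")
    grids = np.meshgrid(*([np.arange(3)] * n_loci), indexing="ij")
    dosage = np.stack([g.ravel() for g in grids], axis=1)
    geno = np.zeros((dosage.shape[0], n_loci, 2), dtype=np.uint8)
    geno[:, :, 0] = (dosage >= 1)
    geno[:, :, 1] = (dosage == 2)
    return geno
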