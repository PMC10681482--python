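"""Spatial and demographic state of a simulated even-aged stand.

A stand is a single rectangular parcel tiled by a regular grid of square
pixels (15 m x 15 m by default).  Each pixel behaves as an independent
even-aged sub-stand: growth, competition and mortality never look across
pixel boundaries; pixels interact only through seed and pollen flow during
regeneration.  Trees are stored in a struct-of-arrays container
(:class:`TreePopulation`) so that the annual processes can run vectorized
over thousands of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

# Tree status codes.  Transitions are one-way from ALIVE.
ALIVE = 0
DEAD_SELFTHINNING = 1
DEAD_DISTURBANCE = 2
REMOVED_THINNING = 3
REMOVED_HARVEST = 4

STATUS_LABELS = {
    ALIVE: "alive",
    DEAD_SELFTHINNING: "dead_selfthinning",
    DEAD_DISTURBANCE: "dead_disturbance",
    REMOVED_THINNING: "removed_thinning",
    REMOVED_HARVEST: "removed_harvest",
}


@dataclass
class Stand:
    """Rectangular parcel with a homogeneous environment.

    Parameters
    ----------
    width_m, depth_m:
        Extent of the rectangle in meters; the origin sits at one corner.
    site_index:
        Dominant height (m) reached at the reference age of 50 years.
    pixel_size:
        Side of the square pixels in meters.  The grid must tile the extent
        exactly.
    """

    width_m: float = 210.0
    depth_m: float = 210.0
    site_index: float = 20.0
    pixel_size: float = 15.0

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.depth_m <= 0:
            raise ValueError("stand extent must be positive")
        if self.site_index <= 0:
            raise ValueError("site index must be positive")
        nx = self.width_m / self.pixel_size
        ny = self.depth_m / self.pixel_size
        if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
            raise ValueError("pixel grid must tile the stand extent exactly")
        self.nx = int(round(nx))
        self.ny = int(round(ny))

    @property
    def area_ha(self) -> float:
        return self.width_m * self.depth_m / 1e4

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size * self.pixel_size / 1e4

    def pixel_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat pixel index for coordinates; half-open intervals [k*s, (k+1)*s)."""
        col = np.floor(np.asarray(x) / self.pixel_size).astype(np.int64)
        row = np.floor(np.asarray(y) / self.pixel_size).astype(np.int64)
        if np.any((col < 0) | (col >= self.nx) | (row < 0) | (row >= self.ny)):
            raise ValueError("coordinates outside the stand extent")
        return row * self.nx + col

    def pixel_centers(self) -> np.ndarray:
        """(n_pixels, 2) array of pixel-center coordinates in meters."""
        cols = np.arange(self.nx)
        rows = np.arange(self.ny)
        cx = (cols + 0.5) * self.pixel_size
        cy = (rows + 0.5) * self.pixel_size
        xx, yy = np.meshgrid(cx, cy)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class SimulationClock:
    """Calendar and stand-age bookkeeping over the management cycles."""

    calendar_year: int = 0
    stand_age: int = 25
    cycle: int = 1
    phase: str = "growth-phase"  # growth-phase | regeneration-window | pre-recruitment-wait


@dataclass
class InitialDiameterDistribution:
    """Diameter distribution at recruitment age.

    Truncated normal with configurable mean and coefficient of variation,
    truncated below at ``min_dbh``.  The defaults describe a dense young
    cohort (7 cm at age 25 under 2800 stems/ha).
    """

    mean: float = 7.0
    cv: float = 0.25
    min_dbh: float = 0.5

    def _frozen(self):
        sd = self.mean * self.cv
        a = (self.min_dbh - self.mean) / sd
        return stats.truncnorm(a, np.inf, loc=self.mean, scale=sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    def expected_mean(self) -> float:
        """Closed-form mean of the truncated distribution."""
        return float(self._frozen().mean())


class TreePopulation:
    """Struct-of-arrays registry of all trees ever created in a run.

    Dead and removed trees are kept (with their status flag) so that the
    pedigree and the per-cycle production ledger stay reconstructible.
    """

    _FLOAT_FIELDS = ("x", "y", "dbh", "height", "crown_height", "volume",
                     "gval", "env", "fec_effect")
    _INT_FIELDS = ("id", "pixel", "age", "mother", "father", "status", "cohort")

    def __init__(self, n_loci: int = 0):
        self.n_loci = n_loci
        for f in self._FLOAT_FIELDS:
            setattr(self, f, np.empty(0, dtype=np.float64))
        for f in self._INT_FIELDS:
            setattr(self, f, np.empty(0, dtype=np.int64))
        self.recruited = np.empty(0, dtype=bool)
        self.geno: Optional[np.ndarray] = (
            np.empty((0, n_loci, 2), dtype=np.uint8) if n_loci else None
        )
        self._next_id = 0

    @property
    def n(self) -> int:
        return self.id.size

    @property
    def alive(self) -> np.ndarray:
        return self.status == ALIVE

    @property
    def alive_recruited(self) -> np.ndarray:
        return (self.status == ALIVE) & self.recruited

    @property
    def circumference(self) -> np.ndarray:
        return np.pi * self.dbh

    def append(self, *, x, y, pixel, age, dbh, mother=None, father=None,
               gval=None, env=None, fec_effect=None, cohort=0, recruited=True,
               geno=None) -> np.ndarray:
        """Append a block of new trees; returns their ids."""
        m = len(np.atleast_1d(x))
        ids = np.arange(self._next_id, self._next_id + m, dtype=np.int64)
        self._next_id += m

        def cat(cur, new, dtype):
            return np.concatenate([cur, np.broadcast_to(
                np.asarray(new, dtype=dtype), (m,)).copy()])

        self.id = np.concatenate([self.id, ids])
        self.x = cat(self.x, x, np.float64)
        self.y = cat(self.y, y, np.float64)
        self.pixel = cat(self.pixel, pixel, np.int64)
        self.age = cat(self.age, age, np.int64)
        self.dbh = cat(self.dbh, dbh, np.float64)
        zeros = np.zeros(m)
        self.height = np.concatenate([self.height, zeros])
        self.crown_height = np.concatenate([self.crown_height, zeros])
        self.volume = np.concatenate([self.volume, zeros])
        self.gval = cat(self.gval, 0.0 if gval is None else gval, np.float64)
        self.env = cat(self.env, 0.0 if env is None else env, np.float64)
        self.fec_effect = cat(self.fec_effect,
                              0.0 if fec_effect is None else fec_effect,
                              np.float64)
        self.mother = cat(self.mother, -1 if mother is None else mother, np.int64)
        self.father = cat(self.father, -1 if father is None else father, np.int64)
        self.status = np.concatenate([self.status,
                                      np.full(m, ALIVE, dtype=np.int64)])
        self.cohort = cat(self.cohort, cohort, np.int64)
        self.recruited = np.concatenate([
            self.recruited, np.full(m, bool(recruited))])
        if self.geno is not None:
            if geno is None:
                geno = np.zeros((m, self.n_loci, 2), dtype=np.uint8)
            self.geno = np.concatenate([self.geno, np.asarray(geno, np.uint8)])
        return ids

    def phenotype(self, env_step: Optional[np.ndarray] = None) -> np.ndarray:
        """Phenotypic vigor: genotypic value + environmental term(s)."""
        p = self.gval + self.env
        if env_step is not None:
            p = p + env_step
        return p

    def status_counts(self) -> dict:
        return {lab: int(np.sum(self.status == code))
                for code, lab in STATUS_LABELS.items()}


def generate_inventory(stand: Stand, density: float, age: int,
                       rng: np.random.Generator,
                       diameters: InitialDiameterDistribution | None = None,
                       ) -> TreePopulation:
    """Create the synthetic initial inventory: uniformly placed trees with
    diameters drawn from the recruitment-age distribution.

    Genotypes, environmental deviations and fecundity effects are assigned
    separately by the genetics initializer.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if diameters is None:
        diameters = InitialDiameterDistribution()
    n = int(round(density * stand.area_ha))
    x = rng.uniform(0.0, stand.width_m, n)
    y = rng.uniform(0.0, stand.depth_m, n)
    dbh = diameters.sample(n, rng)
    pop = TreePopulation(n_loci=0)
    pop.append(x=x, y=y, pixel=stand.pixel_of(x, y), age=age, dbh=dbh,
               cohort=1, recruited=True)
    return pop


def pixel_dendrometrics(pop: TreePopulation, stand: Stand,
                        ndom_per_ha: float = 100.0):
    """Per-pixel stem count N, basal area G (m2), quadratic mean
    circumference Cg (cm) and dominant height Hdom (m).

    Empty pixels report N=0, G=0, Cg=0, Hdom=0.  Hdom is the mean height of
    the ``ndom`` tallest trees, with ndom the per-hectare convention scaled
    to the pixel area (minimum 1).
    """
    npx = stand.n_pixels
    mask = pop.alive_recruited
    px = pop.pixel[mask]
    dbh = pop.dbh[mask]
    h = pop.height[mask]
    N = np.bincount(px, minlength=npx).astype(np.int64)
    G = np.bincount(px, weights=np.pi * (dbh / 200.0) ** 2, minlength=npx)
    c2 = np.bincount(px, weights=(np.pi * dbh) ** 2, minlength=npx)
    with np.errstate(invalid="ignore", divide="ignore"):
        Cg = np.where(N > 0, np.sqrt(c2 / np.maximum(N, 1)), 0.0)
    ndom = max(1, int(round(ndom_per_ha * stand.pixel_area_ha)))
    Hdom = np.zeros(npx)
    if px.size:
        order = np.lexsort((-h, px))
        px_o, h_o = px[order], h[order]
        starts = np.searchsorted(px_o, np.arange(npx))
        ends = np.searchsorted(px_o, np.arange(npx) + 1)
        for p in np.nonzero(N)[0]:
            top = h_o[starts[p]:min(ends[p], starts[p] + ndom)]
            Hdom[p] = top.mean()
    return N, G, Cg, Hdom


def dominant_diameter(pop: TreePopulation, stand: Stand,
                      ndom_per_ha: float = 100.0) -> np.ndarray:
    """Per-pixel mean dbh of the ndom largest trees (anchor for the
    height-diameter relation); 0 for empty pixels."""
    npx = stand.n_pixels
    mask = pop.alive_recruited
    px = pop.pixel[mask]
    dbh = pop.dbh[mask]
    ndom = max(1, int(round(ndom_per_ha * stand.pixel_area_ha)))
    Ddom = np.zeros(npx)
    if px.size:
        order = np.lexsort((-dbh, px))
        px_o, d_o = px[order], dbh[order]
        starts = np.searchsorted(px_o, np.arange(npx))
        ends = np.searchsorted(px_o, np.arange(npx) + 1)
        for p in range(npx):
            if ends[p] > starts[p]:
                Ddom[p] = d_o[starts[p]:min(ends[p], starts[p] + ndom)].mean()
    return Ddom
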