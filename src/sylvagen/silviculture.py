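"""Silvicultural interventions and the seven named management scenarios.

Thinnings are stand-level operations on a target density (stems/ha), with
the trees to remove drawn stand-wide: at random, from below (smallest
first) or from above (largest first).  Every scenario ends each cycle with
a seeding cut leaving 110 seed trees per hectare and, three years later, a
final harvest removing the seed trees so that only the new seedlings
remain.  All interventions in the named scenarios are random, hence
selectively neutral with respect to any heritable trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

THINNING = "thinning"
SEEDING_CUT = "seeding_cut"
FINAL_HARVEST = "final_harvest"


@dataclass(frozen=True)
class Intervention:
    stand_age: int
    kind: str
    target_density: float
    mode: str = "random"

    def __post_init__(self) -> None:
        if self.kind not in (THINNING, SEEDING_CUT, FINAL_HARVEST):
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.mode not in ("random", "from_below", "from_above"):
            raise ValueError(f"unknown thinning mode {self.mode!r}")
        if self.target_density < 0:
            raise ValueError("target density must be >= 0")


@dataclass(frozen=True)
class Scenario:
    name: str
    interventions: Tuple[Intervention, ...]
    n_cycles: int = 4

    def __post_init__(self) -> None:
        ages = [iv.stand_age for iv in self.interventions]
        if ages != sorted(ages):
            raise ValueError("interventions must be sorted by stand age")
        if (len(self.interventions) < 2
                or self.interventions[-2].kind != SEEDING_CUT
                or self.interventions[-1].kind != FINAL_HARVEST):
            raise ValueError("a scenario must end with a seeding cut then a "
                             "final harvest")
        if (self.interventions[-1].stand_age
                - self.interventions[-2].stand_age != 3):
            raise ValueError("final harvest must follow the seeding cut by "
                             "3 years (the regeneration window)")

    @property
    def cycle_length(self) -> int:
        """Stand age at the final harvest (103 or 63 in the named library)."""
        return self.interventions[-1].stand_age

    @property
    def seeding_cut_age(self) -> int:
        return self.interventions[-2].stand_age

    def at_age(self, stand_age: int):
        for iv in self.interventions:
            if iv.stand_age == stand_age:
                return iv
        return None


def _scenario(name: str, thinnings, cut_age: int,
              seed_density: float = 110.0) -> Scenario:
    ivs = [Intervention(a, THINNING, d) for a, d in thinnings]
    ivs.append(Intervention(cut_age, SEEDING_CUT, seed_density))
    ivs.append(Intervention(cut_age + 3, FINAL_HARVEST, 0.0))
    return Scenario(name, tuple(ivs))


_LIBRARY = {
    "U-long": _scenario("U-long", [], 100),
    "U-short": _scenario("U-short", [], 60),
    "B-long": _scenario("B-long", [(25, 1100), (40, 600), (50, 430),
                                   (60, 320), (70, 245), (80, 200)], 100),
    "B-short": _scenario("B-short", [(25, 1100), (30, 600), (40, 200)], 60),
    "E-low": _scenario("E-low", [(40, 2400), (50, 1720), (60, 1280),
                                 (70, 980), (80, 800)], 100),
    "E-delayed": _scenario("E-delayed", [(60, 320), (70, 245), (80, 200)], 100),
    "E-relaxed": _scenario("E-relaxed", [(25, 1100), (70, 245), (80, 200)], 100),
}

SCENARIO_NAMES = tuple(_LIBRARY)


def scenario_library(name: str) -> Scenario:
    """The exact intervention schedule of a named scenario."""
    try:
        return _LIBRARY[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(_LIBRARY)}"
        ) from None


def select_removals(dbh: np.ndarray, tree_ids: np.ndarray, n_remove: int,
                    mode: str, rng: np.random.Generator) -> np.ndarray:
    """Ids of the trees removed by one thinning of ``n_remove`` stems."""
    n_remove = int(n_remove)
    if n_remove <= 0:
        return tree_ids[:0]
    if n_remove >= tree_ids.size:
        return tree_ids.copy()
    if mode == "random":
        pick = rng.choice(tree_ids.size, size=n_remove, replace=False)
        return tree_ids[pick]
    order = np.lexsort((tree_ids, dbh))
    if mode == "from_above":
        order = order[::-1]
    return tree_ids[order[:n_remove]]


def thinning_removal_count(n_alive: int, target_density: float,
                           area_ha: float) -> int:
    """Number of stems to remove to reach the target density (>= 0)."""
    return max(0, n_alive - int(round(target_density * area_ha)))
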