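"""Annual loop and multi-cycle simulation runs.

Each simulated year executes, in order: growth in every pixel, selective
mortality by self-thinning, non-selective mortality by disturbance,
regeneration (while the window opened by the seeding cut is active) and the
scheduled silvicultural intervention, then appends an annual record.  A
management cycle ends with the final harvest; the 25-year pre-recruitment
wait is a single bookkeeping transition in which the accumulated seedlings
are promoted to recruitment age, given random diameters, self-thinned and
randomly reduced to the reset density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import genetics, metrics, regeneration, silviculture
from .config import SimulationConfig
from .core_state import (ALIVE, DEAD_DISTURBANCE, DEAD_SELFTHINNING,
                         REMOVED_HARVEST, REMOVED_THINNING, SimulationClock,
                         TreePopulation, generate_inventory)
from .growth import dominant_height, tree_dimensions
from .mortality import disturbance_death_mask, draw_potential_mortality_rate

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["calendar_year", "cycle", "stand_age", "Nha", "muG.Vig",
                  "VA(Vig)", "He", "VhaProd", "QMD", "DeadS-T", "DeadD"]


@dataclass
class RunSummary:
    """Per-run outcome: evolutionary rate, per-cycle selection differentials
    and dendrometric end-points."""

    scenario: str
    disturbance: str
    n_qtl: Optional[int]
    setup_seed: int
    inventory_seed: int
    dynamics_seed: int
    collapsed: bool = False
    collapse_cycle: Optional[int] = None
    h0: float = float("nan")
    h0_genotypic: float = float("nan")
    n_gen: int = 4
    start_mean_phen: float = float("nan")
    start_var_phen: float = float("nan")
    end_mean_phen: float = float("nan")
    end_var_phen: float = float("nan")
    realized_va: float = float("nan")
    selection_differentials: List[float] = field(default_factory=list)
    dead_selfthinning_per_cycle: List[float] = field(default_factory=list)
    dead_disturbance_per_cycle: List[float] = field(default_factory=list)
    qmd_end_of_cycle: List[float] = field(default_factory=list)
    vhaprod_end_of_cycle: List[float] = field(default_factory=list)


class ForestState:
    """Mutable state of one simulation run."""

    def __init__(self, config: SimulationConfig,
                 setup: Optional[genetics.GeneticSetup] = None,
                 founder_geno: Optional[np.ndarray] = None):
        config.validate()
        self.config = config
        self.stand = config.stand
        self.clock = SimulationClock(
            calendar_year=0, stand_age=config.initial_age, cycle=1)
        self.rng = np.random.default_rng(config.dynamics_seed)
        rng_inv = np.random.default_rng(config.inventory_seed)

        if config.inventory_file is not None:
            from . import io
            self.pop = io.read_inventory(
                config.inventory_file, config.haplotypes_file,
                stand=self.stand)
        else:
            self.pop = generate_inventory(
                self.stand, config.initial_density, config.initial_age,
                rng_inv, config.diameters)

        gcfg = config.genetics
        self.setup: Optional[genetics.GeneticSetup] = None
        if gcfg.variation:
            rng_setup = np.random.default_rng(config.setup_seed)
            if setup is None and config.qtl_map_file is not None:
                # genetics supplied on disk: the inventory's phased
                # genotypes plus the QTL map define the founders exactly
                from . import io
                if self.pop.geno is None:
                    raise ValueError(
                        "a QTL map was given but the inventory carries no "
                        "genotypes")
                qmap = io.read_qtl_map(config.qtl_map_file)
                gv = genetics.genotypic_value(self.pop.geno, qmap)
                setup = genetics.GeneticSetup(
                    qmap=qmap, va_target=gcfg.va_target,
                    mean_target=gcfg.mean_target, h2=gcfg.h2,
                    ve_fixed=genetics.environmental_variance(
                        gcfg.va_target, gcfg.h2, gcfg.ve_step),
                    ve_step=gcfg.ve_step,
                    realized_va=float(np.var(gv, ddof=1)),
                    realized_mean=float(np.mean(gv)),
                    n_iter=0, converged=True)
                founder_geno = self.pop.geno
                rng_setup = np.random.default_rng(
                    np.random.SeedSequence((config.setup_seed, 0xE)))
            elif setup is None or founder_geno is None:
                setup, founder_geno = genetics.init_genetic_setup(
                    gcfg.n_qtl, gcfg.va_target, self.pop.n, rng_setup,
                    mean_target=gcfg.mean_target, h2=gcfg.h2,
                    ve_step=gcfg.ve_step, tol_va=gcfg.tol_va,
                    mean_tol_factor=gcfg.mean_tol_factor,
                    kappa_contrib=gcfg.kappa_contrib,
                    kappa_freq=gcfg.kappa_freq, p_min=gcfg.p_min,
                    n_linkage_groups=gcfg.n_linkage_groups,
                    max_iter=gcfg.max_iter)
            else:
                # advance the setup stream identically so env draws match
                rng_setup = np.random.default_rng(
                    np.random.SeedSequence((config.setup_seed, 0xE)))
            if founder_geno.shape[0] < self.pop.n:
                raise ValueError("founder genotypes fewer than trees")
            self.setup = setup
            self.pop.n_loci = setup.qmap.n_loci
            self.pop.geno = np.asarray(
                founder_geno[: self.pop.n], np.uint8).copy()
            self.pop.gval = genetics.genotypic_value(self.pop.geno, setup.qmap)
            self.pop.env = genetics.draw_env_fixed(
                self.pop.n, setup.ve_fixed, rng_setup)
        self.pop.fec_effect = self.rng.normal(
            0.0, config.fecundity.sd_individual, self.pop.n)

        self._pixel_centers = self.stand.pixel_centers()
        self.regen_years_left = 0
        self.collapsed = False
        self.done = False
        self.records: List[dict] = []
        self._reset_cycle_accumulators()
        self._update_dimensions()

        phen = self.pop.phenotype()[self.pop.alive_recruited]
        self.summary = RunSummary(
            scenario=config.scenario.name,
            disturbance=config.disturbance.kind,
            n_qtl=gcfg.n_qtl if gcfg.variation else None,
            setup_seed=config.setup_seed,
            inventory_seed=config.inventory_seed,
            dynamics_seed=config.dynamics_seed,
            n_gen=config.n_cycles,
            start_mean_phen=float(phen.mean()),
            start_var_phen=float(np.var(phen, ddof=1)),
            realized_va=(self.setup.realized_va if self.setup else 0.0))
        self._start_mean_gval = float(
            self.pop.gval[self.pop.alive_recruited].mean())
        self._start_var_gval = float(
            np.var(self.pop.gval[self.pop.alive_recruited], ddof=1))
        # an intervention scheduled at the initial stand age applies at once
        self._intervene()
        self._append_record()

    # ------------------------------------------------------------------ utils

    def _reset_cycle_accumulators(self) -> None:
        self._cycle_dead_st = 0
        self._cycle_dead_d = 0
        self._cycle_lost_volume = 0.0
        mask = self.pop.alive_recruited
        self._cycle_start_mean_gval = (
            float(self.pop.gval[mask].mean()) if mask.any() else float("nan"))

    def _vigor(self, idx: np.ndarray) -> np.ndarray:
        v = self.pop.gval[idx] + self.pop.env[idx]
        ve_step = self.setup.ve_step if self.setup else 0.0
        if ve_step > 0:
            v = v + self.rng.normal(0.0, np.sqrt(ve_step), idx.size)
        return v

    def _update_dimensions(self) -> None:
        """Recompute heights, crown heights and volumes of recruited trees
        from the height-diameter relation anchored at the pixel dominant
        diameter and the site curve dominant height."""
        g = self.config.growth
        hdom = dominant_height(self.clock.stand_age, self.stand.site_index, g)
        idx = np.flatnonzero(self.pop.alive_recruited)
        if idx.size == 0:
            return
        npx = self.stand.n_pixels
        px = self.pop.pixel[idx]
        dbh = self.pop.dbh[idx]
        ndom = max(1, int(round(g.ndom_per_ha * self.stand.pixel_area_ha)))
        order = np.lexsort((-dbh, px))
        px_o, d_o = px[order], dbh[order]
        starts = np.searchsorted(px_o, np.arange(npx))
        pos = np.arange(px_o.size) - starts[px_o]
        top = pos < ndom
        d_dom = np.zeros(npx)
        counts = np.bincount(px_o[top], minlength=npx)
        np.divide(np.bincount(px_o[top], weights=d_o[top], minlength=npx),
                  counts, out=d_dom, where=counts > 0)
        h, ch, vol = tree_dimensions(dbh, d_dom[px], hdom, g)
        self.pop.height[idx] = h
        self.pop.crown_height[idx] = ch
        self.pop.volume[idx] = vol

    def _kill(self, tree_indices: np.ndarray, status: int,
              count_volume: bool = True) -> None:
        if tree_indices.size == 0:
            return
        self.pop.status[tree_indices] = status
        if count_volume:
            self._cycle_lost_volume += float(
                self.pop.volume[tree_indices].sum())

    # -------------------------------------------------------------- processes

    def _grow(self) -> None:
        """Vectorized across pixels: pixel basal-area increments, then a
        simultaneous per-pixel bisection for the allocation thresholds (same
        arithmetic as :func:`allocate_individual_increments`, solved for all
        pixels at once)."""
        g = self.config.growth
        st = self.config.self_thinning
        age = self.clock.stand_age
        d_hdom = (dominant_height(age, self.stand.site_index, g)
                  - dominant_height(age - 1, self.stand.site_index, g))
        idx = np.flatnonzero(self.pop.alive_recruited)
        if idx.size == 0:
            return
        npx = self.stand.n_pixels
        px_area = self.stand.pixel_area_ha
        px = self.pop.pixel[idx]
        circ = np.pi * self.pop.dbh[idx]
        counts = np.bincount(px, minlength=npx)
        g_px = np.bincount(px, weights=(circ / 100.0) ** 2 / (4.0 * np.pi),
                           minlength=npx)
        occupied = counts > 0
        cg = np.zeros(npx)
        np.sqrt(np.divide(np.bincount(px, weights=circ ** 2, minlength=npx),
                          counts, where=occupied, out=cg), out=cg,
                where=occupied)
        rdi = st.rdi(counts / px_area, cg)
        dG = np.zeros(npx)
        if d_hdom > 0:
            dG[occupied] = (g.ba_coef * d_hdom
                            * (g_px[occupied] / px_area) ** g.ba_exponent
                            * (1.0 - np.exp(-rdi[occupied]
                                            / g.low_stocking_scale))
                            * px_area)
            dG = np.clip(dG, 0.0, None)

        vigor = self._vigor(idx)
        v_mean = np.zeros(npx)
        np.divide(np.bincount(px, weights=vigor, minlength=npx), counts,
                  out=v_mean, where=occupied)
        dev_c = np.pi * (vigor - v_mean[px])  # deviations, circumference units
        m = g.alloc_slope

        def implied(sigma_px):
            dc = np.clip(m * (circ - sigma_px[px]) + dev_c, 0.0, None)
            return (np.bincount(px, weights=2.0 * circ * dc + dc ** 2,
                                minlength=npx) / (4.0 * np.pi * 1e4), dc)

        # bracket sigma per pixel wide enough to cover the deviation shifts
        shifted = circ + dev_c / m
        hi = np.zeros(npx)
        np.maximum.at(hi, px, shifted)
        lo = np.full(npx, np.inf)
        np.minimum.at(lo, px, shifted)
        lo[~occupied] = 0.0
        hi[~occupied] = 0.0
        span = np.maximum(hi - lo, 1.0)
        need = occupied & (dG > 0)
        for _ in range(64):
            f, _dc = implied(lo)
            short = need & (f < dG)
            if not short.any():
                break
            lo[short] -= span[short]
            span[short] *= 2.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            f, _dc = implied(mid)
            over = f > dG
            lo = np.where(over, mid, lo)
            hi = np.where(over, hi, mid)
        sigma = 0.5 * (lo + hi)
        sigma[~need] = hi[~need] + 1.0      # zero increments where dG == 0
        _f, dc = implied(sigma)
        self.pop.dbh[idx] += np.clip(dc / np.pi + v_mean[px], 0.0, None)
        self._update_dimensions()

    def _self_thin(self, count_in_cycle: bool = True) -> None:
        """Vectorized smallest-first removal: per pixel, the sequential
        "remove the smallest, recompute, repeat" rule reduces to finding the
        first prefix of the size order whose remaining RDI falls below the
        ceiling (identical to :func:`sylvagen.mortality.self_thinning`)."""
        st = self.config.self_thinning
        idx = np.flatnonzero(self.pop.alive_recruited)
        if idx.size == 0:
            return
        npx = self.stand.n_pixels
        px_area = self.stand.pixel_area_ha
        px = self.pop.pixel[idx]
        order = np.lexsort((self.pop.id[idx], self.pop.dbh[idx], px))
        sub = idx[order]
        px_o = px[order]
        c2 = (np.pi * self.pop.dbh[sub]) ** 2
        starts = np.searchsorted(px_o, np.arange(npx))
        counts = np.bincount(px_o, minlength=npx)
        cum = np.concatenate([[0.0], np.cumsum(c2)])
        pos = np.arange(sub.size) - starts[px_o]
        n_left = counts[px_o] - pos
        seg_end = starts[px_o] + counts[px_o]
        s2_left = cum[seg_end] - cum[pos + starts[px_o]]
        cg_left = np.sqrt(np.maximum(s2_left, 0.0) / n_left)
        rdi = (n_left / px_area) / st.nmax(np.maximum(cg_left, 1e-12))
        ok = rdi <= st.rdi_max
        # first position within each pixel where the remaining stand fits
        stop = np.full(npx, 0, dtype=np.int64)
        if sub.size:
            first_ok = np.full(npx, np.iinfo(np.int64).max, dtype=np.int64)
            np.minimum.at(first_ok, px_o[ok], pos[ok])
            present = counts > 0
            stop[present] = np.where(
                first_ok[present] == np.iinfo(np.int64).max,
                counts[present] - 1, first_ok[present])
        removed = sub[pos < stop[px_o]]
        if removed.size:
            self._kill(removed, DEAD_SELFTHINNING,
                       count_volume=count_in_cycle)
            if count_in_cycle:
                self._cycle_dead_st += removed.size

    def _disturb(self) -> None:
        regime = self.config.disturbance
        rate = draw_potential_mortality_rate(regime, self.rng)
        if rate == 0.0:
            return
        idx = np.flatnonzero(self.pop.alive_recruited)
        if idx.size == 0:
            return
        mask = disturbance_death_mask(
            self.pop.pixel[idx], self.pop.crown_height[idx],
            self.stand.n_pixels, rate, regime, self.rng)
        self._kill(idx[mask], DEAD_DISTURBANCE)
        self._cycle_dead_d += int(mask.sum())

    def _regenerate(self) -> None:
        fec = self.config.fecundity
        idx = np.flatnonzero(self.pop.alive_recruited)
        fertile = idx[regeneration.is_fertile(
            self.pop.age[idx], self.pop.dbh[idx], fec)]
        if fertile.size == 0:
            logger.warning("no fertile tree: no seedlings this year")
            return
        seeds = regeneration.female_fecundity(
            self.pop.dbh[fertile], self.pop.crown_height[fertile],
            self.pop.age[fertile], self.pop.fec_effect[fertile],
            self.rng, fec)
        mothers = fertile[seeds > 0]
        if mothers.size == 0:
            return
        contrib = regeneration.seed_rain_contributions(
            np.column_stack([self.pop.x[mothers], self.pop.y[mothers]]),
            seeds[seeds > 0], self._pixel_centers, self.config.kernel)
        density = contrib.sum(axis=0)          # seeds per m2 at pixel centers
        n_per_pixel = np.round(density * fec.seedling_multiplier).astype(int)
        if n_per_pixel.sum() == 0:
            return
        fathers_pool = fertile
        fw = regeneration.male_fertility(
            self.pop.dbh[fathers_pool], self.pop.age[fathers_pool], fec)
        px_idx, m_idx, f_idx = regeneration.sample_seedling_parents(
            contrib, n_per_pixel, fw, self.rng)
        mother_tree = mothers[m_idx]
        father_tree = fathers_pool[f_idx]
        if not fec.selfing_allowed:
            for _ in range(100):
                clash = mother_tree == father_tree
                if not clash.any():
                    break
                f_idx[clash] = self.rng.choice(
                    fw.size, size=int(clash.sum()), p=fw / fw.sum())
                father_tree = fathers_pool[f_idx]
        n_new = mother_tree.size
        centers = self._pixel_centers[px_idx]
        geno = None
        gval = None
        env = None
        if self.setup is not None:
            geno = regeneration.offspring_genotypes(
                self.pop.geno[mother_tree], self.pop.geno[father_tree],
                self.setup.qmap, self.rng)
            gval = genetics.genotypic_value(geno, self.setup.qmap)
            env = genetics.draw_env_fixed(n_new, self.setup.ve_fixed, self.rng)
        self.pop.append(
            x=centers[:, 0], y=centers[:, 1], pixel=px_idx, age=0, dbh=0.0,
            mother=self.pop.id[mother_tree], father=self.pop.id[father_tree],
            gval=gval, env=env,
            fec_effect=self.rng.normal(0.0, fec.sd_individual, n_new),
            cohort=self.clock.cycle + 1, recruited=False, geno=geno)

    def _intervene(self) -> None:
        iv = self.config.scenario.at_age(self.clock.stand_age)
        if iv is None:
            return
        idx = np.flatnonzero(self.pop.alive_recruited)
        if iv.kind == silviculture.FINAL_HARVEST:
            self._kill(idx, REMOVED_HARVEST,
                       count_volume=self.config.include_removals_in_production)
            return
        if iv.kind == silviculture.SEEDING_CUT:
            fertile = idx[regeneration.is_fertile(
                self.pop.age[idx], self.pop.dbh[idx], self.config.fecundity)]
            target_count = round(iv.target_density * self.stand.area_ha)
            minimum = max(1.0, self.config.collapse_seed_tree_fraction
                          * target_count)
            if fertile.size < minimum:
                self._collapse(
                    f"only {fertile.size} fertile trees at the seeding cut "
                    f"(minimum {minimum:.0f})")
                return
        n_remove = silviculture.thinning_removal_count(
            idx.size, iv.target_density, self.stand.area_ha)
        if n_remove > 0:
            removed = silviculture.select_removals(
                self.pop.dbh[idx], idx, n_remove, iv.mode, self.rng)
            self._kill(removed, REMOVED_THINNING,
                       count_volume=self.config.include_removals_in_production)
        elif iv.kind == silviculture.SEEDING_CUT:
            logger.warning("stand already at or below the seed-tree density")
        if iv.kind == silviculture.SEEDING_CUT:
            survivors = np.flatnonzero(self.pop.alive_recruited)
            sd = metrics.selection_differential(
                float(self.pop.gval[survivors].mean()),
                self._cycle_start_mean_gval)
            self.summary.selection_differentials.append(sd)
            self.regen_years_left = 3
            self.clock.phase = "regeneration-window"

    def _collapse(self, reason: str) -> None:
        logger.warning("population collapse in cycle %d (stand age %d): %s",
                       self.clock.cycle, self.clock.stand_age, reason)
        self.collapsed = True
        self.done = True
        self.summary.collapsed = True
        self.summary.collapse_cycle = self.clock.cycle

    # ------------------------------------------------------------ annual step

    def step_year(self) -> None:
        """Advance the simulation by one process year."""
        if self.done:
            return
        if (not self.pop.alive_recruited.any()
                and self.regen_years_left == 0):
            self._collapse("no alive tree left")
            return
        self.clock.calendar_year += 1
        self.clock.stand_age += 1
        self.pop.age[self.pop.alive] += 1

        sc = self.config.scenario
        at_seeding_cut = self.clock.stand_age == sc.seeding_cut_age
        at_harvest = self.clock.stand_age == sc.cycle_length
        if at_seeding_cut:
            # end-of-cycle dendrometric state, before the cut
            self._grow()
            self._self_thin()
            self._disturb()
            mask = self.pop.alive_recruited
            self.summary.qmd_end_of_cycle.append(
                metrics.quadratic_mean_diameter(self.pop.dbh[mask])
                if mask.any() else float("nan"))
        else:
            self._grow()
            self._self_thin()
            self._disturb()
        if self.regen_years_left > 0:
            self._regenerate()
            self.regen_years_left -= 1
        self._intervene()
        if self.collapsed:
            return
        self._append_record()
        if at_harvest:
            self.summary.vhaprod_end_of_cycle.append(
                self.records[-1]["VhaProd"])
            self.summary.dead_selfthinning_per_cycle.append(
                self._cycle_dead_st / self.stand.area_ha)
            self.summary.dead_disturbance_per_cycle.append(
                self._cycle_dead_d / self.stand.area_ha)
            self._recruit()

    # ------------------------------------------------------------ recruitment

    def _recruit(self) -> None:
        """Bookkept 25-year transition: promote the accumulated seedlings to
        recruitment age, draw their diameters (independently of genotype),
        self-thin, then randomly reset the stand density."""
        cfg = self.config
        seedlings = np.flatnonzero(self.pop.alive & ~self.pop.recruited)
        if seedlings.size == 0:
            self._collapse("no seedling available at recruitment")
            return
        self.clock.cycle += 1
        self.clock.stand_age = cfg.growth.recruitment_age
        self.clock.calendar_year += cfg.growth.recruitment_age
        self.clock.phase = "growth-phase"
        self.pop.age[seedlings] = cfg.growth.recruitment_age
        self.pop.dbh[seedlings] = cfg.diameters.sample(
            seedlings.size, self.rng)
        self.pop.recruited[seedlings] = True
        self._update_dimensions()
        # recruitment-stage self-thinning is part of the regeneration
        # bottleneck, not of the previous cycle's ledger
        self._self_thin(count_in_cycle=False)
        idx = np.flatnonzero(self.pop.alive_recruited)
        target = int(round(cfg.reset_density * self.stand.area_ha))
        if idx.size > target:
            removed = silviculture.select_removals(
                self.pop.dbh[idx], idx, idx.size - target, "random", self.rng)
            self.pop.status[removed] = REMOVED_THINNING
        elif idx.size < target:
            logger.warning(
                "only %d seedlings recruited for a reset target of %d",
                idx.size, target)
        self._reset_cycle_accumulators()
        if self.clock.cycle > cfg.n_cycles:
            self._finalize()
            self.done = True
        else:
            # a thinning scheduled at the recruitment age (Table-1 style
            # age-25 interventions) applies right after the density reset
            self._intervene()
            self._append_record()

    def _finalize(self) -> None:
        mask = self.pop.alive_recruited
        phen = self.pop.phenotype()[mask]
        gv = self.pop.gval[mask]
        s = self.summary
        s.end_mean_phen = float(phen.mean())
        s.end_var_phen = float(np.var(phen, ddof=1))
        if s.start_var_phen + s.end_var_phen > 0:
            s.h0 = metrics.evolutionary_rate_H0(
                s.start_mean_phen, s.end_mean_phen,
                s.start_var_phen, s.end_var_phen, self.config.n_cycles)
        var_g = float(np.var(gv, ddof=1))
        if self._start_var_gval + var_g > 0:
            s.h0_genotypic = metrics.evolutionary_rate_H0(
                self._start_mean_gval, float(gv.mean()),
                self._start_var_gval, var_g, self.config.n_cycles)

    # ---------------------------------------------------------------- records

    def _append_record(self) -> None:
        mask = self.pop.alive_recruited
        n = int(mask.sum())
        area = self.stand.area_ha
        gv = self.pop.gval[mask]
        rec = {
            "calendar_year": self.clock.calendar_year,
            "cycle": self.clock.cycle,
            "stand_age": self.clock.stand_age,
            "Nha": n / area,
            "muG.Vig": float(gv.mean()) if n else float("nan"),
            "VA(Vig)": float(np.var(gv, ddof=1)) if n >= 2 else float("nan"),
            "He": (genetics.expected_heterozygosity(self.pop.geno[mask])
                   if (self.setup is not None and n) else float("nan")),
            "VhaProd": metrics.cumulative_production(
                float(self.pop.volume[mask].sum()),
                self._cycle_lost_volume, area),
            "QMD": (metrics.quadratic_mean_diameter(self.pop.dbh[mask])
                    if n else float("nan")),
            "DeadS-T": self._cycle_dead_st / area,
            "DeadD": self._cycle_dead_d / area,
        }
        self.records.append(rec)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=RECORD_COLUMNS)


def run_simulation(config: SimulationConfig,
                   setup: Optional[genetics.GeneticSetup] = None,
                   founder_geno: Optional[np.ndarray] = None,
                   max_years: int = 100000
                   ) -> Tuple[pd.DataFrame, RunSummary]:
    """Run a full multi-cycle simulation.

    A pre-built genetic setup (with its founder genotypes) may be passed to
    share one architecture across replicate runs; otherwise it is built from
    ``config.setup_seed``.  Returns the annual records and the run summary;
    a collapse short-circuits the run with partial records.
    """
    state = ForestState(config, setup=setup, founder_geno=founder_geno)
    years = 0
    while not state.done and years < max_years:
        state.step_year()
        years += 1
    return state.records_frame(), state.summary
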