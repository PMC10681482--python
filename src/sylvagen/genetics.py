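"""Finite-loci additive quantitative genetics for the vigor trait.

Vigor is controlled by diallelic QTL with purely additive effects: the
"increasing" allele contributes +a_l and its counterpart -a_l, so a
heterozygous locus contributes nothing.  Phenotypes add an individual
environmental deviation with a fixed (lifetime) component and an optional
inter-step component redrawn annually.  The founder population is built by
a stochastic optimizer that draws per-locus variance contributions and
allele frequencies until the realized additive variance and genetic mean of
the founders match their targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats


@dataclass
class QTLMap:
    """Diallelic QTL positions and effects.

    effect:        absolute allelic effect a_l (cm/yr), >= 0.
    init_freq:     initial frequency of the increasing allele, in (0, 1).
    linkage_group: integer group id; groups assort independently.
    position_cM:   map position within the group (Haldane mapping).
    """

    effect: np.ndarray
    init_freq: np.ndarray
    linkage_group: np.ndarray
    position_cM: np.ndarray

    def __post_init__(self) -> None:
        self.effect = np.asarray(self.effect, dtype=np.float64)
        self.init_freq = np.asarray(self.init_freq, dtype=np.float64)
        self.linkage_group = np.asarray(self.linkage_group, dtype=np.int64)
        self.position_cM = np.asarray(self.position_cM, dtype=np.float64)
        L = self.effect.size
        if not (self.init_freq.size == self.linkage_group.size
                == self.position_cM.size == L):
            raise ValueError("QTL map columns must have equal length")
        if np.any(self.effect < 0):
            raise ValueError("allelic effects must be non-negative")
        if np.any((self.init_freq <= 0) | (self.init_freq >= 1)):
            raise ValueError("initial frequencies must lie strictly in (0, 1)")

    @property
    def n_loci(self) -> int:
        return self.effect.size

    def switch_probabilities(self) -> np.ndarray:
        """Per-locus probability of switching the parental haplotype during
        meiosis, relative to the previous locus in map order.

        The first locus of every linkage group gets 0.5 (independent
        assortment); within a group the Haldane mapping function converts
        the distance d (cM) to a recombination fraction (1 - e^(-2d/100))/2.
        """
        L = self.n_loci
        r = np.full(L, 0.5)
        if L > 1:
            same = self.linkage_group[1:] == self.linkage_group[:-1]
            d = np.abs(self.position_cM[1:] - self.position_cM[:-1])
            r[1:][same] = haldane_recombination(d[same])
        return r

    def expected_additive_variance(self) -> float:
        """Linkage-equilibrium additive variance.

        With genotypic values that sum the two allele effects (+a/-a per
        allele, heterozygote zero, homozygotes +/-2a), a locus at frequency
        p contributes 2 p q (2a)^2 = 8 p q a^2 under Hardy-Weinberg.
        """
        p = self.init_freq
        return float(np.sum(8.0 * p * (1.0 - p) * self.effect ** 2))


def haldane_recombination(d_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction for a map distance in centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


def genotypic_value(geno: np.ndarray, qmap: QTLMap) -> np.ndarray:
    """Sum of allelic effects over loci and haplotypes.

    ``geno`` has shape (n, L, 2) (or (L, 2) for a single tree) with allele
    codes 0 (decreasing) / 1 (increasing).  A heterozygous locus contributes
    zero; the homozygotes contribute +/- 2 a_l.
    """
    geno = np.asarray(geno)
    single = geno.ndim == 2
    if single:
        geno = geno[None]
    if geno.shape[1] != qmap.n_loci:
        raise ValueError("genotype length does not match the QTL map")
    dosage = geno.sum(axis=2).astype(np.float64)
    vals = 2.0 * (dosage - 1.0) @ qmap.effect
    return float(vals[0]) if single else vals


def phenotypic_vigor(gval, env_fixed, env_step=0.0):
    """Phenotype = genotypic value + fixed + inter-step environmental terms."""
    return np.asarray(gval, dtype=np.float64) + env_fixed + env_step


def make_gametes(geno: np.ndarray, qmap: QTLMap,
                 rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent genotype, with Mendelian segregation and
    Haldane recombination along linkage groups; no mutation.

    ``geno``: (n, L, 2) -> returns (n, L) haplotypes.
    """
    geno = np.asarray(geno)
    single = geno.ndim == 2
    if single:
        geno = geno[None]
    n, L, _ = geno.shape
    switch = rng.random((n, L)) < qmap.switch_probabilities()[None, :]
    hap_idx = np.cumsum(switch, axis=1) % 2
    gam = np.take_along_axis(geno, hap_idx[:, :, None], axis=2)[:, :, 0]
    return gam[0] if single else gam


def make_gamete(genotype: np.ndarray, qmap: QTLMap,
                rng: np.random.Generator) -> np.ndarray:
    """Single-parent convenience wrapper around :func:`make_gametes`."""
    return make_gametes(np.asarray(genotype), qmap, rng)


def expected_heterozygosity(geno: np.ndarray, qmap: Optional[QTLMap] = None
                            ) -> float:
    """Nei's expected heterozygosity: mean over loci of 2 p (1 - p) with p
    the sample frequency of the increasing allele."""
    geno = np.asarray(geno)
    if geno.ndim != 3 or geno.shape[0] == 0:
        raise ValueError("need at least one individual")
    p = geno.sum(axis=(0, 2)) / (2.0 * geno.shape[0])
    return float(np.mean(2.0 * p * (1.0 - p)))


def additive_variance(gvals: np.ndarray) -> float:
    """Sample variance of genotypic values (realized genetic variance,
    including any selection-induced linkage-disequilibrium covariance)."""
    gvals = np.asarray(gvals, dtype=np.float64)
    if gvals.size < 2:
        raise ValueError("need at least two individuals")
    return float(np.var(gvals, ddof=1))


@dataclass
class GeneticSetup:
    """A realized genetic architecture plus its founder-fit diagnostics."""

    qmap: QTLMap
    va_target: float
    mean_target: float
    h2: float
    ve_fixed: float
    ve_step: float
    realized_va: float
    realized_mean: float
    n_iter: int
    converged: bool

    @property
    def phenotypic_variance(self) -> float:
        return self.va_target + self.ve_fixed + self.ve_step


def environmental_variance(va_target: float, h2: float,
                           ve_step: float = 0.0) -> float:
    """Fixed environmental variance implied by the heritability target:
    VP = VA / h2, VE_fixed = VP - VA - VE_step."""
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    ve = va_target * (1.0 - h2) / h2 - ve_step
    if ve < 0:
        raise ValueError("inter-step variance exceeds the total VE budget")
    return ve


def _default_map_geometry(n_qtl: int, n_linkage_groups: int,
                          rng: np.random.Generator):
    groups = (np.arange(n_qtl) * n_linkage_groups) // max(n_qtl, 1)
    pos = np.empty(n_qtl)
    for g in np.unique(groups):
        m = groups == g
        pos[m] = np.sort(rng.uniform(0.0, 100.0, int(m.sum())))
    return groups, pos


def init_genetic_setup(n_qtl: int, va_target: float, n_founders: int,
                       rng: np.random.Generator, *,
                       mean_target: float = 0.0, h2: float = 0.3,
                       ve_step: float = 0.0, tol_va: float = 0.02,
                       mean_tol_factor: float = 0.05,
                       kappa_contrib: float = 0.5, kappa_freq: float = 2.0,
                       p_min: float = 0.05, n_linkage_groups: int = 10,
                       max_iter: int = 1000,
                       ) -> Tuple[GeneticSetup, np.ndarray]:
    """Stochastic search for a genetic architecture realizing the targets.

    Each iteration draws per-locus contributions to VA from a gamma
    distribution with shape ``kappa_contrib`` (small shape -> few QTL of
    large contribution), allele frequencies from a gamma draw mapped through
    its own CDF into (p_min, 1 - p_min), deduces the allelic effects from
    the HWE identity c_l = 8 p_l q_l a_l^2, and samples founder haplotypes with
    independent Bernoulli(p_l) alleles (linkage equilibrium).  The draw is
    accepted when the realized founder variance is within ``tol_va``
    (relative) of ``va_target`` and the realized mean within
    ``mean_tol_factor * sqrt(va_target)`` of ``mean_target``.

    Returns the setup and the (n_founders, n_qtl, 2) founder genotypes.  If
    ``max_iter`` is exhausted the best draw is returned with
    ``converged=False`` and a warning.
    """
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    if va_target <= 0 or tol_va <= 0:
        raise ValueError("va_target and tol_va must be positive")
    groups, positions = _default_map_geometry(n_qtl, n_linkage_groups, rng)
    mean_tol = mean_tol_factor * np.sqrt(va_target)

    best = None
    best_score = np.inf
    for it in range(1, max_iter + 1):
        contrib = rng.gamma(kappa_contrib, 1.0, n_qtl)
        contrib *= va_target / contrib.sum()
        draw = rng.gamma(kappa_freq, 1.0, n_qtl)
        p = p_min + (1.0 - 2.0 * p_min) * stats.gamma.cdf(draw, kappa_freq)
        # invert the HWE contribution 8 p q a^2 = c_l (homozygotes are +/-2a)
        a = np.sqrt(contrib / (8.0 * p * (1.0 - p)))
        qmap = QTLMap(a, p, groups, positions)
        geno = (rng.random((n_founders, n_qtl, 2))
                < p[None, :, None]).astype(np.uint8)
        gv = genotypic_value(geno, qmap)
        va = float(np.var(gv, ddof=1))
        mu = float(np.mean(gv))
        err_va = abs(va - va_target) / va_target
        err_mu = abs(mu - mean_target)
        score = err_va / tol_va + err_mu / mean_tol
        if score < best_score:
            best_score = score
            best = (qmap, geno, va, mu, it)
        if err_va <= tol_va and err_mu <= mean_tol:
            break
    qmap, geno, va, mu, it = best
    converged = (abs(va - va_target) / va_target <= tol_va
                 and abs(mu - mean_target) <= mean_tol)
    if not converged:
        warnings.warn(
            f"genetic setup optimizer exhausted {max_iter} iterations; "
            f"best fit VA={va:.3g} mean={mu:.3g} returned", RuntimeWarning)
    setup = GeneticSetup(
        qmap=qmap, va_target=va_target, mean_target=mean_target, h2=h2,
        ve_fixed=environmental_variance(va_target, h2, ve_step),
        ve_step=ve_step, realized_va=va, realized_mean=mu,
        n_iter=it, converged=converged)
    return setup, geno


def draw_env_fixed(n: int, ve_fixed: float, rng: np.random.Generator
                   ) -> np.ndarray:
    """Lifetime environmental deviations, Normal(0, VE_fixed)."""
    if ve_fixed <= 0:
        return np.zeros(n)
    return rng.normal(0.0, np.sqrt(ve_fixed), n)
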