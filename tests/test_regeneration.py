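"""Fecundity, dispersal kernel, mating and seedling generation."""

import numpy as np
import pytest
from scipy import integrate

import sylvagen.genetics as gen
from sylvagen.regeneration import (DispersalKernel, FecundityParams,
                                   female_fecundity, male_fertility,
                                   offspring_genotypes,
                                   sample_seedling_parents,
                                   seed_rain_contributions)
from sylvagen.fixtures import two_locus_setup


@pytest.fixture
def fec():
    return FecundityParams()


class TestFemaleFecundity:
    def test_below_diameter_threshold_sterile(self, fec, rng):
        seeds = female_fecundity(14.0, 10.0, 60, 0.0, rng, fec)
        assert seeds[0] == 0.0

    def test_at_recruitment_age_sterile(self, fec, rng):
        # fertility requires age strictly above the recruitment age
        seeds = female_fecundity(30.0, 10.0, 25, 0.0, rng, fec)
        assert seeds[0] == 0.0

    def test_larger_tree_produces_more_seed_on_average(self, fec, rng):
        small = female_fecundity(np.full(10000, 20.0), 10.0, 60, 0.0, rng,
                                 fec)
        large = female_fecundity(np.full(10000, 40.0), 10.0, 60, 0.0, rng,
                                 fec)
        assert large.mean() > small.mean()


class TestMaleFertility:
    def test_non_fertile_is_zero(self, fec):
        assert male_fertility(14.0, 60, fec) == 0.0
        assert male_fertility(30.0, 25, fec) == 0.0

    def test_index_is_square_of_diameter(self, fec):
        r = male_fertility(40.0, 60, fec) / male_fertility(20.0, 60, fec)
        assert r == pytest.approx(4.0)

    def test_paternity_shares_follow_squared_diameter(self, fec, rng):
        w = np.array([male_fertility(20.0, 60, fec),
                      male_fertility(40.0, 60, fec)])
        contrib = np.ones((1, 1))
        n = np.array([10000])
        _, _, fathers = sample_seedling_parents(contrib, n, w, rng)
        share = (fathers == 1).mean()
        se = np.sqrt(0.8 * 0.2 / 10000)
        assert abs(share - 0.8) < 3 * se


class TestDispersalKernel:
    def test_density_integrates_to_one(self):
        k = DispersalKernel()
        total, _ = integrate.quad(lambda r: 2 * np.pi * r * k.density(r),
                                  0, 5000, limit=200)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_mean_dispersal_distance(self, rng):
        k = DispersalKernel()
        d = k.sample_distances(10 ** 6, rng)
        assert d.mean() == pytest.approx(240.0, rel=0.01)

    def test_mean_distance_by_quadrature(self):
        k = DispersalKernel()
        mean, _ = integrate.quad(
            lambda r: 2 * np.pi * r * r * k.density(r), 0, 50000, limit=400)
        assert mean == pytest.approx(240.0, rel=1e-3)

    def test_fat_tail_shape_bounds(self):
        with pytest.raises(ValueError):
            DispersalKernel(shape=2.5)


class TestSeedRain:
    def test_single_mother_at_center(self):
        k = DispersalKernel()
        centers = np.array([[7.5, 7.5]])
        contrib = seed_rain_contributions(
            np.array([[7.5, 7.5]]), np.array([1000.0]), centers, k)
        assert contrib[0, 0] == pytest.approx(1000.0 * k.density(0.0))

    def test_contribution_decays_with_distance(self):
        k = DispersalKernel()
        centers = np.array([[0.0, 0.0], [100.0, 0.0]])
        contrib = seed_rain_contributions(
            np.array([[0.0, 0.0]]), np.array([1000.0]), centers, k)
        assert contrib[0, 0] > contrib[0, 1] > 0


class TestSeedlingGeneration:
    def test_equidistant_equal_mothers_share_uniformly(self, rng):
        contrib = np.full((4, 1), 2.5)
        n = np.array([8000])
        _, mothers, _ = sample_seedling_parents(contrib, n,
                                                np.ones(4), rng)
        counts = np.bincount(mothers, minlength=4)
        se = np.sqrt(0.25 * 0.75 * 8000)
        assert np.all(np.abs(counts - 2000) < 3 * se)

    def test_single_fertile_selfing_parent(self, rng):
        contrib = np.array([[4.0]])
        px, mothers, fathers = sample_seedling_parents(
            contrib, np.array([50]), np.array([400.0]), rng)
        assert np.all(mothers == 0) and np.all(fathers == 0)

    def test_offspring_allele_frequency_tracks_weighted_parents(self, rng):
        setup, geno = gen.init_genetic_setup(10, 0.0042, 500, rng)
        qmap = setup.qmap
        mothers_idx = rng.integers(0, 500, 10000)
        weights = rng.uniform(0.5, 2.0, 500)
        fathers_idx = rng.choice(500, size=10000, p=weights / weights.sum())
        off = offspring_genotypes(geno[mothers_idx], geno[fathers_idx],
                                  qmap, rng)
        p_off = off.sum(axis=(0, 2)) / (2 * off.shape[0])
        p_m = geno[mothers_idx].sum(axis=(0, 2)) / (2 * 10000)
        dosage = geno.sum(axis=2) / 2.0
        p_f = (weights[:, None] * dosage).sum(0) / weights.sum()
        expected = 0.5 * (p_m + p_f)
        se = np.sqrt(expected * (1 - expected) / (2 * 10000))
        assert np.all(np.abs(p_off - expected) < 4 * np.maximum(se, 1e-3))

    def test_offspring_alleles_traceable_to_parents(self, rng):
        """Every transmitted haplotype allele exists in the corresponding
        parent at that locus (pedigree integrity at the allele level)."""
        setup, geno = gen.init_genetic_setup(10, 0.0042, 50, rng)
        mi = rng.integers(0, 50, 200)
        fi = rng.integers(0, 50, 200)
        off = offspring_genotypes(geno[mi], geno[fi], setup.qmap, rng)
        for k, parents in ((0, geno[mi]), (1, geno[fi])):
            allele = off[:, :, k]
            ok = (allele == parents[:, :, 0]) | (allele == parents[:, :, 1])
            assert ok.all()

    def test_no_seed_rain_pixel_rejected(self, rng):
        with pytest.raises(ValueError, match="seed rain"):
            sample_seedling_parents(np.zeros((2, 1)), np.array([5]),
                                    np.ones(2), rng)
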