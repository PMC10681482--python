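"""Quantitative genetics: genotype arithmetic, the founder optimizer,
meiosis, and population summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sylvagen.genetics as gen
from sylvagen.fixtures import enumerate_genotypes, two_locus_setup


def hwe_genotype_probs(p):
    """P(dosage = 0, 1, 2) under Hardy-Weinberg."""
    q = 1 - p
    return np.array([q * q, 2 * p * q, p * p])


class TestGenotypicValue:
    def test_fully_heterozygous_is_zero(self):
        setup = two_locus_setup()
        het = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        assert gen.genotypic_value(het, setup.qmap) == 0.0

    def test_single_locus_homozygotes(self):
        qmap = gen.QTLMap([0.05], [0.5], [0], [0.0])
        assert gen.genotypic_value(
            np.array([[1, 1]], np.uint8), qmap) == pytest.approx(0.10)
        assert gen.genotypic_value(
            np.array([[0, 0]], np.uint8), qmap) == pytest.approx(-0.10)

    def test_matches_bruteforce_allele_loop(self, rng):
        L = 50
        qmap = gen.QTLMap(rng.uniform(0, 0.05, L), rng.uniform(0.1, 0.9, L),
                          np.zeros(L, int), np.sort(rng.uniform(0, 100, L)))
        geno = rng.integers(0, 2, (20, L, 2)).astype(np.uint8)
        vals = gen.genotypic_value(geno, qmap)
        for i in range(20):
            expected = 0.0
            for l in range(L):
                for h in range(2):
                    expected += qmap.effect[l] if geno[i, l, h] else \
                        -qmap.effect[l]
            assert vals[i] == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        qmap = gen.QTLMap([0.05], [0.5], [0], [0.0])
        with pytest.raises(ValueError, match="match"):
            gen.genotypic_value(np.zeros((3, 2, 2), np.uint8), qmap)


class TestPhenotype:
    def test_components_sum(self):
        assert gen.phenotypic_vigor(0.02, -0.01, 0.0) == pytest.approx(0.01)

    def test_zero_environment_reduces_to_genotype(self, rng):
        g = rng.normal(size=100)
        np.testing.assert_allclose(gen.phenotypic_vigor(g, 0.0, 0.0), g)

    def test_founder_phenotypic_variance_recovers_va_over_h2(self, rng):
        # VP = VA / h2 = 0.0042 / 0.3 = 0.014
        setup, geno = gen.init_genetic_setup(
            50, 0.0042, 10000, rng, h2=0.3)
        phen = gen.phenotypic_vigor(
            gen.genotypic_value(geno, setup.qmap),
            gen.draw_env_fixed(10000, setup.ve_fixed, rng))
        assert np.var(phen, ddof=1) == pytest.approx(0.014, rel=0.05)


class TestInitGeneticSetup:
    @pytest.mark.parametrize("n_qtl", [10, 50])
    def test_realized_founder_va_within_tolerance(self, n_qtl):
        rng = np.random.default_rng(42 + n_qtl)
        setup, geno = gen.init_genetic_setup(n_qtl, 0.0042, 5000, rng)
        assert setup.converged
        assert 0.004116 <= setup.realized_va <= 0.004284
        # realized VA is the sample variance of the founders' values
        assert setup.realized_va == pytest.approx(
            np.var(gen.genotypic_value(geno, setup.qmap), ddof=1))

    def test_different_optimizer_seeds_give_different_architectures(self):
        s1, _ = gen.init_genetic_setup(
            50, 0.0042, 2000, np.random.default_rng(1))
        s2, _ = gen.init_genetic_setup(
            50, 0.0042, 2000, np.random.default_rng(2))
        assert not np.allclose(s1.qmap.effect, s2.qmap.effect)
        assert not np.allclose(s1.qmap.init_freq, s2.qmap.init_freq)

    def test_single_locus_effect_from_variance_identity(self):
        """At p = 1/2 the HWE identity 8 p q a^2 = VA gives a = sqrt(VA/2),
        checked against a full enumeration of the genotype distribution."""
        va = 0.0042
        a = np.sqrt(va / 2.0)
        qmap = gen.QTLMap([a], [0.5], [0], [0.0])
        geno = enumerate_genotypes(1)
        vals = gen.genotypic_value(geno, qmap)
        probs = hwe_genotype_probs(0.5)
        mean = np.sum(probs * vals)
        assert np.sum(probs * (vals - mean) ** 2) == pytest.approx(va)

    def test_founders_start_near_linkage_equilibrium(self, rng):
        setup, geno = gen.init_genetic_setup(10, 0.0042, 8000, rng)
        hap = geno[:, :, 0]
        corr = np.corrcoef(hap[:, 0], hap[:, 1])[0, 1]
        assert abs(corr) < 3 / np.sqrt(8000)


class TestMakeGamete:
    def test_homozygous_parent_transmits_haplotype(self, rng):
        setup = two_locus_setup()
        parent = np.array([[1, 1], [0, 0]], np.uint8)
        for _ in range(20):
            np.testing.assert_array_equal(
                gen.make_gamete(parent, setup.qmap, rng), [1, 0])

    def test_mendelian_segregation_at_heterozygous_locus(self, rng):
        qmap = gen.QTLMap([0.05], [0.5], [0], [0.0])
        parents = np.tile(np.array([[[1, 0]]], np.uint8), (10000, 1, 1))
        gam = gen.make_gametes(parents, qmap, rng)
        frac = gam[:, 0].mean()
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(10000)

    def test_haldane_recombination_at_50_cM(self, rng):
        # coupling double heterozygote; expected recombinants (1-e^-1)/2
        qmap = gen.QTLMap([0.01, 0.01], [0.5, 0.5], [0, 0], [0.0, 50.0])
        parent = np.array([[1, 0], [1, 0]], np.uint8)
        parents = np.tile(parent[None], (10000, 1, 1))
        gam = gen.make_gametes(parents, qmap, rng)
        rec_frac = (gam[:, 0] != gam[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-1.0))
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert abs(rec_frac - expected) < 3 * se

    def test_unlinked_loci_assort_independently(self, rng):
        qmap = gen.QTLMap([0.01, 0.01], [0.5, 0.5], [0, 1], [0.0, 0.0])
        parent = np.array([[1, 0], [1, 0]], np.uint8)
        parents = np.tile(parent[None], (10000, 1, 1))
        gam = gen.make_gametes(parents, qmap, rng)
        rec_frac = (gam[:, 0] != gam[:, 1]).mean()
        assert abs(rec_frac - 0.5) < 3 * 0.5 / np.sqrt(10000)


class TestPopulationSummaries:
    def test_he_maximal_at_half_frequency(self):
        geno = np.array([[[1, 0]], [[0, 1]]], np.uint8)
        assert gen.expected_heterozygosity(geno) == pytest.approx(0.5)

    def test_fixed_locus_contributes_zero(self):
        geno = np.ones((5, 2, 2), np.uint8)
        geno[:, 1, :] = [1, 0]  # locus 1 at p=0.5, locus 0 fixed
        assert gen.expected_heterozygosity(geno) == pytest.approx(0.25)

    def test_he_matches_allele_counting(self, rng):
        geno = rng.integers(0, 2, (20, 8, 2)).astype(np.uint8)
        he = gen.expected_heterozygosity(geno)
        byhand = []
        for l in range(8):
            p = geno[:, l, :].sum() / 40.0
            byhand.append(2 * p * (1 - p))
        assert he == pytest.approx(np.mean(byhand), abs=1e-12)

    def test_he_requires_individuals(self):
        with pytest.raises(ValueError):
            gen.expected_heterozygosity(np.zeros((0, 3, 2), np.uint8))

    def test_monomorphic_population_has_zero_variance(self):
        assert gen.additive_variance(np.zeros(10)) == 0.0

    def test_founder_variance_matches_hwe_identity(self, rng):
        setup, geno = gen.init_genetic_setup(20, 0.0042, 8000, rng)
        va = gen.additive_variance(gen.genotypic_value(geno, setup.qmap))
        p_hat = geno.sum(axis=(0, 2)) / (2 * geno.shape[0])
        expected = np.sum(8 * p_hat * (1 - p_hat) * setup.qmap.effect ** 2)
        assert va == pytest.approx(expected, rel=0.05)

    def test_truncation_selection_reduces_variance(self, rng):
        setup, geno = gen.init_genetic_setup(30, 0.0042, 4000, rng)
        gv = gen.genotypic_value(geno, setup.qmap)
        survivors = gv[gv > np.median(gv)]
        assert gen.additive_variance(survivors) < gen.additive_variance(gv)


class TestInheritanceProperties:
    def test_allele_conservation_under_random_mating(self, rng):
        setup, geno = gen.init_genetic_setup(10, 0.0042, 2000, rng)
        mothers = geno[rng.integers(0, 2000, 5000)]
        fathers = geno[rng.integers(0, 2000, 5000)]
        off = np.stack([gen.make_gametes(mothers, setup.qmap, rng),
                        gen.make_gametes(fathers, setup.qmap, rng)], axis=2)
        p_parent = geno.sum(axis=(0, 2)) / (2 * geno.shape[0])
        p_off = off.sum(axis=(0, 2)) / (2 * off.shape[0])
        se = np.sqrt(p_parent * (1 - p_parent) / (2 * off.shape[0]))
        # sampling of parents adds variance; allow a broad 4-SE band
        assert np.all(np.abs(p_off - p_parent) < 4 * np.maximum(se, 1e-3))

    def test_heritability_recovered_by_midparent_regression(self, rng):
        setup, geno = gen.init_genetic_setup(50, 0.0042, 4000, rng, h2=0.3)
        n_fam = 4000
        mi = rng.integers(0, 4000, n_fam)
        fi = rng.integers(0, 4000, n_fam)
        off = np.stack([gen.make_gametes(geno[mi], setup.qmap, rng),
                        gen.make_gametes(geno[fi], setup.qmap, rng)], axis=2)
        gv = gen.genotypic_value(geno, setup.qmap)
        env = lambda n: gen.draw_env_fixed(n, setup.ve_fixed, rng)
        phen = gv + env(4000)
        off_phen = gen.genotypic_value(off, setup.qmap) + env(n_fam)
        midparent = 0.5 * (phen[mi] + phen[fi])
        beta = np.polyfit(midparent, off_phen, 1)[0]
        assert beta == pytest.approx(0.3, abs=0.1)


class TestEnvironmentalVariance:
    def test_budget_identity(self):
        assert gen.environmental_variance(0.0042, 0.3) == pytest.approx(
            0.0042 * 0.7 / 0.3)

    def test_interstep_over_budget_rejected(self):
        with pytest.raises(ValueError):
            gen.environmental_variance(0.0042, 0.9, ve_step=0.01)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_he_bounded_for_diallelic_loci(seed):
    rng = np.random.default_rng(seed)
    geno = (rng.random((rng.integers(1, 30), 5, 2)) < rng.random(5)[None, :, None])
    he = gen.expected_heterozygosity(geno.astype(np.uint8))
    assert 0.0 <= he <= 0.5
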