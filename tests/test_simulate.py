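"""Simulator: founding LD, drift, trait architecture, selection response."""

import numpy as np
import pytest

from popdiseq import (
    SimConfig,
    allele_freqs,
    assign_effects,
    expected_d_decay,
    expected_founding_d,
    found_composite,
    gene_diversity,
    haldane_c,
    phenotypes,
    random_mate,
    sample_individuals,
    select_truncation,
    temporal_scan,
)
from popdiseq.simulate import SimulationError


def _enumeration_d(c: float) -> float:
    """Oracle: gamete-type enumeration for an AB/ab double heterozygote.

    F1 gametes come as AB and ab with frequency (1-c)/2 each and Ab, aB with
    c/2 each; the gamete-pool D is then freq(AB) - p_A p_B.
    """
    freq = {"AB": (1 - c) / 2, "ab": (1 - c) / 2, "Ab": c / 2, "aB": c / 2}
    p_a = freq["AB"] + freq["Ab"]
    p_b = freq["AB"] + freq["aB"]
    return freq["AB"] - p_a * p_b


class TestFoundingLD:
    @pytest.mark.parametrize("c", [0.0, 0.1, 0.25, 0.5])
    def test_expected_d_matches_gamete_enumeration(self, c):
        assert expected_founding_d(c) == pytest.approx(_enumeration_d(c), abs=1e-15)

    def test_completely_linked_pair_gives_quarter(self):
        assert expected_founding_d(0.0) == 0.25

    def test_realized_gametic_d(self, small_config):
        """Linked pairs hit (1-2c)/4 in |D|; unlinked pairs stay near 0."""
        linked, unlinked = [], []
        for s in range(20):
            cfg = SimConfig(**{**small_config.__dict__, "seed": 100 + s, "pop_size": 100})
            pop = found_composite(cfg)
            m = pop.genome.map
            cols = {m.snp_id[i]: i for i in range(len(m))}
            linked.append(abs(pop.gametic_d(cols["s1_0"], cols["s1_1"])))   # 3 Mb apart
            unlinked.append(pop.gametic_d(cols["s1_0"], cols["s2_0"]))      # other chromosome
        c = haldane_c(3e6, small_config.cm_per_mb)
        assert np.mean(linked) == pytest.approx((1 - 2 * c) / 4, abs=0.03)
        assert abs(np.mean(unlinked)) < 0.02
        assert np.mean(np.abs(unlinked)) < 4 / np.sqrt(100)


class TestExpectedPropagation:
    @pytest.mark.parametrize("c", [0.0, 0.05, 0.1, 0.25, 0.5])
    def test_decay_recursion_closed_form(self, c):
        d = d0 = expected_founding_d(c)
        for t in range(1, 21):
            d *= 1 - c
            assert abs(expected_d_decay(d0, c, t) - d) <= 1e-12

    def test_haldane_monotone_and_capped(self):
        dist = np.linspace(0, 5e8, 200)
        c = haldane_c(dist)
        assert np.all(np.diff(c) >= 0)
        assert c[0] == 0.0
        assert np.all(c <= 0.5)


class TestArchitecture:
    def test_default_architecture_counts_and_fractions(self):
        arch = assign_effects(SimConfig(seed=3))
        assert arch.n_loci == 100
        assert arch.is_qtl.sum() == 19
        # each QTL explains exactly the configured share of Vp at p = 0.5
        np.testing.assert_allclose(arch.qtl_variance_fractions(), 0.024, atol=1e-12)
        assert np.all(np.abs(arch.d / arch.a) <= 1.2 + 1e-9)

    def test_extreme_homozygotes_pin_the_genotypic_range(self):
        arch = assign_effects(SimConfig(seed=4))
        hi = arch.genotypic_values(np.full((1, arch.n_loci), 2))
        lo = arch.genotypic_values(np.zeros((1, arch.n_loci), dtype=int))
        assert hi[0] == pytest.approx(50.0)
        assert lo[0] == pytest.approx(5.0)

    def test_additive_limit(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "dominance_range": (0.0, 0.0)})
        arch = assign_effects(cfg)
        assert np.all(arch.d == 0.0)

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(SimulationError, match="exceeds h2"):
            SimConfig(n_qtl=30, per_qtl_var_fraction=0.024, h2=0.5)

    def test_causal_positions_avoid_analysis_snps(self, small_config):
        arch = assign_effects(small_config)
        panel = small_config.panel()
        panel_keys = set(zip(map(int, panel.chromosome), map(int, panel.position_bp)))
        arch_keys = set(zip(map(int, arch.chromosome), map(int, arch.position_bp)))
        assert not panel_keys & arch_keys


class TestPhenotypes:
    def test_h2_one_gives_exact_genotypic_values(self, small_config):
        arch = assign_effects(small_config)
        pop = phenotypes(found_composite(small_config, arch), arch, h2=1.0)
        np.testing.assert_array_equal(pop.y, pop.g)

    def test_h2_zero_rejected(self, small_config):
        arch = assign_effects(small_config)
        pop = found_composite(small_config, arch)
        with pytest.raises(SimulationError):
            phenotypes(pop, arch, h2=0.0)

    def test_heritability_recovered_at_n300(self):
        """Regression of y on g: slope 1, R^2 near the configured h2 = 0.5."""
        r2s, slopes = [], []
        for s in range(3):
            cfg = SimConfig(pop_size=300, seed=40 + s)
            arch = assign_effects(cfg)
            pop = phenotypes(found_composite(cfg, arch), arch)
            slope = np.polyfit(pop.g, pop.y, 1)[0]
            r2s.append(np.corrcoef(pop.g, pop.y)[0, 1] ** 2)
            slopes.append(slope)
        assert np.mean(r2s) == pytest.approx(0.5, abs=0.05)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.15)


class TestRandomMating:
    def test_zero_generations_is_identity(self, small_config):
        pop = found_composite(small_config)
        pop2 = random_mate(pop, 0)
        np.testing.assert_array_equal(pop.haplotypes, pop2.haplotypes)

    def test_allele_frequencies_conserved_in_expectation(self, small_config):
        deltas = []
        for s in range(30):
            cfg = SimConfig(**{**small_config.__dict__, "seed": 200 + s})
            pop = found_composite(cfg)
            p0 = allele_freqs(pop.genotype_matrix()).p
            p2 = allele_freqs(random_mate(pop, 2).genotype_matrix()).p
            deltas.append(np.mean(p2 - p0))
        assert abs(np.mean(deltas)) < 0.01

    def test_he_decay_matches_wright_fisher_rate(self, small_config):
        """Equal contributions: Ne ~ 2N - 1, so He shrinks by ~(1 - 1/(2Ne))^t."""
        n, t = 50, 10
        ratios = []
        for s in range(30):
            cfg = SimConfig(**{**small_config.__dict__, "seed": 300 + s, "pop_size": n})
            pop = found_composite(cfg)
            he0 = gene_diversity(allele_freqs(pop.genotype_matrix()))[1]
            he1 = gene_diversity(allele_freqs(random_mate(pop, t).genotype_matrix()))[1]
            ratios.append(he1 / he0)
        expected = (1 - 1 / (2 * (2 * n - 1))) ** t
        assert np.mean(ratios) == pytest.approx(expected, abs=0.02)

    def test_offspring_count_can_grow_from_few_parents(self, small_config):
        pop = found_composite(small_config)
        small = sample_individuals(pop, 6, rng_seed=1)
        grown = random_mate(small, 1, n_offspring=40)
        assert grown.n_individuals == 40


class TestSampling:
    def test_full_sample_is_permutation(self, small_config):
        pop = found_composite(small_config)
        samp = sample_individuals(pop, pop.n_individuals, rng_seed=2)
        a = np.sort(pop.haplotypes.reshape(pop.n_individuals, -1), axis=0)
        b = np.sort(samp.haplotypes.reshape(pop.n_individuals, -1), axis=0)
        np.testing.assert_array_equal(a, b)

    def test_single_individual_and_oversample_error(self, small_config):
        pop = found_composite(small_config)
        assert sample_individuals(pop, 1, rng_seed=3).n_individuals == 1
        with pytest.raises(SimulationError):
            sample_individuals(pop, pop.n_individuals + 1)

    def test_sample_frequency_close_to_population(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "pop_size": 200})
        pop = found_composite(cfg)
        samp = sample_individuals(pop, 50, rng_seed=4)
        p_pop = allele_freqs(pop.genotype_matrix()).p
        p_s = allele_freqs(samp.genotype_matrix()).p
        bound = 3 * np.sqrt(p_pop * (1 - p_pop) / (2 * 50))
        assert np.mean(np.abs(p_s - p_pop) <= bound) >= 0.90


class TestSelection:
    def test_no_selection_keeps_everyone(self, small_config):
        arch = assign_effects(small_config)
        pop = phenotypes(found_composite(small_config, arch), arch)
        sel = select_truncation(pop, 1.0)
        assert sel.n_individuals == pop.n_individuals

    def test_too_few_parents_rejected(self, small_config):
        arch = assign_effects(small_config)
        pop = phenotypes(found_composite(small_config, arch), arch)
        with pytest.raises(SimulationError):
            select_truncation(pop, 0.01)

    def test_response_to_selection_is_monotone(self):
        """Four cycles of 20% truncation push the genotypic mean up each cycle."""
        cfg = SimConfig(pop_size=100, seed=77)
        arch = assign_effects(cfg)
        pop = phenotypes(found_composite(cfg, arch), arch)
        means = [pop.g.mean()]
        for _ in range(4):
            parents = select_truncation(pop, 0.2, "high")
            pop = phenotypes(random_mate(parents, 1, n_offspring=100), arch)
            means.append(pop.g.mean())
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_selection_inflates_temporal_significance(self):
        """Truncation selection drags linked SNP frequencies along (hitchhiking),
        so more SNPs show significant change than under pure drift."""
        sel_counts, drift_counts = [], []
        for s in range(4):
            cfg = SimConfig(pop_size=100, seed=500 + s)
            arch = assign_effects(cfg)
            base = phenotypes(found_composite(cfg, arch), arch)
            g0 = base.genotype_matrix()
            sel = base
            for _ in range(4):
                sel = phenotypes(random_mate(select_truncation(sel, 0.2), 1,
                                             n_offspring=100), arch)
            drift = random_mate(base, 4)
            sel_counts.append(temporal_scan(g0, sel.genotype_matrix())[1].n_significant)
            drift_counts.append(temporal_scan(g0, drift.genotype_matrix())[1].n_significant)
        assert sum(sel_counts) > sum(drift_counts)
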