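"""Allele frequencies, HWE, EM haplotype estimation, LD measures, F_ST."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdiseq import (
    GenotypeMatrix,
    MISSING,
    SnpMap,
    allele_freqs,
    em_haplotype_freqs,
    fst_pairwise,
    gene_diversity,
    hwe_test,
    ld_all_pairs,
    ld_decay_table,
    ld_from_haplotypes,
    ld_summaries,
    polymorphic_mask,
)
from popdiseq.popgen import (
    HaplotypeFreqs,
    PopgenError,
    em_step,
    genotype_loglik,
    snp_gate,
)


def _matrix(columns, chroms=None, positions=None):
    cols = [np.asarray(c, dtype=np.int8) for c in columns]
    m = len(cols)
    snp_map = SnpMap(
        [f"s{j}" for j in range(m)],
        chroms if chroms is not None else [1] * m,
        np.asarray(positions) if positions is not None else np.arange(1, m + 1) * 1000,
    )
    return GenotypeMatrix([f"i{k}" for k in range(len(cols[0]))], np.column_stack(cols), snp_map)


class TestSingleLocus:
    def test_allele_frequency_examples(self):
        f = allele_freqs(_matrix([[0, 1, 2], [2, 2, 2], [0, 1, MISSING]]))
        assert f.p[0] == 0.5
        assert (f.p[1], f.maf[1]) == (1.0, 0.0)
        assert f.p[2] == 0.25  # over the 2 called individuals
        assert list(f.n_called) == [3, 3, 2]

    def test_all_missing_snp_rejected(self):
        with pytest.raises(PopgenError):
            allele_freqs(_matrix([[MISSING, MISSING]]))

    def test_polymorphic_boundary(self):
        f = allele_freqs(_matrix([[0, 1, 2]]))
        f.maf = np.array([0.009, 0.01, 0.0])
        assert list(polymorphic_mask(f)) == [False, True, False]

    def test_gene_diversity_values(self):
        f = allele_freqs(_matrix([[0, 1, 2]]))
        f.p = np.array([0.5, 0.9, 0.0])
        he, mean = gene_diversity(f)
        np.testing.assert_allclose(he, [0.5, 0.18, 0.0], atol=1e-15)
        assert mean == pytest.approx(np.mean([0.5, 0.18, 0.0]))


class TestHwe:
    def test_perfect_proportions(self):
        r = hwe_test(([25], [50], [25]))
        assert r.chi2[0] == pytest.approx(0.0)
        assert r.p_value[0] == pytest.approx(1.0)
        assert r.in_equilibrium[0]

    @pytest.mark.parametrize("counts", [(50, 0, 50), (0, 100, 0)])
    def test_extreme_departures(self, counts):
        r = hwe_test(([counts[0]], [counts[1]], [counts[2]]))
        assert r.chi2[0] == pytest.approx(100.0)  # expected (25, 50, 25) at n=100
        assert r.p_value[0] < 1e-20
        assert not r.in_equilibrium[0]

    def test_monomorphic_untestable(self):
        r = hwe_test(([0], [0], [10]))
        assert not r.testable[0]
        assert not r.in_equilibrium[0]


class TestEm:
    def test_unambiguous_table_closed_form(self):
        # 10 AABB + 10 aabb individuals, no double heterozygote
        table = np.zeros((3, 3))
        table[2, 2] = 10
        table[0, 0] = 10
        h = em_haplotype_freqs(table)
        assert h.em_iterations <= 2
        assert (h.p_AB, h.p_ab, h.p_Ab, h.p_aB) == (0.5, 0.5, 0.0, 0.0)

    def test_all_double_heterozygotes_is_a_likelihood_ridge(self):
        table = np.zeros((3, 3))
        table[1, 1] = 20
        h = em_haplotype_freqs(table)
        assert h.phase_uninformative
        assert (h.p_AB, h.p_Ab, h.p_aB, h.p_ab) == (0.25, 0.25, 0.25, 0.25)
        # likelihood is flat across phase splits with the same marginals
        ll_cis = genotype_loglik(table, [0.5, 0.0, 0.0, 0.5])
        ll_trans = genotype_loglik(table, [0.0, 0.5, 0.5, 0.0])
        assert ll_cis == pytest.approx(ll_trans, abs=1e-12)

    def test_marginals_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = rng.integers(0, 20, size=(3, 3)).astype(float)
            h = em_haplotype_freqs(table)
            n = table.sum()
            p_a = (2 * table[2].sum() + table[1].sum()) / (2 * n)
            p_b = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
            assert h.p_A == pytest.approx(p_a, abs=1e-6)
            assert h.p_B == pytest.approx(p_b, abs=1e-6)

    def test_loglik_monotone_over_iterations(self):
        rng = np.random.default_rng(1)
        table = rng.integers(0, 30, size=(3, 3)).astype(float)
        h = np.array([0.1, 0.2, 0.3, 0.4])
        lls = [genotype_loglik(table, h)]
        for _ in range(50):
            h = em_step(table, h)
            lls.append(genotype_loglik(table, h))
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_em_beats_grid_and_random_search_oracles(self):
        """EM should reach at least the likelihood of (a) a fine 1-D grid over
        p_AB at the observed allele frequencies and (b) random simplex search."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            true = rng.dirichlet([2, 2, 2, 2])
            # sample 200 diploids under random union of gametes
            hap = {"AB": true[0], "Ab": true[1], "aB": true[2], "ab": true[3]}
            geno = {(0, 0): hap["ab"] ** 2, (0, 1): 2 * hap["aB"] * hap["ab"],
                    (0, 2): hap["aB"] ** 2, (1, 0): 2 * hap["Ab"] * hap["ab"],
                    (1, 1): 2 * (hap["AB"] * hap["ab"] + hap["Ab"] * hap["aB"]),
                    (1, 2): 2 * hap["AB"] * hap["aB"], (2, 0): hap["Ab"] ** 2,
                    (2, 1): 2 * hap["AB"] * hap["Ab"], (2, 2): hap["AB"] ** 2}
            cells = list(geno)
            draws = rng.multinomial(200, [geno[c] for c in cells])
            table = np.zeros((3, 3))
            for (i, j), n in zip(cells, draws):
                table[i, j] = n
            h = em_haplotype_freqs(table)

            n = table.sum()
            p_a = (2 * table[2].sum() + table[1].sum()) / (2 * n)
            p_b = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
            best = -np.inf
            lo = max(0.0, p_a + p_b - 1.0)
            hi = min(p_a, p_b)
            for pab in np.linspace(lo, hi, 2001):
                cand = [pab, p_a - pab, p_b - pab, 1 - p_a - p_b + pab]
                if min(cand) < -1e-12:
                    continue
                best = max(best, genotype_loglik(table, np.clip(cand, 0, 1)))
            for cand in rng.dirichlet([1, 1, 1, 1], size=2000):
                best = max(best, genotype_loglik(table, cand))
            assert h.em_loglik >= best - 1e-6


class TestLdMeasures:
    def test_independence(self):
        h = HaplotypeFreqs(0.25, 0.25, 0.25, 0.25, 1, 0.0)
        pair = ld_from_haplotypes(h)
        assert (pair.D, pair.Dprime, pair.r2) == (0.0, 0.0, 0.0)

    def test_complete_association(self):
        pair = ld_from_haplotypes(HaplotypeFreqs(0.5, 0.0, 0.0, 0.5, 1, 0.0))
        assert (pair.D, pair.Dprime, pair.r2) == (0.25, 1.0, 1.0)

    def test_worked_example(self):
        pair = ld_from_haplotypes(HaplotypeFreqs(0.5, 0.1, 0.2, 0.2, 1, 0.0))
        assert pair.D == pytest.approx(0.08)
        # cross-check: D = p_AB - p_A p_B = 0.5 - 0.6 * 0.7
        assert pair.D == pytest.approx(0.5 - 0.6 * 0.7)
        assert pair.Dprime == pytest.approx(0.08 / 0.18)
        assert pair.r2 == pytest.approx(0.0064 / 0.0504)

    def test_monomorphic_marginal_rejected(self):
        with pytest.raises(PopgenError, match="monomorphic"):
            ld_from_haplotypes(HaplotypeFreqs(0.5, 0.5, 0.0, 0.0, 1, 0.0))

    def test_direct_formula_oracle_on_random_inputs(self):
        """1,000 random haplotype-frequency vectors against direct substitution."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            pab, pAb, paB, pabb = rng.dirichlet([1, 1, 1, 1])
            h = HaplotypeFreqs(pab, pAb, paB, pabb, 1, 0.0)
            if not (0 < h.p_A < 1 and 0 < h.p_B < 1):
                continue
            pair = ld_from_haplotypes(h)
            d = pab * pabb - pAb * paB
            dmax = min(h.p_A * (1 - h.p_B), (1 - h.p_A) * h.p_B) if d > 0 else \
                min(h.p_A * h.p_B, (1 - h.p_A) * (1 - h.p_B))
            assert abs(pair.D - d) <= 1e-12
            assert abs(pair.Dprime - (0.0 if d == 0 else abs(d) / dmax)) <= 1e-12
            assert abs(pair.r2 - (0.0 if d == 0 else d * d / (
                h.p_A * (1 - h.p_A) * h.p_B * (1 - h.p_B)))) <= 1e-12
            assert 0.0 <= pair.Dprime <= 1.0 + 1e-12
            assert 0.0 <= pair.r2 <= 1.0 + 1e-12

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=200)
    def test_bounds_property(self, raw):
        freqs = np.asarray(raw) / np.sum(raw)
        h = HaplotypeFreqs(*freqs, 1, 0.0)
        if not (1e-9 < h.p_A < 1 - 1e-9 and 1e-9 < h.p_B < 1 - 1e-9):
            return
        pair = ld_from_haplotypes(h)
        assert 0.0 <= pair.Dprime <= 1.0 + 1e-9
        assert 0.0 <= pair.r2 <= 1.0 + 1e-9

    def test_dprime_is_one_when_a_class_is_empty(self):
        pair = ld_from_haplotypes(HaplotypeFreqs(0.5, 0.3, 0.0, 0.2, 1, 0.0))
        assert pair.D != 0
        assert pair.Dprime == pytest.approx(1.0)


class TestPairScan:
    def _hwe_like(self, rng, n, m):
        # HWE genotypes at p = 0.5 so the gate keeps nearly everything
        return _matrix([rng.binomial(2, 0.5, size=n) for _ in range(m)],
                       chroms=[1] * (m // 2) + [2] * (m - m // 2))

    def test_pair_count(self):
        g = self._hwe_like(np.random.default_rng(4), 200, 10)
        pairs, report = ld_all_pairs(g)
        assert len(pairs) == 45
        assert report.n_snps == 10

    def test_gate_attrition_reported(self):
        rng = np.random.default_rng(5)
        cols = [rng.binomial(2, 0.5, 100) for _ in range(4)]
        cols.append(np.zeros(100))                      # monomorphic
        cols.append(np.repeat([0, 2], 50))              # HWE-violating
        mask, report = snp_gate(_matrix(cols))
        assert report.n_snps == 6
        assert report.n_polymorphic == 5
        assert report.n_hwe == 4
        assert mask.sum() == 4

    def test_too_few_gated_snps_raises_with_attrition(self):
        g = _matrix([[0] * 10, [0, 2] * 5])
        with pytest.raises(PopgenError, match="Np="):
            ld_all_pairs(g)

    def test_summaries_identical_pairs(self):
        g = self._hwe_like(np.random.default_rng(6), 300, 8)
        pairs, _ = ld_all_pairs(g)
        const = pairs.copy()
        const["D"] = 0.1
        const["Dprime"] = 0.5
        const["r2"] = 0.25
        summ = ld_summaries(const)
        assert summ.loc["all", "mean_absD"] == pytest.approx(0.1)
        assert summ.loc["linked", "mean_Dprime"] == pytest.approx(0.5)
        # pooled means bracketed by per-chromosome means
        chrom_rows = summ.drop(index=["linked", "all"])
        assert chrom_rows["mean_r2"].min() <= summ.loc["linked", "mean_r2"] \
            <= chrom_rows["mean_r2"].max() + 1e-12

    def test_decay_single_pair_and_errors(self):
        g = self._hwe_like(np.random.default_rng(7), 200, 8)
        pairs, _ = ld_all_pairs(g)
        one = pairs[pairs["same_chromosome"]].head(1).copy()
        one["distance_bp"] = 5e6
        one["D"] = 0.2
        dec = ld_decay_table(one, 10.0)
        assert len(dec) == 1
        assert dec.iloc[0]["mean_absD"] == pytest.approx(0.2)
        assert dec.iloc[0]["bin_mid_mb"] == pytest.approx(5.0)
        with pytest.raises(PopgenError):
            ld_decay_table(pairs, 0.0)


class TestFst:
    def test_identical_populations_zero(self, toy_genotypes):
        res = fst_pairwise(toy_genotypes, toy_genotypes.copy())
        assert res.mean_fst == pytest.approx(0.0)

    def test_fixed_difference_is_one(self):
        a = _matrix([[2, 2, 2, 2]])
        b = _matrix([[0, 0, 0, 0]])
        assert fst_pairwise(a, b).fst[0] == pytest.approx(1.0)

    def test_worked_example(self):
        # p = 0.8 vs 0.2: H_S = 0.32, H_T = 0.5, Fst = 0.36
        a = _matrix([[2, 2, 2, 1, 1]])
        b = _matrix([[0, 0, 0, 1, 1]])
        res = fst_pairwise(a, b)
        assert res.h_s[0] == pytest.approx(0.32)
        assert res.h_t[0] == pytest.approx(0.5)
        assert res.fst[0] == pytest.approx(0.36)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a = _matrix([rng.binomial(2, 0.3, 50) for _ in range(5)])
        b = _matrix([rng.binomial(2, 0.7, 50) for _ in range(5)])
        assert fst_pairwise(a, b).mean_fst == pytest.approx(fst_pairwise(b, a).mean_fst)
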