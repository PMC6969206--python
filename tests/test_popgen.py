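import numpy as np
import pytest

import oracles
from achconnect import (
    GenotypeTable,
    HaplotypeSet,
    allelic_richness,
    bonferroni,
    bruvo_distance,
    diversity_diff_test,
    fst_microsat,
    g_double_prime_st,
    haplotype_diversity,
    minimum_spanning_network,
    nucleotide_diversity,
    phi_pt,
    standardize_sample_size,
)


def random_haps(rng, n, length=30, pool=6):
    pool_seqs = ["".join(rng.choice(list("ACGT"), length)) for _ in range(pool)]
    return [pool_seqs[i] for i in rng.integers(0, pool, n)]


def random_gt(rng, sites_n, loci=4, pool=5):
    alleles = 100 + 2 * np.arange(pool)
    sites, rows = [], []
    for code, n in sites_n:
        sites += [code] * n
        rows.append(alleles[rng.integers(0, pool, size=(n, loci, 2))])
    return GenotypeTable(
        sites=np.array(sites),
        loci=[f"L{k}" for k in range(loci)],
        alleles=np.vstack(rows),
        repeat_units=np.full(loci, 2),
    )


def genos_list(gt, code):
    idx = gt.site_indices(code)
    return [
        [tuple(gt.alleles[i, l]) for l in range(gt.n_loci)] for i in idx
    ]


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["AAAA", "AAAA", "CCCC", "CCCC"], 2 / 3),  # (4/3)(1 - 0.5)
            (["AAAA"] * 6, 0.0),
            (["AAAA", "CAAA", "ACAA", "AACA", "AAAC"], 1.0),  # all distinct, n=5
        ],
    )
    def test_worked_examples(self, seqs, expected):
        est = haplotype_diversity(HaplotypeSet("s", seqs))
        assert est.value == pytest.approx(expected, abs=1e-12)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            haplotype_diversity(HaplotypeSet("s", ["AAAA"]))

    def test_matches_naive_and_is_label_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seqs = random_haps(rng, int(rng.integers(4, 20)))
            est = haplotype_diversity(HaplotypeSet("s", seqs))
            assert est.value == pytest.approx(oracles.naive_h(seqs), abs=1e-10)
            shuffled = [seqs[i] for i in rng.permutation(len(seqs))]
            est2 = haplotype_diversity(HaplotypeSet("s", shuffled))
            assert est2.value == pytest.approx(est.value, abs=1e-12)
            assert est2.sd == pytest.approx(est.sd, abs=1e-12)


class TestNucleotideDiversity:
    def test_one_of_ten_sites(self):
        est = nucleotide_diversity(HaplotypeSet("s", ["AAAAAAAAAA", "CAAAAAAAAA"]))
        assert est.value == pytest.approx(0.1, abs=1e-12)

    def test_identical_sequences_zero(self):
        est = nucleotide_diversity(HaplotypeSet("s", ["ACGT" * 3] * 5))
        assert est.value == 0.0

    def test_three_sequence_average(self):
        # pairwise differences {1, 1, 2} over length 10 -> mean 0.1333
        seqs = ["AAAAAAAAAA", "CAAAAAAAAA", "AGAAAAAAAA"]
        est = nucleotide_diversity(HaplotypeSet("s", seqs))
        assert est.value == pytest.approx(0.13333333, abs=1e-6)

    def test_gaps_and_ns_excluded_pairwise(self):
        est = nucleotide_diversity(HaplotypeSet("s", ["ANAAA", "C-AAA"]))
        # comparable sites: positions 0,2,3,4 -> 1 difference of 4... position 1
        # has N vs -, excluded; position 0 differs
        assert est.value == pytest.approx(0.25, abs=1e-12)

    def test_matches_naive(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            seqs = random_haps(rng, int(rng.integers(3, 15)))
            est = nucleotide_diversity(HaplotypeSet("s", seqs))
            assert est.value == pytest.approx(oracles.naive_pi(seqs), abs=1e-10)


class TestPhiPT:
    def test_fixed_difference_phi_one(self):
        a = HaplotypeSet("A", ["AAAA"] * 10)
        b = HaplotypeSet("B", ["CCCC"] * 10)
        dm = phi_pt([a, b], permutations=99, seed=1)
        assert dm.values[0, 1] == pytest.approx(1.0)
        # only a permutation reproducing the exact split ties the observed value
        assert dm.p_raw[0, 1] == pytest.approx(1 / 100)

    def test_identical_composition_non_positive(self):
        seqs = ["AAAA"] * 3 + ["CCCC"] * 3
        dm = phi_pt(
            [HaplotypeSet("A", seqs), HaplotypeSet("B", seqs)], permutations=0
        )
        assert dm.values[0, 1] <= 0.0

    def test_matches_naive_amova(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            sa = random_haps(rng, int(rng.integers(3, 12)))
            sb = random_haps(rng, int(rng.integers(3, 12)))
            dm = phi_pt(
                [HaplotypeSet("A", sa), HaplotypeSet("B", sb)], permutations=0
            )
            assert dm.values[0, 1] == pytest.approx(
                oracles.naive_phi_pt(sa, sb), abs=1e-10
            )

    def test_symmetric_under_population_swap(self):
        rng = np.random.default_rng(3)
        sa, sb = random_haps(rng, 8), random_haps(rng, 6)
        d1 = phi_pt([HaplotypeSet("A", sa), HaplotypeSet("B", sb)], permutations=0)
        d2 = phi_pt([HaplotypeSet("B", sb), HaplotypeSet("A", sa)], permutations=0)
        assert d1.values[0, 1] == pytest.approx(d2.values[0, 1], abs=1e-12)

    def test_small_site_dropped_with_warning(self):
        a = HaplotypeSet("A", ["AAAA"] * 4)
        b = HaplotypeSet("B", ["CCCC"] * 4)
        c = HaplotypeSet("C", ["GGGG"])
        with pytest.warns(UserWarning, match="dropped"):
            dm = phi_pt([a, b, c], permutations=0)
        assert dm.ids == ["A", "B"]


class TestMicrosatDifferentiation:
    def _fixed_pair(self):
        return GenotypeTable(
            sites=np.array(["A"] * 4 + ["B"] * 4),
            loci=["L1"],
            alleles=np.array([[[100, 100]]] * 4 + [[[102, 102]]] * 4),
            repeat_units=np.array([2]),
        )

    def test_fixed_difference(self):
        gt = self._fixed_pair()
        # H_S = 0, H_T = 0.5: the H_T/H_S ratio form gives F_ST = 1
        assert fst_microsat(gt, permutations=0).values[0, 1] == pytest.approx(1.0)
        assert g_double_prime_st(gt, permutations=0).values[0, 1] == pytest.approx(1.0)

    def test_identical_frequencies_zero(self):
        gt = GenotypeTable(
            sites=np.array(["A"] * 2 + ["B"] * 2),
            loci=["L1"],
            alleles=np.array([[[100, 102]], [[100, 102]], [[100, 102]], [[100, 102]]]),
            repeat_units=np.array([2]),
        )
        assert fst_microsat(gt, permutations=0).values[0, 1] == pytest.approx(0.0)
        assert g_double_prime_st(gt, permutations=0).values[0, 1] == pytest.approx(0.0)

    def test_monomorphic_pair_reported_zero(self):
        gt = GenotypeTable(
            sites=np.array(["A", "A", "B", "B"]),
            loci=["L1"],
            alleles=np.array([[[100, 100]]] * 4),
            repeat_units=np.array([2]),
        )
        assert fst_microsat(gt, permutations=0).values[0, 1] == 0.0

    def test_match_naive_and_gppst_dominates_fst(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            gt = random_gt(rng, [("A", int(rng.integers(4, 12))), ("B", int(rng.integers(4, 12)))])
            f = fst_microsat(gt, permutations=0).values[0, 1]
            g = g_double_prime_st(gt, permutations=0).values[0, 1]
            ga, gb = genos_list(gt, "A"), genos_list(gt, "B")
            assert f == pytest.approx(oracles.naive_fst(ga, gb, gt.n_loci), abs=1e-10)
            assert g == pytest.approx(oracles.naive_gppst(ga, gb, gt.n_loci), abs=1e-10)
            assert g >= f - 1e-10

    def test_gppst_one_for_disjoint_allele_pools(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            a_pool = 100 + 2 * np.arange(4)
            b_pool = 200 + 2 * np.arange(4)
            alleles = np.concatenate(
                [
                    a_pool[rng.integers(0, 4, (n, 2, 2))],
                    b_pool[rng.integers(0, 4, (n, 2, 2))],
                ]
            )
            gt = GenotypeTable(
                sites=np.array(["A"] * n + ["B"] * n),
                loci=["L1", "L2"],
                alleles=alleles,
                repeat_units=np.array([2, 2]),
            )
            assert g_double_prime_st(gt, permutations=0).values[0, 1] == pytest.approx(
                1.0, abs=1e-10
            )


class TestAllelicRichness:
    def test_single_allele_everywhere(self):
        gt = GenotypeTable(
            sites=np.array(["A"] * 3),
            loci=["L1"],
            alleles=np.array([[[100, 100]]] * 3),
            repeat_units=np.array([2]),
        )
        [est] = allelic_richness(gt, bootstraps=0)
        assert est.value == 1.0

    def test_four_distinct_alleles(self):
        gt = GenotypeTable(
            sites=np.array(["A", "A"]),
            loci=["L1"],
            alleles=np.array([[[100, 102]], [[104, 106]]]),
            repeat_units=np.array([2]),
        )
        [est] = allelic_richness(gt, bootstraps=0)
        assert est.value == 4.0

    def test_subsampling_never_increases_richness(self):
        rng = np.random.default_rng(6)
        gt = random_gt(rng, [("A", 10)])
        [full] = allelic_richness(gt, standard_n=10, bootstraps=0)
        [sub] = allelic_richness(gt, standard_n=5, bootstraps=0)
        assert full.value >= sub.value

    def test_standardization_drops_most_missing_first(self):
        alleles = np.array(
            [[[100, 102], [100, 100]], [[0, 0], [0, 0]], [[100, 100], [102, 102]]]
        )
        gt = GenotypeTable(
            sites=np.array(["A"] * 3),
            loci=["L1", "L2"],
            alleles=alleles,
            repeat_units=np.array([2, 2]),
        )
        std = standardize_sample_size(gt, 2)
        assert std.n == 2
        assert not np.any(std.alleles == 0)  # the all-missing row went first

    def test_bootstrap_ci_brackets_point_and_matches_naive(self):
        rng = np.random.default_rng(7)
        gt = random_gt(rng, [("A", 12)], loci=3)
        [est] = allelic_richness(gt, bootstraps=200, seed=1)
        assert est.ci[0] <= est.value <= est.ci[1]
        assert est.value == pytest.approx(
            oracles.naive_ar(genos_list(gt, "A"), gt.n_loci), abs=1e-10
        )


class TestDiversityDiffTest:
    def test_identical_sets_p_one(self):
        h = HaplotypeSet("A", ["AAAA", "CCCC"] * 3)
        res = diversity_diff_test(h, h, iterations=200, seed=0)
        assert res["h"] == 1.0 and res["pi"] == 1.0

    def test_extreme_difference_minimal_p(self):
        a = HaplotypeSet("A", ["A" * 25] * 20)
        base = "A" * 25
        variants = [base[:k] + "C" + base[k + 1 :] for k in range(20)]
        b = HaplotypeSet("B", variants)
        res = diversity_diff_test(a, b, iterations=999, seed=1)
        assert res["h"] == pytest.approx(1 / 1000, abs=1e-9)

    def test_permutation_distribution_uniform_under_null(self):
        # p-values across independent null splits should be ~Uniform(0,1)
        from scipy.stats import kstest

        rng = np.random.default_rng(8)
        pool = random_haps(rng, 40, pool=12)
        ps = []
        for _ in range(300):
            idx = rng.permutation(40)
            a = HaplotypeSet("a", [pool[i] for i in idx[:20]])
            b = HaplotypeSet("b", [pool[i] for i in idx[20:]])
            ps.append(
                diversity_diff_test(a, b, iterations=199, seed=int(rng.integers(2**31)))["h"]
            )
        assert kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_scaling_capping_identity(self):
        assert bonferroni([0.01], m=10)[0] == pytest.approx(0.10)
        assert bonferroni([0.5], m=10)[0] == 1.0
        assert bonferroni([0.3], m=1)[0] == pytest.approx(0.3)

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)


class TestBruvo:
    def _gt(self, rows, units=(2,)):
        return GenotypeTable(
            sites=np.array(["A"] * len(rows)),
            loci=[f"L{k}" for k in range(len(units))],
            alleles=np.array(rows),
            repeat_units=np.array(units),
        )

    def test_single_repeat_step_half(self):
        gt = self._gt([[[100, 100]], [[102, 102]]])
        assert bruvo_distance(gt)[0, 1] == pytest.approx(0.5)

    def test_identical_genotypes_zero(self):
        gt = self._gt([[[100, 102]], [[100, 102]]])
        assert bruvo_distance(gt)[0, 1] == 0.0

    def test_two_repeat_step_three_quarters(self):
        gt = self._gt([[[100, 100]], [[104, 104]]])
        assert bruvo_distance(gt)[0, 1] == pytest.approx(0.75)

    def test_minimum_weight_pairing_and_naive_agreement(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            rows = 100 + 2 * rng.integers(0, 8, size=(6, 3, 2))
            gt = self._gt(rows, units=(2, 2, 2))
            D = bruvo_distance(gt)
            for i in range(6):
                for j in range(i + 1, 6):
                    g1 = [tuple(rows[i, l]) for l in range(3)]
                    g2 = [tuple(rows[j, l]) for l in range(3)]
                    assert D[i, j] == pytest.approx(
                        oracles.naive_bruvo(g1, g2, [2, 2, 2]), abs=1e-10
                    )

    def test_missing_allele_averaged_addition_loss(self):
        gt = self._gt([[[100, 0]], [[102, 104]]])
        # repeat units: a = {50, ?}, b = {51, 52}
        # addition imputes ? with 51 then 52 (min-weight pairing each time):
        #   d({50,51},{51,52}) = min(0.5, 0.375) = 0.375
        #   d({50,52},{51,52}) = min(0.25, 0.625) = 0.25
        # loss imputes ? with the remaining own allele:
        #   d({50,50},{51,52}) = 0.625
        d_add = np.mean([0.375, 0.25])
        d_loss = 0.625
        assert bruvo_distance(gt)[0, 1] == pytest.approx(0.5 * (d_add + d_loss))

    def test_zero_repeat_unit_rejected(self):
        with pytest.raises(ValueError, match="repeat unit"):
            self._gt([[[100, 100]]], units=(0,))


class TestMSN:
    def test_chain_recovered(self):
        D = np.array(
            [[0.0, 1.0, 3.0], [1.0, 0.0, 1.5], [3.0, 1.5, 0.0]]
        )
        net = minimum_spanning_network(D)
        got = {(r["a"], r["b"]) for _, r in net.iterrows()}
        assert got == {(0, 1), (1, 2)}

    def test_tied_edges_collapse_into_loops(self):
        # equilateral triangle: all three tied edges kept
        D = np.ones((3, 3)) - np.eye(3)
        net = minimum_spanning_network(D)
        assert len(net) == 3

    def test_spanning(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        net = minimum_spanning_network(D)
        # union-find over returned edges must connect all nodes
        parent = list(range(8))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for _, r in net.iterrows():
            parent[find(int(r["a"]))] = find(int(r["b"]))
        assert len({find(k) for k in range(8)}) == 1
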