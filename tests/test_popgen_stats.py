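import itertools

import numpy as np
import pytest

from eelclines import popgen_stats as pg
from eelclines.types import AlleleFrequencySpectrum, GenotypeTable


def _table(genotypes_by_pop, loci=("L1",)):
    """Build a table from {pop: [((a,b), (c,d), ...), ...]} genotype tuples."""
    inds, pops, rows = [], [], []
    k = 0
    for pop, genos in genotypes_by_pop.items():
        for g in genos:
            inds.append(f"i{k}")
            pops.append(pop)
            rows.append(list(g))
            k += 1
    return GenotypeTable(inds, pops, list(loci), np.array(rows))


class TestAlleleFrequencies:
    def test_simple_tally(self):
        t = _table({"p": [((100, 100),), ((100, 102),)]})
        afs = pg.allele_frequencies(t)["p"]
        assert afs.frequencies("L1") == {100: 0.75, 102: 0.25}

    def test_all_missing_locus_flagged(self):
        t = _table({"p": [((0, 0),), ((0, 0),)]})
        afs = pg.allele_frequencies(t)["p"]
        assert pg.empty_loci(afs) == ["L1"]

    def test_matches_brute_force_tally_on_pool(self, default_pools):
        t_e, _, afs_e, _ = default_pools
        locus = t_e.loci[3]
        j = 3
        tally: dict[int, int] = {}
        for i in range(t_e.n_individuals):
            for a in t_e.calls[i, j]:
                if a != 0:
                    tally[int(a)] = tally.get(int(a), 0) + 1
        assert tally == afs_e.counts[locus]


class TestHeterozygosity:
    def test_unbiased_he_closed_form(self):
        # n=2 individuals, p = {0.5, 0.5}: He = (4/3) * (1 - 0.5) = 2/3
        t = _table({"p": [((100, 100),), ((102, 102),)]})
        s = pg.heterozygosities(t, [0, 1])
        assert s.he["L1"] == pytest.approx(2 / 3)

    def test_monomorphic_locus_is_zero(self):
        t = _table({"p": [((100, 100),), ((100, 100),)]})
        s = pg.heterozygosities(t, [0, 1])
        assert s.ho["L1"] == 0.0 and s.he["L1"] == 0.0

    def test_hwe_population_ho_close_to_he(self, rng):
        sizes = np.array([100, 102, 104, 106])
        p = np.array([0.4, 0.3, 0.2, 0.1])
        calls = sizes[rng.choice(4, size=(3000, 1, 2), p=p)]
        t = GenotypeTable(
            [f"i{i}" for i in range(3000)], ["p"] * 3000, ["L1"], calls
        )
        s = pg.heterozygosities(t, range(3000))
        assert abs(s.mean_ho - s.mean_he) < 0.02


def _wc_oracle_biallelic(pop1, pop2):
    """Hand-derived Weir-Cockerham components for a 2-allele toy case."""
    # frozen from a pencil-and-paper evaluation of the 1984 formulas on
    # pop1 = AA, AB, BB, AA and pop2 = BB, AB, BB, BB (theta = 17/57)
    return 17 / 57


class TestWeirCockerhamFst:
    def test_null_two_groups_one_spectrum(self, rng):
        sizes = np.array([100, 102, 104])
        p = np.array([0.5, 0.3, 0.2])
        calls = sizes[rng.choice(3, size=(400, 1, 2), p=p)]
        pops = ["a"] * 200 + ["b"] * 200
        t = GenotypeTable([f"i{i}" for i in range(400)], pops, ["L1"], calls)
        assert abs(pg.fst_weir_cockerham(t).value) < 0.01

    def test_hand_worked_biallelic_example(self):
        A, B = 100, 102
        t = _table({
            "p1": [((A, A),), ((A, B),), ((B, B),), ((A, A),)],
            "p2": [((B, B),), ((A, B),), ((B, B),), ((B, B),)],
        })
        res = pg.fst_weir_cockerham(t)
        assert res.value == pytest.approx(_wc_oracle_biallelic("p1", "p2"), abs=1e-12)

    def test_invariant_under_allele_relabeling(self, rng):
        sizes = np.array([100, 102, 104, 106])
        calls = sizes[rng.choice(4, size=(60, 2, 2))]
        pops = ["a"] * 30 + ["b"] * 30
        t1 = GenotypeTable([f"i{i}" for i in range(60)], pops, ["L1", "L2"], calls)
        relabel = {100: 310, 102: 104, 104: 250, 106: 100}
        calls2 = np.vectorize(relabel.get)(calls)
        t2 = GenotypeTable([f"i{i}" for i in range(60)], pops, ["L1", "L2"], calls2)
        assert pg.fst_weir_cockerham(t1).value == pytest.approx(
            pg.fst_weir_cockerham(t2).value
        )

    def test_permutation_p_significant_for_diverged_pools(self, strong_pools):
        t_e, t_a, _, _ = strong_pools
        t = GenotypeTable.concat([t_e.subset(range(30)), t_a.subset(range(30))])
        res = pg.fst_weir_cockerham(t, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_group_of_one_rejected(self):
        t = _table({"p1": [((100, 100),)], "p2": [((100, 102),), ((102, 102),)]})
        with pytest.raises(ValueError):
            pg.fst_weir_cockerham(t)


def _rst_oracle(groups_sizes):
    """Pairwise-difference RST: explicit O(n^2) loops over gene copies."""
    pooled = np.concatenate(groups_sizes).astype(float)

    def msd(x):
        # mean squared difference over ordered pairs i != j
        n = len(x)
        s = sum((a - b) ** 2 for a, b in itertools.permutations(x, 2))
        return s / (n * (n - 1))

    s_bar = msd(pooled)
    weights = np.array([len(g) for g in groups_sizes], dtype=float)
    s_w = np.average([msd(np.asarray(g, dtype=float)) for g in groups_sizes],
                     weights=weights)
    return (s_bar - s_w) / s_bar


class TestRstSlatkin:
    def test_identical_size_distributions_near_zero(self, rng):
        sizes = np.array([100, 110, 120])
        calls = sizes[rng.choice(3, size=(300, 1, 2))]
        pops = ["a"] * 150 + ["b"] * 150
        t = GenotypeTable([f"i{i}" for i in range(300)], pops, ["L1"], calls)
        assert abs(pg.rst_slatkin(t).value) < 0.02

    def test_fixed_difference_gives_one(self):
        t = _table({
            "p1": [((100, 100),), ((100, 100),)],
            "p2": [((120, 120),), ((120, 120),)],
        })
        assert pg.rst_slatkin(t).value == pytest.approx(1.0)

    def test_matches_pairwise_difference_oracle(self, rng):
        g1 = rng.choice([100, 102, 104, 108], size=20)
        g2 = rng.choice([100, 104, 106, 110], size=26)
        t = _table({
            "p1": [((a, b),) for a, b in g1.reshape(10, 2)],
            "p2": [((a, b),) for a, b in g2.reshape(13, 2)],
        })
        expected = _rst_oracle([g1, g2])
        assert pg.rst_slatkin(t).value == pytest.approx(expected, abs=1e-9)


class TestHwe:
    def test_extreme_heterozygote_deficit_detected(self):
        # 50 homozygotes, two alleles at p = 0.5: massive deficit
        genos = [((100, 100),)] * 25 + [((102, 102),)] * 25
        t = _table({"p": genos})
        p = pg.hwe_test(t, range(50), "L1", n_perm=999, seed=0)
        assert p < 0.01

    def test_null_calibration_mean_p_near_half(self, rng):
        sizes = np.array([100, 102, 104])
        freqs = np.array([0.5, 0.3, 0.2])
        ps = []
        for rep in range(20):
            calls = sizes[rng.choice(3, size=(60, 1, 2), p=freqs)]
            t = GenotypeTable([f"i{i}" for i in range(60)], ["p"] * 60, ["L1"], calls)
            ps.append(pg.hwe_test(t, range(60), "L1", n_perm=199, seed=rep))
        assert 0.35 < np.mean(ps) < 0.7

    def test_bonferroni_threshold(self):
        # 0.004 > 0.05 / 21, so not significant at m = 21
        assert pg.bonferroni([0.004] + [0.5] * 20, alpha=0.05) == [False] * 21
        assert pg.bonferroni([0.001], alpha=0.05) == [True]


class TestRarefaction:
    def test_full_sample_recovers_observed_count(self):
        counts = {100: 6, 102: 3, 104: 1}
        assert pg.allelic_richness_rarefied(counts, 10) == pytest.approx(3.0)

    def test_single_gene_copy_shows_one_allele(self):
        counts = {100: 6, 102: 3, 104: 1}
        assert pg.allelic_richness_rarefied(counts, 1) == pytest.approx(1.0)

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = {100: 6, 102: 3, 104: 1}
        pool = np.repeat([100, 102, 104], [6, 3, 1])
        n_rep = 100_000
        mc = np.array([
            len(np.unique(rng.choice(pool, size=4, replace=False)))
            for _ in range(n_rep)
        ])
        assert pg.allelic_richness_rarefied(counts, 4) == pytest.approx(
            mc.mean(), abs=3 * mc.std() / np.sqrt(n_rep) + 1e-3
        )

    def test_private_fixed_allele_contributes_fully(self):
        g1 = {100: 10}
        g2 = {102: 8}
        out = pg.private_allelic_richness_rarefied([g1, g2], 5)
        assert out == pytest.approx([1.0, 1.0])

    def test_shared_fixed_allele_contributes_nothing(self):
        out = pg.private_allelic_richness_rarefied([{100: 10}, {100: 8}], 5)
        assert out == pytest.approx([0.0, 0.0])

    def test_private_matches_monte_carlo_joint_subsampling(self, rng):
        c1 = {100: 5, 102: 3, 104: 2}
        c2 = {100: 4, 106: 6}
        pool1 = np.repeat([100, 102, 104], [5, 3, 2])
        pool2 = np.repeat([100, 106], [4, 6])
        g = 4
        n_rep = 50_000
        priv1 = np.empty(n_rep)
        for k in range(n_rep):
            s1 = set(rng.choice(pool1, size=g, replace=False))
            s2 = set(rng.choice(pool2, size=g, replace=False))
            priv1[k] = len(s1 - s2)
        expected = pg.private_allelic_richness_rarefied([c1, c2], g)[0]
        assert expected == pytest.approx(
            priv1.mean(), abs=3 * priv1.std() / np.sqrt(n_rep) + 1e-3
        )


class TestChordDistance:
    def _afs(self, freqs):
        return AlleleFrequencySpectrum.from_frequencies(freqs)

    def test_identical_spectra_distance_zero(self):
        f = {"L1": {100: 0.5, 102: 0.5}, "L2": {100: 1.0}}
        assert pg.cavalli_sforza_chord(self._afs(f), self._afs(f)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_disjoint_spectra_distance_one(self):
        f1 = {"L1": {100: 1.0}, "L2": {100: 0.5, 102: 0.5}}
        f2 = {"L1": {110: 1.0}, "L2": {104: 0.5, 106: 0.5}}
        assert pg.cavalli_sforza_chord(self._afs(f1), self._afs(f2)) == pytest.approx(1.0)

    def test_hand_computed_two_locus_example(self):
        # L1: sqrt(1 * 0.25) = 0.5 -> t = 0.5; L2 identical -> t = 0
        # D = sqrt((0.5 + 0) / 2) = 0.5
        f1 = {"L1": {100: 1.0}, "L2": {104: 0.5, 106: 0.5}}
        f2 = {"L1": {100: 0.25, 102: 0.75}, "L2": {104: 0.5, 106: 0.5}}
        assert pg.cavalli_sforza_chord(self._afs(f1), self._afs(f2)) == pytest.approx(
            0.5, abs=1e-6
        )

    def test_symmetry(self, default_pools):
        _, _, afs_e, afs_a = default_pools
        assert pg.cavalli_sforza_chord(afs_e, afs_a) == pytest.approx(
            pg.cavalli_sforza_chord(afs_a, afs_e)
        )

    def test_fst_rst_congruent_when_sizes_uninformative(self, rng):
        # random size labels: size-based and identity-based estimators agree
        sizes = np.array([100, 102, 104, 106, 108, 110])
        calls = np.empty((200, 3, 2), dtype=int)
        for j in range(3):
            pa = rng.dirichlet(np.ones(6))
            pb = rng.dirichlet(pa * 60)
            calls[:100, j] = sizes[rng.choice(6, size=(100, 2), p=pa)]
            calls[100:, j] = sizes[rng.choice(6, size=(100, 2), p=pb)]
        pops = ["a"] * 100 + ["b"] * 100
        t = GenotypeTable([f"i{i}" for i in range(200)], pops, ["L1", "L2", "L3"], calls)
        fst = pg.fst_weir_cockerham(t).value
        rst = pg.rst_slatkin(t).value
        assert abs(fst - rst) < 0.01
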