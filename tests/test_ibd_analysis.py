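import itertools

import numpy as np
import pytest

from eelclines import popgen_stats as pg
from eelclines.cline_simulation import ClineScenario, build_f1_cline
from eelclines.ibd_analysis import (
    GeneFlowFit,
    extrapolate_gene_flow,
    fit_gene_flow_curves,
    genetic_distance_matrix,
    mantel_test,
    run_ibd_experiment,
)
from eelclines.types import AlleleFrequencySpectrum, DistanceMatrix


def _dm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{k}" for k in range(len(values))]
    return DistanceMatrix(labels=labels, values=values)


@pytest.fixture(scope="module")
def small_cline(default_pools):
    t_e, t_a, _, _ = default_pools
    sc = ClineScenario(increment_pct=4, mode="f1_parents", seed=2,
                       n_populations=5, offspring_per_population=40)
    return build_f1_cline(sc, t_e, t_a)


class TestGeneticDistanceMatrix:
    def test_symmetric_zero_diagonal(self, small_cline):
        dm = genetic_distance_matrix(small_cline)
        np.testing.assert_allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_entries_match_chord_on_extracted_spectra(self, small_cline):
        dm = genetic_distance_matrix(small_cline)
        a1 = AlleleFrequencySpectrum.from_table(small_cline.populations[1])
        a3 = AlleleFrequencySpectrum.from_table(small_cline.populations[3])
        assert dm.values[1, 3] == pytest.approx(pg.cavalli_sforza_chord(a1, a3))

    def test_duplicated_population_gives_zero_entry(self, small_cline):
        import copy

        c = copy.copy(small_cline)
        c.populations = [small_cline.populations[0], small_cline.populations[0],
                         small_cline.populations[2], small_cline.populations[3]]
        c.realized_fractions = [0.0, 0.0, 0.1, 0.2]
        dm = genetic_distance_matrix(c)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-6)


class TestMantel:
    def test_perfect_linear_relation(self):
        # 10 transect sites with distinct spacings: only the identity and
        # the reversal reproduce r = 1 among the 10! permutations
        pos = np.cumsum([0, 1, 3, 2, 7, 4, 9, 5, 8, 6]).astype(float)
        geo = _dm(np.abs(pos[:, None] - pos[None, :]))
        gen = _dm(0.1 * geo.values)
        res = mantel_test(gen, geo, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.b == pytest.approx(0.1)
        assert res.p == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_on_five_sites(self, rng):
        n = 5
        a = rng.random((n, n))
        gen = _dm(np.triu(a, 1) + np.triu(a, 1).T)
        b = rng.random((n, n))
        geo = _dm(np.triu(b, 1) + np.triu(b, 1).T)
        iu = np.triu_indices(n, 1)
        d = geo.values[iu]
        r_obs = np.corrcoef(gen.values[iu], d)[0, 1]
        count = sum(
            np.corrcoef(gen.values[np.ix_(p, p)][iu], d)[0, 1] >= r_obs
            for p in map(list, itertools.permutations(range(n)))
        )
        exact_p = count / 120  # includes identity, as extreme as itself
        res = mantel_test(gen, geo, n_perm=4999, seed=1)
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(exact_p, abs=0.03)

    def test_matches_scikit_bio(self, small_cline, geography):
        skbio = pytest.importorskip("skbio")
        gd = genetic_distance_matrix(small_cline)
        geo5 = _dm(geography.values[:5, :5], labels=gd.labels)
        res = mantel_test(gd, geo5, n_perm=999, seed=0)
        r_sk, p_sk, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(gd.values, gd.labels),
            skbio.DistanceMatrix(geo5.values, geo5.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(r_sk, abs=1e-12)
        assert res.p == pytest.approx(p_sk, abs=0.05)

    def test_invariant_under_affine_rescaling(self, small_cline, geography):
        gd = genetic_distance_matrix(small_cline)
        geo5 = _dm(geography.values[:5, :5], labels=gd.labels)
        r1 = mantel_test(gd, geo5, n_perm=99, seed=0).r
        scaled = _dm(3.7 * geo5.values, labels=gd.labels)
        r2 = mantel_test(gd, scaled, n_perm=99, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        geo = _dm(np.ones((4, 4)) - np.eye(4))
        gen = _dm([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]])
        with pytest.raises(ValueError, match="variance"):
            mantel_test(gen, geo, n_perm=9)

    def test_too_few_populations_rejected(self):
        m = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="at least 4"):
            mantel_test(m, m)


class TestGeneFlowFit:
    def test_exact_linear_r_recovered(self):
        levels = [1, 2, 3, 4]
        r = [0.15, 0.25, 0.35, 0.45]
        b = [1e-6 * np.exp(0.5 * l) for l in levels]
        fit = fit_gene_flow_curves(levels, r, b)
        assert fit.r_intercept == pytest.approx(0.05)
        assert fit.r_slope == pytest.approx(0.1)
        assert fit.r_r2 == pytest.approx(1.0)

    def test_exact_exponential_b_recovered(self):
        levels = np.array([1.0, 2.0, 3.0, 4.0])
        b = -2e-6 * np.exp(0.3 * levels)  # negative slopes supported
        fit = fit_gene_flow_curves(levels, levels * 0.1, b)
        assert fit.b_amplitude == pytest.approx(-2e-6, rel=1e-6)
        assert fit.b_rate == pytest.approx(0.3, abs=1e-6)

    def test_matches_independent_least_squares(self, rng):
        levels = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = 0.05 + 0.12 * levels + rng.normal(0, 0.01, 5)
        fit = fit_gene_flow_curves(levels, r, np.exp(levels))
        X = np.column_stack([np.ones(5), levels])
        beta, *_ = np.linalg.lstsq(X, r, rcond=None)
        assert fit.r_intercept == pytest.approx(beta[0])
        assert fit.r_slope == pytest.approx(beta[1])

    def test_too_few_scenarios_rejected(self):
        with pytest.raises(ValueError):
            fit_gene_flow_curves([1, 2], [0.1, 0.2], [1.0, 2.0])


class TestExtrapolation:
    def _fit(self):
        levels = [1, 2, 3, 4]
        return fit_gene_flow_curves(levels, [0.1 * l for l in levels],
                                    [np.exp(l) for l in levels])

    def test_inversion_arithmetic(self):
        ex = extrapolate_gene_flow(self._fit(), target_r=0.27)
        assert ex.increment_pct == pytest.approx(2.7)
        assert ex.mean_hybrid_fraction_pct == pytest.approx(5.5 * 2.7)
        assert ex.max_hybrid_fraction_pct == pytest.approx(11 * 2.7)
        assert not ex.out_of_range

    def test_round_trip_through_forward_prediction(self):
        fit = self._fit()
        ex = extrapolate_gene_flow(fit, target_r=0.33)
        assert fit.predict_r(ex.increment_pct) == pytest.approx(0.33, abs=1e-9)

    def test_out_of_range_flagged(self):
        ex = extrapolate_gene_flow(self._fit(), target_r=0.95)
        assert ex.out_of_range


class TestExperiment:
    def test_fit_produced_and_results_tidy(self, default_pools, geography):
        t_e, t_a, _, _ = default_pools
        results, fit = run_ibd_experiment(
            [1, 2, 4], geography, mode="f1_parents",
            pool_european=t_e, pool_american=t_a,
            n_replicates=2, n_perm=49, seed=0,
        )
        assert len(results) == 6
        assert set(results.columns) >= {"increment_pct", "replicate", "r", "b", "p"}
        assert isinstance(fit, GeneFlowFit)

    def test_determinism(self, default_pools, geography):
        t_e, t_a, _, _ = default_pools
        kw = dict(mode="f1_parents", pool_european=t_e, pool_american=t_a,
                  n_replicates=2, n_perm=49, seed=3)
        r1, _ = run_ibd_experiment([1, 2, 3], geography, **kw)
        r2, _ = run_ibd_experiment([1, 2, 3], geography, **kw)
        assert r1.equals(r2)
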