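import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from peradigm import risk_mapping as rm
from peradigm.ehr_io import Cohort
from peradigm.genotype_carriers import CarrierTable
from peradigm.individual_embedding import EmbeddingSet


def make_set(rng, n, d=8, prefix="I"):
    mat = rng.normal(size=(n, d))
    return EmbeddingSet([f"{prefix}{i:03d}" for i in range(n)], mat)


class TestCosine:
    def test_self_similarity_one(self):
        v = np.array([1.0, 2.0, -3.0])
        assert rm.cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        assert rm.cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-6, max_value=1e6),
        seed=st.integers(0, 100),
    )
    def test_scale_invariance_and_bounds(self, scale, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=4), rng.normal(size=4)
        c1, c2 = rm.cosine(u, v), rm.cosine(u, scale * v)
        assert c1 == pytest.approx(c2, abs=1e-9)
        assert -1.0 <= c1 <= 1.0

    def test_zero_vector_error(self):
        with pytest.raises(ValueError, match="zero vector"):
            rm.cosine(np.zeros(3), np.ones(3))


class TestSimilarityScores:
    def test_single_case_equals_direct_cosine(self):
        rng = np.random.default_rng(0)
        es = make_set(rng, 5)
        s = rm.similarity_scores(es, ["I000"])
        for i, eid in enumerate(es.ids):
            assert s[eid] == pytest.approx(
                rm.cosine(es.matrix[i], es.matrix[0]), abs=1e-12
            )

    def test_identical_case_embeddings_single_cosine(self):
        mat = np.vstack([np.tile([1.0, 2.0], (3, 1)), [[0.0, 1.0]]])
        es = EmbeddingSet(["C1", "C2", "C3", "X"], mat)
        s = rm.similarity_scores(es, ["C1", "C2", "C3"])
        assert s["X"] == pytest.approx(rm.cosine(mat[3], mat[0]))

    def test_matches_reference_mean_of_cosines(self):
        rng = np.random.default_rng(1)
        es = make_set(rng, 20)
        cases = ["I002", "I005", "I011"]
        s = rm.similarity_scores(es, cases)
        case_mat = es.matrix[es.subset_indices(cases)]
        for i, eid in enumerate(es.ids):
            assert s[eid] == pytest.approx(
                rm.individual_score(es.matrix[i], case_mat), abs=1e-12
            )

    def test_exclude_self_removes_self_pair(self):
        rng = np.random.default_rng(2)
        es = make_set(rng, 4)
        cases = ["I000", "I001"]
        s = rm.similarity_scores(es, cases, exclude_self=True)
        # I000's score should be its cosine to I001 alone
        assert s["I000"] == pytest.approx(rm.cosine(es.matrix[0], es.matrix[1]))

    def test_exclude_self_with_single_case_error(self):
        rng = np.random.default_rng(3)
        es = make_set(rng, 3)
        with pytest.raises(ValueError, match="exclude_self"):
            rm.similarity_scores(es, ["I000"], exclude_self=True)


class TestGeneRiskScore:
    def test_single_carrier(self):
        s = pd.Series({"A": 0.3, "B": 0.5})
        assert rm.gene_risk_score(["A"], s) == 0.3

    def test_mean_of_carriers(self):
        s = pd.Series({"A": 0.1, "B": 0.3})
        assert rm.gene_risk_score(["A", "B"], s) == pytest.approx(0.2)

    def test_no_usable_carrier_error(self):
        with pytest.raises(ValueError, match="usable"):
            rm.gene_risk_score(["Z"], pd.Series({"A": 0.1}))

    def test_upper_bound_when_carriers_equal_cases(self):
        mat = np.tile([1.0, 1.0], (4, 1))
        es = EmbeddingSet(list("ABCD"), mat)
        s = rm.similarity_scores(es, ["A", "B", "C", "D"])
        assert rm.gene_risk_score(list("ABCD"), s) == pytest.approx(1.0)


class TestNullDistribution:
    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=500)
        a = rm.null_distribution(20, v, n_reps=500, seed=9, keep_scores=True)
        b = rm.null_distribution(20, v, n_reps=500, seed=9, keep_scores=True)
        assert (a.mu0, a.sigma) == (b.mu0, b.sigma)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_mu0_approaches_population_mean(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=2000)
        summ = rm.null_distribution(25, v, n_reps=10_000, seed=0)
        se = v.std() / np.sqrt(25) / np.sqrt(10_000)
        assert abs(summ.mu0 - v.mean()) < 3 * se * 2  # fpc-conservative

    def test_sample_size_exceeding_pool_error(self):
        with pytest.raises(ValueError, match="exceeds pool"):
            rm.null_distribution(10, np.ones(5), n_reps=10, seed=0)

    def test_full_pool_degenerate_sigma_flagged(self, caplog):
        v = np.arange(10.0)
        summ = rm.null_distribution(10, v, n_reps=100, seed=0)
        assert summ.sigma == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            rm.risk_pvalue(0.5, summ)

    def test_sampling_without_replacement_unbiased_variance(self):
        # variance of means matches the finite-population formula
        rng = np.random.default_rng(2)
        v = rng.normal(size=400)
        n = 40
        summ = rm.null_distribution(n, v, n_reps=20_000, seed=1)
        expect = v.var() / n * (1 - (n - 1) / (v.size - 1))
        assert summ.sigma**2 == pytest.approx(expect, rel=0.1)


class TestNullCache:
    def test_cached_equals_fresh(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=300)
        cache = rm.NullCache(v, n_reps=400, seed=5)
        summ = cache.get(12)
        fresh = rm.null_distribution(12, v, n_reps=400, seed=5)
        assert (summ.mu0, summ.sigma) == (fresh.mu0, fresh.sigma)
        assert cache.get(12) is summ


class TestRiskPvalue:
    def _summ(self):
        return rm.NullSummary(n=10, mu0=0.2, sigma=0.05, n_reps=100, seed=0)

    def test_score_at_null_mean_gives_half(self):
        z, p, fl = rm.risk_pvalue(0.2, self._summ())
        assert z == 0.0 and p == pytest.approx(0.5) and not fl

    def test_normal_quantile(self):
        z, p, _ = rm.risk_pvalue(0.2 + 1.6449 * 0.05, self._summ())
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_floor_applied(self):
        z, p, fl = rm.risk_pvalue(0.2 + 50 * 0.05, self._summ())
        assert p == rm.P_FLOOR and fl


class TestAdjustPvalues:
    def test_bonferroni_worked_example(self):
        # one gene at p=2.44e-6 among 15,889 tested genes
        p = np.full(15_889, 0.9)
        p[0] = 2.44e-6
        adj = rm.adjust_pvalues(p, "bonferroni")
        assert adj[0] == pytest.approx(3.877e-2, rel=5e-3)

    def test_bonferroni_capped_at_one(self):
        adj = rm.adjust_pvalues([0.5, 0.6, 0.7], "bonferroni")
        assert adj[0] == 1.0

    def test_bh_step_up_hand_computed(self):
        adj = rm.adjust_pvalues([0.01, 0.02, 0.03], "bh")
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        for method in ("bonferroni", "bh"):
            assert np.all(rm.adjust_pvalues(p, method) >= p - 1e-15)


class TestScanGenes:
    def _setup(self, rng, n=200, d=6):
        es = make_set(rng, n, d)
        cases = set(es.ids[:10])
        cohort = Cohort(cases, set(es.ids[10:]), {"X00"})
        return es, cohort

    def test_result_per_gene_and_determinism(self):
        rng = np.random.default_rng(0)
        es, cohort = self._setup(rng)
        table = CarrierTable(
            {
                f"G{j}": set(rng.choice(es.ids, 15, replace=False))
                for j in range(8)
            }
        )
        a = rm.scan_genes(table, es, cohort, n_reps=300, seed=3)
        b = rm.scan_genes(table, es, cohort, n_reps=300, seed=3)
        assert len(a) == len(table.genes())
        pd.testing.assert_frame_equal(a, b)

    def test_monotonicity_in_case_overlap(self):
        # replacing a carrier embedding by a case embedding never lowers R
        rng = np.random.default_rng(4)
        es, cohort = self._setup(rng, 100)
        scores = rm.similarity_scores(es, cohort.case_ids)
        case = next(iter(cohort.case_ids))
        others = [i for i in es.ids if i not in cohort.case_ids]
        base = list(rng.choice(others, 10, replace=False))
        r0 = rm.gene_risk_score(base, scores)
        worst = max(base, key=lambda i: -scores[i])
        r1 = rm.gene_risk_score([case] + [i for i in base if i != worst], scores)
        assert r1 >= r0 or scores[case] >= scores[worst]

    def test_overlap_column(self):
        rng = np.random.default_rng(5)
        es, cohort = self._setup(rng, 50)
        gene_members = set(list(cohort.case_ids)[:3]) | set(es.ids[-5:])
        table = CarrierTable({"G0": gene_members})
        out = rm.scan_genes(table, es, cohort, n_reps=200, seed=0)
        assert out.loc[0, "overlap_with_disease"] == 3

    def test_zscore_and_percentile_pvalues_rank_concordant(self):
        rng = np.random.default_rng(6)
        es, cohort = self._setup(rng, 300)
        table = CarrierTable(
            {
                f"G{j}": set(rng.choice(es.ids, rng.integers(5, 40), replace=False))
                for j in range(60)
            }
        )
        out = rm.scan_genes(
            table, es, cohort, n_reps=2000, seed=1, keep_null_scores=True
        )
        from scipy.stats import spearmanr

        rho = spearmanr(out["p_raw"], out["p_emp"]).statistic
        assert rho > 0.99
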