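import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest

from peradigm import association_weights as aw
from peradigm.ehr_io import CodeFrequencyTable
from tests.conftest import make_history


def simulate_code_histories(rng, n, code_probs, outcome=None, betas=None):
    """Independent logistic code assignment, mirroring the generative model."""
    ids = [f"I{i:03d}" for i in range(n)]
    outcome = np.zeros(n) if outcome is None else outcome
    hist = {}
    for i, eid in enumerate(ids):
        codes = []
        for code, p0 in code_probs.items():
            b = 0.0 if betas is None else betas.get(code, 0.0)
            eta = np.log(p0 / (1 - p0)) + b * outcome[i]
            if rng.random() < expit(eta):
                codes.append(code)
        hist[eid] = make_history(eid, codes)
    return hist, ids


class TestInformationContent:
    def test_frequency_one_gives_zero(self):
        assert aw.information_content(1.0) == 0.0

    def test_natural_log(self):
        assert aw.information_content(np.exp(-2)) == pytest.approx(2.0)

    def test_monotone_decreasing_in_frequency(self):
        r = np.array([0.001, 0.01, 0.5, 1.0])
        ic = aw.information_content(r)
        assert np.all(np.diff(ic) < 0)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_error(self, bad):
        with pytest.raises(ValueError):
            aw.information_content(bad)


class TestComputeWeight:
    def test_p_one_gives_half_ic(self):
        assert aw.compute_weight(1.0, 0.5, 2.0, "pvalue_ic") == pytest.approx(1.0)

    def test_p_to_zero_approaches_ic(self):
        w = aw.compute_weight(1e-300, 0.5, 2.0, "pvalue_ic")
        assert w == pytest.approx(2.0, rel=1e-6)

    def test_ic_only_scheme(self):
        assert aw.compute_weight(0.3, 0.5, 3.0, "ic_only") == 3.0

    def test_effect_schemes_use_absolute_beta(self):
        w_pos = aw.compute_weight(0.5, 2.0, 1.0, "effect_only")
        w_neg = aw.compute_weight(0.5, -2.0, 1.0, "effect_only")
        assert w_pos == w_neg

    def test_primary_weight_bounds(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-12, 1, 100)
        ic = rng.uniform(0, 10, 100)
        w = aw.compute_weight(p, np.zeros(100), ic, "pvalue_ic")
        assert np.all(w >= 0.5 * ic - 1e-12)
        assert np.all(w <= ic + 1e-12)

    def test_monotone_decreasing_in_p_and_increasing_in_ic(self):
        w1 = aw.compute_weight(0.01, 0.0, 2.0)
        w2 = aw.compute_weight(0.5, 0.0, 2.0)
        assert w1 > w2
        assert aw.compute_weight(0.5, 0.0, 3.0) > aw.compute_weight(0.5, 0.0, 2.0)

    def test_unknown_scheme_error(self):
        with pytest.raises(ValueError, match="scheme"):
            aw.compute_weight(0.5, 0.0, 1.0, "magic")


class TestScanPhenotypes:
    def test_recovers_planted_log_odds(self, toy_covariates):
        rng = np.random.default_rng(42)
        n = 5000
        cov = pd.DataFrame(
            {"age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n)},
            index=pd.Index([f"I{i:03d}" for i in range(n)], name="eid"),
        )
        outcome = (rng.random(n) < 0.3).astype(float)
        hist, ids = simulate_code_histories(
            rng, n, {"A01": 0.05, "B02": 0.05}, outcome, {"A01": 2.0}
        )
        out = set(np.array(ids)[outcome.astype(bool)])
        res = aw.scan_phenotypes(hist, out, cov).set_index("code")
        assert res.loc["A01", "beta"] == pytest.approx(2.0, abs=0.3)
        assert res.loc["A01", "p_value"] < 1e-10
        assert res.loc["B02", "p_value"] > 1e-4

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        n = 800
        cov = pd.DataFrame(
            {"age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n)},
            index=pd.Index([f"I{i:03d}" for i in range(n)], name="eid"),
        )
        outcome = rng.random(n) < 0.3
        probs = {f"N{j:03d}": 0.1 for j in range(500)}
        hist, ids = simulate_code_histories(rng, n, probs, outcome.astype(float))
        res = aw.scan_phenotypes(hist, set(np.array(ids)[outcome]), cov)
        p = res.loc[~res["excluded"], "p_value"].to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01

    def test_singleton_code_flagged_excluded(self, toy_covariates):
        hist = {
            eid: make_history(
                eid, (["COMMON"] if i % 3 else []) + ([] if i else ["RARE1"])
            )
            for i, eid in enumerate(toy_covariates.index[:50])
        }
        res = aw.scan_phenotypes(hist, set(list(hist)[:10]), toy_covariates)
        res = res.set_index("code")
        assert bool(res.loc["RARE1", "excluded"])
        assert not bool(res.loc["COMMON", "excluded"])


class TestFirthLogit:
    def test_finite_under_complete_separation(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        beta, se = aw.firth_logit(X, y)
        assert np.all(np.isfinite(beta)) and np.all(np.isfinite(se))
        assert se[1] > 0

    def test_matches_ml_on_well_behaved_data(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(4000), rng.normal(size=4000)])
        y = (rng.random(4000) < expit(X @ np.array([-1.0, 1.0]))).astype(float)
        beta, se = aw.firth_logit(X, y)
        ml = sm.Logit(y, X).fit(disp=0)
        assert beta[1] == pytest.approx(ml.params[1], abs=0.05)
        assert se[1] == pytest.approx(ml.bse[1], rel=0.1)


class TestWeightTableAndSchemes:
    def _scan_df(self):
        return pd.DataFrame(
            {
                "code": ["A", "B", "C"],
                "n_with_code": [10, 20, 1],
                "beta": [2.0, 0.1, np.nan],
                "intercept": [0.0, 0.0, np.nan],
                "p_value": [1e-6, 0.8, np.nan],
                "method": ["ml", "ml", "none"],
                "converged": [True, True, False],
                "excluded": [False, False, True],
            }
        )

    def _freq(self):
        return CodeFrequencyTable({"A": 0.01, "B": 0.02, "C": 0.001}, 1000)

    def test_excluded_codes_get_neutral_weight(self):
        tab = aw.build_weight_table(self._scan_df(), self._freq()).set_index("code")
        assert tab.loc["C", "weight"] == pytest.approx(
            0.5 * aw.information_content(0.001)
        )

    def test_adjusted_pvalues_bonferroni_over_fitted(self):
        tab = aw.build_weight_table(self._scan_df(), self._freq()).set_index("code")
        assert tab.loc["A", "p_adjusted"] == pytest.approx(2e-6)
        assert np.isnan(tab.loc["C", "p_adjusted"])

    def test_scheme_self_correlation_and_symmetry(self):
        freq = self._freq()
        tabs = {
            s: aw.build_weight_table(self._scan_df(), freq, scheme=s)
            for s in ("pvalue_ic", "ic_only", "pvalue_only")
        }
        corr = aw.compare_schemes(tabs)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_constant_p_makes_pvalue_ic_proportional_to_ic(self):
        scan = self._scan_df()
        scan["p_value"] = 0.5
        scan["excluded"] = False
        scan["converged"] = True
        scan["beta"] = 1.0
        tabs = {
            s: aw.build_weight_table(scan, self._freq(), scheme=s)
            for s in ("pvalue_ic", "ic_only")
        }
        corr = aw.compare_schemes(tabs)
        assert corr.loc["pvalue_ic", "ic_only"] == pytest.approx(1.0)

    def test_zero_variance_weights_reported_missing(self):
        scan = self._scan_df()
        freq = CodeFrequencyTable({"A": 0.01, "B": 0.01, "C": 0.01}, 1000)
        tabs = {
            "ic_only": aw.build_weight_table(scan, freq, scheme="ic_only"),
            "pvalue_ic": aw.build_weight_table(scan, freq, scheme="pvalue_ic"),
        }
        corr = aw.compare_schemes(tabs)
        assert np.isnan(corr.loc["ic_only", "pvalue_ic"])
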