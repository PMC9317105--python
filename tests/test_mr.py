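"""MR estimators: Wald ratio, IVW, pleiotropy outlier test, FDR, consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from mrpath import (
    AnalysisError,
    MRResult,
    consistency_filter,
    fdr_adjust,
    ivw,
    ivw_regression,
    outlier_corrected_ivw,
    pleiotropy_test,
    simulate_summary_instruments,
    wald_ratio,
)
from mrpath.mr import PleiotropyReport, format_pvalue


def _pair(beta_exp, beta_out, se_out, se_exp=0.05, snp="rs1"):
    return pd.Series({"SNP": snp, "beta_exp": beta_exp, "se_exp": se_exp,
                      "beta_out": beta_out, "se_out": se_out})


def _pairs(be, bo, so):
    return pd.DataFrame({"SNP": [f"v{i}" for i in range(len(be))],
                         "beta_exp": be, "se_exp": 0.01,
                         "beta_out": bo, "se_out": so})


class TestWald:
    def test_arithmetic(self):
        r = wald_ratio(_pair(0.3, 0.6, 0.1))
        assert r.beta == pytest.approx(2.0)
        assert r.se == pytest.approx(0.1 / 0.3)
        assert r.ci_low == pytest.approx(r.beta - 1.96 * r.se)
        assert r.n_instruments == 1

    def test_null_numerator(self):
        r = wald_ratio(_pair(0.3, 0.0, 0.1))
        assert r.beta == 0.0 and r.p == 1.0

    def test_zero_denominator_errors(self):
        with pytest.raises(AnalysisError):
            wald_ratio(_pair(0.0, 0.5, 0.1))

    def test_second_order_se_larger(self):
        r1 = wald_ratio(_pair(0.3, 0.6, 0.1))
        r2 = wald_ratio(_pair(0.3, 0.6, 0.1), second_order=True)
        assert r2.se > r1.se

    def test_single_instrument_coverage(self):
        hits = 0
        for s in range(200):
            pairs, truth = simulate_summary_instruments(
                n_instruments=1, variance_explained=0.02, causal_effect=0.5,
                seed=s)
            r = wald_ratio(pairs.iloc[0])
            hits += abs(r.beta - 0.5) <= 3 * r.se
        assert hits / 200 >= 0.95


class TestIVW:
    def test_single_pair_reduces_to_wald(self):
        pairs = _pairs([0.3], [0.6], [0.1])
        r_ivw = ivw(pairs)
        r_wald = wald_ratio(pairs.iloc[0])
        assert r_ivw.beta == r_wald.beta
        assert r_ivw.se == r_wald.se
        assert r_ivw.method == "wald"

    def test_equal_weights_average_ratios(self):
        r = ivw(_pairs([1.0, 1.0], [1.0, 3.0], [1.0, 1.0]))
        assert r.beta == pytest.approx(2.0)
        assert r.se == pytest.approx(1 / np.sqrt(2))

    def test_zero_exposure_beta_named(self):
        with pytest.raises(AnalysisError, match="v1"):
            ivw(_pairs([0.2, 0.0], [0.1, 0.1], [0.1, 0.1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_formulations_agree(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 15))
        pairs = _pairs(rng.uniform(0.05, 0.4, m) * rng.choice([-1, 1], m),
                       rng.normal(0, 0.2, m), rng.uniform(0.01, 0.1, m))
        assert ivw(pairs).beta == pytest.approx(ivw_regression(pairs).beta, abs=1e-10)
        assert ivw(pairs).se == pytest.approx(ivw_regression(pairs).se, abs=1e-10)

    def test_instrument_order_irrelevant(self):
        rng = np.random.default_rng(9)
        pairs = _pairs(rng.uniform(0.1, 0.3, 8), rng.normal(0, 0.1, 8),
                       rng.uniform(0.02, 0.1, 8))
        shuffled = pairs.sample(frac=1, random_state=1).reset_index(drop=True)
        assert ivw(pairs).beta == pytest.approx(ivw(shuffled).beta, rel=1e-12)


class TestPleiotropy:
    def test_perfect_fit_gives_p_one(self):
        be = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        pairs = _pairs(be, 0.4 * be, np.full(5, 0.05))
        report = pleiotropy_test(pairs, n_sim=200, seed=0)
        assert report.rss_observed == pytest.approx(0.0)
        assert report.global_rss_p == 1.0
        assert report.outliers == ()

    def test_input_guards(self):
        pairs = _pairs([0.1, 0.2, 0.3], [0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        with pytest.raises(AnalysisError):
            pleiotropy_test(pairs, n_sim=200, seed=0)
        with pytest.raises(AnalysisError):
            pleiotropy_test(_pairs([0.1] * 5, [0.1] * 5, [0.1] * 5), n_sim=50, seed=0)

    def test_global_p_uniform_under_null(self):
        """Calibration of the resampling null with exact exposure betas."""
        ps = []
        for s in range(200):
            pairs, _ = simulate_summary_instruments(seed=s, exposure_noise=False)
            ps.append(pleiotropy_test(pairs, n_sim=500, seed=s).global_rss_p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_outlier_flagged_and_correction_helps(self):
        flagged = improved = 0
        for s in range(20):
            pairs, truth = simulate_summary_instruments(
                pleiotropy_ratio=5.0, seed=s)
            report = pleiotropy_test(pairs, n_sim=1_000, seed=s)
            target = truth["pleiotropic_snps"][0]
            if target in report.outliers:
                flagged += 1
                plain, corr = ivw(pairs), outlier_corrected_ivw(pairs, report)
                improved += abs(corr.beta - 0.3) < abs(plain.beta - 0.3)
        assert flagged >= 18
        assert improved >= 0.85 * flagged

    def test_no_outliers_equals_plain_ivw(self):
        pairs, _ = simulate_summary_instruments(seed=1)
        report = PleiotropyReport(1.0, pd.Series(dtype=float), (), 0.0, 100, 0)
        corr = outlier_corrected_ivw(pairs, report)
        plain = ivw(pairs)
        assert corr.beta == plain.beta and corr.se == plain.se
        assert corr.method == "ivw_outlier_corrected"

    def test_zero_weight_instrument_negligible(self):
        pairs, _ = simulate_summary_instruments(seed=2)
        ghost = pd.DataFrame([{"SNP": "ghost", "beta_exp": 0.2, "se_exp": 0.01,
                               "beta_out": 5.0, "se_out": 1e8}])
        with_ghost = pd.concat([pairs, ghost], ignore_index=True)
        report = PleiotropyReport(1.0, pd.Series(dtype=float), ("ghost",), 0.0, 100, 0)
        assert abs(outlier_corrected_ivw(with_ghost, report).beta
                   - ivw(with_ghost).beta) < 1e-12

    def test_all_flagged_errors(self):
        pairs, _ = simulate_summary_instruments(n_instruments=4, seed=3)
        report = PleiotropyReport(0.01, pd.Series(dtype=float),
                                  tuple(pairs["SNP"]), 1.0, 100, 0)
        with pytest.raises(AnalysisError):
            outlier_corrected_ivw(pairs, report)


class TestFdrAndConsistency:
    def test_bh_hand_computed(self):
        assert fdr_adjust([0.01])[0] == pytest.approx(0.01)
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
        q = fdr_adjust([0.001, 0.3, 0.04])
        assert (q >= [0.001, 0.3, 0.04]).all()

    def _res(self, beta, p, q=None):
        return MRResult("ivw", beta, 0.1, beta - 0.196, beta + 0.196, p,
                        n_instruments=5, q=q)

    def test_consistency_rules(self):
        single = {"ggt": self._res(0.5, 0.001), "mcv": self._res(0.2, 0.3),
                  "bread": self._res(-0.1, 0.01), "orphan": self._res(0.1, 0.01)}
        multiple = {"ggt": self._res(0.4, 0.001, q=0.004),
                    "mcv": self._res(0.3, 0.001, q=0.004),
                    "bread": self._res(0.1, 0.001, q=0.004)}
        kept = consistency_filter(single, multiple)
        assert kept == ["ggt"]  # mcv: single n.s.; bread: sign flip; orphan: missing


def test_pvalue_display_never_zero():
    assert format_pvalue(0.0) == "<1e-15"
    assert format_pvalue(1e-300) == "<1e-15"
    assert format_pvalue(0.04) == "0.04"
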