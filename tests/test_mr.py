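"""Two-sample MR: instruments, estimators, sensitivity diagnostics."""

import numpy as np
import pandas as pd
import pytest

from xtrait import datasets, simulate
from xtrait.mr import (MRData, egger, f_approx, heterogeneity, ivw,
                       leave_one_out, mode_estimators, mr_all,
                       select_instruments, wald_ratio, weighted_median)
from xtrait.sumstats import LDReference, SummaryStats, harmonize_pair

from conftest import make_sumstats


@pytest.fixture(scope="module")
def study_instruments():
    """The 11 published endometriosis-on-migraine instruments."""
    t = datasets.load_mr_instruments()
    return MRData(pd.DataFrame({
        "snp_id": t.snp_id,
        "beta_exposure": t.beta_exposure, "se_exposure": t.se_exposure,
        "p_exposure": t.p_exposure,
        "beta_outcome": t.beta_outcome, "se_outcome": t.se_outcome,
        "p_outcome": t.p_outcome,
        "wald_ratio": t.wald_ratio, "se_ratio": t.se_ratio,
        "f_approx": t.f_stat,
    }))


class TestWaldRatio:
    def test_published_instrument(self):
        """rs74485684: outcome 0.04 over exposure 0.11 gives ratio 0.36."""
        ratio, _ = wald_ratio(0.11, 0.02, 0.04, 0.01)
        assert round(ratio, 2) == 0.36

    def test_zero_outcome(self):
        ratio, se = wald_ratio(0.2, 0.02, 0.0, 0.01)
        assert ratio == 0.0 and se == pytest.approx(0.05)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.02, 0.1, 0.01)

    def test_second_order_se_against_monte_carlo(self):
        bx, sx, by, sy = 0.25, 0.02, 0.1, 0.03
        _, se2 = wald_ratio(bx, sx, by, sy, second_order=True)
        rng = np.random.default_rng(0)
        draws = (by + sy * rng.standard_normal(200_000)) / \
                (bx + sx * rng.standard_normal(200_000))
        assert se2 == pytest.approx(draws.std(), rel=0.05)


class TestFStat:
    def test_simple_values(self):
        assert f_approx(1.0, 1.0) == 1.0
        assert f_approx(2.0, 1.0) == 4.0

    def test_consistent_with_exposure_pvalue(self):
        """On unrounded synthetic data F equals the squared p-implied z."""
        from scipy import stats
        pair, _ = simulate.gen_mr_scenario(10, 0.2, seed=3)
        data = MRData.from_pair(pair)
        z_from_p = stats.norm.isf(data.table["p_exposure"] / 2)
        np.testing.assert_allclose(data.table["f_approx"], z_from_p ** 2,
                                   rtol=1e-6)


class TestIVW:
    def test_published_or_rounds_to_098(self, study_instruments):
        fit = ivw(study_instruments, mode="multiplicative_re")
        assert round(fit.odds_ratio, 2) == 0.98
        assert round(fit.se, 2) == 0.05

    def test_equal_ses_mean_of_ratios(self):
        data = MRData(pd.DataFrame({
            "snp_id": ["a", "b", "c"],
            "beta_exposure": [0.1] * 3, "se_exposure": [0.01] * 3,
            "p_exposure": [1e-9] * 3,
            "beta_outcome": [0.01, 0.02, 0.06], "se_outcome": [0.01] * 3,
            "p_outcome": [0.5] * 3,
            "wald_ratio": [0.1, 0.2, 0.6], "se_ratio": [0.1] * 3,
            "f_approx": [100.0] * 3,
        }))
        fit = ivw(data, mode="fixed")
        assert fit.beta == pytest.approx(0.3)

    def test_single_instrument_returns_ratio(self):
        data = MRData(pd.DataFrame({
            "snp_id": ["a"], "beta_exposure": [0.2], "se_exposure": [0.02],
            "p_exposure": [1e-9], "beta_outcome": [0.05],
            "se_outcome": [0.02], "p_outcome": [0.01],
            "wald_ratio": [0.25], "se_ratio": [0.1], "f_approx": [100.0],
        }))
        fit = ivw(data, mode="fixed")
        assert fit.beta == pytest.approx(0.25)
        assert fit.se == pytest.approx(0.1)

    def test_estimate_within_ratio_range(self, study_instruments):
        fit = ivw(study_instruments)
        r = study_instruments.ratios
        assert r.min() <= fit.beta <= r.max()

    def test_rescaling_equivariance(self, study_instruments):
        """Scaling exposure effects by c scales estimates by 1/c."""
        c = 2.5
        t = study_instruments.table.copy()
        t["beta_exposure"] *= c
        t["se_exposure"] *= c
        t["wald_ratio"] /= c
        t["se_ratio"] /= c
        scaled = MRData(t)
        assert ivw(scaled).beta == pytest.approx(ivw(study_instruments).beta / c)
        assert egger(scaled).beta == pytest.approx(egger(study_instruments).beta / c)
        wm0 = weighted_median(study_instruments, n_boot=200, seed=0)
        wm1 = weighted_median(scaled, n_boot=200, seed=0)
        assert wm1.beta == pytest.approx(wm0.beta / c)


class TestEgger:
    def test_points_on_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        data = MRData(pd.DataFrame({
            "snp_id": list("abcd"),
            "beta_exposure": bx, "se_exposure": [0.01] * 4,
            "p_exposure": [1e-9] * 4,
            "beta_outcome": 0.5 * bx, "se_outcome": [0.02] * 4,
            "p_outcome": [0.01] * 4,
            "wald_ratio": [0.5] * 4, "se_ratio": 0.02 / bx,
            "f_approx": [100.0] * 4,
        }))
        fit = egger(data)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)

    def test_two_instruments_exact_interpolation(self):
        data = MRData(pd.DataFrame({
            "snp_id": ["a", "b"],
            "beta_exposure": [0.1, 0.3], "se_exposure": [0.01] * 2,
            "p_exposure": [1e-9] * 2,
            "beta_outcome": [0.05, 0.25], "se_outcome": [0.02] * 2,
            "p_outcome": [0.01] * 2,
            "wald_ratio": [0.5, 0.833], "se_ratio": [0.2, 0.066],
            "f_approx": [100.0] * 2,
        }))
        fit = egger(data)
        # exact line through the two points: slope 1, intercept -0.05
        assert fit.beta == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(-0.05)
        assert fit.q == pytest.approx(0.0, abs=1e-12)

    def test_pleiotropy_intercept_recovery(self):
        """Directional pleiotropy of 0.05 lands inside the intercept CI
        in at least 90% of replicates."""
        hits = 0
        for rep in range(100):
            pair, _ = simulate.gen_mr_scenario(
                30, 0.3, pleiotropy_mean=0.05, pleiotropy_sd=0.02,
                seed=500 + rep)
            fit = egger(MRData.from_pair(pair))
            lo = fit.intercept - 1.96 * fit.intercept_se
            hi = fit.intercept + 1.96 * fit.intercept_se
            hits += lo <= 0.05 <= hi
        assert hits >= 90

    def test_df_bookkeeping_eleven_instruments(self, study_instruments):
        """Q has k-1 = 10 df about IVW; Q' has k-2 = 9 about Egger."""
        _, df_q, _ = heterogeneity(study_instruments, about="ivw")
        _, df_qp, _ = heterogeneity(study_instruments, about="egger")
        assert df_q == 10 and df_qp == 9


class TestWeightedMedian:
    def test_published_estimate_rounds(self, study_instruments):
        fit = weighted_median(study_instruments, n_boot=2000, seed=1)
        assert round(fit.beta, 2) == -0.09

    def test_equal_weights_odd_k_middle_ratio(self):
        data = MRData(pd.DataFrame({
            "snp_id": list("abc"),
            "beta_exposure": [0.1] * 3, "se_exposure": [0.01] * 3,
            "p_exposure": [1e-9] * 3,
            "beta_outcome": [0.01, 0.03, 0.09], "se_outcome": [0.01] * 3,
            "p_outcome": [0.5] * 3,
            "wald_ratio": [0.1, 0.3, 0.9], "se_ratio": [0.1] * 3,
            "f_approx": [100.0] * 3,
        }))
        fit = weighted_median(data, n_boot=100, seed=0)
        assert fit.beta == pytest.approx(0.3)

    def test_estimate_within_ratio_range(self, study_instruments):
        fit = weighted_median(study_instruments, n_boot=200, seed=2)
        r = study_instruments.ratios
        assert r.min() <= fit.beta <= r.max()

    def test_bootstrap_se_stability(self, study_instruments):
        a = weighted_median(study_instruments, n_boot=5000, seed=3)
        b = weighted_median(study_instruments, n_boot=10_000, seed=3)
        assert abs(a.se - b.se) / b.se < 0.05


class TestModes:
    def test_all_ratios_equal(self):
        data = MRData(pd.DataFrame({
            "snp_id": list("abcd"),
            "beta_exposure": [0.1] * 4, "se_exposure": [0.01] * 4,
            "p_exposure": [1e-9] * 4,
            "beta_outcome": [0.02] * 4, "se_outcome": [0.01] * 4,
            "p_outcome": [0.5] * 4,
            "wald_ratio": [0.2] * 4, "se_ratio": [0.1, 0.12, 0.09, 0.11],
            "f_approx": [100.0] * 4,
        }))
        simple, weighted = mode_estimators(data, n_boot=50, seed=0)
        # grid resolution bounds the attainable accuracy
        assert simple.beta == pytest.approx(0.2, abs=1e-3)
        assert weighted.beta == pytest.approx(0.2, abs=1e-3)

    def test_mode_in_dominant_cluster(self):
        ratios = [0.3, 0.31, 0.29, 0.3, 0.32, -0.5]
        data = MRData(pd.DataFrame({
            "snp_id": list("abcdef"),
            "beta_exposure": [0.1] * 6, "se_exposure": [0.01] * 6,
            "p_exposure": [1e-9] * 6,
            "beta_outcome": [r * 0.1 for r in ratios],
            "se_outcome": [0.01] * 6, "p_outcome": [0.5] * 6,
            "wald_ratio": ratios, "se_ratio": [0.05] * 6,
            "f_approx": [100.0] * 6,
        }))
        simple, weighted = mode_estimators(data, n_boot=50, seed=1)
        assert 0.2 < simple.beta < 0.4
        assert 0.2 < weighted.beta < 0.4


class TestSelection:
    def _exposure_with_blocks(self, m=338, block=31):
        """Significant SNPs spread over tight LD blocks (10 full + 1 rest)."""
        betas = np.full(m, 0.2)
        ss = make_sumstats([f"rs{i}" for i in range(1, m + 1)], betas,
                           ses=np.full(m, 0.02))
        assert (ss.table["pvalue"] < 5e-8).all()
        ld = simulate.gen_ld_reference(m, block, 0.99)
        return ss, ld

    def test_published_structure_gives_eleven(self):
        """338 significant SNPs in 11 tight blocks collapse to 11 instruments."""
        exposure, ld = self._exposure_with_blocks()
        outcome = make_sumstats(list(exposure.table["snp_id"]),
                                np.full(len(exposure), 0.01),
                                ses=np.full(len(exposure), 0.01))
        data = select_instruments(exposure, outcome, ld, r2=0.001)
        assert len(data) == 11

    def test_p_thresh_one_clumping_alone(self):
        exposure, ld = self._exposure_with_blocks(m=12, block=4)
        outcome = make_sumstats(list(exposure.table["snp_id"]),
                                np.full(len(exposure), 0.01),
                                ses=np.full(len(exposure), 0.01))
        data = select_instruments(exposure, outcome, ld, p_thresh=1.0, r2=0.001)
        assert len(data) == 3

    def test_single_block_errors(self):
        m = 10
        ss = make_sumstats([f"rs{i}" for i in range(1, m + 1)],
                           np.full(m, 0.2), ses=np.full(m, 0.02))
        ld = simulate.gen_ld_reference(m, m, 0.99)
        outcome = make_sumstats(list(ss.table["snp_id"]), np.full(m, 0.01),
                                ses=np.full(m, 0.01))
        with pytest.raises(ValueError, match="fewer than 2"):
            select_instruments(ss, outcome, ld, r2=0.001)


class TestDiagnostics:
    def test_homogeneous_q_near_df(self):
        """Under homogeneity E[Q] = df."""
        qs = []
        for rep in range(100):
            pair, _ = simulate.gen_mr_scenario(11, 0.2, seed=900 + rep)
            q, df, _ = heterogeneity(MRData.from_pair(pair), about="ivw")
            qs.append(q)
        assert np.mean(qs) == pytest.approx(10, abs=1.5)

    def test_leave_one_out_identical_instruments(self):
        data = MRData(pd.DataFrame({
            "snp_id": list("abcd"),
            "beta_exposure": [0.1] * 4, "se_exposure": [0.01] * 4,
            "p_exposure": [1e-9] * 4,
            "beta_outcome": [0.02] * 4, "se_outcome": [0.01] * 4,
            "p_outcome": [0.5] * 4,
            "wald_ratio": [0.2] * 4, "se_ratio": [0.1] * 4,
            "f_approx": [100.0] * 4,
        }))
        loo = leave_one_out(data, method=ivw)
        assert len(loo) == 4
        np.testing.assert_allclose(loo["beta"], 0.2)

    def test_fe_ivw_equals_egger_through_origin(self):
        """Constraining the Egger intercept to zero recovers fixed-effect IVW
        (verified numerically via a no-intercept weighted regression)."""
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.3, 8)
        by = 0.4 * bx + rng.normal(0, 0.01, 8)
        sy = np.full(8, 0.02)
        data = MRData(pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(8)],
            "beta_exposure": bx, "se_exposure": [0.01] * 8,
            "p_exposure": [1e-9] * 8,
            "beta_outcome": by, "se_outcome": sy, "p_outcome": [0.5] * 8,
            "wald_ratio": by / bx, "se_ratio": sy / bx,
            "f_approx": (bx / 0.01) ** 2,
        }))
        fit = ivw(data, mode="fixed")
        w = 1.0 / sy ** 2
        slope_no_icpt = np.sum(w * bx * by) / np.sum(w * bx ** 2)
        assert fit.beta == pytest.approx(slope_no_icpt)

    def test_theta_recovery_coverage(self):
        """True effect 0.3 inside the IVW CI in at least 90 of 100 draws."""
        hits = 0
        for rep in range(100):
            pair, _ = simulate.gen_mr_scenario(11, 0.3, seed=rep)
            fit = ivw(MRData.from_pair(pair))
            lo, hi = fit.ci
            hits += lo <= 0.3 <= hi
        assert hits >= 90

    def test_null_pvalue_calibration(self):
        """theta = 0, no pleiotropy: IVW p roughly uniform over replicates."""
        from scipy import stats
        ps = []
        for rep in range(200):
            pair, _ = simulate.gen_mr_scenario(11, 0.0, seed=3000 + rep)
            ps.append(ivw(MRData.from_pair(pair)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_mr_all_bundle(self, study_instruments):
        fits = mr_all(study_instruments, seed=0, n_boot=500)
        assert {"ivw", "egger", "weighted_median", "simple_mode",
                "weighted_mode"} <= set(fits)
        assert fits["ivw"].q_df == 10
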