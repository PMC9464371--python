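"""aSPU statistic, null-correlation estimation and Monte-Carlo p-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan import aspu_scan, aspu_single, estimate_null_corr, spu_statistic
from pleioscan.aspu import (NullCorr, _aspu_in_memory, _aspu_streaming,
                            _mask_seed_seq, aspu_naive_oracle)


class TestSpuStatistic:
    @pytest.mark.parametrize("gamma,expected", [(1, 2.0), (2, 14.0),
                                                (3, 20.0)])
    def test_powered_sums(self, gamma, expected):
        assert spu_statistic([1.0, -2.0, 3.0], gamma) == expected

    def test_missing_traits_dropped(self):
        assert spu_statistic([1.0, np.nan, 3.0], 1) == 4.0

    def test_no_available_traits_rejected(self):
        with pytest.raises(ValueError):
            spu_statistic([np.nan, np.nan], 2)

    def test_inf_gamma_is_max_abs_z(self):
        assert spu_statistic([1.0, -2.5, 2.0], np.inf) == 2.5


def _z_frame(Z, traits=("A", "B", "C", "D")):
    df = pd.DataFrame(Z, columns=list(traits[: Z.shape[1]]))
    df.insert(0, "SNP", [f"s{i}" for i in range(len(df))])
    df["CHR"] = "1"
    df["POS"] = np.arange(len(df))
    return df


class TestEstimateNullCorr:
    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(0)
        df = _z_frame(rng.standard_normal((10_000, 4)))
        nc = estimate_null_corr(df, ["A", "B", "C", "D"], thin=1)
        off = nc.R[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.03)

    def test_duplicated_columns_near_one(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5000)
        df = _z_frame(np.column_stack([z, z]), traits=("A", "B"))
        nc = estimate_null_corr(df, ["A", "B"], thin=1)
        assert nc.R[0, 1] >= 0.99

    def test_truncation_bias_matches_oracle(self):
        """|z|<2 selection shrinks the estimate; reproduce with a direct
        truncated-MVN simulation."""
        rho = 0.5
        R = np.array([[1.0, rho], [rho, 1.0]])
        rng = np.random.default_rng(2)
        z = rng.multivariate_normal([0, 0], R, size=200_000)
        keep = np.all(np.abs(z) < 2, axis=1)
        oracle = np.corrcoef(z[keep].T)[0, 1]

        df = _z_frame(z[:50_000], traits=("A", "B"))
        nc = estimate_null_corr(df, ["A", "B"], thin=1)
        assert nc.R[0, 1] == pytest.approx(oracle, abs=0.03)
        assert nc.R[0, 1] < rho  # biased toward zero

    def test_too_few_snps_advises_relaxing(self):
        rng = np.random.default_rng(3)
        df = _z_frame(rng.standard_normal((5000, 2)), traits=("A", "B"))
        with pytest.raises(ValueError, match="relax"):
            estimate_null_corr(df, ["A", "B"], thin=100)


class TestAspuSingle:
    def test_chi2_1df_oracle(self):
        res = aspu_single(np.array([1.96]), np.eye(1), gammas=(2,),
                          B=1_000_000, seed=0)
        expected = stats.chi2.sf(1.96**2, 1)
        mcse = np.sqrt(expected * (1 - expected) / 1e6)
        assert abs(res.p_gamma[2] - expected) < 3 * mcse

    def test_chi2_2df_closed_form(self):
        res = aspu_single(np.array([2.0, 2.0]), np.eye(2), gammas=(2,),
                          B=1_000_000, seed=1)
        expected = np.exp(-4.0)  # chi2_2 survival at 8
        mcse = np.sqrt(expected * (1 - expected) / 1e6)
        assert abs(res.p_gamma[2] - expected) < 3 * mcse

    def test_null_z_gives_p_near_one(self):
        res = aspu_single(np.zeros(3), np.eye(3), B=1000, seed=2)
        assert res.p_aspu > 0.9
        assert all(p > 0.9 for p in res.p_gamma.values())

    def test_minp_bounds(self):
        res = aspu_single(np.array([2.0, -1.0, 0.5]), np.eye(3),
                          B=20_000, seed=3)
        pmin = min(res.p_gamma.values())
        n_gamma = len(res.p_gamma)
        unit = 1.0 / (res.b_used + 1)
        assert res.p_aspu >= pmin - unit
        assert res.p_aspu <= n_gamma * pmin + 5 * np.sqrt(pmin / res.b_used) \
            + unit

    def test_rank_trick_identical_to_naive_oracle(self):
        z = np.array([1.5, -0.7])
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        pg_oracle, pa_oracle = aspu_naive_oracle(z, R, (1, 2, 3, 4), 2000,
                                                 seed=4)
        res = aspu_single(z, R, gammas=(1, 2, 3, 4), B=2000, seed=4)
        assert res.p_gamma == pg_oracle
        assert res.p_aspu == pa_oracle

    def test_streaming_identical_to_in_memory(self):
        mask = np.ones(3, dtype=bool)
        R = np.array([[1, 0.3, 0.1], [0.3, 1, 0.2], [0.1, 0.2, 1.0]])
        chol = np.linalg.cholesky(R)
        zs = np.array([[2.0, 1.0, -1.5], [4.0, 4.0, 4.0]])
        gammas = (1, 2, 3, 4, 5, 6, 7, 8)
        pg1, pa1 = _aspu_in_memory(zs, chol, gammas, 100_000,
                                   _mask_seed_seq(5, 0, mask))
        pg2, pa2 = _aspu_streaming(zs, chol, gammas, 100_000,
                                   _mask_seed_seq(5, 0, mask), topk=100_000)
        assert np.array_equal(pg1, pg2)
        assert np.array_equal(pa1, pa2)

    def test_even_gamma_monotone_in_signal(self):
        R = np.eye(2)
        p_prev = None
        for scale in (0.5, 1.0, 2.0, 3.0):
            res = aspu_single(scale * np.array([1.0, 1.0]), R, gammas=(2, 4),
                              B=5000, seed=6)
            if p_prev is not None:
                assert res.p_gamma[2] <= p_prev[2]
                assert res.p_gamma[4] <= p_prev[4]
            p_prev = res.p_gamma

    def test_inf_gamma_variant_bonferroni_like(self):
        """With gamma=inf only, the max-|Z| MC p matches the analytic
        1-(2*Phi(m)-1)^K tail for independent traits."""
        z = np.array([2.5, 0.3, -1.0])
        res = aspu_single(z, np.eye(3), gammas=(np.inf,), B=200_000, seed=30)
        expected = 1.0 - (1.0 - 2 * stats.norm.sf(2.5)) ** 3
        assert res.p_gamma[np.inf] == pytest.approx(expected, abs=0.003)

    def test_missing_trait_uses_submatrix(self):
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        res = aspu_single(np.array([2.0, np.nan]), R, gammas=(2,),
                          B=200_000, seed=7)
        expected = stats.chi2.sf(4.0, 1)
        assert res.p_gamma[2] == pytest.approx(expected, abs=0.005)

    def test_power_ordering_sparse_vs_dense(self):
        """Large gamma favours one-trait signal; gamma=1 is competitive for
        spread, same-signed signal."""
        R = np.eye(4)
        sparse = aspu_single(np.array([4.0, 0.0, 0.0, 0.0]), R,
                             gammas=(1, 8), B=50_000, seed=8)
        assert sparse.p_gamma[8] <= sparse.p_gamma[1]
        dense = aspu_single(np.array([2.0, 2.0, 2.0, 2.0]), R,
                            gammas=(1, 8), B=50_000, seed=9)
        assert dense.p_gamma[1] <= dense.p_gamma[8]


class TestAspuScan:
    def _null_corr(self, K=4, rho=0.0):
        R = np.full((K, K), rho)
        np.fill_diagonal(R, 1.0)
        traits = ["A", "B", "C", "D"][:K]
        return NullCorr(R=R, traits=traits, n_snps_used=0,
                        selection_rule="fixture")

    def test_type_one_error_calibrated(self):
        nc = self._null_corr(rho=0.3)
        rng = np.random.default_rng(10)
        Z = rng.multivariate_normal(np.zeros(4), nc.R, size=2000)
        df = _z_frame(Z)
        res = aspu_scan(df, nc, schedule=(10_000,), seed=11)
        frac = (res["P_ASPU"] < 0.05).mean()
        assert 0.040 <= frac <= 0.061

    def test_huge_signal_saturates_final_stage(self):
        nc = self._null_corr()
        df = _z_frame(np.vstack([np.full(4, 8.0), np.zeros(4)]))
        res = aspu_scan(df, nc, schedule=(1000, 10_000, 100_000), seed=12)
        hot = res.set_index("SNP").loc["s0"]
        cold = res.set_index("SNP").loc["s1"]
        assert hot["B_USED"] == 100_000
        assert hot["P_ASPU"] == pytest.approx(1 / 100_001)
        assert cold["B_USED"] == 1000

    def test_same_seed_identical_output(self):
        nc = self._null_corr(rho=0.2)
        rng = np.random.default_rng(13)
        df = _z_frame(rng.multivariate_normal(np.zeros(4), nc.R, size=50))
        a = aspu_scan(df, nc, schedule=(2000, 20_000), seed=14)
        b = aspu_scan(df, nc, schedule=(2000, 20_000), seed=14)
        pd.testing.assert_frame_equal(a, b)

    def test_result_independent_of_snp_order(self):
        nc = self._null_corr(rho=0.2)
        rng = np.random.default_rng(15)
        df = _z_frame(rng.multivariate_normal(np.zeros(4), nc.R, size=40))
        a = aspu_scan(df, nc, schedule=(2000,), seed=16).set_index("SNP")
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = aspu_scan(shuffled, nc, schedule=(2000,), seed=16).set_index("SNP")
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_decreasing_schedule_rejected(self):
        nc = self._null_corr()
        df = _z_frame(np.zeros((2, 4)))
        with pytest.raises(ValueError, match="increasing"):
            aspu_scan(df, nc, schedule=(1000, 500), seed=0)

    def test_chi2_4df_grid_agreement(self):
        """SPU(2) Monte-Carlo p matches the chi-square_4 survival function
        across a grid of observed Z magnitudes."""
        nc = self._null_corr()
        for scale in (1.0, 1.5, 2.0, 2.5):
            z = np.full(4, scale)
            res = aspu_single(z, nc.R, gammas=(2,), B=200_000, seed=17)
            expected = stats.chi2.sf(np.sum(z**2), 4)
            mcse = np.sqrt(expected * (1 - expected) / 200_000)
            assert abs(res.p_gamma[2] - expected) < 3 * mcse + 1e-5
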