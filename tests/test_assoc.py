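"""GWAS, QC, inverse-variance meta-analysis and inflation diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan import (effective_n, genomic_lambda, ivw_meta, qc_filter,
                       run_gwas)
from pleioscan.assoc import harmonize_to_reference, meta_analyze


class TestEffectiveN:
    def test_formula(self):
        assert effective_n(1000, 0.25, 0.8) == pytest.approx(300.0)

    def test_zero_info_zero_neff(self):
        assert effective_n(1000, 0.25, 0.0) == 0.0

    def test_boundary_retained_under_strict_rule(self):
        # n_eff exactly 30 survives an "< 30" exclusion
        neff = effective_n(60, 0.5, 1.0)
        assert neff == 30.0
        df = _sumstat_rows([dict(INFO=1.0, NEFF=neff, EAF=0.5)])
        kept, _ = qc_filter(df)
        assert len(kept) == 1


def _sumstat_rows(overrides):
    base = dict(SNP="s", CHR="1", POS=1, EA="A", OA="G", EAF=0.3,
                BETA=0.1, SE=0.05, Z=2.0, P=0.045, N=1000, INFO=0.9,
                NEFF=400.0, TRAIT="CRP", STUDY="x")
    rows = []
    for i, ov in enumerate(overrides):
        row = dict(base, SNP=f"s{i}", **ov)
        rows.append(row)
    return pd.DataFrame(rows)


class TestQcFilter:
    def test_info_just_below_threshold_dropped(self):
        kept, _ = qc_filter(_sumstat_rows([dict(INFO=0.39)]))
        assert len(kept) == 0

    def test_maf_exactly_at_threshold_retained(self):
        kept, _ = qc_filter(_sumstat_rows([dict(EAF=0.05)]))
        assert len(kept) == 1

    def test_one_failure_per_rule_plus_one_pass(self):
        df = _sumstat_rows([
            dict(INFO=0.2),            # fails imputation
            dict(NEFF=10.0),           # fails effective N
            dict(EAF=0.01),            # fails MAF (low side)
            dict(EAF=0.97),            # fails MAF (high side)
            dict(),                    # passes
        ])
        kept, audit = qc_filter(df)
        assert len(kept) == 1 and kept.iloc[0]["SNP"] == "s4"
        counts = dict(zip(audit["reason"], audit["n_failed"]))
        assert counts == {"info": 1, "neff": 1, "maf": 2, "any": 4}


class TestIvwMeta:
    def test_single_study_identity(self):
        rec = ivw_meta([(0.12, 0.03)])
        assert rec.beta_meta == pytest.approx(0.12)
        assert rec.se_meta == pytest.approx(0.03)

    def test_equal_weight_case(self):
        rec = ivw_meta([(1.0, 1.0), (1.0, 1.0)])
        assert rec.beta_meta == pytest.approx(1.0)
        assert rec.se_meta == pytest.approx(1 / np.sqrt(2))

    def test_hand_weighted_mean(self):
        rec = ivw_meta([(1.0, 1.0), (3.0, 1.0)])
        assert rec.beta_meta == pytest.approx(2.0)
        assert rec.se_meta == pytest.approx(1 / np.sqrt(2))

    def test_k_identical_studies_shrink_se_by_sqrt_k(self):
        for k in (2, 3, 5):
            rec = ivw_meta([(0.2, 0.07)] * k)
            assert rec.se_meta == pytest.approx(0.07 / np.sqrt(k))
            assert rec.beta_meta == pytest.approx(0.2)

    def test_order_invariance(self):
        studies = [(0.1, 0.02), (-0.3, 0.05), (0.2, 0.01)]
        a = ivw_meta(studies)
        b = ivw_meta(studies[::-1])
        assert a.beta_meta == pytest.approx(b.beta_meta, abs=1e-15)
        assert a.se_meta == pytest.approx(b.se_meta, abs=1e-15)

    def test_se_meta_not_larger_than_best_study(self):
        rec = ivw_meta([(0.1, 0.5), (0.0, 0.02), (0.3, 1.0)])
        assert rec.se_meta <= 0.02
        assert rec.direction == "+0+"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw_meta([])


class TestHarmonize:
    def _row(self, ea, oa, beta=0.1, eaf=0.3, ref_eaf=None):
        row = pd.Series(dict(SNP="s", EA=ea, OA=oa, BETA=beta, Z=2.0,
                             EAF=eaf))
        if ref_eaf is not None:
            row["REF_EAF"] = ref_eaf
        return row

    def test_swapped_alleles_flip_sign(self):
        out = harmonize_to_reference("A", "G", self._row("G", "A", beta=0.1))
        assert out["BETA"] == pytest.approx(-0.1)
        assert out["EAF"] == pytest.approx(0.7)

    def test_identical_alleles_unchanged(self):
        out = harmonize_to_reference("A", "G", self._row("A", "G"))
        assert out["BETA"] == pytest.approx(0.1)

    def test_strand_flip_resolved_by_complement(self):
        out = harmonize_to_reference("A", "G", self._row("T", "C"))
        assert out["BETA"] == pytest.approx(0.1)

    def test_ambiguous_at_snp_oriented_by_eaf(self):
        out = harmonize_to_reference(
            "A", "T", self._row("A", "T", eaf=0.42, ref_eaf=0.44)
        )
        assert out is not None and out["BETA"] == pytest.approx(0.1)

    def test_ambiguous_conflicting_eaf_dropped(self):
        # both orientations (EAF 0.45 or 0.55) sit > 0.2 from the
        # reference frequency, so the SNP cannot be oriented safely
        out = harmonize_to_reference(
            "C", "G", self._row("C", "G", eaf=0.45, ref_eaf=0.10)
        )
        assert out is None

    def test_incompatible_sets_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            harmonize_to_reference("A", "G", self._row("A", "C"))


class TestRunGwas:
    @staticmethod
    def _toy(n=800, m=5, seed=0, n_clusters=None):
        rng = np.random.default_rng(seed)
        dosage = pd.DataFrame(
            rng.binomial(2, 0.3, size=(n, m)).astype(float),
            columns=[f"s{j}" for j in range(m)],
        )
        pcs = pd.DataFrame(rng.standard_normal((n, 3)),
                           columns=["PC1", "PC2", "PC3"])
        clusters = (np.arange(n) if n_clusters is None
                    else np.arange(n) % n_clusters)
        y = pd.Series(rng.standard_normal(n))
        return y, dosage, pcs, clusters

    def test_singleton_clusters_equal_hc0(self):
        import statsmodels.api as sm

        y, dosage, pcs, clusters = self._toy()
        res = run_gwas(y, dosage, pcs, clusters)
        for j, snp in enumerate(dosage.columns):
            X = sm.add_constant(
                np.column_stack([dosage[snp], pcs.to_numpy()])
            )
            fit = sm.OLS(y.to_numpy(), X).fit(cov_type="HC0")
            assert res.iloc[j]["BETA"] == pytest.approx(fit.params[1],
                                                        abs=1e-10)
            assert res.iloc[j]["SE"] == pytest.approx(fit.bse[1], abs=1e-10)

    def test_cluster_sandwich_matches_gee(self):
        import statsmodels.api as sm

        y, dosage, pcs, clusters = self._toy(n=600, m=3, seed=1,
                                             n_clusters=150)
        res = run_gwas(y, dosage, pcs, clusters)
        for j, snp in enumerate(dosage.columns):
            X = sm.add_constant(
                np.column_stack([dosage[snp], pcs.to_numpy()])
            )
            gee = sm.GEE(
                y.to_numpy(), X, groups=np.asarray(clusters),
                cov_struct=sm.cov_struct.Independence(),
            ).fit()
            assert res.iloc[j]["BETA"] == pytest.approx(gee.params[1],
                                                        rel=1e-6)
            assert res.iloc[j]["SE"] == pytest.approx(gee.bse[1], rel=1e-4)

    def test_null_type_one_error_calibrated(self):
        y, dosage, pcs, clusters = self._toy(n=900, m=2000, seed=2,
                                             n_clusters=300)
        res = run_gwas(y, dosage, pcs, clusters)
        frac = (res["P"] < 0.05).mean()
        assert 0.040 <= frac <= 0.061

    def test_effect_recovered_within_3se(self):
        rng = np.random.default_rng(3)
        n = 50_000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = pd.Series(0.1 * g + rng.standard_normal(n))
        dosage = pd.DataFrame({"s": g})
        pcs = pd.DataFrame(rng.standard_normal((n, 2)))
        res = run_gwas(y, dosage, pcs, np.arange(n))
        assert abs(res.iloc[0]["BETA"] - 0.1) < 3 * res.iloc[0]["SE"]

    def test_monomorphic_snp_flagged_and_qc_dropped(self):
        y, dosage, pcs, clusters = self._toy(n=200, m=2)
        dosage["mono"] = 0.0
        res = run_gwas(y, dosage, pcs, clusters)
        row = res[res["SNP"] == "mono"].iloc[0]
        assert row["BETA"] == 0.0 and row["EAF"] == 0.0
        kept, _ = qc_filter(res)
        assert "mono" not in set(kept["SNP"])

    def test_permuted_phenotype_lambda_in_null_band(self):
        y, dosage, pcs, clusters = self._toy(n=800, m=1500, seed=4,
                                             n_clusters=200)
        rng = np.random.default_rng(5)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = run_gwas(y_perm, dosage, pcs, clusters)
        lam = genomic_lambda(res["P"])
        assert 0.9 < lam < 1.1


class TestMetaAnalyze:
    def test_pooling_two_homogeneous_studies(self):
        rng = np.random.default_rng(6)
        rows = []
        for study in ("a", "b"):
            rows.append(_sumstat_rows([dict(BETA=0.1 + rng.normal(0, 0.01),
                                            SE=0.05, STUDY=study)]))
        meta = meta_analyze(rows)
        assert meta.iloc[0]["SE"] == pytest.approx(0.05 / np.sqrt(2))
        assert meta.iloc[0]["K_STUDIES"] == 2
        assert len(meta.iloc[0]["DIRECTION"]) == 2


class TestGenomicLambda:
    def test_uniform_pvalues_lambda_near_one(self):
        rng = np.random.default_rng(7)
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert 0.98 <= lam <= 1.02

    def test_all_half_gives_lambda_one(self):
        lam = genomic_lambda(np.full(200, 0.5))
        assert lam == pytest.approx(1.0, abs=1e-10)

    def test_inflated_chi2_scales_lambda(self):
        rng = np.random.default_rng(8)
        chi2 = 1.1 * rng.chisquare(1, size=200_000)
        p = stats.chi2.sf(chi2, 1)
        assert genomic_lambda(p) == pytest.approx(1.1, abs=0.02)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            genomic_lambda(np.full(50, 0.5))
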