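import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrpipe.meta import (
    LDMatrix,
    conditional_scan,
    define_loci,
    fixed_effects_meta,
    genomic_inflation,
    heterogeneity,
    meta_analyze,
    random_effects_meta,
    read_ld_matrix,
    variance_explained,
    write_ld_matrix,
)
from mrpipe.simulate import SimConfig, simulate_individual, simulate_region
from mrpipe.sumstats import intersect_and_align


class TestFixedEffects:
    def test_identical_studies_pool_to_se_over_sqrt_k(self):
        r = fixed_effects_meta([0.2, 0.2], [0.02, 0.02])
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.02 / np.sqrt(2))

    def test_equal_weight_hand_example(self):
        r = fixed_effects_meta([0.1, 0.3], [0.1, 0.1])
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.0707107, abs=1e-6)
        assert r.q == pytest.approx(2.0)

    def test_single_cohort_passthrough(self):
        r = fixed_effects_meta([0.205], [0.014])
        assert (r.beta, r.se, r.q, r.i2) == (0.205, 0.014, 0.0, 0.0)

    def test_pooled_se_not_above_smallest_cohort_se(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ses = rng.uniform(0.01, 0.5, 4)
            r = fixed_effects_meta(rng.normal(0, 1, 4), ses)
            assert r.se <= ses.min() + 1e-12

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_meta([np.nan, 0.1], [0.1, 0.1])


class TestRandomEffects:
    def test_homogeneous_input_truncates_tau2_and_equals_fixed(self):
        fe = fixed_effects_meta([0.2, 0.21], [0.1, 0.1])
        re = random_effects_meta([0.2, 0.21], [0.1, 0.1])
        assert re.tau2 == 0.0
        assert re.beta == pytest.approx(fe.beta)
        assert re.se == pytest.approx(fe.se)

    def test_dersimonian_laird_hand_example(self):
        r = random_effects_meta([0.1, 0.3], [0.1, 0.1])
        assert r.tau2 == pytest.approx(0.01)
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)

    def test_pooled_beta_monotone_in_any_cohort_beta(self):
        base = random_effects_meta([0.1, 0.3, 0.2], [0.1, 0.2, 0.15]).beta
        up = random_effects_meta([0.1, 0.5, 0.2], [0.1, 0.2, 0.15]).beta
        assert up > base

    def test_random_se_at_least_fixed_se(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            b, s = rng.normal(0, 1, 5), rng.uniform(0.05, 0.4, 5)
            assert random_effects_meta(b, s).se >= fixed_effects_meta(b, s).se - 1e-12

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError, match="fixed"):
            random_effects_meta([0.1], [0.1])


class TestHeterogeneity:
    @pytest.mark.parametrize("q, k, expected", [
        (13.43, 4, 0.777),   # strong cross-cohort heterogeneity
        (6.416, 4, 0.532),   # moderate
        (0.955, 4, 0.0),     # below expectation -> truncated to zero
    ])
    def test_i2_from_q_matches_reported_values(self, q, k, expected):
        from mrpipe.meta import i_squared
        assert i_squared(q, k) == pytest.approx(expected, abs=5e-4)

    def test_equal_betas_give_zero_q(self):
        q, q_p, i2 = heterogeneity([0.1, 0.1, 0.1], [0.2, 0.1, 0.3], 0.1)
        assert q == 0.0 and i2 == 0.0 and q_p == pytest.approx(1.0)

    @given(st.floats(0.1, 10))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_i2_invariant_to_common_rescaling(self, c):
        b = np.array([0.05, 0.3, -0.1, 0.2])
        s = np.array([0.1, 0.05, 0.2, 0.08])
        pooled = fixed_effects_meta(b, s).beta
        _, _, i2 = heterogeneity(b, s, pooled)
        pooled_c = fixed_effects_meta(c * b, c * s).beta
        _, _, i2_c = heterogeneity(c * b, c * s, pooled_c)
        assert i2_c == pytest.approx(i2, rel=1e-9)


class TestGenomicInflation:
    def test_null_calibrated_statistics_give_unity(self):
        median_chi2 = stats.chi2.ppf(0.5, 1)
        assert genomic_inflation(chisq=[median_chi2] * 5) == pytest.approx(1.0)

    def test_median_two_example(self):
        assert genomic_inflation(chisq=[1, 2, 3]) == pytest.approx(2 / stats.chi2.ppf(0.5, 1), rel=1e-6)

    def test_null_gwas_lambda_near_one(self):
        rng = np.random.default_rng(42)
        lam = genomic_inflation(z=rng.standard_normal(10_000))
        assert 0.9 < lam < 1.1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(chisq=[])


class TestVarianceExplained:
    @pytest.mark.parametrize("beta, se, n, expected", [
        (0.205, 0.014, 10584, 0.0199),
        (0.109, 0.017, 10584, 0.0039),
        (0.074, 0.014, 10584, 0.0026),
    ])
    def test_reported_fractions_reproduced(self, beta, se, n, expected):
        assert variance_explained(beta, se, n) == pytest.approx(expected, abs=5e-5)

    def test_null_effect_explains_nothing(self):
        assert variance_explained(0.0, 0.1, 1000) == 0.0


def _meta_df(rows):
    df = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "BETA", "SE", "P", "N"])
    df["MLOG10P"] = -np.log10(df["P"])
    return df


class TestDefineLoci:
    def test_nothing_significant_gives_empty_list(self):
        df = _meta_df([("rs1", "1", 100, 0.1, 0.1, 0.5, 1000)])
        assert define_loci(df) == []

    def test_greedy_clump_picks_strongest_lead(self):
        df = _meta_df([
            ("rs1", "1", 100_000, 0.2, 0.03, 1e-9, 1000),
            ("rs2", "1", 200_000, 0.2, 0.03, 1e-10, 1000),
            ("rs3", "1", 300_000, 0.2, 0.03, 1e-8 * 0.9, 1000),
        ])
        loci = define_loci(df, window_bp=1_000_000)
        assert len(loci) == 1
        assert loci[0].lead["SNP"] == "rs2"
        assert loci[0].n_members == 3

    def test_distant_signals_split_into_loci_separated_beyond_window(self):
        df = _meta_df([
            ("rs1", "1", 100_000, 0.2, 0.03, 1e-10, 1000),
            ("rs2", "1", 2_100_000, 0.2, 0.03, 1e-9, 1000),
            ("rs3", "2", 100_000, 0.2, 0.03, 1e-12, 1000),
        ])
        loci = define_loci(df, window_bp=500_000)
        assert len(loci) == 3
        leads = [(l.lead["CHR"], l.lead["POS"]) for l in loci]
        for i, (c1, p1) in enumerate(leads):
            for c2, p2 in leads[i + 1:]:
                assert c1 != c2 or abs(p1 - p2) > 500_000

    def test_wide_association_region_forms_single_locus(self):
        # dense cluster of significant SNPs collapses to one locus
        pos = 100_000 + 5_000 * np.arange(69)
        df = _meta_df([(f"rs{i}", "12", p, 0.2, 0.02, 1e-12, 1000)
                       for i, p in enumerate(pos)])
        loci = define_loci(df, window_bp=500_000)
        assert len(loci) == 1
        assert loci[0].n_members == 69


class TestLDMatrix:
    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1, 0.5], [0.4, 1]]))

    def test_round_trip_through_file(self, tmp_path):
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        path = tmp_path / "ld.txt"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.snps == ["rs1", "rs2"]
        np.testing.assert_allclose(back.r, ld.r)


def _locus_df(snps, pos, eafs, betas, ses):
    return pd.DataFrame({"SNP": snps, "CHR": "1", "POS": pos, "EAF": eafs,
                         "BETA": betas, "SE": ses})


class TestConditionalScan:
    def test_independent_snp_unchanged(self):
        ld = LDMatrix(["lead", "rs2"], np.eye(2))
        df = _locus_df(["lead", "rs2"], [100, 200], [0.5, 0.5], [0.3, 0.15], [0.02, 0.02])
        out = conditional_scan(df, ld, "lead")
        row = out[out["SNP"] == "rs2"].iloc[0]
        assert row["BETA_COND"] == pytest.approx(0.15)
        assert row["SE_COND"] == pytest.approx(0.02)

    def test_shadow_signal_vanishes_conditioned_on_lead(self):
        # marginal of rs2 is purely LD reflection of the lead: 0.15 = 0.5*0.3
        ld = LDMatrix(["lead", "rs2"], np.array([[1, 0.5], [0.5, 1]]))
        df = _locus_df(["lead", "rs2"], [100, 200], [0.5, 0.5], [0.3, 0.15], [0.02, 0.02])
        out = conditional_scan(df, ld, "lead")
        assert out[out["SNP"] == "rs2"]["BETA_COND"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_high_collinearity_flagged_ignored(self):
        r = np.sqrt(0.95)
        ld = LDMatrix(["lead", "rs2"], np.array([[1, r], [r, 1]]))
        df = _locus_df(["lead", "rs2"], [100, 200], [0.5, 0.5], [0.3, 0.29], [0.02, 0.02])
        out = conditional_scan(df, ld, "lead")
        assert out[out["SNP"] == "rs2"]["STATUS"].iloc[0] == "ignored"

    def test_distant_snp_returned_unconditioned(self):
        ld = LDMatrix(["lead", "rs2"], np.array([[1, 0.3], [0.3, 1]]))
        df = _locus_df(["lead", "rs2"], [100, 100 + 11_000_000], [0.5, 0.5],
                       [0.3, 0.15], [0.02, 0.02])
        out = conditional_scan(df, ld, "lead")
        row = out[out["SNP"] == "rs2"].iloc[0]
        assert row["STATUS"] == "unconditioned"
        assert row["BETA_COND"] == pytest.approx(0.15)

    @pytest.mark.parametrize("r", [0.0, 0.3, 0.5, 0.8])
    def test_agrees_with_joint_ols_on_individual_data(self, r):
        """Summary-level conditioning matches two-SNP OLS within 2 SE."""
        n = 5000
        cfg = SimConfig(m_variants=2, n_blocks=1, rho=max(r, 1e-9), n_causal=1,
                        h2_exp=0.01, h2_shares=None, seed=11)
        region = simulate_region(cfg)
        joint = region.truth.joint
        x, y = simulate_individual(region, joint, n, seed=11)

        marg_beta, marg_se = [], []
        for j in range(2):
            xj = x[:, j]
            b = xj @ y / (xj @ xj)
            resid = y - b * xj
            se = np.sqrt(resid @ resid / (n - 2) / (xj @ xj))
            marg_beta.append(b)
            marg_se.append(se)

        xx = np.column_stack([x[:, 0], x[:, 1]])
        bj, *_ = np.linalg.lstsq(xx, y, rcond=None)
        h = np.linalg.inv(xx.T @ xx)
        resid = y - xx @ bj
        sj = np.sqrt(np.diag(h) * (resid @ resid) / (n - 2))

        # express marginals on a per-allele scale the scan converts back from
        eaf = 0.5
        scale = np.sqrt(2 * eaf * (1 - eaf))
        df = _locus_df(["rs1", "rs2"], [100, 200], [eaf, eaf],
                       np.array(marg_beta) / scale, np.array(marg_se) / scale)
        out = conditional_scan(df, region.ld, "rs1")
        row = out[out["SNP"] == "rs2"].iloc[0]
        beta_cond_std = row["BETA_COND"] * scale
        assert beta_cond_std == pytest.approx(bj[1], abs=2 * sj[1])


class TestMetaAnalyzeTable:
    def test_vectorized_table_matches_scalar_api(self, study_dataset):
        _, _, panels, _ = study_dataset
        aligned = intersect_and_align(panels)
        table = meta_analyze(aligned, method="fixed")
        labels = aligned.attrs["cohorts"]
        j = 17
        r = fixed_effects_meta(
            [aligned.loc[j, f"BETA_{l}"] for l in labels],
            [aligned.loc[j, f"SE_{l}"] for l in labels],
        )
        assert table.loc[j, "BETA"] == pytest.approx(r.beta, rel=1e-12)
        assert table.loc[j, "SE"] == pytest.approx(r.se, rel=1e-12)
        assert table.loc[j, "Q"] == pytest.approx(r.q, rel=1e-9, abs=1e-12)

    def test_random_effects_table_se_at_least_fixed(self, study_dataset):
        _, _, panels, _ = study_dataset
        aligned = intersect_and_align(panels)
        fixed = meta_analyze(aligned, method="fixed")
        random = meta_analyze(aligned, method="random")
        assert (random["SE"].to_numpy() >= fixed["SE"].to_numpy() - 1e-12).all()
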