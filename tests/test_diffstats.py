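"""Inferential statistics: exact small-instance oracles and calibration."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats, special

from proteopower import diffstats, prep
from proteopower.containers import ExpressionMatrix, SampleMetadata, ValidationError
from proteopower.diffstats import (
    DesignSpec,
    anova_per_protein,
    benjamini_hochberg,
    moderated_fit,
    partial_correlation,
    pca,
    retention_and_overlap,
    squeeze_variances,
    trigamma_inverse,
)
from proteopower.synthdata import SyntheticConfig, generate_study


def two_group_metadata(n_per_group=3):
    """Minimal metadata: one binary factor of interest (ighv_status)."""
    rows = []
    for i in range(2 * n_per_group):
        grp = "M" if i < n_per_group else "UM"
        rows.append(
            {
                "patient_id": f"P{i + 1}",
                "prep_day": 1 + i % 2,
                "ms_run": 1,
                "ighv_status": grp,
                "ighv_percent": 5.0 if grp == "M" else 0.5,
                "wbc_class": "low" if i % 2 else "high",
                "gender": "M" if i % 3 else "F",
            }
        )
    t = pd.DataFrame(rows)
    t.index = pd.Index([f"s{i}" for i in range(len(t))])
    return SampleMetadata(t)


def expr(values, scale="log2"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(df, scale=scale)


class TestBenjaminiHochberg:
    def test_single_p(self):
        np.testing.assert_allclose(benjamini_hochberg([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(benjamini_hochberg([0.005, 0.5]), [0.01, 0.5])

    def test_matches_brute_force_definition(self, rng):
        p = rng.uniform(size=97)
        m = p.size
        order = np.argsort(p)
        rank = np.empty(m, dtype=int)
        rank[order] = np.arange(1, m + 1)
        brute = np.array(
            [min(min(1.0, m * p[j] / rank[j]) for j in range(m) if p[j] >= p[i])
             for i in range(m)]
        )
        np.testing.assert_allclose(benjamini_hochberg(p), brute, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), q_sm, atol=1e-12)

    def test_q_at_least_p_and_order_preserving(self, rng):
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q[np.argsort(p)] == np.sort(q))

    def test_nan_passthrough_and_range_check(self):
        q = benjamini_hochberg([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])
        with pytest.raises(ValidationError):
            benjamini_hochberg([1.5])


class TestAnova:
    def test_f_equals_squared_pooled_t(self):
        """Balanced one-factor two-level design: F = t^2 (here 13.5)."""
        meta = two_group_metadata(3)
        m = expr([[1, 2, 3, 4, 5, 6]])
        res = anova_per_protein(m, meta, DesignSpec(factors=("ighv_status",)))
        F = res["ighv_status"].table["statistic"].iloc[0]
        # pooled t on (1,2,3) vs (4,5,6): t = 3 / sqrt(1 * 2/3), F = t^2 = 13.5
        assert F == pytest.approx(13.5, abs=1e-9)
        t, p = stats.ttest_ind([4, 5, 6], [1, 2, 3])
        assert F == pytest.approx(t**2, abs=1e-9)
        assert res["ighv_status"].table["p_value"].iloc[0] == pytest.approx(p, abs=1e-12)
        assert res["ighv_status"].table["effect"].iloc[0] == pytest.approx(3.0)

    def test_equal_group_means_give_f_zero(self):
        meta = two_group_metadata(3)
        m = expr([[1, 2, 3, 1, 2, 3]])
        res = anova_per_protein(m, meta, DesignSpec(factors=("ighv_status",)))
        assert res["ighv_status"].table["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["ighv_status"].table["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_type_ii_against_statsmodels(self, small_log2):
        """Joint five-factor model: per-factor F matches statsmodels anova_lm."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        log2m, metadata, _ = small_log2
        design = DesignSpec()
        res = anova_per_protein(log2m, metadata, design)
        t = metadata.table.copy()
        for pid in log2m.protein_ids[:5]:
            t["y"] = log2m.values.loc[pid].to_numpy()
            fit = smf.ols(
                "y ~ C(ighv_status) + C(wbc_class) + C(gender) + C(prep_day) + C(ms_run)",
                data=t,
            ).fit()
            tab = sm.stats.anova_lm(fit, typ=2)
            for factor, row_name in [
                ("ighv_status", "C(ighv_status)"),
                ("prep_day", "C(prep_day)"),
                ("ms_run", "C(ms_run)"),
            ]:
                mine = res[factor].table.loc[pid, "statistic"]
                ref = tab.loc[row_name, "F"]
                assert mine == pytest.approx(ref, rel=1e-8), factor

    def test_null_prep_day_p_values_uniform(self, null_log2):
        """Zero-effect study: prep-day p-values are ~uniform."""
        log2m, metadata, _ = null_log2
        res = anova_per_protein(log2m, metadata)
        p = res["prep_day"].table["p_value"].to_numpy()
        frac = np.mean(p <= 0.05)
        assert frac == pytest.approx(0.05, abs=0.025)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01
        # BH at 10% FDR admits occasional false discoveries under the null
        assert res["prep_day"].n_significant <= 2

    def test_confounded_design_names_aliased_pair(self):
        meta = two_group_metadata(3)
        t = meta.table.copy()
        t["wbc_class"] = np.where(t["ighv_status"] == "UM", "high", "low")
        with pytest.raises(ValidationError, match="ighv_status.*wbc_class"):
            anova_per_protein(
                expr(np.random.default_rng(0).normal(size=(3, 6))),
                SampleMetadata(t),
                DesignSpec(factors=("ighv_status", "wbc_class")),
            )


class TestModeratedFit:
    def test_single_protein_equals_ordinary_t(self):
        meta = two_group_metadata(4)
        m = expr([[1.0, 2.2, 2.9, 4.1, 5.0, 6.3, 7.1, 7.9]])
        res = moderated_fit(m, meta, DesignSpec(factors=("ighv_status",),
                                                contrast=("ighv_status", "UM", "M")))
        t_ref, _ = stats.ttest_ind(m.to_numpy()[0, 4:], m.to_numpy()[0, :4])
        assert res.table["statistic"].iloc[0] == pytest.approx(t_ref, abs=1e-6)

    def test_hyperparameter_recovery_from_scaled_inv_chi2(self, rng):
        """Variances from a scaled inverse-chi^2 (d0=4, s0^2=0.25) are
        recovered by the moment-matching estimator within 15%."""
        d0_true, s02_true, df = 4.0, 0.25, 10
        n = 5000
        s2 = d0_true * s02_true / rng.chisquare(d0_true, size=n)
        s2 = s2 * rng.chisquare(df, size=n) / df
        d0, s02, _ = squeeze_variances(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s02 == pytest.approx(s02_true, rel=0.15)

    def test_infinite_prior_df_pools_variances(self):
        meta = two_group_metadata(4)
        rng = np.random.default_rng(5)
        m = expr(rng.normal(size=(40, 8)))
        res = moderated_fit(
            m, meta,
            DesignSpec(factors=("ighv_status",), contrast=("ighv_status", "UM", "M")),
            d0_override=np.inf,
        )
        s02 = res.extras["s0_squared"]
        # all moderated t share the pooled variance: t = effect / (s0 * c)
        c = np.sqrt(1.0 / 4 + 1.0 / 4)
        expected = res.table["effect"] / (np.sqrt(s02) * c)
        np.testing.assert_allclose(res.table["statistic"], expected, atol=1e-9)

    def test_trigamma_inverse_round_trip(self):
        for y in (0.1, 1.0, 5.0, 40.0):
            x = float(special.polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-8)

    def test_matches_r_limma(self, tmp_path, small_log2):
        """Moderated t, p and effects agree with the limma reference."""
        log2m, metadata, _ = small_log2
        sub = ExpressionMatrix(log2m.values.iloc[:80], scale="log2")
        res = moderated_fit(
            sub, metadata,
            DesignSpec(factors=("ighv_status", "wbc_class", "gender"),
                       contrast=("ighv_status", "UM", "M")),
        )
        sub.values.to_csv(tmp_path / "mat.tsv", sep="\t")
        metadata.table.to_csv(tmp_path / "meta.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"mat <- as.matrix(read.delim('{tmp_path}/mat.tsv', row.names=1, check.names=FALSE))\n"
            f"meta <- read.delim('{tmp_path}/meta.tsv', row.names=1)\n"
            "design <- model.matrix(~ I(ighv_status=='UM') + wbc_class + gender, data=meta)\n"
            "fit <- eBayes(lmFit(mat, design))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], effect=fit$coefficients[,2],"
            " d0=fit$df.prior, s02=fit$s2.prior)\n"
            f"write.table(out, '{tmp_path}/ref.tsv', sep='\\t', quote=FALSE, col.names=NA)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(res.table["statistic"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res.table["p_value"], ref["p"], atol=1e-10)
        assert res.extras["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res.extras["s0_squared"] == pytest.approx(ref["s02"].iloc[0], rel=1e-6)


class TestPartialCorrelation:
    def test_no_confounders_equals_pearson(self, rng):
        meta = two_group_metadata(5)
        Y = rng.normal(size=(20, 10))
        m = expr(Y)
        res = partial_correlation(m, meta, confounders=())
        x = meta.table["ighv_percent"].to_numpy()
        for i in range(20):
            r_ref = stats.pearsonr(Y[i], x).statistic
            assert res.table["effect"].iloc[i] == pytest.approx(r_ref, abs=1e-10)

    def test_first_order_closed_form(self, rng):
        """With one confounder, the residual method equals the recursive
        formula r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        n = 200
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = 0.3 * z + 0.4 * x + rng.normal(size=n)
        r_xy = stats.pearsonr(x, y).statistic
        r_xz = stats.pearsonr(x, z).statistic
        r_yz = stats.pearsonr(y, z).statistic
        closed = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        # residual method by hand
        zc = np.column_stack([np.ones(n), z])
        rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
        ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
        r_resid = stats.pearsonr(rx, ry).statistic
        assert r_resid == pytest.approx(closed, abs=1e-10)

    def test_confounder_only_signal_vanishes(self):
        meta = two_group_metadata(5)
        wbc = (meta.table["wbc_class"] == "high").to_numpy(dtype=float)
        m = expr([2.0 + 3.0 * wbc])
        res = partial_correlation(m, meta, confounders=("wbc_class",))
        assert abs(res.table["effect"].iloc[0]) < 1e-8

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        meta = two_group_metadata(6)
        Y = rng.normal(size=(15, 12))
        res = partial_correlation(m := expr(Y), meta)
        x = meta.table["ighv_percent"].to_numpy()
        wbc = (meta.table["wbc_class"] == "high").to_numpy(dtype=float)
        gen = (meta.table["gender"] == "M").to_numpy(dtype=float)
        for i in range(0, 15, 3):
            df = pd.DataFrame({"y": Y[i], "x": x, "wbc": wbc, "gender": gen})
            ref = pg.partial_corr(df, x="x", y="y", covar=["wbc", "gender"])
            assert res.table["effect"].iloc[i] == pytest.approx(
                ref["r"].iloc[0], abs=1e-8
            )
            assert res.table["p_value"].iloc[i] == pytest.approx(
                ref["p_val"].iloc[0], abs=1e-8
            )


class TestPca:
    def test_duplicated_samples_get_identical_scores(self, rng):
        Y = rng.normal(size=(30, 4))
        Y = np.column_stack([Y, Y[:, 0]])
        res = pca(expr(Y))
        np.testing.assert_allclose(
            res.scores.iloc[0].to_numpy(), res.scores.iloc[-1].to_numpy(), atol=1e-9
        )

    def test_variance_conservation(self, rng):
        Y = rng.normal(size=(25, 8))
        res = pca(expr(Y))
        total = Y.var(axis=1, ddof=1).sum()
        assert res.variance_explained.sum() == pytest.approx(total, rel=1e-9)
        assert res.fraction_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self, rng):
        Y = rng.normal(size=(10, 6))
        res = pca(expr(Y))
        Yc = Y - Y.mean(axis=1, keepdims=True)
        cov = Yc @ Yc.T / (Y.shape[1] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            res.variance_explained[: len(eigvals)], eigvals[: Y.shape[1]][: len(res.variance_explained)],
            atol=1e-9,
        )
        # scores reproduce the centred data through the loadings
        recon = res.loadings.to_numpy() @ res.scores.to_numpy().T
        np.testing.assert_allclose(recon, Yc, atol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            pca(expr([[1.0], [2.0]]))


class TestRetentionAndOverlap:
    def test_identical_sets_full_retention(self):
        out = retention_and_overlap({1, 2, 3}, {1, 2, 3})
        assert out["retained_fraction"] == 1.0

    def test_disjoint_sets(self):
        out = retention_and_overlap({1, 2}, {3, 4})
        assert out["retained_fraction"] == 0.0
        assert out["intersection"] == 0

    def test_partial_overlap_counts(self):
        a = set(range(1, 11))
        b = set(range(1, 10)) | {11}
        out = retention_and_overlap(a, b, names=("A", "B"))
        assert out["retained_fraction"] == pytest.approx(0.9)
        assert out["intersection"] == 9
        assert out["venn_counts"][("A",)] == 1
        assert out["venn_counts"][("B",)] == 1
        assert out["venn_counts"][("A", "B")] == 9

    def test_empty_before_set_is_undefined(self):
        assert retention_and_overlap(set(), {1})["retained_fraction"] is None

    def test_three_set_venn_partitions_universe(self):
        sets = [{1, 2, 3, 4}, {3, 4, 5}, {4, 5, 6, 7}]
        out = retention_and_overlap(*sets)
        assert sum(out["venn_counts"].values()) == len(set().union(*sets))
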