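"""Covariate-adjusted group statistics: ANCOVA, LSD posthoc, FDR, partial r."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from motornet import (
    ancova_group_effect,
    fdr_bh,
    partial_correlation,
    posthoc_pairwise_lsd,
    run_group_analysis,
)


def _table(rng, shift=(0.0, 0.0, 0.0), n=(11, 15, 16), age_by_group=(51, 65, 60)):
    """Small synthetic feature table with group/age/gender/FMA columns."""
    rows = []
    for g, mu, ng, age_mu in zip(("Healthy", "Mild", "MtS"), shift, n, age_by_group):
        for i in range(ng):
            rows.append(
                {
                    "subject_id": f"{g}{i}",
                    "group": g,
                    "age": age_mu + rng.normal(0, 5),
                    "gender": "male" if rng.random() < 0.8 else "female",
                    "FMA": None if g == "Healthy" else rng.uniform(20, 99),
                    "feat": mu + rng.normal(0, 1),
                }
            )
    return pd.DataFrame(rows)


def _ancova_f_oracle(table, feature):
    """Partial F by explicit residual-sum-of-squares ratio (matrix algebra)."""
    y = table[feature].to_numpy(float)
    n = len(y)
    male = (table["gender"] == "male").to_numpy(float)
    age = table["age"].to_numpy(float)
    g_mild = (table["group"] == "Mild").to_numpy(float)
    g_mts = (table["group"] == "MtS").to_numpy(float)
    X_full = np.column_stack([np.ones(n), g_mild, g_mts, age, male])
    X_red = np.column_stack([np.ones(n), age, male])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    df_full = n - X_full.shape[1]
    f = ((rss(X_red) - rss(X_full)) / 2) / (rss(X_full) / df_full)
    p = float(scipy.stats.f.sf(f, 2, df_full))
    return f, p


class TestAncova:
    def test_f_statistic_matches_matrix_algebra_oracle(self):
        rng = np.random.default_rng(0)
        table = _table(rng, shift=(0.0, 0.5, 1.2))
        f, p = ancova_group_effect(table, "feat")
        f_o, p_o = _ancova_f_oracle(table, "feat")
        assert f == pytest.approx(f_o)
        assert p == pytest.approx(p_o)

    def test_null_p_values_are_uniform(self):
        # identical group distributions → p ~ U(0,1); KS must not reject
        rng = np.random.default_rng(1)
        pvals = [
            ancova_group_effect(_table(rng, age_by_group=(55, 55, 55)), "feat")[1]
            for _ in range(200)
        ]
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(2)
        table = _table(rng, shift=(0.0, 5.0, 10.0), n=(10, 10, 10))
        _, p = ancova_group_effect(table, "feat")
        assert p < 0.001

    def test_age_confounded_group_effect_is_reduced_by_adjustment(self):
        # feature driven purely by age, age confounded with group
        rng = np.random.default_rng(3)
        table = _table(rng, age_by_group=(45, 60, 75))
        table["feat"] = 0.3 * table["age"] + rng.normal(0, 1, len(table))
        f_adj, _ = ancova_group_effect(table, "feat")
        # unadjusted comparison: one-way ANOVA F
        groups = [g["feat"].to_numpy() for _, g in table.groupby("group")]
        f_unadj = scipy.stats.f_oneway(*groups).statistic
        assert f_adj < f_unadj

    def test_collinear_design_rejected_with_column_name(self):
        rng = np.random.default_rng(4)
        table = _table(rng)
        # age constant within each group → collinear with the group dummies
        table["age"] = table["group"].map({"Healthy": 45.0, "Mild": 60.0, "MtS": 75.0})
        with pytest.raises(ValueError, match="collinear"):
            ancova_group_effect(table, "feat")

    def test_degenerate_covariates_are_dropped_not_fatal(self):
        rng = np.random.default_rng(10)
        table = _table(rng, shift=(0.0, 1.0, 2.0))
        table["gender"] = "male"  # single level: term omitted from the model
        f, p = ancova_group_effect(table, "feat")
        assert np.isfinite(f) and 0 <= p <= 1


class TestPosthocLsd:
    def test_null_per_contrast_false_positive_rate_near_alpha(self):
        # LSD applies no multiplicity adjustment, so the calibrated quantity
        # is the per-contrast rate (~5%), not the family-wise rate
        rng = np.random.default_rng(5)
        n_sig = n_tot = 0
        for _ in range(20):
            ph = posthoc_pairwise_lsd(_table(rng, age_by_group=(55, 55, 55)), "feat")
            n_sig += int((ph["p"] < 0.05).sum())
            n_tot += len(ph)
        assert n_sig <= 0.15 * n_tot

    def test_ordered_means_give_significant_signed_contrasts(self):
        rng = np.random.default_rng(6)
        table = _table(rng, shift=(0.0, 4.0, 8.0), n=(10, 10, 10))
        ph = posthoc_pairwise_lsd(table, "feat").set_index(["group1", "group2"])
        assert (ph["p"] < 0.01).all()
        assert ph.loc[("Healthy", "Mild"), "estimate"] > 0
        assert ph.loc[("Healthy", "MtS"), "estimate"] > 0
        assert ph.loc[("Mild", "MtS"), "estimate"] > 0

    def test_two_groups_give_single_contrast(self):
        rng = np.random.default_rng(7)
        table = _table(rng, n=(10, 10, 0))
        ph = posthoc_pairwise_lsd(table, "feat")
        assert len(ph) == 1


class TestFdrBH:
    def test_hand_computed_example(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.123]) == pytest.approx([0.123])

    def test_all_ones_stay_one(self):
        assert np.all(fdr_bh([1.0, 1.0, 1.0]) == 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_adjusted_never_below_raw_and_rank_preserving(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=20)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = scipy.stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_identical_variables_give_unit_correlation(self, rng):
        x = rng.standard_normal(40)
        cov = rng.standard_normal((40, 1))
        r, _ = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_shared_confound_is_removed(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.standard_normal(100)
        x = 2.0 * c + rng.standard_normal(100)
        y = -1.5 * c + rng.standard_normal(100)
        r, _ = partial_correlation(x, y, c)
        assert abs(r) < 0.2

    def test_invariant_to_affine_transform_of_covariates(self, rng):
        c = rng.standard_normal((60, 2))
        x = c @ [1.0, -0.5] + rng.standard_normal(60)
        y = c @ [0.3, 0.8] + rng.standard_normal(60)
        r1, p1 = partial_correlation(x, y, c)
        r2, p2 = partial_correlation(x, y, 3.0 * c + 7.0)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        c = rng.standard_normal(45)
        x = c + rng.standard_normal(45)
        y = 0.5 * c + rng.standard_normal(45)
        r, p = partial_correlation(x, y, c)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "c": c}), x="x", y="y", covar="c"
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_constant_residual_flagged_as_nan(self, rng):
        c = rng.standard_normal(30)
        x = 2.0 * c + 1.0  # fully explained by covariate
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="constant residuals"):
            r, p = partial_correlation(x, y, c)
        assert np.isnan(r) and np.isnan(p)


class TestRunGroupAnalysis:
    def test_report_structure_and_determinism(self):
        rng = np.random.default_rng(8)
        table = _table(rng, shift=(0.0, 0.5, 1.0)).rename(columns={"feat": "C_AUC"})
        a = run_group_analysis(table, features=["C_AUC"])
        b = run_group_analysis(table, features=["C_AUC"])
        assert a.anova.equals(b.anova)
        assert a.posthoc.equals(b.posthoc)
        assert len(a.anova) == 1
        assert len(a.posthoc) == 3
        assert set(a.fma_correlations.columns) == {"feature", "r", "p"}
        assert "schema_version" in a.to_json()

    def test_identical_groups_rarely_fdr_significant_per_threshold(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            table = _table(rng, age_by_group=(55, 55, 55)).rename(
                columns={"feat": "C_AUC"}
            )
            long = []
            for thr in np.round(np.linspace(0.3, 0.7, 11), 2):
                for _, row in table.iterrows():
                    long.append(
                        {
                            "subject_id": row["subject_id"],
                            "threshold": thr,
                            "metric": "C",
                            "value": rng.normal(),
                        }
                    )
            rep = run_group_analysis(
                table, per_threshold=pd.DataFrame(long), features=["C_AUC"]
            )
            hits += int((rep.per_threshold["p_fdr"] < 0.05).any())
        assert hits <= 1
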