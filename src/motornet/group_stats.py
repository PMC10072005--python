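"""Covariate-adjusted group statistics on network AUC features.

Group differences are tested per feature with an ANCOVA — an ordinary linear
model ``feature ~ group + age + gender`` whose group term is judged by a
partial F-test — followed by pairwise posthoc contrasts in the Fisher LSD
convention (unadjusted pairwise t-tests on the covariate-adjusted means,
gated by a significant omnibus test).  Per-threshold group tests are
corrected with Benjamini–Hochberg FDR within each metric across the 41
thresholds.  Patient features are related to motor function by partial
correlation with the Fugl-Meyer Assessment score, controlling age and gender.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AUC_FEATURES",
    "ancova_group_effect",
    "posthoc_pairwise_lsd",
    "fdr_bh",
    "partial_correlation",
    "run_group_analysis",
    "GroupStatsReport",
]

AUC_FEATURES = (
    "C_AUC",
    "L_AUC",
    "GE_AUC",
    "LE_AUC",
    "T_AUC",
    "gamma_AUC",
    "lambda_AUC",
    "delta_AUC",
)

def _check_table(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    for col in ("group", "age", "gender", feature):
        if col not in table.columns:
            raise ValueError(f"feature table lacks column {col!r}")
    sub = table.dropna(subset=[feature, "group", "age", "gender"])
    counts = sub["group"].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need at least 2 groups with at least 2 subjects each")
    return sub


def _covariate_terms(table: pd.DataFrame) -> str:
    """Age and gender terms, omitting any covariate without variation."""
    terms = []
    if table["age"].nunique() > 1:
        terms.append("age")
    if table["gender"].nunique() > 1:
        terms.append("C(gender)")
    return " + ".join(terms)


def _fit_ancova(table: pd.DataFrame, feature: str):
    rhs = "C(group)"
    cov = _covariate_terms(table)
    if cov:
        rhs += " + " + cov
    model = smf.ols(f"Q('{feature}') ~ {rhs}", data=table)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify which column drops the rank deficit when removed
        for idx, name in enumerate(model.exog_names):
            reduced = np.delete(exog, idx, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"design matrix is rank deficient: column {name!r} is collinear")
        raise ValueError("design matrix is rank deficient")
    return model.fit()


def ancova_group_effect(table: pd.DataFrame, feature: str) -> tuple[float, float]:
    """Partial F-test of the group factor, adjusting for age and gender.

    Returns ``(F, p)`` for the group term of the linear model
    ``feature ~ group + age + gender`` (type-II sum of squares, i.e. the
    group term tested against the full-model residual).
    """
    sub = _check_table(table, feature)
    fit = _fit_ancova(sub, feature)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table_anova = anova_lm(fit, typ=2)
    row = table_anova.loc["C(group)"]
    return float(row["F"]), float(row["PR(>F)"])


def posthoc_pairwise_lsd(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Pairwise contrasts of covariate-adjusted group means (Fisher LSD).

    Each contrast uses the pooled residual error of the full ANCOVA model;
    LSD means no multiplicity adjustment beyond the gating omnibus test
    (the caller decides the gating).  Returns one row per group pair with
    the adjusted mean difference, t statistic and p-value.
    """
    sub = _check_table(table, feature)
    fit = _fit_ancova(sub, feature)
    groups = sorted(sub["group"].unique())
    names = list(fit.params.index)

    def level_vector(g: str) -> np.ndarray:
        v = np.zeros(len(names))
        col = f"C(group)[T.{g}]"
        if col in names:
            v[names.index(col)] = 1.0
        return v

    rows = []
    for g1, g2 in combinations(groups, 2):
        contrast = level_vector(g2) - level_vector(g1)
        res = fit.t_test(contrast)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "estimate": float(np.ravel(res.effect)[0]),
                "t": float(np.ravel(res.tvalue)[0]),
                "p": float(np.ravel(res.pvalue)[0]),
            }
        )
    return pd.DataFrame(rows)


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_correlation(
    x, y, covariates=None
) -> tuple[float, float]:
    """Pearson correlation of ``x`` and ``y`` after removing ``covariates``.

    Both variables are residualized on the covariates (with intercept) by
    least squares; the p-value uses a t distribution with ``n − 2 − k``
    degrees of freedom, ``k`` the number of covariates.  With no covariates
    this reduces exactly to the plain Pearson correlation.  Constant
    residuals make the correlation undefined: ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need more observations than covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        warnings.warn("constant residuals: partial correlation undefined")
        return float("nan"), float("nan")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = float(2 * scipy.stats.t.sf(abs(t), df))
    return r, p


def _gender_numeric(series: pd.Series) -> np.ndarray:
    if series.dtype.kind in "if":
        return series.to_numpy(dtype=float)
    return (series.astype(str).str.lower() == "male").to_numpy(dtype=float)


@dataclass
class GroupStatsReport:
    """Machine-readable result of the full group analysis."""

    anova: pd.DataFrame  # per feature: F, p
    posthoc: pd.DataFrame  # per feature × group pair
    fma_correlations: pd.DataFrame  # per feature: r, p (patients only)
    per_threshold: pd.DataFrame | None = None  # long: metric, threshold, F, p, p_fdr
    notes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": 1,
            "anova": self.anova.to_dict(orient="records"),
            "posthoc": self.posthoc.to_dict(orient="records"),
            "fma_correlations": self.fma_correlations.to_dict(orient="records"),
            "per_threshold": None
            if self.per_threshold is None
            else self.per_threshold.to_dict(orient="records"),
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_group_analysis(
    table: pd.DataFrame,
    per_threshold: pd.DataFrame | None = None,
    features=AUC_FEATURES,
    alpha: float = 0.05,
) -> GroupStatsReport:
    """ANCOVA + LSD posthoc per AUC feature, FMA partial correlations, and
    optional per-threshold tests with BH-FDR within each metric.

    ``per_threshold``, if given, is the long table with columns
    ``subject_id, threshold, metric, value`` joined against the metadata in
    ``table``; group tests reuse the same covariate-adjusted model, and the
    FDR family is the 41 thresholds within one metric.
    """
    features = [f for f in features if f in table.columns]
    anova_rows, posthoc_frames = [], []
    for feat in features:
        f_stat, p = ancova_group_effect(table, feat)
        anova_rows.append({"feature": feat, "F": f_stat, "p": p})
        ph = posthoc_pairwise_lsd(table, feat)
        ph.insert(0, "feature", feat)
        ph["gated_significant"] = (p < alpha) & (ph["p"] < alpha)
        posthoc_frames.append(ph)
    anova = pd.DataFrame(anova_rows)
    posthoc = pd.concat(posthoc_frames, ignore_index=True)

    patients = table[table["group"].isin(["Mild", "MtS"])].dropna(subset=["FMA"])
    corr_rows = []
    for feat in features:
        cov = np.column_stack(
            [patients["age"].to_numpy(float), _gender_numeric(patients["gender"])]
        )
        r, p = partial_correlation(
            patients[feat].to_numpy(float), patients["FMA"].to_numpy(float), cov
        )
        corr_rows.append({"feature": feat, "r": r, "p": p})
    fma_corr = pd.DataFrame(corr_rows)

    pt_result = None
    if per_threshold is not None:
        meta_cols = ["subject_id", "group", "age", "gender"]
        merged = per_threshold.merge(table[meta_cols], on="subject_id")
        rows = []
        for metric, m_frame in merged.groupby("metric", sort=False):
            for thr, t_frame in m_frame.groupby("threshold", sort=True):
                tbl = t_frame.rename(columns={"value": "metric_value"})
                try:
                    f_stat, p = ancova_group_effect(tbl, "metric_value")
                except ValueError:
                    f_stat, p = float("nan"), float("nan")
                rows.append(
                    {"metric": metric, "threshold": thr, "F": f_stat, "p": p}
                )
        pt_result = pd.DataFrame(rows)
        pt_result["p_fdr"] = np.nan
        for metric, idx in pt_result.groupby("metric", sort=False).groups.items():
            pvals = pt_result.loc[idx, "p"]
            finite = pvals.notna()
            if finite.any():
                pt_result.loc[pvals.index[finite], "p_fdr"] = fdr_bh(
                    pvals[finite].to_numpy()
                )

    return GroupStatsReport(
        anova=anova,
        posthoc=posthoc,
        fma_correlations=fma_corr,
        per_threshold=pt_result,
        notes={
            "model": "feature ~ group + age + gender (type-II partial F)",
            "posthoc": "Fisher LSD: unadjusted pairwise t, gated by omnibus p < alpha",
            "fdr_family": "41 thresholds within one metric",
            "alpha": alpha,
        },
    )
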