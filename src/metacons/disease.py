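"""Disease associations of conserved metabolites.

Rank-sum tests of conservation between disease-annotated and other
metabolites (with class/pathway exclusion variants), a multivariate model over
broad disease conditions, the aggregate cross-organ conservation score, a
logistic biomarker classifier with ROC/AUC, and the disease-count
association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "group_conservation_test",
    "multivariate_disease_model",
    "aggregate_mcs",
    "biomarker_roc",
    "disease_count_association",
    "ClassifierReport",
]


def _log_scores(mcs: pd.DataFrame) -> pd.DataFrame:
    df = mcs.copy()
    if "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    df = df[np.isfinite(df["mcs"]) & (df["mcs"] > 0)]
    df["log2_mcs"] = np.log2(df["mcs"])
    return df


def group_conservation_test(
    mcs: pd.DataFrame,
    flags: pd.Series,
    exclusions: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Are flagged metabolites more conserved?  Per-organ rank-sum + pooled model.

    Per organ a two-sided Wilcoxon rank-sum test of log scores between flagged
    and unflagged metabolites; pooled across organs a linear model
    log2(MCS) ~ organ + flag.  ``exclusions`` maps variant name -> boolean
    Series of metabolites to drop; each variant is re-run and reported.
    """
    df = _log_scores(mcs)
    variants: dict[str, pd.Index] = {"all": df["metabolite"].unique()}
    if exclusions:
        for name, excl in exclusions.items():
            keep = excl.index[~excl.astype(bool)]
            variants[name] = pd.Index(keep)

    rows = []
    for variant, keep in variants.items():
        sub = df[df["metabolite"].isin(keep)]
        merged = sub.merge(flags.rename("flag"), left_on="metabolite", right_index=True)
        for organ, grp in merged.groupby("organ"):
            a = grp.loc[grp["flag"].astype(bool), "log2_mcs"]
            b = grp.loc[~grp["flag"].astype(bool), "log2_mcs"]
            if len(a) < 2 or len(b) < 2:
                logger.warning("variant %s organ %s: group too small; skipped", variant, organ)
                continue
            method = "exact" if (len(a) < 20 and len(b) < 20 and grp["log2_mcs"].is_unique) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append(
                {
                    "variant": variant,
                    "organ": organ,
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "median_flagged": float(a.median()),
                    "median_unflagged": float(b.median()),
                    "n_flagged": len(a),
                    "n_unflagged": len(b),
                }
            )
        # pooled linear model with organ covariate
        if merged["flag"].astype(bool).nunique() == 2:
            X = pd.get_dummies(merged["organ"], prefix="organ", drop_first=True, dtype=float)
            X["flag"] = merged["flag"].astype(float).to_numpy()
            fit = sm.OLS(merged["log2_mcs"].to_numpy(float), sm.add_constant(np.asarray(X, float))).fit()
            rows.append(
                {
                    "variant": variant,
                    "organ": "pooled",
                    "statistic": float(fit.params[-1]),
                    "p_value": float(fit.pvalues[-1]),
                    "median_flagged": math.nan,
                    "median_unflagged": math.nan,
                    "n_flagged": int(merged["flag"].astype(bool).sum()),
                    "n_unflagged": int((~merged["flag"].astype(bool)).sum()),
                }
            )
    return pd.DataFrame(rows)


def multivariate_disease_model(
    mcs: pd.DataFrame,
    memberships: pd.DataFrame,
    alpha: float = 0.05,
    min_organs: int = 3,
) -> pd.DataFrame:
    """Independently associated broad disease conditions.

    Conditions first pass a univariate filter (two-sided rank-sum p < alpha in
    at least ``min_organs`` of the organs); the survivors enter one linear
    model of log2(MCS) on all their flags plus organ, and conditions with a
    coefficient p < alpha are reported as independent.  Duplicate-membership
    conditions are collapsed to the first (collinearity guard).
    """
    df = _log_scores(mcs)
    organs = sorted(df["organ"].unique())
    retained = []
    for cond in memberships.columns:
        flag = memberships[cond].astype(bool)
        n_sig = 0
        for organ in organs:
            sub = df[df["organ"] == organ].merge(
                flag.rename("flag"), left_on="metabolite", right_index=True
            )
            a = sub.loc[sub["flag"], "log2_mcs"]
            b = sub.loc[~sub["flag"], "log2_mcs"]
            if len(a) < 2 or len(b) < 2:
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            if res.pvalue < alpha and a.median() > b.median():
                n_sig += 1
        if n_sig >= min_organs:
            retained.append(cond)
    if not retained:
        return pd.DataFrame(columns=["condition", "coef", "p_value", "independent"])

    # collapse duplicated membership vectors
    kept: list[str] = []
    seen: dict[bytes, str] = {}
    for cond in retained:
        key = memberships[cond].astype(bool).to_numpy().tobytes()
        if key in seen:
            logger.warning("condition %s duplicates %s; collapsed", cond, seen[key])
            continue
        seen[key] = cond
        kept.append(cond)

    merged = df.merge(memberships[kept].astype(float), left_on="metabolite", right_index=True)
    X = pd.get_dummies(merged["organ"], prefix="organ", drop_first=True, dtype=float)
    for cond in kept:
        X[cond] = merged[cond].to_numpy()
    fit = sm.OLS(merged["log2_mcs"].to_numpy(float), sm.add_constant(np.asarray(X, float))).fit()
    offset = X.shape[1] - len(kept) + 1  # constant + organ dummies
    rows = []
    for i, cond in enumerate(kept):
        coef = float(fit.params[offset + i])
        p = float(fit.pvalues[offset + i])
        rows.append({"condition": cond, "coef": coef, "p_value": p, "independent": p < alpha})
    return pd.DataFrame(rows)


def aggregate_mcs(normalized_scores: pd.DataFrame) -> pd.Series:
    """Per-metabolite median of the normalized (log2, organ-centered) scores."""
    complete = normalized_scores.dropna()
    n_dropped = normalized_scores.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info("%d metabolites missing an organ dropped from aggregate score", n_dropped)
    return complete.median(axis=1).rename("aggregate_mcs")


@dataclass
class ClassifierReport:
    """Logistic biomarker classifier on a single conservation covariate."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_rank: float
    coef: float
    intercept: float
    n_positive: int
    n_negative: int


def biomarker_roc(score: pd.Series, labels: pd.Series) -> ClassifierReport:
    """ROC of predicting disease association from the aggregate score alone.

    The ROC sweeps thresholds on the score itself (an unpenalized logistic fit
    on the single covariate is reported alongside); AUC by the trapezoid rule
    over ROC points and, as a cross-check, by the rank (Mann-Whitney) formula
    - identical for any single-covariate score.
    """
    common = score.index.intersection(labels.index)
    s = score.loc[common].astype(float)
    y = labels.loc[common].astype(bool)
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)  # unpenalized
    lr.fit(s.to_numpy().reshape(-1, 1), y.to_numpy())
    sv = s.to_numpy()
    fpr, tpr, _ = roc_curve(y.to_numpy(), sv)
    a_trap = float(_trapezoid_auc(fpr, tpr))
    u = stats.mannwhitneyu(sv[y.to_numpy()], sv[~y.to_numpy()], alternative="two-sided").statistic
    a_rank = float(u) / (int(y.sum()) * int((~y).sum()))
    return ClassifierReport(
        fpr=fpr,
        tpr=tpr,
        auc=a_trap,
        auc_rank=a_rank,
        coef=float(lr.coef_[0, 0]),
        intercept=float(lr.intercept_[0]),
        n_positive=int(y.sum()),
        n_negative=int((~y).sum()),
    )


def disease_count_association(
    score: pd.Series,
    n_diseases: pd.Series,
    abundance: pd.Series | None = None,
    essential: pd.Series | None = None,
) -> dict:
    """Spearman correlation of conservation with the number of associated
    diseases, plus a multivariate model controlling abundance and essentiality.

    The count covers all specific disease associations.  The multivariate
    linear model is log score ~ count + log10 abundance + essential flag; the
    count coefficient and p are reported.
    """
    common = score.index.intersection(n_diseases.index)
    s = score.loc[common].astype(float)
    c = n_diseases.loc[common].astype(float)
    if (c == 0).all():
        return {"rho": math.nan, "p": math.nan, "flag": "all counts zero"}
    rho, p = stats.spearmanr(s, c)
    out = {"rho": float(rho), "p": float(p), "n": len(common)}
    if abundance is not None and essential is not None:
        X = pd.DataFrame({"count": c})
        X["log_abundance"] = np.log10(abundance.loc[common].astype(float))
        X["essential"] = essential.loc[common].astype(float)
        fit = sm.OLS(s.to_numpy(), sm.add_constant(np.asarray(X, float))).fit()
        out["count_coef"] = float(fit.params[1])
        out["count_p"] = float(fit.pvalues[1])
    return out
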