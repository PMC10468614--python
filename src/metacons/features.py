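"""Variance in conservation scores explained by metabolite features.

Univariate scan: for each feature, the gain in R^2 over an organ-only linear
model of log2 conservation scores pooled across organs, with a nested-model F
test and Benjamini-Hochberg adjustment.  Multivariate: AIC-guided
bidirectional stepwise selection starting from the individually significant
features, with per-feature independent contributions measured as the
adjusted-R^2 drop on single removal.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "essential_metabolite_flags",
    "univariate_scan",
    "multivariate_selection",
    "StepwiseReport",
]

# continuous features with heavy right skew are log-transformed before modeling
DEFAULT_LOG_FEATURES = ("abundance", "molecular_weight", "ld50", "network_degree")


def essential_metabolite_flags(
    reaction_gene_map: dict[str, dict],
    essential_genes: set[str],
) -> dict[str, bool]:
    """Essential-metabolite flags from gene-knockout data.

    ``reaction_gene_map`` maps reaction id -> {"genes": [...], "metabolites":
    [...]}.  A reaction is essential iff strictly more than half of its genes
    are essential; a metabolite is flagged iff it participates in at least one
    essential reaction.  Reactions with an empty gene list are excluded.
    """
    flags: dict[str, bool] = {}
    for rid, entry in reaction_gene_map.items():
        genes = list(entry.get("genes", []))
        mets = list(entry.get("metabolites", []))
        if not genes:
            logger.warning("reaction %s has no associated genes; excluded", rid)
            continue
        n_ess = sum(g in essential_genes for g in genes)
        essential = n_ess > len(genes) / 2
        for m in mets:
            flags[m] = flags.get(m, False) or essential
    return flags


def _prepare_response(mcs: pd.DataFrame) -> pd.DataFrame:
    df = mcs.copy()
    if "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    df = df[np.isfinite(df["mcs"]) & (df["mcs"] > 0)]
    df["log2_mcs"] = np.log2(df["mcs"])
    return df[["metabolite", "organ", "log2_mcs"]]


def _organ_dummies(organ: pd.Series) -> pd.DataFrame:
    d = pd.get_dummies(organ, prefix="organ", drop_first=True, dtype=float)
    return d


def _feature_column(values: pd.Series, name: str, log_features) -> pd.Series | None:
    v = values.astype(float) if values.dtype != object else values
    if name in log_features:
        v = pd.Series(np.log10(v.astype(float)), index=v.index)
    return v


@dataclass
class UnivariateResult:
    feature: str
    delta_r2: float
    p_value: float
    p_fdr: float = math.nan
    n: int = 0


def univariate_scan(
    mcs: pd.DataFrame,
    features: pd.DataFrame,
    log_features: tuple[str, ...] = DEFAULT_LOG_FEATURES,
    class_column: str = "chemical_class",
    fdr_alpha: float = 0.01,
) -> pd.DataFrame:
    """Delta-R^2 of each feature over an organ-only model, with BH-adjusted p.

    The response is log2(MCS) pooled over organs with organ membership as a
    categorical covariate.  Categorical class columns are expanded and each
    level tested as its own binary feature; binary pathway columns are tested
    as-is.  Complete cases per feature; constant features are skipped.
    """
    resp = _prepare_response(mcs)
    feats = features.copy()
    if class_column in feats.columns:
        dummies = pd.get_dummies(feats[class_column], prefix="class", dtype=float)
        feats = pd.concat([feats.drop(columns=[class_column]), dummies], axis=1)

    results: list[UnivariateResult] = []
    for name in feats.columns:
        col = _feature_column(feats[name], name, log_features)
        merged = resp.merge(
            col.rename("x"), left_on="metabolite", right_index=True, how="inner"
        ).dropna(subset=["x", "log2_mcs"])
        if merged.empty or merged["x"].nunique() < 2:
            logger.warning("feature %s constant or empty; skipped", name)
            continue
        y = merged["log2_mcs"].to_numpy(float)
        organ_X = _organ_dummies(merged["organ"])
        X0 = sm.add_constant(organ_X, has_constant="add")
        X1 = sm.add_constant(
            pd.concat([organ_X, merged["x"].reset_index(drop=True).astype(float)], axis=1),
            has_constant="add",
        )
        m0 = sm.OLS(y, np.asarray(X0, float)).fit()
        m1 = sm.OLS(y, np.asarray(X1, float)).fit()
        delta_r2 = max(m1.rsquared - m0.rsquared, 0.0)
        df_num = m0.df_resid - m1.df_resid
        if df_num <= 0 or m1.df_resid <= 0:
            continue
        f = (m0.ssr - m1.ssr) / df_num / (m1.ssr / m1.df_resid)
        p = float(stats.f.sf(f, df_num, m1.df_resid)) if np.isfinite(f) else 1.0
        results.append(UnivariateResult(feature=name, delta_r2=delta_r2, p_value=p, n=len(merged)))

    table = pd.DataFrame([r.__dict__ for r in results])
    if table.empty:
        return table
    table["p_fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = table["p_fdr"] < fdr_alpha
    return table.sort_values("delta_r2", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Multivariate stepwise selection
# ---------------------------------------------------------------------------


@dataclass
class StepwiseReport:
    """Selected model with per-feature independent contributions (% scale)."""

    selected: list[str]
    aic: float
    adj_r2: float
    independent_contribution: dict[str, float] = field(default_factory=dict)
    clipped: list[str] = field(default_factory=list)
    features_total_variance_explained: float = math.nan
    full_model_r2: float = math.nan


def _design(
    df: pd.DataFrame, groups: dict[str, list[str]], members: list[str]
) -> np.ndarray:
    cols = []
    for g in members:
        cols.extend(groups[g])
    X = df[cols].to_numpy(float) if cols else np.empty((len(df), 0))
    return np.column_stack([np.ones(len(df)), X])


def _fit(df: pd.DataFrame, y: np.ndarray, groups, members) -> sm.regression.linear_model.RegressionResults:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.OLS(y, _design(df, groups, members)).fit()


def multivariate_selection(
    mcs: pd.DataFrame,
    features: pd.DataFrame,
    candidates: list[str],
    log_features: tuple[str, ...] = DEFAULT_LOG_FEATURES,
    class_column: str = "chemical_class",
) -> StepwiseReport:
    """Bidirectional AIC-stepwise model of log2(MCS) on candidate features.

    The initial model contains every candidate plus organ membership (which is
    never eligible for removal); chemical class enters as one multilevel
    factor.  After selection, each retained feature's independent contribution
    is the adjusted-R^2 drop when it alone is removed (clipped at zero with a
    flag), and the features-total variance explained subtracts organ
    membership's independent effect from the selected model's adjusted R^2.
    """
    resp = _prepare_response(mcs)
    feats = features.copy()
    groups: dict[str, list[str]] = {}
    work = pd.DataFrame(index=feats.index)
    for name in candidates:
        if name == class_column and name in feats.columns:
            dummies = pd.get_dummies(feats[name], prefix="class", drop_first=True, dtype=float)
            for c in dummies.columns:
                work[c] = dummies[c]
            groups[name] = list(dummies.columns)
        elif name in feats.columns:
            col = _feature_column(feats[name], name, log_features)
            work[name] = col.astype(float)
            groups[name] = [name]
        else:
            raise KeyError(f"candidate feature {name!r} not in feature table")

    merged = resp.merge(work, left_on="metabolite", right_index=True, how="inner").dropna()
    y = merged["log2_mcs"].to_numpy(float)
    organ_X = _organ_dummies(merged["organ"]).reset_index(drop=True)
    merged = merged.reset_index(drop=True)
    for c in organ_X.columns:
        merged[c] = organ_X[c]
    groups = dict(groups)
    groups["organ"] = list(organ_X.columns)

    # drop exact duplicate columns (singular-fit guard)
    seen: dict[bytes, str] = {}
    for g, cols in list(groups.items()):
        if g == "organ":
            continue
        key = merged[cols].round(12).to_numpy().tobytes()
        if key in seen:
            logger.warning("feature %s duplicates %s; dropped from search", g, seen[key])
            del groups[g]
        else:
            seen[key] = g

    removable = [g for g in groups if g != "organ"]
    current = set(groups)  # start from the full candidate model
    best = _fit(merged, y, groups, sorted(current))
    best_aic = best.aic
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, set[str]]] = []
        for g in sorted(current - {"organ"}):
            m = _fit(merged, y, groups, sorted(current - {g}))
            moves.append((m.aic, current - {g}))
        for g in sorted(set(removable) - current):
            m = _fit(merged, y, groups, sorted(current | {g}))
            moves.append((m.aic, current | {g}))
        if moves:
            aic, members = min(moves, key=lambda t: t[0])
            if aic < best_aic - 1e-9:
                best_aic, current = aic, members
                improved = True

    final = _fit(merged, y, groups, sorted(current))
    contributions: dict[str, float] = {}
    clipped: list[str] = []
    for g in sorted(current):
        reduced = _fit(merged, y, groups, sorted(current - {g}))
        drop = final.rsquared_adj - reduced.rsquared_adj
        if drop < 0:
            clipped.append(g)
            drop = 0.0
        contributions[g] = 100.0 * drop
    organ_effect = contributions.get("organ", 0.0)
    return StepwiseReport(
        selected=sorted(current - {"organ"}),
        aic=float(best_aic),
        adj_r2=float(final.rsquared_adj),
        independent_contribution=contributions,
        clipped=clipped,
        features_total_variance_explained=100.0 * final.rsquared_adj - organ_effect,
        full_model_r2=float(final.rsquared),
    )
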