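"""Cross-organ comparison of conservation scores.

Scores are log2-transformed and zero-centered per organ (organs differ in
their metabolome-wide divergence), deviations single out metabolites unusually
conserved in one organ, and the association between between-organ level
differences and score differences is tested against a permutation null that
reshuffles each metabolite's organ labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import TraitMatrix

__all__ = [
    "normalize_scores",
    "organ_deviation",
    "crossorgan_association",
    "CrossOrganResult",
]


def normalize_scores(mcs: pd.DataFrame, min_organs: int | None = None) -> pd.DataFrame:
    """Metabolite x organ table of log2 scores centered to zero per organ.

    Input is a long table with columns metabolite, organ, mcs.  Only
    metabolites with a finite, uncensored score in every organ (or in
    ``min_organs`` organs if given) are retained; the rest are dropped and
    counted in the ``attrs['n_dropped']`` annotation.
    """
    df = mcs.copy()
    if "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    df = df[np.isfinite(df["mcs"]) & (df["mcs"] > 0)]
    wide = df.pivot_table(index="metabolite", columns="organ", values="mcs")
    n_organs = wide.shape[1]
    if n_organs < 2:
        raise ValueError("need scores from >= 2 organs")
    need = n_organs if min_organs is None else min_organs
    complete = wide.dropna(thresh=need)
    complete = complete.dropna()  # restrict to the complete block
    n_dropped = wide.shape[0] - complete.shape[0]
    normalized = np.log2(complete)
    normalized = normalized - normalized.mean(axis=0)
    normalized.attrs["n_dropped"] = int(n_dropped)
    return normalized


def organ_deviation(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-(metabolite, organ) deviation from the mean of the other organs.

    The top 10 % most strongly deviating metabolites per organ (ceiling rule,
    ties broken by metabolite id) are flagged.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 organs")
    k = scores.shape[1]
    totals = scores.sum(axis=1)
    rows = []
    n_top = math.ceil(scores.shape[0] / 10)
    for organ in scores.columns:
        others_mean = (totals - scores[organ]) / (k - 1)
        dev = scores[organ] - others_mean
        order = dev.to_frame("deviation").reset_index()
        order = order.sort_values(
            ["deviation", "metabolite"], ascending=[False, True]
        ).reset_index(drop=True)
        order["organ"] = organ
        order["top_decile"] = order.index < n_top
        rows.append(order)
    out = pd.concat(rows, ignore_index=True)
    return out[["metabolite", "organ", "deviation", "top_decile"]]


@dataclass(frozen=True)
class CrossOrganResult:
    rho: float
    p_perm: float
    n_perm: int
    n_points: int
    seed: int
    points: pd.DataFrame  # metabolite, pair, level_log2fc, score_diff


def _pairwise_diffs(wide: pd.DataFrame, pairs: list[tuple[str, str]]) -> np.ndarray:
    return np.column_stack([wide[a].to_numpy() - wide[b].to_numpy() for a, b in pairs])


def crossorgan_association(
    traits: TraitMatrix,
    scores: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    signed: bool = True,
) -> CrossOrganResult:
    """Spearman association of between-organ level and score differences.

    For each metabolite and unordered organ pair (fixed alphabetical organ
    order, so signs are reproducible), the level difference is the species-mean
    log2 fold change and the score difference is the difference of normalized
    scores.  The one-sided permutation p reshuffles each metabolite's organ
    score labels independently; +1 smoothing prevents p = 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    organs = sorted(scores.columns)
    pairs = [(organs[i], organs[j]) for i in range(len(organs)) for j in range(i + 1, len(organs))]

    # species-mean log2 fold change of levels per metabolite and organ pair
    agg_by_organ = {}
    for organ in organs:
        agg_by_organ[organ] = traits.aggregated(organ)  # species x metabolite, log10
    mets = list(scores.index)
    lvl_fc = np.full((len(mets), len(pairs)), np.nan)
    log2_of_10 = math.log2(10.0)
    for jp, (a, b) in enumerate(pairs):
        A, B = agg_by_organ[a], agg_by_organ[b]
        common_sp = A.index.intersection(B.index)
        for im, met in enumerate(mets):
            if met not in A.columns or met not in B.columns:
                continue
            diff = (A.loc[common_sp, met] - B.loc[common_sp, met]).dropna()
            if len(diff):
                lvl_fc[im, jp] = diff.mean() * log2_of_10
    score_mat = scores.loc[mets, organs].to_numpy()
    pair_idx = [(organs.index(a), organs.index(b)) for a, b in pairs]
    score_diff = np.column_stack([score_mat[:, i] - score_mat[:, j] for i, j in pair_idx])

    mask = np.isfinite(lvl_fc) & np.isfinite(score_diff)
    x = lvl_fc[mask]
    y = score_diff[mask]
    if not signed:
        x, y = np.abs(x), np.abs(y)
    if len(x) < 2:
        raise ValueError("too few metabolite-pair points for a correlation")
    rho = float(stats.spearmanr(x, y).statistic)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC805]))
    xr = stats.rankdata(x)
    count = 0
    for _ in range(n_perm):
        perm_scores = score_mat.copy()
        # independent within-metabolite shuffle of organ labels
        keys = rng.random(perm_scores.shape)
        order = np.argsort(keys, axis=1)
        perm_scores = np.take_along_axis(perm_scores, order, axis=1)
        sd = np.column_stack([perm_scores[:, i] - perm_scores[:, j] for i, j in pair_idx])
        yp = sd[mask]
        if not signed:
            yp = np.abs(yp)
        with np.errstate(invalid="ignore"):
            rp = np.corrcoef(xr, stats.rankdata(yp))[0, 1]
        if np.isfinite(rp) and rp >= rho:
            count += 1
    p = (1 + count) / (n_perm + 1)

    points = pd.DataFrame(
        {
            "metabolite": np.repeat(mets, len(pairs))[mask.ravel()],
            "pair": np.tile([f"{a}-{b}" for a, b in pairs], len(mets))[mask.ravel()],
            "level_log2fc": x if signed else lvl_fc[mask],
            "score_diff": y if signed else score_diff[mask],
        }
    )
    return CrossOrganResult(
        rho=rho, p_perm=float(p), n_perm=n_perm, n_points=int(mask.sum()), seed=seed, points=points
    )
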