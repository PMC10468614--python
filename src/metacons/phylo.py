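"""Brownian-motion rate estimation on phylogenies and metabolite conservation scores.

The conservation score of a metabolite is the inverse of the maximum-likelihood
Brownian-motion rate ``sigma^2`` fitted to its mean log10 relative levels across
the tips of a time-calibrated phylogeny: slowly diverging metabolites get high
scores.  Fits can optionally account for per-tip sampling variance (replicate
noise), in which case the trait covariance is ``sigma^2 * C + diag(se^2)`` and
the rate is found by bounded 1-D likelihood maximization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "TraitMatrix",
    "BMFit",
    "VariancePartition",
    "parse_phylogeny",
    "aggregate_replicates",
    "fit_bm",
    "mcs_table",
    "clade_split_mcs",
    "bootstrap_variance_partition",
]


class PhylogenyError(ValueError):
    """Malformed tree or tree/trait mismatch."""


class Phylogeny:
    """Rooted tree with branch lengths in time units, wrapping a dendropy tree.

    Branch lengths are mandatory (the BM fit needs elapsed time) and tip labels
    must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._vcv_cache: dict[tuple[str, ...], np.ndarray] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy reports the offending position
            raise PhylogenyError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None:
                raise PhylogenyError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dup}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                raise PhylogenyError(
                    "missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'an internal node'}; "
                    "BM fitting requires branch lengths in time units"
                )
            if node.edge.length < 0:
                raise PhylogenyError("negative branch length")

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tip_labels)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths (root edge, if any, ignored)."""
        out = {}
        for leaf, d in self._node_depths().items():
            if leaf.is_leaf():
                out[leaf.taxon.label] = d
        return out

    def _node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    # -- subtree extraction -------------------------------------------

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree induced by ``labels``, rooted at their MRCA.

        Branch lengths along retained paths are preserved (unifurcations are
        collapsed by summing edge lengths).  Missing species are never imputed;
        callers prune per metabolite to the measured species.
        """
        keep = set(labels)
        have = set(self.tip_labels)
        missing = keep - have
        if missing:
            raise PhylogenyError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise PhylogenyError("need at least 2 tips to induce a subtree")
        sub = self._tree.extract_tree_with_taxa_labels(keep)
        sub.purge_taxon_namespace()
        # re-root at the MRCA of the retained tips: drop any stem chain
        while (
            sub.seed_node.num_child_nodes() == 1
        ):  # pragma: no cover - dendropy usually collapses this
            child = sub.seed_node.child_nodes()[0]
            sub.seed_node = child
        sub.seed_node.edge.length = None
        sub.seed_node.parent_node = None
        return Phylogeny(sub)

    def scale_branch_lengths(self, k: float) -> "Phylogeny":
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= k
        return Phylogeny(clone)

    # -- phylogenetic covariance --------------------------------------

    def vcv(self, order: Sequence[str]) -> np.ndarray:
        """BM covariance structure: C[i, j] = depth of the MRCA of tips i, j."""
        key = tuple(order)
        if key in self._vcv_cache:
            return self._vcv_cache[key]
        idx = {label: i for i, label in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))
        depths = self._node_depths()
        # postorder: at each internal node, pairs of tips drawn from two
        # different child subtrees have that node as their MRCA
        tipsets: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                mine = [idx[lab]] if lab in idx else []
                if mine:
                    C[mine[0], mine[0]] = depths[node]
            else:
                mine = []
                kids = [tipsets[c] for c in node.child_nodes()]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = depths[node]
                    mine.extend(kids[a])
            tipsets[node] = mine
        found = len(tipsets[self._tree.seed_node])
        if found != n:
            raise PhylogenyError("vcv order contains tips not in the tree")
        self._vcv_cache[key] = C
        return C


def parse_phylogeny(text: str) -> Phylogeny:
    """Parse a Newick string with mandatory branch lengths."""
    return Phylogeny.from_newick(text)


# ---------------------------------------------------------------------------
# Trait matrices
# ---------------------------------------------------------------------------

REQUIRED_TRAIT_COLUMNS = ("organ", "species", "metabolite", "replicate", "level")


class TraitMatrix:
    """Species x metabolite x replicate relative levels for one or more organs.

    Stored long-format (columns ``organ, species, metabolite, replicate,
    level``) with levels on the linear scale; the aggregated view is the mean
    of the log10-transformed replicate levels per (organ, species, metabolite).
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_TRAIT_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        data = data.loc[:, list(REQUIRED_TRAIT_COLUMNS)].copy()
        bad = data[~(data["level"] > 0)]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                "nonpositive level for organ="
                f"{row['organ']!r} species={row['species']!r} "
                f"metabolite={row['metabolite']!r} replicate={row['replicate']!r}: "
                f"{row['level']!r} (levels must be > 0 before log transform)"
            )
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "TraitMatrix":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @property
    def organs(self) -> list[str]:
        return sorted(self.data["organ"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite"].unique())

    def for_organ(self, organ: str) -> "TraitMatrix":
        sub = self.data[self.data["organ"] == organ]
        if sub.empty:
            raise ValueError(f"no measurements for organ {organ!r}")
        return TraitMatrix(sub)

    def aggregated(self, organ: str | None = None) -> pd.DataFrame:
        """Wide table (species x metabolite) of mean log10 levels."""
        df = self.data
        if organ is not None:
            df = df[df["organ"] == organ]
            if df.empty:
                raise ValueError(f"no measurements for organ {organ!r}")
        elif df["organ"].nunique() > 1:
            raise ValueError("multiple organs present; pass organ=...")
        logged = df.assign(loglevel=np.log10(df["level"].to_numpy(float)))
        return logged.pivot_table(
            index="species", columns="metabolite", values="loglevel", aggfunc="mean"
        )

    def replicate_se(self, organ: str | None = None) -> pd.DataFrame:
        """Standard error of the per-(species, metabolite) mean log10 level."""
        df = self.data
        if organ is not None:
            df = df[df["organ"] == organ]
        logged = df.assign(loglevel=np.log10(df["level"].to_numpy(float)))
        g = logged.groupby(["species", "metabolite"])["loglevel"]
        se = g.std(ddof=1) / np.sqrt(g.count())
        return se.unstack("metabolite")


def aggregate_replicates(raw: TraitMatrix) -> pd.DataFrame:
    """Mean log10 relative level per (organ, species, metabolite), long format."""
    df = raw.data.assign(loglevel=np.log10(raw.data["level"].to_numpy(float)))
    out = (
        df.groupby(["organ", "species", "metabolite"], as_index=False)["loglevel"]
        .mean()
        .rename(columns={"loglevel": "mean_log10_level"})
    )
    return out


# ---------------------------------------------------------------------------
# Brownian-motion fitting
# ---------------------------------------------------------------------------

# bounded search bracket for log10(sigma^2) in SE-aware fits
_LOG10_SIGMA2_LO = -12.0
_LOG10_SIGMA2_HI = 6.0
_LOG10_SIGMA2_XTOL = 1e-10


@dataclass(frozen=True)
class BMFit:
    """Maximum-likelihood Brownian-motion fit for one trait on one tree.

    ``sigma2`` is the trait variance accrued per unit branch-length time; the
    estimator uses denominator ``n`` (plain ML, not REML).  When ``se_mode``
    is true, per-tip sampling variances were added to the trait covariance and
    ``sigma2`` came from bounded numeric maximization.
    """

    sigma2: float
    root_state: float
    loglik: float
    n_tips: int
    se_mode: bool = False

    @property
    def mcs(self) -> float:
        """Conservation score: inverse evolutionary rate (inf when sigma2 = 0)."""
        return 1.0 / self.sigma2 if self.sigma2 > 0 else math.inf

    @property
    def censored(self) -> bool:
        return self.sigma2 <= 0


def _bm_profile(C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form profiled ML for V = sigma2 * C: returns (sigma2, mu, loglik)."""
    n = len(y)
    try:
        cf = linalg.cho_factor(C)
    except linalg.LinAlgError as exc:
        raise PhylogenyError(
            "singular phylogenetic covariance (e.g. zero-length cherry creating "
            "identical tips); cannot fit BM"
        ) from exc
    one = np.ones(n)
    Ci1 = linalg.cho_solve(cf, one)
    Ciy = linalg.cho_solve(cf, y)
    mu = float(one @ Ciy / (one @ Ci1))
    r = y - mu
    q = float(r @ linalg.cho_solve(cf, r))
    sigma2 = q / n
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if sigma2 <= 0:
        # all residuals zero: degenerate, likelihood unbounded
        return 0.0, mu, math.inf
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetC + n)
    return sigma2, mu, loglik


def _mvn_profile_loglik(V: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Profile mu out of a MVN(mu*1, V) likelihood; returns (loglik, mu)."""
    n = len(y)
    cf = linalg.cho_factor(V)
    one = np.ones(n)
    Vi1 = linalg.cho_solve(cf, one)
    Viy = linalg.cho_solve(cf, y)
    mu = float(one @ Viy / (one @ Vi1))
    r = y - mu
    q = float(r @ linalg.cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * math.log(2 * math.pi) + logdet + q), mu


def fit_bm(
    tree: Phylogeny,
    tip_values: Mapping[str, float],
    tip_se: Mapping[str, float] | None = None,
) -> BMFit:
    """ML Brownian-motion fit of ``y ~ MVN(mu * 1, sigma2 * C + D)``.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips i and j on the
    tree pruned to the species with data; ``D = diag(se^2)`` when per-tip
    sampling SDs are supplied, else zero.  With ``D = 0`` the rate has the
    closed form ``r' C^-1 r / n`` at the GLS mean; otherwise it is found by
    bounded Brent search over log10(sigma2).
    """
    species = sorted(k for k, v in tip_values.items() if np.isfinite(v))
    if len(species) < 2:
        raise PhylogenyError("BM fit needs >= 2 tips with trait values")
    sub = tree.prune_to(species) if set(species) != set(tree.tip_labels) else tree
    order = sorted(sub.tip_labels)
    C = sub.vcv(order)
    y = np.array([float(tip_values[s]) for s in order])

    if np.allclose(y, y[0], rtol=0.0, atol=0.0):
        # zero trait variance: rate 0, conservation score censored (infinite)
        return BMFit(
            sigma2=0.0,
            root_state=float(y[0]),
            loglik=math.inf,
            n_tips=len(y),
            se_mode=tip_se is not None,
        )

    if tip_se is None:
        sigma2, mu, loglik = _bm_profile(C, y)
        return BMFit(sigma2=sigma2, root_state=mu, loglik=loglik, n_tips=len(y))

    se = np.array([float(tip_se.get(s, 0.0)) for s in order])
    se = np.where(np.isfinite(se), se, 0.0)
    D = np.diag(se**2)

    def neg_loglik(log10_s2: float) -> float:
        V = (10.0**log10_s2) * C + D
        try:
            ll, _ = _mvn_profile_loglik(V, y)
        except linalg.LinAlgError:
            return math.inf
        return -ll

    res = optimize.minimize_scalar(
        neg_loglik,
        bounds=(_LOG10_SIGMA2_LO, _LOG10_SIGMA2_HI),
        method="bounded",
        options={"xatol": _LOG10_SIGMA2_XTOL},
    )
    sigma2 = float(10.0 ** res.x)

    # polish on the score equation dL/dsigma2 = 0: near the optimum the
    # likelihood value is flat to machine precision, but its gradient is not
    def score(s2: float) -> float:
        V = s2 * C + D
        cf = linalg.cho_factor(V)
        one = np.ones(len(y))
        mu = float(one @ linalg.cho_solve(cf, y) / (one @ linalg.cho_solve(cf, one)))
        Vir = linalg.cho_solve(cf, y - mu)
        return float(Vir @ (C @ Vir) - np.trace(linalg.cho_solve(cf, C)))

    try:
        lo, hi = sigma2 / 1.5, sigma2 * 1.5
        if score(lo) > 0 > score(hi):
            sigma2 = float(optimize.brentq(score, lo, hi, xtol=1e-300, rtol=1e-15))
    except (linalg.LinAlgError, ValueError):
        pass
    V = sigma2 * C + D
    loglik, mu = _mvn_profile_loglik(V, y)
    return BMFit(sigma2=sigma2, root_state=mu, loglik=loglik, n_tips=len(y), se_mode=True)


# ---------------------------------------------------------------------------
# Conservation-score tables
# ---------------------------------------------------------------------------


def mcs_table(
    tree: Phylogeny,
    traits: TraitMatrix,
    use_se: bool = False,
) -> pd.DataFrame:
    """Conservation scores for every metabolite in every organ.

    One row per (metabolite, organ) with >= 2 measured species; the tree is
    pruned per metabolite to the measured species before fitting.  Columns:
    metabolite, organ, sigma2, mcs, n_tips, censored.
    """
    rows = []
    tips = set(tree.tip_labels)
    for organ in traits.organs:
        agg = traits.aggregated(organ)
        se_tab = traits.replicate_se(organ) if use_se else None
        for metabolite in agg.columns:
            col = agg[metabolite].dropna()
            col = col[col.index.isin(tips)]
            if len(col) < 2:
                logger.info(
                    "skipping %s/%s: only %d measured species", metabolite, organ, len(col)
                )
                continue
            tip_se = None
            if use_se:
                s = se_tab[metabolite].reindex(col.index).fillna(0.0)
                tip_se = s.to_dict()
            fit = fit_bm(tree, col.to_dict(), tip_se)
            rows.append(
                {
                    "metabolite": metabolite,
                    "organ": organ,
                    "sigma2": fit.sigma2,
                    "mcs": fit.mcs,
                    "n_tips": fit.n_tips,
                    "censored": fit.censored,
                }
            )
    return pd.DataFrame(rows, columns=["metabolite", "organ", "sigma2", "mcs", "n_tips", "censored"])


def clade_split_mcs(
    tree: Phylogeny,
    traits: TraitMatrix,
    clade_a: Iterable[str],
    clade_b: Iterable[str],
    organ: str | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Conservation scores fitted separately on two disjoint clades.

    Each clade's fits run on the subtree rooted at the clade MRCA with the
    original branch lengths.  Returns (per-metabolite table, Pearson r of
    log10 scores, p) over metabolites scored (uncensored) in both clades.
    """
    a, b = set(clade_a), set(clade_b)
    if a & b:
        raise ValueError(f"clades overlap: {sorted(a & b)}")
    if organ is None:
        organs = traits.organs
        if len(organs) != 1:
            raise ValueError("multiple organs present; pass organ=...")
        organ = organs[0]
    sub_traits = traits.for_organ(organ)
    sub_a = tree.prune_to(a & set(tree.tip_labels))
    sub_b = tree.prune_to(b & set(tree.tip_labels))
    agg = sub_traits.aggregated(organ)
    rows = []
    for metabolite in agg.columns:
        col = agg[metabolite].dropna()
        rec: dict[str, object] = {"metabolite": metabolite}
        for name, sub in (("a", sub_a), ("b", sub_b)):
            vals = col[col.index.isin(sub.tip_labels)]
            if len(vals) < 2:
                rec[f"mcs_{name}"] = np.nan
                continue
            fit = fit_bm(sub, vals.to_dict())
            rec[f"mcs_{name}"] = fit.mcs
        rows.append(rec)
    table = pd.DataFrame(rows)
    both = table.replace([np.inf], np.nan).dropna()
    if both.empty:
        raise ValueError("no metabolite has >= 2 measured species in both clades")
    n_censored = len(table.dropna()) - len(both)
    if n_censored:
        logger.info("%d censored (sigma2 = 0) metabolites excluded from correlation", n_censored)
    la, lb = np.log10(both["mcs_a"]), np.log10(both["mcs_b"])
    if la.nunique() < 2 or lb.nunique() < 2:
        raise ValueError("degenerate clade-split scores (constant in one clade)")
    r, p = stats.pearsonr(la, lb)
    return table, float(r), float(p)


# ---------------------------------------------------------------------------
# Replicate-noise bootstrap and variance partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariancePartition:
    """One-way ANOVA split of bootstrap score variance for one organ.

    ``between_metabolite_fraction`` is the share of total variance in
    log10 conservation scores attributable to metabolite identity;
    ``error_fraction`` is the share due to replicate measurement noise.
    """

    organ: str
    between_metabolite_fraction: float
    error_fraction: float
    n_boot: int

    def __post_init__(self):
        total = self.between_metabolite_fraction + self.error_fraction
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("variance fractions must sum to 1")


def bootstrap_variance_partition(
    raw: TraitMatrix,
    tree: Phylogeny,
    n_boot: int = 100,
    seed: int = 0,
    organ: str | None = None,
) -> VariancePartition:
    """Partition conservation-score variance into metabolite vs replicate noise.

    Replicates are resampled with replacement within each (species,
    metabolite); scores are refit per bootstrap replicate; a one-way
    random-effects ANOVA on log10(MCS) with metabolite as the factor splits
    total variance into between-metabolite and error components.  Pairs with a
    single replicate are removed first (resampling cannot perturb them).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if organ is None:
        organs = raw.organs
        if len(organs) != 1:
            raise ValueError("multiple organs present; pass organ=...")
        organ = organs[0]
    df = raw.data[raw.data["organ"] == organ].copy()
    counts = df.groupby(["species", "metabolite"])["level"].transform("size")
    df = df[counts > 1]
    if df.empty:
        raise ValueError("no (species, metabolite) pair has > 1 replicate")
    df["loglevel"] = np.log10(df["level"].to_numpy(float))
    tips = set(tree.tip_labels)
    df = df[df["species"].isin(tips)]

    groups = df.groupby(["species", "metabolite"])["loglevel"]
    keys = list(groups.groups)
    arrays = [groups.get_group(k).to_numpy() for k in keys]

    master = np.random.SeedSequence(seed)
    boot_scores: dict[str, list[float]] = {}
    for b, child in enumerate(master.spawn(n_boot)):
        rng = np.random.default_rng(child)
        means = {
            k: float(rng.choice(arr, size=len(arr), replace=True).mean())
            for k, arr in zip(keys, arrays)
        }
        agg = pd.Series(means).unstack()  # species x metabolite
        for metabolite in agg.columns:
            col = agg[metabolite].dropna()
            if len(col) < 2:
                continue
            fit = fit_bm(tree, col.to_dict())
            if fit.sigma2 > 0:
                boot_scores.setdefault(metabolite, []).append(math.log10(fit.mcs))

    samples = [np.asarray(v) for v in boot_scores.values() if len(v) >= 2]
    if len(samples) < 2:
        raise ValueError("fewer than 2 metabolites with bootstrap score distributions")
    # balanced one-way random-effects components from the ANOVA mean squares
    k = len(samples)
    ns = np.array([len(s) for s in samples])
    grand = np.concatenate(samples).mean()
    ssb = float(sum(n * (s.mean() - grand) ** 2 for n, s in zip(ns, samples)))
    ssw = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
    msb = ssb / (k - 1)
    dfw = int(ns.sum() - k)
    msw = ssw / dfw if dfw > 0 else 0.0
    n0 = (ns.sum() - (ns**2).sum() / ns.sum()) / (k - 1)
    var_between = max((msb - msw) / n0, 0.0)
    var_error = msw
    total = var_between + var_error
    if total == 0.0:
        return VariancePartition(organ, 1.0, 0.0, n_boot)
    return VariancePartition(
        organ=organ,
        between_metabolite_fraction=var_between / total,
        error_fraction=var_error / total,
        n_boot=n_boot,
    )
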