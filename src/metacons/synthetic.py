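"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: ultrametric
pure-birth trees, trait matrices evolved by Brownian motion with per-metabolite
rates, replicate noise and optional lineage shifts, desk-scale kinetic models,
and feature/disease tables with planted effects.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .kinetics.model import KineticModel, Reaction
from .phylo import Phylogeny, TraitMatrix

# defaults chosen to mimic the mammalian study conditions: per-metabolite
# rates spanning ~3 decades, small replicate noise, 26 species, 2-4 replicates
SIGMA2_RANGE = (1e-2, 1e1)  # log-uniform sampling range for BM rates
REPLICATE_NOISE_SD = 0.1  # log10 scale
TREE_DEPTH = 1.0  # normalized root-to-tip depth of simulated trees


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with depth normalized to TREE_DEPTH."""
    if n_species < 2:
        raise ValueError("need n_species >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7EE]))

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    # active lineages: (node, birth_time)
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    labels = [f"sp{i+1:03d}" for i in range(len(active))]
    for (node, born), label in zip(active, labels):
        node.edge.length = t_end - born
        node.taxon = taxon_ns.new_taxon(label)
    # normalize depth
    scale = TREE_DEPTH / t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return Phylogeny(tree)


def clade_bipartition(tree: Phylogeny, min_size: int = 2) -> tuple[list[str], list[str]]:
    """Split the tips into a clade and its complement, as balanced as possible.

    Picks the internal node whose descendant tip count is closest to half the
    tree, subject to both sides having at least ``min_size`` tips.
    """
    n = len(tree.tip_labels)
    best = None
    for node in tree._tree.preorder_internal_node_iter():
        if node is tree._tree.seed_node:
            continue
        tips = [l.taxon.label for l in node.leaf_iter()]
        if len(tips) < min_size or n - len(tips) < min_size:
            continue
        score = abs(len(tips) - n / 2)
        if best is None or score < best[0]:
            best = (score, tips)
    if best is None:
        raise ValueError("tree has no bipartition with both sides >= min_size")
    clade = best[1]
    rest = [t for t in tree.tip_labels if t not in set(clade)]
    return clade, rest


# ---------------------------------------------------------------------------
# Brownian-motion traits
# ---------------------------------------------------------------------------


def simulate_bm_traits(
    tree: Phylogeny,
    sigma2: Mapping[str, float] | Sequence[float],
    replicate_noise_sd: float | Sequence[float] = REPLICATE_NOISE_SD,
    n_reps: int = 3,
    shift: tuple[Sequence[str], float] | None = None,
    seed: int = 0,
    organ: str = "organ1",
) -> TraitMatrix:
    """Evolve log10 trait values by BM along the tree; export linear levels.

    Root value 0 on the log10 scale; along each branch a Normal(0,
    sigma2 * branch_length) increment is added.  ``shift`` optionally adds a
    constant to all tips in a clade (a lineage-specific shift scenario).
    Replicates are tip value + Normal(0, replicate_noise_sd); a per-metabolite
    noise-SD vector is accepted (e.g. noise proportional to each metabolite's
    among-species SD).  Exported levels are 10**value.
    """
    if isinstance(sigma2, Mapping):
        met_ids = list(sigma2)
        rates = np.array([float(sigma2[m]) for m in met_ids])
    else:
        rates = np.asarray(sigma2, dtype=float)
        met_ids = [f"met{i+1:03d}" for i in range(len(rates))]
    if np.any(rates < 0):
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0]))

    dtree = tree._tree
    values: dict[dendropy.Node, np.ndarray] = {dtree.seed_node: np.zeros(len(rates))}
    tip_values: dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node is not dtree.seed_node:
            bl = node.edge.length
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(rates * bl), size=len(rates)
            )
        if node.is_leaf():
            tip_values[node.taxon.label] = values[node].copy()
    if shift is not None:
        clade_tips, magnitude = shift
        for sp in clade_tips:
            tip_values[sp] = tip_values[sp] + magnitude

    noise = np.broadcast_to(np.asarray(replicate_noise_sd, dtype=float), (len(rates),))
    rows = []
    for sp in sorted(tip_values):
        base = tip_values[sp]
        for rep in range(1, n_reps + 1):
            noisy = base + rng.normal(0.0, noise, size=len(rates))
            for m, v in zip(met_ids, noisy):
                rows.append((organ, sp, m, rep, 10.0**v))
    return TraitMatrix(
        pd.DataFrame(rows, columns=["organ", "species", "metabolite", "replicate", "level"])
    )


def sample_sigma2(
    n_metabolites: int, seed: int = 0, low: float = SIGMA2_RANGE[0], high: float = SIGMA2_RANGE[1]
) -> np.ndarray:
    """Log-uniform per-metabolite BM rates over the study-like ~3-decade range."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x516]))
    return 10.0 ** rng.uniform(math.log10(low), math.log10(high), size=n_metabolites)


def simulate_multiorgan_traits(
    tree: Phylogeny,
    n_metabolites: int = 40,
    organs: Sequence[str] = ("brain", "heart", "kidney", "liver"),
    seed: int = 0,
    n_reps: int = 3,
    replicate_noise_sd: float = REPLICATE_NOISE_SD,
    organ_offsets: Mapping[str, float] | None = None,
) -> tuple[TraitMatrix, pd.DataFrame]:
    """Four-organ trait matrix with a shared per-metabolite rate plus organ jitter.

    Rates are shared across organs up to a lognormal organ-specific factor, so
    cross-organ score correlations are positive but imperfect, as in real
    organ panels.  Returns the combined TraitMatrix and the true rate table
    (metabolite x organ).
    """
    base = sample_sigma2(n_metabolites, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0F6]))
    frames = []
    truth = {}
    for i, organ in enumerate(organs):
        jitter = 10.0 ** rng.normal(0.0, 0.15, size=n_metabolites)
        rates = base * jitter
        truth[organ] = rates
        tm = simulate_bm_traits(
            tree,
            rates,
            replicate_noise_sd=replicate_noise_sd,
            n_reps=n_reps,
            seed=seed + 1000 * (i + 1),
            organ=organ,
        )
        df = tm.data
        if organ_offsets and organ in organ_offsets:
            df = df.assign(level=df["level"] * 10.0 ** organ_offsets[organ])
        frames.append(df)
    met_ids = [f"met{i+1:03d}" for i in range(n_metabolites)]
    truth_df = pd.DataFrame(truth, index=met_ids)
    return TraitMatrix(pd.concat(frames, ignore_index=True)), truth_df


# ---------------------------------------------------------------------------
# Toy kinetic models
# ---------------------------------------------------------------------------


def toy_kinetic_model() -> KineticModel:
    """Fixed 8-reaction desk-scale kinetic model.

    Pathway: boundary source -> A -> B -> C -> boundary sink with
    Michaelis-Menten steps, a branch B -> D -> boundary sink, a reversible
    mass-action shunt A <-> C, and an ATP/ADP cofactor pair cycled by the
    A -> B step and a regeneration reaction.  Designated key fluxes are the C
    export (R_cexp) and the cofactor regeneration (R_reg); both are nonzero at
    the wild-type steady state.
    """
    reactions = [
        Reaction(
            "R_src",
            {"A": 1.0},
            "Vsrc * S0 / (Ksrc + S0)",
            {"Vsrc": 2.0, "Ksrc": 10.0},
        ),
        Reaction(
            "R_ab",
            {"A": -1.0, "ATP": -1.0, "B": 1.0, "ADP": 1.0},
            "Vab * A / (Kab + A) * ATP / (Katp + ATP)",
            {"Vab": 4.0, "Kab": 1.0, "Katp": 0.5},
        ),
        Reaction(
            "R_bc",
            {"B": -1.0, "C": 1.0},
            "Vbc * B / (Kbc + B)",
            {"Vbc": 2.0, "Kbc": 1.0},
        ),
        Reaction(
            "R_cexp",
            {"C": -1.0, "Xc": 1.0},
            "Vcx * C / (Kcx + C)",
            {"Vcx": 3.0, "Kcx": 1.5},
        ),
        Reaction(
            "R_bd",
            {"B": -1.0, "D": 1.0},
            "Vbd * B / (Kbd + B)",
            {"Vbd": 1.2, "Kbd": 2.0},
        ),
        Reaction(
            "R_dexp",
            {"D": -1.0, "Xd": 1.0},
            "kdx * D",
            {"kdx": 0.8},
        ),
        Reaction(
            "R_shunt",
            {"A": -1.0, "C": 1.0},
            "kf * A - kr * C",
            {"kf": 0.3, "kr": 0.2},
        ),
        Reaction(
            "R_reg",
            {"ADP": -1.0, "ATP": 1.0},
            "Vreg * ADP / (Kreg + ADP)",
            {"Vreg": 6.0, "Kreg": 0.7},
        ),
    ]
    return KineticModel(
        species={"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0, "ATP": 1.0, "ADP": 1.0},
        boundary={"S0": 10.0, "Xc": 0.0, "Xd": 0.0},
        reactions=reactions,
        name="toy8",
    )


TOY_KEY_FLUXES = ["R_cexp", "R_reg"]


def toy_monotone_model() -> KineticModel:
    """Minimal model where one metabolite is perfectly coupled to the key flux.

    The only mutable parameter is the source rate Vin; at steady state
    A = Vin / 2 and the sink flux equals Vin, so |dA/A| is a strictly monotone
    (identical) function of |dv/v| across any mutant ensemble.
    """
    return KineticModel(
        species={"A": 0.5},
        boundary={"Sin": 1.0, "Sout": 0.0},
        reactions=[
            Reaction("R_in", {"A": 1.0}, "Vin", {"Vin": 1.0}),
            Reaction("R_out", {"A": -1.0}, "2.0 * A", {}),
        ],
        name="toy_monotone",
    )


def toy_decoupled_model(n_branches: int = 10) -> KineticModel:
    """Parallel independent branches; metabolites in other branches are
    decoupled from the key flux.

    Branch i: boundary source -> A_i (constant rate V_i) -> sink (k_i * A_i).
    The key flux is branch 1's export; metabolites of the other branches never
    respond to the mutations that move it.
    """
    species = {}
    reactions = []
    for i in range(1, n_branches + 1):
        a = f"A{i}"
        species[a] = 1.0
        reactions.append(Reaction(f"Rin{i}", {a: 1.0}, f"V{i}", {f"V{i}": 1.0}))
        reactions.append(Reaction(f"Rout{i}", {a: -1.0}, f"k{i} * {a}", {f"k{i}": 1.0}))
    return KineticModel(
        species=species, boundary={}, reactions=reactions, name="toy_parallel"
    )


# ---------------------------------------------------------------------------
# Features and disease labels with planted effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffects:
    """Generating parameters for synthetic feature/disease tables."""

    abundance_partial_r2: float = 0.3  # share of log-MCS variance abundance explains
    disease_odds_ratio: float = 6.0  # odds multiplier per SD of log conservation
    disease_prevalence: float = 0.3
    n_noise_features: int = 4
    count_slope: float = 0.5  # log-rate slope of disease counts on standardized log-MCS
    seed: int = 0


def synth_features_and_labels(
    log_mcs: pd.Series, spec: PlantedEffects = PlantedEffects()
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Feature table and disease annotations with planted effects on conservation.

    ``log_mcs`` is an aggregate log-scale conservation score per metabolite.
    Abundance is generated with the stated partial correlation to it; noise
    features are independent; IEM-like flags are drawn with the stated odds
    ratio for above-median conservation; specific-disease counts are Poisson
    with a log-rate proportional to standardized conservation.  Returns
    (features, disease annotations, provenance of all generating parameters).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xFEA7]))
    mets = list(log_mcs.index)
    z = (log_mcs - log_mcs.mean()) / log_mcs.std(ddof=0)
    rho = math.sqrt(spec.abundance_partial_r2)
    log_abundance = rho * z + math.sqrt(1 - rho**2) * rng.normal(size=len(mets))

    features = pd.DataFrame(index=pd.Index(mets, name="metabolite"))
    features["abundance"] = 10.0 ** (log_abundance + 1.0)  # nmol/g-like scale
    features["molecular_weight"] = 10.0 ** rng.normal(2.2, 0.3, size=len(mets))
    features["ld50"] = 10.0 ** rng.normal(3.0, 0.6, size=len(mets))
    features["network_degree"] = rng.poisson(6.0, size=len(mets)) + 1
    features["chemical_class"] = rng.choice(
        ["amino_acid", "sugar", "nucleotide", "organic_acid"], size=len(mets)
    )
    for j in range(spec.n_noise_features):
        features[f"noise{j+1}"] = rng.normal(size=len(mets))

    # dose-response labels: odds multiplied by the stated ratio per SD of
    # standardized log conservation, centered at the target prevalence
    q = spec.disease_prevalence
    logit = math.log(q / (1 - q)) + math.log(spec.disease_odds_ratio) * z.to_numpy()
    iem = rng.random(len(mets)) < 1.0 / (1.0 + np.exp(-logit))
    counts = rng.poisson(np.exp(math.log(1.5) + spec.count_slope * z.to_numpy()))
    disease = pd.DataFrame(
        {
            "iem": iem,
            "n_specific_diseases": counts,
        },
        index=pd.Index(mets, name="metabolite"),
    )
    provenance = {
        "abundance_partial_r2": spec.abundance_partial_r2,
        "disease_odds_ratio": spec.disease_odds_ratio,
        "disease_prevalence": spec.disease_prevalence,
        "n_noise_features": spec.n_noise_features,
        "count_slope": spec.count_slope,
        "seed": spec.seed,
    }
    return features, disease, provenance
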