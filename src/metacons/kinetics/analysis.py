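"""Analyses on kinetic-evolution output: in-silico conservation scores,
fitness coupling, reaction essentiality and random key-flux nulls."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evolve import EvolutionConfig, Trajectory, evolve, mutate
from .model import KineticModel
from .solve import SteadyState, steady_state

logger = logging.getLogger(__name__)

# metabolites of the erythrocyte model whose simulated variability is zero or
# underestimated (moiety-pinned cofactors, or pinned to constant transport
# boundary levels); excluded from in-silico score analyses of that model
ERYTHROCYTE_EXCLUDED_METABOLITES = ("NAD", "P1NADPH", "GSH", "Pyr", "Lac")

# |v| < ZERO_FLUX_TOL * |v0| counts as "dropped to zero": the threshold sits
# well below any non-essential deviation but above the floor set by the
# knockdown factor itself (a knocked reaction's own flux scales with it)
ZERO_FLUX_TOL = 1e-3


@dataclass
class InSilicoMCS:
    """Per-metabolite evolution rate and conservation score from one trajectory."""

    table: pd.DataFrame  # metabolite, evolution_rate, score, flagged

    def scores(self) -> pd.Series:
        ok = self.table[~self.table["flagged"]]
        return ok.set_index("metabolite")["score"]


def insilico_mcs(
    traj: Trajectory,
    wildtype: SteadyState | None = None,
    exclude: tuple[str, ...] = (),
) -> InSilicoMCS:
    """Evolution rate ER_i = var(X_i(t) / X_i(0)) / T and score 1 / ER_i.

    The variance (denominator n-1) is taken over the within-run trajectory of
    the concentration ratio to the wild type.  Metabolites with zero rate, a
    zero wild-type level, or on the ``exclude`` list are flagged.
    """
    if traj.T < 2:
        raise ValueError("need T >= 2 iterations to compute a variance")
    wt = wildtype if wildtype is not None else traj.wildtype
    x0 = wt.concentrations
    rows = []
    for i, met in enumerate(traj.species_ids):
        if x0[i] == 0:
            rows.append({"metabolite": met, "evolution_rate": math.nan, "score": math.nan, "flagged": True})
            continue
        ratios = traj.concentrations[:, i] / x0[i]
        er = float(np.var(ratios, ddof=1)) / traj.T
        flagged = er == 0.0 or met in exclude
        rows.append(
            {
                "metabolite": met,
                "evolution_rate": er,
                "score": 1.0 / er if er > 0 else math.inf,
                "flagged": flagged,
            }
        )
    return InSilicoMCS(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Single-mutation ensembles and fitness coupling
# ---------------------------------------------------------------------------


@dataclass
class MutantEnsemble:
    """Relative responses of all fluxes/metabolites to independent single mutations.

    Rows are mutants; ``flux_rel`` holds |delta v / v0| (columns = reactions),
    ``conc_rel`` holds |delta X / X0| (columns = species).  Fluxes/species with
    zero wild-type value get NaN columns.
    """

    flux_rel: np.ndarray
    conc_rel: np.ndarray
    wildtype: SteadyState
    reaction_ids: list[str]
    species_ids: list[str]


def mutant_ensemble(
    model: KineticModel,
    n_mut: int = 10_000,
    sigma_mut: float = 1e-2,
    seed: int = 0,
) -> MutantEnsemble:
    """Draw ``n_mut`` independent single mutations of the wild type.

    Mutants without a steady state are resampled until ``n_mut`` valid mutants
    are collected.
    """
    wt = steady_state(model)
    if not wt.converged:
        raise RuntimeError("wild-type model does not reach a steady state")
    v0 = wt.fluxes
    x0 = wt.concentrations
    flux_rel = np.empty((n_mut, len(v0)))
    conc_rel = np.empty((n_mut, len(x0)))
    i = 0
    attempt = 0
    max_attempts = n_mut * 1000
    while i < n_mut:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED, attempt]))
        attempt += 1
        if attempt > max_attempts:
            raise RuntimeError("too many non-converging mutants; model unsuitable")
        ev = mutate(model, model.p0, sigma_mut, rng)
        p_new = model.p0.copy()
        p_new[model.parameter_index[ev.parameter_id]] = ev.new_value
        ss = steady_state(model, p=p_new, x0=wt.concentrations)
        if not ss.converged:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            flux_rel[i] = np.abs((ss.fluxes - v0) / v0)
            conc_rel[i] = np.abs((ss.concentrations - x0) / x0)
        i += 1
    return MutantEnsemble(
        flux_rel=flux_rel,
        conc_rel=conc_rel,
        wildtype=wt,
        reaction_ids=list(model.reaction_ids),
        species_ids=list(model.species_ids),
    )


def _rank_columns(a: np.ndarray) -> np.ndarray:
    """Column-wise average ranks (ties get their mean rank)."""
    out = np.empty_like(a, dtype=float)
    for j in range(a.shape[1]):
        out[:, j] = stats.rankdata(a[:, j])
    return out


def coupling_from_ensemble(
    ensemble: MutantEnsemble, key_reactions: list[str]
) -> pd.DataFrame:
    """Fitness coupling: mean Spearman correlation of |dX/X0| with each key |dv/v0|.

    Returns one row per metabolite with the per-key rank correlations and
    their arithmetic mean (the coupling).  Metabolites with zero wild-type
    level are excluded with a warning.
    """
    key_idx = [ensemble.reaction_ids.index(r) for r in key_reactions]
    flux_ranks = _rank_columns(ensemble.flux_rel[:, key_idx])
    n = flux_ranks.shape[0]
    rows = []
    for i, met in enumerate(ensemble.species_ids):
        col = ensemble.conc_rel[:, i]
        if not np.all(np.isfinite(col)):
            logger.warning("metabolite %s has zero wild-type level; excluded", met)
            continue
        cr = stats.rankdata(col)
        rec: dict[str, object] = {"metabolite": met}
        cors = []
        for k, rid in enumerate(key_reactions):
            fr = flux_ranks[:, k]
            if np.ptp(fr) == 0 or np.ptp(cr) == 0:
                rho = math.nan
            else:
                rho = float(np.corrcoef(fr, cr)[0, 1])
            rec[f"rho_{rid}"] = rho
            cors.append(rho)
        rec["coupling"] = float(np.nanmean(cors)) if not all(math.isnan(c) for c in cors) else math.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def fitness_coupling(
    model: KineticModel,
    key_reactions: list[str],
    n_mut: int = 10_000,
    sigma_mut: float = 1e-2,
    seed: int = 0,
    ensemble: MutantEnsemble | None = None,
) -> pd.DataFrame:
    """Fitness coupling of every metabolite to the key fluxes (see Eq. above)."""
    if ensemble is None:
        ensemble = mutant_ensemble(model, n_mut=n_mut, sigma_mut=sigma_mut, seed=seed)
    return coupling_from_ensemble(ensemble, key_reactions)


# ---------------------------------------------------------------------------
# In-silico reaction essentiality
# ---------------------------------------------------------------------------


def reaction_essentiality(
    model: KineticModel,
    key_reactions: list[str],
    knockdown: float = 1e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Essentiality by near-complete knockdown of each reaction's rate law.

    A reaction is essential iff, after multiplying its rate law by
    ``knockdown`` and re-solving, at least one key flux drops to ~zero
    (|v| < ZERO_FLUX_TOL * |v0|).  Metabolites are essential iff they are a
    substrate or product of >= 1 essential reaction.  Reactions whose
    knocked-down model has no steady state are reported as non-evaluable.
    """
    keys = [model.reaction_index(r) for r in key_reactions]
    wt = steady_state(model)
    if not wt.converged:
        raise RuntimeError("wild-type model does not reach a steady state")
    v0 = wt.fluxes[keys]
    if np.any(v0 == 0):
        raise ValueError("a wild-type key flux is zero; key set misconfigured")
    rxn_rows = []
    essential_rxns = []
    for j, rid in enumerate(model.reaction_ids):
        mult = np.ones(len(model.reaction_ids))
        mult[j] = knockdown
        ss = steady_state(model, multipliers=mult, x0=wt.concentrations)
        if not ss.converged:
            rxn_rows.append({"reaction": rid, "essential": None, "evaluable": False})
            continue
        dropped = np.abs(ss.fluxes[keys]) < ZERO_FLUX_TOL * np.abs(v0)
        essential = bool(dropped.any())
        if essential:
            essential_rxns.append(rid)
        rxn_rows.append({"reaction": rid, "essential": essential, "evaluable": True})
    rxn_table = pd.DataFrame(rxn_rows)

    met_rows = []
    for met in model.species_ids:
        touching = [
            r for r in model.reactions if met in r.stoichiometry and r.stoichiometry[met] != 0
        ]
        evaluable_flags = [
            bool(rxn_table.loc[rxn_table["reaction"] == r.id, "evaluable"].iloc[0])
            for r in touching
        ]
        ess = any(r.id in essential_rxns for r in touching)
        # a metabolite is only non-evaluable if its status hinges on a failed
        # knockdown: no essential evaluable neighbour and >=1 failed one
        evaluable = ess or all(evaluable_flags) or not touching
        met_rows.append({"metabolite": met, "essential": ess if evaluable else None, "evaluable": evaluable})
    return rxn_table, pd.DataFrame(met_rows)


# ---------------------------------------------------------------------------
# Random key-flux combinations
# ---------------------------------------------------------------------------


def random_keyflux_scan(
    model: KineticModel,
    abundances: pd.Series,
    designated_keys: list[str],
    n_combos: int = 10_000,
    n_sim_combos: int = 0,
    config: EvolutionConfig | None = None,
    ensemble: MutantEnsemble | None = None,
    n_mut: int = 10_000,
    seed: int = 0,
    max_combo_size: int = 4,
) -> dict:
    """Null distribution of the abundance-coupling correlation over random key sets.

    A single precomputed single-mutation ensemble is reused across combos
    (sizes uniform in 1..max_combo_size, fluxes without replacement).  For the
    first ``n_sim_combos`` combos one stabilizing-selection run is additionally
    simulated and Spearman(abundance, in-silico score) recorded.  Returns the
    null vectors, the designated key set's statistics, and one-sided empirical
    p-values.
    """
    if n_combos < 1:
        raise ValueError("n_combos must be >= 1")
    if ensemble is None:
        ensemble = mutant_ensemble(model, n_mut=n_mut, sigma_mut=config.sigma_mut if config else 1e-2, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0B0]))
    rxns = list(model.reaction_ids)

    def combo_stat(keys: list[str]) -> float:
        cpl = coupling_from_ensemble(ensemble, keys).set_index("metabolite")["coupling"]
        common = cpl.index.intersection(abundances.index)
        cpl = cpl.loc[common].dropna()
        ab = abundances.loc[cpl.index]
        if len(cpl) < 3 or cpl.nunique() < 2:
            return math.nan
        return float(stats.spearmanr(ab, cpl).statistic)

    null_coupling = []
    null_mcs = []
    combos = []
    for c in range(n_combos):
        size = int(rng.integers(1, max_combo_size + 1))
        keys = list(rng.choice(rxns, size=size, replace=False))
        combos.append(keys)
        null_coupling.append(combo_stat(keys))
    observed = combo_stat(designated_keys)

    for c in range(min(n_sim_combos, n_combos)):
        cfg = config or EvolutionConfig()
        keys = combos[c]
        wtks = ensemble.wildtype.fluxes[[model.reaction_index(r) for r in keys]]
        if np.any(wtks == 0):
            null_mcs.append(math.nan)
            continue
        traj = evolve(model, keys, EvolutionConfig(
            omega=cfg.omega, sigma_mut=cfg.sigma_mut, T=cfg.T, n_reps=1,
            seed=int(np.random.SeedSequence([seed, 0x51B, c]).generate_state(1)[0] % (2**31)),
        ))
        sc = insilico_mcs(traj).scores()
        common = sc.index.intersection(abundances.index)
        sc = np.log10(sc.loc[common])
        if len(sc) < 3:
            null_mcs.append(math.nan)
            continue
        null_mcs.append(float(stats.spearmanr(abundances.loc[common], sc).statistic))

    null_arr = np.asarray([v for v in null_coupling if not math.isnan(v)])
    if null_arr.size and np.ptp(null_arr) == 0:
        logger.warning("degenerate null distribution (all combos identical)")
        p = math.nan
    else:
        p = float((1 + np.sum(null_arr >= observed)) / (null_arr.size + 1))
    return {
        "observed_rho": observed,
        "null_coupling_rho": null_coupling,
        "null_mcs_rho": null_mcs,
        "p_one_sided": p,
        "combos": combos,
    }
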