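"""MCMC evolution of kinetic parameters under genetic drift or stabilizing selection.

Per iteration a single kinetic parameter is mutated multiplicatively
(``p' = p * 10^alpha``, ``alpha ~ N(0, sigma_mut^2)``), the mutant's steady
state is computed (proposals without a steady state are resampled within the
iteration), and the mutation is accepted iff its key-flux deviation ``z`` from
the wild type is below the selection threshold ``omega`` (``omega = inf``
recovers pure drift: every steady-state-reaching mutant fixes).  Accepted
neutral mutants fix with probability 1 because the timescale is rescaled by
the effective population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import KineticModel
from .solve import SteadyState, steady_state


@dataclass(frozen=True)
class EvolutionConfig:
    """Simulation settings: selection threshold, mutation size, length, seed.

    ``omega`` is the neutral band on the key-flux deviation z (``math.inf``
    for drift); ``sigma_mut`` the SD of the log10 mutation factor; ``T`` the
    number of iterations per run.
    """

    omega: float = 1e-4
    sigma_mut: float = 1e-2
    T: int = 10_000
    n_reps: int = 10
    seed: int = 0
    resample_budget: int = 1000

    def __post_init__(self):
        if not (self.omega > 0):
            raise ValueError("omega must be positive (use math.inf for drift)")
        if not (self.sigma_mut > 0):
            raise ValueError("sigma_mut must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass(frozen=True)
class MutationEvent:
    reaction_id: str
    parameter_id: str
    old_value: float
    alpha: float

    @property
    def factor(self) -> float:
        return 10.0**self.alpha

    @property
    def new_value(self) -> float:
        return self.old_value * self.factor


def mutate(
    model: KineticModel,
    p: np.ndarray,
    sigma_mut: float,
    rng: np.random.Generator,
) -> MutationEvent:
    """Draw one mutation: reaction uniform, one of its parameters uniform.

    Reactions without kinetic parameters are resampled.  The drawn event
    applies to the current (evolved) parameter vector ``p``.
    """
    candidates = [r for r in model.reaction_ids if model.reaction_parameters[r]]
    if not candidates:
        raise ValueError("model has no kinetic parameters to mutate")
    while True:
        rid = model.reaction_ids[rng.integers(len(model.reaction_ids))]
        if model.reaction_parameters[rid]:
            break
    pnames = model.reaction_parameters[rid]
    pname = pnames[rng.integers(len(pnames))]
    alpha = float(rng.normal(0.0, sigma_mut))
    return MutationEvent(
        reaction_id=rid,
        parameter_id=pname,
        old_value=float(p[model.parameter_index[pname]]),
        alpha=alpha,
    )


def selection_distance(
    mutant: SteadyState, wildtype: SteadyState, keys: list[int] | np.ndarray
) -> float:
    """Euclidean norm of the key fluxes' relative deviations from wild type."""
    keys = np.asarray(keys, dtype=int)
    v0 = wildtype.fluxes[keys]
    if np.any(v0 == 0):
        raise ValueError("wild-type key flux is zero; key set misconfigured")
    v = mutant.fluxes[keys]
    return float(np.linalg.norm((v - v0) / v0))


@dataclass
class Trajectory:
    """Per-iteration record of one MCMC evolution run."""

    concentrations: np.ndarray  # (T, n_species): state *after* iteration t
    accepted: np.ndarray  # (T,) bool
    z: np.ndarray  # (T,) proposed mutant's key-flux deviation
    wildtype: SteadyState
    final_parameters: np.ndarray
    n_resampled: int = 0  # proposals discarded for lack of a steady state
    n_rejected: int = 0  # proposals rejected by selection
    species_ids: list[str] = field(default_factory=list)

    @property
    def T(self) -> int:
        return len(self.accepted)

    @property
    def acceptance_fraction(self) -> float:
        """Fraction of steady-state-reaching proposals that were accepted."""
        return float(self.accepted.mean())


class EvolutionError(RuntimeError):
    pass


def _iteration_rng(seed: int, rep: int, t: int, attempt: int) -> np.random.Generator:
    # counter-based child seeds: reproducible and order-independent
    return np.random.default_rng(np.random.SeedSequence([seed, rep, t, attempt]))


def evolve(
    model: KineticModel,
    key_reactions: list[str],
    config: EvolutionConfig,
    rep: int = 0,
) -> Trajectory:
    """Run one MCMC evolution trajectory of ``config.T`` iterations.

    Selection-rejected proposals consume an iteration with the state
    unchanged; proposals without a steady state are resampled within the
    iteration.  Raises if the wild type has no steady state or the resample
    budget is exhausted.
    """
    keys = [model.reaction_index(r) for r in key_reactions]
    wt = steady_state(model)
    if not wt.converged:
        raise EvolutionError(
            f"wild-type model does not reach a steady state (residual {wt.residual:.3g})"
        )
    p = model.p0.copy()
    x_cur = wt.concentrations.copy()

    n = len(model.species_ids)
    conc = np.empty((config.T, n))
    accepted = np.zeros(config.T, dtype=bool)
    zs = np.empty(config.T)
    n_resampled = 0
    n_rejected = 0

    for t in range(config.T):
        ss = None
        for attempt in range(config.resample_budget):
            rng = _iteration_rng(config.seed, rep, t, attempt)
            ev = mutate(model, p, config.sigma_mut, rng)
            p_new = p.copy()
            p_new[model.parameter_index[ev.parameter_id]] = ev.new_value
            trial = steady_state(model, p=p_new, x0=x_cur)
            if trial.converged:
                ss = trial
                break
            n_resampled += 1
        if ss is None:
            raise EvolutionError(
                f"iteration {t}: {config.resample_budget} consecutive proposals "
                "without a steady state; aborting run "
                f"(rep={rep}, seed={config.seed})"
            )
        z = selection_distance(ss, wt, keys)
        zs[t] = z
        if z < config.omega:
            accepted[t] = True
            p = p_new
            x_cur = ss.concentrations.copy()
        else:
            n_rejected += 1
        conc[t] = x_cur

    return Trajectory(
        concentrations=conc,
        accepted=accepted,
        z=zs,
        wildtype=wt,
        final_parameters=p,
        n_resampled=n_resampled,
        n_rejected=n_rejected,
        species_ids=list(model.species_ids),
    )
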