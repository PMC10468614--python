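"""Steady-state solver for kinetic models.

Strategy: damped Newton iteration on the ODE right-hand side augmented with
moiety-conservation constraints (so conserved totals set by the starting
concentrations are respected), falling back to stiff time integration when
Newton stalls.  Failure to converge is a value, never an exception: the
evolution simulator discards such mutants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import KineticModel

ABS_TOL = 1e-9  # max |dx/dt| for convergence, concentration/time units
NEG_TOL = 1e-12  # concentrations above -NEG_TOL are clipped to zero
MAX_NEWTON_STEPS = 200
T_MAX_INTEGRATION = 1e6
DIVERGENCE_BOUND = 1e12


@dataclass
class SteadyState:
    """Concentrations and fluxes at (or nearest approach to) a fixed point."""

    concentrations: np.ndarray
    fluxes: np.ndarray
    converged: bool
    residual: float

    def concentration_of(self, model: KineticModel, species_id: str) -> float:
        return float(self.concentrations[model.species_ids.index(species_id)])

    def flux_of(self, model: KineticModel, reaction_id: str) -> float:
        return float(self.fluxes[model.reaction_index(reaction_id)])


def _failed(model: KineticModel, x: np.ndarray, p, multipliers) -> SteadyState:
    res = model.rhs(x, p, multipliers)
    return SteadyState(
        concentrations=x.copy(),
        fluxes=model.fluxes(x, p, multipliers),
        converged=False,
        residual=float(np.max(np.abs(res))) if np.all(np.isfinite(res)) else math.inf,
    )


def _newton(model, x0, p, multipliers, totals, L):
    """Damped Newton on [f(x); L'x - totals]; returns (x, ok)."""
    x = x0.copy()
    n_con = L.shape[1]

    def F(x):
        f = model.rhs(x, p, multipliers)
        if n_con:
            return np.concatenate([f, L.T @ x - totals])
        return f

    fx = F(x)
    if not np.all(np.isfinite(fx)):
        return x, False
    norm = float(np.linalg.norm(fx))
    for _ in range(MAX_NEWTON_STEPS):
        if float(np.max(np.abs(fx[: len(x)]))) < ABS_TOL and np.min(x) > -NEG_TOL:
            return x, True
        J = model.jacobian(x, p, multipliers)
        if not np.all(np.isfinite(J)):
            return x, False
        A = np.vstack([J, L.T]) if n_con else J
        step, *_ = np.linalg.lstsq(A, -fx, rcond=None)
        if not np.all(np.isfinite(step)):
            return x, False
        lam = 1.0
        improved = False
        for _ in range(40):
            x_new = x + lam * step
            f_new = F(x_new)
            if np.all(np.isfinite(f_new)):
                n_new = float(np.linalg.norm(f_new))
                if n_new < norm * (1 - 1e-4 * lam) or n_new < ABS_TOL:
                    x, fx, norm = x_new, f_new, n_new
                    improved = True
                    break
            lam *= 0.5
        if not improved:
            return x, False
        if np.linalg.norm(x) > DIVERGENCE_BOUND:
            return x, False
    ok = float(np.max(np.abs(fx[: len(x)]))) < ABS_TOL and np.min(x) > -NEG_TOL
    return x, ok


def steady_state(
    model: KineticModel,
    p: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    multipliers: np.ndarray | None = None,
) -> SteadyState:
    """Find x >= 0 with max|dx/dt| < ABS_TOL, or report non-convergence.

    ``x0`` defaults to the model's declared initial concentrations; passing
    the current evolved state speeds up the Newton phase for small mutations.
    """
    x0 = model.x0 if x0 is None else np.asarray(x0, dtype=float).copy()
    L = model.moieties
    totals = L.T @ x0 if L.shape[1] else np.zeros(0)

    x, ok = _newton(model, x0, p, multipliers, totals, L)
    if ok:
        return _finish(model, x, p, multipliers)

    # fallback: stiff integration in expanding time chunks, with Newton polish
    x = x0.copy()
    t_reached = 0.0
    for t_end in (1e1, 1e2, 1e3, 1e4, 1e5, T_MAX_INTEGRATION):
        try:
            sol = solve_ivp(
                lambda t, y: model.rhs(y, p, multipliers),
                (t_reached, t_end),
                x,
                method="LSODA",
                jac=lambda t, y: model.jacobian(y, p, multipliers),
                rtol=1e-8,
                atol=1e-10,
            )
        except Exception:
            return _failed(model, x, p, multipliers)
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            return _failed(model, x, p, multipliers)
        x = sol.y[:, -1]
        t_reached = t_end
        if np.linalg.norm(x) > DIVERGENCE_BOUND:
            return _failed(model, x, p, multipliers)
        res = model.rhs(x, p, multipliers)
        if float(np.max(np.abs(res))) < ABS_TOL and np.min(x) > -NEG_TOL:
            return _finish(model, x, p, multipliers)
        x_n, ok = _newton(model, x, p, multipliers, totals, L)
        if ok:
            return _finish(model, x_n, p, multipliers)
    return _failed(model, x, p, multipliers)


def _finish(model, x, p, multipliers) -> SteadyState:
    x = x.copy()
    x[(x < 0) & (x > -NEG_TOL)] = 0.0
    if np.min(x) < 0:
        return _failed(model, x, p, multipliers)
    res = model.rhs(x, p, multipliers)
    return SteadyState(
        concentrations=x,
        fluxes=model.fluxes(x, p, multipliers),
        converged=True,
        residual=float(np.max(np.abs(res))),
    )
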