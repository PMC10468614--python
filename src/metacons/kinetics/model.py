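"""Declarative kinetic reaction-network models.

A model is a set of variable species with initial concentrations, boundary
species held at fixed concentrations, and reactions with arbitrary infix
rate-law expressions over species, boundary species and reaction-local kinetic
parameters.  Parameter ids are globally unique, so each parameter has exactly
one owning reaction.  Models round-trip through a native YAML text format and
through SBML Level 3 (local parameters on each kinetic law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import sympy
import yaml


class ModelFormatError(ValueError):
    """Model source failed to parse or validate."""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]  # species -> net coefficient (products positive)
    rate_law: str  # infix expression over species, boundary species, parameters
    parameters: dict[str, float] = field(default_factory=dict)


class KineticModel:
    """Parameterized reaction network with compiled ODE right-hand side."""

    def __init__(
        self,
        species: Mapping[str, float],
        boundary: Mapping[str, float],
        reactions: Sequence[Reaction],
        name: str = "model",
    ):
        self.name = name
        self.species = dict(species)
        self.boundary = dict(boundary)
        self.reactions = list(reactions)
        self._validate()
        self._compile()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        if not self.species:
            raise ModelFormatError("model declares no variable species")
        overlap = set(self.species) & set(self.boundary)
        if overlap:
            raise ModelFormatError(f"species declared both variable and boundary: {sorted(overlap)}")
        declared = set(self.species) | set(self.boundary)
        seen_params: dict[str, str] = {}
        seen_rxn: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen_rxn:
                raise ModelFormatError(f"duplicate reaction id {rxn.id!r}")
            seen_rxn.add(rxn.id)
            for sp in rxn.stoichiometry:
                if sp not in declared:
                    raise ModelFormatError(
                        f"reaction {rxn.id!r}: undeclared species {sp!r} in stoichiometry"
                    )
            for pname in rxn.parameters:
                if pname in declared:
                    raise ModelFormatError(
                        f"reaction {rxn.id!r}: parameter {pname!r} collides with a species name"
                    )
                if pname in seen_params:
                    raise ModelFormatError(
                        f"parameter {pname!r} owned by both reaction "
                        f"{seen_params[pname]!r} and {rxn.id!r}; ids must be unique"
                    )
                seen_params[pname] = rxn.id
        for rxn in self.reactions:
            expr = _parse_rate_law(rxn.id, rxn.rate_law)
            allowed = declared | set(rxn.parameters)
            unknown = {str(s) for s in expr.free_symbols} - allowed
            if unknown:
                raise ModelFormatError(
                    f"reaction {rxn.id!r}: rate law references undeclared symbol(s) "
                    f"{sorted(unknown)}"
                )

    # -- compilation ---------------------------------------------------

    def _compile(self) -> None:
        self.species_ids = list(self.species)
        self.reaction_ids = [r.id for r in self.reactions]
        self.parameter_index: dict[str, int] = {}
        self.parameter_owner: dict[str, str] = {}
        p0 = []
        for rxn in self.reactions:
            for pname, val in rxn.parameters.items():
                self.parameter_index[pname] = len(p0)
                self.parameter_owner[pname] = rxn.id
                p0.append(float(val))
        self.p0 = np.asarray(p0, dtype=float)
        self.reaction_parameters: dict[str, list[str]] = {
            r.id: list(r.parameters) for r in self.reactions
        }

        x_syms = [sympy.Symbol(s) for s in self.species_ids]
        p_syms = [sympy.Symbol(p) for p in self.parameter_index]
        m_syms = [sympy.Symbol(f"_mult_{r.id}") for r in self.reactions]
        bound_subs = {sympy.Symbol(b): sympy.Float(v) for b, v in self.boundary.items()}

        flux_exprs = []
        for rxn, m in zip(self.reactions, m_syms):
            expr = _parse_rate_law(rxn.id, rxn.rate_law).xreplace(bound_subs)
            flux_exprs.append(m * expr)

        # stoichiometric matrix over variable species only
        S = np.zeros((len(self.species_ids), len(self.reactions)))
        sp_index = {s: i for i, s in enumerate(self.species_ids)}
        for j, rxn in enumerate(self.reactions):
            for sp, coef in rxn.stoichiometry.items():
                if sp in sp_index:
                    S[sp_index[sp], j] = float(coef)
        self.stoich = S

        dxdt_exprs = [
            sympy.Add(*[S[i, j] * flux_exprs[j] for j in range(len(flux_exprs)) if S[i, j] != 0])
            for i in range(len(x_syms))
        ]
        jac_exprs = [[sympy.diff(e, x) for x in x_syms] for e in dxdt_exprs]

        args = (x_syms, p_syms, m_syms)
        self._flux_fn = sympy.lambdify(args, flux_exprs, modules="numpy")
        self._rhs_fn = sympy.lambdify(args, dxdt_exprs, modules="numpy")
        self._jac_fn = sympy.lambdify(args, jac_exprs, modules="numpy")
        self._ones = np.ones(len(self.reactions))

        # conserved moieties: left null space of S (constant linear combinations)
        if S.size:
            from scipy.linalg import null_space

            L = null_space(S.T)
            self.moieties = L if L.size else np.zeros((len(self.species_ids), 0))
        else:  # pragma: no cover
            self.moieties = np.zeros((len(self.species_ids), 0))

    # -- numeric evaluation --------------------------------------------

    @property
    def x0(self) -> np.ndarray:
        return np.array([self.species[s] for s in self.species_ids], dtype=float)

    def rhs(self, x: np.ndarray, p: np.ndarray | None = None, multipliers=None) -> np.ndarray:
        p = self.p0 if p is None else p
        m = self._ones if multipliers is None else multipliers
        return np.asarray(self._rhs_fn(x, p, m), dtype=float)

    def jacobian(self, x: np.ndarray, p: np.ndarray | None = None, multipliers=None) -> np.ndarray:
        p = self.p0 if p is None else p
        m = self._ones if multipliers is None else multipliers
        return np.asarray(self._jac_fn(x, p, m), dtype=float)

    def fluxes(self, x: np.ndarray, p: np.ndarray | None = None, multipliers=None) -> np.ndarray:
        p = self.p0 if p is None else p
        m = self._ones if multipliers is None else multipliers
        return np.asarray(self._flux_fn(x, p, m), dtype=float)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    # -- native format -------------------------------------------------

    @classmethod
    def from_native(cls, text: str) -> "KineticModel":
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ModelFormatError(f"invalid YAML: {exc}") from exc
        if not isinstance(doc, dict):
            raise ModelFormatError("model document must be a mapping")
        for section in ("species", "reactions"):
            if section not in doc:
                raise ModelFormatError(f"missing section {section!r}")
        reactions = []
        for i, r in enumerate(doc["reactions"]):
            for key in ("id", "stoichiometry", "rate"):
                if key not in r:
                    raise ModelFormatError(f"reaction #{i}: missing key {key!r}")
            reactions.append(
                Reaction(
                    id=str(r["id"]),
                    stoichiometry={str(k): float(v) for k, v in r["stoichiometry"].items()},
                    rate_law=str(r["rate"]),
                    parameters={str(k): float(v) for k, v in (r.get("parameters") or {}).items()},
                )
            )
        return cls(
            species={str(k): float(v) for k, v in doc["species"].items()},
            boundary={str(k): float(v) for k, v in (doc.get("boundary") or {}).items()},
            reactions=reactions,
            name=str(doc.get("name", "model")),
        )

    @classmethod
    def from_native_file(cls, path) -> "KineticModel":
        return cls.from_native(Path(path).read_text())

    def to_native(self) -> str:
        # hand-rolled emitter: floats via repr so a write/read round trip is
        # value-identical
        lines = [f"name: {self.name}", "species:"]
        for s, v in self.species.items():
            lines.append(f"  {s}: {v!r}")
        lines.append("boundary:")
        for s, v in self.boundary.items():
            lines.append(f"  {s}: {v!r}")
        lines.append("reactions:")
        for rxn in self.reactions:
            lines.append(f"  - id: {rxn.id}")
            stoich = ", ".join(f"{k}: {v!r}" for k, v in rxn.stoichiometry.items())
            lines.append(f"    stoichiometry: {{{stoich}}}")
            lines.append(f"    rate: {rxn.rate_law!r}")
            if rxn.parameters:
                pars = ", ".join(f"{k}: {v!r}" for k, v in rxn.parameters.items())
                lines.append(f"    parameters: {{{pars}}}")
        return "\n".join(lines) + "\n"

    def to_native_file(self, path) -> None:
        Path(path).write_text(self.to_native())

    # -- SBML ----------------------------------------------------------

    @classmethod
    def from_sbml_file(cls, path) -> "KineticModel":
        from . import sbml

        return sbml.read_sbml(path)

    def to_sbml_file(self, path) -> None:
        from . import sbml

        sbml.write_sbml(self, path)


_RATE_LAW_CACHE: dict[str, sympy.Expr] = {}


def _parse_rate_law(reaction_id: str, text: str) -> sympy.Expr:
    if text in _RATE_LAW_CACHE:
        return _RATE_LAW_CACHE[text]
    try:
        expr = sympy.parse_expr(text, evaluate=True)
    except Exception as exc:
        raise ModelFormatError(f"reaction {reaction_id!r}: cannot parse rate law {text!r}: {exc}") from exc
    _RATE_LAW_CACHE[text] = expr
    return expr


def load_model(path) -> KineticModel:
    """Load a model from the native format or SBML, dispatching on suffix."""
    p = Path(path)
    if p.suffix.lower() in {".xml", ".sbml"}:
        return KineticModel.from_sbml_file(p)
    return KineticModel.from_native_file(p)
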