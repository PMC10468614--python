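"""SBML Level 3 import/export for kinetic models.

Kinetic parameters are stored as local parameters of each reaction's kinetic
law, preserving the one-owning-reaction invariant.  Rate laws are converted
between Python infix (``**``) and SBML infix (``^``) notation.
"""

from __future__ import annotations

import libsbml

from .model import KineticModel, ModelFormatError, Reaction


def _check(value, message: str):
    if value is None:
        raise ModelFormatError(f"SBML export failed: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise ModelFormatError(f"SBML export failed ({value}): {message}")
    return value


def write_sbml(model: KineticModel, path) -> None:
    doc = libsbml.SBMLDocument(3, 2)
    m = doc.createModel()
    m.setId(model.name.replace(" ", "_") or "model")
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    for sid, value in list(model.species.items()) + list(model.boundary.items()):
        sp = m.createSpecies()
        sp.setId(sid)
        sp.setCompartment("cell")
        sp.setInitialConcentration(float(value))
        sp.setBoundaryCondition(sid in model.boundary)
        sp.setConstant(sid in model.boundary)
        sp.setHasOnlySubstanceUnits(False)

    for rxn in model.reactions:
        r = m.createReaction()
        r.setId(rxn.id)
        r.setReversible(True)
        for sid, coef in rxn.stoichiometry.items():
            ref = r.createProduct() if coef > 0 else r.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        kl = r.createKineticLaw()
        for pname, pval in rxn.parameters.items():
            lp = kl.createLocalParameter()
            lp.setId(pname)
            lp.setValue(float(pval))
        ast = libsbml.parseL3Formula(rxn.rate_law.replace("**", "^"))
        _check(ast, f"cannot parse rate law of {rxn.id!r}")
        kl.setMath(ast)

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path) -> KineticModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"SBML parse error: {err.getMessage() if err else 'unknown'}")
    m = doc.getModel()
    if m is None:
        raise ModelFormatError("SBML document contains no model")

    species: dict[str, float] = {}
    boundary: dict[str, float] = {}
    for i in range(m.getNumSpecies()):
        sp = m.getSpecies(i)
        value = sp.getInitialConcentration()
        if sp.getBoundaryCondition() or sp.getConstant():
            boundary[sp.getId()] = value
        else:
            species[sp.getId()] = value

    reactions = []
    for i in range(m.getNumReactions()):
        r = m.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        kl = r.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise ModelFormatError(f"reaction {r.getId()!r} has no kinetic law")
        formula = libsbml.formulaToL3String(kl.getMath()).replace("^", "**")
        params = {}
        for j in range(kl.getNumLocalParameters()):
            lp = kl.getLocalParameter(j)
            params[lp.getId()] = lp.getValue()
        for j in range(kl.getNumParameters()):  # SBML L2-style
            lp = kl.getParameter(j)
            if lp.getId() not in params:
                params[lp.getId()] = lp.getValue()
        reactions.append(
            Reaction(id=r.getId(), stoichiometry=stoich, rate_law=formula, parameters=params)
        )

    # global parameters (if any) become boundary-like constants folded into
    # the owning reaction is impossible; treat them as boundary values
    for i in range(m.getNumParameters()):
        gp = m.getParameter(i)
        boundary.setdefault(gp.getId(), gp.getValue())

    return KineticModel(
        species=species, boundary=boundary, reactions=reactions, name=m.getId() or "model"
    )
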