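"""Reading and writing metabolic models.

Two formats are supported:

* **SBML** Level 3 with the fbc package (flux bounds, gene-product
  associations, biomass objective), via python-libsbml.
* A human-writable **tabular** dialect (TSV) used for synthetic fixtures::

    [model]
    id<TAB><model id>
    objective<TAB><reaction id>
    [metabolites]
    id<TAB>name<TAB>compartment
    glc_e<TAB>glucose<TAB>e
    [reactions]
    id<TAB>equation<TAB>lower<TAB>upper<TAB>gpr
    R1<TAB>2 A + B => C<TAB>0<TAB>1000<TAB>g1 and (g2 or g3)

  Equations use ``=>`` (irreversible) or ``<=>`` (reversible); one side may
  be empty for exchange reactions (``A =>`` exports A).  Empty bounds default
  to (0, 1000) for irreversible and (-1000, 1000) for reversible reactions.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import libsbml

from .gpr import GPRRule, parse_gpr
from .model import (
    DEFAULT_LOWER_REV,
    DEFAULT_UPPER,
    FluxSolution,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = ["load_model", "save_model", "ModelParseError", "write_flux_tsv",
           "parse_equation", "format_equation"]


class ModelParseError(ValueError):
    """A model file is malformed; the message names the offending element."""


# ---------------------------------------------------------------------------
# reaction equation strings
# ---------------------------------------------------------------------------

def parse_equation(text: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"2 A + B => C"`` into a signed stoichiometry and a reversible flag."""
    if "<=>" in text:
        sep, reversible = "<=>", True
    elif "=>" in text:
        sep, reversible = "=>", False
    else:
        raise ModelParseError(f"equation {text!r}: missing '=>' or '<=>'")
    left, right = text.split(sep, 1)
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if not parts:
                raise ModelParseError(f"equation {text!r}: empty term")
            if len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ModelParseError(
                        f"equation {text!r}: bad coefficient {parts[0]!r}"
                    ) from exc
                met = parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise ModelParseError(f"equation {text!r}: bad term {term.strip()!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelParseError(f"equation {text!r}: no net stoichiometry")
    return stoich, reversible


def format_equation(stoich: Dict[str, float], reversible: bool) -> str:
    def side(items):
        return " + ".join(
            met if coef == 1.0 else f"{coef:g} {met}" for met, coef in items
        )

    left = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    right = [(m, c) for m, c in sorted(stoich.items()) if c > 0]
    arrow = "<=>" if reversible else "=>"
    return f"{side(left)} {arrow} {side(right)}".strip()


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def _load_tabular(path: Path) -> MetabolicModel:
    model_id = path.stem
    objective: Optional[str] = None
    mets: List[Metabolite] = []
    rxn_rows: List[Tuple[int, List[str]]] = []
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip().strip("[]").lower()
            continue
        fields = line.split("\t")
        if section == "model":
            if len(fields) != 2:
                raise ModelParseError(f"{path.name}:{lineno}: bad [model] row")
            key, value = fields
            if key == "id":
                model_id = value
            elif key == "objective":
                objective = value
            else:
                raise ModelParseError(f"{path.name}:{lineno}: unknown key {key!r}")
        elif section == "metabolites":
            if fields[0] == "id":
                continue
            if len(fields) != 3:
                raise ModelParseError(
                    f"{path.name}:{lineno}: metabolite row needs 3 fields"
                )
            mets.append(Metabolite(fields[0], fields[1], fields[2]))
        elif section == "reactions":
            if fields[0] == "id":
                continue
            rxn_rows.append((lineno, fields))
        else:
            raise ModelParseError(f"{path.name}:{lineno}: row outside any section")

    model = MetabolicModel(model_id, metabolites=mets)
    for lineno, fields in rxn_rows:
        if len(fields) != 5:
            raise ModelParseError(f"{path.name}:{lineno}: reaction row needs 5 fields")
        rid, equation, lo_s, hi_s, gpr_s = fields
        stoich, reversible = parse_equation(equation)
        lo = float(lo_s) if lo_s else (DEFAULT_LOWER_REV if reversible else 0.0)
        hi = float(hi_s) if hi_s else DEFAULT_UPPER
        try:
            rxn = Reaction(rid, stoich, lo, hi, parse_gpr(gpr_s))
            model.add_reaction(rxn)
        except ModelValidationError as exc:
            raise ModelParseError(f"{path.name}:{lineno}: {exc}") from exc
    if objective is None or objective not in model.reactions:
        raise ModelParseError(
            f"{path.name}: objective reaction {objective!r} missing or undeclared"
        )
    model.objective_id = objective
    model.validate()
    return model


def _save_tabular(model: MetabolicModel, path: Path) -> None:
    lines = ["[model]", f"id\t{model.id}", f"objective\t{model.objective_id}"]
    lines += ["[metabolites]", "id\tname\tcompartment"]
    for m in model.metabolites.values():
        lines.append(f"{m.id}\t{m.name}\t{m.compartment}")
    lines += ["[reactions]", "id\tequation\tlower\tupper\tgpr"]
    for r in model.reactions.values():
        eq = format_equation(r.stoichiometry, r.reversible)
        lines.append(
            f"{r.id}\t{eq}\t{r.lower_bound:.17g}\t{r.upper_bound:.17g}\t{r.gpr.to_string()}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML (L3 + fbc)
# ---------------------------------------------------------------------------

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    s = _SID_RE.sub("_", raw)
    if not s or s[0].isdigit():
        s = "_" + s
    return s


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.id))
    sm.setName(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sm.createCompartment()
        comp.setId(_sid(comp_id))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sid(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid(gene))
        gp.setLabel(gene)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_sid = {g: _sid(g) for g in model.genes}

    def build_assoc(node, parent):
        kind, payload = node
        if kind == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(gene_sid[payload])
        elif kind == "and":
            op = parent.createAnd()
            for child in payload:
                build_assoc(child, op)
        else:
            op = parent.createOr()
            for child in payload:
                build_assoc(child, op)

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sid(rxn.id))
        sr.setName(rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid(met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            build_assoc(rxn.gpr.tree, gpa)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid(model.objective_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _assoc_to_node(assoc, label_of):
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        return ("gene", label_of(assoc.getGeneProduct()))
    children = [_assoc_to_node(assoc.getAssociation(i), label_of)
                for i in range(assoc.getNumAssociations())]
    if assoc.isFbcAnd():
        return ("and", children)
    if assoc.isFbcOr():
        return ("or", children)
    raise ModelParseError("unsupported gene association element")


def _load_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(
            f"{path.name}: SBML error at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelParseError(f"{path.name}: no <model> element")
    mplug = sm.getPlugin("fbc")

    model = MetabolicModel(sm.getName() or sm.getId())
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        model.add_metabolite(
            Metabolite(sp.getId(), sp.getName() or sp.getId(), sp.getCompartment())
        )

    def gene_label(gp_id: str) -> str:
        gp = mplug.getGeneProduct(gp_id) if mplug else None
        return gp.getLabel() if gp is not None and gp.isSetLabel() else gp_id

    def param_value(pid: str, default: float) -> float:
        par = sm.getParameter(pid)
        return par.getValue() if par is not None else default

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        reversible = sr.getReversible()
        lo = DEFAULT_LOWER_REV if reversible else 0.0
        hi = DEFAULT_UPPER
        gpr = GPRRule(None)
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lo = param_value(rplug.getLowerFluxBound(), lo)
            if rplug.isSetUpperFluxBound():
                hi = param_value(rplug.getUpperFluxBound(), hi)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = GPRRule(_assoc_to_node(gpa.getAssociation(), gene_label))
        try:
            model.add_reaction(Reaction(sr.getId(), stoich, lo, hi, gpr))
        except ModelValidationError as exc:
            raise ModelParseError(f"{path.name}: reaction {sr.getId()!r}: {exc}") from exc

    objective_id = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if objective_id is None or objective_id not in model.reactions:
        raise ModelParseError(f"{path.name}: missing fbc objective (biomass) reaction")
    model.objective_id = objective_id
    model.validate()
    return model


# ---------------------------------------------------------------------------
# public dispatch
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: Optional[str]) -> str:
    if format:
        return format
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    return "tabular"


def load_model(path: Union[str, Path], format: Optional[str] = None) -> MetabolicModel:
    """Load a model from SBML (``.xml``/``.sbml``) or the tabular dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        return _load_sbml(path)
    if fmt == "tabular":
        return _load_tabular(path)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path: Union[str, Path],
               format: Optional[str] = None) -> None:
    """Write a model; format inferred from the extension unless given."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _save_sbml(model, path)
    elif fmt == "tabular":
        _save_tabular(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def write_flux_tsv(solution: FluxSolution, path: Union[str, Path]) -> None:
    lines = ["reaction\tflux"]
    lines += [f"{rid}\t{v:.10g}" for rid, v in solution.fluxes.items()]
    Path(path).write_text("\n".join(lines) + "\n")
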