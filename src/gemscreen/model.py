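"""In-memory representation of a genome-scale metabolic model (GEM).

A GEM is a set of metabolites (species, tagged by compartment), reactions
(signed stoichiometries with flux bounds and a GPR rule), and a designated
biomass objective reaction whose maximal steady-state flux proxies growth.
Exchange with the environment is modeled by explicit single-metabolite
exchange reactions; the steady-state balance applies to every metabolite.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

from .gpr import GPRRule, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "ModelValidationError",
    "apply_knockout",
]

DEFAULT_UPPER = 1000.0
DEFAULT_LOWER_REV = -1000.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name, self.compartment)


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    gpr: GPRRule = field(default_factory=GPRRule)

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> Set[str]:
        return set(self.gpr.genes)

    @property
    def is_exchange(self) -> bool:
        """Single-metabolite stoichiometry: crosses the system boundary."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            self.id, dict(self.stoichiometry), self.lower_bound, self.upper_bound, self.gpr
        )


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class MetabolicModel:
    """A GEM: metabolites, reactions, derived gene set, biomass objective."""

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: Optional[str] = None,
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.objective_id = objective_id
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        if not met.compartment:
            raise ModelValidationError(f"metabolite {met.id!r}: empty compartment")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    # -- derived ----------------------------------------------------------
    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions.values():
            out |= r.genes
        return out

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def objective(self) -> Reaction:
        if self.objective_id is None or self.objective_id not in self.reactions:
            raise ModelValidationError(
                f"model {self.id!r}: objective reaction {self.objective_id!r} not found"
            )
        return self.reactions[self.objective_id]

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any violated invariant."""
        _ = self.objective  # existence
        for r in self.reactions.values():
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(f"reaction {r.id!r}: inverted bounds")
            for met_id in r.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {met_id!r}"
                    )

    def copy(self, new_id: Optional[str] = None) -> "MetabolicModel":
        m = MetabolicModel(new_id or self.id, objective_id=self.objective_id)
        m.metabolites = {k: v.copy() for k, v in self.metabolites.items()}
        m.reactions = {k: v.copy() for k, v in self.reactions.items()}
        return m

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


def apply_knockout(model: MetabolicModel, knocked_out: Iterable[str]) -> MetabolicModel:
    """Return a copy with every reaction whose GPR fails under the knockout closed.

    A reaction is disabled (both bounds set to 0) iff its GPR evaluates false
    when the ``knocked_out`` genes are removed; spontaneous reactions are never
    touched.  Genes absent from the model are ignored with a warning.
    """
    ko = set(knocked_out)
    unknown = ko - model.genes
    if unknown:
        warnings.warn(
            f"knockout genes not in model {model.id!r}: {sorted(unknown)}",
            stacklevel=2,
        )
    out = model.copy()
    for rxn in out.reactions.values():
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(ko):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
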