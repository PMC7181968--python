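"""Single-gene essentiality by in silico knockout with biomass maximization.

Two knockout routes are provided and must agree:

* the direct route evaluates each reaction's GPR under the knockout and
  closes disabled reactions;
* the logic-transformed route (LTM) first rewrites the model so every
  reaction carries exactly one gene label.  A GPR in disjunctive normal form
  with d disjuncts becomes d parallel duplicate reactions, each labeled by
  its disjunct (a single gene, or a composite pseudo-gene for an AND
  conjunction).  The duplicates share the source reaction's flux capacity
  through a coupling pseudo-metabolite, so the transformation preserves the
  wild-type optimum; a knockout of any constituent gene disables every
  duplicate whose label contains it.

A gene is called essential when its knockout drops the maximal biomass flux
below ``threshold`` times the wild-type optimum (default 1e-3, i.e. growth
is effectively abolished).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .fba import LPProblem, fba
from .gpr import GPRRule
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "LTMModel",
    "EssentialityResult",
    "ConsensusResult",
    "logic_transform",
    "essential_genes",
    "consensus_essentiality",
]

DEFAULT_THRESHOLD = 1e-3


@dataclass
class LTMModel:
    """A logic-transformed model plus the label/reaction provenance maps."""

    model: MetabolicModel
    # label -> constituent original genes (singleton for plain genes)
    label_genes: Dict[str, FrozenSet[str]]
    # expanded reaction id -> source reaction id
    reaction_source: Dict[str, str]
    # reactions whose DNF exceeded the cap; direct GPR evaluation is used
    fallback_reactions: Set[str] = field(default_factory=set)

    def labels_hit(self, knocked_out: Iterable[str]) -> Set[str]:
        ko = set(knocked_out)
        return {lab for lab, genes in self.label_genes.items() if genes & ko}


def _composite_label(genes: FrozenSet[str]) -> str:
    return "&".join(sorted(genes))


def logic_transform(model: MetabolicModel, max_disjuncts: int = 64) -> LTMModel:
    """Rewrite ``model`` so each reaction is associated with one gene label.

    Reactions whose DNF would exceed ``max_disjuncts`` duplicates keep their
    original GPR and are flagged for direct evaluation during knockouts.
    """
    out = MetabolicModel(model.id + "_ltm", objective_id=model.objective_id)
    for met in model.metabolites.values():
        out.add_metabolite(met.copy())

    label_genes: Dict[str, FrozenSet[str]] = {}
    reaction_source: Dict[str, str] = {}
    fallback: Set[str] = set()

    for rxn in model.reactions.values():
        disjuncts = rxn.gpr.dnf() if not rxn.gpr.is_empty else []
        if not disjuncts:
            out.add_reaction(rxn.copy())
            reaction_source[rxn.id] = rxn.id
            continue
        if len(disjuncts) > max_disjuncts:
            warnings.warn(
                f"reaction {rxn.id!r}: DNF has {len(disjuncts)} disjuncts "
                f"(cap {max_disjuncts}); keeping original GPR", stacklevel=2,
            )
            out.add_reaction(rxn.copy())
            reaction_source[rxn.id] = rxn.id
            fallback.add(rxn.id)
            continue
        if len(disjuncts) == 1:
            genes = disjuncts[0]
            label = _composite_label(genes)
            label_genes[label] = genes
            dup = rxn.copy()
            dup.gpr = GPRRule.from_string(" and ".join(sorted(genes)))
            out.add_reaction(dup)
            reaction_source[rxn.id] = rxn.id
            continue
        # d > 1: parallel duplicates sharing capacity via a pseudo-metabolite.
        # Each duplicate carries the full stoichiometry plus one unit of the
        # coupling metabolite; a single unlabeled drain with the source bounds
        # caps the summed flux at the original capacity.
        cap_met = f"_cap_{rxn.id}"
        out.add_metabolite(Metabolite(cap_met, f"capacity of {rxn.id}", "pseudo"))
        span = max(abs(rxn.lower_bound), abs(rxn.upper_bound))
        for k, genes in enumerate(sorted(disjuncts, key=_composite_label), start=1):
            label = _composite_label(genes)
            label_genes[label] = genes
            dup_id = f"{rxn.id}__d{k}"
            stoich = dict(rxn.stoichiometry)
            stoich[cap_met] = stoich.get(cap_met, 0.0) + 1.0
            dup = Reaction(
                dup_id,
                stoich,
                -span if rxn.lower_bound < 0 else 0.0,
                span,
                GPRRule.from_string(" and ".join(sorted(genes))),
            )
            out.add_reaction(dup)
            reaction_source[dup_id] = rxn.id
        drain_id = f"{rxn.id}__cap"
        out.add_reaction(
            Reaction(drain_id, {cap_met: -1.0}, rxn.lower_bound, rxn.upper_bound)
        )
        reaction_source[drain_id] = rxn.id

    ltm = LTMModel(out, label_genes, reaction_source, fallback)
    return ltm


@dataclass
class EssentialityResult:
    """Per-gene knockout growth, growth ratio and essentiality flags."""

    wild_type_growth: float
    threshold: float
    ko_growth: Dict[str, float]
    growth_ratio: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.growth_ratio:
            wt = self.wild_type_growth
            self.growth_ratio = {
                g: (v / wt if wt > 0 else float("nan")) for g, v in self.ko_growth.items()
            }

    @property
    def essential(self) -> Set[str]:
        return {g for g, r in self.growth_ratio.items() if r < self.threshold}

    def is_essential(self, gene: str) -> bool:
        return self.growth_ratio[gene] < self.threshold

    def to_frame(self):
        import pandas as pd

        genes = sorted(self.ko_growth)
        return pd.DataFrame(
            {
                "gene": genes,
                "ko_growth": [self.ko_growth[g] for g in genes],
                "growth_ratio": [self.growth_ratio[g] for g in genes],
                "essential": [self.is_essential(g) for g in genes],
            }
        )


def _ko_objective(problem: LPProblem, model: MetabolicModel,
                  knocked_out: Set[str]) -> float:
    """Objective after closing reactions disabled by the knockout; bounds restored."""
    touched: List[Tuple[str, float, float]] = []
    for rxn in model.reactions.values():
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(knocked_out):
            touched.append((rxn.id, rxn.lower_bound, rxn.upper_bound))
            problem.set_bounds(rxn.id, 0.0, 0.0)
    try:
        sol = problem.solve()
        return sol.objective_value if sol.optimal else 0.0
    finally:
        for rid, lo, hi in touched:
            problem.set_bounds(rid, lo, hi)


def essential_genes(
    model: MetabolicModel,
    threshold: float = DEFAULT_THRESHOLD,
    genes: Optional[Iterable[str]] = None,
    use_ltm: bool = False,
) -> EssentialityResult:
    """Scan single-gene knockouts, maximizing biomass after each.

    One LP instance is reused across knockouts with bound updates only; the
    results are identical to independent per-gene solves.  With ``use_ltm``
    the scan runs on the logic-transformed model (same growth values within
    LP tolerance).
    """
    wt = fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise ValueError(
            f"model {model.id!r}: wild-type growth is not positive; essentiality undefined"
        )
    scan_genes = sorted(set(genes) if genes is not None else model.genes)

    if use_ltm:
        ltm = logic_transform(model)
        problem = LPProblem(ltm.model)
        work_model = ltm.model
    else:
        problem = LPProblem(model)
        work_model = model

    ko_growth: Dict[str, float] = {}
    for gene in scan_genes:
        ko_growth[gene] = _ko_objective(problem, work_model, {gene})
    return EssentialityResult(wt.objective_value, threshold, ko_growth)


@dataclass
class ConsensusResult:
    """Essentiality tallied across an ensemble of models.

    ``fraction`` counts a gene absent from a model as non-essential there;
    ``fraction_present`` conditions on the models that contain the gene.
    """

    fraction: Dict[str, float]
    fraction_present: Dict[str, float]
    n_models: int
    n_present: Dict[str, int]
    per_model: Dict[str, Set[str]]  # model id -> essential set

    @property
    def consensus_set(self) -> Set[str]:
        return {g for g, f in self.fraction.items() if f == 1.0}

    @property
    def union_set(self) -> Set[str]:
        """Genes essential in at least one model."""
        return {g for g, f in self.fraction.items() if f > 0.0}

    def to_frame(self):
        import pandas as pd

        genes = sorted(self.fraction)
        return pd.DataFrame(
            {
                "gene": genes,
                "fraction": [self.fraction[g] for g in genes],
                "fraction_present": [self.fraction_present[g] for g in genes],
                "n_models_present": [self.n_present[g] for g in genes],
            }
        )


def consensus_essentiality(
    models: Sequence[MetabolicModel],
    threshold: float = DEFAULT_THRESHOLD,
) -> ConsensusResult:
    """Run the knockout scan on every model and tally per-gene essentiality."""
    if not models:
        raise ValueError("empty ensemble")
    per_model: Dict[str, Set[str]] = {}
    essential_count: Dict[str, int] = {}
    present_count: Dict[str, int] = {}
    present_essential: Dict[str, int] = {}
    for m in models:
        res = essential_genes(m, threshold=threshold)
        ess = res.essential
        per_model[m.id] = ess
        for g in m.genes:
            present_count[g] = present_count.get(g, 0) + 1
            if g in ess:
                essential_count[g] = essential_count.get(g, 0) + 1
                present_essential[g] = present_essential.get(g, 0) + 1
    n = len(models)
    all_genes = set(present_count)
    fraction = {g: essential_count.get(g, 0) / n for g in all_genes}
    fraction_present = {
        g: present_essential.get(g, 0) / present_count[g] for g in all_genes
    }
    return ConsensusResult(fraction, fraction_present, n, present_count, per_model)
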