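"""Shared fixtures: hand-built toy models, random model factories, and an
independent LP oracle assembled reaction-by-reaction with COBRApy."""

from __future__ import annotations

import numpy as np
import pytest

from gemscreen.gpr import parse_gpr
from gemscreen.model import MetabolicModel, Metabolite, Reaction
from gemscreen.synthetic import generate_toy_gem


@pytest.fixture
def chain_model() -> MetabolicModel:
    """uptake ->A (bounds [0,10]), A-> biomass (bounds [0,5])."""
    m = MetabolicModel("chain", objective_id="bm")
    m.add_metabolite(Metabolite("A", "A", "c"))
    m.add_reaction(Reaction("up", {"A": 1.0}, 0.0, 10.0))
    m.add_reaction(Reaction("bm", {"A": -1.0}, 0.0, 5.0))
    return m


@pytest.fixture
def two_pathway_model() -> MetabolicModel:
    """Two single-gene pathways feeding one biomass; every gene essential."""
    model, truth = generate_toy_gem(
        n_pathways=2, gpr_mix=(1.0, 0.0, 0.0), chain_len=2, seed=11
    )
    model.truth = truth  # type: ignore[attr-defined]
    return model


def make_random_model(seed: int) -> MetabolicModel:
    """A random toy GEM (<= ~30 reactions) with varied GPRs, extra side
    branches and randomized bounds, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n_pathways = int(rng.integers(1, 4))
    chain_len = int(rng.integers(1, 4))
    mix = rng.dirichlet([1.0, 1.0, 1.0])
    model, _ = generate_toy_gem(
        n_pathways=n_pathways, gpr_mix=tuple(mix), chain_len=chain_len,
        seed=int(rng.integers(2**31)),
    )
    # randomize uptake capacities
    for rxn in model.exchange_reactions():
        if rxn.lower_bound < 0:
            rxn.lower_bound = -round(float(rng.uniform(1.0, 20.0)), 3)
    # sprinkle side reactions, some reversible
    internal = sorted(
        met for met, m in model.metabolites.items() if m.compartment == "c"
    )
    for s in range(int(rng.integers(0, 5))):
        sub = internal[int(rng.integers(len(internal)))]
        wid = f"side_{s}"
        model.add_metabolite(Metabolite(wid, wid, "c"))
        rev = bool(rng.random() < 0.5)
        model.add_reaction(
            Reaction(
                f"RS_{s}", {sub: -1.0, wid: 1.0},
                -round(float(rng.uniform(0, 50)), 3) if rev else 0.0,
                round(float(rng.uniform(1, 50)), 3),
            )
        )
        model.add_reaction(Reaction(f"EX_{wid}", {wid: -1.0}, 0.0, 1000.0))
    model.validate()
    return model


def to_cobra(model: MetabolicModel):
    """Independent LP assembly of the same constraints with COBRApy."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {mid: cobra.Metabolite(mid, compartment=m.compartment)
            for mid, m in model.metabolites.items()}
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    cm.objective = cm.reactions.get_by_id(model.objective_id)
    return cm


def cobra_max_growth(model: MetabolicModel) -> float:
    """Max biomass flux from the independently assembled COBRApy LP."""
    cm = to_cobra(model)
    value = cm.slim_optimize(error_value=float("nan"))
    return 0.0 if np.isnan(value) else float(value)
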