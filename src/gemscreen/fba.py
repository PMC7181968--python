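"""Flux balance analysis: maximize the biomass flux by linear programming.

The LP is  max c'v  s.t.  S v = 0,  lb <= v <= ub,  where S is the
stoichiometric matrix over ALL metabolites (boundary exchange happens through
explicit exchange reactions) and c selects the objective reaction.  Solved
with the HiGHS simplex/IPM backends via scipy.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .model import FluxSolution, MetabolicModel

__all__ = ["fba", "FBAError", "LPProblem", "steady_state_residual"]

FEASIBILITY_TOL = 1e-9
OBJECTIVE_TOL = 1e-6


class FBAError(RuntimeError):
    """The LP solver failed for a reason other than infeasible/unbounded."""


class LPProblem:
    """A reusable LP image of a model: matrices built once, bounds mutable.

    Supports efficient repeated solves under bound changes (gene-knockout
    scans): results are identical to assembling a fresh LP per solve.
    """

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rxn_ids = list(model.reactions)
        self.met_ids = list(model.metabolites)
        met_index = {m: i for i, m in enumerate(self.met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(self.rxn_ids):
            for met_id, coef in model.reactions[rid].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coef)
        self.S = csr_matrix(
            (vals, (rows, cols)), shape=(len(self.met_ids), len(self.rxn_ids))
        )
        self.lb = np.array([model.reactions[r].lower_bound for r in self.rxn_ids])
        self.ub = np.array([model.reactions[r].upper_bound for r in self.rxn_ids])
        self.c = np.zeros(len(self.rxn_ids))
        self.c[self.rxn_ids.index(model.objective_id)] = 1.0
        self._j = {r: j for j, r in enumerate(self.rxn_ids)}

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        j = self._j[rxn_id]
        self.lb[j] = lower
        self.ub[j] = upper

    def solve(self, maximize: bool = True, feasibility_only: bool = False) -> FluxSolution:
        c = np.zeros_like(self.c) if feasibility_only else (-self.c if maximize else self.c)
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
        )
        if res.status == 0:
            fluxes = dict(zip(self.rxn_ids, res.x))
            obj = fluxes[self.model.objective_id]
            sol = FluxSolution("optimal", obj, fluxes)
            self._check(sol)
            return sol
        if res.status == 2:
            return FluxSolution("infeasible", float("nan"), {})
        if res.status == 3:
            return FluxSolution("unbounded", float("inf"), {})
        raise FBAError(f"LP solver failed (status {res.status}): {res.message}")

    def _check(self, sol: FluxSolution) -> None:
        v = np.array([sol.fluxes[r] for r in self.rxn_ids])
        residual = np.abs(self.S @ v).max() if len(v) else 0.0
        if residual > 1e-6:
            raise FBAError(f"steady-state residual {residual:.2e} exceeds 1e-6")
        if ((v - self.lb) < -1e-6).any() or ((self.ub - v) < -1e-6).any():
            raise FBAError("flux bound violation beyond tolerance")


def steady_state_residual(model: MetabolicModel, fluxes: Dict[str, float]) -> float:
    """Max absolute net production over all metabolites for a flux vector."""
    net: Dict[str, float] = {m: 0.0 for m in model.metabolites}
    for rid, v in fluxes.items():
        for met_id, coef in model.reactions[rid].stoichiometry.items():
            net[met_id] += coef * v
    return max((abs(x) for x in net.values()), default=0.0)


def fba(model: MetabolicModel, problem: Optional[LPProblem] = None) -> FluxSolution:
    """Maximize the model's biomass objective at steady state.

    Returns the optimal objective value and a flux vector, or a solution with
    status ``infeasible``/``unbounded``.  Repeated solves of the same model
    give the same objective value (flux vectors may differ under degeneracy).
    """
    model.validate()
    return (problem or LPProblem(model)).solve()
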