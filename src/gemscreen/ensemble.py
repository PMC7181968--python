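"""Ensembles of personalized metabolic models.

Models reconstructed per patient from one generic reconstruction differ in
which reactions they carry.  Their pairwise Hamming distance — the number of
reactions present in exactly one of the two models — forms a distance matrix
on which hierarchical clustering exposes model subgroups; the top split of
the dendrogram yields a two-group partition.  Merging the ensemble (union of
metabolites, reactions and genes, widest bounds, OR of member GPRs) produces
a generic tumor model on which consensus essentiality can be run.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .gpr import GPRRule, parse_gpr
from .model import MetabolicModel, Reaction

__all__ = [
    "hamming_distance",
    "DistanceMatrix",
    "distance_matrix",
    "top_split_clusters",
    "merge_models",
    "MergeConflictError",
    "survival_by_cluster",
]


class MergeConflictError(ValueError):
    """Shared reaction ids with conflicting stoichiometry."""


def hamming_distance(m1: MetabolicModel, m2: MetabolicModel) -> int:
    """|R1 symmetric-difference R2| over reaction-id sets."""
    return len(set(m1.reactions) ^ set(m2.reactions))


@dataclass
class DistanceMatrix:
    model_ids: List[str]
    values: np.ndarray  # symmetric, zero diagonal, integer counts

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.model_ids, columns=self.model_ids)


def distance_matrix(models: Sequence[MetabolicModel]) -> DistanceMatrix:
    """All pairwise Hamming distances over an ensemble."""
    if len(models) < 1:
        raise ValueError("empty ensemble")
    ids = [m.id for m in models]
    if len(set(ids)) != len(ids):
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate model ids: {dupes}")
    sets = [set(m.reactions) for m in models]
    n = len(models)
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = len(sets[i] ^ sets[j])
    return DistanceMatrix(ids, D)


def _agglomerate(D: np.ndarray, linkage: str) -> List[Tuple[int, int]]:
    """Merge order for agglomerative clustering with a deterministic tie-break.

    Among minimal-distance cluster pairs the lexicographically smallest pair
    (by lowest member index) merges first.  Returns the merge sequence over
    live cluster keys; clusters are keyed by their lowest member index.
    """
    n = D.shape[0]
    members: Dict[int, List[int]] = {i: [i] for i in range(n)}
    merges: List[Tuple[int, int]] = []

    def cluster_dist(a: int, b: int) -> float:
        block = D[np.ix_(members[a], members[b])]
        if linkage == "complete":
            return float(block.max())
        if linkage == "average":
            return float(block.mean())
        if linkage == "single":
            return float(block.min())
        raise ValueError(f"unknown linkage {linkage!r}")

    while len(members) > 1:
        keys = sorted(members)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = cluster_dist(a, b)
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        _, a, b = best
        members[a] = members[a] + members[b]
        del members[b]
        merges.append((a, b))
    return merges


def top_split_clusters(
    matrix: DistanceMatrix, linkage: str = "complete"
) -> Tuple[List[str], List[str]]:
    """Cut the agglomerative dendrogram at its top split into two model groups.

    Deterministic: ties in inter-cluster distance merge the lexicographically
    smallest pair first.  The group containing the first model is returned
    first.
    """
    n = len(matrix.model_ids)
    if n < 2:
        raise ValueError("need at least 2 models to split")
    merges = _agglomerate(matrix.values.astype(float), linkage)
    # undo the final merge: its two operands are the top-split clusters
    a, b = merges[-1]
    members: Dict[int, List[int]] = {i: [i] for i in range(n)}
    for x, y in merges[:-1]:
        members[x] = members[x] + members[y]
        del members[y]
    group_a = sorted(members[a])
    group_b = sorted(members[b])
    first = group_a if 0 in group_a else group_b
    second = group_b if first is group_a else group_a
    ids = matrix.model_ids
    return [ids[i] for i in first], [ids[i] for i in second]


def merge_models(models: Sequence[MetabolicModel], merged_id: str = "merged") -> MetabolicModel:
    """Union-merge an ensemble into one generic model.

    Metabolites, reactions and genes are unioned; a reaction shared by several
    members keeps the widest bounds seen and the OR of the distinct member
    GPRs; the objective is the (most frequent) member biomass reaction.
    Identical reaction ids must carry identical stoichiometry.
    """
    if not models:
        raise ValueError("empty ensemble")
    merged = MetabolicModel(merged_id)
    # canonical order: sorted ids, so merging is order-invariant
    all_met_ids: Dict[str, MetabolicModel] = {}
    for m in models:
        for met_id in m.metabolites:
            all_met_ids.setdefault(met_id, m)
    for met_id in sorted(all_met_ids):
        merged.add_metabolite(all_met_ids[met_id].metabolites[met_id].copy())

    rxn_members: Dict[str, List[Reaction]] = {}
    for m in models:
        for rxn in m.reactions.values():
            rxn_members.setdefault(rxn.id, []).append(rxn)
    for rid in sorted(rxn_members):
        group = rxn_members[rid]
        ref = group[0]
        for other in group[1:]:
            if other.stoichiometry != ref.stoichiometry:
                raise MergeConflictError(
                    f"reaction {rid!r}: conflicting stoichiometry across members"
                )
        lo = min(r.lower_bound for r in group)
        hi = max(r.upper_bound for r in group)
        gpr_strings = []
        for r in group:
            s = r.gpr.to_string()
            if s and s not in gpr_strings:
                gpr_strings.append(s)
        gpr_strings.sort()
        if not gpr_strings:
            gpr = GPRRule(None)
        elif len(gpr_strings) == 1:
            gpr = parse_gpr(gpr_strings[0])
        else:
            gpr = parse_gpr(" or ".join(f"({s})" for s in gpr_strings))
        merged.add_reaction(Reaction(rid, dict(ref.stoichiometry), lo, hi, gpr))

    objectives = Counter(m.objective_id for m in models)
    top = objectives.most_common()
    if len(top) > 1:
        warnings.warn(
            f"member objectives differ ({dict(objectives)}); "
            f"using most frequent {top[0][0]!r}", stacklevel=2,
        )
    merged.objective_id = top[0][0]
    merged.validate()
    return merged


def survival_by_cluster(clinical, group1: Sequence[str], group2: Sequence[str]):
    """Two-sample t-test of mean survival days between two model clusters.

    ``clinical`` is a DataFrame with columns ``sample_id`` and ``days``;
    model ids are matched to sample ids.  Returns (mean1, mean2, t, p).
    """
    from scipy import stats

    days = clinical.set_index("sample_id")["days"]
    d1 = days.reindex([g for g in group1 if g in days.index]).dropna()
    d2 = days.reindex([g for g in group2 if g in days.index]).dropna()
    t, p = stats.ttest_ind(d1, d2, equal_var=False)
    return float(d1.mean()), float(d2.mean()), float(t), float(p)
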