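"""Reporter-metabolite scoring over the gene-metabolite topology of a GEM.

Each metabolite aggregates the differential-expression evidence of its
neighboring genes: with per-gene z-scores (from directional p-values via the
inverse normal), a metabolite with k neighbor genes scores

    z_raw = sum(z_g) / sqrt(k)

which is then corrected against a Monte-Carlo background of random size-k
gene sets drawn from all scored genes:  z_corr = (z_raw - mu_k) / sigma_k,
with an upper-tail normal p.  Metabolites whose neighborhood is unusually
enriched in significant expression change — transcriptional hotspots around
a metabolite — rank at the top.  Ubiquitous currency metabolites (ATP,
NADH, H2O, ...) connect unrelated reactions and are removed before scoring.

A reporter subnetwork is a connected gene-metabolite subgraph maximizing the
same aggregate over its member genes, found by greedy seeded expansion with
simulated-annealing refinement.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from math import exp, sqrt
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import HIGH_VS_LOW, GeneScoreTable
from .model import MetabolicModel

__all__ = [
    "DEFAULT_CURRENCY_METABOLITES",
    "GeneMetaboliteGraph",
    "build_graph",
    "gene_z",
    "gene_z_scores",
    "ReporterScore",
    "reporter_metabolites",
    "ReporterSubnetwork",
    "reporter_subnetwork",
    "metabolite_gene_degree",
]

# The 20 ubiquitous currency metabolites pruned from the network, matched by
# name (compartment-insensitive, case-insensitive, unicode minus normalized).
DEFAULT_CURRENCY_METABOLITES = (
    "H2O", "CO2", "O2", "H+", "HCO3-", "Na+", "CoA", "Pi", "PPi", "AMP",
    "ADP", "ATP", "NAD+", "NADH", "NADP+", "NADPH", "PAP", "PAPS", "FAD",
    "FADH2",
)

P_CLAMP = 1e-15


def _norm_name(name: str) -> str:
    """Currency-matching canonical form: strip compartment suffix ([c], _c),
    normalize the unicode minus homoglyph, lowercase."""
    s = unicodedata.normalize("NFKC", name).replace("−", "-").strip()
    if s.endswith("]") and "[" in s:
        s = s[: s.rindex("[")].strip()
    return s.lower()


@dataclass
class GeneMetaboliteGraph:
    """Bipartite adjacency: gene ~ metabolite iff some reaction involving the
    metabolite carries the gene in its GPR."""

    met_genes: Dict[str, FrozenSet[str]]  # metabolite id -> neighbor genes
    currency_removed: bool

    @property
    def metabolites(self) -> List[str]:
        return list(self.met_genes)

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for gs in self.met_genes.values():
            out |= gs
        return out

    def gene_mets(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for met, gs in self.met_genes.items():
            for g in gs:
                out.setdefault(g, set()).add(met)
        return out


def build_graph(
    model: MetabolicModel,
    remove_currency: bool = True,
    currency_list: Sequence[str] = DEFAULT_CURRENCY_METABOLITES,
) -> GeneMetaboliteGraph:
    """Build the gene-metabolite bipartite graph of a model.

    With ``remove_currency``, metabolites whose name (or id, when the name is
    empty) matches the currency list across any compartment are dropped.
    """
    currency = {_norm_name(c) for c in currency_list}
    met_genes: Dict[str, Set[str]] = {}
    for rxn in model.reactions.values():
        genes = rxn.gpr.genes
        if not genes:
            continue
        for met_id in rxn.stoichiometry:
            met = model.metabolites[met_id]
            if remove_currency and _norm_name(met.name or met.id) in currency:
                continue
            met_genes.setdefault(met_id, set()).update(genes)
    return GeneMetaboliteGraph(
        {m: frozenset(gs) for m, gs in met_genes.items()}, remove_currency
    )


def gene_z(p: float, in_direction: bool) -> float:
    """Directional z-score from a two-sided p-value.

    For the "up" run a gene changing in the up direction contributes
    z = Phi^{-1}(1 - p/2); a gene changing the other way contributes
    Phi^{-1}(p/2) (negative).  p is clamped away from 0/1 before inversion.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p-value {p} outside (0, 1]")
    p_dir = p / 2 if in_direction else 1 - p / 2
    p_dir = min(max(p_dir, P_CLAMP), 1 - P_CLAMP)
    return float(stats.norm.isf(p_dir))


def gene_z_scores(table: GeneScoreTable, direction: str) -> Dict[str, float]:
    """Per-gene directional z for a 'up'- or 'down'-in-low-survival run."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    df = table.table
    # under high-vs-low orientation, log2fc < 0 means up in the low group
    if table.orientation == HIGH_VS_LOW:
        up_in_low = df["log2fc"] < 0
    else:
        up_in_low = df["log2fc"] > 0
    in_dir = up_in_low if direction == "up" else ~up_in_low
    return {
        g: gene_z(p, bool(d))
        for g, p, d in zip(df["gene"], df["p"], in_dir)
    }


@dataclass
class ReporterScore:
    metabolite: str
    k: int
    z_raw: float
    mu_k: float
    sigma_k: float
    z_corr: float
    p: float
    direction: str


def _backgrounds(
    z_values: np.ndarray, sizes: Set[int], n_background: int, rng: np.random.Generator
) -> Dict[int, Tuple[float, float]]:
    """Monte-Carlo (mu_k, sigma_k) of sum(z)/sqrt(k) over random gene sets."""
    out: Dict[int, Tuple[float, float]] = {}
    n = len(z_values)
    for k in sorted(sizes):
        if k >= n:
            # degenerate: every draw is (almost) the whole pool
            out[k] = (float(z_values.sum() / sqrt(k)), 1.0)
            continue
        if k <= max(1, n // 10):
            # with-replacement draws are an adequate background for k << n
            idx = rng.integers(0, n, size=(n_background, k))
            samples = z_values[idx].sum(axis=1) / sqrt(k)
        else:
            samples = np.empty(n_background)
            for b in range(n_background):
                pick = rng.choice(n, size=k, replace=False)
                samples[b] = z_values[pick].sum() / sqrt(k)
        mu = float(samples.mean())
        sd = float(samples.std(ddof=1))
        out[k] = (mu, sd if sd > 0 else 1.0)
    return out


def reporter_metabolites(
    graph: GeneMetaboliteGraph,
    gene_z_by_direction: Dict[str, Dict[str, float]],
    n_background: int = 10000,
    seed: int = 0,
) -> Dict[str, List[ReporterScore]]:
    """Score every metabolite in each direction and rank by p ascending.

    ``gene_z_by_direction`` maps direction ('up'/'down') to per-gene z-scores
    (see :func:`gene_z_scores`).  Graph genes without a z are dropped with a
    warning; metabolites left with no scored neighbor are excluded.
    """
    import warnings

    results: Dict[str, List[ReporterScore]] = {}
    for direction, zmap in gene_z_by_direction.items():
        # background pool: every scored gene, not only those in the graph
        scored_genes = sorted(zmap)
        missing = graph.genes - set(zmap)
        if missing:
            warnings.warn(
                f"{len(missing)} graph genes lack a z-score and are dropped",
                stacklevel=2,
            )
        z_arr = np.array([zmap[g] for g in scored_genes])
        gene_index = {g: i for i, g in enumerate(scored_genes)}
        met_neighbors = {
            m: [gene_index[g] for g in gs if g in gene_index]
            for m, gs in graph.met_genes.items()
        }
        met_neighbors = {m: idx for m, idx in met_neighbors.items() if idx}
        sizes = {len(idx) for idx in met_neighbors.values()}
        rng = np.random.default_rng(seed)
        bg = _backgrounds(z_arr, sizes, n_background, rng)
        scores = []
        for met, idx in met_neighbors.items():
            k = len(idx)
            z_raw = float(z_arr[idx].sum() / sqrt(k))
            mu, sd = bg[k]
            z_corr = (z_raw - mu) / sd
            p = float(stats.norm.sf(z_corr))
            p = min(max(p, P_CLAMP), 1 - P_CLAMP)
            scores.append(ReporterScore(met, k, z_raw, mu, sd, z_corr, p, direction))
        scores.sort(key=lambda s: (s.p, s.metabolite))
        results[direction] = scores
    return results


def reporter_scores_frame(scores: Sequence[ReporterScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": s.metabolite,
                "k": s.k,
                "z_raw": s.z_raw,
                "z_corr": s.z_corr,
                "p": s.p,
                "direction": s.direction,
            }
            for s in scores
        ]
    )


@dataclass
class ReporterSubnetwork:
    """A connected gene-metabolite subgraph with its aggregate gene score."""

    genes: List[str]
    metabolites: List[str]
    score: float
    met_gene_degree: Dict[str, int]

    @property
    def size(self) -> int:
        return len(self.genes) + len(self.metabolites)


def _subnet_score(gene_set: Set[str], zmap: Dict[str, float]) -> float:
    if not gene_set:
        return float("-inf")
    return sum(zmap[g] for g in gene_set) / sqrt(len(gene_set))


def _gene_projection(graph: GeneMetaboliteGraph) -> Dict[str, Set[str]]:
    """Gene adjacency: two genes are neighbors iff they share a metabolite."""
    adj: Dict[str, Set[str]] = {g: set() for g in graph.genes}
    for gs in graph.met_genes.values():
        gl = sorted(gs)
        for i, a in enumerate(gl):
            for b in gl[i + 1:]:
                adj[a].add(b)
                adj[b].add(a)
    return adj


def _is_connected(nodes: Set[str], adj: Dict[str, Set[str]]) -> bool:
    if not nodes:
        return False
    seen = set()
    stack = [next(iter(sorted(nodes)))]
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        stack.extend((adj[u] & nodes) - seen)
    return seen == nodes


def reporter_subnetwork(
    graph: GeneMetaboliteGraph,
    zmap: Dict[str, float],
    size_budget: int = 25,
    seed: int = 0,
    n_anneal: int = 2000,
) -> ReporterSubnetwork:
    """Search for a connected subnetwork maximizing sum(z)/sqrt(n genes).

    Greedy seeded expansion from the top-scoring gene, followed by simulated
    annealing over add/remove moves (geometric cooling, T0=1.0, factor such
    that T ends near 1e-3); connectivity of the gene projection is preserved
    at every step.  Deterministic for a fixed seed.  ``size_budget`` caps the
    number of member genes.
    """
    scored = {g: z for g, z in zmap.items() if g in graph.genes}
    if not scored:
        raise ValueError("no scored genes present in the graph")
    adj = _gene_projection(graph)
    rng = np.random.default_rng(seed)

    # greedy seed: best gene, then best-scoring adjacent addition
    current: Set[str] = {max(sorted(scored), key=lambda g: scored[g])}
    improved = True
    while improved and len(current) < size_budget:
        improved = False
        frontier = sorted(
            {g for u in current for g in adj[u] if g in scored} - current
        )
        if not frontier:
            break
        base = _subnet_score(current, scored)
        best_gain, best_gene = 0.0, None
        for g in frontier:
            gain = _subnet_score(current | {g}, scored) - base
            if gain > best_gain + 1e-12:
                best_gain, best_gene = gain, g
        if best_gene is not None:
            current.add(best_gene)
            improved = True

    # annealing refinement
    best = set(current)
    best_score = _subnet_score(best, scored)
    T = 1.0
    cool = (1e-3) ** (1.0 / max(n_anneal, 1))
    for _ in range(n_anneal):
        T *= cool
        cur_score = _subnet_score(current, scored)
        add_frontier = sorted(
            {g for u in current for g in adj[u] if g in scored} - current
        )
        removable = sorted(
            g for g in current
            if len(current) > 1 and _is_connected(current - {g}, adj)
        )
        moves = []
        if add_frontier and len(current) < size_budget:
            moves.append("add")
        if removable:
            moves.append("remove")
        if not moves:
            break
        move = moves[int(rng.integers(len(moves)))]
        if move == "add":
            g = add_frontier[int(rng.integers(len(add_frontier)))]
            cand = current | {g}
        else:
            g = removable[int(rng.integers(len(removable)))]
            cand = current - {g}
        delta = _subnet_score(cand, scored) - cur_score
        if delta > 0 or rng.random() < exp(min(delta / max(T, 1e-9), 0)):
            current = cand
            s = _subnet_score(current, scored)
            if s > best_score:
                best, best_score = set(current), s

    mets = sorted(m for m, gs in graph.met_genes.items() if gs & best)
    degree = {m: len(graph.met_genes[m] & best) for m in mets}
    return ReporterSubnetwork(sorted(best), mets, best_score, degree)


def metabolite_gene_degree(subnetwork: ReporterSubnetwork, metabolite: str) -> int:
    """Number of gene neighbors of a metabolite within the subnetwork."""
    if metabolite not in subnetwork.met_gene_degree:
        raise KeyError(f"metabolite {metabolite!r} not in subnetwork")
    return subnetwork.met_gene_degree[metabolite]
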