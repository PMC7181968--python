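"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions end to end without any external
download: toy GEMs with known essential genes, ensembles of model variants
with a planted two-cluster reaction-presence structure, expression matrices
with planted survival-associated differential expression and co-expression
blocks, metabolic-task batteries with known pass/fail status, tumor/healthy
model pairs with planted toxic and non-toxic targets, and gene x cell-line
dependency-score matrices.  Every generator is deterministic given its seed,
and the planted truth is returned (and serializable to JSON) for assertions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .gpr import GPRRule, parse_gpr
from .model import MetabolicModel, Metabolite, Reaction
from .fba import fba
from .tasks import MetabolicTask, TaskBound

__all__ = [
    "SyntheticTruth",
    "generate_toy_gem",
    "generate_ensemble",
    "generate_expression",
    "generate_tasks",
    "generate_dependency_matrix",
    "generate_target_scenario",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Requested parameters cannot produce a valid artifact."""


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic artifact bundle."""

    seed: int
    essential_genes: Set[str] = field(default_factory=set)
    toxic_genes: Set[str] = field(default_factory=set)
    model_cluster_labels: Dict[str, int] = field(default_factory=dict)
    de_genes_up: Set[str] = field(default_factory=set)
    de_genes_down: Set[str] = field(default_factory=set)
    coexpr_blocks: List[List[str]] = field(default_factory=list)
    task_expectations: Dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "seed": self.seed,
            "essential_genes": sorted(self.essential_genes),
            "toxic_genes": sorted(self.toxic_genes),
            "model_cluster_labels": self.model_cluster_labels,
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "coexpr_blocks": [sorted(b) for b in self.coexpr_blocks],
            "task_expectations": self.task_expectations,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            essential_genes=set(d["essential_genes"]),
            toxic_genes=set(d["toxic_genes"]),
            model_cluster_labels={k: int(v) for k, v in d["model_cluster_labels"].items()},
            de_genes_up=set(d["de_genes_up"]),
            de_genes_down=set(d["de_genes_down"]),
            coexpr_blocks=[list(b) for b in d["coexpr_blocks"]],
            task_expectations={k: bool(v) for k, v in d["task_expectations"].items()},
        )

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            seed=self.seed,
            essential_genes=self.essential_genes | other.essential_genes,
            toxic_genes=self.toxic_genes | other.toxic_genes,
            model_cluster_labels={**self.model_cluster_labels, **other.model_cluster_labels},
            de_genes_up=self.de_genes_up | other.de_genes_up,
            de_genes_down=self.de_genes_down | other.de_genes_down,
            coexpr_blocks=self.coexpr_blocks + other.coexpr_blocks,
            task_expectations={**self.task_expectations, **other.task_expectations},
        )


# ---------------------------------------------------------------------------
# toy GEM
# ---------------------------------------------------------------------------

def generate_toy_gem(
    n_pathways: int = 3,
    gpr_mix: Tuple[float, float, float] = (0.4, 0.3, 0.3),
    chain_len: int = 3,
    seed: int = 0,
    model_id: str = "toy",
    gene_prefix: str = "g",
) -> Tuple[MetabolicModel, SyntheticTruth]:
    """Build a toy GEM of linear biosynthesis pathways feeding one biomass.

    Each of the ``n_pathways`` pathways is a chain: an exchange reaction
    imports a substrate, ``chain_len`` conversion steps produce a precursor,
    and the biomass reaction consumes one precursor from every pathway.
    Chain reactions carry GPRs drawn per ``gpr_mix`` = (single gene, OR
    isozyme pair, AND complex pair).  Because every chain is the unique route
    to its precursor, the ground-truth essential set is exactly: the gene of
    every single-gene step plus both genes of every AND step; OR isozymes are
    individually dispensable.
    """
    if n_pathways < 1:
        raise GenerationError("n_pathways must be >= 1")
    if chain_len < 1:
        raise GenerationError("chain_len must be >= 1")
    mix = np.asarray(gpr_mix, float)
    if mix.min() < 0 or mix.sum() <= 0:
        raise GenerationError("gpr_mix must be nonnegative with positive sum")
    mix = mix / mix.sum()
    rng = np.random.default_rng(seed)

    model = MetabolicModel(model_id)
    truth = SyntheticTruth(seed=seed)
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"{gene_prefix}{gene_counter:03d}"

    precursors = []
    for i in range(1, n_pathways + 1):
        mets = [Metabolite(f"X{i}_{j}", f"X{i}_{j}", "e" if j == 0 else "c")
                for j in range(chain_len + 1)]
        for m in mets:
            model.add_metabolite(m)
        # uptake: negative flux imports the substrate
        model.add_reaction(
            Reaction(f"EX_X{i}_0", {f"X{i}_0": -1.0}, -10.0, 1000.0)
        )
        for j in range(1, chain_len + 1):
            kind = rng.choice(3, p=mix)
            if kind == 0:
                g = next_gene()
                gpr = parse_gpr(g)
                truth.essential_genes.add(g)
            elif kind == 1:
                a, b = next_gene(), next_gene()
                gpr = parse_gpr(f"{a} or {b}")
            else:
                a, b = next_gene(), next_gene()
                gpr = parse_gpr(f"{a} and {b}")
                truth.essential_genes.update((a, b))
            model.add_reaction(
                Reaction(
                    f"R{i}_{j}",
                    {f"X{i}_{j-1}": -1.0, f"X{i}_{j}": 1.0},
                    0.0,
                    1000.0,
                    gpr,
                )
            )
        precursors.append(f"X{i}_{chain_len}")

    model.add_metabolite(Metabolite("biomass_c", "biomass", "c"))
    stoich = {p: -1.0 for p in precursors}
    stoich["biomass_c"] = 1.0
    model.add_reaction(Reaction("biomass", stoich, 0.0, 1000.0))
    model.add_reaction(Reaction("EX_biomass", {"biomass_c": -1.0}, 0.0, 1000.0))
    model.objective_id = "biomass"
    model.validate()
    sol = fba(model)
    if not sol.optimal or sol.objective_value <= 0:
        raise GenerationError("toy GEM has no positive wild-type growth")
    return model, truth


# ---------------------------------------------------------------------------
# ensembles with planted two-cluster structure
# ---------------------------------------------------------------------------

def generate_ensemble(
    base: MetabolicModel,
    n_models: int = 30,
    n_variable_reactions: int = 40,
    separation: int = 10,
    noise: float = 0.05,
    seed: int = 0,
) -> Tuple[List[MetabolicModel], SyntheticTruth]:
    """Derive an ensemble of model variants with two planted clusters.

    ``n_variable_reactions`` dead-end side reactions (never on the biomass
    path) are appended to the base model; two archetype presence/absence
    vectors differing in ``separation`` of them define the clusters, and each
    member flips every presence bit independently with probability ``noise``.
    Cluster labels (1/2) are recorded in the truth.
    """
    if separation > n_variable_reactions:
        raise GenerationError("separation cannot exceed n_variable_reactions")
    if n_models < 1:
        raise GenerationError("n_models must be >= 1")
    rng = np.random.default_rng(seed)

    core = base.copy(base.id + "_core")
    internal = [m for m in core.metabolites if not m.startswith("W_")]
    var_ids = []
    substrates = sorted(
        met_id
        for rxn in core.reactions.values()
        if not rxn.is_exchange
        for met_id, c in rxn.stoichiometry.items()
        if c > 0
    )
    if not substrates:
        raise GenerationError("base model has no internal products to branch from")
    for v in range(n_variable_reactions):
        w = f"W_{v}"
        core.add_metabolite(Metabolite(w, w, "c"))
        # byproduct export path: side reaction is the variable unit, its
        # exchange is part of the shared core
        core.add_reaction(Reaction(f"EX_{w}", {w: -1.0}, 0.0, 1000.0))
        sub = substrates[int(rng.integers(len(substrates)))]
        var_ids.append(f"V_{v}")
        core.add_reaction(
            Reaction(f"V_{v}", {sub: -1.0, w: 1.0}, 0.0, 1000.0)
        )

    archetype1 = rng.random(n_variable_reactions) < 0.5
    flip_idx = rng.choice(n_variable_reactions, size=separation, replace=False)
    archetype2 = archetype1.copy()
    archetype2[flip_idx] = ~archetype2[flip_idx]

    truth = SyntheticTruth(seed=seed)
    models: List[MetabolicModel] = []
    for k in range(n_models):
        label = 1 if k < (n_models + 1) // 2 else 2
        pattern = (archetype1 if label == 1 else archetype2).copy()
        flips = rng.random(n_variable_reactions) < noise
        pattern ^= flips
        mid = f"{base.id}_m{k:03d}"
        m = core.copy(mid)
        for v, present in enumerate(pattern):
            if not present:
                m.remove_reaction(f"V_{v}")
        sol = fba(m)
        if not sol.optimal or sol.objective_value <= 0:
            raise GenerationError(f"member {mid} lost positive growth")
        truth.model_cluster_labels[mid] = label
        models.append(m)
    return models, truth


# ---------------------------------------------------------------------------
# expression matrices with planted DE and co-expression blocks
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int = 2000,
    n_samples: int = 120,
    survival_median_days: float = 350.0,
    de_effect: float = 2.0,
    n_de_up: int = 50,
    n_de_down: int = 50,
    block_sizes: Sequence[int] = (),
    block_rho: float = 0.99,
    noise_sd: float = 1.0,
    frac_alive: float = 0.0,
    seed: int = 0,
    survival_days: Optional[Sequence[float]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a survival-annotated expression cohort on the log2 scale.

    Survival times are exponential with the given median (an explicit
    ``survival_days`` vector overrides the draw); expression is log-normal
    (normal on the log2 scale).  Planted DE genes shift by ``de_effect``
    between the low and high survival tertiles ("up" genes are higher in the
    low-survival group); co-expression blocks share a latent factor giving
    expected pairwise correlation ``block_rho``.  Returns (expression genes x
    samples, clinical table, truth).
    """
    if sum(block_sizes) + n_de_up + n_de_down > n_genes:
        raise GenerationError("block sizes plus DE genes exceed n_genes")
    rng = np.random.default_rng(seed)
    samples = [f"S{j:04d}" for j in range(n_samples)]
    if survival_days is not None:
        days = np.asarray(survival_days, float)
        if len(days) != n_samples:
            raise GenerationError("survival_days length mismatch")
    else:
        days = rng.exponential(survival_median_days / np.log(2), size=n_samples)
    days = np.maximum(np.round(days), 1.0)
    vital = np.where(rng.random(n_samples) < frac_alive, "alive", "dead")
    clinical = pd.DataFrame(
        {"sample_id": samples, "vital_status": vital, "days": days.astype(int)}
    )

    dead_days = days[vital == "dead"]
    if len(dead_days) < 3:
        raise GenerationError("too few dead samples for tertile stratification")
    lo_cut = float(np.quantile(dead_days, 1 / 3, method="linear"))
    hi_cut = float(np.quantile(dead_days, 2 / 3, method="linear"))
    if lo_cut >= hi_cut:
        raise GenerationError("degenerate survival distribution: tertile cut points coincide")
    low_mask = (vital == "dead") & (days < lo_cut)

    genes = [f"G{j:05d}" for j in range(n_genes)]
    base_mean = rng.normal(5.0, 1.0, size=n_genes)
    X = base_mean[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    truth = SyntheticTruth(seed=seed)
    cursor = 0
    for size in block_sizes:
        block = genes[cursor:cursor + size]
        f = rng.normal(0.0, 1.0, size=n_samples)
        eps = rng.normal(0.0, 1.0, size=(size, n_samples))
        X[cursor:cursor + size] = (
            base_mean[cursor:cursor + size, None]
            + noise_sd * (np.sqrt(block_rho) * f[None, :] + np.sqrt(1 - block_rho) * eps)
        )
        truth.coexpr_blocks.append(block)
        cursor += size
    up = genes[cursor:cursor + n_de_up]
    cursor += n_de_up
    down = genes[cursor:cursor + n_de_down]
    truth.de_genes_up = set(up)
    truth.de_genes_down = set(down)
    up_idx = [genes.index(g) for g in up]
    down_idx = [genes.index(g) for g in down]
    X[np.ix_(up_idx, np.where(low_mask)[0])] += de_effect
    X[np.ix_(down_idx, np.where(low_mask)[0])] -= de_effect

    expr = pd.DataFrame(X, index=genes, columns=samples)
    return expr, clinical, truth


# ---------------------------------------------------------------------------
# metabolic tasks
# ---------------------------------------------------------------------------

def _reachable(model: MetabolicModel, source: str) -> Set[str]:
    """Metabolites producible from ``source`` plus open-uptake substrates,
    following irreversible reaction directions (reversible: both ways)."""
    have = {source}
    for rxn in model.exchange_reactions():
        if rxn.lower_bound < 0:
            have.add(next(iter(rxn.stoichiometry)))
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions.values():
            if rxn.is_exchange:
                continue
            subs = {m for m, c in rxn.stoichiometry.items() if c < 0}
            prods = {m for m, c in rxn.stoichiometry.items() if c > 0}
            if subs <= have and not prods <= have:
                have |= prods
                changed = True
            if rxn.reversible and prods <= have and not subs <= have:
                have |= subs
                changed = True
    return have


def generate_tasks(
    model: MetabolicModel,
    n_tasks: int = 8,
    n_infeasible: int = 2,
    seed: int = 0,
) -> Tuple[List[MetabolicTask], SyntheticTruth]:
    """Build a task battery with known pass/fail status on ``model``.

    Feasible tasks demand a metabolite reachable from an importable
    substrate; infeasible tasks demand a product whose every producing route
    requires a different (closed) substrate.  Task-only reachability is
    computed against the model with all exchanges closed except the task
    input, matching the checking semantics.
    """
    if n_infeasible > n_tasks:
        raise GenerationError("n_infeasible cannot exceed n_tasks")
    rng = np.random.default_rng(seed)
    importable = sorted(
        next(iter(rxn.stoichiometry))
        for rxn in model.exchange_reactions()
        if rxn.lower_bound < 0
    )
    if not importable:
        raise GenerationError("model has no importable substrates")

    # reachable products per input, with only that input open
    closed = model.copy(model.id + "__probe")
    for rxn in closed.exchange_reactions():
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    reach: Dict[str, Set[str]] = {}
    for src in importable:
        reach[src] = _reachable(closed, src) - {src}

    truth = SyntheticTruth(seed=seed)
    tasks: List[MetabolicTask] = []
    n_feasible = n_tasks - n_infeasible
    for t in range(n_feasible):
        src = importable[int(rng.integers(len(importable)))]
        prods = sorted(reach[src])
        if not prods:
            raise GenerationError(f"no product reachable from {src}")
        out = prods[int(rng.integers(len(prods)))]
        tid = f"T{t+1:02d}"
        tasks.append(
            MetabolicTask(
                tid,
                f"produce {out} from {src}",
                inputs=[TaskBound(src, 0.0, 10.0)],
                outputs=[TaskBound(out, 0.1, 10.0)],
            )
        )
        truth.task_expectations[tid] = True
    made = 0
    for src in importable:
        if made >= n_infeasible:
            break
        unreachable = sorted(
            m
            for other in importable
            if other != src
            for m in reach[other]
            if m not in reach[src] and m != src
        )
        if not unreachable:
            continue
        out = unreachable[int(rng.integers(len(unreachable)))]
        tid = f"T{n_feasible + made + 1:02d}"
        tasks.append(
            MetabolicTask(
                tid,
                f"produce {out} from {src} (no route)",
                inputs=[TaskBound(src, 0.0, 10.0)],
                outputs=[TaskBound(out, 0.1, 10.0)],
            )
        )
        truth.task_expectations[tid] = False
        made += 1
    if made < n_infeasible:
        raise GenerationError(
            "cannot plant the requested number of infeasible tasks "
            "(every product is reachable from every substrate)"
        )
    return tasks, truth


# ---------------------------------------------------------------------------
# dependency-score matrices
# ---------------------------------------------------------------------------

def generate_dependency_matrix(
    genes: Sequence[str],
    n_cell_lines: int = 31,
    essential_genes: Sequence[str] = (),
    sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x cell-line dependency scores: essential ~ N(-1, sd), rest ~ N(0, sd)."""
    essential = set(essential_genes)
    unknown = essential - set(genes)
    if unknown:
        raise GenerationError(f"essential genes not in gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    centers = np.array([-1.0 if g in essential else 0.0 for g in genes])
    X = centers[:, None] + rng.normal(0.0, sd, size=(len(genes), n_cell_lines))
    if sd == 0:
        X = np.tile(centers[:, None], (1, n_cell_lines))
    cols = [f"CL{j:03d}" for j in range(n_cell_lines)]
    return pd.DataFrame(X, index=list(genes), columns=cols)


# ---------------------------------------------------------------------------
# tumor/healthy target scenario
# ---------------------------------------------------------------------------

def generate_target_scenario(
    n_pathways: int = 4,
    chain_len: int = 3,
    n_toxic: int = 2,
    n_nontoxic: int = 3,
    seed: int = 0,
) -> Tuple[MetabolicModel, MetabolicModel, List[MetabolicTask], SyntheticTruth]:
    """Plant a tumor/healthy pair where tumor-essential genes split into
    toxic and non-toxic drug targets.

    The tumor model is a single-gene toy GEM (every chain gene essential).
    ``n_toxic`` of its essential genes also catalyze sole-route steps in the
    healthy model, so removing their reactions breaks a healthy task;
    ``n_nontoxic`` are absent from the healthy model entirely.  The healthy
    task battery holds one production task per healthy pathway.
    """
    tumor, tumor_truth = generate_toy_gem(
        n_pathways=n_pathways,
        gpr_mix=(1.0, 0.0, 0.0),
        chain_len=chain_len,
        seed=seed,
        model_id="tumor",
        gene_prefix="tg",
    )
    essential = sorted(tumor_truth.essential_genes)
    if n_toxic + n_nontoxic > len(essential):
        raise GenerationError("not enough tumor-essential genes to split")
    rng = np.random.default_rng(seed + 1)
    picked = rng.choice(len(essential), size=n_toxic + n_nontoxic, replace=False)
    toxic = [essential[i] for i in sorted(picked[:n_toxic])]
    nontoxic = [essential[i] for i in sorted(picked[n_toxic:])]

    # healthy model: enough single-gene pathways to host every toxic gene
    n_healthy_pathways = max(n_toxic, 2)
    healthy, _ = generate_toy_gem(
        n_pathways=n_healthy_pathways,
        gpr_mix=(1.0, 0.0, 0.0),
        chain_len=chain_len,
        seed=seed + 2,
        model_id="healthy",
        gene_prefix="hg",
    )
    # plant each toxic gene as the sole catalyst of the first step of one
    # healthy pathway (replacing the healthy-only gene there)
    for i, gene in enumerate(toxic, start=1):
        healthy.reactions[f"R{i}_1"].gpr = parse_gpr(gene)

    tasks: List[MetabolicTask] = []
    for i in range(1, n_healthy_pathways + 1):
        tasks.append(
            MetabolicTask(
                f"HT{i:02d}",
                f"produce X{i}_{chain_len} from X{i}_0",
                inputs=[TaskBound(f"X{i}_0", 0.0, 10.0)],
                outputs=[TaskBound(f"X{i}_{chain_len}", 0.1, 10.0)],
            )
        )

    truth = SyntheticTruth(
        seed=seed,
        essential_genes=set(essential),
        toxic_genes=set(toxic),
        task_expectations={t.id: True for t in tasks},
    )
    # the planted non-toxic target set is essential minus toxic-on-healthy;
    # genes neither toxic nor picked as nontoxic are absent from healthy too,
    # so the screen's shortlist is every essential gene not planted toxic
    return tumor, healthy, tasks, truth
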