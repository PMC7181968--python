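"""Metabolic-task feasibility and the healthy-tissue toxicity screen.

A metabolic task asks whether a model can produce specified outputs from
specified allowed inputs — e.g. "synthesize nucleotides from glucose and
ammonia".  Checking a task closes every boundary exchange, opens temporary
uptake reactions for the task inputs (within the stated uptake interval) and
temporary sink reactions forcing the outputs (within the production
interval), and tests LP feasibility of the steady state.

The toxicity screen runs a task battery on a healthy-tissue model after
removing, for each candidate gene in turn, the reactions coupled to it.  A
candidate whose removal breaks any task the healthy cell must perform is a
toxic target; tumor-essential genes that survive the screen form the drug-
target shortlist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .fba import LPProblem
from .model import MetabolicModel, Reaction
from .essentiality import EssentialityResult

__all__ = [
    "TaskBound",
    "MetabolicTask",
    "check_task",
    "run_tasks",
    "gene_reactions",
    "ToxicityReport",
    "toxicity_screen",
    "shortlist_targets",
    "load_tasks_tsv",
    "save_tasks_tsv",
    "BaselineError",
]

PASS, FAIL, UNTESTABLE = "pass", "fail", "untestable"


class BaselineError(RuntimeError):
    """The unmodified healthy model fails its own task battery."""


@dataclass
class TaskBound:
    metabolite: str
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower < 0 or self.lower > self.upper:
            raise ValueError(
                f"task bound for {self.metabolite!r}: need 0 <= lower <= upper"
            )


@dataclass
class MetabolicTask:
    id: str
    description: str = ""
    inputs: List[TaskBound] = field(default_factory=list)
    outputs: List[TaskBound] = field(default_factory=list)
    should_fail: bool = False


def _task_status(model: MetabolicModel, task: MetabolicTask) -> str:
    """Raw feasibility (before the should_fail inversion), or 'untestable'."""
    for tb in task.inputs + task.outputs:
        if tb.metabolite not in model.metabolites:
            return UNTESTABLE
    work = model.copy(model.id + "__task")
    # close every boundary exchange; the task supplies its own boundary
    for rxn in work.reactions.values():
        if rxn.is_exchange:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    for i, tb in enumerate(task.inputs):
        work.add_reaction(
            Reaction(f"__task_in_{i}", {tb.metabolite: 1.0}, tb.lower, tb.upper)
        )
    for i, tb in enumerate(task.outputs):
        work.add_reaction(
            Reaction(f"__task_out_{i}", {tb.metabolite: -1.0}, tb.lower, tb.upper)
        )
    problem = LPProblem(work)
    sol = problem.solve(feasibility_only=True)
    return PASS if sol.status == "optimal" else FAIL


def check_task(model: MetabolicModel, task: MetabolicTask) -> str:
    """'pass' | 'fail' | 'untestable'; a should-fail task passes when infeasible."""
    status = _task_status(model, task)
    if status == UNTESTABLE:
        return UNTESTABLE
    if task.should_fail:
        return PASS if status == FAIL else FAIL
    return status


def run_tasks(model: MetabolicModel, tasks: Sequence[MetabolicTask]) -> Dict[str, str]:
    return {t.id: check_task(model, t) for t in tasks}


def gene_reactions(model: MetabolicModel, gene: str, mode: str = "knockout") -> Set[str]:
    """Reactions coupled to ``gene``.

    ``knockout`` (default): reactions whose GPR evaluates false when the gene
    alone is knocked out — consistent with the knockout semantics used on the
    tumor side.  ``listing``: every reaction naming the gene in its GPR.
    """
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model {model.id!r}")
    if mode == "knockout":
        return {
            r.id
            for r in model.reactions.values()
            if not r.gpr.is_empty and not r.gpr.evaluate({gene})
        }
    if mode == "listing":
        return {r.id for r in model.reactions.values() if gene in r.gpr.genes}
    raise ValueError(f"unknown coupling mode {mode!r}")


@dataclass
class ToxicityReport:
    """Per-candidate task outcomes on the healthy model."""

    candidates: List[str]
    removed_reactions: Dict[str, Set[str]]
    task_results: Dict[str, Dict[str, str]]  # gene -> task id -> status
    toxic: Dict[str, bool]
    absent: Set[str]
    baseline: Dict[str, str]
    untestable_tasks: Set[str]

    @property
    def nontoxic(self) -> Set[str]:
        return {g for g in self.candidates if not self.toxic[g]}

    def to_frame(self):
        import pandas as pd

        rows = []
        for g in self.candidates:
            n_failed = sum(1 for s in self.task_results.get(g, {}).values() if s == FAIL)
            rows.append(
                {
                    "gene": g,
                    "n_reactions_removed": len(self.removed_reactions.get(g, set())),
                    "n_tasks_failed": n_failed,
                    "toxic": self.toxic[g],
                    "absent_from_model": g in self.absent,
                }
            )
        return pd.DataFrame(rows)


def toxicity_screen(
    healthy: MetabolicModel,
    tasks: Sequence[MetabolicTask],
    candidates: Iterable[str],
    coupling_mode: str = "knockout",
) -> ToxicityReport:
    """Screen candidate genes for toxicity on a healthy-tissue model.

    For each candidate independently, its coupled reactions are removed from
    the intact healthy model and the full task battery is re-run; a candidate
    is toxic iff any task fails.  The unmodified model must pass every
    testable task or the screen aborts (a model-quality error).  Candidates
    absent from the healthy model are non-toxic by definition.
    """
    candidates = sorted(set(candidates))
    baseline = run_tasks(healthy, tasks)
    untestable = {tid for tid, s in baseline.items() if s == UNTESTABLE}
    failed = [tid for tid, s in baseline.items() if s == FAIL]
    if failed:
        raise BaselineError(
            f"healthy model {healthy.id!r} fails baseline tasks: {failed}"
        )

    healthy_genes = healthy.genes
    removed: Dict[str, Set[str]] = {}
    results: Dict[str, Dict[str, str]] = {}
    toxic: Dict[str, bool] = {}
    absent: Set[str] = set()
    for gene in candidates:
        if gene not in healthy_genes:
            absent.add(gene)
            toxic[gene] = False
            removed[gene] = set()
            results[gene] = {}
            continue
        rxns = gene_reactions(healthy, gene, mode=coupling_mode)
        removed[gene] = rxns
        work = healthy.copy(healthy.id + f"__ko_{gene}")
        for rid in rxns:
            work.reactions[rid].lower_bound = 0.0
            work.reactions[rid].upper_bound = 0.0
        res = run_tasks(work, tasks)
        results[gene] = res
        toxic[gene] = any(s == FAIL for s in res.values())
    return ToxicityReport(candidates, removed, results, toxic, absent, baseline, untestable)


def shortlist_targets(
    essentiality: EssentialityResult, report: ToxicityReport
) -> List[str]:
    """Essential AND non-toxic genes, sorted by knockout growth ratio ascending."""
    essential = essentiality.essential
    screened = set(report.candidates)
    if essential and screened.isdisjoint(essential):
        raise ValueError(
            "toxicity screen covers none of the essential genes; "
            "screen/essentiality mismatch"
        )
    short = [g for g in essential if g in screened and not report.toxic[g]]
    return sorted(short, key=lambda g: (essentiality.growth_ratio[g], g))


# ---------------------------------------------------------------------------
# task list TSV: one row per constrained metabolite
# columns: task_id  description  direction(in|out)  metabolite  lower  upper  should_fail
# ---------------------------------------------------------------------------

def save_tasks_tsv(tasks: Sequence[MetabolicTask], path: Union[str, Path]) -> None:
    lines = ["task_id\tdescription\tdirection\tmetabolite\tlower\tupper\tshould_fail"]
    for t in tasks:
        for tb in t.inputs:
            lines.append(
                f"{t.id}\t{t.description}\tin\t{tb.metabolite}\t{tb.lower:g}\t{tb.upper:g}\t{int(t.should_fail)}"
            )
        for tb in t.outputs:
            lines.append(
                f"{t.id}\t{t.description}\tout\t{tb.metabolite}\t{tb.lower:g}\t{tb.upper:g}\t{int(t.should_fail)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def load_tasks_tsv(path: Union[str, Path]) -> List[MetabolicTask]:
    path = Path(path)
    tasks: Dict[str, MetabolicTask] = {}
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    expected = ["task_id", "description", "direction", "metabolite", "lower", "upper", "should_fail"]
    if header != expected:
        raise ValueError(f"{path.name}: unexpected task header {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise ValueError(f"{path.name}:{lineno}: need 7 fields")
        tid, desc, direction, met, lo, hi, sf = fields
        task = tasks.setdefault(tid, MetabolicTask(tid, desc, should_fail=bool(int(sf))))
        tb = TaskBound(met, float(lo), float(hi))
        if direction == "in":
            task.inputs.append(tb)
        elif direction == "out":
            task.outputs.append(tb)
        else:
            raise ValueError(f"{path.name}:{lineno}: direction must be in|out")
    return list(tasks.values())
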