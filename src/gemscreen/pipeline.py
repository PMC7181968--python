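"""End-to-end orchestration of the screening pipeline on a run directory.

``simulate`` materializes a synthetic input bundle (models, expression,
clinical, tasks, dependency scores, truth JSON) under a run directory;
``run`` executes the analysis stages in dependency order, each writing its
typed outputs plus a machine-readable manifest (stage, input checksums,
seed, runtime).  Reruns with identical config and inputs reproduce the
outputs: deterministic stages byte-identical, stochastic stages identical at
the fixed derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from . import cohort, coexpression, ensemble, essentiality, reporter, synthetic, tasks as tasks_mod
from .io import load_model, save_model
from .model import MetabolicModel

logger = logging.getLogger("gemscreen")

__all__ = ["PipelineConfig", "simulate", "run", "load_config"]


@dataclass
class PipelineConfig:
    """Every tunable of every stage, with the documented defaults."""

    out_dir: str = "run"
    seed: int = 0

    # synthetic bundle
    n_pathways: int = 4
    chain_len: int = 3
    n_models: int = 30
    n_variable_reactions: int = 40
    separation: int = 10
    noise: float = 0.05
    n_genes: int = 2000
    n_samples: int = 120
    de_effect: float = 2.0
    n_de_up: int = 50
    n_de_down: int = 50
    block_sizes: List[int] = field(default_factory=lambda: [8, 8, 8])
    block_rho: float = 0.99
    n_tasks: int = 8
    n_infeasible: int = 2
    n_cell_lines: int = 31
    dependency_sd: float = 0.1
    n_toxic: int = 2
    n_nontoxic: int = 3

    # analysis tunables
    alpha: float = 0.05
    de_orientation: str = cohort.HIGH_VS_LOW
    corr_cutoff: float = 0.99
    corr_mode: str = "threshold"
    walk_length: int = 4
    min_cluster_size: int = 5
    min_cluster_corr: float = 0.5
    linkage: str = "complete"
    essentiality_threshold: float = 1e-3
    coupling_mode: str = "knockout"
    remove_currency: bool = True
    n_background: int = 10000
    subnet_budget: int = 25

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def load_config(path: Union[str, Path], **overrides) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected; overrides win."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(out_dir: Path, stage: str, inputs: Sequence[Path], seed: int,
              t0: float, outputs: Sequence[Path]) -> None:
    payload = {
        "stage": stage,
        "seed": seed,
        "runtime_s": round(time.time() - t0, 3),
        "inputs": {p.name: _checksum(p) for p in inputs if p.exists()},
        "outputs": [p.name for p in outputs],
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2) + "\n")
    logger.info("stage %s done in %.2fs", stage, payload["runtime_s"])


def simulate(config: PipelineConfig) -> Path:
    """Generate the full synthetic input bundle under the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    t0 = time.time()

    tumor, healthy, task_list, scenario_truth = synthetic.generate_target_scenario(
        n_pathways=config.n_pathways,
        chain_len=config.chain_len,
        n_toxic=config.n_toxic,
        n_nontoxic=config.n_nontoxic,
        seed=config.stage_seed("scenario"),
    )
    models, ens_truth = synthetic.generate_ensemble(
        tumor,
        n_models=config.n_models,
        n_variable_reactions=config.n_variable_reactions,
        separation=config.separation,
        noise=config.noise,
        seed=config.stage_seed("ensemble"),
    )
    expr, clinical, expr_truth = synthetic.generate_expression(
        n_genes=config.n_genes,
        n_samples=config.n_samples,
        de_effect=config.de_effect,
        n_de_up=config.n_de_up,
        n_de_down=config.n_de_down,
        block_sizes=config.block_sizes,
        block_rho=config.block_rho,
        seed=config.stage_seed("expression"),
    )
    dep = synthetic.generate_dependency_matrix(
        sorted(tumor.genes),
        n_cell_lines=config.n_cell_lines,
        essential_genes=sorted(scenario_truth.essential_genes),
        sd=config.dependency_sd,
        seed=config.stage_seed("dependency"),
    )

    save_model(tumor, out / "tumor.tsv")
    save_model(healthy, out / "healthy.tsv")
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    for m in models:
        save_model(m, model_dir / f"{m.id}.tsv")
    tasks_mod.save_tasks_tsv(task_list, out / "tasks.tsv")
    expr.to_csv(out / "expression.tsv", sep="\t")
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    dep.to_csv(out / "dependency.tsv", sep="\t")
    truth = scenario_truth.merge(ens_truth).merge(expr_truth)
    truth.to_json(out / "truth.json")
    _manifest(out, "simulate", [], config.seed, t0,
              [out / "tumor.tsv", out / "healthy.tsv", out / "tasks.tsv",
               out / "expression.tsv", out / "clinical.tsv", out / "dependency.tsv",
               out / "truth.json"])
    return out


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing input {path.name}; run {produced_by!r} first"
        )
    return path


def run(config: PipelineConfig, stages: Optional[Sequence[str]] = None) -> Dict[str, object]:
    """Execute the analysis stages on a simulated (or user-provided) bundle.

    Returns a summary dict of the headline outputs per stage.
    """
    out = Path(config.out_dir)
    all_stages = ["stratify", "de", "coexpress", "distance", "merge",
                  "essential", "screen", "reporter", "validate"]
    stages = list(stages) if stages else all_stages
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    summary: Dict[str, object] = {}

    clinical = pd.read_csv(_require(out / "clinical.tsv", "stratify", "simulate"), sep="\t")
    expr = pd.read_csv(out / "expression.tsv", sep="\t", index_col=0)

    low = high = None
    if "stratify" in stages:
        t0 = time.time()
        low, high, cuts = cohort.stratify_survival(clinical)
        (out / "groups.json").write_text(json.dumps(
            {"low": low, "high": high, "cut_low": cuts[0], "cut_high": cuts[1]},
            indent=2) + "\n")
        summary["stratify"] = {"n_low": len(low), "n_high": len(high), "cuts": cuts}
        _manifest(out, "stratify", [out / "clinical.tsv"], config.seed, t0,
                  [out / "groups.json"])

    score_table = None
    if "de" in stages:
        t0 = time.time()
        groups = json.loads(_require(out / "groups.json", "de", "stratify").read_text())
        score_table = cohort.simple_de(expr, groups["low"], groups["high"])
        score_table.table.to_csv(out / "de.tsv", sep="\t", index=False)
        up, down = cohort.split_de(score_table, alpha=config.alpha)
        (out / "de_up_in_low.txt").write_text("\n".join(sorted(up)) + "\n")
        (out / "de_down_in_low.txt").write_text("\n".join(sorted(down)) + "\n")
        summary["de"] = {"n_up_in_low": len(up), "n_down_in_low": len(down)}
        _manifest(out, "de", [out / "expression.tsv", out / "groups.json"],
                  config.seed, t0, [out / "de.tsv"])

    if "coexpress" in stages:
        t0 = time.time()
        corr = coexpression.correlation_matrix(expr)
        net = coexpression.build_network(corr, cutoff=config.corr_cutoff,
                                         mode=config.corr_mode)
        clusters: List[coexpression.GeneCluster] = []
        if net.nodes:
            partition = coexpression.walktrap_communities(net, walk_length=config.walk_length)
            clusters = coexpression.filter_clusters(
                partition, corr, min_size=config.min_cluster_size,
                min_corr=config.min_cluster_corr)
        rows = [
            {"cluster": c.cluster_id, "gene": g, "mean_correlation": c.mean_correlation}
            for c in clusters for g in c.members
        ]
        pd.DataFrame(rows, columns=["cluster", "gene", "mean_correlation"]).to_csv(
            out / "coexpression_clusters.tsv", sep="\t", index=False)
        net.write_sif(out / "coexpression.sif")
        summary["coexpress"] = {"n_edges": len(net.edges), "n_clusters": len(clusters)}
        _manifest(out, "coexpress", [out / "expression.tsv"], config.seed, t0,
                  [out / "coexpression_clusters.tsv", out / "coexpression.sif"])

    models: Optional[List[MetabolicModel]] = None

    def load_ensemble() -> List[MetabolicModel]:
        model_dir = out / "models"
        _require(model_dir / ".", "distance", "simulate")
        return [load_model(p) for p in sorted(model_dir.glob("*.tsv"))]

    if "distance" in stages:
        t0 = time.time()
        models = load_ensemble()
        dm = ensemble.distance_matrix(models)
        dm.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
        g1, g2 = ensemble.top_split_clusters(dm, linkage=config.linkage)
        pd.DataFrame(
            [{"model_id": m, "cluster": 1} for m in g1]
            + [{"model_id": m, "cluster": 2} for m in g2]
        ).to_csv(out / "model_clusters.tsv", sep="\t", index=False)
        summary["distance"] = {"n_cluster1": len(g1), "n_cluster2": len(g2)}
        _manifest(out, "distance", [], config.seed, t0,
                  [out / "distance_matrix.tsv", out / "model_clusters.tsv"])

    merged = None
    if "merge" in stages:
        t0 = time.time()
        models = models or load_ensemble()
        merged = ensemble.merge_models(models, merged_id="generic")
        save_model(merged, out / "generic.tsv")
        summary["merge"] = {"n_reactions": len(merged.reactions)}
        _manifest(out, "merge", [], config.seed, t0, [out / "generic.tsv"])

    ess = None
    if "essential" in stages:
        t0 = time.time()
        merged = merged or load_model(_require(out / "generic.tsv", "essential", "merge"))
        ess = essentiality.essential_genes(
            merged, threshold=config.essentiality_threshold, use_ltm=True)
        ess.to_frame().to_csv(out / "essentiality.tsv", sep="\t", index=False)
        models = models or load_ensemble()
        consensus = essentiality.consensus_essentiality(
            models, threshold=config.essentiality_threshold)
        consensus.to_frame().to_csv(out / "consensus.tsv", sep="\t", index=False)
        summary["essential"] = {
            "n_essential": len(ess.essential),
            "n_union": len(consensus.union_set),
            "n_consensus": len(consensus.consensus_set),
        }
        _manifest(out, "essential", [out / "generic.tsv"], config.seed, t0,
                  [out / "essentiality.tsv", out / "consensus.tsv"])

    if "screen" in stages:
        t0 = time.time()
        if ess is None:
            edf = pd.read_csv(_require(out / "essentiality.tsv", "screen", "essential"), sep="\t")
            ess = essentiality.EssentialityResult(
                wild_type_growth=float("nan"),
                threshold=config.essentiality_threshold,
                ko_growth=dict(zip(edf["gene"], edf["ko_growth"])),
                growth_ratio=dict(zip(edf["gene"], edf["growth_ratio"])),
            )
        healthy = load_model(_require(out / "healthy.tsv", "screen", "simulate"))
        task_list = tasks_mod.load_tasks_tsv(_require(out / "tasks.tsv", "screen", "simulate"))
        report = tasks_mod.toxicity_screen(
            healthy, task_list, ess.essential, coupling_mode=config.coupling_mode)
        report.to_frame().to_csv(out / "toxicity.tsv", sep="\t", index=False)
        shortlist = tasks_mod.shortlist_targets(ess, report)
        (out / "shortlist.txt").write_text("\n".join(shortlist) + "\n")
        summary["screen"] = {"n_toxic": sum(report.toxic.values()),
                             "shortlist": shortlist}
        _manifest(out, "screen", [out / "healthy.tsv", out / "tasks.tsv"],
                  config.seed, t0, [out / "toxicity.tsv", out / "shortlist.txt"])

    if "reporter" in stages:
        t0 = time.time()
        merged = merged or load_model(_require(out / "generic.tsv", "reporter", "merge"))
        if score_table is None:
            df = pd.read_csv(_require(out / "de.tsv", "reporter", "de"), sep="\t")
            score_table = cohort.GeneScoreTable(df, orientation=config.de_orientation)
        graph = reporter.build_graph(merged, remove_currency=config.remove_currency)
        zmaps = {
            d: reporter.gene_z_scores(score_table, d) for d in ("up", "down")
        }
        # graph genes are model genes; synthetic expression genes are G*****:
        # keep the overlap, or fall back to a uniform-null z for model genes
        overlap = graph.genes & set(zmaps["up"])
        if not overlap:
            rng_seed = config.stage_seed("reporter-null")
            import numpy as np

            rng = np.random.default_rng(rng_seed)
            genes = sorted(graph.genes)
            pvals = rng.uniform(size=len(genes))
            zmaps = {
                "up": {g: reporter.gene_z(p, True) for g, p in zip(genes, pvals)},
                "down": {g: reporter.gene_z(p, False) for g, p in zip(genes, pvals)},
            }
        ranked = reporter.reporter_metabolites(
            graph, zmaps, n_background=config.n_background,
            seed=config.stage_seed("reporter"))
        frames = [reporter.reporter_scores_frame(v) for v in ranked.values()]
        pd.concat(frames).to_csv(out / "reporter.tsv", sep="\t", index=False)
        subnet = reporter.reporter_subnetwork(
            graph, zmaps["up"], size_budget=config.subnet_budget,
            seed=config.stage_seed("subnetwork"))
        (out / "subnetwork.json").write_text(json.dumps(
            {"genes": subnet.genes, "metabolites": subnet.metabolites,
             "score": subnet.score, "met_gene_degree": subnet.met_gene_degree},
            indent=2) + "\n")
        summary["reporter"] = {"n_metabolites": len(ranked["up"]),
                               "subnet_size": subnet.size}
        _manifest(out, "reporter", [out / "generic.tsv"], config.seed, t0,
                  [out / "reporter.tsv", out / "subnetwork.json"])

    if "validate" in stages:
        t0 = time.time()
        dep = pd.read_csv(_require(out / "dependency.tsv", "validate", "simulate"),
                          sep="\t", index_col=0)
        targets: List[str]
        if (out / "shortlist.txt").exists():
            targets = [l for l in (out / "shortlist.txt").read_text().splitlines() if l]
        elif ess is not None:
            targets = sorted(ess.essential)
        else:
            raise FileNotFoundError(
                "stage 'validate': no shortlist.txt; run 'screen' first")
        table, skipped = cohort.dependency_validation(dep, targets)
        table.to_csv(out / "validation.tsv", sep="\t", index=False)
        summary["validate"] = {
            "n_targets": len(table),
            "n_skipped": len(skipped),
            "median_of_medians": float(table["median"].median()) if len(table) else None,
        }
        _manifest(out, "validate", [out / "dependency.tsv"], config.seed, t0,
                  [out / "validation.tsv"])

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
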