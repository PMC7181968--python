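"""Metabolic-task feasibility checks and the toxicity screen."""

import pytest

from gemscreen.essentiality import essential_genes
from gemscreen.gpr import parse_gpr
from gemscreen.model import MetabolicModel, Metabolite, Reaction
from gemscreen.synthetic import generate_target_scenario, generate_tasks, generate_toy_gem
from gemscreen.tasks import (
    BaselineError, MetabolicTask, TaskBound, check_task, gene_reactions,
    load_tasks_tsv, run_tasks, save_tasks_tsv, shortlist_targets, toxicity_screen,
)


@pytest.fixture
def linear_model():
    """EX_A -(uptake)-> A -g1-> B; one producible product B."""
    m = MetabolicModel("lin", objective_id="conv")
    m.add_metabolite(Metabolite("A", "A", "e"))
    m.add_metabolite(Metabolite("B", "B", "c"))
    m.add_metabolite(Metabolite("C", "C", "c"))
    m.add_reaction(Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0))
    m.add_reaction(Reaction("conv", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, parse_gpr("g1")))
    m.add_reaction(Reaction("EX_B", {"B": -1.0}, 0.0, 1000.0))
    return m


class TestCheckTask:
    def test_unproducible_output_fails(self, linear_model):
        task = MetabolicTask("t", inputs=[TaskBound("A", 0, 10)],
                             outputs=[TaskBound("C", 0.1, 10)])
        assert check_task(linear_model, task) == "fail"

    def test_reachable_output_passes(self, linear_model):
        task = MetabolicTask("t", inputs=[TaskBound("A", 0, 10)],
                             outputs=[TaskBound("B", 0.1, 10)])
        assert check_task(linear_model, task) == "pass"

    def test_unresolvable_metabolite_untestable(self, linear_model):
        task = MetabolicTask("t", inputs=[TaskBound("ghost", 0, 10)],
                             outputs=[TaskBound("B", 0.1, 10)])
        assert check_task(linear_model, task) == "untestable"

    def test_should_fail_inverts(self, linear_model):
        task = MetabolicTask("t", inputs=[TaskBound("A", 0, 10)],
                             outputs=[TaskBound("C", 0.1, 10)], should_fail=True)
        assert check_task(linear_model, task) == "pass"

    def test_model_exchanges_closed_during_task(self, linear_model):
        # without the task input, B cannot be made even though EX_A imports A
        task = MetabolicTask("t", outputs=[TaskBound("B", 0.1, 10)])
        assert check_task(linear_model, task) == "fail"

    def test_monotone_under_reaction_removal(self):
        """A task failing on a model also fails on any sub-model."""
        import numpy as np

        model, _ = generate_toy_gem(n_pathways=3, gpr_mix=(1, 0, 0), seed=0)
        tasks, _ = generate_tasks(model, n_tasks=6, n_infeasible=2, seed=1)
        rng = np.random.default_rng(2)
        statuses = {t.id: check_task(model, t) for t in tasks}
        removable = [r for r in model.reactions if r != model.objective_id]
        for _ in range(5):
            sub = model.copy("sub")
            drop = rng.choice(removable, size=3, replace=False)
            for rid in drop:
                sub.remove_reaction(rid)
            for t in tasks:
                if t.should_fail:
                    continue
                if statuses[t.id] == "fail":
                    assert check_task(sub, t) == "fail"


class TestGeneReactions:
    def test_isozyme_gene_modes(self, linear_model):
        linear_model.reactions["conv"].gpr = parse_gpr("g1 or g2")
        assert gene_reactions(linear_model, "g1", mode="knockout") == set()
        assert gene_reactions(linear_model, "g1", mode="listing") == {"conv"}

    def test_sole_gene_both_modes(self, linear_model):
        assert gene_reactions(linear_model, "g1", mode="knockout") == {"conv"}
        assert gene_reactions(linear_model, "g1", mode="listing") == {"conv"}

    def test_complex_gene_both_modes(self, linear_model):
        linear_model.reactions["conv"].gpr = parse_gpr("g1 and g2")
        assert gene_reactions(linear_model, "g2", mode="knockout") == {"conv"}
        assert gene_reactions(linear_model, "g2", mode="listing") == {"conv"}

    def test_unknown_gene_error(self, linear_model):
        with pytest.raises(KeyError):
            gene_reactions(linear_model, "ghost")


class TestToxicityScreen:
    def test_absent_candidate_nontoxic(self, linear_model):
        task = MetabolicTask("t", inputs=[TaskBound("A", 0, 10)],
                             outputs=[TaskBound("B", 0.1, 10)])
        report = toxicity_screen(linear_model, [task], {"not_here"})
        assert report.toxic["not_here"] is False
        assert "not_here" in report.absent

    def test_route_severing_candidate_toxic(self, linear_model):
        task = MetabolicTask("t", inputs=[TaskBound("A", 0, 10)],
                             outputs=[TaskBound("B", 0.1, 10)])
        report = toxicity_screen(linear_model, [task], {"g1"})
        assert report.toxic["g1"] is True
        assert report.removed_reactions["g1"] == {"conv"}

    def test_baseline_failure_aborts(self, linear_model):
        bad = MetabolicTask("t", inputs=[TaskBound("A", 0, 10)],
                            outputs=[TaskBound("C", 0.1, 10)])
        with pytest.raises(BaselineError):
            toxicity_screen(linear_model, [bad], {"g1"})

    def test_candidate_order_irrelevant(self):
        tumor, healthy, tasks, truth = generate_target_scenario(seed=1)
        cands = sorted(truth.essential_genes)
        a = toxicity_screen(healthy, tasks, cands)
        b = toxicity_screen(healthy, tasks, cands[::-1])
        assert a.toxic == b.toxic

    def test_planted_shortlist_recovered(self):
        tumor, healthy, tasks, truth = generate_target_scenario(seed=2)
        ess = essential_genes(tumor)
        report = toxicity_screen(healthy, tasks, ess.essential)
        shortlist = shortlist_targets(ess, report)
        assert set(shortlist) == truth.essential_genes - truth.toxic_genes


class TestShortlist:
    def test_all_toxic_empty(self, linear_model):
        linear_model.reactions["EX_A"].gpr = parse_gpr("g1")  # make g1 ubiquitous
        res = essential_genes(linear_model)
        task = MetabolicTask("t", inputs=[TaskBound("A", 0, 10)],
                             outputs=[TaskBound("B", 0.1, 10)])
        report = toxicity_screen(linear_model, [task], res.essential)
        assert shortlist_targets(res, report) == []

    def test_disjoint_screen_rejected(self):
        tumor, healthy, tasks, _ = generate_target_scenario(seed=3)
        ess = essential_genes(tumor)
        report = toxicity_screen(healthy, tasks, {"unrelated"})
        with pytest.raises(ValueError, match="mismatch"):
            shortlist_targets(ess, report)

    def test_sorted_by_growth_ratio(self):
        tumor, healthy, tasks, _ = generate_target_scenario(seed=4)
        ess = essential_genes(tumor)
        report = toxicity_screen(healthy, tasks, ess.essential)
        shortlist = shortlist_targets(ess, report)
        ratios = [ess.growth_ratio[g] for g in shortlist]
        assert ratios == sorted(ratios)


def test_task_tsv_round_trip(tmp_path):
    model, _ = generate_toy_gem(n_pathways=2, gpr_mix=(1, 0, 0), seed=5)
    tasks, _ = generate_tasks(model, n_tasks=5, n_infeasible=1, seed=6)
    p = tmp_path / "tasks.tsv"
    save_tasks_tsv(tasks, p)
    again = load_tasks_tsv(p)
    assert len(again) == len(tasks)
    for t1, t2 in zip(sorted(tasks, key=lambda t: t.id),
                      sorted(again, key=lambda t: t.id)):
        assert t1.id == t2.id and t1.should_fail == t2.should_fail
        assert [(b.metabolite, b.lower, b.upper) for b in t1.inputs] == \
               [(b.metabolite, b.lower, b.upper) for b in t2.inputs]
        assert [(b.metabolite, b.lower, b.upper) for b in t1.outputs] == \
               [(b.metabolite, b.lower, b.upper) for b in t2.outputs]
    assert run_tasks(model, tasks) == run_tasks(model, again)
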