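"""Reporter metabolites: graph building, z-scores, calibration, subnetworks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gemscreen.cohort import HIGH_VS_LOW, GeneScoreTable
from gemscreen.gpr import parse_gpr
from gemscreen.model import MetabolicModel, Metabolite, Reaction
from gemscreen.reporter import (
    DEFAULT_CURRENCY_METABOLITES, GeneMetaboliteGraph, build_graph, gene_z,
    gene_z_scores, metabolite_gene_degree, reporter_metabolites,
    reporter_subnetwork,
)


def _graph(met_genes):
    return GeneMetaboliteGraph(
        {m: frozenset(gs) for m, gs in met_genes.items()}, currency_removed=False
    )


class TestBuildGraph:
    def test_default_currency_list_has_20_entries(self):
        assert len(DEFAULT_CURRENCY_METABOLITES) == 20

    def test_cofactor_stripped_from_adjacency(self):
        m = MetabolicModel("m", objective_id="r")
        for mid, name in [("atp_c", "ATP"), ("adp_c", "ADP"),
                          ("a_c", "A"), ("b_c", "B")]:
            m.add_metabolite(Metabolite(mid, name, "c"))
        m.add_reaction(
            Reaction("r", {"atp_c": -1, "a_c": -1, "adp_c": 1, "b_c": 1},
                     0, 10, parse_gpr("g"))
        )
        graph = build_graph(m, remove_currency=True)
        assert set(graph.met_genes) == {"a_c", "b_c"}
        assert graph.met_genes["a_c"] == {"g"}

    def test_no_currency_model_unchanged(self):
        m = MetabolicModel("m", objective_id="r")
        m.add_metabolite(Metabolite("x_c", "X", "c"))
        m.add_metabolite(Metabolite("y_c", "Y", "c"))
        m.add_reaction(Reaction("r", {"x_c": -1, "y_c": 1}, 0, 10, parse_gpr("g")))
        with_rm = build_graph(m, remove_currency=True)
        without = build_graph(m, remove_currency=False)
        assert with_rm.met_genes == without.met_genes

    def test_unicode_minus_and_compartment_suffix_match(self):
        m = MetabolicModel("m", objective_id="r")
        m.add_metabolite(Metabolite("hco3", "HCO3− [c]", "c"))
        m.add_metabolite(Metabolite("a", "A", "c"))
        m.add_reaction(Reaction("r", {"hco3": -1, "a": 1}, 0, 10, parse_gpr("g")))
        graph = build_graph(m, remove_currency=True)
        assert set(graph.met_genes) == {"a"}

    def test_spontaneous_reactions_contribute_no_genes(self):
        m = MetabolicModel("m", objective_id="r")
        m.add_metabolite(Metabolite("a", "A", "c"))
        m.add_metabolite(Metabolite("b", "B", "c"))
        m.add_reaction(Reaction("r", {"a": -1, "b": 1}, 0, 10))
        assert build_graph(m).met_genes == {}


class TestGeneZ:
    def test_directional_quantile(self):
        # one-directional p=0.05 -> z = Phi^{-1}(0.975)? no: p/2 = 0.025 upper tail
        assert gene_z(0.05, True) == pytest.approx(stats.norm.isf(0.025), abs=1e-9)
        assert gene_z(0.10, True) == pytest.approx(1.6449, abs=1e-4)

    def test_up_down_antisymmetric(self):
        for p in [0.001, 0.05, 0.5, 0.99]:
            assert gene_z(p, True) + gene_z(p, False) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_p(self):
        zs = [gene_z(p, True) for p in [0.001, 0.01, 0.1, 0.5, 0.9999]]
        assert zs == sorted(zs, reverse=True)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            gene_z(0.0, True)
        with pytest.raises(ValueError):
            gene_z(1.5, True)

    def test_orientation_maps_up_in_low_genes(self):
        df = pd.DataFrame(
            {"gene": ["up_g", "down_g"], "log2fc": [-2.0, 2.0], "p": [0.01, 0.01]}
        )
        table = GeneScoreTable(df, orientation=HIGH_VS_LOW)
        z_up = gene_z_scores(table, "up")
        assert z_up["up_g"] > 0 > z_up["down_g"]
        z_down = gene_z_scores(table, "down")
        assert z_down["down_g"] > 0 > z_down["up_g"]


class TestReporterMetabolites:
    def test_single_significant_neighbor_scores_near_its_z(self):
        rng = np.random.default_rng(0)
        pool = {f"bg{i}": gene_z(p, True) for i, p in enumerate(rng.uniform(size=2000))}
        pool["sig"] = gene_z(0.05, True)
        graph = _graph({"met": {"sig"}})
        scores = reporter_metabolites(graph, {"up": pool}, n_background=10000, seed=1)
        s = scores["up"][0]
        # mu_1 ~ 0, sigma_1 ~ 1 under the uniform null background
        assert s.z_corr == pytest.approx(pool["sig"], abs=0.15)

    def test_null_calibration(self):
        """Uniform-null p-values: corrected z ~ N(0,1), type-I error near 0.05."""
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(500)]
        zmap = {g: gene_z(p, True) for g, p in zip(genes, rng.uniform(size=500))}
        met_genes = {}
        for m in range(300):
            k = int(rng.integers(3, 12))
            met_genes[f"m{m}"] = set(rng.choice(genes, size=k, replace=False))
        graph = _graph(met_genes)
        scores = reporter_metabolites(graph, {"up": zmap}, n_background=10000, seed=3)["up"]
        z = np.array([s.z_corr for s in scores])
        assert abs(z.mean()) <= 3 / np.sqrt(len(z))
        assert 0.8 <= z.var() <= 1.2
        type1 = np.mean([s.p < 0.05 for s in scores])
        assert 0.03 <= type1 <= 0.07

    def test_planted_metabolite_ranks_first(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(400)]
        pvals = dict(zip(genes, rng.uniform(size=400)))
        planted = genes[:5]
        for g in planted:
            pvals[g] = 0.001
        zmap = {g: gene_z(p, True) for g, p in pvals.items()}
        met_genes = {"hot": set(planted)}
        for m in range(199):
            met_genes[f"m{m}"] = set(rng.choice(genes[5:], size=5, replace=False))
        scores = reporter_metabolites(_graph(met_genes), {"up": zmap},
                                      n_background=5000, seed=5)["up"]
        assert scores[0].metabolite == "hot"

    def test_ranking_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(100)]
        zmap = {g: float(rng.normal()) for g in genes}
        met_genes = {f"m{i}": set(rng.choice(genes, size=4, replace=False))
                     for i in range(30)}
        graph = _graph(met_genes)
        a = reporter_metabolites(graph, {"up": zmap}, n_background=2000, seed=7)["up"]
        shuffled = dict(sorted(zmap.items(), reverse=True))
        b = reporter_metabolites(graph, {"up": shuffled}, n_background=2000, seed=7)["up"]
        assert [s.metabolite for s in a] == [s.metabolite for s in b]
        assert [s.z_corr for s in a] == [s.z_corr for s in b]

    def test_zero_degree_metabolite_excluded(self):
        zmap = {"g1": 1.0}
        graph = _graph({"m1": {"g1"}, "m2": {"unscored"}})
        scores = reporter_metabolites(graph, {"up": zmap}, n_background=100, seed=8)
        assert [s.metabolite for s in scores["up"]] == ["m1"]


class TestSubnetwork:
    def test_top_star_returned(self):
        graph = _graph({"hub": {"a", "b", "c"}, "cold": {"x", "y"}})
        zmap = {"a": 3.0, "b": 2.5, "c": 2.0, "x": -1.0, "y": -2.0}
        sub = reporter_subnetwork(graph, zmap, size_budget=5, seed=0)
        assert set(sub.genes) == {"a", "b", "c"}
        assert "hub" in sub.metabolites

    def test_budget_one_single_best_gene(self):
        graph = _graph({"m1": {"a", "b"}, "m2": {"b", "c"}})
        zmap = {"a": 1.0, "b": 5.0, "c": 0.5}
        sub = reporter_subnetwork(graph, zmap, size_budget=1, seed=0)
        assert sub.genes == ["b"]
        assert set(sub.metabolites) == {"m1", "m2"}

    def test_planted_cluster_recovered(self):
        """A connected high-z cluster in a null background is recovered with
        node recall >= 0.9 across seeds."""
        rng = np.random.default_rng(9)
        hot_genes = [f"hot{i}" for i in range(8)]
        bg_genes = [f"bg{i}" for i in range(80)]
        met_genes = {}
        for i in range(7):  # chain of metabolites connecting hot genes
            met_genes[f"hm{i}"] = {hot_genes[i], hot_genes[i + 1]}
        for m in range(40):
            met_genes[f"bm{m}"] = set(rng.choice(bg_genes, size=3, replace=False))
        # weak bridge between hot cluster and background
        met_genes["bridge"] = {hot_genes[0], bg_genes[0]}
        zmap = {g: 3.0 for g in hot_genes}
        zmap.update({g: float(rng.normal()) for g in bg_genes})
        recalls = []
        for seed in range(20):
            sub = reporter_subnetwork(_graph(met_genes), zmap, size_budget=10, seed=seed)
            recalls.append(len(set(sub.genes) & set(hot_genes)) / len(hot_genes))
        assert np.mean(recalls) >= 0.9

    def test_degree_recount(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(30)]
        met_genes = {f"m{i}": set(rng.choice(genes, size=4, replace=False))
                     for i in range(15)}
        zmap = {g: float(rng.normal()) for g in genes}
        sub = reporter_subnetwork(_graph(met_genes), zmap, size_budget=10, seed=1)
        for met in sub.metabolites:
            brute = sum(1 for g in sub.genes if g in met_genes[met])
            assert metabolite_gene_degree(sub, met) == brute
            assert brute <= len(met_genes[met])
        with pytest.raises(KeyError):
            metabolite_gene_degree(sub, "ghost")
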