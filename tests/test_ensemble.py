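"""Hamming distances, top-split clustering, ensemble merging."""

import itertools

import numpy as np
import pytest

from gemscreen.ensemble import (
    DistanceMatrix, MergeConflictError, distance_matrix, hamming_distance,
    merge_models, top_split_clusters,
)
from gemscreen.fba import fba
from gemscreen.model import MetabolicModel, Metabolite, Reaction
from gemscreen.synthetic import generate_ensemble, generate_toy_gem


def _presence_model(mid, rxn_ids):
    m = MetabolicModel(mid, objective_id=rxn_ids[0])
    m.add_metabolite(Metabolite("A", "A", "c"))
    m.add_reaction(Reaction(rxn_ids[0], {"A": 1.0}, 0, 10))
    for rid in rxn_ids[1:]:
        m.add_reaction(Reaction(rid, {"A": -1.0}, 0, 10))
    return m


class TestHamming:
    def test_identical_models_zero(self):
        a = _presence_model("a", ["r1", "r2", "r3"])
        b = _presence_model("b", ["r1", "r2", "r3"])
        assert hamming_distance(a, b) == 0

    def test_symmetric_difference_count(self):
        a = _presence_model("a", ["a", "b", "c"])
        b = _presence_model("b", ["b", "d"])
        assert hamming_distance(a, b) == 3

    def test_matches_bit_vector_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"r{i}" for i in range(1, 30)]
        for trial in range(20):
            bits_a = rng.random(len(universe)) < 0.5
            bits_b = rng.random(len(universe)) < 0.5
            a = _presence_model("a", ["obj"] + [r for r, p in zip(universe, bits_a) if p])
            b = _presence_model("b", ["obj"] + [r for r, p in zip(universe, bits_b) if p])
            assert hamming_distance(a, b) == int(np.sum(bits_a != bits_b))


class TestDistanceMatrix:
    def test_two_identical(self):
        models = [_presence_model("a", ["r1"]), _presence_model("b", ["r1"])]
        dm = distance_matrix(models)
        assert dm.values.tolist() == [[0, 0], [0, 0]]

    def test_symmetry_and_metric(self):
        base, _ = generate_toy_gem(n_pathways=2, seed=1)
        models, _ = generate_ensemble(base, n_models=8, n_variable_reactions=20,
                                      separation=6, noise=0.2, seed=2)
        dm = distance_matrix(models)
        D = dm.values
        assert (D == D.T).all()
        assert (np.diag(D) == 0).all()
        for i, j, k in itertools.permutations(range(8), 3):
            assert D[i, k] <= D[i, j] + D[j, k]

    def test_duplicate_ids_rejected(self):
        models = [_presence_model("a", ["r1"]), _presence_model("a", ["r2"])]
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix(models)


class TestTopSplit:
    def test_noise_free_exact_recovery(self):
        base, _ = generate_toy_gem(n_pathways=2, seed=1)
        models, truth = generate_ensemble(base, n_models=10, n_variable_reactions=20,
                                          separation=10, noise=0.0, seed=3)
        g1, g2 = top_split_clusters(distance_matrix(models))
        labels = truth.model_cluster_labels
        assert len({labels[m] for m in g1}) == 1
        assert len({labels[m] for m in g2}) == 1
        assert {labels[g1[0]], labels[g2[0]]} == {1, 2}

    def test_all_zero_matrix_degenerate_tie_break(self):
        """Under lower-index-first merging the final merge attaches the last
        model, so the degenerate split is singleton-vs-rest."""
        dm = DistanceMatrix([f"m{i}" for i in range(5)], np.zeros((5, 5), dtype=int))
        g1, g2 = top_split_clusters(dm)
        assert g1 == ["m0", "m1", "m2", "m3"]
        assert g2 == ["m4"]

    def test_noisy_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        base, _ = generate_toy_gem(n_pathways=2, seed=1)
        models, truth = generate_ensemble(base, n_models=30, n_variable_reactions=40,
                                          separation=10, noise=0.05, seed=4)
        g1, g2 = top_split_clusters(distance_matrix(models))
        found = {m: 1 for m in g1} | {m: 2 for m in g2}
        ids = [m.id for m in models]
        ari = adjusted_rand_score(
            [truth.model_cluster_labels[i] for i in ids], [found[i] for i in ids]
        )
        assert ari == 1.0

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_matches_scipy_on_distinct_distances(self, linkage):
        from scipy.cluster.hierarchy import cut_tree
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        n = 12
        # distinct pairwise distances -> no ties, both routes must agree
        vals = rng.permutation(np.arange(1, n * (n - 1) // 2 + 1)).astype(float)
        D = squareform(vals)
        dm = DistanceMatrix([f"m{i}" for i in range(n)], D.astype(int))
        g1, g2 = top_split_clusters(dm, linkage=linkage)
        Z = scipy_linkage(vals, method=linkage)
        labels = cut_tree(Z, n_clusters=2).ravel()
        ours = {f"m{i}": (1 if f"m{i}" in g1 else 2) for i in range(n)}
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, [ours[f"m{i}"] for i in range(n)]) == 1.0


class TestMerge:
    def test_merge_single_is_identity(self):
        model, _ = generate_toy_gem(n_pathways=2, seed=6)
        merged = merge_models([model])
        assert set(merged.reactions) == set(model.reactions)
        assert merged.objective_id == model.objective_id
        assert fba(merged).objective_value == pytest.approx(
            fba(model).objective_value, abs=1e-8
        )

    def test_merge_keeps_both_variants(self):
        base, _ = generate_toy_gem(n_pathways=2, seed=7)
        models, _ = generate_ensemble(base, n_models=4, n_variable_reactions=10,
                                      separation=5, noise=0.3, seed=8)
        merged = merge_models(models)
        union = set().union(*(set(m.reactions) for m in models))
        assert set(merged.reactions) == union
        for m in models:
            assert set(m.reactions) <= set(merged.reactions)

    def test_merge_order_invariant(self):
        base, _ = generate_toy_gem(n_pathways=2, seed=9)
        models, _ = generate_ensemble(base, n_models=5, n_variable_reactions=10,
                                      separation=5, noise=0.3, seed=10)
        a = merge_models(models)
        b = merge_models(models[::-1])
        assert list(a.reactions) == list(b.reactions)
        for rid in a.reactions:
            ra, rb = a.reactions[rid], b.reactions[rid]
            assert (ra.lower_bound, ra.upper_bound) == (rb.lower_bound, rb.upper_bound)
            assert ra.gpr.to_string() == rb.gpr.to_string()

    def test_objective_dominance(self):
        """Merged wild-type growth >= every member's (fluxes extend by zeros)."""
        base, _ = generate_toy_gem(n_pathways=3, seed=11)
        models, _ = generate_ensemble(base, n_models=6, n_variable_reactions=15,
                                      separation=7, noise=0.2, seed=12)
        merged = merge_models(models)
        merged_growth = fba(merged).objective_value
        for m in models:
            assert merged_growth >= fba(m).objective_value - 1e-8

    def test_gpr_or_union(self):
        a = _presence_model("a", ["obj", "r"])
        b = _presence_model("b", ["obj", "r"])
        a.reactions["r"].gpr = __import__("gemscreen.gpr", fromlist=["parse_gpr"]).parse_gpr("g1")
        b.reactions["r"].gpr = __import__("gemscreen.gpr", fromlist=["parse_gpr"]).parse_gpr("g2")
        merged = merge_models([a, b])
        rule = merged.reactions["r"].gpr
        assert rule.evaluate({"g1"}) and rule.evaluate({"g2"})
        assert not rule.evaluate({"g1", "g2"})

    def test_conflicting_stoichiometry_rejected(self):
        a = _presence_model("a", ["obj", "r"])
        b = _presence_model("b", ["obj", "r"])
        b.reactions["r"].stoichiometry = {"A": -2.0}
        with pytest.raises(MergeConflictError, match="r"):
            merge_models([a, b])
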