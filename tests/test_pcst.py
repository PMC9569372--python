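import pytest

from regforest import pcst
from regforest.pcst import (ForestValidationError, PCSTInstance, SteinerForest,
                            Tree, pcst_objective, solve_exact, solve_pcsf,
                            strong_prune, write_forest)
from regforest.synthetic import gen_small_pcst_instance


def forest_of(instance, *node_edge_pairs):
    trees = [Tree(nodes=frozenset(nodes), edges=tuple(edges))
             for nodes, edges in node_edge_pairs]
    f = SteinerForest(trees=trees, objective=0.0)
    f.objective = pcst_objective(instance, f)
    return f


class TestObjective:
    def test_empty_forest_forfeits_all_prizes(self, path_instance):
        f = SteinerForest(trees=[], objective=0.0)
        assert pcst_objective(path_instance, f) == pytest.approx(10.0)

    def test_full_path(self, path_instance):
        f = forest_of(path_instance,
                      ({"A", "B", "C"}, [("A", "B"), ("B", "C")]))
        assert pcst_objective(path_instance, f) == pytest.approx(2.0)

    def test_single_node_tree(self, path_instance):
        f = forest_of(path_instance, ({"A"}, []))
        assert pcst_objective(path_instance, f) == pytest.approx(5.0)

    def test_unknown_edge_rejected(self, path_instance):
        f = SteinerForest(trees=[Tree(nodes=frozenset({"A", "C"}),
                                      edges=(("A", "C"),))], objective=0.0)
        with pytest.raises(ForestValidationError):
            pcst_objective(path_instance, f)


class TestSolveExact:
    def test_zero_prizes_give_empty_forest(self):
        inst = PCSTInstance(nodes=["A", "B"], edges={("A", "B"): 1.0},
                            prizes={}, omega=1.0)
        f = solve_exact(inst)
        assert f.n_trees == 0
        assert f.objective == pytest.approx(0.0)

    def test_path_optimum_is_full_path(self, path_instance):
        f = solve_exact(path_instance)
        assert f.sort_key() == [["A", "B", "C"]]
        assert f.objective == pytest.approx(2.0)

    def test_expensive_star_stays_empty(self):
        nodes = ["C0", "L1", "L2", "L3", "L4"]
        inst = PCSTInstance(nodes=nodes,
                            edges={("C0", leaf): 10.0 for leaf in nodes[1:]},
                            prizes={v: 1.0 for v in nodes}, omega=1.0)
        f = solve_exact(inst)
        assert f.n_trees == 0
        assert f.objective == pytest.approx(5.0)

    def test_size_cap(self):
        nodes = [f"v{i}" for i in range(16)]
        inst = PCSTInstance(nodes=nodes,
                            edges={(f"v{i}", f"v{i+1}"): 1.0 for i in range(15)},
                            prizes={}, omega=1.0)
        with pytest.raises(ValueError, match="solve_pcsf"):
            solve_exact(inst, max_nodes=15)


class TestStrongPrune:
    def test_zero_prize_leaf_removed(self):
        tree = Tree(nodes=frozenset({"r", "x"}), edges=(("r", "x"),))
        pruned = strong_prune(tree, {"r": 5.0}, {("r", "x"): 1.0})
        assert set(pruned.nodes) == {"r"}

    def test_profitable_tree_is_fixed_point(self):
        tree = Tree(nodes=frozenset({"r", "a", "b"}),
                    edges=(("a", "r"), ("a", "b")))
        prizes = {"r": 2.0, "a": 2.0, "b": 2.0}
        costs = {("a", "r"): 1.0, ("a", "b"): 1.0}
        once = strong_prune(tree, prizes, costs)
        assert once.nodes == tree.nodes
        again = strong_prune(once, prizes, costs)
        assert again.nodes == once.nodes and again.edges == once.edges

    def test_chain_prunes_every_unprofitable_subtree(self):
        # r(5) -1- a(0) -3- b(2): b's prize cannot pay its edge, and once b
        # is gone neither can a's, so only r survives.
        tree = Tree(nodes=frozenset({"r", "a", "b"}),
                    edges=(("a", "r"), ("a", "b")))
        pruned = strong_prune(tree, {"r": 5.0, "b": 2.0},
                              {("a", "r"): 1.0, ("a", "b"): 3.0})
        assert set(pruned.nodes) == {"r"}

    def test_objective_never_increases(self):
        inst = gen_small_pcst_instance(n_nodes=9, topology="random", seed=5)
        full = solve_pcsf(inst, pruning="none")
        pruned = solve_pcsf(inst, pruning="strong")
        assert pruned.objective <= full.objective + 1e-9

    def test_non_tree_input_rejected(self):
        bad = Tree(nodes=frozenset({"a", "b", "c"}),
                   edges=(("a", "b"), ("b", "c"), ("a", "c")))
        with pytest.raises(ForestValidationError):
            strong_prune(bad, {}, {("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1})


class TestSolvePCSF:
    def test_matches_oracle_on_path(self, path_instance):
        inst = PCSTInstance(nodes=path_instance.nodes, edges=path_instance.edges,
                            prizes=path_instance.prizes, omega=5.0)
        assert solve_pcsf(inst).sort_key() == solve_exact(inst).sort_key()

    def test_two_profitable_components_make_two_trees(self):
        edges = {("A", "B"): 0.5, ("C", "D"): 0.5, ("B", "C"): 100.0}
        inst = PCSTInstance(nodes=["A", "B", "C", "D"], edges=edges,
                            prizes={"A": 3.0, "B": 3.0, "C": 3.0, "D": 3.0},
                            omega=1.0)
        f = solve_pcsf(inst)
        assert f.n_trees == 2
        assert f.sort_key() == [["A", "B"], ["C", "D"]]
        assert solve_exact(inst).sort_key() == f.sort_key()

    def test_omega_above_total_prize_gives_empty_forest(self, path_instance):
        f = solve_pcsf(path_instance, omega=11.0)
        assert f.n_trees == 0

    def test_deterministic_serialization(self, tmp_path):
        inst = gen_small_pcst_instance(n_nodes=10, topology="random", seed=9)
        for run in ("a", "b"):
            paths = write_forest(solve_pcsf(inst), inst, tmp_path / run)
        a = (tmp_path / "a.forest.tsv").read_bytes()
        b = (tmp_path / "b.forest.tsv").read_bytes()
        assert a == b
        assert (tmp_path / "a.manifest.json").read_bytes() == \
               (tmp_path / "b.manifest.json").read_bytes()


def omega_objective(instance, forest):
    return forest.objective + instance.omega * forest.n_trees


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_factor_two_and_validity(self, seed):
        topo = ["path", "star", "random"][seed % 3]
        inst = gen_small_pcst_instance(n_nodes=4 + seed % 9, topology=topo,
                                       seed=seed)
        exact = solve_exact(inst)
        heur = solve_pcsf(inst)
        # validity: recomputing the objective runs the full forest checks
        assert pcst_objective(inst, heur) == pytest.approx(heur.objective,
                                                           abs=1e-9)
        oe, oh = omega_objective(inst, exact), omega_objective(inst, heur)
        if oe > 1e-12:
            assert oh / oe <= 2.0
        else:
            assert oh <= 1e-12


class TestMonotonicity:
    def test_collected_prize_nondecreasing_in_beta(self):
        for seed in (1, 2, 3):
            inst = gen_small_pcst_instance(n_nodes=8, topology="random",
                                           seed=seed)
            prev = -1.0
            for beta in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0):
                scaled = PCSTInstance(
                    nodes=inst.nodes, edges=inst.edges,
                    prizes={k: v * beta for k, v in inst.prizes.items()},
                    omega=inst.omega)
                f = solve_exact(scaled)
                collected = sum(inst.prizes.get(v, 0.0) for v in f.node_set())
                assert collected >= prev - 1e-9
                prev = collected

    def test_tree_count_nonincreasing_in_omega(self):
        for seed in (1, 2, 3, 4):
            inst = gen_small_pcst_instance(n_nodes=9, topology="random",
                                           seed=seed)
            prev = len(inst.nodes)
            for omega in (0.1, 0.3, 1.0, 3.0, 10.0, 30.0):
                redo = PCSTInstance(nodes=inst.nodes, edges=inst.edges,
                                    prizes=inst.prizes, omega=omega)
                f = solve_exact(redo)
                assert f.n_trees <= prev
                prev = f.n_trees


class TestInstanceValidation:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            PCSTInstance(nodes=["A"], edges={("A", "A"): 1.0}, prizes={})
        with pytest.raises(ValueError):
            PCSTInstance(nodes=["A", "B"], edges={("A", "B"): 0.0}, prizes={})
        with pytest.raises(ValueError):
            PCSTInstance(nodes=["A", "B"], edges={}, prizes={"A": -1.0})
        with pytest.raises(ValueError):
            PCSTInstance(nodes=["A"], edges={}, prizes={}, omega=0.0)

    def test_instance_roundtrip(self, tmp_path):
        inst = gen_small_pcst_instance(n_nodes=7, topology="random", seed=3)
        pcst.write_instance(inst, tmp_path / "inst")
        back = pcst.read_instance(tmp_path / "inst", omega=inst.omega)
        assert back.nodes == inst.nodes
        assert back.edges.keys() == inst.edges.keys()
        for k in inst.edges:
            assert back.edges[k] == pytest.approx(inst.edges[k], abs=1e-12)
        for v in inst.nodes:
            assert back.prize(v) == pytest.approx(inst.prize(v), abs=1e-12)
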