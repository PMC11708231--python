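"""Coalescent simulator: model validation, gene trees, pattern sampling."""

import math

import numpy as np
import pytest
from scipy.stats import binomtest

from deltastats.patterns import PATTERNS
from deltastats.simulator import (
    AdmixtureGraphModel,
    GeneFlowEdge,
    GeneTree,
    GeneTreeNode,
    branch_intervals,
    build_scenario_model,
    drop_mutations,
    simulate_gene_tree,
    simulate_pattern_counts,
)
from deltastats.predictions import enumerate_nonzero_events
from deltastats.statistics import BINOMIALS, compute_panel


class TestModelValidation:
    def test_defaults_valid(self):
        for shape in "SAQ":
            AdmixtureGraphModel(shape=shape)

    def test_unknown_shape(self):
        with pytest.raises(ValueError):
            AdmixtureGraphModel(shape="Z")

    def test_node_order_enforced(self):
        with pytest.raises(ValueError, match="increase"):
            AdmixtureGraphModel(shape="S", node_times={"12": 2.5, "1234": 2.0})

    def test_beta_range(self):
        with pytest.raises(ValueError, match="beta"):
            AdmixtureGraphModel(
                shape="S",
                edges=[GeneFlowEdge(source="1", target="3", time=0.5, beta=1.5)],
            )

    def test_admixture_time_in_target_branch(self):
        with pytest.raises(ValueError, match="outside target"):
            AdmixtureGraphModel(
                shape="S", edges=[GeneFlowEdge(source="5", target="1", time=1.5)]
            )

    def test_ghost_needed_when_source_absent(self):
        with pytest.raises(ValueError, match="ghost"):
            AdmixtureGraphModel(
                shape="S", edges=[GeneFlowEdge(source="1234", target="1", time=0.5)]
            )
        AdmixtureGraphModel(
            shape="S",
            edges=[GeneFlowEdge(source="1234", target="1", time=0.5, ghost_join=2.5)],
        )

    def test_sampling_time_within_branch(self):
        AdmixtureGraphModel(shape="S", sampling_times={"2": 0.5})
        with pytest.raises(ValueError, match="sampling"):
            AdmixtureGraphModel(shape="S", sampling_times={"2": 1.5})

    def test_yaml_roundtrip(self, tmp_path):
        model = AdmixtureGraphModel(
            shape="Q",
            sampling_times={"3": 0.25},
            edges=[GeneFlowEdge(source="123", target="2", time=0.4, ghost_join=2.4)],
        )
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = AdmixtureGraphModel.from_yaml(path)
        assert back.to_dict() == model.to_dict()


class TestScenarioModels:
    def test_all_nonzero_events_realizable(self):
        for tree in "SAQ":
            for event in enumerate_nonzero_events(tree):
                model = build_scenario_model(tree, event)
                assert model.edges[0].beta == 0.1
                model.compile_events()

    def test_instantaneous_when_branches_overlap(self):
        model = build_scenario_model("S", "5->1")
        assert model.edges[0].ghost_join is None

    def test_ghost_when_source_deeper(self):
        model = build_scenario_model("S", "34->2")
        edge = model.edges[0]
        assert edge.ghost_join is not None
        assert edge.time < 1.0 < edge.ghost_join < 2.0

    def test_source_branch_stretched_when_needed(self):
        # 3->12 in S: terminal branch 3 must outlive the start of branch 12
        model = build_scenario_model("S", "3->12")
        assert model.node_times["34"] == pytest.approx(1.8)
        iv = branch_intervals("S", model.node_times)
        t_a = model.edges[0].time
        assert iv["3"][0] < t_a < iv["3"][1]
        assert iv["12"][0] < t_a < iv["12"][1]


class TestGeneTrees:
    def test_kingman_total_length(self, rng):
        # nearly-degenerate node times put all five lineages in one population;
        # E[total length] = sum_{k=2..5} 2/(k-1) = 25/6
        model = AdmixtureGraphModel(
            shape="S", node_times={"12": 1e-6, "34": 1e-6, "1234": 2e-6, "root": 3e-6}
        )
        lengths = [
            simulate_gene_tree(model, rng).total_branch_length for _ in range(2000)
        ]
        se = np.std(lengths) / math.sqrt(len(lengths))
        assert abs(np.mean(lengths) - 25 / 6) < 4 * se + 1e-4

    def test_leaf_times_respect_sampling_times(self, rng):
        model = AdmixtureGraphModel(shape="S", sampling_times={"2": 0.5})
        tree = simulate_gene_tree(model, rng)

        def leaf_times(node, acc):
            if node.leaf is not None:
                acc[node.leaf] = node.time
            for c in node.children:
                leaf_times(c, acc)
            return acc

        times = leaf_times(tree.root, {})
        assert times[1] == 0.5 and all(times[i] == 0.0 for i in (0, 2, 3, 4))

    def test_null_topology_symmetry(self, rng):
        # P(((1,3),(2,4)),5) = P(((2,3),(1,4)),5) under the null S model
        model = AdmixtureGraphModel(shape="S")
        n_a = n_b = 0
        for _ in range(3000):
            masks = {m for m, _ in simulate_gene_tree(model, rng).edges()}
            if 0b00101 in masks and 0b01010 in masks:  # {1,3} and {2,4}
                n_a += 1
            elif 0b00110 in masks and 0b01001 in masks:  # {2,3} and {1,4}
                n_b += 1
        assert n_a + n_b > 50
        assert binomtest(n_a, n_a + n_b, 0.5).pvalue > 1e-3

    def test_newick_well_formed(self, rng):
        tree = simulate_gene_tree(AdmixtureGraphModel(shape="A"), rng)
        nwk = tree.newick()
        assert nwk.endswith(");") and all(str(i) in nwk for i in range(1, 6))


class TestDropMutations:
    def _star(self):
        leaves = [GeneTreeNode(time=0.0, leaf=i) for i in range(5)]
        return GeneTree(root=GeneTreeNode(time=1.0, children=tuple(leaves)))

    def test_star_tree_yields_uniform_singletons(self, rng):
        tree = self._star()
        pats = drop_mutations(tree, mu=200.0, rng=rng)
        assert len(pats) > 500
        assert all(p.count("B") == 1 for p in pats)
        counts = {p: pats.count(p) for p in set(pats)}
        assert len(counts) == 5
        assert max(counts.values()) < 2 * min(counts.values())

    def test_cherry_branch_yields_doubleton(self, rng):
        cherry = GeneTreeNode(
            time=1.0,
            children=(GeneTreeNode(0.0, leaf=0), GeneTreeNode(0.0, leaf=1)),
        )
        # make the internal {1,2} edge overwhelmingly long
        top = GeneTreeNode(time=100.0, children=(cherry, GeneTreeNode(99.9, leaf=2)))
        mid = GeneTreeNode(time=100.1, children=(top, GeneTreeNode(100.0, leaf=3)))
        root = GeneTreeNode(time=100.2, children=(mid, GeneTreeNode(100.1, leaf=4)))
        pats = drop_mutations(GeneTree(root=root), mu=1.0, rng=rng)
        assert pats and pats.count("BBAAA") / len(pats) > 0.9

    def test_zero_mutations_empty(self, rng):
        assert drop_mutations(self._star(), mu=1e-9, rng=rng) == []


class TestPatternCounts:
    def test_reproducible_under_seed(self):
        model = AdmixtureGraphModel(shape="S")
        a = simulate_pattern_counts(model, 5000, 77).as_array()
        b = simulate_pattern_counts(model, 5000, 77).as_array()
        c = simulate_pattern_counts(model, 5000, 78).as_array()
        assert (a == b).all() and not (a == c).all()

    def test_total_equals_requested(self):
        pc = simulate_pattern_counts(AdmixtureGraphModel(shape="Q"), 4000, 3)
        assert pc.total() == 4000 == pc.n_sites_retained

    def test_beta_zero_edge_equals_no_edge(self):
        null = AdmixtureGraphModel(shape="S")
        noop = AdmixtureGraphModel(
            shape="S", edges=[GeneFlowEdge(source="1", target="3", time=0.5, beta=0.0)]
        )
        a = simulate_pattern_counts(null, 20000, 5).as_array()
        b = simulate_pattern_counts(noop, 20000, 5).as_array()
        assert (a == b).all()

    def test_equal_probability_sets_balanced_under_null(self):
        # exact binomial test per tree-S equal probability pair at level 0.001
        pc = simulate_pattern_counts(AdmixtureGraphModel(shape="S"), 100000, 11)
        for name in ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8"):
            left, right = BINOMIALS[name]
            nl, nr = int(pc[left]), int(pc[right])
            assert binomtest(nl, nl + nr, 0.5).pvalue > 1e-3, name

    def test_kernel_agrees_with_python_walk(self, rng):
        # length-weighted pattern proportions from the reference walk vs the
        # size-biased kernel sampler
        model = AdmixtureGraphModel(shape="S")
        mass = np.zeros(len(PATTERNS))
        from deltastats.simulator import _MASK_TO_ROW

        for _ in range(3000):
            for mask, length in simulate_gene_tree(model, rng).edges():
                row = _MASK_TO_ROW[mask]
                if row >= 0:
                    mass[row] += length
        expected = mass / mass.sum()
        observed = simulate_pattern_counts(model, 50000, 13).as_array()
        observed /= observed.sum()
        assert np.max(np.abs(observed - expected)) < 0.02

    def test_admixture_shifts_the_right_patterns(self):
        # 1->3 pulls lineage 3 into population 1: BABAA inflates over BAABA
        model = build_scenario_model("S", "1->3")
        pc = simulate_pattern_counts(model, 100000, 17)
        assert pc["BABAA"] > 1.2 * pc["BAABA"]
        panel = compute_panel(pc, "S", include_singletons=False)
        assert panel.classifications == ("+", "+", "+", "0")


class TestMsprimeOracle:
    def test_null_pattern_distribution_matches_msprime(self):
        # independent structured-coalescent implementation of the null S model
        msprime = pytest.importorskip("msprime")
        from deltastats.simulator import _MASK_TO_ROW

        dem = msprime.Demography()
        for name in ("p1", "p2", "p3", "p4", "p5", "p12", "p34", "p1234", "p12345"):
            dem.add_population(name=name, initial_size=1.0)
        dem.add_population_split(time=1.0, derived=["p1", "p2"], ancestral="p12")
        dem.add_population_split(time=1.0, derived=["p3", "p4"], ancestral="p34")
        dem.add_population_split(time=2.0, derived=["p12", "p34"], ancestral="p1234")
        dem.add_population_split(time=3.0, derived=["p1234", "p5"], ancestral="p12345")
        samples = [
            msprime.SampleSet(1, population=f"p{i}", ploidy=1) for i in range(1, 6)
        ]
        mass = np.zeros(len(PATTERNS))
        reps = msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=1,
            sequence_length=1, num_replicates=4000, random_seed=99,
        )
        for ts in reps:
            tree = ts.first()
            for u in tree.nodes():
                parent = tree.parent(u)
                if parent == -1:
                    continue
                mask = 0
                for leaf in tree.leaves(u):
                    mask |= 1 << leaf
                row = _MASK_TO_ROW[mask]
                if row >= 0:
                    mass[row] += tree.time(parent) - tree.time(u)
        expected = mass / mass.sum()
        observed = simulate_pattern_counts(
            AdmixtureGraphModel(shape="S"), 100000, 23
        ).as_array()
        observed /= observed.sum()
        assert np.max(np.abs(observed - expected)) < 0.02
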