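import itertools

import networkx as nx
import numpy as np
import pytest

import orthotree as ot
from orthotree.species_overlap import OrthologPairSet
from orthotree.tree_io import OrthotreeError

from conftest import run_inference, simulate_tree


def pair_set(records):
    ps = OrthologPairSet()
    for g1, g2, s in records:
        ps.add(g1, g2, mrca_id=0, support=s)
    return ps


# ---------------------------------------------------------------------------
# Independent dense-numpy MCL used as oracle for the sparse implementation.
# ---------------------------------------------------------------------------

def dense_mcl(adj, inflation, loops=1.0, iters=300):
    m = np.array(adj, dtype=float)
    np.fill_diagonal(m, loops)
    m = m / m.sum(axis=0)
    for _ in range(iters):
        prev = m
        m = np.linalg.matrix_power(m, 2) ** inflation
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < 1e-9:
            break
    clusters = set()
    for i in range(len(m)):
        if m[i, i] > 1e-8:
            clusters.add(frozenset(np.flatnonzero(m[i] > 1e-8)))
    return clusters


class TestBuildGraph:
    def test_edges_and_nodes(self):
        ps = pair_set([("A_x1", "B_y1", 0.9), ("A_x2", "B_y2", 0.8)])
        g = ot.build_graph(ps, ["A_x1", "B_y1", "A_x2", "B_y2"])
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 2
        assert g["A_x1"]["B_y1"]["weight"] == 0.9

    def test_min_support_prunes_and_keeps_isolated_nodes(self):
        ps = pair_set([("A_x1", "B_y1", 0.9), ("A_x2", "B_y2", 0.8)])
        g = ot.build_graph(ps, ["A_x1", "B_y1", "A_x2", "B_y2"],
                           min_support=0.85)
        assert g.number_of_edges() == 1
        assert g.degree["A_x2"] == 0 and g.degree["B_y2"] == 0

    def test_pruning_keeps_edges_exactly_at_threshold(self):
        ps = pair_set([("A_x1", "B_y1", 0.8)])
        g = ot.build_graph(ps, ["A_x1", "B_y1"], min_support=0.8)
        assert g.number_of_edges() == 1

    def test_unweighted_mode(self):
        ps = pair_set([("A_x1", "B_y1", 0.9)])
        g = ot.build_graph(ps, ["A_x1", "B_y1"], weighted=False)
        assert g["A_x1"]["B_y1"]["weight"] == 1.0

    def test_missing_support_counts_as_one(self):
        ps = pair_set([("A_x1", "B_y1", None)])
        g = ot.build_graph(ps, ["A_x1", "B_y1"], min_support=0.99)
        assert g.number_of_edges() == 1


class TestMCL:
    def test_disconnected_cliques(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        for inflation in (1.2, 1.6, 2.0):
            assert sorted(map(sorted, ot.mcl(adj, inflation=inflation))) == [
                [0, 1], [2, 3]]

    def test_weak_bridge_between_cliques_matches_oracle(self):
        g = nx.Graph()
        for u, v in itertools.combinations(range(3), 2):
            g.add_edge(u, v, weight=1.0)
        for u, v in itertools.combinations(range(3, 6), 2):
            g.add_edge(u, v, weight=1.0)
        g.add_edge(2, 3, weight=0.1)
        adj = nx.to_numpy_array(g, weight="weight")
        got = {frozenset(c) for c in ot.mcl(adj, inflation=1.6)}
        assert got == dense_mcl(adj, 1.6)
        assert got == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_k4_single_cluster_matches_oracle(self):
        adj = nx.to_numpy_array(nx.complete_graph(4))
        got = {frozenset(c) for c in ot.mcl(adj, inflation=1.6)}
        assert got == dense_mcl(adj, 1.6) == {frozenset(range(4))}

    def test_invalid_matrices_rejected(self):
        with pytest.raises(OrthotreeError, match="square"):
            ot.mcl(np.zeros((2, 3)))
        with pytest.raises(OrthotreeError, match="nonnegative"):
            ot.mcl(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_partition_covers_all_nodes(self):
        adj = nx.to_numpy_array(nx.erdos_renyi_graph(12, 0.3, seed=5))
        clusters = ot.mcl(adj, inflation=1.6)
        flat = sorted(i for c in clusters for i in c)
        assert flat == list(range(12))

    def test_permutation_equivariance_on_clique_graphs(self):
        adj = np.zeros((5, 5))
        for u, v in itertools.combinations(range(3), 2):
            adj[u, v] = adj[v, u] = 1.0
        adj[3, 4] = adj[4, 3] = 1.0
        base = {frozenset(c) for c in ot.mcl(adj, inflation=1.6)}
        perm = np.array([3, 0, 4, 1, 2])
        padj = adj[np.ix_(perm, perm)]
        got = {frozenset(int(perm[i]) for i in c)
               for c in ot.mcl(padj, inflation=1.6)}
        assert got == base


def all_clique_partitions(n):
    """Every partition of range(n), each block a uniform clique."""
    def partitions(elements):
        if not elements:
            yield []
            return
        head, *rest = elements
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield [[head]] + part
    yield from partitions(list(range(n)))


@pytest.mark.parametrize("n", range(1, 7))
def test_clique_components_recovered_exactly(n):
    """On disjoint uniform cliques MCL equals connected components, and
    raising the inflation never merges clusters (granularity monotone)."""
    for blocks in all_clique_partitions(n):
        adj = np.zeros((n, n))
        for block in blocks:
            for u, v in itertools.combinations(block, 2):
                adj[u, v] = adj[v, u] = 1.0
        expected = sorted(sorted(b) for b in blocks)
        previous = None
        for inflation in (1.2, 1.6, 2.0):
            got = sorted(sorted(c) for c in ot.mcl(adj, inflation=inflation))
            assert got == expected
            if previous is not None:
                assert len(got) >= len(previous)
            previous = got


class TestOrthogroups:
    def test_two_components_two_orthogroups(self, two_cherry_tree):
        _, _, ogs = run_inference(two_cherry_tree)
        assert ogs.as_partition() == [{"A_x1", "B_y1"}, {"A_x2", "B_y2"}]

    def test_isolated_genes_become_singletons(self):
        t = ot.parse_gene_tree("(A_x1,A_x2);")
        _, _, ogs = run_inference(t)
        assert sorted(map(sorted, ogs.as_partition())) == [["A_x1"], ["A_x2"]]

    def test_dense_graph_single_orthogroup(self, nested_tree):
        _, pairs, ogs = run_inference(nested_tree)
        assert len(pairs) == 5
        assert ogs.as_partition() == [{"A_x1", "B_y1", "B_y2", "C_z1"}]

    def test_ids_ordered_by_size_then_member(self):
        ogs = ot.OrthogroupSet.from_clusters([{"z1"}, {"b1", "b2"}, {"a9"}])
        assert list(ogs.groups) == ["OG0", "OG1", "OG2"]
        assert ogs.groups["OG0"] == ["b1", "b2"]
        assert ogs.groups["OG1"] == ["a9"]  # 'a9' < 'z1'
        assert ogs.groups["OG2"] == ["z1"]


class TestOrthogroupSupport:
    def test_mrca_support(self, two_cherry_tree):
        assert ot.orthogroup_support(two_cherry_tree, ["A_x1", "B_y1"]) == 0.9

    def test_singleton_support_missing(self, two_cherry_tree):
        assert ot.orthogroup_support(two_cherry_tree, ["A_x1"]) is None

    def test_whole_tree_gets_root_support(self, two_cherry_tree):
        members = two_cherry_tree.leaf_labels
        assert ot.orthogroup_support(two_cherry_tree, members) is None  # root

    def test_unknown_member_rejected(self, two_cherry_tree):
        with pytest.raises(OrthotreeError):
            ot.orthogroup_support(two_cherry_tree, ["nope"])


class TestRestrictToSpecies:
    def setup_method(self):
        # ingroup genes h1,f1,h2,f2 all linked through outgroup gene n1,
        # plus direct edges (h1,f1) and (h2,f2)
        self.genes = ["H_h1", "F_f1", "H_h2", "F_f2", "N_n1"]
        self.species_of = {g: g.split("_")[0] for g in self.genes}
        self.pairs = pair_set([
            ("H_h1", "N_n1", 1.0), ("F_f1", "N_n1", 1.0),
            ("H_h2", "N_n1", 1.0), ("F_f2", "N_n1", 1.0),
            ("H_h1", "F_f1", 1.0), ("H_h2", "F_f2", 1.0)])

    def test_full_graph_is_one_orthogroup(self):
        g = ot.build_graph(self.pairs, self.genes)
        ogs = ot.assign_orthogroups(g)
        assert ogs.as_partition() == [set(self.genes)]

    def test_ingroup_restriction_splits_hierarchically(self):
        ogs = ot.restrict_to_species(self.pairs, self.genes, {"H", "F"},
                                     self.species_of)
        assert sorted(map(sorted, ogs.as_partition())) == [
            ["F_f1", "H_h1"], ["F_f2", "H_h2"]]
        assert ogs.unassigned == ["N_n1"]

    def test_full_ingroup_is_a_noop(self):
        ogs = ot.restrict_to_species(self.pairs, self.genes, {"H", "F", "N"},
                                     self.species_of)
        full = ot.assign_orthogroups(ot.build_graph(self.pairs, self.genes))
        assert ogs.as_partition() == full.as_partition()
        assert ogs.unassigned == []

    def test_disjoint_ingroup_leaves_all_unassigned(self):
        with pytest.warns(UserWarning, match="ingroup"):
            ogs = ot.restrict_to_species(self.pairs, self.genes, {"X"},
                                         self.species_of)
        assert len(ogs) == 0
        assert ogs.unassigned == sorted(self.genes)


@pytest.mark.parametrize("seed", range(5))
def test_support_pruning_never_grows_clusters(seed):
    """Each cluster after pruning fits inside some unpruned cluster."""
    sim = simulate_tree(seed, dup_rate=0.4, max_leaves=40)
    tree = ot.assign_supports(sim.tree, sim.events, spec_beta=(2.0, 2.0),
                              dup_beta=(2.0, 2.0), seed=seed)
    events = ot.classify_events(tree)
    pairs = ot.extract_ortholog_pairs(tree, events)
    base = ot.assign_orthogroups(ot.build_graph(pairs, tree.leaf_labels))
    for min_support in (0.3, 0.6, 0.9):
        pruned = ot.assign_orthogroups(
            ot.build_graph(pairs, tree.leaf_labels, min_support=min_support))
        for cluster in pruned.as_partition():
            assert any(cluster <= ref for ref in base.as_partition())
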