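import itertools

import pytest

import orthotree as ot
from orthotree.species_overlap import DUPLICATION, SPECIATION
from orthotree.tree_io import OrthotreeError

from conftest import simulate_tree


class TestOverlapScore:
    @pytest.mark.parametrize("left,right,expected", [
        ({"A", "B"}, {"A", "B"}, 1.0),
        ({"A"}, {"B"}, 0.0),
        ({"A", "B", "C"}, {"A", "D"}, 0.25),
    ])
    def test_jaccard(self, left, right, expected):
        assert ot.species_overlap_score(left, right) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(OrthotreeError):
            ot.species_overlap_score(set(), {"A"})


class TestClassifyEvents:
    def test_two_cherry_tree(self, two_cherry_tree):
        events = ot.classify_events(two_cherry_tree, threshold=0.0)
        by_score = sorted((e.overlap_score, e.event) for e in events.values())
        assert by_score == [(0.0, SPECIATION), (0.0, SPECIATION),
                            (1.0, DUPLICATION)]

    def test_single_species_tree_all_duplications(self):
        t = ot.parse_gene_tree("((A_x1,A_x2),A_x3);")
        events = ot.classify_events(t)
        assert all(e.event == DUPLICATION for e in events.values())

    def test_threshold_uses_strict_inequality(self):
        # child sets {A,B,C} vs {A,D}: score 0.25 <= 0.3 -> speciation
        t = ot.parse_gene_tree("(((A_x1,B_y1),C_z1),(A_x2,D_w1));")
        root_event = ot.classify_events(t, threshold=0.3)[t.root.id]
        assert root_event.overlap_score == pytest.approx(0.25)
        assert root_event.event == SPECIATION
        assert ot.classify_events(t, threshold=0.0)[t.root.id].event == DUPLICATION

    def test_unrooted_tree_rejected(self, two_cherry_tree):
        two_cherry_tree.rooted = False
        with pytest.raises(OrthotreeError, match="root"):
            ot.classify_events(two_cherry_tree)

    def test_polytomy_uses_max_pairwise_score(self):
        t = ot.parse_gene_tree("(A_x1,B_y1,(A_x2,C_z1));")
        event = ot.classify_events(t)[t.root.id]
        # subtree species {A} vs {B} vs {A,C}: max pairwise Jaccard = 1/2
        assert event.overlap_score == pytest.approx(0.5)
        assert event.event == DUPLICATION


class TestExtractPairs:
    def test_cross_cherry_pairs_excluded_at_duplication_root(self, two_cherry_tree):
        events = ot.classify_events(two_cherry_tree)
        pairs = ot.extract_ortholog_pairs(two_cherry_tree, events)
        assert pairs.keys() == {("A_x1", "B_y1"), ("A_x2", "B_y2")}
        assert pairs.get("A_x1", "B_y1").support == 0.9
        assert pairs.get("A_x2", "B_y2").support == 0.8

    def test_in_paralog_pair_excluded(self, nested_tree):
        events = ot.classify_events(nested_tree)
        pairs = ot.extract_ortholog_pairs(nested_tree, events)
        assert pairs.keys() == {
            ("A_x1", "B_y1"), ("A_x1", "B_y2"),
            ("A_x1", "C_z1"), ("B_y1", "C_z1"), ("B_y2", "C_z1")}
        assert ("B_y1", "B_y2") not in pairs

    def test_one_species_pair_is_empty(self):
        t = ot.parse_gene_tree("(A_x1,A_x2);")
        pairs = ot.extract_ortholog_pairs(t, ot.classify_events(t))
        assert len(pairs) == 0

    def test_polytomy_pairs_only_across_disjoint_children(self):
        t = ot.parse_gene_tree("(A_x1,B_y1,(A_x2,C_z1));")
        pairs = ot.extract_ortholog_pairs(t, ot.classify_events(t))
        # A_x1 vs the {A,C} subtree overlaps; all other child pairs are
        # disjoint, and the inner (A_x2, C_z1) cherry is a speciation
        assert pairs.keys() == {("A_x1", "B_y1"), ("A_x2", "B_y1"),
                                ("B_y1", "C_z1"), ("A_x2", "C_z1")}


# ---------------------------------------------------------------------------
# Brute-force oracle: per-pair MRCA by ancestor-path intersection, event
# re-derived from the MRCA's child leaf sets. Independent of the postorder
# implementation under test.
# ---------------------------------------------------------------------------

def brute_force_events_and_pairs(tree, threshold=0.0):
    def path_up(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def leaf_species(node):
        return {lf.species for lf in node.leaves()}

    events = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        score = max(
            len(leaf_species(a) & leaf_species(b)) /
            len(leaf_species(a) | leaf_species(b))
            for a, b in itertools.combinations(node.children, 2)
        ) if len(node.children) > 1 else 0.0
        events[node.id] = DUPLICATION if score > threshold else SPECIATION

    pairs = set()
    leaves = tree.leaves
    for a, b in itertools.combinations(leaves, 2):
        pa, pb = path_up(a), path_up(b)
        ids_b = {n.id for n in pb}
        mrca = next(n for n in pa if n.id in ids_b)
        ca = next(c for c in mrca.children if a.id in {x.id for x in c.preorder()})
        cb = next(c for c in mrca.children if b.id in {x.id for x in c.preorder()})
        sa, sb = leaf_species(ca), leaf_species(cb)
        if len(sa & sb) / len(sa | sb) <= threshold:
            pairs.add(tuple(sorted((a.label, b.label))))
    return events, pairs


@pytest.mark.parametrize("seed", range(25))
def test_events_and_pairs_match_brute_force_oracle(seed):
    sim = simulate_tree(seed, max_leaves=30)
    tree = sim.tree
    events = ot.classify_events(tree)
    pairs = ot.extract_ortholog_pairs(tree, events)
    oracle_events, oracle_pairs = brute_force_events_and_pairs(tree)
    assert {i: e.event for i, e in events.items()} == oracle_events
    assert pairs.keys() == oracle_pairs


@pytest.mark.parametrize("seed", range(6))
def test_threshold_monotonicity(seed):
    """Raising the overlap threshold never loses ortholog pairs."""
    sim = simulate_tree(seed, dup_rate=0.5, max_leaves=30)
    tree = sim.tree
    previous = set()
    for threshold in (0.0, 0.2, 0.5, 0.8):
        pairs = ot.extract_ortholog_pairs(
            tree, ot.classify_events(tree, threshold=threshold)).keys()
        assert previous <= pairs
        previous = pairs


def test_species_tree_congruent_gene_tree_is_all_speciations():
    sim = simulate_tree(3, n_species=6, dup_rate=0.0, root_copies=1)
    tree = sim.tree
    events = ot.classify_events(tree)
    assert all(e.event == SPECIATION for e in events.values())
    pairs = ot.extract_ortholog_pairs(tree, events)
    n = len(tree)
    assert len(pairs) == n * (n - 1) // 2
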