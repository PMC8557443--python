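"""Midpoint and orthogroup-parsimony rooting of gene trees.

The species-overlap algorithm needs a rooted tree.  Besides accepting
precomputed roots, two heuristics are provided: classic midpoint rooting
(root at the midpoint of the longest leaf-to-leaf path) and an iterative
variant that scores every edge by the minimal achievable maximum root-to-tip
distance when the root is placed optimally on it, tries the n best-ranked
candidates, and keeps the root that minimises the number of resulting
orthogroups — an implicit parsimony criterion on ancestral gene copies that
protects against long internal branches attracting the midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .tree_io import GeneTree, Node, OrthotreeError
from .species_overlap import classify_events, extract_ortholog_pairs
from .graph_cluster import assign_orthogroups, build_graph


@dataclass
class RootCandidate:
    """A candidate root position on one edge of the unrooted tree."""
    edge: tuple[int, int]        # (u, v) vertex ids in the unrooted view
    position: float              # offset from u along the edge
    score: float                 # minimal achievable max root-to-tip distance
    rank: int                    # 1 = the midpoint root


class _UnrootedView:
    """Undirected edge-list view of a gene tree with a suppressed root.

    Node supports, which in rooted NEWICK annotate the edge above a node, are
    carried on the edges so they follow the bipartition across re-rootings.
    A degree-2 root is dissolved into a single edge (lengths summed).
    """

    def __init__(self, tree: GeneTree, assume_unit_lengths: bool = False):
        self.payload: dict[int, Node] = {}       # vertex id -> original node
        self.adj: dict[int, list[tuple[int, float, Optional[float]]]] = {}
        self.edge_order: dict[frozenset, int] = {}  # preorder edge index

        def length_of(node: Node) -> float:
            if node.length is None:
                if assume_unit_lengths:
                    return 1.0
                raise OrthotreeError(
                    "tree has missing branch lengths; pass "
                    "assume_unit_lengths=True (CLI: --unit-lengths) to proceed")
            return node.length

        root = tree.root
        suppress = len(root.children) == 2
        idx = 0
        for node in tree.preorder():
            if suppress and node is root:
                continue
            self.payload[node.id] = node
            self.adj[node.id] = []
        if suppress:
            a, b = root.children
            length = length_of(a) + length_of(b)
            support = a.support if a.support is not None else b.support
            self._add_edge(a.id, b.id, length, support, idx)
            idx += 1
        for node in tree.preorder():
            for child in node.children:
                if suppress and node is root:
                    continue
                self._add_edge(node.id, child.id, length_of(child),
                               child.support, idx)
                idx += 1

    def _add_edge(self, u: int, v: int, length: float,
                  support: Optional[float], index: int) -> None:
        self.adj[u].append((v, length, support))
        self.adj[v].append((u, length, support))
        self.edge_order[frozenset((u, v))] = index

    @property
    def edges(self) -> list[tuple[int, int]]:
        ordered = sorted(self.edge_order, key=self.edge_order.get)
        return [tuple(sorted(e)) for e in ordered]

    def edge_data(self, u: int, v: int) -> tuple[float, Optional[float]]:
        for w, length, support in self.adj[u]:
            if w == v:
                return length, support
        raise KeyError((u, v))

    # -- farthest-leaf distances -------------------------------------------
    def directed_heights(self) -> dict[tuple[int, int], float]:
        """h[(u, v)] = max distance from v to any leaf in v's side away from u."""
        h: dict[tuple[int, int], float] = {}
        for start in self.adj:
            for nbr, _, _ in self.adj[start]:
                self._height(start, nbr, h)
        return h

    def _height(self, u: int, v: int, h: dict) -> float:
        # iterative post-order over directed edges to avoid recursion limits
        stack = [(u, v, False)]
        while stack:
            a, b, expanded = stack.pop()
            if (a, b) in h:
                continue
            downstream = [(b, w, lw) for w, lw, _ in self.adj[b] if w != a]
            if not downstream:
                h[(a, b)] = 0.0
                continue
            if not expanded:
                stack.append((a, b, True))
                stack.extend((x, y, False) for x, y, _ in downstream)
            else:
                h[(a, b)] = max(lw + h[(b, w)] for b_, w, lw in downstream)
        return h[(u, v)]

    # -- re-rooting ---------------------------------------------------------
    def rooted_at(self, edge: tuple[int, int], position: float,
                  rooted_flag: bool = True) -> GeneTree:
        u, v = edge
        length, support = self.edge_data(u, v)
        if not 0.0 <= position <= length + 1e-12:
            raise OrthotreeError(
                f"root position {position} outside edge of length {length}")
        root = Node()
        left = self._orient(u, v)
        right = self._orient(v, u)
        left.length, right.length = position, length - position
        # both root edges represent the same bipartition
        left.support = right.support = support
        root.add_child(left)
        root.add_child(right)
        return GeneTree(root, rooted=rooted_flag)

    def _orient(self, top: int, away_from: int) -> Node:
        src = self.payload[top]
        node = Node(label=src.label, species=src.species, gene_id=src.gene_id)
        stack = [(top, away_from, node)]
        while stack:
            vid, parent, new = stack.pop()
            for nbr, length, support in self.adj[vid]:
                if nbr == parent:
                    continue
                s = self.payload[nbr]
                child = Node(label=s.label, species=s.species, gene_id=s.gene_id,
                             length=length, support=support)
                new.add_child(child)
                stack.append((nbr, vid, child))
        return node


def rank_root_candidates(tree: GeneTree, n: int,
                         assume_unit_lengths: bool = False) -> list[RootCandidate]:
    """Score every edge by the minimal achievable maximum root-to-tip distance
    and return the best ``min(n, #edges)`` candidates.

    For an edge (u, v) of length L with farthest-leaf distances h_u and h_v on
    either side, a root at offset x from u sees a maximum tip distance of
    max(h_u + x, h_v + L - x); the optimum is x* = clamp((h_v - h_u + L)/2,
    0, L).  Candidate 1 is the plain midpoint root; ties are broken by the
    preorder index of the edge.
    """
    if n < 1:
        raise OrthotreeError(f"number of root candidates must be >= 1: {n}")
    if len(tree) < 2:
        raise OrthotreeError("rooting requires at least 2 leaves")
    view = _UnrootedView(tree, assume_unit_lengths=assume_unit_lengths)
    h = view.directed_heights()
    candidates = []
    for u, v in view.edges:
        length, _ = view.edge_data(u, v)
        h_u = h[(v, u)]
        h_v = h[(u, v)]
        x = min(max((h_v - h_u + length) / 2.0, 0.0), length)
        score = max(h_u + x, h_v + length - x)
        candidates.append((score, view.edge_order[frozenset((u, v))], u, v, x))
    candidates.sort(key=lambda c: (c[0], c[1]))
    return [RootCandidate(edge=(u, v), position=x, score=score, rank=i + 1)
            for i, (score, _, u, v, x) in enumerate(candidates[:n])]


def _apply_candidate(tree: GeneTree, cand: RootCandidate,
                     assume_unit_lengths: bool = False) -> GeneTree:
    view = _UnrootedView(tree, assume_unit_lengths=assume_unit_lengths)
    return view.rooted_at(cand.edge, cand.position)


def midpoint_root(tree: GeneTree, assume_unit_lengths: bool = False) -> GeneTree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    cand = rank_root_candidates(tree, 1, assume_unit_lengths=assume_unit_lengths)[0]
    return _apply_candidate(tree, cand, assume_unit_lengths=assume_unit_lengths)


def count_orthogroups(tree: GeneTree, overlap_threshold: float = 0.0,
                      inflation: float = 1.6, min_support: float = 0.0,
                      weighted: bool = True) -> int:
    events = classify_events(tree, threshold=overlap_threshold)
    pairs = extract_ortholog_pairs(tree, events)
    graph = build_graph(pairs, tree.leaf_labels, weighted=weighted,
                        min_support=min_support)
    return len(assign_orthogroups(graph, inflation=inflation))


def iterative_root(tree: GeneTree, n: int = 10, overlap_threshold: float = 0.0,
                   inflation: float = 1.6, min_support: float = 0.0,
                   assume_unit_lengths: bool = False) -> GeneTree:
    """Try the n best midpoint-like root candidates and keep the one that
    minimises the number of orthogroups; ties go to the lower rank (closest
    to the plain midpoint)."""
    candidates = rank_root_candidates(tree, n,
                                      assume_unit_lengths=assume_unit_lengths)
    best_tree, best_count = None, None
    for cand in candidates:
        rooted = _apply_candidate(tree, cand,
                                  assume_unit_lengths=assume_unit_lengths)
        count = count_orthogroups(rooted, overlap_threshold=overlap_threshold,
                                  inflation=inflation, min_support=min_support)
        if best_count is None or count < best_count:
            best_tree, best_count = rooted, count
    return best_tree
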