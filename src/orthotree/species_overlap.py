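"""Speciation/duplication calling by species overlap, and ortholog-pair extraction.

An internal node of a rooted gene tree is called a duplication when its child
subtrees share species: under a duplication both daughter copies persist in
the descendant species, so their species compositions overlap, while under a
speciation the daughters are separated into disjoint species sets.  The
overlap score used here is the Jaccard index of the child species sets, so
the default threshold of 0 reproduces the strict rule "any shared species
implies a duplication" while still permitting a configurable tolerance for
minor tree inaccuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Optional

from .tree_io import GeneTree, Node, OrthotreeError, effective_support

SPECIATION = "speciation"
DUPLICATION = "duplication"


def species_overlap_score(left_species: set, right_species: set) -> float:
    """Jaccard overlap |L ∩ R| / |L ∪ R| between two child species sets."""
    if not left_species or not right_species:
        raise OrthotreeError("species overlap is undefined for an empty species set")
    inter = len(left_species & right_species)
    union = len(left_species | right_species)
    return inter / union


@dataclass
class NodeEvent:
    """Speciation/duplication call for one internal node."""
    node_id: int
    event: str                       # SPECIATION or DUPLICATION
    overlap_score: float
    support: Optional[float]
    child_species: list[set] = field(default_factory=list)


class EventMap(dict):
    """node id -> :class:`NodeEvent`; remembers the threshold it was built with."""

    def __init__(self, *args, threshold: float = 0.0):
        super().__init__(*args)
        self.threshold = threshold


def classify_events(tree: GeneTree, threshold: float = 0.0) -> EventMap:
    """Classify every internal node of a rooted gene tree.

    A binary node is a duplication iff the Jaccard overlap of its two child
    species sets strictly exceeds ``threshold``; a polytomy uses the maximum
    overlap over all unordered pairs of child subtrees.  Leaves carry no event.
    """
    if not tree.rooted:
        raise OrthotreeError("species overlap requires a rooted tree; root it first")
    if not 0.0 <= threshold < 1.0:
        raise OrthotreeError(f"species-overlap threshold must be in [0, 1): {threshold}")
    events = EventMap(threshold=threshold)
    species_of: dict[int, set] = {}
    for node in tree.postorder():
        if node.is_leaf:
            species_of[node.id] = {node.species}
            continue
        child_sets = [species_of[c.id] for c in node.children]
        species_of[node.id] = set().union(*child_sets)
        if len(child_sets) == 1:
            score = 0.0  # unifurcation: nothing to compare
        else:
            score = max(species_overlap_score(a, b)
                        for a, b in combinations(child_sets, 2))
        event = DUPLICATION if score > threshold else SPECIATION
        events[node.id] = NodeEvent(node_id=node.id, event=event,
                                    overlap_score=score, support=node.support,
                                    child_species=child_sets)
    return events


@dataclass(frozen=True)
class OrthologPair:
    """An unordered ortholog pair with the support of its MRCA node."""
    gene1: str
    gene2: str
    mrca_id: int
    support: Optional[float]

    @property
    def effective_support(self) -> float:
        return effective_support(self.support)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


class OrthologPairSet:
    """Set of pairwise orthology relations extracted from one rooted tree."""

    def __init__(self, pairs: Optional[list[OrthologPair]] = None):
        self.pairs: list[OrthologPair] = pairs or []
        self._by_key = {p.key: p for p in self.pairs}

    def add(self, gene1: str, gene2: str, mrca_id: int,
            support: Optional[float]) -> None:
        g1, g2 = sorted((gene1, gene2))
        pair = OrthologPair(g1, g2, mrca_id, support)
        if pair.key not in self._by_key:
            self.pairs.append(pair)
            self._by_key[pair.key] = pair

    def __iter__(self) -> Iterator[OrthologPair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(sorted(pair)) in self._by_key

    def get(self, gene1: str, gene2: str) -> Optional[OrthologPair]:
        return self._by_key.get(tuple(sorted((gene1, gene2))))

    def keys(self) -> set[tuple[str, str]]:
        return set(self._by_key)


def extract_ortholog_pairs(tree: GeneTree, events: EventMap) -> OrthologPairSet:
    """All gene pairs whose MRCA is a speciation node.

    For binary nodes this is exactly "emit every cross-child pair at
    speciation nodes".  At a polytomy, pairs are emitted only across those
    child-subtree pairs whose pairwise overlap passes the threshold, which is
    the conservative reading of an unresolved node (no arbitrary
    binarisation).
    """
    threshold = events.threshold
    pairs = OrthologPairSet()
    leaves_of: dict[int, list[Node]] = {}
    species_of: dict[int, set] = {}
    for node in tree.postorder():
        if node.is_leaf:
            leaves_of[node.id] = [node]
            species_of[node.id] = {node.species}
            continue
        leaves_of[node.id] = [lf for c in node.children for lf in leaves_of[c.id]]
        species_of[node.id] = set().union(*(species_of[c.id] for c in node.children))
        if node.id not in events:
            continue
        for a, b in combinations(node.children, 2):
            score = species_overlap_score(species_of[a.id], species_of[b.id])
            if score > threshold:
                continue
            for la in leaves_of[a.id]:
                for lb in leaves_of[b.id]:
                    pairs.add(la.label, lb.label, node.id, node.support)
    return pairs
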