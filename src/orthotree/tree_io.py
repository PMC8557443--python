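"""Gene-tree container and NEWICK input/output.

Gene trees are read from NEWICK text in which every leaf label carries a
species prefix ("<species><delimiter><gene id>") and internal node labels,
when present, are interpreted as statistical supports (bootstrap 0-100 or
posterior probabilities 0-1).  Parsing and serialisation are delegated to
:mod:`dendropy`; the in-package :class:`GeneTree` is a light parent/child
node structure because downstream steps (re-rooting on arbitrary edge
positions, bipartition-attached supports) need direct manipulation.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import pandas as pd


class NewickParseError(ValueError):
    """Raised when NEWICK text cannot be parsed or leaf labels are malformed."""


class OrthotreeError(ValueError):
    """Generic user-facing error for invalid pipeline input."""


# ---------------------------------------------------------------------------
# Core tree structure
# ---------------------------------------------------------------------------

class Node:
    """A node of a gene tree.

    Attributes
    ----------
    label : str or None
        Full leaf label (species prefix included); ``None`` for internal nodes.
    species, gene_id : str or None
        Parsed species prefix and gene identifier (the full label, so that
        identifiers stay globally unique).
    length : float or None
        Branch length of the edge above this node.
    support : float or None
        Statistical support of the edge above this node; ``None`` = missing.
    """

    def __init__(self, label=None, species=None, gene_id=None, length=None,
                 support=None, children=None):
        self.id: int = -1
        self.label: Optional[str] = label
        self.species: Optional[str] = species
        self.gene_id: Optional[str] = gene_id
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: list["Node"] = list(children) if children else []
        self.parent: Optional["Node"] = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def __repr__(self):  # pragma: no cover - debugging aid
        tag = self.label if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {tag}>"


class GeneTree:
    """Rooted gene tree with species-tagged leaves.

    Node ids are assigned in preorder at construction time and are stable for
    the lifetime of the object; any operation that changes topology returns a
    new :class:`GeneTree`.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._index()

    def _index(self) -> None:
        self._by_id: dict[int, Node] = {}
        for i, node in enumerate(self.root.preorder()):
            node.id = i
            self._by_id[i] = node
        self._leaf_map = {n.label: n for n in self.root.leaves()}

    # -- basic accessors ----------------------------------------------------
    def node(self, node_id: int) -> Node:
        return self._by_id[node_id]

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    @property
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def species(self) -> set[str]:
        return {n.species for n in self.leaves}

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_map[label]
        except KeyError:
            raise OrthotreeError(f"gene {label!r} is not a leaf of the tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._leaf_map

    def __len__(self) -> int:
        return len(self._leaf_map)

    # -- queries ------------------------------------------------------------
    def ancestors(self, node: Node) -> list[Node]:
        """Path from ``node`` (inclusive) to the root (inclusive)."""
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of a set of leaf labels."""
        labels = list(labels)
        if not labels:
            raise OrthotreeError("mrca of an empty gene set is undefined")
        paths = [self.ancestors(self.leaf(lb)) for lb in labels]
        common = set(n.id for n in paths[0])
        for p in paths[1:]:
            common &= {n.id for n in p}
        # the first common ancestor walking up from any member is the MRCA
        for n in paths[0]:
            if n.id in common:
                return n
        raise OrthotreeError("disconnected tree: no common ancestor")  # pragma: no cover

    def depths(self) -> dict[int, int]:
        """Node id -> number of edges from the root."""
        out = {self.root.id: 0}
        for node in self.preorder():
            for c in node.children:
                out[c.id] = out[node.id] + 1
        return out

    def copy(self) -> "GeneTree":
        return GeneTree(_copy_subtree(self.root), rooted=self.rooted)

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self):  # pragma: no cover
        return f"<GeneTree {len(self)} leaves, {len(self.species)} species>"


def _copy_subtree(node: Node) -> Node:
    new = Node(label=node.label, species=node.species, gene_id=node.gene_id,
               length=node.length, support=node.support)
    for c in node.children:
        new.add_child(_copy_subtree(c))
    return new


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _dendropy_to_node(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
    else:
        support = None
        if dnode.label not in (None, ""):
            try:
                support = float(dnode.label)
            except ValueError:
                support = None  # non-numeric internal label: not a support
        node = Node(length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add_child(_dendropy_to_node(child))
    return node


def parse_newick(newick_text: str) -> Node:
    """Parse NEWICK text into a raw :class:`Node` tree (no species splitting)."""
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed NEWICK: {exc}") from exc
    return _dendropy_to_node(dtree.seed_node)


def parse_gene_tree(newick_text: str, delimiter: str = "_",
                    species_field: int = 0) -> GeneTree:
    """Read a gene tree whose leaf labels are ``<species><delimiter><gene>``.

    The species is the first ``species_field + 1`` delimiter-separated fields
    of the leaf label; the gene identifier is the full label, which keeps
    identifiers globally unique.  Branch lengths, node supports and polytomies
    are preserved as-is.
    """
    if not delimiter:
        raise OrthotreeError("species delimiter must be a non-empty string")
    root = parse_newick(newick_text)
    for leaf in root.leaves():
        parts = leaf.label.split(delimiter)
        if len(parts) < species_field + 2:
            raise NewickParseError(
                f"leaf {leaf.label!r} does not contain the species delimiter "
                f"{delimiter!r} (expected '<species>{delimiter}<gene id>')")
        leaf.species = delimiter.join(parts[:species_field + 1])
        leaf.gene_id = leaf.label
    return GeneTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Support normalisation
# ---------------------------------------------------------------------------

def normalize_supports(tree: GeneTree, scale: str = "auto") -> GeneTree:
    """Bring node supports onto the [0, 1] scale.

    ``scale='auto'`` treats the supports as bootstrap percentages whenever any
    value exceeds 1 and divides all of them by 100; otherwise they are assumed
    to be posterior probabilities and left untouched.  Missing supports stay
    missing: consumers treat them as 1.0 (fully trusted) while reports show
    "NA".  The operation is idempotent.
    """
    if scale not in ("auto", "percent", "fraction"):
        raise OrthotreeError(f"unknown support scale {scale!r}")
    tree = tree.copy()
    values = [n.support for n in tree.preorder() if n.support is not None]
    if not values:
        return tree
    if min(values) < 0 or max(values) > 100:
        raise OrthotreeError(
            f"node supports outside [0, 100]: min={min(values)}, max={max(values)}")
    percent = scale == "percent" or (scale == "auto" and max(values) > 1)
    if percent:
        for n in tree.preorder():
            if n.support is not None:
                n.support = n.support / 100.0
    return tree


def effective_support(support: Optional[float]) -> float:
    """Missing supports are fully trusted wherever a support is consumed."""
    return 1.0 if support is None else support


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _fmt_support(s: Optional[float]) -> Optional[str]:
    if s is None:
        return None
    return format(s, "g")


def _node_to_dendropy(node: Node, dtree: "dendropy.Tree",
                      dparent: "dendropy.Node") -> None:
    dnode = dendropy.Node()
    dnode.edge.length = node.length
    if node.is_leaf:
        dnode.taxon = dtree.taxon_namespace.new_taxon(label=node.label)
    else:
        dnode.label = _fmt_support(node.support)
    dparent.add_child(dnode)
    for c in node.children:
        _node_to_dendropy(c, dtree, dnode)


def write_newick(tree: GeneTree) -> str:
    """Serialise a :class:`GeneTree` to single-line NEWICK text."""
    dtree = dendropy.Tree()
    dtree.seed_node.edge.length = tree.root.length
    dtree.seed_node.label = _fmt_support(tree.root.support)
    for c in tree.root.children:
        _node_to_dendropy(c, dtree, dtree.seed_node)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
        real_value_format_specifier=".6f",
    )
    return text.strip()


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

PAIRS_COLUMNS = ["gene1", "gene2", "support", "same_og"]
MEMBERSHIP_COLUMNS = ["gene", "orthogroup", "og_support",
                      "annotation", "annotation_support", "og_name"]


@dataclass
class OutputBundle:
    """The pipeline's three deliverables: pair table, membership table,
    orthogroup-annotated NEWICK tree."""

    pairs_table: pd.DataFrame
    membership_table: pd.DataFrame
    annotated_tree: str

    def write(self, prefix: str) -> list[str]:
        paths = [f"{prefix}.ortholog_pairs.tsv",
                 f"{prefix}.ortholog_groups.tsv",
                 f"{prefix}.annotated.newick"]
        self.pairs_table.to_csv(paths[0], sep="\t", index=False)
        self.membership_table.to_csv(paths[1], sep="\t", index=False)
        with open(paths[2], "w") as fh:
            fh.write(self.annotated_tree + "\n")
        return paths


def _og_sort_key(og_id: str):
    # "OG10" must sort after "OG2"
    digits = "".join(ch for ch in og_id if ch.isdigit())
    return (int(digits) if digits else 0, og_id)


def _na(value) -> str:
    if value is None:
        return "NA"
    return format(value, "g")


def write_outputs(tree: GeneTree, orthogroups, pairs, annotations=None,
                  og_names=None) -> OutputBundle:
    """Assemble the output tables and the annotated tree.

    Parameters
    ----------
    orthogroups : OrthogroupSet
        Must cover every leaf of ``tree`` (unassigned outgroup genes allowed).
    pairs : OrthologPairSet
    annotations : mapping gene -> GeneAnnotation, optional
    og_names : mapping orthogroup id -> name, optional
    """
    annotations = annotations or {}
    og_names = og_names or {}
    leaves = tree.leaf_labels
    assigned = set(orthogroups.gene_to_og) | set(orthogroups.unassigned)
    missing = [lb for lb in leaves if lb not in assigned]
    if missing:
        raise OrthotreeError(
            f"orthogroup partition does not cover leaves: {missing[:5]}")

    rows = []
    for gene in leaves:
        og = orthogroups.gene_to_og.get(gene, "unassigned")
        og_support = orthogroups.supports.get(og)
        ann = annotations.get(gene)
        rows.append({
            "gene": gene,
            "orthogroup": og,
            "og_support": _na(og_support),
            "annotation": "/".join(ann.names) if ann and ann.names else "NA",
            "annotation_support": _na(ann.support) if ann and ann.names else "NA",
            "og_name": og_names.get(og, ""),
        })
    membership = pd.DataFrame(rows, columns=MEMBERSHIP_COLUMNS)
    membership = membership.sort_values(
        by=["orthogroup", "gene"],
        key=lambda col: col.map(_og_sort_key) if col.name == "orthogroup" else col,
        kind="mergesort").reset_index(drop=True)

    prow = []
    for p in pairs:
        g1, g2 = sorted((p.gene1, p.gene2))
        same = (orthogroups.gene_to_og.get(g1) is not None
                and orthogroups.gene_to_og.get(g1) == orthogroups.gene_to_og.get(g2))
        prow.append({"gene1": g1, "gene2": g2,
                     "support": _na(p.support), "same_og": same})
    pairs_table = pd.DataFrame(prow, columns=PAIRS_COLUMNS)
    if len(pairs_table):
        pairs_table = pairs_table.sort_values(
            by=["gene1", "gene2"], kind="mergesort").reset_index(drop=True)

    annotated = tree.copy()
    for leaf in annotated.leaves:
        leaf.label = f"{leaf.label}|{orthogroups.gene_to_og.get(leaf.label, 'unassigned')}"
    return OutputBundle(pairs_table=pairs_table, membership_table=membership,
                        annotated_tree=write_newick(annotated))
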