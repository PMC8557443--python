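"""Evolutionary relationship of gene pairs: ortholog, in-paralog, out-paralog.

A pair whose MRCA is a speciation node is an ortholog pair.  Pairs descending
from a duplication are paralogs, split operationally by orthogroup
co-membership: *in-paralogs* share an orthogroup (duplicates retained within
the family at the chosen scope), *out-paralogs* sit in different orthogroups
(duplicates predating the scope).  Note that this is the orthogroup-relative
reading of the terms, not the classical species-pair-relative definition:
the split depends on the clustering, not on a reference speciation event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .tree_io import GeneTree, OrthotreeError
from .species_overlap import EventMap, SPECIATION
from .graph_cluster import OrthogroupSet

ORTHOLOG = "ortholog"
IN_PARALOG = "in-paralog"
OUT_PARALOG = "out-paralog"


@dataclass(frozen=True)
class PairRelationship:
    gene1: str
    gene2: str
    relation: str
    same_orthogroup: bool
    support: Optional[float]


def classify_pair(tree: GeneTree, events: EventMap, ogs: OrthogroupSet,
                  g: str, h: str) -> PairRelationship:
    """Classify the relationship between two genes of the tree.

    Orthologs may end up in different orthogroups after support pruning; they
    are still reported as orthologs with ``same_orthogroup=False`` rather
    than suppressed, since the tree and the graph can legitimately disagree.
    """
    if g == h:
        raise OrthotreeError("cannot classify a gene against itself")
    for gene in (g, h):
        if gene not in tree:
            raise OrthotreeError(f"unknown gene {gene!r}")
    mrca = tree.mrca([g, h])
    same = (ogs.gene_to_og.get(g) is not None
            and ogs.gene_to_og.get(g) == ogs.gene_to_og.get(h))
    if events[mrca.id].event == SPECIATION:
        relation = ORTHOLOG
    else:
        relation = IN_PARALOG if same else OUT_PARALOG
    return PairRelationship(gene1=g, gene2=h, relation=relation,
                            same_orthogroup=same, support=mrca.support)


def classify_all_vs_focal(tree: GeneTree, events: EventMap, ogs: OrthogroupSet,
                          focal_gene: str) -> list[PairRelationship]:
    """One relationship record per other gene, in tree preorder."""
    if focal_gene not in tree:
        raise OrthotreeError(f"unknown focal gene {focal_gene!r}")
    return [classify_pair(tree, events, ogs, focal_gene, leaf.label)
            for leaf in tree.leaves if leaf.label != focal_gene]
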