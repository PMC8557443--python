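"""Gene and orthogroup naming from reference-species dictionaries.

Genes are annotated with the names of the reference genes they are orthologous
to; orthogroups inherit the names of the reference genes they contain, joined
with "/" into a composite name when there are several; and orthogroups with no
reference gene receive a "like:" label propagated from the closest named
orthogroups in the tree, optionally gated by a minimum support on the
connecting ancestor.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .tree_io import GeneTree, OrthotreeError, effective_support
from .species_overlap import OrthologPairSet
from .graph_cluster import OrthogroupSet


def natural_key(name: str):
    """Numeric-aware sort key so NKX2-2 orders before NKX2-8 before NKX2-10."""
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", name)]


@dataclass
class AnnotationDict:
    """Reference gene id -> gene name mapping for one or more reference species."""
    names: dict[str, str] = field(default_factory=dict)
    species: set[str] = field(default_factory=set)

    @classmethod
    def from_tsv(cls, path: str) -> "AnnotationDict":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["gene_id", "name"], dtype=str)
        df = df.dropna()
        return cls(names=dict(zip(df["gene_id"], df["name"])))

    def merged_with(self, other: "AnnotationDict") -> "AnnotationDict":
        merged = dict(self.names)
        merged.update(other.names)
        return AnnotationDict(names=merged, species=self.species | other.species)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.names

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class GeneAnnotation:
    """Reference names attached to one gene, with the support of the deepest
    (closest to the root) tree node the annotation rests on."""
    names: list[str] = field(default_factory=list)
    support: Optional[float] = None


def annotate_genes(pairs: OrthologPairSet, annot: AnnotationDict,
                   tree: GeneTree) -> dict[str, GeneAnnotation]:
    """Annotate each gene with the names of its reference orthologs.

    The annotation support is the support of the deepest MRCA among the
    pairs that contribute a name (the node closest to the root: the weakest
    link the whole annotation hangs from).
    """
    leaf_set = set(tree.leaf_labels)
    absent = [g for g in annot.names if g not in leaf_set]
    if absent:
        warnings.warn(f"{len(absent)} reference gene ids are not in the tree "
                      f"and were ignored (e.g. {absent[:3]})")
    depths = tree.depths()
    hits: dict[str, list[tuple[str, int, Optional[float]]]] = {}
    for pair in pairs:
        for gene, ref in ((pair.gene1, pair.gene2), (pair.gene2, pair.gene1)):
            if ref in annot.names:
                hits.setdefault(gene, []).append(
                    (annot.names[ref], depths[pair.mrca_id], pair.support))
    out: dict[str, GeneAnnotation] = {}
    for gene in tree.leaf_labels:
        rows = hits.get(gene)
        if not rows:
            out[gene] = GeneAnnotation()
            continue
        names = sorted({name for name, _, _ in rows}, key=natural_key)
        deepest = min(rows, key=lambda r: r[1])
        out[gene] = GeneAnnotation(names=names, support=deepest[2])
    return out


def name_orthogroups(ogs: OrthogroupSet, annot: AnnotationDict) -> dict[str, str]:
    """Composite orthogroup names from the reference genes they contain.

    Several reference genes give a "/"-joined, naturally sorted composite name
    ("NKX2-2/NKX2-8"); orthogroups without a reference gene stay unnamed
    (empty string) pending propagation.
    """
    names: dict[str, str] = {}
    for og_id, members in ogs.groups.items():
        found = sorted({annot.names[g] for g in members if g in annot.names},
                       key=natural_key)
        names[og_id] = "/".join(found)
    return names


def propagate_like_labels(tree: GeneTree, ogs: OrthogroupSet,
                          names: dict[str, str], min_support: float = 0.0
                          ) -> tuple[dict[str, str], dict[str, Optional[float]]]:
    """Label unnamed orthogroups after their closest named neighbours.

    For each unnamed orthogroup, walk from the MRCA of its members toward the
    root; the first node whose support passes ``min_support`` (missing
    supports are fully trusted) and whose descendant leaves include members of
    at least one named orthogroup donates a "like:" label aggregating the
    names of *all* named orthogroups under it.  Returns the updated name map
    and, per propagated orthogroup, the support of the donating ancestor.
    """
    names = dict(names)
    like_supports: dict[str, Optional[float]] = {}
    named_ogs = {og for og, nm in names.items() if nm}
    if not named_ogs:
        return names, like_supports

    # per node: which named orthogroups have members below it
    named_below: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            og = ogs.gene_to_og.get(node.label)
            named_below[node.id] = {og} if og in named_ogs else set()
        else:
            named_below[node.id] = set().union(
                *(named_below[c.id] for c in node.children))

    for og_id, members in ogs.groups.items():
        if names.get(og_id):
            continue
        node = tree.mrca(members)
        while node is not None:
            donors = named_below[node.id]
            if donors and effective_support(node.support) >= min_support:
                donor_names = sorted({names[d] for d in donors}, key=natural_key)
                names[og_id] = "like:" + "/".join(donor_names)
                like_supports[og_id] = node.support
                break
            node = node.parent
    return names, like_supports
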