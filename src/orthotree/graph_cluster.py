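"""Ortholog graph construction and Markov clustering into orthogroups.

Pairwise orthology relations form an undirected graph over the genes of the
tree; edges can be weighted by the statistical support of the tree node that
induced them and pruned below a minimum support.  The graph is partitioned
with the Markov cluster algorithm (MCL): random-walk expansion alternated
with inflation (elementwise powering) of a column-stochastic matrix until a
steady state, whose attractors define the clusters.  Inflation controls
granularity; the default is 1.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .tree_io import GeneTree, OrthotreeError
from .species_overlap import OrthologPairSet


def build_graph(pairs: OrthologPairSet, all_genes: Iterable[str],
                weighted: bool = True, min_support: float = 0.0) -> nx.Graph:
    """Build the ortholog graph over ``all_genes``.

    Edges whose supporting-node support (missing treated as 1.0) falls below
    ``min_support`` are removed; pruning keeps edges exactly at the threshold.
    In unweighted mode every surviving edge gets weight 1.
    """
    if not 0.0 <= min_support <= 1.0:
        raise OrthotreeError(f"min_support must be in [0, 1]: {min_support}")
    graph = nx.Graph()
    graph.add_nodes_from(all_genes)
    for pair in pairs:
        s = pair.effective_support
        if s < min_support:
            continue
        graph.add_edge(pair.gene1, pair.gene2, weight=s if weighted else 1.0)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

class MCLConvergenceWarning(UserWarning):
    pass


def _column_normalize(m: sp.csr_matrix) -> sp.csr_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    d = sp.diags(1.0 / sums)
    return (m @ d).tocsr()


def mcl(adjacency, inflation: float = 1.6, expansion: int = 2,
        loop_value: float = 1.0, max_iter: int = 100, tol: float = 1e-6,
        prune_cutoff: float = 1e-5) -> list[set[int]]:
    """Markov clustering of a symmetric nonnegative adjacency matrix.

    Self-loops of ``loop_value`` are added, columns are normalised, and the
    matrix is iterated (expansion = matrix power, then inflation = elementwise
    power and renormalisation, with entries below ``prune_cutoff`` dropped)
    until the L-infinity change falls below ``tol``.  Clusters are read from
    the attractor rows of the steady state; a node attracted by several
    clusters is assigned to the one holding its largest steady-state mass,
    ties to the lowest cluster index.

    Returns a partition of node indices as a list of disjoint sets.
    """
    a = sp.csr_matrix(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise OrthotreeError(f"adjacency matrix must be square, got {a.shape}")
    if a.nnz and a.data.min() < 0:
        raise OrthotreeError("adjacency matrix must be nonnegative")
    if inflation <= 1:
        raise OrthotreeError(f"inflation must be > 1: {inflation}")
    n = a.shape[0]
    if n == 0:
        return []
    a = a.tolil()
    a.setdiag(loop_value)
    m = _column_normalize(a.tocsr())

    converged = False
    for _ in range(max_iter):
        nxt = m
        for _ in range(expansion - 1):
            nxt = nxt @ m
        nxt = nxt.power(inflation)
        nxt.data[nxt.data < prune_cutoff] = 0.0
        nxt.eliminate_zeros()
        nxt = _column_normalize(nxt)
        delta = abs(nxt - m).max() if (nxt - m).nnz else 0.0
        m = nxt
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; "
                      "clusters read from the last iterate", MCLConvergenceWarning)

    m = m.tocsr()
    diag = m.diagonal()
    attractors = np.flatnonzero(diag > 1e-8)
    clusters: list[set[int]] = []
    attractor_rows: list[list[int]] = []
    seen: dict[frozenset, int] = {}
    for i in attractors:
        members = frozenset(m.indices[m.indptr[i]:m.indptr[i + 1]])
        if members in seen:
            attractor_rows[seen[members]].append(i)
        else:
            seen[members] = len(clusters)
            clusters.append(set(members))
            attractor_rows.append([i])

    assignment: dict[int, int] = {}
    for j in range(n):
        best, best_mass = None, -1.0
        for ci, members in enumerate(clusters):
            if j not in members:
                continue
            mass = sum(m[i, j] for i in attractor_rows[ci])
            if mass > best_mass + 1e-12:
                best, best_mass = ci, mass
        if best is None:
            clusters.append({j})
            attractor_rows.append([j])
            best = len(clusters) - 1
        assignment[j] = best

    out: dict[int, set[int]] = {}
    for j, ci in assignment.items():
        out.setdefault(ci, set()).add(j)
    return [out[ci] for ci in sorted(out)]


# ---------------------------------------------------------------------------
# Orthogroups
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupSet:
    """A labelled partition of genes into orthogroups.

    Ids are "OG0", "OG1", ... assigned by decreasing cluster size with ties
    broken by the lexicographically smallest member, so outputs are
    reproducible.  Genes excluded from clustering (outgroup genes under
    ingroup restriction) are listed in ``unassigned``.
    """
    groups: dict[str, list[str]] = field(default_factory=dict)
    supports: dict[str, Optional[float]] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.gene_to_og = {g: og for og, members in self.groups.items()
                           for g in members}

    @classmethod
    def from_clusters(cls, clusters: Iterable[set[str]],
                      unassigned: Iterable[str] = ()) -> "OrthogroupSet":
        ordered = sorted((sorted(c) for c in clusters),
                         key=lambda c: (-len(c), c[0]))
        groups = {f"OG{i}": members for i, members in enumerate(ordered)}
        return cls(groups=groups, unassigned=sorted(unassigned))

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def members(self, og_id: str) -> list[str]:
        return self.groups[og_id]

    def as_partition(self) -> list[set[str]]:
        return [set(m) for m in self.groups.values()]


def assign_orthogroups(graph: nx.Graph, inflation: float = 1.6,
                       **mcl_kwargs) -> OrthogroupSet:
    """Partition the ortholog graph into orthogroups with MCL.

    Isolated genes become singleton orthogroups (every gene must appear in
    the membership table).
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return OrthogroupSet.from_clusters([])
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight",
                                   format="csr")
    clusters = mcl(adj, inflation=inflation, **mcl_kwargs)
    named = [{nodes[i] for i in c} for c in clusters]
    return OrthogroupSet.from_clusters(named)


def orthogroup_support(tree: GeneTree, members: Sequence[str]) -> Optional[float]:
    """Support of the MRCA of an orthogroup's members.

    Missing for singletons (their MRCA is a leaf) and when the MRCA carries no
    support; never imputed.
    """
    if not members:
        raise OrthotreeError("orthogroup_support of an empty member set")
    node = tree.mrca(members)
    return node.support


def attach_supports(tree: GeneTree, ogs: OrthogroupSet) -> OrthogroupSet:
    """Fill ``ogs.supports`` in place from the tree; returns ``ogs``."""
    for og_id, members in ogs.groups.items():
        ogs.supports[og_id] = orthogroup_support(tree, members)
    return ogs


def restrict_to_species(pairs: OrthologPairSet, all_genes: Iterable[str],
                        ingroup: set[str], species_of: dict[str, str],
                        inflation: float = 1.6, min_support: float = 0.0,
                        weighted: bool = True) -> OrthogroupSet:
    """Cluster only the genes of an ingroup of species.

    Orthology edges are kept only when both endpoints belong to ingroup
    species; outgroup genes are reported as unassigned.  Restricting the
    taxonomic scope this way yields more granular, hierarchical orthogroups:
    ingroup genes connected only through an outgroup gene fall apart into
    separate clusters.
    """
    if not ingroup:
        raise OrthotreeError("ingroup species set must be non-empty")
    all_genes = list(all_genes)
    in_genes = [g for g in all_genes if species_of[g] in ingroup]
    out_genes = [g for g in all_genes if species_of[g] not in ingroup]
    if not in_genes:
        warnings.warn("no genes belong to the ingroup species; "
                      "all genes left unassigned")
        return OrthogroupSet.from_clusters([], unassigned=out_genes)
    kept = OrthologPairSet(
        [p for p in pairs
         if species_of[p.gene1] in ingroup and species_of[p.gene2] in ingroup])
    graph = build_graph(kept, in_genes, weighted=weighted, min_support=min_support)
    ogs = assign_orthogroups(graph, inflation=inflation)
    return OrthogroupSet(groups=ogs.groups, supports=ogs.supports,
                         unassigned=sorted(out_genes))
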