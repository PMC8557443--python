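"""Gene-tree simulation with known orthogroup ground truth.

Gene families are evolved down a species tree under a duplication-loss
process: k independent gene lineages start at the species-tree root, each
lineage accrues duplications along every species branch as a Poisson process
of rate ``dup_rate`` per unit branch length, survives each branch with
probability exp(-loss_rate * t), and bifurcates into both daughters at every
species-tree speciation.  The surviving gene tree (extinct lineages pruned,
unifurcations suppressed) is returned together with the true orthogroup
partition — one orthogroup per root lineage that left descendants — and the
generating event of every internal node, which makes every pipeline stage
testable without external data.

The process has no incomplete lineage sorting and no transfer, so each true
orthogroup is exactly the monophyletic clade of one root lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tree_io import GeneTree, Node, OrthotreeError, parse_newick
from .species_overlap import SPECIATION, DUPLICATION


@dataclass
class SimulationConfig:
    """Parameters of one simulation.

    species_tree : NEWICK text with branch lengths; leaf labels are species
        names (they must not contain the gene-label delimiter "_").
    dup_rate, loss_rate : events per unit branch length.
    root_copies : number of independent gene lineages at the species root;
        each surviving lineage defines one true orthogroup.
    spec_beta, dup_beta : Beta parameters for supports drawn on speciation
        and duplication nodes by :func:`assign_supports`.
    """
    species_tree: str
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    root_copies: int = 1
    spec_beta: tuple[float, float] = (9.0, 1.0)
    dup_beta: tuple[float, float] = (9.0, 1.0)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise OrthotreeError("duplication and loss rates must be nonnegative")
        if self.root_copies < 1:
            raise OrthotreeError("root_copies must be >= 1")


@dataclass
class SimTruth:
    """A simulated gene tree paired with its ground truth."""
    tree: Optional[GeneTree]
    truth: dict[str, set[str]] = field(default_factory=dict)
    events: dict[int, str] = field(default_factory=dict)
    extinct: bool = False

    def truth_of(self, gene: str) -> str:
        for og, members in self.truth.items():
            if gene in members:
                return og
        raise KeyError(gene)


class _Simulator:
    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.counter = 0
        self.sp_root = parse_newick(config.species_tree)
        if len(self.sp_root.leaves()) < 2:
            raise OrthotreeError("species tree must have at least 2 leaves")

    def _new_leaf(self, species: str, dist: float) -> Node:
        self.counter += 1
        label = f"{species}_g{self.counter}"
        node = Node(label=label, species=species, gene_id=label, length=dist)
        return node

    def _speciate(self, sp_node: Node, dist: float) -> Optional[Node]:
        """A lineage reaching species-tree node ``sp_node``; returns the gene
        subtree rooted ``dist`` below its parent gene node, or None if extinct."""
        if sp_node.is_leaf:
            return self._new_leaf(sp_node.label, dist)
        kids = [self._evolve_branch(child) for child in sp_node.children]
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            alive[0].length += dist
            return alive[0]
        node = Node(length=dist, children=alive)
        node.event_kind = SPECIATION
        return node

    def _evolve_branch(self, sp_node: Node) -> Optional[Node]:
        """One lineage entering the branch above ``sp_node`` from the top."""
        t_branch = sp_node.length
        if t_branch is None:
            raise OrthotreeError(
                f"species tree branch above {sp_node.label or 'internal node'} "
                "has no length")
        return self._evolve_segment(sp_node, t_branch, 0.0)

    def _evolve_segment(self, sp_node: Node, t_remaining: float,
                        dist_accum: float) -> Optional[Node]:
        lam = self.cfg.dup_rate
        wait = self.rng.exponential(1.0 / lam) if lam > 0 else np.inf
        if wait < t_remaining:
            left = self._evolve_segment(sp_node, t_remaining - wait, 0.0)
            right = self._evolve_segment(sp_node, t_remaining - wait, 0.0)
            alive = [k for k in (left, right) if k is not None]
            if not alive:
                return None
            if len(alive) == 1:
                alive[0].length += dist_accum + wait
                return alive[0]
            node = Node(length=dist_accum + wait, children=alive)
            node.event_kind = DUPLICATION
            return node
        # reached the bottom of the species branch: per-branch survival
        mu = self.cfg.loss_rate
        if mu > 0 and self.rng.random() >= np.exp(-mu * sp_node.length):
            return None
        return self._speciate(sp_node, dist_accum + t_remaining)

    def run(self) -> SimTruth:
        lineages = []
        for _ in range(self.cfg.root_copies):
            lineages.append(self._speciate(self.sp_root, 0.0))
        alive = [(i, g) for i, g in enumerate(lineages) if g is not None]
        if not alive:
            return SimTruth(tree=None, extinct=True)
        truth = {f"trueOG{i}": {lf.label for lf in g.leaves()}
                 for i, g in alive}
        if len(alive) == 1:
            root = alive[0][1]
        else:
            # join the surviving root copies by a ladder of ancient duplications
            root = alive[0][1]
            for _, g in alive[1:]:
                root.length = 0.0
                g.length = 0.0
                join = Node(children=[root, g])
                join.event_kind = DUPLICATION
                root = join
        root.length = None
        tree = GeneTree(root, rooted=True)
        events = {n.id: getattr(n, "event_kind") for n in tree.preorder()
                  if not n.is_leaf}
        return SimTruth(tree=tree, truth=truth, events=events)


def simulate_gene_tree(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> SimTruth:
    """Run one duplication-loss simulation; see the module docstring.

    Returns an extinct :class:`SimTruth` (``tree is None``) when no lineage
    survives; callers may re-draw with a fresh seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _Simulator(config, rng).run()


def assign_supports(tree: GeneTree, events: dict[int, str],
                    spec_beta: tuple[float, float] = (9.0, 1.0),
                    dup_beta: tuple[float, float] = (9.0, 1.0),
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> GeneTree:
    """Draw per-node supports from event-specific Beta distributions.

    Defaults Beta(9, 1) emulate well-resolved trees (mean 0.9); skewed
    parameters such as Beta(1, 9) inject poorly supported nodes to exercise
    support pruning.  The root keeps no support, as in typical NEWICK output.
    """
    for name, (a, b) in (("spec_beta", spec_beta), ("dup_beta", dup_beta)):
        if a <= 0 or b <= 0:
            raise OrthotreeError(f"{name} parameters must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = tree.copy()
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        a, b = spec_beta if events.get(node.id, SPECIATION) == SPECIATION else dup_beta
        node.support = float(rng.beta(a, b))
    return tree


def random_species_tree(n_species: int, rng: np.random.Generator,
                        branch_range: tuple[float, float] = (0.1, 0.5)) -> str:
    """Random binary species tree over species "s1".."sN" (NEWICK text).

    Topology by sequential random joins; branch lengths uniform in
    ``branch_range`` — roughly the shape of a moderately divergent clade.
    """
    if n_species < 2:
        raise OrthotreeError("need at least 2 species")
    lo, hi = branch_range

    def blen() -> str:
        return format(rng.uniform(lo, hi), ".4f")

    subtrees = [f"s{i + 1}:{blen()}" for i in range(n_species)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b}):{blen()}")
    newick = subtrees[0]
    newick = newick[:newick.rfind(":")]  # strip the root branch length
    return newick + ";"
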