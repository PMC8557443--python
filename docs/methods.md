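# Methods

## The model

`orthotree` infers orthology from the topology of a single rooted gene tree,
with no species tree.  The underlying assumption is the classical one for
species-overlap methods: after a speciation, the two daughter lineages are
carried by disjoint sets of descendant species, whereas after a duplication
both copies persist in the same species, so the child subtrees of a
duplication node share species.  An internal node with child species sets
*L* and *R* therefore receives the overlap score *J = |L ∩ R| / |L ∪ R|*
(Jaccard index) and is called a duplication iff *J >* threshold.  At the
default threshold 0 this is exactly "any shared species ⇒ duplication"; the
Jaccard form gives the threshold a scale-free meaning for nonzero values.
The inequality is strict so that disjoint bipartitions remain speciations at
threshold 0.  Polytomies are never binarized: the node score is the maximum
pairwise Jaccard over its child subtrees, and ortholog pairs are emitted
only across child pairs that individually pass the threshold.

Two genes are orthologs iff their MRCA is a speciation node.  The ortholog
graph (genes = nodes, ortholog pairs = edges, MRCA supports = optional
weights, edges below `min_support` pruned, missing supports trusted as 1.0)
is partitioned by Markov clustering.  MCL's random-walk expansion is what
lets the method tolerate local tree errors: co-orthologs separated by a
duplication are usually reconnected through their shared orthologs in other
species, so clusters correspond to gene families at the root scope even when
no single speciation node covers them.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `sos` (overlap threshold) | 0.0 | tolerated species overlap at speciations; larger = fewer, larger orthogroups |
| `inflation` | 1.6 | MCL granularity; larger = finer clusters |
| `min_support` | 0.0 | support below which ortholog edges are pruned (supports auto-rescaled from 0–100 to 0–1 when any value exceeds 1) |
| `root` | `keep` | `midpoint`, or `iterative` with `iter_n` (default 10) candidates |
| `min_annot_support` | 0.0 | support gate on the ancestor donating a `like:` label |

MCL internals (expansion 2, self-loop weight 1, L∞ tolerance 1e-6, prune
cutoff 1e-5, 100 iterations) are conventional MCL defaults, exposed as
keyword arguments; the attractor-overlap tie-break assigns a node to the
cluster holding its largest steady-state mass, ties to the lowest cluster
index, so output is deterministic.

## Rooting

Midpoint rooting places the root halfway along the longest leaf-to-leaf
path.  For the iterative variant each edge is scored by the minimal
achievable maximum root-to-tip distance when a root is placed optimally on
it — for edge (u, v) of length L with farthest-leaf distances h_u, h_v on
either side, the optimum sits at x\* = clamp((h_v − h_u + L)/2, 0, L).  This
is the natural generalisation of "midpoint" to a per-edge ranking; ranks are
tie-broken by preorder edge index so candidate 1 is always the plain
midpoint.  The top *n* candidates are each used to root the tree, the full
event-calling + clustering pipeline is run, and the root with the fewest
orthogroups wins (ties to the lower rank).  Because candidate 1 is the
midpoint, the chosen root never yields more orthogroups than midpoint
rooting.  Node supports are attached to edges (bipartitions) during
re-rooting, so they survive any root placement; a root placed exactly on a
node keeps a zero-length edge so the tree stays strictly rooted.  Trees
without branch lengths are rooted only under an explicit unit-length flag.

## Annotation

Genes receive the names of all reference genes they pair with; the
annotation support is the support of the deepest such MRCA (closest to the
root — the weakest link the annotation hangs from; when several nodes
qualify this is the deepest, not the best-supported, one).  Orthogroup names
join their member reference names with "/" in natural (numeric-aware) sort
order, so permuting the dictionary changes nothing.  Unnamed orthogroups
walk from the MRCA of their members toward the root and take a
`like:`-prefixed copy of the names of **all** named orthogroups below the
first qualifying ancestor (support ≥ `min_annot_support`, missing = trusted).
The walk includes the starting MRCA itself, which matters only when an
orthogroup is non-monophyletic in the tree.

In/out-paralog classification is orthogroup-relative: a duplication-derived
pair is an in-paralog when both genes share an orthogroup, an out-paralog
otherwise.  This is the operational, clustering-dependent reading of the
terms, not the classical species-pair-relative definition.  Orthologs split
across orthogroups by support pruning are reported as orthologs with
`same_og = False`, not suppressed.

## The simulator and what a green test establishes

The simulator evolves k independent gene lineages down a species tree:
duplications arrive as a Poisson process (rate λ per unit branch length),
every lineage reaching the end of a branch of length t survives with
probability exp(−μt), and all surviving lineages bifurcate at species-tree
speciations.  Loss is per-branch survival rather than a full birth–death
with mid-branch death times: the ground-truth partition and event log are
what the tests need, not waiting-time realism.  Truth orthogroups are the
descendant sets of the k root lineages (the root taxonomic scope); multiple
root copies are joined by zero-length duplication nodes.  Supports, when
requested, are drawn from event-specific Beta distributions (default
Beta(9, 1), mean 0.9, emulating well-resolved trees; Beta(1, 9) on
speciations exercises pruning).

Simulated trees are therefore topologically *true*: no reconstruction error,
no incomplete lineage sorting, no transfer, and orthogroups are exactly
monophyletic when μ = 0.  A green recovery test establishes that the
pipeline inverts the duplication–loss process on correct trees; robustness
to tree error is probed separately by tip randomization (uniformly permuting
a fraction of leaf labels, preserving shape and lengths), which reproduces
the characteristic asymmetry that precision degrades slowly while recall
collapses.  None of this certifies behaviour on real, inferred trees with
misplaced subtrees or model misspecification.

Default experiment scales (100 recovery trees of 4–8 species; one ~200-gene
tree × 4 corruption fractions × 20 seeds) were chosen so the whole suite
runs in well under a minute on one CPU while keeping the stochastic
assertions stable across seeds.

## Benchmark scoring

Families are scored only over reference-covered genes, so a curated subset
can be scored inside a larger tree.  `best` mode matches each family to the
single orthogroup maximising F (ties: larger intersection, then smaller
orthogroup, then id); `majority` scores the union of orthogroups in which
strictly more than half of the reference-covered members belong to the
family.  Majority mode typically raises recall at equal precision, and the
tests check this on simulations; it is not a theorem (a family split across
one minority-share orthogroup and one small majority orthogroup can reverse
it), so it is asserted empirically, not proved.  The adjusted Rand index is
computed from the pair-counting contingency table; two degenerate identical
partitions (all singletons, or one cluster) return 1 by convention.

## Known limitations

- Orthology calls inherit every topological error of the input tree; the
  tool performs no tree correction.
- The species-overlap heuristic cannot distinguish a duplication followed by
  complementary losses from a speciation; with μ > 0 recovery is not exact.
- `like:` propagation aggregates all named orthogroups under the donating
  ancestor; with very permissive support gates and deep walks the label can
  become broad.
- Ingroup restriction reports outgroup genes as unassigned rather than
  clustering them separately.
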