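"""Scoring predicted orthogroups against reference gene families.

Per-family precision/recall/F-score against either the single best-matching
orthogroup or the union of orthogroups in which the family holds a majority;
size-weighted means across families; the adjusted Rand index between the two
clusterings; and a tip-randomization corruption of the input tree used to
probe robustness to gene misplacement.

Evaluation is restricted to the genes covered by the reference families, so a
curated subset of the tree can be scored without penalising predictions on
unannotated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .tree_io import GeneTree, OrthotreeError
from .graph_cluster import OrthogroupSet


@dataclass
class FamilyScore:
    family: str
    matched_ogs: list[str]
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float
    size: int


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def score_families(reference: Mapping[str, set], ogs: OrthogroupSet,
                   mode: str = "best") -> list[FamilyScore]:
    """Score each reference family against the predicted orthogroups.

    ``mode='best'`` matches each family to the single orthogroup maximising
    the F-score (ties: larger intersection, then smaller orthogroup, then
    id); ``mode='majority'`` scores the family against the union of all
    orthogroups in which strictly more than half of the reference-covered
    members belong to it.  Only genes appearing in some reference family
    enter the TP/FP/FN counts.
    """
    if mode not in ("best", "majority"):
        raise OrthotreeError(f"unknown scoring mode {mode!r}")
    fams = {f: set(m) for f, m in reference.items()}
    universe: set = set()
    for fam, members in fams.items():
        overlap = universe & members
        if overlap:
            raise OrthotreeError(
                f"reference families overlap (e.g. {sorted(overlap)[:3]})")
        universe |= members

    covered = {og: [g for g in members if g in universe]
               for og, members in ogs.groups.items()}
    covered = {og: mem for og, mem in covered.items() if mem}

    scores = []
    for fam in sorted(fams):
        fam_set = fams[fam]
        if mode == "best":
            best = None  # (-f, -inter, size, og)
            for og, mem in covered.items():
                inter = len(fam_set.intersection(mem))
                if inter == 0:
                    continue
                tp, fp, fn = inter, len(mem) - inter, len(fam_set) - inter
                _, _, f = _prf(tp, fp, fn)
                key = (-f, -inter, len(mem), og)
                if best is None or key < best[0]:
                    best = (key, og, tp, fp, fn)
            if best is None:
                matched, tp, fp, fn = [], 0, 0, len(fam_set)
            else:
                matched, tp, fp, fn = [best[1]], best[2], best[3], best[4]
        else:
            matched = [og for og, mem in covered.items()
                       if len(fam_set.intersection(mem)) * 2 > len(mem)]
            matched.sort()
            predicted = set().union(*(covered[og] for og in matched)) if matched else set()
            tp = len(predicted & fam_set)
            fp = len(predicted - fam_set)
            fn = len(fam_set - predicted)
        p, r, f = _prf(tp, fp, fn)
        scores.append(FamilyScore(family=fam, matched_ogs=matched, tp=tp,
                                  fp=fp, fn=fn, precision=p, recall=r,
                                  f_score=f, size=len(fam_set)))
    return scores


def weighted_mean(scores: Sequence[FamilyScore]) -> tuple[float, float, float]:
    """Family-size-weighted mean precision, recall and F-score."""
    if not scores:
        raise OrthotreeError("cannot average an empty score list")
    w = np.array([s.size for s in scores], dtype=float)
    p = np.array([s.precision for s in scores])
    r = np.array([s.recall for s in scores])
    f = np.array([s.f_score for s in scores])
    return (float(np.average(p, weights=w)),
            float(np.average(r, weights=w)),
            float(np.average(f, weights=w)))


def adjusted_rand_index(p: Iterable[set], q: Iterable[set]) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    1 for identical partitions; expectation 0 under random labelling with the
    same cluster sizes.
    """
    p = [set(c) for c in p if c]
    q = [set(c) for c in q if c]
    up = set().union(*p) if p else set()
    uq = set().union(*q) if q else set()
    if up != uq:
        raise OrthotreeError("partitions cover different element sets")

    def c2(x: int) -> float:
        return x * (x - 1) / 2.0

    index = sum(c2(len(a & b)) for a in p for b in q)
    sum_a = sum(c2(len(a)) for a in p)
    sum_b = sum(c2(len(b)) for b in q)
    n_pairs = c2(len(up))
    expected = sum_a * sum_b / n_pairs if n_pairs else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions trivial (all-singletons or one cluster)
    return (index - expected) / (max_index - expected)


def robustness_experiment(tree: GeneTree, truth: Mapping[str, set],
                          fractions: Sequence[float] = (0.0, 0.05, 0.1, 0.2),
                          n_seeds: int = 20, base_seed: int = 0,
                          mode: str = "best"):
    """Mean precision/recall under increasing tip randomization.

    For every corruption fraction, ``n_seeds`` independently corrupted copies
    of the tree are pushed through event calling, pair extraction and MCL
    clustering, and scored against the true families.  Returns a list of
    (fraction, mean precision, mean recall) triples.
    """
    from .species_overlap import classify_events, extract_ortholog_pairs
    from .graph_cluster import assign_orthogroups, build_graph

    out = []
    for fraction in fractions:
        ps, rs = [], []
        for i in range(n_seeds):
            corrupted = randomize_tips(tree, fraction, seed=base_seed + i + 1)
            events = classify_events(corrupted)
            pairs = extract_ortholog_pairs(corrupted, events)
            ogs = assign_orthogroups(
                build_graph(pairs, corrupted.leaf_labels))
            p, r, _ = weighted_mean(score_families(truth, ogs, mode=mode))
            ps.append(p)
            rs.append(r)
        out.append((fraction, float(np.mean(ps)), float(np.mean(rs))))
    return out


def randomize_tips(tree: GeneTree, fraction: float, seed: int) -> GeneTree:
    """Randomly permute a fraction of the leaf labels.

    ``ceil(fraction * n)`` leaves are sampled uniformly and their full labels
    (species prefix included) permuted uniformly among themselves; topology,
    branch lengths and supports are untouched.  This corrupts gene placement
    while preserving tree shape, emulating misassembled gene trees.
    """
    if not 0.0 <= fraction <= 1.0:
        raise OrthotreeError(f"fraction must be in [0, 1]: {fraction}")
    tree = tree.copy()
    leaves = tree.leaves
    m = math.ceil(fraction * len(leaves))
    if m < 2:
        return tree
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(leaves), size=m, replace=False)
    chosen = [leaves[i] for i in chosen_idx]
    perm = rng.permutation(m)
    originals = [(lf.label, lf.species, lf.gene_id) for lf in chosen]
    for lf, src in zip(chosen, (originals[i] for i in perm)):
        lf.label, lf.species, lf.gene_id = src
    tree._index()
    return tree
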