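import numpy as np
import pytest

import orthotree as ot


# Toy trees used across modules (species prefix "_", supports as fractions).
TWO_CHERRY = "((A_x1:1.0,B_y1:1.0)0.9:1.0,(A_x2:1.0,B_y2:1.0)0.8:1.0);"
NESTED = "((A_x1:1.0,(B_y1:1.0,B_y2:1.0)0.5:1.0)0.9:1.0,C_z1:1.0);"


@pytest.fixture
def two_cherry_tree():
    return ot.parse_gene_tree(TWO_CHERRY)


@pytest.fixture
def nested_tree():
    return ot.parse_gene_tree(NESTED)


def run_inference(tree, sos=0.0, inflation=1.6, min_support=0.0, weighted=True):
    """Rooted tree -> (events, pairs, orthogroups); the core of the pipeline."""
    events = ot.classify_events(tree, threshold=sos)
    pairs = ot.extract_ortholog_pairs(tree, events)
    graph = ot.build_graph(pairs, tree.leaf_labels, weighted=weighted,
                           min_support=min_support)
    ogs = ot.assign_orthogroups(graph, inflation=inflation)
    return events, pairs, ogs


def simulate_tree(seed, n_species=None, dup_rate=None, root_copies=None,
                  loss_rate=0.0, max_leaves=None):
    """One seeded duplication-loss simulation over a random species tree.

    Returns the SimTruth; re-draws internally (advancing the same generator)
    if all lineages go extinct.
    """
    rng = np.random.default_rng(seed)
    if n_species is None:
        n_species = int(rng.integers(4, 9))
    if dup_rate is None:
        dup_rate = float(rng.choice([0.0, 0.3, 0.6]))
    if root_copies is None:
        root_copies = int(rng.integers(1, 4))
    while True:
        sp = ot.random_species_tree(n_species, rng)
        cfg = ot.SimulationConfig(species_tree=sp, dup_rate=dup_rate,
                                  loss_rate=loss_rate, root_copies=root_copies)
        sim = ot.simulate_gene_tree(cfg, rng=rng)
        if sim.extinct:
            continue
        if max_leaves is not None and len(sim.tree) > max_leaves:
            continue
        return sim
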