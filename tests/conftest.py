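import numpy as np
import pytest

import indelopt as idl


@pytest.fixture
def tie_instance():
    """4-leaf instance with two tied optimal histories.

    Two cherries with patterns 101 and 110; the root can take either
    pattern at equal cost.
    """
    tree = idl.parse_newick("((A,B),(C,D));")
    records = [("A", "M-K"), ("B", "M-K"), ("C", "MK-"), ("D", "MK-")]
    aln = idl.reduce_columns(idl.encode_alignment(records))
    poag = idl.build_poag(aln)
    return tree, aln, poag


@pytest.fixture
def worked_pair():
    """Ancestor/descendant gap patterns used throughout the model docs."""
    E = np.array([1, 0, 0, 1, 1], dtype=np.uint8)
    F = np.array([0, 0, 1, 0, 1], dtype=np.uint8)
    return E, F


def make_random_instance(rng, max_assignments=200_000):
    """Random small tree + binary alignment whose brute force fits the cap."""
    while True:
        n = int(rng.integers(3, 6))
        m = int(rng.integers(3, 9))
        mat = rng.integers(0, 2, size=(n, m)).astype(np.uint8)
        if not (mat.any(axis=1).all() and mat.any(axis=0).all()):
            continue
        ids = [f"s{i}" for i in range(n)]
        params = idl.SimulationParams(
            n_leaves=n, delta=0.1, seed=int(rng.integers(2**31))
        )
        tree = idl.generate_tree(params)
        for j, leaf in enumerate(tree.leaf_indices):
            tree.node_labels[leaf] = ids[j]
        aln = idl.BinaryAlignment(ids, mat)
        poag = idl.build_poag(aln)
        n_paths = len(poag.paths(cap=max_assignments))
        if n_paths ** len(tree.internal_indices) > max_assignments:
            continue
        return tree, aln, poag
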