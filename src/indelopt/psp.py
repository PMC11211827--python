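"""Position-specific parsimony (PSP) baseline.

Each alignment column is treated as an independent binary character and
solved with Fitch's small-parsimony algorithm: a bottom-up pass builds
candidate state sets (intersection where non-empty, else union), a
top-down pass resolves ambiguity by preferring the parent's state, with
an ambiguous root defaulting to 1 (residue present).  Because columns
are independent, PSP can assemble ancestral patterns whose indel
arrangement occurs in no extant sequence (novel POAG edges) — the
weakness the whole-sequence formulation removes.
"""

from __future__ import annotations

import numpy as np

from .alignment import BinaryAlignment
from .mip import leaf_patterns
from .tree import PhyloTree

__all__ = ["psp_infer", "fitch_column_cost"]


def _fitch_sets(
    tree: PhyloTree, column_states: dict[int, int]
) -> tuple[dict[int, frozenset[int]], int]:
    """Bottom-up pass: candidate state sets per node plus the union count."""
    sets: dict[int, frozenset[int]] = {
        leaf: frozenset({column_states[leaf]}) for leaf in tree.leaf_indices
    }
    cost = 0
    for k in sorted(tree.internal_indices, reverse=True):  # children first
        child_sets = [sets[c] for c in tree.children_of[k]]
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[k] = inter
        else:
            sets[k] = frozenset.union(*child_sets)
            cost += 1
    return sets, cost


def fitch_column_cost(tree: PhyloTree, column_states: dict[int, int]) -> int:
    """Minimum number of state changes for one binary column (Fitch count)."""
    return _fitch_sets(tree, column_states)[1]


def psp_infer(
    tree: PhyloTree, aln: BinaryAlignment, root_tie_state: int = 1
) -> dict[int, np.ndarray]:
    """Per-column Fitch ancestral states assembled into node patterns.

    Returns patterns for every node (leaves echo the alignment rows).
    Tie-breaks are deterministic: the top-down pass keeps the parent's
    state whenever it is a candidate; an ambiguous root takes
    ``root_tie_state`` (default 1).
    """
    leaves = leaf_patterns(tree, aln)
    m = aln.m
    patterns = {k: np.zeros(m, dtype=np.uint8) for k in tree.internal_indices}
    patterns.update({k: v.copy() for k, v in leaves.items()})

    for i in range(m):
        column = {leaf: int(leaves[leaf][i]) for leaf in tree.leaf_indices}
        sets, _ = _fitch_sets(tree, column)
        states: dict[int, int] = {}
        for k in sorted(tree.internal_indices):  # parents first
            cands = sets[k]
            if len(cands) == 1:
                (states[k],) = cands
            elif k == tree.root_index:
                states[k] = root_tie_state
            else:
                parent_state = states[tree.parent_of[k]]
                states[k] = parent_state if parent_state in cands else root_tie_state
        for k, s in states.items():
            patterns[k][i] = s
    return patterns
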