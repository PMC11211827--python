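"""Evaluation of ancestral indel assignments.

Three complementary views of a full gap-pattern assignment on a tree:

* **indel score** — the minimum number of indel *events* the assignment
  implies, counting each maximal run of ancestor/descendant differences
  once and counting gap-orientation reversals as separate events;
* **evolutionary cohesiveness** — an ancestor is "incohesive" if at some
  site its state contradicts its parent *and all* of its children
  simultaneously (content blinking in or out for one generation);
* **footprint conformity** — an ancestor is "non-conforming" if its gap
  pattern uses an edge absent from the extant POAG, i.e. an indel
  arrangement no extant sequence exhibits.

A virtual site 0 with state 1 in every sequence (the dummy-start
convention) means a difference at site 1 always opens an event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import POAG, pattern_edges
from .tree import PhyloTree

__all__ = [
    "IndelMetrics",
    "branch_indel_events",
    "indel_score",
    "incohesive_ancestors",
    "nonconforming_ancestors",
    "compare_to_truth",
    "evaluate_assignment",
]


@dataclass
class IndelMetrics:
    indel_score: int = 0
    events_per_branch: dict[tuple[int, int], int] = field(default_factory=dict)
    incohesive_ancestors: list[tuple[int, list[int]]] = field(default_factory=list)
    incohesive_percent: float = 0.0
    nonconforming_ancestors: list[tuple[int, list[tuple[int, int]]]] = field(
        default_factory=list
    )
    nonconforming_percent: float = 0.0
    pattern_mismatches_vs_truth: dict[int, int] | None = None
    exact_pattern_matches: int | None = None


def branch_indel_events(ancestor_pattern, child_pattern) -> int:
    """Minimum indel events on one branch.

    A site counts iff the two patterns differ there and at least one of
    the two sequences changed state relative to the previous site (the
    virtual site 0 is occupied in both, so a site-1 difference always
    counts).
    """
    a = np.asarray(ancestor_pattern, dtype=int)
    c = np.asarray(child_pattern, dtype=int)
    if a.shape != c.shape:
        raise ValueError(f"pattern length mismatch: {a.shape} vs {c.shape}")
    a_prev = np.concatenate(([1], a[:-1]))
    c_prev = np.concatenate(([1], c[:-1]))
    events = (a != c) & ((a_prev != a) | (c_prev != c))
    return int(events.sum())


def indel_score(
    tree: PhyloTree, patterns_all_nodes: dict[int, np.ndarray]
) -> IndelMetrics:
    """Total indel events over every branch of the tree.

    The root contributes only through its outgoing branches.
    """
    per_branch: dict[tuple[int, int], int] = {}
    for k, l in tree.branches:
        for node in (k, l):
            if node not in patterns_all_nodes:
                raise ValueError(
                    f"no pattern for node {node} ({tree.node_labels[node]})"
                )
        per_branch[(k, l)] = branch_indel_events(
            patterns_all_nodes[k], patterns_all_nodes[l]
        )
    return IndelMetrics(
        indel_score=sum(per_branch.values()), events_per_branch=per_branch
    )


def incohesive_ancestors(
    tree: PhyloTree, patterns_all_nodes: dict[int, np.ndarray]
) -> tuple[list[tuple[int, list[int]]], float]:
    """Ancestors whose state at some site contradicts parent AND all children.

    Eligible ancestors are internal nodes with a parent (the root has no
    ancestor to contradict; leaf states are data).  Returns the flagged
    (node, 1-based sites) list and the percentage over eligible nodes.
    """
    eligible = [k for k in tree.internal_indices if k in tree.parent_of]
    flagged: list[tuple[int, list[int]]] = []
    for k in eligible:
        me = np.asarray(patterns_all_nodes[k], dtype=int)
        parent = np.asarray(patterns_all_nodes[tree.parent_of[k]], dtype=int)
        kids = [
            np.asarray(patterns_all_nodes[c], dtype=int) for c in tree.children_of[k]
        ]
        bad = me != parent
        for kid in kids:
            bad &= me != kid
        sites = [int(i) + 1 for i in np.flatnonzero(bad)]
        if sites:
            flagged.append((k, sites))
    pct = 100.0 * len(flagged) / len(eligible) if eligible else 0.0
    return flagged, round(pct, 1)


def nonconforming_ancestors(
    patterns_all_nodes: dict[int, np.ndarray],
    poag: POAG,
    ancestor_indices: list[int] | None = None,
) -> tuple[list[tuple[int, list[tuple[int, int]]]], float]:
    """Ancestors whose footprint uses edges not present in the extant POAG.

    All-gap ancestral patterns are flagged as degenerate (edge
    ``(0, m+1)``) rather than erroring.
    """
    if ancestor_indices is None:
        ancestor_indices = sorted(patterns_all_nodes)
    edge_set = set(poag.edges)
    flagged: list[tuple[int, list[tuple[int, int]]]] = []
    for k in ancestor_indices:
        pat = np.asarray(patterns_all_nodes[k], dtype=int)
        if not pat.any():
            flagged.append((k, [(0, poag.end)]))
            continue
        novel = [e for e in pattern_edges(pat) if e not in edge_set]
        if novel:
            flagged.append((k, novel))
    pct = 100.0 * len(flagged) / len(ancestor_indices) if ancestor_indices else 0.0
    return flagged, round(pct, 1)


def compare_to_truth(
    inferred_patterns: dict[int, np.ndarray],
    true_patterns: dict[int, np.ndarray],
) -> tuple[dict[int, int], int]:
    """Per-node Hamming distance to the ground truth + exact-match count."""
    if set(inferred_patterns) != set(true_patterns):
        raise ValueError(
            "node sets differ: "
            f"{sorted(set(inferred_patterns) ^ set(true_patterns))}"
        )
    mismatches = {
        k: int(
            (np.asarray(inferred_patterns[k], dtype=int)
             != np.asarray(true_patterns[k], dtype=int)).sum()
        )
        for k in inferred_patterns
    }
    exact = sum(1 for v in mismatches.values() if v == 0)
    return mismatches, exact


def evaluate_assignment(
    tree: PhyloTree,
    patterns_all_nodes: dict[int, np.ndarray],
    poag: POAG,
    true_patterns: dict[int, np.ndarray] | None = None,
) -> IndelMetrics:
    """All metrics for one full assignment (convenience wrapper)."""
    metrics = indel_score(tree, patterns_all_nodes)
    metrics.incohesive_ancestors, metrics.incohesive_percent = incohesive_ancestors(
        tree, patterns_all_nodes
    )
    anc = {k: patterns_all_nodes[k] for k in tree.internal_indices}
    (
        metrics.nonconforming_ancestors,
        metrics.nonconforming_percent,
    ) = nonconforming_ancestors(anc, poag, tree.internal_indices)
    if true_patterns is not None:
        true_anc = {k: true_patterns[k] for k in tree.internal_indices}
        (
            metrics.pattern_mismatches_vs_truth,
            metrics.exact_pattern_matches,
        ) = compare_to_truth(anc, true_anc)
    return metrics
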