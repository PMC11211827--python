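"""Rooted phylogenetic trees with parsimony-friendly node indexing.

Nodes are indexed with the root as 1, the remaining internal nodes
(ancestors) following in breadth-first order, and the leaves (extants)
after all internal nodes, also breadth-first.  For a strictly bifurcating
tree with ``n`` leaves this gives internal indices ``{1, ..., n-1}`` and
leaf indices ``{n, ..., 2n-1}``, and every branch ``(k, l)`` — ``k`` the
direct ancestor of ``l`` — satisfies ``k < l``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["PhyloTree", "TreeError", "parse_newick", "write_newick"]


class TreeError(ValueError):
    """Raised for malformed or invalid input trees."""


@dataclass
class PhyloTree:
    """A rooted tree indexed for ancestral indel inference.

    Attributes
    ----------
    node_labels : dict[int, str]
        Label per node index; unnamed internal nodes get ``"N<index>"``.
    parent_of : dict[int, int]
        Parent index for every non-root node.
    children_of : dict[int, list[int]]
        Child indices per internal node, in input order.
    branch_lengths : dict[int, float | None]
        Length of the branch above each non-root node (``None`` if absent).
        Preserved from the input but ignored by parsimony inference.
    """

    node_labels: dict[int, str]
    parent_of: dict[int, int]
    children_of: dict[int, list[int]]
    branch_lengths: dict[int, float | None] = field(default_factory=dict)

    root_index: int = 1

    @property
    def leaf_indices(self) -> list[int]:
        return sorted(k for k in self.node_labels if k not in self.children_of)

    @property
    def internal_indices(self) -> list[int]:
        return sorted(self.children_of)

    @property
    def branches(self) -> list[tuple[int, int]]:
        """All ordered branches ``(k, l)`` with ``k`` the direct ancestor."""
        return sorted((p, c) for c, p in self.parent_of.items())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def leaf_label_to_index(self) -> dict[str, int]:
        return {self.node_labels[i]: i for i in self.leaf_indices}

    def root_to_leaf_distances(self) -> dict[int, float]:
        """Path length from the root to each leaf (requires branch lengths)."""
        dist = {self.root_index: 0.0}
        for parent, child in self.branches:  # sorted => parents first
            bl = self.branch_lengths.get(child)
            if bl is None:
                raise TreeError(f"node {child} has no branch length")
            dist[child] = dist[parent] + bl
        return {leaf: dist[leaf] for leaf in self.leaf_indices}

    def validate(self) -> None:
        n_int = len(self.internal_indices)
        n = self.n_leaves
        if n < 2:
            raise TreeError(f"tree must have >= 2 leaves, got {n}")
        if self.root_index != 1 or 1 in self.parent_of:
            raise TreeError("root must be node 1 and have no parent")
        for k in self.node_labels:
            if k != self.root_index and k not in self.parent_of:
                raise TreeError(f"non-root node {k} has no parent")
        for parent, child in self.branches:
            if parent not in self.children_of:
                raise TreeError(f"branch parent {parent} is not internal")
            if parent >= child:
                raise TreeError(
                    f"indexing violated: branch ({parent},{child}) needs parent < child"
                )
        if set(self.internal_indices) != set(range(1, n_int + 1)):
            raise TreeError("internal indices must be 1..|N|")
        if set(self.leaf_indices) != set(range(n_int + 1, n_int + n + 1)):
            raise TreeError("leaf indices must follow internal indices")
        leaf_labels = [self.node_labels[i] for i in self.leaf_indices]
        dupes = {x for x in leaf_labels if leaf_labels.count(x) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")


def parse_newick(text: str, allow_multifurcation: bool = False) -> PhyloTree:
    """Parse a rooted Newick string into an indexed :class:`PhyloTree`.

    Multifurcating nodes are rejected unless ``allow_multifurcation`` is
    set (the inference model only needs the branch set, not bifurcation,
    but strictness catches accidentally unrooted inputs).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    root = dtree.seed_node
    if root.is_leaf():
        raise TreeError("tree must have >= 2 leaves")

    # Breadth-first walk: internal nodes first get 1..|N|, leaves then
    # |N|+1..|N|+n, both in BFS discovery order.
    bfs: list[dendropy.Node] = [root]
    for node in bfs:
        bfs.extend(node.child_nodes())

    internals = [v for v in bfs if not v.is_leaf()]
    leaves = [v for v in bfs if v.is_leaf()]
    if len(leaves) < 2:
        raise TreeError(f"tree must have >= 2 leaves, got {len(leaves)}")
    if not allow_multifurcation:
        for v in internals:
            deg = len(v.child_nodes())
            if deg != 2:
                raise TreeError(
                    f"node with {deg} children: tree is not strictly bifurcating "
                    "(pass allow_multifurcation=True to accept, or root the tree)"
                )

    index: dict[dendropy.Node, int] = {}
    for i, v in enumerate(internals, start=1):
        index[v] = i
    for j, v in enumerate(leaves, start=len(internals) + 1):
        index[v] = j

    labels: dict[int, str] = {}
    parent_of: dict[int, int] = {}
    children_of: dict[int, list[int]] = {}
    branch_lengths: dict[int, float | None] = {}
    for v, i in index.items():
        if v.is_leaf():
            if v.taxon is None or not v.taxon.label:
                raise TreeError("leaf without a label")
            labels[i] = v.taxon.label
        else:
            labels[i] = v.label if v.label else f"N{i}"
            children_of[i] = [index[c] for c in v.child_nodes()]
        if v is not root:
            parent_of[i] = index[v.parent_node]
            branch_lengths[i] = v.edge.length

    tree = PhyloTree(labels, parent_of, children_of, branch_lengths)
    tree.validate()
    return tree


def write_newick(tree: PhyloTree, include_branch_lengths: bool = True) -> str:
    """Serialize back to Newick; round-trips topology and all labels."""

    def render(i: int) -> str:
        label = _quote(tree.node_labels[i])
        if i in tree.children_of:
            inner = ",".join(render(c) for c in tree.children_of[i])
            out = f"({inner}){label}"
        else:
            out = label
        bl = tree.branch_lengths.get(i)
        if include_branch_lengths and bl is not None:
            out += f":{bl:.10g}"
        return out

    return render(tree.root_index) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label
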