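"""Binary gap/non-gap encoding of alignments and the partial-order
alignment graph (POAG) of indel footprints.

An aligned FASTA file is reduced to a 0/1 matrix (1 = residue, 0 = gap);
only this gap structure is used by indel inference.  The POAG is the
union, over all extant sequences, of directed edges between consecutive
occupied sites, augmented with a dummy start site 0 and dummy end site
m+1 so that terminal gaps need no special casing.  Each sequence's edge
path from start to end is its "indel footprint".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "BinaryAlignment",
    "POAG",
    "encode_alignment",
    "read_fasta_alignment",
    "reduce_columns",
    "build_poag",
    "pattern_edges",
]


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


@dataclass
class BinaryAlignment:
    """Binary gap/non-gap matrix over extant sequences.

    ``matrix[r, i]`` is 1 iff row ``r`` has a residue at (1-based) site
    ``i+1``.  ``column_map[i]`` lists the original MSA columns (1-based)
    that reduced site ``i+1`` represents; before reduction it is the
    identity.
    """

    row_ids: list[str]
    matrix: np.ndarray  # shape (n_rows, m), dtype uint8
    column_map: list[list[int]] = field(default_factory=list)
    dropped_columns: list[int] = field(default_factory=list)  # all-gap originals

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D")
        if not self.column_map:
            self.column_map = [[j + 1] for j in range(self.matrix.shape[1])]
        if len(self.row_ids) != self.matrix.shape[0]:
            raise AlignmentError("row_ids / matrix shape mismatch")
        if len(self.column_map) != self.matrix.shape[1]:
            raise AlignmentError("column_map / matrix width mismatch")
        if not np.isin(self.matrix, (0, 1)).all():
            raise AlignmentError("matrix entries must be 0 or 1")
        empties = [self.row_ids[r] for r in np.flatnonzero(~self.matrix.any(axis=1))]
        if empties:
            raise AlignmentError(f"fully gapped sequence(s): {empties}")

    @property
    def m(self) -> int:
        """Number of (possibly reduced) sites."""
        return self.matrix.shape[1]

    @property
    def original_width(self) -> int:
        return sum(len(cols) for cols in self.column_map) + len(self.dropped_columns)

    def row(self, row_id: str) -> np.ndarray:
        return self.matrix[self.row_ids.index(row_id)]

    def expand_pattern(self, pattern: np.ndarray) -> np.ndarray:
        """Map a reduced-coordinate binary pattern back to original columns."""
        pattern = np.asarray(pattern, dtype=np.uint8)
        if pattern.shape != (self.m,):
            raise AlignmentError(f"pattern length {pattern.shape} != m={self.m}")
        out = np.zeros(self.original_width, dtype=np.uint8)  # dropped stay gapped
        for i, cols in enumerate(self.column_map):
            for c in cols:
                out[c - 1] = pattern[i]
        return out


@dataclass
class POAG:
    """Partial-order alignment graph over sites ``0..m+1``.

    ``edges`` are ordered pairs ``(i, j)``, ``i < j``, with 0 the dummy
    start and ``m+1`` the dummy end.  ``footprints`` maps each extant row
    id to its start-to-end edge path.
    """

    m: int
    edges: list[tuple[int, int]]
    footprints: dict[str, list[tuple[int, int]]]

    @property
    def start(self) -> int:
        return 0

    @property
    def end(self) -> int:
        return self.m + 1

    @property
    def in_edges(self) -> dict[int, list[tuple[int, int]]]:
        out: dict[int, list[tuple[int, int]]] = {s: [] for s in range(self.m + 2)}
        for e in self.edges:
            out[e[1]].append(e)
        return out

    @property
    def out_edges(self) -> dict[int, list[tuple[int, int]]]:
        out: dict[int, list[tuple[int, int]]] = {s: [] for s in range(self.m + 2)}
        for e in self.edges:
            out[e[0]].append(e)
        return out

    def paths(self, cap: int = 10**6) -> list[tuple[int, ...]]:
        """Enumerate all start-to-end site paths (for small instances)."""
        out_edges = self.out_edges
        results: list[tuple[int, ...]] = []
        stack: list[tuple[int, tuple[int, ...]]] = [(0, (0,))]
        while stack:
            site, path = stack.pop()
            if site == self.end:
                results.append(path)
                if len(results) > cap:
                    raise AlignmentError(f"more than {cap} POAG paths")
                continue
            for _, j in out_edges[site]:
                stack.append((j, path + (j,)))
        return results


def read_fasta_alignment(path_or_handle) -> list[tuple[str, str]]:
    """Read an aligned FASTA file into ``(id, sequence)`` pairs."""
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    if not records:
        raise AlignmentError("empty alignment input")
    return [(r.id, str(r.seq)) for r in records]


def encode_alignment(
    records: list[tuple[str, str]], gap_chars: str = "-."
) -> BinaryAlignment:
    """Encode aligned sequences as a binary matrix (1 = residue, 0 = gap)."""
    if not records:
        raise AlignmentError("empty alignment input")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
    (width,) = lengths
    if width < 1:
        raise AlignmentError("alignment has zero columns")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence identifiers")
    gaps = set(gap_chars)
    matrix = np.array(
        [[0 if ch in gaps else 1 for ch in seq] for _, seq in records],
        dtype=np.uint8,
    )
    return BinaryAlignment(ids, matrix)


def reduce_columns(aln: BinaryAlignment, collapse_identical: bool = False) -> BinaryAlignment:
    """Apply the lossless column preprocessing.

    Columns gapped in every row are dropped; each maximal run of >= 2
    consecutive all-occupied columns collapses to one representative
    site.  ``collapse_identical`` additionally collapses runs of columns
    with identical binary pattern (off by default).  ``column_map``
    records the original columns behind each surviving site so inference
    output can be expanded back.
    """
    mat = aln.matrix
    keep_cols: list[list[int]] = []  # original 1-based columns per reduced site
    keep_pattern: list[np.ndarray] = []
    dropped = list(aln.dropped_columns)

    def mergeable(col: np.ndarray, prev: np.ndarray) -> bool:
        if collapse_identical:
            return bool((col == prev).all())
        return bool(col.all() and prev.all())

    for j in range(mat.shape[1]):
        col = mat[:, j]
        orig = list(aln.column_map[j])
        if not col.any():  # all-gap column: removed entirely
            dropped.extend(orig)
            continue
        # only originally-consecutive runs collapse: a dropped or differing
        # column in between breaks the run
        adjacent = bool(keep_cols) and keep_cols[-1][-1] + 1 == orig[0]
        if keep_pattern and adjacent and mergeable(col, keep_pattern[-1]):
            keep_cols[-1].extend(orig)
        else:
            keep_cols.append(orig)
            keep_pattern.append(col.copy())

    if not keep_pattern:
        raise AlignmentError("alignment reduces to zero columns")
    reduced = np.column_stack(keep_pattern).astype(np.uint8)
    return BinaryAlignment(list(aln.row_ids), reduced, keep_cols, sorted(dropped))


def pattern_edges(pattern: np.ndarray) -> list[tuple[int, int]]:
    """Indel footprint of a binary site pattern.

    Returns the ordered edge path from dummy start 0 through the
    pattern's occupied sites (1-based) to dummy end ``m+1``.
    """
    pattern = np.asarray(pattern, dtype=np.uint8)
    m = pattern.shape[0]
    occupied = [int(i) + 1 for i in np.flatnonzero(pattern)]
    if not occupied:
        raise AlignmentError("all-gap pattern has no footprint")
    nodes = [0] + occupied + [m + 1]
    return list(zip(nodes[:-1], nodes[1:]))


def build_poag(aln: BinaryAlignment) -> POAG:
    """Union of extant indel footprints, with dummy start/end sites."""
    footprints: dict[str, list[tuple[int, int]]] = {}
    edge_set: set[tuple[int, int]] = set()
    for rid, row in zip(aln.row_ids, aln.matrix):
        fp = pattern_edges(row)
        footprints[rid] = fp
        edge_set.update(fp)
    return POAG(aln.m, sorted(edge_set), footprints)
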