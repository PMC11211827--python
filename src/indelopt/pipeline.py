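"""End-to-end convenience wrappers: alignment + tree in, solution out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import (
    BinaryAlignment,
    POAG,
    build_poag,
    encode_alignment,
    reduce_columns,
)
from .metrics import IndelMetrics, evaluate_assignment
from .mip import (
    IndelModel,
    IndelSolution,
    SolveConfig,
    enumerate_optima,
    leaf_patterns,
)
from .tree import PhyloTree

__all__ = ["InferenceResult", "infer_indel_history", "full_patterns"]


@dataclass
class InferenceResult:
    tree: PhyloTree
    alignment: BinaryAlignment  # reduced coordinates
    poag: POAG
    solutions: list[IndelSolution]  # canonical order; [0] is reported
    metrics: IndelMetrics

    @property
    def solution(self) -> IndelSolution:
        return self.solutions[0]


def full_patterns(
    tree: PhyloTree, aln: BinaryAlignment, solution: IndelSolution
) -> dict[int, np.ndarray]:
    """Ancestral + extant patterns as one map (reduced coordinates)."""
    full = leaf_patterns(tree, aln)
    full.update(solution.ancestral_patterns)
    return full


def infer_indel_history(
    records: list[tuple[str, str]],
    tree: PhyloTree,
    config: SolveConfig | None = None,
    enumerate_ties: bool = False,
) -> InferenceResult:
    """Encode, reduce, build the POAG, solve the MIP, score the solution.

    With ``enumerate_ties`` all alternative optima (up to
    ``config.max_alternatives``) are returned in canonical order.
    """
    config = config or SolveConfig()
    aln = reduce_columns(encode_alignment(records))
    poag = build_poag(aln)
    model = IndelModel(tree, aln, poag, config)
    first = model.solve()
    if enumerate_ties and first.status == "optimal":
        solutions = enumerate_optima(model, first)
    else:
        solutions = [first]
    metrics = evaluate_assignment(
        tree, full_patterns(tree, aln, solutions[0]), poag
    )
    return InferenceResult(tree, aln, poag, solutions, metrics)
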