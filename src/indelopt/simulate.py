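"""Synthetic indel-evolution data with recorded ground truth.

Generates a random strictly bifurcating tree whose branch lengths are
Gamma(kappa, theta) draws rescaled so the mean root-to-leaf distance
equals delta, then evolves gap patterns from an all-occupied root down
every branch: indel events arrive as a Poisson count proportional to
branch length and current sequence length, each event is an insertion
or deletion with equal probability, with geometrically distributed
length and a uniform position.  Insertions open fresh alignment columns
that are gapped everywhere outside the subtree below the event, so the
emitted extant alignment is perfect by construction and every node's
true gap pattern is known.

Columns with no residue in any extant sequence are dropped from both
the alignment and all recorded patterns: the truth is reported in
observable coordinates (history that left no trace in the extants, such
as an insertion later fully deleted, is not representable as columns).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .metrics import indel_score
from .tree import PhyloTree, write_newick

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "generate_tree",
    "evolve_indels",
    "simulate",
    "write_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Generator settings.

    delta is the mean root-to-leaf evolutionary distance; kappa/theta
    the Gamma shape/scale for raw branch lengths (theta 0.2); indel_rate
    the expected events per unit branch length for a root-length
    sequence; indel lengths are geometric with the given mean.
    """

    n_leaves: int = 50
    delta: float = 0.1
    kappa: float = 1.0
    theta: float = 0.2
    root_length: int = 200
    indel_rate: float = 1.0
    mean_indel_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        for name in ("delta", "kappa", "theta", "indel_rate", "mean_indel_length"):
            if getattr(self, name) < 0 or (
                name in ("delta", "kappa", "theta", "mean_indel_length")
                and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")


@dataclass
class SimulationResult:
    tree: PhyloTree
    true_patterns: dict[int, np.ndarray]
    extant_records: list[tuple[str, str]]
    truth_indel_score: int
    params: SimulationParams


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def generate_tree(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> PhyloTree:
    """Random bifurcating tree; mean root-to-leaf distance rescaled to delta."""
    rng = rng if rng is not None else _rng(params, 0)
    n = params.n_leaves
    # grow topology: split a uniformly chosen current leaf until n leaves
    children: dict[int, list[int]] = {0: [1, 2]}
    tips = [1, 2]
    next_id = 3
    while len(tips) < n:
        pos = int(rng.integers(len(tips)))
        v = tips.pop(pos)
        children[v] = [next_id, next_id + 1]
        tips.extend([next_id, next_id + 1])
        next_id += 2

    # breadth-first reindex: internals 1..n-1, leaves n..2n-1
    order = [0]
    for v in order:
        order.extend(children.get(v, []))
    internals = [v for v in order if v in children]
    leaves = [v for v in order if v not in children]
    index = {v: i for i, v in enumerate(internals, start=1)}
    index.update({v: j for j, v in enumerate(leaves, start=len(internals) + 1)})

    labels = {index[v]: f"N{index[v]}" for v in internals}
    labels.update(
        {index[v]: f"t{j}" for j, v in enumerate(leaves, start=1)}
    )
    parent_of = {
        index[c]: index[v] for v, cs in children.items() for c in cs
    }
    children_of = {index[v]: [index[c] for c in cs] for v, cs in children.items()}

    lengths = {
        c: float(rng.gamma(params.kappa, params.theta)) for c in parent_of
    }
    tree = PhyloTree(labels, parent_of, children_of, lengths)
    mean_depth = float(np.mean(list(tree.root_to_leaf_distances().values())))
    scale = params.delta / mean_depth if mean_depth > 0 else 1.0
    tree.branch_lengths = {c: bl * scale for c, bl in lengths.items()}
    tree.validate()
    return tree


def evolve_indels(
    tree: PhyloTree,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Evolve gap patterns down the tree; record full ground truth."""
    rng = rng if rng is not None else _rng(params, 1)
    geom_p = 1.0 / params.mean_indel_length
    patterns: dict[int, list[int]] = {
        tree.root_index: [1] * params.root_length
    }

    def splice_zeros(at: int, length: int) -> None:
        for pat in patterns.values():
            pat[at:at] = [0] * length

    for parent, child in tree.branches:  # parents always precede children
        cur = list(patterns[parent])
        bl = tree.branch_lengths.get(child) or 0.0
        present = sum(cur)
        lam = params.indel_rate * bl * present / params.root_length
        n_events = int(rng.poisson(lam)) if lam > 0 else 0
        for _ in range(n_events):
            present_idx = [g for g, v in enumerate(cur) if v == 1]
            L = len(present_idx)
            length = int(rng.geometric(geom_p))
            if rng.random() < 0.5 and L > 1:  # deletion
                start = int(rng.integers(L))
                removed = min(length, L - start)
                if removed >= L:
                    removed = L - 1  # never delete the whole sequence
                    logger.info("deletion truncated to keep sequence non-empty")
                for g in present_idx[start : start + removed]:
                    cur[g] = 0
            else:  # insertion (also taken when a deletion would empty the row)
                anchor = int(rng.integers(L + 1))
                at = present_idx[anchor - 1] + 1 if anchor > 0 else (
                    present_idx[0] if L else 0
                )
                splice_zeros(at, length)
                cur[at:at] = [1] * length
        patterns[child] = cur

    # observable coordinates: keep columns with >= 1 extant residue
    mat = np.array([patterns[leaf] for leaf in tree.leaf_indices], dtype=np.uint8)
    keep = np.flatnonzero(mat.any(axis=0))
    true_patterns = {
        k: np.asarray(v, dtype=np.uint8)[keep] for k, v in patterns.items()
    }
    records = [
        (
            tree.node_labels[leaf],
            "".join("X" if v else "-" for v in true_patterns[leaf]),
        )
        for leaf in tree.leaf_indices
    ]
    score = indel_score(tree, true_patterns).indel_score
    return SimulationResult(tree, true_patterns, records, score, params)


def simulate(params: SimulationParams) -> SimulationResult:
    """Tree generation plus indel evolution, fully determined by the seed."""
    return evolve_indels(generate_tree(params), params)


def write_dataset(result: SimulationResult, outdir: str | Path) -> Path:
    """Write tree.nwk, extants.fasta, truth.json and params.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(write_newick(result.tree) + "\n")
    with open(outdir / "extants.fasta", "w") as fh:
        for rid, seq in result.extant_records:
            fh.write(f">{rid}\n{seq}\n")
    truth = {
        "patterns": {
            result.tree.node_labels[k]: "".join(map(str, v.tolist()))
            for k, v in sorted(result.true_patterns.items())
        },
        "truth_indel_score": result.truth_indel_score,
        "params": asdict(result.params),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    (outdir / "params.json").write_text(
        json.dumps(asdict(result.params), indent=1) + "\n"
    )
    return outdir


def load_dataset(outdir: str | Path) -> tuple[Path, Path, dict]:
    """Paths to tree/alignment plus the parsed truth record."""
    outdir = Path(outdir)
    truth = json.loads((outdir / "truth.json").read_text())
    return outdir / "tree.nwk", outdir / "extants.fasta", truth
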