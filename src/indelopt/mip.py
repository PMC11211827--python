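"""Globally optimal ancestral indel inference as a mixed-integer program.

The model assigns every ancestor (internal tree node) a start-to-end
path through the extant POAG.  Binary variables:

* ``a_ki`` — residue present (1) or gap (0) at ancestor ``k``, site ``i``;
* ``y_kp`` — ancestor ``k`` uses POAG edge ``p``;
* ``d_bi`` — the two ends of branch ``b`` differ at site ``i``;
* ``g_bi`` — a run of differences opens (or the gap orientation
  reverses) at site ``i`` on branch ``b``.

Flow-conservation constraints tie ``y`` to ``a`` (in-degree = presence =
out-degree at every real site, unit flow at the dummy start/end), so
each ancestor's edges form exactly one POAG path.  ``d`` is the
linearized absolute difference |a_k - a_l|; both the lower bounds
(d >= +/-(a_k - a_l)) and the upper bounds (d <= a_k + a_l,
d <= 2 - a_k - a_l) are imposed — the upper bounds matter because the
gap-opening constraint subtracts the previous site's ``d``, so an
under-constrained ``d`` could be inflated at cost 1 to dodge an opening
at cost alpha.  ``g`` obeys the affine-gap bookkeeping: it equals ``d``
at site 1, covers every 0->1 rise of ``d``, and covers gap-orientation
reversals (a deletion immediately following an insertion, or vice
versa, counts as two events).  The objective minimizes
``sum_b sum_i (d_bi + alpha * g_bi)``: total site differences plus
``alpha`` per opened event, an affine gap penalty applied along every
branch of the tree.

The solver is HiGHS via :func:`scipy.optimize.milp`.  The problem is a
large network-flow core with side constraints and solves quickly in
practice despite the small-parsimony problem being NP-hard in general.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .alignment import POAG, AlignmentError, BinaryAlignment, pattern_edges
from .tree import PhyloTree

__all__ = [
    "SolveConfig",
    "IndelSolution",
    "IndelModel",
    "ModelError",
    "build_model",
    "solve",
    "enumerate_optima",
    "evaluate_objective",
    "affine_gap_vectors",
    "brute_force_optimum",
    "leaf_patterns",
]

_OBJ_TOL = 1e-6


class ModelError(RuntimeError):
    """Raised for inconsistent model inputs or solver failures."""


@dataclass
class SolveConfig:
    """Solver settings.

    alpha weighs opening a new indel event against extending one
    (default 2: one opening costs as much as two changed sites).
    """

    alpha: float = 2.0
    time_limit_seconds: float = 3600.0
    solver_backend: str = "highs"
    threads: int = 1
    random_seed: int | None = None
    max_alternatives: int = 10

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.time_limit_seconds <= 0:
            raise ValueError("time_limit_seconds must be > 0")
        if self.solver_backend != "highs":
            raise ModelError(
                f"solver backend {self.solver_backend!r} not available; "
                "this build supports 'highs' (scipy.optimize.milp)"
            )


@dataclass
class IndelSolution:
    """One optimal (or incumbent) assignment of ancestral gap patterns."""

    ancestral_patterns: dict[int, np.ndarray]
    selected_edges: dict[int, list[tuple[int, int]]]
    objective_value: float
    status: str  # optimal | feasible_time_limit | infeasible | error
    alpha_used: float
    solution_rank: int = 1
    gap: float = 0.0

    def pattern_strings(self, tree: PhyloTree) -> dict[str, str]:
        return {
            tree.node_labels[k]: "".join(map(str, v.tolist()))
            for k, v in sorted(self.ancestral_patterns.items())
        }


def leaf_patterns(tree: PhyloTree, aln: BinaryAlignment) -> dict[int, np.ndarray]:
    """Map tree leaf indices to alignment rows; hard error on mismatch."""
    by_label = {rid: aln.matrix[r] for r, rid in enumerate(aln.row_ids)}
    leaf_labels = {tree.node_labels[i] for i in tree.leaf_indices}
    missing = sorted(leaf_labels - set(by_label))
    extra = sorted(set(by_label) - leaf_labels)
    if missing or extra:
        raise ModelError(
            f"tree/alignment mismatch: leaves missing from alignment {missing}, "
            f"alignment rows not in tree {extra}"
        )
    return {i: by_label[tree.node_labels[i]] for i in tree.leaf_indices}


class IndelModel:
    """Sparse MILP over one tree + reduced alignment + POAG."""

    def __init__(
        self,
        tree: PhyloTree,
        aln: BinaryAlignment,
        poag: POAG,
        config: SolveConfig | None = None,
    ):
        self.tree = tree
        self.aln = aln
        self.poag = poag
        self.config = config or SolveConfig()
        if not poag.edges:
            raise ModelError("empty POAG")
        if poag.m != aln.m:
            raise ModelError("POAG and alignment disagree on site count")

        self.leaves = leaf_patterns(tree, aln)
        m = aln.m
        self.internals = tree.internal_indices
        self.branch_list = tree.branches
        self.edge_index = {e: j for j, e in enumerate(poag.edges)}
        nN, nE, nB = len(self.internals), len(poag.edges), len(self.branch_list)
        self._int_pos = {k: p for p, k in enumerate(self.internals)}

        # variable layout: [a (nN*m) | y (nN*nE) | d (nB*m) | g (nB*m)]
        self.a_off = 0
        self.y_off = nN * m
        self.d_off = self.y_off + nN * nE
        self.g_off = self.d_off + nB * m
        self.n_vars = self.g_off + nB * m
        self.m = m

        self._build()

    # -- variable index helpers -------------------------------------------
    def a_var(self, k: int, i: int) -> int:
        """a-variable of internal node k at 1-based site i."""
        return self.a_off + self._int_pos[k] * self.m + (i - 1)

    def y_var(self, k: int, edge: tuple[int, int]) -> int:
        return self.y_off + self._int_pos[k] * len(self.poag.edges) + self.edge_index[edge]

    def d_var(self, b: int, i: int) -> int:
        return self.d_off + b * self.m + (i - 1)

    def g_var(self, b: int, i: int) -> int:
        return self.g_off + b * self.m + (i - 1)

    def _state(self, node: int, i: int):
        """(var_index, None) for an ancestor, (None, constant) for a leaf."""
        if node in self._int_pos:
            return self.a_var(node, i), None
        return None, int(self.leaves[node][i - 1])

    # -- model assembly ----------------------------------------------------
    def _build(self) -> None:
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        lb: list[float] = []
        ub: list[float] = []
        r = 0

        def add_row(terms: list[tuple[int, float]], lo: float, hi: float) -> None:
            nonlocal r
            for c, v in terms:
                rows.append(r)
                cols.append(c)
                vals.append(v)
            lb.append(lo)
            ub.append(hi)
            r += 1

        in_e, out_e = self.poag.in_edges, self.poag.out_edges
        m = self.m
        INF = np.inf

        # flow: per ancestor, in-sum = a = out-sum at each real site;
        # unit flow out of dummy start and into dummy end
        for k in self.internals:
            for i in range(1, m + 1):
                add_row(
                    [(self.y_var(k, e), 1.0) for e in in_e[i]]
                    + [(self.a_var(k, i), -1.0)],
                    0.0, 0.0,
                )
                add_row(
                    [(self.y_var(k, e), 1.0) for e in out_e[i]]
                    + [(self.a_var(k, i), -1.0)],
                    0.0, 0.0,
                )
            add_row([(self.y_var(k, e), 1.0) for e in out_e[0]], 1.0, 1.0)
            add_row([(self.y_var(k, e), 1.0) for e in in_e[m + 1]], 1.0, 1.0)

        # d = |a_k - a_l|, linearized from both sides
        for b, (k, l) in enumerate(self.branch_list):
            for i in range(1, m + 1):
                dv = self.d_var(b, i)
                kv, kc = self._state(k, i)
                lv, lc = self._state(l, i)
                # d - (a_k - a_l) >= 0  and  d + (a_k - a_l) >= 0
                for sk, sl in ((-1.0, 1.0), (1.0, -1.0)):
                    terms = [(dv, 1.0)]
                    shift = 0.0
                    if kv is not None:
                        terms.append((kv, sk))
                    else:
                        shift -= sk * kc
                    if lv is not None:
                        terms.append((lv, sl))
                    else:
                        shift -= sl * lc
                    add_row(terms, shift, INF)
                # d - a_k - a_l <= 0  and  d + a_k + a_l <= 2
                for sgn, cap in ((-1.0, 0.0), (1.0, 2.0)):
                    terms = [(dv, 1.0)]
                    shift = cap
                    if kv is not None:
                        terms.append((kv, sgn))
                    else:
                        shift -= sgn * kc
                    if lv is not None:
                        terms.append((lv, sgn))
                    else:
                        shift -= sgn * lc
                    add_row(terms, -INF, shift)

        # affine gap opening
        for b, (k, l) in enumerate(self.branch_list):
            add_row([(self.g_var(b, 1), 1.0), (self.d_var(b, 1), -1.0)], 0.0, 0.0)
            for i in range(2, m + 1):
                # g_i >= d_i - d_{i-1}
                add_row(
                    [
                        (self.g_var(b, i), 1.0),
                        (self.d_var(b, i), -1.0),
                        (self.d_var(b, i - 1), 1.0),
                    ],
                    0.0, INF,
                )
                # gap-orientation reversal bounds:
                # g_i >= a_k(i-1) + a_l(i) - a_l(i-1) - a_k(i) - 1  and the mirror
                for coeffs in (
                    ((k, i - 1, -1.0), (l, i, -1.0), (l, i - 1, 1.0), (k, i, 1.0)),
                    ((k, i, -1.0), (l, i - 1, -1.0), (l, i, 1.0), (k, i - 1, 1.0)),
                ):
                    terms = [(self.g_var(b, i), 1.0)]
                    shift = -1.0
                    for node, site, sgn in coeffs:
                        v, c = self._state(node, site)
                        if v is not None:
                            terms.append((v, sgn))
                        else:
                            shift -= sgn * c
                    add_row(terms, shift, INF)

        self._A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(r, self.n_vars)
        )
        self._lb = np.array(lb)
        self._ub = np.array(ub)

        c = np.zeros(self.n_vars)
        nBm = len(self.branch_list) * m
        c[self.d_off : self.d_off + nBm] = 1.0
        c[self.g_off :] = self.config.alpha
        self.objective = c

    @property
    def n_constraints(self) -> int:
        return self._A.shape[0]

    # -- solving -----------------------------------------------------------
    def solve(
        self, extra_constraints: list[LinearConstraint] | None = None
    ) -> IndelSolution:
        cons = [LinearConstraint(self._A, self._lb, self._ub)]
        if extra_constraints:
            cons.extend(extra_constraints)
        res = milp(
            c=self.objective,
            constraints=cons,
            integrality=np.ones(self.n_vars),
            bounds=Bounds(0, 1),
            options={
                "time_limit": self.config.time_limit_seconds,
                "mip_rel_gap": 0.0,
            },
        )
        if res.status == 2 or (res.status != 0 and res.x is None):
            status = "infeasible" if res.status == 2 else "error"
            return IndelSolution({}, {}, float("nan"), status, self.config.alpha)
        status = "optimal" if res.status == 0 else "feasible_time_limit"
        sol = self._extract(res.x, status, res.mip_gap or 0.0)
        self._verify(sol)
        return sol

    def _extract(self, x: np.ndarray, status: str, gap: float) -> IndelSolution:
        x = np.round(x).astype(int)
        patterns: dict[int, np.ndarray] = {}
        edges: dict[int, list[tuple[int, int]]] = {}
        for k in self.internals:
            patterns[k] = np.array(
                [x[self.a_var(k, i)] for i in range(1, self.m + 1)], dtype=np.uint8
            )
            edges[k] = sorted(
                e for e in self.poag.edges if x[self.y_var(k, e)] == 1
            )
        obj = float(self.objective @ x)
        return IndelSolution(patterns, edges, obj, status, self.config.alpha, gap=gap)

    def _verify(self, sol: IndelSolution) -> None:
        """Re-check path structure and objective independently of the solver."""
        for k, es in sol.selected_edges.items():
            expected = pattern_edges(sol.ancestral_patterns[k])
            if sorted(expected) != es:
                raise ModelError(
                    f"solver returned non-path edge set for ancestor {k}"
                )
            if not set(es) <= set(self.poag.edges):
                raise ModelError(f"ancestor {k} uses edges outside the POAG")
        full = dict(self.leaves)
        full.update(sol.ancestral_patterns)
        obj, _, _ = evaluate_objective(full, self.tree, self.config.alpha)
        if abs(obj - sol.objective_value) > _OBJ_TOL:
            raise ModelError(
                f"objective mismatch: solver {sol.objective_value} vs "
                f"recomputed {obj}"
            )
        sol.objective_value = obj

    # -- alternative optima --------------------------------------------------
    def no_good_cut(self, sol: IndelSolution) -> LinearConstraint:
        """Exclude exactly one edge assignment: sum of its y's <= Q - 1."""
        idx = [
            self.y_var(k, e) for k, es in sol.selected_edges.items() for e in es
        ]
        row = sparse.csr_matrix(
            (np.ones(len(idx)), (np.zeros(len(idx), dtype=int), idx)),
            shape=(1, self.n_vars),
        )
        return LinearConstraint(row, -np.inf, len(idx) - 1)

    def objective_fix(self, value: float) -> LinearConstraint:
        row = sparse.csr_matrix(self.objective.reshape(1, -1))
        return LinearConstraint(row, value - _OBJ_TOL, value + _OBJ_TOL)


def build_model(
    tree: PhyloTree,
    aln: BinaryAlignment,
    poag: POAG,
    config: SolveConfig | None = None,
) -> IndelModel:
    return IndelModel(tree, aln, poag, config)


def solve(model: IndelModel, config: SolveConfig | None = None) -> IndelSolution:
    if config is not None:
        model.config = config
    return model.solve()


def enumerate_optima(
    model: IndelModel,
    first: IndelSolution,
    config: SolveConfig | None = None,
) -> list[IndelSolution]:
    """All optima tied with ``first``, via iterated no-good cuts.

    Each accepted solution contributes one cut that forbids exactly its
    own edge assignment; the objective is pinned to the first optimum so
    the search stops (reports infeasible) once the ties are exhausted.
    Solutions are returned in canonical order (lexicographic by
    concatenated ancestral patterns) and ranked.
    """
    if config is not None:
        model.config = config
    cfg = model.config
    if first.status != "optimal":
        raise ModelError("enumeration requires a proven-optimal first solution")
    found = [first]
    cuts = [model.objective_fix(first.objective_value), model.no_good_cut(first)]
    while len(found) < max(cfg.max_alternatives, 1):
        sol = model.solve(extra_constraints=cuts)
        if sol.status != "optimal":
            break
        if sol.objective_value > first.objective_value + _OBJ_TOL:
            break
        found.append(sol)
        cuts.append(model.no_good_cut(sol))

    def key(s: IndelSolution) -> str:
        return "".join(
            "".join(map(str, s.ancestral_patterns[k].tolist()))
            for k in sorted(s.ancestral_patterns)
        )

    found.sort(key=key)
    for rank, s in enumerate(found, start=1):
        s.solution_rank = rank
    return found


# -- objective evaluation (solver-independent) -----------------------------

def affine_gap_vectors(
    ancestor: np.ndarray,
    child: np.ndarray,
    include_reversal: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference vector d and minimal gap-opening vector g for one branch.

    ``d_i = |a_i - c_i|``.  ``g`` is the smallest binary vector with
    ``g_1 = d_1``, ``g_i >= d_i - d_{i-1}`` (a run of differences
    opens), and — when ``include_reversal`` — the two reversal bounds
    that force an opening where the gap orientation flips between
    consecutive sites (insertion abutting deletion).
    """
    a = np.asarray(ancestor, dtype=int)
    c = np.asarray(child, dtype=int)
    if a.shape != c.shape:
        raise ValueError(f"pattern length mismatch: {a.shape} vs {c.shape}")
    d = np.abs(a - c)
    g = np.zeros_like(d)
    if d.size == 0:
        return d, g
    g[0] = d[0]
    for i in range(1, d.size):
        bound = d[i] - d[i - 1]
        if include_reversal:
            bound = max(
                bound,
                a[i - 1] + c[i] - c[i - 1] - a[i] - 1,
                a[i] + c[i - 1] - c[i] - a[i - 1] - 1,
            )
        g[i] = 1 if bound >= 1 else 0
    return d, g


def evaluate_objective(
    patterns_all_nodes: dict[int, np.ndarray],
    tree: PhyloTree,
    alpha: float,
) -> tuple[float, dict[tuple[int, int], np.ndarray], dict[tuple[int, int], np.ndarray]]:
    """Score a complete assignment: sum over branches of sum(d + alpha*g).

    Returns the objective and the per-branch d and g vectors.
    """
    lengths = {len(v) for v in patterns_all_nodes.values()}
    if len(lengths) > 1:
        raise ValueError(f"pattern lengths differ: {sorted(lengths)}")
    total = 0.0
    d_out: dict[tuple[int, int], np.ndarray] = {}
    g_out: dict[tuple[int, int], np.ndarray] = {}
    for k, l in tree.branches:
        if k not in patterns_all_nodes or l not in patterns_all_nodes:
            missing = k if k not in patterns_all_nodes else l
            raise ValueError(f"no pattern for node {missing}")
        d, g = affine_gap_vectors(patterns_all_nodes[k], patterns_all_nodes[l])
        d_out[(k, l)] = d
        g_out[(k, l)] = g
        total += float(d.sum() + alpha * g.sum())
    return total, d_out, g_out


def _branch_cost(a: np.ndarray, c: np.ndarray, alpha: float) -> float:
    d, g = affine_gap_vectors(a, c)
    return float(d.sum() + alpha * g.sum())


def brute_force_optimum(
    tree: PhyloTree,
    aln: BinaryAlignment,
    poag: POAG,
    alpha: float = 2.0,
    cap: int = 10**6,
) -> tuple[float, list[dict[int, np.ndarray]]]:
    """Exhaustive oracle: try every assignment of POAG paths to ancestors.

    Scores all (#paths)^|N| assignments by broadcasting per-branch cost
    lookup tables over one tensor axis per ancestor, and returns the
    minimum objective plus every argmin assignment.  Only for small
    instances.
    """
    try:
        paths = poag.paths(cap=cap)
    except AlignmentError as exc:
        raise ModelError(
            f"POAG path count exceeds cap {cap}; use the MIP instead"
        ) from exc
    internals = tree.internal_indices
    n_assign = len(paths) ** len(internals)
    if n_assign > cap:
        raise ModelError(
            f"{n_assign} assignments exceed cap {cap}; use the MIP instead"
        )
    leaf = leaf_patterns(tree, aln)
    m = aln.m
    path_patterns = []
    for p in paths:
        v = np.zeros(m, dtype=np.uint8)
        for site in p[1:-1]:
            v[site - 1] = 1
        path_patterns.append(v)
    P = len(path_patterns)
    nN = len(internals)
    axis = {k: ax for ax, k in enumerate(internals)}

    # path-vs-path branch costs, shared by every internal-internal branch
    pair = np.empty((P, P))
    for s in range(P):
        for t in range(P):
            pair[s, t] = _branch_cost(path_patterns[s], path_patterns[t], alpha)

    total = np.zeros((P,) * nN)
    for k, l in tree.branches:
        if l in axis:  # internal child
            block = pair
            if axis[k] > axis[l]:
                block = pair.T  # transpose so axes land in tensor order
            total = total + block.reshape(
                [P if i in (axis[k], axis[l]) else 1 for i in range(nN)]
            )
        else:  # leaf child: vector cost against the ancestor's path
            vec = np.array(
                [_branch_cost(pp, leaf[l], alpha) for pp in path_patterns]
            )
            shape = [1] * nN
            shape[axis[k]] = P
            total = total + vec.reshape(shape)

    best = float(total.min())
    argmins = [
        {k: path_patterns[idx[axis[k]]].copy() for k in internals}
        for idx in zip(*np.nonzero(total <= best + _OBJ_TOL))
    ]
    return best, argmins
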