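import numpy as np
import pytest

import indelopt as idl
from conftest import make_random_instance
from indelopt.mip import ModelError


class TestAffineGapVectors:
    """The two-sequence example that motivates the affine-gap constraints."""

    def test_difference_vector(self, worked_pair):
        E, F = worked_pair
        d, _ = idl.affine_gap_vectors(E, F)
        assert d.tolist() == [1, 0, 1, 1, 0]

    def test_opening_without_reversal_rule(self, worked_pair):
        E, F = worked_pair
        _, g = idl.affine_gap_vectors(E, F, include_reversal=False)
        assert g.tolist() == [1, 0, 1, 0, 0]

    def test_reversal_forces_site4_opening(self, worked_pair):
        # insertion at site 3 abutting a deletion at site 4: the gap
        # orientation reverses, so site 4 opens a second event
        E, F = worked_pair
        _, g = idl.affine_gap_vectors(E, F)
        assert g[3] == 1
        assert g.tolist() == [1, 0, 1, 1, 0]

    def test_identical_patterns_cost_nothing(self):
        p = np.array([1, 0, 1, 1], dtype=np.uint8)
        d, g = idl.affine_gap_vectors(p, p)
        assert d.sum() == 0 and g.sum() == 0

    def test_reversal_pair_110_011(self):
        d, g = idl.affine_gap_vectors(np.array([1, 1, 0]), np.array([0, 1, 1]))
        assert d.tolist() == [1, 0, 1]
        assert g.tolist() == [1, 0, 1]

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.integers(0, 2, size=8)
            b = rng.integers(0, 2, size=8)
            da, ga = idl.affine_gap_vectors(a, b)
            db, gb = idl.affine_gap_vectors(b, a)
            assert (da == db).all() and (ga == gb).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            idl.affine_gap_vectors(np.ones(3), np.ones(4))


class TestEvaluateObjective:
    def test_worked_pair_objective(self, worked_pair):
        """One branch, alpha=2: 3 differences + 2 * 3 openings = 9."""
        E, F = worked_pair
        tree = idl.parse_newick("(A,B);")
        iA, iB = tree.leaf_label_to_index["A"], tree.leaf_label_to_index["B"]
        patterns = {1: E, iA: F, iB: E}
        obj, d, g = idl.evaluate_objective(patterns, tree, alpha=2.0)
        assert d[(1, iA)].tolist() == [1, 0, 1, 1, 0]
        assert g[(1, iA)].tolist() == [1, 0, 1, 1, 0]
        assert d[(1, iB)].sum() == 0
        assert obj == 9.0

    def test_missing_node_rejected(self):
        tree = idl.parse_newick("(A,B);")
        with pytest.raises(ValueError, match="node"):
            idl.evaluate_objective({1: np.ones(3)}, tree, 2.0)


class TestModelStructure:
    def test_variable_counts(self):
        # 2-leaf tree: 1 ancestor, 2 branches; width-5 alignment
        tree = idl.parse_newick("(A,B);")
        aln = idl.BinaryAlignment(
            ["A", "B"],
            np.array([[1, 0, 0, 1, 1], [0, 0, 1, 0, 1]], dtype=np.uint8),
        )
        poag = idl.build_poag(aln)
        model = idl.IndelModel(tree, aln, poag)
        nE = len(poag.edges)
        # 5 a-vars + nE y-vars + 2 branches * 5 sites of d and of g
        assert model.n_vars == 5 + nE + 10 + 10

    def test_alpha_zero_objective_is_pure_difference(self, tie_instance):
        tree, aln, poag = tie_instance
        model = idl.IndelModel(tree, aln, poag, idl.SolveConfig(alpha=0.0))
        assert (model.objective[model.g_off:] == 0).all()
        assert (model.objective[model.d_off:model.g_off] == 1).all()

    def test_leaf_alignment_mismatch_rejected(self):
        tree = idl.parse_newick("(A,B);")
        aln = idl.BinaryAlignment(
            ["A", "C"], np.array([[1, 1], [1, 1]], dtype=np.uint8)
        )
        with pytest.raises(ModelError, match="B"):
            idl.IndelModel(tree, aln, idl.build_poag(aln))


class TestSolve:
    def test_identical_extants_cost_zero(self):
        tree = idl.parse_newick("((A,B),C);")
        records = [(x, "MK-V") for x in "ABC"]
        aln = idl.reduce_columns(idl.encode_alignment(records))
        poag = idl.build_poag(aln)
        sol = idl.IndelModel(tree, aln, poag).solve()
        assert sol.status == "optimal"
        assert sol.objective_value == 0.0
        extant = aln.matrix[0]
        for pat in sol.ancestral_patterns.values():
            assert (pat == extant).all()

    def test_tie_instance_optimum(self, tie_instance):
        tree, aln, poag = tie_instance
        best, argmins = idl.brute_force_optimum(tree, aln, poag, alpha=2.0)
        sol = idl.IndelModel(tree, aln, poag).solve()
        assert sol.status == "optimal"
        assert sol.objective_value == best
        assert len(argmins) == 2
        roots = {"".join(map(str, a[1].tolist())) for a in argmins}
        assert roots == {"101", "110"}

    def test_solution_edges_form_paths_in_poag(self, tie_instance):
        tree, aln, poag = tie_instance
        sol = idl.IndelModel(tree, aln, poag).solve()
        for k, edges in sol.selected_edges.items():
            assert set(edges) <= set(poag.edges)
            assert sorted(idl.pattern_edges(sol.ancestral_patterns[k])) == edges

    def test_feasibility_floor(self):
        # copying one extant footprint everywhere bounds the optimum above
        rng = np.random.default_rng(17)
        for _ in range(10):
            tree, aln, poag = make_random_instance(rng)
            sol = idl.IndelModel(tree, aln, poag).solve()
            leaf = idl.leaf_patterns(tree, aln)
            for row in aln.matrix:
                full = dict(leaf)
                full.update({k: row for k in tree.internal_indices})
                ub, _, _ = idl.evaluate_objective(full, tree, 2.0)
                assert sol.objective_value <= ub + 1e-6

    def test_fitch_lower_bound_at_alpha_zero(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            tree, aln, poag = make_random_instance(rng)
            sol = idl.IndelModel(tree, aln, poag, idl.SolveConfig(alpha=0.0)).solve()
            fitch_total = sum(
                idl.fitch_column_cost(
                    tree,
                    {leaf: int(aln.matrix[r][i]) for r, leaf in
                     enumerate(tree.leaf_indices)},
                )
                for i in range(aln.m)
            )
            assert sol.objective_value >= fitch_total - 1e-6

    def test_objective_monotone_in_alpha(self):
        params = idl.SimulationParams(n_leaves=10, delta=0.4, seed=9)
        res = idl.simulate(params)
        aln = idl.reduce_columns(idl.encode_alignment(res.extant_records))
        poag = idl.build_poag(aln)
        objs, gaps = [], []
        for alpha in (0.0, 1.0, 2.0, 4.0):
            model = idl.IndelModel(res.tree, aln, poag, idl.SolveConfig(alpha=alpha))
            sol = model.solve()
            _, _, g = idl.evaluate_objective(
                idl.full_patterns(res.tree, aln, sol), res.tree, alpha
            )
            objs.append(sol.objective_value)
            gaps.append(sum(v.sum() for v in g.values()))
        assert objs == sorted(objs)
        assert gaps == sorted(gaps, reverse=True)


class TestOracleEquivalence:
    def test_mip_matches_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            tree, aln, poag = make_random_instance(rng)
            best, _ = idl.brute_force_optimum(tree, aln, poag, alpha=2.0)
            sol = idl.IndelModel(tree, aln, poag).solve()
            assert sol.objective_value == pytest.approx(best, abs=1e-6)

    def test_cap_exceeded_raises(self):
        tree = idl.parse_newick("((A,B),(C,D));")
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 2, size=(4, 12)).astype(np.uint8)
        mat[:, 0] = 1
        aln = idl.BinaryAlignment(list("ABCD"), mat)
        poag = idl.build_poag(aln)
        with pytest.raises(ModelError, match="cap"):
            idl.brute_force_optimum(tree, aln, poag, cap=10)


class TestEnumerateOptima:
    def test_tie_yields_exactly_two(self, tie_instance):
        tree, aln, poag = tie_instance
        model = idl.IndelModel(tree, aln, poag, idl.SolveConfig(max_alternatives=10))
        first = model.solve()
        sols = idl.enumerate_optima(model, first)
        assert len(sols) == 2
        assert sols[0].objective_value == sols[1].objective_value
        e0 = sols[0].selected_edges
        e1 = sols[1].selected_edges
        assert e0 != e1
        roots = {"".join(map(str, s.ancestral_patterns[1].tolist())) for s in sols}
        assert roots == {"101", "110"}
        assert [s.solution_rank for s in sols] == [1, 2]

    def test_unique_optimum_yields_one(self):
        tree = idl.parse_newick("(A,B);")
        records = [("A", "MKV"), ("B", "MKV")]
        aln = idl.reduce_columns(idl.encode_alignment(records))
        poag = idl.build_poag(aln)
        model = idl.IndelModel(tree, aln, poag)
        sols = idl.enumerate_optima(model, model.solve())
        assert len(sols) == 1

    def test_max_alternatives_cap(self, tie_instance):
        tree, aln, poag = tie_instance
        model = idl.IndelModel(tree, aln, poag, idl.SolveConfig(max_alternatives=1))
        sols = idl.enumerate_optima(model, model.solve())
        assert len(sols) == 1

    def test_enumeration_matches_brute_force_argmin_count(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            tree, aln, poag = make_random_instance(rng, max_assignments=50_000)
            best, argmins = idl.brute_force_optimum(tree, aln, poag, alpha=2.0)
            model = idl.IndelModel(
                tree, aln, poag, idl.SolveConfig(max_alternatives=len(argmins) + 5)
            )
            sols = idl.enumerate_optima(model, model.solve())
            assert len(sols) == len(argmins)
            assert all(s.objective_value == pytest.approx(best) for s in sols)
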