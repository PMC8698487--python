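"""Comparison matrix, true-negative injection, lowest-common-value matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mvcpair.pair_matching as pm
from mvcpair import (
    CohortConfig,
    ComparisonMatrix,
    GroundTruth,
    ICPParams,
    Side,
    build_comparison_matrix,
    generate_cohort,
    inject_true_negatives,
    lcv_match,
    mirror,
    mvc_value,
    score_matches,
)
from mvcpair.errors import ConfigurationError

from conftest import make_blob


def matrix(values, left=None, right=None) -> ComparisonMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ComparisonMatrix(
        left or [f"L{i+1}" for i in range(n)],
        right or [f"R{j+1}" for j in range(m)],
        values,
    )


def truth_for(pairs, lefts, rights) -> GroundTruth:
    l2r = {l: None for l in lefts}
    l2r.update(pairs)
    r2l = {r: None for r in rights}
    return GroundTruth(l2r, r2l)


class TestBuildMatrix:
    PARAMS = ICPParams(n_points=400, seed=1, convergence_tol=1e-4, max_iterations=20)

    def test_two_shapes_diagonal_near_zero(self):
        a, b = make_blob(40), make_blob(41)
        lefts = [a.replace(element_id="L1"), b.replace(element_id="L2")]
        # anatomical rights are reflected copies; the pipeline mirrors them back
        rights = [
            mirror(mirror(a).replace(element_id="R1", side=Side.RIGHT)),
            mirror(mirror(b).replace(element_id="R2", side=Side.RIGHT)),
        ]
        M = build_comparison_matrix(lefts, rights, self.PARAMS)
        assert M.values[0, 0] < 1e-6 and M.values[1, 1] < 1e-6
        assert M.values[0, 1] > 0.1 and M.values[1, 0] > 0.1

    def test_single_cell_equals_mvc_value(self):
        a, b = make_blob(42), make_blob(43)
        left = a.replace(element_id="L1")
        right = mirror(b.replace(element_id="R1", side=Side.RIGHT))
        M = build_comparison_matrix([left], [right], self.PARAMS)
        assert M.values[0, 0] == pytest.approx(
            mvc_value(left, right, self.PARAMS), abs=1e-12
        )

    def test_unmirrored_rights_rejected(self):
        a = make_blob(44)
        with pytest.raises(ValueError):
            build_comparison_matrix(
                [a], [a.replace(element_id="R1", side=Side.RIGHT)], self.PARAMS
            )

    def test_failed_registration_becomes_inf(self, monkeypatch):
        a, b = make_blob(45), make_blob(46)
        lefts = [a.replace(element_id="L1"), b.replace(element_id="L2")]
        rights = [mirror(a.replace(element_id="R1", side=Side.RIGHT))]

        real = pm.register

        def flaky(moving, fixed, params=None, **kw):
            if moving.element_id == "L2":
                raise RuntimeError("synthetic failure")
            return real(moving, fixed, params, **kw)

        monkeypatch.setattr(pm, "register", flaky)
        M = build_comparison_matrix(lefts, rights, self.PARAMS)
        assert np.isfinite(M.values[0, 0])
        assert np.isinf(M.values[1, 0])

    def test_deterministic_across_runs(self):
        cfg = CohortConfig(n_individuals=3, seed=9, mesh_resolution=(24, 10))
        meshes, _ = generate_cohort(cfg)
        lefts = [m for m in meshes if m.side == Side.LEFT]
        rights = [mirror(m) for m in meshes if m.side == Side.RIGHT]
        M1 = build_comparison_matrix(lefts, rights, self.PARAMS)
        M2 = build_comparison_matrix(lefts, rights, self.PARAMS)
        assert np.array_equal(M1.values, M2.values)

    def test_csv_round_trip(self, tmp_path):
        M = matrix([[0.1, 2.0], [3.0, 0.4]])
        p = M.to_csv(tmp_path / "m.csv")
        back = ComparisonMatrix.from_csv(p)
        assert back.left_ids == M.left_ids and back.right_ids == M.right_ids
        assert np.allclose(back.values, M.values)


class TestInjectTrueNegatives:
    def _setup(self, n=10):
        vals = np.random.default_rng(0).uniform(1, 2, size=(n, n))
        lefts = [f"L{i}" for i in range(n)]
        rights = [f"R{i}" for i in range(n)]
        M = ComparisonMatrix(lefts, rights, vals)
        truth = truth_for({f"L{i}": f"R{i}" for i in range(n)}, lefts, rights)
        return M, truth

    def test_zero_fraction_unchanged(self):
        M, truth = self._setup()
        red, t2, removed = inject_true_negatives(M, truth, 0.0, seed=1)
        assert removed == [] and np.array_equal(red.values, M.values)

    def test_exact_removal_count_and_none_truth(self):
        M, truth = self._setup(10)
        red, t2, removed = inject_true_negatives(M, truth, 0.2, seed=3)
        assert len(removed) == 2
        assert len(red.left_ids) + len(red.right_ids) == 18
        # 8 intact pairs remain; the 2 surviving singletons map to NONE
        paired = sum(v is not None for v in t2.left_to_right.values())
        assert paired == 8
        singles = sum(v is None for v in t2.left_to_right.values()) + sum(
            v is None for v in t2.right_to_left.values()
        )
        assert singles == 2

    def test_deterministic(self):
        M, truth = self._setup()
        a = inject_true_negatives(M, truth, 0.3, seed=5)[2]
        b = inject_true_negatives(M, truth, 0.3, seed=5)[2]
        assert a == b

    def test_excessive_fraction_rejected(self):
        M, truth = self._setup(3)
        with pytest.raises(ConfigurationError):
            inject_true_negatives(M, truth, 0.9, seed=1)


class TestLcvMatch:
    def test_mutual_minima_both_matched(self):
        assert lcv_match(matrix([[1, 5], [6, 2]])) == [("L1", "R1"), ("L2", "R2")]

    def test_non_mutual_minimum_blocks(self):
        # L2's row minimum is R1, but R1's column minimum is L1 (already used
        # by the mutual pair L1-R2? no: L1's row min is R2) -> only (L1, R2)
        assert lcv_match(matrix([[1, 0.5], [2, 3]])) == [("L1", "R2")]

    def test_tied_minimum_abstains(self):
        assert lcv_match(matrix([[1.0, 1.0]])) == []

    def test_rank_window_three_recovers_blocked_match(self):
        # mutual-argmin proposes nothing beyond (L1,R1); within rank 3 the
        # greedy sweep also pairs L2 with R2
        vals = [[1.0, 1.1, 9], [1.05, 1.2, 9], [9, 9, 0.5]]
        got = lcv_match(matrix(vals), rank_window=3)
        assert ("L3", "R3") in got and ("L1", "R1") in got and ("L2", "R2") in got

    def test_proposals_are_partial_matching(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.uniform(size=(rng.integers(1, 6), rng.integers(1, 6)))
            for w in (1, 2, 3):
                props = lcv_match(matrix(vals), rank_window=w)
                ls = [l for l, _ in props]
                rs = [r for _, r in props]
                assert len(set(ls)) == len(ls) and len(set(rs)) == len(rs)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.permutations(list(range(9))), min_size=1, max_size=1))
    def test_matches_mutual_argmin_oracle(self, perms):
        vals = np.asarray(perms[0], dtype=float).reshape(3, 3) + 1.0
        got = set(lcv_match(matrix(vals)))
        expected = set()
        for i in range(3):
            j = int(np.argmin(vals[i]))
            if int(np.argmin(vals[:, j])) == i:
                expected.add((f"L{i+1}", f"R{j+1}"))
        assert got == expected

    def test_invariant_to_row_column_permutation(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(size=(5, 5))
        base = set(lcv_match(matrix(vals)))
        pr = rng.permutation(5)
        pc = rng.permutation(5)
        M2 = ComparisonMatrix(
            [f"L{i+1}" for i in pr], [f"R{j+1}" for j in pc], vals[np.ix_(pr, pc)]
        )
        assert set(lcv_match(M2)) == base


class TestScoreMatches:
    def test_sensitivity_formula(self):
        # 5 pairs; proposals hit 4 of them -> per-element tp=8, fn=2
        lefts = [f"L{i}" for i in range(5)]
        rights = [f"R{i}" for i in range(5)]
        vals = np.full((5, 5), 2.0) + np.diag([-1.0] * 5)
        M = ComparisonMatrix(lefts, rights, vals)
        truth = truth_for({f"L{i}": f"R{i}" for i in range(5)}, lefts, rights)
        props = [(f"L{i}", f"R{i}") for i in range(4)]
        rep = score_matches(props, truth, M)
        assert (rep.tp, rep.fn) == (8, 2)
        assert rep.sensitivity == pytest.approx(0.80)

    def test_zero_specificity_when_no_true_negatives(self):
        lefts, rights = ["L1", "L2"], ["R1", "R2"]
        M = ComparisonMatrix(lefts, rights, np.ones((2, 2)))
        truth = truth_for({"L1": "R2", "L2": "R1"}, lefts, rights)
        rep = score_matches([("L1", "R1"), ("L2", "R2")], truth, M)
        assert rep.tn == 0 and rep.fp > 0
        assert rep.specificity == 0.0

    def test_specificity_undefined_without_negatives(self):
        lefts, rights = ["L1"], ["R1"]
        M = ComparisonMatrix(lefts, rights, np.array([[0.2]]))
        truth = truth_for({"L1": "R1"}, lefts, rights)
        rep = score_matches([("L1", "R1")], truth, M)
        assert rep.sensitivity == 1.0
        assert rep.specificity is None
        assert (rep.tn, rep.fp) == (0, 0)

    def test_every_element_receives_one_determination(self):
        lefts = [f"L{i}" for i in range(4)]
        rights = [f"R{i}" for i in range(3)]
        M = ComparisonMatrix(lefts, rights, np.ones((4, 3)))
        truth = truth_for({"L0": "R0", "L1": "R1"}, lefts, rights)
        rep = score_matches([("L0", "R0"), ("L2", "R1")], truth, M)
        assert rep.tp + rep.tn + rep.fp + rep.fn == 7
        assert set(rep.determinations) == set(lefts) | set(rights)

    def test_unknown_proposal_rejected(self):
        M = ComparisonMatrix(["L1"], ["R1"], np.array([[1.0]]))
        truth = truth_for({"L1": "R1"}, ["L1"], ["R1"])
        with pytest.raises(ValueError):
            score_matches([("LX", "R1")], truth, M)
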