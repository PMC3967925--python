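import numpy as np
import pytest

from conftest import random_bundle
from oracles import (
    DictEdgeTable,
    brute_best,
    brute_p1_optimum,
    match_cells,
    random_dict_table,
)

from mrfalign._dp import make_transitions
from mrfalign.aligner import (
    AlignmentPath,
    admm_align_scores,
    linearized_dp_scores,
    objective_p1,
    path_node_score,
    path_to_indicators,
    viterbi_align,
    _zero_indicators,
)
from mrfalign.node_potential import ScoreBundle


def diag_bundle(n, bonus=5.0):
    match = np.full((n, n), -1.0)
    np.fill_diagonal(match, bonus)
    return ScoreBundle(match=match, ins_t=np.full(n, -2.0),
                       ins_s=np.full(n, -2.0), trans=make_transitions())


class TestViterbi:
    def test_identity_alignment_on_diagonal_scores(self):
        path = viterbi_align(diag_bundle(5))
        assert [u for _, _, u in path.triples] == ["M"] * 5
        assert path.aligned_pairs == [(i, i) for i in range(5)]
        assert path.score == pytest.approx(25.0)

    def test_all_equal_scores_canonical_path(self):
        b = ScoreBundle(match=np.zeros((3, 3)), ins_t=np.zeros(3),
                        ins_s=np.zeros(3), trans=make_transitions())
        path = viterbi_align(b)
        # M preferred over I_T over I_S on ties: pure diagonal
        assert [u for _, _, u in path.triples] == ["M", "M", "M"]

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            nT = int(rng.integers(1, 5))
            nS = int(rng.integers(1, 5))
            b = random_bundle(nT, nS, rng, trans_scale=0.3)
            path = viterbi_align(b)
            match, ins_t, ins_s, trans = b.grids()
            best, _ = brute_best(match, ins_t, ins_s, trans)
            assert path.score == pytest.approx(best, abs=1e-9)
            path.validate(nT, nS)
            assert path_node_score(path, b) == pytest.approx(path.score, abs=1e-9)

    def test_nonfinite_scores_rejected(self):
        b = diag_bundle(3)
        b.match[0, 0] = np.nan
        with pytest.raises(ValueError):
            viterbi_align(b)


class TestAlignmentPath:
    def test_validate_rejects_non_monotone(self):
        path = AlignmentPath(triples=[(1, 1, "M"), (1, 1, "M")])
        with pytest.raises(ValueError):
            path.validate(2, 2)

    def test_validate_rejects_is_to_it(self):
        path = AlignmentPath(triples=[(0, 1, "I_S"), (1, 1, "I_T")])
        with pytest.raises(ValueError):
            path.validate(1, 1)

    def test_validate_requires_full_consumption(self):
        path = AlignmentPath(triples=[(1, 1, "M")])
        with pytest.raises(ValueError):
            path.validate(2, 2)


class TestObjectiveP1:
    def test_fewer_than_two_matches_node_only(self, rng):
        b = random_bundle(2, 1, rng)
        path = viterbi_align(b)
        table = random_dict_table(2, 1, rng)
        if len(path.aligned_pairs) < 2:
            assert objective_p1(path, b, table) == pytest.approx(
                path_node_score(path, b)
            )

    def test_zero_edge_table_equals_viterbi_score(self, rng):
        b = random_bundle(4, 4, rng)
        path = viterbi_align(b)
        assert objective_p1(path, b, None) == pytest.approx(path.score)
        zero = DictEdgeTable({}, (4, 4))
        assert objective_p1(path, b, zero) == pytest.approx(path.score)

    def test_hand_summed_edge_term(self):
        b = diag_bundle(4)
        path = viterbi_align(b)  # matches (0,0)..(3,3), L = 4
        theta = {((0, 2), (0, 2)): 1.5, ((1, 3), (1, 3)): -0.5}
        table = DictEdgeTable(theta, (4, 4), min_separation=2)
        # ordered-pair edge sum = 2 * (1.5 - 0.5); scaled by 1/L
        expected = path_node_score(path, b) + (2.0 * (1.5 - 0.5)) / 4
        assert objective_p1(path, b, table) == pytest.approx(expected)

    def test_invalid_path_rejected(self, rng):
        b = random_bundle(3, 3, rng)
        bad = AlignmentPath(triples=[(1, 1, "M")])
        with pytest.raises(ValueError):
            objective_p1(bad, b, None)


class TestLinearizedScores:
    def test_reduces_to_node_scores(self, rng):
        b = random_bundle(3, 4, rng)
        empty = _zero_indicators(3, 4)
        eff = linearized_dp_scores(empty, _zero_indicators(3, 4), 0.0, b,
                                   None, 5, lam_sign=-1.0)
        # symmetric node split: exactly half the node scores (argmax-equal)
        assert np.allclose(eff.match, 0.5 * b.match)
        assert np.allclose(eff.ins_t[:, 0], 0.5 * b.ins_t)

    def test_single_fixed_cell_gains_scaled_edge_term(self, rng):
        nT = nS = 5
        b = random_bundle(nT, nS, rng)
        table = random_dict_table(nT, nS, rng, min_separation=2)
        fixed = _zero_indicators(nT, nS)
        fixed.zm[1, 1] = 1.0
        fixed.cells.append((1, 1))
        L = 5
        eff = linearized_dp_scores(fixed, _zero_indicators(nT, nS), 0.0, b,
                                   table, L, lam_sign=-1.0)
        for k in range(nT):
            for l in range(nS):
                expected = 0.5 * b.match[k, l] + table.potential(1, k, 1, l) / L
                assert eff.match[k, l] == pytest.approx(expected)

    def test_dp_on_linearized_scores_matches_enumeration(self, rng):
        # SP solve = brute-force maximization of the same linear objective
        for _ in range(10):
            nT, nS = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            b = random_bundle(nT, nS, rng)
            table = random_dict_table(nT, nS, rng)
            z_path = viterbi_align(b)
            z = path_to_indicators(z_path, nT, nS)
            lam = _zero_indicators(nT, nS)
            lam.zm += rng.normal(0, 0.2, size=(nT, nS))
            eff = linearized_dp_scores(z, lam, 0.5, b, table, z_path.L,
                                       lam_sign=-1.0)
            sol = viterbi_align(
                ScoreBundle(match=eff.match, ins_t=eff.ins_t,
                            ins_s=eff.ins_s, trans=eff.trans)
            )
            match, ins_t, ins_s, trans = eff.grids()
            best, _ = brute_best(match, ins_t, ins_s, trans)
            assert sol.score == pytest.approx(best, abs=1e-9)


class TestADMM:
    def test_zero_edge_converges_to_viterbi_at_iteration_one(self, rng):
        for _ in range(10):
            b = random_bundle(int(rng.integers(2, 6)), int(rng.integers(2, 6)), rng)
            res = admm_align_scores(b, edge_table=None, rho=0.5)
            vit = viterbi_align(b)
            assert res.converged
            assert res.converged_at == 1
            assert res.alignment.triples == vit.triples
            assert res.objective == pytest.approx(vit.score)

    def test_best_seen_at_least_viterbi(self, rng):
        for _ in range(10):
            nT, nS = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            b = random_bundle(nT, nS, rng)
            table = random_dict_table(nT, nS, rng, scale=0.8)
            res = admm_align_scores(b, edge_table=table, rho=0.5, max_iter=20)
            assert res.objective >= res.viterbi_objective - 1e-9

    def test_exhaustive_optimum_bounds_admm(self, rng):
        for _ in range(15):
            nT, nS = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            b = random_bundle(nT, nS, rng)
            table = random_dict_table(nT, nS, rng, scale=0.8)
            res = admm_align_scores(b, edge_table=table, rho=0.5, max_iter=20)
            match, ins_t, ins_s, trans = b.grids()
            opt, _ = brute_p1_optimum(
                match, ins_t, ins_s, trans,
                lambda u, v: table.potential(u[0], v[0], u[1], v[1]),
                L_mode="path",
            )
            # optimum uses each candidate path's own L; the ADMM result
            # evaluates P1 at its own L, so the bound needs the same rule
            own = objective_p1(res.alignment, b, table)
            assert own <= opt + 1e-9

    def test_determinism(self, rng):
        b = random_bundle(5, 5, rng)
        table = random_dict_table(5, 5, rng)
        r1 = admm_align_scores(b, edge_table=table, rho=0.5, max_iter=15)
        r2 = admm_align_scores(b, edge_table=table, rho=0.5, max_iter=15)
        assert r1.alignment.triples == r2.alignment.triples
        assert r1.objective == r2.objective
        assert r1.trace == r2.trace

    def test_dual_upper_bounds_returned_objective(self, rng):
        for _ in range(10):
            nT, nS = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            b = random_bundle(nT, nS, rng)
            table = random_dict_table(nT, nS, rng, scale=0.5)
            res = admm_align_scores(b, edge_table=table, rho=0.5, max_iter=20)
            for rec in res.trace:
                assert rec["dual"] >= res.objective - 1e-9

    def test_trace_and_feasibility(self, rng):
        b = random_bundle(4, 6, rng)
        table = random_dict_table(4, 6, rng)
        res = admm_align_scores(b, edge_table=table, rho=0.5, max_iter=12)
        res.alignment.validate(4, 6)
        assert res.iterations >= 1
        assert len(res.trace) == res.iterations
        if res.converged:
            assert res.trace[-1]["disagreement"] == 0
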