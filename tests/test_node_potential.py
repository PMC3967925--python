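import numpy as np
import pytest

from conftest import random_bundle
from oracles import brute_logz

from mrfalign.mrf import build_mrf
from mrfalign.msa_io import MSA
from mrfalign.node_potential import (
    NodeScorer,
    ProfileScorer,
    ReferenceAlignment,
    ScoreBundle,
    alignment_posteriors,
    estimate_background,
    load_scorer,
    log_partition,
    save_scorer,
    train_scorer,
)


def toy_models(rng, ncol_t=6, ncol_s=6, nseq=8):
    letters = list("ARNDCQEGH")
    mt = build_mrf(MSA(sequences=[
        "".join(rng.choice(letters, size=ncol_t)) for _ in range(nseq)]))
    ms = build_mrf(MSA(sequences=[
        "".join(rng.choice(letters, size=ncol_s)) for _ in range(nseq)]))
    return mt, ms


class TestReferenceAlignment:
    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            ReferenceAlignment(pairs=[(0, 1), (1, 0)], len_t=3, len_s=3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ReferenceAlignment(pairs=[(5, 0)], len_t=3, len_s=3)

    def test_to_triples_is_valid_path(self):
        from mrfalign.aligner import AlignmentPath

        ref = ReferenceAlignment(pairs=[(1, 0), (3, 3)], len_t=5, len_s=5)
        path = AlignmentPath(triples=ref.to_triples())
        path.validate(5, 5)
        assert path.aligned_pairs == [(1, 0), (3, 3)]


class TestScoreVertex:
    def test_zero_scorer_outputs_zero(self, rng):
        mt, ms = toy_models(rng)
        scorer = NodeScorer(window=mt.context_window)
        ct = mt.profile_context(2)
        cs = ms.profile_context(3)
        assert scorer.score_vertex(ct, cs, "M") == 0.0
        assert scorer.score_vertex(ct, None, "I_T") == 0.0
        assert scorer.score_vertex(None, cs, "I_S") == 0.0

    def test_missing_context_rejected(self, rng):
        mt, ms = toy_models(rng)
        scorer = NodeScorer(window=mt.context_window)
        with pytest.raises(ValueError):
            scorer.score_vertex(mt.profile_context(0), None, "M")
        with pytest.raises(ValueError):
            scorer.score_vertex(None, None, "I_T")

    def test_hand_forward_pass(self):
        # 2 hidden units, hand-set weights, hand-set single-column context
        scorer = NodeScorer(window=0, hidden=2)
        d = 21
        scorer.ins_t_net["W1"] = np.zeros((2, d))
        scorer.ins_t_net["W1"][0, 0] = 1.0   # reads P(A)
        scorer.ins_t_net["W1"][1, 1] = -2.0  # reads P(C)
        scorer.ins_t_net["b1"] = np.array([0.1, -0.1])
        scorer.ins_t_net["W2"] = np.array([0.5, 1.5])
        scorer.ins_t_net["b2"] = np.array([0.25])
        from mrfalign.mrf import ProfileContext

        row = np.zeros((1, 21))
        row[0, 0], row[0, 1] = 0.6, 0.4
        ctx = ProfileContext(matrix=row)
        h = np.tanh([1.0 * 0.6 + 0.1, -2.0 * 0.4 - 0.1])
        expected = 0.5 * h[0] + 1.5 * h[1] + 0.25
        assert scorer.score_vertex(ctx, None, "I_T") == pytest.approx(expected)

    def test_background_offsets_mean_to_zero(self, rng):
        mt, ms = toy_models(rng, ncol_t=8, ncol_s=8)
        scorer = NodeScorer.random_init(window=mt.context_window, seed=1, scale=0.3)
        pool = [mt.profile_context(i) for i in range(mt.ncol)]
        pool += [ms.profile_context(i) for i in range(ms.ncol)]
        scorer = estimate_background(scorer, pool, n_samples=4000, seed=2)
        rng2 = np.random.default_rng(7)
        vals = []
        for _ in range(4000):
            a = pool[rng2.integers(len(pool))]
            b = pool[rng2.integers(len(pool))]
            vals.append(scorer.score_vertex(a, b, "M"))
        assert abs(np.mean(vals)) < 0.05  # tolerance from sample size


class TestEstimateBackground:
    def test_constant_network(self, rng):
        mt, _ = toy_models(rng)
        scorer = NodeScorer(window=mt.context_window)
        scorer.match_net["b2"] = np.array([3.25])
        pool = [mt.profile_context(i) for i in range(mt.ncol)]
        out = estimate_background(scorer, pool, n_samples=50, seed=0)
        assert out.background[0] == pytest.approx(3.25)

    def test_determinism(self, rng):
        mt, _ = toy_models(rng)
        scorer = NodeScorer.random_init(window=mt.context_window, seed=3, scale=0.2)
        pool = [mt.profile_context(i) for i in range(mt.ncol)]
        b1 = estimate_background(scorer, pool, n_samples=500, seed=11).background
        b2 = estimate_background(scorer, pool, n_samples=500, seed=11).background
        assert np.array_equal(b1, b2)

    def test_bad_samples(self, rng):
        mt, _ = toy_models(rng)
        scorer = NodeScorer(window=mt.context_window)
        with pytest.raises(ValueError):
            estimate_background(scorer, [mt.profile_context(0)], n_samples=0)
        with pytest.raises(ValueError):
            estimate_background(scorer, [], n_samples=10)


class TestForwardAlgorithm:
    def test_logz_matches_enumeration(self, rng):
        for _ in range(25):
            nT, nS = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            b = random_bundle(nT, nS, rng, trans_scale=0.4)
            match, ins_t, ins_s, trans = b.grids()
            expected = brute_logz(match, ins_t, ins_s, trans)
            assert log_partition(b) == pytest.approx(expected, abs=1e-8)


class TestTraining:
    def _training_pair(self, rng):
        mt, ms = toy_models(rng, ncol_t=8, ncol_s=8, nseq=10)
        ref = ReferenceAlignment(
            pairs=[(0, 0), (1, 1), (2, 2), (4, 3), (5, 4), (6, 6), (7, 7)],
            len_t=8, len_s=8,
        )
        return mt, ms, ref

    def test_fit_training_set_posterior(self, rng):
        mt, ms, ref = self._training_pair(rng)
        scorer = train_scorer([(mt, ms, ref)], l2_lambda=0.01, epochs=80,
                              seed=0, hidden=10, n_background_samples=200)
        post = alignment_posteriors(scorer, mt, ms)
        for i, j in ref.pairs:
            assert post[i, j] > 0.9

    def test_loss_non_increasing(self, rng):
        mt, ms, ref = self._training_pair(rng)
        history = []
        train_scorer([(mt, ms, ref)], l2_lambda=0.1, epochs=30, seed=0,
                     hidden=8, n_background_samples=100, history=history)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_huge_l2_shrinks_scores(self, rng):
        mt, ms, ref = self._training_pair(rng)
        scorer = train_scorer([(mt, ms, ref)], l2_lambda=1e6, epochs=30,
                              seed=0, hidden=8, n_background_samples=100)
        bundle = scorer.score_bundle(mt, ms)
        assert np.max(np.abs(bundle.match)) < 1e-2

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            train_scorer([])


class TestProfileScorer:
    def test_bundle_shapes_and_identical_family_diagonal(self, rng):
        mt, _ = toy_models(rng)
        scorer = ProfileScorer()
        b = scorer.score_bundle(mt, mt)
        assert b.match.shape == (mt.ncol, mt.ncol)
        # self-comparison: diagonal is the column self-similarity, maximal
        # against shuffled columns on average
        assert np.mean(np.diag(b.match)) > np.mean(b.match)


def test_scorer_persistence_roundtrip(tmp_path, rng):
    scorer = NodeScorer.random_init(window=2, hidden=4, seed=5, scale=0.2)
    scorer.background = np.array([0.1, -0.2, 0.3])
    path = tmp_path / "scorer.npz"
    save_scorer(scorer, path)
    back = load_scorer(path)
    assert back.window == 2 and back.hidden == 4
    assert np.allclose(back.match_net["W1"], scorer.match_net["W1"])
    assert np.allclose(back.background, scorer.background)
    mt, ms = toy_models(np.random.default_rng(0), ncol_t=5, ncol_s=5)
    # boundary contexts zero-padded per convention; scores stay finite
    b = back.score_bundle(mt, ms)
    assert np.all(np.isfinite(b.match))
    assert np.all(np.isfinite(b.ins_t)) and np.all(np.isfinite(b.ins_s))
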