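import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrfalign.distances import (
    DataError,
    DistanceBins,
    DistancePredictor,
    DistanceStats,
    bin_of,
    count_aligned,
    count_background,
    load_predictor,
    pairwise_distances,
    predict_edge_distribution,
    read_stats_tsv,
    read_structure,
    save_predictor,
    train_distance_predictor,
    write_stats_tsv,
)
from mrfalign.mrf import ProfileContext
from mrfalign.node_potential import ReferenceAlignment

BINS = DistanceBins()


class TestBins:
    def test_default_schema_has_13_bins(self):
        assert BINS.nbins == 13
        assert BINS.edges[0] == 4.0 and BINS.edges[-1] == 15.0

    def test_bin_of_examples(self):
        assert bin_of(3.2) == 0
        assert bin_of(20.0) == 12
        assert bin_of(4.0) == 1  # left-closed [4, 5)
        assert bin_of(14.999) == 11
        assert bin_of(15.0) == 12

    def test_bin_of_negative(self):
        with pytest.raises(ValueError):
            bin_of(-0.1)

    def test_bin_of_vectorized(self):
        out = bin_of(np.array([0.0, 4.5, 9.5, 100.0]))
        assert list(out) == [0, 1, 6, 12]

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            DistanceBins(edges=(5.0, 4.0))

    @given(st.floats(0.0, 1e6, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_total_on_nonnegative_reals(self, d):
        b = bin_of(d)
        assert 0 <= b < BINS.nbins


class TestCountBackground:
    def test_single_pair_distance(self):
        coords = np.array([[0.0, 0, 0], [7.3, 0, 0]])
        stats = count_background([coords], min_separation=1)
        counts = stats.background_counts
        assert counts.sum() == 1
        assert counts[bin_of(7.3)] == 1  # bin [7, 8)

    def test_smoothing_on_empty_counts_gives_uniform(self):
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        stats = count_background([coords], min_separation=6, alpha=1.0)
        assert np.allclose(stats.p_background, 1.0 / BINS.nbins)

    def test_empty_structure_set(self):
        with pytest.raises(DataError):
            count_background([])

    def test_matches_direct_loop_count(self, rng):
        coords = rng.normal(0, 8, size=(30, 3))
        stats = count_background([coords], min_separation=6, alpha=1.0)
        expected = np.zeros(BINS.nbins)
        for i in range(30):
            for k in range(i + 6, 30):
                d = float(np.sqrt(((coords[i] - coords[k]) ** 2).sum()))
                expected[bin_of(d)] += 1
        assert np.allclose(stats.background_counts, expected)
        smoothed = (expected + 1.0) / (expected + 1.0).sum()
        assert np.allclose(stats.p_background, smoothed)

    def test_order_invariance_and_duplicates(self, rng):
        a = rng.normal(0, 8, size=(15, 3))
        b = rng.normal(0, 8, size=(12, 3))
        s1 = count_background([a, b], min_separation=6)
        s2 = count_background([b, a], min_separation=6)
        assert np.allclose(s1.p_background, s2.p_background)
        dup = count_background([a, a], min_separation=6)
        single = count_background([a], min_separation=6)
        assert np.allclose(dup.background_counts, 2 * single.background_counts)


class TestCountAligned:
    def test_identity_alignment_diagonal_mass(self, rng):
        coords = rng.normal(0, 8, size=(20, 3))
        ref = ReferenceAlignment(pairs=[(i, i) for i in range(20)],
                                 len_t=20, len_s=20)
        p = count_aligned([(coords, coords, ref)], min_separation=6, alpha=0.0)
        off_diag = p - np.diag(np.diag(p))
        assert np.allclose(off_diag, 0.0)

    def test_single_cell_before_smoothing(self):
        ct = np.array([[0.0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0],
                       [0, 0, 0], [0, 0, 0], [4.5, 0, 0]])
        cs = np.array([[0.0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0],
                       [0, 0, 0], [0, 0, 0], [9.5, 0, 0]])
        ref = ReferenceAlignment(pairs=[(0, 0), (6, 6)], len_t=7, len_s=7)
        p = count_aligned([(ct, cs, ref)], min_separation=6, alpha=0.0)
        assert p[1, 6] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_out_of_range_index(self):
        coords = np.zeros((3, 3))
        ref = ReferenceAlignment(pairs=[(0, 0), (4, 4)], len_t=5, len_s=5)
        with pytest.raises(DataError):
            count_aligned([(coords, np.zeros((5, 3)), ref)], min_separation=1)

    def test_independence_approximation(self, rng):
        # uniformly random distances on both sides: joint ~ product of
        # marginals at large sample size
        n = 4000
        d_t = rng.uniform(0, 20, size=n)
        d_s = rng.uniform(0, 20, size=n)
        counts = np.zeros((BINS.nbins, BINS.nbins))
        for a, b in zip(d_t, d_s):
            counts[bin_of(float(a)), bin_of(float(b))] += 1
        p = counts / counts.sum()
        outer = np.outer(p.sum(axis=1), p.sum(axis=0))
        assert np.max(np.abs(p - outer)) < 4.0 / np.sqrt(n)


class TestPredictor:
    def test_untrained_predictor_uniform(self):
        pred = DistancePredictor()
        ctx = ProfileContext(matrix=np.zeros((11, 21)))
        out = predict_edge_distribution(pred, ctx, ctx, np.zeros(11), separation=8)
        assert np.allclose(out, 1.0 / pred.nbins)

    def test_hand_set_single_hidden_unit(self):
        pred = DistancePredictor(window=0, n_mi_features=1, hidden=1, nbins=3)
        # input: ctx_i (21) + ctx_k (21) + cross (21) + mi (1) + sep (1)
        pred.W1 = np.zeros((1, pred.input_dim))
        pred.W1[0, -2] = 2.0  # reads the MI feature
        pred.W2 = np.array([[1.0], [0.0], [-1.0]])
        pred.b2 = np.array([0.1, 0.0, -0.1])
        ctx = ProfileContext(matrix=np.full((1, 21), 1 / 21))
        out = predict_edge_distribution(pred, ctx, ctx, np.array([0.7]),
                                        separation=0)
        h = np.tanh(2.0 * 0.7)
        logits = np.array([h + 0.1, 0.0, -h - 0.1])
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        assert np.allclose(out, expected)

    def test_rows_normalized(self, rng):
        pred = DistancePredictor()
        pred.W1 = rng.normal(0, 0.1, size=pred.W1.shape)
        pred.W2 = rng.normal(0, 0.1, size=pred.W2.shape)
        X = rng.normal(0, 1, size=(20, pred.input_dim))
        out = pred.predict_batch(X)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert (out >= 0).all()

    def test_training_learns_feature(self, rng):
        # single informative feature (the MI slot): high value => bin 0
        pred0 = DistancePredictor(window=0, n_mi_features=1, hidden=4, nbins=3)
        n = 400
        X = rng.normal(0, 0.1, size=(n, pred0.input_dim))
        signal = rng.integers(0, 2, size=n)
        X[:, -2] = signal * 2.0 - 1.0
        y = np.where(signal == 1, 0, 2)
        pred = train_distance_predictor(
            X, y, window=0, n_mi_features=1, hidden=4, nbins=3,
            epochs=200, seed=0,
        )
        probs = pred.predict_batch(X)
        assert (probs[signal == 1, 0] > 0.8).mean() > 0.9
        assert (probs[signal == 0, 2] > 0.8).mean() > 0.9

    def test_use_mi_false_zeroes_mi_inputs(self, rng):
        pred = DistancePredictor(n_mi_features=11)
        pred.W1 = rng.normal(0, 0.1, size=pred.W1.shape)
        pred.W2 = rng.normal(0, 0.1, size=pred.W2.shape)
        X = rng.normal(0, 1, size=(5, pred.input_dim))
        X0 = X.copy()
        X0[:, -(11 + 1):-1] = 0.0
        pred.use_mi = False
        assert np.allclose(pred.predict_batch(X), pred.predict_batch(X0))


class TestStatsIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        n = BINS.nbins
        bg = rng.random(n) + 0.1
        bg /= bg.sum()
        al = rng.random((n, n)) + 0.1
        al /= al.sum()
        stats = DistanceStats(p_background=bg, p_aligned=al)
        path = tmp_path / "stats.tsv"
        write_stats_tsv(stats, path)
        back = read_stats_tsv(path)
        assert np.allclose(back.p_background, bg)
        assert np.allclose(back.p_aligned, al)
        assert back.bins.edges == BINS.edges

    def test_stats_validation(self):
        n = BINS.nbins
        with pytest.raises(ValueError):
            DistanceStats(p_background=np.zeros(n),
                          p_aligned=np.full((n, n), 1.0 / n**2))

    def test_predictor_roundtrip(self, tmp_path, rng):
        pred = DistancePredictor(hidden=4)
        pred.W1 = rng.normal(size=pred.W1.shape)
        path = tmp_path / "pred.npz"
        save_predictor(pred, path)
        back = load_predictor(path)
        assert np.allclose(back.W1, pred.W1)
        assert back.nbins == pred.nbins and back.use_mi == pred.use_mi


class TestStructureIO:
    def test_pdb_roundtrip_with_synthetic_writer(self, tmp_path, rng):
        from mrfalign.synthetic import write_pdb

        coords = rng.normal(0, 10, size=(12, 3)).round(3)
        path = tmp_path / "chain.pdb"
        write_pdb(coords, path)
        back = read_structure(path)
        assert back.shape == (12, 3)
        assert np.allclose(back, coords, atol=1e-3)

    def test_missing_chain(self, tmp_path, rng):
        from mrfalign.synthetic import write_pdb

        path = tmp_path / "chain.pdb"
        write_pdb(rng.normal(size=(5, 3)), path)
        with pytest.raises(DataError):
            read_structure(path, chain="Z")
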