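"""Tests for dictionary learning, assignment, encoding and word diagnostics."""

import numpy as np
import pytest

from gazedict import (
    Dictionary,
    KernelConfig,
    assign,
    encode_bow,
    learn_dictionary,
    purity_profile,
    quality_heatmap,
    word_quality_table,
)
from gazedict.modeseek import seek_all

from conftest import make_dataset, random_dataset
from test_modeseek import grid_argmax_quality


class TestLearnDictionary:
    def test_two_cluster_centroids_near_oracle_modes(self, two_cluster_data, cfg30):
        d = learn_dictionary(two_cluster_data, cfg30, K=2, subsample_rate=0.25, seed=0)
        o_pos, _ = grid_argmax_quality(two_cluster_data, cfg30, (100.0, 100.0), 2 * cfg30.h)
        o_neg, _ = grid_argmax_quality(two_cluster_data, cfg30, (500.0, 400.0), 2 * cfg30.h)
        dists = [
            min(np.linalg.norm(c - o_pos), np.linalg.norm(c - o_neg))
            for c in d.centroids
        ]
        assert max(dists) <= 0.1 * cfg30.h
        # both modes represented
        assert np.linalg.norm(d.centroids[0] - d.centroids[1]) > cfg30.h

    def test_full_subsample_with_K_equal_distinct(self):
        data = random_dataset(30, n_pos=20, n_neg=20)
        cfg = KernelConfig(h=25.0)
        trajs = seek_all(data.points, data, cfg)
        finals = np.unique(np.array([t.final for t in trajs]), axis=0)
        d = learn_dictionary(data, cfg, K=len(finals), subsample_rate=1.0, seed=0)
        got = set(map(tuple, np.round(d.centroids, 9)))
        want = set(map(tuple, np.round(finals, 9)))
        assert got == want

    def test_deterministic_under_seed(self, two_cluster_data, cfg30):
        d1 = learn_dictionary(two_cluster_data, cfg30, K=4, subsample_rate=0.3, seed=5)
        d2 = learn_dictionary(two_cluster_data, cfg30, K=4, subsample_rate=0.3, seed=5)
        assert np.array_equal(d1.centroids, d2.centroids)

    def test_oversized_K_rejected(self, two_cluster_data, cfg30):
        with pytest.raises(ValueError, match="smaller K|cannot support"):
            learn_dictionary(two_cluster_data, cfg30, K=300, subsample_rate=0.05, seed=0)


class TestAssignEncode:
    def test_centroid_maps_to_itself_and_ties_break_low(self):
        d = Dictionary(np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]]), method_tag="t")
        part = assign([[10.0, 0.0]], d)
        assert part.assignment[0] == 1
        # (5,0) equidistant to words 0 and 1 -> lowest index wins
        part = assign([[5.0, 0.0]], d)
        assert part.assignment[0] == 0

    def test_matches_bruteforce_nearest(self):
        rng = np.random.default_rng(31)
        cents = rng.uniform(0, 100, (7, 2))
        pts = rng.uniform(0, 100, (50, 2))
        d = Dictionary(cents, method_tag="t")
        got = assign(pts, d).assignment
        brute = [
            int(np.argmin([np.hypot(*(p - c)) for c in cents])) for p in pts
        ]
        assert list(got) == brute

    def test_histogram_frequencies(self):
        d = Dictionary(np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]]), method_tag="t")
        # assignments [2,2,0,1,2] -> histogram (0.2, 0.2, 0.6)
        pts = [[200.0, 1.0], [201.0, 0.0], [1.0, 0.0], [99.0, 0.0], [199.0, 0.0]]
        f = encode_bow(pts, d)
        assert f.histogram == pytest.approx([0.2, 0.2, 0.6])
        assert f.n_fixations == 5
        # counts recoverable exactly
        assert np.allclose(f.histogram * f.n_fixations, [1, 1, 3])

    def test_one_hot_and_scale_invariance(self):
        d = Dictionary(np.array([[0.0, 0.0], [50.0, 0.0]]), method_tag="t")
        pts = [[0.0, 0.0]] * 4
        assert encode_bow(pts, d).histogram == pytest.approx([1.0, 0.0])
        seq = [[0.0, 0.0], [50.0, 0.0], [49.0, 1.0]]
        assert encode_bow(seq + seq, d).histogram == pytest.approx(
            encode_bow(seq, d).histogram
        )

    def test_empty_sequence_rejected(self):
        d = Dictionary(np.array([[0.0, 0.0], [1.0, 1.0]]), method_tag="t")
        with pytest.raises(ValueError, match="no fixations"):
            encode_bow(np.empty((0, 2)), d)


class TestWordQuality:
    def _table(self, seed=33, K=6):
        data = random_dataset(seed, n_pos=60, n_neg=40)
        rng = np.random.default_rng(seed)
        cents = data.points[rng.choice(data.n, K, replace=False)]
        d = Dictionary(cents, method_tag="t")
        return data, d, word_quality_table(data, d)

    def test_counts_and_identities(self):
        data, d, table = self._table()
        assert sum(w.coverage for w in table) == data.n
        for w in table:
            assert w.quality == abs(w.n_pos - w.n_neg)
            if w.defined:
                assert w.purity_pos + w.purity_neg == pytest.approx(1.0)
                assert w.quality == pytest.approx(w.purity_abs * w.coverage)
                assert 0.0 <= w.purity_abs <= 1.0

    def test_known_word_arithmetic(self):
        # word with 8 positive and 2 negative members
        pos = np.tile([[10.0, 10.0]], (8, 1))
        neg = np.tile([[11.0, 10.0]], (2, 1))
        far = np.tile([[500.0, 400.0]], (5, 1))
        data = make_dataset(np.vstack([pos, far]), neg)
        d = Dictionary(np.array([[10.0, 10.0], [500.0, 400.0]]), method_tag="t")
        w0, w1 = word_quality_table(data, d)
        assert (w0.n_pos, w0.n_neg, w0.coverage) == (8, 2, 10)
        assert w0.purity_pos == pytest.approx(0.8)
        assert w0.purity_abs == pytest.approx(0.6)
        assert w0.quality == 6
        assert (w1.n_pos, w1.n_neg, w1.quality) == (5, 0, 5)

    def test_balanced_word_has_zero_quality(self):
        pts = np.tile([[50.0, 50.0]], (4, 1))
        data = make_dataset(pts, pts)
        d = Dictionary(np.array([[50.0, 50.0], [300.0, 300.0]]), method_tag="t")
        w0, w1 = word_quality_table(data, d)
        assert w0.purity_abs == 0.0 and w0.quality == 0.0
        assert not w1.defined  # covers nothing

    def test_purity_profile_sorted(self):
        _, _, table = self._table(seed=34, K=8)
        prof = purity_profile(table, "pos")
        assert len(prof) == 8
        assert np.all(np.diff(prof) <= 0.0)
        const = purity_profile([w for w in table if w.defined][:1] * 3, "neg")
        assert np.all(const == const[0])


class TestQualityHeatmap:
    def test_identical_classes_zero_map(self):
        rng = np.random.default_rng(35)
        pts = rng.uniform(0, 600, (30, 2))
        data = make_dataset(pts, pts)
        qs, qa, xs, ys = quality_heatmap(data, KernelConfig(h=40.0), step=20.0)
        assert np.allclose(qs, 0.0, atol=1e-18)
        assert np.allclose(qa, 0.0, atol=1e-18)

    def test_argmax_at_positive_cluster(self):
        rng = np.random.default_rng(36)
        pos = rng.normal((350.0, 250.0), 8.0, (150, 2))
        data = make_dataset(pos, np.empty((0, 2)))
        qs, qa, xs, ys = quality_heatmap(data, KernelConfig(h=30.0), step=5.0)
        iy, ix = np.unravel_index(np.argmax(qa), qa.shape)
        assert abs(xs[ix] - 350.0) <= 10.0 and abs(ys[iy] - 250.0) <= 10.0

    def test_class_swap_negates_signed_map(self):
        data = random_dataset(37)
        swapped = make_dataset(data.points_neg, data.points_pos)
        cfg = KernelConfig(h=30.0)
        qs1, _, _, _ = quality_heatmap(data, cfg, step=25.0)
        qs2, _, _, _ = quality_heatmap(swapped, cfg, step=25.0)
        assert np.allclose(qs1, -qs2, atol=1e-16)
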