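"""Unit and property tests for the KDE / quality-surface core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazedict import (
    BalancedDensityError,
    IsolatedQueryError,
    KernelConfig,
    grad_quality_signed,
    kde,
    quality_signed,
    supervised_shift_vector,
    weighted_mean,
)

from conftest import make_dataset, random_dataset


def brute_force_kde(x, points, h, c_d, d, n_total):
    """Independent double-loop KDE oracle."""
    total = 0.0
    for p in points:
        total += math.exp(-((x[0] - p[0]) ** 2 + (x[1] - p[1]) ** 2) / (2 * h * h))
    return c_d / (n_total * h**d) * total


class TestKde:
    def test_single_point_closed_form(self):
        cfg = KernelConfig(h=1.0)
        assert kde((0.0, 0.0), [(0.0, 0.0)], cfg) == pytest.approx(1.0 / (2 * math.pi))

    def test_empty_set_is_zero(self):
        assert kde((3.0, 4.0), np.empty((0, 2)), KernelConfig(h=5.0)) == 0.0

    def test_gaussian_tail_vanishes(self):
        cfg = KernelConfig(h=2.0)
        val = kde((40.0 * cfg.h, 0.0), [(0.0, 0.0), (1.0, 1.0)], cfg)
        assert 0.0 <= val <= 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kde((np.nan, 0.0), [(0.0, 0.0)], KernelConfig(h=1.0))
        with pytest.raises(ValueError):
            KernelConfig(h=0.0)
        with pytest.raises(ValueError):
            KernelConfig(h=-3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (25, 2))
        x = rng.uniform(0, 100, 2)
        cfg = KernelConfig(h=12.0)
        expected = brute_force_kde(x, pts, cfg.h, cfg.c_d, cfg.d, len(pts))
        assert kde(x, pts, cfg) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-500, 500), st.floats(-500, 500), st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_equivariance(self, tx, ty, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, (10, 2))
        x = rng.uniform(0, 50, 2)
        cfg = KernelConfig(h=8.0)
        t = np.array([tx, ty])
        assert kde(x + t, pts + t, cfg) == pytest.approx(kde(x, pts, cfg), rel=1e-9)


class TestQualitySigned:
    def test_bruteforce_oracle(self):
        data = random_dataset(7)
        cfg = KernelConfig(h=15.0)
        x = (310.0, 255.0)
        qp = brute_force_kde(x, data.points_pos, cfg.h, cfg.c_d, cfg.d, data.n)
        qn = brute_force_kde(x, data.points_neg, cfg.h, cfg.c_d, cfg.d, data.n)
        qv = quality_signed(x, data, cfg)
        assert qv.q_signed == pytest.approx(qp - qn, rel=1e-12)
        assert qv.q_abs == abs(qv.q_signed)

    def test_identical_classes_give_zero(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, (15, 2))
        data = make_dataset(pts, pts)
        for x in rng.uniform(0, 100, (5, 2)):
            assert quality_signed(x, data, KernelConfig(h=10.0)).q_signed == pytest.approx(0.0, abs=1e-18)

    def test_one_class_empty_reduces_to_kde(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 60, (12, 2))
        data = make_dataset(pts, np.empty((0, 2)))
        cfg = KernelConfig(h=10.0)
        x = (30.0, 30.0)
        assert quality_signed(x, data, cfg).q_signed == pytest.approx(
            kde(x, pts, cfg, n_total=data.n), rel=1e-14
        )
        assert quality_signed(x, data, cfg).q_signed > 0

    def test_class_swap_antisymmetry(self):
        data = random_dataset(9)
        swapped = make_dataset(data.points_neg, data.points_pos)
        cfg = KernelConfig(h=20.0)
        for x in np.random.default_rng(1).uniform(200, 400, (5, 2)):
            a = quality_signed(x, data, cfg)
            b = quality_signed(x, swapped, cfg)
            assert a.q_signed == pytest.approx(-b.q_signed, rel=1e-12)
            assert a.q_abs == pytest.approx(b.q_abs, rel=1e-12)


class TestWeightedMean:
    def test_single_point(self):
        p = np.array([42.0, 17.0])
        assert weighted_mean((0.0, 0.0), [p], KernelConfig(h=5.0)) == pytest.approx(p)

    def test_symmetric_fixed_point(self):
        pts = np.array([[-3.0, 0.0], [3.0, 0.0], [0.0, -3.0], [0.0, 3.0]])
        out = weighted_mean((0.0, 0.0), pts, KernelConfig(h=4.0))
        assert out == pytest.approx([0.0, 0.0], abs=1e-14)

    def test_direct_formula(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 50, (20, 2))
        x = np.array([25.0, 25.0])
        h = 9.0
        w = np.exp(-np.sum((pts - x) ** 2, axis=1) / (2 * h * h))
        expected = (w[:, None] * pts).sum(0) / w.sum()
        assert weighted_mean(x, pts, KernelConfig(h=h)) == pytest.approx(expected, rel=1e-12)

    def test_isolated_query_raises(self):
        with pytest.raises(IsolatedQueryError):
            weighted_mean((1e6, 1e6), [(0.0, 0.0)], KernelConfig(h=1.0))


class TestGradient:
    @pytest.mark.parametrize("seed,h", [(0, 10.0), (1, 30.0), (2, 60.0)])
    def test_matches_finite_differences(self, seed, h):
        data = random_dataset(seed, n_pos=40, n_neg=35)
        cfg = KernelConfig(h=h)
        rng = np.random.default_rng(seed + 100)
        for _ in range(5):
            x = data.points[rng.integers(data.n)] + rng.normal(0, h / 4, 2)
            g = grad_quality_signed(x, data, cfg)
            step = 1e-5 * h
            fd = np.array([
                (quality_signed(x + dv, data, cfg).q_signed
                 - quality_signed(x - dv, data, cfg).q_signed) / (2 * step)
                for dv in (np.array([step, 0.0]), np.array([0.0, step]))
            ])
            assert np.linalg.norm(g - fd) <= 1e-6 * max(np.linalg.norm(fd), 1e-300)

    def test_zero_on_identical_classes(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 80, (18, 2))
        data = make_dataset(pts, pts)
        g = grad_quality_signed((40.0, 40.0), data, KernelConfig(h=12.0))
        assert np.allclose(g, 0.0, atol=1e-20)

    def test_vanishes_at_kde_mode(self):
        # one-class reduction: gradient of a plain KDE is ~0 at its mode
        rng = np.random.default_rng(8)
        pts = rng.normal((200.0, 200.0), 10.0, (300, 2))
        data = make_dataset(pts, np.empty((0, 2)))
        cfg = KernelConfig(h=40.0)  # large h: mode ~ sample mean
        from gazedict import classic_mean_shift

        mode = classic_mean_shift(pts.mean(0), pts, cfg).final
        g = grad_quality_signed(mode, data, cfg)
        dens = quality_signed(mode, data, cfg).q_abs
        assert np.linalg.norm(g) <= 1e-2 * dens / cfg.h


class TestSupervisedShift:
    def test_all_positive_reduces_to_mean_shift(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 60, (30, 2))
        data = make_dataset(pts, np.empty((0, 2)))
        cfg = KernelConfig(h=10.0)
        x = np.array([30.0, 30.0])
        m, s = supervised_shift_vector(x, data, cfg)
        assert x + m == pytest.approx(weighted_mean(x, pts, cfg), rel=1e-12)
        assert s > 0

    def test_signed_sum_matches_quality_identity(self):
        # s = (N h^d / c_d) * q_signed
        data = random_dataset(12)
        cfg = KernelConfig(h=18.0)
        rng = np.random.default_rng(13)
        for x in rng.uniform(250, 380, (20, 2)):
            _, s = supervised_shift_vector(x, data, cfg)
            expected = data.n * cfg.h**cfg.d / cfg.c_d * quality_signed(x, data, cfg).q_signed
            assert s == pytest.approx(expected, rel=1e-10)

    def test_moves_in_dual_ascent_direction(self):
        data = random_dataset(21, n_pos=30, n_neg=25)
        cfg = KernelConfig(h=25.0)
        rng = np.random.default_rng(22)
        for x in rng.uniform(250, 380, (15, 2)):
            m, s = supervised_shift_vector(x, data, cfg)
            g = grad_quality_signed(x, data, cfg)
            assert np.sign(s) * float(m @ g) >= -1e-18

    def test_balanced_region_raises(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        data = make_dataset(pts, pts)  # exact cancellation everywhere
        with pytest.raises(BalancedDensityError):
            supervised_shift_vector((5.0, 1.0), data, KernelConfig(h=6.0))
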