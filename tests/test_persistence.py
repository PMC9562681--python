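import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from topotag.persistence import (
    FiltrationSpec,
    h0_diagram,
    h1_diagram,
    naive_reduction_oracle,
)

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


def bars_multiset(diagram):
    return np.sort(diagram.bars, axis=0)


def assert_diagrams_equal(a, b, atol=1e-12):
    assert a.dimension == b.dimension
    assert a.bars.shape == b.bars.shape
    np.testing.assert_allclose(bars_multiset(a), bars_multiset(b), atol=atol)
    assert a.n_essential == b.n_essential


class TestH0:
    def test_two_points_one_finite_bar(self):
        d = h0_diagram([[0.0, 0.0], [3.0, 4.0]])
        np.testing.assert_allclose(d.bars, [[0.0, 5.0]])
        assert d.n_essential == 1

    def test_unit_square_deaths_are_mst_weights(self):
        d = h0_diagram(SQUARE)
        np.testing.assert_allclose(sorted(d.deaths), [1.0, 1.0, 1.0])
        assert (d.births == 0).all()

    def test_single_point_only_essential(self):
        d = h0_diagram([[1.0, 2.0]])
        assert len(d) == 0 and d.n_essential == 1

    def test_empty_cloud(self):
        d = h0_diagram(np.empty((0, 2)))
        assert len(d) == 0 and d.n_essential == 0

    def test_duplicate_points_zero_bars_discarded(self):
        d = h0_diagram([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        np.testing.assert_allclose(d.bars, [[0.0, 1.0]])

    def test_deaths_match_scipy_mst_on_random_clouds(self, rng):
        """Finite H0 deaths = sorted Euclidean MST edge weights (independent
        scipy implementation)."""
        for _ in range(20):
            pts = rng.uniform(0, 10, (rng.integers(2, 40), 2))
            mst = minimum_spanning_tree(squareform(pdist(pts)))
            expected = np.sort(mst.data[mst.data > 0])
            np.testing.assert_allclose(np.sort(h0_diagram(pts).deaths), expected,
                                       atol=1e-9)


class TestH1:
    def test_unit_square_single_bar(self):
        d = h1_diagram(SQUARE, FiltrationSpec(2.0))
        np.testing.assert_allclose(d.bars, [[1.0, np.sqrt(2.0)]])
        assert d.n_essential == 0

    def test_collinear_points_no_cycles(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        d = h1_diagram(pts, FiltrationSpec(20.0))
        assert len(d) == 0

    def test_regular_hexagon_bar_born_at_side_length(self):
        ang = np.arange(6) * np.pi / 3
        hexagon = np.column_stack([np.cos(ang), np.sin(ang)])
        d = h1_diagram(hexagon, FiltrationSpec(2.5))
        assert len(d) == 1
        # death scale cross-checked against the naive reduction oracle
        np.testing.assert_allclose(d.bars, [[1.0, np.sqrt(3.0)]], atol=1e-9)
        o = naive_reduction_oracle(hexagon, FiltrationSpec(2.5))
        assert_diagrams_equal(d, o[1], atol=1e-9)

    def test_open_class_clamped_at_max_scale(self):
        spec = FiltrationSpec(1.2)
        d = h1_diagram(SQUARE, spec)
        np.testing.assert_allclose(d.bars, [[1.0, 1.2]])
        assert d.n_essential == 1
        assert_diagrams_equal(d, naive_reduction_oracle(SQUARE, spec)[1])

    def test_max_scale_validation(self):
        with pytest.raises(ValueError):
            FiltrationSpec(0.0)
        with pytest.raises(ValueError):
            FiltrationSpec(-1.0)


class TestOracleEquivalence:
    def test_random_clouds_match_naive_reduction(self, rng):
        """Optimized H0/H1 equal the textbook dense reduction exactly on
        random instances of up to 12 points."""
        for _ in range(200):
            n = int(rng.integers(1, 13))
            pts = rng.uniform(0, 1, (n, 2))
            spec = FiltrationSpec(float(rng.uniform(0.2, 2.0)))
            oracle = naive_reduction_oracle(pts, spec)
            assert_diagrams_equal(h0_diagram(pts, spec), oracle[0])
            assert_diagrams_equal(h1_diagram(pts, spec), oracle[1])

    def test_oracle_refuses_large_clouds(self, rng):
        with pytest.raises(ValueError, match="15"):
            naive_reduction_oracle(rng.uniform(0, 1, (16, 2)), FiltrationSpec(1.0))

    def test_oracle_empty_input(self):
        o = naive_reduction_oracle(np.empty((0, 2)), FiltrationSpec(1.0))
        assert len(o[0]) == 0 and len(o[1]) == 0


class TestInvariances:
    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale, seed):
        """Scaling coordinates by c scales every birth/death by c."""
        pts = np.random.default_rng(seed).uniform(0, 1, (9, 2))
        spec = FiltrationSpec(2.0)
        spec_scaled = FiltrationSpec(2.0 * scale)
        for dim, f in ((0, lambda p, s: h0_diagram(p, s)),
                       (1, h1_diagram)):
            base = f(pts, spec)
            scaled = f(pts * scale, spec_scaled)
            np.testing.assert_allclose(
                bars_multiset(scaled), bars_multiset(base) * scale,
                rtol=1e-9, atol=1e-12)

    @given(angle=st.floats(0.0, 2 * np.pi), dx=st.floats(-30, 30),
           dy=st.floats(-30, 30), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, angle, dx, dy, seed):
        pts = np.random.default_rng(seed).uniform(0, 1, (10, 2))
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T + [dx, dy]
        spec = FiltrationSpec(2.0)
        np.testing.assert_allclose(
            bars_multiset(h0_diagram(moved)), bars_multiset(h0_diagram(pts)),
            atol=1e-9)
        np.testing.assert_allclose(
            bars_multiset(h1_diagram(moved, spec)),
            bars_multiset(h1_diagram(pts, spec)), atol=1e-9)

    def test_stability_under_small_perturbation(self, rng):
        """Perturbing every point by at most delta moves matched bar
        endpoints by at most 2*delta (bottleneck stability, checked on a
        cloud with one prominent loop)."""
        ang = np.linspace(0, 2 * np.pi, 14, endpoint=False)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        delta = 1e-3
        spec = FiltrationSpec(3.0)
        base = h1_diagram(pts, spec)
        for _ in range(5):
            noise = rng.uniform(-1, 1, pts.shape)
            noise *= delta / np.linalg.norm(noise, axis=1, keepdims=True).max()
            pert = h1_diagram(pts + noise, spec)
            assert len(pert) == len(base)
            np.testing.assert_allclose(bars_multiset(pert), bars_multiset(base),
                                       atol=2 * delta)
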