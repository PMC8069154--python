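"""Simplex information geometry: softmax, Fisher metric, distances, geodesics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actinf.geometry import (
    BoundaryWarning,
    as_belief,
    floor_beliefs,
    geodesic_distance,
    geodesic_path,
    information_distance,
    inverse_fisher_metric,
    path_information_length,
    softmax,
)

from conftest import random_belief


class TestSoftmax:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ((0.0, 0.0, 0.0), (1 / 3, 1 / 3, 1 / 3)),
            ((0.0, 0.0), (0.5, 0.5)),  # two-component case reduces to the sigmoid
            ((np.log(0.2), np.log(0.3), np.log(0.5)), (0.2, 0.3, 0.5)),
        ],
    )
    def test_values(self, v, expected):
        np.testing.assert_allclose(softmax(np.array(v)), expected, atol=1e-12)

    def test_two_components_equal_sigmoid(self):
        for x in (-3.0, -0.5, 0.0, 1.7, 10.0):
            sig = 1.0 / (1.0 + np.exp(-x))
            np.testing.assert_allclose(softmax([x, 0.0]), [sig, 1.0 - sig], atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-30, 30), min_size=2, max_size=6),
        st.floats(-100, 100),
    )
    def test_shift_invariance_and_validity(self, v, c):
        s = softmax(np.array(v))
        assert np.all(s >= 0) and abs(s.sum() - 1.0) < 1e-10
        np.testing.assert_allclose(softmax(np.array(v) + c), s, atol=1e-10)

    @pytest.mark.parametrize("bad", [[np.nan, 0.0], [np.inf, 1.0]])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            softmax(bad)


class TestInverseFisherMetric:
    def test_uniform_and_binary(self):
        np.testing.assert_allclose(
            inverse_fisher_metric(np.full(4, 0.25)), np.diag([0.25] * 4)
        )
        np.testing.assert_allclose(inverse_fisher_metric([0.5, 0.5]), np.diag([0.5, 0.5]))

    def test_action_is_elementwise_product(self, rng):
        for _ in range(20):
            s = random_belief(rng, 5)
            u = rng.normal(size=5)
            np.testing.assert_allclose(inverse_fisher_metric(s) @ u, s * u, atol=1e-12)

    def test_boundary_warns(self):
        with pytest.warns(BoundaryWarning):
            inverse_fisher_metric([1.0, 0.0])


class TestInformationDistance:
    def test_identity_and_symmetry(self, rng):
        for _ in range(20):
            a, b = random_belief(rng, 4), random_belief(rng, 4)
            assert information_distance(a, a) == 0.0
            d = information_distance(a, b)
            assert d >= 0
            assert d == pytest.approx(information_distance(b, a), abs=1e-12)
            if not np.allclose(a, b):
                assert d > 0

    def test_orthogonal_vertices(self):
        d = information_distance([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        assert d == pytest.approx(2 * np.sqrt(2), abs=1e-12)

    def test_triangle_inequality(self, rng):
        for kind in ("chord", "arc"):
            for _ in range(100):
                a, b, c = (random_belief(rng, 4) for _ in range(3))
                dab = information_distance(a, b, kind)
                dbc = information_distance(b, c, kind)
                dac = information_distance(a, c, kind)
                assert dac <= dab + dbc + 1e-12

    def test_chord_below_arc_with_ratio_to_one(self, rng):
        a = random_belief(rng, 4)
        prev_ratio = 0.0
        for h in (0.3, 0.1, 0.03, 0.01):
            b = floor_beliefs(a + h * np.array([1.0, -1.0, 0.5, -0.5]) / 4)
            chord = information_distance(a, b, "chord")
            arc = information_distance(a, b, "arc")
            assert chord <= arc + 1e-12
            ratio = chord / arc
            assert ratio >= prev_ratio - 1e-9  # approaches 1 monotonically from below
            prev_ratio = ratio
        assert prev_ratio > 1 - 1e-4

    def test_local_agreement_with_fisher_metric(self, rng):
        # d(a, a+h)^2 ~ h^T diag(1/a) h: the metric is the Hessian of the KL
        for _ in range(20):
            a = floor_beliefs(random_belief(rng, 4) + 0.05)
            u = rng.normal(size=4)
            u -= u.mean()
            u /= np.linalg.norm(u)
            h = 1e-4
            b = a + h * u
            quad = np.sqrt(h * h * np.sum(u * u / a))
            assert information_distance(a, b) == pytest.approx(quad, rel=1e-3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            information_distance([0.5, 0.5], [1 / 3, 1 / 3, 1 / 3])


class TestPathLength:
    def test_single_point_and_additivity(self, rng):
        a, b, c = (random_belief(rng, 3) for _ in range(3))
        assert path_information_length([a]).total_length == 0.0
        p = path_information_length([a, b, c])
        expected = information_distance(a, b) + information_distance(b, c)
        assert p.total_length == pytest.approx(expected, abs=1e-12)
        assert len(p.step_distances) == 2
        np.testing.assert_allclose(p.cumulative[-1], p.total_length)

    def test_refinement_increases_toward_arc(self, rng):
        a, b = floor_beliefs(random_belief(rng, 4) + 0.02), floor_beliefs(
            random_belief(rng, 4) + 0.02
        )
        arc = geodesic_distance(a, b)
        prev = information_distance(a, b)  # the endpoint chord
        for k in (2, 4, 16, 64, 256):
            total = path_information_length(geodesic_path(a, b, k)).total_length
            assert total >= prev - 1e-9
            assert total >= information_distance(a, b) - 1e-12
            prev = total
        assert prev == pytest.approx(arc, rel=1e-4)


class TestGeodesic:
    def test_constant_path(self, rng):
        a = random_belief(rng, 3)
        for p in geodesic_path(a, a, 8):
            np.testing.assert_allclose(p, a, atol=1e-12)

    def test_midpoint_symmetry(self):
        pts = geodesic_path([0.9, 0.1], [0.1, 0.9], k=2)
        np.testing.assert_allclose(pts[1], [0.5, 0.5], atol=1e-12)

    def test_endpoints_exact(self, rng):
        a, b = random_belief(rng, 5), random_belief(rng, 5)
        pts = geodesic_path(a, b, 10)
        np.testing.assert_allclose(pts[0], floor_beliefs(a), atol=1e-15)
        np.testing.assert_allclose(pts[-1], floor_beliefs(b), atol=1e-15)
        for p in pts:
            as_belief(p)  # every interpolate is a valid belief

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            geodesic_path([0.5, 0.5], [0.2, 0.3, 0.5])
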