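"""Resampling, fiber-core weighting and along-tract profiling."""

import numpy as np
import pytest

from tractcompart.io import ScalarVolume, StreamlineBundle
from tractcompart import profile as prof


def straight_bundle(n_fibers=1, length=98.0, offset_step=0.0):
    lines = []
    for i in range(n_fibers):
        lines.append(np.array([[i * offset_step, 0.0, 0.0],
                               [i * offset_step, 0.0, length]]))
    return StreamlineBundle(lines, anchor=np.zeros(3))


class TestOrient:
    def test_reversed_polyline_flipped(self):
        line = np.array([[0.0, 0, 10], [0, 0, 0]])
        b = StreamlineBundle([line], anchor=np.zeros(3))
        out = prof.orient_streamlines(b)
        np.testing.assert_allclose(out.streamlines[0][0], [0, 0, 0])

    def test_already_oriented_unchanged(self):
        line = np.array([[0.0, 0, 0], [0, 0, 10]])
        b = StreamlineBundle([line], anchor=np.zeros(3))
        out = prof.orient_streamlines(b)
        np.testing.assert_allclose(out.streamlines[0], line)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        lines = [np.cumsum(rng.normal(size=(10, 3)), axis=0) for _ in range(8)]
        b = StreamlineBundle(lines, anchor=np.zeros(3))
        once = prof.orient_streamlines(b)
        twice = prof.orient_streamlines(once)
        for a, c in zip(once, twice):
            np.testing.assert_array_equal(a, c)


class TestResample:
    def test_straight_segment_uniform_spacing(self):
        line = np.array([[0.0, 0, 0], [0, 0, 98.0]])
        nodes = prof.resample_streamline(line)
        np.testing.assert_allclose(nodes[:, 2], np.arange(0, 100, 2), atol=1e-9)

    def test_endpoints_preserved(self):
        line = np.array([[1.0, 2, 3], [4, 5, 6]])
        nodes = prof.resample_streamline(line)
        np.testing.assert_array_equal(nodes[0], line[0])
        np.testing.assert_array_equal(nodes[-1], line[-1])

    def test_quarter_circle_equal_chords(self):
        # radius-10 planar quarter circle: arc length 5*pi, equal chords
        theta = np.linspace(0, np.pi / 2, 2000)
        line = np.c_[10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)]
        nodes = prof.resample_streamline(line)
        chords = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        assert np.ptp(chords) / chords.mean() < 1e-4
        arcs = np.linalg.norm(np.diff(line, axis=0), axis=1).sum()
        assert arcs == pytest.approx(5 * np.pi, rel=1e-5)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            prof.resample_streamline(np.zeros((3, 3)))


class TestCore:
    def test_single_fiber_core_is_fiber(self):
        b = straight_bundle(1)
        r = prof.resample_bundle(b)
        np.testing.assert_allclose(r.core_mean, r.points[0])
        np.testing.assert_allclose(r.core_cov,
                                   np.broadcast_to(prof.CORE_EPS * np.eye(3),
                                                   (50, 3, 3)), atol=1e-12)

    def test_mirror_symmetric_fibers_core_in_plane(self):
        lines = [np.array([[1.0, 0, 0], [1.0, 0, 50]]),
                 np.array([[-1.0, 0, 0], [-1.0, 0, 50]])]
        b = StreamlineBundle(lines, anchor=np.array([0.0, 0, 0]))
        r = prof.resample_bundle(b)
        np.testing.assert_allclose(r.core_mean[:, 0], 0.0, atol=1e-12)

    def test_gaussian_cloud_covariance_recovered(self):
        rng = np.random.default_rng(11)
        base = np.array([[0.0, 0, 0], [0, 0, 50]])
        lines = [base + np.r_[rng.normal(0, 1, 2), 0.0] for _ in range(100)]
        b = StreamlineBundle(lines, anchor=np.zeros(3))
        r = prof.resample_bundle(b)
        diag = np.diagonal(r.core_cov, axis1=1, axis2=2)
        assert abs(diag[:, :2].mean() - 1.0) < 0.2  # sampling error at n=100


class TestWeights:
    def test_single_fiber_weight_one(self):
        w = prof.core_weights(np.array([[1.0, 2, 3]]), np.array([1.0, 2, 3]),
                              np.eye(3))
        np.testing.assert_allclose(w, [1.0])

    def test_equidistant_pair_equal_weights(self):
        pts = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        w = prof.core_weights(pts, np.zeros(3), np.eye(3))
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_hand_evaluated_kernel(self):
        # Mahalanobis distances (0, 1, 1) -> weights prop. (1, e^-1/2, e^-1/2)
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
        w = prof.core_weights(pts, np.zeros(3), np.eye(3))
        expected = np.array([1.0, np.exp(-0.5), np.exp(-0.5)])
        np.testing.assert_allclose(w, expected / expected.sum(), atol=1e-12)


class TestSampling:
    def test_voxel_center_value(self, identity_volume):
        assert prof.sample_scalar(identity_volume,
                                  np.array([3.0, 2.0, 1.0])) == 3.0

    def test_midpoint_average(self, identity_volume):
        assert prof.sample_scalar(identity_volume,
                                  np.array([3.5, 2.0, 1.0])) == 3.5

    def test_constant_everywhere(self, constant_volume):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 7, size=(20, 3))
        np.testing.assert_allclose(prof.sample_scalar(constant_volume, pts),
                                   0.57)

    def test_outside_grid_raises(self, constant_volume):
        with pytest.raises(ValueError, match="outside"):
            prof.sample_scalar(constant_volume, np.array([50.0, 0, 0]))


class TestTractProfile:
    def test_constant_volume_constant_profile(self, constant_volume):
        b = straight_bundle(3, length=7.0, offset_step=0.5)
        r = prof.resample_bundle(b)
        p = prof.tract_profile(r, constant_volume, "RD")
        np.testing.assert_allclose(p.values, 0.57, atol=1e-12)
        assert p.valid.sum() == 45 and not p.valid[45:].any()

    def test_linear_field_linear_profile(self):
        data = np.broadcast_to(np.arange(16, dtype=float)[None, None, :],
                               (4, 4, 16)).copy()
        vol = ScalarVolume(data, np.eye(4))
        b = StreamlineBundle([np.array([[1.5, 1.5, 0.0], [1.5, 1.5, 15.0]])],
                             anchor=np.array([1.5, 1.5, 0.0]))
        p = prof.tract_profile(prof.resample_bundle(b), vol, "AD")
        expected = np.linspace(0, 15, 50)
        np.testing.assert_allclose(p.values, expected, atol=1e-6)

    def test_single_fiber_profile_equals_point_samples(self, identity_volume):
        b = StreamlineBundle([np.array([[0.0, 3, 3], [7.0, 3, 3]])],
                             anchor=np.array([0.0, 3, 3]))
        r = prof.resample_bundle(b)
        p = prof.tract_profile(r, identity_volume, "MD")
        direct = prof.sample_scalar(identity_volume, r.points[0])
        np.testing.assert_allclose(p.values, direct, atol=1e-12)

    def test_identical_fibers_match_unweighted_mean(self, identity_volume):
        line = np.array([[0.0, 3, 3], [7.0, 3, 3]])
        b = StreamlineBundle([line.copy() for _ in range(4)],
                             anchor=np.array([0.0, 3, 3]))
        r = prof.resample_bundle(b)
        p = prof.tract_profile(r, identity_volume, "MD")
        direct = prof.sample_scalar(identity_volume, r.points[0])
        np.testing.assert_allclose(p.values, direct, atol=1e-9)

    def test_rigid_equivariance(self):
        # shifting bundle and volume affine together leaves the profile fixed
        data = np.broadcast_to(np.arange(16, dtype=float)[None, None, :],
                               (4, 4, 16)).copy()
        shift = np.array([5.0, -3.0, 2.0])
        vol = ScalarVolume(data, np.eye(4))
        aff2 = np.eye(4)
        aff2[:3, 3] = shift
        vol2 = ScalarVolume(data, aff2)
        line = np.array([[1.5, 1.5, 0.0], [1.5, 1.5, 15.0]])
        b1 = StreamlineBundle([line], anchor=line[0])
        b2 = StreamlineBundle([line + shift], anchor=line[0] + shift)
        p1 = prof.tract_profile(prof.resample_bundle(b1), vol, "AD")
        p2 = prof.tract_profile(prof.resample_bundle(b2), vol2, "AD")
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)
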