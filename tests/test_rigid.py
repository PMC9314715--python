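"""Kabsch pose fitting, tracking policies and the pair-distance precision
statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from jawkin.errors import ConfigError
from jawkin.io import MarkerTrajectorySet
from jawkin.rigid import (
    RigidBodyDefinition,
    fit_rigid_pose,
    marker_pair_distance_sd,
    precision_report,
    track_body,
)
from jawkin.transforms import rot_z

from conftest import random_rotation

TETRA = np.array([[0.0, 0, 0], [10, 0, 0], [5, 8.66, 0], [5, 2.89, 8.16]])


def traj_from(positions, markers=None, rate=320.0, trial_id="t"):
    markers = markers or [f"m{i + 1}" for i in range(positions.shape[1])]
    return MarkerTrajectorySet(trial_id, rate, markers, np.asarray(positions, float))


def body_from(coords, name="b", labels=None):
    coords = np.asarray(coords, float)
    labels = labels or tuple(f"m{i + 1}" for i in range(len(coords)))
    return RigidBodyDefinition(name=name, marker_labels=labels, reference_coords=coords)


class TestFitRigidPose:
    def test_identity_motion(self):
        tf, resid = fit_rigid_pose(TETRA, TETRA)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, 0.0, atol=1e-12)
        assert resid <= 1e-12

    def test_recovers_known_transform(self):
        R = rot_z(30.0)
        obs = TETRA @ R.T + np.array([1.0, 2.0, 3.0])
        tf, resid = fit_rigid_pose(TETRA, obs)
        assert np.allclose(tf.rotation, R, atol=1e-9)
        assert np.allclose(tf.translation, [1, 2, 3], atol=1e-9)
        assert resid <= 1e-9

    def test_proper_rotation_even_for_reflected_observations(self):
        obs = TETRA.copy()
        obs[:, 2] *= -1  # a reflection: best proper fit must still have det +1
        tf, _ = fit_rigid_pose(TETRA, obs)
        assert np.isclose(np.linalg.det(tf.rotation), 1.0, atol=1e-9)

    def test_near_planar_marker_set_stays_proper(self):
        flat = TETRA.copy()
        flat[:, 2] *= 1e-9
        tf, _ = fit_rigid_pose(flat, flat @ rot_z(40.0).T)
        assert tf.is_proper(tol=1e-8)

    @given(st.integers(0, 2**32 - 1))
    def test_equivariance_under_pre_rotation(self, seed):
        """Rotating the observations by Q turns the fit R into Q @ R with the
        same residual."""
        rng = np.random.default_rng(seed)
        obs = TETRA + rng.normal(scale=0.1, size=TETRA.shape)
        Q = random_rotation(rng)
        tf1, r1 = fit_rigid_pose(TETRA, obs)
        tf2, r2 = fit_rigid_pose(TETRA, obs @ Q.T)
        assert np.allclose(tf2.rotation, Q @ tf1.rotation, atol=1e-8)
        assert np.isclose(r1, r2, atol=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_rigid_pose(TETRA[:2], TETRA[:2])
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid_pose(line, line)


class TestTrackBody:
    def test_noise_free_rigid_motion_recovered(self):
        rng = np.random.default_rng(5)
        F = 40
        rots = np.stack([random_rotation(rng) for _ in range(F)])
        trans = rng.normal(scale=5.0, size=(F, 3))
        world = np.einsum("fij,nj->fni", rots, TETRA) + trans[:, None, :]
        ps = track_body(traj_from(world), body_from(TETRA))
        assert np.allclose(ps.rotations, rots, atol=1e-9)
        assert np.allclose(ps.translations, trans, atol=1e-9)
        assert np.nanmax(ps.residuals_mm) <= 1e-9

    def test_four_marker_body_survives_one_missing_marker(self):
        world = np.tile(TETRA, (20, 1, 1)).astype(float)
        world[5:15, 3] = np.nan
        ps = track_body(traj_from(world), body_from(TETRA))
        assert ps.valid.all()

    def test_three_marker_body_missing_frame_only(self):
        tri = TETRA[:3]
        world = np.tile(tri, (10, 1, 1)).astype(float)
        world[4, 0] = np.nan
        ps = track_body(traj_from(world), body_from(tri))
        assert not ps.valid[4]
        assert ps.valid.sum() == 9
        assert np.isnan(ps.residuals_mm[4])

    def test_unknown_marker_label_raises(self):
        world = np.tile(TETRA, (2, 1, 1))
        body = body_from(TETRA, labels=("m1", "m2", "m3", "nope"))
        with pytest.raises(ConfigError, match="nope"):
            track_body(traj_from(world), body)


class TestPairDistanceSd:
    def test_rigid_motion_gives_zero_sd(self):
        rng = np.random.default_rng(11)
        rots = np.stack([random_rotation(rng) for _ in range(50)])
        world = np.einsum("fij,nj->fni", rots, TETRA)
        for _, sd in marker_pair_distance_sd(traj_from(world), body_from(TETRA)):
            assert sd < 1e-9

    def test_static_pair_noise_gives_sigma_sqrt2(self):
        """Closed form: each coordinate gets N(0, sigma^2) noise, so the
        inter-marker distance fluctuates with s.d. sigma * sqrt(2)."""
        sigma, F = 0.1, 10_000
        rng = np.random.default_rng(2)
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.0, 10, 0]])
        world = np.tile(base, (F, 1, 1)) + rng.normal(scale=sigma, size=(F, 3, 3))
        sds = dict(marker_pair_distance_sd(traj_from(world), body_from(base)))
        for sd in sds.values():
            assert sd == pytest.approx(sigma * np.sqrt(2), rel=0.05)

    def test_alternating_distance_closed_form(self):
        F = 1000
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [5.0, 8, 0]])
        world = np.tile(base, (F, 1, 1))
        world[1::2, 1, 0] = 10.2  # pair (m1, m2) alternates 10.0 / 10.2
        sds = dict(marker_pair_distance_sd(traj_from(world), body_from(base)))
        assert sds[("m1", "m2")] == pytest.approx(0.1 * np.sqrt(F / (F - 1)), abs=1e-12)

    def test_pair_with_too_few_frames_omitted(self):
        world = np.tile(TETRA[:3], (5, 1, 1)).astype(float)
        world[1:, 2] = np.nan  # m3 visible in only one frame
        pairs = [p for p, _ in marker_pair_distance_sd(traj_from(world), body_from(TETRA[:3]))]
        assert pairs == [("m1", "m2")]


class TestPrecisionReport:
    @staticmethod
    def _triangle(d12, d13, d23):
        x3 = (d12**2 + d13**2 - d23**2) / (2 * d12)
        return np.array([[0.0, 0, 0], [d12, 0, 0], [x3, np.sqrt(d13**2 - x3**2), 0]])

    def test_pooled_hand_values(self):
        # two frames per pair: s.d. of {a, a + delta} is delta / sqrt(2);
        # engineered so pooled pair s.d. values are exactly {0.1, 0.1, 0.2}
        r2 = np.sqrt(2.0)
        world = np.stack(
            [self._triangle(10, 10, 10), self._triangle(10 + 0.1 * r2, 10 + 0.1 * r2, 10 + 0.2 * r2)]
        )
        rep = precision_report([(traj_from(world), body_from(world[0]))])
        assert rep.n_pairs == 3
        assert rep.grand_mean_mm == pytest.approx(0.4 / 3, abs=1e-9)
        assert rep.sd_mm == pytest.approx(np.std([0.1, 0.1, 0.2], ddof=1), abs=1e-9)
        assert rep.sem_mm == pytest.approx(rep.sd_mm / np.sqrt(3), abs=1e-12)

    def test_identical_sd_values_have_zero_dispersion(self):
        world = np.stack([self._triangle(10, 10, 10), self._triangle(10.1, 10.1, 10.1)])
        rep = precision_report([(traj_from(world), body_from(world[0]))])
        assert rep.grand_mean_mm == pytest.approx(0.1 / np.sqrt(2), abs=1e-9)
        assert rep.sd_mm == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_study_grand_mean_zero(self):
        world = np.tile(TETRA, (30, 1, 1))
        rep = precision_report([(traj_from(world), body_from(TETRA))])
        assert rep.grand_mean_mm <= 1e-12

    def test_empty_report_raises(self):
        world = np.full((1, 3, 3), np.nan)
        with pytest.raises(ValueError, match="empty"):
            precision_report([(traj_from(world), body_from(TETRA[:3]))])
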