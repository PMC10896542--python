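import numpy as np
import pytest

from udmc import (
    ErrorReport,
    LandmarkFrame,
    PhantomSpec,
    Trajectory,
    build_correspondence_field,
    deformation_intensity,
    eval_control_error,
    eval_loo_error,
    generate_phantom_sequence,
    register_sequence,
    subsample_sequence,
    track_virtual_landmarks,
    trajectory_length,
)


def _identity_fields(seq):
    return [
        build_correspondence_field(seq[i], seq[i], M=20)
        for i in range(len(seq) - 1)
    ]


class TestTracking:
    def test_static_sequence_gives_constant_trajectories(self):
        data = generate_phantom_sequence(
            PhantomSpec(resolution=300, n_frames=4, motion="static")
        )
        fields = register_sequence(data.sequence, data.landmark_frames)
        seeds = data.sequence[0].vertices[:5]
        trajs = track_virtual_landmarks(fields, seeds)
        for traj, seed in zip(trajs, seeds):
            assert np.abs(traj.points - seed).max() < 1e-6

    def test_rigid_translation_followed_exactly(self):
        spec = PhantomSpec(
            resolution=400, n_frames=4, motion="rigid_translation",
            amplitude=(10.0, 0.0, 0.0),
        )
        data = generate_phantom_sequence(spec)
        fields = register_sequence(data.sequence, data.landmark_frames)
        seeds = data.sequence[0].vertices[50:55]
        trajs = track_virtual_landmarks(fields, seeds)
        for traj, seed in zip(trajs, seeds):
            for i in range(4):
                want = seed + np.array([10.0, 0, 0]) * i
                assert np.abs(traj.points[i] - want).max() < 1e-6

    def test_remeshed_phantom_beats_static_baseline(self, bounce_phantom):
        from udmc import CropSpec, MeshSequence, crop_breast
        from udmc.phantom import _envelope

        data = bounce_phantom
        cropped = MeshSequence(
            [
                crop_breast(m, lf)
                for m, lf in zip(data.sequence.frames, data.landmark_frames)
            ],
            fps=data.sequence.fps,
        )
        fields = register_sequence(cropped, data.landmark_frames)
        # ground-truth surface samples on the moving breast mound
        env = _envelope(data.spec, data.vertex_uv[0])
        sel = np.nonzero((env > 0.2) & (env < 0.95))[0][::7][:10]
        uv = data.vertex_uv[0][sel]
        gt_tracks = data.ground_truth.track_uv(uv)  # (10, F, 3)
        seeds = gt_tracks[:, 0, :]
        trajs = track_virtual_landmarks(fields, seeds)
        tracked = np.stack([t.points for t in trajs])
        err = np.linalg.norm(tracked - gt_tracks, axis=2).mean()
        baseline = np.linalg.norm(seeds[:, None, :] - gt_tracks, axis=2).mean()
        assert err * 3.0 <= baseline


class TestTrajectoryLength:
    def test_constant_trajectory_has_zero_length(self):
        traj = Trajectory(np.zeros((5, 3)), np.arange(5.0))
        assert trajectory_length(traj) == 0.0

    def test_three_four_five(self):
        traj = Trajectory([[0, 0, 0], [3, 4, 0]], [0.0, 1.0])
        assert trajectory_length(traj) == pytest.approx(5.0)

    def test_sinusoid_arc_length_against_quadrature(self):
        t = np.linspace(0, 1, 2001)
        pts = np.stack([t * 100, 40 * np.sin(2 * np.pi * t), np.zeros_like(t)], axis=1)
        traj = Trajectory(pts, t)
        from scipy.integrate import quad

        arc, _ = quad(
            lambda s: np.hypot(100.0, 40 * 2 * np.pi * np.cos(2 * np.pi * s)), 0, 1,
            limit=200,
        )
        assert trajectory_length(traj) == pytest.approx(arc, rel=0.005)

    def test_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.normal(0, 10, (20, 3))
        traj = Trajectory(pts, np.arange(20.0))
        R = Rotation.random(random_state=1).as_matrix()
        moved = Trajectory(pts @ R.T + [5, 6, 7], np.arange(20.0))
        assert trajectory_length(moved) == pytest.approx(trajectory_length(traj))


class TestDeformationIntensity:
    def test_static_sequence_is_zero_everywhere(self):
        data = generate_phantom_sequence(
            PhantomSpec(resolution=400, n_frames=4, motion="static")
        )
        fields = register_sequence(data.sequence, data.landmark_frames)
        imap = deformation_intensity(data.sequence, fields, n_samples=50)
        assert imap.intensity.max() < 1e-6
        assert imap.vertex_intensity.max() < 1e-6

    def test_rigid_translation_intensity_is_path_length(self):
        d = 7.0
        F = 5
        spec = PhantomSpec(
            resolution=400, n_frames=F, motion="rigid_translation",
            amplitude=(d, 0.0, 0.0),
        )
        data = generate_phantom_sequence(spec)
        fields = register_sequence(data.sequence, data.landmark_frames)
        imap = deformation_intensity(data.sequence, fields, n_samples=50)
        want = (F - 1) * d
        assert np.abs(imap.intensity - want).max() < 0.01 * want

    def test_apex_moves_more_than_base_ring(self, bounce_phantom):
        data = bounce_phantom
        fields = register_sequence(data.sequence, data.landmark_frames)
        imap = deformation_intensity(data.sequence, fields, n_samples=60)
        from udmc.phantom import _envelope

        # classify samples by the analytic envelope at their frame-1 uv
        uv0 = data.vertex_uv[0]
        verts0 = data.sequence[0].vertices
        idx = [
            int(np.argmin(np.linalg.norm(verts0 - s, axis=1)))
            for s in imap.sample_points
        ]
        env = _envelope(data.spec, uv0[idx])
        apex = imap.intensity[env > 0.7]
        base = imap.intensity[env < 0.1]
        assert len(apex) and len(base)
        assert apex.mean() > base.mean()

    def test_subsampled_sequence_has_shorter_paths(self, bounce_phantom):
        data = bounce_phantom
        fields = register_sequence(data.sequence, data.landmark_frames)
        imap_full = deformation_intensity(data.sequence, fields, n_samples=30)
        sub_seq, sub_lms = subsample_sequence(data.sequence, data.landmark_frames, 2)
        sub_fields = register_sequence(sub_seq, sub_lms)
        # track the same frame-1 sample points through the halved sequence
        trajs = track_virtual_landmarks(sub_fields, imap_full.sample_points)
        sub_len = np.array([trajectory_length(t) for t in trajs])
        assert np.all(sub_len <= imap_full.intensity + 1e-6)


class TestErrorReports:
    def test_aggregates_match_raw_matrix(self, rng):
        errors = rng.uniform(0, 5, (6, 9))
        rep = ErrorReport(errors, np.arange(6), np.arange(9.0))
        assert rep.mean == pytest.approx(errors.mean())
        assert rep.sd == pytest.approx(errors.std())
        assert np.allclose(rep.frame_mean, errors.mean(axis=0))

    def test_perfect_fields_give_zero_control_error(self, tps_phantom):
        data = tps_phantom
        fields = register_sequence(data.sequence, data.landmark_frames)
        rep = eval_control_error(fields, data.landmarks)
        assert rep.errors.max() <= 1e-6

    def test_identity_fields_error_equals_displacement(self, bounce_phantom):
        data = bounce_phantom
        fields = _identity_fields(data.sequence)
        rep = eval_control_error(fields, data.landmarks)
        disp = np.linalg.norm(
            data.landmarks.positions - data.landmarks.positions[:, :1], axis=2
        )
        assert np.abs(rep.errors - disp).max() < 1e-6

    def test_frame_count_mismatch_fatal(self, bounce_phantom):
        fields = _identity_fields(bounce_phantom.sequence)
        with pytest.raises(ValueError, match="frames"):
            eval_control_error(fields[:-1], bounce_phantom.landmarks)

    def test_loo_with_five_landmarks_rejected_early(self, bounce_phantom):
        data = bounce_phantom
        small = data.landmarks
        keep = small.landmark_ids[:5]
        reduced = small
        for lid in small.landmark_ids[5:]:
            reduced = reduced.drop(int(lid))
        with pytest.raises(ValueError, match="at least 6"):
            eval_loo_error(data.sequence, data.landmark_frames, reduced)

    def test_loo_small_on_redundant_motion_and_above_control(self, tps_phantom):
        data = tps_phantom
        rep_loo = eval_loo_error(data.sequence, data.landmark_frames, data.landmarks)
        peak = np.linalg.norm(
            data.landmarks.positions - data.landmarks.positions[:, :1], axis=2
        ).max()
        assert rep_loo.mean < 0.05 * peak
        fields = register_sequence(data.sequence, data.landmark_frames)
        rep_c = eval_control_error(fields, data.landmarks)
        assert rep_c.mean <= rep_loo.mean

    def test_error_accumulates_over_frames(self):
        # sequential chaining accumulates: last-frame error >= first-frame
        # error on average over noisy-landmark replicates
        finals, firsts = [], []
        for seed in range(20):
            spec = PhantomSpec(
                resolution=250, n_frames=4, motion="bounce_swing",
                remesh=True, seed=seed,
            )
            data = generate_phantom_sequence(spec)
            rng = np.random.default_rng(seed + 1000)
            noisy = [
                LandmarkFrame(
                    lf.coords + rng.normal(0, 0.5, lf.coords.shape),
                    lf.landmark_ids, lf.timestamp,
                )
                for lf in data.landmark_frames
            ]
            fields = register_sequence(data.sequence, noisy)
            rep = eval_control_error(fields, data.landmarks)
            firsts.append(rep.frame_mean[0])
            finals.append(rep.frame_mean[-1])
        assert np.mean(finals) >= np.mean(firsts)
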