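import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from udmc import (
    LandmarkTrajectorySet,
    Mesh,
    PhantomSpec,
    alignment_distance,
    axis_prealign,
    estimate_similarity,
    extract_reference_points,
    generate_phantom_sequence,
    phantom_landmark_trajectories,
    search_time_offset,
    simulate_mocap_stream,
)
from udmc.calibration import ReferencePointSet, local_gray_gradient


def _random_rotation(rng):
    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


class TestAxisPrealign:
    def test_identity_spec(self):
        pts = np.array([[1.0, 2.0, 3.0]])
        assert np.array_equal(axis_prealign(pts, "x,y,z"), pts)

    def test_signed_permutation_example(self):
        assert np.allclose(axis_prealign([1.0, 2.0, 3.0], "y,-x,z"), [2.0, -1.0, 3.0])

    def test_spec_then_inverse_restores_points(self, rng):
        pts = rng.normal(0, 10, (7, 3))
        fwd = axis_prealign(pts, "z,-x,-y")
        # inverse of (x,y,z)->(z,-x,-y) is (x,y,z)->(-y,-z,x)
        back = axis_prealign(fwd, "-y,-z,x")
        assert np.allclose(back, pts)

    @pytest.mark.parametrize("bad", ["x,y", "x,x,z", "a,b,c"])
    def test_malformed_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            axis_prealign(np.zeros((3, 3)), bad)


class TestSimilarityEstimation:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.uniform(0, 100, (10, 3))
        st = estimate_similarity(pts, pts, mode="corresponded")
        assert abs(st.scale - 1.0) < 1e-9
        assert np.abs(st.rotation_fine - np.eye(3)).max() < 1e-9
        assert np.abs(st.translation).max() < 1e-9

    def test_corresponded_recovery_exact(self, rng):
        src = rng.uniform(0, 100, (30, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        tgt = 0.98 * src @ R.T + np.array([100.0, -50.0, 20.0])
        st = estimate_similarity(src, tgt, mode="corresponded")
        assert abs(st.scale - 0.98) < 1e-6
        assert np.abs(st.rotation_fine - R).max() < 1e-6
        assert np.abs(st.translation - [100.0, -50.0, 20.0]).max() < 1e-6

    def test_corresponded_recovery_random_transforms(self, rng):
        # property: zero-noise recovery to 1e-6 over many random similarities
        for _ in range(100):
            src = rng.uniform(-50, 50, (12, 3))
            s = rng.uniform(0.5, 2.0)
            R = _random_rotation(rng)
            T = rng.uniform(-100, 100, 3)
            tgt = s * src @ R.T + T
            st = estimate_similarity(src, tgt, mode="corresponded")
            assert abs(st.scale - s) < 1e-6
            assert np.abs(st.rotation_fine - R).max() < 1e-6
            assert np.abs(st.translation - T).max() < 1e-6
            assert np.abs(st.apply(src) - tgt).max() < 1e-6

    def test_uncorresponded_recovery_with_noise(self, rng):
        src = rng.uniform(0, 100, (30, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        T = np.array([100.0, -50.0, 20.0])
        tgt = 0.98 * src @ R.T + T
        shuffled = tgt[rng.permutation(30)] + rng.normal(0, 0.5, (30, 3))
        st = estimate_similarity(src, shuffled, mode="uncorresponded")
        assert abs(st.scale - 0.98) / 0.98 < 0.01
        cos_angle = np.clip((np.trace(st.rotation_fine @ R.T) - 1) / 2, -1, 1)
        assert np.degrees(np.arccos(cos_angle)) < 1.0
        assert np.linalg.norm(st.translation - T) < 1.0

    def test_degenerate_geometry_rejected(self):
        line = np.array([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            estimate_similarity(line, line)

    def test_inverse_round_trip(self, rng):
        st = estimate_similarity(
            rng.uniform(0, 10, (8, 3)), rng.uniform(0, 10, (8, 3)), mode="corresponded"
        )
        pts = rng.uniform(0, 10, (5, 3))
        assert np.abs(st.inverse().apply(st.apply(pts)) - pts).max() < 1e-9


class TestReferencePoints:
    def _flat_mesh(self, n_side=12, gray=None):
        g = np.linspace(0, 1, n_side)
        uu, vv = np.meshgrid(g, g, indexing="ij")
        verts = np.column_stack([uu.ravel() * 100, vv.ravel() * 100, np.zeros(n_side**2)])
        faces = []
        for i in range(n_side - 1):
            for j in range(n_side - 1):
                a = i * n_side + j
                faces.append((a, a + n_side, a + n_side + 1))
                faces.append((a, a + n_side + 1, a + 1))
        return Mesh(verts, faces, gray)

    def test_uniform_gray_selects_nothing(self):
        mesh = self._flat_mesh(gray=np.full(144, 30.0))
        ref = extract_reference_points(mesh)
        assert len(ref.points) == 0
        assert np.all(ref.gradients == 0)

    def test_missing_gray_is_fatal(self):
        with pytest.raises(ValueError, match="gray"):
            extract_reference_points(self._flat_mesh())

    def test_gradient_matches_brute_force(self, rng):
        mesh = self._flat_mesh(n_side=10, gray=rng.uniform(0, 255, 100))
        grad = local_gray_gradient(mesh, n_neighbors=100)
        # brute-force double loop
        V, g = mesh.vertices, mesh.gray
        n = len(V)
        brute = np.zeros(n)
        for i in range(n):
            d = np.linalg.norm(V - V[i], axis=1)
            order = np.argsort(d)[1 : min(100, n - 1) + 1]
            brute[i] = np.max(np.abs(g[i] - g[order]) / (d[order] + 1e-5))
        assert np.allclose(grad, brute, atol=1e-12)

    def test_single_bright_vertex_selection_is_local(self, rng):
        mesh = self._flat_mesh(n_side=23)  # 529 vertices
        gray = np.zeros(529)
        bright = 264
        gray[bright] = 255.0
        mesh.gray = gray
        ref = extract_reference_points(mesh)
        assert len(ref.points) > 0
        d = np.linalg.norm(mesh.vertices - mesh.vertices[bright], axis=1)
        ball = np.sort(d)[min(100, 528)]
        assert np.all(np.linalg.norm(ref.points - mesh.vertices[bright], axis=1) <= ball)

    def test_painted_phantom_selection_near_landmarks(self):
        spec = PhantomSpec(resolution=1200, n_frames=1, motion="static", texture=True)
        data = generate_phantom_sequence(spec)
        ref = extract_reference_points(data.sequence[0])
        sites = data.landmarks.positions[:, 0, :]
        d = np.min(
            np.linalg.norm(ref.points[:, None, :] - sites[None, :, :], axis=2), axis=1
        )
        frac = np.mean(d <= 2 * spec.spot_radius)
        assert frac >= 0.95


def _vertex_reference_sets(seq):
    return [
        ReferencePointSet(m.vertices, np.arange(m.n_vertices), np.zeros(m.n_vertices), 0.0, i)
        for i, m in enumerate(seq.frames)
    ]


@pytest.fixture(scope="module")
def offset_setup():
    spec = PhantomSpec(resolution=900, n_frames=11, motion="bounce_swing", remesh=False)
    data = generate_phantom_sequence(spec)
    gt_hi = phantom_landmark_trajectories(spec, np.arange(0, 1.0001, 0.01))
    refs = _vertex_reference_sets(data.sequence)
    return spec, data, gt_hi, refs


class TestTemporalAlignment:

    def test_distance_zero_at_true_offset(self, offset_setup):
        _, data, gt_hi, refs = offset_setup
        stream = simulate_mocap_stream(gt_hi, 100.0, 0.0)
        d = alignment_distance(0.0, stream, refs, data.sequence.timestamps)
        assert d < 1e-6

    def test_distance_matches_speed_times_time_error(self):
        # landmarks moving at 100 mm/s; a 0.1 s clock error costs ~10 mm
        times = np.arange(0, 2.0001, 0.01)
        K = 5
        rng = np.random.default_rng(1)
        offsets = rng.uniform(0, 500, (K, 1, 3))  # well separated landmarks
        pos = offsets + times[None, :, None] * np.array([100.0, 0, 0])
        trajs = LandmarkTrajectorySet(np.arange(K), times, pos)
        scan_times = np.arange(0.5, 1.5, 0.1)
        refs = []
        for i, t in enumerate(scan_times):
            pts = (offsets[:, 0, :] + t * np.array([100.0, 0, 0]))
            refs.append(ReferencePointSet(pts, np.arange(K), np.zeros(K), 0.0, i))
        assert alignment_distance(0.0, trajs, refs, scan_times) < 1e-9
        d = alignment_distance(0.1, trajs, refs, scan_times)
        assert d == pytest.approx(10.0, rel=0.01)

    def test_distance_minimum_at_true_offset(self, offset_setup):
        _, data, gt_hi, refs = offset_setup
        stream = simulate_mocap_stream(gt_hi, 100.0, -0.25)
        ts = data.sequence.timestamps
        d_opt = alignment_distance(-0.25, stream, refs, ts)
        assert d_opt <= alignment_distance(-0.15, stream, refs, ts)
        assert d_opt <= alignment_distance(-0.35, stream, refs, ts)

    def test_all_frames_skipped_is_fatal(self, offset_setup):
        _, data, gt_hi, refs = offset_setup
        stream = simulate_mocap_stream(gt_hi, 100.0, 0.0)
        with pytest.raises(ValueError, match="overlap"):
            alignment_distance(50.0, stream, refs, data.sequence.timestamps)

    @pytest.mark.parametrize("true_offset", [0.0, -0.25, 3.14])
    def test_grid_search_recovers_injected_offset(self, offset_setup, true_offset):
        _, data, gt_hi, refs = offset_setup
        stream = simulate_mocap_stream(gt_hi, 100.0, true_offset)
        ta = search_time_offset(stream, refs, data.sequence.timestamps)
        assert abs(ta.offset - true_offset) <= 0.01
        assert len(ta.coarse_curve) == len(ta.coarse_grid) == 101
        assert len(ta.fine_curve) == len(ta.fine_grid) == 101
        assert np.isclose(ta.coarse_grid[1] - ta.coarse_grid[0], 0.2)
        assert np.isclose(ta.fine_grid[1] - ta.fine_grid[0], 0.01)
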