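"""Synthetic 4D breast-scan phantom with exact ground-truth correspondence.

The phantom is a parametric torso patch (a gently curved plate) carrying a
smooth breast mound; a material point is identified by its surface
parameters (u, v) in [0, 1]^2, so its trajectory under any motion family is
known in closed form.  This gives every other module a test surface with
exact dense ground truth:

* per-frame triangle meshes, optionally *remeshed* — each frame sampled on
  an independently jittered parameter grid so vertex counts and
  connectivity differ between frames, as in real 4D scans;
* exact landmark trajectories at ~30 quasi-uniform surface sites, six of
  which ("contour" ids 0, 1, 10, 17, 25, 26) sit on the breast boundary
  ring so automatic cropping is exercised realistically;
* a simulated MoCap stream: ground truth resampled at the MoCap rate,
  shifted by a known clock offset, moved into a different coordinate frame,
  and optionally noised — the recovery target for calibration;
* optional painted gray texture: Gaussian bright spots at the landmark
  sites, emulating optical markers recorded into the scan texture.

Motion families: ``static``, ``rigid_translation``, ``affine``,
``bounce_swing`` (vertical damped sinusoid plus lateral sinusoid whose
amplitude decays with parametric distance from the breast apex — the apex
moves most, the base ring not at all, by construction) and
``tps_from_landmarks`` (each frame is the TPS image of the previous one,
solved on the landmark motion itself, so the pipeline's motion model can be
exact).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import SimilarityTransform
from .core_io import (
    LandmarkFrame,
    LandmarkTrajectorySet,
    Mesh,
    MeshSequence,
    resample_trajectories,
)
from .tps import TPSMap, evaluate_tps, solve_tps

logger = logging.getLogger("udmc")

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "PhantomGroundTruth",
    "analytic_displacement",
    "generate_phantom_sequence",
    "paint_landmark_texture",
    "simulate_mocap_stream",
    "landmark_sites_uv",
    "phantom_landmark_trajectories",
]

MOTION_FAMILIES = (
    "static",
    "rigid_translation",
    "affine",
    "tps_from_landmarks",
    "bounce_swing",
)

CONTOUR_IDS = (0, 1, 10, 17, 25, 26)

# fixed unit-strain pattern for the affine family (per frame, scaled by amplitude)
_AFFINE_GEN = np.array(
    [
        [0.010, 0.004, 0.000],
        [0.000, -0.006, 0.002],
        [0.002, 0.000, 0.008],
    ]
)


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic sequence.

    Defaults mirror the 10 fps evaluation condition: an 11-frame, ~3000
    vertex-per-frame sequence with 30 exact landmarks, 2 Hz bouncing at
    desk-scale amplitudes, and a 100 fps MoCap stream.
    """

    # geometry (mm)
    torso_width: float = 400.0
    torso_height: float = 400.0
    torso_curvature: float = 60.0  # chest plate bow depth
    breast_radius_x: float = 90.0
    breast_depth: float = 60.0  # mound protrusion along +y
    breast_radius_z: float = 90.0
    # sampling
    resolution: int = 3000  # per-frame vertex count target
    n_landmarks: int = 30
    remesh: bool = False
    # motion
    motion: str = "bounce_swing"
    amplitude: tuple = (10.0, 5.0, 25.0)  # mm (lateral, anterior, vertical)
    frequency: float = 2.0  # Hz
    damping: float = 0.3  # 1/s
    drift: float = 2.0  # mm/s non-periodic lateral drift at the apex
    # timing
    fps: float = 10.0
    n_frames: int = 11
    # streams
    noise_sigma: float = 0.0  # mm, MoCap only
    seed: int = 0
    mocap_rate: float = 100.0
    mocap_offset: float = 0.0  # s, injected clock offset (delta*)
    # texture
    texture: bool = False
    spot_radius: float = 10.0  # mm
    spot_contrast: float = 120.0

    def __post_init__(self) -> None:
        if self.motion not in MOTION_FAMILIES:
            raise ValueError(f"unknown motion family {self.motion!r}")
        if self.fps <= 0 or self.n_frames < 1:
            raise ValueError("fps must be positive and n_frames >= 1")
        if min(self.amplitude) < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes and noise must be nonnegative")
        if self.motion == "tps_from_landmarks" and self.remesh:
            raise ValueError(
                "tps_from_landmarks requires remesh=off (vertex identity "
                "must be preserved between frames)"
            )

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


# ---------------------------------------------------------------------------
# Parametric surface and analytic motion
# ---------------------------------------------------------------------------

def _base_surface(spec: PhantomSpec, uv: np.ndarray) -> np.ndarray:
    """Rest position of material points (u, v): curved plate plus breast mound."""
    uv = np.asarray(uv, dtype=float).reshape(-1, 2)
    x = (uv[:, 0] - 0.5) * spec.torso_width
    z = (uv[:, 1] - 0.5) * spec.torso_height
    y = -spec.torso_curvature * (2.0 * uv[:, 0] - 1.0) ** 2
    y = y + spec.breast_depth * _envelope(spec, uv)
    return np.column_stack([x, y, z])


def _envelope(spec: PhantomSpec, uv: np.ndarray) -> np.ndarray:
    """Smooth apex-to-base decay: 1 at the breast apex, 0 on/outside the base ring."""
    uv = np.asarray(uv, dtype=float).reshape(-1, 2)
    x = (uv[:, 0] - 0.5) * spec.torso_width
    z = (uv[:, 1] - 0.5) * spec.torso_height
    rho = np.sqrt((x / spec.breast_radius_x) ** 2 + (z / spec.breast_radius_z) ** 2)
    return np.cos(0.5 * np.pi * np.minimum(rho, 1.0)) ** 2


def analytic_displacement(spec: PhantomSpec, uv, t: float) -> np.ndarray:
    """Closed-form position of material points (u, v) at time t (seconds).

    For ``tps_from_landmarks`` this law governs the *landmark sites* (the
    dense surface is their TPS interpolation, built frame-recursively in
    :func:`generate_phantom_sequence`).
    """
    uv = np.asarray(uv, dtype=float).reshape(-1, 2)
    base = _base_surface(spec, uv)
    if spec.motion == "static":
        return base
    if spec.motion == "rigid_translation":
        return base + np.asarray(spec.amplitude, float) * (t * spec.fps)
    if spec.motion == "affine":
        center = _base_surface(spec, np.array([[0.5, 0.5]]))[0]
        A = np.eye(3) + (t * spec.fps) * (np.mean(spec.amplitude) / 10.0) * _AFFINE_GEN
        return center + (base - center) @ A.T
    # bounce_swing law (also the landmark law of tps_from_landmarks)
    e = _envelope(spec, uv)[:, None]
    ax, ay, az = spec.amplitude
    damp = np.exp(-spec.damping * t)
    w = 2.0 * np.pi * spec.frequency
    disp = np.zeros_like(base)
    disp[:, 2] = -az * np.sin(w * t) * damp
    disp[:, 0] = ax * np.sin(0.5 * w * t + 0.7) * damp + spec.drift * t
    disp[:, 1] = ay * np.sin(w * t + 1.2) * damp
    return base + e * disp


# ---------------------------------------------------------------------------
# Landmark sites
# ---------------------------------------------------------------------------

def landmark_sites_uv(spec: PhantomSpec) -> np.ndarray:
    """Quasi-uniform landmark parameter sites, indexed by landmark id.

    The six contour ids sit evenly on the breast base ring; the remaining
    ids fill the mound interior on a Fibonacci (golden-angle) spiral.
    """
    n = spec.n_landmarks
    if n < 7:
        raise ValueError("phantom needs at least 7 landmarks")
    uv = np.zeros((n, 2))
    contour = [i for i in CONTOUR_IDS if i < n]
    ru = spec.breast_radius_x / spec.torso_width
    rv = spec.breast_radius_z / spec.torso_height

    def ring_point(theta: float, rho: float) -> np.ndarray:
        return np.array([0.5 + rho * ru * np.cos(theta), 0.5 + rho * rv * np.sin(theta)])

    for j, lid in enumerate(contour):
        uv[lid] = ring_point(2.0 * np.pi * j / len(contour), 1.0)
    interior = [i for i in range(n) if i not in contour]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for j, lid in enumerate(interior):
        rho = 0.88 * np.sqrt((j + 0.5) / len(interior))
        uv[lid] = ring_point(j * golden, rho)
    return uv


def phantom_landmark_trajectories(spec: PhantomSpec, times) -> LandmarkTrajectorySet:
    """Exact landmark tracks at arbitrary times (analytic law, no noise)."""
    times = np.asarray(times, dtype=float).ravel()
    uv = landmark_sites_uv(spec)
    positions = np.stack(
        [analytic_displacement(spec, uv, float(t)) for t in times], axis=1
    )  # (K, T, 3)
    return LandmarkTrajectorySet(np.arange(spec.n_landmarks), times, positions)


# ---------------------------------------------------------------------------
# Mesh sampling
# ---------------------------------------------------------------------------

def _grid_uv(
    n_u: int, n_v: int, jitter: float = 0.0, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Structured (u, v) grid plus its triangulation; optional interior jitter."""
    u = np.linspace(0.0, 1.0, n_u)
    v = np.linspace(0.0, 1.0, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uv = np.column_stack([uu.ravel(), vv.ravel()])
    if jitter > 0 and rng is not None:
        interior = (
            (uv[:, 0] > 0) & (uv[:, 0] < 1) & (uv[:, 1] > 0) & (uv[:, 1] < 1)
        )
        cell = np.array([1.0 / (n_u - 1), 1.0 / (n_v - 1)])
        uv[interior] += rng.uniform(-jitter, jitter, (interior.sum(), 2)) * cell
    faces = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            a = i * n_v + j
            b = (i + 1) * n_v + j
            c = (i + 1) * n_v + j + 1
            d = i * n_v + j + 1
            faces.append((a, b, c))
            faces.append((a, c, d))
    return uv, np.asarray(faces, dtype=int)


def _snap_landmarks_to_grid(uv: np.ndarray, lm_uv: np.ndarray) -> np.ndarray:
    """Move the nearest free grid node onto each landmark site (exact vertices)."""
    uv = uv.copy()
    taken: set[int] = set()
    for site in lm_uv:
        d = np.linalg.norm(uv - site, axis=1)
        order = np.argsort(d)
        for idx in order:
            if idx not in taken:
                uv[idx] = site
                taken.add(int(idx))
                break
    return uv


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomGroundTruth:
    """Exact dense correspondence for a generated sequence.

    ``track_uv`` works for every family; ``track_points`` transports
    arbitrary frame-1 positions and is available for the TPS-recursive
    family (where frame-1 position alone determines the track).
    """

    spec: PhantomSpec
    times: np.ndarray
    tps_chain: list[TPSMap] = field(default_factory=list)

    def position_uv(self, uv, t: float) -> np.ndarray:
        if self.spec.motion == "tps_from_landmarks":
            raise ValueError(
                "tps_from_landmarks ground truth is frame-recursive; use track_uv"
            )
        return analytic_displacement(self.spec, uv, t)

    def track_uv(self, uv) -> np.ndarray:
        """(P, F, 3) exact track of material points given by parameters."""
        uv = np.asarray(uv, dtype=float).reshape(-1, 2)
        if self.spec.motion == "tps_from_landmarks":
            frame1 = analytic_displacement(self.spec, uv, float(self.times[0]))
            return self.track_points(frame1)
        return np.stack(
            [analytic_displacement(self.spec, uv, float(t)) for t in self.times],
            axis=1,
        )

    def track_points(self, points_frame1) -> np.ndarray:
        """(P, F, 3) exact track of arbitrary frame-1 positions (TPS family)."""
        if self.spec.motion != "tps_from_landmarks":
            raise ValueError("track_points is defined for tps_from_landmarks only")
        pts = np.asarray(points_frame1, dtype=float).reshape(-1, 3)
        out = [pts]
        for tps in self.tps_chain:
            out.append(evaluate_tps(tps, out[-1]))
        return np.stack(out, axis=1)


@dataclass
class PhantomData:
    """Everything one phantom run produces."""

    spec: PhantomSpec
    sequence: MeshSequence
    landmarks: LandmarkTrajectorySet  # exact, at the scan frame times
    landmark_frames: list[LandmarkFrame]
    ground_truth: PhantomGroundTruth
    vertex_uv: list[np.ndarray]  # per-frame (N_i, 2) material parameters


def generate_phantom_sequence(spec: PhantomSpec) -> PhantomData:
    """Generate the mesh sequence, exact landmark tracks, and ground truth.

    With ``remesh`` on, every frame uses an independently jittered parameter
    grid (differing vertex counts and connectivity); with it off, one fixed
    grid whose nearest nodes are snapped onto the landmark sites, so the
    landmarks are exact mesh vertices in every frame.  Generation is
    deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.frame_times
    lm_uv = landmark_sites_uv(spec)
    lm_set = phantom_landmark_trajectories(spec, times)

    n_side = max(4, int(round(np.sqrt(spec.resolution))))
    frames: list[Mesh] = []
    vertex_uv: list[np.ndarray] = []
    chain: list[TPSMap] = []

    if spec.motion == "tps_from_landmarks":
        uv, faces = _grid_uv(n_side, n_side)
        uv = _snap_landmarks_to_grid(uv, lm_uv)
        # frame 1 follows the landmark law exactly, so landmark sites are
        # mesh vertices at their trajectory positions; later frames are the
        # TPS images of the previous frame under the landmark motion
        V = analytic_displacement(spec, uv, float(times[0]))
        frames.append(Mesh(V, faces, None, 0, float(times[0])))
        vertex_uv.append(uv)
        for i in range(1, spec.n_frames):
            tps = solve_tps(lm_set.positions[:, i - 1], lm_set.positions[:, i])
            V = evaluate_tps(tps, V)
            chain.append(tps)
            frames.append(Mesh(V, faces.copy(), None, i, float(times[i])))
            vertex_uv.append(uv)
    else:
        for i, t in enumerate(times):
            if spec.remesh:
                # alternating parity guarantees consecutive frames differ in count
                n_u = n_side + int(rng.integers(0, 2)) + 2 * (i % 2)
                n_v = n_side + int(rng.integers(0, 2))
                uv, faces = _grid_uv(n_u, n_v, jitter=0.3, rng=rng)
            else:
                uv, faces = _grid_uv(n_side, n_side)
                uv = _snap_landmarks_to_grid(uv, lm_uv)
            V = analytic_displacement(spec, uv, float(t))
            mesh = Mesh(V, faces, None, i, float(t))
            frames.append(mesh)
            vertex_uv.append(uv)

    if spec.texture:
        for i, mesh in enumerate(frames):
            painted = paint_landmark_texture(
                mesh, lm_set.positions[:, i], spec.spot_radius, spec.spot_contrast
            )
            frames[i] = painted

    seq = MeshSequence(frames, fps=spec.fps, name=f"phantom-{spec.motion}")
    gt = PhantomGroundTruth(spec=spec, times=times, tps_chain=chain)
    return PhantomData(
        spec=spec,
        sequence=seq,
        landmarks=lm_set,
        landmark_frames=lm_set.frames(),
        ground_truth=gt,
        vertex_uv=vertex_uv,
    )


# ---------------------------------------------------------------------------
# Texture painting and MoCap simulation
# ---------------------------------------------------------------------------

def paint_landmark_texture(
    mesh: Mesh, landmark_sites, spot_radius: float = 10.0, contrast: float = 120.0
) -> Mesh:
    """Paint Gaussian gray spots at the landmark sites.

    Background gray 30; each spot peaks at ``30 + contrast`` at its site and
    decays with sigma ``spot_radius / 2``; the sum is clipped to [0, 255].
    """
    sites = np.asarray(landmark_sites, dtype=float).reshape(-1, 3)
    d2 = ((mesh.vertices[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    sigma2 = (spot_radius / 2.0) ** 2
    gray = 30.0 + contrast * np.exp(-d2 / (2.0 * sigma2)).sum(axis=1)
    out = mesh.copy()
    out.gray = np.clip(gray, 0.0, 255.0)
    return out


def simulate_mocap_stream(
    gt: LandmarkTrajectorySet,
    rate: float,
    offset: float = 0.0,
    transform: SimilarityTransform | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> LandmarkTrajectorySet:
    """Simulate the MoCap recording of ground-truth landmark tracks.

    Resamples the ground truth at the MoCap rate, shifts the timestamps by
    ``-offset`` (so recovering ``+offset`` re-aligns the clocks, i.e.
    ``t_scan = t_mocap + offset``), moves positions into the MoCap frame via
    the *inverse* of ``transform`` (the scan-from-mocap calibration), and
    adds seeded Gaussian noise.
    """
    if rate <= 0:
        raise ValueError("mocap rate must be positive")
    t0, t1 = gt.times[0], gt.times[-1]
    n = int(np.floor((t1 - t0) * rate)) + 1
    sample_times = t0 + np.arange(n) / rate
    frames = resample_trajectories(gt, sample_times)
    positions = np.stack([f.coords for f in frames], axis=1)  # (K, T, 3)
    if transform is not None:
        inv = transform.inverse()
        positions = inv.apply(positions.reshape(-1, 3)).reshape(positions.shape)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, sigma, positions.shape)
    return LandmarkTrajectorySet(
        gt.landmark_ids.copy(), sample_times - offset, positions
    )
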