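"""Spatio-temporal calibration of the MoCap stream to the 4D scan.

The two acquisition systems differ in coordinate frame and in clock origin:

* **spatial**: scanner coordinates relate to MoCap coordinates by a
  similarity transform ``x_scan = s * R_fine * R_axis * x_mocap + T``, where
  ``R_axis`` is a coarse signed axis permutation and ``(s, R_fine, T)`` is a
  refined fit, estimated either closed-form from corresponded landmark pairs
  (Umeyama) or by probabilistic rigid registration with scale (rigid CPD,
  EM over a Gaussian mixture) when correspondence is unknown;
* **temporal**: MoCap timestamps relate to scan timestamps by an unknown
  offset, ``t_scan = t_mocap + delta``.  The offset is recovered by grid
  search: for each candidate, MoCap landmark tracks are resampled at the
  shifted scan times and their mean distance to texture-derived reference
  points on each scan frame is minimized.  Reference points are the vertices
  whose local gray-gradient exceeds the frame mean by two standard
  deviations — i.e. the marker spots themselves.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_io import LandmarkTrajectorySet, Mesh, resample_trajectories

logger = logging.getLogger("udmc")

__all__ = [
    "SimilarityTransform",
    "TemporalAlignment",
    "ReferencePointSet",
    "axis_prealign",
    "axis_map_matrix",
    "estimate_similarity",
    "extract_reference_points",
    "alignment_distance",
    "search_time_offset",
]


# ---------------------------------------------------------------------------
# Similarity transform
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTransform:
    """``x' = s * R_fine * R_axis * x + T`` with uniform scale s > 0."""

    scale: float = 1.0
    rotation_fine: np.ndarray = field(default_factory=lambda: np.eye(3))
    rotation_axis: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation_fine = np.asarray(self.rotation_fine, dtype=float).reshape(3, 3)
        self.rotation_axis = np.asarray(self.rotation_axis, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        R = self.rotation_fine
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation_fine is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation_fine must have determinant +1")
        Ax = self.rotation_axis
        ok = (
            np.isin(Ax, (-1.0, 0.0, 1.0)).all()
            and (np.abs(Ax).sum(axis=0) == 1).all()
            and (np.abs(Ax).sum(axis=1) == 1).all()
        )
        if not ok:
            raise ValueError("rotation_axis must be a signed permutation matrix")

    @property
    def rotation(self) -> np.ndarray:
        return self.rotation_fine @ self.rotation_axis

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = pts.reshape(-1, 3)
        out = self.scale * pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "SimilarityTransform":
        R = self.rotation
        s_inv = 1.0 / self.scale
        return SimilarityTransform(
            scale=s_inv,
            rotation_fine=R.T,
            rotation_axis=np.eye(3),
            translation=-s_inv * (R.T @ self.translation),
        )

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation_fine": self.rotation_fine.tolist(),
            "rotation_axis": self.rotation_axis.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            d["scale"],
            np.array(d["rotation_fine"]),
            np.array(d["rotation_axis"]),
            np.array(d["translation"]),
        )


_AXIS_TOKEN = re.compile(r"^([+\-−]?)([xyz])$")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def axis_map_matrix(spec: str) -> np.ndarray:
    """Parse a signed-permutation spec like ``"y,-x,z"`` into a 3x3 matrix.

    Token i names which source axis (with sign) becomes output axis i, e.g.
    ``"y,-x,z"`` maps (1, 2, 3) to (2, -1, 3).
    """
    tokens = [t.strip().lower() for t in spec.split(",")]
    if len(tokens) != 3:
        raise ValueError(f"axis map needs 3 comma-separated tokens: {spec!r}")
    R = np.zeros((3, 3))
    used = set()
    for row, tok in enumerate(tokens):
        m = _AXIS_TOKEN.match(tok)
        if not m:
            raise ValueError(f"malformed axis token {tok!r} in {spec!r}")
        sign = -1.0 if m.group(1) in ("-", "−") else 1.0
        col = _AXIS_INDEX[m.group(2)]
        if col in used:
            raise ValueError(f"axis {m.group(2)!r} used twice in {spec!r}")
        used.add(col)
        R[row, col] = sign
    return R


def axis_prealign(points, axis_map: str) -> np.ndarray:
    """Relabel axes of a point set by a signed permutation (coarse orientation)."""
    R = axis_map_matrix(axis_map)
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    out = pts @ R.T
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Similarity estimation
# ---------------------------------------------------------------------------

def _umeyama(source: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Closed-form least-squares similarity fit for corresponded point sets."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    xs = source - mu_s
    xt = target - mu_t
    cov = xt.T @ xs / len(source)
    U, d, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_s = (xs**2).sum() / len(source)
    s = float(np.trace(np.diag(d) @ S) / var_s)
    T = mu_t - s * R @ mu_s
    return s, R, T


def _rigid_cpd(
    source: np.ndarray,
    target: np.ndarray,
    outlier_weight: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Rigid + uniform-scale point-set registration by EM over a Gaussian mixture.

    Each source point (after the candidate similarity transform) is a mixture
    component; E-step computes soft assignments of target points, M-step
    re-solves the similarity in closed form under those weights.
    """
    X, Y = target, source  # X: data (N,3), Y: centroids (M,3)
    N, M = len(X), len(Y)
    s, R, T = 1.0, np.eye(3), np.zeros(3)
    TY = Y.copy()
    sigma2 = (
        (X**2).sum() * M + (Y**2).sum() * N
        - 2.0 * X.sum(axis=0) @ Y.sum(axis=0)
    ) / (3.0 * N * M)
    prev_q = np.inf
    converged = False
    for _ in range(max_iter):
        # E-step
        d2 = ((X[:, None, :] - TY[None, :, :]) ** 2).sum(axis=2)  # (N, M)
        num = np.exp(-d2 / (2.0 * sigma2))
        c = (
            (2.0 * np.pi * sigma2) ** 1.5
            * outlier_weight / max(1e-12, 1.0 - outlier_weight)
            * M / N
        )
        den = num.sum(axis=1, keepdims=True) + c
        den[den < 1e-300] = 1e-300
        P = num / den
        Np = P.sum()
        if Np < 1e-12:
            logger.warning("rigid CPD: all points classified as outliers")
            break
        # M-step (closed-form weighted similarity)
        Pt1 = P.sum(axis=1)  # (N,)
        P1 = P.sum(axis=0)  # (M,)
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y) / Np
        Xc = X - mu_x
        Yc = Y - mu_y
        A = Xc.T @ P @ Yc
        U, d, Vt = np.linalg.svd(A)
        Sgn = np.eye(3)
        if np.linalg.det(U) * np.linalg.det(Vt) < 0:
            Sgn[2, 2] = -1.0
        R = U @ Sgn @ Vt
        denom = (P1 * (Yc**2).sum(axis=1)).sum()
        s = float(np.trace(np.diag(d) @ Sgn) / denom)
        T = mu_x - s * R @ mu_y
        TY = s * Y @ R.T + T
        err = (
            Pt1 @ (X**2).sum(axis=1)
            - 2.0 * (X * (P @ TY)).sum()
            + P1 @ (TY**2).sum(axis=1)
        )
        sigma2_new = max(err / (3.0 * Np), 1e-12)
        q = err / (2 * sigma2) + Np * 1.5 * np.log(sigma2)
        if abs(prev_q - q) < tol * max(1.0, abs(q)):
            sigma2 = sigma2_new
            converged = True
            break
        prev_q = q
        sigma2 = sigma2_new
    if not converged:
        logger.warning("rigid CPD did not converge in %d iterations", max_iter)
    return s, R, T


def estimate_similarity(
    source, target, mode: str = "corresponded", **cpd_kwargs
) -> SimilarityTransform:
    """Estimate the similarity transform mapping ``source`` onto ``target``.

    ``mode="corresponded"`` requires equal-size, order-matched point sets and
    uses the closed-form least-squares (Umeyama) solution; ``"uncorresponded"``
    runs rigid CPD with scale.  The returned transform has ``R_axis = I``;
    coarse axis pre-alignment is applied separately via :func:`axis_prealign`.
    """
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    for name, pts in (("source", source), ("target", target)):
        if len(pts) < 3:
            raise ValueError(f"{name} needs at least 3 points")
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
            raise ValueError(f"{name} points are collinear (degenerate geometry)")
    if mode == "corresponded":
        if len(source) != len(target):
            raise ValueError("corresponded mode requires equal-size point sets")
        s, R, T = _umeyama(source, target)
    elif mode == "uncorresponded":
        s, R, T = _rigid_cpd(source, target, **cpd_kwargs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SimilarityTransform(scale=s, rotation_fine=R, translation=T)


# ---------------------------------------------------------------------------
# Texture-gradient reference points
# ---------------------------------------------------------------------------

@dataclass
class ReferencePointSet:
    """High-gray-gradient vertices of one scan frame (the marker spots)."""

    points: np.ndarray  # (S, 3) selected vertex positions
    indices: np.ndarray  # (S,) selected vertex indices
    gradients: np.ndarray  # (N,) per-vertex local gray gradient
    threshold: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.indices = np.asarray(self.indices, dtype=int).ravel()
        self.gradients = np.asarray(self.gradients, dtype=float).ravel()


def local_gray_gradient(mesh: Mesh, n_neighbors: int = 100) -> np.ndarray:
    """Per-vertex local gray gradient.

    For each vertex x with gray g(x), over the nearest ``min(n_neighbors, N-1)``
    vertices x', the maximum of ``|g(x) - g(x')| / (||x - x'|| + 1e-5)``.
    """
    if mesh.gray is None:
        raise ValueError("mesh has no per-vertex gray values")
    N = mesh.n_vertices
    if N < 2:
        raise ValueError("gradient needs at least 2 vertices")
    k = min(n_neighbors, N - 1)
    tree = cKDTree(mesh.vertices)
    dists, idx = tree.query(mesh.vertices, k=k + 1)
    # first column is the vertex itself (distance 0)
    dists, idx = dists[:, 1:], idx[:, 1:]
    dg = np.abs(mesh.gray[:, None] - mesh.gray[idx])
    return (dg / (dists + 1e-5)).max(axis=1)


def extract_reference_points(mesh: Mesh, n_neighbors: int = 100) -> ReferencePointSet:
    """Select vertices whose local gray gradient exceeds mean + 2 SD.

    A zero-variance gray field yields an empty selection: uniform texture
    carries no alignment signal.
    """
    grad = local_gray_gradient(mesh, n_neighbors)
    sd = grad.std()
    threshold = grad.mean() + 2.0 * sd
    if sd == 0.0:
        sel = np.zeros(0, dtype=int)
    else:
        sel = np.nonzero(grad > threshold)[0]
    return ReferencePointSet(
        points=mesh.vertices[sel],
        indices=sel,
        gradients=grad,
        threshold=float(threshold),
        frame_index=mesh.frame_index,
    )


# ---------------------------------------------------------------------------
# Temporal alignment
# ---------------------------------------------------------------------------

@dataclass
class TemporalAlignment:
    """Result of the two-stage clock-offset grid search."""

    offset: float  # delta (s): t_scan = t_mocap + delta
    coarse_grid: np.ndarray
    coarse_curve: np.ndarray
    fine_grid: np.ndarray
    fine_curve: np.ndarray

    def __post_init__(self) -> None:
        for name in ("coarse", "fine"):
            g = np.asarray(getattr(self, f"{name}_grid"), dtype=float)
            c = np.asarray(getattr(self, f"{name}_curve"), dtype=float)
            if len(g) != len(c):
                raise ValueError("distance curve length must equal candidate count")
            setattr(self, f"{name}_grid", g)
            setattr(self, f"{name}_curve", c)


def alignment_distance(
    delta: float,
    trajs: LandmarkTrajectorySet,
    ref_sets: list[ReferencePointSet],
    scan_times,
) -> float:
    """Mean landmark-to-reference distance (mm) at a candidate clock offset.

    For each scan frame, the MoCap tracks are resampled at
    ``t_mocap = t_scan - delta``; each landmark is matched to its nearest
    reference point of that frame and the distances are averaged.  Frames
    whose shifted time leaves the MoCap recording are skipped (and counted);
    if all frames are skipped the offset is outside the overlap.
    """
    scan_times = np.asarray(scan_times, dtype=float).ravel()
    if len(scan_times) != len(ref_sets):
        raise ValueError("one reference point set per scan frame required")
    lo, hi = trajs.times[0], trajs.times[-1]
    frame_means = []
    skipped = 0
    for t_scan, ref in zip(scan_times, ref_sets):
        t_mocap = t_scan - delta
        if t_mocap < lo or t_mocap > hi or len(ref.points) == 0:
            skipped += 1
            continue
        (frame,) = resample_trajectories(trajs, [t_mocap])
        tree = cKDTree(ref.points)
        d, _ = tree.query(frame.coords)
        frame_means.append(float(np.mean(d)))
    if not frame_means:
        raise ValueError(
            f"offset {delta:g} s outside overlap: all {skipped} frames skipped"
        )
    if skipped:
        logger.debug("alignment_distance(delta=%g): %d frames skipped", delta, skipped)
    return float(np.mean(frame_means))


def search_time_offset(
    trajs: LandmarkTrajectorySet,
    ref_sets: list[ReferencePointSet],
    scan_times,
    coarse_range: tuple[float, float] = (-10.0, 10.0),
    n_coarse: int = 100,
    fine_halfwidth: float = 0.5,
    n_fine: int = 100,
) -> TemporalAlignment:
    """Two-stage grid search for the clock offset.

    The coarse stage slices ``coarse_range`` (default [-10, 10] s) into
    ``n_coarse`` intervals (step 0.2 s); the fine stage re-slices a
    +/- ``fine_halfwidth`` window around the coarse optimum into ``n_fine``
    intervals (step 0.01 s).  Candidates without temporal overlap score
    infinity.
    """

    def curve(grid: np.ndarray) -> np.ndarray:
        vals = np.full(len(grid), np.inf)
        for i, delta in enumerate(grid):
            try:
                vals[i] = alignment_distance(delta, trajs, ref_sets, scan_times)
            except ValueError:
                pass
        return vals

    coarse_grid = np.linspace(coarse_range[0], coarse_range[1], n_coarse + 1)
    coarse_curve = curve(coarse_grid)
    if not np.isfinite(coarse_curve).any():
        raise ValueError("no candidate offset overlaps the MoCap recording")
    delta1 = float(coarse_grid[int(np.argmin(coarse_curve))])
    fine_grid = np.linspace(delta1 - fine_halfwidth, delta1 + fine_halfwidth, n_fine + 1)
    fine_curve = curve(fine_grid)
    delta2 = float(fine_grid[int(np.argmin(fine_curve))])
    logger.info("temporal alignment: coarse delta=%g s, fine delta=%g s", delta1, delta2)
    return TemporalAlignment(delta2, coarse_grid, coarse_curve, fine_grid, fine_curve)
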