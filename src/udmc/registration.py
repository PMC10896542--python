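"""Dense inter-frame correspondence: TPS morph, post-alignment, local fields.

For each consecutive frame pair (i, i+1) of the cropped sequence:

1. **morph** — a TPS motion model solved on the sparse landmark pairs
   (frame-i landmarks -> frame-(i+1) landmarks) transports every frame-i
   vertex to an estimate of its next-frame position;
2. **post-alignment** — each morphed vertex is replaced by its globally
   nearest point on the actually scanned frame-(i+1) surface (point-to-plane
   search: projection onto each triangle's plane clamped to the triangle),
   so the estimate acquires the true fine-scale geometry;
3. **correspondence field** — the paired sets (frame-i vertices, aligned
   vertices) define a continuous map: a query point is transported by a
   local TPS solved on its M nearest frame-i vertices and their aligned
   partners.

Accelerated nearest-surface-point and k-nearest-vertex queries are designed
to return results identical to brute force (candidate pruning is
conservative; ties break to the lowest index).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_io import LandmarkFrame, Mesh, MeshSequence
from .tps import TPSMap, evaluate_tps, solve_tps

logger = logging.getLogger("udmc")

__all__ = [
    "RegistrationParams",
    "CorrespondenceField",
    "morph_frame",
    "closest_point_on_surface",
    "closest_points_on_surface",
    "closest_points_brute",
    "knearest_vertices",
    "post_align",
    "build_correspondence_field",
    "map_point",
    "map_points",
    "register_sequence",
]


@dataclass
class RegistrationParams:
    """Free parameters of the dense-correspondence stage."""

    M: int = 20  # local TPS neighbourhood size
    regularization: float = 0.0  # TPS lambda
    post_align: bool = True
    decimate_target_to: int | None = None  # baseline-style target decimation

    def __post_init__(self) -> None:
        if self.M < 5:
            raise ValueError("M must be at least 5 (TPS solvability)")
        if self.regularization < 0:
            raise ValueError("regularization must be nonnegative")


# ---------------------------------------------------------------------------
# Point-to-surface queries
# ---------------------------------------------------------------------------

def _point_triangle_closest(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Vectorized closest point on triangles.

    ``points`` (n, 3) paired with ``tri`` (n, 3, 3); returns (n, 3) closest
    points.  Standard region classification on barycentric coordinates.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = points - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = points - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    mask = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[mask] = a[mask]
    done |= mask

    mask = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[mask] = b[mask]
    done |= mask

    mask = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[mask] = c[mask]
    done |= mask

    vc = d1 * d4 - d3 * d2
    mask = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    if mask.any():
        t = d1[mask] / (d1[mask] - d3[mask])
        out[mask] = a[mask] + t[:, None] * ab[mask]
        done |= mask

    vb = d5 * d2 - d1 * d6
    mask = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    if mask.any():
        t = d2[mask] / (d2[mask] - d6[mask])
        out[mask] = a[mask] + t[:, None] * ac[mask]
        done |= mask

    va = d3 * d6 - d5 * d4
    mask = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    if mask.any():
        t = (d4[mask] - d3[mask]) / ((d4[mask] - d3[mask]) + (d5[mask] - d6[mask]))
        out[mask] = b[mask] + t[:, None] * (c[mask] - b[mask])
        done |= mask

    mask = ~done  # interior
    if mask.any():
        denom = va[mask] + vb[mask] + vc[mask]
        denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
        v = vb[mask] / denom
        w = vc[mask] / denom
        out[mask] = a[mask] + v[:, None] * ab[mask] + w[:, None] * ac[mask]
    return out


class _SurfaceLocator:
    """Accelerated (but exact) closest-point-on-surface queries for one mesh.

    For each query, the distance to the nearest *vertex* bounds the true
    surface distance from above; every triangle whose centroid lies within
    that bound plus the largest centroid-to-corner radius is a candidate, so
    the candidate set provably contains the nearest triangle.  Ties break to
    the lowest face index.
    """

    def __init__(self, mesh: Mesh):
        if mesh.n_faces == 0:
            raise ValueError("closest-point search requires a mesh with faces")
        self.mesh = mesh
        self.tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self.tri_radius = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.max_radius = float(self.tri_radius.max())
        self.vertex_tree = cKDTree(mesh.vertices)
        self.centroid_tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        d_up, _ = self.vertex_tree.query(points)
        radii = d_up + self.max_radius + 1e-9
        cand = self.centroid_tree.query_ball_point(points, radii)
        qi = np.concatenate(
            [np.full(len(c), i) for i, c in enumerate(cand)]
        ).astype(int)
        ti = np.concatenate([np.asarray(c, dtype=int) for c in cand])
        closest = _point_triangle_closest(points[qi], self.tri[ti])
        d = np.linalg.norm(points[qi] - closest, axis=1)
        # per-query argmin with (distance, face index) lexicographic tie-break
        order = np.lexsort((ti, d, qi))
        qi_s = qi[order]
        first = np.ones(len(qi_s), dtype=bool)
        first[1:] = qi_s[1:] != qi_s[:-1]
        sel = order[first]
        out_pts = closest[sel]
        out_face = ti[sel]
        out_dist = d[sel]
        return out_pts, out_face, out_dist


def closest_points_on_surface(mesh: Mesh, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest points on a triangulated surface for a batch of queries.

    Returns (points_on_surface, face_indices, distances).
    """
    return _SurfaceLocator(mesh).query(points)


def closest_point_on_surface(mesh: Mesh, query) -> tuple[np.ndarray, int, float]:
    """Closest point on the surface for a single query point."""
    pts, fi, d = closest_points_on_surface(mesh, np.asarray(query, float).reshape(1, 3))
    return pts[0], int(fi[0]), float(d[0])


def closest_points_brute(mesh: Mesh, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brute-force closest point over all triangles (oracle for the index)."""
    if mesh.n_faces == 0:
        raise ValueError("closest-point search requires a mesh with faces")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.vertices[mesh.faces]
    n_q, n_f = len(points), len(tri)
    qi = np.repeat(np.arange(n_q), n_f)
    ti = np.tile(np.arange(n_f), n_q)
    closest = _point_triangle_closest(points[qi], tri[ti])
    d = np.linalg.norm(points[qi] - closest, axis=1)
    order = np.lexsort((ti, d, qi))
    qi_s = qi[order]
    first = np.ones(len(qi_s), dtype=bool)
    first[1:] = qi_s[1:] != qi_s[:-1]
    sel = order[first]
    return closest[sel], ti[sel], d[sel]


def knearest_vertices(vertices: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest vertices to a query point.

    Deterministic: ties broken by lowest vertex index (full lexicographic
    sort on (distance, index)).
    """
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(vertices - np.asarray(query, float).reshape(3), axis=1)
    order = np.lexsort((np.arange(len(d)), d))
    return order[:k]


# ---------------------------------------------------------------------------
# Morph and post-alignment
# ---------------------------------------------------------------------------

def morph_frame(
    breast_i: Mesh,
    lm_i: LandmarkFrame,
    lm_next: LandmarkFrame,
    regularization: float = 0.0,
) -> Mesh:
    """TPS-morph a breast mesh towards the next frame using landmark pairs.

    Solves the TPS on (frame-i landmarks -> frame-(i+1) landmarks) and
    evaluates it at every vertex; connectivity is unchanged.
    """
    if breast_i.n_vertices == 0:
        raise ValueError("cannot morph an empty mesh")
    if not np.array_equal(lm_i.landmark_ids, lm_next.landmark_ids):
        raise ValueError("landmark frames must share the same id set")
    tps = solve_tps(lm_i.coords, lm_next.coords, regularization)
    out = breast_i.copy()
    out.vertices = evaluate_tps(tps, breast_i.vertices)
    return out


def post_align(v_morph: Mesh, target: Mesh) -> Mesh:
    """Replace every morphed vertex by its nearest point on the target surface.

    Connectivity is copied from the morphed mesh; every output vertex lies on
    the target surface by construction.
    """
    if target.n_vertices == 0:
        raise ValueError("post-alignment target is empty")
    pts, _, _ = closest_points_on_surface(target, v_morph.vertices)
    out = v_morph.copy()
    out.vertices = pts
    out.timestamp = target.timestamp
    out.frame_index = target.frame_index
    return out


# ---------------------------------------------------------------------------
# Correspondence field
# ---------------------------------------------------------------------------

@dataclass
class CorrespondenceField:
    """Dense frame-to-frame correspondence with a continuous local-TPS query rule.

    Stores the paired vertex sets ``source_vertices`` (frame i) and
    ``aligned_vertices`` (their partners on the frame-(i+1) surface); queries
    are answered by solving a TPS on the M source vertices nearest the query.
    """

    source_vertices: np.ndarray
    aligned_vertices: np.ndarray
    M: int = 20
    frame_pair: tuple[int, int] = (0, 1)
    regularization: float = 0.0
    time_pair: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.source_vertices = np.asarray(self.source_vertices, float).reshape(-1, 3)
        self.aligned_vertices = np.asarray(self.aligned_vertices, float).reshape(-1, 3)
        if len(self.source_vertices) != len(self.aligned_vertices):
            raise ValueError("source and aligned vertex counts must match")
        n = len(self.source_vertices)
        if self.M > n:
            logger.warning("M=%d exceeds vertex count %d; clamped", self.M, n)
            self.M = n

    def save(self, path_stem: str) -> None:
        np.savez(
            path_stem + ".npz",
            source=self.source_vertices,
            aligned=self.aligned_vertices,
        )
        with open(path_stem + ".json", "w") as fh:
            json.dump(
                {
                    "frame_pair": list(self.frame_pair),
                    "time_pair": list(self.time_pair),
                    "M": self.M,
                    "regularization": self.regularization,
                },
                fh,
            )

    @classmethod
    def load(cls, path_stem: str) -> "CorrespondenceField":
        arrays = np.load(path_stem + ".npz")
        meta_path = path_stem + ".json"
        meta = {}
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(
            arrays["source"],
            arrays["aligned"],
            M=int(meta.get("M", 20)),
            frame_pair=tuple(meta.get("frame_pair", (0, 1))),
            regularization=float(meta.get("regularization", 0.0)),
            time_pair=tuple(meta.get("time_pair", (0.0, 0.0))),
        )


def build_correspondence_field(
    breast_i: Mesh, aligned: Mesh, M: int = 20, regularization: float = 0.0
) -> CorrespondenceField:
    """Pair frame-i vertices with their aligned next-frame positions."""
    if breast_i.n_vertices != aligned.n_vertices:
        raise ValueError("source and aligned meshes must have equal vertex counts")
    return CorrespondenceField(
        breast_i.vertices.copy(),
        aligned.vertices.copy(),
        M=M,
        frame_pair=(breast_i.frame_index, aligned.frame_index),
        regularization=regularization,
        time_pair=(breast_i.timestamp, aligned.timestamp),
    )


def map_point(field: CorrespondenceField, x) -> np.ndarray:
    """Transport one point from frame i to frame i+1 via the local TPS.

    Solves a TPS on the M nearest source vertices (ties to lowest index) and
    their aligned partners, then evaluates it at the query.  Degenerate
    neighbourhoods escalate: 2M neighbours, then regularization 1e-6, then
    fail.
    """
    x = np.asarray(x, dtype=float).reshape(3)
    n = len(field.source_vertices)
    attempts = [
        (field.M, field.regularization),
        (min(2 * field.M, n), field.regularization),
        (min(2 * field.M, n), max(field.regularization, 1e-6)),
    ]
    last_exc: Exception | None = None
    for k, lam in attempts:
        idx = knearest_vertices(field.source_vertices, x, k)
        try:
            tps = solve_tps(
                field.source_vertices[idx], field.aligned_vertices[idx], lam
            )
        except np.linalg.LinAlgError as exc:
            last_exc = exc
            continue
        return evaluate_tps(tps, x)
    raise np.linalg.LinAlgError(
        f"local TPS neighbourhood degenerate at query {x}"
    ) from last_exc


def map_points(field: CorrespondenceField, points) -> np.ndarray:
    """Vectorized convenience wrapper over :func:`map_point`."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return np.array([map_point(field, p) for p in pts])


# ---------------------------------------------------------------------------
# Sequence driver
# ---------------------------------------------------------------------------

def register_sequence(
    seq: MeshSequence,
    landmark_frames: list[LandmarkFrame],
    params: RegistrationParams | None = None,
) -> list[CorrespondenceField]:
    """Run morph -> post-align -> field construction over all frame pairs.

    Expects one landmark frame per mesh frame with matching timestamps;
    returns F-1 correspondence fields.
    """
    params = params or RegistrationParams()
    if len(landmark_frames) != len(seq):
        raise ValueError(
            f"{len(landmark_frames)} landmark frames for {len(seq)} mesh frames"
        )
    for mesh, lf in zip(seq.frames, landmark_frames):
        if abs(mesh.timestamp - lf.timestamp) > 1e-6:
            raise ValueError(
                f"timestamp mismatch at frame {mesh.frame_index}: "
                f"mesh {mesh.timestamp} vs landmarks {lf.timestamp}"
            )
    if len(seq) < 2:
        logger.warning("sequence has %d frame(s); no fields to build", len(seq))
        return []
    fields = []
    for i in range(len(seq) - 1):
        t0 = time.perf_counter()
        try:
            source = seq[i]
            target = seq[i + 1]
            if params.decimate_target_to is not None:
                from .preprocess import decimate_mesh

                target = decimate_mesh(target, params.decimate_target_to)
            morphed = morph_frame(
                source, landmark_frames[i], landmark_frames[i + 1],
                params.regularization,
            )
            aligned = post_align(morphed, target) if params.post_align else morphed
            fields.append(
                build_correspondence_field(
                    source, aligned, params.M, params.regularization
                )
            )
        except Exception as exc:
            raise RuntimeError(f"registration failed at frame pair ({i}, {i + 1}): {exc}") from exc
        logger.info(
            "frame pair (%d, %d) registered in %.3f s",
            i, i + 1, time.perf_counter() - t0,
        )
    return fields
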