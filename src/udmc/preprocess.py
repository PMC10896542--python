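"""Automatic breast-region cropping and mesh decimation.

Cropping is driven entirely by the six breast-contour landmarks (default ids
{0, 1, 10, 17, 25, 26}): a height slab ``[h_min - psi, h_max + psi]`` around
the contour landmarks, a half-space bounded by the least-squares breast
plane pushed back by ``psi`` along its normal, and a connectivity filter
that drops disconnected leftovers.  ``psi`` defaults to 30 mm.

Decimation is quadric-error-metric (QEM) edge collapse, used both to prepare
decimated meshes and to evenly sample a surface (each surviving vertex
represents a surface patch).
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .core_io import LandmarkFrame, Mesh

logger = logging.getLogger("udmc")

__all__ = [
    "Plane",
    "CropSpec",
    "estimate_breast_plane",
    "crop_breast",
    "connected_components",
    "decimate_mesh",
]

DEFAULT_CONTOUR_IDS = (0, 1, 10, 17, 25, 26)

_AXES = {
    "+x": np.array([1.0, 0, 0]), "-x": np.array([-1.0, 0, 0]),
    "+y": np.array([0, 1.0, 0]), "-y": np.array([0, -1.0, 0]),
    "+z": np.array([0, 0, 1.0]), "-z": np.array([0, 0, -1.0]),
}


@dataclass
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")

    def signed_distance(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return (pts - self.point) @ self.normal


@dataclass
class CropSpec:
    """Configuration for automatic breast cropping."""

    contour_ids: tuple = DEFAULT_CONTOUR_IDS
    psi: float = 30.0  # mm margin, reused for slab and plane shift
    height_axis: str = "+z"
    landmark_snap_mm: float = 2.0  # component-retention distance to landmarks

    def __post_init__(self) -> None:
        self.contour_ids = tuple(int(i) for i in self.contour_ids)
        if self.psi < 0:
            raise ValueError("psi must be nonnegative")
        if len(self.contour_ids) < 3:
            raise ValueError("need at least 3 contour landmark ids")
        if self.height_axis not in _AXES:
            raise ValueError(f"height_axis must be one of {sorted(_AXES)}")

    @property
    def height_vector(self) -> np.ndarray:
        return _AXES[self.height_axis]


def estimate_breast_plane(
    contour, psi: float, orient_reference=None
) -> Plane:
    """Least-squares breast plane from the contour landmarks.

    The plane passes through the contour centroid ``c_o``.  The normal solves
    the stacked equations ``(c_k - c_o)^T n = 0`` plus one normalization row
    ``sum_i sign_i * n_i = 1`` — the L1 normalization linearized with the
    sign pattern of the total-least-squares (SVD) normal — in the
    least-squares sense, then is rescaled to unit length.  If
    ``orient_reference`` (typically the mean of all landmarks, which sit on
    the anterior breast surface) is given, the normal is flipped so that the
    reference has nonnegative signed distance; otherwise the largest-magnitude
    component is made positive for determinism.

    The returned plane is shifted by ``psi`` against the normal:
    ``point = c_o - psi * n_hat``, so the kept half-space includes a margin.
    """
    contour = np.asarray(contour, dtype=float).reshape(-1, 3)
    if len(contour) < 3:
        raise ValueError("need at least 3 contour points")
    c_o = contour.mean(axis=0)
    D = contour - c_o
    U, svals, Vt = np.linalg.svd(D, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("contour points are collinear; plane is undefined")
    n0 = Vt[-1]
    sgn = np.where(n0 >= 0, 1.0, -1.0)
    A = np.vstack([D, sgn])
    b = np.zeros(len(D) + 1)
    b[-1] = 1.0
    n, *_ = np.linalg.lstsq(A, b, rcond=None)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("degenerate contour configuration")
    n_hat = n / norm
    if orient_reference is not None:
        ref = np.asarray(orient_reference, dtype=float).reshape(3)
        if (ref - c_o) @ n_hat < 0:
            n_hat = -n_hat
    else:
        i = int(np.argmax(np.abs(n_hat)))
        if n_hat[i] < 0:
            n_hat = -n_hat
    return Plane(point=c_o - psi * n_hat, normal=n_hat)


def connected_components(mesh: Mesh) -> np.ndarray:
    """Label vertices by face-edge connectivity (vertices share a label iff
    connected through a path of face edges)."""
    n = mesh.n_vertices
    if mesh.n_faces == 0:
        return np.arange(n)
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = _cc(adj, directed=False)
    return labels


def _submesh(mesh: Mesh, vertex_mask: np.ndarray) -> Mesh:
    """Restrict a mesh to masked vertices; faces crossing the cut are dropped."""
    keep_idx = np.nonzero(vertex_mask)[0]
    remap = -np.ones(mesh.n_vertices, dtype=int)
    remap[keep_idx] = np.arange(len(keep_idx))
    if mesh.n_faces:
        fmask = vertex_mask[mesh.faces].all(axis=1)
        faces = remap[mesh.faces[fmask]]
    else:
        faces = np.zeros((0, 3), int)
    return Mesh(
        mesh.vertices[keep_idx],
        faces,
        None if mesh.gray is None else mesh.gray[keep_idx],
        mesh.frame_index,
        mesh.timestamp,
    )


def crop_breast(mesh: Mesh, landmarks: LandmarkFrame, spec: CropSpec | None = None) -> Mesh:
    """Crop the breast region of a body mesh using the contour landmarks.

    Keeps vertices inside the contour height slab and anterior to the shifted
    breast plane, drops faces crossing a cut (no re-tessellation; vertex
    positions are never modified), then removes disconnected parts: every
    component holding a vertex within ``landmark_snap_mm`` of any landmark is
    retained, falling back to the largest-area component if none qualifies.
    """
    spec = spec or CropSpec()
    contour = landmarks.subset(np.array(spec.contour_ids)).coords
    axis = spec.height_vector
    h = mesh.vertices @ axis
    h_lm = contour @ axis
    lo, hi = h_lm.min() - spec.psi, h_lm.max() + spec.psi
    plane = estimate_breast_plane(
        contour, spec.psi, orient_reference=landmarks.coords.mean(axis=0)
    )
    mask = (h >= lo) & (h <= hi) & (plane.signed_distance(mesh.vertices) >= 0)
    if not mask.any():
        raise ValueError("crop removed everything; check axis/orientation")
    sub = _submesh(mesh, mask)
    labels = connected_components(sub)
    keep_labels = _retained_components(sub, labels, landmarks.coords, spec.landmark_snap_mm)
    out = _submesh(sub, np.isin(labels, keep_labels))
    if out.n_vertices == 0:
        raise ValueError("crop removed everything; check axis/orientation")
    return out


def _retained_components(
    mesh: Mesh, labels: np.ndarray, landmark_coords: np.ndarray, snap_mm: float
) -> np.ndarray:
    from scipy.spatial import cKDTree

    tree = cKDTree(landmark_coords)
    d, _ = tree.query(mesh.vertices)
    near = np.unique(labels[d <= snap_mm])
    if near.size:
        return near
    # fall back to the largest-area component
    if mesh.n_faces == 0:
        counts = np.bincount(labels)
        return np.array([int(np.argmax(counts))])
    tri = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    face_labels = labels[mesh.faces[:, 0]]
    area_per = np.zeros(labels.max() + 1)
    np.add.at(area_per, face_labels, areas)
    return np.array([int(np.argmax(area_per))])


# ---------------------------------------------------------------------------
# Quadric-error-metric decimation
# ---------------------------------------------------------------------------

def _plane_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex 4x4 quadrics: area-weighted sum of incident face-plane quadrics."""
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(n, axis=1)
    ok = area2 > 1e-12
    n_unit = np.zeros_like(n)
    n_unit[ok] = n[ok] / area2[ok, None]
    d = -(n_unit * tri[:, 0]).sum(axis=1)
    p = np.hstack([n_unit, d[:, None]])  # (F, 4) plane coefficients
    Kp = p[:, :, None] * p[:, None, :] * (0.5 * area2)[:, None, None]
    Q = np.zeros((len(vertices), 4, 4))
    for c in range(3):
        np.add.at(Q, faces[:, c], Kp)
    return Q


def _collapse_target(Q: np.ndarray, va: np.ndarray, vb: np.ndarray, bbox) -> tuple[np.ndarray, float]:
    """Optimal collapse position for quadric Q, clamped to candidate points
    (optimal solve, midpoint, endpoints) within the mesh bounding box."""
    A = Q[:3, :3]
    b = -Q[:3, 3]
    candidates = [va, vb, 0.5 * (va + vb)]
    try:
        v_opt = np.linalg.solve(A + 1e-9 * np.trace(A) * np.eye(3) / 3.0, b)
        if np.all(v_opt >= bbox[0] - 1e-9) and np.all(v_opt <= bbox[1] + 1e-9):
            candidates.insert(0, v_opt)
    except np.linalg.LinAlgError:
        pass
    best, best_cost = None, np.inf
    for v in candidates:
        h = np.append(v, 1.0)
        cost = float(h @ Q @ h)
        if cost < best_cost:
            best, best_cost = v, cost
    return best, max(best_cost, 0.0)


def decimate_mesh(mesh: Mesh, target_vertices: int) -> Mesh:
    """Quadric-error-metric edge-collapse decimation to ~``target_vertices``.

    Vertices are removed one collapse at a time in increasing quadric-error
    order until the target count is reached; the collapse position is the
    quadric-optimal point (clamped to the original bounding box so decimation
    never inflates the mesh).  If the mesh runs out of collapsible edges the
    best effort so far is returned with a warning.
    """
    if target_vertices < 4:
        raise ValueError("target_vertices must be at least 4")
    if mesh.n_vertices <= target_vertices or mesh.n_faces == 0:
        return mesh.copy()

    V = mesh.vertices.copy()
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set] = {i: set() for i in range(len(V))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)
    Q = _plane_quadrics(V, mesh.faces)
    bbox = (V.min(axis=0), V.max(axis=0))
    alive = np.ones(len(V), dtype=bool)
    version = np.zeros(len(V), dtype=np.int64)

    def edges_of(v: int):
        nb = set()
        for fi in vert_faces[v]:
            nb.update(faces[fi])
        nb.discard(v)
        return nb

    heap: list = []
    counter = itertools.count()

    def push_edge(a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        pos, cost = _collapse_target(Q[a] + Q[b], V[a], V[b], bbox)
        heapq.heappush(
            heap, (cost, next(counter), a, b, version[a], version[b], pos)
        )

    seen = set()
    for f in faces.values():
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                push_edge(*key)
    del seen

    n_alive = int(alive.sum())

    def remove_face(fi: int, touched: set) -> None:
        f = faces.pop(fi)
        for v in f:
            vert_faces[v].discard(fi)
        touched.update(f)

    while n_alive > target_vertices and heap:
        cost, _, a, b, va, vb, pos = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or version[a] != va or version[b] != vb:
            continue
        shared = vert_faces[a] & vert_faces[b]
        if not shared:  # not an edge anymore
            continue
        V[a] = pos
        Q[a] = Q[a] + Q[b]
        alive[b] = False
        n_alive -= 1
        touched: set = set()
        for fi in list(shared):
            remove_face(fi, touched)
        for fi in list(vert_faces[b]):
            f = faces[fi]
            newf = tuple(a if v == b else v for v in f)
            if len(set(newf)) < 3:  # degenerate after merge
                remove_face(fi, touched)
                continue
            faces[fi] = newf
            vert_faces[b].discard(fi)
            vert_faces[a].add(fi)
        version[a] += 1
        # orphan checks only after the rewrite is complete (a may be
        # transiently face-free while its shared faces are removed)
        touched.add(a)
        touched.discard(b)
        for v in touched:
            if alive[v] and not vert_faces[v]:
                alive[v] = False
                n_alive -= 1
        if alive[a]:
            for nb in edges_of(a):
                push_edge(a, nb)

    if n_alive > target_vertices:
        logger.warning(
            "decimation stalled at %d vertices (target %d); returning best effort",
            n_alive, target_vertices,
        )

    used = sorted({v for f in faces.values() for v in f})
    remap = {old: new for new, old in enumerate(used)}
    new_faces = np.array(
        [[remap[v] for v in f] for f in faces.values()], dtype=int
    ).reshape(-1, 3)
    new_verts = V[used]
    gray = None
    if mesh.gray is not None:
        gray = mesh.gray[used]  # nearest-original approximation
    return Mesh(new_verts, new_faces, gray, mesh.frame_index, mesh.timestamp)
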