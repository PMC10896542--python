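"""Core data model and I/O for 4D surface-scan sequences and MoCap trajectories.

The pipeline works on two streams recorded simultaneously:

* a 4D scan — one triangular surface mesh per frame, with per-frame vertex
  counts and connectivity that generally differ (each frame is reconstructed
  independently by the scanner);
* MoCap landmark trajectories — K corresponded marker tracks, possibly at a
  different sampling rate and with an unknown clock offset.

All lengths are millimetres; timestamps are seconds.  Unit conversion (e.g.
reporting errors in cm) happens only at the reporting layer.
"""

from __future__ import annotations

import glob as _glob
import io
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import make_interp_spline

logger = logging.getLogger("udmc")

__all__ = [
    "Mesh",
    "MeshSequence",
    "LandmarkFrame",
    "LandmarkTrajectorySet",
    "Trajectory",
    "read_mesh",
    "write_mesh",
    "read_mesh_sequence",
    "read_landmark_trajectories",
    "write_landmark_trajectories",
    "resample_trajectories",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """A single triangulated surface frame.

    Parameters
    ----------
    vertices : (N, 3) float array, mm.
    faces : (F, 3) int array of vertex indices (may be empty).
    gray : optional (N,) float array of per-vertex gray values in [0, 255].
    frame_index : position of this frame in its sequence.
    timestamp : acquisition time in seconds.
    """

    vertices: np.ndarray
    faces: np.ndarray
    gray: np.ndarray | None = None
    frame_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise ValueError("face indices out of range")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if same.any():
                raise ValueError(
                    f"{int(same.sum())} faces have repeated vertex indices"
                )
        if self.gray is not None:
            self.gray = np.asarray(self.gray, dtype=float).ravel()
            if len(self.gray) != n:
                raise ValueError(
                    f"gray has {len(self.gray)} values for {n} vertices"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "Mesh":
        return Mesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.gray is None else self.gray.copy(),
            self.frame_index,
            self.timestamp,
        )


@dataclass
class MeshSequence:
    """An ordered 4D scan: one mesh per frame at a nominal frame rate."""

    frames: list[Mesh]
    fps: float
    name: str = ""

    def __post_init__(self) -> None:
        ts = np.array([f.timestamp for f in self.frames], dtype=float)
        if len(ts) > 1:
            if not np.all(np.diff(ts) > 0):
                raise ValueError("frame timestamps must be strictly increasing")
            expected = np.arange(len(ts)) / self.fps + ts[0]
            if np.abs(ts - expected).max() > 1e-6:
                raise ValueError(
                    "frame timestamps inconsistent with fps beyond 1e-6 s"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Mesh:
        return self.frames[i]

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])


@dataclass
class LandmarkFrame:
    """K corresponded landmark positions at one instant, ordered by id."""

    coords: np.ndarray
    landmark_ids: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.landmark_ids = np.asarray(self.landmark_ids, dtype=int).ravel()
        if len(self.coords) != len(self.landmark_ids):
            raise ValueError("coords and landmark_ids length mismatch")
        if len(np.unique(self.landmark_ids)) != len(self.landmark_ids):
            raise ValueError("duplicate landmark ids in frame")
        order = np.argsort(self.landmark_ids, kind="stable")
        self.landmark_ids = self.landmark_ids[order]
        self.coords = self.coords[order]

    def subset(self, ids) -> "LandmarkFrame":
        ids = np.asarray(ids, dtype=int)
        mask = np.isin(self.landmark_ids, ids)
        missing = set(ids.tolist()) - set(self.landmark_ids.tolist())
        if missing:
            raise KeyError(f"landmark ids not present: {sorted(missing)}")
        return LandmarkFrame(self.coords[mask], self.landmark_ids[mask], self.timestamp)

    def drop(self, landmark_id: int) -> "LandmarkFrame":
        mask = self.landmark_ids != landmark_id
        if mask.all():
            raise KeyError(f"landmark id {landmark_id} not present")
        return LandmarkFrame(self.coords[mask], self.landmark_ids[mask], self.timestamp)


@dataclass
class LandmarkTrajectorySet:
    """K landmark tracks sharing a common time base.

    ``positions`` has shape (K, T, 3); row k is the track of ``landmark_ids[k]``.
    Same-id points in consecutive frames are corresponding material points —
    this ordering convention is what makes the tracks usable as prior
    correspondence for the motion model.
    """

    landmark_ids: np.ndarray
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.landmark_ids = np.asarray(self.landmark_ids, dtype=int).ravel()
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.positions = np.asarray(self.positions, dtype=float)
        K, T = len(self.landmark_ids), len(self.times)
        if self.positions.shape != (K, T, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({K}, {T}, 3)"
            )
        if T > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        order = np.argsort(self.landmark_ids, kind="stable")
        self.landmark_ids = self.landmark_ids[order]
        self.positions = self.positions[order]

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_ids)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def sampling_rate(self) -> float:
        if len(self.times) < 2:
            return float("nan")
        return 1.0 / float(np.mean(np.diff(self.times)))

    def frame(self, i: int) -> LandmarkFrame:
        return LandmarkFrame(self.positions[:, i, :], self.landmark_ids, float(self.times[i]))

    def frames(self) -> list[LandmarkFrame]:
        return [self.frame(i) for i in range(self.n_frames)]

    def track(self, landmark_id: int) -> np.ndarray:
        idx = np.nonzero(self.landmark_ids == landmark_id)[0]
        if not idx.size:
            raise KeyError(f"landmark id {landmark_id} not present")
        return self.positions[idx[0]]

    def drop(self, landmark_id: int) -> "LandmarkTrajectorySet":
        mask = self.landmark_ids != landmark_id
        if mask.all():
            raise KeyError(f"landmark id {landmark_id} not present")
        return LandmarkTrajectorySet(
            self.landmark_ids[mask], self.times, self.positions[mask]
        )


@dataclass
class Trajectory:
    """One tracked point: positions over frames plus its seed."""

    points: np.ndarray
    times: np.ndarray
    seed_point: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed_frame: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.times = np.asarray(self.times, dtype=float).ravel()
        if len(self.points) != len(self.times):
            raise ValueError("points and times length mismatch")
        if self.seed_point is None:
            self.seed_point = self.points[self.seed_frame].copy()
        else:
            self.seed_point = np.asarray(self.seed_point, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

# Rec. 709 luma weights, used when an input mesh carries RGB instead of gray.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _gray_from_trimesh(tm: trimesh.Trimesh) -> np.ndarray | None:
    raw = tm.metadata.get("_ply_raw", {})
    vdata = raw.get("vertex", {}).get("data") if isinstance(raw, dict) else None
    if vdata is not None:
        for key in ("gray", "quality"):
            try:
                col = vdata[key]
            except (KeyError, ValueError, IndexError):
                continue
            return np.asarray(col, dtype=float).ravel()
    # fall back to vertex colors -> luma
    try:
        colors = np.asarray(tm.visual.vertex_colors, dtype=float)
    except Exception:
        return None
    if colors is None or len(colors) == 0 or len(colors) != len(tm.vertices):
        return None
    rgb = colors[:, :3]
    if np.allclose(rgb, rgb[0]):  # uninformative default color
        return None
    return rgb @ _LUMA


def read_mesh(path: str, frame_index: int = 0, timestamp: float = 0.0) -> Mesh:
    """Read a PLY or OBJ triangle mesh.

    Non-triangular faces are fan-triangulated (with a warning).  Per-vertex
    gray is taken from a PLY ``gray``/``quality`` property, or from RGB vertex
    colors via Rec. 709 luma.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"mesh file not found: {path}")
    try:
        loaded = trimesh.load(path, process=False)
        if isinstance(loaded, trimesh.Scene):
            loaded = loaded.to_mesh()
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise ValueError(f"could not parse mesh file {path}: {exc}") from exc
    if isinstance(loaded, trimesh.PointCloud) or (
        hasattr(loaded, "faces") and len(loaded.faces) == 0
    ):
        logger.warning("mesh %s has no faces; loading as point cloud", path)
        verts = np.asarray(loaded.vertices, dtype=float)
        gray = None
        if hasattr(loaded, "metadata"):
            fake = trimesh.Trimesh(vertices=verts, faces=np.zeros((0, 3), int), process=False)
            fake.metadata.update(loaded.metadata)
            gray = _gray_from_trimesh(fake)
        return Mesh(verts, np.zeros((0, 3), int), gray, frame_index, timestamp)
    if not isinstance(loaded, trimesh.Trimesh):
        raise ValueError(f"{path} did not parse as a triangle mesh")
    if _file_has_polygon_faces(path):
        logger.warning("%s contains non-triangular faces; fan-triangulated", path)
    gray = _gray_from_trimesh(loaded)
    return Mesh(
        np.asarray(loaded.vertices, dtype=float),
        np.asarray(loaded.faces, dtype=int),
        gray,
        frame_index,
        timestamp,
    )


def _file_has_polygon_faces(path: str) -> bool:
    """Cheap check whether an OBJ file declares faces with > 3 vertices."""
    if os.path.splitext(path)[1].lower() != ".obj":
        return False
    try:
        with open(path, "r", errors="ignore") as fh:
            for line in fh:
                if line.startswith("f ") and len(line.split()) > 4:
                    return True
    except OSError:
        return False
    return False


def write_mesh(mesh: Mesh, path: str) -> None:
    """Write a mesh as ASCII PLY (double precision) or OBJ.

    PLY carries gray as a float ``quality`` vertex property so that a
    write/read round trip preserves vertices to well below 1e-6 mm and gray
    exactly.  OBJ output drops gray (the format has no standard slot for it).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        if mesh.gray is not None:
            logger.warning("OBJ output drops per-vertex gray (%s)", path)
        buf = io.StringIO()
        for v in mesh.vertices:
            buf.write(f"v {v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")
        for f in mesh.faces:
            buf.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
        _write_text(path, buf.getvalue())
        return
    if ext != ".ply":
        raise ValueError(f"unsupported mesh format: {path}")
    if mesh.n_faces == 0:
        logger.warning("writing face-free mesh (point cloud) to %s", path)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if mesh.gray is not None:
        lines.append("property double quality")
    lines += [
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    body = []
    if mesh.gray is not None:
        for v, g in zip(mesh.vertices, mesh.gray):
            body.append(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g} {g:.17g}")
    else:
        for v in mesh.vertices:
            body.append(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    for f in mesh.faces:
        body.append(f"3 {f[0]} {f[1]} {f[2]}")
    _write_text(path, "\n".join(lines + body) + "\n")


def _write_text(path: str, text: str) -> None:
    try:
        with open(path, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


_FRAME_NUM = re.compile(r"(\d+)(?!.*\d)")


def read_mesh_sequence(path_pattern: str, fps: float, name: str = "") -> MeshSequence:
    """Read a numbered mesh sequence matching a glob pattern.

    Frames are ordered by the last integer in each filename and assigned
    timestamps ``index / fps`` starting at 0.
    """
    paths = sorted(_glob.glob(path_pattern))
    if not paths:
        raise FileNotFoundError(f"no mesh files match pattern: {path_pattern}")

    def sort_key(p: str):
        m = _FRAME_NUM.search(os.path.basename(p))
        return (int(m.group(1)) if m else 0, p)

    paths.sort(key=sort_key)
    frames = [
        read_mesh(p, frame_index=i, timestamp=i / fps) for i, p in enumerate(paths)
    ]
    return MeshSequence(frames, fps=fps, name=name or path_pattern)


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["frame", "time", "landmark_id", "x", "y", "z"]


def read_landmark_trajectories(path: str) -> LandmarkTrajectorySet:
    """Read MoCap/ground-truth trajectories from a CSV.

    Expected columns: ``frame, time, landmark_id, x, y, z`` (mm).  Every
    landmark id must be present in every frame, exactly once.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    dup = df.duplicated(subset=["frame", "landmark_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (frame, id) = ({int(row['frame'])}, {int(row['landmark_id'])})"
        )
    ids = np.sort(df["landmark_id"].unique())
    frames = np.sort(df["frame"].unique())
    counts = df.groupby("frame")["landmark_id"].apply(set)
    full = set(int(i) for i in ids)
    problems = [
        (int(f), sorted(full - s)) for f, s in counts.items() if s != full
    ]
    if problems:
        f, missing = problems[0]
        raise ValueError(f"{path}: frame {f} missing landmark id(s) {missing}")
    df = df.sort_values(["landmark_id", "frame"])
    times = (
        df.drop_duplicates("frame").sort_values("frame")["time"].to_numpy(float)
    )
    K, T = len(ids), len(frames)
    positions = df[["x", "y", "z"]].to_numpy(float).reshape(K, T, 3)
    return LandmarkTrajectorySet(ids, times, positions)


def write_landmark_trajectories(trajs: LandmarkTrajectorySet, path: str) -> None:
    rows = []
    for k, lid in enumerate(trajs.landmark_ids):
        for i, t in enumerate(trajs.times):
            x, y, z = trajs.positions[k, i]
            rows.append((i, t, int(lid), x, y, z))
    pd.DataFrame(rows, columns=_TRAJ_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trajectory resampling
# ---------------------------------------------------------------------------

def resample_trajectories(
    trajs: LandmarkTrajectorySet, query_times
) -> list[LandmarkFrame]:
    """Resample all landmark tracks at arbitrary times.

    Uses piecewise-quadratic spline interpolation per coordinate, which makes
    the continuous tracks exact on quadratic motion and exact at the recorded
    samples.  Queries outside the recorded interval are refused.
    """
    query_times = np.atleast_1d(np.asarray(query_times, dtype=float))
    t = trajs.times
    lo, hi = t[0], t[-1]
    bad = (query_times < lo - 1e-12) | (query_times > hi + 1e-12)
    if bad.any():
        raise ValueError(
            f"query time {query_times[bad][0]:g} s outside recorded range "
            f"[{lo:g}, {hi:g}] s (extrapolation refused)"
        )
    K, T = trajs.n_landmarks, trajs.n_frames
    if T == 1:
        out = np.repeat(trajs.positions[:, 0:1, :], len(query_times), axis=1)
    else:
        k = min(2, T - 1)
        flat = trajs.positions.reshape(K, T, 3).transpose(1, 0, 2).reshape(T, -1)
        spline = make_interp_spline(t, flat, k=k)
        qt = np.clip(query_times, lo, hi)
        out = spline(qt).reshape(len(query_times), K, 3).transpose(1, 0, 2)
    return [
        LandmarkFrame(out[:, i, :], trajs.landmark_ids, float(qt_i))
        for i, qt_i in enumerate(query_times)
    ]
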