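"""Downstream tasks and evaluation protocols.

* **virtual landmark tracking** — chain the per-pair correspondence fields:
  a seed point in frame 1 is transported field by field through the whole
  sequence, yielding a trajectory for an arbitrary (unmarked) surface point;
* **deformation intensity** — evenly sample the first cropped frame (QEM
  decimation), track each sample, and use its trajectory length (mm) as a
  local deformation magnitude; full-resolution vertices are coloured by
  their nearest sample (Voronoi assignment);
* **control-landmark evaluation** — track seeds placed at the frame-1
  ground-truth landmark positions and report the Euclidean deviation from
  the ground-truth tracks (mean, pooled SD, frame-wise curve);
* **leave-one-out evaluation** — exclude each landmark in turn from the
  motion-model controls, rebuild all fields, and track the held-out landmark
  as a non-control accuracy estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import LandmarkFrame, LandmarkTrajectorySet, MeshSequence, Trajectory
from .preprocess import decimate_mesh
from .registration import (
    CorrespondenceField,
    RegistrationParams,
    map_point,
    register_sequence,
)

logger = logging.getLogger("udmc")

__all__ = [
    "IntensityMap",
    "ErrorReport",
    "track_virtual_landmarks",
    "trajectory_length",
    "deformation_intensity",
    "eval_control_error",
    "eval_loo_error",
    "subsample_sequence",
]


def track_virtual_landmarks(
    fields: list[CorrespondenceField], seeds
) -> list[Trajectory]:
    """Track seed points (frame-1 coordinates) through the field chain."""
    seeds = np.asarray(seeds, dtype=float).reshape(-1, 3)
    if not fields:
        raise ValueError("no correspondence fields to track through")
    times = [fields[0].time_pair[0]] + [f.time_pair[1] for f in fields]
    trajectories = []
    for seed in seeds:
        pts = [seed]
        for i, fld in enumerate(fields):
            try:
                pts.append(map_point(fld, pts[-1]))
            except Exception as exc:
                raise RuntimeError(
                    f"tracking failed at frame pair {fld.frame_pair}: {exc}"
                ) from exc
        trajectories.append(
            Trajectory(np.array(pts), np.array(times), seed_point=seed, seed_frame=0)
        )
    return trajectories


def trajectory_length(traj: Trajectory) -> float:
    """Total path length (mm): sum of consecutive point-to-point distances."""
    if len(traj) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(traj.points, axis=0), axis=1).sum())


@dataclass
class IntensityMap:
    """Deformation intensity at sample points plus full-resolution colouring."""

    sample_points: np.ndarray  # (S, 3) frame-1 positions of the samples
    intensity: np.ndarray  # (S,) trajectory length per sample, mm
    vertex_intensity: np.ndarray  # (N,) nearest-sample intensity per frame-1 vertex
    trajectories: list[Trajectory] | None = None

    def __post_init__(self) -> None:
        self.sample_points = np.asarray(self.sample_points, float).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, float).ravel()
        self.vertex_intensity = np.asarray(self.vertex_intensity, float).ravel()
        if len(self.intensity) != len(self.sample_points):
            raise ValueError("one intensity value per sample point required")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensity must be nonnegative")


def deformation_intensity(
    seq: MeshSequence,
    fields: list[CorrespondenceField],
    n_samples: int = 100,
) -> IntensityMap:
    """Deformation-intensity map over the first frame of a cropped sequence.

    The first frame is evenly sampled to ``n_samples`` virtual landmarks by
    quadric decimation; each is tracked through the sequence and scored by
    trajectory length.  Every full-resolution frame-1 vertex inherits the
    intensity of its nearest sample.
    """
    if len(fields) != len(seq) - 1:
        raise ValueError("fields must cover the sequence (F-1 fields)")
    first = seq[0]
    sampled = decimate_mesh(first, min(n_samples, first.n_vertices))
    samples = sampled.vertices
    trajs = track_virtual_landmarks(fields, samples)
    intensity = np.array([trajectory_length(t) for t in trajs])
    # Voronoi colouring: nearest sample per full-resolution vertex,
    # deterministic tie-break to the lowest sample index
    d = np.linalg.norm(
        first.vertices[:, None, :] - samples[None, :, :], axis=2
    )
    nearest = np.argmin(d, axis=1)  # argmin returns first occurrence on ties
    return IntensityMap(samples, intensity, intensity[nearest], trajs)


# ---------------------------------------------------------------------------
# Error reports
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Per-landmark, per-frame tracking error with pooled aggregates (mm).

    The SD pools all (landmark, frame) error samples.
    """

    errors: np.ndarray  # (K, F) Euclidean error, mm
    landmark_ids: np.ndarray
    times: np.ndarray
    mode: str = "control"  # "control" | "leave-one-out"

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        self.landmark_ids = np.asarray(self.landmark_ids, dtype=int).ravel()
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.errors.shape != (len(self.landmark_ids), len(self.times)):
            raise ValueError("errors must be (n_landmarks, n_frames)")
        if np.any(self.errors < 0):
            raise ValueError("errors must be nonnegative")

    @property
    def mean(self) -> float:
        return float(self.errors.mean())

    @property
    def sd(self) -> float:
        return float(self.errors.std())

    @property
    def frame_mean(self) -> np.ndarray:
        return self.errors.mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, lid in enumerate(self.landmark_ids):
            for i, t in enumerate(self.times):
                rows.append((int(lid), i, t, self.errors[k, i]))
        return pd.DataFrame(
            rows, columns=["landmark_id", "frame", "time", "error_mm"]
        )

    def summary(self, unit: str = "mm") -> dict:
        scale = 0.1 if unit == "cm" else 1.0
        return {
            "mode": self.mode,
            "mean": self.mean * scale,
            "sd": self.sd * scale,
            "unit": unit,
            "n_landmarks": int(len(self.landmark_ids)),
            "n_frames": int(len(self.times)),
        }


def _gt_matrix(gt: LandmarkTrajectorySet) -> np.ndarray:
    return gt.positions  # (K, F, 3)


def eval_control_error(
    fields: list[CorrespondenceField], gt: LandmarkTrajectorySet
) -> ErrorReport:
    """Tracking error on control landmarks.

    Seeds are the frame-1 ground-truth positions; errors are per landmark and
    per frame against the ground-truth tracks (frame 1 included, error 0).
    """
    if gt.n_frames != len(fields) + 1:
        raise ValueError(
            f"ground truth has {gt.n_frames} frames but fields imply {len(fields) + 1}"
        )
    seeds = gt.positions[:, 0, :]
    trajs = track_virtual_landmarks(fields, seeds)
    tracked = np.stack([t.points for t in trajs])  # (K, F, 3)
    errors = np.linalg.norm(tracked - _gt_matrix(gt), axis=2)
    return ErrorReport(errors, gt.landmark_ids, gt.times, mode="control")


def eval_loo_error(
    seq: MeshSequence,
    landmark_frames: list[LandmarkFrame],
    gt: LandmarkTrajectorySet,
    params: RegistrationParams | None = None,
) -> ErrorReport:
    """Leave-one-out (non-control) tracking error.

    Each landmark is excluded in turn from the TPS controls, the whole field
    chain is rebuilt, and the held-out landmark is tracked from its frame-1
    ground-truth position.  Requires at least 6 landmarks so that 5 controls
    remain after exclusion.
    """
    params = params or RegistrationParams()
    if gt.n_landmarks < 6:
        raise ValueError("leave-one-out needs at least 6 landmarks")
    if gt.n_frames != len(seq):
        raise ValueError("ground-truth frame count must match the sequence")
    errors = np.zeros((gt.n_landmarks, gt.n_frames))
    for k, lid in enumerate(gt.landmark_ids):
        lms_excl = [lf.drop(int(lid)) for lf in landmark_frames]
        fields = register_sequence(seq, lms_excl, params)
        seed = gt.positions[k, 0, :]
        (traj,) = track_virtual_landmarks(fields, seed.reshape(1, 3))
        errors[k] = np.linalg.norm(traj.points - gt.positions[k], axis=1)
        logger.info(
            "leave-one-out landmark %d: mean error %.3f mm", lid, errors[k].mean()
        )
    return ErrorReport(errors, gt.landmark_ids, gt.times, mode="leave-one-out")


def subsample_sequence(
    seq: MeshSequence, landmark_frames: list[LandmarkFrame], chunk: int
) -> tuple[MeshSequence, list[LandmarkFrame]]:
    """Build a reduced-rate sub-dataset by loading 1 frame per chunk of ``chunk``.

    ``chunk=12`` turns a 120 fps sequence into a 10 fps one, ``chunk=2`` into
    60 fps, ``chunk=1`` leaves it unchanged.
    """
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    idx = list(range(0, len(seq), chunk))
    frames = []
    lms = []
    new_fps = seq.fps / chunk
    for new_i, i in enumerate(idx):
        m = seq[i].copy()
        m.frame_index = new_i
        m.timestamp = new_i / new_fps
        frames.append(m)
        lf = landmark_frames[i]
        lms.append(LandmarkFrame(lf.coords.copy(), lf.landmark_ids.copy(), m.timestamp))
    return MeshSequence(frames, fps=new_fps, name=f"{seq.name}-sub{chunk}"), lms
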