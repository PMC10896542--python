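"""Three-dimensional thin-plate-spline (TPS) interpolation.

The TPS is the motion model of the pipeline: given K control points
``c_k`` and their value points (the same landmarks in the next frame), the
map

    f(x) = a_0 + a^T x + sum_k w_k * phi(||x - c_k||),   phi(r) = r^2 ln r

interpolates the control/value pairs exactly (at zero regularization) and
extends the motion smoothly to the whole surface.  The kernel weights are
subject to the standard orthogonality side conditions

    sum_k w_k = 0    and    sum_k w_k c_k^T = 0,

which make the augmented system square and well posed and guarantee that an
exactly affine control->value relation is reproduced with vanishing kernel
weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["TPSMap", "tps_kernel", "solve_tps", "evaluate_tps"]


def tps_kernel(r):
    """TPS radial kernel ``phi(r) = r^2 ln r``, continuously extended by 0 at r=0.

    Accepts scalars or arrays of nonnegative distances.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("tps_kernel requires nonnegative distances")
    out = np.zeros_like(r)
    pos = r > 0
    rp = r[pos]
    out[pos] = rp * rp * np.log(rp)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class TPSMap:
    """A solved TPS transform: affine part plus kernel weights at control sites."""

    control_sites: np.ndarray  # (K, 3)
    affine_offset: np.ndarray  # (3,)  a_0
    affine_matrix: np.ndarray  # (3, 3): x contributes x @ affine_matrix
    kernel_weights: np.ndarray  # (K, 3)
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.control_sites = np.asarray(self.control_sites, dtype=float).reshape(-1, 3)
        self.affine_offset = np.asarray(self.affine_offset, dtype=float).reshape(3)
        self.affine_matrix = np.asarray(self.affine_matrix, dtype=float).reshape(3, 3)
        self.kernel_weights = np.asarray(self.kernel_weights, dtype=float).reshape(-1, 3)
        if len(self.kernel_weights) != len(self.control_sites):
            raise ValueError("one kernel weight vector per control site required")

    def __call__(self, points) -> np.ndarray:
        return evaluate_tps(self, points)

    # small structured text serialization, mainly for debugging runs
    def to_json(self) -> str:
        return json.dumps(
            {
                "control_sites": self.control_sites.tolist(),
                "affine_offset": self.affine_offset.tolist(),
                "affine_matrix": self.affine_matrix.tolist(),
                "kernel_weights": self.kernel_weights.tolist(),
                "regularization": self.regularization,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TPSMap":
        d = json.loads(text)
        return cls(
            np.array(d["control_sites"]),
            np.array(d["affine_offset"]),
            np.array(d["affine_matrix"]),
            np.array(d["kernel_weights"]),
            float(d["regularization"]),
        )


def solve_tps(controls, values, regularization: float = 0.0) -> TPSMap:
    """Solve a 3D TPS mapping ``controls -> values``.

    Builds and solves the augmented symmetric system

        [ Phi + lam*I   P ] [ W ]   [ values ]
        [ P^T           0 ] [ A ] = [ 0      ]

    with ``Phi_jk = phi(||c_j - c_k||)`` and ``P = [1, c^T]``; the three
    coordinates share one factorization.  At ``lam = 0`` the map interpolates
    the pairs exactly.

    Raises on duplicate controls and on singular (collinear/degenerate)
    configurations, advising a positive regularization in the latter case.
    """
    controls = np.asarray(controls, dtype=float).reshape(-1, 3)
    values = np.asarray(values, dtype=float).reshape(-1, 3)
    K = len(controls)
    if values.shape != (K, 3):
        raise ValueError("controls and values must have identical shapes")
    if K < 5:
        raise ValueError(f"TPS needs at least 5 control points, got {K}")
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    D = cdist(controls, controls)
    iu = np.triu_indices(K, k=1)
    dup = np.nonzero(D[iu] < 1e-12)[0]
    if dup.size:
        j, k = iu[0][dup[0]], iu[1][dup[0]]
        raise ValueError(f"duplicate control points at indices {j} and {k}")

    Phi = tps_kernel(D)
    P = np.hstack([np.ones((K, 1)), controls])  # (K, 4)
    A = np.zeros((K + 4, K + 4))
    A[:K, :K] = Phi + regularization * np.eye(K)
    A[:K, K:] = P
    A[K:, :K] = P.T
    rhs = np.zeros((K + 4, 3))
    rhs[:K] = values
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "TPS system is singular (collinear or coplanar-degenerate "
            "controls); retry with regularization > 0"
        ) from exc
    # guard against near-singular solves that "succeed" numerically
    if not np.all(np.isfinite(sol)) or np.abs(sol).max() > 1e12:
        raise np.linalg.LinAlgError(
            "TPS system is numerically singular; retry with regularization > 0"
        )
    tps = TPSMap(
        control_sites=controls,
        affine_offset=sol[K],
        affine_matrix=sol[K + 1 :],
        kernel_weights=sol[:K],
        regularization=regularization,
    )
    if regularization == 0.0:
        resid = np.abs(evaluate_tps(tps, controls) - values).max()
        scale = max(1.0, np.abs(values).max())
        if resid > 1e-6 * scale:
            raise np.linalg.LinAlgError(
                f"TPS interpolation residual {resid:.3g} mm indicates an "
                "ill-conditioned control configuration; retry with "
                "regularization > 0"
            )
    return tps


def evaluate_tps(tps: TPSMap, points) -> np.ndarray:
    """Evaluate a solved TPS map at query points (vectorized, deterministic)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    out = (
        tps.affine_offset
        + pts @ tps.affine_matrix
        + tps_kernel(cdist(pts, tps.control_sites)) @ tps.kernel_weights
    )
    return out[0] if single else out
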