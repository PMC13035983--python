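"""Shared linear-algebra primitives.

PCA frames, total-least-squares plane fits, and angle computations used by
both the cochlear and vestibular measurement chains.  Every angle reported
downstream goes through :func:`angle_between_vectors`, so the folding
convention (angles between undirected axes live in [0, 90] degrees) is
defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PcaFrame",
    "PlaneFit",
    "pca_frame",
    "fit_plane",
    "angle_between_vectors",
    "angle_between_planes",
]


@dataclass(frozen=True)
class PcaFrame:
    """Principal-component frame of a 3-D point cloud.

    Attributes
    ----------
    centroid_mm : (3,) float array
        Mean of the input points.
    axes : (3, 3) float array
        Orthonormal principal directions as *rows*, ordered by descending
        explained variance.  Sign convention: each axis is flipped so its
        largest-magnitude component is positive, then the third axis is
        adjusted (if needed) to keep the frame right-handed.
    eigenvalues : (3,) float array
        Covariance eigenvalues, sorted descending.
    """

    centroid_mm: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express world points in this frame (centered, rotated)."""
        return (np.asarray(points, dtype=float) - self.centroid_mm) @ self.axes.T

    def to_world_direction(self, v: np.ndarray) -> np.ndarray:
        """Map a direction from frame coordinates back to world coordinates."""
        return np.asarray(v, dtype=float) @ self.axes


@dataclass(frozen=True)
class PlaneFit:
    """Total-least-squares plane through a point cloud."""

    normal: np.ndarray
    centroid_mm: np.ndarray
    rms_residual_mm: float


def _apply_sign_convention(axes: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-|component| is positive; keep right-handed."""
    axes = axes.copy()
    for i in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if axes.shape[0] == 3 and np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def _sorted_eig(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("expected an (N, 3) point array")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite values")
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / points.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    axes = eigvecs[:, order].T  # rows
    return centroid, axes, eigvals


def pca_frame(points: np.ndarray) -> PcaFrame:
    """Principal-component frame of a point cloud.

    Requires at least 4 points spanning at least a plane: collinear input
    (rank < 2 covariance) is rejected.  A perfectly planar cloud is accepted;
    its third axis is the plane normal with eigenvalue 0.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 4:
        raise ValueError("pca_frame requires at least 4 points")
    centroid, axes, eigvals = _sorted_eig(points)
    if eigvals[1] <= 1e-12 * max(eigvals[0], 1.0):
        raise ValueError("degenerate point cloud: points are (near-)collinear")
    axes = _apply_sign_convention(axes)
    return PcaFrame(centroid_mm=centroid, axes=axes, eigenvalues=eigvals)


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Orthogonal (total-least-squares) plane fit.

    The normal is the eigenvector of the smallest covariance eigenvalue and
    the RMS residual is the square root of that eigenvalue.  There is no
    privileged axis: the fit is invariant under rigid motion of the points.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("fit_plane requires at least 3 points")
    centroid, axes, eigvals = _sorted_eig(points)
    if eigvals[1] <= 1e-12 * max(eigvals[0], 1.0):
        raise ValueError("cannot fit a plane to (near-)collinear points")
    normal = _apply_sign_convention(axes)[2]
    return PlaneFit(
        normal=normal,
        centroid_mm=centroid,
        rms_residual_mm=float(np.sqrt(eigvals[2])),
    )


def angle_between_vectors(u: np.ndarray, v: np.ndarray, *, fold: bool = False) -> float:
    """Angle between two 3-vectors in degrees.

    theta = arccos(u . v / (|u| |v|)) in [0, 180].  With ``fold=True`` the
    result is min(theta, 180 - theta) in [0, 90], appropriate when either
    vector is an undirected axis (e.g. a plane normal), whose sign is
    arbitrary.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle undefined for zero vector")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(c)))
    if fold:
        theta = min(theta, 180.0 - theta)
    return theta


def angle_between_planes(p: PlaneFit, q: PlaneFit) -> float:
    """Dihedral angle between two fitted planes, folded to [0, 90] degrees."""
    return angle_between_vectors(p.normal, q.normal, fold=True)
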