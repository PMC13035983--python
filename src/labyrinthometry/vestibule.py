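"""Vestibular measurement: ellipsoid fit, principal diameters, section areas
and vestibular-plane-to-canal angles.

The vestibule is approximated by a least-squares ellipsoid.  Points are
first rotated into their PCA frame (making the structure approximately
axis-aligned), surface-representative samples are selected, and the
linearized canonical form

    A' x^2 + B' y^2 + C' z^2 = 1        (A' = 1/a^2, ...)

is solved by ordinary least squares.  Semi-axes are a_i = 1/sqrt(coeff_i);
the reported principal *diameters* A >= B >= C are the full axes 2 a_i.  A
general 9-parameter quadric mode (cross terms and linear terms) is
available for sensitivity analysis.

The three central cross-section planes are named by the diameter pair that
spans them (AB, AC, BC); the normal of plane AB is the C-axis direction, and
the plane-to-canal angles are folded angles between that normal and each
canal-plane normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PlaneFit, angle_between_vectors, pca_frame
from .volume_io import VoxelCloud, voxel_volume

__all__ = [
    "EllipsoidFit",
    "VestibularMetrics",
    "fit_ellipsoid",
    "section_areas",
    "vestibular_plane_angles",
    "measure_vestibule",
]

PLANE_NORMAL_AXIS = {"AB": 2, "AC": 1, "BC": 0}  # plane name -> normal axis index


@dataclass(frozen=True)
class EllipsoidFit:
    """Least-squares ellipsoid: center, sorted principal diameters and the
    world directions paired with them."""

    center_mm: np.ndarray
    diameters_mm: tuple[float, float, float]  # A >= B >= C
    axis_dirs: np.ndarray  # rows paired with (A, B, C)
    coeffs: tuple[float, float, float]  # (A', B', C') of the linearized form
    rms_algebraic_residual: float


@dataclass(frozen=True)
class VestibularMetrics:
    volume_mm3: float
    length_a_mm: float
    length_b_mm: float
    length_c_mm: float
    area_ab_mm2: float
    area_ac_mm2: float
    area_bc_mm2: float
    angles_deg: dict[str, dict[str, float]]  # plane -> canal -> degrees


def _lattice_axes(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Recover the (possibly world-rotated) voxel-lattice axes of a cloud.

    Face-neighbor pairs sit at distance exactly one spacing along a lattice
    axis, whatever the cloud's rigid pose; the three distinct displacement
    directions among such pairs are the lattice axes.
    """
    from scipy.spatial import cKDTree

    sub = pts[:: max(1, len(pts) // 4000)]
    tree = cKDTree(sub)
    pairs = tree.query_pairs(r=1.01 * spacing, output_type="ndarray")
    if len(pairs) < 3:
        return np.eye(3)
    d = sub[pairs[:, 1]] - sub[pairs[:, 0]]
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    axes: list[np.ndarray] = []
    for v in d:
        if all(abs(v @ a) < 0.5 for a in axes):
            axes.append(v)
        if len(axes) == 3:
            break
    while len(axes) < 3:
        # degenerate slab: complete the basis
        cand = np.eye(3)[np.argmin([max(abs(c @ a) for a in axes) for c in np.eye(3)])]
        axes.append(cand - sum((cand @ a) * a for a in axes))
        axes[-1] /= np.linalg.norm(axes[-1])
    u, _, vt = np.linalg.svd(np.array(axes))
    return u @ vt  # nearest orthonormal frame, rows = lattice axes


def _surface_samples(cloud: VoxelCloud, mode: str) -> np.ndarray:
    """Surface-representative points from a solid voxel cloud.

    ``"face_midpoints"`` places one sample on the midpoint of every voxel
    face whose 6-neighbor is outside the structure; these midpoints straddle
    the true surface symmetrically, so the half-voxel inward bias of raw
    boundary-voxel centers cancels to first order.  ``"surface_centers"``
    returns the centers of boundary voxels (biased ~ half a voxel inward);
    ``"solid"`` returns all voxel centers.  The voxel lattice may be rigidly
    posed in world space; its axes are recovered from the data.
    """
    pts = cloud.points_mm
    if mode == "solid":
        return pts
    if mode not in ("face_midpoints", "surface_centers"):
        raise ValueError(f"unknown surface-sampling mode {mode!r}")
    spacing = float(cloud.spacing_mm[0])
    A = _lattice_axes(pts, spacing)  # rows = lattice axes in world coords
    lattice = (pts - pts[0]) @ A.T / spacing
    idx = np.rint(lattice).astype(np.int64)
    idx -= idx.min(axis=0)
    shape = idx.max(axis=0) + 3
    occ = np.zeros(tuple(shape), dtype=bool)
    idx1 = idx + 1  # pad so every neighbor lookup is in-bounds
    occ[tuple(idx1.T)] = True
    samples = []
    centers_mask = np.zeros(len(pts), dtype=bool)
    for axis in range(3):
        for sign in (-1, 1):
            nb = idx1.copy()
            nb[:, axis] += sign
            exposed = ~occ[tuple(nb.T)]
            centers_mask |= exposed
            if mode == "face_midpoints":
                face = pts[exposed] + sign * 0.5 * spacing * A[axis]
                samples.append(face)
    if mode == "face_midpoints":
        return np.vstack(samples)
    return pts[centers_mask]


def _fit_axis_aligned(local: np.ndarray) -> tuple[np.ndarray, float]:
    design = local**2
    rhs = np.ones(local.shape[0])
    coef, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    resid = design @ coef - rhs
    return coef, float(np.sqrt(np.mean(resid**2)))


def _fit_general_quadric(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """9-parameter quadric fit; returns (center, semi_axes, axes_rows, rms)."""
    x, y, z = pts.T
    design = np.column_stack(
        [x * x, y * y, z * z, x * y, x * z, y * z, x, y, z]
    )
    rhs = np.ones(len(pts))
    th, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    A = np.array(
        [
            [th[0], th[3] / 2, th[4] / 2],
            [th[3] / 2, th[1], th[5] / 2],
            [th[4] / 2, th[5] / 2, th[2]],
        ]
    )
    b = th[6:9]
    center = -0.5 * np.linalg.solve(A, b)
    scale = 1.0 + center @ A @ center + b @ center
    eigval, eigvec = np.linalg.eigh(A / scale)
    if np.any(eigval <= 0):
        raise ValueError("non-ellipsoidal fit: quadric has non-positive eigenvalue")
    semi = 1.0 / np.sqrt(eigval)
    resid = design @ th - rhs
    return center, semi, eigvec.T, float(np.sqrt(np.mean(resid**2)))


def fit_ellipsoid(
    cloud: VoxelCloud | np.ndarray,
    *,
    sample: str = "face_midpoints",
    model: str = "axis_aligned",
) -> EllipsoidFit:
    """Fit an ellipsoid to a vestibular voxel cloud (or raw surface points).

    When given a :class:`VoxelCloud` of a *solid* structure, surface samples
    are selected according to ``sample`` (fitting all solid voxels biases the
    semi-axes low).  A raw (N, 3) array is taken to already contain surface
    points.  ``model="axis_aligned"`` fits the 3-coefficient linearized form
    in the PCA frame; ``model="general"`` fits a full quadric with cross and
    linear terms.
    """
    if isinstance(cloud, VoxelCloud):
        pts = _surface_samples(cloud, sample)
    else:
        pts = np.asarray(cloud, dtype=float)
    if pts.shape[0] < 10:
        raise ValueError("ellipsoid fit requires at least 10 points")

    if model == "general":
        center, semi, axes, rms = _fit_general_quadric(pts)
        order = np.argsort(semi)[::-1]
        semi, axes = semi[order], axes[order]
        coeffs = tuple(1.0 / semi**2)
    elif model == "axis_aligned":
        frame = pca_frame(pts)
        local = frame.to_local(pts)
        coef, rms = _fit_axis_aligned(local)
        if np.any(coef <= 0):
            raise ValueError(
                "non-ellipsoidal fit: a solved coefficient is non-positive"
            )
        semi = 1.0 / np.sqrt(coef)
        order = np.argsort(semi)[::-1]
        semi = semi[order]
        axes = frame.axes[order]
        coeffs = tuple(coef[order])
        center = frame.centroid_mm
    else:
        raise ValueError(f"unknown ellipsoid model {model!r}")

    return EllipsoidFit(
        center_mm=np.asarray(center, dtype=float),
        diameters_mm=tuple(2.0 * semi),
        axis_dirs=np.asarray(axes, dtype=float),
        coeffs=tuple(float(c) for c in coeffs),
        rms_algebraic_residual=rms,
    )


def section_areas(fit: EllipsoidFit) -> tuple[float, float, float]:
    """Areas of the three central cross-sections (AB, AC, BC) in mm^2.

    The central section spanned by diameters d1, d2 is an ellipse of area
    pi * (d1/2) * (d2/2) = (pi/4) d1 d2.
    """
    a, b, c = fit.diameters_mm
    return (np.pi / 4 * a * b, np.pi / 4 * a * c, np.pi / 4 * b * c)


def vestibular_plane_angles(
    fit: EllipsoidFit, canal_fits: dict[str, PlaneFit]
) -> dict[str, dict[str, float]]:
    """Folded angles between each central ellipsoid plane and each canal plane.

    Plane AB is spanned by the A and B diameters, so its normal is the C-axis
    direction (AC <-> B axis, BC <-> A axis).
    """
    out: dict[str, dict[str, float]] = {}
    for plane, axis_idx in PLANE_NORMAL_AXIS.items():
        normal = fit.axis_dirs[axis_idx]
        out[plane] = {
            canal: angle_between_vectors(normal, cfit.normal, fold=True)
            for canal, cfit in canal_fits.items()
        }
    return out


def measure_vestibule(
    cloud: VoxelCloud,
    canal_fits: dict[str, PlaneFit],
    *,
    sample: str = "face_midpoints",
    model: str = "axis_aligned",
) -> VestibularMetrics:
    """Full vestibular measurement.

    The volume comes from the voxel count alone (it is independent of the
    ellipsoid fit); lengths, areas and angles come from the fit.
    """
    fit = fit_ellipsoid(cloud, sample=sample, model=model)
    areas = section_areas(fit)
    return VestibularMetrics(
        volume_mm3=voxel_volume(cloud),
        length_a_mm=fit.diameters_mm[0],
        length_b_mm=fit.diameters_mm[1],
        length_c_mm=fit.diameters_mm[2],
        area_ab_mm2=areas[0],
        area_ac_mm2=areas[1],
        area_bc_mm2=areas[2],
        angles_deg=vestibular_plane_angles(fit, canal_fits),
    )
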