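"""Cochlear measurement chain.

The cochlea's spiral shape has no natural axis-aligned bounding directions,
so measurement starts with *spatial calibration*: PCA of the voxel
coordinates puts the spiral in the plane of the first two principal axes,
with the third (least-variance) axis serving as the modiolar axis.  In the
calibrated planar coordinates the chain is:

1. round window  = point with the largest x-coordinate;
2. BLD           = largest distance from the round window to any point
                   (the basal long diameter);
3. BSD           = after rotating so the round-window -> far-point line is
                   the +x axis, the largest y-extent within any narrow
                   x-bin (the basal short diameter);
4. CH            = axial extent of the calibrated Z coordinate;
5. CDL / 2TL / BTL = affine regressions on BLD;
6. modiolus-canal angles = folded angles between the modiolar axis and the
   canal plane normals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PcaFrame, PlaneFit, angle_between_vectors, pca_frame
from .volume_io import VoxelCloud, voxel_volume

__all__ = [
    "CalibratedCochlea",
    "CochlearMetrics",
    "calibrate",
    "round_window_center",
    "basal_long_diameter",
    "basal_short_diameter",
    "cochlear_height",
    "derived_lengths",
    "modiolus_canal_angles",
    "measure_cochlea",
]


@dataclass(frozen=True)
class CalibratedCochlea:
    """Cochlear voxel cloud in its PCA ("cochlear") coordinate system.

    ``coords3`` are the centered points expressed in the PCA axes with Z the
    least-variance direction, so the duct spirals about Z; ``coords2`` is the
    projection onto the first two axes.  ``modiolar_axis`` is the third PCA
    axis mapped back to world coordinates.
    """

    coords2: np.ndarray
    coords3: np.ndarray
    frame: PcaFrame
    modiolar_axis: np.ndarray


@dataclass(frozen=True)
class CochlearMetrics:
    volume_mm3: float
    bld_mm: float
    bsd_mm: float
    ch_mm: float
    cdl_mm: float
    tl2_mm: float
    btl_mm: float
    round_window_mm: tuple[float, float]
    basal_far_point_mm: tuple[float, float]
    angle_modiolus_lsc_deg: float
    angle_modiolus_psc_deg: float
    angle_modiolus_ssc_deg: float


def calibrate(
    cloud: VoxelCloud | np.ndarray, *, basal_plus_x: bool = False
) -> CalibratedCochlea:
    """Spatially calibrate a cochlear voxel cloud via PCA.

    With ``basal_plus_x`` the sign of the first axis is chosen so that the
    farther in-plane extreme lies on +x (putting the wide basal side, hence
    the round window, at positive x regardless of the default
    largest-component-positive sign rule).  The second axis is re-derived to
    keep the frame right-handed.
    """
    points = cloud.points_mm if isinstance(cloud, VoxelCloud) else np.asarray(cloud)
    if points.shape[0] < 100:
        raise ValueError("cochlear calibration requires at least 100 voxels")
    frame = pca_frame(points)
    if basal_plus_x:
        local = frame.to_local(points)
        if np.max(local[:, 0]) < -np.min(local[:, 0]):
            axes = frame.axes.copy()
            axes[0] = -axes[0]
            axes[1] = np.cross(axes[2], axes[0])
            frame = PcaFrame(
                centroid_mm=frame.centroid_mm,
                axes=axes,
                eigenvalues=frame.eigenvalues,
            )
    coords3 = frame.to_local(points)
    return CalibratedCochlea(
        coords2=coords3[:, :2],
        coords3=coords3,
        frame=frame,
        modiolar_axis=frame.axes[2].copy(),
    )


def round_window_center(coords2: np.ndarray) -> np.ndarray:
    """Point with the largest x-coordinate; ties broken by largest y."""
    coords2 = np.asarray(coords2, dtype=float)
    xmax = coords2[:, 0].max()
    cand = coords2[coords2[:, 0] == xmax]
    return cand[np.argmax(cand[:, 1])].copy()


def basal_long_diameter(
    coords2: np.ndarray, rw: np.ndarray
) -> tuple[float, np.ndarray]:
    """Largest planar distance from the round-window point.

    Returns ``(BLD, far_point)``; on exact distance ties the first point
    encountered (row order) is returned.
    """
    coords2 = np.asarray(coords2, dtype=float)
    d = np.linalg.norm(coords2 - np.asarray(rw, dtype=float), axis=1)
    i = int(np.argmax(d))
    return float(d[i]), coords2[i].copy()


def basal_short_diameter(
    coords2: np.ndarray,
    rw: np.ndarray,
    far: np.ndarray,
    bin_width_mm: float = 0.1,
) -> float:
    """Largest y-extent perpendicular to the round-window -> far-point line.

    The planar coordinates are rotated so that line lies along +x, then x is
    binned at ``bin_width_mm`` (continuous coordinates almost never share an
    exact x value) and the maximum of (max y - min y) over bins containing at
    least two points is returned.
    """
    rw = np.asarray(rw, dtype=float)
    far = np.asarray(far, dtype=float)
    axis = far - rw
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("round-window and far point coincide")
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    c, s = axis / norm
    rot = np.array([[c, s], [-s, c]])
    local = (np.asarray(coords2, dtype=float) - rw) @ rot.T
    bins = np.floor(local[:, 0] / bin_width_mm).astype(np.int64)
    order = np.argsort(bins, kind="stable")
    bins_sorted = bins[order]
    y_sorted = local[order, 1]
    boundaries = np.flatnonzero(np.diff(bins_sorted)) + 1
    best = -np.inf
    for lo, hi in zip(
        np.concatenate([[0], boundaries]),
        np.concatenate([boundaries, [len(bins_sorted)]]),
    ):
        if hi - lo >= 2:
            seg = y_sorted[lo:hi]
            best = max(best, float(seg.max() - seg.min()))
    if not np.isfinite(best):
        raise ValueError("no x-bin contains two or more points; widen the bin")
    return best


def cochlear_height(coords3: np.ndarray, *, mode: str = "extent") -> float:
    """Cochlear height along the calibrated Z (modiolar) axis.

    ``mode="extent"`` (default) returns max(Z) - min(Z), the full axial
    extent.  ``mode="absolute"`` returns max|Z| - min|Z|; with centered PCA
    coordinates this is roughly half the axial extent and is retained only
    for fidelity experiments.
    """
    z = np.asarray(coords3, dtype=float)[:, 2]
    if mode == "extent":
        return float(z.max() - z.min())
    if mode == "absolute":
        az = np.abs(z)
        return float(az.max() - az.min())
    raise ValueError(f"unknown cochlear-height mode {mode!r}")


#: Affine regression coefficients (slope, intercept-style constant) mapping
#: the basal long diameter to duct lengths.
CDL_SLOPE, CDL_OFFSET = 4.16, -4.0
TL2_SLOPE = 3.65
BTL_SLOPE = 2.43


def derived_lengths(
    bld_mm: float, *, literal_sign: bool = False
) -> tuple[float, float, float]:
    """Regression-derived duct lengths (CDL, 2TL, BTL) from the BLD.

        CDL = 4.16 * BLD - 4
        2TL = 3.65 * (BLD - 1)
        BTL = 2.43 * (BLD - 1)

    The CDL regression is sometimes quoted with a negated slope
    (-4.16 * BLD - 4), which yields negative lengths for any positive BLD and
    is inconsistent with published cochlear duct lengths of ~33 mm at
    BLD ~ 9 mm; requesting that literal form raises instead of silently
    returning a negative length.
    """
    if literal_sign:
        raise ValueError(
            "literal CDL form -4.16*BLD - 4 produces negative lengths for any "
            "positive BLD; use the sign-corrected default"
        )
    if bld_mm <= 1.0:
        raise ValueError("derived lengths require BLD > 1 mm")
    cdl = CDL_SLOPE * bld_mm + CDL_OFFSET
    tl2 = TL2_SLOPE * (bld_mm - 1.0)
    btl = BTL_SLOPE * (bld_mm - 1.0)
    return cdl, tl2, btl


def modiolus_canal_angles(
    axis: np.ndarray, canal_fits: dict[str, PlaneFit]
) -> dict[str, float]:
    """Folded angles (degrees, [0, 90]) between the modiolar axis and each
    canal-plane normal."""
    return {
        name: angle_between_vectors(axis, fit.normal, fold=True)
        for name, fit in canal_fits.items()
    }


def measure_cochlea(
    cloud: VoxelCloud,
    canal_fits: dict[str, PlaneFit],
    *,
    bin_width_mm: float | None = None,
    ch_mode: str = "extent",
    basal_plus_x: bool = False,
) -> CochlearMetrics:
    """Run the full cochlear measurement chain on one voxel cloud."""
    cal = calibrate(cloud, basal_plus_x=basal_plus_x)
    rw = round_window_center(cal.coords2)
    bld, far = basal_long_diameter(cal.coords2, rw)
    if bin_width_mm is None:
        bin_width_mm = float(cloud.spacing_mm[0])
    bsd = basal_short_diameter(cal.coords2, rw, far, bin_width_mm)
    ch = cochlear_height(cal.coords3, mode=ch_mode)
    cdl, tl2, btl = derived_lengths(bld)
    angles = modiolus_canal_angles(cal.modiolar_axis, canal_fits)
    return CochlearMetrics(
        volume_mm3=voxel_volume(cloud),
        bld_mm=bld,
        bsd_mm=bsd,
        ch_mm=ch,
        cdl_mm=cdl,
        tl2_mm=tl2,
        btl_mm=btl,
        round_window_mm=(float(rw[0]), float(rw[1])),
        basal_far_point_mm=(float(far[0]), float(far[1])),
        angle_modiolus_lsc_deg=angles["LSC"],
        angle_modiolus_psc_deg=angles["PSC"],
        angle_modiolus_ssc_deg=angles["SSC"],
    )
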