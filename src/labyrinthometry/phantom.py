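"""Synthetic labyrinth phantoms with analytically known geometry.

Voxelized stand-ins for segmented inner-ear label volumes, built from three
primitive shapes:

* **cochlea** — a conical helical tube: an elliptical spiral centerline
  (constant radius over the basal turn, then tapering toward the apex) swept
  by a circular tube whose radius also tapers.  It is not anatomically exact;
  it is designed to have a well-defined basal long/short diameter, axial
  height, and modiolar (spiral) axis, which is what the measurement chain
  consumes.
* **vestibule** — a solid ellipsoid with optional smooth radial surface
  perturbation.
* **semicircular canals** — partial tori lying exactly in configurable
  planes.

Every generated structure records its ground truth (volumes, axes, plane
normals, diameters) in *world* coordinates, i.e. after the whole-assembly
rigid pose has been applied, so recovery by the measurement modules can be
checked against construction.

Overlaps in the assembled label volume are resolved by the fixed priority
cochlea > vestibule > PSC > LSC > SSC (the default geometry is disjoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .volume_io import DEFAULT_LABEL_MAP, LabelVolume, write_label_volume

__all__ = [
    "Pose",
    "CochleaSpec",
    "VestibuleSpec",
    "CanalSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_cochlea_mask",
    "make_vestibule_mask",
    "make_canal_mask",
    "assemble_labyrinth",
]

CANAL_NAMES = ("PSC", "LSC", "SSC")


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z to ``axis`` (minimal rotation)."""
    axis = _unit(axis)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    rotvec = np.cross(z, axis)
    rotvec = rotvec / np.linalg.norm(rotvec) * np.arccos(np.clip(c, -1, 1))
    return Rotation.from_rotvec(rotvec).as_matrix()


def _orthonormal_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane basis (e1, e2) for a plane with unit ``normal``."""
    n = _unit(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(helper, n))
    e2 = np.cross(n, e1)
    return e1, e2


@dataclass(frozen=True)
class Pose:
    """Rigid transform: rotation (rotation-vector, radians) then translation."""

    rotvec: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(np.asarray(self.rotvec, dtype=float)).as_matrix()

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + np.asarray(self.translation_mm, dtype=float)

    def apply_direction(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.matrix.T

    def invert_points(self, points: np.ndarray) -> np.ndarray:
        return (points - np.asarray(self.translation_mm, dtype=float)) @ self.matrix


@dataclass(frozen=True)
class CochleaSpec:
    """Conical-helix cochlear tube.

    ``basal_long_diameter_mm`` / ``basal_short_diameter_mm`` are the full
    outer diameters of the basal turn (centerline ellipse plus tube); the
    spiral radius is constant over the first full turn so the basal chord is
    exact by construction.  ``height_mm`` is the total axial extent of the
    tube along the modiolar axis, including the tube thickness at both ends.
    """

    basal_long_diameter_mm: float = 9.0
    basal_short_diameter_mm: float = 6.5
    height_mm: float = 4.0
    n_turns: float = 2.5
    tube_radius_base_mm: float = 0.92
    tube_radius_apex_mm: float = 0.55
    apex_spiral_radius_mm: float = 0.6
    modiolar_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class VestibuleSpec:
    """Solid ellipsoid vestibule.

    Default semi-axes give principal diameters 6.14 / 4.59 / 2.19 mm, the
    scale of adult vestibular measurements; the analytic volume is then
    (4/3)*pi*a*b*c ~= 32.3 mm^3.  (A real vestibule is not ellipsoidal, so
    its voxel volume, ~54 mm^3, exceeds the volume of its best-fit
    ellipsoid; the pure-ellipsoid phantom cannot show both numbers at once.)
    """

    semi_axes_mm: tuple[float, float, float] = (3.07, 2.295, 1.095)
    center_mm: tuple[float, float, float] = (8.0, 0.0, 2.0)
    orientation_rotvec: tuple[float, float, float] = (0.0, 0.0, 0.0)
    surface_noise_mm: float = 0.0


@dataclass(frozen=True)
class CanalSpec:
    """Partial torus lying exactly in the plane with the given unit normal."""

    plane_normal: tuple[float, float, float]
    center_mm: tuple[float, float, float]
    torus_major_radius_mm: float = 2.8
    torus_minor_radius_mm: float = 0.6
    arc_fraction: float = 0.75


def _default_canals() -> dict[str, CanalSpec]:
    # Plane normals chosen so the angles between the (default, +z) modiolar
    # axis and the canal normals land at roughly the adult values:
    # LSC ~58 deg, PSC ~74 deg, SSC ~41.5 deg.
    d = {
        "LSC": CanalSpec(
            plane_normal=(np.sin(np.radians(58.0)), 0.0, np.cos(np.radians(58.0))),
            center_mm=(8.5, 0.0, 8.5),
        ),
        "PSC": CanalSpec(
            plane_normal=(
                0.0,
                np.sin(np.radians(74.0)),
                np.cos(np.radians(74.0)),
            ),
            center_mm=(12.0, 6.0, 2.0),
        ),
        "SSC": CanalSpec(
            plane_normal=(
                np.sin(np.radians(41.5)) * np.cos(np.radians(225.0)),
                np.sin(np.radians(41.5)) * np.sin(np.radians(225.0)),
                np.cos(np.radians(41.5)),
            ),
            center_mm=(8.5, -6.0, 4.0),
        ),
    }
    return {k: replace(v, plane_normal=tuple(_unit(v.plane_normal))) for k, v in d.items()}


@dataclass(frozen=True)
class PhantomSpec:
    """Complete synthetic labyrinth: five substructures plus a rigid pose."""

    voxel_spacing_mm: float = 0.1
    cochlea: CochleaSpec = field(default_factory=CochleaSpec)
    vestibule: VestibuleSpec = field(default_factory=VestibuleSpec)
    canals: dict[str, CanalSpec] = field(default_factory=_default_canals)
    rigid_pose: Pose = field(default_factory=Pose)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        if set(self.canals) != set(CANAL_NAMES):
            raise ValueError(f"canals must be exactly {CANAL_NAMES}")


@dataclass
class GroundTruth:
    """Construction-time truth, in world coordinates (pose applied)."""

    volumes_mm3: dict[str, float] = field(default_factory=dict)
    modiolar_axis: np.ndarray | None = None
    canal_normals: dict[str, np.ndarray] = field(default_factory=dict)
    vestibular_semi_axes_mm: np.ndarray | None = None
    vestibular_axes: np.ndarray | None = None
    vestibular_center_mm: np.ndarray | None = None
    cochlear_height_mm: float | None = None
    basal_long_diameter_mm: float | None = None
    basal_short_diameter_mm: float | None = None
    round_window_mm: np.ndarray | None = None

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(**{**self.__dict__})
        out.volumes_mm3 = {**self.volumes_mm3, **other.volumes_mm3}
        out.canal_normals = {**self.canal_normals, **other.canal_normals}
        for name in (
            "modiolar_axis",
            "vestibular_semi_axes_mm",
            "vestibular_axes",
            "vestibular_center_mm",
            "cochlear_height_mm",
            "basal_long_diameter_mm",
            "basal_short_diameter_mm",
            "round_window_mm",
        ):
            v = getattr(other, name)
            if v is not None:
                setattr(out, name, v)
        return out


# ---------------------------------------------------------------------------
# Cochlea


def _raw_centerline(
    spec: CochleaSpec, alpha: float, kappa: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Centerline samples and tube radii in the cochlea's canonical frame.

    Canonical frame: modiolar axis = +z, basal turn starting on +x at z near
    the bottom.  ``alpha`` sets the turn inclination (axial wobble
    ``alpha * slope * sin(phi)``), ``kappa`` a small in-plane radial
    modulation ``1 + kappa * sin(2 phi)``; both modulations vanish at the
    basal-diameter extremes (phi multiples of pi/2), so the constructed
    basal long/short diameters are unaffected.
    """
    if spec.n_turns <= 0:
        raise ValueError("n_turns must be positive")
    rt0, rt1 = spec.tube_radius_base_mm, spec.tube_radius_apex_mm
    if min(rt0, rt1) <= 0:
        raise ValueError("tube radii must be positive")
    a0 = spec.basal_long_diameter_mm / 2.0 - rt0
    b0 = spec.basal_short_diameter_mm / 2.0 - rt0
    if a0 <= 0 or b0 <= 0 or b0 > a0:
        raise ValueError("basal diameters incompatible with tube radius")
    phi_total = 2.0 * np.pi * spec.n_turns
    phi = np.linspace(0.0, phi_total, n_samples)
    # Taper starts after the first full turn (or immediately if < 1 turn).
    phi_taper0 = min(2.0 * np.pi, phi_total)
    denom = max(phi_total - phi_taper0, 1e-12)
    s = np.clip((phi - phi_taper0) / denom, 0.0, 1.0)
    a = a0 + (spec.apex_spiral_radius_mm - a0) * s
    b = a * (b0 / a0)
    rt = rt0 + (rt1 - rt0) * s
    z0 = rt0
    z1 = spec.height_mm - rt1
    if z1 <= z0:
        raise ValueError("height too small for the tube radii")
    slope = (z1 - z0) / phi_total
    z = z0 + slope * phi + alpha * slope * np.sin(phi)
    # Rescale affinely so the tube's axial extent is exactly [0, height].
    lo = np.min(z - rt)
    hi = np.max(z + rt)
    z = (z - lo) * (spec.height_mm / (hi - lo))
    radial = 1.0 + kappa * np.sin(2.0 * phi)
    pts = np.column_stack([a * radial * np.cos(phi), b * radial * np.sin(phi), z])
    return pts, rt


def _tube_cross_covariance(
    spec: CochleaSpec, alpha: float, kappa: float, probe_spacing: float = 0.2
) -> np.ndarray:
    """(cov_yz, cov_xy) of the swept tube, from a coarse voxelization."""
    pts, rt = _raw_centerline(spec, alpha, kappa, 2000)
    lo = pts.min(axis=0) - rt.max()
    hi = pts.max(axis=0) + rt.max()
    axes = [np.arange(lo[d], hi[d] + probe_spacing, probe_spacing) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    probes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    dist, idx = cKDTree(pts).query(probes, k=1)
    inside = probes[dist <= rt[np.minimum(idx, len(rt) - 1)]]
    centered = inside - inside.mean(axis=0)
    cov = centered.T @ centered / len(inside)
    return np.array([cov[1, 2], cov[0, 1]])


def _solve_decorrelation(spec: CochleaSpec) -> tuple[float, float]:
    """Choose the turn inclination and in-plane modulation so the tube's
    yz and xy covariance components vanish.

    A conical helix with a monotone axial advance has nonzero cov(y, z) and
    cov(x, y) second moments, which would rotate its principal axes away
    from the construction frame; a few Newton steps on the (alpha, kappa)
    amplitudes remove both, keeping the least-variance axis of the voxelized
    tube aligned with the constructed modiolar axis.
    """
    params = np.zeros(2)
    for _ in range(3):
        f0 = _tube_cross_covariance(spec, params[0], params[1])
        if np.all(np.abs(f0) < 1e-4):
            break
        jac = np.zeros((2, 2))
        h = 0.02
        for j in range(2):
            step = np.zeros(2)
            step[j] = h
            fj = _tube_cross_covariance(spec, *(params + step))
            jac[:, j] = (fj - f0) / h
        params = params - np.linalg.solve(jac, f0)
    return float(params[0]), float(params[1])


_DECORRELATION_CACHE: dict[CochleaSpec, tuple[float, float]] = {}


def _cochlea_centerline(spec: CochleaSpec, n_samples: int = 4000):
    """Decorrelated centerline samples and tube radii (canonical frame)."""
    if spec not in _DECORRELATION_CACHE:
        _raw_centerline(spec, 0.0, 0.0, 8)  # validate parameters first
        _DECORRELATION_CACHE[spec] = _solve_decorrelation(spec)
    alpha, kappa = _DECORRELATION_CACHE[spec]
    return _raw_centerline(spec, alpha, kappa, n_samples)


def _cochlea_truth(spec: CochleaSpec, pose: Pose) -> GroundTruth:
    pts, rt = _cochlea_centerline(spec)
    # Tube volume by first-order sweep formula (exact when the tube radius is
    # below the centerline curvature radius; near the apex this slightly
    # overcounts, so the value is approximate at the few-percent level).
    ds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    r_mid = 0.5 * (rt[:-1] + rt[1:])
    vol = float(np.sum(np.pi * r_mid**2 * ds))
    R = _rotation_from_z(spec.modiolar_axis)
    center = np.asarray(spec.center_mm, dtype=float)
    axis_world = pose.apply_direction(R @ np.array([0.0, 0.0, 1.0]))
    # Outer surface point at the basal end of the tube (round-window stand-in).
    rw_canonical = np.array(
        [spec.basal_long_diameter_mm / 2.0, 0.0, spec.tube_radius_base_mm]
    )
    rw_world = pose.apply_points((R @ rw_canonical) + center)
    return GroundTruth(
        volumes_mm3={"cochlea": vol},
        modiolar_axis=axis_world,
        cochlear_height_mm=spec.height_mm,
        basal_long_diameter_mm=spec.basal_long_diameter_mm,
        basal_short_diameter_mm=spec.basal_short_diameter_mm,
        round_window_mm=rw_world,
    )


class _CochleaShape:
    """Membership test for the swept cochlear tube, in world coordinates."""

    def __init__(self, spec: CochleaSpec, pose: Pose):
        self.spec = spec
        self.pose = pose
        self.R = _rotation_from_z(spec.modiolar_axis)
        self.center = np.asarray(spec.center_mm, dtype=float)
        pts, rt = _cochlea_centerline(spec)
        self._tree = cKDTree(pts)
        self._radii = rt
        self._rmax = float(np.max(rt))

    def bounds_world(self) -> np.ndarray:
        s = self.spec
        a_out = s.basal_long_diameter_mm / 2.0
        b_out = s.basal_short_diameter_mm / 2.0
        corners = np.array(
            [
                [sx * a_out, sy * b_out, z]
                for sx in (-1, 1)
                for sy in (-1, 1)
                for z in (0.0, s.height_mm)
            ]
        )
        world = self.pose.apply_points(corners @ self.R.T + self.center)
        return np.vstack([world.min(axis=0), world.max(axis=0)])

    def contains(self, points_world: np.ndarray) -> np.ndarray:
        local = (self.pose.invert_points(points_world) - self.center) @ self.R
        dist, idx = self._tree.query(local, k=1, distance_upper_bound=self._rmax + 0.05)
        inside = np.zeros(points_world.shape[0], dtype=bool)
        ok = np.isfinite(dist)
        inside[ok] = dist[ok] <= self._radii[np.minimum(idx[ok], len(self._radii) - 1)]
        return inside


# ---------------------------------------------------------------------------
# Vestibule

# Fixed low-order smooth directional basis used for the optional surface
# perturbation (quadratic spherical harmonics without normalization).
def _noise_basis(u: np.ndarray) -> np.ndarray:
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    return np.column_stack(
        [x, y, z, x * y, x * z, y * z, x * x - y * y, 3 * z * z - 1.0]
    )


class _VestibuleShape:
    def __init__(self, spec: VestibuleSpec, pose: Pose, seed: int):
        axes = np.asarray(spec.semi_axes_mm, dtype=float)
        if np.any(axes <= 0):
            raise ValueError("vestibular semi-axes must be positive")
        if not (axes[0] >= axes[1] >= axes[2]):
            warnings.warn(
                "vestibular semi-axes not sorted descending; normalizing",
                stacklevel=3,
            )
            axes = np.sort(axes)[::-1]
        self.semi_axes = axes
        self.spec = spec
        self.pose = pose
        self.Rv = Rotation.from_rotvec(
            np.asarray(spec.orientation_rotvec, dtype=float)
        ).as_matrix()
        self.center = np.asarray(spec.center_mm, dtype=float)
        rng = np.random.default_rng(seed)
        coef = rng.standard_normal(8)
        if spec.surface_noise_mm > 0:
            # Normalize the random field to unit RMS over sampled directions.
            probe = rng.standard_normal((2048, 3))
            probe /= np.linalg.norm(probe, axis=1, keepdims=True)
            vals = _noise_basis(probe) @ coef
            coef = coef / max(np.std(vals), 1e-12)
        self._coef = coef

    def bounds_world(self) -> np.ndarray:
        pad = self.semi_axes[0] + self.spec.surface_noise_mm * 3.0
        corners = np.array(
            [[sx * pad, sy * pad, sz * pad] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        world = self.pose.apply_points(corners + self.center)
        return np.vstack([world.min(axis=0), world.max(axis=0)])

    def contains(self, points_world: np.ndarray) -> np.ndarray:
        local = (self.pose.invert_points(points_world) - self.center) @ self.Rv
        q = local / self.semi_axes
        m = np.linalg.norm(q, axis=1)
        if self.spec.surface_noise_mm == 0:
            return m <= 1.0
        r = np.linalg.norm(local, axis=1)
        u = np.divide(local, r[:, None], out=np.zeros_like(local), where=r[:, None] > 0)
        f = self.spec.surface_noise_mm * (_noise_basis(u) @ self._coef)
        # Radial surface displacement of f millimetres along each ray.
        ray = np.divide(r, m, out=np.full_like(r, np.inf), where=m > 0)
        return (m - 1.0) * np.where(np.isfinite(ray), ray, 0.0) <= f

    def truth(self) -> GroundTruth:
        a, b, c = self.semi_axes
        axes_world = np.vstack(
            [self.pose.apply_direction(self.Rv[:, i]) for i in range(3)]
        )
        return GroundTruth(
            volumes_mm3={"vestibule": float(4.0 / 3.0 * np.pi * a * b * c)},
            vestibular_semi_axes_mm=self.semi_axes.copy(),
            vestibular_axes=axes_world,
            vestibular_center_mm=self.pose.apply_points(self.center[None, :])[0],
        )


# ---------------------------------------------------------------------------
# Canals


class _CanalShape:
    def __init__(self, spec: CanalSpec, pose: Pose):
        if spec.arc_fraction <= 0 or spec.arc_fraction > 1:
            raise ValueError("arc_fraction must lie in (0, 1]")
        if spec.torus_minor_radius_mm <= 0 or spec.torus_major_radius_mm <= 0:
            raise ValueError("torus radii must be positive")
        self.spec = spec
        self.pose = pose
        self.n = _unit(spec.plane_normal)
        self.e1, self.e2 = _orthonormal_basis(self.n)
        self.center = np.asarray(spec.center_mm, dtype=float)

    def bounds_world(self) -> np.ndarray:
        pad = self.spec.torus_major_radius_mm + self.spec.torus_minor_radius_mm
        corners = np.array(
            [[sx * pad, sy * pad, sz * pad] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        world = self.pose.apply_points(corners + self.center)
        return np.vstack([world.min(axis=0), world.max(axis=0)])

    def contains(self, points_world: np.ndarray) -> np.ndarray:
        q = self.pose.invert_points(points_world) - self.center
        h = q @ self.n
        u = q @ self.e1
        v = q @ self.e2
        r_inplane = np.hypot(u, v)
        d = np.hypot(r_inplane - self.spec.torus_major_radius_mm, h)
        inside = d <= self.spec.torus_minor_radius_mm
        if self.spec.arc_fraction < 1.0:
            psi = np.arctan2(v, u)
            inside &= np.abs(psi) <= np.pi * self.spec.arc_fraction
        return inside

    def truth(self, name: str) -> GroundTruth:
        arc_len = 2.0 * np.pi * self.spec.arc_fraction * self.spec.torus_major_radius_mm
        vol = float(np.pi * self.spec.torus_minor_radius_mm**2 * arc_len)
        return GroundTruth(
            volumes_mm3={name: vol},
            canal_normals={name: self.pose.apply_direction(self.n)},
        )


# ---------------------------------------------------------------------------
# Voxelization


def _make_grid(bounds: np.ndarray, spacing: float, margin: float = 0.25):
    lo = np.floor((bounds[0] - margin) / spacing) * spacing
    hi = bounds[1] + margin
    shape = np.ceil((hi - lo) / spacing).astype(int)
    return lo, shape


def _voxel_centers(origin: np.ndarray, shape: np.ndarray, spacing: float):
    axes = [origin[d] + (np.arange(shape[d]) + 0.5) * spacing for d in range(3)]
    return axes


def _rasterize(shape, origin, spacing, contains) -> np.ndarray:
    """Evaluate a membership predicate over all voxel centers, slab by slab."""
    ax, ay, az = _voxel_centers(origin, shape, spacing)
    mask = np.zeros(tuple(shape), dtype=bool)
    slab = max(1, int(4_000_000 / max(shape[1] * shape[2], 1)))
    for i0 in range(0, shape[0], slab):
        i1 = min(i0 + slab, shape[0])
        X, Y, Z = np.meshgrid(ax[i0:i1], ay, az, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        mask[i0:i1] = contains(pts).reshape(i1 - i0, len(ay), len(az))
    return mask


def _check_resolution(spec: PhantomSpec) -> None:
    s = spec.voxel_spacing_mm
    c = spec.cochlea
    if 2.0 * min(c.tube_radius_base_mm, c.tube_radius_apex_mm) < 2.0 * s:
        raise ValueError(
            "voxel spacing too coarse to resolve the cochlear tube "
            f"(tube diameter {2 * min(c.tube_radius_base_mm, c.tube_radius_apex_mm):.3f} mm "
            f"< 2 voxels at {s} mm)"
        )
    if min(spec.vestibule.semi_axes_mm) < 3.0 * s:
        raise ValueError("vestibular semi-axes must span at least 3 voxels")
    for name, canal in spec.canals.items():
        if canal.torus_minor_radius_mm < 1.5 * s:
            raise ValueError(f"{name}: torus minor radius must span at least 1.5 voxels")


def make_cochlea_mask(spec: PhantomSpec):
    """Voxelize the cochlear tube on its own minimal grid.

    Returns ``(mask, origin_mm, truth)`` where ``mask`` is a boolean array,
    ``origin_mm`` the corner of voxel (0,0,0) in world coordinates, and
    ``truth`` a :class:`GroundTruth` with the constructed height, basal
    diameters, modiolar axis and approximate tube volume.
    """
    _check_resolution(spec)
    shape_obj = _CochleaShape(spec.cochlea, spec.rigid_pose)
    origin, shape = _make_grid(shape_obj.bounds_world(), spec.voxel_spacing_mm)
    mask = _rasterize(shape, origin, spec.voxel_spacing_mm, shape_obj.contains)
    return mask, origin, _cochlea_truth(spec.cochlea, spec.rigid_pose)


def make_vestibule_mask(spec: PhantomSpec):
    """Voxelize the (optionally perturbed) ellipsoidal vestibule."""
    _check_resolution(spec)
    shape_obj = _VestibuleShape(spec.vestibule, spec.rigid_pose, spec.seed)
    origin, shape = _make_grid(shape_obj.bounds_world(), spec.voxel_spacing_mm)
    mask = _rasterize(shape, origin, spec.voxel_spacing_mm, shape_obj.contains)
    return mask, origin, shape_obj.truth()


def make_canal_mask(spec: PhantomSpec, which: str):
    """Voxelize one semicircular canal (partial torus)."""
    if which not in spec.canals:
        raise KeyError(f"unknown canal {which!r}")
    _check_resolution(spec)
    shape_obj = _CanalShape(spec.canals[which], spec.rigid_pose)
    origin, shape = _make_grid(shape_obj.bounds_world(), spec.voxel_spacing_mm)
    mask = _rasterize(shape, origin, spec.voxel_spacing_mm, shape_obj.contains)
    return mask, origin, shape_obj.truth(which)


def assemble_labyrinth(
    spec: PhantomSpec,
    path: str | None = None,
    *,
    origin_mm: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> tuple[LabelVolume, GroundTruth]:
    """Voxelize all five substructures on one grid and label them.

    Overlaps are resolved by the fixed priority cochlea > vestibule >
    PSC > LSC > SSC (higher priority wins).  If ``origin_mm``/``shape`` are
    omitted the grid is sized to contain the posed assembly; if given and a
    structure does not fit, an error names it.  With ``path`` the volume is
    also written as NIfTI (spacing in the header).
    """
    _check_resolution(spec)
    pose = spec.rigid_pose
    shapes: dict[str, object] = {
        "cochlea": _CochleaShape(spec.cochlea, pose),
        "vestibule": _VestibuleShape(spec.vestibule, pose, spec.seed),
    }
    for name in CANAL_NAMES:
        shapes[name] = _CanalShape(spec.canals[name], pose)

    spacing = spec.voxel_spacing_mm
    all_bounds = np.array([s.bounds_world() for s in shapes.values()])
    bounds = np.vstack(
        [all_bounds[:, 0, :].min(axis=0), all_bounds[:, 1, :].max(axis=0)]
    )
    if origin_mm is None or shape is None:
        origin_mm, shape = _make_grid(bounds, spacing)
    else:
        origin_mm = np.asarray(origin_mm, dtype=float)
        shape = np.asarray(shape, dtype=int)
        grid_hi = origin_mm + shape * spacing
        for name, s in shapes.items():
            b = s.bounds_world()
            if np.any(b[0] < origin_mm) or np.any(b[1] > grid_hi):
                raise ValueError(f"grid too small to contain structure {name!r}")

    labels = np.zeros(tuple(shape), dtype=np.int16)
    truth = GroundTruth()
    # Paint lowest priority first so higher priority overwrites.
    priority = ["SSC", "LSC", "PSC", "vestibule", "cochlea"]
    for name in priority:
        s = shapes[name]
        mask = _rasterize(np.asarray(shape), origin_mm, spacing, s.contains)
        labels[mask] = DEFAULT_LABEL_MAP[name]
        if name == "cochlea":
            truth = truth.merge(_cochlea_truth(spec.cochlea, pose))
        elif name == "vestibule":
            truth = truth.merge(s.truth())
        else:
            truth = truth.merge(s.truth(name))

    vol = LabelVolume(
        voxels=labels,
        spacing_mm=np.full(3, spacing),
        origin_mm=origin_mm,
        label_map=dict(DEFAULT_LABEL_MAP),
    )
    missing = [n for n in DEFAULT_LABEL_MAP if vol.count(n) == 0]
    if missing:
        raise ValueError(f"assembly produced empty structures: {missing}")
    if path is not None:
        write_label_volume(vol, path)
    return vol, truth
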