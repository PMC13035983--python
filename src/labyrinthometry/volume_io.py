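"""Labeled-volume I/O and voxel-cloud extraction.

A :class:`LabelVolume` is a 3-D integer grid with isotropic (nominally
0.1 mm) spacing and a name→label map covering the five inner-ear
substructures.  All downstream measurement operates on millimetre
coordinates of voxel *centers*; the convention used throughout the package
is

    world = origin_mm + (index + 1/2) * spacing_mm     (0-based indices)

so ``origin_mm`` is the corner of voxel (0, 0, 0).  NIfTI stores the world
position of the *center* of voxel (0, 0, 0) in its affine, so the two
conventions are interconverted on read/write; the offset lives only here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "DEFAULT_LABEL_MAP",
    "LabelVolume",
    "VoxelCloud",
    "read_label_volume",
    "write_label_volume",
    "extract_voxel_cloud",
    "voxel_volume",
]

#: Canonical substructure labels: cochlea, vestibule and the posterior,
#: lateral and superior semicircular canals.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "cochlea": 1,
    "vestibule": 2,
    "PSC": 3,
    "LSC": 4,
    "SSC": 5,
}


@dataclass
class LabelVolume:
    """3-D labeled voxel grid with physical spacing."""

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must have an integer dtype")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        present = set(np.unique(self.voxels).tolist()) - {0}
        known = set(self.label_map.values())
        stray = sorted(present - known)
        if stray:
            raise ValueError(f"volume contains labels not in the label map: {stray}")

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel (product of spacings)."""
        return float(np.prod(self.spacing_mm))

    def count(self, structure: str) -> int:
        return int(np.count_nonzero(self.voxels == self.label_map[structure]))


@dataclass(frozen=True)
class VoxelCloud:
    """Millimetre coordinates of one substructure's voxel centers."""

    points_mm: np.ndarray
    source_label: str
    spacing_mm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "points_mm", np.asarray(self.points_mm, dtype=float))
        object.__setattr__(
            self, "spacing_mm", np.asarray(self.spacing_mm, dtype=float).reshape(3)
        )
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3:
            raise ValueError("points_mm must be (N, 3)")
        if self.points_mm.shape[0] < 1:
            raise ValueError("a voxel cloud needs at least one point")
        if not np.all(np.isfinite(self.points_mm)):
            raise ValueError("voxel coordinates must be finite")

    def __len__(self) -> int:
        return self.points_mm.shape[0]


def write_label_volume(vol: LabelVolume, path: str) -> None:
    """Write a label volume as NIfTI with spacing and origin in the affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing_mm)
    # NIfTI affine addresses voxel centers; shift by half a voxel.
    affine[:3, 3] = vol.origin_mm + 0.5 * vol.spacing_mm
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, path)


def read_label_volume(path: str, label_map: dict[str, int] | None = None) -> LabelVolume:
    """Read a NIfTI label volume.

    The data must be integer-valued (a float array holding exact integers is
    accepted and cast).  Spacing is taken from the header; anisotropic
    spacing is accepted with a warning.  Labels not present in ``label_map``
    raise an error listing the strays.
    """
    if label_map is None:
        label_map = dict(DEFAULT_LABEL_MAP)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError(f"{path}: voxel data is not integer-valued")
        data = rounded.astype(np.int32)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        warnings.warn(
            f"{path}: anisotropic spacing {tuple(spacing)}; measurements assume "
            "isotropic voxels",
            stacklevel=2,
        )
    center0 = np.asarray(img.affine[:3, 3], dtype=float)
    scales = np.linalg.norm(img.affine[:3, :3], axis=0)
    if not np.allclose(scales, spacing, rtol=1e-4):
        spacing = scales
    origin = center0 - 0.5 * spacing
    return LabelVolume(
        voxels=data, spacing_mm=spacing, origin_mm=origin, label_map=label_map
    )


def extract_voxel_cloud(vol: LabelVolume, structure: str) -> VoxelCloud:
    """Millimetre voxel-center coordinates of one labeled substructure."""
    if structure not in vol.label_map:
        raise KeyError(f"unknown structure {structure!r}; have {sorted(vol.label_map)}")
    idx = np.argwhere(vol.voxels == vol.label_map[structure])
    if idx.shape[0] == 0:
        raise ValueError(f"structure {structure!r} has no voxels in this volume")
    points = vol.origin_mm + (idx + 0.5) * vol.spacing_mm
    return VoxelCloud(points_mm=points, source_label=structure, spacing_mm=vol.spacing_mm)


def voxel_volume(cloud: VoxelCloud) -> float:
    """Voxel-count volume in mm^3: N times the volume of one voxel.

    At 0.1 mm isotropic spacing each voxel contributes 0.001 mm^3.  The
    conversion is always computed from the stored spacing, never hard-coded.
    """
    return len(cloud) * float(np.prod(cloud.spacing_mm))
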