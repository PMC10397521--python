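"""Volumetric containers, NIfTI I/O, and geometry helpers.

Every image in the pipeline (T1w, T2w, M0, TIGR, CBF) is carried as a
:class:`Volume`: a 3-D scalar grid plus a NIfTI-style 4x4 affine mapping
0-based voxel indices to world coordinates in millimetres.  Binary ROIs are
:class:`Mask` objects sharing the same geometry.

Conventions
-----------
* World coordinates follow the stored orientation of the file; files are
  reoriented to closest-canonical (RAS) on load so voxel (0,0,0) keeps its
  world position while axes are consistently ordered.
* The midsagittal plane is the world ``x = 0`` plane of the common space.
* Missing data is carried as NaN and excluded from all means/SDs downstream
  (never zero-filled, which would bias CBF summaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.affines import apply_affine
from scipy import ndimage


class VolumeIOError(IOError):
    """A NIfTI file could not be read or has a malformed header."""


class AlignmentError(ValueError):
    """Two grids expected to be voxel-aligned differ in shape or affine."""


class MidlineError(ValueError):
    """A lesion straddles the midsagittal plane beyond tolerance."""


class EmptyRoiError(ValueError):
    """A region of interest is empty after restriction/erosion."""


# 6-connectivity (faces only): one erosion iteration removes one voxel.
EROSION_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class Volume:
    """A 3-D scalar grid with voxel-to-world geometry.

    Parameters
    ----------
    data:
        3-D float array; NaN marks missing voxels.
    affine:
        4x4 voxel-index -> world-mm affine (NIfTI convention).
    """

    data: np.ndarray
    affine: np.ndarray
    _world: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("voxel-to-world mapping is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacings must all be positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (norms of the affine columns)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_from_voxel(self, ijk) -> np.ndarray:
        return apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def voxel_from_world(self, xyz) -> np.ndarray:
        return apply_affine(np.linalg.inv(self.affine), np.asarray(xyz, dtype=float))

    def world_grids(self) -> tuple:
        """World x/y/z coordinate of every voxel centre (three 3-D arrays)."""
        if self._world is None or self._world[0].shape != self.data.shape[:3]:
            ii, jj, kk = np.meshgrid(
                *(np.arange(n, dtype=float) for n in self.data.shape[:3]),
                indexing="ij",
            )
            a = self.affine
            x = a[0, 0] * ii + a[0, 1] * jj + a[0, 2] * kk + a[0, 3]
            y = a[1, 0] * ii + a[1, 1] * jj + a[1, 2] * kk + a[1, 3]
            z = a[2, 0] * ii + a[2, 1] * jj + a[2, 2] * kk + a[2, 3]
            self._world = (x, y, z)
        return self._world

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(self.data.copy() if data is None else data, self.affine.copy())


@dataclass
class Mask:
    """A binary grid aligned to a reference :class:`Volume`.

    ``label`` is a free-form role tag (lesion | GM | WM | CSF | brain | air).
    """

    data: np.ndarray
    affine: np.ndarray
    label: str = "mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(abs(np.linalg.det(self.affine[:3, :3])))

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(float), self.affine)

    def intersect(self, other: "Mask", label: str | None = None) -> "Mask":
        check_aligned(self, other)
        return Mask(self.data & other.data, self.affine, label or self.label)


@dataclass(frozen=True)
class SphereRoi:
    """A spherical ROI given by a world-mm centre and radius."""

    center: tuple
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


def check_aligned(a, b) -> None:
    """Raise :class:`AlignmentError` unless two grids share shape and affine."""
    if a.data.shape[:3] != b.data.shape[:3]:
        raise AlignmentError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-4):
        raise AlignmentError("affine mismatch between aligned grids")


def read_volume(path, canonical: bool = True) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    With ``canonical=True`` (default) the image is reoriented to the closest
    RAS orientation; the data array is permuted/flipped but every voxel keeps
    its world coordinate, so geometry-aware code sees an identical image.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        if canonical:
            img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj, dtype=float)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # malformed header, truncated file, ...
        raise VolumeIOError(f"failed to load NIfTI volume {path.name}: {exc}") from exc
    return Volume(data, affine)


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` (or 4-D stack) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), volume.affine)
    nib.save(img, str(path))


def read_mask(path, label: str = "mask") -> Mask:
    vol = read_volume(path)
    return Mask(vol.data > 0.5, vol.affine, label)


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def sphere_mask(reference: Volume | Mask, roi: SphereRoi, label: str = "sphere") -> Mask:
    """Voxels whose world-centre distance to ``roi.center`` is <= radius."""
    ref = reference if isinstance(reference, Volume) else reference.as_volume()
    x, y, z = ref.world_grids()
    cx, cy, cz = roi.center
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    data = d2 <= roi.radius**2
    if not data.any():
        warnings.warn(
            f"sphere ROI at {roi.center} r={roi.radius} mm lies entirely outside "
            "the grid; returning an empty mask",
            stacklevel=2,
        )
    return Mask(data, ref.affine, label)


def erode_mask(mask: Mask, iterations: int = 1) -> Mask:
    """Binary erosion with the 6-connectivity (faces-only) element.

    One iteration peels one voxel; ``iterations=0`` is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or not mask.data.any():
        return Mask(mask.data.copy(), mask.affine, mask.label)
    eroded = ndimage.binary_erosion(
        mask.data, structure=EROSION_STRUCTURE, iterations=iterations
    )
    return Mask(eroded, mask.affine, mask.label)


def contralesional_hemisphere(
    brain: Mask,
    lesion: Mask,
    midline_x: float = 0.0,
    tolerance: float = 0.10,
) -> Mask:
    """Brain half on the opposite side of the midsagittal plane from the lesion.

    The lesion must be predominantly unilateral: at least ``1 - tolerance`` of
    its voxels on one side of the world ``x = midline_x`` plane.
    """
    check_aligned(brain, lesion)
    if not lesion.data.any():
        raise EmptyRoiError("lesion mask is empty")
    x, _, _ = lesion.as_volume().world_grids()
    lx = x[lesion.data]
    frac_left = float(np.mean(lx < midline_x))
    frac_right = 1.0 - frac_left
    if min(frac_left, frac_right) > tolerance:
        raise MidlineError(
            "lesion straddles the midsagittal plane: "
            f"{frac_left:.1%} left / {frac_right:.1%} right of x={midline_x:g}"
        )
    lesion_left = frac_left >= frac_right
    side = x > midline_x if lesion_left else x < midline_x
    return Mask(brain.data & side, brain.affine, "contralesional")


def anterior_half(mask: Mask) -> Mask:
    """Restrict a mask to the anterior (world +y) half of its bounding box."""
    if not mask.data.any():
        raise EmptyRoiError(f"mask '{mask.label}' is empty")
    _, y, _ = mask.as_volume().world_grids()
    ymask = y[mask.data]
    ymid = 0.5 * (ymask.min() + ymask.max())
    return Mask(mask.data & (y > ymid), mask.affine, mask.label + "_anterior")
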