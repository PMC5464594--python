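"""Volumes, masks and seed points on a physical grid.

Axis convention
---------------
Arrays are indexed ``(z, y, x)``; ``spacing`` and ``origin`` follow the same
order, in millimetres.  A voxel index ``i`` maps to the physical position

    position = origin + i * spacing

i.e. the grid is axis-aligned with no direction cosines (an identity
orientation matrix is required of every file read).  Seed points are always
stored in physical mm so that they survive cropping and resampled displays.

Volumes hold CT intensities in Hounsfield units; masks are boolean on the
same grid.  Physical volumes are reported canonically in mm^3 (see
:class:`VolumeMeasure`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "GRID_TOL_MM",
    "GridMismatchError",
    "MetadataError",
    "ImageVolume",
    "BinaryMask",
    "SeedPoint",
    "CropResult",
    "VolumeMeasure",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "centroid_of_mask",
    "crop_about_seed",
    "crop_mask_about_seed",
    "paste_mask",
    "mask_volume",
    "read_seed_csv",
    "write_seed_csv",
]

#: Tolerance (mm) used when deciding whether two grids are "the same";
#: absorbs floating-point noise in file metadata.
GRID_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Two objects that must share a grid (shape, spacing, origin) do not."""


class MetadataError(ValueError):
    """An image file lacks the spacing/orientation metadata we require."""


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector (z, y, x), got shape {arr.shape}")
    return arr


@dataclass
class ImageVolume:
    """A 3-D scalar image (HU) with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def physical_to_index(self, position) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical position."""
        return (np.asarray(position, dtype=float) - self.origin) / self.spacing

    def contains(self, position) -> bool:
        """Whether a physical point lies within the volume's extent.

        The extent includes the half-voxel border around edge voxel centers.
        """
        idx = self.physical_to_index(position)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def grid_matches(self, other, tol: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class BinaryMask:
    """A boolean segmentation aligned to an :class:`ImageVolume` grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got ndim={self.data.ndim}")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    shape = ImageVolume.shape
    voxel_volume_mm3 = ImageVolume.voxel_volume_mm3
    index_to_physical = ImageVolume.index_to_physical
    physical_to_index = ImageVolume.physical_to_index
    contains = ImageVolume.contains
    grid_matches = ImageVolume.grid_matches

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def like(self, data: np.ndarray) -> "BinaryMask":
        """A new mask with the same grid and different voxel data."""
        return BinaryMask(data, self.spacing.copy(), self.origin.copy())


@dataclass
class SeedPoint:
    """A point in physical mm, ordered (z, y, x) like the grid axes."""

    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = _as_vec3(self.position, "position")


@dataclass
class CropResult:
    """A cropped sub-volume plus its voxel offset in the parent grid."""

    volume: ImageVolume
    voxel_offset: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_offset = np.asarray(self.voxel_offset, dtype=int)


@dataclass(frozen=True)
class VolumeMeasure:
    """Physical volume of a mask.

    ``mm3`` is the canonical unit.  ``ml`` is a display conversion
    (1 ml = 1000 mm^3) provided because clinical reports often print ml;
    typical lung nodules measure hundreds of mm^3, i.e. well below 1 ml.
    """

    voxel_count: int
    mm3: float

    @property
    def ml(self) -> float:
        return self.mm3 / 1000.0

    def __str__(self) -> str:
        return f"{self.voxel_count} voxels = {self.mm3:.2f} mm^3"


# ---------------------------------------------------------------------------
# File I/O (NRRD and NIfTI-1 via SimpleITK)
# ---------------------------------------------------------------------------

_NRRD_EXT = (".nrrd", ".nhdr")
_NIFTI_EXT = (".nii", ".nii.gz")


def _check_supported(path: str) -> None:
    low = str(path).lower()
    if not (low.endswith(_NRRD_EXT) or low.endswith(_NIFTI_EXT)):
        raise ValueError(f"unsupported image format: {path!r} (expected NRRD or NIfTI)")


def _nrrd_header_has_spacing(path: str) -> bool:
    """Check the NRRD ASCII header for a spacing-bearing field.

    SimpleITK folds 'space directions'/'spacings' into the image spacing
    (defaulting to 1 mm when absent), so absence must be detected from the
    raw header text, which by the format ends at the first blank line.
    """
    with open(path, "rb") as fh:
        head = fh.read(65536)
    header = head.split(b"\n\n", 1)[0]
    for line in header.splitlines():
        key = line.split(b":", 1)[0].strip().lower()
        if key in (b"space directions", b"spacings"):
            return True
    return False


def _read_sitk(path: str) -> sitk.Image:
    _check_supported(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    low = str(path).lower()
    if low.endswith(_NRRD_EXT) and not _nrrd_header_has_spacing(path):
        raise MetadataError(
            f"{path}: NRRD header carries no spacing metadata "
            "('space directions' or 'spacings' field required)"
        )
    reader = sitk.ImageFileReader()
    reader.SetFileName(str(path))
    img = reader.Execute()
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        # NIfTI written by us round-trips through LPS with an identity
        # matrix; oblique/flipped orientations are out of scope.
        raise MetadataError(
            f"{path}: non-identity direction matrix is not supported "
            f"(got {direction.tolist()})"
        )
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = np.asarray(img.GetSpacing(), dtype=float)[::-1]
    origin = np.asarray(img.GetOrigin(), dtype=float)[::-1]
    return data, spacing, origin


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing(tuple(float(s) for s in np.asarray(spacing)[::-1]))
    img.SetOrigin(tuple(float(o) for o in np.asarray(origin)[::-1]))
    return img


def read_volume(path: str) -> ImageVolume:
    """Read an NRRD or NIfTI-1 scalar volume (HU) with its grid metadata."""
    data, spacing, origin = _from_sitk(_read_sitk(path))
    return ImageVolume(data.astype(np.float64), spacing, origin)


def write_volume(volume: ImageVolume, path: str) -> None:
    _check_supported(path)
    sitk.WriteImage(_to_sitk(volume.data, volume.spacing, volume.origin), str(path))


def read_mask(path: str, reference: ImageVolume | None = None) -> BinaryMask:
    """Read a binary mask; optionally verify it shares ``reference``'s grid."""
    data, spacing, origin = _from_sitk(_read_sitk(path))
    mask = BinaryMask(data > 0, spacing, origin)
    if reference is not None and not mask.grid_matches(reference):
        raise GridMismatchError(
            f"{path}: mask grid (shape {mask.shape}, spacing {mask.spacing}, "
            f"origin {mask.origin}) does not match the reference volume"
        )
    return mask


def write_mask(mask: BinaryMask, path: str) -> None:
    _check_supported(path)
    sitk.WriteImage(
        _to_sitk(mask.data.astype(np.uint8), mask.spacing, mask.origin), str(path)
    )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def centroid_of_mask(mask: BinaryMask) -> SeedPoint:
    """Unweighted mean of foreground voxel centers, in physical mm.

    This is the seed-initialization rule of the segmentation study: each
    algorithm run is seeded at the centroid of one manual contour.  For
    non-convex masks the centroid may fall outside the mask itself.
    """
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise ValueError("cannot compute the centroid of an empty mask")
    mean_index = idx.mean(axis=0)
    return SeedPoint(mask.index_to_physical(mean_index))


def _crop_bounds(grid, seed: SeedPoint, radius_mm: float):
    if radius_mm <= 0:
        raise ValueError(f"crop radius must be > 0 mm, got {radius_mm}")
    if not grid.contains(seed.position):
        raise ValueError(
            f"seed {seed.position} lies outside the volume's physical extent"
        )
    seed_idx = np.round(grid.physical_to_index(seed.position)).astype(int)
    seed_idx = np.clip(seed_idx, 0, np.array(grid.shape) - 1)
    half = np.floor(radius_mm / grid.spacing).astype(int)
    lo = np.maximum(seed_idx - half, 0)
    hi = np.minimum(seed_idx + half + 1, np.array(grid.shape))
    return lo, hi


def crop_about_seed(
    volume: ImageVolume, seed: SeedPoint, radius_mm: float = 30.0
) -> CropResult:
    """Axis-aligned cube of ``seed +/- radius_mm`` per axis, clipped to the image.

    The box spans ``floor(radius_mm / spacing)`` voxels on each side of the
    seed voxel, inclusive of the seed slice, mirroring the 30 mm working
    region the segmenter crops around each seed to bound computation.
    """
    lo, hi = _crop_bounds(volume, seed, radius_mm)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = ImageVolume(
        volume.data[sl].copy(),
        volume.spacing.copy(),
        volume.index_to_physical(lo),
    )
    return CropResult(sub, lo)


def crop_mask_about_seed(
    mask: BinaryMask, seed: SeedPoint, radius_mm: float = 30.0
) -> tuple[BinaryMask, np.ndarray]:
    """Same box rule as :func:`crop_about_seed`, for a mask grid."""
    lo, hi = _crop_bounds(mask, seed, radius_mm)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub = BinaryMask(mask.data[sl].copy(), mask.spacing.copy(), mask.index_to_physical(lo))
    return sub, lo


def paste_mask(crop_mask: BinaryMask, voxel_offset, parent_grid) -> BinaryMask:
    """Paste a cropped mask back onto its parent grid (zeros elsewhere)."""
    voxel_offset = np.asarray(voxel_offset, dtype=int)
    full = np.zeros(parent_grid.shape, dtype=bool)
    sl = tuple(
        slice(int(o), int(o + s)) for o, s in zip(voxel_offset, crop_mask.shape)
    )
    full[sl] = crop_mask.data
    return BinaryMask(full, parent_grid.spacing.copy(), parent_grid.origin.copy())


def mask_volume(mask: BinaryMask) -> VolumeMeasure:
    """Voxel count and physical volume (mm^3) of a mask."""
    n = mask.voxel_count
    return VolumeMeasure(n, n * mask.voxel_volume_mm3)


# ---------------------------------------------------------------------------
# Seed CSV plumbing
# ---------------------------------------------------------------------------

_SEED_COLUMNS = ["case_id", "nodule_id", "reader_id", "x_mm", "y_mm", "z_mm"]


def read_seed_csv(path: str):
    """Seed-point table with columns (case_id, nodule_id, reader_id, x_mm, y_mm, z_mm).

    Returns a pandas DataFrame; convert a row to a :class:`SeedPoint` with
    ``SeedPoint([row.z_mm, row.y_mm, row.x_mm])`` (grid axis order is z,y,x).
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in _SEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: seed CSV missing columns {missing}")
    return df


def write_seed_csv(rows, path: str) -> None:
    """Write seed rows (dicts with the standard seed columns) to CSV."""
    import pandas as pd

    pd.DataFrame(list(rows), columns=_SEED_COLUMNS).to_csv(path, index=False)
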