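"""Synthetic chest-CT phantom with ground truth and simulated readers.

The phantom is a deliberately simple thorax: a soft-tissue body (+40 HU)
containing two ellipsoidal lung cavities of aerated parenchyma (-850 HU
plus Gaussian noise), curved tubular vessels of soft-tissue density, and a
single nodule whose shape and density follow the standard radiological
taxonomy — texture (solid / part-solid / ground-glass), lobulation,
spiculation, and attachment (isolated / juxtapleural / juxtavascular).
Every structure comes with an exact voxel mask, which is what real
multi-reader datasets never provide; these masks serve as ground truth for
validating the segmenter and the reader-variability statistics.

Simulated "readers" are produced by perturbing the true nodule boundary
with smooth spatially correlated offsets of bounded magnitude, emulating
the slice-by-slice variability of human contouring without its systematic
biases (no per-slice jaggedness, no reader-specific over/under-calling).

All randomness flows from a single integer seed; identical specs produce
voxel-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .metrics import SegmentationSet
from .volume_io import BinaryMask, ImageVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_thorax",
    "generate_reader_variants",
    "sphericity",
    "LUNG_HU",
    "WALL_HU",
    "VESSEL_HU",
    "SOLID_HU",
    "HALO_HU",
    "GROUND_GLASS_HU",
]

LUNG_HU = -850.0  # aerated parenchyma
WALL_HU = 40.0  # chest wall / soft tissue
VESSEL_HU = 40.0  # contrastless vessel blood pool / wall
SOLID_HU = 20.0  # solid nodule tissue
HALO_HU = -500.0  # part-solid ground-glass halo
GROUND_GLASS_HU = -550.0  # non-solid nodule

TEXTURE_CLASSES = ("solid", "part_solid", "ground_glass")
ATTACHMENTS = ("isolated", "juxtapleural", "juxtavascular")

# Fraction of the nodule radius occupied by the ground-glass halo of a
# part-solid nodule (outer 40%; the solid core spans the inner 60%).
PART_SOLID_HALO_FRACTION = 0.4


@dataclass
class PhantomSpec:
    """Generative parameters of one phantom thorax with one nodule."""

    shape: tuple[int, int, int] = (96, 112, 144)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    nodule_center_mm: tuple[float, float, float] | None = None  # default: lung center
    nodule_radius_mm: float = 8.0
    texture_class: str = "solid"
    lobulation_degree: float = 0.0
    spiculation_degree: float = 0.0
    attachment: str = "isolated"
    noise_sd: float = 20.0  # HU, typical low-dose CT parenchymal noise
    vessel_count: int = 2  # background vessels per lung
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.nodule_radius_mm <= 0:
            raise ValueError("nodule_radius_mm must be > 0")
        if self.texture_class not in TEXTURE_CLASSES:
            raise ValueError(f"texture_class must be one of {TEXTURE_CLASSES}")
        if self.attachment not in ATTACHMENTS:
            raise ValueError(f"attachment must be one of {ATTACHMENTS}")
        if not (0.0 <= self.lobulation_degree <= 1.0):
            raise ValueError("lobulation_degree must lie in [0, 1]")
        if not (0.0 <= self.spiculation_degree <= 1.0):
            raise ValueError("spiculation_degree must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Generated volume plus exact structure masks."""

    volume: ImageVolume
    nodule_mask: BinaryMask
    wall_mask: BinaryMask
    vessel_mask: BinaryMask
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Geometry helpers (all in physical mm on the (z, y, x) grid)
# ---------------------------------------------------------------------------


def _coord_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _lung_geometry(shape, spacing):
    """Two ellipsoidal cavities centered about the body midline."""
    extent = np.array(shape) * np.array(spacing)
    center = extent / 2.0
    semi = np.array([0.42 * extent[0], 0.36 * extent[1], 0.20 * extent[2]])
    offset_x = 0.24 * extent[2]
    left_c = np.array([center[0], center[1], center[2] - offset_x])
    right_c = np.array([center[0], center[1], center[2] + offset_x])
    return left_c, right_c, semi


def _ellipsoid_mask(grids, center, semi):
    zz, yy, xx = grids
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _paint_tube(mask: np.ndarray, points: np.ndarray, radius_mm: float, spacing) -> None:
    """Union of balls along a polyline of centerline points (in-place)."""
    spacing = np.asarray(spacing, dtype=float)
    r_vox = np.ceil(radius_mm / spacing).astype(int)
    offs_axes = [np.arange(-r, r + 1) for r in r_vox]
    oz, oy, ox = np.meshgrid(*offs_axes, indexing="ij")
    ball = (
        (oz * spacing[0]) ** 2 + (oy * spacing[1]) ** 2 + (ox * spacing[2]) ** 2
    ) <= radius_mm**2
    offsets = np.stack([oz[ball], oy[ball], ox[ball]], axis=1)
    shape = np.array(mask.shape)
    for p in points:
        idx = np.round(p / spacing).astype(int) + offsets
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True


def _random_walk_vessel(rng, start, direction, length_mm, lung_c, lung_semi):
    """Smoothly curving centerline confined to one lung cavity."""
    step = 1.0  # mm
    pos = np.asarray(start, dtype=float).copy()
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    points = [pos.copy()]
    for _ in range(int(length_mm / step)):
        d = d + 0.25 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        nxt = pos + step * d
        rel = (nxt - lung_c) / (0.9 * lung_semi)
        if np.dot(rel, rel) > 1.0:  # about to leave the cavity: turn inward
            d = (lung_c - pos) / np.linalg.norm(lung_c - pos)
            nxt = pos + step * d
        pos = nxt
        points.append(pos.copy())
    return np.asarray(points)


def _build_nodule_mask(spec: PhantomSpec, grids, center, rng) -> np.ndarray:
    """Base sphere, optionally lobulated (sphere union) and spiculated (spikes)."""
    zz, yy, xx = grids
    r = spec.nodule_radius_mm

    def ball(c, radius):
        return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius**2

    mask = ball(center, r)
    if spec.lobulation_degree > 0:
        n_lobes = 1 + int(round(3 * spec.lobulation_degree))  # 2-4 spheres total
        for _ in range(n_lobes):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            offset = spec.lobulation_degree * 0.7 * r
            lobe_r = rng.uniform(0.55, 0.8) * r
            mask |= ball(center + offset * direction, lobe_r)
    if spec.spiculation_degree > 0:
        n_spikes = max(1, int(round(10 * spec.spiculation_degree)))
        length = (0.3 + 0.9 * spec.spiculation_degree) * r
        base_r = 0.15 * r + 0.5
        rel = np.stack([zz - center[0], yy - center[1], xx - center[2]])
        dist = np.sqrt((rel**2).sum(axis=0))
        for _ in range(n_spikes):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            t = np.einsum("i,i...->...", d, rel)
            perp2 = np.maximum(dist**2 - t**2, 0.0)
            frac = np.clip((t - 0.6 * r) / (r + length - 0.6 * r), 0.0, 1.0)
            spike = (t >= 0.6 * r) & (t <= r + length) & (
                perp2 <= (base_r * (1.0 - frac)) ** 2
            )
            mask |= spike
    return mask


def generate_thorax(spec: PhantomSpec) -> PhantomTruth:
    """Build the phantom volume and its ground-truth masks.

    Deterministic for a fixed ``spec`` (including ``rng_seed``).  Raises if
    the nodule extends outside the grid or, for ``attachment='isolated'``,
    outside the lung cavity.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    grids = _coord_grids(shape, spacing)
    extent = np.array(shape) * spacing

    left_c, right_c, semi = _lung_geometry(shape, spacing)
    lung_region = _ellipsoid_mask(grids, left_c, semi) | _ellipsoid_mask(
        grids, right_c, semi
    )

    # --- nodule placement -------------------------------------------------
    r = spec.nodule_radius_mm
    if spec.nodule_center_mm is not None:
        center = np.asarray(spec.nodule_center_mm, dtype=float)
    elif spec.attachment == "juxtapleural":
        # centre pushed laterally until the pleural surface cuts the nodule
        center = right_c.copy()
        center[2] = right_c[2] + semi[2] - 0.55 * r
    else:
        center = right_c.copy()
    if np.any(center - r < -0.5 * spacing) or np.any(center + r > extent + 0.5 * spacing):
        raise ValueError(
            f"nodule of radius {r} mm at {center} extends outside the grid (extent {extent})"
        )

    nodule = _build_nodule_mask(spec, grids, center, rng)
    if not nodule.any():
        raise ValueError("nodule mask is empty; check radius against spacing")
    if np.any(
        np.array([a.min() if a.size else 0 for a in np.nonzero(nodule)]) == 0
    ) or np.any(
        np.array([a.max() for a in np.nonzero(nodule)]) == np.array(shape) - 1
    ):
        raise ValueError("nodule touches the grid boundary; enlarge the grid")
    if spec.attachment == "isolated" and np.any(nodule & ~lung_region):
        raise ValueError("isolated nodule does not fit inside the lung cavity")

    # --- vessels ----------------------------------------------------------
    # Background vessels must not touch the nodule (only the dedicated
    # juxtavascular vessel may): exclusion ball = farthest nodule voxel
    # from the centre plus tube radius plus a parenchymal margin.
    nodule_extent = 0.0
    nz = np.nonzero(nodule)
    pts_mm = np.stack([nz[k] * spacing[k] for k in range(3)], axis=1)
    nodule_extent = float(np.sqrt(((pts_mm - center) ** 2).sum(axis=1)).max())

    vessel = np.zeros(shape, dtype=bool)
    for lung_c in (left_c, right_c):
        for _ in range(spec.vessel_count):
            start = lung_c + rng.uniform(-0.3, 0.3) * semi
            direction = rng.standard_normal(3)
            radius = rng.uniform(1.0, 3.0)
            pts = _random_walk_vessel(
                rng, start, direction, length_mm=0.9 * semi.max(), lung_c=lung_c,
                lung_semi=semi,
            )
            clear = nodule_extent + radius + 2.0
            pts = pts[np.sqrt(((pts - center) ** 2).sum(axis=1)) > clear]
            _paint_tube(vessel, pts, radius, spacing)
    if spec.attachment == "juxtavascular":
        # dedicated vessel running axially, tangent to the nodule surface
        vr = 2.5
        touch = center + np.array([0.0, r + 0.6 * vr, 0.0])
        zs = np.arange(max(touch[0] - 30.0, 0.0), min(touch[0] + 30.0, extent[0]), 1.0)
        pts = np.stack(
            [zs, np.full_like(zs, touch[1]), np.full_like(zs, touch[2])], axis=1
        )
        _paint_tube(vessel, pts, vr, spacing)
    vessel &= lung_region
    vessel &= ~nodule

    # --- assemble HU volume ----------------------------------------------
    vol = np.full(shape, WALL_HU, dtype=np.float64)
    vol[lung_region] = LUNG_HU
    vol[vessel] = VESSEL_HU
    if spec.texture_class == "solid":
        vol[nodule] = SOLID_HU
    elif spec.texture_class == "ground_glass":
        vol[nodule] = GROUND_GLASS_HU
    else:  # part_solid: solid core, ground-glass halo in the outer radius band
        depth = ndimage.distance_transform_edt(nodule, sampling=spacing)
        core = nodule & (depth >= PART_SOLID_HALO_FRACTION * r)
        vol[nodule] = HALO_HU
        vol[core] = SOLID_HU
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=shape)

    origin = np.zeros(3)
    volume = ImageVolume(vol, spacing, origin)
    wall = ~lung_region & ~nodule
    return PhantomTruth(
        volume=volume,
        nodule_mask=BinaryMask(nodule, spacing, origin),
        wall_mask=BinaryMask(wall, spacing, origin),
        vessel_mask=BinaryMask(vessel, spacing, origin),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Simulated readers
# ---------------------------------------------------------------------------

#: correlation length (mm) of the smooth boundary-perturbation fields
_READER_FIELD_SIGMA_MM = 4.0


def generate_reader_variants(
    truth_mask: BinaryMask,
    n: int = 4,
    variability_mm: float = 1.0,
    rng_seed: int = 0,
) -> SegmentationSet:
    """Simulate ``n`` manual contours by smooth boundary perturbation.

    Each variant thresholds the truth's signed distance field at a smooth
    random offset field: unit-variance Gaussian noise blurred at a 4 mm
    correlation length, scaled to ``variability_mm / 2`` standard
    deviation and hard-clipped to ``+/- variability_mm``, so boundary
    displacements never exceed the stated variability.  ``variability_mm
    = 0`` reproduces the truth exactly.  Deterministic for a fixed seed.
    """
    if variability_mm < 0:
        raise ValueError("variability_mm must be >= 0")
    if truth_mask.voxel_count == 0:
        raise ValueError("truth mask is empty")
    rng = np.random.default_rng(rng_seed)
    spacing = truth_mask.spacing
    inside = truth_mask.data
    sdf = ndimage.distance_transform_edt(
        ~inside, sampling=spacing
    ) - ndimage.distance_transform_edt(inside, sampling=spacing)

    variants = []
    sigma_vox = _READER_FIELD_SIGMA_MM / spacing
    for _ in range(n):
        field_ = ndimage.gaussian_filter(
            rng.standard_normal(truth_mask.shape), sigma=sigma_vox
        )
        std = field_.std()
        if std > 0:
            field_ = field_ / std
        offset = np.clip(field_ * (variability_mm / 2.0), -variability_mm, variability_mm)
        data = sdf <= offset
        if not data.any():
            raise ValueError(
                f"variability {variability_mm} mm erased the structure entirely"
            )
        inter = int(np.count_nonzero(data & inside))
        dice = 200.0 * inter / (int(data.sum()) + int(inside.sum()))
        if dice < 50.0:
            raise ValueError(
                f"reader variant overlaps truth with Dice {dice:.1f}% < 50%; "
                "variability is too large relative to the structure"
            )
        variants.append(truth_mask.like(data))
    if n == 4:
        return SegmentationSet(variants, method="manual")
    # non-standard set sizes are returned as a plain list for ad-hoc use
    return variants  # type: ignore[return-value]


def sphericity(mask: BinaryMask) -> float:
    """Isoperimetric sphericity pi^(1/3) (6V)^(2/3) / A (1 for a ball).

    Surface area from a marching-cubes triangulation of the mask at its
    physical spacing; volume from the voxel count.
    """
    from skimage import measure

    if mask.voxel_count == 0:
        raise ValueError("cannot compute sphericity of an empty mask")
    padded = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=tuple(mask.spacing)
    )
    area = measure.mesh_surface_area(verts, faces)
    volume = mask.voxel_count * mask.voxel_volume_mm3
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
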