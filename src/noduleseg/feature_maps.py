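"""Feature maps and their fusion into the front-propagation speed map.

Four maps, each scaled to [0, 1] where 1 means "propagate freely" and 0
means "blocked", are combined by a voxelwise minimum so that any single
blocking structure halts the front:

1. **chest wall** — lung cavity segmented by HU threshold plus morphology;
   the front may only move inside the lung;
2. **vessels** — multiscale Hessian line filter (Sato); tubular bright
   structures are penalized;
3. **nodule/parenchyma interface** — 3-D Canny edges, dilated one voxel,
   form a thin blocking shell at density discontinuities;
4. **density** — a sigmoid of HU that suppresses densities incompatible
   with nodular tissue (midpoint -200 HU for solid, -500 HU for non-solid
   nodules, softness 100 HU).

The density channel is the sigmoid-transformed member of the pool; each of
the other channels carries its own [0, 1] transform, and the speed map is
their pointwise minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume_io import GridMismatchError, ImageVolume, _to_sitk

__all__ = [
    "FeatureMap",
    "SpeedMap",
    "SigmoidParams",
    "chest_wall_map",
    "vesselness_map",
    "edge_interface_map",
    "density_map",
    "fuse_speed_map",
]


@dataclass
class FeatureMap:
    """Scalar field in [0, 1] on an image grid; 1 = free, 0 = blocked."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    name: str = "feature"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"{self.name}: values [{lo}, {hi}] outside [0, 1]")
        np.clip(self.data, 0.0, 1.0, out=self.data)

    @property
    def shape(self):
        return self.data.shape

    def grid_matches(self, other, tol: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


class SpeedMap(FeatureMap):
    """The fused propagation speed F in [0, 1]."""


@dataclass(frozen=True)
class SigmoidParams:
    """Density-sigmoid parameters: alpha = HU softness, beta = HU midpoint."""

    alpha: float = 100.0
    beta: float = -200.0

    def __post_init__(self) -> None:
        if self.alpha == 0:
            raise ValueError("sigmoid alpha must be non-zero")

    @classmethod
    def solid(cls) -> "SigmoidParams":
        return cls(100.0, -200.0)

    @classmethod
    def nonsolid(cls) -> "SigmoidParams":
        return cls(100.0, -500.0)


def _like(volume: ImageVolume, data: np.ndarray, name: str) -> FeatureMap:
    return FeatureMap(data, volume.spacing.copy(), volume.origin.copy(), name)


# ---------------------------------------------------------------------------
# 1. chest wall
# ---------------------------------------------------------------------------


def chest_wall_map(
    volume: ImageVolume,
    lung_threshold_hu: float = -500.0,
    closing_radius_vox: int = 3,
    min_component_fraction: float = 0.01,
) -> FeatureMap:
    """Blocks everything outside the lung cavity.

    Low-density voxels (< threshold) are kept, small speckle components are
    dropped, and the lung mask is morphologically closed (ball radius in
    voxels) and hole-filled.  The closing reabsorbs juxtapleural
    indentations and thin vessels into the lung; the hole filling restores
    solid nodules (which sit above the threshold) as interior lung.  The
    map is 1 inside the lung, 0 elsewhere.
    """
    low = volume.data < lung_threshold_hu
    if not low.any():
        warnings.warn(
            "no voxels below the lung threshold; chest-wall map is all-blocking",
            stacklevel=2,
        )
        return _like(volume, np.zeros(volume.shape), "chest_wall")
    labels, n = ndimage.label(low)
    if n > 1:
        sizes = ndimage.sum_labels(low, labels, index=np.arange(1, n + 1))
        keep = 1 + np.flatnonzero(sizes >= min_component_fraction * sizes.max())
        lung = np.isin(labels, keep)
    else:
        lung = low
    if closing_radius_vox > 0:
        ball = _ball_structure(closing_radius_vox)
        # closing with explicit border handling: dilation treats the outside
        # as background, erosion as foreground, so the image border itself
        # does not eat into the lung mask
        lung = ndimage.binary_erosion(
            ndimage.binary_dilation(lung, structure=ball, border_value=0),
            structure=ball,
            border_value=1,
        )
    lung = ndimage.binary_fill_holes(lung)
    return _like(volume, lung.astype(np.float64), "chest_wall")


def _ball_structure(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz**2 + yy**2 + xx**2) <= radius**2


# ---------------------------------------------------------------------------
# 2. vessels (multiscale Hessian line filter)
# ---------------------------------------------------------------------------


def _hessian_eigenvalues(data: np.ndarray, spacing: np.ndarray, sigma_mm: float):
    """Eigenvalues (ascending) of the scale-normalized Gaussian Hessian.

    Derivatives are taken per axis with sigma in voxels = sigma_mm/spacing
    and converted to physical units (HU/mm^2); normalization by sigma^2
    makes responses comparable across scales.
    """
    sigma_vox = sigma_mm / spacing
    h = np.empty(data.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = ndimage.gaussian_filter(data, sigma=sigma_vox, order=order)
            d /= spacing[i] * spacing[j]
            h[..., i, j] = d
            h[..., j, i] = d
    h *= sigma_mm**2
    return np.linalg.eigvalsh(h)  # ascending


def _sato_line_measure(eigs: np.ndarray, alpha: float = 0.25) -> np.ndarray:
    """Bright-line measure from Hessian eigenvalues (ascending order).

    With l3 <= l2 <= l1 (so l3, l2 are the two most negative), a bright
    tube has l3 ~ l2 << 0 and |l1| small:

        |l3| * (l2/l3)          , then damped by the l1 term:
        * (1 + l1/|l2|)         if l1 <= 0
        * (1 - alpha*l1/|l2|)   if 0 < l1 < |l2|/alpha
        0                       otherwise
    """
    l3 = eigs[..., 0]
    l2 = eigs[..., 1]
    l1 = eigs[..., 2]
    out = np.zeros(l1.shape, dtype=np.float64)
    tube = l2 < 0  # implies l3 < 0 too
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(tube, -l3 * np.where(l3 < 0, l2 / l3, 0.0), 0.0)
        abs_l2 = np.abs(l2)
        damp_neg = 1.0 + np.where(abs_l2 > 0, l1 / abs_l2, 0.0)
        damp_pos = 1.0 - alpha * np.where(abs_l2 > 0, l1 / abs_l2, np.inf)
    out = np.where(
        tube & (l1 <= 0),
        base * np.clip(damp_neg, 0.0, None),
        np.where(tube & (l1 > 0), base * np.clip(damp_pos, 0.0, None), 0.0),
    )
    return out


def vesselness_map(
    volume: ImageVolume, scales_mm=(1.0, 2.0, 4.0)
) -> FeatureMap:
    """Penalty map 1 - normalized multiscale vesselness.

    The line measure is evaluated at each scale and maximized over scales;
    the maximum response in the crop normalizes it to [0, 1], and the map
    is its complement, so vessel centerlines approach 0 while blob-like
    and flat regions stay near 1.  A constant volume yields an all-ones map.
    """
    scales = tuple(float(s) for s in scales_mm)
    if len(scales) == 0 or any(s <= 0 for s in scales):
        raise ValueError(f"scales must be positive, got {scales_mm}")
    best = np.zeros(volume.shape, dtype=np.float64)
    for s in scales:
        eigs = _hessian_eigenvalues(volume.data, volume.spacing, s)
        np.maximum(best, _sato_line_measure(eigs), out=best)
    peak = best.max()
    if peak <= 0:
        return _like(volume, np.ones(volume.shape), "vesselness")
    return _like(volume, 1.0 - best / peak, "vesselness")


# ---------------------------------------------------------------------------
# 3. nodule/parenchyma interface (3-D Canny)
# ---------------------------------------------------------------------------


def edge_interface_map(
    volume: ImageVolume,
    sigma_mm: float = 1.0,
    low_thr: float | None = None,
    high_thr: float | None = None,
    low_pct: float = 70.0,
    high_pct: float = 90.0,
) -> FeatureMap:
    """Thin blocking shell (map = 0) at Canny edges, 1 elsewhere.

    Hysteresis thresholds default to the 70th/90th percentiles of the
    smoothed gradient-magnitude distribution of the crop, which adapts to
    any HU contrast without absolute-unit tuning: Gaussian smoothing at
    ``sigma_mm`` suppresses noise gradients far below tissue-interface
    gradients, and non-maximum suppression thins whatever passes.
    Detected edges are dilated by one voxel before blocking.
    """
    if low_thr is not None and high_thr is not None and not (0 <= low_thr <= high_thr):
        raise ValueError("thresholds must satisfy 0 <= low_thr <= high_thr")
    img = _to_sitk(volume.data, volume.spacing, volume.origin)
    if low_thr is None or high_thr is None:
        grad = sitk.GradientMagnitudeRecursiveGaussian(img, sigma=float(sigma_mm))
        gmag = sitk.GetArrayFromImage(grad)
        auto_high = float(np.percentile(gmag, high_pct))
        auto_low = float(np.percentile(gmag, low_pct))
        if high_thr is None:
            high_thr = auto_high
        if low_thr is None:
            low_thr = min(auto_low, high_thr)
    variance = [float(sigma_mm) ** 2] * 3
    edges_img = sitk.CannyEdgeDetection(
        sitk.Cast(img, sitk.sitkFloat64),
        lowerThreshold=float(low_thr),
        upperThreshold=float(high_thr),
        variance=variance,
    )
    edges = sitk.GetArrayFromImage(edges_img) > 0
    if edges.any():
        edges = ndimage.binary_dilation(edges, iterations=1)
    return _like(volume, (~edges).astype(np.float64), "edge_interface")


# ---------------------------------------------------------------------------
# 4. density
# ---------------------------------------------------------------------------


def density_map(volume: ImageVolume, params: SigmoidParams) -> FeatureMap:
    """Voxelwise sigmoid of HU: 1 / (1 + exp(-(I - beta)/alpha)).

    Monotone non-decreasing in intensity for alpha > 0, so low-density
    parenchyma is suppressed and nodular densities pass.
    """
    z = (volume.data - params.beta) / params.alpha
    data = 1.0 / (1.0 + np.exp(-z))
    return _like(volume, data, "density")


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def fuse_speed_map(maps) -> SpeedMap:
    """Voxelwise minimum of the feature maps, clipped to [0, 1].

    Min-pooling makes each map an absorbing veto: a zero anywhere blocks
    the front there regardless of the other channels.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("fuse_speed_map needs at least one feature map")
    first = maps[0]
    for m in maps[1:]:
        if not first.grid_matches(m):
            raise GridMismatchError("feature maps must share a single grid")
    fused = np.minimum.reduce([m.data for m in maps])
    return SpeedMap(
        np.clip(fused, 0.0, 1.0), first.spacing.copy(), first.origin.copy(), "speed"
    )
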