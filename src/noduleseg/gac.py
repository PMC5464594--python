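"""Geodesic-active-contour level-set segmentation.

A front, represented implicitly as the zero level of a signed scalar field
``phi`` (negative inside), is propagated from seed spheres under the fused
speed map F:

    d(phi)/dt = - w_p * F * |grad phi|                (outward propagation)
                + w_c * F * kappa * |grad phi|        (curvature smoothing)
                + w_a * (grad F . grad phi)           (edge attraction)

Propagation uses Godunov upwind differencing, the curvature term central
differences (mean-curvature form), and the advection term axis-wise
upwinding against its transport velocity.  All finite differences are
spacing-aware, so anisotropic grids evolve in physical units.  ``phi`` is
periodically redistanced with a Euclidean distance transform and clamped
to a band around the front; the time step obeys a CFL bound combining all
three terms.  Evolution stops when the RMS change of ``phi`` in the band
drops below tolerance, or at the iteration cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import GacParams, SegmentationConfig
from .feature_maps import (
    SigmoidParams,
    SpeedMap,
    chest_wall_map,
    density_map,
    edge_interface_map,
    fuse_speed_map,
    vesselness_map,
)
from .volume_io import (
    BinaryMask,
    ImageVolume,
    SeedPoint,
    crop_about_seed,
    paste_mask,
)

__all__ = ["LevelSetState", "initialize_front", "evolve", "segment_nodule"]

#: half-width (in multiples of the largest voxel dimension) of the band
#: within which phi is treated as active; phi is clamped beyond it
_BAND_VOXELS = 8.0


@dataclass
class LevelSetState:
    """Signed level-set field (negative inside) on an image grid."""

    phi: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    iteration: int = 0

    @property
    def shape(self):
        return self.phi.shape

    @property
    def mask(self) -> np.ndarray:
        return self.phi < 0


def initialize_front(
    seeds, grid, init_radius_mm: float = 2.0
) -> LevelSetState:
    """Signed distance to the union of seed spheres (negative inside)."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed point is required")
    if init_radius_mm <= 0:
        raise ValueError("init_radius_mm must be > 0")
    for s in seeds:
        if not grid.contains(s.position):
            raise ValueError(f"seed {s.position} lies outside the grid extent")
    axes = [
        grid.origin[k] + np.arange(grid.shape[k]) * grid.spacing[k] for k in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    dist = np.full(grid.shape, np.inf)
    for s in seeds:
        d = np.sqrt(
            (zz - s.position[0]) ** 2
            + (yy - s.position[1]) ** 2
            + (xx - s.position[2]) ** 2
        )
        np.minimum(dist, d, out=dist)
    return LevelSetState(dist - init_radius_mm, grid.spacing.copy(), grid.origin.copy())


# ---------------------------------------------------------------------------
# finite-difference helpers (spacing-aware)
# ---------------------------------------------------------------------------


def _one_sided(phi: np.ndarray, axis: int, h: float):
    """Backward and forward differences with edge replication."""
    fwd = (np.roll(phi, -1, axis=axis) - phi) / h
    bwd = (phi - np.roll(phi, 1, axis=axis)) / h
    # zero the wrapped faces so the boundary acts as a Neumann wall
    sl_last = [slice(None)] * 3
    sl_last[axis] = -1
    fwd[tuple(sl_last)] = 0.0
    sl_first = [slice(None)] * 3
    sl_first[axis] = 0
    bwd[tuple(sl_first)] = 0.0
    return bwd, fwd


def _central(phi: np.ndarray, axis: int, h: float) -> np.ndarray:
    g = np.gradient(phi, h, axis=axis)
    return g


def _godunov_gradient_expand(phi: np.ndarray, spacing) -> np.ndarray:
    """|grad phi| upwinded for outward motion (speed >= 0)."""
    total = np.zeros_like(phi)
    for ax in range(3):
        bwd, fwd = _one_sided(phi, ax, spacing[ax])
        total += np.maximum(bwd, 0.0) ** 2 + np.minimum(fwd, 0.0) ** 2
    return np.sqrt(total)


def _curvature_times_gradient(phi: np.ndarray, spacing) -> np.ndarray:
    """kappa * |grad phi| via the standard central-difference formula."""
    gz = _central(phi, 0, spacing[0])
    gy = _central(phi, 1, spacing[1])
    gx = _central(phi, 2, spacing[2])
    gzz = _central(gz, 0, spacing[0])
    gyy = _central(gy, 1, spacing[1])
    gxx = _central(gx, 2, spacing[2])
    gzy = _central(gz, 1, spacing[1])
    gzx = _central(gz, 2, spacing[2])
    gyx = _central(gy, 2, spacing[2])
    g2 = gz**2 + gy**2 + gx**2
    num = (
        gzz * (gy**2 + gx**2)
        + gyy * (gz**2 + gx**2)
        + gxx * (gz**2 + gy**2)
        - 2.0 * (gz * gy * gzy + gz * gx * gzx + gy * gx * gyx)
    )
    return num / (g2 + 1e-12)


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """EDT-based signed distance, negative inside; preserves voxel signs."""
    inside = mask
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    return d_out - d_in


def _reinitialize(phi: np.ndarray, spacing) -> np.ndarray:
    """Redistance phi away from the front, keeping near-front values.

    A plain sign-based EDT redistancing quantizes the interface to voxel
    signs and discards sub-voxel front motion, which stalls slowly
    penetrating fronts; values at voxels face-adjacent to a sign change
    are therefore preserved and only the far field is replaced.
    """
    inside = phi < 0
    near = np.zeros_like(inside)
    for ax in range(3):
        shifted = np.roll(inside, 1, axis=ax)
        shifted[tuple(slice(0, 1) if a == ax else slice(None) for a in range(3))] = (
            inside[tuple(slice(0, 1) if a == ax else slice(None) for a in range(3))]
        )
        near |= inside ^ shifted
        shifted = np.roll(inside, -1, axis=ax)
        shifted[tuple(slice(-1, None) if a == ax else slice(None) for a in range(3))] = (
            inside[tuple(slice(-1, None) if a == ax else slice(None) for a in range(3))]
        )
        near |= inside ^ shifted
    sdf = _signed_distance(inside, spacing)
    sdf[near] = phi[near]
    return sdf


def evolve(
    state: LevelSetState,
    speed: SpeedMap,
    params: GacParams | None = None,
    return_info: bool = False,
):
    """Propagate the front under the speed map; return the inside as a mask.

    Deterministic for fixed inputs.  An all-zero speed map freezes the
    front: the initialization is returned unchanged with a warning.
    """
    params = params or GacParams()
    if state.shape != speed.shape or not np.allclose(
        state.spacing, speed.spacing, atol=1e-3
    ):
        raise ValueError("level-set state and speed map must share one grid")
    spacing = np.asarray(state.spacing, dtype=float)
    F = np.clip(speed.data, 0.0, 1.0)

    info: dict = {"iterations": 0, "converged": False, "dt": 0.0, "rms": []}
    if not np.any(F > 0):
        warnings.warn("speed map is identically zero; returning the initialization",
                      stacklevel=2)
        mask = BinaryMask(state.mask, spacing.copy(), state.origin.copy())
        return (mask, info) if return_info else mask

    w_p = params.propagation_weight
    w_c = params.curvature_weight
    w_a = params.advection_weight

    gF = [
        _central(F, ax, spacing[ax]) if w_a > 0 else None for ax in range(3)
    ]

    # CFL bound combining the hyperbolic terms (first order in 1/h) and the
    # parabolic curvature term (1/h^2)
    if params.dt is not None:
        dt = float(params.dt)
    else:
        f_max = float(F.max())
        denom = w_p * f_max * float(np.sum(1.0 / spacing))
        if w_a > 0:
            denom += float(
                sum(np.abs(g).max() / h for g, h in zip(gF, spacing))
            ) * w_a
        denom += 2.0 * w_c * f_max * float(np.sum(1.0 / spacing**2))
        dt = params.cfl / denom if denom > 0 else params.cfl
    info["dt"] = dt

    band_mm = _BAND_VOXELS * float(spacing.max())
    phi = np.clip(state.phi, -band_mm, band_mm).astype(np.float64)

    for it in range(1, params.max_iterations + 1):
        dphi = np.zeros_like(phi)
        if w_p > 0:
            dphi -= w_p * F * _godunov_gradient_expand(phi, spacing)
        if w_c > 0:
            dphi += w_c * F * _curvature_times_gradient(phi, spacing)
        if w_a > 0:
            for ax in range(3):
                bwd, fwd = _one_sided(phi, ax, spacing[ax])
                # transport velocity is -grad F; take the upwind side
                d_up = np.where(gF[ax] < 0, bwd, fwd)
                dphi += w_a * gF[ax] * d_up
        phi_new = np.clip(phi + dt * dphi, -band_mm, band_mm)

        # convergence is judged at the front itself (voxels within one
        # voxel of the zero level), not in the far field where advection
        # keeps transporting phi without moving the contour
        band = np.abs(phi) < 1.5 * float(spacing.max())
        if band.any():
            rms = float(np.sqrt(np.mean((phi_new[band] - phi[band]) ** 2)))
        else:
            rms = 0.0
        info["rms"].append(rms)
        phi = phi_new
        state.iteration += 1
        info["iterations"] = it

        if it % params.reinit_interval == 0:
            phi = np.clip(_reinitialize(phi, spacing), -band_mm, band_mm)
        if rms < params.rms_tolerance:
            info["converged"] = True
            break

    state.phi = phi
    mask = BinaryMask(phi < 0, spacing.copy(), state.origin.copy())
    return (mask, info) if return_info else mask


def segment_nodule(
    volume: ImageVolume,
    seeds,
    texture_class: str = "solid",
    params: GacParams | None = None,
    config: SegmentationConfig | None = None,
    return_details: bool = False,
):
    """Full semiautomatic pipeline: crop, feature maps, fuse, evolve, paste.

    The volume is cropped to a 30 mm working cube about the seeds, the four
    feature maps are computed there (the density sigmoid midpoint chosen by
    texture class), min-pooled into the speed map, and the front evolved
    from seed spheres.  The result is restricted to the connected component
    containing a seed and pasted back onto the parent grid.  Deterministic
    for fixed inputs and configuration.
    """
    config = config or SegmentationConfig()
    params = params or config.gac
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed point is required")
    for s in seeds:
        if not volume.contains(s.position):
            raise ValueError(f"seed {s.position} lies outside the volume")

    center = SeedPoint(np.mean([s.position for s in seeds], axis=0))
    crop = crop_about_seed(volume, center, config.crop_radius_mm)
    sub = crop.volume

    maps = []
    if config.use_chest_wall_map:
        maps.append(
            chest_wall_map(sub, config.lung_threshold_hu, config.closing_radius_vox)
        )
    if config.use_vessel_map:
        maps.append(vesselness_map(sub, config.sato_scales_mm))
    if config.use_edge_map:
        maps.append(
            edge_interface_map(
                sub,
                sigma_mm=config.canny_sigma_mm,
                low_pct=config.canny_low_pct,
                high_pct=config.canny_high_pct,
            )
        )
    sigmoid = SigmoidParams(config.sigmoid_alpha, config.beta_for(texture_class))
    maps.append(density_map(sub, sigmoid))
    speed = fuse_speed_map(maps)

    state = initialize_front(seeds, sub, params.init_radius_mm)
    mask_crop = evolve(state, speed, params)

    data = mask_crop.data
    if data.any():
        labels, _ = ndimage.label(data)
        keep = set()
        for s in seeds:
            idx = np.round(sub.physical_to_index(s.position)).astype(int)
            idx = np.clip(idx, 0, np.array(sub.shape) - 1)
            lab = labels[tuple(idx)]
            if lab > 0:
                keep.add(int(lab))
        if keep:
            data = np.isin(labels, sorted(keep))
        else:
            warnings.warn(
                "no connected component contains a seed; returning an empty mask",
                stacklevel=2,
            )
            data = np.zeros_like(data)
    else:
        warnings.warn("segmentation is empty", stacklevel=2)
    mask_crop = BinaryMask(data, sub.spacing.copy(), sub.origin.copy())
    result = paste_mask(mask_crop, crop.voxel_offset, volume)
    if return_details:
        return result, {"speed": speed, "crop": crop, "maps": maps}
    return result
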