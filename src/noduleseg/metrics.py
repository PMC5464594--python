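"""Multi-reader robustness and agreement statistics for segmentations.

A *segmentation set* holds exactly four masks of one nodule produced by one
method — four radiologists contouring manually, or four algorithm runs each
seeded from one radiologist's contour centroid.  Two complementary views are
computed on such sets:

Robustness (within a method)
    * the **region of uncertainty** ``delta``: the physical volume of the
      union of the four masks minus their intersection.  ``delta = 0`` iff
      the four masks are identical (a perfectly robust method).
    * the **pairwise Dice stability index** ``dsi``: the mean Dice overlap
      over the six unordered pairs of the four masks, in percent; 100%
      again means perfect robustness.

Agreement (algorithm vs readers)
    * ``DSI_Agree``: the mean Dice of the four algorithm masks against a
      consensus reference built from the reader masks.  The reference is
      ambiguous between the readers' intersection and their union, so both
      variants are always computed and reported side by side.

Empty-mask convention: the Dice of two empty masks is 100% and of an empty
vs a non-empty mask 0% (identity of indiscernibles); results that relied on
this convention carry ``flagged=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .volume_io import BinaryMask, GridMismatchError, VolumeMeasure, mask_volume

__all__ = [
    "SegmentationSet",
    "RobustnessResult",
    "AgreementResult",
    "BlandAltmanResult",
    "dice_pct",
    "uncertainty_region",
    "pairwise_dsi",
    "agreement_dsi",
    "mean_volume",
    "robustness",
    "bland_altman",
]

SET_SIZE = 4  # a set is complete only with four contours of the nodule

_PAIRS = [(i, j) for i in range(SET_SIZE) for j in range(i + 1, SET_SIZE)]


@dataclass
class SegmentationSet:
    """Exactly four binary masks of one nodule on one grid."""

    masks: Sequence[BinaryMask]
    method: str = "manual"  # "manual" or "algorithm"

    def __post_init__(self) -> None:
        self.masks = tuple(self.masks)
        if len(self.masks) != SET_SIZE:
            raise ValueError(
                f"a SegmentationSet requires exactly {SET_SIZE} masks, "
                f"got {len(self.masks)}"
            )
        ref = self.masks[0]
        for k, m in enumerate(self.masks[1:], start=1):
            if not ref.grid_matches(m):
                raise GridMismatchError(f"mask {k} is not on the same grid as mask 0")

    @property
    def spacing(self) -> np.ndarray:
        return self.masks[0].spacing

    @property
    def voxel_volume_mm3(self) -> float:
        return self.masks[0].voxel_volume_mm3


@dataclass(frozen=True)
class RobustnessResult:
    delta: VolumeMeasure  # region of uncertainty
    dsi: float  # mean pairwise Dice, percent
    flagged: bool = False


@dataclass(frozen=True)
class AgreementResult:
    dsi_vs_intersection: float  # percent
    dsi_vs_union: float  # percent
    flagged: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    differences: np.ndarray  # a - b, per pair
    means: np.ndarray  # (a + b) / 2, per pair
    mean_difference: float
    sd_difference: float
    loa_lower: float  # mean - 1.96 sd
    loa_upper: float  # mean + 1.96 sd


def _dice_counts(n_a: int, n_b: int, n_ab: int) -> tuple[float, bool]:
    """Dice in percent from voxel counts, with the empty-set convention."""
    if n_a == 0 and n_b == 0:
        return 100.0, True
    if n_a == 0 or n_b == 0:
        return 0.0, True
    return 100.0 * n_ab / ((n_a + n_b) / 2.0), False


def dice_pct(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity of two masks in percent (empty-set convention applies)."""
    if not a.grid_matches(b):
        raise GridMismatchError("Dice requires both masks on one grid")
    n_ab = int(np.count_nonzero(a.data & b.data))
    value, _ = _dice_counts(a.voxel_count, b.voxel_count, n_ab)
    return value


def uncertainty_region(seg_set: SegmentationSet) -> VolumeMeasure:
    """Region of uncertainty ``delta``: volume(union) - volume(intersection).

    Zero iff the four masks coincide voxel-for-voxel.
    """
    stack = np.stack([m.data for m in seg_set.masks])
    union = stack.any(axis=0)
    inter = stack.all(axis=0)
    n = int(np.count_nonzero(union)) - int(np.count_nonzero(inter))
    return VolumeMeasure(n, n * seg_set.voxel_volume_mm3)


def pairwise_dsi(seg_set: SegmentationSet) -> tuple[float, bool]:
    """Mean Dice over the six unordered mask pairs, in percent.

    Returns ``(dsi, flagged)`` where ``flagged`` marks use of the
    empty-mask convention in any pair.
    """
    counts = [m.voxel_count for m in seg_set.masks]
    flagged = False
    total = 0.0
    for i, j in _PAIRS:
        n_ab = int(np.count_nonzero(seg_set.masks[i].data & seg_set.masks[j].data))
        term, used_convention = _dice_counts(counts[i], counts[j], n_ab)
        flagged = flagged or used_convention
        total += term
    return total / len(_PAIRS), flagged


def robustness(seg_set: SegmentationSet) -> RobustnessResult:
    """Convenience bundle of ``delta`` and ``dsi`` for one set."""
    dsi, flagged = pairwise_dsi(seg_set)
    return RobustnessResult(uncertainty_region(seg_set), dsi, flagged)


def agreement_dsi(
    algo_set: SegmentationSet, ref_set: SegmentationSet
) -> AgreementResult:
    """Mean Dice of the four algorithm masks against a reader consensus.

    The consensus reference is taken once as the readers' intersection and
    once as their union; both values are reported because the choice
    materially changes the number and neither is canonical.
    """
    if not algo_set.masks[0].grid_matches(ref_set.masks[0]):
        raise GridMismatchError("algorithm and reference sets must share a grid")
    ref_stack = np.stack([m.data for m in ref_set.masks])
    results = {}
    flagged = False
    for name, ref in (("intersection", ref_stack.all(axis=0)),
                      ("union", ref_stack.any(axis=0))):
        n_ref = int(np.count_nonzero(ref))
        total = 0.0
        for m in algo_set.masks:
            n_ab = int(np.count_nonzero(m.data & ref))
            term, used_convention = _dice_counts(m.voxel_count, n_ref, n_ab)
            flagged = flagged or used_convention
            total += term
        results[name] = total / SET_SIZE
    return AgreementResult(results["intersection"], results["union"], flagged)


def mean_volume(seg_set: SegmentationSet) -> VolumeMeasure:
    """Arithmetic mean of the four masks' physical volumes.

    With no ground truth available on real data, the mean of the four
    manual volumes stands in as the nodule-volume estimate.
    """
    measures = [mask_volume(m) for m in seg_set.masks]
    mean_n = sum(m.voxel_count for m in measures) / SET_SIZE
    mean_mm3 = sum(m.mm3 for m in measures) / SET_SIZE
    return VolumeMeasure(int(round(mean_n)), mean_mm3)


def bland_altman(v_a: Iterable[float], v_b: Iterable[float]) -> BlandAltmanResult:
    """Bland-Altman summary of paired volume estimates (a - b).

    Limits of agreement are ``mean_difference +/- 1.96 * sd`` where ``sd``
    is the sample standard deviation (ddof=1) of the differences; with a
    single pair or identical lists the sd is 0.
    """
    a = np.asarray(list(v_a), dtype=float)
    b = np.asarray(list(v_b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired lists must have equal length, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("bland_altman requires at least one pair")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return BlandAltmanResult(
        differences=diff,
        means=(a + b) / 2.0,
        mean_difference=mean_diff,
        sd_difference=sd,
        loa_lower=mean_diff - 1.96 * sd,
        loa_upper=mean_diff + 1.96 * sd,
    )
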