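import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import noduleseg as ns
from noduleseg.metrics import SegmentationSet

from _oracles import (
    brute_agreement,
    brute_pairwise_dsi,
    brute_uncertainty_voxels,
)
from conftest import cube_mask, random_mask_quadruple


def _set(masks, method="manual"):
    return SegmentationSet(masks, method)


def _const_masks(datas, spacing=(1, 1, 1)):
    return [ns.BinaryMask(d, spacing, (0, 0, 0)) for d in datas]


class TestUncertaintyRegion:
    def test_identical_masks_give_zero(self):
        m = cube_mask((6, 6, 6), (1, 1, 1), (4, 4, 4))
        delta = ns.uncertainty_region(_set([m, m, m, m]))
        assert delta.voxel_count == 0 and delta.mm3 == 0.0

    def test_disjoint_masks(self):
        masks = [cube_mask((8, 8, 8), (0, 0, 2 * k), (10, 1, 2 * k + 1)) for k in range(4)]
        for m in masks:
            assert m.voxel_count == 8  # sanity on the construction
        delta = ns.uncertainty_region(_set(masks))
        assert delta.voxel_count == 32

    def test_nested_masks_union_minus_intersection(self):
        sizes = [10, 20, 30, 40]
        datas = []
        for s in sizes:
            d = np.zeros((4, 4, 4), bool)
            d.flat[:s] = True
            datas.append(d)
        delta = ns.uncertainty_region(_set(_const_masks(datas)))
        assert delta.voxel_count == 40 - 10

    def test_physical_units(self):
        m0 = cube_mask((4, 4, 4), (0, 0, 0), (1, 1, 1), spacing=(2, 2, 2))
        m1 = cube_mask((4, 4, 4), (0, 0, 0), (2, 1, 1), spacing=(2, 2, 2))
        delta = ns.uncertainty_region(_set([m0, m0, m0, m1]))
        assert delta.mm3 == pytest.approx(1 * 8.0)


class TestPairwiseDsi:
    def test_identical_masks_100(self):
        m = cube_mask((6, 6, 6), (0, 0, 0), (3, 3, 3))
        dsi, flagged = ns.pairwise_dsi(_set([m] * 4))
        assert dsi == pytest.approx(100.0)
        assert not flagged

    def test_disjoint_masks_0(self):
        masks = [cube_mask((8, 8, 8), (0, 0, 2 * k), (8, 1, 2 * k + 1)) for k in range(4)]
        dsi, _ = ns.pairwise_dsi(_set(masks))
        assert dsi == pytest.approx(0.0)

    def test_three_quarters_example(self):
        # A = B = C = a 4-voxel cube, D = its 2-voxel half:
        # three pairs at 100%, three at 2/3 -> 83.33%
        full = cube_mask((4, 4, 4), (0, 0, 0), (1, 1, 4))
        half = cube_mask((4, 4, 4), (0, 0, 0), (1, 1, 2))
        dsi, _ = ns.pairwise_dsi(_set([full, full, full, half]))
        assert dsi == pytest.approx(250.0 / 3.0, abs=1e-10)

    def test_empty_set_conventions(self):
        empty = cube_mask((4, 4, 4), (0, 0, 0), (0, 0, 0))
        full = cube_mask((4, 4, 4), (0, 0, 0), (2, 2, 2))
        dsi_all_empty, flagged = ns.pairwise_dsi(_set([empty] * 4))
        assert dsi_all_empty == pytest.approx(100.0) and flagged
        dsi_mixed, flagged2 = ns.pairwise_dsi(_set([full, full, full, empty]))
        assert dsi_mixed == pytest.approx((3 * 100.0 + 3 * 0.0) / 6.0) and flagged2


class TestAgreementDsi:
    def test_identical_sets_100(self):
        m = cube_mask((6, 6, 6), (1, 1, 1), (4, 4, 4))
        res = ns.agreement_dsi(_set([m] * 4, "algorithm"), _set([m] * 4))
        assert res.dsi_vs_intersection == pytest.approx(100.0)
        assert res.dsi_vs_union == pytest.approx(100.0)

    def test_disjoint_sets_0(self):
        a = cube_mask((8, 8, 8), (0, 0, 0), (2, 2, 2))
        b = cube_mask((8, 8, 8), (4, 4, 4), (6, 6, 6))
        res = ns.agreement_dsi(_set([a] * 4, "algorithm"), _set([b] * 4))
        assert res.dsi_vs_intersection == 0.0 and res.dsi_vs_union == 0.0

    def test_half_cube_example(self):
        # algo = four copies of an 8-voxel cube, refs = four copies of its
        # 4-voxel half: both references equal the half -> 4/((8+4)/2) = 66.67%
        algo = cube_mask((4, 4, 4), (0, 0, 0), (2, 2, 2))
        ref = cube_mask((4, 4, 4), (0, 0, 0), (1, 2, 2))
        res = ns.agreement_dsi(_set([algo] * 4, "algorithm"), _set([ref] * 4))
        assert res.dsi_vs_intersection == pytest.approx(200.0 / 3.0, abs=1e-10)
        assert res.dsi_vs_union == pytest.approx(200.0 / 3.0, abs=1e-10)


class TestMeanVolume:
    def test_equal_volumes(self):
        d = np.zeros((5, 5, 5), bool)
        d.flat[:100] = True
        m = ns.BinaryMask(d, (1, 1, 1), (0, 0, 0))
        assert ns.mean_volume(_set([m] * 4)).mm3 == pytest.approx(100.0)

    def test_arithmetic_mean(self):
        empty = np.zeros((8, 8, 8), bool)
        full = np.zeros((8, 8, 8), bool)
        full.flat[:400] = True
        masks = _const_masks([empty, empty, empty, full])
        assert ns.mean_volume(_set(masks)).mm3 == pytest.approx(100.0)

    def test_recount_on_random_masks(self):
        rng = np.random.default_rng(3)
        masks = random_mask_quadruple(rng, spacing=(2.0, 1.0, 0.5))
        expected = sum(m.voxel_count for m in masks) / 4.0 * 1.0
        assert ns.mean_volume(_set(masks)).mm3 == pytest.approx(expected)


class TestOracleEquivalence:
    def test_random_quadruples_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            masks = random_mask_quadruple(rng)
            arrays = [m.data for m in masks]
            s = _set(masks)
            assert ns.uncertainty_region(s).voxel_count == brute_uncertainty_voxels(arrays)
            dsi, _ = ns.pairwise_dsi(s)
            assert dsi == pytest.approx(brute_pairwise_dsi(arrays), abs=1e-9)
            ref = _set(random_mask_quadruple(rng))
            res = ns.agreement_dsi(s, ref)
            bi, bu = brute_agreement(arrays, [m.data for m in ref.masks])
            assert res.dsi_vs_intersection == pytest.approx(bi, abs=1e-9)
            assert res.dsi_vs_union == pytest.approx(bu, abs=1e-9)

    def test_nearest_neighbour_upsampling_preserves_overlap_metrics(self):
        rng = np.random.default_rng(13)
        masks = random_mask_quadruple(rng)
        up = [
            ns.BinaryMask(
                np.repeat(np.repeat(np.repeat(m.data, 2, 0), 2, 1), 2, 2),
                (0.5, 0.5, 0.5),
                (0, 0, 0),
            )
            for m in masks
        ]
        dsi_lo, _ = ns.pairwise_dsi(_set(masks))
        dsi_hi, _ = ns.pairwise_dsi(_set(up))
        assert dsi_hi == pytest.approx(dsi_lo, abs=1e-9)
        d_lo = ns.uncertainty_region(_set(masks))
        d_hi = ns.uncertainty_region(_set(up))
        assert d_hi.mm3 == pytest.approx(d_lo.mm3, abs=1e-9)  # 8x voxels, 1/8 volume


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=hst.integers(0, 10_000), perm=hst.permutations(range(4)))
def test_metrics_bounded_and_permutation_invariant(seed, perm):
    rng = np.random.default_rng(seed)
    masks = random_mask_quadruple(rng, shape=(6, 6, 6))
    s = _set(masks)
    s_perm = _set([masks[i] for i in perm])
    dsi, _ = ns.pairwise_dsi(s)
    dsi_p, _ = ns.pairwise_dsi(s_perm)
    assert 0.0 <= dsi <= 100.0
    assert dsi == pytest.approx(dsi_p, abs=1e-12)
    d = ns.uncertainty_region(s)
    assert d.voxel_count >= 0
    assert d.voxel_count == ns.uncertainty_region(s_perm).voxel_count
    identical = all(np.array_equal(masks[0].data, m.data) for m in masks)
    assert (d.voxel_count == 0) == identical


def test_set_requires_exactly_four_masks_on_one_grid():
    m = cube_mask((4, 4, 4), (0, 0, 0), (2, 2, 2))
    with pytest.raises(ValueError):
        _set([m, m, m])
    other = cube_mask((4, 4, 4), (0, 0, 0), (2, 2, 2), spacing=(2, 2, 2))
    with pytest.raises(Exception):
        _set([m, m, m, other])


class TestBlandAltman:
    def test_identical_lists(self):
        res = ns.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_constant_offset(self):
        res = ns.bland_altman([1.0, 2.0, 3.0], [6.0, 7.0, 8.0])
        assert res.mean_difference == pytest.approx(-5.0)
        assert res.sd_difference == pytest.approx(0.0)

    def test_limits_match_recomputation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(100, 10, 40)
        b = a + rng.normal(5, 3, 40)
        res = ns.bland_altman(a, b)
        d = a - b
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ns.bland_altman([1.0, 2.0], [1.0])
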