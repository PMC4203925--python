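"""Cut-off rules, dose-level binning, and degenerate-substructure handling."""

import numpy as np
import pytest

from dosepaint.core import ImageGrid, ROIMask, SUVVolume
from dosepaint.segmentation import (
    EmptySubvolumeWarning,
    ThresholdSpec,
    build_dose_levels,
    check_substructure_validity,
    compute_cutoff,
    drop_degenerate_levels,
)

from conftest import random_case


def brute_force_level_counts(volume, gtv, cutoff_suv, n_levels):
    """Independent per-voxel loop applying the bin rule directly."""
    max_suv = volume.values[gtv.member].max()
    boundaries = np.linspace(cutoff_suv / max_suv * 100.0, 100.0, n_levels + 1)
    counts = [0] * n_levels
    for idx in np.ndindex(*volume.grid.shape):
        if not gtv.member[idx] or volume.values[idx] < cutoff_suv:
            continue
        u = volume.values[idx] / max_suv * 100.0
        for k in range(n_levels):
            closed_top = k == n_levels - 1
            if boundaries[k] <= u < boundaries[k + 1] or (closed_top and u == 100.0):
                counts[k] += 1
                break
    return counts


def uniform_case(grid, values_flat):
    values = np.asarray(values_flat, float).reshape(grid.shape)
    gtv = ROIMask(grid=grid, member=np.ones(grid.shape, bool), label="GTV")
    return SUVVolume(grid=grid, values=values), gtv


class TestComputeCutoff:
    def test_percent_of_max(self):
        grid = ImageGrid(shape=(2, 2, 2))
        vol, gtv = uniform_case(grid, [1, 2, 3, 4, 5, 6, 7, 7.9])
        cut = compute_cutoff(vol, gtv, ThresholdSpec("percent_max", 40))
        assert cut == pytest.approx(3.16)

    def test_absolute_value_passes_through(self, small_phantom):
        cut = compute_cutoff(
            small_phantom.tracer_b, small_phantom.gtv, ThresholdSpec("absolute_suv", 1.4)
        )
        assert cut == 1.4

    def test_tumor_to_muscle_scales_muscle_mean(self, small_phantom):
        case = small_phantom
        spec = ThresholdSpec("tumor_to_muscle", 2.0)
        cut = compute_cutoff(case.tracer_b, case.gtv, spec, muscle=case.muscle)
        assert cut == pytest.approx(
            2.0 * case.tracer_b.values[case.muscle.member].mean()
        )

    def test_tumor_to_muscle_requires_muscle(self, small_phantom):
        with pytest.raises(ValueError, match="muscle"):
            compute_cutoff(
                small_phantom.tracer_b,
                small_phantom.gtv,
                ThresholdSpec("tumor_to_muscle", 2.0),
            )

    def test_percent_100_returns_exact_max(self):
        grid = ImageGrid(shape=(2, 2, 2))
        vol, gtv = uniform_case(grid, [1, 2, 3, 4, 5, 6, 7, 7.9])
        assert compute_cutoff(vol, gtv, ThresholdSpec("percent_max", 100)) == 7.9

    def test_cutoff_above_max_warns_empty_subvolume(self):
        grid = ImageGrid(shape=(2, 2, 2))
        vol, gtv = uniform_case(grid, [1] * 8)
        with pytest.warns(EmptySubvolumeWarning):
            compute_cutoff(vol, gtv, ThresholdSpec("absolute_suv", 5.0))

    def test_empty_gtv_rejected(self, grid8):
        vol = SUVVolume(grid=grid8, values=np.ones(grid8.shape))
        empty = ROIMask(grid=grid8, member=np.zeros(grid8.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            compute_cutoff(vol, empty, ThresholdSpec("percent_max", 40))

    @pytest.mark.parametrize(
        "method,value",
        [("percent_max", 0), ("percent_max", 101), ("absolute_suv", -1), ("bogus", 40)],
    )
    def test_invalid_spec_rejected(self, method, value):
        with pytest.raises(ValueError):
            ThresholdSpec(method, value)


class TestBuildDoseLevels:
    def test_equal_bins_between_cutoff_and_max(self):
        grid = ImageGrid(shape=(3, 3, 3))
        vol, gtv = uniform_case(grid, np.linspace(1, 10, 27))
        levels = build_dose_levels(vol, gtv, cutoff_suv=4.0, n_levels=5)
        np.testing.assert_allclose(levels.boundaries_pct, [40, 52, 64, 76, 88, 100])
        np.testing.assert_allclose(levels.iso_pct, [46, 58, 70, 82, 94])
        assert levels.cutoff_pct == pytest.approx(40.0)

    def test_iso_is_midpoint_of_boundaries(self, small_phantom):
        import dosepaint as dp

        case = small_phantom
        cut = compute_cutoff(case.tracer_a, case.gtv, ThresholdSpec("percent_max", 40))
        levels = build_dose_levels(case.tracer_a, case.gtv, cut, n_levels=7)
        np.testing.assert_allclose(
            levels.iso_pct,
            (levels.boundaries_pct[:-1] + levels.boundaries_pct[1:]) / 2,
        )

    def test_single_bin_collects_all_superthreshold_voxels(self):
        grid = ImageGrid(shape=(3, 3, 3))
        vol, gtv = uniform_case(grid, np.linspace(1, 10, 27))
        levels = build_dose_levels(vol, gtv, cutoff_suv=5.0, n_levels=1)
        expected = (vol.values >= 5.0).sum()
        assert levels.level_masks[0].voxel_count == expected

    def test_unique_max_voxel_lands_in_top_level(self, rng, grid8):
        vol, gtv = random_case(rng, grid8)
        argmax = np.unravel_index(
            np.where(gtv.member.ravel(), vol.values.ravel(), -1).argmax(), grid8.shape
        )
        levels = build_dose_levels(vol, gtv, cutoff_suv=1.0, n_levels=5)
        assert levels.level_masks[-1].member[argmax]

    def test_cutoff_at_or_above_max_rejected(self):
        grid = ImageGrid(shape=(2, 2, 2))
        vol, gtv = uniform_case(grid, [1, 2, 3, 4, 5, 6, 7, 8])
        with pytest.raises(ValueError, match="empty high-risk"):
            build_dose_levels(vol, gtv, cutoff_suv=8.0, n_levels=5)

    def test_partition_matches_brute_force(self, rng, grid8):
        for _ in range(10):
            vol, gtv = random_case(rng, grid8)
            cutoff = 0.4 * vol.values[gtv.member].max()
            levels = build_dose_levels(vol, gtv, cutoff, n_levels=5)
            assert levels.level_voxel_counts() == brute_force_level_counts(
                vol, gtv, cutoff, 5
            )
            union = np.zeros(grid8.shape, bool)
            for m in levels.level_masks:
                assert not (union & m.member).any(), "levels overlap"
                union |= m.member
            np.testing.assert_array_equal(
                union, gtv.member & (vol.values >= cutoff)
            )

    def test_monotone_nesting_reproduces_superthreshold_sets(self, rng, grid8):
        vol, gtv = random_case(rng, grid8)
        cutoff = 0.3 * vol.values[gtv.member].max()
        levels = build_dose_levels(vol, gtv, cutoff, n_levels=5)
        max_suv = levels.max_suv
        for k in range(5):
            cum = np.any([m.member for m in levels.level_masks[k:]], axis=0)
            thresh = levels.boundaries_pct[k] / 100.0 * max_suv
            np.testing.assert_array_equal(cum, gtv.member & (vol.values >= thresh))

    def test_percent_cutoff_is_scale_equivariant(self, rng, grid8):
        vol, gtv = random_case(rng, grid8)
        spec = ThresholdSpec("percent_max", 40)
        cut1 = compute_cutoff(vol, gtv, spec)
        scaled = SUVVolume(grid=grid8, values=vol.values * 3.5)
        cut2 = compute_cutoff(scaled, gtv, spec)
        assert cut2 == pytest.approx(3.5 * cut1)
        lev1 = build_dose_levels(vol, gtv, cut1, n_levels=5)
        lev2 = build_dose_levels(scaled, gtv, cut2, n_levels=5)
        for m1, m2 in zip(lev1.level_masks, lev2.level_masks):
            np.testing.assert_array_equal(m1.member, m2.member)


class TestSubstructureValidity:
    def test_multi_slice_mask_is_valid(self, grid8):
        member = np.zeros(grid8.shape, bool)
        member[2, 2, 1:4] = True
        v = check_substructure_validity(ROIMask(grid=grid8, member=member))
        assert v.valid and v.axial_slices == 3

    def test_single_slice_mask_is_invalid(self, grid8):
        member = np.zeros(grid8.shape, bool)
        member[1:5, 1:5, 3] = True
        v = check_substructure_validity(ROIMask(grid=grid8, member=member))
        assert not v.valid and v.axial_slices == 1

    def test_empty_mask_is_invalid(self, grid8):
        v = check_substructure_validity(
            ROIMask(grid=grid8, member=np.zeros(grid8.shape, bool))
        )
        assert not v.valid and v.axial_slices == 0


def crafted_levels(grid, top_single_slice=True):
    """A volume whose DP5 occupies one axial slice (and DP1-4 several)."""
    values = np.ones(grid.shape)
    values[1, 1, 1:5] = 4.5   # DP1 zone (40-52% of max 10)
    values[2, 2, 1:5] = 5.5   # DP2
    values[3, 3, 1:5] = 6.5   # DP3
    values[4, 4, 1:5] = 7.8   # DP4
    if top_single_slice:
        values[5, 5, 3] = 9.5  # DP5 on one slice
        values[5, 6, 3] = 10.0
    else:
        values[5, 5, 2:5] = 9.5
        values[5, 6, 3] = 10.0
    gtv = ROIMask(grid=grid, member=np.ones(grid.shape, bool), label="GTV")
    vol = SUVVolume(grid=grid, values=values)
    return vol, gtv, build_dose_levels(vol, gtv, cutoff_suv=4.0, n_levels=5)


class TestDropDegenerateLevels:
    def test_single_slice_top_level_merges_downward(self, grid8):
        vol, gtv, levels = crafted_levels(grid8, top_single_slice=True)
        before = levels.level_voxel_counts()
        dropped = drop_degenerate_levels(levels)
        assert dropped.dropped_levels == [5]
        after = dropped.level_voxel_counts()
        assert after[4] == 0
        assert after[3] == before[3] + before[4]
        assert sum(after) == sum(before)

    def test_no_degenerate_levels_is_identity(self, grid8):
        _, _, levels = crafted_levels(grid8, top_single_slice=False)
        out = drop_degenerate_levels(levels)
        assert out.dropped_levels == []
        for a, b in zip(out.level_masks, levels.level_masks):
            np.testing.assert_array_equal(a.member, b.member)

    def test_all_levels_degenerate_reverts_to_base(self, grid8):
        values = np.ones(grid8.shape)
        values[2, 2, 3] = 10.0
        values[3, 3, 3] = 9.0
        gtv = ROIMask(grid=grid8, member=np.ones(grid8.shape, bool))
        vol = SUVVolume(grid=grid8, values=values)
        levels = build_dose_levels(vol, gtv, cutoff_suv=8.0, n_levels=5)
        dropped = drop_degenerate_levels(levels)
        assert dropped.dropped_levels == [1, 2, 3, 4, 5]
        assert sum(dropped.level_voxel_counts()) == 0

    def test_merge_skips_invalid_intermediate_levels(self, grid8):
        # DP4 and DP5 both single-slice: both merge into DP3
        values = np.ones(grid8.shape)
        values[1, 1, 1:5] = 4.5
        values[2, 2, 1:5] = 5.5
        values[3, 3, 1:5] = 6.5
        values[4, 4, 3] = 7.8
        values[5, 5, 3] = 10.0
        gtv = ROIMask(grid=grid8, member=np.ones(grid8.shape, bool))
        vol = SUVVolume(grid=grid8, values=values)
        levels = build_dose_levels(vol, gtv, cutoff_suv=4.0, n_levels=5)
        before = levels.level_voxel_counts()
        dropped = drop_degenerate_levels(levels)
        assert dropped.dropped_levels == [4, 5]
        after = dropped.level_voxel_counts()
        assert after[2] == before[2] + before[3] + before[4]
        assert after[3] == after[4] == 0
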