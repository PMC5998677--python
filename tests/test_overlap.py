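"""Overlap metrics: accuracy, between-/within-subject, CV%, tissue makeup."""

import numpy as np
import pytest

from avp.geometry import Angulation, VoxelSpec
from avp.image import ImageVolume
from avp.overlap import (
    AcquiredVoxel,
    accuracy,
    between_subject_overlap,
    cv_percent,
    tissue_fractions,
    within_subject_overlap,
)
from avp.rasterize import Grid, VoxelMask, rasterize_voxel, threshold_table

T = 0.65


def toy_grid(n=20):
    return Grid(shape=(n, n, 1), spacing=(0.5, 0.5, 0.5),
                origin=(-n / 4, -n / 4, -0.25))


def block_mask(grid, i0, i1, j0, j1):
    """A binary rectangular mask on a toy grid."""
    v = np.zeros(grid.shape)
    v[i0:i1, j0:j1, 0] = 1.0
    return VoxelMask(v, grid)


def brute_force_metric(numerator_masks, denominator_mask, t):
    """Exhaustive per-pixel oracle shared by all three overlap metrics."""
    mean = sum(m.values for m in numerator_masks) / len(numerator_masks)
    num = 0
    den = 0
    for idx in np.ndindex(mean.shape):
        if mean[idx] > t:
            num += 1
        if denominator_mask.values[idx] > t:
            den += 1
    return 100.0 * num / den


class TestAccuracy:
    def test_identical_masks_give_exactly_100(self):
        g = toy_grid()
        m = block_mask(g, 4, 12, 4, 12)
        assert accuracy(m, m, T) == 100.0

    def test_disjoint_masks_give_zero_above_half(self):
        g = toy_grid()
        a = block_mask(g, 0, 5, 0, 5)
        b = block_mask(g, 10, 15, 10, 15)
        assert accuracy(a, b, T) == 0.0

    def test_matches_brute_force_on_shifted_masks(self):
        g = toy_grid()
        tmpl = block_mask(g, 4, 12, 4, 12)
        subj = block_mask(g, 6, 14, 5, 13)
        assert accuracy(subj, tmpl, T) == pytest.approx(
            brute_force_metric([subj, tmpl], tmpl, T)
        )

    def test_empty_template_superlevel_rejected(self):
        g = toy_grid()
        empty = VoxelMask(np.zeros(g.shape), g)
        with pytest.raises(ValueError):
            accuracy(block_mask(g, 0, 4, 0, 4), empty, T)

    def test_mismatched_grids_rejected(self):
        a = block_mask(toy_grid(20), 0, 4, 0, 4)
        b = block_mask(toy_grid(24), 0, 4, 0, 4)
        with pytest.raises(ValueError):
            accuracy(a, b, T)


class TestBetweenSubject:
    def test_all_identical_masks_give_100_for_any_n(self):
        g = toy_grid()
        m = block_mask(g, 4, 12, 4, 12)
        for n in (1, 2, 5):
            assert between_subject_overlap([m] * n, m, T) == 100.0

    def test_single_mask_reduces_to_accuracy_construction(self):
        g = toy_grid()
        tmpl = block_mask(g, 4, 12, 4, 12)
        subj = block_mask(g, 6, 14, 5, 13)
        got = between_subject_overlap([subj], tmpl, T)
        assert got == pytest.approx(brute_force_metric([subj], tmpl, T))

    def test_three_shifted_masks_match_brute_force(self):
        g = toy_grid()
        tmpl = block_mask(g, 4, 12, 4, 12)
        masks = [block_mask(g, 4 + d, 12 + d, 4, 12) for d in (0, 1, 2)]
        got = between_subject_overlap(masks, tmpl, T)
        assert got == pytest.approx(brute_force_metric(masks, tmpl, T))

    def test_permutation_invariance(self):
        g = toy_grid()
        tmpl = block_mask(g, 4, 12, 4, 12)
        masks = [block_mask(g, 4 + d, 12 + d, 4 + d, 12 + d)
                 for d in (0, 1, 2)]
        fwd = between_subject_overlap(masks, tmpl, T)
        rev = between_subject_overlap(masks[::-1], tmpl, T)
        assert fwd == rev

    def test_empty_list_rejected(self):
        g = toy_grid()
        with pytest.raises(ValueError):
            between_subject_overlap([], block_mask(g, 4, 12, 4, 12), T)


class TestWithinSubject:
    def test_identical_timepoints_against_self_denominator(self):
        g = toy_grid()
        m = block_mask(g, 4, 12, 4, 12)
        assert within_subject_overlap([m, m], m, T) == 100.0

    def test_disjoint_timepoints_give_zero(self):
        g = toy_grid()
        a = block_mask(g, 0, 5, 0, 5)
        b = block_mask(g, 10, 15, 10, 15)
        assert within_subject_overlap([a, b], a, T) == 0.0

    def test_one_pixel_shift_matches_brute_force(self):
        g = toy_grid()
        a = block_mask(g, 4, 12, 4, 12)
        b = block_mask(g, 5, 13, 4, 12)
        got = within_subject_overlap([a, b], a, T)
        assert got == pytest.approx(brute_force_metric([a, b], a, T))

    def test_single_timepoint_rejected(self):
        g = toy_grid()
        m = block_mask(g, 4, 12, 4, 12)
        with pytest.raises(ValueError):
            within_subject_overlap([m], m, T)


class TestCvPercent:
    def test_constant_values_give_zero(self):
        assert cv_percent([5.0, 5.0, 5.0]) == 0.0

    def test_closed_form_sd_over_mean(self):
        # sd({1,2,3}) = 1 (n-1 denominator), mean = 2
        assert cv_percent([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([10.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([-1.0, 1.0])


class TestTissueFractions:
    def grid_and_mask(self):
        g = Grid(shape=(16, 16, 16), spacing=(0.5, 0.5, 0.5),
                 origin=(-4, -4, -4))
        v = np.zeros(g.shape)
        v[4:12, 4:12, 4:12] = 1.0
        return g, VoxelMask(v, g)

    def uniform_pve(self, g, gm, wm, csf):
        affine = g.affine
        shape = (12, 12, 12)
        a = affine.copy()
        return {
            "gm": ImageVolume(np.full(shape, gm), a),
            "wm": ImageVolume(np.full(shape, wm), a),
            "csf": ImageVolume(np.full(shape, csf), a),
        }

    def test_pure_gray_matter(self):
        g, mask = self.grid_and_mask()
        fr = tissue_fractions(self.uniform_pve(g, 1.0, 0.0, 0.0), mask, T)
        assert fr["gm"] == pytest.approx(100.0)
        assert fr["wm"] == 0.0 and fr["csf"] == 0.0

    def test_half_gray_half_white(self):
        g, mask = self.grid_and_mask()
        fr = tissue_fractions(self.uniform_pve(g, 0.5, 0.5, 0.0), mask, T)
        assert fr["gm"] == pytest.approx(50.0)
        assert fr["wm"] == pytest.approx(50.0)

    def test_fractions_conserve_to_100(self):
        g, mask = self.grid_and_mask()
        fr = tissue_fractions(self.uniform_pve(g, 0.55, 0.4, 0.05), mask, T)
        assert sum(fr.values()) == pytest.approx(100.0, abs=0.5)

    def test_empty_region_rejected(self):
        g, _ = self.grid_and_mask()
        empty = VoxelMask(np.zeros(g.shape), g)
        with pytest.raises(ValueError):
            tissue_fractions(self.uniform_pve(g, 1, 0, 0), empty, T)


class TestFigureArithmetic:
    """The worked 2D example: a rotated 6 x 6 mm voxel on the 0.5 mm grid."""

    def test_percent_total_voxel_from_printed_areas(self):
        # masks engineered to the printed superlevel areas (mm^2, one slab):
        # 37 above 0.60, 34 above 0.65, 32 above 0.70
        g = Grid(shape=(16, 16, 1), spacing=(0.5, 0.5, 1.0),
                 origin=(-4, -4, -0.5))
        v = np.zeros(g.shape)
        areas = {0.72: 32.0, 0.67: 2.0, 0.62: 3.0}  # cumulative 32, 34, 37
        flat = v.reshape(-1)
        start = 0
        for val, area in areas.items():
            n = int(round(area / 0.25))
            flat[start:start + n] = val
            start += n
        mask = VoxelMask(flat.reshape(g.shape), g)
        table = threshold_table(mask, [0.60, 0.65, 0.70],
                                nominal_volume=36.0)
        assert table.percent_total[0] == pytest.approx(102.8, abs=0.1)
        assert table.percent_total[1] == pytest.approx(94.4, abs=0.1)
        assert table.percent_total[2] == pytest.approx(88.9, abs=0.1)

    def test_accuracy_from_printed_areas(self):
        # template superlevel 34 mm^2; averaged overlap superlevel 31 mm^2
        g = Grid(shape=(16, 16, 1), spacing=(0.5, 0.5, 1.0),
                 origin=(-4, -4, -0.5))
        tmpl = np.zeros(g.shape)
        subj = np.zeros(g.shape)
        tmpl.reshape(-1)[:136] = 1.0            # 34 mm^2
        subj.reshape(-1)[:124] = 1.0            # overlapping 31 mm^2
        subj.reshape(-1)[136:148] = 1.0         # remainder elsewhere
        got = accuracy(VoxelMask(subj, g), VoxelMask(tmpl, g), T)
        assert got == pytest.approx(91.1, abs=0.1)


class TestPipelineEcho:
    def test_sidecar_roundtrip_preserves_masks_bit_for_bit(self, tmp_path):
        """Metrics from written-then-reread acquisition specs are identical."""
        from avp.io import read_acquired_voxel, write_sidecar

        spec = VoxelSpec("demo", "l_dlpfc", (15, 20, 15), (32.1, 24.9, 22.6),
                         Angulation(7.3, 19.8, 15.2))
        av = AcquiredVoxel("sub-01", "baseline", spec)
        p = tmp_path / "voxel.json"
        write_sidecar(av, p)
        back = read_acquired_voxel(p)
        assert back.spec == spec
        grid = Grid.for_spec(spec, margin=4.0)
        m1 = rasterize_voxel(spec, grid)
        m2 = rasterize_voxel(back.spec, grid)
        assert np.array_equal(m1.values, m2.values)
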