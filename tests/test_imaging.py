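"""Projections, segmentation, masking, and the cytosolic-fraction measure."""

import dataclasses
import warnings

import numpy as np
import pytest

from abpcensus import imaging, synth
from abpcensus.errors import UndefinedFractionError, ValidationError


def _stack_from(voxels, z_step=0.2, pixel_size=0.065):
    return synth.ImageStack(np.asarray(voxels, float), z_step, pixel_size)


@pytest.fixture(scope="module")
def patch_cell():
    # standard acquisition geometry (35 slices, 2.25 µm radius)
    params = dataclasses.replace(
        synth.SynthParams(), n_structures=6, target_fraction=0.75, seed=7,
    )
    stack, truth = synth.generate_cell_stack(params)
    return params, stack, truth


class TestProject:
    def test_constant_stack_projects_to_the_constant(self):
        stack = _stack_from(np.full((2, 4, 8, 8), 3.0))
        for mode in ("average", "maximum"):
            proj = imaging.project(stack, 0, mode)
            assert np.allclose(proj.pixels, 3.0)

    def test_single_slice_is_identity(self):
        vox = np.random.default_rng(0).uniform(0, 10, size=(2, 1, 6, 6))
        stack = _stack_from(vox)
        proj = imaging.project(stack, 1, "maximum")
        assert np.allclose(proj.pixels, vox[1, 0])

    def test_two_slice_average_and_maximum(self):
        vox = np.zeros((2, 2, 3, 3))
        vox[0, 0], vox[0, 1] = 1.0, 3.0
        stack = _stack_from(vox)
        assert np.allclose(imaging.project(stack, 0, "average").pixels, 2.0)
        assert np.allclose(imaging.project(stack, 0, "maximum").pixels, 3.0)

    def test_average_never_exceeds_maximum(self, patch_cell):
        _, stack, _ = patch_cell
        avg = imaging.project(stack, 0, "average").pixels
        mx = imaging.project(stack, 0, "maximum").pixels
        assert np.all(avg <= mx + 1e-9)

    def test_bad_mode_rejected(self, patch_cell):
        with pytest.raises(ValidationError):
            imaging.project(patch_cell[1], 0, "median")


class TestSegmentCells:
    def test_single_cell_mask_overlaps_ground_truth(self, patch_cell):
        _, stack, truth = patch_cell
        cells = imaging.segment_cells(imaging.project(stack, 0, "average"))
        assert len(cells) == 1
        gt2d = truth.cell_mask.any(axis=0)
        overlap = (cells[0].mask & gt2d).sum() / gt2d.sum()
        assert overlap >= 0.95

    def test_blank_image_finds_nothing(self):
        stack = _stack_from(np.random.default_rng(1).normal(2, 0.5, (2, 5, 64, 64)).clip(0))
        with pytest.warns(UserWarning):
            cells = imaging.segment_cells(imaging.project(stack, 0, "average"))
        assert cells == []

    def test_two_well_separated_cells_found(self, patch_cell):
        _, stack, _ = patch_cell
        # tile the same cell twice along x with a dark gap between
        vox = stack.voxels
        gap = np.zeros((2, vox.shape[1], vox.shape[2], 12))
        double = np.concatenate([vox, gap, vox], axis=3)
        cells = imaging.segment_cells(
            imaging.project(_stack_from(double), 0, "average")
        )
        assert len(cells) == 2

    def test_plug_in_segmenter_is_used(self, patch_cell):
        _, stack, truth = patch_cell
        gt2d = truth.cell_mask.any(axis=0).astype(int)
        cells = imaging.segment_cells(
            imaging.project(stack, 0, "average"), segmenter=lambda img: gt2d
        )
        assert len(cells) == 1
        assert cells[0].area_px == gt2d.sum()


class TestBackground:
    def test_zero_autofluorescence_measures_zero(self, small_params):
        p = dataclasses.replace(small_params, autofluorescence=0.0,
                                read_noise_sd=0.0, poisson_gain=0.0,
                                structure_kind="none", cytosol_intensity=0.0,
                                target_fraction=None)
        stack, _ = synth.generate_cell_stack(p)
        # nothing to segment in a dark image -> background defaults to 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bg = imaging.estimate_background([imaging.project(stack, 0, "average")])
        assert bg == pytest.approx(0.0, abs=1e-6)

    def test_autofluorescent_cells_measured_near_truth(self, small_params):
        p = dataclasses.replace(small_params, autofluorescence=20.0,
                                structure_kind="none", cytosol_intensity=0.0,
                                target_fraction=None)
        stack, _ = synth.generate_cell_stack(p)
        bg = imaging.estimate_background([imaging.project(stack, 0, "average")])
        # the projected mean of an in-cell autofluorescence field is below the
        # per-voxel level (columns shorter than the stack): accept 8..20
        assert 8.0 < bg < 20.0


class TestStructureMask:
    def test_zero_set_point_masks_everything(self):
        img = np.random.default_rng(0).uniform(1, 5, (16, 16))
        assert imaging.make_structure_mask(img, 0.0).all()

    def test_set_point_above_maximum_gives_empty_mask(self):
        img = np.full((8, 8), 5.0)
        with pytest.warns(UserWarning):
            mask = imaging.make_structure_mask(img, 10.0)
        assert not mask.any()

    def test_mask_monotone_shrinking_in_set_point(self, patch_cell):
        _, stack, _ = patch_cell
        marker = imaging.project(stack, 1, "maximum")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = [imaging.make_structure_mask(marker, sp) for sp in (10, 50, 150)]
        assert masks[0].sum() >= masks[1].sum() >= masks[2].sum()
        assert not (masks[2] & ~masks[1]).any()  # nested

    def test_mask_covers_ground_truth_structures(self, patch_cell):
        _, stack, truth = patch_cell
        marker = imaging.project(stack, 1, "maximum")
        cells = imaging.segment_cells(imaging.project(stack, 0, "average"))
        sp = imaging.auto_set_point(marker, cells[0].mask)
        mask = imaging.make_structure_mask(marker, sp,
                                           dilate_px=imaging.DEFAULT_MASK_DILATE_PX)
        gt2d = truth.structure_voxel_set.any(axis=0)
        assert (mask & gt2d).sum() / gt2d.sum() >= 0.95


class TestCytosolicFraction:
    def test_uniform_cell_has_fraction_one(self):
        img = np.full((32, 32), 7.0)
        cell = np.zeros((32, 32), bool)
        cell[4:28, 4:28] = True
        struct = np.zeros_like(cell)
        struct[10:14, 10:14] = True
        res = imaging.cytosolic_fraction(img, cell, struct)
        assert res.cytosolic_fraction == pytest.approx(1.0)
        assert not res.flagged

    def test_recovers_ground_truth_within_tolerance(self, patch_cell):
        """With autofluorescence background measured on label-free cells and
        subtracted (as the protocol prescribes), the median recovery error
        over a handful of cells stays within 0.05 of the 0.75 ground truth."""
        params, _, _ = patch_cell
        bg_params = dataclasses.replace(
            params, cytosol_intensity=0.0, structure_kind="none",
            target_fraction=None,
        )
        bg_stack, _ = synth.generate_cell_stack(bg_params)
        background = imaging.estimate_background(
            [imaging.project(bg_stack, 0, "average")]
        )
        errors = []
        for seed in range(5):
            stack, truth = synth.generate_cell_stack(
                dataclasses.replace(params, seed=seed)
            )
            rows = imaging.measure_stack(stack, background=background)
            assert len(rows) == 1
            errors.append(rows[0]["cytosolic_fraction"] - truth.true_cytosolic_fraction)
        assert abs(float(np.median(errors))) < 0.05

    def test_structure_mask_covering_cell_is_undefined(self):
        img = np.full((16, 16), 5.0)
        cell = np.ones((16, 16), bool)
        with pytest.raises(UndefinedFractionError):
            imaging.cytosolic_fraction(img, cell, cell)

    def test_nonpositive_cell_mean_after_background_rejected(self):
        img = np.full((16, 16), 5.0)
        cell = np.ones((16, 16), bool)
        struct = np.zeros_like(cell)
        struct[:2] = True
        with pytest.raises(UndefinedFractionError):
            imaging.cytosolic_fraction(img, cell, struct, background=10.0)

    def test_scale_invariance_with_proportional_background(self, patch_cell):
        _, stack, _ = patch_cell
        abp = imaging.project(stack, 0, "average")
        marker = imaging.project(stack, 1, "maximum")
        cells = imaging.segment_cells(abp)
        sp = imaging.auto_set_point(marker, cells[0].mask)
        mask = imaging.make_structure_mask(marker, sp, dilate_px=3)
        bg = 5.0
        base = imaging.cytosolic_fraction(abp.pixels, cells[0].mask, mask, bg)
        scaled = imaging.cytosolic_fraction(abp.pixels * 4.0, cells[0].mask, mask, bg * 4.0)
        assert scaled.cytosolic_fraction == pytest.approx(
            base.cytosolic_fraction, rel=1e-9
        )

    def test_structure_free_cells_measure_fraction_near_one(self):
        fractions = []
        for seed in range(8):
            p = synth.SynthParams(structure_kind="none", cell_radius=1.6,
                                  n_slices=21, seed=seed)
            stack, _ = synth.generate_cell_stack(p)
            abp = imaging.project(stack, 0, "average")
            cells = imaging.segment_cells(abp)
            struct = np.zeros_like(cells[0].mask)
            res = imaging.cytosolic_fraction(abp, cells[0].mask, struct)
            fractions.append(res.cytosolic_fraction)
        assert np.mean(fractions) == pytest.approx(1.0, abs=0.02)


class TestThresholdSweep:
    def test_uniform_cell_is_insensitive(self):
        img = np.full((32, 32), 6.0)
        cell = np.zeros((32, 32), bool)
        cell[4:28, 4:28] = True
        marker = np.zeros((32, 32))
        marker[10:14, 10:14] = 100.0
        sweep = imaging.threshold_sweep(img, cell, marker, set_point=50.0)
        assert sweep.sensitivity == pytest.approx(0.0, abs=1e-12)
        assert all(r.cytosolic_fraction == pytest.approx(1.0) for r in sweep.results)

    def test_patch_cell_sensitivity_below_5_points(self, patch_cell):
        _, stack, _ = patch_cell
        abp = imaging.project(stack, 0, "average")
        marker = imaging.project(stack, 1, "maximum")
        cells = imaging.segment_cells(abp)
        sp = imaging.auto_set_point(marker, cells[0].mask)
        sweep = imaging.threshold_sweep(
            abp, cells[0].mask, marker, sp,
            dilate_px=imaging.DEFAULT_MASK_DILATE_PX,
        )
        assert sweep.sensitivity < 0.05

    def test_zero_set_point_rejected(self, patch_cell):
        _, stack, _ = patch_cell
        abp = imaging.project(stack, 0, "average")
        marker = imaging.project(stack, 1, "maximum")
        with pytest.raises(ValidationError):
            imaging.threshold_sweep(abp, np.ones(abp.pixels.shape, bool), marker, 0.0)

    def test_fraction_tends_to_one_as_set_point_grows(self, patch_cell):
        _, stack, _ = patch_cell
        abp = imaging.project(stack, 0, "average")
        marker = imaging.project(stack, 1, "maximum")
        cells = imaging.segment_cells(abp)
        fracs = []
        for sp in (20.0, 80.0, 1e6):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask = imaging.make_structure_mask(marker, sp)
            fracs.append(
                imaging.cytosolic_fraction(abp, cells[0].mask, mask).cytosolic_fraction
            )
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)
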