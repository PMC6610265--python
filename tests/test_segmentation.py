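"""ROI/VOI segmentation: region growing, spheres, background, exclusions."""

import numpy as np
import pytest

from fetdyn import phantom
from fetdyn.core import ImageGeometry, RegionMask, RegionError, StaticImage, windowed_mean_image
from fetdyn.segmentation import (
    SeedBelowThresholdError,
    SegmentationConfig,
    background_mean,
    find_max_voxel,
    mirror_across_midsagittal,
    plausibility_check,
    region_grow,
    segment_roi90,
    segment_tbr,
    segment_voi90,
    sphere_voi,
)

import helpers


def _static(values, spacing=(2.0, 2.0, 2.0)):
    values = np.asarray(values, dtype=float)
    return StaticImage(ImageGeometry(values.shape, spacing), values)


class TestFindMaxVoxel:
    def test_single_global_max(self):
        vals = np.zeros((3, 3, 3))
        vals[1, 2, 0] = 5.0
        assert find_max_voxel(_static(vals)) == (1, 2, 0)

    def test_tie_breaks_to_smallest_index(self):
        vals = np.zeros((3, 3, 3))
        vals[2, 2, 2] = 5.0
        vals[1, 0, 2] = 5.0
        assert find_max_voxel(_static(vals)) == (1, 0, 2)

    def test_restricted_search_and_empty_region(self, rng):
        vals = rng.uniform(0, 1, (5, 5, 5))
        vals[0, 0, 0] = 10.0  # global max outside the search region
        region = np.zeros((5, 5, 5), dtype=bool)
        region[2:4, 2:4, 2:4] = True
        z, y, x = find_max_voxel(_static(vals), region)
        assert region[z, y, x]
        # independent exhaustive-scan oracle over the region
        best = max(
            ((vals[i], i) for i in np.ndindex(5, 5, 5) if region[i]),
            key=lambda p: (p[0], [-c for c in p[1]]),
        )
        assert vals[z, y, x] == best[0]
        with pytest.raises(RegionError):
            find_max_voxel(_static(vals), np.zeros((5, 5, 5), dtype=bool))

    def test_phantom_max_lies_inside_hot_lesion(self):
        geom = ImageGeometry((16, 24, 24), (3.0, 3.0, 3.0))
        model = phantom.KineticModel("constant", amplitude=4.0)
        cz, cy, cx = geom.center_world
        spec = phantom.PhantomSpec(
            geometry=geom,
            brain=phantom.brain_structure(geom),
            structures=[phantom.Structure("lesion", phantom.Sphere((cz, cy, cx), 7.0), model)],
        )
        img, truth, _ = phantom.build_phantom(spec)
        summed = windowed_mean_image(img, 20, 40)
        assert find_max_voxel(summed) in truth["lesion"].voxel_set()


class TestRegionGrow:
    def test_hand_checkable_line(self):
        vals = np.array([[[1.0, 9.0, 10.0, 9.0, 1.0]]])
        mask = region_grow(_static(vals), (0, 0, 2), threshold=9.0, mode="3d")
        assert mask.voxel_set() == {(0, 0, 1), (0, 0, 2), (0, 0, 3)}

    def test_uniform_image_grows_to_entire_volume(self):
        vals = np.full((4, 5, 6), 2.0)
        mask = region_grow(_static(vals), (0, 0, 0), threshold=2.0, mode="3d")
        assert mask.n_voxels == 4 * 5 * 6

    def test_seed_below_threshold_is_an_error(self):
        vals = np.zeros((3, 3, 3))
        with pytest.raises(SeedBelowThresholdError):
            region_grow(_static(vals), (1, 1, 1), threshold=1.0)

    def test_2d_mode_stays_in_seed_slice(self):
        vals = np.full((3, 4, 4), 5.0)
        mask = region_grow(_static(vals), (1, 0, 0), threshold=1.0, mode="2d")
        assert mask.dimensionality == 2 and mask.slice_index == 1
        assert mask.n_voxels == 16

    @pytest.mark.parametrize("mode", ["2d", "3d"])
    def test_matches_bfs_flood_fill_on_random_volumes(self, mode, rng):
        """Oracle equivalence on 100 random 9x9x9 volumes."""
        mismatches = 0
        for _ in range(100):
            vals = rng.uniform(0, 1, (9, 9, 9))
            thr = rng.uniform(0.3, 0.7)
            above = vals >= thr
            if not above.any():
                continue
            seeds = np.argwhere(above)
            seed = tuple(seeds[rng.integers(len(seeds))])
            mask = region_grow(_static(vals), seed, thr, mode=mode)
            if mode == "3d":
                oracle = helpers.bfs_component_3d(above, seed, connectivity=26)
            else:
                comp = helpers.bfs_component_2d(above[seed[0]], seed[1:], connectivity=8)
                oracle = {(seed[0], y, x) for y, x in comp}
            mismatches += mask.voxel_set() != oracle
        assert mismatches == 0

    def test_monotone_in_threshold(self, rng):
        vals = rng.uniform(0, 1, (9, 9, 9))
        seed = tuple(np.unravel_index(np.argmax(vals), vals.shape))
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            mask = region_grow(_static(vals), seed, thr).voxel_set()
            if prev is not None:
                assert mask <= prev
            prev = mask


@pytest.fixture
def lesion_phantom():
    geom = ImageGeometry((20, 28, 28), (3.0, 3.0, 3.0))
    cz, cy, cx = geom.center_world
    core = phantom.Structure(
        "core", phantom.Sphere((cz, cy, cx - 6), 3.5),
        phantom.KineticModel("increasing", amplitude=3.0, tau=8.0),
    )
    lesion = phantom.Structure(
        "lesion", phantom.Sphere((cz, cy, cx - 6), 8.0),
        phantom.KineticModel("increasing", amplitude=2.6, tau=8.0),
    )
    spec = phantom.PhantomSpec(
        geometry=geom,
        brain=phantom.brain_structure(geom, amplitude=1.0),
        structures=[core, lesion],
        priority=["core", "lesion"],
    )
    img, truth, _ = phantom.build_phantom(spec)
    return img, truth, windowed_mean_image(img, 20, 40)


class TestThresholdDefinitions:
    def test_roi90_threshold_is_90pct_of_max(self):
        vals = np.zeros((1, 1, 5))
        vals[0, 0] = [1.0, 8.9, 10.0, 9.1, 1.0]
        mask = segment_roi90(_static(vals))
        # threshold 9.0 keeps the 10.0 and 9.1 voxels only
        assert mask.voxel_set() == {(0, 0, 2), (0, 0, 3)}

    def test_roi90_and_voi90_scale_invariant(self, lesion_phantom):
        _, _, summed = lesion_phantom
        scaled = StaticImage(summed.geometry, summed.values * 3.7, summed.window)
        assert segment_roi90(summed).voxel_set() == segment_roi90(scaled).voxel_set()
        assert segment_voi90(summed).voxel_set() == segment_voi90(scaled).voxel_set()

    def test_masks_contained_in_truth_lesion(self, lesion_phantom):
        _, truth, summed = lesion_phantom
        lesion_voxels = truth["core"].voxel_set() | truth["lesion"].voxel_set()
        voi = segment_voi90(summed)
        roi = segment_roi90(summed)
        assert voi.voxel_set() <= lesion_voxels
        assert roi.voxel_set() <= {v for v in lesion_voxels if v[0] == roi.slice_index}

    def test_roi90_subset_of_voi90_in_max_slice(self, lesion_phantom):
        _, _, summed = lesion_phantom
        roi = segment_roi90(summed)
        voi = segment_voi90(summed)
        assert roi.voxel_set() <= voi.intersect_slice(roi.slice_index).voxel_set()

    def test_tbr_threshold_arithmetic(self):
        vals = np.zeros((1, 1, 5))
        vals[0, 0] = [1.0, 3.1, 4.0, 3.3, 3.1]
        mask = segment_tbr(_static(vals), (0, 0, 2), background=2.0, mode="3d")
        # threshold 3.2: keeps 4.0 and 3.3 (>= is inclusive)
        assert mask.voxel_set() == {(0, 0, 2), (0, 0, 3)}

    def test_tbr_invariant_when_image_and_background_scale_together(self, lesion_phantom):
        _, _, summed = lesion_phantom
        a = 2.5
        scaled = StaticImage(summed.geometry, summed.values * a, summed.window)
        m1 = segment_tbr(summed, None, background=1.0, mode="3d")
        m2 = segment_tbr(scaled, None, background=a, mode="3d")
        assert m1.voxel_set() == m2.voxel_set()

    def test_tbr_segmentation_includes_adjacent_vessel(self):
        """The threshold-region-growing failure mode: growth spills into an
        early-peaking vessel with sufficient late uptake."""
        img, truth, labels = phantom.build_phantom(phantom.vessel_scene())
        summed = windowed_mean_image(img, 20, 40)
        hint = RegionMask(
            np.vstack([truth["lesion"].voxels, truth["lesion_core"].voxels])
        )
        seed = find_max_voxel(summed, hint)
        bg = background_mean(summed, mirror_across_midsagittal(img.geometry, seed))
        mask = segment_tbr(summed, seed, bg, mode="2d")
        assert mask.voxel_set() & truth["vessel"].voxel_set()


class TestBackgroundMean:
    def test_uniform_image(self):
        vals = np.full((20, 20, 20), 2.0)
        assert background_mean(_static(vals), (10, 10, 10)) == pytest.approx(2.0)

    def test_default_diameter_is_20mm(self):
        cfg = SegmentationConfig()
        assert cfg.background_diameter_mm == 20.0

    def test_phantom_background_recovers_brain_amplitude(self):
        geom = ImageGeometry((24, 32, 32), (3.0, 3.0, 3.0))
        spec = phantom.PhantomSpec(
            geometry=geom, brain=phantom.brain_structure(geom, amplitude=1.2)
        )
        img, _, _ = phantom.build_phantom(spec)
        summed = windowed_mean_image(img, 20, 40)
        ci = tuple(n // 2 for n in geom.shape)
        assert background_mean(summed, ci) == pytest.approx(1.2, rel=1e-9)

    def test_sphere_outside_volume_is_an_error(self):
        vals = np.full((10, 10, 10), 1.0)
        with pytest.raises(RegionError):
            background_mean(_static(vals), (0, 0, 0))


class TestSphereVoi:
    def test_two_ml_sphere_volume_on_fine_grid(self):
        geom = ImageGeometry((30, 30, 30), (1.0, 1.0, 1.0))
        center = geom.voxel_to_world((15, 15, 15))
        mask = sphere_voi(geom, center, 15.6)
        analytic = 4.0 / 3.0 * np.pi * (15.6 / 2) ** 3 / 1000.0
        assert analytic == pytest.approx(1.99, abs=0.01)
        assert mask.volume_ml(geom) == pytest.approx(analytic, rel=0.05)

    def test_subvoxel_sphere_is_single_voxel(self):
        geom = ImageGeometry((5, 5, 5), (2.0, 2.0, 2.0))
        mask = sphere_voi(geom, geom.voxel_to_world((2, 2, 2)), 1.0)
        assert mask.voxel_set() == {(2, 2, 2)}

    @pytest.mark.parametrize("spacing,tol", [(2.0, 0.15), (1.0, 0.05), (0.5, 0.02)])
    def test_volume_converges_to_analytic_with_resolution(self, spacing, tol):
        n = int(30 / spacing)
        geom = ImageGeometry((n, n, n), (spacing,) * 3)
        center = geom.voxel_to_world((n // 2, n // 2, n // 2))
        mask = sphere_voi(geom, center, 15.6)
        analytic = 4.0 / 3.0 * np.pi * 7.8**3 / 1000.0
        assert mask.volume_ml(geom) == pytest.approx(analytic, rel=tol)


class TestPlausibilityCheck:
    def test_small_mask_passes(self, small_geometry):
        mask = RegionMask(np.array([[1, 1, 1], [1, 1, 2]]))
        assert plausibility_check(mask, small_geometry).passed

    def test_whole_head_mask_excluded_by_volume(self):
        geom = ImageGeometry((40, 50, 50), (2.0, 2.0, 2.0))
        mask = RegionMask.from_array(np.ones(geom.shape, dtype=bool))
        result = plausibility_check(mask, geom)
        assert not result.passed and "mL" in result.reason

    def test_mask_escaping_brain_excluded(self, small_geometry):
        brain = np.zeros(small_geometry.shape, dtype=bool)
        brain[:, :, :6] = True
        mask = RegionMask.from_array(np.ones(small_geometry.shape, dtype=bool) & ~brain)
        result = plausibility_check(mask, small_geometry, brain_mask=brain)
        assert not result.passed and "outside the brain" in result.reason

    def test_scalp_flood_excluded_by_brain_criterion(self):
        """A low threshold that grows into the scalp shell trips the check."""
        geom = ImageGeometry((20, 28, 28), (3.0, 3.0, 3.0))
        cz, cy, cx = geom.center_world
        brain = phantom.brain_structure(geom, amplitude=1.0)
        scalp = phantom.Structure(
            "scalp",
            phantom.EllipsoidShell(
                (cz, cy, cx),
                brain.shape.semiaxes,
                tuple(s + 4 for s in brain.shape.semiaxes),
            ),
            phantom.KineticModel("constant", amplitude=2.0),
        )
        spec = phantom.PhantomSpec(geometry=geom, brain=brain, structures=[scalp])
        img, truth, _ = phantom.build_phantom(spec)
        summed = windowed_mean_image(img, 20, 40)
        seed = find_max_voxel(summed, truth["scalp"])
        mask = region_grow(summed, seed, threshold=1.5, mode="3d")
        envelope = phantom.brain_envelope(spec)
        result = plausibility_check(
            mask, geom, SegmentationConfig(max_plausible_volume_ml=1e6), envelope
        )
        assert not result.passed and "outside the brain" in result.reason
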