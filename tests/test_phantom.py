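import numpy as np
import pytest
from scipy import ndimage

from pwml.phantom import (
    LesionSpec,
    PhantomParams,
    PlacementError,
    distribute_lesions,
    generate_slice,
    generate_source_case,
    inject_lesions,
    inject_lesions_with_records,
    sample_lesion_count,
)
from pwml.rng import substream
from pwml.types import BACKGROUND, CORTEX, VENTRICLE, WHITE_MATTER, BoundingBox


class TestGenerateSlice:
    def test_deterministic(self):
        a, ta = generate_slice(PhantomParams(), seed=1)
        b, tb = generate_slice(PhantomParams(), seed=1)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(ta.labels, tb.labels)

    def test_all_tissues_present(self, phantom_slice):
        _, tis = phantom_slice
        for label in (BACKGROUND, CORTEX, WHITE_MATTER, VENTRICLE):
            assert tis.region(label).sum() > 0

    def test_labels_partition_every_pixel(self, phantom_slice):
        _, tis = phantom_slice
        assert set(np.unique(tis.labels)) <= {BACKGROUND, CORTEX, WHITE_MATTER, VENTRICLE}

    def test_wm_single_connected_component_inside_cortex(self, phantom_slice):
        _, tis = phantom_slice
        wm = tis.region(WHITE_MATTER)
        _, n = ndimage.label(wm, structure=np.ones((3, 3)))
        assert n == 1
        # every WM pixel's 4-neighborhood is brain tissue (never background)
        grown = ndimage.binary_dilation(wm)
        assert not (grown & tis.region(BACKGROUND)).any()

    def test_label_histogram_matches_flood_fill_oracle(self):
        """Label counts equal region areas found by independent flood fill."""
        _, tis = generate_slice(PhantomParams(), seed=2)
        hist = np.bincount(tis.labels.ravel(), minlength=4)
        for label in (CORTEX, WHITE_MATTER, VENTRICLE):
            region = tis.labels == label
            filled, n = ndimage.label(region, structure=np.ones((3, 3)))
            oracle_area = sum(
                int((filled == i).sum()) for i in range(1, n + 1)
            )
            assert oracle_area == hist[label]

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(image_size=32)

    def test_bad_intensity_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(wm_mean=300)


class TestInjectLesions:
    def test_zero_count_is_identity(self, phantom_slice):
        img, tis = phantom_slice
        out, boxes = inject_lesions(img, tis, LesionSpec(count=0), seed=0)
        assert boxes == []
        assert np.array_equal(out.pixels, img.pixels)

    def test_boxes_fully_inside_white_matter(self):
        img, tis = generate_slice(PhantomParams(), seed=4)
        _, boxes = inject_lesions(img, tis, LesionSpec(count=7), seed=3)
        assert len(boxes) == 7
        wm = tis.region(WHITE_MATTER)
        for b in boxes:
            assert wm[b.slices].all()

    def test_lesions_do_not_overlap(self):
        img, tis = generate_slice(PhantomParams(), seed=4)
        _, recs = inject_lesions_with_records(img, tis, LesionSpec(count=10), seed=9)
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                assert a.box.iou(b.box) == 0.0

    def test_pixels_outside_footprints_conserved(self):
        img, tis = generate_slice(PhantomParams(), seed=4)
        out, recs = inject_lesions_with_records(img, tis, LesionSpec(count=5), seed=7)
        changed = out.pixels.astype(int) != img.pixels.astype(int)
        footprint = np.zeros_like(changed)
        for r in recs:
            # bumps are truncated at 2 sigma around the center
            rad = int(np.ceil(2.0 * r.sigma))
            cx, cy = int(r.center[0]), int(r.center[1])
            footprint[cy - rad:cy + rad + 1, cx - rad:cx + rad + 1] = True
        assert not (changed & ~footprint).any()

    def test_mean_contrast_inside_mask(self):
        """Mean added intensity inside each mask is >= half the peak contrast."""
        contrast = 40.0
        img, tis = generate_slice(PhantomParams(noise_sd=5.0), seed=6)
        out, recs = inject_lesions_with_records(
            img, tis, LesionSpec(count=5, contrast=contrast), seed=8
        )
        delta = out.pixels.astype(float) - img.pixels.astype(float)
        for r in recs:
            # recompute against the injection record: mean over the mask only
            yy, xx = np.mgrid[r.box.y_min:r.box.y_max, r.box.x_min:r.box.x_max]
            d2 = (xx - r.center[0]) ** 2 + (yy - r.center[1]) ** 2
            inside = d2 <= (1.6651 * r.sigma) ** 2
            # the continuum mean of the truncated profile over its mask is
            # 0.54*contrast; pixelation of the smallest masks overweights
            # boundary pixels and can pull the discrete mean down to
            # ~0.46*contrast, so that is the honest lower bound here
            assert delta[r.box.slices][inside].mean() >= 0.45 * contrast

    def test_boxes_are_tight_mask_bounding_boxes(self):
        img, tis = generate_slice(PhantomParams(), seed=4)
        _, recs = inject_lesions_with_records(img, tis, LesionSpec(count=4), seed=2)
        for r in recs:
            yy, xx = np.mgrid[0:img.height, 0:img.width]
            d2 = (xx - r.center[0]) ** 2 + (yy - r.center[1]) ** 2
            mask = d2 <= (1.6651 * r.sigma) ** 2
            assert r.box == BoundingBox.from_mask(mask)

    def test_impossible_placement_raises(self):
        img, tis = generate_slice(PhantomParams(), seed=4)
        with pytest.raises(PlacementError):
            inject_lesions(img, tis, LesionSpec(count=500), seed=0)

    def test_deterministic(self):
        img, tis = generate_slice(PhantomParams(), seed=4)
        a, ra = inject_lesions(img, tis, LesionSpec(count=6), seed=5)
        b, rb = inject_lesions(img, tis, LesionSpec(count=6), seed=5)
        assert np.array_equal(a.pixels, b.pixels)
        assert ra == rb


class TestCases:
    def test_distribute_lesions_even_split(self):
        assert distribute_lesions(19, 7) == [3, 3, 3, 3, 3, 2, 2]
        assert distribute_lesions(17, 6) == [3, 3, 3, 3, 3, 2]
        assert sum(distribute_lesions(19, 7)) == 19

    def test_source_case_totals(self):
        case = generate_source_case("caseA", 19, 7, seed=0)
        assert len(case) == 7
        assert sum(len(sl.records) for sl in case) == 19

    def test_count_sampling_respects_bounds(self):
        spec = LesionSpec()
        rng = substream(0, "counts")
        counts = [sample_lesion_count(spec, rng) for _ in range(500)]
        assert min(counts) >= 1 and max(counts) <= 19
        assert 4.0 < np.mean(counts) < 9.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            LesionSpec(count=-1)
        with pytest.raises(ValueError):
            LesionSpec(diameter_px=(0.5, 6))
        with pytest.raises(ValueError):
            LesionSpec(contrast=0)
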