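import numpy as np
import pytest

from astroquant import mito, synthetic
from astroquant.imaging import LabelMask
from astroquant.mito import MitoConfig


def disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestEnhance:
    def test_flat_image_stays_flat(self):
        img = np.full((64, 64), 37.0)
        out = mito.enhance(img, 0.2)
        assert np.ptp(out) == 0.0

    def test_output_bounded(self, rng):
        img = rng.random((128, 128)) * 500
        out = mito.enhance(img, 0.2)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_contrast_ratio_increases_on_gradient_background(self):
        # bright filament over a strong illumination gradient
        img = np.tile(np.linspace(50, 250, 128), (128, 1))
        img[60:63, 20:100] += 80.0
        fil = np.zeros_like(img, dtype=bool)
        fil[60:63, 20:100] = True
        out = mito.enhance(img, 0.2)
        before = img[fil].mean() / img[~fil].mean()
        after = out[fil].mean() / out[~fil].mean()
        assert after > before


class TestDetectFibrils:
    def test_blank_image_gives_empty_mask(self):
        assert not mito.detect_fibrils(np.zeros((64, 64)), 0.25, 0.2).any()

    def test_straight_filament_recall(self):
        img = np.zeros((128, 128))
        img[64:67, 20:108] = 1.0
        truth = img > 0
        mask = mito.detect_fibrils(img, 0.3, 0.2)
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.9

    def test_isolated_speckles_suppressed(self, rng):
        img = np.zeros((128, 128))
        img[64:67, 20:108] = 1.0  # one real filament
        speckles = [(10, 10), (20, 100), (100, 30), (110, 110)]
        for y, x in speckles:
            img[y, x] = 1.0
        mask = mito.detect_fibrils(img, 0.3, 0.2)
        assert not any(mask[y, x] for y, x in speckles)

    def test_subpixel_scale_rejected(self):
        with pytest.raises(ValueError, match="below one pixel"):
            mito.detect_fibrils(np.zeros((32, 32)), scale_um=0.05, pixel_size_um=0.2)


class TestSkeletonizeAndCount:
    def test_empty_mask_gives_zero_segments(self):
        cells = LabelMask(np.ones((32, 32), dtype=int), kind="cells")
        skel = mito.skeletonize_and_count(np.zeros((32, 32), bool), cells, 0.2)
        assert skel[1].n_components == 0 and skel[1].n_branches == 0

    def test_two_disjoint_bars_count_two(self):
        mask = np.zeros((64, 64), bool)
        mask[10:13, 5:40] = True
        mask[40:43, 10:50] = True
        cells = LabelMask(np.ones((64, 64), dtype=int), kind="cells")
        skel = mito.skeletonize_and_count(mask, cells, 0.2)
        assert skel[1].n_components == 2

    def test_segment_length_of_straight_bar(self):
        mask = np.zeros((64, 64), bool)
        mask[30:33, 10:50] = True  # 40 px long, 3 px wide
        cells = LabelMask(np.ones((64, 64), dtype=int), kind="cells")
        skel = mito.skeletonize_and_count(mask, cells, 0.5)
        total = skel[1].segments.length_um.sum()
        assert total == pytest.approx(0.5 * 39, rel=0.15)

    def test_counts_match_truth_on_noiseless_field(self, mito_field, mito_metrics):
        spec, (stack, nuclei, cells, truth) = mito_field
        merged = truth.table.merge(mito_metrics, on="cell_id")
        assert (merged.n_mitochondria == merged.n_mito_true).all()


class TestPerinuclearZone:
    def test_zone_contains_nucleus_and_hits_target_area(self):
        nucleus = disk_mask((128, 128), 64, 64, 20)
        zone = mito.grow_perinuclear_zone(nucleus, 1.2)
        assert (zone & nucleus).sum() == nucleus.sum()
        # within one dilation step of 1.2x the nucleus area
        ring = zone.sum() - nucleus.sum()
        target = 0.2 * nucleus.sum()
        boundary = np.count_nonzero(
            zone & ~mito.grow_perinuclear_zone(nucleus, 1.0)
        )
        assert abs(ring - target) <= max(boundary * 0.1, 200)
        assert zone.sum() >= 1.2 * nucleus.sum()

    def test_analytic_ring_area_for_circular_nucleus(self):
        r = 25
        nucleus = disk_mask((256, 256), 128, 128, r)
        zone = mito.grow_perinuclear_zone(nucleus, 1.2)
        # a disk grown to 1.2x area has radius r*sqrt(1.2)
        expected = np.pi * (1.2 * r**2)
        assert zone.sum() == pytest.approx(expected, rel=0.02)


class TestPerinuclearRatio:
    def test_uniform_coverage_gives_ratio_one(self):
        cell = disk_mask((128, 128), 64, 64, 50)
        nucleus = disk_mask((128, 128), 64, 64, 15)
        _, ratio = mito.perinuclear_ratio(cell, nucleus, cell, 0.2)
        assert ratio == pytest.approx(1.0)

    def test_all_signal_in_zone_gives_inverse_area_fraction(self):
        cell = disk_mask((256, 256), 128, 128, 80)
        nucleus = disk_mask((256, 256), 128, 128, 25)
        zone = mito.grow_perinuclear_zone(nucleus, 1.2)
        pz, ratio = mito.perinuclear_ratio(zone, nucleus, cell, 0.2)
        frac_area = (zone & cell).sum() / cell.sum()
        assert ratio == pytest.approx(1.0 / frac_area)

    def test_no_signal_reports_nan(self):
        cell = disk_mask((64, 64), 32, 32, 20)
        nucleus = disk_mask((64, 64), 32, 32, 6)
        _, ratio = mito.perinuclear_ratio(
            np.zeros((64, 64), bool), nucleus, cell, 0.2
        )
        assert np.isnan(ratio)

    def test_nucleus_outside_cell_raises(self):
        cell = disk_mask((64, 64), 20, 20, 12)
        nucleus = disk_mask((64, 64), 50, 50, 6)
        with pytest.raises(ValueError, match="not contained"):
            mito.perinuclear_ratio(cell, nucleus, cell, 0.2, cell_id=1, nucleus_id=1)

    def test_ratio_increases_with_perinuclear_fraction(self):
        means = []
        for pf in (0.2, 0.8):
            spec = synthetic.SyntheticImageSpec(
                image_size_px=(640, 640), n_cells=3, mito_per_cell=20,
                perinuclear_fraction=pf, min_separation_um=0.0, seed=21,
            )
            stack, nuclei, cells, _ = synthetic.generate_image(spec)
            m = mito.analyze_mito(stack, nuclei, cells)
            means.append(np.nanmean(m.perinuclear_ratio))
        assert means[1] > means[0]


class TestMetricsInvariance:
    def test_intensity_rescaling_only_scales_integrated_intensity(self, mito_field):
        spec, (stack, nuclei, cells, truth) = mito_field
        from dataclasses import replace

        m1 = mito.analyze_mito(stack, nuclei, cells)
        scaled = replace(stack, pixels=stack.pixels * 2.5)
        m2 = mito.analyze_mito(scaled, nuclei, cells)
        assert (m1.n_mitochondria == m2.n_mitochondria).all()
        np.testing.assert_allclose(m1.mito_area_um2, m2.mito_area_um2)
        np.testing.assert_allclose(m2.mito_intensity, 2.5 * m1.mito_intensity)

    def test_density_area_bounded_by_one(self, mito_metrics):
        assert ((mito_metrics.density_area >= 0)
                & (mito_metrics.density_area <= 1)).all()


class TestFiberMorphometry:
    def test_blank_channel_gives_zero_fiber_area(self):
        cells = LabelMask(disk_mask((128, 128), 64, 64, 40).astype(int), kind="cells")
        df = mito.fiber_morphometry(np.zeros((128, 128)), cells, 0.5)
        assert (df.fiber_area_um2 == 0).all()

    def test_known_filament_area_recovered(self):
        lab = np.zeros((128, 128), dtype=int)
        lab[20:120, 20:120] = 1
        img = np.zeros((128, 128))
        img[60:62, 40:80] = 100.0  # 80 px of fiber at 1 um/px
        cfg = MitoConfig(filament_width_um=2.0, rolling_ball_radius_um=20.0)
        df = mito.fiber_morphometry(img, LabelMask(lab, kind="cells"), 1.0, cfg)
        assert df.fiber_area_um2[0] == pytest.approx(80.0, rel=0.25)

    def test_doubling_pixel_size_quadruples_areas(self):
        lab = np.zeros((64, 64), dtype=int)
        lab[10:50, 10:50] = 1
        cells = LabelMask(lab, kind="cells")
        img = np.zeros((64, 64))
        a = mito.fiber_morphometry(img, cells, 1.0)
        b = mito.fiber_morphometry(img, cells, 2.0)
        assert b.area_um2[0] == pytest.approx(4 * a.area_um2[0])
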