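"""Chimeric Organoid Analyzer: focus, segmentation, measurement."""

import numpy as np
import pytest

from portalquant.containers import Image2D, ImageStack
from portalquant.organoid import (
    AnalyzerParams,
    measure_chimeric_organoid,
    segment_gfp_area,
    segment_organoid_area,
    segment_tomato_clusters,
    select_focus_slice,
)
from portalquant.synthetic import (
    OrganoidParams,
    RenderConfig,
    generate_organoid_scene,
    render_organoid,
)


def _textured_ellipse(rng, shape=(120, 120), center=(60, 60), axes=(40, 28)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    inside = ((xx - center[1]) / axes[0]) ** 2 + ((yy - center[0]) / axes[1]) ** 2 <= 1
    img = np.full(shape, 10.0)
    img[inside] += 60 + 40 * rng.random(int(inside.sum()))
    return img, inside


class TestFocusSelection:
    def test_single_slice_returns_zero(self):
        stack = ImageStack(np.random.default_rng(0).random((1, 1, 10, 10)), ("brightfield",), 1.0)
        assert select_focus_slice(stack) == 0

    def test_identical_slices_tie_to_lowest_z(self):
        plane = np.random.default_rng(1).random((12, 12))
        stack = ImageStack(np.stack([plane] * 4)[:, None], ("brightfield",), 1.0)
        assert select_focus_slice(stack) == 0

    def test_planted_focus_recovered(self, organoid_scene_and_stack):
        scene, stack = organoid_scene_and_stack
        assert select_focus_slice(stack) == scene.focus_z


class TestOrganoidSegmentation:
    def test_blank_field_yields_no_organoid(self):
        assert segment_organoid_area(Image2D(np.full((60, 60), 5.0), 1.0), AnalyzerParams()) is None

    def test_textured_ellipse_area_within_15_percent(self, rng):
        img, inside = _textured_ellipse(rng)
        mask = segment_organoid_area(Image2D(img, 1.0), AnalyzerParams())
        assert mask is not None
        assert mask.area_um2() == pytest.approx(inside.sum(), rel=0.15)

    def test_largest_component_rule_ignores_distant_speckle(self, rng):
        img, _ = _textured_ellipse(rng)
        img[2:7, 110:115] += 80 * rng.random((5, 5))  # distant textured speckle
        mask = segment_organoid_area(Image2D(img, 1.0), AnalyzerParams())
        from portalquant.imaging import connected_components

        assert connected_components(mask).n_labels == 1
        assert not mask.values[0:10, 105:120].any()


class TestGfpSegmentation:
    def test_blank_channel_yields_empty_mask(self):
        mask = segment_gfp_area(Image2D(np.full((40, 40), 10.0), 1.0), AnalyzerParams())
        assert not mask.values.any()

    def test_noise_only_channel_is_rejected_by_contrast_guard(self):
        noise = np.random.default_rng(3).normal(10, 3, (80, 80))
        mask = segment_gfp_area(Image2D(noise, 1.0), AnalyzerParams())
        assert not mask.values.any()

    def test_two_level_noiseless_image_segmented_exactly(self):
        img = np.full((50, 50), 10.0)
        img[10:30, 15:35] = 200.0
        mask = segment_gfp_area(Image2D(img, 1.0), AnalyzerParams(gfp_smooth_sigma_px=1.0))
        expected = img > 100
        # allow a 1-px rim from smoothing
        core = expected.copy()
        core[9:31, 14:36] = img[9:31, 14:36] > 0  # bounding region
        assert mask.values[12:28, 17:33].all()
        assert not mask.values[~core].any()

    def test_planted_fraction_recovered(self, organoid_scene_and_stack):
        scene, stack = organoid_scene_and_stack
        m = measure_chimeric_organoid(stack)
        assert 0.15 <= m.gfp_area_fraction <= 0.35


class TestTomatoSegmentation:
    def test_zero_clusters_yields_zero_labels(self):
        noise = np.random.default_rng(4).normal(10, 3, (80, 80))
        lm = segment_tomato_clusters(Image2D(noise, 1.0), AnalyzerParams())
        assert lm.n_labels == 0

    def test_five_disjoint_clusters_counted_exactly(self):
        img = np.full((150, 150), 10.0)
        for cy, cx in ((20, 20), (20, 120), (75, 75), (130, 30), (130, 120)):
            yy, xx = np.mgrid[0:150, 0:150]
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 16] = 150.0
        lm = segment_tomato_clusters(Image2D(img, 1.0), AnalyzerParams())
        assert lm.n_labels == 5

    def test_sub_area_cluster_is_excluded(self):
        # the area filter acts on the segmented band-pass blob (the DoG
        # spreads objects by ~sigma_small), so the cutoff sits between the
        # two blobs' segmented areas (121 and 81 μm² here)
        img = np.full((100, 100), 10.0)
        yy, xx = np.mgrid[0:100, 0:100]
        img[(yy - 30) ** 2 + (xx - 30) ** 2 <= 16] = 150.0
        img[(yy - 70) ** 2 + (xx - 70) ** 2 <= 2] = 150.0
        lm = segment_tomato_clusters(
            Image2D(img, 1.0), AnalyzerParams(min_cluster_area_um2=100.0)
        )
        assert lm.n_labels == 1
        assert lm.table.centroid_y_px.iloc[0] == pytest.approx(30.0, abs=1.0)


class TestMeasurement:
    def test_gfp_fully_outside_organoid_contributes_zero_area(self, rng):
        bf, _ = _textured_ellipse(rng, shape=(120, 160))
        gfp = np.full((120, 160), 10.0)
        gfp[10:40, 120:150] = 200.0  # outside the ellipse
        tom = np.full((120, 160), 10.0)
        stack = ImageStack(
            np.stack([bf, gfp, tom])[None], ("brightfield", "gfp", "tomato"), 1.0
        )
        m = measure_chimeric_organoid(stack)
        assert m.organoid_found
        assert m.gfp_area_um2 == 0.0

    def test_uniform_gfp_inside_organoid_normalizes_to_its_level(self, rng):
        bf, inside = _textured_ellipse(rng)
        g = 37.0
        gfp = np.zeros((120, 120))
        gfp[inside] = g
        tom = np.full((120, 120), 0.0)
        stack = ImageStack(
            np.stack([bf, gfp, tom])[None], ("brightfield", "gfp", "tomato"), 1.0
        )
        m = measure_chimeric_organoid(stack)
        assert m.gfp_mean_intensity_norm == pytest.approx(g, rel=0.02)

    def test_intensity_scaling_scales_norm_but_not_areas(self, rng):
        scene = generate_organoid_scene(OrganoidParams(gfp_area_fraction=0.3), seed=9)
        cfg = RenderConfig.for_organoid(scene, seed=9, shot_noise=False, read_noise_sd=0.0)
        stack = render_organoid(scene, cfg)
        m1 = measure_chimeric_organoid(stack)
        scaled = ImageStack(stack.values.copy(), stack.channel_roles, stack.pixel_size_um)
        scaled.values[:, 1] *= 3.0
        m2 = measure_chimeric_organoid(scaled)
        assert m2.gfp_mean_intensity_norm == pytest.approx(3 * m1.gfp_mean_intensity_norm, rel=1e-9)
        assert m2.gfp_area_um2 == m1.gfp_area_um2
        assert m2.organoid_area_um2 == m1.organoid_area_um2

    def test_measurement_invariants_hold_on_recovery_scene(self, organoid_scene_and_stack):
        scene, stack = organoid_scene_and_stack
        m = measure_chimeric_organoid(stack)
        assert m.gfp_area_um2 <= m.organoid_area_um2
        assert m.tomato_area_um2 <= m.organoid_area_um2 + 1e-9 or m.n_tomato_clusters >= 1
        assert 0 <= m.gfp_area_fraction <= 1
        assert m.contacted == (m.n_tomato_clusters >= 1)

    def test_no_organoid_gives_null_row(self):
        blank = np.full((60, 60), 10.0)
        stack = ImageStack(
            np.stack([blank, blank, blank])[None], ("brightfield", "gfp", "tomato"), 1.0
        )
        m = measure_chimeric_organoid(stack)
        assert not m.organoid_found
        assert np.isnan(m.organoid_area_um2)
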