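"""Liver Cell Distances pipeline: masks, gating, nuclei, distances, summary."""

import numpy as np
import pandas as pd
import pytest

from portalquant.containers import BinaryMask, Image2D, ImageStack
from portalquant.distances import (
    ChannelMaskParams,
    DistanceRunConfig,
    DistanceTable,
    build_gated_mask,
    combine_double_mask,
    default_tissue_config,
    extract_opn_nuclei,
    measure_nucleus_distances,
    run_distance_pipeline,
    summarize_fov,
)
from portalquant.errors import DegenerateMaskError, ShapeMismatchError
from portalquant.imaging import connected_components
from portalquant.synthetic import RenderConfig, TissueParams, generate_tissue_scene, render_tissue


def _one_channel_stack(plane, role="opn", ps=1.0):
    return ImageStack(np.asarray(plane, float)[None, None], (role,), ps)


class TestGatedMask:
    def test_background_only_channel_yields_empty_mask(self):
        stack = _one_channel_stack(np.full((32, 32), 7.0))
        mask = build_gated_mask(stack, ChannelMaskParams("opn", smooth_sigma_px=0))
        assert not mask.values.any()

    def test_intensity_gate_drops_dim_component(self):
        img = np.zeros((40, 40))
        img[5:10, 5:10] = 10.0     # dim blob, raw mean 10
        img[25:30, 25:30] = 100.0  # bright blob, raw mean 100
        stack = _one_channel_stack(img)
        params = ChannelMaskParams("opn", smooth_sigma_px=0, min_mean_intensity=50.0)
        mask = build_gated_mask(stack, params)
        lm = connected_components(mask)
        assert lm.n_labels == 1
        assert img[mask.values].mean() == pytest.approx(100.0)

    def test_zero_gate_equals_ungated_segmentation(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 1, (30, 30))
        img[10:20, 10:20] += 80
        stack = _one_channel_stack(img)
        gated = build_gated_mask(stack, ChannelMaskParams("opn", min_mean_intensity=0.0))
        ungated = build_gated_mask(stack, ChannelMaskParams("opn"))
        np.testing.assert_array_equal(gated.values, ungated.values)


class TestDoubleMask:
    def test_and_with_empty_is_empty(self):
        a = BinaryMask(np.ones((5, 5), dtype=bool), 1.0)
        b = BinaryMask(np.zeros((5, 5), dtype=bool), 1.0)
        assert not combine_double_mask(a, b).values.any()

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        a = BinaryMask(rng.random((6, 6)) < 0.5, 1.0)
        np.testing.assert_array_equal(combine_double_mask(a, a).values, a.values)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(2)
        a = BinaryMask(rng.random((7, 7)) < 0.5, 1.0)
        b = BinaryMask(rng.random((7, 7)) < 0.5, 1.0)
        out = combine_double_mask(a, b).values
        for y in range(7):
            for x in range(7):
                assert out[y, x] == (a.values[y, x] and b.values[y, x])

    def test_shape_mismatch_raises(self):
        a = BinaryMask(np.ones((5, 5), dtype=bool), 1.0)
        b = BinaryMask(np.ones((6, 6), dtype=bool), 1.0)
        with pytest.raises(ShapeMismatchError):
            combine_double_mask(a, b)


class TestExtractNuclei:
    def test_nucleus_outside_marker_mask_is_not_labelled(self):
        nuc = np.zeros((20, 20), dtype=bool)
        nuc[2:6, 2:6] = True
        opn = np.zeros((20, 20), dtype=bool)
        opn[10:18, 10:18] = True
        lm = extract_opn_nuclei(BinaryMask(nuc, 1.0), BinaryMask(opn, 1.0))
        assert lm.n_labels == 0

    def test_at_least_five_um2_keeps_exact_boundary_area(self):
        # blobs of 2, 5 and 12 px at 1 μm/px: the 5 μm² blob is kept
        nuc = np.zeros((30, 30), dtype=bool)
        nuc[1, 1:3] = True
        nuc[10, 10:15] = True
        nuc[20:23, 20:24] = True
        full = BinaryMask(np.ones((30, 30), dtype=bool), 1.0)
        lm = extract_opn_nuclei(BinaryMask(nuc, 1.0), full, min_area_um2=5.0)
        assert lm.n_labels == 2
        assert sorted(lm.table.area_um2) == [5.0, 12.0]

    def test_planted_duct_nuclei_count_recovered(self, contact_scene_and_stack):
        scene, stack = contact_scene_and_stack
        cfg = default_tissue_config()
        nuclei_mask = combine_double_mask(
            build_gated_mask(stack, cfg.mask_params("nuclei")),
            build_gated_mask(stack, cfg.mask_params("opn")),
        )
        full = BinaryMask(np.ones(nuclei_mask.shape, dtype=bool), nuclei_mask.pixel_size_um)
        lm = extract_opn_nuclei(nuclei_mask, full)
        assert lm.n_labels == len(scene.duct_nuclei)


class TestMeasureDistances:
    def test_nucleus_inside_target_has_negative_mean_and_contact(self):
        nuc = np.zeros((20, 20), dtype=bool)
        nuc[8:12, 8:12] = True
        target = np.zeros((20, 20), dtype=bool)
        target[5:15, 5:15] = True
        full = BinaryMask(np.ones((20, 20), dtype=bool), 1.0)
        lm = extract_opn_nuclei(BinaryMask(nuc, 1.0), full)
        table = measure_nucleus_distances(
            lm, BinaryMask(target, 1.0), Image2D(np.zeros((20, 20)), 1.0)
        )
        rec = table.records.iloc[0]
        assert rec.mean_signed_distance_um < 0
        assert rec.contacted == 1

    def test_single_pixel_pair_measures_five_um(self):
        nuc = np.zeros((8, 8), dtype=bool)
        nuc[4, 3] = True  # (y=4, x=3)
        target = np.zeros((8, 8), dtype=bool)
        target[0, 0] = True
        full = BinaryMask(np.ones((8, 8), dtype=bool), 1.0)
        lm = extract_opn_nuclei(BinaryMask(nuc, 1.0), full, min_area_um2=0.0)
        table = measure_nucleus_distances(
            lm, BinaryMask(target, 1.0), Image2D(np.zeros((8, 8)), 1.0)
        )
        assert table.records.iloc[0].mean_signed_distance_um == pytest.approx(5.0)

    def test_degenerate_target_raises_naming_the_problem(self):
        full = BinaryMask(np.ones((8, 8), dtype=bool), 1.0)
        nuc = np.zeros((8, 8), dtype=bool)
        nuc[1, 1] = True
        lm = extract_opn_nuclei(BinaryMask(nuc, 1.0), full, min_area_um2=0.0)
        with pytest.raises(DegenerateMaskError, match="target"):
            measure_nucleus_distances(lm, full, Image2D(np.zeros((8, 8)), 1.0))


class TestSummarize:
    @staticmethod
    def _table(distances, contacted):
        records = pd.DataFrame(
            dict(
                label=range(1, len(distances) + 1),
                x_um=0.0, y_um=0.0, area_um2=10.0, mean_opn_intensity=1.0,
                mean_signed_distance_um=distances,
                min_signed_distance_um=distances,
                contacted=contacted,
            )
        )
        return DistanceTable(records)

    def test_all_contacted_is_100_percent(self):
        s = summarize_fov(self._table([-1.0, -2.0], [1, 1]))
        assert s["pct_contacted"] == 100.0

    def test_median_and_percentage_arithmetic(self):
        s = summarize_fov(self._table([-1.0, 3.0, 8.0], [1, 0, 0]))
        assert s["median_distance_um"] == pytest.approx(3.0)
        assert s["pct_contacted"] == pytest.approx(100 / 3)
        assert s["tukey_stats"].median == pytest.approx(3.0)

    def test_empty_table_yields_marker_row_not_crash(self):
        s = summarize_fov(DistanceTable(pd.DataFrame(columns=["mean_signed_distance_um", "contacted"])))
        assert s["n_nuclei"] == 0
        assert np.isnan(s["median_distance_um"])


class TestEndToEnd:
    def test_contact_monotone_in_tau(self, contact_scene_and_stack):
        _, stack = contact_scene_and_stack
        pcts = []
        for tau in (0.0, 1.0, 3.0, 8.0):
            cfg = default_tissue_config(tau_contact_um=tau)
            table = run_distance_pipeline(stack, cfg)
            pcts.append(table.records.contacted.mean())
        assert pcts == sorted(pcts)

    def test_distance_median_recovery_on_one_scene(self):
        params = TissueParams(
            n_dc=10, n_msc=80, ring_radius_um=60, field_um=280, distance_median_um=8.0
        )
        scene = generate_tissue_scene(params, seed=21)
        stack = render_tissue(scene, RenderConfig.for_tissue(scene, seed=21))
        cfg = default_tissue_config(
            nuclei_roles=("nuclei", "pdgfra_gfp"),
            target_roles=("opn",),
            contact_target_role=None,
            min_nucleus_area_um2=2.0,
        )
        table = run_distance_pipeline(stack, cfg)
        recovered = float(np.median(table.records.mean_signed_distance_um))
        planted = float(np.median(scene.planted_distance_um))
        assert abs(recovered - planted) <= max(scene.pixel_size_um, 0.1 * planted)

    def test_sub_threshold_debris_never_appears(self):
        params = TissueParams(n_dc=10, n_msc=5, ring_radius_um=40, field_um=220, n_debris=12)
        scene = generate_tissue_scene(params, seed=8)
        stack = render_tissue(scene, RenderConfig.for_tissue(scene, seed=8))
        table = run_distance_pipeline(stack, default_tissue_config())
        assert len(table) == 10          # duct nuclei only, no debris rows
        assert (table.records.area_um2 >= 5.0).all()
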