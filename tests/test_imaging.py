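"""Imaging stage: segmentation, morphometrics, clusters, neurites, events."""

import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.morphology import disk as disk_se

from gliastat.imaging import (
    ClusterParams,
    ImageScene,
    PhagocyticEvent,
    classify_damage_associated,
    classify_phagocytic_events,
    define_cells,
    detect_clusters,
    form_factor,
    form_factor_of_mask,
    intensity_metrics,
    neurite_length_density,
    nuclear_translocation,
    percent_nuclear_positive,
    segment_nuclei,
)
from gliastat.imaging.types import CellObject


def _scene(channels, pixel_size=1.0, background=None):
    return ImageScene(channels=channels, pixel_size=pixel_size, background=background or {})


def _cell_from_masks(nucleus, cell, label=1, pixel_size=1.0):
    return CellObject(
        label=label,
        nucleus_mask=nucleus,
        cell_mask=cell,
        area=float(cell.sum()) * pixel_size**2,
        perimeter=1.0,
        form_factor=1.0,
    )


class TestSegmentation:
    def test_blank_dapi_zero_nuclei(self):
        scene = _scene({"DAPI": np.zeros((64, 64))})
        assert segment_nuclei(scene).max() == 0

    def test_well_separated_nuclei_counted_exactly(self, cluster_scene):
        labels = segment_nuclei(cluster_scene.scene)
        assert labels.max() == cluster_scene.label_masks["nuclei"].max()

    def test_touching_disks_split_by_seeded_watershed(self):
        img = np.zeros((80, 80))
        rr, cc = draw_disk((40, 30), 10)
        img[rr, cc] = 100
        rr, cc = draw_disk((40, 46), 10)
        img[rr, cc] = 100
        labels = segment_nuclei(_scene({"DAPI": img}), threshold=50)
        assert labels.max() == 2


class TestDefineCells:
    def test_zero_cfse_cells_equal_nuclei_and_flagged(self, cluster_scene):
        scene = cluster_scene.scene
        blank = _scene({**scene.channels, "CFSE": np.zeros(scene.shape)}, scene.pixel_size)
        nuclei = segment_nuclei(scene)
        cells = define_cells(nuclei, blank)
        assert all(c.no_growth for c in cells)
        for c in cells:
            assert np.array_equal(c.cell_mask, c.nucleus_mask)

    def test_masks_match_generator_truth(self, cluster_scene):
        scene = cluster_scene.scene
        cells = define_cells(segment_nuclei(scene), scene)
        mg = cluster_scene.label_masks["microglia"]
        assert len(cells) == mg.max()
        for c in cells:
            lab = np.bincount(mg[c.nucleus_mask]).argmax()
            truth = mg == lab
            iou = (c.cell_mask & truth).sum() / (c.cell_mask | truth).sum()
            assert iou >= 0.7

    def test_raising_threshold_never_grows_cells(self, cluster_scene):
        scene = cluster_scene.scene
        nuclei = segment_nuclei(scene)
        lo = define_cells(nuclei, scene, threshold=30.0)
        hi = define_cells(nuclei, scene, threshold=90.0)
        for a, b in zip(lo, hi):
            assert b.cell_mask.sum() <= a.cell_mask.sum()

    def test_cells_are_disjoint_and_cover_nuclei(self, cluster_scene):
        scene = cluster_scene.scene
        cells = define_cells(segment_nuclei(scene), scene)
        total = np.zeros(scene.shape, dtype=int)
        for c in cells:
            assert (c.nucleus_mask & ~c.cell_mask).sum() == 0
            total += c.cell_mask
        assert total.max() == 1


class TestFormFactor:
    def test_analytic_circle_is_exactly_one(self):
        r = 7.3
        assert form_factor(math.pi * r * r, 2 * math.pi * r) == 1.0

    def test_analytic_square(self):
        s = 11.0
        assert form_factor(s * s, 4 * s) == pytest.approx(math.pi / 4)

    def test_rasterized_circle_within_two_percent(self):
        assert 0.98 <= form_factor_of_mask(disk_se(50).astype(bool)) <= 1.02

    def test_degenerate_mask_raises(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(ValueError, match="degenerate"):
            form_factor_of_mask(m)

    def test_pixel_size_invariance(self):
        m = disk_se(20).astype(bool)
        assert form_factor_of_mask(m, 0.5) == pytest.approx(form_factor_of_mask(m, 2.0))


class TestIntensity:
    def _one_cell(self):
        cell = np.zeros((20, 20), bool)
        cell[5:15, 5:15] = True
        nucleus = np.zeros_like(cell)
        nucleus[8:12, 8:12] = True
        return _cell_from_masks(nucleus, cell)

    def test_background_equal_to_signal_gives_zero_mfi(self):
        c = self._one_cell()
        scene = _scene({"CD68": np.full((20, 20), 10.0)}, background={"CD68": 10.0})
        mfi, integ = intensity_metrics(c, scene, "CD68")
        assert mfi == 0.0 and integ == 0.0

    def test_integrated_intensity_scales_with_pixel_area(self):
        c = self._one_cell()
        scene = _scene({"CD68": np.full((20, 20), 5.0)}, pixel_size=2.0)
        _, integ = intensity_metrics(c, scene, "CD68")
        assert integ == pytest.approx(5.0 * 100 * 4.0)

    def test_linearity_after_background(self):
        c = self._one_cell()
        img = np.random.default_rng(1).uniform(1, 9, (20, 20))
        m1, _ = intensity_metrics(c, _scene({"x": img}), "x")
        m2, _ = intensity_metrics(c, _scene({"x": 2 * img}), "x")
        assert m2 == pytest.approx(2 * m1)


class TestNuclearTranslocation:
    def test_equal_intensities_not_positive_at_default(self):
        cell = self._painted(1.0)
        ratio, pos = nuclear_translocation(cell[0], cell[1], "RELB")
        assert ratio == pytest.approx(1.0)
        assert not pos

    def test_three_to_one_ratio_positive(self):
        cell = self._painted(3.0)
        ratio, pos = nuclear_translocation(cell[0], cell[1], "RELB")
        assert ratio == pytest.approx(3.0)
        assert pos

    def test_percent_positive_on_generated_scene(self, cluster_scene):
        scene = cluster_scene.scene
        cells = define_cells(segment_nuclei(scene), scene)
        pct = percent_nuclear_positive(cells, scene, "RELB")
        truth_pct = 100 * np.mean(list(cluster_scene.truth_translocated.values()))
        assert pct == pytest.approx(truth_pct, abs=1.0)

    @staticmethod
    def _painted(ratio):
        cell = np.zeros((20, 20), bool)
        cell[2:18, 2:18] = True
        nucleus = np.zeros_like(cell)
        nucleus[8:12, 8:12] = True
        img = np.where(nucleus, 10.0 * ratio, np.where(cell, 10.0, 0.0))
        return _cell_from_masks(nucleus, cell), _scene({"RELB": img})


class TestClusters:
    def _grid_cells(self, n, gap_px, size=6, shape=(200, 200)):
        cells = []
        for i in range(n):
            m = np.zeros(shape, bool)
            r0 = 50
            c0 = 20 + i * (size + gap_px)
            m[r0 : r0 + size, c0 : c0 + size] = True
            nuc = np.zeros_like(m)
            nuc[r0 + 2 : r0 + 4, c0 + 2 : c0 + 4] = True
            cells.append(_cell_from_masks(nuc, m, label=i + 1))
        return cells

    def test_area_gate_rejects_small_union(self):
        # 6 contiguous 6x6 cells at 1 um/px: union 216 um^2 << 4000
        cells = self._grid_cells(6, gap_px=2)
        assert detect_clusters(cells, 1.0) == []

    def test_count_gate_rejects_few_cells(self):
        # 4 large contiguous cells: union area 4*40*40 = 6400 > 4000, but < 5 cells
        cells = []
        for i in range(4):
            m = np.zeros((300, 300), bool)
            m[100:140, 10 + i * 42 : 50 + i * 42] = True
            nuc = np.zeros_like(m)
            nuc[115:125, 20 + i * 42 : 30 + i * 42] = True
            cells.append(_cell_from_masks(nuc, m, label=i + 1))
        assert detect_clusters(cells, 1.0) == []

    def test_generated_cluster_detected_with_gates(self, cluster_scene):
        scene = cluster_scene.scene
        cells = define_cells(segment_nuclei(scene), scene)
        rois = detect_clusters(cells, scene.pixel_size)
        assert len(rois) == 1
        roi = rois[0]
        assert roi.n_cells == 6
        assert roi.area_um2 > 4000
        assert (roi.core_mask & ~roi.expanded_mask).sum() == 0

    def test_order_invariance_and_idempotence(self, cluster_scene):
        scene = cluster_scene.scene
        cells = define_cells(segment_nuclei(scene), scene)
        a = detect_clusters(cells, scene.pixel_size)
        b = detect_clusters(list(reversed(cells)), scene.pixel_size)
        assert len(a) == len(b) == 1
        assert a[0].member_labels == b[0].member_labels


class TestNeurites:
    def test_straight_segment_closed_form(self):
        img = np.zeros((100, 100))
        img[50, 0:100] = 10.0
        roi = np.ones((100, 100), bool)  # 1e4 um^2 at 1 um/px
        scene = _scene({"TUBB3": img})
        d = neurite_length_density(scene, roi, threshold=5.0)
        assert d == pytest.approx(99.0 / 1e4)

    def test_empty_roi_zero_density(self):
        scene = _scene({"TUBB3": np.zeros((50, 50))})
        roi = np.ones((50, 50), bool)
        assert neurite_length_density(scene, roi, threshold=5.0) == 0.0

    def test_damaged_cluster_density_below_undamaged(self):
        from gliastat.simulate import ClusterSpec, SceneConfig, render_coculture_scene

        def density(frac):
            cfg = SceneConfig(
                seed=11,
                clusters=(ClusterSpec(6, 5000.0, damaged=True),),
                damage_fraction_in_clusters=frac,
                n_single_cells=0,
            )
            truth = render_coculture_scene(cfg)
            return neurite_length_density(truth.scene, truth.truth_clusters[0].mask)

        assert density(0.6) < density(0.0)

    def test_damage_boundary_inclusive(self):
        assert classify_damage_associated(0.5, 1.0)  # exactly half: damaged
        assert not classify_damage_associated(0.6, 1.0)
        with pytest.raises(ValueError):
            classify_damage_associated(0.1, 0.0)


class TestEvents:
    def test_marker_logic(self):
        out = classify_phagocytic_events(
            [
                PhagocyticEvent(ctv=True, caspase3=True, tubb3=True, dapi=True),
                PhagocyticEvent(ctv=True, caspase3=False, tubb3=True, dapi=False),
            ]
        )
        assert out["apoptosis_axis_counts"]["apoptotic_soma"] == 1
        assert out["apoptosis_axis_counts"]["nonapoptotic_uptake"] == 1
        assert out["structure_axis_counts"] == {"soma": 1, "neurite": 1}

    def test_relative_frequencies(self):
        events = [PhagocyticEvent(ctv=True, tubb3=True, dapi=True)] * 3 + [
            PhagocyticEvent(ctv=True, tubb3=True, dapi=False)
        ] * 7
        out = classify_phagocytic_events(events)
        assert out["structure_axis_freq"]["soma"] == pytest.approx(0.3)
        assert out["structure_axis_freq"]["neurite"] == pytest.approx(0.7)

    def test_tubb3_negative_excluded_from_structure_axis(self):
        out = classify_phagocytic_events([PhagocyticEvent(ctv=True, tubb3=False)])
        assert out["excluded_structure_axis"] == 1
        assert out["structure_axis_counts"] == {}
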