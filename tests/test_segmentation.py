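"""Segmentation and annulus construction against brute-force oracles."""

import numpy as np
import pytest

from asipipe import (
    AnnulusSpec,
    SceneConfig,
    SegmentationParams,
    annulus_offset_sweep,
    make_annulus,
    max_project,
    segment_nuclei,
    simulate_scene,
)
from asipipe.segmentation import LabeledField

PX = 0.3


def brute_force_annulus(labels, cell_id, offset, width):
    """Naive per-pixel oracle: distance of every pixel to every nucleus pixel."""
    ys, xs = np.nonzero(labels == cell_id)
    h, w = labels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - ys) ** 2 + (xx[..., None] - xs) ** 2
    dist = np.sqrt(d2.min(axis=-1))
    ring = (dist > offset) & (dist <= offset + width)
    return ring & (labels == 0)


class TestMaxProject:
    @pytest.mark.parametrize("planes,expected", [
        ([10.0, 20.0], 20.0),
        ([7.0], 7.0),
    ])
    def test_constant_planes(self, planes, expected):
        stack = np.stack([np.full((4, 4), v) for v in planes])
        assert np.all(max_project(stack) == expected)

    def test_bright_pixel_survives(self):
        stack = np.zeros((2, 5, 5))
        stack[0, 2, 3] = 99.0
        assert max_project(stack)[2, 3] == 99.0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.zeros((0, 4, 4)))


class TestSegmentNuclei:
    def test_blank_image_yields_empty_labeling(self):
        field = segment_nuclei(np.zeros((64, 64)))
        assert field.n_cells == 0

    @pytest.mark.parametrize("seed,n", [(0, 10), (1, 40), (2, 90)])
    def test_count_and_iou_on_separated_scenes(self, seed, n):
        cfg = SceneConfig(pixel_size=PX, n_cells=n, field_shape=(620, 620),
                          seed=seed, true_asi=0.6)
        scene = simulate_scene(cfg)
        field = segment_nuclei(max_project(scene.dapi_stack))
        assert field.n_cells == scene.n_cells
        for k in range(1, scene.n_cells + 1):
            t = scene.truth_labels == k
            labs, cnts = np.unique(field.labels[t], return_counts=True)
            labs, cnts = labs[labs > 0], cnts[labs > 0]
            assert labs.size
            d = field.labels == labs[np.argmax(cnts)]
            iou = (t & d).sum() / (t | d).sum()
            assert iou >= 0.9

    def test_dumbbell_split_by_watershed(self):
        # two discs fused by a thin neck; split_touching must recover both
        img = np.zeros((80, 120))
        yy, xx = np.mgrid[0:80, 0:120]
        img[(yy - 40) ** 2 + (xx - 40) ** 2 <= 14**2] = 200.0
        img[(yy - 40) ** 2 + (xx - 80) ** 2 <= 14**2] = 200.0
        img[(np.abs(yy - 40) <= 2) & (xx >= 40) & (xx <= 80)] = 200.0
        split = segment_nuclei(img, SegmentationParams(split_touching=True))
        fused = segment_nuclei(img, SegmentationParams(split_touching=False))
        assert split.n_cells == 2
        assert fused.n_cells == 1

    def test_area_filter_drops_specks(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        img[(yy - 50) ** 2 + (xx - 50) ** 2 <= 12**2] = 200.0
        img[20:23, 20:23] = 200.0  # 9-px speck below min_nucleus_area
        field = segment_nuclei(img)
        assert field.n_cells == 1

    def test_border_nucleus_excluded_by_default(self):
        img = np.zeros((100, 100))
        yy, xx = np.mgrid[0:100, 0:100]
        img[(yy - 2) ** 2 + (xx - 50) ** 2 <= 12**2] = 200.0
        assert segment_nuclei(img).n_cells == 0
        keep = SegmentationParams(exclude_border=False)
        assert segment_nuclei(img, keep).n_cells == 1


class TestMakeAnnulus:
    def _disc_field(self, r=10, shape=(64, 64), center=None):
        h, w = shape
        cy, cx = center or (h // 2, w // 2)
        yy, xx = np.mgrid[0:h, 0:w]
        labels = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2).astype(np.int32)
        return LabeledField(labels=labels, dapi_proj=labels * 200.0)

    @pytest.mark.parametrize("offset,width", [(0, 3), (2, 3), (0, 1), (5, 4)])
    def test_pixel_exact_vs_brute_force(self, offset, width):
        field = self._disc_field()
        mask = make_annulus(field, 1, AnnulusSpec(offset=offset, width=width))
        oracle = brute_force_annulus(field.labels, 1, offset, width)
        assert np.array_equal(mask, oracle)

    def test_excludes_neighbour_nuclei(self):
        # two nuclei 2 px apart: annulus of cell 1 contains no pixel of cell 2
        labels = np.zeros((60, 60), dtype=np.int32)
        yy, xx = np.mgrid[0:60, 0:60]
        labels[(yy - 30) ** 2 + (xx - 20) ** 2 <= 8**2] = 1
        n2 = ((yy - 30) ** 2 + (xx - 38) ** 2 <= 8**2) & (labels == 0)
        labels[n2] = 2
        field = LabeledField(labels=labels, dapi_proj=labels * 100.0)
        mask = make_annulus(field, 1, AnnulusSpec(offset=0, width=3))
        assert not np.any(mask & (labels > 0))

    def test_annulus_disjoint_from_all_nuclei(self, small_scene):
        field = segment_nuclei(max_project(small_scene.dapi_stack))
        union = field.labels > 0
        for cid in field.cell_ids:
            mask = make_annulus(field, int(cid))
            assert not np.any(mask & union)

    def test_width_distance_band(self):
        field = self._disc_field(r=12, shape=(80, 80))
        offset, width = 1.0, 3.0
        mask = make_annulus(field, 1, AnnulusSpec(offset=offset, width=width))
        ys, xs = np.nonzero(field.labels == 1)
        ay, ax = np.nonzero(mask)
        d = np.sqrt(
            ((ay[:, None] - ys) ** 2 + (ax[:, None] - xs) ** 2).min(axis=1))
        assert np.all(d > offset)
        assert np.all(d < offset + width + 1)

    def test_um_unit_conversion(self):
        field = self._disc_field()
        um = make_annulus(field, 1, AnnulusSpec(offset=0, width=0.9, unit="um"),
                          pixel_size=0.3)
        px = make_annulus(field, 1, AnnulusSpec(offset=0, width=3))
        assert np.array_equal(um, px)
        with pytest.raises(ValueError, match="pixel_size"):
            make_annulus(field, 1, AnnulusSpec(offset=0, width=3, unit="um"))

    def test_invalid_inputs(self):
        field = self._disc_field()
        with pytest.raises(KeyError):
            make_annulus(field, 7)
        with pytest.raises(ValueError):
            AnnulusSpec(offset=0, width=0)
        with pytest.raises(ValueError):
            AnnulusSpec(offset=-1, width=3)


class TestOffsetSweep:
    def test_homogeneous_field_flat_in_offset(self, small_scene):
        field = segment_nuclei(max_project(small_scene.dapi_stack))
        homogeneous = np.full(field.labels.shape, 120.0)
        summary, per_cell = annulus_offset_sweep(
            field, homogeneous, offsets=[0, 1, 2, 5])
        assert np.allclose(summary["mean_asi"], 0.5)
        assert (per_cell.groupby("offset").size() == field.n_cells).all()

    def test_bright_perinuclear_ring_detected(self):
        # ring of extra signal hugging the nucleus: ASI falls once the
        # annulus is pushed past the ring
        labels = np.zeros((90, 90), dtype=np.int32)
        yy, xx = np.mgrid[0:90, 0:90]
        d = np.sqrt((yy - 45.0) ** 2 + (xx - 45.0) ** 2)
        labels[d <= 12] = 1
        field = LabeledField(labels=labels, dapi_proj=labels * 200.0)
        psmad = np.full((90, 90), 50.0)
        psmad[labels == 1] = 100.0
        psmad[(d > 12) & (d <= 15)] = 300.0   # bright ring at offset 0-3
        summary, _ = annulus_offset_sweep(field, psmad, offsets=[0, 4])
        asi_on_ring = summary.loc[summary.offset == 0, "mean_asi"].item()
        asi_past_ring = summary.loc[summary.offset == 4, "mean_asi"].item()
        assert asi_on_ring < 0.5 < asi_past_ring

    def test_single_offset_single_row(self, small_scene):
        field = segment_nuclei(max_project(small_scene.dapi_stack))
        summary, _ = annulus_offset_sweep(
            field, np.full(field.labels.shape, 10.0), offsets=[2])
        assert len(summary) == 1

    def test_no_offsets_rejected(self, small_scene):
        field = segment_nuclei(max_project(small_scene.dapi_stack))
        with pytest.raises(ValueError):
            annulus_offset_sweep(field, field.dapi_proj, offsets=[])
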