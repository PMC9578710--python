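"""NCR, PLA and IHC pipelines against synthetic ground truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from hipposhuttle.quant import (
    NcrRecord,
    SegmentationMaskSet,
    density_split,
    focus_score,
    ihc_quantify,
    ncr_for_fov,
    pla_count,
    segment_channels,
)
from hipposhuttle.synth import (
    SceneSpec,
    make_geometry,
    make_ihc_tiles,
    make_ncr_dataset,
    make_pla_scene,
    render_fluorescence,
)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="module")
def rendered_scene():
    spec = SceneSpec(shape=(256, 256), n_cells=6, seed=11)
    geometry, truth = make_geometry(spec)
    effector = np.zeros(geometry.shape)
    effector[geometry.mask("cytoplasm")] = 1.0
    effector[geometry.mask("nucleus")] = 2.0
    stack, _ = render_fluorescence(geometry, {"effector": effector}, spec, seed=3)
    return spec, geometry, truth, stack


class TestSegmentation:
    def test_nuclear_mask_recovers_ground_truth(self, rendered_scene):
        _, geometry, truth, stack = rendered_scene
        masks = segment_channels(stack)
        assert dice(masks.nuclear_mask, truth.nuclear_mask) >= 0.95

    def test_blank_image_gives_empty_masks(self):
        masks = segment_channels(np.zeros((2, 64, 64)))
        assert not masks.nuclear_mask.any()
        assert not masks.cell_mask.any()

    def test_touching_cells_keep_distinct_nuclei(self):
        from skimage.measure import label

        stack = np.zeros((2, 64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        # two abutting cells sharing a boundary, nuclei well separated
        cell = (np.hypot(rr - 32, cc - 20) < 14) | (np.hypot(rr - 32, cc - 44) < 14)
        nuc = (np.hypot(rr - 32, cc - 20) < 5) | (np.hypot(rr - 32, cc - 44) < 5)
        stack[0][nuc] = 100.0
        stack[1][cell] = 80.0
        masks = segment_channels(stack)
        assert label(masks.nuclear_mask).max() == 2

    def test_mask_set_invariants_enforced(self):
        nuc = np.zeros((4, 4), bool)
        nuc[1, 1] = True
        with pytest.raises(ValueError, match="contained"):
            SegmentationMaskSet(nuc, np.zeros((4, 4), bool), np.zeros((4, 4), bool))


class TestNcr:
    def test_uniform_image_gives_unit_ncr(self, rendered_scene):
        _, geometry, _, stack = rendered_scene
        masks = segment_channels(stack)
        rec = ncr_for_fov(np.full(geometry.shape, 37.0), masks)
        assert rec.ncr == pytest.approx(1.0)

    def test_direct_means(self):
        nuc = np.zeros((8, 8), bool)
        nuc[2:4, 2:4] = True
        cell = np.zeros((8, 8), bool)
        cell[1:6, 1:6] = True
        masks = SegmentationMaskSet(nuc, cell, cell & ~nuc)
        img = np.where(nuc, 200.0, 100.0)
        rec = ncr_for_fov(img, masks)
        assert rec.ncr == pytest.approx(2.0)
        assert rec.cell_count == 1

    def test_scale_invariance(self, rendered_scene):
        _, geometry, _, stack = rendered_scene
        masks = segment_channels(stack)
        r1 = ncr_for_fov(stack[1], masks).ncr
        r2 = ncr_for_fov(stack[1] * 7.3, masks).ncr
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_empty_cytoplasm_flags_record(self):
        nuc = np.zeros((8, 8), bool)
        nuc[2:4, 2:4] = True
        masks = SegmentationMaskSet(nuc, nuc.copy(), np.zeros((8, 8), bool))
        rec = ncr_for_fov(np.ones((8, 8)), masks)
        assert not rec.valid and np.isnan(rec.ncr)

    def test_rendered_fov_ncr_matches_truth_within_5_percent(self, rendered_scene):
        _, geometry, _, stack = rendered_scene
        masks = segment_channels(stack)
        rec = ncr_for_fov(stack[1], masks)
        assert rec.ncr == pytest.approx(2.0, rel=0.05)


class TestDensitySplit:
    def test_mean_threshold(self):
        recs = [
            NcrRecord("a", 10, 1, 1, 1.0),
            NcrRecord("b", 30, 1, 1, 1.0),
        ]
        out = density_split(recs)
        assert out["mean_cell_count"] == 20
        assert [r.fov_id for r in out["low"]] == ["a"]
        assert [r.fov_id for r in out["high"]] == ["b"]

    def test_ties_go_high(self):
        recs = [NcrRecord(str(i), 5, 1, 1, 1.0) for i in range(3)]
        out = density_split(recs)
        assert out["low"] == [] and len(out["high"]) == 3

    def test_rejects_too_few_records(self):
        with pytest.raises(ValueError):
            density_split([NcrRecord("a", 1, 1, 1, 1.0)])

    def test_ncr_decreases_with_density_in_generated_dataset(self):
        fovs = make_ncr_dataset(10, seed=2, spec=SceneSpec(shape=(192, 192), n_cells=4))
        records = []
        for i, (stack, truth) in enumerate(fovs):
            masks = segment_channels(stack)
            rec = ncr_for_fov(stack[1], masks, fov_id=str(i))
            assert rec.valid
            records.append(rec)
        out = density_split(records)
        assert out["low"] and out["high"]
        med = lambda rs: np.median([r.ncr for r in rs])
        assert med(out["low"]) > med(out["high"])


class TestPla:
    @staticmethod
    def _disk_scene():
        """One circular nucleus, 3 dots inside, 2 in the dilation ring."""
        h = w = 128
        rr, cc = np.mgrid[0:h, 0:w]
        nuc = np.hypot(rr - 64, cc - 64) < 20
        nuclei_img = np.where(nuc, 150.0, 5.0)
        dot_img = np.full((h, w), 3.0)
        for r0, c0 in [(60, 60), (64, 70), (70, 62), (64, 90), (40, 64)]:
            dot_img[np.hypot(rr - r0, cc - c0) < 2] = 180.0
        return nuclei_img, dot_img

    def test_constructed_counts(self):
        nuclei_img, dot_img = self._disk_scene()
        res = pla_count(nuclei_img, dot_img, dilate_iterations=30)
        assert res.n_nuclei == 1
        assert (res.dots_nuclear, res.dots_cytoplasmic) == (3, 2)
        assert res.dots_per_nucleus == pytest.approx(3.0)

    def test_zero_dilation_empties_the_ring(self):
        nuclei_img, dot_img = self._disk_scene()
        res = pla_count(nuclei_img, dot_img, dilate_iterations=0)
        assert res.dots_cytoplasmic == 0
        assert res.dots_unassigned == 2

    def test_counts_partition_detected_dots(self):
        nuclei_img, dot_img, _ = make_pla_scene(3, 8.0, 4.0, seed=5)
        res = pla_count(nuclei_img, dot_img)
        assert res.dots_total == res.dots_nuclear + res.dots_cytoplasmic + res.dots_unassigned
        assert res.dots_nuclear >= 0 and res.dots_cytoplasmic >= 0

    def test_no_nuclei_flags_result(self):
        img = np.full((64, 64), 5.0)
        dots = np.full((64, 64), 5.0)
        dots[30:32, 30:32] = 200.0
        res = pla_count(img, dots)
        assert not res.valid
        assert res.n_nuclei == 0 and res.dots_nuclear == 0


class TestIhc:
    def test_tissueless_tile_is_excluded(self):
        tiles, _ = make_ihc_tiles(1, tissue_fractions=[0.0], seed=0)
        recs = ihc_quantify(tiles, tile_area_mm2=1.0)
        assert recs[0].excluded

    def test_low_tissue_tile_excluded_at_cutoff(self):
        tiles, truth = make_ihc_tiles(1, tissue_fractions=[0.3], seed=1)
        recs = ihc_quantify(tiles, tile_area_mm2=1.0, tissue_fraction_cutoff=0.5)
        assert recs[0].excluded

    def test_full_tissue_density(self):
        # 5 positive nuclei stamped deterministically on a full-tissue tile
        tile = np.full((400, 400), 0.35)
        rr, cc = np.mgrid[0:400, 0:400]
        for r0, c0 in [(50, 50), (120, 300), (200, 200), (300, 80), (350, 350)]:
            tile[np.hypot(rr - r0, cc - c0) < 3] = 1.2
        recs = ihc_quantify([tile], tile_area_mm2=1.0)
        assert not recs[0].excluded
        assert recs[0].tissue_fraction == pytest.approx(1.0)
        assert recs[0].positive_nuclei == 5
        assert recs[0].density == pytest.approx(5.0)

    def test_unknown_resolution_rejected(self):
        with pytest.raises(ValueError, match="area"):
            ihc_quantify([np.zeros((10, 10))])

    def test_density_invariant_to_binning(self):
        tiles, _ = make_ihc_tiles(4, tissue_fractions=(0.7, 0.95),
                                  densities_per_mm2=(40.0,), seed=7)
        r1 = ihc_quantify(tiles, tile_area_mm2=1.0, binning=1)
        r2 = ihc_quantify(tiles, tile_area_mm2=1.0, binning=2)
        for a, b in zip(r1, r2):
            if not a.excluded and a.positive_nuclei > 0:
                assert b.density == pytest.approx(a.density, rel=0.10)

    def test_density_rank_recovery(self):
        tiles, truth = make_ihc_tiles(
            12, tissue_fractions=(0.6, 0.95),
            densities_per_mm2=(2.0, 10.0, 50.0), seed=3,
        )
        recs = ihc_quantify(tiles, tile_area_mm2=1.0)
        from scipy.stats import spearmanr

        true_d = [t["density"] for t in truth.counts["tiles"]]
        got_d = [r.density for r in recs]
        rho = spearmanr(true_d, got_d).statistic
        assert rho >= 0.9


def test_focus_score_orders_sharp_before_blurred(rendered_scene):
    _, _, _, stack = rendered_scene
    sharp = stack[0]
    blurred = ndi.gaussian_filter(sharp, 4.0)
    assert focus_score(sharp) > focus_score(blurred)
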