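import math

import numpy as np
import pandas as pd
import pytest

from cytoquant import imgproc, synthkit


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentAndTrack:
    def test_nucleus_iou_vs_truth(self, small_scene):
        scene, images, itruth, _ = small_scene
        _, nuc_masks, tracks = imgproc.segment_and_track(images)
        truth0 = itruth.nucleus_masks[0]
        for lab in np.unique(truth0)[1:]:
            tmask = truth0 == lab
            best = max(
                (_iou(tmask, nuc_masks[0] == s) for s in np.unique(nuc_masks[0])[1:]),
                default=0.0,
            )
            assert best > 0.8

    def test_single_static_cell_single_track(self):
        spec = synthkit.SyntheticTraceSpec(n_cells=1, n_frames=20, event_rate=0.0,
                                           noise_sd=0.0, seed=0)
        _, truth = synthkit.gen_trace_ensemble(spec)
        scene = synthkit.SyntheticSceneSpec(image_shape=(96, 96), n_lipoplexes=0)
        images, _ = synthkit.gen_image_sequence(scene, truth, seed=0)
        _, _, tracks = imgproc.segment_and_track(images)
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 20

    def test_cell_leaving_fov_terminates_track(self):
        spec = synthkit.SyntheticTraceSpec(n_cells=1, n_frames=20, event_rate=0.0,
                                           noise_sd=0.0, seed=0)
        _, truth = synthkit.gen_trace_ensemble(spec)
        scene = synthkit.SyntheticSceneSpec(
            image_shape=(96, 96), n_lipoplexes=0, cell_drift_px_per_frame=(0.0, 8.0))
        images, _ = synthkit.gen_image_sequence(scene, truth, seed=0)
        _, _, tracks = imgproc.segment_and_track(images)
        main = tracks[tracks["track_id"] == 1]
        assert main["frame"].max() < 19  # gone before the last frame

    def test_empty_frames_no_tracks(self):
        images = {"nuclear": np.zeros((3, 64, 64)), "eGFP": np.zeros((3, 64, 64))}
        cell, nuc, tracks = imgproc.segment_and_track(images)
        assert tracks.empty
        assert cell.max() == 0 and nuc.max() == 0


class TestMaskLipoplexes:
    def test_blob_only_in_z2_masked_in_z1(self):
        z1 = np.zeros((50, 50))
        z2 = np.zeros((50, 50))
        z2[20:23, 20:23] = 100.0
        mask = imgproc.mask_lipoplexes(z1, z2, intensity_threshold=50, margin_px=3)
        assert mask[21, 21] > 0
        assert mask[21, 25] > 0  # dilated margin
        assert mask[21, 30] == 0

    def test_blank_frames_empty_mask(self):
        z = np.zeros((30, 30))
        assert imgproc.mask_lipoplexes(z, z, 10.0).max() == 0

    def test_border_blob_clipped_no_error(self):
        z1 = np.zeros((40, 40))
        z1[0:2, 38:40] = 100.0
        mask = imgproc.mask_lipoplexes(z1, np.zeros_like(z1), 50, margin_px=3)
        assert mask.shape == z1.shape
        assert mask[0, 39] > 0


class TestMeasureTraces:
    def _uniform_setup(self, v=20.0, b=5.0):
        h = w = 60
        img = np.full((h, w), b)
        cells = np.zeros((h, w), dtype=np.int32)
        nucs = np.zeros((h, w), dtype=np.int32)
        yy, xx = np.mgrid[0:h, 0:w]
        cell = (yy - 30) ** 2 + (xx - 30) ** 2 <= 15 ** 2
        nuc = (yy - 30) ** 2 + (xx - 30) ** 2 <= 6 ** 2
        cells[cell] = 1
        nucs[nuc] = 1
        img[cell & ~nuc] = v + b
        images = {"siRNA": img[None], "eGFP": img[None]}
        lips = np.zeros((1, h, w), dtype=np.int32)
        return images, cells[None], nucs[None], lips

    def test_uniform_cytosol_corrected_median(self):
        images, cells, nucs, lips = self._uniform_setup(v=20.0, b=5.0)
        table = imgproc.measure_traces(images, cells, nucs, lips)
        assert table["median_siRNA_cytosolmask"].iloc[0] == pytest.approx(20.0)

    def test_bright_blob_excluded_by_lipoplex_mask(self):
        images, cells, nucs, lips = self._uniform_setup(v=20.0, b=5.0)
        images["siRNA"][0][30, 40] = 1e6
        lips[0][30, 40] = 1
        table = imgproc.measure_traces(images, cells, nucs, lips)
        assert table["median_siRNA_cytosolmask"].iloc[0] == pytest.approx(20.0)

    def test_fully_masked_cell_flagged_missing(self):
        images, cells, nucs, lips = self._uniform_setup()
        lips[0][cells[0] > 0] = 1  # everything lipoplex-masked
        table = imgproc.measure_traces(images, cells, nucs, lips)
        assert np.isnan(table["median_siRNA_cytosolmask"].iloc[0])
        assert "empty_cytosol_mask" in table["flags"].iloc[0]

    def test_constant_offset_invariance(self):
        images, cells, nucs, lips = self._uniform_setup()
        t1 = imgproc.measure_traces(images, cells, nucs, lips)
        images2 = {k: v + 37.0 for k, v in images.items()}
        t2 = imgproc.measure_traces(images2, cells, nucs, lips)
        for col in ("median_siRNA_cytosolmask", "median_siRNA_cellmask", "median_eGFP_nucleusmask"):
            assert t1[col].iloc[0] == pytest.approx(t2[col].iloc[0])

    def test_rendered_scene_measurements_recover_traces(self, small_scene):
        scene, images, itruth, trace_truth = small_scene
        from cytoquant import calibration as cal

        table = imgproc.measure_traces(images, itruth.cell_masks, itruth.nucleus_masks,
                                       itruth.lipoplex_masks)
        ref, blank = synthkit.gen_reference_stack(scene)
        model = cal.build_reference(ref, blank)
        ev = trace_truth.events.iloc[0]
        fr = int(ev.frame) + 1
        row = table[(table.track_id == int(ev.track_id) + 1) & (table.frame == fr)].iloc[0]
        conc = cal.to_concentration(row.median_siRNA_cytosolmask,
                                    (row.centroid_row, row.centroid_col), model)
        assert conc == pytest.approx(trace_truth.traces_clean[int(ev.track_id), fr], rel=0.05)


class TestGeometry:
    def test_diameter_closed_form(self):
        # one particle of area pi µm² -> diameter 2 µm
        img = np.zeros((40, 40))
        # 314 pixels at 0.1 µm/px -> area 3.14 µm² ~ pi -> d ~ 2
        yy, xx = np.mgrid[0:40, 0:40]
        img[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = 10.0
        n_px = int((img > 1).sum())
        d = imgproc.lipoplex_diameters(img, 1.0, 0.1)
        assert d[0] == pytest.approx(2 * math.sqrt(n_px * 0.01 / math.pi))

    def test_diameter_hand_arithmetic_79px(self):
        img = np.zeros((20, 20))
        img.flat[:79] = 10.0  # 79 contiguous pixels
        d = imgproc.lipoplex_diameters(img, 1.0, 0.1)
        assert len(d) == 1
        assert d[0] == pytest.approx(1.003, abs=2e-3)

    def test_blank_image_no_particles(self):
        assert imgproc.lipoplex_diameters(np.zeros((10, 10)), 1.0, 0.1).size == 0

    def test_cytosol_volume_hand_arithmetic(self):
        v = imgproc.cytosol_volume([100.0] * 10, [20.0] * 5, 1.0)
        assert v == pytest.approx(900.0)

    def test_cytosol_volume_zero(self):
        assert imgproc.cytosol_volume([50.0, 50.0], [50.0, 50.0], 2.0) == 0.0

    def test_nucleus_larger_than_cell_rejected(self):
        with pytest.raises(ValueError):
            imgproc.cytosol_volume([10.0], [20.0], 1.0)

    def test_synthetic_geometry_matches_typical_cytosol_volume(self):
        # default scene geometry, stacked over ~11 planes at 1 µm, should
        # emulate the typical ~5000 fL cytosol (IQR 3800-5900 fL)
        scene = synthkit.SyntheticSceneSpec()
        cell_area = math.pi * scene.cell_radius_um ** 2
        nuc_area = math.pi * scene.nucleus_radius_um ** 2
        v = imgproc.cytosol_volume([cell_area] * 11, [nuc_area] * 5, 1.0)
        assert 3800 < v < 5900


def test_frame_pair_validation():
    with pytest.raises(ValueError):
        imgproc.FramePair(z1=np.zeros((4, 4)), z2=np.zeros((5, 5)))
    with pytest.raises(ValueError):
        imgproc.FramePair(z1=np.zeros((4, 4)), z2=np.zeros((4, 4)), frame_index=-1)
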