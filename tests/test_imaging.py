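"""Background correction, puncta detection, AP/AL logic, segmentation and
tracking."""

import numpy as np
import pytest

from autoprofiler.imaging import (
    DetectionParams,
    Punctum,
    classify_puncta,
    detect_spots,
    rolling_ball_correct,
    segment_cells,
    track_cells,
)
from autoprofiler.synthgen import render_gaussian_spots, two_cell_crossing


def _punctum(pixels, channel="TRITC", label=1):
    pix = np.array(pixels, dtype=np.intp)
    return Punctum(label=label, frame=0, channel=channel, pixels=pix,
                   centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())))


class TestRollingBall:
    def test_flat_field_removed_entirely(self, detection_params):
        corrected = rolling_ball_correct(np.full((48, 48), 11.0), detection_params)
        assert np.allclose(corrected, 0.0)

    def test_radius_in_pixels(self, detection_params):
        assert detection_params.ball_radius_px == pytest.approx(0.98 / 0.25)

    def test_subpixel_radius_error_names_pixel_size(self):
        params = DetectionParams(rolling_ball_radius_um=0.98, pixel_size_um=1.5)
        with pytest.raises(ValueError, match="1.5"):
            rolling_ball_correct(np.zeros((8, 8)), params)

    def test_spots_preserved_broad_background_removed(self, detection_params):
        yy, xx = np.mgrid[0:128, 0:128]
        broad = 50.0 * np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 40.0**2))
        centers = np.array([[40, 40], [64, 90], [90, 50]])
        spots = render_gaussian_spots((128, 128), centers, 30.0,
                                      detection_params.spot_diameter_px)
        corrected = rolling_ball_correct(broad + spots, detection_params)
        for r, c in centers:
            assert corrected[r, c] == pytest.approx(30.0, rel=0.05)
        spot_free = corrected[:20, :20]
        assert spot_free.max() < 0.1 * 50.0

    def test_approximately_idempotent(self, detection_params):
        # a second pass can only remove the small slope-dependent residual
        # of the first: it never raises values and its effect is bounded by a
        # few percent of the image's dynamic range (exact on flat fields)
        yy, xx = np.mgrid[0:96, 0:96]
        img = 20.0 + 40.0 * np.exp(-((yy - 48) ** 2 + (xx - 48) ** 2) / (2 * 30.0**2))
        once = rolling_ball_correct(img, detection_params)
        twice = rolling_ball_correct(once, detection_params)
        assert (twice <= once + 1e-9).all()
        assert np.abs(twice - once).max() <= 0.05 * np.ptp(img)

    def test_background_bounded_by_image(self, detection_params, rng):
        img = rng.random((40, 40)) * 30
        corrected = rolling_ball_correct(img, detection_params)
        assert (corrected >= 0).all()
        assert (corrected <= img + 1e-9).all()


class TestDetectSpots:
    def test_blank_frame_yields_empty_set(self, detection_params):
        assert detect_spots(np.zeros((64, 64)), detection_params, "GFP") == []

    def test_snr10_spots_fully_recovered(self, detection_params, rng):
        centers = np.array([[r, c] for r in range(20, 200, 40) for c in range(20, 200, 40)])[:20]
        raw = 10.0 + render_gaussian_spots((200, 200), centers, 20.0,
                                           detection_params.spot_diameter_px)
        raw += rng.normal(0, 2.0, (200, 200))
        corrected = rolling_ball_correct(raw, detection_params)
        spots = detect_spots(corrected, detection_params, "GFP")
        det = np.array([s.centroid for s in spots])
        hits = sum(
            1 for c0 in centers
            if np.min(np.hypot(det[:, 0] - c0[0], det[:, 1] - c0[1])) <= 2
        )
        assert hits / len(centers) == 1.0  # recall
        assert hits / len(det) == 1.0  # precision

    def test_tritc_threshold_is_stricter(self, detection_params, rng):
        # same frame, higher contrast cutoff (6 vs 5): TRITC detections are a
        # subset of GFP detections
        centers = np.array([[20 + 24 * i, 100] for i in range(6)])
        amps = np.linspace(8, 30, 6)
        img = np.full((180, 180), 10.0)
        for (r, c), a in zip(centers, amps):
            img += render_gaussian_spots((180, 180), np.array([[r, c]]), a,
                                         detection_params.spot_diameter_px)
        img += rng.normal(0, 2.0, (180, 180))
        corrected = rolling_ball_correct(img, detection_params)
        gfp = {(round(s.centroid[0]), round(s.centroid[1]))
               for s in detect_spots(corrected, detection_params, "GFP")}
        tritc = {(round(s.centroid[0]), round(s.centroid[1]))
                 for s in detect_spots(corrected, detection_params, "TRITC")}
        assert tritc <= gfp

    def test_translation_equivariance(self, detection_params, rng):
        centers = np.array([[40, 40], [80, 120], [120, 60]])
        raw = 10.0 + render_gaussian_spots((160, 160), centers, 25.0,
                                           detection_params.spot_diameter_px)
        raw += rng.normal(0, 2.0, (160, 160))
        corrected = rolling_ball_correct(raw, detection_params)
        shifted = np.roll(corrected, (4, 7), axis=(0, 1))
        a = sorted((round(s.centroid[0] + 4, 4), round(s.centroid[1] + 7, 4))
                   for s in detect_spots(corrected, detection_params, "GFP"))
        b = sorted((round(s.centroid[0], 4), round(s.centroid[1], 4))
                   for s in detect_spots(shifted, detection_params, "GFP"))
        assert a == b

    def test_negative_frame_rejected(self, detection_params):
        with pytest.raises(ValueError):
            detect_spots(np.full((8, 8), -1.0), detection_params, "GFP")


class TestClassifyPuncta:
    def test_no_tritc_means_no_ap_no_al(self):
        gfp = [_punctum([(3, 3), (3, 4)], channel="GFP")]
        ap, al = classify_puncta(gfp, [], (10, 10))
        assert ap == [] and al == []

    def test_one_pixel_overlap_rule(self):
        # 3 TRITC puncta; 2 overlap a GFP punctum by exactly one pixel
        gfp = [_punctum([(2, 2)], "GFP"), _punctum([(6, 6)], "GFP")]
        t1 = _punctum([(2, 2), (2, 3)])
        t2 = _punctum([(6, 6), (7, 6)])
        t3 = _punctum([(9, 0), (9, 1)])
        ap, al = classify_puncta(gfp, [t1, t2, t3], (10, 10))
        assert {p.label for p in ap} == {t1.label, t2.label} and len(ap) == 2
        assert al == [t3]
        assert all(p.cls == "AP" for p in ap) and t3.cls == "AL"

    def test_partition_conserves_tritc_count(self, rng):
        tritc = [_punctum([(int(r), int(c))], label=i)
                 for i, (r, c) in enumerate(rng.integers(0, 30, (25, 2)))]
        gfp = [_punctum([(int(r), int(c))], "GFP")
               for r, c in rng.integers(0, 30, (10, 2))]
        ap, al = classify_puncta(gfp, tritc, (30, 30))
        assert len(ap) + len(al) == len(tritc)

    def test_gfp_only_puncta_stay_unassigned(self):
        gfp = [_punctum([(5, 5)], "GFP")]
        ap, al = classify_puncta(gfp, [], (10, 10))
        assert ap == [] and al == []
        assert gfp[0].cls == "unassigned"

    def test_shape_mismatch_rejected(self):
        bad = _punctum([(50, 50)])
        with pytest.raises(ValueError):
            classify_puncta([], [bad], (10, 10))


class TestSegmentCells:
    def test_single_blob_single_label(self, rng):
        yy, xx = np.mgrid[0:128, 0:128]
        truth = np.hypot(yy - 64, xx - 64) <= 25
        img = np.where(truth, 100.0, 0.0) + rng.normal(0, 2, (128, 128)) + 10
        labels = segment_cells(img)
        assert labels.max() == 1
        overlap = ((labels > 0) & truth).sum() / truth.sum()
        assert overlap >= 0.95

    def test_empty_frame_gives_empty_labels(self, rng):
        assert segment_cells(np.zeros((64, 64))).max() == 0
        noise = 10 + rng.normal(0, 2, (64, 64))
        assert segment_cells(noise).max() == 0

    def test_touching_cells_split_by_watershed(self, rng):
        yy, xx = np.mgrid[0:128, 0:128]
        m1 = np.hypot(yy - 64, xx - 50) <= 22
        m2 = np.hypot(yy - 64, xx - 90) <= 22
        img = np.where(m1 | m2, 100.0, 0.0) + rng.normal(0, 2, (128, 128)) + 10
        labels = segment_cells(img)
        assert labels.max() == 2


class TestTrackCells:
    def test_stationary_cell_single_track(self):
        frame = np.zeros((32, 32), dtype=np.int32)
        frame[10:20, 10:20] = 1
        tracks = track_cells([frame] * 10)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_crossing_cells_keep_identity(self):
        stack, _ = two_cell_crossing()
        tracks = track_cells(stack)
        assert len(tracks) == 2
        for t in tracks:
            assert len(t) == len(stack)
            assert t.labels[0] == t.labels[len(stack) - 1] == t.track_id

    def test_division_keeps_one_daughter_with_parent_id(self):
        stack = np.zeros((4, 60, 80), dtype=np.int32)
        yy, xx = np.mgrid[0:60, 0:80]
        for t in range(2):
            stack[t][np.hypot(yy - 30, xx - 40) <= 14] = 1
        for t in range(2, 4):
            stack[t][np.hypot(yy - 30, xx - 32) <= 10] = 2
            stack[t][np.hypot(yy - 30, xx - 50) <= 10] = 3
        tracks = track_cells(stack)
        assert len(tracks) == 1  # the second daughter is discarded
        assert sorted(tracks[0].labels) == [0, 1, 2, 3]

    def test_nonmonotone_timestamps_rejected(self):
        frame = np.zeros((8, 8), dtype=np.int32)
        with pytest.raises(ValueError):
            track_cells([frame, frame], times=[1.0, 0.5])

    def test_track_ids_stable_under_appending(self):
        stack, _ = two_cell_crossing()
        short = track_cells(stack[:10])
        full = track_cells(stack)
        for a, b in zip(short, full):
            assert a.track_id == b.track_id
            assert all(b.labels[f] == a.labels[f] for f in a.labels)
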