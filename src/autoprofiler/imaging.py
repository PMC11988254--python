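"""Image processing: background correction, puncta detection, AP/AL channel
logic, cell segmentation and single-cell tracking.

The tandem pHluorin-mKate2-LC3 reporter makes autophagosomes (APs) visible in
both the GFP (pHluorin) and TRITC (mKate2) channels, while the acidic
environment of autolysosomes (ALs) quenches pHluorin so they appear in TRITC
only.  Classification therefore reduces to set logic on detected puncta:
TRITC puncta overlapping any GFP punctum are APs, the remainder are ALs, and
GFP-only detections (candidate fast-moving autophagosomes) are kept but
counted in neither class.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

__all__ = [
    "DetectionParams",
    "Punctum",
    "CellTrack",
    "rolling_ball_correct",
    "detect_spots",
    "classify_puncta",
    "segment_cells",
    "track_cells",
]


@dataclass(frozen=True)
class DetectionParams:
    """Physical detection parameters; lengths in micrometres.

    The contrast thresholds act as SNR-like cutoffs: a candidate seed passes
    if (seed peak - local median background) / robust noise SD of the
    corrected frame exceeds the channel's threshold (5 for GFP, 6 for TRITC
    by default).
    """

    rolling_ball_radius_um: float = 0.98
    spot_diameter_um: float = 0.8
    contrast_gfp: float = 5.0
    contrast_tritc: float = 6.0
    pixel_size_um: float = 0.25

    def __post_init__(self):
        for name in ("rolling_ball_radius_um", "spot_diameter_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.contrast_gfp < 0 or self.contrast_tritc < 0:
            raise ValueError("contrast thresholds must be >= 0")

    def contrast_for(self, channel: str) -> float:
        channel = channel.upper()
        if channel == "GFP":
            return self.contrast_gfp
        if channel == "TRITC":
            return self.contrast_tritc
        raise ValueError(f"unknown channel {channel!r}")

    @property
    def ball_radius_px(self) -> float:
        return self.rolling_ball_radius_um / self.pixel_size_um

    @property
    def spot_diameter_px(self) -> float:
        return self.spot_diameter_um / self.pixel_size_um


@dataclass
class Punctum:
    """One detected vesicle candidate."""

    label: int
    frame: int
    channel: str  # provenance: GFP | TRITC
    pixels: np.ndarray  # (k, 2) array of (row, col), 0-based
    centroid: tuple[float, float]
    peak_value: float = 0.0
    cls: str = "unassigned"  # AP | AL | unassigned

    @property
    def area(self) -> int:
        return len(self.pixels)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class CellTrack:
    """One cell followed through time: per-frame label in the label stack."""

    track_id: int
    parent_id: int | None = None
    labels: dict[int, int] = field(default_factory=dict)  # frame -> label value

    @property
    def first_frame(self) -> int:
        return min(self.labels)

    @property
    def last_frame(self) -> int:
        return max(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def rolling_ball_correct(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Subtract a rolling-ball background estimate (ball radius in um).

    The background is the envelope of a ball rolled under the intensity
    surface, so ``background <= image`` pointwise and the corrected frame is
    non-negative.
    """
    radius_px = params.ball_radius_px
    if radius_px < 1:
        raise ValueError(
            f"rolling-ball radius {params.rolling_ball_radius_um} um is below one "
            f"pixel at pixel size {params.pixel_size_um} um/px"
        )
    img = np.asarray(image, dtype=np.float64)
    background = rolling_ball(img, radius=radius_px)
    return np.clip(img - background, 0.0, None)


def _robust_noise_sd(frame: np.ndarray) -> float:
    med = np.median(frame)
    return 1.4826 * np.median(np.abs(frame - med))


def _local_median_background(frame, row, col, r_in, r_out, q=50.0):
    h, w = frame.shape
    r = int(np.ceil(r_out))
    r0, r1 = max(0, row - r), min(h, row + r + 1)
    c0, c1 = max(0, col - r), min(w, col + r + 1)
    win = frame[r0:r1, c0:c1]
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - row, xx - col)
    ann = win[(d >= r_in) & (d <= r_out)]
    if ann.size == 0:
        return float(np.percentile(win, q))
    return float(np.percentile(ann, q))


def _grow_region(frame, seed, stop_frac, max_radius):
    """Region growing: 8-connected pixels above stop_frac of the seed value,
    within max_radius of the seed."""
    h, w = frame.shape
    sr, sc = seed
    floor = stop_frac * frame[sr, sc]
    visited = {(sr, sc)}
    queue = collections.deque([(sr, sc)])
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w) or (nr, nc) in visited:
                    continue
                if np.hypot(nr - sr, nc - sc) > max_radius:
                    continue
                if frame[nr, nc] >= floor:
                    visited.add((nr, nc))
                    queue.append((nr, nc))
    return np.array(sorted(visited), dtype=np.intp)


def detect_spots(
    corrected: np.ndarray,
    params: DetectionParams,
    channel: str,
    frame_index: int = 0,
    grow_stop_frac: float = 0.5,
    max_diameter_factor: float = 3.0,
) -> list[Punctum]:
    """Detect bright puncta of roughly ``spot_diameter_um`` in a corrected frame.

    Candidate seeds are local maxima of a difference-of-Gaussians band-pass
    response at the spot scale; a seed is accepted when its contrast
    (peak minus local median background, in units of the frame's robust noise
    SD) reaches the channel's threshold.  Accepted seeds are grown outward
    while intensity stays above ``grow_stop_frac`` of the seed value, bounded
    at ``max_diameter_factor`` times the spot diameter.
    """
    frame = np.asarray(corrected, dtype=np.float64)
    if frame.min() < 0:
        raise ValueError("detect_spots expects a non-negative corrected frame")
    d_px = params.spot_diameter_px
    sigma = d_px / 2.355  # FWHM -> Gaussian sigma
    dog = gaussian(frame, sigma, preserve_range=True) - gaussian(
        frame, 1.6 * sigma, preserve_range=True
    )
    noise_sd = _robust_noise_sd(frame)
    if noise_sd <= 0:
        noise_sd = max(frame.std(), 1e-12)
    threshold = params.contrast_for(channel)
    peaks = peak_local_max(
        dog,
        min_distance=max(1, int(round(d_px / 2))),
        threshold_abs=1e-9,
        exclude_border=False,
    )
    puncta: list[Punctum] = []
    claimed = np.zeros(frame.shape, dtype=bool)
    # strongest seeds first so overlapping candidates defer to brighter ones
    order = np.argsort(-frame[peaks[:, 0], peaks[:, 1]]) if len(peaks) else []
    for idx in order:
        r, c = int(peaks[idx, 0]), int(peaks[idx, 1])
        if claimed[r, c]:
            continue
        peak_val = frame[r, c]
        # upper-quantile annulus background: an elongated ridge (e.g. a
        # background-subtraction artifact along a cell edge) raises the
        # annulus quantile and is rejected, while an isolated punctum does not
        local_bg = _local_median_background(frame, r, c, 0.75 * d_px, 1.5 * d_px, q=75.0)
        contrast = (peak_val - local_bg) / noise_sd
        if contrast < threshold:
            continue
        pixels = _grow_region(frame, (r, c), grow_stop_frac, max_diameter_factor * d_px / 2)
        claimed[pixels[:, 0], pixels[:, 1]] = True
        puncta.append(
            Punctum(
                label=len(puncta) + 1,
                frame=frame_index,
                channel=channel.upper(),
                pixels=pixels,
                centroid=(float(pixels[:, 0].mean()), float(pixels[:, 1].mean())),
                peak_value=float(peak_val),
            )
        )
    return puncta


def classify_puncta(
    gfp_puncta: list[Punctum],
    tritc_puncta: list[Punctum],
    shape: tuple[int, int],
) -> tuple[list[Punctum], list[Punctum]]:
    """Partition TRITC puncta into APs and ALs by GFP overlap.

    AP = TRITC puncta sharing at least one pixel with the union of GFP
    puncta; AL = the remaining TRITC puncta.  GFP-only puncta are left
    unassigned (candidate fast-moving autophagosomes) and counted in neither
    class.  ``|AP| + |AL| == |TRITC|`` always.
    """
    gfp_union = np.zeros(shape, dtype=bool)
    for p in gfp_puncta:
        if (p.pixels[:, 0].max(initial=-1) >= shape[0]) or (
            p.pixels[:, 1].max(initial=-1) >= shape[1]
        ):
            raise ValueError("GFP punctum outside the stated frame shape")
        gfp_union[p.pixels[:, 0], p.pixels[:, 1]] = True
    ap, al = [], []
    for p in tritc_puncta:
        if (p.pixels[:, 0].max(initial=-1) >= shape[0]) or (
            p.pixels[:, 1].max(initial=-1) >= shape[1]
        ):
            raise ValueError("TRITC punctum outside the stated frame shape")
        if gfp_union[p.pixels[:, 0], p.pixels[:, 1]].any():
            p.cls = "AP"
            ap.append(p)
        else:
            p.cls = "AL"
            al.append(p)
    return ap, al


def segment_cells(
    frame: np.ndarray,
    smooth_sigma: float = 3.0,
    min_area: int = 200,
    peak_min_distance: int = 15,
) -> np.ndarray:
    """Label cells in a single-channel frame.

    Built-in fallback segmenter (externally supplied masks can bypass this
    stage): Gaussian-smoothed intensity thresholding followed by a
    distance-transform watershed to split touching cells.  Returns a label
    image with positive integer labels and 0 background; an all-background
    frame yields an empty (all-zero) label mask.
    """
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a single-channel 2-D frame")
    smoothed = gaussian(img, smooth_sigma, preserve_range=True)
    if smoothed.max() <= 0:
        return np.zeros(img.shape, dtype=np.int32)
    # noise floor keeps pure-noise frames from producing spurious foreground
    noise_floor = np.median(smoothed) + 3 * 1.4826 * np.median(
        np.abs(smoothed - np.median(smoothed))
    )
    try:
        thr = max(threshold_otsu(smoothed), noise_floor)
    except ValueError:  # constant image
        return np.zeros(img.shape, dtype=np.int32)
    fg = smoothed > thr
    fg = remove_small_objects(fg, max_size=min_area)
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(
        distance, min_distance=peak_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels, _ = ndi.label(fg)
        return labels.astype(np.int32)
    labels = watershed(-distance, markers, mask=fg)
    return labels.astype(np.int32)


def _iou_table(prev: np.ndarray, cur: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU for every overlapping (prev label, cur label) pair."""
    both = (prev > 0) & (cur > 0)
    pairs: dict[tuple[int, int], float] = {}
    if not both.any():
        return pairs
    p = prev[both].astype(np.int64)
    c = cur[both].astype(np.int64)
    key = p * (cur.max() + 1) + c
    uniq, counts = np.unique(key, return_counts=True)
    areas_p = np.bincount(prev.ravel())
    areas_c = np.bincount(cur.ravel())
    for k, inter in zip(uniq, counts):
        pl = int(k // (cur.max() + 1))
        cl = int(k % (cur.max() + 1))
        union = areas_p[pl] + areas_c[cl] - inter
        pairs[(pl, cl)] = inter / union
    return pairs


def track_cells(
    label_stack: np.ndarray | list[np.ndarray],
    times: np.ndarray | None = None,
    iou_threshold: float = 0.3,
) -> list[CellTrack]:
    """Greedy overlap tracking of labelled cells through a time series.

    Per frame pair, candidate matches are ranked by IoU and assigned greedily
    one-to-one; matches below ``iou_threshold`` are rejected.  At a division
    the daughter with the larger IoU to the parent keeps the parent's track
    id; the other daughter (still overlapping the parent above threshold) is
    discarded from the output rather than starting a new track.  Labels with
    no overlap to any tracked cell start new tracks, and track ids are stable
    under appending frames.
    """
    frames = [np.asarray(f) for f in label_stack]
    if times is not None:
        times = np.asarray(times, dtype=float)
        if len(times) != len(frames):
            raise ValueError("times length must match number of frames")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")
    if not frames:
        return []
    tracks: list[CellTrack] = []
    next_id = 1
    active: dict[int, CellTrack] = {}  # prev-frame label -> track
    for lab in np.unique(frames[0]):
        if lab == 0:
            continue
        t = CellTrack(track_id=next_id, labels={0: int(lab)})
        next_id += 1
        tracks.append(t)
        active[int(lab)] = t
    discarded_prev: set[int] = set()
    for fi in range(1, len(frames)):
        prev, cur = frames[fi - 1], frames[fi]
        pairs = _iou_table(prev, cur)
        matched_prev: set[int] = set()
        matched_cur: set[int] = set()
        new_active: dict[int, CellTrack] = {}
        new_discarded: set[int] = set()
        for (pl, cl), iou in sorted(pairs.items(), key=lambda kv: -kv[1]):
            if iou < iou_threshold or pl in matched_prev or cl in matched_cur:
                continue
            if pl not in active:
                continue
            track = active[pl]
            track.labels[fi] = cl
            new_active[cl] = track
            matched_prev.add(pl)
            matched_cur.add(cl)
        for lab in np.unique(cur):
            lab = int(lab)
            if lab == 0 or lab in matched_cur:
                continue
            # overlapping a tracked cell (the second daughter of a division)
            # or a previously discarded daughter: discarded by design
            is_daughter = any(
                iou > 0 and (pl in active or pl in discarded_prev)
                for (pl, cl), iou in pairs.items()
                if cl == lab
            )
            if is_daughter:
                new_discarded.add(lab)
                continue
            t = CellTrack(track_id=next_id, labels={fi: lab})
            next_id += 1
            tracks.append(t)
            new_active[lab] = t
        active = new_active
        discarded_prev = new_discarded
    return tracks
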