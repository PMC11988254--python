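"""Synthetic two-channel time-lapse scenes and synthetic feature tables.

The raw microscopy behind this kind of experiment is rarely public, so every
downstream stage is exercised against synthetic data with known ground truth:

* :func:`generate_scene` renders cells (random smooth blobs) carrying
  puncta of two classes on a two-channel stack. Autophagosome-like (AP)
  puncta are co-located in both channels; autolysosome-like (AL) puncta
  appear in the TRITC channel only, mimicking pHluorin quenching in acidic
  vesicles.  Treatment presets modulate intensity over time (rapamycin-like
  dimming), carve dark voids into cells (wortmannin-like) and set per-cell
  Poisson puncta rates.
* :func:`generate_feature_table` skips the imaging stage and draws a
  single-cell feature table directly, with per-treatment effect sizes stated
  in robust-SD (modified-Z) units, for testing the statistics and the
  classifier in isolation.

Puncta are rendered as 2-D Gaussian profiles whose FWHM equals the preset
punctum diameter; same preset and seed give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogue import build_catalogue

__all__ = [
    "ScenePreset",
    "FrameSet",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "generate_feature_table",
    "render_gaussian_spots",
    "two_cell_crossing",
    "write_scene",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell density cannot be placed."""


@dataclass(frozen=True)
class ScenePreset:
    """Study conditions for one synthetic treatment arm.

    Rates are expected puncta per cell (Poisson means) and may be a scalar or
    a per-timepoint sequence.  ``intensity_trend`` is a per-channel
    multiplicative factor applied per hour (1.0 = stable; < 1 dims, as
    rapamycin does to the reporter). ``void_fraction`` is the fraction of the
    cell area rendered as dark voids (wortmannin-like).
    """

    treatment_label: str = "DMSO"
    n_cells: int = 8
    image_shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = 0.25
    mean_cell_intensity: tuple[float, float] = (100.0, 80.0)  # (GFP, TRITC)
    ap_rate: float | tuple[float, ...] = 3.0
    al_rate: float | tuple[float, ...] = 3.0
    puncta_diameter_um: float = 0.8
    puncta_amplitude: tuple[float, float] = (120.0, 120.0)
    intensity_trend: tuple[float, float] = (1.0, 1.0)
    void_fraction: float = 0.0
    cell_radius_um: tuple[float, float] = (6.0, 9.0)
    psf_sigma_um: float = 0.75  # optical blur applied to the cell body
    noise_sd: float = 2.0
    background: float = 10.0
    frame_interval_h: float = 0.5
    drift_px: float = 1.0
    divisions: tuple[tuple[int, int], ...] = ()  # (cell index, frame index)
    shot_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if min(self.image_shape) <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 <= self.void_fraction < 1:
            raise ValueError("void_fraction must be in [0, 1)")
        for r in (self.ap_rate, self.al_rate):
            if np.any(np.asarray(r, dtype=float) < 0):
                raise ValueError("puncta rates must be >= 0")

    def rate_at(self, which: str, t: int) -> float:
        r = self.ap_rate if which == "AP" else self.al_rate
        arr = np.atleast_1d(np.asarray(r, dtype=float))
        return float(arr[min(t, len(arr) - 1)])


@dataclass
class FrameSet:
    """Two-channel time-lapse stack with acquisition metadata."""

    gfp: np.ndarray  # (T, H, W)
    tritc: np.ndarray  # (T, H, W)
    times_h: np.ndarray  # (T,)
    pixel_size_um: float
    treatment: str
    date: str = "20230114"
    well: str = "B02"
    position: int = 1

    @property
    def n_timepoints(self) -> int:
        return self.gfp.shape[0]


@dataclass
class GroundTruth:
    """Per-frame truth: cell label masks, puncta and lineage."""

    labels: np.ndarray  # (T, H, W) int32, 0 = background
    # per frame: list of (row, col, class, cell_label); class in {"AP", "AL"}
    puncta: list[list[tuple[float, float, str, int]]] = field(default_factory=list)
    lineage: dict[int, tuple[int, int]] = field(default_factory=dict)  # parent -> daughters

    def puncta_count(self, frame: int, cls: str | None = None) -> int:
        return sum(1 for p in self.puncta[frame] if cls is None or p[2] == cls)


def _blob_mask(shape, center, radius, coeffs, phases) -> np.ndarray:
    """Random smooth blob: low-order Fourier perturbation of a circle."""
    from skimage.draw import polygon

    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    r = radius * (
        1.0
        + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(coeffs, phases)))
    )
    r = np.clip(r, 2.0, None)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    rr, cc = polygon(rows, cols, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def render_gaussian_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitude: float,
    fwhm_px: float,
) -> np.ndarray:
    """Render 2-D Gaussian spots (FWHM in pixels) onto a zero image."""
    img = np.zeros(shape, dtype=np.float64)
    sigma = fwhm_px / 2.355
    half = max(2, int(np.ceil(3 * sigma)))
    for r0, c0 in np.atleast_2d(centers):
        r0i, c0i = int(round(r0)), int(round(c0))
        rs = slice(max(0, r0i - half), min(shape[0], r0i + half + 1))
        cs = slice(max(0, c0i - half), min(shape[1], c0i + half + 1))
        yy, xx = np.mgrid[rs, cs]
        img[rs, cs] += amplitude * np.exp(
            -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma**2)
        )
    return img


class _Cell:
    def __init__(self, label, center, radius, coeffs, phases, brightness):
        self.label = label
        self.center = np.asarray(center, dtype=float)
        self.radius = radius
        self.coeffs = coeffs
        self.phases = phases
        self.brightness = brightness  # per-channel multiplier


def generate_scene(preset: ScenePreset, n_timepoints: int) -> tuple[FrameSet, GroundTruth]:
    """Render a two-channel synthetic time-lapse with ground truth.

    Deterministic for a fixed (preset, seed).  Raises
    :class:`PlacementError` when the requested number of non-overlapping
    cells cannot be placed after bounded retries.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(preset.seed)
    h, w = preset.image_shape
    px = preset.pixel_size_um
    r_lo, r_hi = (r / px for r in preset.cell_radius_um)
    fwhm_px = preset.puncta_diameter_um / px

    cells: list[_Cell] = []
    margin = r_hi + 4
    for i in range(preset.n_cells):
        for attempt in range(300):
            radius = rng.uniform(r_lo, r_hi)
            center = rng.uniform([margin, margin], [h - margin, w - margin])
            if all(
                np.hypot(*(center - c.center)) >= 0.95 * (radius + c.radius)
                for c in cells
            ):
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{preset.n_cells} after 300 retries; "
                "reduce n_cells or enlarge the image"
            )
        cells.append(
            _Cell(
                label=i + 1,
                center=center,
                radius=radius,
                coeffs=rng.normal(0, 0.05, size=3),
                phases=rng.uniform(0, 2 * np.pi, size=3),
                brightness=1.0 + 0.1 * rng.standard_normal(2),
            )
        )
    next_label = preset.n_cells + 1

    # per-cell void centres, fixed over time
    voids: dict[int, list[tuple[float, float, float]]] = {}
    if preset.void_fraction > 0:
        for c in cells:
            vlist = []
            target = preset.void_fraction * np.pi * c.radius**2
            covered = 0.0
            while covered < target:
                vr = 0.25 * c.radius * rng.uniform(0.7, 1.3)
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, 0.6 * c.radius)
                vlist.append((c.center[0] + rad * np.sin(ang), c.center[1] + rad * np.cos(ang), vr))
                covered += np.pi * vr**2
            voids[c.label] = vlist

    gfp = np.empty((n_timepoints, h, w))
    tritc = np.empty((n_timepoints, h, w))
    labels = np.zeros((n_timepoints, h, w), dtype=np.int32)
    times = np.arange(n_timepoints) * preset.frame_interval_h
    gt = GroundTruth(labels=labels)
    div_schedule = dict(((ci, f), True) for ci, f in preset.divisions)

    for t in range(n_timepoints):
        # divisions scheduled for this frame
        for ci, f in list(div_schedule):
            if f == t and 0 <= ci < len(cells):
                parent = cells[ci]
                offset = np.array([0.0, parent.radius * 0.55])
                d1 = _Cell(next_label, parent.center - offset, parent.radius * 0.7,
                           parent.coeffs, parent.phases, parent.brightness)
                d2 = _Cell(next_label + 1, parent.center + offset, parent.radius * 0.7,
                           parent.coeffs, parent.phases, parent.brightness)
                gt.lineage[parent.label] = (d1.label, d2.label)
                next_label += 2
                cells[ci] = d1
                cells.append(d2)
                del div_schedule[(ci, f)]

        trend = [f ** times[t] for f in preset.intensity_trend]
        frame_g = np.full((h, w), preset.background, dtype=np.float64)
        frame_t = np.full((h, w), preset.background, dtype=np.float64)
        frame_puncta: list[tuple[float, float, str, int]] = []
        for c in cells:
            c.center += rng.normal(0, preset.drift_px, size=2)
            mask = _blob_mask((h, w), c.center, c.radius, c.coeffs, c.phases)
            labels[t][mask] = c.label
            ig = preset.mean_cell_intensity[0] * c.brightness[0] * trend[0]
            it = preset.mean_cell_intensity[1] * c.brightness[1] * trend[1]
            cell_g = np.where(mask, ig, 0.0)
            cell_t = np.where(mask, it, 0.0)
            for vy, vx, vr in voids.get(c.label, []):
                yy, xx = np.mgrid[0:h, 0:w]
                vmask = mask & (np.hypot(yy - vy, xx - vx) <= vr)
                cell_g[vmask] *= 0.15
                cell_t[vmask] *= 0.15
            if preset.psf_sigma_um > 0:
                from scipy.ndimage import gaussian_filter

                s = preset.psf_sigma_um / px
                cell_g = gaussian_filter(cell_g, s)
                cell_t = gaussian_filter(cell_t, s)
            frame_g += cell_g
            frame_t += cell_t
            # puncta: uniform positions within the cell interior
            pix = np.argwhere(mask)
            for cls in ("AP", "AL"):
                n = rng.poisson(preset.rate_at(cls, t))
                if len(pix) == 0:
                    n = 0
                for _ in range(n):
                    r0, c0 = pix[rng.integers(len(pix))] + rng.uniform(-0.5, 0.5, 2)
                    spot_t = render_gaussian_spots(
                        (h, w), np.array([[r0, c0]]),
                        preset.puncta_amplitude[1] * trend[1], fwhm_px)
                    frame_t += spot_t
                    if cls == "AP":
                        frame_g += render_gaussian_spots(
                            (h, w), np.array([[r0, c0]]),
                            preset.puncta_amplitude[0] * trend[0], fwhm_px)
                    frame_puncta.append((float(r0), float(c0), cls, c.label))
        if preset.shot_noise:
            frame_g = rng.poisson(np.clip(frame_g, 0, None)).astype(np.float64)
            frame_t = rng.poisson(np.clip(frame_t, 0, None)).astype(np.float64)
        frame_g += rng.normal(0, preset.noise_sd, size=(h, w))
        frame_t += rng.normal(0, preset.noise_sd, size=(h, w))
        gfp[t] = frame_g
        tritc[t] = frame_t
        gt.puncta.append(frame_puncta)

    fs = FrameSet(
        gfp=gfp, tritc=tritc, times_h=times, pixel_size_um=px,
        treatment=preset.treatment_label,
    )
    return fs, gt


def two_cell_crossing(
    n_frames: int = 24, shape: tuple[int, int] = (64, 120), radius: int = 9
) -> tuple[np.ndarray, dict[int, tuple[int, int]]]:
    """Label-mask stack of two cells passing each other without merging.

    Cell 1 moves left-to-right on one lane, cell 2 right-to-left on another;
    per-frame IoU to a cell's own previous mask stays > 0.5 while cross IoU
    stays < 0.2.  Returns the stack and the expected final column of each
    track id, for identity-swap checks.
    """
    h, w = shape
    y1, y2 = h // 2 - radius, h // 2 + radius
    x_start, x_end = 2 * radius, w - 2 * radius
    xs1 = np.linspace(x_start, x_end, n_frames)
    xs2 = xs1[::-1]
    stack = np.zeros((n_frames, h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for t in range(n_frames):
        stack[t][np.hypot(yy - y1, xx - xs1[t]) <= radius] = 1
        stack[t][np.hypot(yy - y2, xx - xs2[t]) <= radius] = 2
    return stack, {1: (int(xs1[0]), int(xs1[-1])), 2: (int(xs2[0]), int(xs2[-1]))}


def generate_feature_table(
    effects: dict[str, dict[str, float | np.ndarray]],
    n_cells: int,
    n_timepoints: int,
    seed: int,
    features: list[str] | None = None,
    plate: str = "plate1",
    frame_interval_h: float = 0.5,
) -> pd.DataFrame:
    """Draw a synthetic single-cell feature table with stated effect structure.

    DMSO cells are drawn from a per-feature null distribution; each treated
    arm is shifted by ``effects[treatment][feature]`` robust SDs (a scalar,
    or a per-timepoint sequence).  Unknown feature names are rejected.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2 per treatment")
    spec = build_catalogue()
    names = list(features) if features is not None else list(spec.names)
    for n in names:
        if n not in spec:
            raise ValueError(f"unknown feature name: {n!r}")
    for treatment, shifts in effects.items():
        for fname in shifts:
            if fname not in names:
                raise ValueError(f"unknown feature name in effects[{treatment!r}]: {fname!r}")

    rng = np.random.default_rng(seed)
    mu = rng.uniform(10.0, 100.0, size=len(names))
    sigma = mu * rng.uniform(0.05, 0.2, size=len(names))
    times = (np.arange(n_timepoints) + 1) * frame_interval_h

    treatments = ["DMSO"] + [t for t in effects if t != "DMSO"]
    frames = []
    cell_counter = 0
    for wi, treatment in enumerate(treatments):
        shifts = effects.get(treatment, {})
        for ci in range(n_cells):
            cell_id = cell_counter
            cell_counter += 1
            base = rng.normal(mu, sigma, size=(n_timepoints, len(names)))
            for fname, eff in shifts.items():
                j = names.index(fname)
                eff_t = np.broadcast_to(np.atleast_1d(np.asarray(eff, dtype=float)),
                                        (n_timepoints,)) if np.ndim(eff) else np.full(n_timepoints, eff)
                base[:, j] += np.asarray(eff_t, dtype=float) * sigma[j]
            df = pd.DataFrame(base, columns=names)
            df.insert(0, "cell_id", cell_id)
            df.insert(1, "time", times)
            df.insert(2, "treatment", treatment)
            df.insert(3, "plate", plate)
            df.insert(4, "well", f"{chr(65 + wi)}01")
            df.insert(5, "position", 1)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_scene(fs: FrameSet, gt: GroundTruth, outdir: str | Path) -> list[Path]:
    """Write a scene to disk: per-channel multi-page TIFFs named
    ``date_well_pPosition_channel.tif``, label TIFF and lineage JSON."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for channel, stack in (("GFP", fs.gfp), ("TRITC", fs.tritc)):
        path = outdir / f"{fs.date}_{fs.well}_p{fs.position}_{channel}.tif"
        tifffile.imwrite(path, stack.astype(np.float32))
        written.append(path)
    lab_path = outdir / f"{fs.date}_{fs.well}_p{fs.position}_labels.tif"
    tifffile.imwrite(lab_path, gt.labels)
    written.append(lab_path)
    lineage_path = outdir / f"{fs.date}_{fs.well}_p{fs.position}_lineage.json"
    lineage_path.write_text(json.dumps({str(k): v for k, v in gt.lineage.items()}))
    written.append(lineage_path)
    return written
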