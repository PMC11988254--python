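"""End-to-end orchestration: configuration, metadata conventions, and the
image -> features -> statistics -> models pipeline.

Image files follow the ``date_well_pPosition_channel.tif`` naming convention
(e.g. ``20230114_B03_p2_GFP.tif``) so that every frame can be linked to its
replicate date, well, position and channel, and a plate-map CSV links wells
to treatments.  The pipeline stages run in order

    simulate/load -> correct -> detect -> classify -> segment -> track ->
    extract -> standardize -> select -> {classify+explain, cluster,
    similarity, predict}

with every output table carrying the catalogue hash and a config hash in a
run manifest; reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, mlexplain, profiles, similarity, synthgen
from .catalogue import build_catalogue
from .features import METADATA_COLUMNS, extract_cell_features, feature_columns
from .imaging import DetectionParams

__all__ = [
    "RunConfig",
    "parse_filename_metadata",
    "check_unique_image_keys",
    "extract_scene_features",
    "pivot_cell_timepoints",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_FILENAME_RE = re.compile(
    r"^(?P<date>\d{8})_(?P<well>[A-Ha-h]\d{2})_p(?P<position>\d+)_"
    r"(?P<channel>GFP|TRITC)\.(tif|tiff)$"
)


def parse_filename_metadata(name: str) -> tuple[str, str, int, str]:
    """Parse ``date_well_pPosition_channel.tif`` into its metadata fields.

    Returns (ISO date, well, position, channel); a non-matching name raises
    with the expected pattern.
    """
    m = _FILENAME_RE.match(Path(name).name)
    if not m:
        raise ValueError(
            f"image file name {name!r} does not match the expected pattern "
            "'YYYYMMDD_<well>_p<position>_<GFP|TRITC>.tif'"
        )
    raw = m.group("date")
    date = f"{raw[:4]}-{raw[4:6]}-{raw[6:]}"
    return date, m.group("well"), int(m.group("position")), m.group("channel")


def check_unique_image_keys(names: list[str]) -> None:
    """Reject duplicate (date, well, position, channel) keys across files."""
    seen: dict[tuple, str] = {}
    for n in names:
        key = parse_filename_metadata(n)
        if key in seen:
            raise ValueError(
                f"duplicate image key {key} in {n!r} and {seen[key]!r}; "
                "replicates acquired on different days must not share labels"
            )
        seen[key] = n


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    n_timepoints: int = 3
    treatments: list[dict] = field(default_factory=list)  # ScenePreset kwargs
    detection: DetectionParams = field(default_factory=DetectionParams)
    classifier: mlexplain.ClassifierConfig = field(
        default_factory=mlexplain.ClassifierConfig
    )
    z_threshold: float = 0.5
    alpha: float = 0.05
    nan_mode: str = "nan"  # paper-mimicking NaN handling vs "zero" imputation
    reference_treatment: str = "rapamycin_100nM"
    cargo: dict[str, float] = field(default_factory=dict)
    use_groundtruth_masks: bool = False
    shap_max_samples: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "detection" in raw:
            raw["detection"] = DetectionParams(**raw["detection"])
        if "classifier" in raw:
            raw["classifier"] = mlexplain.ClassifierConfig(**raw["classifier"])
        return cls(**raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # the hash covers parameters, not paths
        blob = json.dumps(d, sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def extract_scene_features(
    fs: synthgen.FrameSet,
    params: DetectionParams,
    labels: np.ndarray | None = None,
    nan_mode: str = "nan",
    plate: str = "plate1",
    well: str = "B02",
    position: int = 1,
) -> pd.DataFrame:
    """Run detection, segmentation, tracking and feature extraction on one
    two-channel stack, returning a single-cell feature table.

    ``labels`` supplies externally generated per-frame cell label masks
    (e.g. ground truth or a trained segmenter), bypassing the built-in
    segmenter.
    """
    n_t = fs.n_timepoints
    corrected_g, corrected_t = [], []
    puncta_per_frame = []
    label_stack = []
    for t in range(n_t):
        cg = imaging.rolling_ball_correct(fs.gfp[t], params)
        ct = imaging.rolling_ball_correct(fs.tritc[t], params)
        gfp_p = imaging.detect_spots(cg, params, "GFP", frame_index=t)
        tritc_p = imaging.detect_spots(ct, params, "TRITC", frame_index=t)
        ap, al = imaging.classify_puncta(gfp_p, tritc_p, cg.shape)
        puncta_per_frame.append((ap, al))
        corrected_g.append(cg)
        corrected_t.append(ct)
        if labels is not None:
            label_stack.append(np.asarray(labels[t]))
        else:
            label_stack.append(imaging.segment_cells(fs.gfp[t]))
    tracks = imaging.track_cells(label_stack, times=fs.times_h)

    rows = []
    prev_centroid: dict[int, tuple[float, float]] = {}
    for track in tracks:
        for t in sorted(track.labels):
            lab = track.labels[t]
            mask = label_stack[t] == lab
            if not mask.any():
                continue
            ap, al = puncta_per_frame[t]
            in_cell = lambda p: mask[
                min(int(round(p.centroid[0])), mask.shape[0] - 1),
                min(int(round(p.centroid[1])), mask.shape[1] - 1),
            ]
            cell_ap = [p for p in ap if in_cell(p)]
            cell_al = [p for p in al if in_cell(p)]
            ys, xs = np.nonzero(mask)
            centroid = (ys.mean(), xs.mean())
            disp = (
                float(np.hypot(centroid[0] - prev_centroid[track.track_id][0],
                               centroid[1] - prev_centroid[track.track_id][1]))
                if track.track_id in prev_centroid
                else 0.0
            )
            prev_centroid[track.track_id] = centroid
            row = extract_cell_features(
                mask, corrected_g[t], corrected_t[t], cell_ap, cell_al,
                displacement=disp, nan_mode=nan_mode,
            )
            meta = pd.Series(
                {
                    "cell_id": f"{fs.treatment}_{track.track_id}",
                    "time": float(fs.times_h[t]),
                    "treatment": fs.treatment,
                    "plate": plate,
                    "well": well,
                    "position": position,
                }
            )
            rows.append(pd.concat([meta, row]))
    if not rows:
        spec = build_catalogue()
        return pd.DataFrame(columns=METADATA_COLUMNS + spec.names)
    return pd.DataFrame(rows).reset_index(drop=True)


def pivot_cell_timepoints(
    std_table: pd.DataFrame, features: list[str], timepoints: list[float] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Cell x (feature, timepoint) matrix from a standardized table.

    Concatenates each cell's selected features over the requested timepoints
    (cells missing any timepoint are dropped) and returns (X, y) with y the
    treatment label per cell.
    """
    times = timepoints or sorted(std_table["time"].astype(float).unique())
    wide = std_table.pivot_table(
        index=["cell_id", "treatment"], columns="time", values=features
    )
    wide = wide.dropna(axis=0)
    cols = []
    keep = []
    for f in features:
        for t in times:
            if (f, t) in wide.columns:
                keep.append((f, t))
                cols.append(mlexplain.timepoint_column(f, float(t)))
    X = wide[keep]
    X.columns = cols
    y = X.index.get_level_values("treatment").to_series(index=X.index)
    X = X.reset_index(drop=True)
    return X, y.reset_index(drop=True)


def _write_csv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline on synthetic scenes defined by the config.

    Returns the run directory.  Each stage appends artifacts; no stage
    mutates a previous stage's outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = build_catalogue()
    chash = config.config_hash()
    khash = spec.catalogue_hash()
    stamp = f"config_hash={chash} catalogue_hash={khash} seed={config.seed}"
    t0 = _time.time()

    # --- simulate + extract ------------------------------------------------
    tables = []
    for i, preset_kwargs in enumerate(config.treatments):
        kwargs = dict(preset_kwargs)
        kwargs.setdefault("seed", config.seed + i)
        preset = synthgen.ScenePreset(**kwargs)
        fs, gt = synthgen.generate_scene(preset, config.n_timepoints)
        fs.well = f"{chr(65 + i)}01"
        labels = gt.labels if config.use_groundtruth_masks else None
        tab = extract_scene_features(
            fs, config.detection, labels=labels, nan_mode=config.nan_mode,
            well=fs.well,
        )
        logger.info(
            "stage=extract treatment=%s cells=%d elapsed=%.1fs",
            preset.treatment_label, tab["cell_id"].nunique() if len(tab) else 0,
            _time.time() - t0,
        )
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    _write_csv(table, out / "features.csv", stamp)

    # --- standardize -------------------------------------------------------
    table = profiles.drop_nan_features(table)
    std = profiles.modified_z(table)
    _write_csv(std, out / "standardized.csv", stamp)

    # --- select ------------------------------------------------------------
    feats = feature_columns(std)
    records = []
    treatments = [t for t in std["treatment"].unique() if t != "DMSO"]
    for tr in treatments:
        for t in sorted(std["time"].unique()):
            rec = profiles.select_significant(
                std, tr, t, z_threshold=config.z_threshold, alpha=config.alpha
            )
            rec.insert(0, "treatment", tr)
            records.append(rec)
    sig = pd.concat(records, ignore_index=True)
    _write_csv(sig, out / "significance.csv", stamp)
    selected = sorted(sig.loc[sig["significant"], "feature"].unique())
    logger.info("stage=select features=%d elapsed=%.1fs", len(selected), _time.time() - t0)

    result = {"n_cells": int(table["cell_id"].nunique()),
              "n_features_after_nan": len(feats),
              "n_selected": len(selected),
              "config_hash": chash, "catalogue_hash": khash, "seed": config.seed}

    # --- classify + explain ------------------------------------------------
    if selected and len(treatments) >= 1:
        X, y = pivot_cell_timepoints(std, selected)
        class_counts = y.value_counts()
        if len(class_counts) >= 2 and class_counts.min() >= config.classifier.folds:
            Xp, removed = mlexplain.prune_correlated(
                X, config.classifier.correlation_threshold
            )
            model, report = mlexplain.train_and_evaluate(Xp, y, config.classifier)
            result["micro_f1_mean"] = report.mean_f1
            result["micro_f1_sd"] = report.sd_f1
            rng = np.random.default_rng(config.seed)
            idx = rng.choice(
                len(Xp), size=min(config.shap_max_samples, len(Xp)), replace=False
            )
            attr = mlexplain.shapley_attribution(model, Xp.iloc[idx])
            groups, top = mlexplain.group_importance(attr, spec)
            _write_csv(groups.reset_index(), out / "group_importance.csv", stamp)
            _write_csv(top, out / "top_features.csv", stamp)
            logger.info("stage=classify f1=%.3f elapsed=%.1fs",
                        report.mean_f1, _time.time() - t0)

    # --- profiles + similarity + standard curve ----------------------------
    if selected:
        prof = {
            tr: profiles.build_profile(std, tr, selected)
            for tr in std["treatment"].unique()
        }
        sims = []
        ref = config.reference_treatment
        if ref in prof:
            for tr, p in prof.items():
                if tr == ref:
                    continue
                sims.append(
                    similarity.profile_similarity(p, prof[ref], treatment=tr, reference=ref)
                )
            sim_df = pd.DataFrame(
                [{"treatment": s.treatment, "reference": s.reference, "r": s.r,
                  "n": s.n} for s in sims]
            )
            _write_csv(sim_df, out / "similarity.csv", stamp)
            if config.cargo:
                cargo = similarity.normalize_cargo(config.cargo, ref)
                train = [s for s in sims if s.treatment in cargo]
                if len(train) >= 3:
                    curve = similarity.fit_standard_curve(train, cargo)
                    result["standard_curve_r2"] = curve.r_squared
                    result["standard_curve_slope"] = curve.slope

    (out / "manifest.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return out
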