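"""Per-object and per-cell feature extraction over the 949-name catalogue.

Whole-cell and autophagosome (AP) features are measured on the GFP channel
(better signal-to-noise); autolysosome (AL) features on the TRITC channel.
Per-vesicle features are aggregated within each cell using six descriptive
statistics (mean, 25%, 50%, 75%, max, min) with linear-interpolation
quartiles, and the two vesicle counts are appended.

Cells with no vesicle of a class have those aggregates set either to NaN
("nan" mode, which downstream NaN-column removal then drops) or to zero
("zero" mode).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .catalogue import (
    CELL_ONLY,
    STAT_PREFIXES,
    VESICLE_BASE,
    FeatureSpec,
    build_catalogue,
)
from .imaging import Punctum
from .texture import haralick_features, zernike_moments

__all__ = [
    "METADATA_COLUMNS",
    "base_object_features",
    "extract_cell_features",
    "feature_columns",
    "build_catalogue",
]

#: metadata columns present in every feature table, alongside the catalogue
METADATA_COLUMNS = ["cell_id", "time", "treatment", "plate", "well", "position"]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Catalogue feature columns of a table (everything except metadata)."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def base_object_features(
    mask: np.ndarray, image: np.ndarray, levels: int = 64
) -> dict[str, float]:
    """The 72 per-object base features (structure, intensity, texture, Zernike).

    ``mask`` is a boolean object mask and ``image`` the matching intensity
    frame.  Undefined values (e.g. texture of a single pixel, aspect ratio of
    a degenerate object) are returned as NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("object mask is empty")
    props = regionprops(mask.astype(np.uint8), intensity_image=image)[0]
    vals = image[mask].astype(np.float64)

    out: dict[str, float] = {}
    area = float(props.area)
    perimeter = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    out["area"] = area
    out["perimeter"] = perimeter
    out["eccentricity"] = float(props.eccentricity)
    out["major_axis_length"] = major
    out["minor_axis_length"] = minor
    out["solidity"] = float(props.solidity)
    out["extent"] = float(props.extent)
    out["orientation"] = float(props.orientation)
    out["circularity"] = 4 * np.pi * area / perimeter**2 if perimeter > 0 else np.nan
    out["aspect_ratio"] = major / minor if minor > 0 else np.nan

    out["mean_intensity"] = float(vals.mean())
    out["min_intensity"] = float(vals.min())
    out["max_intensity"] = float(vals.max())
    out["median_intensity"] = float(np.median(vals))
    out["intensity_sd"] = float(vals.std())
    out["integrated_intensity"] = float(vals.sum())
    out["intensity_q25"] = float(np.percentile(vals, 25))
    out["intensity_q75"] = float(np.percentile(vals, 75))
    out["intensity_range"] = float(vals.max() - vals.min())

    # texture on the object's bounding box
    r0, c0, r1, c1 = props.bbox
    tex = haralick_features(image[r0:r1, c0:c1], mask[r0:r1, c0:c1], levels=levels)
    from .catalogue import TEXTURE_BASE

    for name, v in zip(TEXTURE_BASE, tex):
        out[name] = float(v)

    radius = 0.5 * major
    if radius > 0:
        zm = zernike_moments(mask, radius)
    else:
        zm = np.full(25, np.nan)
    for i, v in enumerate(zm):
        out[f"Zernike_moment_{i}"] = float(v)
    return out


def _cell_only_features(
    mask: np.ndarray, image: np.ndarray, displacement: float
) -> dict[str, float]:
    props = regionprops(mask.astype(np.uint8), intensity_image=image)[0]
    vals = image[mask].astype(np.float64)
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    rho = np.hypot(ys - cy, xs - cx)
    med_rho = np.median(rho)
    inner = vals[rho <= med_rho]
    outer = vals[rho > med_rho]
    med_int = np.median(vals)
    out = {
        "displacement": float(displacement),
        "bbox_fill": float(props.extent),
        "edge_contact": float(
            ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1
        ),
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "euler_number": float(props.euler_number),
        "convex_area": float(props.area_convex),
        "feret_diameter_max": float(props.feret_diameter_max),
        "perimeter_area_ratio": float(props.perimeter / props.area),
        "intensity_cv": float(vals.std() / vals.mean()) if vals.mean() != 0 else np.nan,
        "radial_intensity_ratio": (
            float(inner.mean() / outer.mean())
            if outer.size and outer.mean() != 0
            else np.nan
        ),
        "dark_area_fraction": float((vals < 0.5 * med_int).mean()) if med_int > 0 else np.nan,
    }
    return out


def _aggregate(values: np.ndarray) -> dict[str, float]:
    """Six descriptive statistics with linear-interpolation quartiles.

    NaN entries from individual vesicles (e.g. a numerically singular texture
    statistic) are ignored as long as at least one vesicle has a value.
    """
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return {s: np.nan for s in STAT_PREFIXES}
    return {
        "mean": float(finite.mean()),
        "25%": float(np.percentile(finite, 25)),
        "50%": float(np.percentile(finite, 50)),
        "75%": float(np.percentile(finite, 75)),
        "max": float(finite.max()),
        "min": float(finite.min()),
    }


def extract_cell_features(
    cell_mask: np.ndarray,
    gfp_frame: np.ndarray,
    tritc_frame: np.ndarray,
    ap_puncta: list[Punctum],
    al_puncta: list[Punctum],
    displacement: float = 0.0,
    nan_mode: str = "nan",
    levels: int = 64,
) -> pd.Series:
    """One 949-entry feature row for a single cell at a single timepoint.

    ``ap_puncta`` / ``al_puncta`` must already be restricted to this cell.
    ``nan_mode`` controls aggregates for cells with zero vesicles of a class:
    ``"nan"`` leaves them undefined (the downstream NaN-column rule then
    removes them) while ``"zero"`` imputes 0.
    """
    if nan_mode not in ("nan", "zero"):
        raise ValueError("nan_mode must be 'nan' or 'zero'")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    empty_fill = np.nan if nan_mode == "nan" else 0.0

    row: dict[str, float] = {}
    row.update(base_object_features(cell_mask, gfp_frame, levels=levels))
    row.update(_cell_only_features(cell_mask, gfp_frame, displacement))

    for entity, puncta, frame in (("AP", ap_puncta, gfp_frame), ("AL", al_puncta, tritc_frame)):
        if puncta:
            per_object = pd.DataFrame(
                [base_object_features(p.to_mask(frame.shape), frame, levels=levels) for p in puncta]
            )
            for base in VESICLE_BASE:
                stats = _aggregate(per_object[base].to_numpy())
                for stat, v in stats.items():
                    row[f"{stat}_{entity}_{base}"] = v
        else:
            for base in VESICLE_BASE:
                for stat in STAT_PREFIXES:
                    row[f"{stat}_{entity}_{base}"] = empty_fill
        row[f"{entity}_number"] = float(len(puncta))

    spec = build_catalogue()
    return pd.Series([row[n] for n in spec.names], index=spec.names, dtype=float)
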