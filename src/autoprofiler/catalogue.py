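"""The morphological feature catalogue.

Every cell row in a :class:`~autoprofiler.features` table carries the same 949
named features, organised along two axes:

* **biological entity** — the whole cell (``Cell``), autophagosomes (``AP``,
  vesicles visible in both reporter channels) and autolysosomes (``AL``,
  vesicles visible in the red channel only);
* **morphological type** — ``structure`` (geometry, incl. Zernike shape
  moments), ``intensity`` and ``texture`` (Haralick co-occurrence statistics).

Per-vesicle features are aggregated over all vesicles of a cell with six
descriptive statistics (mean, 25%, 50%, 75%, max, min), so each of the 72
per-vesicle base features yields six named columns per vesicle class, plus the
two vesicle-count features ``AP_number`` and ``AL_number``:

    6 stats x 72 base x 2 classes  +  83 whole-cell  +  2 counts  =  949
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

__all__ = [
    "CatalogueEntry",
    "FeatureSpec",
    "build_catalogue",
    "STRUCTURE_BASE",
    "INTENSITY_BASE",
    "TEXTURE_BASE",
    "ZERNIKE_BASE",
    "VESICLE_BASE",
    "CELL_ONLY",
    "STAT_PREFIXES",
    "HARALICK_NAMES",
]

# 10 geometric descriptors computed from the object mask
STRUCTURE_BASE = [
    "area",
    "perimeter",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "solidity",
    "extent",
    "orientation",
    "circularity",
    "aspect_ratio",
]

# 9 intensity descriptors computed over the object's pixels
INTENSITY_BASE = [
    "mean_intensity",
    "min_intensity",
    "max_intensity",
    "median_intensity",
    "intensity_sd",
    "integrated_intensity",
    "intensity_q25",
    "intensity_q75",
    "intensity_range",
]

# the 14 classical Haralick statistics of the gray-level co-occurrence matrix
HARALICK_NAMES = [
    "ASM",
    "contrast",
    "correlation",
    "variance",
    "IDM",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "IMC1",
    "IMC2",
    "MCC",
]

# each summarised by its mean and range over the four 2-D directions -> 28
TEXTURE_BASE = [f"{h}_{s}" for h in HARALICK_NAMES for s in ("mean", "range")]

# magnitudes of the 25 Zernike polynomial moments up to radial degree 8
ZERNIKE_BASE = [f"Zernike_moment_{i}" for i in range(25)]

# 72 base features computed for every segmented object (cell or vesicle)
VESICLE_BASE = STRUCTURE_BASE + INTENSITY_BASE + TEXTURE_BASE + ZERNIKE_BASE

# 11 additional whole-cell-only features
CELL_ONLY = [
    "displacement",
    "bbox_fill",
    "edge_contact",
    "equivalent_diameter",
    "euler_number",
    "convex_area",
    "feret_diameter_max",
    "perimeter_area_ratio",
    "intensity_cv",
    "radial_intensity_ratio",
    "dark_area_fraction",
]

# descriptive-statistic prefixes used to aggregate per-vesicle features
STAT_PREFIXES = ["mean", "25%", "50%", "75%", "max", "min"]

_CELL_ONLY_TYPE = {
    "displacement": "structure",
    "bbox_fill": "structure",
    "edge_contact": "structure",
    "equivalent_diameter": "structure",
    "euler_number": "structure",
    "convex_area": "structure",
    "feret_diameter_max": "structure",
    "perimeter_area_ratio": "structure",
    "intensity_cv": "intensity",
    "radial_intensity_ratio": "intensity",
    "dark_area_fraction": "intensity",
}


def _base_type(base: str) -> str:
    if base in STRUCTURE_BASE or base in ZERNIKE_BASE:
        return "structure"
    if base in INTENSITY_BASE:
        return "intensity"
    if base in TEXTURE_BASE:
        return "texture"
    return _CELL_ONLY_TYPE[base]


@dataclass(frozen=True)
class CatalogueEntry:
    """One named feature with its entity/type/statistic/channel tags."""

    name: str
    entity: str  # Cell | AP | AL
    mtype: str  # structure | intensity | texture | number
    statistic: str | None  # one of STAT_PREFIXES, or None for cell/count features
    base: str  # underlying per-object feature name
    channel: str  # GFP | TRITC


class FeatureSpec:
    """Ordered catalogue of the 949 feature names with their tags."""

    def __init__(self, entries: list[CatalogueEntry]):
        self.entries = entries
        self.names = [e.name for e in entries]
        self._by_name = {e.name: e for e in entries}
        if len(self._by_name) != len(self.names):
            raise ValueError("catalogue names are not unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def entry(self, name: str) -> CatalogueEntry:
        return self._by_name[name]

    def group_of(self, name: str) -> str:
        """Importance group: 'vesicle_number' for counts, else 'entity/type'."""
        e = self._by_name[name]
        if e.mtype == "number":
            return "vesicle_number"
        return f"{e.entity}/{e.mtype}"

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(self.group_of(e.name), None)
        return list(seen)

    def catalogue_hash(self) -> str:
        h = hashlib.sha256()
        for e in self.entries:
            h.update(f"{e.name}|{e.entity}|{e.mtype}|{e.statistic}|{e.channel}\n".encode())
        return h.hexdigest()[:16]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "entity": [e.entity for e in self.entries],
                "type": [e.mtype for e in self.entries],
                "statistic": [e.statistic for e in self.entries],
                "base": [e.base for e in self.entries],
                "channel": [e.channel for e in self.entries],
            }
        )


def build_catalogue() -> FeatureSpec:
    """Build the deterministic, ordered 949-feature catalogue.

    Order: 83 whole-cell features (GFP channel), then for each vesicle class
    (AP from GFP, AL from TRITC) the 6x72 statistic-prefixed aggregates
    followed by the vesicle count.
    """
    entries: list[CatalogueEntry] = []
    for base in VESICLE_BASE + CELL_ONLY:
        entries.append(
            CatalogueEntry(base, "Cell", _base_type(base), None, base, "GFP")
        )
    for entity, channel in (("AP", "GFP"), ("AL", "TRITC")):
        for stat in STAT_PREFIXES:
            for base in VESICLE_BASE:
                entries.append(
                    CatalogueEntry(
                        f"{stat}_{entity}_{base}", entity, _base_type(base), stat, base, channel
                    )
                )
        entries.append(
            CatalogueEntry(f"{entity}_number", entity, "number", None, "number", channel)
        )
    spec = FeatureSpec(entries)
    assert len(spec) == 949
    return spec
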