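"""GI quantification ratios: gastric emptying, nerve density, IGVE density,
stool water content.

All four are simple ratio statistics over pre-segmented inputs: a
region-integrated fluorescence table (stomach vs rest of gut), a binary
nerve mask with a manually counted number of innervated enteric ganglia, and
wet/dry stool weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NerveField:
    """A segmented whole-mount field: binary nerve mask, the number of
    intraganglionic varicose endings (IGVE)-bearing ganglia counted in it,
    and the field area in pixels (80 um x 80 um region convention)."""

    nerve_mask: np.ndarray
    ganglia_innervated_count: int
    field_area: int | None = None

    def __post_init__(self) -> None:
        if self.nerve_mask.ndim != 2:
            raise ValueError("nerve mask must be 2-D")
        if self.ganglia_innervated_count < 0:
            raise ValueError("ganglia count must be >= 0")

    @property
    def area(self) -> int:
        return self.field_area if self.field_area is not None else self.nerve_mask.size


def gastric_emptying_pct(
    stomach_signal: float | np.ndarray, rest_of_gut_signal: float | np.ndarray
) -> dict[str, float | np.ndarray]:
    """Percent gastric emptying from region-integrated radiant efficiency.

    Emptying is the non-stomach share of the total gut signal,
    ``100 * rest / (stomach + rest)``; the complementary stomach-retention
    percentage is co-reported so either orientation of the ratio is
    recoverable.
    """
    stomach = np.asarray(stomach_signal, dtype=float)
    rest = np.asarray(rest_of_gut_signal, dtype=float)
    if (stomach < 0).any() or (rest < 0).any():
        raise ValueError("region signals must be non-negative")
    total = stomach + rest
    if (total <= 0).any():
        raise ValueError("total gut signal must be > 0")
    emptying = 100.0 * rest / total
    retention = 100.0 * stomach / total
    if emptying.ndim == 0:
        return {"emptying_pct": float(emptying), "retention_pct": float(retention)}
    return {"emptying_pct": emptying, "retention_pct": retention}


def nerve_density(field: NerveField) -> float:
    """Nerve density = NerveArea / TotalArea, in [0, 1]."""
    area = field.area
    if area <= 0:
        raise ValueError("field area must be > 0")
    return float(np.count_nonzero(field.nerve_mask) / area)


def igve_density(field: NerveField) -> dict[str, float]:
    """IGVE density = LabeledGanglia / TotalArea (per px² and per 1000 px²)."""
    area = field.area
    if area <= 0:
        raise ValueError("field area must be > 0")
    per_px2 = field.ganglia_innervated_count / area
    return {"igve_per_px2": per_px2, "igve_per_1000px2": 1000.0 * per_px2}


def water_content_pct(
    wet_weight: float | np.ndarray, dry_weight: float | np.ndarray
) -> float | np.ndarray:
    """Stool water content, ``100 * (wet - dry) / wet`` (percent of wet
    weight, the standard moisture-content convention)."""
    wet = np.asarray(wet_weight, dtype=float)
    dry = np.asarray(dry_weight, dtype=float)
    if (wet <= 0).any():
        raise ValueError("wet weight must be > 0")
    if (dry < 0).any() or (dry > wet).any():
        raise ValueError("dry weight must satisfy 0 <= dry <= wet")
    out = 100.0 * (wet - dry) / wet
    return float(out) if out.ndim == 0 else out


# -- table front-ends ------------------------------------------------------


def emptying_table(regions: pd.DataFrame) -> pd.DataFrame:
    """Apply gastric_emptying_pct to a table with stomach_signal and
    rest_of_gut_signal columns."""
    res = gastric_emptying_pct(
        regions["stomach_signal"].to_numpy(),
        regions["rest_of_gut_signal"].to_numpy(),
    )
    out = regions.copy()
    out["emptying_pct"] = res["emptying_pct"]
    out["retention_pct"] = res["retention_pct"]
    return out


def water_content_table(stools: pd.DataFrame) -> pd.DataFrame:
    """Apply water_content_pct to a table with wet/dry weight columns."""
    out = stools.copy()
    out["water_content_pct"] = water_content_pct(
        stools["wet_weight_mg"].to_numpy(), stools["dry_weight_mg"].to_numpy()
    )
    return out


def otsu_nerve_mask(image: np.ndarray) -> np.ndarray:
    """Otsu-threshold helper for synthetic fluorescence fields only; real
    masks are consumed pre-segmented."""
    from skimage.filters import threshold_otsu

    return image > threshold_otsu(image)
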