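"""Per-nucleus intensity measurement, sensor/reference ratios, normalization
and heat-map rendering.

Intensities are always measured on the raw channels: background subtraction
and smoothing exist only to build the segmentation mask. The per-nucleus
ratio is mean(sensor)/mean(reference); dividing by a co-expressed nuclear
reference cancels expression level and illumination, so the ratio reports
the O₂-dependent turnover of the sensor alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import matplotlib
import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .image_io import Stack
from .segmentation import LabelMask

__all__ = [
    "BlobTable",
    "COLUMNS",
    "measure_blobs",
    "normalize_per_specimen",
    "normalize_to_reference_condition",
    "render_heatmap",
    "render_legend",
]

log = logging.getLogger(__name__)

COLUMNS = [
    "blob_id",
    "section",
    "centroid_row",
    "centroid_col",
    "area",
    "mean_reference",
    "mean_sensor",
    "ratio",
    "normalized_ratio",
    "region",
    "valid",
]


@dataclass
class BlobTable:
    """One record per segmented nucleus per section.

    ``records`` is a DataFrame with :data:`COLUMNS`. ``normalization``
    documents the applied scheme and factor, or ``None`` before any
    normalization (then ``normalized_ratio`` equals ``ratio``). Records
    with a zero reference mean carry ``valid=False`` and are excluded from
    ratio statistics.
    """

    records: pd.DataFrame
    specimen_id: str = ""
    normalization: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"blob table missing columns {missing}")
        ids = self.records["blob_id"]
        if ids.duplicated().any():
            raise ValueError("blob_ids are not unique")

    def __len__(self) -> int:
        return len(self.records)

    def finite_ratios(self, field_name: str = "ratio") -> np.ndarray:
        vals = self.records.loc[self.records["valid"], field_name].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def region_values(self, region: str, field_name: str = "normalized_ratio") -> np.ndarray:
        sel = self.records["valid"] & (self.records["region"] == region)
        vals = self.records.loc[sel, field_name].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS,
        [int, int, float, float, int, float, float, float, float, object, bool],
    )})


def measure_blobs(
    mask: LabelMask,
    stack: Stack,
    sensor_channel: str = "sensor",
    reference_channel: str = "reference",
    specimen_id: str = "",
) -> BlobTable:
    """Measure mean raw intensities and the sensor/reference ratio per blob."""
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} does not match stack shape {stack.shape}")
    sensor = np.asarray(stack.channel(sensor_channel), dtype=np.float64)
    reference = np.asarray(stack.channel(reference_channel), dtype=np.float64)

    rows: list[dict] = []
    for s in range(mask.shape[0]):
        lab = mask.labels[s]
        if not lab.any():
            continue
        intensity = np.stack([reference[s], sensor[s]], axis=-1)
        for prop in regionprops(lab, intensity_image=intensity):
            mean_ref, mean_sen = (float(v) for v in prop.intensity_mean)
            valid = mean_ref > 0
            ratio = mean_sen / mean_ref if valid else np.nan
            if not valid:
                log.warning(
                    "blob %d (section %d): zero reference mean, excluded from ratio statistics",
                    prop.label, s,
                )
            rows.append(
                {
                    "blob_id": int(prop.label),
                    "section": s,
                    "centroid_row": float(prop.centroid[0]),
                    "centroid_col": float(prop.centroid[1]),
                    "area": int(prop.area),
                    "mean_reference": mean_ref,
                    "mean_sensor": mean_sen,
                    "ratio": ratio,
                    "normalized_ratio": ratio,
                    "region": "unassigned",
                    "valid": valid,
                }
            )
    df = pd.DataFrame(rows) if rows else _empty_records()
    return BlobTable(records=df, specimen_id=specimen_id, normalization=None)


def normalize_per_specimen(table: BlobTable) -> BlobTable:
    """Normalise to the mean ratio of all nuclei of the specimen.

    The normalization factor is the arithmetic mean of all finite ratios;
    after normalization the mean normalized ratio equals 1 by construction.
    """
    ratios = table.finite_ratios("ratio")
    if ratios.size == 0:
        raise ValueError("cannot normalize: no finite ratios in table")
    factor = float(np.mean(ratios))
    df = table.records.copy()
    df["normalized_ratio"] = df["ratio"] / factor
    log.info("specimen %s: per-specimen normalization factor %.6g", table.specimen_id, factor)
    return replace(table, records=df, normalization={"scheme": "per_specimen", "factor": factor})


def normalize_to_reference_condition(
    tables: list[BlobTable], reference_condition_ids: set[str] | list[str]
) -> list[BlobTable]:
    """Normalise all specimens to the pooled mean ratio of a reference condition.

    A single factor — the mean over all nuclei ratios pooled across the
    reference-condition specimens (e.g. the normoxic samples) — divides
    every record of every table. Per-specimen means are then the averages
    of the normalised per-nucleus ratios.
    """
    ref_ids = set(reference_condition_ids)
    ref_tables = [t for t in tables if t.specimen_id in ref_ids]
    if not ref_tables:
        raise ValueError("reference condition subset is empty")
    pooled = np.concatenate([t.finite_ratios("ratio") for t in ref_tables])
    if pooled.size == 0:
        raise ValueError("reference condition has no finite ratios")
    factor = float(np.mean(pooled))
    log.info("reference-condition normalization factor %.6g (pooled over %d specimens)",
             factor, len(ref_tables))
    out = []
    for t in tables:
        df = t.records.copy()
        df["normalized_ratio"] = df["ratio"] / factor
        out.append(replace(t, records=df,
                           normalization={"scheme": "reference_condition", "factor": factor}))
    return out


DEFAULT_LUT = "coolwarm"  # blue (low ratio, well oxygenated) -> red (high ratio, hypoxic)


def _lut_colors(lut: str, n: int = 256) -> np.ndarray:
    cmap = matplotlib.colormaps[lut]
    return (np.asarray(cmap(np.linspace(0, 1, n)))[:, :3] * 255).astype(np.uint8)


def render_heatmap(
    mask: LabelMask,
    table: BlobTable,
    value_field: str = "normalized_ratio",
    value_range: tuple[float, float] = (0.0, 2.0),
    lut: str = DEFAULT_LUT,
) -> np.ndarray:
    """False-colour every blob by its ratio value; background stays black.

    Values are mapped through ``lut(clamp((v - lo) / (hi - lo)))``; blobs
    outside the range are clamped to the end colours and counted in the log.
    Returns an (S, H, W, 3) uint8 stack; pair with :func:`render_legend`.
    """
    lo, hi = value_range
    if lo >= hi:
        raise ValueError("value_range must satisfy lo < hi")
    df = table.records
    present = np.unique(mask.labels[mask.labels > 0])
    known = set(df["blob_id"].tolist())
    missing = [int(v) for v in present if int(v) not in known]
    if missing:
        raise ValueError(f"labels without a blob record: {missing[:5]}")
    colors = _lut_colors(lut)
    max_label = int(mask.labels.max(initial=0))
    paint = np.zeros((max_label + 1, 3), dtype=np.uint8)
    vals = df[value_field].to_numpy(dtype=float)
    frac = (vals - lo) / (hi - lo)
    clamped = int(np.sum((frac < 0) | (frac > 1)))
    if clamped:
        log.info("%d blobs clamped to the %s LUT end colours", clamped, lut)
    idx = np.round(np.clip(frac, 0.0, 1.0) * (colors.shape[0] - 1)).astype(int)
    for blob_id, ci in zip(df["blob_id"].to_numpy(dtype=int), idx):
        paint[blob_id] = colors[ci]
    return paint[mask.labels]


def render_legend(
    value_range: tuple[float, float],
    lut: str = DEFAULT_LUT,
    size: tuple[int, int] = (24, 256),
) -> np.ndarray:
    """Horizontal colour-scale legend strip (H, W, 3) for a heat map."""
    lo, hi = value_range
    if lo >= hi:
        raise ValueError("value_range must satisfy lo < hi")
    h, w = size
    colors = _lut_colors(lut, w)
    return np.broadcast_to(colors[None, :, :], (h, w, 3)).copy()
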