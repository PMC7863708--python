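"""End-to-end orchestration of the four-category study workflow.

Each stored acquisition is analyzed twice: once as acquired (its
``random`` or ``standardized`` category) and once after fascia-anchored
normalization (``random-normalized`` / ``standardized-normalized``), so
every physical image contributes two result rows.  Unreadable or invalid
records are excluded and logged, never aborting the batch — mirroring how
a clinical study excludes images in which the fascia cannot be seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import ToolConfig, default_config
from .errors import RenoGrayError
from .grayscale import (
    BrightnessRanges,
    brightness_distribution,
    compute_gsm,
    pseudocolor_render,
    rasterize_polygon,
    region_pixels,
)
from .image_io import AcquisitionRecord, GrayImage, PolygonROI, read_gray_bmp, read_roi
from .normalization import NormalizationFactor, normalize_image
from .operator_stats import StatReport, compare_physicians

logger = logging.getLogger("renogray")

CATEGORIES = (
    "random",
    "standardized",
    "random-normalized",
    "standardized-normalized",
)


def _mask_cache_key(roi: PolygonROI, width: int, height: int):
    return (roi.label, tuple(map(tuple, roi.vertices)), width, height)


class _MaskCache:
    """Rasterization memo: simulated studies reuse a handful of ROI
    geometries across hundreds of images."""

    def __init__(self) -> None:
        self._store: dict = {}

    def get(self, roi: PolygonROI, width: int, height: int):
        key = _mask_cache_key(roi, width, height)
        if key not in self._store:
            self._store[key] = rasterize_polygon(roi, width, height)
        return self._store[key]


def analyze_image(
    image: GrayImage,
    kidney_roi: PolygonROI,
    ranges: BrightnessRanges,
    fascia_roi: PolygonROI | None = None,
    normalize: bool = False,
    config: ToolConfig | None = None,
    mask_cache: _MaskCache | None = None,
) -> tuple[dict, NormalizationFactor | None]:
    """Analyze one image: optional normalization, then kidney GSM and the
    brightness distribution.

    Returns ``(row, factor)`` where ``row`` maps column names (gsm,
    band_01..band_NN percentages, ranges_source, normalized) to values and
    ``factor`` is the normalization factor when normalization ran.
    """
    if config is None:
        config = default_config()
    cache = mask_cache or _MaskCache()
    factor = None
    if normalize:
        if fascia_roi is None:
            raise RenoGrayError("normalization requested without a fascia ROI")
        image, factor = normalize_image(image, fascia_roi, config.rounding_policy)
        logger.info(
            "normalized %s: medF0=%.1f Fn=%.4f policy=%s",
            image.source_id,
            factor.medF0,
            factor.fn,
            factor.policy_mode,
        )
    mask = cache.get(kidney_roi, image.width, image.height)
    pixels = region_pixels(image, mask)
    gsm = compute_gsm(pixels)
    dist = brightness_distribution(pixels, ranges)
    row: dict = {
        "gsm": gsm.gsm,
        "n_pixels": gsm.n,
        "mean": gsm.mean,
        "sd": gsm.sd,
        "min": gsm.min,
        "max": gsm.max,
    }
    for i, pct in enumerate(dist.percentages, start=1):
        row[f"band_{i:02d}"] = float(pct)
    row["ranges_source"] = ranges.source
    row["normalized"] = bool(normalize)
    return row, factor


def render_pseudocolor(
    image: GrayImage, kidney_roi: PolygonROI, ranges: BrightnessRanges
):
    """Pseudocolor overlay of the kidney region (convenience wrapper)."""
    mask = rasterize_polygon(kidney_roi, image.width, image.height)
    return pseudocolor_render(image, mask, ranges)


@dataclass
class Exclusion:
    """One record dropped from a batch, with the reason."""

    record: AcquisitionRecord
    reason: str


@dataclass
class StudyResult:
    """Output of :func:`run_study_pipeline`: the four-category results
    table, one statistical report per category with >= 2 groups, and the
    exclusion log."""

    table: pd.DataFrame
    reports: dict[str, StatReport]
    exclusions: list[Exclusion] = field(default_factory=list)


def _record_row_base(record: AcquisitionRecord) -> dict:
    return {
        "patient_id": record.patient_id,
        "side": record.side,
        "physician_id": record.physician_id,
        "device_id": record.device_id,
        "method": record.method,
        "image_path": record.image_path,
    }


def run_study_pipeline(
    records: Sequence[AcquisitionRecord],
    config: ToolConfig | None = None,
    base_dir: str | Path | None = None,
    grouping: str = "physician",
) -> StudyResult:
    """Run the full four-category analysis over a study manifest.

    Every readable record yields a raw-category row and, when its fascia
    ROI is usable, a normalized-category row.  Records whose files are
    missing or invalid are excluded and logged; the run always completes.
    Statistical reports are produced for each category with at least two
    groups present.
    """
    if config is None:
        config = default_config()
    base = Path(base_dir) if base_dir is not None else Path(".")
    cache = _MaskCache()
    rows: list[dict] = []
    exclusions: list[Exclusion] = []
    for record in records:
        try:
            image = read_gray_bmp(base / record.image_path)
            kidney_roi = read_roi(base / record.kidney_roi_path)
            fascia_roi = read_roi(base / record.fascia_roi_path)
        except (OSError, RenoGrayError) as exc:
            logger.warning("excluding %s: %s", record.image_path, exc)
            exclusions.append(Exclusion(record, str(exc)))
            continue
        try:
            raw_row, _ = analyze_image(
                image, kidney_roi, config.ranges, config=config, mask_cache=cache
            )
            norm_row, _ = analyze_image(
                image,
                kidney_roi,
                config.ranges,
                fascia_roi=fascia_roi,
                normalize=True,
                config=config,
                mask_cache=cache,
            )
        except RenoGrayError as exc:
            logger.warning("excluding %s: %s", record.image_path, exc)
            exclusions.append(Exclusion(record, str(exc)))
            continue
        base_cols = _record_row_base(record)
        rows.append({**base_cols, "category": record.method, **raw_row})
        rows.append(
            {**base_cols, "category": record.method + "-normalized", **norm_row}
        )
    table = pd.DataFrame(rows)
    reports: dict[str, StatReport] = {}
    if len(table):
        for category in CATEGORIES:
            if category not in set(table["category"]):
                continue
            try:
                reports[category] = compare_physicians(
                    table, category, grouping=grouping, alpha=config.alpha
                )
            except RenoGrayError as exc:
                # e.g. a single group left after exclusions, or too few
                # observations for the omnibus test
                logger.warning("no report for %s: %s", category, exc)
    logger.info(
        "study pipeline: %d records in, %d rows out, %d excluded",
        len(records),
        len(rows),
        len(exclusions),
    )
    return StudyResult(table=table, reports=reports, exclusions=exclusions)


def analyze_simulated_study(
    n_patients: int,
    effects,
    spec,
    seed: int,
    config: ToolConfig | None = None,
    patient_mean_sd: float = 6.0,
) -> pd.DataFrame:
    """Simulate a study in memory and analyze it, skipping the disk.

    Equivalent to ``generate_study`` + ``run_study_pipeline`` but without
    writing BMP/ROI files; used for replicate-heavy statistical checks.
    """
    from .phantom import iter_study_images

    if config is None:
        config = default_config()
    cache = _MaskCache()
    rows: list[dict] = []
    for item in iter_study_images(n_patients, effects, spec, seed, patient_mean_sd):
        base_cols = _record_row_base(item.record)
        raw_row, _ = analyze_image(
            item.image, item.kidney_roi, config.ranges, config=config, mask_cache=cache
        )
        norm_row, _ = analyze_image(
            item.image,
            item.kidney_roi,
            config.ranges,
            fascia_roi=item.fascia_roi,
            normalize=True,
            config=config,
            mask_cache=cache,
        )
        rows.append({**base_cols, "category": item.record.method, **raw_row})
        rows.append(
            {**base_cols, "category": item.record.method + "-normalized", **norm_row}
        )
    return pd.DataFrame(rows)
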