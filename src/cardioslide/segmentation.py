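"""Whole-slide nucleus segmentation.

Orchestrates the five-step recipe: grayscale conversion, integer
bicubic enlargement, Otsu binarization, morphological-gradient contour
extraction, and connected-component labeling with an area cap, then
crops each surviving object's bounding rectangle out of the enlarged
grayscale slide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core_imaging import (
    DegenerateInputError,
    DetectedObject,
    RasterImage,
    StructuringElement,
    bicubic_upscale,
    binarize,
    label_components,
    morphological_gradient,
    otsu_threshold,
    to_grayscale,
)

logger = logging.getLogger("cardioslide")

MAX_AREA_UNLIMITED = 2**63 - 1  # sentinel: no area cap


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation recipe.

    ``upscale_factor`` is per axis; the default of 4 gives the 16-fold
    area enlargement the recipe calls for.  ``max_area_px`` (default
    512) and ``min_area_px`` are measured in upscaled-frame pixels on
    the contour component, since labeling happens after enlargement.
    """

    upscale_factor: int = 4
    max_area_px: int = 512
    min_area_px: int = 1
    se_size: int = 3
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.upscale_factor < 1:
            raise ValueError("upscale_factor must be >= 1")
        if self.max_area_px < 1 or self.min_area_px < 1:
            raise ValueError("area bounds must be >= 1")


@dataclass(frozen=True)
class NucleusCrop:
    """One extracted nucleus image, in upscaled-slide coordinates."""

    image: RasterImage
    source_slide_id: str
    patient_id: str
    bbox: tuple[int, int, int, int]
    area_px: int

    def __post_init__(self) -> None:
        r0, c0, h, w = self.bbox
        if self.image.shape != (h, w):
            raise ValueError("crop dimensions must equal bbox dimensions")

    def bbox_in_original_frame(self, upscale_factor: int) -> tuple[int, int, int, int]:
        """Bounding rectangle mapped back to pre-enlargement slide
        coordinates, rounded outward so the nucleus stays covered."""
        r0, c0, h, w = self.bbox
        r0o, c0o = r0 // upscale_factor, c0 // upscale_factor
        r1o = -((r0 + h) // -upscale_factor)   # ceil division
        c1o = -((c0 + w) // -upscale_factor)
        return (r0o, c0o, r1o - r0o, c1o - c0o)


def filter_by_area(
    objects: Sequence[DetectedObject],
    max_area_px: int,
    min_area_px: int = 1,
) -> list[DetectedObject]:
    """Keep objects with ``min_area_px <= area_px <= max_area_px``
    ("512 pixels or less" is inclusive), preserving input order."""
    return [o for o in objects if min_area_px <= o.area_px <= max_area_px]


def segment_nuclei(
    slide: RasterImage | np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    slide_id: str = "slide",
    patient_id: str = "unknown",
) -> list[NucleusCrop]:
    """Run the full segmentation recipe on one slide.

    Crops are taken from the enlarged grayscale image — the coordinate
    frame in which object areas were measured.  A constant slide has no
    Otsu threshold; it yields an empty result with a logged warning
    rather than an error.
    """
    gray = to_grayscale(slide)
    big = bicubic_upscale(gray, config.upscale_factor)
    try:
        t = otsu_threshold(big)
    except DegenerateInputError:
        logger.warning("slide %s is constant; no nuclei segmented", slide_id)
        return []
    mask = binarize(big, t)
    contours = morphological_gradient(mask, StructuringElement.square(config.se_size))
    objects = label_components(contours, connectivity=config.connectivity)
    kept = filter_by_area(objects, config.max_area_px, config.min_area_px)
    crops = []
    for obj in kept:
        r0, c0, h, w = obj.bbox
        crops.append(NucleusCrop(
            image=big.with_pixels(big.pixels[r0:r0 + h, c0:c0 + w]),
            source_slide_id=slide_id,
            patient_id=patient_id,
            bbox=obj.bbox,
            area_px=obj.area_px,
        ))
    return crops


def write_crops(
    crops: Sequence[NucleusCrop], out_dir: str | Path, manifest_path: str | Path | None = None
) -> pd.DataFrame:
    """Write one PNG per crop plus a CSV manifest row per crop."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, crop in enumerate(crops):
        path = out / f"{crop.source_slide_id}_nucleus{i:05d}.png"
        iio.imwrite(path, crop.image.pixels)
        r0, c0, h, w = crop.bbox
        rows.append({
            "item_path": str(path),
            "slide_id": crop.source_slide_id,
            "patient_id": crop.patient_id,
            "row_min": r0, "col_min": c0, "height": h, "width": w,
            "area_px": crop.area_px,
        })
    df = pd.DataFrame(rows)
    if manifest_path is not None:
        df.to_csv(manifest_path, index=False)
    return df
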