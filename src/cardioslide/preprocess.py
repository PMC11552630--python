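"""Dual-stain composite construction and whole-slide tiling.

Pairs a nuclei (DAPI) channel with a DNA-damage (gamma-H2A.X) channel,
auto-adjusts brightness/contrast per channel from the intensity
histogram, overlays them into an RGB composite (nuclei -> blue,
damage -> red by convention), and tiles composites into fixed-size
non-overlapping patches.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .core_imaging import ParameterError, RasterImage

#: Fraction of pixels saturated at each histogram tail by the automatic
#: brightness/contrast adjustment (the familiar "Auto" behaviour).
DEFAULT_SATURATION = 0.0035


class AlignmentError(ValueError):
    """Channel shapes disagree."""


@dataclass(frozen=True)
class ChannelPair:
    """Simultaneously acquired nuclei + damage channels of one patient."""

    nuclei: RasterImage
    damage: RasterImage
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.nuclei.shape != self.damage.shape:
            raise AlignmentError(
                f"channel shapes differ: {self.nuclei.shape} vs {self.damage.shape}"
            )


@dataclass(frozen=True)
class Patch:
    """One fixed-size tile of a composite image.

    ``image`` is an (s, s) or (s, s, 3) uint8 array; ``grid_pos`` is the
    (tile_row, tile_col) position in the tiling grid; ``label`` is the
    patient-level class inherited by every patch (weak labeling).
    """

    image: np.ndarray
    patient_id: str
    grid_pos: tuple[int, int]
    label: int | None = None


def auto_contrast(
    channel: RasterImage, saturation_fraction: float = DEFAULT_SATURATION
) -> RasterImage:
    """Histogram-based linear brightness/contrast normalisation.

    The low/high cut intensities are the smallest/largest intensities at
    which the cumulative histogram passes ``saturation_fraction`` of the
    pixel count from either tail; the [low, high] range is then mapped
    linearly onto the full output range with rounding and clipping.
    A constant channel is returned unchanged.
    """
    if not (0.0 <= saturation_fraction < 0.5):
        raise ParameterError("saturation_fraction must lie in [0, 0.5)")
    px = channel.pixels
    n_levels = 1 << channel.bitdepth
    hist = np.bincount(px.ravel(), minlength=n_levels)
    n = px.size
    cdf = np.cumsum(hist)
    cut = saturation_fraction * n
    low = int(np.searchsorted(cdf, cut, side="right"))
    high = int(np.searchsorted(cdf, n - cut, side="left"))
    if high <= low:
        return channel
    hi_out = channel.max_value
    scale = hi_out / (high - low)
    # per-intensity lookup table: cheap even on whole-slide images
    levels = np.arange(n_levels, dtype=np.float64)
    lut = np.clip(np.floor((levels - low) * scale + 0.5), 0, hi_out)
    lut = lut.astype(px.dtype)
    return channel.with_pixels(lut[px])


def overlay_channels(
    pair: ChannelPair,
    saturation_fraction: float = DEFAULT_SATURATION,
    channel_map: tuple[int, int] = (2, 0),
) -> np.ndarray:
    """Merge the two stains into an 8-bit RGB composite.

    Each channel is auto-contrasted independently, then placed into the
    RGB planes given by ``channel_map`` = (nuclei_plane, damage_plane);
    the default (2, 0) shows nuclei in blue and damage foci in red, the
    conventional fluorophore display.  The remaining plane stays zero.
    """
    nuc = auto_contrast(pair.nuclei, saturation_fraction)
    dmg = auto_contrast(pair.damage, saturation_fraction)
    if channel_map[0] == channel_map[1]:
        raise ParameterError("nuclei and damage must map to distinct planes")
    h, w = nuc.shape
    composite = np.zeros((h, w, 3), dtype=np.uint8)
    composite[..., channel_map[0]] = _to_uint8(nuc)
    composite[..., channel_map[1]] = _to_uint8(dmg)
    return composite


def _to_uint8(img: RasterImage) -> np.ndarray:
    if img.bitdepth == 8:
        return img.pixels
    return (img.pixels >> 8).astype(np.uint8)


def tile_patches(
    image: np.ndarray | RasterImage,
    patch_size: int = 128,
    patient_id: str = "unknown",
    label: int | None = None,
) -> list[Patch]:
    """Cut an image into a non-overlapping grid of square patches.

    Stride equals ``patch_size``; partial tiles at the right/bottom
    edges are dropped, so the patch count is
    ``floor(H / s) * floor(W / s)``.  Patches are emitted in row-major
    grid order and inherit the patient label.
    """
    if patch_size < 1:
        raise ParameterError("patch_size must be >= 1")
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    h, w = arr.shape[:2]
    s = patch_size
    patches = []
    for tr in range(h // s):
        for tc in range(w // s):
            patches.append(Patch(
                image=arr[tr * s:(tr + 1) * s, tc * s:(tc + 1) * s].copy(),
                patient_id=patient_id,
                grid_pos=(tr, tc),
                label=label,
            ))
    return patches


def patch_grid_count(height: int, width: int, patch_size: int) -> int:
    """Number of patches :func:`tile_patches` produces for a given shape."""
    return (height // patch_size) * (width // patch_size)
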