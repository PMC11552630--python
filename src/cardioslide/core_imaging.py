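"""Low-level image primitives for fluorescence slide processing.

All operations are pure functions over :class:`RasterImage` /
:class:`BinaryMask`.  They implement the individual steps of the
nucleus-segmentation recipe (grayscale conversion, bicubic enlargement,
Otsu binarization, morphological gradient, connected-component
labeling) so each can be tested against an independent brute-force
oracle.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
import numpy as np
from scipy import ndimage


class ChannelRole(str, enum.Enum):
    """What a single-channel image depicts."""

    NUCLEI = "nuclei"       # DAPI: nuclear DNA
    DAMAGE = "damage"       # gamma-H2A.X: DNA double-strand-break foci
    COMPOSITE = "composite"
    GENERIC = "generic"


class ImageFormatError(ValueError):
    """Raised for images whose shape/channel layout is unsupported."""


class ParameterError(ValueError):
    """Raised for out-of-range operation parameters."""


class DegenerateInputError(ValueError):
    """Raised when an operation is undefined for the given input
    (e.g. thresholding a constant image)."""


# ITU-R BT.601 luminance weights for 3-channel -> grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class RasterImage:
    """A 2-D intensity grid with bit depth and channel role.

    ``pixels`` is an unsigned-integer array; intensities must lie in
    ``[0, 2**bitdepth - 1]``.
    """

    pixels: np.ndarray
    bitdepth: int = 8
    channel_role: ChannelRole = ChannelRole.GENERIC

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageFormatError(
                f"RasterImage requires a 2-D array, got ndim={px.ndim}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("both dimensions must be >= 1")
        if self.bitdepth not in (8, 16):
            raise ParameterError(f"bitdepth must be 8 or 16, got {self.bitdepth}")
        hi = (1 << self.bitdepth) - 1
        if px.min() < 0 or px.max() > hi:
            raise ImageFormatError(
                f"intensities outside [0, {hi}] for bitdepth {self.bitdepth}"
            )
        dtype = np.uint8 if self.bitdepth == 8 else np.uint16
        object.__setattr__(self, "pixels", px.astype(dtype, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bitdepth) - 1

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        return dataclasses.replace(self, pixels=pixels)


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D grid over {0, 1}."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageFormatError("BinaryMask requires a 2-D array")
        if not np.isin(px, (0, 1)).all():
            raise ImageFormatError("mask values must be 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class StructuringElement:
    """Odd-sided boolean footprint with its origin at the centre cell."""

    footprint: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or fp.shape[0] % 2 == 0 or fp.shape[1] % 2 == 0:
            raise ParameterError("footprint must be 2-D with odd side lengths")
        if not fp.any():
            raise ParameterError("footprint must contain at least one true cell")
        if not fp[fp.shape[0] // 2, fp.shape[1] // 2]:
            raise ParameterError("origin (centre) cell must be true")
        object.__setattr__(self, "footprint", fp)

    @classmethod
    def square(cls, size: int = 3) -> "StructuringElement":
        return cls(np.ones((size, size), dtype=bool))


@dataclass(frozen=True)
class DetectedObject:
    """One labeled connected foreground region.

    ``bbox`` is (row_min, col_min, height, width), 0-based, half-open;
    ``area_px`` is the component's foreground pixel count, measured in
    the coordinate frame of the mask it was labeled in (the upscaled
    frame in the segmentation pipeline).
    """

    object_id: int
    area_px: int
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        r0, c0, h, w = self.bbox
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        if h < 1 or w < 1 or r0 < 0 or c0 < 0:
            raise ValueError(f"invalid bbox {self.bbox}")
        if self.area_px > h * w:
            raise ValueError("area cannot exceed bounding-box area")


# ---------------------------------------------------------------------------
# Step 1: grayscale conversion
# ---------------------------------------------------------------------------

def to_grayscale(image: np.ndarray | RasterImage, bitdepth: int = 8) -> RasterImage:
    """Convert a 1- or 3-channel raster to a single-channel grayscale image.

    1-channel input is returned unchanged; 3-channel input is combined
    with BT.601 luminance weights and rounded half-up.
    """
    if isinstance(image, RasterImage):
        return image
    arr = np.asarray(image)
    if arr.ndim == 2:
        return RasterImage(arr, bitdepth=bitdepth)
    if arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        luma = np.floor(arr.astype(np.float64) @ w + 0.5)
        hi = (1 << bitdepth) - 1
        return RasterImage(np.clip(luma, 0, hi), bitdepth=bitdepth)
    raise ImageFormatError(
        f"expected 1- or 3-channel input, got shape {arr.shape}"
    )


# ---------------------------------------------------------------------------
# Step 2: bicubic enlargement
# ---------------------------------------------------------------------------

def _cubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys convolution kernel (a = -0.5, the classic bicubic)."""
    x = np.abs(x)
    out = np.zeros_like(x)
    m1 = x <= 1
    m2 = (x > 1) & (x < 2)
    out[m1] = (a + 2) * x[m1] ** 3 - (a + 3) * x[m1] ** 2 + 1
    out[m2] = a * x[m2] ** 3 - 5 * a * x[m2] ** 2 + 8 * a * x[m2] - 4 * a
    return out


def _axis_weights(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample positions and 4-tap kernel weights for one axis.

    Corner-aligned mapping: output index i samples input coordinate
    ``i * (n_in - 1) / (n_out - 1)`` (identity when n_out == n_in), so
    the first and last samples land exactly on the input corners.
    Out-of-range taps are clamped to the edge.
    """
    if n_out == 1 or n_in == 1:
        coords = np.zeros(n_out)
    else:
        coords = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    base = np.floor(coords).astype(np.int64)
    frac = coords - base
    offsets = np.arange(-1, 3)
    idx = base[:, None] + offsets[None, :]
    weights = _cubic_kernel(frac[:, None] - offsets[None, :])
    # Partition of unity holds analytically; renormalise to kill rounding drift.
    weights /= weights.sum(axis=1, keepdims=True)
    np.clip(idx, 0, n_in - 1, out=idx)
    return idx, weights


def bicubic_upscale(image: RasterImage, factor: int) -> RasterImage:
    """Enlarge an image by an integer factor per axis with bicubic
    (Keys a = -0.5) interpolation, corner-aligned, edge-clamped.

    Interpolated intensities are rounded and clipped to the valid range.
    A factor of 1 returns the input unchanged.
    """
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"upscale factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return image
    src = image.pixels.astype(np.float64)
    h, w = src.shape
    ridx, rw = _axis_weights(h, h * factor)
    cidx, cw = _axis_weights(w, w * factor)
    # separable: rows then columns
    tmp = (rw[:, :, None] * src[ridx]).sum(axis=1)
    out = (cw[None, :, :] * tmp[:, cidx]).sum(axis=2)
    out = np.clip(np.floor(out + 0.5), 0, image.max_value)
    return image.with_pixels(out)


# ---------------------------------------------------------------------------
# Step 3: Otsu threshold + binarization
# ---------------------------------------------------------------------------

def otsu_threshold(image: RasterImage) -> int:
    """Threshold maximizing between-class variance of the histogram.

    Foreground is defined downstream as intensity strictly greater than
    the returned threshold.  Ties are broken toward the lowest
    threshold.  A constant image has no valid separation and raises
    :class:`DegenerateInputError`.
    """
    px = image.pixels
    n_levels = 1 << image.bitdepth
    hist = np.bincount(px.ravel(), minlength=n_levels).astype(np.float64)
    nz = np.nonzero(hist)[0]
    if nz.size < 2:
        raise DegenerateInputError("constant image: Otsu threshold is undefined")
    total = hist.sum()
    prob = hist / total
    omega = np.cumsum(prob)                      # P(class0) for t = 0..L-1
    mu = np.cumsum(prob * np.arange(n_levels))   # first moment of class0
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def binarize(image: RasterImage, threshold: int) -> BinaryMask:
    """Mask pixel = 1 iff intensity is strictly greater than ``threshold``."""
    if not (0 <= threshold <= image.max_value):
        raise ParameterError(
            f"threshold {threshold} outside [0, {image.max_value}]"
        )
    return BinaryMask((image.pixels > threshold).astype(np.uint8))


# ---------------------------------------------------------------------------
# Step 4: morphological gradient
# ---------------------------------------------------------------------------

def morphological_gradient(
    mask: BinaryMask, se: StructuringElement | None = None
) -> BinaryMask:
    """Dilation minus erosion of a binary mask (object contours).

    Borders use reflect padding, so a constant mask yields an all-zero
    gradient (no spurious contour at the image edge).
    """
    if se is None:
        se = StructuringElement.square(3)
    px = mask.pixels
    dil = ndimage.grey_dilation(px, footprint=se.footprint, mode="reflect")
    ero = ndimage.grey_erosion(px, footprint=se.footprint, mode="reflect")
    return BinaryMask(dil - ero)


# ---------------------------------------------------------------------------
# Step 5: connected-component labeling
# ---------------------------------------------------------------------------

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_components(mask: BinaryMask, connectivity: int = 8) -> list[DetectedObject]:
    """Label maximal connected foreground regions.

    Returns one :class:`DetectedObject` per region with its pixel-count
    area and tight bounding rectangle.  Objects are emitted in label
    order (raster order of first encounter); an empty mask yields an
    empty list.
    """
    if connectivity not in _STRUCTURES:
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    labeled, n = ndimage.label(mask.pixels, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    areas = np.bincount(labeled.ravel(), minlength=n + 1)
    slices = ndimage.find_objects(labeled)
    objects = []
    for i, sl in enumerate(slices, start=1):
        rs, cs = sl
        objects.append(
            DetectedObject(
                object_id=i,
                area_px=int(areas[i]),
                bbox=(rs.start, cs.start, rs.stop - rs.start, cs.stop - cs.start),
            )
        )
    return objects
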