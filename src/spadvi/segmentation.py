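"""Plant/background separation: index-based gray conversion, Kapur
maximum-entropy thresholding, and mask application.

RGB scenes are collapsed to a single channel with the excess-green index
(2G - R - B on bit-depth-scaled channels); multispectral scenes with NDVI.
Both indices are higher on vegetation, so the default polarity treats the
upper class as plant. The Kapur threshold maximizes the sum of Shannon
entropies of the two classes of the gray histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (BandError, DegenerateInputError, EmptyMaskError,
                     SegmentationError, ShapeError)
from .synthscene import BANDS


@dataclass
class GrayImage:
    """Single-channel float image plus a validity mask.

    ``valid`` is False where the conversion formula was undefined (zero
    denominators); such pixels are excluded from histograms and always map
    to background.
    """

    values: np.ndarray
    valid: np.ndarray

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def _scaled(img: np.ndarray) -> np.ndarray:
    """Scale integer DN to [0, 1] by bit depth; pass floats through."""
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    return img.astype(float)


def gray_exg(rgb: np.ndarray) -> GrayImage:
    """Excess-green gray conversion of an RGB image (channels R, G, B)."""
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ShapeError(f"expected HxWx3 RGB image, got shape {rgb.shape}")
    s = _scaled(rgb)
    r, g, b = s[..., 0], s[..., 1], s[..., 2]
    return GrayImage(values=2.0 * g - r - b,
                     valid=np.ones(rgb.shape[:2], dtype=bool))


def gray_ndvi(ms: np.ndarray, band_order: tuple[str, ...] = BANDS) -> GrayImage:
    """NDVI gray conversion of a multispectral stack.

    Pixels with NIR + Red = 0 are flagged invalid (value set to 0) and are
    excluded from the segmentation histogram.
    """
    if ms.ndim != 3 or ms.shape[-1] != len(band_order):
        raise ShapeError(
            f"expected HxWx{len(band_order)} stack, got shape {ms.shape}")
    try:
        nir_i = band_order.index("nir")
        red_i = band_order.index("red")
    except ValueError as exc:
        raise BandError("band order must include 'nir' and 'red'") from exc
    s = _scaled(ms)
    nir, red = s[..., nir_i], s[..., red_i]
    denom = nir + red
    valid = denom != 0
    values = np.zeros_like(denom)
    np.divide(nir - red, denom, out=values, where=valid)
    return GrayImage(values=values, valid=valid)


def kapur_threshold(gray: GrayImage, n_bins: int = 256) -> float:
    """Maximum-entropy (Kapur) threshold of a gray image.

    Valid pixels are histogrammed into ``n_bins`` equal-width bins over
    [min, max]; for every candidate cut the sum of the Shannon entropies of
    the two classes is computed (empty bins contribute zero, the x ln x -> 0
    limit) and the bin boundary maximizing it is returned in gray units.
    Ties resolve to the smallest cut. Natural logarithm throughout — the
    base only rescales the objective.
    """
    if n_bins < 2:
        raise DegenerateInputError("n_bins must be >= 2")
    v = gray.valid_values()
    if v.size < 2 or v.min() == v.max():
        raise DegenerateInputError(
            "constant or empty gray image: no threshold exists")
    counts, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = counts / counts.sum()
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])

    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    # candidate cut t splits bins [0, t) | [t, n_bins); both classes non-empty
    p0 = cum_p[:-1]
    p1 = 1.0 - p0
    s0 = cum_plogp[:-1]
    s1 = cum_plogp[-1] - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (np.log(p0) - s0 / p0) + (np.log(p1) - s1 / p1)
    h[(p0 <= 0) | (p1 <= 0)] = -np.inf
    if not np.isfinite(h).any():
        raise DegenerateInputError("no cut leaves both classes non-empty")
    # ties (exact or floating-point — cuts through empty bins share H)
    # resolve to the smallest cut
    hmax = np.max(h)
    t = int(np.argmax(h >= hmax - 1e-9 * max(abs(hmax), 1.0))) + 1
    return float(edges[t])


def segment(gray: GrayImage, threshold: float,
            plant_is_high: bool = True) -> np.ndarray:
    """Binarize a gray image at a threshold; returns a boolean plant mask.

    Invalid pixels are always background. An all-plant or all-background
    result is a failure, not a mask.
    """
    if plant_is_high:
        mask = gray.values > threshold
    else:
        mask = gray.values < threshold
    mask &= gray.valid
    n = int(mask.sum())
    if n == 0 or n == mask.size:
        raise SegmentationError(
            f"segmentation produced a trivial mask ({n} of {mask.size} plant px)")
    return mask


def segment_scene(image: np.ndarray, kind: str, n_bins: int = 256,
                  band_order: tuple[str, ...] = BANDS,
                  exclude=None) -> np.ndarray:
    """Convenience: gray-convert (``kind`` in {'rgb','ms'}), Kapur, binarize.

    ``exclude`` is an optional rectangle (e.g. the white reference panel)
    marked invalid before thresholding — a calibration region is not scene
    content and would otherwise distort the gray histogram.
    """
    if kind == "rgb":
        gray = gray_exg(image)
    elif kind == "ms":
        gray = gray_ndvi(image, band_order)
    else:
        raise BandError(f"unknown image kind {kind!r}")
    if exclude is not None:
        gray.valid[exclude.slices()] = False
    return segment(gray, kapur_threshold(gray, n_bins))


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Blank the background: float copy with NaN outside the plant mask.

    NaN acts as the sentinel that every downstream statistic excludes;
    plant pixels are unchanged.
    """
    if mask.shape != image.shape[:2]:
        raise ShapeError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}")
    if not mask.any():
        raise EmptyMaskError("mask selects no plant pixels")
    out = image.astype(float).copy()
    out[~mask.astype(bool)] = np.nan
    return out


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a, b = mask_a.astype(bool), mask_b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise EmptyMaskError("both masks are empty")
    return float(np.logical_and(a, b).sum() / union)
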