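"""Vegetation-index extraction: plant-mask channel means, white-plate
correction, and the 10 RGB + 10 multispectral index formulas.

Indices are computed from corrected channel *means* (mean first, formula
second), not from per-pixel index maps. White-plate correction divides each
plant channel mean by the white-panel mean of the same channel, treating
the panel as a 100%-reflectance reference; the ratio cancels global scene
brightness, so no further bit-depth normalization is needed.

Two formulas are kept exactly as this pipeline's source convention prints
them even where common literature differs: RGBVI uses (G² − B·R²)/(G² + B·R²)
and the "renormalized difference" RDVI uses (NDVI/DVI)^0.5. Pass
``literature_formulas=True`` for the standard variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CorrectionError, EmptyMaskError, ShapeError

RGB_INDEX_NAMES = ("ExG", "ExGR", "NGRDI", "NGBDI", "RGRI", "GBRI", "CIVE",
                   "VEG", "RGBVI", "MGRVI")
MS_INDEX_NAMES = ("NDVI", "RVI", "DVI", "EVI", "RDVI", "REVI", "NDRE",
                  "RERVI", "REDVI", "sCCCI")


@dataclass
class ChannelMeans:
    """Mean (optionally white-corrected) value per channel over a region."""

    values: dict[str, float]
    n_pixels: int

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass
class IndexVector:
    """Named index values with per-index validity flags.

    An index is invalid (NaN value, flag False) when its formula hits a zero
    denominator or a negative radicand; invalidity is recorded, never raised.
    """

    values: dict[str, float] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)

    def set(self, name: str, value: float | None) -> None:
        ok = value is not None and math.isfinite(value)
        self.values[name] = float(value) if ok else float("nan")
        self.valid[name] = bool(ok)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values)


def mask_mean(image: np.ndarray, mask: np.ndarray,
              channel_names: tuple[str, ...]) -> ChannelMeans:
    """Arithmetic mean DN per channel over mask-true pixels."""
    if image.ndim != 3 or image.shape[-1] != len(channel_names):
        raise ShapeError(
            f"image shape {image.shape} does not carry {len(channel_names)} channels")
    if mask.shape != image.shape[:2]:
        raise ShapeError("mask/image shape mismatch")
    m = mask.astype(bool)
    n = int(m.sum())
    if n == 0:
        raise EmptyMaskError("mask selects no pixels")
    sel = image[m].astype(float)
    return ChannelMeans(
        values={c: float(sel[:, i].mean()) for i, c in enumerate(channel_names)},
        n_pixels=n)


def region_mean(image: np.ndarray, rect,
                channel_names: tuple[str, ...]) -> ChannelMeans:
    """Channel means over a rectangular region (e.g. the white panel)."""
    rows, cols = rect.slices()
    sub = image[rows, cols].astype(float)
    if sub.size == 0:
        raise EmptyMaskError("empty panel region")
    return ChannelMeans(
        values={c: float(sub[..., i].mean()) for i, c in enumerate(channel_names)},
        n_pixels=int(sub.shape[0] * sub.shape[1]))


def white_correct(plant: ChannelMeans, panel: ChannelMeans) -> ChannelMeans:
    """Divide plant channel means by panel means (panel = reflectance 1.0)."""
    corrected = {}
    for c, v in plant.values.items():
        p = panel.values.get(c)
        if p is None or p <= 0:
            raise CorrectionError(f"white panel mean for channel {c!r} is not positive")
        corrected[c] = v / p
    return ChannelMeans(values=corrected, n_pixels=plant.n_pixels)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den != 0 else None


def rgb_indices(c: ChannelMeans, literature_formulas: bool = False) -> IndexVector:
    """The 10 RGB vegetation indices from corrected R, G, B means."""
    r, g, b = c["red"], c["green"], c["blue"]
    iv = IndexVector()
    exg = 2.0 * g - r - b
    iv.set("ExG", exg)
    iv.set("ExGR", exg - (1.4 * r - g))
    iv.set("NGRDI", _ratio(g - r, g + r))
    iv.set("NGBDI", _ratio(g - b, g + b))
    iv.set("RGRI", _ratio(r, g))
    iv.set("GBRI", _ratio(b, g))
    iv.set("CIVE", 0.441 * r - 0.811 * g + 0.385 * b + 18.78745)
    veg = None
    if r > 0 and b > 0:
        veg = g / (r ** 0.667 * b ** (1.0 - 0.667))
    iv.set("VEG", veg)
    if literature_formulas:
        iv.set("RGBVI", _ratio(g * g - b * r, g * g + b * r))
    else:
        iv.set("RGBVI", _ratio(g * g - b * r * r, g * g + b * r * r))
    iv.set("MGRVI", _ratio(g * g - r * r, g * g + r * r))
    return iv


def ms_indices(c: ChannelMeans, literature_formulas: bool = False) -> IndexVector:
    """The 10 multispectral vegetation indices from corrected band means."""
    blue, red = c["blue"], c["red"]
    nir, re = c["nir"], c["red_edge"]
    iv = IndexVector()
    ndvi = _ratio(nir - red, nir + red)
    iv.set("NDVI", ndvi)
    iv.set("RVI", _ratio(nir, red))
    dvi = nir - red
    iv.set("DVI", dvi)
    iv.set("EVI", _ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0))
    rdvi = None
    if literature_formulas:
        if nir + red > 0:
            rdvi = (nir - red) / math.sqrt(nir + red)
    elif ndvi is not None and dvi != 0 and ndvi / dvi >= 0:
        rdvi = math.sqrt(ndvi / dvi)
    iv.set("RDVI", rdvi)
    revi = _ratio(nir, re)
    iv.set("REVI", revi - 1.0 if revi is not None else None)
    ndre = _ratio(nir - re, nir + re)
    iv.set("NDRE", ndre)
    iv.set("RERVI", revi)
    iv.set("REDVI", nir - re)
    iv.set("sCCCI", _ratio(ndre, ndvi) if ndre is not None and ndvi is not None
           else None)
    return iv


def indices_from_scene(scene, n_bins: int = 256,
                       literature_formulas: bool = False) -> dict:
    """Segment one rendered scene and extract both corrected index sets.

    Returns a flat dict (id, shade, spad_measured, all 20 indices, masks'
    Jaccard against ground truth) suitable as one feature-table row.
    """
    from . import segmentation as seg
    from .synthscene import BANDS

    rgb_names = ("red", "green", "blue")
    row: dict = {"id": scene.record.id, "shade": scene.record.shade,
                 "spad_true": scene.record.spad_true,
                 "spad_measured": scene.record.spad_measured}

    mask_rgb = seg.segment_scene(scene.rgb, "rgb", n_bins=n_bins,
                                 exclude=scene.white_panel)
    plant = mask_mean(scene.rgb, mask_rgb, rgb_names)
    panel = region_mean(scene.rgb, scene.white_panel, rgb_names)
    rgb_iv = rgb_indices(white_correct(plant, panel), literature_formulas)
    row.update({f"rgb_{k}": v for k, v in rgb_iv.values.items()})

    mask_ms = seg.segment_scene(scene.ms, "ms", n_bins=n_bins,
                                exclude=scene.white_panel)
    plant_ms = mask_mean(scene.ms, mask_ms, BANDS)
    panel_ms = region_mean(scene.ms, scene.white_panel, BANDS)
    ms_iv = ms_indices(white_correct(plant_ms, panel_ms), literature_formulas)
    row.update({f"ms_{k}": v for k, v in ms_iv.values.items()})

    row["jaccard_rgb"] = seg.jaccard(mask_rgb, scene.truth_mask)
    row["jaccard_ms"] = seg.jaccard(mask_ms, scene.truth_mask)
    return row


def feature_table_from_scenes(scenes, n_bins: int = 256,
                              literature_formulas: bool = False) -> pd.DataFrame:
    """Per-seedling feature table (20 indices) from rendered scene pairs."""
    return pd.DataFrame([indices_from_scene(s, n_bins, literature_formulas)
                         for s in scenes])


def feature_table_from_band_means(df: pd.DataFrame,
                                  literature_formulas: bool = False
                                  ) -> pd.DataFrame:
    """Index feature table from per-seedling corrected band means.

    Consumes the layout of :func:`spadvi.synthscene.simulate_feature_table`
    (columns ``ms_<band>`` and ``rgb_<channel>``).
    """
    rows = []
    for _, r in df.iterrows():
        row = {k: r[k] for k in ("id", "shade", "spad_true", "spad_measured")}
        rgb = ChannelMeans({c: r[f"rgb_{c}"] for c in ("red", "green", "blue")}, 1)
        ms = ChannelMeans({b: r[f"ms_{b}"] for b in
                           ("blue", "green", "red", "nir", "red_edge")}, 1)
        row.update({f"rgb_{k}": v for k, v in
                    rgb_indices(rgb, literature_formulas).values.items()})
        row.update({f"ms_{k}": v for k, v in
                    ms_indices(ms, literature_formulas).values.items()})
        rows.append(row)
    return pd.DataFrame(rows)
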