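"""Synthetic seedling populations and canopy scenes with known ground truth.

The study design emulated here: four shade levels (0%, 25%, 50%, 75% of
incident light blocked by netting), 50 seedlings per level, each seedling
characterised by a SPAD reading (unitless chlorophyll-meter proxy averaged
over three leaves) and imaged from above by an 8-bit RGB camera and a
co-registered 5-band (blue/green/red/NIR/red-edge) 16-bit multispectral
camera, with a white reference panel in frame.

Shade conditions both shift the SPAD distribution (group means 18.39,
25.76, 31.81, 29.26 for 0/25/50/75% shade) and darken the scene globally;
the white panel lets downstream stages cancel the latter.

The chlorophyll-to-reflectance link is a per-band exponential decay
(Beer-Lambert-like): rho_band(SPAD) = baseline * exp(-k * SPAD) + floor.
Decay rates are ordered k_red > k_green > k_red_edge > k_nir = 0, which
reproduces the qualitative behaviour vegetation indices exploit: red and
green reflectance fall with chlorophyll while the NIR plateau is flat, so
NDVI/NDRE rise with SPAD and the red/green ratio falls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError, IOStageError

BANDS = ("blue", "green", "red", "nir", "red_edge")
#: MS band -> RGB channel mapping (RGB images store channels in R,G,B order)
RGB_FROM_MS = (2, 1, 0)

DEFAULT_SHADE_LEVELS = (0.0, 0.25, 0.50, 0.75)
DEFAULT_MEAN_SPAD = (18.39, 25.76, 31.81, 29.26)
DEFAULT_ILLUMINATION = (1.0, 0.75, 0.5, 0.25)
SPAD_FLOOR = 5.0


@dataclass(frozen=True)
class ShadeConfig:
    """Shade-level design of the synthetic population.

    ``levels`` are shade fractions (0 = full sun); ``illumination_scale``
    multiplies all scene radiance for that level and must not increase with
    shade, so that the white-plate correction is genuinely exercised.
    """

    levels: tuple[float, ...] = DEFAULT_SHADE_LEVELS
    mean_spad: tuple[float, ...] = DEFAULT_MEAN_SPAD
    sd_spad: tuple[float, ...] = (3.0, 3.0, 3.0, 3.0)
    n_per_level: int = 50
    illumination_scale: tuple[float, ...] = DEFAULT_ILLUMINATION

    def __post_init__(self) -> None:
        arrays = {
            "levels": self.levels,
            "mean_spad": self.mean_spad,
            "sd_spad": self.sd_spad,
            "illumination_scale": self.illumination_scale,
        }
        for name, vals in arrays.items():
            if len(vals) != len(self.levels):
                raise ConfigError(f"{name} must have one entry per shade level")
            if not all(math.isfinite(v) for v in vals):
                raise ConfigError(f"non-finite value in {name}")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ConfigError("shade levels must be strictly increasing")
        if self.levels[0] < 0 or self.levels[-1] >= 1:
            raise ConfigError("shade levels must lie in [0, 1)")
        if any(s < 0 for s in self.sd_spad):
            raise ConfigError("sd_spad must be non-negative")
        if self.n_per_level < 1:
            raise ConfigError("n_per_level must be >= 1")
        if any(not 0 < s <= 1 for s in self.illumination_scale):
            raise ConfigError("illumination_scale must lie in (0, 1]")
        if any(b > a for a, b in zip(self.illumination_scale,
                                     self.illumination_scale[1:])):
            raise ConfigError("illumination_scale must not increase with shade")

    def illumination_for(self, shade: float) -> float:
        for lvl, scale in zip(self.levels, self.illumination_scale):
            if math.isclose(lvl, shade):
                return scale
        raise ConfigError(f"shade {shade} is not one of the configured levels")


@dataclass(frozen=True)
class SeedlingRecord:
    """One seedling: ground-truth and meter-style SPAD plus its shade level."""

    id: str
    shade: float
    spad_true: float
    spad_measured: float

    def __post_init__(self) -> None:
        if not (self.spad_true > 0 and self.spad_measured > 0):
            raise ConfigError("SPAD values must be positive")


@dataclass(frozen=True)
class BandOptics:
    """Per-band leaf optics: rho(SPAD) = baseline * exp(-k * SPAD) + floor."""

    baseline: float
    k: float
    floor: float


@dataclass(frozen=True)
class SpectralModel:
    """Chlorophyll -> reflectance link plus soil background reflectance.

    Defaults give, at SPAD 30: leaf reflectance ~0.05 (blue), 0.18 (green),
    0.08 (red), 0.45 (NIR, SPAD-independent), 0.32 (red edge); soil follows
    a brightening-with-wavelength soil line. The decay-rate ordering
    k_red > k_green > k_red_edge > k_nir = 0 is enforced.
    """

    leaf: dict[str, BandOptics] = field(default_factory=lambda: {
        "blue": BandOptics(0.08, 0.040, 0.03),
        "green": BandOptics(0.25, 0.030, 0.08),
        "red": BandOptics(0.30, 0.060, 0.03),
        "nir": BandOptics(0.05, 0.000, 0.40),
        "red_edge": BandOptics(0.35, 0.015, 0.10),
    })
    soil: dict[str, float] = field(default_factory=lambda: {
        "blue": 0.10, "green": 0.15, "red": 0.20, "nir": 0.25,
        "red_edge": 0.22,
    })

    def __post_init__(self) -> None:
        for band in BANDS:
            if band not in self.leaf or band not in self.soil:
                raise ConfigError(f"missing optics for band {band!r}")
        k = {b: self.leaf[b].k for b in BANDS}
        if not (k["red"] > k["green"] > k["red_edge"] >= k["nir"] >= 0):
            raise ConfigError(
                "decay rates must satisfy k_red > k_green > k_red_edge >= k_nir >= 0")


def leaf_reflectance(spad: float, model: SpectralModel, band: str) -> float:
    """Leaf reflectance in (0, 1) for one band at the given SPAD value."""
    if band not in BANDS:
        raise ConfigError(f"unknown band {band!r}; expected one of {BANDS}")
    if not spad > 0:
        raise ConfigError("spad must be positive")
    opt = model.leaf[band]
    rho = opt.baseline * math.exp(-opt.k * spad) + opt.floor
    return min(max(rho, 1e-6), 1.0 - 1e-6)


def sample_population(cfg: ShadeConfig, noise_sd: float = 1.0,
                      seed: int = 0) -> list[SeedlingRecord]:
    """Draw the seedling population.

    Per level, ``spad_true ~ Normal(mean, sd)`` truncated below at 5 SPAD
    (redrawn until valid); ``spad_measured`` is the mean of three leaf
    readings ``spad_true + Normal(0, noise_sd)``, mimicking the three-leaf
    averaging protocol of a handheld meter.
    """
    if not math.isfinite(noise_sd) or noise_sd < 0:
        raise ConfigError("noise_sd must be finite and non-negative")
    rng = np.random.default_rng(seed)
    records: list[SeedlingRecord] = []
    for lvl, mean, sd in zip(cfg.levels, cfg.mean_spad, cfg.sd_spad):
        for i in range(cfg.n_per_level):
            spad = mean if sd == 0 else _truncated_normal(rng, mean, sd)
            leaves = spad + (0.0 if noise_sd == 0
                             else rng.normal(0.0, noise_sd, size=3))
            measured = float(np.mean(leaves)) if noise_sd else spad
            records.append(SeedlingRecord(
                id=f"s{int(round(lvl * 100)):02d}_{i:03d}",
                shade=lvl,
                spad_true=float(spad),
                spad_measured=max(float(measured), 0.1),
            ))
    return records


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float = SPAD_FLOOR) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lower:
            return float(v)
    raise ConfigError("truncated-normal sampling failed; mean far below floor")


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [row0, row1) x [col0, col1), 0-based."""

    row0: int
    row1: int
    col0: int
    col1: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def to_json(self) -> list[int]:
        return [self.row0, self.row1, self.col0, self.col1]


@dataclass
class ScenePair:
    """Co-registered RGB (8-bit) and 5-band MS (16-bit) renders of one seedling."""

    rgb: np.ndarray
    ms: np.ndarray
    white_panel: Rect
    truth_mask: np.ndarray
    record: SeedlingRecord


def _scene_reflectance(record: SeedlingRecord, model: SpectralModel,
                       geometry_seed: int, shape: tuple[int, int],
                       texture_sd: float = 0.05,
                       band_noise_sd: float = 0.01,
                       rgb_band_noise_sd: float = 0.01,
                       leaf_spad_cv: float = 0.15):
    """Noise-bearing reflectance fields; illumination is applied afterwards.

    Returns (ms_refl HxWx5, rgb_refl HxWx3, truth_mask, panel rect). All
    stochastic texture lives here so that re-rendering the same seedling at
    a different illumination scale changes radiance strictly linearly.

    Three variability sources shape the histograms downstream segmentation
    sees: (i) per-pixel leaf-scale chlorophyll heterogeneity
    (``leaf_spad_cv``, a coefficient of variation — leaf-to-leaf variation
    roughly scales with the mean and is why meter protocols average several
    leaves); (ii) a spectrally flat brightness field (leaf angle and
    micro-shadow affect all bands together); (iii) a small independent
    per-band term. All noise is clipped at two standard deviations so no
    lone outlier stretches the gray histogram. The white panel is
    spatially uniform, as a calibrated reference plate is.
    """
    from skimage.draw import ellipse

    h, w = shape
    panel_side = max(8, min(h, w) // 8)
    if h < 4 * panel_side or w < 4 * panel_side:
        raise GeometryError(
            f"scene {shape} too small for a {panel_side}px white panel plus plant")
    panel = Rect(2, 2 + panel_side, 2, 2 + panel_side)

    rng = np.random.default_rng([int(geometry_seed), 0xC0FFEE])
    mask = np.zeros(shape, dtype=bool)
    cy, cx = h * 0.55, w * 0.5
    n_blobs = int(rng.integers(6, 10))
    for _ in range(n_blobs):
        ecy = cy + rng.uniform(-0.10, 0.10) * h
        ecx = cx + rng.uniform(-0.12, 0.12) * w
        a = rng.uniform(0.12, 0.24) * min(h, w)
        b = rng.uniform(0.12, 0.24) * min(h, w)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(ecy, ecx, a, b, shape=shape, rotation=rot)
        mask[rr, cc] = True
    mask[panel.slices()] = False
    if not mask.any():
        raise GeometryError("plant geometry produced an empty canopy")

    def _clipped_noise(sd: float, size) -> np.ndarray:
        x = rng.normal(0.0, sd, size=size)
        return np.clip(x, -2.0 * sd, 2.0 * sd)

    pixel_spad = np.clip(
        record.spad_true
        + _clipped_noise(leaf_spad_cv * record.spad_true, int(mask.sum())),
        SPAD_FLOOR, None)
    ms = np.empty((h, w, len(BANDS)), dtype=float)
    for bi, band in enumerate(BANDS):
        ms[..., bi] = model.soil[band]
        opt = model.leaf[band]
        ms[..., bi][mask] = np.clip(
            opt.baseline * np.exp(-opt.k * pixel_spad) + opt.floor,
            1e-6, 1.0 - 1e-6)

    brightness = 1.0 + _clipped_noise(texture_sd, (h, w))
    texture = brightness[..., None] * (1.0 + _clipped_noise(band_noise_sd,
                                                            ms.shape))
    ms = np.clip(ms * texture, 0.0, 1.0)
    ms[panel.slices() + (slice(None),)] = 1.0  # uniform reference plate

    # RGB camera sees broader bands: same scene with extra spectral-mixing noise
    rgb = ms[..., list(RGB_FROM_MS)].copy()
    rgb *= 1.0 + _clipped_noise(rgb_band_noise_sd, rgb.shape)
    np.clip(rgb, 0.0, 1.0, out=rgb)
    rgb[panel.slices() + (slice(None),)] = 1.0
    return ms, rgb, mask, panel


def quantize(radiance: np.ndarray, bit_depth: int,
             rng: np.random.Generator) -> np.ndarray:
    """Floor-quantize radiance in [0,1] to integer DN with sub-LSB dither.

    DN = floor(radiance * (2^bits - 1) + u), u ~ U[0,1): the floor rule per
    pixel, but unbiased in expectation so channel means survive 8-bit depth.
    """
    max_dn = 2 ** bit_depth - 1
    dn = np.floor(radiance * max_dn + rng.random(radiance.shape))
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    return np.clip(dn, 0, max_dn).astype(dtype)


def render_scene(record: SeedlingRecord, model: SpectralModel,
                 cfg: ShadeConfig, geometry_seed: int,
                 shape: tuple[int, int] = (96, 96),
                 exposure: str = "auto") -> ScenePair:
    """Render one seedling's co-registered RGB + MS scene pair.

    Plant pixels (elliptical leaf blobs with multiplicative texture noise)
    carry leaf reflectance, background carries soil reflectance, the white
    panel carries reflectance 1.0; everything is scaled by the shade level's
    illumination factor before dithered floor quantization (16-bit MS,
    8-bit RGB). Same record + seed => bit-identical output.

    ``exposure="auto"`` (default) emulates what both field cameras actually
    do — aperture-priority metering on the RGB camera and automatic
    exposure on the MS camera: a per-scene gain holds the white panel near
    90% of full scale, with an independent seeded few-percent metering
    jitter per camera. Scene DN brightness therefore varies scene to scene
    in a way unknown to downstream stages, which is precisely why the
    white-plate correction is needed. ``exposure="fixed"`` disables the
    gains so DN scale linearly with ambient illumination.
    """
    if exposure not in ("auto", "fixed"):
        raise ConfigError("exposure must be 'auto' or 'fixed'")
    scale = cfg.illumination_for(record.shade)
    ms_refl, rgb_refl, mask, panel = _scene_reflectance(
        record, model, geometry_seed, shape)
    drng = np.random.default_rng([int(geometry_seed), 0xD17])
    if exposure == "auto":
        jrng = np.random.default_rng([int(geometry_seed), 0xE4])
        gain_rgb = 0.90 * jrng.uniform(0.95, 1.05) / scale
        gain_ms = 0.90 * jrng.uniform(0.95, 1.05) / scale
    else:
        gain_rgb = gain_ms = 1.0
    ms = quantize(np.clip(ms_refl * scale * gain_ms, 0.0, 1.0), 16, drng)
    rgb = quantize(np.clip(rgb_refl * scale * gain_rgb, 0.0, 1.0), 8, drng)
    return ScenePair(rgb=rgb, ms=ms, white_panel=panel, truth_mask=mask,
                     record=record)


def render_population(records: Sequence[SeedlingRecord], model: SpectralModel,
                      cfg: ShadeConfig, seed: int,
                      shape: tuple[int, int] = (96, 96)) -> list[ScenePair]:
    """Render every record; per-scene geometry seeds derive from ``seed``."""
    root = np.random.SeedSequence(seed)
    geo_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in root.spawn(len(records))]
    return [render_scene(r, model, cfg, gs, shape=shape)
            for r, gs in zip(records, geo_seeds)]


def simulate_feature_table(cfg: ShadeConfig, model: SpectralModel | None = None,
                           seed: int = 0, band_noise_cv: float = 0.20,
                           noise_sd: float = 1.0) -> pd.DataFrame:
    """Desk-scale shortcut past the imaging chain: corrected band means.

    Emulates what segmentation + white correction recover — one reflectance
    value per band per seedling — with multiplicative lognormal noise
    (default CV 20%, canopy-scale variability from leaf angle, gaps and
    specular effects that the rendered flat-leaf scenes do not carry). RGB
    channels get band noise independent from the MS channels, as two
    cameras would. Columns: id, shade, spad_measured, spad_true and the
    per-band corrected means consumed by :mod:`spadvi.indices`.
    """
    model = model or SpectralModel()
    records = sample_population(cfg, noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng([seed, 0xFEA7])
    sigma = math.sqrt(math.log(1.0 + band_noise_cv ** 2))
    rows = []
    for rec in records:
        base = {b: leaf_reflectance(rec.spad_true, model, b) for b in BANDS}
        row = {"id": rec.id, "shade": rec.shade,
               "spad_true": rec.spad_true, "spad_measured": rec.spad_measured}
        for b in BANDS:
            row[f"ms_{b}"] = base[b] * rng.lognormal(-0.5 * sigma ** 2, sigma)
        for b in ("red", "green", "blue"):
            row[f"rgb_{b}"] = base[b] * rng.lognormal(-0.5 * sigma ** 2, sigma)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset IO

def records_to_frame(records: Sequence[SeedlingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": r.id, "shade": r.shade, "spad_true": r.spad_true,
          "spad_measured": r.spad_measured} for r in records])


def write_dataset(scenes: Sequence[ScenePair], outdir: str | Path) -> dict:
    """Write scenes (PNG + 5-band TIFF), the records CSV and a manifest JSON.

    The manifest maps seedling ids to file paths and white-panel rectangles
    (0-based, row-major, half-open) and declares the MS band order.
    """
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    (outdir / "scenes").mkdir(parents=True, exist_ok=True)
    entries = {}
    for sc in scenes:
        rid = sc.record.id
        rgb_path = f"scenes/{rid}_rgb.png"
        ms_path = f"scenes/{rid}_ms.tif"
        mask_path = f"scenes/{rid}_truth.png"
        iio.imwrite(outdir / rgb_path, sc.rgb)
        tifffile.imwrite(outdir / ms_path, np.moveaxis(sc.ms, -1, 0))
        iio.imwrite(outdir / mask_path,
                    (sc.truth_mask.astype(np.uint8) * 255))
        entries[rid] = {"rgb": rgb_path, "ms": ms_path, "truth": mask_path,
                        "panel": sc.white_panel.to_json(),
                        "shade": sc.record.shade}
    records_to_frame([sc.record for sc in scenes]).to_csv(
        outdir / "records.csv", index=False)
    manifest = {"band_order": list(BANDS), "records": "records.csv",
                "scenes": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def load_dataset(outdir: str | Path) -> tuple[list[ScenePair], pd.DataFrame]:
    """Load a dataset written by :func:`write_dataset`."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise IOStageError(f"no manifest.json under {outdir}")
    manifest = json.loads(manifest_path.read_text())
    records = pd.read_csv(outdir / manifest["records"])
    by_id = {r["id"]: r for _, r in records.iterrows()}
    scenes = []
    for rid, entry in manifest["scenes"].items():
        row = by_id[rid]
        rec = SeedlingRecord(id=rid, shade=float(row["shade"]),
                             spad_true=float(row["spad_true"]),
                             spad_measured=float(row["spad_measured"]))
        ms = np.moveaxis(tifffile.imread(outdir / entry["ms"]), 0, -1)
        scenes.append(ScenePair(
            rgb=iio.imread(outdir / entry["rgb"]),
            ms=ms,
            white_panel=Rect(*entry["panel"]),
            truth_mask=iio.imread(outdir / entry["truth"]) > 0,
            record=rec))
    return scenes, records
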