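"""Image-derived perfusion metrics.

Two frame-level measurements recur in percolation analyses of plasma/dye
transport maps: (i) color-occupancy ratios, where each pixel of a contour
frame is assigned to a palette class (red = filled bulk, green+yellow =
graded rim, blue = unfilled interstitium, white = pore) and class counts
are reported with blue normalised to one; and (ii) binarised wetted-area
extraction from dye-imaging frames, converting above-threshold pixel counts
to physical area through a pixel scale.

Pixel classes are defined by HSV hue bands with a brightness/saturation
rule for white pores; the bands are configurable since published contour
palettes vary.  A colorbar lookup-table inversion is provided to map
contour colors back to a dimensionless intensity S in [0, 1]; it is a
nearest-neighbor approximation intended for synthetic, palette-pure frames.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv

from .rad_solver import AreaSeries

__all__ = [
    "RGBFrame",
    "ColorCounts",
    "PaletteRules",
    "OccupancyRatios",
    "UndefinedRatioError",
    "classify_pixels",
    "occupancy_ratios",
    "wetted_area_series",
    "read_frames",
    "intensity_from_lut",
    "DEFAULT_PALETTE",
]


class UndefinedRatioError(ValueError):
    """Blue-normalised ratio requested with zero blue pixels (saturated)."""


@dataclass
class RGBFrame:
    """One RGB image frame with optional acquisition metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    timestamp: float | None = None
    pixel_scale: float | None = None  # physical length per pixel

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PaletteRules:
    """Hue bands (degrees) and the white-pore brightness/saturation rule."""

    red_bands: tuple[tuple[float, float], ...] = ((0.0, 20.0), (340.0, 360.0))
    green_yellow_band: tuple[float, float] = (40.0, 160.0)
    blue_band: tuple[float, float] = (190.0, 260.0)
    white_value_min: float = 0.9
    white_saturation_max: float = 0.1


DEFAULT_PALETTE = PaletteRules()


@dataclass(frozen=True)
class ColorCounts:
    """Per-class pixel counts; classes partition the frame."""

    red: int
    green_yellow: int
    blue: int
    white_pore: int
    other: int

    @property
    def total(self) -> int:
        return self.red + self.green_yellow + self.blue + self.white_pore + self.other


@dataclass(frozen=True)
class OccupancyRatios:
    """Pixel-count ratios with blue normalised to 1 (white excluded)."""

    r_to_b: float
    gy_to_b: float
    gy_to_r: float


def classify_pixels(frame: RGBFrame, palette: PaletteRules = DEFAULT_PALETTE) -> ColorCounts:
    """Assign every pixel to exactly one palette class and count them.

    White pores are split off first by the brightness/saturation rule; the
    remaining pixels are binned by hue.  Pixels matching no band count as
    "other", so the class counts always sum to H*W.
    """
    px = frame.pixels
    if px.size == 0:
        raise ValueError("empty frame")
    hsv = rgb2hsv(px)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]

    white = (val > palette.white_value_min) & (sat < palette.white_saturation_max)
    red = np.zeros_like(white)
    for lo, hi in palette.red_bands:
        red |= (hue >= lo) & (hue < hi)
    glo, ghi = palette.green_yellow_band
    gy = (hue >= glo) & (hue < ghi)
    blo, bhi = palette.blue_band
    blue = (hue >= blo) & (hue < bhi)

    red &= ~white
    gy &= ~white & ~red
    blue &= ~white & ~red & ~gy
    other = ~(white | red | gy | blue)
    return ColorCounts(
        red=int(red.sum()),
        green_yellow=int(gy.sum()),
        blue=int(blue.sum()),
        white_pore=int(white.sum()),
        other=int(other.sum()),
    )


def occupancy_ratios(counts: ColorCounts) -> OccupancyRatios:
    """R:B, (G+Y):B and (G+Y):R from class counts (white already excluded)."""
    if counts.blue == 0:
        raise UndefinedRatioError("no blue pixels: frame saturated, B-ratios undefined")
    gy_to_r = float("nan") if counts.red == 0 else counts.green_yellow / counts.red
    return OccupancyRatios(
        r_to_b=counts.red / counts.blue,
        gy_to_b=counts.green_yellow / counts.blue,
        gy_to_r=gy_to_r,
    )


def wetted_area_series(
    frames: Sequence[RGBFrame],
    threshold: int = 50,
    pixel_scale: float | None = None,
) -> AreaSeries:
    """Binarised wetted area per frame, converted to physical units.

    A pixel counts as wetted (dye-covered) when its red channel exceeds
    the larger of the green and blue channels by more than ``threshold``
    (byte levels) - dyed liquid is strongly red-dominant against both the
    white background and pale pore walls.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    shape = frames[0].shape
    times, areas = [], []
    for i, fr in enumerate(frames):
        if fr.shape != shape:
            raise ValueError("inconsistent frame sizes in sequence")
        px = fr.pixels.astype(np.int16)
        wet = (px[..., 0] - np.maximum(px[..., 1], px[..., 2])) > threshold
        scale = pixel_scale if pixel_scale is not None else (fr.pixel_scale or 1.0)
        times.append(fr.timestamp if fr.timestamp is not None else float(i))
        areas.append(float(wet.sum()) * scale**2)
    units = "mm2" if pixel_scale is not None else "px2"
    return AreaSeries(
        np.asarray(times), np.asarray(areas), threshold=None, units=units,
        meta={"binarize_threshold": threshold},
    )


def read_frames(directory: str | Path, manifest: str | Path) -> list[RGBFrame]:
    """Load PNG frames listed in a manifest CSV (columns: file, time_s).

    The optional ``pixel_scale`` column carries physical length per pixel.
    """
    directory = Path(directory)
    frames: list[RGBFrame] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = Image.open(directory / row["file"]).convert("RGB")
            frames.append(
                RGBFrame(
                    pixels=np.asarray(img, dtype=np.uint8),
                    timestamp=float(row["time_s"]),
                    pixel_scale=float(row["pixel_scale"]) if row.get("pixel_scale") else None,
                )
            )
    frames.sort(key=lambda f: (f.timestamp is None, f.timestamp))
    return frames


def intensity_from_lut(
    frame: RGBFrame, lut_colors: np.ndarray, lut_values: np.ndarray
) -> np.ndarray:
    """Map pixel colors to intensities by nearest-neighbor LUT inversion.

    ``lut_colors`` is (K, 3) RGB bytes sampling a colorbar and
    ``lut_values`` the matching intensities in [0, 1].  Approximate: exact
    only for palette-pure (synthetic) frames whose colors appear in the LUT.
    """
    lut_colors = np.asarray(lut_colors, dtype=float)
    lut_values = np.asarray(lut_values, dtype=float)
    if lut_colors.ndim != 2 or lut_colors.shape[1] != 3 or len(lut_colors) != len(lut_values):
        raise ValueError("LUT colors must be (K, 3) with matching values")
    flat = frame.pixels.reshape(-1, 3).astype(float)
    d2 = ((flat[:, None, :] - lut_colors[None, :, :]) ** 2).sum(axis=2)
    return lut_values[np.argmin(d2, axis=1)].reshape(frame.shape)
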