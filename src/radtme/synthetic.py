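"""Ground-truth-known synthetic fixtures.

Every input the analysis stack consumes can be emulated with a known
generating law, so the whole pipeline is testable without simulation or
experiment data: bounded intensity samples with exactly prescribed means,
piecewise power-law area series with a known breakpoint, per-model paired
ensembles with a known condition effect, palette-pure RGB frame sequences
with exact per-class pixel counts, and per-model inlet time series.

All generators are deterministic under a fixed seed and return the
parameters actually used in a ``manifest`` dict alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .imaging import RGBFrame
from .rad_solver import AreaSeries

__all__ = [
    "InfeasibleSpecError",
    "gen_intensity_pair",
    "gen_piecewise_powerlaw",
    "gen_model_ensemble",
    "gen_block_frame",
    "gen_disk_frames",
    "gen_inlet_series",
]


class InfeasibleSpecError(ValueError):
    """Requested moments cannot be realised with support in [0, 1]."""


def _beta_exact_mean(mean: float, spread: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Beta sample on [0,1] recentred to hit ``mean`` exactly.

    The beta distribution is reparameterised by (mean, sd); the draw is then
    affinely contracted about the target mean until it fits in [0, 1], which
    leaves the sample mean exact to floating precision without clipping.
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleSpecError("mean must lie strictly inside (0, 1)")
    if spread <= 0 or spread**2 >= mean * (1.0 - mean):
        raise InfeasibleSpecError("spread incompatible with a beta law at this mean")
    kappa = mean * (1.0 - mean) / spread**2 - 1.0
    x = rng.beta(mean * kappa, (1.0 - mean) * kappa, size=n)
    centred = x - x.mean()
    scale = 1.0
    for _ in range(100):
        cand = mean + scale * centred
        if cand.min() >= 0.0 and cand.max() <= 1.0:
            return cand
        scale *= 0.9
    raise InfeasibleSpecError("could not fit the sample inside [0, 1]")


def gen_intensity_pair(
    mean_a: float, mean_b: float, spread: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two bounded intensity samples with sample means exactly as requested.

    Emulates paired ROI pixel-intensity distributions; the exact means make
    mean-difference identities (e.g. the area between exceedance curves)
    reproducible to floating precision.
    """
    rng = np.random.default_rng(seed)
    a = _beta_exact_mean(mean_a, spread, n, rng)
    b = _beta_exact_mean(mean_b, spread, n, rng)
    manifest = {
        "kind": "intensity_pair",
        "mean_a": mean_a,
        "mean_b": mean_b,
        "spread": spread,
        "n": n,
        "seed": seed,
    }
    return a, b, manifest


def gen_piecewise_powerlaw(
    m1: float,
    b1: float,
    m2: float,
    t_star: float,
    t_range: tuple[float, float],
    n_points: int = 60,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AreaSeries:
    """Area series following two power laws joined continuously at t*.

    log10 A = m1 * log10 t + b1 before t*, slope m2 after, with the second
    intercept b2 = b1 + (m1 - m2) * log10 t* enforcing continuity.  Times
    are log-spaced over ``t_range``; optional multiplicative lognormal
    noise of relative magnitude ``noise_sd``.
    """
    t_lo, t_hi = t_range
    if not 0 < t_lo < t_star < t_hi:
        raise ValueError("need 0 < t_lo < t_star < t_hi")
    times = np.logspace(math.log10(t_lo), math.log10(t_hi), n_points)
    x = np.log10(times)
    xs = math.log10(t_star)
    b2 = b1 + (m1 - m2) * xs
    logA = np.where(x < xs, m1 * x + b1, m2 * x + b2)
    area = 10.0**logA
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        area = area * np.exp(rng.normal(0.0, noise_sd, size=n_points))
    return AreaSeries(
        times,
        area,
        units="mm2",
        meta={
            "kind": "piecewise_powerlaw",
            "m1": m1,
            "b1": b1,
            "m2": m2,
            "b2": b2,
            "t_star": t_star,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def gen_model_ensemble(
    n_models: int,
    base_mean: float,
    effect: float,
    model_sd: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Paired per-model means (non-EHD, EHD = non-EHD + effect + jitter).

    Emulates an across-geometry ensemble in which one condition shifts the
    per-model mean intensity by a common effect plus model-level jitter.
    Returns (non_ehd, ehd, manifest).
    """
    if n_models < 2:
        raise ValueError("need at least two models")
    rng = np.random.default_rng(seed)
    non = base_mean + rng.normal(0.0, model_sd, size=n_models)
    ehd = non + effect + rng.normal(0.0, model_sd, size=n_models)
    manifest = {
        "kind": "model_ensemble",
        "n_models": n_models,
        "base_mean": base_mean,
        "effect": effect,
        "model_sd": model_sd,
        "seed": seed,
    }
    return non, ehd, manifest


# palette-pure RGB bytes for the contour-map classes
_CLASS_RGB = {
    "red": (255, 0, 0),
    "green_yellow": (0, 255, 0),
    "blue": (0, 0, 255),
    "white_pore": (255, 255, 255),
    "other": (128, 0, 128),
}


def gen_block_frame(
    shape: tuple[int, int], composition: dict[str, float], seed: int = 0
) -> tuple[RGBFrame, dict[str, int]]:
    """Frame with exactly known per-class pixel counts.

    ``composition`` maps class names to fractions summing to <= 1 (the
    remainder is filled with blue).  Pixels are laid out in contiguous
    scan-order blocks, so counts are exact by construction; returns the
    frame and the ground-truth counts.
    """
    h, w = shape
    total = h * w
    counts: dict[str, int] = {}
    assigned = 0
    for name, fr in composition.items():
        if name not in _CLASS_RGB:
            raise ValueError(f"unknown class {name}")
        c = int(round(fr * total))
        counts[name] = c
        assigned += c
    if assigned > total:
        raise ValueError("composition exceeds the frame")
    counts["blue"] = counts.get("blue", 0) + (total - assigned)

    flat = np.empty((total, 3), dtype=np.uint8)
    pos = 0
    for name, c in counts.items():
        flat[pos : pos + c] = _CLASS_RGB[name]
        pos += c
    return RGBFrame(flat.reshape(h, w, 3)), counts


def gen_disk_frames(
    times: Sequence[float],
    growth_rate: float,
    shape: tuple[int, int] = (200, 200),
    pixel_scale: float = 1.0,
) -> list[RGBFrame]:
    """Red dye disk growing as r(t) = sqrt(growth_rate * t) on white.

    The wetted area is pi * growth_rate * t (up to pixelisation), so a
    log-log fit of the extracted series has unit slope.  ``pixel_scale``
    is the physical length of one pixel; the disk radius is in physical
    units.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rr = np.hypot((xx - cx) * pixel_scale, (yy - cy) * pixel_scale)
    frames = []
    for t in times:
        r = math.sqrt(max(growth_rate * t, 0.0))
        px = np.full((h, w, 3), 255, dtype=np.uint8)
        mask = rr <= r
        px[mask] = (220, 20, 20)
        frames.append(RGBFrame(px, timestamp=float(t), pixel_scale=pixel_scale))
    return frames


def gen_inlet_series(
    n_models: int,
    n_times: int = 50,
    t_end: float = 0.2,
    p_base: float = 2780.0,
    u_base: float = 3.4e-5,
    rel_sd: float = 0.05,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-model fenestral (times, pressure, velocity) on a common grid.

    Each member is a smooth ramp-to-plateau with model-specific random
    amplitude, emulating vessel-scale start-up transients.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, n_times)
    ramp = 1.0 - np.exp(-t / (0.1 * t_end + 1e-30))
    members = []
    for _ in range(n_models):
        ap = 1.0 + rng.normal(0.0, rel_sd)
        au = 1.0 + rng.normal(0.0, rel_sd)
        members.append((t.copy(), p_base * ap * ramp, u_base * au * ramp))
    return members
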