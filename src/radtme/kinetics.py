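"""Two-regime power-law kinetics of wetted/occupied-area growth.

Plasma ingress through a fenestra into a fiber-dense interstitium shows two
successive growth regimes of the wetted area A(t): a steep advection-driven
stage followed by a shallow diffusion-controlled stage.  On log-log axes a
power law ``A = 10^b * t^m`` is a straight line, so the analysis reduces to
an unconstrained two-segment ordinary-least-squares fit in
``(log10 t, log10 A)`` with the segment boundary chosen to minimise the
total residual sum of squares.  The module also provides the temporal
calibration between two model variants (single time-axis rescale matching
their breakpoints) and the thickness-based timescale reconciliation between
a 3D constant-flow experiment and its 2D per-depth numerical surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .rad_solver import AreaSeries

__all__ = [
    "SegmentFit",
    "BreakpointFit",
    "ScalingReconciliation",
    "InsufficientDataError",
    "InvalidForLogError",
    "ols_loglog",
    "two_segment_breakpoint",
    "predict_area",
    "breakpoint_offset",
    "temporal_calibration",
    "rescale_time",
    "scaling_reconciliation",
    "residual_curve",
]

#: Minimum points per segment; R^2 is uninformative below three points.
DEFAULT_MIN_SEG = 3


class InsufficientDataError(ValueError):
    """Too few samples for the requested fit."""


class InvalidForLogError(ValueError):
    """Non-positive time or area cannot be log-transformed."""


@dataclass(frozen=True)
class SegmentFit:
    """One straight-line fit in (log10 t, log10 A) space."""

    slope: float
    intercept: float
    r_squared: float
    index_range: tuple[int, int]  # half-open [start, stop)
    rss: float = 0.0


@dataclass(frozen=True)
class BreakpointFit:
    """Unconstrained two-segment fit with its transition time t*."""

    t_star: float
    advection_fit: SegmentFit
    diffusion_fit: SegmentFit
    total_rss: float
    degenerate: bool = False


@dataclass(frozen=True)
class ScalingReconciliation:
    """3D-experiment vs 2D-model timescale/thickness reconciliation record."""

    dt_exp: float
    dt_cfd: float
    timescale_ratio: float
    h_exp: float
    h_eff: float
    f_t: float
    f_a: float


def _logxy(times: np.ndarray, areas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(times <= 0) or np.any(areas <= 0):
        raise InvalidForLogError("times and areas must be strictly positive")
    return np.log10(times), np.log10(areas)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R^2 and RSS of ordinary least squares on (x, y)."""
    xb, yb = x.mean(), y.mean()
    sxx = float(np.sum((x - xb) ** 2))
    if sxx == 0.0:
        raise InvalidForLogError("degenerate abscissa: all times equal")
    m = float(np.sum((x - xb) * (y - yb)) / sxx)
    b = float(yb - m * xb)
    resid = y - (m * x + b)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - yb) ** 2))
    r2 = 1.0 if tss == 0.0 else 1.0 - rss / tss
    return m, b, r2, rss


def ols_loglog(
    series: AreaSeries, start: int = 0, stop: int | None = None
) -> SegmentFit:
    """OLS power-law fit of ``series`` samples ``[start:stop]`` in log10 space."""
    stop = len(series.times) if stop is None else stop
    t = series.times[start:stop]
    a = series.area[start:stop]
    if len(t) < 2:
        raise InsufficientDataError("need at least two points for a line")
    x, y = _logxy(t, a)
    m, b, r2, rss = _ols(x, y)
    return SegmentFit(m, b, r2, (start, stop), rss)


def two_segment_breakpoint(series: AreaSeries, min_seg: int = DEFAULT_MIN_SEG) -> BreakpointFit:
    """Scan all admissible splits; keep the one minimising the total RSS.

    The breakpoint time is reported at the geometric mean of the last
    pre-split and first post-split sample times.  If every admissible split
    yields (numerically) the same total RSS - a single pure power law - the
    earliest split is returned with ``degenerate=True``.
    """
    n = len(series.times)
    if n < 2 * min_seg:
        raise InsufficientDataError(f"need at least {2 * min_seg} points")
    x, y = _logxy(series.times, series.area)

    best = None
    rss_all = []
    for split in range(min_seg, n - min_seg + 1):
        m1, b1, r21, rss1 = _ols(x[:split], y[:split])
        m2, b2, r22, rss2 = _ols(x[split:], y[split:])
        total = rss1 + rss2
        rss_all.append(total)
        if best is None or total < best[0] - 1e-15:
            best = (total, split, (m1, b1, r21, rss1), (m2, b2, r22, rss2))

    total, split, f1, f2 = best
    tss = float(np.sum((y - y.mean()) ** 2))
    scale = max(tss, 1.0)
    degenerate = bool(np.ptp(rss_all) <= 1e-10 * scale)
    t_star = float(np.sqrt(series.times[split - 1] * series.times[split]))
    adv = SegmentFit(*f1[:3], (0, split), f1[3])
    diff = SegmentFit(*f2[:3], (split, n), f2[3])
    return BreakpointFit(t_star, adv, diff, total, degenerate)


def predict_area(fit: SegmentFit, t: float) -> float:
    """One-sided model prediction A(t) = 10^b * t^m (series area units)."""
    if t <= 0:
        raise ValueError("t must be positive")
    return float(10.0**fit.intercept * t**fit.slope)


def breakpoint_offset(bp: BreakpointFit) -> tuple[float, float]:
    """Relative mismatch of the one-sided predictions at t*.

    Returns ``(A_adv - A_diff) / A_diff`` and the same difference relative
    to the mean of the two predictions.
    """
    a_adv = predict_area(bp.advection_fit, bp.t_star)
    a_diff = predict_area(bp.diffusion_fit, bp.t_star)
    rel = (a_adv - a_diff) / a_diff
    rel_mean = (a_adv - a_diff) / ((a_adv + a_diff) / 2.0)
    return rel, rel_mean


def temporal_calibration(t_star_slow: float, t_star_fast: float) -> float:
    """Time-axis stretch k = t*_slow / t*_fast aligning two model variants."""
    if t_star_slow <= 0 or t_star_fast <= 0:
        raise ValueError("breakpoints must be positive")
    return t_star_slow / t_star_fast


def rescale_time(series: AreaSeries, k: float) -> AreaSeries:
    """Return the series on the rescaled time axis t / k."""
    if k <= 0:
        raise ValueError("k must be positive")
    return AreaSeries(
        series.times / k,
        series.area.copy(),
        threshold=series.threshold,
        units=series.units,
        meta={**series.meta, "time_rescale_k": k},
    )


def scaling_reconciliation(
    t_exp_end: float, t_star_exp: float, t_star_cfd: float, h_exp: float
) -> ScalingReconciliation:
    """Post-transition timescale ratio and inferred effective 2D thickness.

    Under constant-flow feeding of a thin layer of thickness H, mass
    conservation gives Q = eps * H * dA/dt, so timescales are proportional
    to thickness at leading order.  Comparing the post-transition windows
    ``(t_exp_end - t*_exp) / t*_cfd`` therefore estimates the thickness
    ratio, from which the per-depth surrogate's effective thickness
    ``h_eff = H_exp / ratio`` follows; the same ratio doubles as the time
    (f_t) and area (f_a) rescaling factors.
    """
    if not (t_exp_end > t_star_exp > 0) or t_star_cfd <= 0:
        raise ValueError("require t_exp_end > t_star_exp > 0 and t_star_cfd > 0")
    ratio = (t_exp_end - t_star_exp) / t_star_cfd
    h_eff = h_exp / ratio
    return ScalingReconciliation(
        dt_exp=t_exp_end - t_star_exp,
        dt_cfd=t_star_cfd,
        timescale_ratio=ratio,
        h_exp=h_exp,
        h_eff=h_eff,
        f_t=ratio,
        f_a=h_exp / h_eff,
    )


def residual_curve(
    exp_series: AreaSeries, cfd_series: AreaSeries, f_t: float, f_a: float
) -> tuple[np.ndarray, np.ndarray]:
    """log10(A_exp / (A_cfd,scaled)) at experiment times after rescaling.

    The model series is rescaled by ``t -> t * f_t`` and ``A -> A * f_a``
    and interpolated in log-log space onto the experiment times that fall
    inside the rescaled support.
    """
    xt = np.log10(cfd_series.times * f_t)
    xa = np.log10(cfd_series.area * f_a)
    te = np.asarray(exp_series.times, dtype=float)
    inside = (te >= 10 ** xt.min()) & (te <= 10 ** xt.max())
    if not np.any(inside):
        raise ValueError("no overlap between experiment times and rescaled model support")
    tt = te[inside]
    interp = np.interp(np.log10(tt), xt, xa)
    resid = np.log10(exp_series.area[inside]) - interp
    return tt, resid
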