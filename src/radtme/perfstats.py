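"""Paired perfusion-intensity statistics.

Plasma penetration at a fenestral region of interest is summarised by a
dimensionless intensity ``S`` in [0, 1] per pixel.  Comparing an
electrohydrodynamically forced (EHD) condition against its non-EHD baseline
over the same ROI yields two paired empirical distributions, which this
module summarises with the standard nonparametric toolkit:

* Cohen's d (pooled-SD standardised mean difference),
* probability of superiority (AUC) and Cliff's delta = 2*AUC - 1,
* the Hodges-Lehmann median of paired differences,
* exceedance (survival) curves E(tau) = P(S > tau) and the area between
  them (ABC), which for samples bounded in [0, 1] equals the difference of
  sample means,
* high-intensity fractions at a stringent threshold,

plus an across-model ensemble summary (grand means, bootstrap CI on the
mean paired difference, exact two-sided Wilcoxon signed-rank test).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ExceedanceCurve",
    "PairedComparison",
    "EnsembleSummary",
    "DegenerateDistributionError",
    "UnpairedSamplesError",
    "cohens_d",
    "auc_superiority",
    "cliffs_delta_from_auc",
    "hodges_lehmann_paired",
    "exceedance_curve",
    "exceedance_pair",
    "area_between_curves",
    "abc_from_samples",
    "high_intensity_fraction",
    "compare",
    "ensemble_summary",
]


class DegenerateDistributionError(ValueError):
    """Zero pooled variance: standardised effect size undefined."""


class UnpairedSamplesError(ValueError):
    """Elementwise paired statistic requested on unequal-length samples."""


def _as_sample(values, name: str = "sample", unit_interval: bool = False) -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    if unit_interval and (a.min() < 0.0 or a.max() > 1.0):
        raise ValueError(f"{name} must lie in [0, 1]")
    return a


@dataclass(frozen=True)
class ExceedanceCurve:
    """Survival curve E(tau) = fraction of values strictly above tau."""

    thresholds: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("thresholds and values must align")
        if np.any(np.diff(t) < 0):
            raise ValueError("thresholds must be non-decreasing")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PairedComparison:
    """Full effect-size report for one EHD vs non-EHD ROI pair."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    pooled_sd: float
    cohen_d: float
    auc: float
    cliffs_delta: float
    hl_shift: float | None
    abc: float
    threshold_fractions: dict[float, tuple[float, float]]
    n_a: int
    n_b: int


@dataclass(frozen=True)
class EnsembleSummary:
    """Across-model paired summary (one mean per model and condition)."""

    per_model_a: np.ndarray
    per_model_b: np.ndarray
    grand_mean_a: float
    grand_mean_b: float
    delta: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    seed: int
    wilcoxon_p: float
    relative_gain_percent: float
    degenerate: bool = False


def cohens_d(a, b) -> float:
    """Standardised mean difference with the pooled (n-1) standard deviation."""
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in both samples")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    sp = np.sqrt(((len(a) - 1) * sa**2 + (len(b) - 1) * sb**2) / (len(a) + len(b) - 2))
    if sp == 0:
        raise DegenerateDistributionError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / sp)


def auc_superiority(a, b) -> float:
    """P(a > b) over all cross pairs, ties counted one half.

    Computed from the rank-based Mann-Whitney U statistic.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    u1 = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(u1 / (len(a) * len(b)))


def cliffs_delta_from_auc(auc: float) -> float:
    """Cliff's delta = 2*AUC - 1."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    return 2.0 * auc - 1.0


def hodges_lehmann_paired(a, b, method: str = "elementwise") -> float:
    """Location shift between paired samples.

    ``elementwise`` (default): median of the per-pixel differences a_i - b_i.
    ``cross``: classical two-sample Hodges-Lehmann, the median over all
    cross-pair differences a_i - b_j.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    if method == "elementwise":
        if len(a) != len(b):
            raise UnpairedSamplesError("elementwise shift needs equal-length samples")
        return float(np.median(a - b))
    if method == "cross":
        return float(np.median(a[:, None] - b[None, :]))
    raise ValueError("method must be 'elementwise' or 'cross'")


def exceedance_curve(values, grid) -> ExceedanceCurve:
    """E(tau) = #{S > tau} / N on the supplied threshold grid."""
    s = _as_sample(values, "values")
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0.0 or grid.max() > 1.0):
        raise ValueError("grid must lie within [0, 1]")
    sorted_s = np.sort(s)
    # count of values strictly greater than tau
    e = len(s) - np.searchsorted(sorted_s, grid, side="right")
    return ExceedanceCurve(grid, e / len(s))


def exceedance_pair(a, b) -> tuple[ExceedanceCurve, ExceedanceCurve]:
    """Both curves on the pooled breakpoint grid (exact step representation).

    The grid contains 0, 1 and every distinct sample value in [0, 1), so
    each curve is exactly constant between consecutive grid points and
    step-function integration over the grid is exact.
    """
    a = _as_sample(a, "a", unit_interval=True)
    b = _as_sample(b, "b", unit_interval=True)
    pooled = np.concatenate([a, b])
    grid = np.unique(np.concatenate([[0.0, 1.0], pooled[pooled < 1.0]]))
    return exceedance_curve(a, grid), exceedance_curve(b, grid)


def area_between_curves(e1: ExceedanceCurve, e2: ExceedanceCurve) -> float:
    """Integral over [0, 1] of E1 - E2 by right-continuous step integration.

    Exact whenever the common grid contains every jump location of both
    curves (use :func:`exceedance_pair` to build such a grid).
    """
    if e1.thresholds.shape != e2.thresholds.shape or not np.allclose(
        e1.thresholds, e2.thresholds
    ):
        raise ValueError("curves must share a common grid; resample first")
    tau = e1.thresholds
    if tau[0] > 0.0 or tau[-1] < 1.0:
        raise ValueError("grid must span [0, 1] for the ABC integral")
    diff = e1.values - e2.values
    widths = np.diff(tau)
    return float(np.sum(diff[:-1] * widths))


def abc_from_samples(a, b) -> float:
    """Exact area between the two exceedance curves of bounded samples.

    For S in [0, 1] the survival-expectation identity makes this equal to
    ``mean(a) - mean(b)``; the step integration computes it without using
    that shortcut.
    """
    e1, e2 = exceedance_pair(a, b)
    return area_between_curves(e1, e2)


def high_intensity_fraction(values, tau: float) -> float:
    """Percentage of values strictly above tau."""
    s = _as_sample(values, "values")
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    return float(100.0 * np.mean(s > tau))


def compare(a, b, taus: Sequence[float] = (0.7,)) -> PairedComparison:
    """All paired effect sizes for one ROI pair (a = EHD, b = non-EHD)."""
    a = _as_sample(a, "a", unit_interval=True)
    b = _as_sample(b, "b", unit_interval=True)
    auc = auc_superiority(a, b)
    try:
        hl = hodges_lehmann_paired(a, b)
    except UnpairedSamplesError:
        hl = None
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    sp = np.sqrt(((len(a) - 1) * sa**2 + (len(b) - 1) * sb**2) / (len(a) + len(b) - 2))
    return PairedComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(sa),
        sd_b=float(sb),
        pooled_sd=float(sp),
        cohen_d=cohens_d(a, b),
        auc=auc,
        cliffs_delta=cliffs_delta_from_auc(auc),
        hl_shift=hl,
        abc=abc_from_samples(a, b),
        threshold_fractions={
            float(t): (high_intensity_fraction(a, t), high_intensity_fraction(b, t))
            for t in taus
        },
        n_a=len(a),
        n_b=len(b),
    )


def ensemble_summary(
    means_a,
    means_b,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> EnsembleSummary:
    """Across-model summary of paired per-model means (a = EHD, b = non-EHD).

    The bootstrap resamples models with replacement and reports the
    percentile CI of the mean paired difference; the Wilcoxon signed-rank
    test uses the exact null distribution (zero differences dropped).
    """
    a = _as_sample(means_a, "means_a")
    b = _as_sample(means_b, "means_b")
    if len(a) != len(b):
        raise UnpairedSamplesError("need one paired mean per model")
    if len(a) < 2:
        raise ValueError("need at least two models")
    d = a - b
    delta = float(a.mean() - b.mean())

    degenerate = bool(np.all(d == 0.0))
    if degenerate:
        p = 1.0
        ci_low = ci_high = 0.0
    else:
        p = float(
            stats.wilcoxon(d[d != 0.0], alternative="two-sided", method="exact").pvalue
        )
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(d), size=(n_boot, len(d)))
        boots = d[idx].mean(axis=1)
        alpha = 1.0 - ci_level
        ci_low, ci_high = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])

    gm_b = float(b.mean())
    gain = 0.0 if gm_b == 0 else 100.0 * delta / gm_b
    return EnsembleSummary(
        per_model_a=a,
        per_model_b=b,
        grand_mean_a=float(a.mean()),
        grand_mean_b=gm_b,
        delta=delta,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
        wilcoxon_p=p,
        relative_gain_percent=float(gain),
        degenerate=degenerate,
    )
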