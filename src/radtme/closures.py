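"""Constitutive and electrohydrodynamic closure evaluators.

Standalone, pluggable formulas used by the vessel-scale multiphase blood
flow description: Carreau-Yasuda-type shear-thinning blood viscosity with
hematocrit-dependent coefficients, the RBC agglomeration shape factor, the
Kelvin electric body force and its phase-aggregated form, the
interpenetrating-phase fraction constraint, and ensemble averaging of
per-model fenestral inlet series.  SI units at this module's boundary
(Pa*s, V/m, C/m^3, kg/m^3); shear rates in 1/s.

No field equations are solved here - electric fields, charge densities and
permittivity gradients are caller-supplied samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

__all__ = [
    "RheologyParams",
    "CarreauCoeffs",
    "PhaseFractions",
    "EHDParams",
    "EMFieldSample",
    "InletSeries",
    "PhaseValidity",
    "REGISTRY",
    "carreau_coefficients",
    "apparent_viscosity",
    "mixture_viscosity",
    "rbc_shape_factor",
    "kelvin_force",
    "phase_aggregated_force",
    "validate_phase_fractions",
    "ensemble_inlet_average",
    "refinement_delta",
]

#: Parameter registry: material, electrical and numerical constants of the
#: vessel-scale model, plus the mesh-refinement study table (element size in
#: um, element count, domain-averaged pressure in Pa and velocity in m/s).
REGISTRY: dict = {
    "relaxation_time_s": 0.110,
    "eta_plasma_Pa_s": 0.001,
    "eta_wbc_Pa_s": 0.011,
    "rho_plasma_kg_m3": 1030.0,
    "rho_rbc_kg_m3": 1100.0,
    "rho_wbc_kg_m3": 1080.0,
    "d_rbc_um": 7.0,
    "d_wbc_um": 14.0,
    "zeta_V": -0.01,
    "eps0_F_m": 8.854e-12,
    "sigma_plasma_S_m": 1.2,
    "sigma_rbc_S_m": 0.52,
    "sigma_wbc_S_m": 0.64,
    "vessel_inlet_pressure_Pa": 3325.0,
    "vessel_outlet_pressure_Pa": 2128.0,
    "ecm_outlet_pressure_Pa": 2780.0,
    "rho_air_kg_m3": 1.225,
    "eta_air_Pa_s": 1.8e-5,
    "time_step_s": 1.0e-4,
    "n_time_steps": 2000,
    "mesh_refinement_study": [
        # (element size um, elements, P_avg Pa, V_avg m/s)
        (5.0, 8_000, 2193.67, 3.1e-5),
        (3.0, 19_000, 2180.66, 4.3e-5),
        (1.00, 77_000, 2180.26, 3.43e-5),
        (0.76, 80_000, 2180.48, 3.44e-5),
    ],
}


class IncompatibleGridsError(ValueError):
    """Member inlet series do not share a time grid."""


@dataclass(frozen=True)
class RheologyParams:
    """Blood rheology constants (SI)."""

    relaxation_time: float = REGISTRY["relaxation_time_s"]
    eta_plasma: float = REGISTRY["eta_plasma_Pa_s"]
    eta_wbc: float = REGISTRY["eta_wbc_Pa_s"]
    rho_plasma: float = REGISTRY["rho_plasma_kg_m3"]
    rho_rbc: float = REGISTRY["rho_rbc_kg_m3"]
    rho_wbc: float = REGISTRY["rho_wbc_kg_m3"]
    d_rbc_um: float = REGISTRY["d_rbc_um"]
    d_wbc_um: float = REGISTRY["d_wbc_um"]

    def __post_init__(self) -> None:
        for name in ("relaxation_time", "eta_plasma", "eta_wbc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CarreauCoeffs:
    """Hematocrit-dependent Carreau-Yasuda coefficients a, b."""

    a: float
    b: float
    branch: str  # "high-shear" | "low-shear"
    yasuda_k: float | None = None


@dataclass(frozen=True)
class PhaseFractions:
    """Plasma / RBC / WBC volume fractions summing to one."""

    alpha_p: float
    alpha_r: float
    alpha_w: float

    def __post_init__(self) -> None:
        rep = validate_phase_fractions(self.alpha_p, self.alpha_r, self.alpha_w)
        if not rep.valid:
            raise ValueError("; ".join(rep.violations))


@dataclass(frozen=True)
class EHDParams:
    """Electrical constants and phase charge densities for the Kelvin force."""

    zeta: float = REGISTRY["zeta_V"]
    eps0: float = REGISTRY["eps0_F_m"]
    eps_r: float = 1.0
    rho_e_p: float = 0.0
    rho_e_r: float = 0.0
    rho_e_w: float = 0.0

    def __post_init__(self) -> None:
        if self.eps0 <= 0 or self.eps_r <= 0:
            raise ValueError("permittivities must be positive")


@dataclass(frozen=True)
class EMFieldSample:
    """Pointwise electric-field data (caller-supplied; no Poisson solve)."""

    E: tuple[float, float]
    rho_e: float = 0.0
    grad_eps: tuple[float, float] = (0.0, 0.0)
    normE_sq: float | None = None

    def __post_init__(self) -> None:
        if self.normE_sq is not None:
            if not math.isclose(self.normE_sq, self.E[0] ** 2 + self.E[1] ** 2, rel_tol=1e-9):
                raise ValueError("normE_sq inconsistent with E")


@dataclass(frozen=True)
class InletSeries:
    """Per-model fenestral pressure/velocity series and ensemble means."""

    times: np.ndarray
    pressure: np.ndarray  # (n_models, n_times) Pa
    velocity: np.ndarray  # (n_models, n_times) m/s
    p_mean: np.ndarray
    u_mean: np.ndarray


@dataclass(frozen=True)
class PhaseValidity:
    valid: bool
    violations: tuple[str, ...]
    total: float


_HIGH_A = (122.28, -51.213, 16.305)
_HIGH_B = (0.8092, -0.8246, -0.3503)
_LOW_A = (70.782, -22.454, 9.7193)
_LOW_B = (-0.8913, 2.0679, -1.7814)


def _poly3(coeffs: tuple[float, float, float], x: float) -> float:
    c3, c2, c1 = coeffs
    return c3 * x**3 + c2 * x**2 + c1 * x


def carreau_coefficients(alpha_r: float, gamma_dot: float) -> CarreauCoeffs:
    """Shear- and hematocrit-dependent Carreau-Yasuda coefficients.

    For shear rates >= 6 1/s the high-shear polynomial pair applies.  Below
    6 1/s a Yasuda-exponent branch applies with k = ln(ln g)/ln g and
    b = 1 + k * poly(alpha_r).  That exponent is undefined for g <= 1, so
    the low-shear branch is restricted to g in (1, 6); at or below 1 1/s
    the high-shear coefficient set (which has the correct Newtonian plateau
    limit) is used instead and a warning is emitted.
    """
    if not 0.0 <= alpha_r < 1.0:
        raise ValueError("alpha_r must lie in [0, 1)")
    if gamma_dot < 0:
        raise ValueError("gamma_dot must be non-negative")
    if gamma_dot >= 6.0:
        return CarreauCoeffs(
            a=1.0 + _poly3(_HIGH_A, alpha_r),
            b=1.0 + _poly3(_HIGH_B, alpha_r),
            branch="high-shear",
        )
    if gamma_dot <= 1.0:
        warnings.warn(
            "Yasuda exponent undefined for shear rate <= 1 1/s; "
            "falling back to the high-shear coefficient set",
            stacklevel=2,
        )
        return CarreauCoeffs(
            a=1.0 + _poly3(_HIGH_A, alpha_r),
            b=1.0 + _poly3(_HIGH_B, alpha_r),
            branch="high-shear",
        )
    k = math.log(math.log(gamma_dot)) / math.log(gamma_dot)
    return CarreauCoeffs(
        a=1.0 + _poly3(_LOW_A, alpha_r),
        b=1.0 + k * _poly3(_LOW_B, alpha_r),
        branch="low-shear",
        yasuda_k=k,
    )


def apparent_viscosity(
    gamma_dot: float, alpha_r: float, params: RheologyParams | None = None
) -> float:
    """Shear-thinning blood viscosity, Pa*s.

    eta = eta_plasma * a * (1 + (tau * g)^2)^((b - 1)/2), with a, b from
    :func:`carreau_coefficients`.  The Carreau expression is read as the
    hematocrit-dependent viscosity in multiples of the baseline plasma
    viscosity (a and b are dimensionless).
    """
    params = params or RheologyParams()
    cc = carreau_coefficients(alpha_r, gamma_dot)
    factor = (1.0 + (params.relaxation_time * gamma_dot) ** 2) ** ((cc.b - 1.0) / 2.0)
    return params.eta_plasma * cc.a * factor


def mixture_viscosity(
    phases: PhaseFractions,
    gamma_dot: float,
    params: RheologyParams | None = None,
    policy: str = "aggregate",
    eta_rbc: float | None = None,
) -> float:
    """Volume-fraction-weighted mixture viscosity, Pa*s.

    ``aggregate`` (default): the plasma+RBC suspension contributes the
    shear- and hematocrit-dependent apparent viscosity, WBCs their own
    constant, so mu = (alpha_p + alpha_r) * eta_app(alpha_r, g)
    + alpha_w * eta_WBC.  No separate constant RBC viscosity exists in this
    reading - the RBC effect lives inside eta_app.

    ``weighted``: the literal three-term sum
    alpha_r * eta_rbc + alpha_p * eta_app + alpha_w * eta_WBC, which
    requires a caller-supplied constant ``eta_rbc``.
    """
    params = params or RheologyParams()
    eta_app = apparent_viscosity(gamma_dot, phases.alpha_r, params)
    if policy == "aggregate":
        return (phases.alpha_p + phases.alpha_r) * eta_app + phases.alpha_w * params.eta_wbc
    if policy == "weighted":
        if eta_rbc is None:
            raise ValueError("weighted policy requires eta_rbc")
        return (
            phases.alpha_r * eta_rbc
            + phases.alpha_p * eta_app
            + phases.alpha_w * params.eta_wbc
        )
    raise ValueError("policy must be 'aggregate' or 'weighted'")


def rbc_shape_factor(gamma_dot: float, params: RheologyParams | None = None) -> float:
    """Dynamic RBC agglomeration shape factor.

    xi = 1.5 * (1 + (tau * g)^2)^0.058697 for g <= 300 1/s, else 1.
    """
    if gamma_dot < 0:
        raise ValueError("gamma_dot must be non-negative")
    params = params or RheologyParams()
    if gamma_dot > 300.0:
        return 1.0
    return 1.5 * (1.0 + (params.relaxation_time * gamma_dot) ** 2) ** 0.058697


def kelvin_force(sample: EMFieldSample) -> tuple[float, float]:
    """Kelvin electric body force density f = rho_e * E - 0.5 * grad_eps * |E|^2.

    With a spatially uniform permittivity (grad_eps = 0) this reduces to
    the Coulomb term rho_e * E.  Units N/m^3.
    """
    ex, ey = sample.E
    n2 = sample.normE_sq if sample.normE_sq is not None else ex**2 + ey**2
    gx, gy = sample.grad_eps
    return (sample.rho_e * ex - 0.5 * gx * n2, sample.rho_e * ey - 0.5 * gy * n2)


def phase_aggregated_force(params: EHDParams, E: tuple[float, float]) -> tuple[float, float]:
    """Phase-summed EHD force components applied on glycocalyx patches.

    F = (sum_k rho_e,k) * E + zeta * eps0 * eps_r * E, componentwise.
    """
    rho = params.rho_e_p + params.rho_e_r + params.rho_e_w
    scale = rho + params.zeta * params.eps0 * params.eps_r
    return (scale * E[0], scale * E[1])


def validate_phase_fractions(alpha_p: float, alpha_r: float, alpha_w: float) -> PhaseValidity:
    """Check the interpenetrating-phase constraints; never raises."""
    violations: list[str] = []
    for name, a in (("alpha_p", alpha_p), ("alpha_r", alpha_r), ("alpha_w", alpha_w)):
        if not 0.0 <= a <= 1.0:
            violations.append(f"{name}={a} outside [0, 1]")
    total = alpha_p + alpha_r + alpha_w
    if abs(total - 1.0) > 1e-12:
        violations.append(f"fractions sum to {total}, not 1")
    return PhaseValidity(valid=not violations, violations=tuple(violations), total=total)


def ensemble_inlet_average(
    members: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> InletSeries:
    """Pointwise arithmetic mean of per-model (times, pressure, velocity).

    All members must share one time grid; no implicit resampling.
    """
    if not members:
        raise ValueError("no member series supplied")
    t0 = np.asarray(members[0][0], dtype=float)
    ps, us = [], []
    for t, p, u in members:
        t = np.asarray(t, dtype=float)
        if t.shape != t0.shape or not np.allclose(t, t0):
            raise IncompatibleGridsError("member series do not share a time grid")
        ps.append(np.asarray(p, dtype=float))
        us.append(np.asarray(u, dtype=float))
    pressure = np.vstack(ps)
    velocity = np.vstack(us)
    return InletSeries(
        times=t0,
        pressure=pressure,
        velocity=velocity,
        p_mean=pressure.mean(axis=0),
        u_mean=velocity.mean(axis=0),
    )


def refinement_delta(level_a: int = -2, level_b: int = -1) -> tuple[float, float]:
    """Absolute change in domain-averaged pressure and velocity between two
    rows of the registry's mesh-refinement study (default: the two finest).
    """
    study = REGISTRY["mesh_refinement_study"]
    _, _, pa, va = study[level_a]
    _, _, pb, vb = study[level_b]
    return (abs(pb - pa), abs(vb - va))
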