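"""Fenestra layouts and random circular fiber fields.

The extracellular matrix (ECM) around a tumor microvessel is modelled as a
rectangular domain crowded with impermeable circular fiber bundles.  This
module generates the two geometric ingredients of that picture:

* evenly spaced fenestra (vessel-wall aperture) center positions along the
  vessel axis, one per ensemble member, and
* non-overlapping circular fiber packings realised by random sequential
  addition (RSA) at a prescribed packing fraction ``phi``.

Coordinates use micrometers with the origin at the lower-left corner of the
domain, x rightward and y upward.  Fibers are kept fully interior to the
domain so that the packing-fraction bookkeeping is exact and every fiber
contributes a closed boundary loop to downstream meshing.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RectDomain",
    "Circle",
    "FiberField",
    "FenestraLayout",
    "FenestraSpec",
    "GeometryError",
    "InvalidCountError",
    "InfeasibleLayoutError",
    "InvalidFractionError",
    "PackingInfeasibleError",
    "fenestra_centers",
    "fiber_radius_for_packing",
    "generate_fiber_field",
    "packing_fraction",
    "porosity",
    "write_fiber_field",
    "read_fiber_field",
]

#: Default clearance between fibers (and between a fiber and a wall), um.
#: Prevents mesh degeneracy between near-touching boundaries.
DEFAULT_MIN_GAP = 0.02

#: Realized packing fraction must land within this of the target.
PHI_TOLERANCE = 0.002


class GeometryError(ValueError):
    """Base class for geometry construction failures."""


class InvalidCountError(GeometryError):
    """A count argument (models, fibers) is out of range."""


class InfeasibleLayoutError(GeometryError):
    """Requested layout cannot fit in the stated vessel length."""


class InvalidFractionError(GeometryError):
    """Packing fraction outside [0, 1)."""


class PackingInfeasibleError(GeometryError):
    """RSA placement exhausted its attempt budget.

    Carries the fibers placed so far in :attr:`partial_field`.
    """

    def __init__(self, message: str, partial_field: "FiberField | None" = None):
        super().__init__(message)
        self.partial_field = partial_field


@dataclass(frozen=True)
class RectDomain:
    """Axis-aligned rectangular ECM domain, side lengths in micrometers."""

    length_x: float
    length_y: float

    def __post_init__(self) -> None:
        if self.length_x <= 0 or self.length_y <= 0:
            raise GeometryError("domain side lengths must be strictly positive")

    @property
    def area(self) -> float:
        return self.length_x * self.length_y


@dataclass(frozen=True)
class Circle:
    """Circular fiber cross-section (micrometers)."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("circle radius must be strictly positive")

    def inside(self, domain: RectDomain, margin: float = 0.0) -> bool:
        r = self.radius + margin
        return (
            r <= self.center_x <= domain.length_x - r
            and r <= self.center_y <= domain.length_y - r
        )


@dataclass
class FiberField:
    """A realised non-overlapping circle packing with its provenance."""

    domain: RectDomain
    fibers: list[Circle]
    min_gap: float
    seed: int
    target_phi: float | None = None

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (x, y, r) arrays; empty arrays for an empty field."""
        if not self.fibers:
            z = np.empty(0)
            return z, z.copy(), z.copy()
        x = np.array([c.center_x for c in self.fibers])
        y = np.array([c.center_y for c in self.fibers])
        r = np.array([c.radius for c in self.fibers])
        return x, y, r

    def validate(self) -> None:
        """Raise if any pairwise gap or interiority invariant is violated."""
        x, y, r = self.as_arrays()
        for c in self.fibers:
            if not c.inside(self.domain):
                raise GeometryError(f"fiber at ({c.center_x}, {c.center_y}) clips the domain wall")
        n = len(self.fibers)
        if n > 1:
            d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
            req = r[:, None] + r[None, :] + self.min_gap
            iu = np.triu_indices(n, k=1)
            if np.any(d[iu] < req[iu] - 1e-12):
                raise GeometryError("fiber pair violates the minimum-gap constraint")
        if self.target_phi is not None:
            if abs(packing_fraction(self) - self.target_phi) > PHI_TOLERANCE:
                raise GeometryError("realized packing fraction misses the target")


@dataclass(frozen=True)
class FenestraLayout:
    """Equally spaced fenestra centers along the vessel axis."""

    vessel_length: float
    clearance: float
    n_models: int
    centers: tuple[float, ...]
    delta_l: float
    l_eff: float


@dataclass(frozen=True)
class FenestraSpec:
    """A single aperture on one edge of the ECM rectangle.

    ``center_offset`` is measured along the named edge from its low end.
    """

    width: float
    edge: str = "bottom"
    center_offset: float = 0.0

    _EDGES = ("bottom", "top", "left", "right")

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise GeometryError("fenestra width must be positive")
        if self.edge not in self._EDGES:
            raise GeometryError(f"edge must be one of {self._EDGES}")

    def span(self, domain: RectDomain) -> tuple[float, float]:
        """Return (lo, hi) coordinates of the aperture along its edge."""
        edge_len = domain.length_x if self.edge in ("bottom", "top") else domain.length_y
        lo = self.center_offset - self.width / 2.0
        hi = self.center_offset + self.width / 2.0
        if lo < -1e-12 or hi > edge_len + 1e-12:
            raise GeometryError("fenestra aperture not contained in its edge")
        return max(lo, 0.0), min(hi, edge_len)


def fenestra_centers(n_models: int, vessel_length: float, clearance: float) -> FenestraLayout:
    """Place ``n_models`` fenestra centers evenly over the admissible span.

    The admissible span excludes a clearance zone at each end of the vessel,
    so centers run from ``clearance`` to ``vessel_length - clearance`` in
    steps of ``delta_l = l_eff / (n_models - 1)``.
    """
    if n_models < 2:
        raise InvalidCountError("need at least two models for a spacing")
    if 2 * clearance >= vessel_length:
        raise InfeasibleLayoutError("clearance zones exceed the vessel length")
    l_eff = vessel_length - 2.0 * clearance
    delta_l = l_eff / (n_models - 1)
    centers = tuple(clearance + i * delta_l for i in range(n_models))
    return FenestraLayout(
        vessel_length=vessel_length,
        clearance=clearance,
        n_models=n_models,
        centers=centers,
        delta_l=delta_l,
        l_eff=l_eff,
    )


def fiber_radius_for_packing(phi: float, domain: RectDomain, n_fibers: int) -> float:
    """Common radius giving ``n_fibers`` equal circles a packing fraction ``phi``.

    Solves n * pi * r^2 = phi * A_dom.
    """
    if not 0.0 <= phi < 1.0:
        raise InvalidFractionError("phi must lie in [0, 1)")
    if n_fibers < 1:
        raise InvalidCountError("need at least one fiber")
    return math.sqrt(phi * domain.area / (n_fibers * math.pi))


def packing_fraction(field: FiberField) -> float:
    """Area fraction of the domain occupied by fibers, sum(pi r^2) / A_dom."""
    _, _, r = field.as_arrays()
    return float(np.sum(np.pi * r**2) / field.domain.area)


def porosity(field: FiberField) -> float:
    """Pore (interstitial) fraction epsilon = 1 - phi."""
    return 1.0 - packing_fraction(field)


def generate_fiber_field(
    domain: RectDomain,
    n_fibers: int,
    radius: float | tuple[float, float],
    min_gap: float = DEFAULT_MIN_GAP,
    seed: int = 0,
    max_attempts: int = 100_000,
    target_phi: float | None = None,
) -> FiberField:
    """Random-sequential-addition placement of non-overlapping circles.

    ``radius`` is either a fixed value (all fibers equal, the small
    transport-domain convention) or a ``(lo, hi)`` range sampled uniformly
    (the large ECM-style field).  Candidate centers are drawn uniformly over
    the interior region admitting the candidate radius plus a wall gap;
    candidates overlapping an accepted fiber are rejected.  Deterministic
    for a fixed seed.
    """
    if n_fibers < 0:
        raise InvalidCountError("n_fibers must be non-negative")
    if n_fibers == 0:
        return FiberField(domain, [], min_gap, seed, target_phi)

    if isinstance(radius, tuple):
        r_lo, r_hi = radius
        if not 0 < r_lo <= r_hi:
            raise GeometryError("radius range must be positive and ordered")
        r_max = r_hi
    else:
        if radius <= 0:
            raise GeometryError("radius must be positive")
        r_lo = r_hi = r_max = float(radius)

    if n_fibers * math.pi * r_max**2 > domain.area:
        raise PackingInfeasibleError(
            f"required fiber area {n_fibers * math.pi * r_max**2:.1f} exceeds "
            f"domain area {domain.area:.1f}"
        )

    rng = np.random.default_rng(seed)
    xs: list[float] = []
    ys: list[float] = []
    rs: list[float] = []
    attempts = 0
    while len(xs) < n_fibers and attempts < max_attempts:
        attempts += 1
        r = r_lo if r_lo == r_hi else float(rng.uniform(r_lo, r_hi))
        margin = r + min_gap
        if domain.length_x <= 2 * margin or domain.length_y <= 2 * margin:
            continue
        cx = float(rng.uniform(margin, domain.length_x - margin))
        cy = float(rng.uniform(margin, domain.length_y - margin))
        if xs:
            d = np.hypot(np.asarray(xs) - cx, np.asarray(ys) - cy)
            if np.any(d < np.asarray(rs) + r + min_gap):
                continue
        xs.append(cx)
        ys.append(cy)
        rs.append(r)

    fibers = [Circle(x, y, r) for x, y, r in zip(xs, ys, rs)]
    out = FiberField(domain, fibers, min_gap, seed, target_phi)
    if len(fibers) < n_fibers:
        raise PackingInfeasibleError(
            f"placed {len(fibers)}/{n_fibers} fibers in {max_attempts} attempts",
            partial_field=out,
        )
    out.validate()
    return out


def write_fiber_field(field: FiberField, csv_path: str | Path) -> None:
    """Write a field as CSV (x, y, r in um) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "r"])
        for c in field.fibers:
            w.writerow([repr(c.center_x), repr(c.center_y), repr(c.radius)])
    sidecar = {
        "length_x": field.domain.length_x,
        "length_y": field.domain.length_y,
        "min_gap": field.min_gap,
        "seed": field.seed,
        "target_phi": field.target_phi,
        "phi": packing_fraction(field),
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_fiber_field(csv_path: str | Path) -> FiberField:
    """Round-trip counterpart of :func:`write_fiber_field`."""
    csv_path = Path(csv_path)
    with open(csv_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    fibers = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            fibers.append(Circle(float(row["x"]), float(row["y"]), float(row["r"])))
    return FiberField(
        domain=RectDomain(meta["length_x"], meta["length_y"]),
        fibers=fibers,
        min_gap=meta["min_gap"],
        seed=meta["seed"],
        target_phi=meta["target_phi"],
    )
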