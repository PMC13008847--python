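"""Reverse advection-diffusion (RAD) transport on fiber-obstructed domains.

The RAD surrogate replaces a full multiphase interstitial-flow computation
with a single linear scalar transport equation for the plasma-borne solute
concentration ``c(x, y, t)``::

    dc/dt + w . grad(c) - D * lap(c) = 0

on a rectangular ECM domain perforated by impermeable circular fibers.  A
constant concentration is held on a small fenestral aperture of the boundary
(Dirichlet inlet); all other boundaries, including every fiber surface, are
zero-flux.  "Reverse" refers to the transport regime the surrogate targets
(progression biased against the forward Darcy-perfusion expectation), not to
negative diffusivity: the advection velocity ``w`` is an imposed, spatially
uniform phenomenological drive normal to the fenestra.

Discretisation: piecewise-linear (P1) finite elements on an unstructured
Delaunay triangulation with the fiber interiors carved out, lumped mass,
and unconditionally stable backward-Euler time stepping.  Optional SUPG
(streamline-upwind Petrov-Galerkin) stabilisation engages automatically
when the cell Peclet number exceeds 2.  The equation is linear, so the
solver works on the normalised concentration ``c / c_in`` internally and
rescales on output.

The occupied interstitial area ``A(t)`` - the region where the normalised
concentration exceeds a threshold ``theta`` - is extracted exactly per
element from the linear interpolant, and is the quantity handed to the
kinetics module for two-regime power-law analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay

from .geometry import FenestraSpec, FiberField, RectDomain

__all__ = [
    "RADParams",
    "SpatialMesh",
    "ConcentrationField",
    "AreaSeries",
    "SolverError",
    "InvalidGeometryError",
    "MeshRefinementRequired",
    "SolverFailure",
    "StabilityWarning",
    "build_mesh",
    "solve_rad",
    "occupied_area_series",
    "boundary_loop_count",
    "render_concentration",
]

_TOL = 1e-9


class SolverError(RuntimeError):
    """Base class for transport-solver failures."""


class InvalidGeometryError(SolverError):
    """Fenestra/fiber configuration is not meshable."""


class MeshRefinementRequired(SolverError):
    """Requested resolution cannot resolve the fenestra or fiber gaps."""


class SolverFailure(SolverError):
    """Linear solve produced non-finite values."""


class StabilityWarning(UserWarning):
    """Discrete maximum principle violated beyond tolerance."""


@dataclass
class RADParams:
    """Physical and numerical parameters of a RAD run.

    diffusivity
        Effective diffusivity D, um^2/s.
    omega
        Imposed advection (w_x, w_y), um/s.  Spatially uniform; by default
        only the component normal to the fenestra is non-zero.
    inlet_concentration
        Dirichlet value c_in held on the fenestra, model units.  A pure
        scale for this linear problem.
    t_end, n_steps
        Simulated interval (s) and number of uniform implicit steps.
    output_times
        Times (s) at which snapshots are returned; snapped to the step grid.
    occupancy_threshold
        Fraction of c_in defining "occupied" for area extraction.
    supg
        True / False / "auto": SUPG stabilisation policy ("auto" engages it
        only where the cell Peclet number exceeds 2).
    """

    diffusivity: float
    omega: tuple[float, float] = (0.0, 0.0)
    inlet_concentration: float = 1.0
    t_end: float = 1.0
    n_steps: int = 2000
    output_times: Sequence[float] = dc_field(default_factory=list)
    occupancy_threshold: float = 0.05
    supg: bool | str = "auto"

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if not 0.0 < self.occupancy_threshold < 1.0:
            raise ValueError("occupancy_threshold must lie in (0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")


@dataclass
class SpatialMesh:
    """Conforming P1 triangulation of the pore space.

    ``node_circle`` maps each node to the fiber index whose boundary it
    samples (-1 for nodes not on a fiber).  ``boundary_edges`` lists the
    edges belonging to exactly one triangle together with a tag in
    {"inlet", "outer", "fiber"}.
    """

    nodes: np.ndarray  # (N, 2) um
    triangles: np.ndarray  # (M, 3) int, counter-clockwise
    boundary_edges: np.ndarray  # (K, 2) int
    boundary_tags: np.ndarray  # (K,) str
    node_circle: np.ndarray  # (N,) int
    inlet_nodes: np.ndarray  # int indices
    h: float
    domain: RectDomain
    fenestra: FenestraSpec
    n_fibers: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self) -> np.ndarray:
        x = self.nodes[self.triangles, 0]
        y = self.nodes[self.triangles, 1]
        return 0.5 * (
            (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
            - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
        )


@dataclass
class ConcentrationField:
    """Nodal concentration snapshot at one time."""

    mesh: SpatialMesh
    values: np.ndarray  # model units, len == n_nodes
    time: float
    c_in: float

    def normalized(self) -> np.ndarray:
        """C~ = c / c_in (dimensionless, in [0, 1] up to solver tolerance)."""
        return self.values / self.c_in if self.c_in != 0 else self.values


@dataclass
class AreaSeries:
    """Occupied/wetted area versus time.

    ``units`` is "um2" for solver output; imaging pipelines may flag "mm2".
    """

    times: np.ndarray
    area: np.ndarray
    threshold: float | None = None
    units: str = "um2"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.times.shape != self.area.shape:
            raise ValueError("times and area must have matching shapes")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, f"area_{self.units}": self.area}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AreaSeries":
        df = pd.read_csv(path)
        area_col = [c for c in df.columns if c.startswith("area")]
        if not area_col:
            raise ValueError("no area column found")
        units = area_col[0].split("_", 1)[1] if "_" in area_col[0] else "um2"
        return cls(df["time_s"].to_numpy(), df[area_col[0]].to_numpy(), units=units)


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------


def _edge_points_1d(length: float, h: float) -> np.ndarray:
    n = max(2, int(round(length / h)) + 1)
    return np.linspace(0.0, length, n)


def build_mesh(field: FiberField, fenestra: FenestraSpec, h: float) -> SpatialMesh:
    """Triangulate the pore space with a tagged fenestral inlet.

    Points are laid along the outer rectangle, along each fiber circle (plus
    an offset guard ring improving boundary element quality), and on an
    interior hexagonal lattice of pitch ``h``; a Delaunay triangulation of
    the union is pruned of triangles whose centroid falls inside a fiber.
    """
    domain = field.domain
    if h >= fenestra.width:
        raise MeshRefinementRequired(
            f"h={h} um cannot resolve the {fenestra.width} um fenestra"
        )
    lo, hi = fenestra.span(domain)
    cx_arr, cy_arr, r_arr = field.as_arrays()

    # Fenestra must sit on clear wall: no fiber may intersect the aperture.
    if len(r_arr):
        if fenestra.edge in ("bottom", "top"):
            ey = 0.0 if fenestra.edge == "bottom" else domain.length_y
            px = np.clip(cx_arr, lo, hi)
            dist = np.hypot(cx_arr - px, cy_arr - ey)
        else:
            ex = 0.0 if fenestra.edge == "left" else domain.length_x
            py = np.clip(cy_arr, lo, hi)
            dist = np.hypot(cx_arr - ex, cy_arr - py)
        if np.any(dist <= r_arr):
            raise InvalidGeometryError("a fiber overlaps the fenestra aperture")

    pts: list[np.ndarray] = []
    labels: list[np.ndarray] = []  # -2 interior/ring, -1 outer, -3 inlet, i>=0 circle i

    def _append(xy: np.ndarray, lab: int | np.ndarray) -> None:
        if len(xy) == 0:
            return
        pts.append(np.atleast_2d(xy))
        if np.isscalar(lab):
            labels.append(np.full(len(pts[-1]), lab, dtype=int))
        else:
            labels.append(np.asarray(lab, dtype=int))

    # --- outer boundary, edge by edge (corners emitted once) ---
    hf = min(h, fenestra.width / 4.0)

    def _edge_coords(length: float, is_fen_edge: bool) -> tuple[np.ndarray, np.ndarray]:
        base = _edge_points_1d(length, h)
        if not is_fen_edge:
            return base, np.full(len(base), -1, dtype=int)
        fen = np.linspace(lo, hi, max(5, int(math.ceil(fenestra.width / hf)) + 1))
        keep = (base < lo - 0.45 * hf) | (base > hi + 0.45 * hf)
        coords = np.concatenate([base[keep], fen])
        lab = np.concatenate(
            [np.full(keep.sum(), -1, dtype=int), np.full(len(fen), -3, dtype=int)]
        )
        order = np.argsort(coords)
        return coords[order], lab[order]

    Lx, Ly = domain.length_x, domain.length_y
    for edge in ("bottom", "right", "top", "left"):
        is_fen = edge == fenestra.edge
        if edge in ("bottom", "top"):
            s, lab = _edge_coords(Lx, is_fen)
            y = 0.0 if edge == "bottom" else Ly
            xy = np.column_stack([s, np.full(len(s), y)])
        else:
            s, lab = _edge_coords(Ly, is_fen)
            x = 0.0 if edge == "left" else Lx
            xy = np.column_stack([np.full(len(s), x), s])
        # drop the trailing corner so each corner appears exactly once
        if edge in ("right", "top", "left"):
            mask = ~((np.abs(xy[:, 0]) < _TOL) & (np.abs(xy[:, 1]) < _TOL))
            if edge == "right":
                mask &= ~((np.abs(xy[:, 0] - Lx) < _TOL) & (np.abs(xy[:, 1]) < _TOL))
            if edge == "top":
                mask &= ~((np.abs(xy[:, 0] - Lx) < _TOL) & (np.abs(xy[:, 1] - Ly) < _TOL))
            if edge == "left":
                mask &= ~((np.abs(xy[:, 1] - Ly) < _TOL) & (np.abs(xy[:, 0]) < _TOL))
            xy, lab = xy[mask], lab[mask]
        _append(xy, lab)

    # --- fiber circles and guard rings ---
    ring_pts: list[np.ndarray] = []
    for i, (cx, cy, r) in enumerate(zip(cx_arr, cy_arr, r_arr)):
        n_c = max(16, int(math.ceil(2 * math.pi * r / (0.8 * h))))
        th = np.linspace(0.0, 2 * math.pi, n_c, endpoint=False)
        circ = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        _append(circ, i)
        s_c = 2 * math.pi * r / n_c
        ring = np.column_stack(
            [
                cx + (r + 0.6 * s_c) * np.cos(th + math.pi / n_c),
                cy + (r + 0.6 * s_c) * np.sin(th + math.pi / n_c),
            ]
        )
        ring_pts.append(ring)

    margin = 0.35 * h
    for i, ring in enumerate(ring_pts):
        keep = (
            (ring[:, 0] > margin)
            & (ring[:, 0] < Lx - margin)
            & (ring[:, 1] > margin)
            & (ring[:, 1] < Ly - margin)
        )
        if len(r_arr) > 1:
            d = np.hypot(ring[:, 0, None] - cx_arr[None, :], ring[:, 1, None] - cy_arr[None, :])
            d[:, i] = np.inf
            keep &= np.min(d - r_arr[None, :], axis=1) > 0.25 * h
        _append(ring[keep], -2)

    # --- interior hexagonal lattice ---
    inset = 0.7 * h
    dy = h * math.sqrt(3) / 2.0
    rows = np.arange(inset, Ly - inset + _TOL, dy)
    lat: list[np.ndarray] = []
    for j, yv in enumerate(rows):
        xs = np.arange(inset + (0.5 * h if j % 2 else 0.0), Lx - inset + _TOL, h)
        lat.append(np.column_stack([xs, np.full(len(xs), yv)]))
    if lat:
        lat_xy = np.concatenate(lat)
        if len(r_arr):
            d = np.hypot(
                lat_xy[:, 0, None] - cx_arr[None, :], lat_xy[:, 1, None] - cy_arr[None, :]
            )
            keep = np.min(d - r_arr[None, :], axis=1) > 1.0 * h
            lat_xy = lat_xy[keep]
        _append(lat_xy, -2)

    points = np.concatenate(pts)
    labs = np.concatenate(labels)

    # dedupe coincident points (first occurrence keeps its label)
    _, idx = np.unique(np.round(points / (1e-7 * h)), axis=0, return_index=True)
    idx = np.sort(idx)
    points, labs = points[idx], labs[idx]

    tri = Delaunay(points)
    t = tri.simplices.copy()

    # orient counter-clockwise
    x, y = points[:, 0], points[:, 1]
    a2 = (x[t[:, 1]] - x[t[:, 0]]) * (y[t[:, 2]] - y[t[:, 0]]) - (
        x[t[:, 2]] - x[t[:, 0]]
    ) * (y[t[:, 1]] - y[t[:, 0]])
    flip = a2 < 0
    t[flip] = t[flip][:, [0, 2, 1]]
    a2 = np.abs(a2)

    keep = a2 > 1e-12 * h * h
    if len(r_arr):
        cxs = points[t].mean(axis=1)
        d = np.hypot(cxs[:, 0, None] - cx_arr[None, :], cxs[:, 1, None] - cy_arr[None, :])
        keep &= np.all(d >= r_arr[None, :] - _TOL, axis=1)
    t = t[keep]

    # drop nodes unused by any kept triangle
    used = np.unique(t)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    points, labs, t = points[used], labs[used], remap[t]

    # boundary edges = edges in exactly one triangle
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    se = np.sort(edges, axis=1)
    uniq, counts = np.unique(se, axis=0, return_counts=True)
    bedges = uniq[counts == 1]

    tags = np.empty(len(bedges), dtype=object)
    for k, (i, j) in enumerate(bedges):
        li, lj = labs[i], labs[j]
        if li >= 0 and li == lj:
            tags[k] = "fiber"
        elif li == -3 and lj == -3:
            tags[k] = "inlet"
        else:
            tags[k] = "outer"

    inlet_nodes = np.flatnonzero(labs == -3)
    if len(inlet_nodes) == 0:
        raise InvalidGeometryError("fenestra produced no inlet nodes")

    return SpatialMesh(
        nodes=points,
        triangles=t,
        boundary_edges=bedges,
        boundary_tags=tags.astype(str),
        node_circle=np.where(labs >= 0, labs, -1),
        inlet_nodes=inlet_nodes,
        h=h,
        domain=domain,
        fenestra=fenestra,
        n_fibers=len(r_arr),
    )


def boundary_loop_count(mesh: SpatialMesh) -> int:
    """Number of closed boundary loops (outer rectangle + one per fiber)."""
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent.setdefault(a, a) != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in mesh.boundary_edges:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    return len({find(int(i)) for i in np.unique(mesh.boundary_edges)})


# ---------------------------------------------------------------------------
# P1 finite-element transport solve
# ---------------------------------------------------------------------------


def _assemble(mesh: SpatialMesh, params: RADParams):
    p, t = mesh.nodes, mesh.triangles
    x, y = p[t, 0], p[t, 1]
    # shape-function gradient ingredients: grad_i = (b_i, c_i) / (2A)
    b = y[:, [1, 2, 0]] - y[:, [2, 0, 1]]
    c = x[:, [2, 0, 1]] - x[:, [1, 2, 0]]
    area = 0.5 * (x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2])
    if np.any(area <= 0):
        raise SolverFailure("degenerate or misoriented element encountered")

    D = params.diffusivity
    wx, wy = params.omega
    wnorm = math.hypot(wx, wy)

    # per-element SUPG parameter (0 where not engaged)
    tau = np.zeros(len(t))
    if params.supg is True or params.supg == "auto":
        if wnorm > 0:
            e01 = np.hypot(x[:, 1] - x[:, 0], y[:, 1] - y[:, 0])
            e12 = np.hypot(x[:, 2] - x[:, 1], y[:, 2] - y[:, 1])
            e20 = np.hypot(x[:, 0] - x[:, 2], y[:, 0] - y[:, 2])
            h_e = np.maximum(np.maximum(e01, e12), e20)
            pe = wnorm * h_e / (2.0 * D)
            engaged = pe > 2.0 if params.supg == "auto" else pe > 0
            with np.errstate(over="ignore"):
                coth = 1.0 / np.tanh(np.clip(pe, 1e-12, 700.0))
            tau = np.where(engaged, h_e / (2.0 * wnorm) * (coth - 1.0 / np.clip(pe, 1e-12, None)), 0.0)

    rows, cols, k_vals, c_vals, m_vals = [], [], [], [], []
    wg = wx * b + wy * c  # (M, 3): 2A * (w . grad_j)
    for i in range(3):
        for j in range(3):
            rows.append(t[:, i])
            cols.append(t[:, j])
            k_vals.append(D * (b[:, i] * b[:, j] + c[:, i] * c[:, j]) / (4.0 * area))
            # Galerkin advection + SUPG streamline terms
            adv = wg[:, j] / 6.0
            adv = adv + tau * wg[:, i] * wg[:, j] / (4.0 * area)
            c_vals.append(adv)
            # lumped Galerkin mass on the diagonal + SUPG transient term
            m = np.where(i == j, area / 3.0, 0.0)
            m = m + tau * wg[:, i] / 6.0
            m_vals.append(m)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = mesh.n_nodes
    K = sp.coo_matrix((np.concatenate(k_vals), (rows, cols)), shape=(n, n)).tocsr()
    C = sp.coo_matrix((np.concatenate(c_vals), (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((np.concatenate(m_vals), (rows, cols)), shape=(n, n)).tocsr()
    return K, C, M


def solve_rad(mesh: SpatialMesh, params: RADParams) -> list[ConcentrationField]:
    """Advance the RAD equation and return snapshots at the output times.

    Starts from ``c = 0`` everywhere, holds ``c = c_in`` on the fenestra
    for t > 0, and uses backward-Euler steps of ``t_end / n_steps``.  The
    returned fields carry physical units (``c_in`` times the internally
    normalised solution).
    """
    K, C, M = _assemble(mesh, params)
    dt = params.t_end / params.n_steps
    n = mesh.n_nodes

    A = (M / dt + K + C).tolil()
    dir_nodes = mesh.inlet_nodes
    free = np.ones(n, dtype=bool)
    free[dir_nodes] = False
    # Dirichlet rows -> identity
    mask = sp.diags(free.astype(float))
    A = (mask @ A.tocsr()) + sp.diags((~free).astype(float))
    lu = splu(A.tocsc())
    Mdt = M / dt

    out_times = list(params.output_times) if len(list(params.output_times)) else [params.t_end]
    steps = [min(params.n_steps, max(0, int(round(tt / dt)))) for tt in out_times]
    want: dict[int, list[int]] = {}
    for pos, s in enumerate(steps):
        want.setdefault(s, []).append(pos)

    c = np.zeros(n)
    snaps: list[ConcentrationField | None] = [None] * len(out_times)
    if 0 in want:
        for pos in want[0]:
            snaps[pos] = ConcentrationField(mesh, np.zeros(n), 0.0, params.inlet_concentration)

    max_step = max(steps)
    for k in range(1, max_step + 1):
        rhs = Mdt @ c
        rhs[dir_nodes] = 1.0
        c = lu.solve(rhs)
        if not np.all(np.isfinite(c)):
            raise SolverFailure(f"non-finite solution at step {k}")
        if k in want:
            for pos in want[k]:
                snaps[pos] = ConcentrationField(
                    mesh, c * params.inlet_concentration, k * dt, params.inlet_concentration
                )

    lover = max(0.0, float(-c.min()))
    rover = max(0.0, float(c.max() - 1.0))
    if max(lover, rover) > 1e-8:
        warnings.warn(
            f"discrete maximum principle violated by {max(lover, rover):.3e} "
            "(normalised units); consider SUPG stabilisation or refinement",
            StabilityWarning,
            stacklevel=2,
        )
    return [s for s in snaps if s is not None]


# ---------------------------------------------------------------------------
# Occupied-area extraction
# ---------------------------------------------------------------------------


def _fraction_above(vals: np.ndarray, theta: float) -> np.ndarray:
    """Exact area fraction of each triangle where the P1 interpolant > theta."""
    vs = np.sort(vals, axis=1)
    v1, v2, v3 = vs[:, 0], vs[:, 1], vs[:, 2]
    frac = np.zeros(len(vs))
    frac[theta <= v1] = 1.0
    hi = (theta >= v2) & (theta < v3)
    den_hi = (v3 - v1) * (v3 - v2)
    safe = hi & (den_hi > 0)
    frac[safe] = (v3[safe] - theta) ** 2 / den_hi[safe]
    lo = (theta > v1) & (theta < v2)
    den_lo = (v2 - v1) * (v3 - v1)
    safe = lo & (den_lo > 0)
    frac[safe] = 1.0 - (theta - v1[safe]) ** 2 / den_lo[safe]
    return frac


def occupied_area_series(
    fields: Sequence[ConcentrationField], theta: float | None = None
) -> AreaSeries:
    """Area of {c/c_in > theta} per snapshot via per-element linear coverage."""
    if not fields:
        raise ValueError("empty field sequence")
    mesh = fields[0].mesh
    for f in fields:
        if f.mesh is not mesh:
            raise ValueError("all fields must share one mesh")
    if theta is None:
        theta = 0.05
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    areas = mesh.element_areas()
    t_idx = mesh.triangles
    out_t, out_a = [], []
    for f in fields:
        v = f.normalized()[t_idx]
        out_t.append(f.time)
        out_a.append(float(np.sum(_fraction_above(v, theta) * areas)))
    meta = {
        "n_fibers": mesh.n_fibers,
        "pore_area_um2": float(areas.sum()),
    }
    return AreaSeries(np.array(out_t), np.array(out_a), threshold=theta, meta=meta)


def render_concentration(field: ConcentrationField, path: str | Path) -> None:
    """Write a filled-contour PNG of the normalised concentration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = field.mesh
    fig, ax = plt.subplots(figsize=(6, 3.2))
    tc = ax.tripcolor(
        m.nodes[:, 0], m.nodes[:, 1], m.triangles, field.normalized(), shading="gouraud",
        vmin=0.0, vmax=1.0, cmap="viridis",
    )
    fig.colorbar(tc, ax=ax, label=r"$\tilde{C} = c/c_{in}$")
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"t = {field.time:.4g} s")
    fig.savefig(path, dpi=130, bbox_inches="tight")
    plt.close(fig)
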