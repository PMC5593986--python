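"""2D Brownian dynamics of tracer lipids in a heterogeneous membrane patch.

The simulator produces seeded trajectories of point tracers diffusing in a
periodic square box whose diffusivity landscape can contain circular
nanodomains (slower interior and/or partitioning boundaries) and a square
meshwork of semi-permeable lines.  These are the minimal geometries behind
the three diffusion-law signatures the analysis modules classify: free
Brownian motion (t0 = 0), transient trapping in nanodomains (t0 > 0) and
meshwork/gel-hindered diffusion (t0 < 0).

Units: lengths in micrometres, times in seconds, diffusivities in um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "NanoDomain",
    "Meshwork",
    "MembraneModel",
    "SimConfig",
    "TrajectorySet",
    "build_membrane",
    "simulate",
    "msd",
    "PackingError",
    "TimestepError",
]


class PackingError(ValueError):
    """Requested nanodomain layout cannot be placed in the box."""


class TimestepError(ValueError):
    """Time step too coarse for the finest geometric scale."""


@dataclass(frozen=True)
class NanoDomain:
    """Circular region with its own diffusivity and partitioning boundary.

    Parameters
    ----------
    center : (2,) array-like, um
    radius : float, um
    D_in : float, um^2/s — diffusivity inside the domain.
    p_enter : float in [0, 1] — probability a step crossing the boundary
        from outside is accepted.
    p_exit : float in [0, 1] — probability a step crossing outward is
        accepted; ``p_exit < p_enter`` makes the domain trapping.
    """

    center: tuple[float, float]
    radius: float
    D_in: float
    p_enter: float = 1.0
    p_exit: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("domain radius must be positive")
        if self.D_in < 0:
            raise ValueError("D_in must be non-negative")
        for p, name in ((self.p_enter, "p_enter"), (self.p_exit, "p_exit")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class Meshwork:
    """Square lattice of semi-permeable lines (hop-diffusion compartments)."""

    mesh_size: float  # lattice period, um
    p_hop: float  # probability a step crossing a lattice line is accepted

    def __post_init__(self) -> None:
        if self.mesh_size <= 0:
            raise ValueError("mesh_size must be positive")
        if not 0.0 <= self.p_hop <= 1.0:
            raise ValueError("p_hop must lie in [0, 1]")


@dataclass(frozen=True)
class MembraneModel:
    """Geometry and diffusivity landscape of a periodic membrane patch."""

    box_edge: float  # um
    D_out: float  # um^2/s outside any domain
    domains: tuple[NanoDomain, ...] = ()
    mesh: Meshwork | None = None
    scenario_tag: str = "free"

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if self.D_out < 0:
            raise ValueError("D_out must be non-negative")
        object.__setattr__(self, "domains", tuple(self.domains))
        for d in self.domains:
            if d.radius >= self.box_edge / 4:
                raise ValueError("domain radii must be < box_edge/4")
        centers = np.array([d.center for d in self.domains], float)
        radii = np.array([d.radius for d in self.domains], float)
        for i in range(len(self.domains)):
            dx = centers[i + 1:] - centers[i]
            if np.any(np.hypot(dx[:, 0], dx[:, 1]) < radii[i + 1:] + radii[i]):
                raise ValueError("nanodomains must not overlap")

    @property
    def max_diffusivity(self) -> float:
        return max([self.D_out] + [d.D_in for d in self.domains])


@dataclass(frozen=True)
class SimConfig:
    """Run-length, time step and seed of one simulation."""

    n_particles: int = 100
    dt: float = 1e-5  # s
    n_steps: int = 2 ** 17
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.n_steps < 1:
            raise ValueError("need at least one step")


@dataclass
class TrajectorySet:
    """Time-ordered wrapped positions, shape (n_steps, n_particles, 2)."""

    positions: np.ndarray
    dt: float
    box_edge: float
    model_tag: str = "free"

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def unwrapped(self) -> np.ndarray:
        """Remove periodic wraps by minimum-image accumulation of steps."""
        steps = np.diff(self.positions, axis=0)
        steps -= self.box_edge * np.round(steps / self.box_edge)
        out = np.empty_like(self.positions)
        out[0] = self.positions[0]
        np.cumsum(steps, axis=0, out=out[1:])
        out[1:] += self.positions[0]
        return out


def build_membrane(
    box_edge: float = 2.0,
    D_out: float = 2.0,
    n_domains: int = 0,
    domain_radius: float = 0.05,
    D_in: float | None = None,
    p_enter: float = 1.0,
    p_exit: float = 1.0,
    mesh_size: float | None = None,
    p_hop: float = 1.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> MembraneModel:
    """Assemble a :class:`MembraneModel`, placing nanodomains by seeded
    rejection sampling.

    Domains are sampled uniformly with their full disc inside the box and
    rejected on overlap.  The requested area fraction must stay below 0.5;
    an infeasible packing raises :class:`PackingError` after ``max_tries``
    failed placements rather than silently truncating the layout.
    """
    if n_domains < 0:
        raise ValueError("n_domains must be non-negative")
    area_fraction = n_domains * np.pi * domain_radius ** 2 / box_edge ** 2
    if area_fraction >= 0.5:
        raise PackingError(
            f"requested domain area fraction {area_fraction:.2f} >= 0.5"
        )
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    lo, hi = domain_radius, box_edge - domain_radius
    if n_domains and hi <= lo:
        raise PackingError("domain radius does not fit in the box")
    tries = 0
    while len(centers) < n_domains:
        if tries >= max_tries:
            raise PackingError(
                f"placed only {len(centers)}/{n_domains} domains "
                f"after {max_tries} tries"
            )
        tries += 1
        c = rng.uniform(lo, hi, size=2)
        ok = all(
            np.hypot(c[0] - x, c[1] - y) >= 2 * domain_radius
            for x, y in centers
        )
        if ok:
            centers.append((float(c[0]), float(c[1])))
    domains = tuple(
        NanoDomain(
            center=c,
            radius=domain_radius,
            D_in=D_out if D_in is None else D_in,
            p_enter=p_enter,
            p_exit=p_exit,
        )
        for c in centers
    )
    mesh = Meshwork(mesh_size, p_hop) if mesh_size is not None else None
    if mesh is not None:
        tag = "meshwork"
    elif domains:
        tag = "trapped"
    else:
        tag = "free"
    return MembraneModel(
        box_edge=box_edge, D_out=D_out, domains=domains, mesh=mesh,
        scenario_tag=tag,
    )


@njit(cache=True)
def _step_kernel(pos, out, normals, uniforms, box, D_out, dt,
                 dom_x, dom_y, dom_r2, dom_D, dom_pin, dom_pout,
                 n_cells, cell_start, cell_items,
                 mesh_size, p_hop):
    n_chunk = normals.shape[0]
    n_part = pos.shape[0]
    has_mesh = mesh_size > 0.0
    cell_w = box / n_cells if n_cells > 0 else box
    for s in range(n_chunk):
        for i in range(n_part):
            x = pos[i, 0]
            y = pos[i, 1]
            # domain membership at the current position via the cell list
            d0 = -1
            if n_cells > 0:
                cx = int(x / cell_w) % n_cells
                cy = int(y / cell_w) % n_cells
                c = cx * n_cells + cy
                for k in range(cell_start[c], cell_start[c + 1]):
                    j = cell_items[k]
                    ddx = x - dom_x[j]
                    ddy = y - dom_y[j]
                    if ddx * ddx + ddy * ddy <= dom_r2[j]:
                        d0 = j
                        break
            D = dom_D[d0] if d0 >= 0 else D_out
            sig = np.sqrt(2.0 * D * dt)
            nx = x + sig * normals[s, i, 0]
            ny = y + sig * normals[s, i, 1]
            wx = nx % box
            wy = ny % box
            d1 = -1
            if n_cells > 0:
                cx = int(wx / cell_w) % n_cells
                cy = int(wy / cell_w) % n_cells
                c = cx * n_cells + cy
                for k in range(cell_start[c], cell_start[c + 1]):
                    j = cell_items[k]
                    ddx = wx - dom_x[j]
                    ddy = wy - dom_y[j]
                    if ddx * ddx + ddy * ddy <= dom_r2[j]:
                        d1 = j
                        break
            p_acc = 1.0
            if d1 != d0:
                if d0 >= 0:
                    p_acc *= dom_pout[d0]
                if d1 >= 0:
                    p_acc *= dom_pin[d1]
            if has_mesh:
                crossed = (
                    int(np.floor(nx / mesh_size)) != int(np.floor(x / mesh_size))
                    or int(np.floor(ny / mesh_size)) != int(np.floor(y / mesh_size))
                )
                if crossed:
                    p_acc *= p_hop
            if p_acc >= 1.0 or uniforms[s, i] < p_acc:
                pos[i, 0] = wx
                pos[i, 1] = wy
            out[s, i, 0] = pos[i, 0]
            out[s, i, 1] = pos[i, 1]


def _build_cell_list(model: MembraneModel, n_cells: int):
    """CSR cell list: for each grid cell, the domains whose disc may
    intersect it (conservative bounding-box test)."""
    cell_w = model.box_edge / n_cells
    lists: list[list[int]] = [[] for _ in range(n_cells * n_cells)]
    for j, d in enumerate(model.domains):
        x0 = int(np.floor((d.center[0] - d.radius) / cell_w))
        x1 = int(np.floor((d.center[0] + d.radius) / cell_w))
        y0 = int(np.floor((d.center[1] - d.radius) / cell_w))
        y1 = int(np.floor((d.center[1] + d.radius) / cell_w))
        for cx in range(x0, x1 + 1):
            for cy in range(y0, y1 + 1):
                lists[(cx % n_cells) * n_cells + (cy % n_cells)].append(j)
    start = np.zeros(n_cells * n_cells + 1, dtype=np.int64)
    items: list[int] = []
    for c, lst in enumerate(lists):
        items.extend(lst)
        start[c + 1] = len(items)
    return start, np.asarray(items, dtype=np.int64)


def _check_timestep(model: MembraneModel, cfg: SimConfig) -> None:
    rms = np.sqrt(4.0 * model.max_diffusivity * cfg.dt)
    scales = []
    if model.domains:
        scales.append(("domain radius", min(d.radius for d in model.domains)))
    if model.mesh is not None:
        scales.append(("mesh size", model.mesh.mesh_size))
    for name, scale in scales:
        if rms >= scale / 4.0:
            raise TimestepError(
                f"RMS step {rms:.3g} um >= {name} {scale:.3g}/4 um; "
                "reduce dt"
            )


def simulate(
    model: MembraneModel,
    cfg: SimConfig,
    init_positions: np.ndarray | None = None,
) -> TrajectorySet:
    """Run seeded overdamped Brownian dynamics and return the trajectory.

    Per-axis displacements are zero-mean Gaussians with variance
    ``2 * D_local * dt`` where ``D_local`` is the diffusivity at the
    particle's current position.  Steps crossing a nanodomain boundary are
    accepted with ``p_enter`` (outward->in) or ``p_exit`` (in->out); steps
    crossing a meshwork line are accepted with ``p_hop``; rejected steps
    leave the particle in place.  Positions are wrapped into
    ``[0, box_edge)``.

    ``init_positions`` overrides the default seeded uniform initial layout
    (shape ``(n_particles, 2)``, in um).
    """
    _check_timestep(model, cfg)
    rng = np.random.default_rng(cfg.seed)
    if init_positions is None:
        pos = rng.uniform(0.0, model.box_edge, size=(cfg.n_particles, 2))
    else:
        pos = np.array(init_positions, dtype=float)
        if pos.shape != (cfg.n_particles, 2):
            raise ValueError("init_positions must have shape (n_particles, 2)")
        if np.any(pos < 0) or np.any(pos >= model.box_edge):
            raise ValueError("init_positions must lie inside the box")

    homogeneous = not model.domains and model.mesh is None
    if homogeneous:
        sig = np.sqrt(2.0 * model.D_out * cfg.dt)
        steps = rng.normal(0.0, 1.0, size=(cfg.n_steps, cfg.n_particles, 2))
        steps *= sig
        out = np.cumsum(steps, axis=0)
        out += pos[None, :, :]
        out %= model.box_edge
        return TrajectorySet(out, cfg.dt, model.box_edge, model.scenario_tag)

    n_dom = len(model.domains)
    dom_x = np.array([d.center[0] for d in model.domains])
    dom_y = np.array([d.center[1] for d in model.domains])
    dom_r2 = np.array([d.radius ** 2 for d in model.domains])
    dom_D = np.array([d.D_in for d in model.domains])
    dom_pin = np.array([d.p_enter for d in model.domains])
    dom_pout = np.array([d.p_exit for d in model.domains])
    if n_dom:
        r_max = max(d.radius for d in model.domains)
        n_cells = max(1, int(model.box_edge / (4.0 * r_max)))
        cell_start, cell_items = _build_cell_list(model, n_cells)
    else:
        n_cells = 0
        cell_start = np.zeros(1, dtype=np.int64)
        cell_items = np.zeros(0, dtype=np.int64)
    mesh_size = model.mesh.mesh_size if model.mesh is not None else 0.0
    p_hop = model.mesh.p_hop if model.mesh is not None else 1.0

    out = np.empty((cfg.n_steps, cfg.n_particles, 2))
    chunk = 8192
    pos = np.ascontiguousarray(pos)
    for s0 in range(0, cfg.n_steps, chunk):
        s1 = min(s0 + chunk, cfg.n_steps)
        normals = rng.normal(0.0, 1.0, size=(s1 - s0, cfg.n_particles, 2))
        uniforms = rng.uniform(0.0, 1.0, size=(s1 - s0, cfg.n_particles))
        _step_kernel(
            pos, out[s0:s1], normals, uniforms,
            model.box_edge, model.D_out, cfg.dt,
            dom_x, dom_y, dom_r2, dom_D, dom_pin, dom_pout,
            n_cells, cell_start, cell_items,
            mesh_size, p_hop,
        )
    return TrajectorySet(out, cfg.dt, model.box_edge, model.scenario_tag)


def msd(traj: TrajectorySet, lags: "list[int] | np.ndarray") -> "pd.DataFrame":
    """Time- and ensemble-averaged mean squared displacement.

    Periodic wraps are removed by minimum-image unwrapping before squaring,
    so displacements larger than the box are handled correctly.  Returns a
    DataFrame with columns ``lag_time`` (s) and ``msd`` (um^2).
    """
    import pandas as pd

    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 1):
        raise ValueError("lags must be >= 1")
    if np.any(lags >= traj.n_steps):
        raise ValueError("lags must be < n_steps")
    un = traj.unwrapped()
    vals = np.empty(len(lags))
    for i, k in enumerate(lags):
        d = un[k:] - un[:-k]
        vals[i] = np.mean(np.sum(d * d, axis=-1))
    return pd.DataFrame({"lag_time": lags * traj.dt, "msd": vals})
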