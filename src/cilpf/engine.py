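"""Couples mechanics and biochemistry into full simulations.

The update per time step is operator-split:

1. evaluate dH/dphi for every cell, including pairwise exclusion/adhesion;
2. advance every phase field (interface law);
3. recompute each cell's cytosolic pool, CIL production and noise;
4. advance every rho and I with the conservative phi-weighted stencil.

Cells are kept in a stable index order; with the noise amplitude eta = 0
every run is fully deterministic, and with eta > 0 it is reproducible
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import biochemistry as bio
from . import mechanics as mech
from .domain import (Micropattern, ScalarField, center_of_mass, grad_mag,
                     init_phase_field, make_stripe)
from .params import GridSpec, ModelParams, validate_params

__all__ = [
    "CellState", "SimulationState", "Trajectory",
    "relax_single_cell", "setup_collision", "setup_train",
    "step_system", "run_simulation",
]


@dataclass
class CellState:
    """Per-cell fields: phase field phi, active Rac rho, inhibitor I."""

    phi: np.ndarray
    rho: np.ndarray
    I: np.ndarray

    def copy(self) -> "CellState":
        return CellState(self.phi.copy(), self.rho.copy(), self.I.copy())


@dataclass
class SimulationState:
    cells: list[CellState]
    pattern: Micropattern
    grid: GridSpec
    params: ModelParams
    t: float = 0.0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))
    # set when the inhibitor drives the effective Rac detachment negative
    invalid: bool = False


@dataclass
class Trajectory:
    """Sampled observables of a run.

    ``com`` holds raw (x, y) centres of mass; ``x_unwrapped`` removes
    periodic jumps along the stripe so velocities are meaningful.
    Shapes: t (n,), per-cell arrays (n_cells, n, ...), overlaps
    (n_pairs, n) with ``pairs`` listing the (i, j) index tuples.
    """

    t: np.ndarray
    com: np.ndarray
    x_unwrapped: np.ndarray
    vel: np.ndarray
    polarity: np.ndarray
    perimeter: np.ndarray
    rho_front: np.ndarray
    rho_back: np.ndarray
    overlaps: np.ndarray
    pairs: list[tuple[int, int]]
    Lx: float
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.com.shape[0]

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for i in range(self.n_cells):
            for k in range(len(self.t)):
                rows.append({
                    "t": self.t[k], "cell": i,
                    "x": self.com[i, k, 0], "y": self.com[i, k, 1],
                    "x_unwrapped": self.x_unwrapped[i, k],
                    "vx": self.vel[i, k, 0], "vy": self.vel[i, k, 1],
                    "pol_x": self.polarity[i, k, 0],
                    "pol_y": self.polarity[i, k, 1],
                    "perimeter": self.perimeter[i, k],
                    "rho_front": self.rho_front[i, k],
                    "rho_back": self.rho_back[i, k],
                    "overlap_01": (self.overlaps[0, k]
                                   if len(self.pairs) else 0.0),
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df, Lx: float) -> "Trajectory":
        cells = sorted(df["cell"].unique())
        t = np.asarray(sorted(df["t"].unique()), dtype=float)
        n, nc = len(t), len(cells)
        com = np.zeros((nc, n, 2))
        xu = np.zeros((nc, n))
        vel = np.zeros((nc, n, 2))
        pol = np.zeros((nc, n, 2))
        per = np.zeros((nc, n))
        rf = np.zeros((nc, n))
        rb = np.zeros((nc, n))
        ov = np.zeros((1, n))
        for i, c in enumerate(cells):
            sub = df[df["cell"] == c].sort_values("t")
            com[i, :, 0] = sub["x"].to_numpy()
            com[i, :, 1] = sub["y"].to_numpy()
            xu[i] = sub["x_unwrapped"].to_numpy()
            vel[i, :, 0] = sub["vx"].to_numpy()
            vel[i, :, 1] = sub["vy"].to_numpy()
            pol[i, :, 0] = sub["pol_x"].to_numpy()
            pol[i, :, 1] = sub["pol_y"].to_numpy()
            per[i] = sub["perimeter"].to_numpy()
            rf[i] = sub["rho_front"].to_numpy()
            rb[i] = sub["rho_back"].to_numpy()
            if i == 0:
                ov[0] = sub["overlap_01"].to_numpy()
        pairs = [(0, 1)] if nc > 1 else []
        return cls(t, com, xu, vel, pol, per, rf, rb,
                   ov if pairs else np.zeros((0, n)), pairs, Lx)

    @classmethod
    def from_csv(cls, path, Lx: float) -> "Trajectory":
        import pandas as pd
        return cls.from_dataframe(pd.read_csv(path), Lx)


# ---------------------------------------------------------------------------
# observables on fields

def _interface_band(phi: np.ndarray) -> np.ndarray:
    return (phi > 0.25) & (phi < 0.75)


def front_back_rho(phi: np.ndarray, rho: np.ndarray,
                   dx: float) -> tuple[float, float]:
    """(peak, minimum) of rho over the interface band phi in (0.25, 0.75).

    In a polarized cell the band maximum sits at the leading edge (the
    high-Rac plateau reaches the front membrane) and the band minimum at
    the rear pole, so these are the front/back membrane Rac densities.
    For a depolarized cell the two values coincide, which is what makes
    loss of polarity easy to detect.
    """
    band = _interface_band(phi)
    if not band.any():
        return (0.0, 0.0)
    vals = rho[band]
    return (float(vals.max()), float(vals.min()))


def polarity_of_fields(phi: np.ndarray, rho: np.ndarray,
                       dx: float) -> np.ndarray:
    """Unit vector from the phi centroid toward the phi*rho centroid.

    Returns the zero vector for an unpolarized cell (degenerate weight or
    vanishing separation of the two centroids).
    """
    w = phi * rho
    tot = w.sum()
    if tot * dx**2 < 1e-9:
        return np.zeros(2)
    cx, cy = center_of_mass(ScalarField(phi, dx))
    ny, nx = phi.shape
    Lx = nx * dx
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    dxr = (x[None, :] - cx + Lx / 2.0) % Lx - Lx / 2.0
    dyr = y[:, None] - cy
    vx = float((w * dxr).sum() / tot)
    vy = float((w * dyr).sum() / tot)
    norm = np.hypot(vx, vy)
    if norm < 1e-6:
        return np.zeros(2)
    return np.array([vx, vy]) / norm


# ---------------------------------------------------------------------------
# stepping

def step_system(state: SimulationState, dt: float | None = None) -> None:
    """Advance the coupled system by one time step (in place)."""
    g = state.grid
    p = state.params
    if dt is None:
        dt = g.dt
    dx = g.dx
    chi = state.pattern.chi.values
    cells = state.cells
    n = len(cells)

    # (1) forces at the current state
    forces = []
    for i, c in enumerate(cells):
        f = mech.single_cell_force(c.phi, dx, p)
        for j in range(n):
            if j != i:
                f = f + mech.interaction_force(
                    c.phi, cells[j].phi, dx, p.g, p.sigma, p.epsilon)
        forces.append(f)

    # (2) interface update
    old_phis = [c.phi for c in cells]
    for c, f in zip(cells, forces):
        c.phi = mech.phase_field_step(c.phi, c.rho, chi, f, p, dx, dt)

    # (3) chemistry sources at the new interface position
    phis = [c.phi for c in cells]
    rhos = [c.rho for c in cells]
    for i, c in enumerate(cells):
        rho_cyt = bio.cytosolic_density(p.N_tot, c.phi, c.rho, dx)
        f_rho = bio.rho_reaction(c.rho, rho_cyt, c.I, p)
        cil = bio.cil_production(phis, rhos, i, p) if n > 1 \
            else np.zeros_like(c.I)
        noise = bio.noise_increment(c.I.shape, dx, dt, p.eta, state.rng)
        f_I = bio.inhibitor_reaction(c.I, cil, noise, p.k_mI)
        # (4) conservative reaction-diffusion updates
        new_rho = bio.rd_step(c.phi, c.rho, p.D_rho, f_rho, dx, dt,
                              phi_old=old_phis[i])
        new_I = bio.rd_step(c.phi, c.I, p.D_I, f_I, dx, dt,
                            phi_old=old_phis[i])
        c.rho = np.maximum(new_rho, 0.0)
        c.I = new_I
        if float(new_I.min()) < -p.I0:
            state.invalid = True
    state.t += dt


def _sample(state: SimulationState):
    dx = state.grid.dx
    out = []
    for c in state.cells:
        com = center_of_mass(ScalarField(c.phi, dx))
        per = float(grad_mag(c.phi, dx).sum()) * dx**2
        pol = polarity_of_fields(c.phi, c.rho, dx)
        rf, rb = front_back_rho(c.phi, c.rho, dx)
        out.append((com, per, pol, rf, rb))
    n = len(state.cells)
    ovs = []
    for i in range(n):
        for j in range(i + 1, n):
            ovs.append(float((np.clip(state.cells[i].phi, 0.0, None)
                              * np.clip(state.cells[j].phi, 0.0, None)).sum())
                       * dx**2)
    return out, ovs


def _unwrap(x: np.ndarray, Lx: float) -> np.ndarray:
    out = np.asarray(x, dtype=float).copy()
    jumps = np.diff(out)
    shift = np.cumsum(np.where(jumps > Lx / 2, -Lx,
                               np.where(jumps < -Lx / 2, Lx, 0.0)))
    out[1:] += shift
    return out


def run_simulation(state: SimulationState, T_sim: float,
                   sample_every: float = 10.0) -> Trajectory:
    """Advance to ``T_sim``, sampling observables every ``sample_every`` s."""
    g = state.grid
    dt = g.dt
    n_steps = int(round(T_sim / dt))
    stride = max(1, int(round(sample_every / dt)))
    times = [state.t]
    samples, overlaps = [], []
    s0, o0 = _sample(state)
    samples.append(s0)
    overlaps.append(o0)
    for k in range(n_steps):
        step_system(state, dt)
        if (k + 1) % stride == 0 or k == n_steps - 1:
            s, o = _sample(state)
            samples.append(s)
            overlaps.append(o)
            times.append(state.t)
    n_cells = len(state.cells)
    nsamp = len(times)
    t = np.asarray(times)
    com = np.zeros((n_cells, nsamp, 2))
    per = np.zeros((n_cells, nsamp))
    pol = np.zeros((n_cells, nsamp, 2))
    rf = np.zeros((n_cells, nsamp))
    rb = np.zeros((n_cells, nsamp))
    for k, s in enumerate(samples):
        for i, (c, pval, pv, rfi, rbi) in enumerate(s):
            com[i, k] = c
            per[i, k] = pval
            pol[i, k] = pv
            rf[i, k] = rfi
            rb[i, k] = rbi
    xu = np.stack([_unwrap(com[i, :, 0], g.Lx) for i in range(n_cells)])
    vel = np.zeros((n_cells, nsamp, 2))
    if nsamp > 1:
        for i in range(n_cells):
            vel[i, :, 0] = np.gradient(xu[i], t)
            vel[i, :, 1] = np.gradient(com[i, :, 1], t)
    pairs = [(i, j) for i in range(n_cells) for j in range(i + 1, n_cells)]
    ov = (np.asarray(overlaps).T if pairs
          else np.zeros((0, nsamp)))
    return Trajectory(t, com, xu, vel, pol, per, rf, rb, ov, pairs, g.Lx,
                      meta={"params": state.params.to_dict(),
                            "invalid": state.invalid})


# ---------------------------------------------------------------------------
# protocols

def default_single_grid(p: ModelParams) -> GridSpec:
    return GridSpec(nx=96, ny=40, dx=1.0, dt=0.04)


def default_collision_grid(p: ModelParams) -> GridSpec:
    return GridSpec(nx=160, ny=40, dx=1.0, dt=0.04)


def _init_cell(p: ModelParams, grid: GridSpec, center, direction=+1,
               membrane_fraction: float = 0.47,
               wall_width: float = 2.0) -> CellState:
    """Tanh disk with a polarized two-plateau rho profile.

    rho is seeded directly in the wave-pinned configuration: a low rear
    plateau, a high front plateau (scaled with the Hill saturation K_a)
    and a smooth wall through the cell centre, then rescaled so that
    ``membrane_fraction`` of N_tot starts membrane-bound and the rest
    cytosolic. Starting on the pinned branch avoids the long unpolarized
    transient in which the mechanics would shrink the cell.
    """
    phi = init_phase_field(grid, center, p.R_cell, p.epsilon).values
    lo, hi = 0.011, 1.49 * p.K_a
    x = (np.arange(grid.nx) + 0.5) * grid.dx
    dxr = (x - center[0] + grid.Lx / 2.0) % grid.Lx - grid.Lx / 2.0
    prof = lo + (hi - lo) * 0.5 * (1.0 + np.tanh(
        direction * dxr / wall_width))
    rho = phi * prof[None, :]
    bound = float((phi * rho).sum()) * grid.dx**2
    if bound > 0:
        rho *= membrane_fraction * p.N_tot / bound
    return CellState(phi=phi, rho=rho, I=np.zeros_like(phi))


def relax_single_cell(p: ModelParams, grid: GridSpec | None = None,
                      pattern: Micropattern | None = None, seed: int = 0,
                      T_max: float = 1200.0, direction: int = +1,
                      eta: float | None = None):
    """Relax one cell on the stripe until speed and perimeter are stationary.

    Returns ``(CellState, summary)`` where summary reports the steady
    perimeter, front/back rho and speed. Stationarity: relative change of
    perimeter and speed below 1% across a trailing 100 s window. A cell
    that fails to polarize (speed ~ 0) is reported via
    ``summary['polarized'] = False``, not raised.
    """
    bad = validate_params(p, grid)
    if bad:
        raise ValueError("invalid parameters: " + "; ".join(bad))
    if grid is None:
        grid = default_single_grid(p)
    if pattern is None:
        pattern = make_stripe(grid, p.d, p.edge_w)
    if eta is not None:
        p = p.replace(eta=eta)
    cell = _init_cell(p, grid, (grid.Lx / 2.0, grid.Ly / 2.0), direction)
    state = SimulationState([cell], pattern, grid, p,
                            rng=np.random.default_rng(seed))
    dx = grid.dx
    window = 100.0
    check_every = 20.0
    stride = int(round(check_every / grid.dt))
    history: list[tuple[float, float, float]] = []   # (t, P, x_unwrapped)
    com = center_of_mass(ScalarField(cell.phi, dx))
    xu = com[0]
    history.append((0.0, float(grad_mag(cell.phi, dx).sum()) * dx**2, xu))
    t_relaxed = None
    n_steps = int(round(T_max / grid.dt))
    for k in range(n_steps):
        step_system(state)
        if (k + 1) % stride == 0:
            com_new = center_of_mass(ScalarField(cell.phi, dx))
            jump = (com_new[0] - com[0] + grid.Lx / 2.0) % grid.Lx \
                - grid.Lx / 2.0
            xu += jump
            com = com_new
            P = float(grad_mag(cell.phi, dx).sum()) * dx**2
            history.append((state.t, P, xu))
            # stationarity over the trailing window
            t_now = state.t
            past = [h for h in history if h[0] <= t_now - window]
            if past and t_now >= 2 * window:
                t0, P0, x0 = past[-1]
                speed_now = (xu - x0) / (t_now - t0)
                prev = [h for h in history if h[0] <= t_now - 2 * window]
                if prev:
                    t1, P1, x1 = prev[-1]
                    speed_prev = (x0 - x1) / (t0 - t1)
                    dP = abs(P - P0) / max(P, 1e-9)
                    dv = abs(speed_now - speed_prev) / max(
                        abs(speed_now), 1e-9)
                    if dP < 0.01 and dv < 0.01 and abs(speed_now) > 1e-4:
                        t_relaxed = t_now
                        break
    P = float(grad_mag(cell.phi, dx).sum()) * dx**2
    t0, P0, x0 = history[-2] if len(history) > 1 else history[0]
    speed = abs(xu - x0) / max(state.t - t0, 1e-9)
    rfront, rback = front_back_rho(cell.phi, cell.rho, dx)
    summary = {
        "P": P,
        "rho_front": rfront,
        "rho_back": rback,
        "speed": speed,
        "polarized": bool(speed > 1e-3),
        "t_relaxed": t_relaxed if t_relaxed is not None else state.t,
        "stationary": t_relaxed is not None,
    }
    return cell, summary


def _place(cellfields: np.ndarray, shift_cells: int) -> np.ndarray:
    return np.roll(cellfields, shift_cells, axis=1)


def setup_collision(p: ModelParams, grid: GridSpec | None = None,
                    d: float | None = None, gap: float | None = None,
                    seed: int = 0,
                    relaxed: CellState | None = None) -> SimulationState:
    """Head-on assay: two relaxed, mirrored cells approaching on the stripe.

    The left cell polarizes +x, the right cell is its mirror image; their
    centres of mass start ``gap`` apart (default 1.5 cell diameters).
    The relaxation itself is run noise-free so the initial condition is
    mirror-symmetric; replicate-to-replicate variability enters through
    the seeded inhibitor noise during the collision run.
    """
    if d is not None:
        p = p.replace(d=d)
    if grid is None:
        grid = default_collision_grid(p)
    if gap is None:
        gap = 3.0 * p.R_cell
    pattern = make_stripe(grid, p.d, p.edge_w)
    if relaxed is None:
        relaxed, info = relax_single_cell(p, GridSpec(
            nx=grid.nx, ny=grid.ny, dx=grid.dx, dt=grid.dt),
            pattern=pattern, eta=0.0)
    dx = grid.dx
    com = center_of_mass(ScalarField(relaxed.phi, dx))
    x_left = grid.Lx / 2.0 - gap / 2.0
    x_right = grid.Lx / 2.0 + gap / 2.0
    if gap < 2.0 * p.R_cell:
        raise ValueError("cells would overlap at t = 0")
    shift_l = int(round((x_left - com[0]) / dx))
    cell_l = CellState(_place(relaxed.phi, shift_l),
                       _place(relaxed.rho, shift_l),
                       _place(relaxed.I, shift_l))
    # mirror image: flip x, then position
    phi_m = relaxed.phi[:, ::-1].copy()
    rho_m = relaxed.rho[:, ::-1].copy()
    I_m = relaxed.I[:, ::-1].copy()
    com_m = center_of_mass(ScalarField(phi_m, dx))
    shift_r = int(round((x_right - com_m[0]) / dx))
    cell_r = CellState(_place(phi_m, shift_r), _place(rho_m, shift_r),
                       _place(I_m, shift_r))
    return SimulationState([cell_l, cell_r], pattern, grid, p,
                           rng=np.random.default_rng(seed))


def setup_train(p: ModelParams, grid: GridSpec, positions: list[float],
                directions: list[int], seed: int = 0) -> SimulationState:
    """N cells on one long stripe at given x positions and polarities."""
    pattern = make_stripe(grid, p.d, p.edge_w)
    relaxed, _ = relax_single_cell(
        p, GridSpec(nx=grid.nx, ny=grid.ny, dx=grid.dx, dt=grid.dt),
        pattern=pattern, eta=0.0)
    dx = grid.dx
    com = center_of_mass(ScalarField(relaxed.phi, dx))
    phi_m = relaxed.phi[:, ::-1].copy()
    rho_m = relaxed.rho[:, ::-1].copy()
    I_m = relaxed.I[:, ::-1].copy()
    com_m = center_of_mass(ScalarField(phi_m, dx))
    cells = []
    for x0, sgn in zip(positions, directions):
        if sgn >= 0:
            shift = int(round((x0 - com[0]) / dx))
            cells.append(CellState(_place(relaxed.phi, shift),
                                   _place(relaxed.rho, shift),
                                   _place(relaxed.I, shift)))
        else:
            shift = int(round((x0 - com_m[0]) / dx))
            cells.append(CellState(_place(phi_m, shift),
                                   _place(rho_m, shift),
                                   _place(I_m, shift)))
    return SimulationState(cells, pattern, grid, p,
                           rng=np.random.default_rng(seed))
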