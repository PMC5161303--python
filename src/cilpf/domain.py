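"""Grid-resident scalar fields, the micropattern, and geometric observables.

Arrays use the layout ``(ny, nx)``: axis 0 is y (no-flux boundaries),
axis 1 is x (periodic, the stripe axis). The numerical helpers here
(`grad_x`, `grad_y`, `laplacian`, ...) encode those boundary conditions
once so that the mechanics and biochemistry modules share a single
discretisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GridSpec

__all__ = [
    "ScalarField", "Micropattern", "make_stripe", "init_phase_field",
    "perimeter", "area", "center_of_mass", "overlap",
    "grad_x", "grad_y", "laplacian", "grad_mag",
]

# floor used when normalising by |grad phi| or dividing by phi
EPS_MACH = 1e-12


@dataclass
class ScalarField:
    """Values on the lattice plus the spacing needed for quadrature."""

    values: np.ndarray
    dx: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ScalarField expects a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def integrate(self) -> float:
        """Quadrature of the field over the domain, sum(f) dx^2."""
        return float(self.values.sum()) * self.dx**2

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.dx)


@dataclass
class Micropattern:
    """Adhesion field chi in [0, 1]: 1 on the stripe, 0 outside."""

    chi: ScalarField
    d: float
    edge_w: float


# ---------------------------------------------------------------------------
# finite differences (periodic in x, no-flux in y)

def grad_x(f: np.ndarray, dx: float) -> np.ndarray:
    """Centred x-derivative, periodic."""
    return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2.0 * dx)


def grad_y(f: np.ndarray, dx: float) -> np.ndarray:
    """Centred y-derivative; mirror ghost cells give zero normal derivative."""
    p = np.empty((f.shape[0] + 2, f.shape[1]), dtype=f.dtype)
    p[1:-1] = f
    p[0] = f[0]
    p[-1] = f[-1]
    return (p[2:] - p[:-2]) / (2.0 * dx)


def laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian, periodic in x, no-flux (mirror) in y."""
    out = np.roll(f, -1, axis=1) + np.roll(f, 1, axis=1) - 2.0 * f
    p = np.empty((f.shape[0] + 2, f.shape[1]), dtype=f.dtype)
    p[1:-1] = f
    p[0] = f[0]
    p[-1] = f[-1]
    out += p[2:] + p[:-2] - 2.0 * f
    return out / dx**2


def grad_mag(f: np.ndarray, dx: float) -> np.ndarray:
    gx = grad_x(f, dx)
    gy = grad_y(f, dx)
    return np.sqrt(gx * gx + gy * gy)


# ---------------------------------------------------------------------------
# constructors

def make_stripe(grid: GridSpec, d: float, edge_w: float = 1.0) -> Micropattern:
    """Adhesive stripe of width ``d`` centred in y.

    chi = 1 on the stripe interior, 0 outside, with a tanh ramp of width
    ~``edge_w`` across each edge; the chi = 0.5 contour sits exactly at
    |y - y_c| = d/2.
    """
    if d + 2.0 * edge_w >= grid.Ly:
        raise ValueError(
            f"stripe (d={d}, edge_w={edge_w}) does not fit in Ly={grid.Ly}")
    y = (np.arange(grid.ny) + 0.5) * grid.dx
    yc = grid.Ly / 2.0
    if edge_w > 0:
        profile = 0.5 * (1.0 + np.tanh(3.0 * (d / 2.0 - np.abs(y - yc)) / edge_w))
    else:
        profile = (np.abs(y - yc) <= d / 2.0).astype(float)
    chi = np.repeat(profile[:, None], grid.nx, axis=1)
    return Micropattern(ScalarField(chi, grid.dx), d=d, edge_w=edge_w)


def init_phase_field(grid: GridSpec, center: tuple[float, float],
                     R: float, epsilon: float) -> ScalarField:
    """Equilibrium tanh disk: phi = (1 - tanh(3 (|r - c| - R)/eps)) / 2.

    This is the 1-D minimiser of the double-well interface energy wrapped
    around a circle; phi = 1/2 exactly on |r - c| = R. The x-distance is
    evaluated on the periodic torus so cells may be placed anywhere.
    """
    cx, cy = center
    if not (R + 2 * epsilon < grid.Ly):
        raise ValueError("disk does not fit inside the domain in y")
    x = (np.arange(grid.nx) + 0.5) * grid.dx
    y = (np.arange(grid.ny) + 0.5) * grid.dx
    dxs = np.abs(x - cx)
    dxs = np.minimum(dxs, grid.Lx - dxs)       # periodic x
    r = np.sqrt(dxs[None, :] ** 2 + (y[:, None] - cy) ** 2)
    phi = 0.5 * (1.0 - np.tanh(3.0 * (r - R) / epsilon))
    return ScalarField(phi, grid.dx)


# ---------------------------------------------------------------------------
# observables

def _vals(f) -> tuple[np.ndarray, float]:
    if isinstance(f, ScalarField):
        return f.values, f.dx
    raise TypeError("expected a ScalarField")


def perimeter(phi: ScalarField) -> float:
    """P = integral |grad phi| d^2 r (quadrature with centred differences)."""
    v, dx = _vals(phi)
    return float(grad_mag(v, dx).sum()) * dx**2


def area(phi: ScalarField) -> float:
    """A = integral phi d^2 r."""
    return phi.integrate()


def center_of_mass(phi: ScalarField) -> tuple[float, float]:
    """phi-weighted centroid; x handled on the periodic circle.

    Uses the circular-mean construction in x so cells straddling the
    periodic seam get a sensible centre. Raises for an empty field.
    """
    v, dx = _vals(phi)
    m = v.sum()
    if m <= EPS_MACH:
        raise ValueError("center of mass undefined: integral of phi is zero")
    ny, nx = v.shape
    Lx = nx * dx
    theta = 2.0 * np.pi * (np.arange(nx) + 0.5) / nx
    w = v.sum(axis=0)
    cx = np.angle(np.sum(w * np.exp(1j * theta))) / (2.0 * np.pi) * Lx
    cx %= Lx
    y = (np.arange(ny) + 0.5) * dx
    cy = float((v.sum(axis=1) * y).sum() / m)
    return (float(cx), cy)


def overlap(phi_i: ScalarField, phi_j: ScalarField) -> float:
    """Pairwise overlap integral phi_i phi_j d^2 r (the exclusion measure).

    Small negative undershoots of the evolving phase fields are clipped
    so the overlap is non-negative and vanishes for disjoint supports.
    """
    vi, dx = _vals(phi_i)
    vj, dxj = _vals(phi_j)
    if vi.shape != vj.shape or dx != dxj:
        raise ValueError("fields must share a grid")
    vi = np.clip(vi, 0.0, None)
    vj = np.clip(vj, 0.0, None)
    return float((vi * vj).sum()) * dx**2
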