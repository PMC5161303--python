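"""Intracellular Rac and inhibitor dynamics, and CIL production.

Cell polarity follows a mass-conserved wave-pinning scheme: membrane-bound
active Rac (rho, um^-2) exchanges with a well-mixed cytosolic pool rho_cyt,
with cooperative (Hill) recruitment creating bistability; the conserved
total per cell is N_tot. A diffusing inhibitor I raises the Rac detachment
rate to k_c (1 + I/I0); I decays at k_mI, receives delta-correlated Langevin
noise, and is produced at cell-cell contacts through two mechanisms:

* contact repolarization (CR): production wherever another cell's body
  overlaps, at rate k_CR;
* front repolarization (FR): production only where the *front* (high
  phi*rho) of another cell overlaps beyond a critical overlap O_crit, at
  rate k_FR.

I may go negative; it measures the deviation of the detachment rate from
its base value, and the model is equivalent to a strictly positive species
Y = I + I0 with a basal source. Runs where k_c (1 + I/I0) would turn
negative anywhere are rejected as invalid.

Reaction-diffusion inside the moving cell uses the phase-field weighted
form d_t(phi u) = div(phi D grad u) + phi f, whose sharp-interface limit
is the bulk equation with no-flux boundary conditions on the cell edge.
"""

from __future__ import annotations

import numpy as np

from ._kernels import rd_step_kernel
from .domain import EPS_MACH
from .params import ModelParams

__all__ = [
    "sigmoid_S", "rho_reaction", "cytosolic_density", "cil_production",
    "inhibitor_reaction", "noise_increment", "rd_step",
]


def sigmoid_S(x, x0: float = 0.1):
    """S(x) = max(0, tanh(x / x0)): a one-sided saturating switch."""
    return np.maximum(0.0, np.tanh(np.asarray(x, dtype=float) / x0))


def rho_reaction(rho: np.ndarray, rho_cyt: float, I: np.ndarray,
                 p: ModelParams) -> np.ndarray:
    """Wave-pinning exchange term f_rho (um^-2 s^-1).

    f = k_b [rho^2/(K_a^2 + rho^2) + k_a] rho_cyt - k_c [1 + I/I0] rho

    Attachment (basal + cooperative) draws on the cytosolic pool; the
    inhibitor modulates detachment. Both attachment channels are
    proportional to rho_cyt.
    """
    attach = p.k_b * (rho**2 / (p.K_a**2 + rho**2) + p.k_a) * rho_cyt
    detach = p.k_c * (1.0 + I / p.I0) * rho
    return attach - detach


def cytosolic_density(N_tot: float, phi: np.ndarray, rho: np.ndarray,
                      dx: float) -> float:
    """rho_cyt = (N_tot - int phi rho) / int phi, clamped at zero.

    The cytosolic state is assumed fast-diffusing and spatially uniform;
    this closes the per-cell conservation of total Rac exactly.
    """
    pp = np.clip(phi, 0.0, None)
    A = float(pp.sum()) * dx**2
    if A <= EPS_MACH:
        raise ValueError("cytosolic density undefined for an empty cell")
    val = (N_tot - float((pp * rho).sum()) * dx**2) / A
    return max(val, 0.0)


def cil_production(phis: list[np.ndarray], rhos: list[np.ndarray], i: int,
                   p: ModelParams) -> np.ndarray:
    """Inhibitor source in cell i from contact with every other cell.

    I0 * [ k_CR S(sum_j phi_j) + k_FR S((sum_j phi_j rho_j - O_crit)/rho_char) ]

    The CR switch fires on any overlap; the FR switch only where the
    summed front signal phi*rho of the neighbours exceeds O_crit. The
    multiplication by the unit concentration I0 converts the quoted rates
    (1/s) into density production rates (um^-2 s^-1) without changing
    their numeric values.
    """
    shape = phis[i].shape
    if len(phis) <= 1:
        return np.zeros(shape)
    others = np.zeros(shape)
    fronts = np.zeros(shape)
    for j, (pj, rj) in enumerate(zip(phis, rhos)):
        if j == i:
            continue
        others += pj
        fronts += pj * rj
    out = np.zeros(shape)
    if p.k_CR > 0:
        out += p.k_CR * sigmoid_S(others, p.x0)
    if p.k_FR > 0:
        out += p.k_FR * sigmoid_S((fronts - p.O_crit) / p.rho_char, p.x0)
    return p.I0 * out


def inhibitor_reaction(I: np.ndarray, cil_field: np.ndarray,
                       noise_field: np.ndarray, k_mI: float) -> np.ndarray:
    """f_I = -k_mI I + CIL production + Langevin noise."""
    return -k_mI * I + cil_field + noise_field


def noise_increment(shape: tuple[int, int], dx: float, dt: float,
                    eta: float, rng: np.random.Generator) -> np.ndarray:
    """Discretised Langevin source eta*xi for the inhibitor equation.

    xi is Gaussian, delta-correlated in space and time with spectral
    density eta^2, so on the lattice xi has per-site variance
    eta^2/(dx^2 dt) and the returned field eta*xi has variance
    eta^4/(dx^2 dt). Returned as a rate (to be multiplied by dt by the
    integrator); reproducible for a fixed generator state.
    """
    if eta == 0.0:
        return np.zeros(shape)
    std = eta * eta / (dx * np.sqrt(dt))
    return rng.normal(0.0, std, size=shape)


def rd_step(phi: np.ndarray, u: np.ndarray, D: float,
            rate_field: np.ndarray, dx: float, dt: float,
            phi_old: np.ndarray | None = None,
            phi_floor: float = 1e-7) -> np.ndarray:
    """Conservative update of d_t(phi u) = div(phi D grad u) + phi rate.

    Fluxes are evaluated on cell faces with arithmetic-mean phi, periodic
    in x and zero-flux in y, so the lattice sum of phi*u changes exactly
    by sum(phi*rate)*dt (no leakage through the diffuse boundary). When
    the interface has just moved, pass the pre-move field as ``phi_old``
    so the conserved product phi*u is formed consistently.
    """
    if phi_old is None:
        phi_old = phi
    out, ok = rd_step_kernel(phi, phi_old, u, D, rate_field, dx, dt,
                             phi_floor)
    if not ok:
        raise FloatingPointError("reaction-diffusion update produced NaN/inf")
    return out
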