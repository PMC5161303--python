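"""Interface energetics and the overdamped interface-motion law.

The cell boundary is a diffuse interface of width ``epsilon`` carrying a
perimeter-dependent line tension gamma(P) and a bending rigidity kappa;
pairs of cells interact through a soft volume-exclusion penalty (strength
``g``) and a short-ranged interface-interface adhesion (strength ``sigma``).
The interface moves by force balance:

    tau dphi/dt = (alpha rho chi - beta) |grad phi| - (1/epsilon) dH/dphi

Functions here operate on plain ``(ny, nx)`` arrays; discrete energies
(`energy_single`, `energy_interaction`) are written so that the analytic
force arrays are the exact gradients of the discretised functionals, which
the test-suite verifies against brute-force numerical differentiation.
"""

from __future__ import annotations

import numpy as np

from ._kernels import (interaction_force_kernel, perimeter_kernel,
                       propulsion_phase_step, tension_bending_force)
from .domain import grad_x, grad_y, grad_mag, laplacian
from .params import ModelParams

__all__ = [
    "double_well", "double_well_prime", "double_well_second",
    "line_tension", "single_cell_force", "interaction_force",
    "propulsion_term", "phase_field_step",
    "energy_single", "energy_interaction", "C_ADH",
]

# Fixed dimensionless prefactor of the adhesion energy density
# (-sigma * epsilon^3 * C_ADH * |grad phi_i|^2 |grad phi_j|^2).
# The adhesion term acts as a negative interface diffusivity of magnitude
# ~2 sigma eps^3 C_ADH |grad phi|^2; C_ADH is fixed so that this stays
# below the stabilising tension diffusivity gamma*eps over the whole
# adhesion range swept in the collision experiments (sigma <~ 6).
C_ADH = 0.462


def double_well(phi):
    """G(phi) = 18 phi^2 (1 - phi)^2 — minima at the two bulk phases."""
    return 18.0 * phi**2 * (1.0 - phi) ** 2


def double_well_prime(phi):
    """G'(phi) = 36 phi (1 - phi)(1 - 2 phi)."""
    return 36.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def double_well_second(phi):
    """G''(phi) = 36 (1 - 6 phi + 6 phi^2)."""
    return 36.0 * (1.0 - 6.0 * phi + 6.0 * phi**2)


def line_tension(P: float, gamma0: float, gamma_per: float,
                 P_cr: float) -> float:
    """gamma(P): constant below P_cr, linearly stiffening above it.

    The stiffening caps the perimeter growth that strong cell-cell
    adhesion would otherwise drive without limit.
    """
    if P >= P_cr:
        return gamma0 * (1.0 + gamma_per * (P - P_cr))
    return gamma0


def _dirichlet_energy(phi: np.ndarray, dx: float) -> float:
    """Face-based sum of |grad phi|^2 dx^2 (no-flux in y, periodic in x).

    The face-based form makes the 5-point Laplacian its exact discrete
    gradient, so analytic forces match numerical differentiation of the
    energy to round-off.
    """
    ex = (np.roll(phi, -1, axis=1) - phi) / dx
    ey = (phi[1:, :] - phi[:-1, :]) / dx
    return (float((ex**2).sum()) + float((ey**2).sum())) * dx**2


def energy_single(phi: np.ndarray, dx: float, p: ModelParams,
                  gamma: float | None = None) -> float:
    """Discrete single-cell Hamiltonian (tension + bending parts).

    ``gamma`` may be pinned to a fixed value for quasi-static treatment;
    by default it is evaluated from the current perimeter.
    """
    if gamma is None:
        P = float(grad_mag(phi, dx).sum()) * dx**2
        gamma = line_tension(P, p.gamma0, p.gamma_per, p.P_cr)
    eps = p.epsilon
    e_tens = gamma * (0.5 * eps * _dirichlet_energy(phi, dx)
                      + float(double_well(phi).sum()) * dx**2 / eps)
    M = eps * laplacian(phi, dx) - double_well_prime(phi) / eps
    e_bend = 0.5 * p.kappa / eps * float((M**2).sum()) * dx**2
    return e_tens + e_bend


def single_cell_force(phi: np.ndarray, dx: float, p: ModelParams,
                      gamma: float | None = None) -> np.ndarray:
    """dH_single/dphi: tension + bending contributions.

    gamma(P) is treated quasi-statically — re-evaluated from the current
    perimeter each call and applied as a scalar prefactor.
    """
    eps = p.epsilon
    if gamma is None:
        P = perimeter_kernel(phi, dx)
        gamma = line_tension(P, p.gamma0, p.gamma_per, p.P_cr)
    return tension_bending_force(phi, dx, eps, gamma, p.kappa)


def energy_interaction(phi_i: np.ndarray, phi_j: np.ndarray, dx: float,
                       g: float, sigma: float, epsilon: float) -> float:
    """Discrete pair Hamiltonian: exclusion minus adhesion (one pair)."""
    excl = 0.5 * g * float((phi_i * phi_j).sum()) * dx**2
    gi2 = grad_x(phi_i, dx) ** 2 + grad_y(phi_i, dx) ** 2
    gj2 = grad_x(phi_j, dx) ** 2 + grad_y(phi_j, dx) ** 2
    adh = sigma * epsilon**3 * C_ADH * float((gi2 * gj2).sum()) * dx**2
    return excl - adh


def interaction_force(phi_i: np.ndarray, phi_j: np.ndarray, dx: float,
                      g: float, sigma: float, epsilon: float) -> np.ndarray:
    """dH_pair/dphi_i: repulsion from overlap, attraction between interfaces.

    The adhesion variation is 2 sigma eps^3 C_ADH div(|grad phi_j|^2
    grad phi_i); it vanishes wherever the two interfaces do not meet.
    """
    return interaction_force_kernel(phi_i, phi_j, dx, g,
                                    sigma * epsilon**3 * C_ADH)


def propulsion_term(phi: np.ndarray, rho: np.ndarray, chi: np.ndarray,
                    alpha: float, beta: float, tau: float,
                    dx: float) -> np.ndarray:
    """Active interface speed (1/tau)(alpha rho chi - beta)|grad phi|.

    Protrusion requires both Rac (rho) and substrate adhesion (chi); the
    contraction beta acts everywhere on the interface, so off-pattern or
    Rac-poor boundary retracts.
    """
    return (alpha * rho * chi - beta) * grad_mag(phi, dx) / tau


def phase_field_step(phi: np.ndarray, rho: np.ndarray, chi: np.ndarray,
                     force: np.ndarray, p: ModelParams, dx: float,
                     dt: float) -> np.ndarray:
    """One explicit Euler update of the interface law.

    ``force`` is the total dH/dphi for this cell (single-cell plus any
    pairwise interaction terms). Aborts on numerical blow-up; small
    over/undershoots of the [0, 1] band are tolerated (phi is not clipped).
    """
    out, mn, mx = propulsion_phase_step(phi, rho, chi, force, p.alpha,
                                        p.beta, p.tau, p.epsilon, dx, dt)
    if not np.isfinite(mx) or not np.isfinite(mn) or mx > 1.3 or mn < -0.3:
        raise FloatingPointError(
            f"phase field left its admissible band (min={mn:.3g}, "
            f"max={mx:.3g}); reduce dt or check parameters")
    return out
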