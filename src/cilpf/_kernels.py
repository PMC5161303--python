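"""Numba-compiled inner loops for the field updates.

These implement exactly the discretisation defined in :mod:`domain`
(centred differences, periodic in x, mirror/no-flux in y) with explicit
loops, which removes the per-call overhead of many small numpy
temporaries. The public mechanics/biochemistry functions delegate here;
the test-suite checks them against brute-force energy gradients and
closed-form solutions, which covers these kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "tension_bending_force", "interaction_force_kernel",
    "propulsion_phase_step", "rd_step_kernel", "perimeter_kernel",
]


@njit(cache=True)
def _gp(v):
    return 36.0 * v * (1.0 - v) * (1.0 - 2.0 * v)


@njit(cache=True)
def _gpp(v):
    return 36.0 * (1.0 - 6.0 * v + 6.0 * v * v)


@njit(cache=True)
def _lap(f, dx):
    ny, nx = f.shape
    out = np.empty_like(f)
    inv = 1.0 / (dx * dx)
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i < nx - 1 else 0
            out[j, i] = (f[j, im] + f[j, ip] + f[jm, i] + f[jp, i]
                         - 4.0 * f[j, i]) * inv
    return out


@njit(cache=True)
def perimeter_kernel(phi, dx):
    ny, nx = phi.shape
    s = 0.0
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i < nx - 1 else 0
            gx = (phi[j, ip] - phi[j, im]) / (2.0 * dx)
            gy = (phi[jp, i] - phi[jm, i]) / (2.0 * dx)
            s += np.sqrt(gx * gx + gy * gy)
    return s * dx * dx


@njit(cache=True)
def tension_bending_force(phi, dx, eps, gamma, kappa):
    """gamma*(G'/eps - eps*lap(phi)) + kappa*(lap(M) - G''*M/eps^2),
    with M = eps*lap(phi) - G'(phi)/eps."""
    ny, nx = phi.shape
    lap = _lap(phi, dx)
    M = np.empty_like(phi)
    for j in range(ny):
        for i in range(nx):
            M[j, i] = eps * lap[j, i] - _gp(phi[j, i]) / eps
    out = np.empty_like(phi)
    if kappa != 0.0:
        lapM = _lap(M, dx)
        for j in range(ny):
            for i in range(nx):
                out[j, i] = -gamma * M[j, i] + kappa * (
                    lapM[j, i] - _gpp(phi[j, i]) * M[j, i] / (eps * eps))
    else:
        for j in range(ny):
            for i in range(nx):
                out[j, i] = -gamma * M[j, i]
    return out


@njit(cache=True)
def interaction_force_kernel(phi_i, phi_j, dx, g, adh):
    """0.5*g*phi_j + 2*adh*div(|grad phi_j|^2 grad phi_i);
    adh = sigma*eps^3*C_ADH."""
    ny, nx = phi_i.shape
    out = np.empty_like(phi_i)
    if adh == 0.0:
        for j in range(ny):
            for i in range(nx):
                out[j, i] = 0.5 * g * phi_j[j, i]
        return out
    fx = np.empty_like(phi_i)
    fy = np.empty_like(phi_i)
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i < nx - 1 else 0
            gjx = (phi_j[j, ip] - phi_j[j, im]) / (2.0 * dx)
            gjy = (phi_j[jp, i] - phi_j[jm, i]) / (2.0 * dx)
            gj2 = gjx * gjx + gjy * gjy
            fx[j, i] = gj2 * (phi_i[j, ip] - phi_i[j, im]) / (2.0 * dx)
            fy[j, i] = gj2 * (phi_i[jp, i] - phi_i[jm, i]) / (2.0 * dx)
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i < nx - 1 else 0
            div = ((fx[j, ip] - fx[j, im])
                   + (fy[jp, i] - fy[jm, i])) / (2.0 * dx)
            out[j, i] = 0.5 * g * phi_j[j, i] + 2.0 * adh * div
    return out


@njit(cache=True)
def propulsion_phase_step(phi, rho, chi, force, alpha, beta, tau, eps,
                          dx, dt):
    """phi + dt*[(alpha rho chi - beta)|grad phi|/tau - force/(tau eps)].

    Returns (phi_new, min, max) so the caller can detect blow-up.
    """
    ny, nx = phi.shape
    out = np.empty_like(phi)
    mn = 1.0e300
    mx = -1.0e300
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx):
            im = i - 1 if i > 0 else nx - 1
            ip = i + 1 if i < nx - 1 else 0
            gx = (phi[j, ip] - phi[j, im]) / (2.0 * dx)
            gy = (phi[jp, i] - phi[jm, i]) / (2.0 * dx)
            gm = np.sqrt(gx * gx + gy * gy)
            v = phi[j, i] + dt * (
                (alpha * rho[j, i] * chi[j, i] - beta) * gm / tau
                - force[j, i] / (tau * eps))
            out[j, i] = v
            if v < mn:
                mn = v
            if v > mx:
                mx = v
    return out, mn, mx


@njit(cache=True)
def rd_step_kernel(phi, phi_old, u, D, rate, dx, dt, phi_floor):
    """Conservative phi-weighted diffusion + reaction update of u.

    Harmonic-mean face weights of clip(phi, 0, .); periodic x, no-flux y.
    """
    ny, nx = phi.shape
    pp = np.empty_like(phi)
    for j in range(ny):
        for i in range(nx):
            v = phi[j, i]
            pp[j, i] = v if v > 0.0 else 0.0
    W = np.empty_like(phi)
    for j in range(ny):
        for i in range(nx):
            po = phi_old[j, i]
            if po < 0.0:
                po = 0.0
            W[j, i] = po * u[j, i]
    tiny = 1.0e-12
    # x-face fluxes, periodic
    for j in range(ny):
        for i in range(nx):
            ip = i + 1 if i < nx - 1 else 0
            pf = 2.0 * pp[j, i] * pp[j, ip] / (pp[j, i] + pp[j, ip] + tiny)
            flux = pf * D * (u[j, ip] - u[j, i]) / dx * dt / dx
            W[j, i] += flux
            W[j, ip] -= flux
    # y-face fluxes, zero at walls
    for j in range(ny - 1):
        for i in range(nx):
            pf = 2.0 * pp[j, i] * pp[j + 1, i] / (pp[j, i] + pp[j + 1, i]
                                                  + tiny)
            flux = pf * D * (u[j + 1, i] - u[j, i]) / dx * dt / dx
            W[j, i] += flux
            W[j + 1, i] -= flux
    out = np.empty_like(phi)
    ok = True
    for j in range(ny):
        for i in range(nx):
            W[j, i] += dt * pp[j, i] * rate[j, i]
            if pp[j, i] > phi_floor:
                out[j, i] = W[j, i] / pp[j, i]
            else:
                out[j, i] = 0.0
            if not np.isfinite(out[j, i]):
                ok = False
    return out, ok
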