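"""Model constants, grid description, and validation.

All quantities are expressed in micrometres, seconds and piconewtons.
Propulsion strength ``alpha`` is quoted in units of ``alpha0 = 1 pN/um^3``
and adhesion strength ``sigma`` in units of ``sigma0 = 1 pN/um``, so the
numbers stored here can be compared directly with the literature values
(e.g. ``alpha = 0.4`` means ``0.4 alpha0``).

The default constants form a calibrated set: the mechanical and wave-pinning
parameters were tuned (see ``docs/methods.md`` and ``scripts/calibrate.py``)
so that a single relaxed cell on a stripe has perimeter P ~ 56.5 um, a Rac
density of ~1.4 um^-2 at its front and ~0.01 um^-2 at its rear, and so that
the reversal-to-sticking transition at ``alpha = 0.4`` sits near
``sigma ~ 3.86``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

__all__ = ["ModelParams", "GridSpec", "validate_params"]


@dataclass
class ModelParams:
    """Every constant of the mechanical + biochemical model.

    Mechanics
    ---------
    tau : friction coefficient of the interface law (pN s / um^3).
    alpha : propulsion strength, units of alpha0 = 1 pN/um^3.
    beta : uniform contraction strength (pN/um).
    epsilon : phase-field interface width (um).
    gamma0 : base line tension (pN).
    gamma_per : perimeter-elasticity coefficient (1/um).
    P_cr : critical perimeter above which tension stiffens (um).
    kappa : bending modulus (pN um^2).
    g : cell-cell exclusion strength (energy/area).
    sigma : cell-cell adhesion strength, units of sigma0 = 1 pN/um.

    Biochemistry
    ------------
    D_rho, D_I : diffusivities of membrane-bound Rac and of the
        inhibitor (um^2/s).
    k_a : dimensionless base binding factor (basal attachment is k_a*k_b).
    k_b : activation rate (1/s).
    K_a : Hill saturation density of cooperative Rac recruitment (um^-2).
    k_c : base detachment rate (1/s); the inhibitor raises it to
        k_c*(1 + I/I0).
    I0 : inhibitor scale (um^-2); also converts CIL rates to density rates.
    N_tot : conserved total Rac per cell (area-integrated density).
    k_mI : inhibitor decay rate (1/s).
    eta : inhibitor noise amplitude; the Langevin term has spectral
        density eta^2 * delta^2(r-r') delta(t-t').

    Contact inhibition of locomotion
    --------------------------------
    k_CR, k_FR : contact- and front-repolarization production rates (1/s).
    O_crit : critical overlap for front repolarization (um^-2).
    rho_char : normalisation of the FR sigmoid argument (um^-2).
    x0 : sigmoid scale of S(x) = max(0, tanh(x/x0)); dimensionless.

    Geometry / protocol
    -------------------
    R_cell : initial cell radius (um).
    d : stripe width (um).
    edge_w : smoothing length of the stripe edge (um).
    T_sim : default simulation length (s).
    """

    # mechanics
    tau: float = 3.5
    alpha: float = 0.4
    beta: float = 0.2
    epsilon: float = 3.0
    gamma0: float = 1.8
    gamma_per: float = 0.5
    P_cr: float = 58.0
    kappa: float = 0.5
    g: float = 1.5
    sigma: float = 2.25

    # biochemistry
    D_rho: float = 2.0
    D_I: float = 3.0
    k_a: float = 0.005
    k_b: float = 10.0
    K_a: float = 1.0
    k_c: float = 7.0
    I0: float = 1.0
    N_tot: float = 595.0
    k_mI: float = 0.1
    eta: float = 0.25

    # CIL
    k_CR: float = 0.01
    k_FR: float = 0.04
    O_crit: float = 0.15
    rho_char: float = 1.0
    x0: float = 0.1

    # geometry / protocol
    R_cell: float = 9.0
    d: float = 25.0
    edge_w: float = 1.0
    T_sim: float = 2500.0

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the parameter set (order-independent)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GridSpec:
    """Cell-centred lattice: (0, 0) at the domain corner, spacing ``dx``.

    x (axis of the stripe) is periodic; y uses no-flux boundaries.
    """

    nx: int = 160
    ny: int = 40
    dx: float = 1.0
    dt: float = 0.04
    bc_x: str = "periodic"
    bc_y: str = "noflux"

    @property
    def Lx(self) -> float:
        return self.nx * self.dx

    @property
    def Ly(self) -> float:
        return self.ny * self.dx

    @property
    def shape(self) -> tuple[int, int]:
        # array layout is (ny, nx): axis 0 is y, axis 1 is x
        return (self.ny, self.nx)


_POSITIVE = (
    "tau", "alpha", "beta", "epsilon", "gamma0", "P_cr", "g",
    "D_rho", "D_I", "k_a", "k_b", "K_a", "k_c", "I0", "N_tot", "k_mI",
    "rho_char", "x0", "R_cell", "d",
)
_NON_NEGATIVE = ("gamma_per", "kappa", "sigma", "eta", "k_CR", "k_FR",
                 "O_crit", "edge_w", "T_sim")


def validate_params(p: ModelParams, grid: GridSpec | None = None) -> list[str]:
    """Check every invariant; return a list of human-readable violations.

    An empty list means the set is usable. Callers decide whether to abort.
    """
    v: list[str] = []
    for name in _POSITIVE:
        val = getattr(p, name)
        if not (math.isfinite(val) and val > 0):
            v.append(f"{name} must be strictly positive (got {val})")
    for name in _NON_NEGATIVE:
        val = getattr(p, name)
        if not (math.isfinite(val) and val >= 0):
            v.append(f"{name} must be non-negative (got {val})")
    if grid is not None:
        if grid.nx < 4 or grid.ny < 4:
            v.append("grid: nx and ny must each be at least 4")
        if grid.dx <= 0:
            v.append("grid: dx must be positive")
        elif grid.dx > p.epsilon / 2 + 1e-12:
            v.append(f"grid: dx <= epsilon/2 required to resolve the "
                     f"interface (dx={grid.dx}, epsilon={p.epsilon})")
        if grid.dt <= 0:
            v.append("grid: dt must be positive")
        else:
            # explicit-scheme bounds: phi relaxation, bending, diffusion
            # harmonic-mean face weighting doubles the worst-case rate
            dt_diff = grid.dx**2 / (8.0 * max(p.D_rho, p.D_I))
            if grid.dt > dt_diff:
                v.append(f"grid: dt={grid.dt} exceeds diffusive stability "
                         f"bound {dt_diff:.4g}")
        if grid.Ly <= p.d + 4 * p.epsilon:
            v.append(f"grid: Ly > d + 4*epsilon required "
                     f"(Ly={grid.Ly}, d={p.d}, epsilon={p.epsilon})")
    return v
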