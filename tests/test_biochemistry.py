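import numpy as np
import pytest
from scipy.optimize import brentq

from cilpf import biochemistry as bio
from cilpf.domain import init_phase_field
from cilpf.params import GridSpec, ModelParams

GRID = GridSpec(nx=48, ny=40, dx=1.0, dt=0.04)


def static_disk():
    return init_phase_field(GRID, (24.0, 20.0), 9.0, 3.0).values


class TestSigmoid:
    def test_zero_at_origin(self):
        assert bio.sigmoid_S(0.0) == 0.0

    def test_clipped_for_negative_argument(self):
        assert bio.sigmoid_S(-1.0) == 0.0
        assert np.all(bio.sigmoid_S(np.linspace(-5, 0, 7)) == 0.0)

    def test_tanh_value(self):
        assert bio.sigmoid_S(0.1, x0=0.1) == pytest.approx(np.tanh(1.0))


class TestRhoReaction:
    def test_basal_attachment_value(self):
        # at rho = 0 only the basal channel k_a*k_b*rho_cyt remains
        p = ModelParams(k_a=0.1, k_b=10.0)
        f = bio.rho_reaction(np.zeros((2, 2)), 1.0, np.zeros((2, 2)), p)
        assert np.allclose(f, 1.0)

    def test_inhibitor_doubles_detachment(self):
        p = ModelParams()
        rho = np.full((2, 2), 1.0)
        f0 = bio.rho_reaction(rho, 0.0, np.zeros_like(rho), p)
        f1 = bio.rho_reaction(rho, 0.0, np.full_like(rho, p.I0), p)
        assert np.allclose(f1, 2.0 * f0)

    def test_steady_states_match_scalar_root_finding(self):
        """Spatially uniform steady states of f_rho = 0 agree with a
        brute-force bisection of the same scalar expression."""
        p = ModelParams()
        rho_cyt = 1.5

        def f(r):
            return float(bio.rho_reaction(np.array([[r]]), rho_cyt,
                                          np.zeros((1, 1)), p)[0, 0])

        grid = np.linspace(0.0, 8.0, 2000)
        vals = [f(r) for r in grid]
        roots = [brentq(f, grid[i], grid[i + 1])
                 for i in range(len(grid) - 1)
                 if vals[i] * vals[i + 1] < 0]
        assert roots, "expected at least one steady state"
        for r in roots:
            assert abs(f(r)) < 1e-9


class TestCytosol:
    def test_empty_membrane_gives_total_over_area(self):
        phi = static_disk()
        A = phi.sum() * GRID.dx ** 2
        val = bio.cytosolic_density(300.0, phi, np.zeros_like(phi),
                                    GRID.dx)
        assert val == pytest.approx(300.0 / A, rel=1e-12)

    def test_exhausted_pool_clamps_to_zero(self):
        phi = static_disk()
        rho = np.full_like(phi, 10.0)
        assert bio.cytosolic_density(1.0, phi, rho, GRID.dx) == 0.0

    def test_partial_binding_quadrature(self):
        phi = static_disk()
        rho = 0.5 * np.ones_like(phi)
        A = phi.sum() * GRID.dx ** 2
        expect = (300.0 - 0.5 * A) / A
        got = bio.cytosolic_density(300.0, phi, rho, GRID.dx)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError):
            bio.cytosolic_density(1.0, np.zeros((4, 4)),
                                  np.zeros((4, 4)), 1.0)


class TestCilProduction:
    def test_single_cell_produces_nothing(self):
        p = ModelParams(k_CR=0.1, k_FR=0.1)
        phi = static_disk()
        out = bio.cil_production([phi], [np.ones_like(phi)], 0, p)
        assert np.all(out == 0.0)

    def test_fr_silent_below_critical_overlap(self):
        p = ModelParams(k_CR=0.0, k_FR=0.1, O_crit=0.15)
        phi = static_disk()
        other = 0.5 * np.ones_like(phi)
        rho_other = np.full_like(phi, 0.2)      # phi*rho = 0.1 < O_crit
        out = bio.cil_production([phi, other], [phi, rho_other], 0, p)
        assert np.all(out == 0.0)

    def test_pointwise_substitution(self):
        p = ModelParams(k_CR=0.01, k_FR=0.04, O_crit=0.15, rho_char=1.0,
                        x0=0.1, I0=1.0)
        phi_other = np.array([[1.0]])
        rho_other = np.array([[1.4]])           # phi*rho - O_crit = 1.25
        out = bio.cil_production([np.array([[1.0]]), phi_other],
                                 [np.array([[0.0]]), rho_other], 0, p)
        expect = 0.01 * np.tanh(10.0) + 0.04 * np.tanh(12.5)
        assert out[0, 0] == pytest.approx(expect, rel=1e-12)


class TestInhibitor:
    def test_zero_everything_is_zero(self):
        z = np.zeros((3, 3))
        assert np.all(bio.inhibitor_reaction(z, z, z, 0.1) == 0.0)

    def test_exponential_decay_on_static_disk(self):
        """phi-weighted total of I decays as exp(-k_mI t) within 1%
        over three decay times when only decay acts."""
        p = ModelParams()
        phi = static_disk()
        I = np.where(phi > 0.5, 1.0, 0.0)
        dt = GRID.dt
        k = 0.05
        T = 3.0 / k
        m0 = (np.clip(phi, 0, None) * I).sum()
        for _ in range(int(T / dt)):
            rate = bio.inhibitor_reaction(I, np.zeros_like(I),
                                          np.zeros_like(I), k)
            I = bio.rd_step(phi, I, p.D_I, rate, GRID.dx, dt)
        m = (np.clip(phi, 0, None) * I).sum()
        assert m / m0 == pytest.approx(np.exp(-k * T), rel=0.01)

    def test_shifted_variable_form(self):
        """Rewriting the decay about the basal level I0 reproduces the
        dynamics of the strictly positive species Y = I + I0."""
        rng = np.random.default_rng(1)
        I = rng.normal(0, 0.3, (5, 5))
        k = 0.07
        I0 = 1.0
        lhs = bio.inhibitor_reaction(I, np.zeros_like(I),
                                     np.zeros_like(I), k)
        Y = I + I0
        rhs = -k * (Y - I0)
        assert np.allclose(lhs, rhs)


class TestNoise:
    def test_zero_amplitude_is_identically_zero(self):
        rng = np.random.default_rng(0)
        out = bio.noise_increment((8, 8), 1.0, 0.04, 0.0, rng)
        assert np.all(out == 0.0)

    def test_variance_matches_delta_discretisation(self):
        rng = np.random.default_rng(7)
        eta, dx, dt = 0.3, 1.0, 0.04
        draws = bio.noise_increment((400, 300), dx, dt, eta, rng)
        target = eta ** 4 / (dx ** 2 * dt)
        n = draws.size
        se = target * np.sqrt(2.0 / n)
        assert abs(draws.var() - target) < 3 * se

    def test_seeded_reproducibility(self):
        a = bio.noise_increment((6, 6), 1.0, 0.04, 0.2,
                                np.random.default_rng(42))
        b = bio.noise_increment((6, 6), 1.0, 0.04, 0.2,
                                np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestRdStep:
    def test_mass_conserved_without_reaction(self):
        phi = static_disk()
        # u supported well inside the cell so no mass sits in the
        # sub-floor tail
        u = np.where(phi > 0.9, 1.0, 0.0) * (1 + 0.3 * np.sin(
            np.arange(GRID.nx) / 3.0))[None, :]
        m0 = (np.clip(phi, 0, None) * u).sum()
        for _ in range(50):
            u = bio.rd_step(phi, u, 2.0, np.zeros_like(u), GRID.dx,
                            GRID.dt)
        m = (np.clip(phi, 0, None) * u).sum()
        # per-step relative drift below 1e-10 (only the sub-floor tail
        # of the diffuse interface can leak)
        assert abs(m - m0) / m0 < 50 * 1e-10

    def test_uniform_field_stays_uniform(self):
        phi = static_disk()
        u = np.full_like(phi, 0.8)
        u2 = bio.rd_step(phi, u, 2.0, np.zeros_like(u), GRID.dx, GRID.dt)
        inside = phi > 1e-6
        assert np.allclose(u2[inside], 0.8)

    def test_source_adds_expected_mass(self):
        phi = static_disk()
        u = np.zeros_like(phi)
        rate = np.full_like(phi, 0.3)
        u2 = bio.rd_step(phi, u, 2.0, rate, GRID.dx, GRID.dt)
        gained = (np.clip(phi, 0, None) * u2).sum()
        pp = np.clip(phi, 0, None)
        live = pp > 1e-7          # sites the scheme evolves
        expect = (pp * rate)[live].sum() * GRID.dt
        assert gained == pytest.approx(expect, rel=1e-9)
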