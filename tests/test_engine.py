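import numpy as np
import pytest

from cilpf import engine
from cilpf.domain import make_stripe
from cilpf.params import GridSpec, ModelParams


class TestRelaxation:
    def test_summary_reports_steady_polarized_cell(self, relaxed_cell):
        _, s = relaxed_cell
        assert s["polarized"]
        assert s["stationary"]
        assert s["speed"] > 0.01
        assert 50.0 < s["P"] < 62.0
        assert s["rho_front"] > 5 * s["rho_back"]

    def test_rac_conservation_during_migration(self, quiet_params,
                                               relaxed_cell):
        """Total Rac (membrane + cytosol) stays at N_tot while the cell
        crawls."""
        import cilpf.biochemistry as bio
        cell, _ = relaxed_cell
        p = quiet_params
        grid = engine.default_single_grid(p)
        state = engine.SimulationState(
            [cell.copy()], make_stripe(grid, p.d, p.edge_w), grid, p,
            rng=np.random.default_rng(0))
        totals = []
        for k in range(int(100.0 / grid.dt)):
            engine.step_system(state)
            if k % 250 == 0:
                c = state.cells[0]
                pp = np.clip(c.phi, 0, None)
                rc = bio.cytosolic_density(p.N_tot, c.phi, c.rho, grid.dx)
                totals.append((pp * c.rho).sum() * grid.dx**2
                              + rc * pp.sum() * grid.dx**2)
        totals = np.array(totals)
        assert np.max(np.abs(totals - p.N_tot)) / p.N_tot < 1e-3


@pytest.fixture(scope="module")
def collision_state(quiet_params):
    return engine.setup_collision(quiet_params, seed=0)


class TestCollisionSetup:
    def test_initial_state_is_mirror_symmetric(self, collision_state):
        c0, c1 = collision_state.cells
        assert np.allclose(c0.phi, c1.phi[:, ::-1], atol=1e-12)
        assert np.allclose(c0.rho, c1.rho[:, ::-1], atol=1e-12)

    def test_no_initial_overlap(self, collision_state):
        c0, c1 = collision_state.cells
        ov = (np.clip(c0.phi, 0, None) * np.clip(c1.phi, 0, None)).sum()
        assert ov < 1e-6

    def test_overlapping_gap_rejected(self, quiet_params):
        with pytest.raises(ValueError):
            engine.setup_collision(quiet_params, gap=10.0, seed=0)

    def test_mirror_symmetry_preserved_without_noise(self, quiet_params,
                                                     collision_state):
        """The head-on assay is symmetric under x-reflection + swap;
        the noise-free dynamics must preserve that exactly."""
        state = engine.SimulationState(
            [c.copy() for c in collision_state.cells],
            collision_state.pattern, collision_state.grid, quiet_params,
            rng=np.random.default_rng(0))
        for _ in range(200):
            engine.step_system(state)
        c0, c1 = state.cells
        assert np.abs(c0.phi - c1.phi[:, ::-1]).max() < 1e-8
        assert np.abs(c0.rho - c1.rho[:, ::-1]).max() < 1e-8
        assert np.abs(c0.I - c1.I[:, ::-1]).max() < 1e-8


class TestRunSimulation:
    def test_zero_length_run_has_single_sample(self, quiet_params,
                                               relaxed_cell):
        cell, _ = relaxed_cell
        grid = engine.default_single_grid(quiet_params)
        state = engine.SimulationState(
            [cell.copy()], make_stripe(grid, quiet_params.d,
                                       quiet_params.edge_w),
            grid, quiet_params)
        traj = engine.run_simulation(state, 0.0)
        assert len(traj.t) == 1

    def test_times_strictly_increase(self, quiet_params, relaxed_cell):
        cell, _ = relaxed_cell
        grid = engine.default_single_grid(quiet_params)
        state = engine.SimulationState(
            [cell.copy()], make_stripe(grid, quiet_params.d,
                                       quiet_params.edge_w),
            grid, quiet_params)
        traj = engine.run_simulation(state, 40.0, sample_every=5.0)
        assert np.all(np.diff(traj.t) > 0)

    def test_identical_seeds_identical_trajectories(self, default_params,
                                                    relaxed_cell):
        cell, _ = relaxed_cell
        p = default_params  # eta > 0: exercises the seeded noise path
        grid = engine.default_single_grid(p)

        def run():
            state = engine.SimulationState(
                [cell.copy()], make_stripe(grid, p.d, p.edge_w), grid, p,
                rng=np.random.default_rng(123))
            return engine.run_simulation(state, 30.0, sample_every=5.0)

        a, b = run(), run()
        assert np.array_equal(a.com, b.com)
        assert np.array_equal(a.rho_front, b.rho_front)

    def test_single_cell_has_no_cil_inhibitor(self, quiet_params,
                                              relaxed_cell):
        """With one cell the contact sums are empty: no inhibitor is
        produced at eta = 0."""
        cell, _ = relaxed_cell
        p = quiet_params.replace(k_CR=0.5, k_FR=0.5, O_crit=0.0)
        grid = engine.default_single_grid(p)
        state = engine.SimulationState(
            [cell.copy()], make_stripe(grid, p.d, p.edge_w), grid, p)
        for _ in range(100):
            engine.step_system(state)
        assert np.abs(state.cells[0].I).max() < 1e-12


class TestTrajectoryContainer:
    def test_csv_round_trip(self, tmp_path, quiet_params, relaxed_cell):
        cell, _ = relaxed_cell
        grid = engine.default_single_grid(quiet_params)
        state = engine.SimulationState(
            [cell.copy()], make_stripe(grid, quiet_params.d,
                                       quiet_params.edge_w),
            grid, quiet_params)
        traj = engine.run_simulation(state, 20.0, sample_every=5.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = engine.Trajectory.from_csv(path, Lx=grid.Lx)
        assert np.allclose(back.t, traj.t)
        assert np.allclose(back.com, traj.com)
        assert np.allclose(back.vel, traj.vel)

    def test_unwrap_removes_periodic_jumps(self):
        x = np.array([150.0, 155.0, 0.0, 5.0])
        out = engine._unwrap(x, 160.0)
        assert np.allclose(out, [150.0, 155.0, 160.0, 165.0])


class TestMultiCellTrain:
    def test_reversal_parameters_keep_cells_distributed(self):
        """Four cells on a long stripe with strong contact
        repolarization keep reversing off each other and never form a
        permanent aggregate."""
        from cilpf.params import GridSpec
        p = ModelParams(eta=0.0, k_CR=0.1, k_FR=0.0, O_crit=0.0,
                        sigma=2.25)
        grid = GridSpec(nx=240, ny=40, dx=1.0, dt=0.04)
        state = engine.setup_train(
            p, grid, positions=[40.0, 90.0, 140.0, 200.0],
            directions=[+1, -1, +1, -1], seed=0)
        traj = engine.run_simulation(state, 800.0, sample_every=50.0)
        com = traj.com[:, -1, 0]
        dmin = min(
            min(abs(com[i] - com[j]), grid.Lx - abs(com[i] - com[j]))
            for i in range(4) for j in range(i + 1, 4))
        assert dmin > 12.0
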