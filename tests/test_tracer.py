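"""RK4 particle tracing and space-time interpolation."""

import numpy as np
import pytest

from cardioflow4d.datamodel import VelocityField4D
from cardioflow4d.phantoms import rotation_field, uniform_field
from cardioflow4d.tracer import (
    IntegrationConfig,
    emit_particles,
    export_trajectories_csv,
    read_trajectories_csv,
    sample_velocity,
    trace,
)


class TestSampling:
    def test_uniform_field_everywhere(self):
        f = uniform_field((100.0, 0.0, 0.0))
        pts = np.array([[0.0, 0.0, 0.0], [4.3, -2.1, 7.7]])
        v = sample_velocity(f, pts, 13.0)
        assert np.allclose(v, [[1.0, 0.0, 0.0]] * 2)  # mm/ms

    def test_node_returns_stored_value(self):
        rng = np.random.default_rng(0)
        vel = rng.normal(0, 50, (4, 5, 5, 5, 3))
        f = VelocityField4D(vel, (2.0, 2.0, 2.0), 25.0, 100.0, origin=(-4, -4, -4))
        v = sample_velocity(f, np.array([[0.0, -2.0, 2.0]]), 50.0)
        # voxel (iz=3, iy=1, ix=2) at frame 2
        assert np.allclose(v[0], vel[2, 3, 1, 2] * 0.01, atol=1e-12)

    def test_linear_field_midpoint_is_mean(self):
        nz = ny = nx = 4
        vel = np.zeros((2, nz, ny, nx, 3))
        xs = np.arange(nx) * 3.0
        vel[..., 0] = 10.0 * xs  # linear in x
        f = VelocityField4D(vel, (3.0, 3.0, 3.0), 100.0, 500.0)
        v = sample_velocity(f, np.array([[4.5, 0.0, 0.0]]), 0.0)
        expected = 0.5 * (10.0 * 3.0 + 10.0 * 6.0) * 0.01
        assert v[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_outside_grid_is_nan(self):
        f = uniform_field((100.0, 0.0, 0.0), shape=(4, 4, 4))
        v = sample_velocity(f, np.array([[1e4, 0.0, 0.0]]), 0.0)
        assert np.isnan(v).all()

    def test_periodic_time_wrap(self):
        rng = np.random.default_rng(1)
        vel = rng.normal(0, 50, (5, 4, 4, 4, 3))
        f = VelocityField4D(vel, (3.0, 3.0, 3.0), 40.0, 100.0, origin=(-4, -4, -4))
        p = np.array([[0.3, 0.9, -1.2]])
        for t in (13.0, 77.0):
            assert np.allclose(
                sample_velocity(f, p, t), sample_velocity(f, p, t + f.cycle_length)
            )


class TestTrace:
    def test_constant_field_exact(self):
        f = uniform_field((100.0, 0.0, 0.0), shape=(20, 20, 30), spacing=(3, 3, 3))
        cfg = IntegrationConfig(0.0, 50.0, 5.0, "forward")
        seeds = np.array([[-25.0, 0.0, 0.0]])
        ps = trace(f, seeds, cfg)
        assert np.abs(ps.positions[0] - [25.0, 0.0, 0.0]).max() < 1e-12 * 50

    def test_rk4_convergence_order_on_rotation(self):
        om = 2 * np.pi  # rad/s -> one turn per second
        f = rotation_field(om, shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0))
        seed = np.array([[10.0, 0.0, 0.0]])
        errs = []
        for dt in (10.0, 5.0, 2.5):
            ps = trace(f, seed, IntegrationConfig(0.0, 500.0, dt, "forward"))
            true = np.array([10 * np.cos(om * 0.5), -10 * np.sin(om * 0.5), 0.0])
            errs.append(np.linalg.norm(ps.positions[0] - true))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(np.abs(orders - 4.0) < 0.2)

    def test_forward_backward_reversibility(self):
        f = rotation_field(2 * np.pi, shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0))
        seeds = np.array([[10.0, 0.0, 0.0], [5.0, 5.0, 3.0]])
        fwd = trace(f, seeds, IntegrationConfig(0.0, 500.0, 5.0, "forward"))
        back = trace(f, fwd.positions, IntegrationConfig(500.0, 0.0, 5.0, "backward"))
        assert np.abs(back.positions - seeds).max() < 1e-6

    def test_partial_final_step_lands_on_t_end(self):
        f = uniform_field((100.0, 0.0, 0.0), shape=(20, 20, 30))
        cfg = IntegrationConfig(0.0, 12.0, 5.0, "forward")  # 2 full + 2 ms
        ps = trace(f, np.array([[-20.0, 0.0, 0.0]]), cfg)
        assert ps.positions[0, 0] == pytest.approx(-8.0, abs=1e-12)
        assert ps.times[-1] == pytest.approx(12.0)

    def test_leaving_particle_frozen_and_flagged(self):
        f = uniform_field((100.0, 0.0, 0.0), shape=(6, 6, 6))
        cfg = IntegrationConfig(0.0, 500.0, 5.0, "forward")
        ps = trace(f, np.array([[0.0, 0.0, 0.0]]), cfg)
        assert ps.left_grid[0]
        assert ps.status[0] == "left_grid"
        x_max = f.origin[0] + 5 * 3.0
        assert ps.positions[0, 0] <= x_max + 1e-9

    def test_step_displacement_bounded_by_max_speed(self, ventricle):
        field, _gt, seg, _planes = ventricle
        seeds = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, -10.0]])
        ps = trace(field, seeds, IntegrationConfig(0.0, 300.0, 5.0, "forward"),
                   record=True)
        steps = np.diff(ps.trajectories, axis=1)
        vmax_mm_ms = np.abs(field.velocities).max() * 0.01
        assert np.linalg.norm(steps, axis=-1).max() <= vmax_mm_ms * 5.0 * 1.001

    def test_empty_seeds_ok(self):
        f = uniform_field((0.0, 0.0, 0.0))
        ps = trace(f, np.zeros((0, 3)), IntegrationConfig(0.0, 50.0, 5.0))
        assert ps.n == 0

    def test_carried_volume_is_voxel_volume(self):
        f = uniform_field((0.0, 0.0, 0.0), spacing=(3.0, 3.0, 3.0))
        ps = trace(f, np.zeros((1, 3)), IntegrationConfig(0.0, 50.0, 5.0))
        assert ps.carried_volume == pytest.approx(27.0)


class TestEmission:
    def test_cohort_counts(self):
        f = uniform_field((10.0, 0.0, 0.0), shape=(8, 8, 8))
        region = np.zeros((8, 8, 8), dtype=bool)
        region[3:5, 3:8, 3:8] = True  # 50 voxels
        cohorts = emit_particles(f, region, window=(400.0, 500.0), interval=25.0)
        assert len(cohorts) == 4
        assert sum(c.n for _, c in cohorts) == 200

    def test_interval_longer_than_window_single_emission(self):
        f = uniform_field((10.0, 0.0, 0.0), shape=(8, 8, 8))
        region = np.zeros((8, 8, 8), dtype=bool)
        region[4, 4, 4] = True
        cohorts = emit_particles(f, region, window=(0.0, 20.0), interval=50.0)
        assert len(cohorts) == 1

    def test_csv_round_trip(self, tmp_path):
        f = rotation_field(2 * np.pi, shape=(20, 20, 20), spacing=(2.0, 2.0, 2.0))
        seeds = np.array([[5.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
        ps = trace(f, seeds, IntegrationConfig(0.0, 100.0, 5.0), record=True)
        path = tmp_path / "traj.csv"
        export_trajectories_csv(path, ps)
        back = read_trajectories_csv(path)
        assert np.allclose(back.trajectories, ps.trajectories, atol=1e-5)
        assert np.allclose(back.times, ps.times, atol=1e-6)
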