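"""Integrator, thermostats, barostat, SHAKE and dipole rotation."""

import numpy as np
import pytest

from hybridsolv import builder
from hybridsolv.dynamics import (MDEngine, MDProtocol,
                                 apply_weak_coupling_barostat,
                                 minimize_steepest_descent, rotate_dipoles,
                                 run_md, shake)
from hybridsolv.forcefield import (ELBA_WATER, LJParams, ParticleSpec,
                                   total_energy_forces)
from hybridsolv.system import SystemState, Topology
from hybridsolv.units import MVV_TO_KJMOL


def _lj_dimer(r0):
    spec = ParticleSpec(lj=LJParams(3.5, 0.5), mass=30.0, kind="atom")
    top = Topology(specs=[spec, spec], molecule=np.array([0, 1]))
    state = SystemState(positions=np.array([[0.0, 0, 0], [r0, 0, 0]]) + 20.0,
                        box=60.0)
    return top, state


class TestMinimizer:
    def test_lj_dimer_reaches_potential_minimum(self):
        sigma = 3.5
        top, state = _lj_dimer(0.9 * sigma)
        out = minimize_steepest_descent(top, state, r_cut=12.0,
                                        max_steps=500, tolerance=1e-4)
        r = np.linalg.norm(out.positions[1] - out.positions[0])
        assert r == pytest.approx(2 ** (1 / 6) * sigma, abs=1e-3)

    def test_energy_never_increases(self):
        top, state = builder.build_box("water", 40, 13.0, seed=21)
        e0 = total_energy_forces(state, top, 6.0).total
        out = minimize_steepest_descent(top, state, r_cut=6.0, max_steps=150)
        assert total_energy_forces(out, top, 6.0).total <= e0

    def test_start_at_minimum_stays(self):
        sigma = 3.5
        top, state = _lj_dimer(2 ** (1 / 6) * sigma)
        out = minimize_steepest_descent(top, state, r_cut=12.0, max_steps=50,
                                        tolerance=1e-3)
        assert np.abs(out.positions - state.positions).max() < 1e-3


class TestMTSIntegrator:
    def test_zero_forces_leave_state_unchanged_except_time(self):
        spec = ParticleSpec(lj=LJParams(3.0, 0.0), mass=10.0, kind="atom")
        top = Topology(specs=[spec], molecule=np.zeros(1, dtype=np.int64))
        state = SystemState(positions=np.full((1, 3), 15.0), box=40.0)
        eng = MDEngine(top, state, MDProtocol(thermostat_tau=None, pressure=None))
        eng.outer_step()
        assert np.all(state.positions == 15.0)
        assert np.all(state.velocities == 0.0)
        assert state.time_fs == 6.0

    def test_ratio_one_reduces_to_velocity_verlet(self):
        """mts_ratio = 1 with thermostat off is plain velocity Verlet."""
        top, state = _lj_dimer(3.8)
        state.velocities = np.array([[0.004, 0.001, 0.0], [-0.004, 0.0, 0.002]])
        proto = MDProtocol(dt_inner=2.0, mts_ratio=1, thermostat_tau=None,
                           pressure=None, r_cut=12.0)
        eng = MDEngine(top, state.copy(), proto)
        n_steps = 25
        for _ in range(n_steps):
            eng.outer_step()
        # hand-coded velocity Verlet over the total force
        pos = state.positions.copy()
        vel = state.velocities.copy()
        mass = np.array([30.0, 30.0])[:, None]
        acc = 1.0 / MVV_TO_KJMOL  # (kJ/mol/A)/(g/mol) -> A/fs^2
        st = state.copy()
        for _ in range(n_steps):
            st.positions = pos
            f = total_energy_forces(st, top, 12.0).forces
            vel = vel + 0.5 * 2.0 * acc * f / mass
            pos = pos + 2.0 * vel
            st.positions = pos
            f = total_energy_forces(st, top, 12.0).forces
            vel = vel + 0.5 * 2.0 * acc * f / mass
        assert np.abs(eng.state.positions - pos).max() < 1e-9
        assert np.abs(eng.state.velocities - vel).max() < 1e-9

    def test_nve_energy_drift_bounded(self):
        """Multiple-timestep NVE on a CG water box conserves energy."""
        top, state = builder.build_box("water", 64, 12.8, seed=23)
        state = minimize_steepest_descent(top, state, 6.0, max_steps=200)
        eq = MDEngine(top, state, MDProtocol(r_cut=6.0, pressure=None, seed=3))
        eq.initialize_velocities()
        eq.run(int(10000 / 6))  # 10 ps settling
        eng = MDEngine(top, eq.state.copy(),
                       MDProtocol(r_cut=6.0, thermostat_tau=None, pressure=None))
        e0 = eng.total_energy()
        eng.run(int(5000 / 6))  # 5 ps NVE
        assert abs(eng.total_energy() - e0) / top.n_sites < 0.02


class TestLangevin:
    def test_fixed_seed_reproducible(self):
        top, state = builder.build_box("water", 30, 12.5, seed=31)
        a = MDEngine(top, state.copy(), MDProtocol(r_cut=6.0, pressure=None, seed=9))
        a.initialize_velocities()
        a.run(40)
        b = MDEngine(top, state.copy(), MDProtocol(r_cut=6.0, pressure=None, seed=9))
        b.initialize_velocities()
        b.run(40)
        assert np.array_equal(a.state.positions, b.state.positions)
        assert np.array_equal(a.state.velocities, b.state.velocities)

    def test_holds_temperature(self):
        """Mean kinetic temperature near the target over a 40 ps toy run."""
        top, state = builder.build_box("water", 60, 13.4, seed=32)
        state = minimize_steepest_descent(top, state, 6.0, max_steps=200)
        eng = MDEngine(top, state, MDProtocol(r_cut=6.0, pressure=None, seed=4))
        eng.initialize_velocities()
        eng.run(int(15000 / 6))  # settle
        temps = []
        for k in range(int(40000 / 6)):
            eng.outer_step()
            if k % 5 == 0:
                temps.append(eng.kinetic_temperature())
        assert np.mean(temps) == pytest.approx(298.0, abs=12.0)

    def test_two_groups_use_independent_noise(self):
        sol_top, sol_pos = builder.make_toy_solute("lj_site")
        box_top, box_state = builder.build_box("water", 30, 12.5, seed=33)
        top, state, _ = builder.solvate(sol_top, sol_pos + 6.2, box_top,
                                        box_state, clearance=2.8)
        eng = MDEngine(top, state, MDProtocol(r_cut=6.0, pressure=None, seed=5))
        eng.initialize_velocities()
        eng.run(30)
        assert eng.kinetic_temperature("solute") >= 0.0
        assert eng.kinetic_temperature("solvent") > 0.0


class TestBarostat:
    def test_identity_at_target_pressure(self):
        top, state = builder.build_box("water", 10, 20.0, seed=41)
        box0 = state.box.copy()
        mu = apply_weak_coupling_barostat(state, top, measured_pressure=1.0,
                                         dt=6.0, target_pressure=1.0)
        assert mu == 1.0
        assert np.array_equal(state.box, box0)

    def test_expands_when_pressure_exceeds_target(self):
        top, state = builder.build_box("water", 10, 20.0, seed=41)
        v0 = state.volume
        mu = apply_weak_coupling_barostat(state, top, measured_pressure=500.0,
                                         dt=6.0, target_pressure=1.0)
        assert mu > 1.0 and state.volume > v0

    def test_molecule_centre_scaling_preserves_geometry(self):
        top, state = builder.build_box("cyclohexane", 4, 30.0, seed=42)
        d0 = np.linalg.norm(state.positions[1] - state.positions[0])
        apply_weak_coupling_barostat(state, top, measured_pressure=2000.0, dt=6.0)
        assert np.linalg.norm(state.positions[1] - state.positions[0]) == \
            pytest.approx(d0, abs=1e-9)

    def test_npt_density_plateau(self):
        """A toy NPT water run settles to a stable finite density."""
        top, state = builder.build_box("water", 64, 13.2, seed=43)
        state = minimize_steepest_descent(top, state, 6.0, max_steps=200)
        eng = MDEngine(top, state, MDProtocol(r_cut=6.0, pressure=1.0, seed=6))
        eng.initialize_velocities()
        eng.run(int(20000 / 6))  # 20 ps equilibration
        vols = []
        for k in range(int(20000 / 6)):
            eng.outer_step()
            if k % 5 == 0:
                vols.append(eng.state.volume)
        vols = np.array(vols)
        assert np.isfinite(vols).all() and vols.min() > 0
        assert vols.std() / vols.mean() < 0.05


class TestShake:
    def test_satisfied_constraints_unchanged(self):
        pos = np.array([[0.0, 0, 0], [1.09, 0, 0]])
        out = shake(pos, pos.copy(), [(0, 1, 1.09)], masses=[12.0, 1.0])
        assert np.array_equal(out, pos)

    def test_stretched_diatomic_restored(self):
        pos_old = np.array([[0.0, 0, 0], [1.09, 0, 0]])
        pos_new = np.array([[0.0, 0, 0], [1.09 * 1.01, 0, 0]])
        out = shake(pos_old, pos_new, [(0, 1, 1.09)], masses=[12.0, 1.0],
                    max_iter=10)
        d = np.linalg.norm(out[1] - out[0])
        assert abs(d**2 - 1.09**2) < 1e-8

    def test_constraint_forces_conserve_momentum(self):
        masses = np.array([12.0, 1.0])
        pos_old = np.array([[0.0, 0, 0], [1.09, 0, 0]])
        vel = np.array([[0.01, 0, 0], [-0.02, 0.01, 0]])
        pos_new = pos_old + 2.0 * vel
        out = shake(pos_old, pos_new, [(0, 1, 1.09)], masses=masses)
        p_before = (masses[:, None] * (pos_new - pos_old)).sum(axis=0)
        p_after = (masses[:, None] * (out - pos_old)).sum(axis=0)
        assert np.abs(p_before - p_after).max() < 1e-12

    def test_nonconvergence_names_constraint(self):
        pos_old = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pos_new = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        with pytest.raises(RuntimeError, match="constraint 0"):
            shake(pos_old, pos_new, [(0, 1, 1.0)], masses=[1.0, 1.0], max_iter=1)


class TestDipoleRotation:
    def _single_bead(self):
        top = Topology(specs=[ELBA_WATER])
        state = SystemState(positions=np.full((1, 3), 20.0), box=60.0,
                            orientations=np.array([[1.0, 0.0, 0.0]]))
        return top, state

    def test_zero_torque_zero_omega_unchanged(self):
        top, state = self._single_bead()
        rotate_dipoles(state, top, np.zeros((1, 3)), dt=6.0)
        assert np.array_equal(state.orientations, [[1.0, 0.0, 0.0]])

    def test_norm_preserved_many_steps(self):
        top, state = self._single_bead()
        rng = np.random.default_rng(1)
        for _ in range(10000):
            rotate_dipoles(state, top, rng.normal(size=(1, 3)), dt=6.0)
        assert np.linalg.norm(state.orientations[0]) == pytest.approx(1.0, abs=1e-10)

    def test_free_rotation_period_matches_rigid_rotor(self):
        """With no torque a linear rotor turns uniformly: after one period
        2*pi/omega the orientation returns to its start."""
        top, state = self._single_bead()
        omega = 1e-3  # rad/fs
        state.ang_velocities = np.array([[0.0, 0.0, omega]])
        eng = MDEngine(top, state, MDProtocol(thermostat_tau=None, pressure=None))
        rke0 = eng.kinetic_energy()
        period = 2 * np.pi / omega
        n = int(round(period / 6.0))
        for _ in range(n):
            eng.outer_step()
        # residual angle = omega * (rounding of the period to whole steps)
        expected_angle = omega * (n * 6.0 - period)
        got_angle = np.arctan2(eng.state.orientations[0, 1],
                               eng.state.orientations[0, 0])
        assert got_angle == pytest.approx(expected_angle, abs=1e-9)
        assert eng.kinetic_energy() == pytest.approx(rke0, rel=1e-12)


class TestRunMdOrchestration:
    def test_zero_production_returns_empty_series(self):
        top, state = builder.build_box("water", 20, 12.2, seed=51)
        series, eng = run_md(top, state, MDProtocol(r_cut=6.0, pressure=None,
                                                    seed=7),
                             minimize_steps=50, equilibrate_fs=120.0,
                             produce_fs=0.0)
        assert series.time_fs == []
        assert eng.state.time_fs == pytest.approx(120.0)

    def test_observable_record_count(self):
        top, state = builder.build_box("water", 20, 12.2, seed=51)
        series, _ = run_md(top, state, MDProtocol(r_cut=6.0, pressure=None,
                                                  seed=7),
                           produce_fs=600.0, observe_every_fs=60.0)
        assert len(series.time_fs) == 10
        assert np.all(np.diff(series.time_fs) > 0)

    def test_checkpoint_restart_is_bit_exact(self, tmp_path):
        top, state = builder.build_box("water", 25, 12.4, seed=52)
        proto = MDProtocol(r_cut=6.0, pressure=1.0, seed=8)
        a = MDEngine(top, state.copy(), proto)
        a.initialize_velocities()
        a.run(15)
        cp = tmp_path / "ck.npz"
        a.save_checkpoint(cp)
        a.run(15)
        b = MDEngine(top, state.copy(), proto)
        b.initialize_velocities()
        b.load_checkpoint(cp)
        b.run(15)
        assert np.array_equal(a.state.positions, b.state.positions)
        assert np.array_equal(a.state.velocities, b.state.velocities)
        assert np.array_equal(a.state.orientations, b.state.orientations)


def test_force_blowup_reports_diagnostic():
    spec = ParticleSpec(lj=LJParams(3.5, 5.0), mass=10.0, kind="atom")
    top = Topology(specs=[spec, spec], molecule=np.array([0, 1]))
    state = SystemState(positions=np.array([[20.0, 20, 20], [20.4, 20, 20]]),
                        box=60.0)
    with pytest.raises(RuntimeError, match="blow-up"):
        MDEngine(top, state, MDProtocol(thermostat_tau=None, pressure=None,
                                        force_bound=1e3))
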