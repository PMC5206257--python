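"""Pair potentials: shifted-force contracts, oracles, whole-system sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import (central_difference_force, finite_dipole_charge_energy,
                     finite_dipole_pair_energy)
from hybridsolv import builder
from hybridsolv.forcefield import (CYCLOHEXANE_BOND, BondTerm, LJParams,
                                   OverlapError, ParticleSpec, atom_atom_pair,
                                   charge_dipole_sf, coulomb_sf,
                                   dipole_dipole_sf, harmonic_bond,
                                   lj_shifted_force, lorentz_berthelot,
                                   total_energy_forces)
from hybridsolv.system import SystemState, Topology, minimum_image
from hybridsolv.units import COULOMB_K

RC = 12.0
LJ_A = LJParams(3.2, 0.6)
LJ_B = LJParams(3.8, 1.1)
MU_I = 0.54 * np.array([0.27, 0.94, -0.54]) / np.linalg.norm([0.27, 0.94, -0.54])
MU_J = 0.54 * np.array([-0.64, 0.13, 0.77]) / np.linalg.norm([-0.64, 0.13, 0.77])


def _pair_kinds(r_vec):
    return {
        "lj": lambda d: lj_shifted_force(d, LJ_A, LJ_B, RC),
        "dipole_dipole": lambda d: dipole_dipole_sf(d, MU_I, MU_J, RC),
        "charge_dipole": lambda d: charge_dipole_sf(d, 0.7, MU_J, RC),
        "coulomb": lambda d: coulomb_sf(d, 0.7, -0.4, RC),
    }


@pytest.mark.parametrize("kind", ["lj", "dipole_dipole", "charge_dipole", "coulomb"])
@pytest.mark.parametrize("r", [RC, RC + 3.0])
def test_shifted_force_vanishes_at_and_beyond_cutoff(kind, r):
    res = _pair_kinds(None)[kind](np.array([r, 0.0, 0.0]))
    assert res.energy == 0.0
    assert np.all(res.force_on_i == 0.0)
    assert np.all(res.torque_on_i == 0.0) and np.all(res.torque_on_j == 0.0)


@pytest.mark.parametrize("kind", ["lj", "dipole_dipole", "charge_dipole", "coulomb"])
def test_energy_and_force_continuous_at_cutoff(kind):
    """Approaching the cutoff from inside, the energy vanishes
    quadratically and the force linearly (both continuous -> 0)."""
    f = _pair_kinds(None)[kind]
    e1 = f(np.array([RC - 1e-4, 0.0, 0.0]))
    e2 = f(np.array([RC - 1e-5, 0.0, 0.0]))
    assert abs(e2.energy) < abs(e1.energy) / 50  # ~quadratic approach
    assert np.linalg.norm(e2.force_on_i) < np.linalg.norm(e1.force_on_i) / 5
    assert abs(e2.energy) < 1e-6
    assert np.linalg.norm(e2.force_on_i) < 1e-3


def test_lj_matches_plain_lj_plus_shift_oracle():
    """Cyclohexane self-pair at 4.6 A against an independently coded
    plain-LJ + analytic-shift expression."""
    sigma, eps, r = 4.1, 3.19, 4.6

    def plain(rr):
        return 4 * eps * ((sigma / rr) ** 12 - (sigma / rr) ** 6)

    def dplain(rr):
        return (-48 * eps * (sigma / rr) ** 12 + 24 * eps * (sigma / rr) ** 6) / rr

    expected = plain(r) - plain(RC) - (r - RC) * dplain(RC)
    res = lj_shifted_force([r, 0, 0], LJParams(sigma, eps), LJParams(sigma, eps), RC)
    assert res.energy == pytest.approx(expected, abs=1e-12)
    fd = central_difference_force(
        lambda d: lj_shifted_force(d, LJParams(sigma, eps),
                                   LJParams(sigma, eps), RC).energy,
        np.array([r, 0.0, 0.0]))
    assert np.abs(fd - res.force_on_i).max() < 1e-6


@pytest.mark.parametrize("kind", ["lj", "dipole_dipole", "charge_dipole", "coulomb"])
@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_force_matches_finite_differences(kind, seed):
    """Analytic force equals -grad(E) on randomised separations."""
    rng = np.random.default_rng(seed)
    r_vec = rng.uniform(-1, 1, 3)
    r_vec *= rng.uniform(2.5, RC - 0.5) / np.linalg.norm(r_vec)
    f = _pair_kinds(None)[kind]
    res = f(r_vec)
    fd = central_difference_force(lambda d: f(d).energy, r_vec)
    assert np.abs(fd - res.force_on_i).max() < 1e-6


@pytest.mark.parametrize("kind,pair_fn", [
    ("dipole_dipole", lambda d, mj: dipole_dipole_sf(d, MU_I, mj, RC)),
    ("charge_dipole", lambda d, mj: charge_dipole_sf(d, 0.7, mj, RC)),
])
def test_torque_consistent_with_energy(kind, pair_fn):
    """A small rotation of mu_j changes the energy by -tau . dtheta."""
    r_vec = np.array([3.4, -1.1, 2.2])
    axis = np.array([0.3, -0.5, 0.81])
    axis /= np.linalg.norm(axis)
    th = 1e-6

    def rotate(v):
        return (v * np.cos(th) + np.cross(axis, v) * np.sin(th)
                + axis * (axis @ v) * (1 - np.cos(th)))

    res = pair_fn(r_vec, MU_J)
    de = pair_fn(r_vec, rotate(MU_J)).energy - res.energy
    assert de / th == pytest.approx(-(res.torque_on_j @ axis), abs=1e-5)


def test_dipole_inversion_symmetry():
    r_vec = np.array([4.0, 1.0, -2.0])
    base = dipole_dipole_sf(r_vec, MU_I, MU_J, RC).energy
    both = dipole_dipole_sf(r_vec, -MU_I, -MU_J, RC).energy
    one = dipole_dipole_sf(r_vec, -MU_I, MU_J, RC).energy
    assert both == pytest.approx(base, abs=1e-12)
    # the energy is bilinear in the dipoles, so a single flip negates it
    assert one == pytest.approx(-base, abs=1e-12)


def test_finite_dipole_oracle_converges_to_point_dipole():
    """Four-charge finite dipoles approach the point form at order >= 2."""
    r_vec = np.array([5.0, 0.0, 0.0])
    big_rc = 1e6  # suppress the shift terms: compare the ideal point form
    point = dipole_dipole_sf(r_vec, MU_I, MU_J, big_rc).energy
    err1 = abs(finite_dipole_pair_energy(r_vec, MU_I, MU_J, 0.02) - point)
    err2 = abs(finite_dipole_pair_energy(r_vec, MU_I, MU_J, 0.01) - point)
    assert err2 < 1e-4
    assert err1 / err2 > 3.0  # observed order >= 2


def test_charge_dipole_oracle_and_zero_charge():
    r_vec = np.array([6.0, 0.0, 0.0])
    big_rc = 1e6
    point = charge_dipole_sf(r_vec, 1.0, MU_J, big_rc).energy
    err1 = abs(finite_dipole_charge_energy(r_vec, 1.0, MU_J, 0.02) - point)
    err2 = abs(finite_dipole_charge_energy(r_vec, 1.0, MU_J, 0.01) - point)
    assert err2 < 1e-4
    assert err1 / err2 > 3.0
    zero = charge_dipole_sf(r_vec, 0.0, MU_J, RC)
    assert zero.energy == 0.0 and np.all(zero.force_on_i == 0.0)


def test_atom_atom_pair_reduces_to_lj_and_matches_coulomb_closed_form():
    r_vec = np.array([3.0, 0.0, 0.0])
    lj_only = atom_atom_pair(r_vec, 0.0, 0.0, LJ_A, LJ_B, RC)
    ref = lj_shifted_force(r_vec, LJ_A, LJ_B, RC)
    assert lj_only.energy == ref.energy
    assert np.array_equal(lj_only.force_on_i, ref.force_on_i)

    # +1/-1 e at 3 A with LJ off: shifted-force Coulomb closed form
    off = LJParams(1.0, 0.0)
    r = 3.0
    expected = COULOMB_K * (1.0) * (-1.0) * (1 / r - 1 / RC + (r - RC) / RC**2)
    res = atom_atom_pair(r_vec, 1.0, -1.0, off, off, RC)
    assert res.energy < 0
    assert res.energy == pytest.approx(expected, abs=1e-12)


def test_overlap_raises():
    with pytest.raises(OverlapError):
        lj_shifted_force([0.0, 0.0, 0.0], LJ_A, LJ_B, RC)


def test_lorentz_berthelot():
    c = lorentz_berthelot(LJ_A, LJ_B)
    assert c.sigma == pytest.approx(3.5)
    assert c.epsilon == pytest.approx(np.sqrt(0.6 * 1.1))


def test_harmonic_bond_convention():
    term = CYCLOHEXANE_BOND
    assert harmonic_bond(term.r0, term) == (0.0, 0.0)
    e, f = harmonic_bond(4.15, BondTerm(0, 1, 4.05, 12.69))
    assert e == pytest.approx(12.69 * 0.1**2, abs=1e-12)  # E = k (r-r0)^2
    assert f == pytest.approx(-2 * 12.69 * 0.1, abs=1e-12)
    delta = 0.2
    assert harmonic_bond(term.r0 + delta, term)[0] == pytest.approx(
        harmonic_bond(term.r0 - delta, term)[0], abs=1e-12)


def test_particle_spec_invariants():
    with pytest.raises(ValueError):
        ParticleSpec(lj=LJ_A, charge=0.5, dipole_magnitude=0.5, rot_inertia=1.0)
    with pytest.raises(ValueError):
        ParticleSpec(lj=LJ_A, dipole_magnitude=0.5)  # missing rot_inertia
    with pytest.raises(ValueError):
        LJParams(-1.0, 0.5)


# ---------------------------------------------------------------------------
# whole-system evaluation
# ---------------------------------------------------------------------------

def _mixed_system():
    sol_top, sol_pos = builder.make_toy_solute("constrained_diatomic")
    box_top, box_state = builder.build_box("water", 50, 13.4, seed=11)
    return builder.solvate(sol_top, sol_pos + 6.7, box_top, box_state,
                           clearance=2.6)[:2]


def test_net_force_is_zero_and_components_sum(small_water_box):
    top, state = small_water_box
    ef = total_energy_forces(state, top, r_cut=6.0)
    assert np.abs(ef.forces.sum(axis=0)).max() < 1e-9
    assert ef.total == pytest.approx(sum(ef.components.values()), abs=1e-10)


def test_brute_force_python_oracle_equivalence():
    """The compiled sweep equals a per-pair double loop built from the public
    pair functions, on a mixed CG/atom system."""
    top, state = _mixed_system()
    rc = 6.0
    ef = total_energy_forces(state, top, rc, coupling=0.7)
    arr = top.arrays()
    n = top.n_sites
    forces = np.zeros((n, 3))
    e_by_class = {"solvent_solvent": 0.0, "solute_solvent": 0.0,
                  "solute_internal": 0.0}
    for i in range(n):
        for j in range(i + 1, n):
            if arr.molecule[i] == arr.molecule[j]:
                continue
            d = minimum_image(state.positions[i] - state.positions[j], state.box)
            if np.linalg.norm(d) >= rc:
                continue
            res = lj_shifted_force(d, LJParams(arr.sigma[i], arr.eps[i]),
                                   LJParams(arr.sigma[j], arr.eps[j]), rc)
            e = res.energy
            f = res.force_on_i.copy()
            mi, mj = arr.mu_mag[i], arr.mu_mag[j]
            qi, qj = arr.charge[i], arr.charge[j]
            if mi > 0 and mj > 0:
                el = dipole_dipole_sf(d, mi * state.orientations[i],
                                      mj * state.orientations[j], rc)
                e += el.energy
                f += el.force_on_i
            elif mj > 0 and qi != 0:
                el = charge_dipole_sf(d, qi, mj * state.orientations[j], rc)
                e += el.energy
                f += el.force_on_i
            elif mi > 0 and qj != 0:
                el = charge_dipole_sf(-d, qj, mi * state.orientations[i], rc)
                e += el.energy
                f -= el.force_on_i
            elif qi != 0 and qj != 0:
                el = coulomb_sf(d, qi, qj, rc)
                e += el.energy
                f += el.force_on_i
            mixed = arr.solute[i] != arr.solute[j]
            scale = 0.7 if mixed else 1.0
            if mixed:
                e_by_class["solute_solvent"] += 0.7 * e
            elif arr.solute[i]:
                e_by_class["solute_internal"] += e
            else:
                e_by_class["solvent_solvent"] += e
            forces[i] += scale * f
            forces[j] -= scale * f
    for key, val in e_by_class.items():
        assert ef.components[key] == pytest.approx(val, abs=1e-9)
    assert np.abs(ef.forces - forces).max() < 1e-9


def test_cell_list_equals_brute_force():
    top, state = builder.build_box("water", 200, 36.5, seed=12)
    brute = total_energy_forces(state, top, RC, neighbor="brute")
    cell = total_energy_forces(state, top, RC, neighbor="cell")
    assert cell.total == pytest.approx(brute.total, rel=1e-12)
    assert np.abs(cell.forces - brute.forces).max() < 1e-10


def test_isolated_cyclohexane_molecules_beyond_cutoff():
    top, state = builder.map_cyclohexane_to_cg(
        [np.array([[0, 0, 0], [1.3, 0.8, 0], [2.6, 0, 0],
                   [2.6, -1.5, 0], [1.3, -2.3, 0], [0, -1.5, 0]], float),
         np.array([[0, 0, 20], [1.3, 0.8, 20], [2.6, 0, 20],
                   [2.6, -1.5, 20], [1.3, -2.3, 20], [0, -1.5, 20]], float)],
        box=60.0)
    ef = total_energy_forces(state, top, RC)
    assert ef.components["solvent_solvent"] == 0.0


def test_decoupled_endpoint_exerts_no_forces_on_solvent():
    top, state = _mixed_system()
    ef = total_energy_forces(state, top, 6.0, coupling=0.0)
    solvent = ~top.solute
    bonded_free = np.abs(ef.forces_outer[solvent]) + np.abs(ef.forces_inner[solvent])
    # solvent feels only solvent-solvent terms; compare against a pure box
    assert ef.components["solute_solvent"] == 0.0
    ef_full = total_energy_forces(state, top, 6.0, coupling=1.0)
    assert not np.allclose(ef_full.forces[solvent], ef.forces[solvent])
    # and the decoupled solvent forces equal those with the solute deleted
    solvent_idx = np.where(solvent)[0]
    sub_top = Topology(
        specs=[top.specs[i] for i in solvent_idx],
        molecule=top.molecule[solvent_idx],
    )
    sub_state = SystemState(positions=state.positions[solvent_idx],
                            box=state.box,
                            orientations=state.orientations[solvent_idx])
    sub = total_energy_forces(sub_state, sub_top, 6.0)
    assert np.abs(sub.forces - ef.forces[solvent]).max() < 1e-10


def test_overlapping_sites_reported_with_indices():
    top, _ = builder.build_box("water", 2, 30.0, seed=1)
    state = SystemState(positions=np.array([[5.0, 5, 5], [5.0, 5, 5]]),
                        box=30.0,
                        orientations=np.array([[1.0, 0, 0], [0, 1.0, 0]]))
    with pytest.raises(OverlapError) as exc:
        total_energy_forces(state, top, RC)
    assert exc.value.pair == (0, 1)
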