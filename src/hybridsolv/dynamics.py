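"""Propagation: minimisation, multiple-timestep Langevin dynamics, SHAKE,
dipole rotation and a weak-coupling barostat.

The integrator is an impulse (r-RESPA-style) multiple-timestep scheme: the
slowly varying CG-CG non-bonded forces are applied as impulses every outer
step (``dt_inner * mts_ratio``, 6 fs by default), while all other forces
(solute-solvent, solute internal, bonded) advance with the inner timestep
(2 fs by default) using a BAOAB-splitting Langevin step.  With the friction
set to zero the scheme reduces exactly to impulse-MTS velocity Verlet, and
with ``mts_ratio = 1`` to plain velocity Verlet.

Dipolar beads are linear rotors: the orientation is rotated exactly about
the angular velocity (which is kept perpendicular to the dipole axis), so
free rotation conserves rotational kinetic energy and the unit norm is
preserved by construction.  Solute and solvent are coupled to two separate
Langevin thermostats (independent noise streams, same friction 1/tau).

Temperature and pressure coupling constants default to 6 ps; the barostat is
the weak-coupling (Berendsen) scheme with molecule-centre scaling, so
constrained intramolecular geometry is never distorted by the box scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .forcefield import total_energy_forces
from .system import SystemState, Topology, minimum_image
from .units import KB, MVV_TO_KJMOL, PRESSURE_TO_ATM, maxwell_sigma

__all__ = ["MDProtocol", "MDEngine", "ObservableSeries",
           "minimize_steepest_descent", "shake", "rotate_dipoles",
           "apply_weak_coupling_barostat", "run_md"]

_ACC = 1.0 / MVV_TO_KJMOL  # (kJ/mol/A)/(g/mol) -> A/fs^2


@dataclass
class MDProtocol:
    """Integration and coupling parameters.

    dt_inner (fs) and mts_ratio define the timestep split (defaults 2 fs and
    3, i.e. a 6 fs outer step).  ``thermostat_tau``/``barostat_tau`` are in
    ps; ``thermostat_tau = None`` disables the thermostat (NVE), and
    ``pressure = None`` disables the barostat.
    """

    dt_inner: float = 2.0
    mts_ratio: int = 3
    temperature: float = 298.0
    thermostat_tau: float | None = 6.0
    pressure: float | None = 1.0
    barostat_tau: float = 6.0
    compressibility: float = 4.5e-5  # atm^-1, water-like
    r_cut: float = 12.0
    seed: int = 0
    shake_tol: float = 1e-8
    shake_max_iter: int = 500
    force_bound: float = 1.0e6

    def __post_init__(self):
        if self.dt_inner <= 0:
            raise ValueError("dt_inner must be positive")
        if self.mts_ratio < 1:
            raise ValueError("mts_ratio must be >= 1")
        if self.thermostat_tau is not None and self.thermostat_tau <= 0:
            raise ValueError("thermostat_tau must be positive")
        if self.barostat_tau <= 0:
            raise ValueError("barostat_tau must be positive")

    @property
    def dt_outer(self) -> float:
        return self.dt_inner * self.mts_ratio


@dataclass
class ObservableSeries:
    """Per-interval records of the usual thermodynamic observables."""

    time_fs: list = field(default_factory=list)
    potential: list = field(default_factory=list)
    components: list = field(default_factory=list)
    kinetic: list = field(default_factory=list)
    temperature: list = field(default_factory=list)
    temperature_rot: list = field(default_factory=list)
    pressure_atm: list = field(default_factory=list)
    volume: list = field(default_factory=list)
    u_solute_solvent_raw: list = field(default_factory=list)

    def append(self, **kw):
        for k, v in kw.items():
            getattr(self, k).append(v)

    def to_frame(self):
        import pandas as pd
        d = asdict(self)
        comps = d.pop("components")
        df = pd.DataFrame(d)
        if comps:
            for key in comps[0]:
                df["e_" + key] = [c[key] for c in comps]
        return df

    def write_tsv(self, path, header_lines=()):
        df = self.to_frame()
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)


def shake(positions_before, positions_after, constraints, masses,
          box=None, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """SHAKE: project ``positions_after`` onto the constraint manifold.

    Corrections act along the pre-step constraint vectors; each constraint is
    satisfied to |d^2 - d0^2| < tol (A^2).  Raises on non-convergence,
    naming the worst constraint.
    """
    pos = np.array(positions_after, dtype=float)
    old = np.ascontiguousarray(positions_before, dtype=float)
    if box is None:
        box = np.full(3, 1e12)
    box = np.ascontiguousarray(box, dtype=float)
    con = list(constraints)
    if not con:
        return pos
    ci = np.array([c[0] for c in con], dtype=np.int64)
    cj = np.array([c[1] for c in con], dtype=np.int64)
    cd = np.array([c[2] for c in con], dtype=float)
    inv_m = 1.0 / np.asarray(masses, dtype=float)
    n_it, worst, ok = _kernels.shake_kernel(pos, old, box, ci, cj, cd,
                                            inv_m, tol, max_iter)
    if not ok:
        raise RuntimeError(
            f"SHAKE did not converge in {max_iter} iterations; worst "
            f"constraint {worst}: sites ({ci[worst]}, {cj[worst]})")
    return pos


def _rattle_velocities(vel, pos, constraints, masses, box):
    """Remove relative velocity components along constrained bonds."""
    for i, j, _d in constraints:
        d = minimum_image(pos[i] - pos[j], box)
        d2 = float(d @ d)
        mu = 1.0 / (1.0 / masses[i] + 1.0 / masses[j])
        g = float((vel[i] - vel[j]) @ d) * mu / d2
        vel[i] -= g / masses[i] * d
        vel[j] += g / masses[j] * d


def _rodrigues(u, axis_omega, dt):
    """Rotate unit vectors u about axis_omega by |omega| dt (vectorised)."""
    w = np.linalg.norm(axis_omega, axis=1)
    out = u.copy()
    act = w > 0
    if not np.any(act):
        return out
    k = axis_omega[act] / w[act, None]
    th = w[act] * dt
    c = np.cos(th)[:, None]
    s = np.sin(th)[:, None]
    ua = u[act]
    out[act] = ua * c + np.cross(k, ua) * s + k * (np.sum(k * ua, axis=1, keepdims=True)) * (1 - c)
    # renormalise against accumulated round-off
    out[act] /= np.linalg.norm(out[act], axis=1, keepdims=True)
    return out


def rotate_dipoles(state: SystemState, topology: Topology, torques,
                   dt: float) -> None:
    """Kick angular velocities by the torques over dt, then rotate.

    Linear-rotor update: omega += dt * torque / I (components parallel to the
    dipole axis are projected out), followed by exact rotation of the
    orientation about omega.  Orientations stay unit vectors; with zero
    torque the rotational kinetic energy is conserved exactly.
    """
    arr = topology.arrays()
    dip = arr.dipolar
    if not np.any(dip):
        return
    w = state.ang_velocities
    w[dip] += dt * _ACC * torques[dip] / arr.inertia[dip, None]
    u = state.orientations
    w[dip] -= u[dip] * np.sum(w[dip] * u[dip], axis=1, keepdims=True)
    state.orientations[dip] = _rodrigues(u[dip], w[dip], dt)


def apply_weak_coupling_barostat(state: SystemState, topology: Topology,
                                 measured_pressure: float, dt: float,
                                 target_pressure: float = 1.0,
                                 tau_ps: float = 6.0,
                                 compressibility: float = 4.5e-5) -> float:
    """One weak-coupling barostat update; returns the scaling factor mu.

    mu = [1 - (dt/tau) kappa (P0 - P)]^(1/3); the box and the molecule
    centres are scaled isotropically, leaving intramolecular geometry intact.
    """
    tau_fs = tau_ps * 1000.0
    mu = (1.0 - (dt / tau_fs) * compressibility
          * (target_pressure - measured_pressure)) ** (1.0 / 3.0)
    mol = topology.molecule
    pos = state.positions
    box = state.box
    if topology.n_sites == len(np.unique(mol)):
        pos *= mu  # all single-site molecules
    else:
        for m in np.unique(mol):
            idx = np.where(mol == m)[0]
            ref = pos[idx[0]]
            rel = minimum_image(pos[idx] - ref, box)
            centre = ref + rel.mean(axis=0)
            pos[idx] += (mu - 1.0) * centre
    state.box *= mu
    return float(mu)


class MDEngine:
    """Multiple-timestep stochastic-dynamics propagator.

    Holds the mutable simulation state, the current force evaluation and the
    random streams.  ``coupling`` scales all solute-solvent non-bonded terms
    (the f(lambda) of a thermodynamic-integration window; 1 = fully coupled).
    One counter-based random stream is spawned per purpose (initial
    velocities, solvent thermostat, solute thermostat, rotational
    thermostat), so repeat simulations differ only through the seed.
    """

    def __init__(self, topology: Topology, state: SystemState,
                 protocol: MDProtocol, coupling: float = 1.0):
        self.top = topology
        self.state = state
        self.protocol = protocol
        self.coupling = float(coupling)
        self.arr = topology.arrays()
        n = topology.n_sites
        self._mass = self.arr.mass[:, None]
        dip = self.arr.dipolar
        self._dip = dip
        self._inertia = np.where(dip, self.arr.inertia, 1.0)[:, None]
        self._solute_mask = self.arr.solute
        self._pairs_all = _kernels.all_pairs(n)
        cgcg = (self.arr.cg[self._pairs_all[:, 0]]
                & self.arr.cg[self._pairs_all[:, 1]])
        self._pairs_inner = np.ascontiguousarray(self._pairs_all[~cgcg])
        self._has_inner_nb = self._pairs_inner.shape[0] > 0
        self._has_bonds = self.arr.bond_i.size > 0
        self._constraints = topology.constraints
        ss = np.random.SeedSequence(protocol.seed)
        kids = ss.spawn(4)
        self._rng_init = np.random.Generator(np.random.Philox(kids[0]))
        self._rng_solvent = np.random.Generator(np.random.Philox(kids[1]))
        self._rng_solute = np.random.Generator(np.random.Philox(kids[2]))
        self._rng_rot = np.random.Generator(np.random.Philox(kids[3]))
        state.validate(topology)
        self.n_outer_steps = 0
        self._full_eval()

    # ------------------------------------------------------------------
    @property
    def n_dof_trans(self) -> int:
        return 3 * self.top.n_sites - len(self._constraints)

    @property
    def n_dof_rot(self) -> int:
        return 2 * int(self._dip.sum())

    def initialize_velocities(self, temperature: float | None = None) -> None:
        t = self.protocol.temperature if temperature is None else temperature
        n = self.top.n_sites
        sig = maxwell_sigma(self.arr.mass, t)[:, None]
        self.state.velocities = sig * self._rng_init.normal(size=(n, 3))
        self.state.velocities -= self.state.velocities.mean(axis=0)
        w = np.zeros((n, 3))
        if np.any(self._dip):
            sigr = np.sqrt(KB * t / (self.arr.inertia[self._dip] * MVV_TO_KJMOL))[:, None]
            w[self._dip] = sigr * self._rng_init.normal(size=(int(self._dip.sum()), 3))
            u = self.state.orientations[self._dip]
            w[self._dip] -= u * np.sum(w[self._dip] * u, axis=1, keepdims=True)
        self.state.ang_velocities = w
        if self._constraints:
            _rattle_velocities(self.state.velocities, self.state.positions,
                               self._constraints, self.arr.mass, self.state.box)

    # ------------------------------------------------------------------
    def kinetic_temperature(self, group: str = "all") -> float:
        if group == "all":
            mask = np.ones(self.top.n_sites, dtype=bool)
            dof = self.n_dof_trans
        elif group == "solute":
            mask = self._solute_mask
            dof = 3 * int(mask.sum()) - len(self._constraints)
        else:
            mask = ~self._solute_mask
            dof = 3 * int(mask.sum())
        if dof == 0:
            return 0.0
        ke = 0.5 * MVV_TO_KJMOL * float(
            np.sum(self.arr.mass[mask, None] * self.state.velocities[mask] ** 2))
        return 2.0 * ke / (dof * KB)

    def rotational_temperature(self) -> float:
        if self.n_dof_rot == 0:
            return 0.0
        ke = 0.5 * MVV_TO_KJMOL * float(
            np.sum(self._inertia[self._dip] * self.state.ang_velocities[self._dip] ** 2))
        return 2.0 * ke / (self.n_dof_rot * KB)

    def kinetic_energy(self) -> float:
        ke = 0.5 * MVV_TO_KJMOL * float(np.sum(self._mass * self.state.velocities**2))
        ke += 0.5 * MVV_TO_KJMOL * float(
            np.sum(self._inertia[self._dip] * self.state.ang_velocities[self._dip] ** 2))
        return ke

    def total_energy(self) -> float:
        return self.kinetic_energy() + self.energies.total

    def pressure(self) -> float:
        """Instantaneous pressure (atm) from the pairwise virial."""
        ke2 = MVV_TO_KJMOL * float(np.sum(self._mass * self.state.velocities**2))
        p_int = (ke2 + self.energies.virial) / (3.0 * self.state.volume)
        return p_int * PRESSURE_TO_ATM

    # ------------------------------------------------------------------
    def _inner_forces(self):
        st, arr = self.state, self.arr
        n = self.top.n_sites
        if self._has_inner_nb:
            out = _kernels.nonbonded_sweep(
                self._pairs_inner, st.positions, st.box, arr.sigma, arr.eps,
                arr.charge, arr.mu_mag, st.orientations, arr.molecule,
                arr.solute, arr.cg, self.protocol.r_cut, self.coupling)
            f_in = out[4] + out[5]
            t_in = out[6] + out[7]
        else:
            f_in = np.zeros((n, 3))
            t_in = np.zeros((n, 3))
        if self._has_bonds:
            _kernels.bonded_sweep(st.positions, st.box, arr.bond_i, arr.bond_j,
                                  arr.bond_r0, arr.bond_k, f_in)
        return f_in, t_in

    def _full_eval(self):
        from .forcefield import evaluate_pairs
        self.energies = evaluate_pairs(self._pairs_all, self.state, self.top,
                                       self.protocol.r_cut, self.coupling)
        fmax = float(np.abs(self.energies.forces).max()) if self.top.n_sites else 0.0
        if not np.isfinite(self.energies.total) or fmax > self.protocol.force_bound:
            raise RuntimeError(
                f"force blow-up (max |F| = {fmax:.3g} kJ/mol/A) at t = "
                f"{self.state.time_fs} fs; reduce the timestep or re-minimise")

    def _kick(self, forces, torques, dt):
        self.state.velocities += dt * _ACC * forces / self._mass
        if np.any(self._dip):
            w = self.state.ang_velocities
            w[self._dip] += dt * _ACC * torques[self._dip] / self._inertia[self._dip]
            u = self.state.orientations[self._dip]
            w[self._dip] -= u * np.sum(w[self._dip] * u, axis=1, keepdims=True)

    def _drift(self, dt):
        st = self.state
        if self._constraints:
            old = st.positions.copy()
            st.positions = st.positions + dt * st.velocities
            corrected = shake(old, st.positions, self._constraints,
                              self.arr.mass, st.box, self.protocol.shake_tol,
                              self.protocol.shake_max_iter)
            st.velocities += (corrected - st.positions) / dt
            st.positions = corrected
        else:
            st.positions += dt * st.velocities
        if np.any(self._dip):
            st.orientations[self._dip] = _rodrigues(
                st.orientations[self._dip], st.ang_velocities[self._dip], dt)

    def _o_step(self, dt):
        tau = self.protocol.thermostat_tau
        if tau is None:
            return
        gamma = 1.0 / (tau * 1000.0)
        c1 = np.exp(-gamma * dt)
        t = self.protocol.temperature
        v = self.state.velocities
        c2 = np.sqrt((1.0 - c1 * c1) * KB * t / (self.arr.mass * MVV_TO_KJMOL))[:, None]
        sol = self._solute_mask
        if np.any(~sol):
            v[~sol] = c1 * v[~sol] + c2[~sol] * self._rng_solvent.normal(
                size=(int((~sol).sum()), 3))
        if np.any(sol):
            v[sol] = c1 * v[sol] + c2[sol] * self._rng_solute.normal(
                size=(int(sol.sum()), 3))
        if np.any(self._dip):
            w = self.state.ang_velocities
            c2r = np.sqrt((1.0 - c1 * c1) * KB * t
                          / (self.arr.inertia[self._dip] * MVV_TO_KJMOL))[:, None]
            w[self._dip] = c1 * w[self._dip] + c2r * self._rng_rot.normal(
                size=(int(self._dip.sum()), 3))
            u = self.state.orientations[self._dip]
            w[self._dip] -= u * np.sum(w[self._dip] * u, axis=1, keepdims=True)
        if self._constraints:
            _rattle_velocities(v, self.state.positions, self._constraints,
                               self.arr.mass, self.state.box)

    # ------------------------------------------------------------------
    def outer_step(self) -> None:
        """One impulse-MTS cycle of length dt_outer."""
        p = self.protocol
        st, arr = self.state, self.arr
        dt_o, dt_i = p.dt_outer, p.dt_inner
        half_i = 0.5 * dt_i
        n = self.top.n_sites
        self._kick(self.energies.forces_outer, self.energies.torques_outer,
                   0.5 * dt_o)
        do_thermo = p.thermostat_tau is not None
        if do_thermo:
            c1 = float(np.exp(-dt_i / (p.thermostat_tau * 1000.0)))
            noise_t = np.empty((p.mts_ratio, n, 3))
            sol = self._solute_mask
            if np.any(~sol):
                noise_t[:, ~sol] = self._rng_solvent.normal(
                    size=(p.mts_ratio, int((~sol).sum()), 3))
            if np.any(sol):
                noise_t[:, sol] = self._rng_solute.normal(
                    size=(p.mts_ratio, int(sol.sum()), 3))
            if np.any(self._dip):
                noise_r = np.zeros((p.mts_ratio, n, 3))
                noise_r[:, self._dip] = self._rng_rot.normal(
                    size=(p.mts_ratio, int(self._dip.sum()), 3))
            else:
                noise_r = np.zeros((p.mts_ratio, n, 3))
        else:
            c1 = 1.0
            noise_t = np.zeros((1, n, 3))
            noise_r = np.zeros((1, n, 3))
        f_in = self.energies.forces_inner.copy()
        t_in = self.energies.torques_inner.copy()
        _kernels.inner_loop(
            st.positions, st.velocities, st.orientations, st.ang_velocities,
            st.box, arr.sigma, arr.eps, arr.charge, arr.mu_mag, arr.molecule,
            arr.solute, arr.cg, arr.mass, self._inertia[:, 0], self._dip,
            self._pairs_inner, arr.bond_i, arr.bond_j, arr.bond_r0,
            arr.bond_k, arr.con_i, arr.con_j, arr.con_d, p.shake_tol,
            p.shake_max_iter, p.r_cut, self.coupling, p.mts_ratio, dt_i,
            do_thermo, c1, KB * p.temperature, noise_t, noise_r, f_in, t_in)
        self._full_eval()
        self._kick(self.energies.forces_inner, self.energies.torques_inner,
                   half_i)                          # final inner B
        self._kick(self.energies.forces_outer, self.energies.torques_outer,
                   0.5 * dt_o)
        self.state.time_fs += dt_o
        self.n_outer_steps += 1
        if p.pressure is not None:
            mu = apply_weak_coupling_barostat(
                self.state, self.top, self.pressure(), dt_o, p.pressure,
                p.barostat_tau, p.compressibility)
            if abs(mu - 1.0) > 1e-12:
                self._full_eval()

    def run(self, n_outer: int, observe_every: int = 0,
            series: ObservableSeries | None = None) -> ObservableSeries:
        """Run ``n_outer`` outer cycles, recording every ``observe_every``."""
        if series is None:
            series = ObservableSeries()
        for step in range(n_outer):
            self.outer_step()
            if observe_every and (step + 1) % observe_every == 0:
                self.observe(series)
        return series

    def observe(self, series: ObservableSeries) -> None:
        series.append(
            time_fs=self.state.time_fs,
            potential=self.energies.total,
            components=dict(self.energies.components),
            kinetic=self.kinetic_energy(),
            temperature=self.kinetic_temperature(),
            temperature_rot=self.rotational_temperature(),
            pressure_atm=self.pressure(),
            volume=self.state.volume,
            u_solute_solvent_raw=self.energies.u_solute_solvent_raw,
        )

    # ------------------------------------------------------------------
    def set_coupling(self, coupling: float) -> None:
        self.coupling = float(coupling)
        self._full_eval()

    # -------------------------- checkpointing -------------------------
    def save_checkpoint(self, path) -> None:
        st = self.state
        rngs = [self._rng_init, self._rng_solvent, self._rng_solute, self._rng_rot]
        states = json.dumps([_rng_state_to_jsonable(g) for g in rngs])
        np.savez(path, positions=st.positions, box=st.box,
                 orientations=st.orientations, velocities=st.velocities,
                 ang_velocities=st.ang_velocities, time_fs=st.time_fs,
                 n_outer=self.n_outer_steps, coupling=self.coupling,
                 rng_states=np.array(states))

    def load_checkpoint(self, path) -> None:
        data = np.load(path if str(path).endswith(".npz") else f"{path}.npz",
                       allow_pickle=False)
        st = self.state
        st.positions = data["positions"].copy()
        st.box = data["box"].copy()
        st.orientations = data["orientations"].copy()
        st.velocities = data["velocities"].copy()
        st.ang_velocities = data["ang_velocities"].copy()
        st.time_fs = float(data["time_fs"])
        self.n_outer_steps = int(data["n_outer"])
        self.coupling = float(data["coupling"])
        rngs = [self._rng_init, self._rng_solvent, self._rng_solute, self._rng_rot]
        for g, s in zip(rngs, json.loads(str(data["rng_states"]))):
            _rng_state_from_jsonable(g, s)
        self._full_eval()


def _rng_state_to_jsonable(gen: np.random.Generator):
    def conv(o):
        if isinstance(o, dict):
            return {k: conv(v) for k, v in o.items()}
        if isinstance(o, np.ndarray):
            return {"__nd__": o.tolist(), "dtype": str(o.dtype)}
        if isinstance(o, (np.integer,)):
            return int(o)
        return o
    return conv(gen.bit_generator.state)


def _rng_state_from_jsonable(gen: np.random.Generator, state):
    def conv(o):
        if isinstance(o, dict) and "__nd__" in o:
            return np.array(o["__nd__"], dtype=o["dtype"])
        if isinstance(o, dict):
            return {k: conv(v) for k, v in o.items()}
        return o
    gen.bit_generator.state = conv(state)


# ---------------------------------------------------------------------------
def minimize_steepest_descent(topology: Topology, state: SystemState,
                              r_cut: float, max_steps: int = 1000,
                              initial_step: float = 0.2,
                              tolerance: float = 1.0,
                              coupling: float = 1.0) -> SystemState:
    """Steepest-descent minimisation with an adaptive step length.

    Sites move along the force direction (largest displacement =
    current step length); dipoles rotate along their torques analogously.
    A step is accepted only if the energy does not increase, so the energy
    is non-increasing across accepted steps; stops when the maximum force
    falls below ``tolerance`` (kJ/mol/A) or after ``max_steps``.
    """
    state = state.copy()
    arr = topology.arrays()
    ef = total_energy_forces(state, topology, r_cut, coupling)
    if not np.isfinite(ef.total):
        raise RuntimeError("non-finite energy at minimisation entry "
                           "(overlapping sites?)")
    step = initial_step
    dip = arr.dipolar
    for _ in range(max_steps):
        fmax = float(np.abs(ef.forces).max()) if topology.n_sites else 0.0
        tmax = float(np.abs(ef.torques).max()) if np.any(dip) else 0.0
        if max(fmax, tmax) < tolerance:
            break
        scale = step / max(fmax, 1e-30)
        trial = state.copy()
        trial.positions = state.positions + scale * ef.forces
        if topology.constraints:
            trial.positions = shake(state.positions, trial.positions,
                                    topology.constraints, arr.mass, state.box)
        if tmax > 0:
            ang = ef.torques[dip] * (step / max(tmax, 1e-30)) * 0.5
            trial.orientations[dip] = _rodrigues(state.orientations[dip], ang, 1.0)
        ef_trial = total_energy_forces(trial, topology, r_cut, coupling)
        if np.isfinite(ef_trial.total) and ef_trial.total <= ef.total:
            state, ef = trial, ef_trial
            step = min(step * 1.2, 1.0)
        else:
            step *= 0.5
            if step < 1e-10:
                break
    return state


def run_md(topology: Topology, state: SystemState, protocol: MDProtocol,
           minimize_steps: int = 0, equilibrate_fs: float = 0.0,
           produce_fs: float = 0.0, observe_every_fs: float = 60.0,
           coupling: float = 1.0):
    """Minimise / equilibrate / produce in one call.

    Returns ``(ObservableSeries, MDEngine)``; the series covers only the
    production phase, at intervals of ``observe_every_fs`` (rounded to whole
    outer steps, minimum one).
    """
    if minimize_steps:
        state = minimize_steepest_descent(topology, state, protocol.r_cut,
                                          max_steps=minimize_steps,
                                          coupling=coupling)
    engine = MDEngine(topology, state, protocol, coupling)
    engine.initialize_velocities()
    if equilibrate_fs > 0:
        engine.run(int(round(equilibrate_fs / protocol.dt_outer)))
    series = ObservableSeries()
    if produce_fs > 0:
        every = max(1, int(round(observe_every_fs / protocol.dt_outer)))
        engine.run(int(round(produce_fs / protocol.dt_outer)), every, series)
    return series, engine
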