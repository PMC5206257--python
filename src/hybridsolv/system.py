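"""Topology and dynamic state containers.

A :class:`Topology` is the static description of a system (per-site
parameters, bonds, holonomic constraints, molecule membership, solute/solvent
role); a :class:`SystemState` holds everything that evolves in time
(positions, dipole orientations, velocities, angular velocities, the periodic
box).  Both are plain array-backed containers; all physics lives in
:mod:`hybridsolv.forcefield` and :mod:`hybridsolv.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from .forcefield import BondTerm, ParticleSpec


@dataclass
class Topology:
    """Static system description.

    ``molecule[i]`` is the molecule id of site i; ``solute[i]`` tags solute
    sites (solvent otherwise).  ``constraints`` are (i, j, distance) triples
    enforced by SHAKE rather than by a bond potential.
    """

    specs: list[ParticleSpec]
    bonds: list[BondTerm] = field(default_factory=list)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)
    molecule: np.ndarray = None
    solute: np.ndarray = None

    def __post_init__(self):
        n = len(self.specs)
        if self.molecule is None:
            self.molecule = np.arange(n, dtype=np.int64)
        self.molecule = np.asarray(self.molecule, dtype=np.int64)
        if self.solute is None:
            self.solute = np.zeros(n, dtype=bool)
        self.solute = np.asarray(self.solute, dtype=bool)
        if self.molecule.shape != (n,) or self.solute.shape != (n,):
            raise ValueError("molecule / solute arrays must have one entry per site")
        for i, j, d in self.constraints:
            if d <= 0:
                raise ValueError(f"constraint ({i},{j}) has non-positive distance {d}")
        for b in self.bonds:
            if not (0 <= b.site_i < n and 0 <= b.site_j < n):
                raise ValueError("bond site index out of range")
        self._arrays = None

    @property
    def n_sites(self) -> int:
        return len(self.specs)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule))

    def arrays(self) -> SimpleNamespace:
        """Flat per-site parameter arrays (cached)."""
        if self._arrays is None:
            s = self.specs
            self._arrays = SimpleNamespace(
                sigma=np.array([p.lj.sigma for p in s]),
                eps=np.array([p.lj.epsilon for p in s]),
                charge=np.array([p.charge for p in s]),
                mu_mag=np.array([p.dipole_magnitude for p in s]),
                mass=np.array([p.mass for p in s]),
                inertia=np.array([p.rot_inertia for p in s]),
                cg=np.array([p.is_cg for p in s]),
                solute=self.solute.copy(),
                molecule=self.molecule.copy(),
                dipolar=np.array([p.dipole_magnitude > 0 for p in s]),
                bond_i=np.array([b.site_i for b in self.bonds], dtype=np.int64),
                bond_j=np.array([b.site_j for b in self.bonds], dtype=np.int64),
                bond_r0=np.array([b.r0 for b in self.bonds]),
                bond_k=np.array([b.k for b in self.bonds]),
                con_i=np.array([c[0] for c in self.constraints], dtype=np.int64),
                con_j=np.array([c[1] for c in self.constraints], dtype=np.int64),
                con_d=np.array([c[2] for c in self.constraints]),
            )
        return self._arrays

    def merge(self, other: "Topology") -> "Topology":
        """Concatenate two topologies (self first); indices are re-offset."""
        off = self.n_sites
        mol_off = int(self.molecule.max()) + 1 if self.n_sites else 0
        bonds = list(self.bonds) + [
            BondTerm(b.site_i + off, b.site_j + off, b.r0, b.k) for b in other.bonds]
        cons = list(self.constraints) + [
            (i + off, j + off, d) for i, j, d in other.constraints]
        return Topology(
            specs=list(self.specs) + list(other.specs),
            bonds=bonds,
            constraints=cons,
            molecule=np.concatenate([self.molecule, other.molecule + mol_off]),
            solute=np.concatenate([self.solute, other.solute]),
        )


@dataclass
class SystemState:
    """Dynamic state: positions/velocities, dipole orientations, box.

    ``orientations`` are unit vectors for dipolar sites and zero rows
    otherwise; angular velocities live in the lab frame and are kept
    perpendicular to the orientation (linear rotor).
    """

    positions: np.ndarray
    box: np.ndarray
    orientations: np.ndarray = None
    velocities: np.ndarray = None
    ang_velocities: np.ndarray = None
    time_fs: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        n = self.positions.shape[0]
        self.box = np.ascontiguousarray(np.broadcast_to(np.asarray(self.box, dtype=float), (3,)).copy())
        if self.orientations is None:
            self.orientations = np.zeros((n, 3))
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        if self.ang_velocities is None:
            self.ang_velocities = np.zeros((n, 3))
        for name in ("orientations", "velocities", "ang_velocities"):
            arr = np.ascontiguousarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
            setattr(self, name, arr)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def validate(self, topology: Topology, r_cut: float | None = None) -> None:
        dip = topology.arrays().dipolar
        if dip.any():
            norms = np.linalg.norm(self.orientations[dip], axis=1)
            if not np.allclose(norms, 1.0, atol=1e-10):
                raise ValueError("dipole orientations must be unit vectors")
        if r_cut is not None and np.any(self.box < 2 * r_cut):
            raise ValueError(
                f"box {self.box} too small for minimum-image cutoff {r_cut}")

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(), box=self.box.copy(),
            orientations=self.orientations.copy(),
            velocities=self.velocities.copy(),
            ang_velocities=self.ang_velocities.copy(),
            time_fs=self.time_fs)

    def wrap(self) -> None:
        """Wrap coordinates into [0, box) per dimension."""
        self.positions %= self.box


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement(s) for an orthorhombic box."""
    return d - box * np.rint(d / box)
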