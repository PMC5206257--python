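"""Site parameters and pair interactions for the hybrid AA/CG force field.

The solvent is represented with the Elba coarse-grained models: a water
molecule is a single Lennard-Jones bead carrying an embedded point dipole (a
Stockmayer particle), and a cyclohexane molecule is three bonded, uncharged
Lennard-Jones beads.  Solutes are all-atom sites with Lennard-Jones parameters
and fixed point charges.

All truncated non-bonded interactions use the shifted-force construction

    U_sf(r) = U(r) - U(r_c) - (r - r_c) U'(r_c)        for r < r_c,

applied to each radial kernel of the multipole expansion, so that both the
energy and the force go continuously to zero at the cutoff.  Three
electrostatic pair kinds exist:

* dipole-dipole   (CG bead vs CG bead),
* charge-dipole   (atom vs CG bead),
* charge-charge   (atom vs atom; a shifted-force Coulomb term is used in
  place of a reciprocal-space mesh sum, which is adequate for the neutral
  solutes and desk-scale systems this package targets).

Sign conventions: for a pair (i, j) the displacement is ``r_vec = r_i - r_j``
and the returned force acts on site i; the force on j is its negative.
Torques act on whichever sites carry a dipole and are not antisymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import COULOMB_K, DEBYE_TO_EA

__all__ = [
    "LJParams",
    "ParticleSpec",
    "BondTerm",
    "PairResult",
    "OverlapError",
    "lorentz_berthelot",
    "lj_shifted_force",
    "dipole_dipole_sf",
    "charge_dipole_sf",
    "coulomb_sf",
    "atom_atom_pair",
    "harmonic_bond",
    "total_energy_forces",
    "EnergyForces",
    "ELBA_WATER",
    "CYCLOHEXANE_BEAD",
    "CYCLOHEXANE_BOND",
]


class OverlapError(ValueError):
    """Two interaction sites coincide (zero separation)."""

    def __init__(self, i=None, j=None):
        pair = f" between sites {i} and {j}" if i is not None else ""
        super().__init__(f"overlapping sites{pair}: |r| = 0")
        self.pair = (i, j)


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones parameters: sigma in A, epsilon in kJ/mol."""

    sigma: float
    epsilon: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")


@dataclass(frozen=True)
class ParticleSpec:
    """Physical parameters of one interaction site.

    A site is exactly one of: a Stockmayer bead (``dipole_magnitude > 0``), a
    charged atom (``charge != 0``), or a neutral Lennard-Jones site.  Dipolar
    beads need a rotational inertia (g/mol A^2) for their orientational
    dynamics.  ``kind`` tags the site for the interaction dispatch:
    ``cg_water`` and ``cg_cyclohexane`` sites are coarse-grained, ``atom``
    sites are all-atom.
    """

    lj: LJParams
    charge: float = 0.0
    dipole_magnitude: float = 0.0  # e*A
    mass: float = 1.0
    rot_inertia: float = 0.0
    kind: str = "atom"
    name: str = ""

    def __post_init__(self):
        if self.dipole_magnitude > 0 and self.charge != 0:
            raise ValueError("a site carries either a point dipole or a point charge, not both")
        if self.dipole_magnitude > 0 and self.rot_inertia <= 0:
            raise ValueError("dipolar sites need rot_inertia > 0")
        if self.kind not in ("cg_water", "cg_cyclohexane", "atom"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def is_cg(self) -> bool:
        return self.kind.startswith("cg_")


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond  E = k (r - r0)^2  (note: no 1/2 factor).

    The force-constant convention (no 1/2) follows the simulator the
    coarse-grained solvent models were parameterised for; the cyclohexane
    value 1269 kJ/mol/nm^2 converts to 12.69 kJ/mol/A^2 (see
    ``CYCLOHEXANE_BOND``).
    """

    site_i: int
    site_j: int
    r0: float  # A
    k: float   # kJ/mol/A^2

    def __post_init__(self):
        if self.site_i == self.site_j:
            raise ValueError("bond must join two distinct sites")
        if self.r0 <= 0:
            raise ValueError("bond length must be positive")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")


@dataclass
class PairResult:
    """Energy (kJ/mol), force on site i (kJ/mol/A) and torques (kJ/mol)."""

    energy: float
    force_on_i: np.ndarray
    torque_on_i: np.ndarray = field(default_factory=lambda: np.zeros(3))
    torque_on_j: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def force_on_j(self) -> np.ndarray:
        return -self.force_on_i


# ---------------------------------------------------------------------------
# Packaged solvent parameters.
#
# Cyclohexane: three bonded LJ beads; sigma/epsilon are the lipid-tail bead
# values scaled by 0.9 (sigma = 4.1 A, eps = 3.19 kJ/mol), bond r0 = 4.05 A
# with k = 1269 kJ/mol/nm^2 = 12.69 kJ/mol/A^2 in the E = k(r-r0)^2
# convention.
#
# Water: Stockmayer bead.  sigma, epsilon, the dipole moment and the
# rotational inertia are ordinary configurable parameters; the defaults
# below follow the published Elba water model (LJ sigma 3.05 A, epsilon
# 0.55 kcal/mol, dipole 2.6 D).  The rotational inertia is a model parameter
# of the bead, not of real water; the default favours smooth integration at
# a 6 fs outer timestep.
# ---------------------------------------------------------------------------

ELBA_WATER = ParticleSpec(
    lj=LJParams(sigma=3.05, epsilon=0.55 * 4.184),
    dipole_magnitude=2.6 * DEBYE_TO_EA,
    mass=18.01528,
    rot_inertia=4.0,
    kind="cg_water",
    name="W",
)

CYCLOHEXANE_BEAD = ParticleSpec(
    lj=LJParams(sigma=4.1, epsilon=3.19),
    mass=84.15948 / 3.0,
    kind="cg_cyclohexane",
    name="CHX",
)

#: Bond between two cyclohexane beads (r0 = 0.405 nm, k = 1269 kJ/mol/nm^2).
CYCLOHEXANE_BOND = BondTerm(site_i=0, site_j=1, r0=4.05, k=12.69)


def lorentz_berthelot(a: LJParams, b: LJParams) -> LJParams:
    """Cross parameters: arithmetic sigma, geometric epsilon."""
    return LJParams(0.5 * (a.sigma + b.sigma), math.sqrt(a.epsilon * b.epsilon))


# ---------------------------------------------------------------------------
# Scalar shifted-force kernels.  Each returns (value, derivative) of the
# shifted radial kernel at r; all vanish together with their derivative at
# the cutoff.
# ---------------------------------------------------------------------------

def _sf_r3(r: float, rc: float):
    """Shifted-force 1/r^3 kernel (dipole-dipole)."""
    a = 1.0 / r**3 - 1.0 / rc**3 + 3.0 * (r - rc) / rc**4
    da = -3.0 / r**4 + 3.0 / rc**4
    return a, da


def _sf_r2(r: float, rc: float):
    """Shifted-force 1/r^2 kernel (charge-dipole)."""
    h = 1.0 / r**2 - 1.0 / rc**2 + 2.0 * (r - rc) / rc**3
    dh = -2.0 / r**3 + 2.0 / rc**3
    return h, dh


def _sf_r1(r: float, rc: float):
    """Shifted-force 1/r kernel (charge-charge)."""
    u = 1.0 / r - 1.0 / rc + (r - rc) / rc**2
    du = -1.0 / r**2 + 1.0 / rc**2
    return u, du


def _lj_sf(r: float, sigma: float, eps: float, rc: float):
    """Shifted-force LJ: returns (energy, radial force on i along r_hat)."""
    s6 = (sigma / r) ** 6
    s6c = (sigma / rc) ** 6
    u = 4.0 * eps * (s6 * s6 - s6)
    uc = 4.0 * eps * (s6c * s6c - s6c)
    dup = -24.0 * eps * (2.0 * s6 * s6 - s6) / r       # U'(r)
    dupc = -24.0 * eps * (2.0 * s6c * s6c - s6c) / rc  # U'(rc)
    return u - uc - (r - rc) * dupc, -(dup - dupc)


def _norm(r_vec) -> tuple[np.ndarray, float]:
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise OverlapError()
    return r_vec, r


def lj_shifted_force(r_vec, p_i: LJParams, p_j: LJParams, r_cut: float) -> PairResult:
    """Shifted-force Lennard-Jones interaction between two sites.

    Cross parameters come from the Lorentz-Berthelot combination rule.
    Beyond (and exactly at) ``r_cut`` both energy and force are zero.
    """
    r_vec, r = _norm(r_vec)
    if r >= r_cut:
        return PairResult(0.0, np.zeros(3))
    p = lorentz_berthelot(p_i, p_j)
    if p.epsilon == 0.0:
        return PairResult(0.0, np.zeros(3))
    e, fr = _lj_sf(r, p.sigma, p.epsilon, r_cut)
    return PairResult(e, fr * r_vec / r)


def dipole_dipole_sf(r_vec, mu_i, mu_j, r_cut: float) -> PairResult:
    """Shifted-force point-dipole/point-dipole interaction.

    ``mu_i`` and ``mu_j`` are full dipole vectors in e*A.  Far inside the
    cutoff the unshifted part approaches the ideal point-dipole energy
    ``C [mu_i.mu_j - 3 (mu_i.r_hat)(mu_j.r_hat)] / r^3``.
    """
    mu_i = np.asarray(mu_i, dtype=float)
    mu_j = np.asarray(mu_j, dtype=float)
    if np.linalg.norm(mu_i) == 0.0 or np.linalg.norm(mu_j) == 0.0:
        raise ValueError("dipole_dipole_sf needs two non-zero dipoles")
    r_vec, r = _norm(r_vec)
    if r >= r_cut:
        return PairResult(0.0, np.zeros(3))
    a_k, da_k = _sf_r3(r, r_cut)
    bt = 3.0 * a_k / (r * r)
    dbt = 3.0 * da_k / (r * r) - 6.0 * a_k / r**3
    a = float(mu_i @ r_vec)
    b = float(mu_j @ r_vec)
    s1 = float(mu_i @ mu_j)
    rhat = r_vec / r
    energy = COULOMB_K * (s1 * a_k - a * b * bt)
    grad = COULOMB_K * (s1 * da_k * rhat - (mu_i * b + mu_j * a) * bt - a * b * dbt * rhat)
    e_i = -COULOMB_K * (mu_j * a_k - b * r_vec * bt)   # -dU/dmu_i
    e_j = -COULOMB_K * (mu_i * a_k - a * r_vec * bt)
    return PairResult(energy, -grad, np.cross(mu_i, e_i), np.cross(mu_j, e_j))


def charge_dipole_sf(r_vec, q: float, mu, r_cut: float) -> PairResult:
    """Shifted-force charge-dipole interaction.

    Site i carries the charge ``q`` and site j the dipole ``mu``;
    ``r_vec = r_charge - r_dipole``.  The unshifted part approaches
    ``C q (mu . r_hat) / r^2``.  ``q = 0`` gives an identically zero result.
    """
    mu = np.asarray(mu, dtype=float)
    r_vec, r = _norm(r_vec)
    if r >= r_cut or q == 0.0:
        return PairResult(0.0, np.zeros(3))
    h, dh = _sf_r2(r, r_cut)
    big_h = h / r
    dbig_h = dh / r - h / (r * r)
    b = float(mu @ r_vec)
    rhat = r_vec / r
    energy = COULOMB_K * q * b * big_h
    grad = COULOMB_K * q * (mu * big_h + b * dbig_h * rhat)
    e_j = -COULOMB_K * q * r_vec * big_h  # -dU/dmu
    return PairResult(energy, -grad, np.zeros(3), np.cross(mu, e_j))


def coulomb_sf(r_vec, q_i: float, q_j: float, r_cut: float) -> PairResult:
    """Shifted-force Coulomb interaction between two point charges."""
    r_vec, r = _norm(r_vec)
    if r >= r_cut or q_i == 0.0 or q_j == 0.0:
        return PairResult(0.0, np.zeros(3))
    u, du = _sf_r1(r, r_cut)
    return PairResult(COULOMB_K * q_i * q_j * u, -COULOMB_K * q_i * q_j * du * r_vec / r)


def atom_atom_pair(r_vec, q_i, q_j, lj_i: LJParams, lj_j: LJParams, r_cut: float) -> PairResult:
    """Full atom-atom non-bonded pair: shifted-force LJ plus Coulomb.

    With both charges zero this reduces bitwise to ``lj_shifted_force``.
    """
    lj = lj_shifted_force(r_vec, lj_i, lj_j, r_cut)
    if q_i == 0.0 and q_j == 0.0:
        return lj
    cc = coulomb_sf(r_vec, q_i, q_j, r_cut)
    return PairResult(lj.energy + cc.energy, lj.force_on_i + cc.force_on_i)


def harmonic_bond(r: float, term: BondTerm) -> tuple[float, float]:
    """Harmonic bond energy and force magnitude at separation r.

    Returns ``(E, F)`` with ``E = k (r - r0)^2`` and ``F = -dE/dr``; the force
    vector on site i points along ``r_hat = (r_i - r_j)/r`` times ``F``.
    """
    if r <= 0:
        raise ValueError("bond length must be positive")
    dr = r - term.r0
    return term.k * dr * dr, -2.0 * term.k * dr


# ---------------------------------------------------------------------------
# Whole-system evaluation (delegates to compiled array kernels).
# ---------------------------------------------------------------------------

@dataclass
class EnergyForces:
    """Decomposed potential energy and per-site forces/torques.

    ``components`` holds the decomposition in kJ/mol:

    * ``solvent_solvent`` - non-bonded energy among solvent sites,
    * ``solute_solvent``  - coupling-scaled solute/solvent non-bonded energy,
    * ``solute_internal`` - solute-solute non-bonded (inter-molecular only;
      intramolecular non-bonded pairs are excluded),
    * ``bonded``          - all harmonic bond terms (solvent and solute).

    The four components sum to ``total``.

    ``u_solute_solvent_raw`` is the unscaled solute-solvent energy needed for
    thermodynamic-integration derivatives.  ``forces_outer`` holds only the
    CG-CG non-bonded contribution (the slow forces of the multiple-timestep
    split); ``forces_inner`` holds everything else.  ``forces`` is their sum.
    """

    components: dict
    forces: np.ndarray
    torques: np.ndarray
    forces_outer: np.ndarray
    forces_inner: np.ndarray
    torques_outer: np.ndarray
    torques_inner: np.ndarray
    virial: float
    u_solute_solvent_raw: float

    @property
    def total(self) -> float:
        c = self.components
        return (c["solvent_solvent"] + c["solute_solvent"]
                + c["solute_internal"] + c["bonded"])


def total_energy_forces(state, topology, r_cut: float, coupling: float = 1.0,
                        neighbor: str = "auto") -> EnergyForces:
    """Evaluate all energies, forces and torques of a periodic system.

    Parameters
    ----------
    state, topology : SystemState, Topology
    r_cut : cutoff radius, A.
    coupling : scaling factor f applied to every solute-solvent non-bonded
        term (energy, force, virial); 1.0 means fully interacting, 0.0 fully
        decoupled.  This is the value f(lambda) of the coupling function, not
        lambda itself.
    neighbor : "auto", "brute" or "cell"; "cell" needs at least three cells
        of size >= r_cut per box dimension.

    Intramolecular non-bonded interactions are excluded; bonded terms are
    evaluated from the topology's bond list.
    """
    from . import _kernels

    pos = np.ascontiguousarray(state.positions, dtype=float)
    box = np.ascontiguousarray(state.box, dtype=float)
    n = pos.shape[0]

    if neighbor == "cell" or (neighbor == "auto" and n > 400):
        pairs = _kernels.cell_pairs(pos, box, r_cut)
        if pairs is None:
            if neighbor == "cell":
                raise ValueError("box too small for a cell list at this cutoff")
            pairs = _kernels.all_pairs(n)
    else:
        pairs = _kernels.all_pairs(n)
    return evaluate_pairs(pairs, state, topology, r_cut, coupling)


def evaluate_pairs(pairs, state, topology, r_cut: float,
                   coupling: float = 1.0) -> EnergyForces:
    """As :func:`total_energy_forces` but over an explicit candidate pair
    list (which may safely contain pairs beyond the cutoff)."""
    from . import _kernels

    arr = topology.arrays()
    pos = np.ascontiguousarray(state.positions, dtype=float)
    box = np.ascontiguousarray(state.box, dtype=float)
    orient = np.ascontiguousarray(state.orientations, dtype=float)
    try:
        out = _kernels.nonbonded_sweep(
            pairs, pos, box, arr.sigma, arr.eps, arr.charge, arr.mu_mag, orient,
            arr.molecule, arr.solute, arr.cg, float(r_cut), float(coupling))
    except ZeroDivisionError:
        out = (np.nan, 0.0, 0.0, 0.0, None, None, None, None)
    (e_ss, e_uv_raw, e_uu, vir, f_out, f_in, t_out, t_in) = out

    if not np.isfinite(e_ss + e_uv_raw + e_uu):
        from .system import minimum_image
        for i, j in pairs:
            if arr.molecule[i] == arr.molecule[j]:
                continue
            d = minimum_image(pos[i] - pos[j], box)
            if d @ d < 1e-12:
                raise OverlapError(int(i), int(j))
        raise FloatingPointError("non-finite non-bonded energy")

    e_bond = 0.0
    if arr.bond_i.size:
        e_bond = _kernels.bonded_sweep(pos, box, arr.bond_i, arr.bond_j,
                                       arr.bond_r0, arr.bond_k, f_in)

    comps = {
        "solvent_solvent": e_ss,
        "solute_solvent": coupling * e_uv_raw,
        "solute_internal": e_uu,
        "bonded": e_bond,
    }
    return EnergyForces(
        components=comps,
        forces=f_out + f_in,
        torques=t_out + t_in,
        forces_outer=f_out,
        forces_inner=f_in,
        torques_outer=t_out,
        torques_inner=t_in,
        virial=vir,
        u_solute_solvent_raw=e_uv_raw,
    )
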