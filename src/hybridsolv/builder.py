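"""System construction: coarse-graining maps, box building, solvation, toys.

The coarse-graining maps implement the hybrid-model setup: each all-atom
water is replaced by a single Stockmayer bead at the oxygen position, and
each all-atom cyclohexane ring by three bonded beads on ring carbons 1, 3
and 5.  The builders also generate every synthetic fixture the test suite
uses (solvent boxes, toy solutes), so no external files are ever needed.

All builders are deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .forcefield import (BondTerm, CYCLOHEXANE_BEAD, CYCLOHEXANE_BOND,
                         ELBA_WATER, LJParams, ParticleSpec)
from .system import SystemState, Topology, minimum_image
from .units import GCM3_TO_INTERNAL

__all__ = ["map_water_to_cg", "map_cyclohexane_to_cg", "build_box",
           "solvate", "make_toy_solute"]


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def map_water_to_cg(aa_waters, box, seed: int = 0):
    """Coarse-grain all-atom waters to Stockmayer beads.

    Parameters
    ----------
    aa_waters : sequence of mappings with key ``"O"`` (oxygen coordinate,
        required) and optionally ``"H"`` (list of hydrogen coordinates).
    box : orthorhombic box lengths, A.
    seed : used for bead orientations of waters supplied without hydrogens.

    Each bead is placed exactly at the oxygen position.  When hydrogens are
    present the initial dipole points along the H-O-H bisector (from O toward
    the hydrogens, the physical polarisation of the source configuration);
    otherwise a random unit vector from the seeded generator is used.
    """
    rng = _rng(seed)
    n = len(aa_waters)
    pos = np.zeros((n, 3))
    orient = np.zeros((n, 3))
    for m, mol in enumerate(aa_waters):
        if "O" not in mol or mol["O"] is None:
            raise ValueError(f"water molecule {m} has no oxygen coordinate")
        pos[m] = np.asarray(mol["O"], dtype=float)
        hs = mol.get("H")
        if hs is not None and len(hs) > 0:
            d = np.mean([np.asarray(h, dtype=float) - pos[m] for h in hs], axis=0)
            nrm = np.linalg.norm(d)
            if nrm == 0:
                raise ValueError(f"water molecule {m}: degenerate H geometry")
            orient[m] = d / nrm
        else:
            orient[m] = _random_unit(rng)[0]
    top = Topology(specs=[ELBA_WATER] * n, molecule=np.arange(n))
    return top, SystemState(positions=pos, box=box, orientations=orient)


def map_cyclohexane_to_cg(aa_rings, box):
    """Coarse-grain all-atom cyclohexane rings to 3-bead molecules.

    ``aa_rings`` is a sequence of (6, 3) arrays of ring-carbon coordinates in
    ring order; beads are placed exactly on carbons 1, 3 and 5 (indices
    0, 2, 4) and joined into a triangle by three harmonic bonds.
    """
    specs, bonds, mol_ids, coords = [], [], [], []
    for m, ring in enumerate(aa_rings):
        ring = np.asarray(ring, dtype=float)
        if ring.shape != (6, 3):
            raise ValueError(
                f"cyclohexane molecule {m}: expected 6 ring carbons, got {ring.shape[0]}")
        base = 3 * m
        coords.extend([ring[0], ring[2], ring[4]])
        specs.extend([CYCLOHEXANE_BEAD] * 3)
        mol_ids.extend([m] * 3)
        for a, b in ((0, 1), (1, 2), (2, 0)):
            bonds.append(BondTerm(base + a, base + b,
                                  CYCLOHEXANE_BOND.r0, CYCLOHEXANE_BOND.k))
    top = Topology(specs=specs, bonds=bonds, molecule=np.array(mol_ids))
    return top, SystemState(positions=np.array(coords).reshape(-1, 3), box=box)


def _insert_molecules(template_coords, spacing, n_mol, box, rng,
                      min_dist, max_tries=200):
    """Random non-overlapping insertion of rigid molecule templates."""
    placed = []
    all_sites = []
    for m in range(n_mol):
        for attempt in range(max_tries):
            centre = rng.uniform(0.0, 1.0, 3) * box
            # random rotation via QR of a Gaussian matrix
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            cand = template_coords @ q.T + centre
            ok = True
            for site in all_sites:
                d = minimum_image(cand - site, box)
                if np.any(np.sum(d * d, axis=1) < min_dist**2):
                    ok = False
                    break
            if ok:
                placed.append(cand)
                all_sites.extend(cand)
                break
        else:
            raise RuntimeError(
                f"could not place molecule {m} without overlap after {max_tries} tries")
    return np.concatenate(placed, axis=0)


def build_box(species: str, n_molecules: int, box_length: float, seed: int = 0):
    """Build a pure solvent box by random insertion.

    Molecules are inserted with random positions/orientations subject to a
    minimum pair distance of 0.8 sigma; all momenta are zero.  Deterministic
    under ``seed``.
    """
    box = np.full(3, float(box_length))
    rng = _rng(seed)
    if species == "water":
        spec, template = ELBA_WATER, np.zeros((1, 3))
        bonds_per_mol = []
        mol_mass = spec.mass
    elif species == "cyclohexane":
        spec = CYCLOHEXANE_BEAD
        r0 = CYCLOHEXANE_BOND.r0
        # equilateral triangle of side r0 centred at the origin
        h = r0 / np.sqrt(3.0)
        template = np.array([[h, 0, 0],
                             [-h / 2, r0 / 2, 0],
                             [-h / 2, -r0 / 2, 0]])
        bonds_per_mol = [(0, 1), (1, 2), (2, 0)]
        mol_mass = 3 * spec.mass
    else:
        raise ValueError(f"unknown solvent species {species!r}")

    density = n_molecules * mol_mass / float(np.prod(box)) / GCM3_TO_INTERNAL
    if density > 2.0:
        raise ValueError(f"requested density {density:.2f} g/cm^3 is not physical")

    sites_per_mol = template.shape[0]
    if n_molecules == 0:
        top = Topology(specs=[], molecule=np.zeros(0, dtype=np.int64))
        return top, SystemState(positions=np.zeros((0, 3)), box=box)

    pos = _insert_molecules(template, None, n_molecules, box, rng,
                            min_dist=0.8 * spec.lj.sigma)
    specs = [spec] * (sites_per_mol * n_molecules)
    mol = np.repeat(np.arange(n_molecules), sites_per_mol)
    bonds = [BondTerm(m * sites_per_mol + a, m * sites_per_mol + b,
                      CYCLOHEXANE_BOND.r0, CYCLOHEXANE_BOND.k)
             for m in range(n_molecules) for a, b in bonds_per_mol]
    top = Topology(specs=specs, bonds=bonds, molecule=mol)
    orient = np.zeros_like(pos)
    if spec.dipole_magnitude > 0:
        orient = _random_unit(rng, pos.shape[0])
    return top, SystemState(positions=pos, box=box, orientations=orient)


def solvate(solute_top: Topology, solute_pos: np.ndarray,
            solvent_top: Topology, solvent_state: SystemState,
            clearance: float = 3.0):
    """Merge a solute into a solvent box, deleting clashing solvent molecules.

    Any solvent molecule with a site closer than ``clearance`` (minimum
    image) to any solute site is removed whole.  The solute sites come first
    in the merged system and are tagged as solute.
    """
    solute_pos = np.asarray(solute_pos, dtype=float).reshape(-1, 3)
    box = solvent_state.box
    keep_mol = {}
    for m in np.unique(solvent_top.molecule):
        keep_mol[int(m)] = True
    for idx in range(solvent_top.n_sites):
        d = minimum_image(solvent_state.positions[idx] - solute_pos, box)
        if np.any(np.sum(d * d, axis=1) < clearance**2):
            keep_mol[int(solvent_top.molecule[idx])] = False
    keep_sites = np.array([keep_mol[int(m)] for m in solvent_top.molecule])

    old2new = -np.ones(solvent_top.n_sites, dtype=int)
    old2new[keep_sites] = np.arange(int(keep_sites.sum()))
    kept_specs = [s for s, k in zip(solvent_top.specs, keep_sites) if k]
    kept_bonds = [BondTerm(old2new[b.site_i], old2new[b.site_j], b.r0, b.k)
                  for b in solvent_top.bonds
                  if keep_sites[b.site_i] and keep_sites[b.site_j]]
    # re-number kept molecules densely
    kept_mol_ids = solvent_top.molecule[keep_sites]
    _, dense = np.unique(kept_mol_ids, return_inverse=True)
    trimmed = Topology(specs=kept_specs, bonds=kept_bonds,
                       molecule=dense,
                       solute=np.zeros(len(kept_specs), dtype=bool))

    solute_only = Topology(
        specs=list(solute_top.specs), bonds=list(solute_top.bonds),
        constraints=list(solute_top.constraints),
        molecule=solute_top.molecule, solute=np.ones(solute_top.n_sites, dtype=bool))
    merged_top = solute_only.merge(trimmed)

    pos = np.concatenate([solute_pos, solvent_state.positions[keep_sites]])
    orient = np.concatenate([np.zeros((solute_top.n_sites, 3)),
                             solvent_state.orientations[keep_sites]])
    state = SystemState(positions=pos, box=box.copy(), orientations=orient)
    n_deleted = int(len(np.unique(solvent_top.molecule)) - trimmed.n_molecules) \
        if trimmed.n_sites else len(np.unique(solvent_top.molecule))
    return merged_top, state, n_deleted


def make_toy_solute(kind: str, **params):
    """Synthetic single-molecule solutes for testing every interaction path.

    kinds
    -----
    ``lj_site``             one neutral LJ site (sigma, epsilon, mass).
    ``charged_site``        one LJ site with a point charge q, exercising the
                            charge-dipole path in water.
    ``constrained_diatomic`` two charged LJ sites at distance d joined by one
                            SHAKE constraint (charges +/- q).
    """
    if kind == "lj_site":
        sigma = params.get("sigma", 3.5)
        eps = params.get("epsilon", 0.5)
        mass = params.get("mass", 30.0)
        spec = ParticleSpec(lj=LJParams(sigma, eps), mass=mass, kind="atom", name="LJ")
        top = Topology(specs=[spec], molecule=np.zeros(1, dtype=np.int64),
                       solute=np.ones(1, dtype=bool))
        return top, np.zeros((1, 3))
    if kind == "charged_site":
        q = params.get("q", 0.5)
        spec = ParticleSpec(lj=LJParams(params.get("sigma", 3.5),
                                        params.get("epsilon", 0.3)),
                            charge=q, mass=params.get("mass", 30.0),
                            kind="atom", name="Q")
        top = Topology(specs=[spec], molecule=np.zeros(1, dtype=np.int64),
                       solute=np.ones(1, dtype=bool))
        return top, np.zeros((1, 3))
    if kind == "constrained_diatomic":
        d = params.get("d", 1.09)
        q = params.get("q", 0.2)
        s1 = ParticleSpec(lj=LJParams(3.4, 0.4), charge=q, mass=12.011,
                          kind="atom", name="C")
        s2 = ParticleSpec(lj=LJParams(2.6, 0.1), charge=-q, mass=1.008,
                          kind="atom", name="H")
        top = Topology(specs=[s1, s2], constraints=[(0, 1, d)],
                       molecule=np.zeros(2, dtype=np.int64),
                       solute=np.ones(2, dtype=bool))
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        return top, coords
    raise ValueError(f"unknown toy solute kind {kind!r}")
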