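"""File formats: PDB/XYZ structures, prediction tables, run configuration.

Structure input is deliberately minimal: fixed-column ATOM/HETATM records
from PDB files and plain or extended XYZ (three extra columns ``ux uy uz``
carry dipole orientations).  Parse errors always name the offending line.
Tables are comma-separated with a mandatory header row; time series are
tab-separated.  Every writer emits a provenance header (package version,
seed, configuration hash) so any output can be traced to its run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import PredictionRecord

PREDICTION_COLUMNS = ["compound_id", "dg_water", "se_water", "dg_chex",
                      "se_chex", "logd_pred", "se_pred", "logd_exp", "err_exp"]


class FormatError(ValueError):
    """Malformed input file; message includes file and line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path, fmt: str | None = None):
    """Read coordinates and atom names from a PDB or XYZ file.

    Returns ``(names, coords, orientations)`` where orientations is None
    unless the file is an extended XYZ with dipole columns.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        names, coords = _read_pdb(path)
        return names, coords, None
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _read_pdb(path):
    names, coords = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FormatError(path, lineno, "truncated coordinate record")
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError:
                raise FormatError(path, lineno, "unparseable coordinates") from None
            names.append(line[12:16].strip())
            coords.append(xyz)
    return names, np.array(coords, dtype=float).reshape(-1, 3)


def _read_xyz(path):
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise FormatError(path, 1, "empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(path, 1, "first line must be the atom count") from None
    if len(lines) < n + 2:
        raise FormatError(path, len(lines), f"expected {n} atom lines")
    names, coords, orients = [], [], []
    has_orient = None
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) not in (4, 7):
            raise FormatError(path, lineno,
                              "expected 'name x y z' or 'name x y z ux uy uz'")
        if has_orient is None:
            has_orient = len(parts) == 7
        elif has_orient != (len(parts) == 7):
            raise FormatError(path, lineno, "inconsistent column count")
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError:
            raise FormatError(path, lineno, "unparseable number") from None
        names.append(parts[0])
        coords.append(vals[:3])
        if has_orient:
            orients.append(vals[3:])
    coords = np.array(coords, dtype=float).reshape(-1, 3)
    orients = np.array(orients, dtype=float).reshape(-1, 3) if has_orient else None
    return names, coords, orients


def write_xyz(path, names, coords, orientations=None, comment: str = ""):
    """Write (extended) XYZ; dipole orientations become columns 5-7."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n{comment}\n")
        for k, name in enumerate(names):
            x, y, z = coords[k]
            if orientations is not None:
                ux, uy, uz = orientations[k]
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f} "
                         f"{ux:.8f} {uy:.8f} {uz:.8f}\n")
            else:
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

def read_prediction_table(path, groups_path=None,
                          check: bool = True) -> list[PredictionRecord]:
    """Read a prediction table (CSV) into records.

    The schema is the documented 9-column layout; a missing column raises a
    schema error naming it.  ``groups_path`` optionally maps compound_id to
    semicolon-separated group labels.  With ``check=True`` each record's
    stored log D is verified against its free-energy pair.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    groups = {}
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, dtype=str).fillna("")
        for c in ("compound_id", "groups"):
            if c not in gdf.columns:
                raise ValueError(f"{groups_path}: missing column(s) {c}")
        groups = {row.compound_id: frozenset(g for g in row.groups.split(";") if g)
                  for row in gdf.itertuples()}
    records = []
    for row in df.itertuples():
        rec = PredictionRecord(
            compound_id=row.compound_id,
            dg_water=row.dg_water, se_water=row.se_water,
            dg_chex=row.dg_chex, se_chex=row.se_chex,
            logd_pred=row.logd_pred, se_pred=row.se_pred,
            logd_exp=row.logd_exp, err_exp=row.err_exp,
            groups=groups.get(row.compound_id, frozenset()))
        if check:
            rec.check_consistency()
        records.append(rec)
    return records


def write_prediction_table(path, records, seed=None):
    rows = [{c: getattr(r, c) for c in PREDICTION_COLUMNS} for r in records]
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed) + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def packaged_table1() -> list[PredictionRecord]:
    """The packaged 53-compound water/cyclohexane prediction table."""
    with resources.as_file(resources.files("hybridsolv.data") / "table1.csv") as p:
        return read_prediction_table(p)


def packaged_path(name: str) -> Path:
    with resources.as_file(resources.files("hybridsolv.data") / name) as p:
        return p


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run configuration (YAML on disk).

    ``protocol`` and ``schedule`` sub-dicts are passed to
    :class:`~hybridsolv.dynamics.MDProtocol` and
    :class:`~hybridsolv.free_energy.LambdaSchedule`-building helpers;
    ``analysis`` holds alpha / n_boot / confidence.  All referenced files
    must exist at validation time.
    """

    structure: str | None = None
    topology: str | None = None
    output_dir: str = "."
    seed: int = 0
    protocol: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("structure", "topology"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path}: {name} file {p!r} does not exist")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance_header(seed=None, config: RunConfig | None = None) -> str:
    from . import __version__
    parts = [f"# hybridsolv {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config={config.digest()}")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# parameter files
# ---------------------------------------------------------------------------

def read_parameter_file(path):
    """Read a site/bond/constraint parameter file (YAML).

    Schema::

        sites:                      # one entry per site, in order
          - {name: W, kind: cg_water, sigma: 3.05, epsilon: 2.3012,
             dipole: 0.5413, mass: 18.01528, rot_inertia: 4.0}
        bonds:                      # optional: [i, j, r0, k]
          - [0, 1, 4.05, 12.69]
        constraints:                # optional: [i, j, distance]
          - [0, 1, 1.09]

    Units: A, kJ/mol, e, e*A, g/mol, g/mol*A^2.  Returns
    ``(specs, bonds, constraints)`` ready for a Topology.
    """
    import yaml

    from .forcefield import BondTerm, LJParams, ParticleSpec

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "sites" not in data:
        raise ValueError(f"{path}: parameter file needs a 'sites' list")
    specs = []
    for k, site in enumerate(data["sites"]):
        try:
            specs.append(ParticleSpec(
                lj=LJParams(float(site["sigma"]), float(site["epsilon"])),
                charge=float(site.get("charge", 0.0)),
                dipole_magnitude=float(site.get("dipole", 0.0)),
                mass=float(site.get("mass", 1.0)),
                rot_inertia=float(site.get("rot_inertia", 0.0)),
                kind=site.get("kind", "atom"),
                name=str(site.get("name", f"S{k}"))))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad site entry {k}: {exc}") from None
    bonds = [BondTerm(int(i), int(j), float(r0), float(kk))
             for i, j, r0, kk in data.get("bonds", [])]
    constraints = [(int(i), int(j), float(d))
                   for i, j, d in data.get("constraints", [])]
    return specs, bonds, constraints
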