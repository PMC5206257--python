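"""Thermodynamic integration of solvation free energies.

The solute-solvent interaction energy is scaled by the quartic coupling
function

    f(lambda) = (1 - lambda)^4,

so the compound is fully coupled at lambda = 0 and behaves as a gas-phase
molecule at lambda = 1.  The derivative needed for TI is

    dU/dlambda = f'(lambda) * U_sv,   f'(lambda) = -4 (1 - lambda)^3,

with U_sv the *unscaled* solute-solvent energy sampled in the ensemble of
the scaled potential.  A schedule of 25 equally spaced lambda values from 0
to 0.96 is simulated as one continuous trajectory (lambda changed step-wise,
the head of each window discarded as equilibration); the integrand at
lambda = 1 is obtained by linear extrapolation from the last two grid points
and the integral over [0, 1] by the composite trapezium rule.

The solvation free energy is the work of *decoupling*; repeats differ only
in their random seed and are combined as mean +/- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import MDEngine, MDProtocol, minimize_steepest_descent
from .system import SystemState, Topology

__all__ = ["coupling", "make_schedule", "LambdaSchedule", "TISeries",
           "FreeEnergyEstimate", "collect_dudl", "ti_integrate",
           "combine_repeats", "run_solvation_fe", "convergence_delta"]


def coupling(lam: float):
    """Quartic coupling: returns (f, df/dlambda) at lambda."""
    one = 1.0 - lam
    return one**4, -4.0 * one**3


@dataclass
class LambdaSchedule:
    """The lambda grid and per-window sampling protocol.

    Durations are in fs internally; the production protocol (4.8 ns windows,
    1.2 ns discard, 0.6 ps sampling) is the default, and ``desk_scale`` gives
    a preset sized for a single workstation CPU.
    """

    lambdas: np.ndarray
    window_fs: float = 4.8e6
    discard_fs: float = 1.2e6
    sample_every_fs: float = 600.0

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise ValueError("lambda grid must be strictly increasing with >= 2 points")
        if lam[0] != 0.0:
            raise ValueError("lambda grid must start at 0")
        if lam[-1] >= 1.0:
            raise ValueError("lambda = 1 is obtained by extrapolation, not simulated")
        if not 0 <= self.discard_fs < self.window_fs:
            raise ValueError("equilibration discard must be < window length")
        self.lambdas = lam

    @classmethod
    def desk_scale(cls, n: int = 25, lambda_max: float = 0.96,
                   window_fs: float = 1.0e4, discard_fs: float = 2.5e3,
                   sample_every_fs: float = 120.0) -> "LambdaSchedule":
        """Workstation-sized preset: 10 ps windows, 2.5 ps discard."""
        return cls(np.linspace(0.0, lambda_max, n), window_fs, discard_fs,
                   sample_every_fs)


def make_schedule(n: int = 25, lambda_max: float = 0.96, **kw) -> LambdaSchedule:
    """Equally spaced lambda grid from 0 to ``lambda_max`` (default spacing
    0.96/24 = 0.04)."""
    return LambdaSchedule(np.linspace(0.0, lambda_max, n), **kw)


@dataclass
class TISeries:
    """Per-lambda samples of dU/dlambda (and the raw U_sv they came from)."""

    lambdas: np.ndarray
    dudl_samples: list = field(default_factory=list)   # list of 1-D arrays
    usv_samples: list = field(default_factory=list)

    @property
    def means(self) -> np.ndarray:
        return np.array([np.mean(s) for s in self.dudl_samples])

    @property
    def sems(self) -> np.ndarray:
        out = []
        for s in self.dudl_samples:
            s = np.asarray(s)
            out.append(np.std(s, ddof=1) / np.sqrt(s.size) if s.size > 1 else 0.0)
        return np.array(out)

    def write_tsv(self, path, header_lines=()):
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("lambda\tsample\tdudl\n")
            for lam, samples in zip(self.lambdas, self.dudl_samples):
                for k, v in enumerate(np.asarray(samples)):
                    fh.write(f"{lam:.6g}\t{k}\t{v:.10g}\n")


@dataclass
class FreeEnergyEstimate:
    """Solvation free energy, kJ/mol, as mean +/- SE over repeats."""

    dg: float
    se: float
    n_repeats: int
    phase: str = ""

    def __post_init__(self):
        if self.se < 0 or self.n_repeats < 1:
            raise ValueError("se must be >= 0 and n_repeats >= 1")


def collect_dudl(usv_samples, lam: float) -> np.ndarray:
    """dU/dlambda samples from raw solute-solvent energies at one lambda."""
    _, dfdl = coupling(lam)
    return dfdl * np.asarray(usv_samples, dtype=float)


def ti_integrate(lambdas, means) -> float:
    """Trapezium-rule TI with linear extrapolation of the integrand to
    lambda = 1 from the last two grid points."""
    lam = np.asarray(lambdas, dtype=float)
    y = np.asarray(means, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least two lambda points")
    if lam.size != y.size:
        raise ValueError("grid and integrand lengths differ")
    slope = (y[-1] - y[-2]) / (lam[-1] - lam[-2])
    y1 = y[-1] + slope * (1.0 - lam[-1])
    lam_ext = np.append(lam, 1.0)
    y_ext = np.append(y, y1)
    return float(np.trapezoid(y_ext, lam_ext))


def combine_repeats(dg_values, phase: str = "") -> FreeEnergyEstimate:
    """Mean and standard error of the mean over independent repeats."""
    v = np.asarray(list(dg_values), dtype=float)
    if v.size == 0:
        raise ValueError("no repeats to combine")
    se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return FreeEnergyEstimate(float(np.mean(v)), se, int(v.size), phase)


def run_ti_trajectory(topology: Topology, state: SystemState,
                      protocol: MDProtocol, schedule: LambdaSchedule,
                      equilibrate_fs: float = 0.0) -> TISeries:
    """One continuous TI trajectory: lambda changed step-wise window by
    window, the head of each window discarded, U_sv sampled on the rest.

    Integrating the returned series over lambda gives the *decoupling* free
    energy G(gas) - G(solution); the solvation free energy is its negative
    (taken in :func:`run_solvation_fe`).
    """
    engine = MDEngine(topology, state, protocol, coupling=1.0)
    engine.initialize_velocities()
    if equilibrate_fs > 0:
        engine.run(int(round(equilibrate_fs / protocol.dt_outer)))
    dt_o = protocol.dt_outer
    n_win = int(round(schedule.window_fs / dt_o))
    n_disc = int(round(schedule.discard_fs / dt_o))
    every = max(1, int(round(schedule.sample_every_fs / dt_o)))
    series = TISeries(lambdas=schedule.lambdas.copy())
    for lam in schedule.lambdas:
        f, dfdl = coupling(lam)
        engine.set_coupling(f)
        engine.run(n_disc)
        usv = []
        for k in range(n_win - n_disc):
            engine.outer_step()
            if (k + 1) % every == 0:
                usv.append(engine.energies.u_solute_solvent_raw)
        usv = np.asarray(usv)
        series.usv_samples.append(usv)
        series.dudl_samples.append(dfdl * usv)
    return series


def run_solvation_fe(topology: Topology, state: SystemState,
                     protocol: MDProtocol, schedule: LambdaSchedule,
                     n_repeats: int = 1, phase: str = "",
                     equilibrate_fs: float = 0.0, minimize_steps: int = 0,
                     return_series: bool = False):
    """Full solvation free-energy estimate over independent repeats.

    Each repeat re-seeds every random stream (initial velocities and
    thermostat noise) from ``protocol.seed + repeat`` and runs its own
    step-wise TI trajectory.  Returns a :class:`FreeEnergyEstimate`
    (optionally also the per-repeat :class:`TISeries`).
    """
    if minimize_steps:
        state = minimize_steepest_descent(topology, state, protocol.r_cut,
                                          max_steps=minimize_steps)
    dgs, all_series = [], []
    from dataclasses import replace
    for rep in range(n_repeats):
        proto = replace(protocol, seed=protocol.seed + rep)
        series = run_ti_trajectory(topology, state.copy(), proto, schedule,
                                   equilibrate_fs)
        # decoupling work -> solvation free energy
        dgs.append(-ti_integrate(series.lambdas, series.means))
        all_series.append(series)
    est = combine_repeats(dgs, phase)
    if return_series:
        return est, all_series
    return est


def convergence_delta(estimates_short: dict, estimates_long: dict,
                      threshold: float = 1.0) -> dict:
    """Compare free energies at two sampling lengths per compound.

    Returns a report with per-compound |delta|, the mean and max |delta|,
    and the ids whose estimate moved by more than ``threshold`` kJ/mol.
    """
    ids = sorted(set(estimates_short) & set(estimates_long))
    if len(ids) != len(estimates_short) or len(ids) != len(estimates_long):
        missing = set(estimates_short) ^ set(estimates_long)
        raise ValueError(f"compound sets differ: {sorted(missing)}")

    def _dg(v):
        return v.dg if isinstance(v, FreeEnergyEstimate) else float(v)

    deltas = {i: abs(_dg(estimates_long[i]) - _dg(estimates_short[i])) for i in ids}
    vals = np.array([deltas[i] for i in ids])
    return {
        "deltas": deltas,
        "mean_abs_delta": float(vals.mean()) if ids else 0.0,
        "max_abs_delta": float(vals.max()) if ids else 0.0,
        "flagged": [i for i in ids if deltas[i] > threshold],
        "threshold": threshold,
    }
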