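"""Independent oracles used by the tests.

Everything here is deliberately written from first principles (plain Python
sums, four-point-charge electrostatics, explicit quadrature) so it shares no
code path with the package implementation it checks.
"""

import numpy as np

COULOMB_K = 1389.35458  # kJ A / (mol e^2); restated here, not imported
KB = 8.314462618e-3


def finite_dipole_pair_energy(r_vec, mu_i, mu_j, d):
    """Two finite dipoles built from +/- charge pairs of separation d."""
    mu_i = np.asarray(mu_i, float)
    mu_j = np.asarray(mu_j, float)
    ui = mu_i / np.linalg.norm(mu_i)
    uj = mu_j / np.linalg.norm(mu_j)
    qi = np.linalg.norm(mu_i) / d
    qj = np.linalg.norm(mu_j) / d
    r_vec = np.asarray(r_vec, float)
    e = 0.0
    for si, pi in ((qi, r_vec + 0.5 * d * ui), (-qi, r_vec - 0.5 * d * ui)):
        for sj, pj in ((qj, 0.5 * d * uj), (-qj, -0.5 * d * uj)):
            e += COULOMB_K * si * sj / np.linalg.norm(pi - pj)
    return e


def finite_dipole_charge_energy(r_vec, q, mu, d):
    """A charge at r_vec interacting with a finite dipole at the origin."""
    mu = np.asarray(mu, float)
    u = mu / np.linalg.norm(mu)
    qd = np.linalg.norm(mu) / d
    r_vec = np.asarray(r_vec, float)
    e = 0.0
    for s, p in ((qd, 0.5 * d * u), (-qd, -0.5 * d * u)):
        e += COULOMB_K * q * s / np.linalg.norm(r_vec - p)
    return e


def central_difference_force(energy_fn, r_vec, h=1e-6):
    """-grad(E) by central differences; energy_fn maps r_vec -> energy."""
    g = np.zeros(3)
    for k in range(3):
        dp = np.array(r_vec, float)
        dm = np.array(r_vec, float)
        dp[k] += h
        dm[k] -= h
        g[k] = (energy_fn(dp) - energy_fn(dm)) / (2 * h)
    return -g


def trapezium_with_linear_tail(lambdas, means):
    """Composite trapezium over [0, 1] after linearly extrapolating the last
    two grid points to lambda = 1; explicit summation, no numpy quadrature."""
    lam = list(map(float, lambdas))
    y = list(map(float, means))
    slope = (y[-1] - y[-2]) / (lam[-1] - lam[-2])
    y = y + [y[-1] + slope * (1.0 - lam[-1])]
    lam = lam + [1.0]
    total = 0.0
    for k in range(len(lam) - 1):
        total += 0.5 * (y[k] + y[k + 1]) * (lam[k + 1] - lam[k])
    return total


def bedroc_direct(scores, membership, alpha):
    """BEDROC by direct summation over explicit ranks (worst first)."""
    import math
    pairs = sorted(enumerate(scores), key=lambda t: (-t[1], t[0]))
    n_total = len(scores)
    n = sum(bool(m) for m in membership)
    ra = n / n_total
    s = 0.0
    for rank0, (idx, _score) in enumerate(pairs):
        if membership[idx]:
            s += math.exp(-alpha * (rank0 + 1) / n_total)
    rie = s / (ra * (1 - math.exp(-alpha)) / (math.exp(alpha / n_total) - 1))
    factor = ra * math.sinh(alpha / 2) / (
        math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
    const = 1.0 / (1 - math.exp(alpha * (1 - ra)))
    return rie * factor + const


def fep_solvation_estimate(series, coupling_fn, temperature=298.0):
    """Free-energy-perturbation (exponential averaging) oracle.

    Uses the same per-window raw solute-solvent energy samples as TI and
    averages the forward and backward exponential estimates between adjacent
    windows; the 0.96 -> 1 tail uses the same linear extrapolation as TI.
    Returns the solvation free energy (negative decoupling work).
    """
    kt = KB * temperature
    lam = np.asarray(series.lambdas, float)
    dg = 0.0
    for k in range(len(lam) - 1):
        f0, _ = coupling_fn(lam[k])
        f1, _ = coupling_fn(lam[k + 1])
        df = f1 - f0
        duf = df * np.asarray(series.usv_samples[k])
        dub = -df * np.asarray(series.usv_samples[k + 1])
        fwd = -kt * np.log(np.mean(np.exp(-duf / kt)))
        bwd = kt * np.log(np.mean(np.exp(-dub / kt)))
        dg += 0.5 * (fwd + bwd)
    means = [np.mean(s) for s in series.dudl_samples]
    slope = (means[-1] - means[-2]) / (lam[-1] - lam[-2])
    y1 = means[-1] + slope * (1.0 - lam[-1])
    dg += 0.5 * (means[-1] + y1) * (1.0 - lam[-1])
    return -dg
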