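"""Distribution-coefficient predictions and quality statistics.

A water/cyclohexane distribution coefficient is approximated by the
partition coefficient of the neutral species,

    log D ~ log P = [dG_solv(water) - dG_solv(cyclohexane)] / (2.3 R T),

with R the gas constant and T = 298 K.  The factor 2.3 is used literally
(rather than ln 10 = 2.3026); the difference is far below the rounding of
the tabulated free energies.  Standard errors of the two phases propagate
in quadrature.

Quality of a prediction set is quantified by MAD, MSD, RMSD, Pearson's R
and the percentage of correctly predicted signs; systematic deviations of
chemical groups are probed with the BEDROC early-recognition metric
(compounds ranked worst-deviation-first), a bootstrap for its uncertainty
and a Student's t-test of the group's absolute deviations against the whole
population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .units import R_GAS

__all__ = ["PredictionRecord", "GroupDiagnostics", "log_d", "propagate_se",
           "summary_metrics", "sign_accuracy", "sign_accuracy_filtered",
           "deviation_extremes", "bedroc", "uniform_bedroc",
           "uniform_bedroc_analytic", "bootstrap_se", "group_ttest",
           "group_report"]


def log_d(dg_water: float, dg_cyclohexane: float, temperature: float = 298.0) -> float:
    """log D from the two solvation free energies (kJ/mol)."""
    return (dg_water - dg_cyclohexane) / (2.3 * R_GAS * temperature)


def propagate_se(se_water: float, se_cyclohexane: float,
                 temperature: float = 298.0) -> float:
    """Standard error of log D from independent per-phase standard errors."""
    return math.hypot(se_water, se_cyclohexane) / (2.3 * R_GAS * temperature)


@dataclass
class PredictionRecord:
    """One compound: free energies, predicted and experimental log D."""

    compound_id: str
    dg_water: float
    se_water: float
    dg_chex: float
    se_chex: float
    logd_pred: float
    se_pred: float
    logd_exp: float
    err_exp: float
    groups: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for name in ("se_water", "se_chex", "se_pred", "err_exp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 for {self.compound_id}")
        self.groups = frozenset(self.groups)

    def check_consistency(self, tol: float = 0.02) -> None:
        """The stored log D must match the free-energy pair within the
        rounding tolerance of the tabulated inputs."""
        recomputed = log_d(self.dg_water, self.dg_chex)
        if abs(recomputed - self.logd_pred) > tol:
            raise ValueError(
                f"compound {self.compound_id}: stored log D {self.logd_pred} "
                f"inconsistent with free energies (recomputed {recomputed:.3f})")


@dataclass
class GroupDiagnostics:
    """One chemical group's row of the enrichment report."""

    group: str
    n: int
    uniform_bedroc: float
    observed_bedroc: float
    bedroc_se: float
    p_value: float
    msd: float

    def __post_init__(self):
        if not (0.0 <= self.observed_bedroc <= 1.0):
            raise ValueError("BEDROC must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("empty group")


class UndefinedStatisticError(ValueError):
    """A statistic has no defined value on this input (e.g. Pearson's R with
    zero variance, or a filter that excludes every record)."""


def summary_metrics(pred, exp) -> dict:
    """MAD, MSD (= mean(pred - exp)), RMSD and Pearson's R.

    With zero variance on either side R has no defined value and is reported
    as the explicit error state ``None`` (never silently as 1).
    """
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    if p.shape != e.shape or p.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    d = p - e
    if np.std(p) == 0.0 or np.std(e) == 0.0:
        r = None
    else:
        r = float(stats.pearsonr(p, e)[0])
    return {
        "MAD": float(np.mean(np.abs(d))),
        "MSD": float(np.mean(d)),
        "RMSD": float(np.sqrt(np.mean(d * d))),
        "R": r,
    }


def sign_accuracy(pred, exp) -> float:
    """Percentage of records whose predicted sign matches experiment.

    An exact zero on one side only counts as a mismatch; two zeros match.
    """
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    ok = np.sign(p) == np.sign(e)
    return 100.0 * float(np.mean(ok))


def sign_accuracy_filtered(records, confidence: float = 0.95,
                           two_sided: bool = False) -> float:
    """Sign accuracy restricted to records significantly non-zero.

    A record is kept only if both the prediction (|log D| / se) and the
    experiment (|log D| / err) pass a z-test against zero at ``confidence``.
    Determining a *sign* is a one-sided question, so the default critical
    value is the one-sided quantile (1.645 at 95 %); ``two_sided=True``
    switches to the symmetric test (1.96 at 95 %).
    """
    z = stats.norm.ppf((1.0 + confidence) / 2.0) if two_sided \
        else stats.norm.ppf(confidence)
    kept = [r for r in records
            if abs(r.logd_pred) > z * r.se_pred
            and abs(r.logd_exp) > z * r.err_exp]
    if not kept:
        raise UndefinedStatisticError(
            "no record is significantly different from zero")
    return sign_accuracy([r.logd_pred for r in kept],
                         [r.logd_exp for r in kept])


def deviation_extremes(pred, exp, ids=None) -> dict:
    """Largest and second-largest |pred - exp| with their compound ids.

    Ties are broken by first occurrence in input order.
    """
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    if ids is None:
        ids = list(range(p.size))
    dev = np.abs(p - e)
    order = np.argsort(-dev, kind="stable")
    out = {"max": float(dev[order[0]]), "max_id": ids[order[0]]}
    if dev.size > 1:
        out["second"] = float(dev[order[1]])
        out["second_id"] = ids[order[1]]
    return out


def _ranks_worst_first(scores) -> np.ndarray:
    """1-based ranks by descending score, stable in input order."""
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    ranks = np.empty(s.size, dtype=np.int64)
    ranks[order] = np.arange(1, s.size + 1)
    return ranks


def bedroc(scores, membership, alpha: float = 20.0) -> float:
    """Truchon-Bailey BEDROC of one group over a ranked compound list.

    ``scores`` is the ranking statistic (here |deviation|; larger = earlier
    rank), ``membership`` flags the group.  The value lies in [0, 1], is
    invariant under strictly increasing transforms of the scores, and
    saturates toward 1 when all members occupy the top ranks.
    """
    m = np.asarray(membership, dtype=bool)
    n, big_n = int(m.sum()), int(m.size)
    if n == 0 or n == big_n:
        raise ValueError("BEDROC needs at least one member and one non-member")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ranks = _ranks_worst_first(scores)
    ra = n / big_n
    s = float(np.sum(np.exp(-alpha * ranks[m] / big_n)))
    rie_denom = ra * (1.0 - math.exp(-alpha)) / (math.exp(alpha / big_n) - 1.0)
    rie = s / rie_denom
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra))
    const = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return rie * factor + const


def uniform_bedroc_analytic(n_members: int, n_total: int,
                            alpha: float = 20.0) -> float:
    """Exact expectation of BEDROC under uniformly random ranking.

    Under a random permutation E[RIE] = 1 exactly, so the expectation is the
    affine map of the Truchon-Bailey normalisation evaluated at RIE = 1.
    """
    if not 0 < n_members < n_total:
        raise ValueError("need 0 < n_members < n_total")
    ra = n_members / n_total
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra))
    const = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return factor + const


def uniform_bedroc(n_members: int, n_total: int, alpha: float = 20.0,
                   n_mc: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo expectation of BEDROC under random ranking.

    Returns (mean, standard error) over ``n_mc`` seeded random placements of
    the members among the ranks.
    """
    if not 0 < n_members < n_total:
        raise ValueError("need 0 < n_members < n_total")
    rng = np.random.Generator(np.random.Philox(seed))
    ra = n_members / n_total
    rie_denom = ra * (1.0 - math.exp(-alpha)) / (math.exp(alpha / n_total) - 1.0)
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra))
    const = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    vals = np.empty(n_mc)
    all_ranks = np.arange(1, n_total + 1)
    for k in range(n_mc):
        picked = rng.choice(all_ranks, size=n_members, replace=False)
        rie = float(np.sum(np.exp(-alpha * picked / n_total))) / rie_denom
        vals[k] = rie * factor + const
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_mc))


def bootstrap_se(statistic, records, n_boot: int = 500, seed: int = 0) -> float:
    """Bootstrap standard error of ``statistic(records)``.

    Records are resampled with replacement; iterations on which the
    statistic is undefined (degenerate resamples) are skipped.
    """
    records = list(records)
    rng = np.random.Generator(np.random.Philox(seed))
    n = len(records)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(statistic([records[i] for i in idx]))
        except (ValueError, ZeroDivisionError):
            continue
    if len(vals) < 2:
        raise UndefinedStatisticError("too few defined bootstrap iterations")
    return float(np.std(vals, ddof=1))


def group_ttest(group_absdevs, all_absdevs, welch: bool = False) -> float:
    """Two-sided t-test p-value: group absolute deviations vs the entire
    population (group included), pooled variance by default."""
    g = np.asarray(group_absdevs, dtype=float)
    a = np.asarray(all_absdevs, dtype=float)
    res = stats.ttest_ind(g, a, equal_var=not welch)
    return float(res.pvalue)


def group_report(records, alpha: float = 20.0, n_boot: int = 500,
                 seed: int = 0, min_members: int = 5, n_mc: int = 2000,
                 welch: bool = False) -> list[GroupDiagnostics]:
    """Per-group enrichment diagnostics over a prediction set.

    For every group label with at least ``min_members`` members (and at
    least one non-member) the report lists: the group size, the uniform
    BEDROC baseline, the observed BEDROC with its bootstrap standard error,
    the t-test p-value of the group's absolute deviations against the whole
    population, and the group's mean signed deviation.
    """
    records = list(records)
    absdev = np.array([abs(r.logd_pred - r.logd_exp) for r in records])
    labels = sorted({g for r in records for g in r.groups})
    out = []
    for li, lab in enumerate(labels):
        member = np.array([lab in r.groups for r in records])
        n = int(member.sum())
        if n < min_members or n == len(records):
            continue

        def observed(rs, _lab=lab):
            scores = [abs(r.logd_pred - r.logd_exp) for r in rs]
            mem = [_lab in r.groups for r in rs]
            return bedroc(scores, mem, alpha)

        obs = observed(records)
        se = bootstrap_se(observed, records, n_boot=n_boot, seed=seed + li)
        uni = uniform_bedroc_analytic(n, len(records), alpha)
        p = group_ttest(absdev[member], absdev, welch=welch)
        msd = float(np.mean([r.logd_pred - r.logd_exp
                             for r, m in zip(records, member) if m]))
        out.append(GroupDiagnostics(lab, n, uni, obs, se, p, msd))
    return out
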