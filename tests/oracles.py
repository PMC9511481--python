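"""Independent oracles used to verify the implementation.

Everything here is deliberately brute-force or closed-form and shares no
code path with the package: a dense grid search for the logistic fit, the
analytic integral of the kinetic trace model, exact permutation enumeration
for the rank-based group comparison, and an explicit normal-equations solve
for the quadratic bias-plot fit.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def grid_search_logistic(
    conc: np.ndarray,
    resp: np.ndarray,
    bottoms: np.ndarray,
    tops: np.ndarray,
    log_ec50s: np.ndarray,
) -> tuple[float, float, float, float]:
    """Dense brute-force minimizer of the 3-parameter logistic RSS.

    Returns (bottom, top, log10_ec50, rss) of the best grid node.
    """
    best = (np.nan, np.nan, np.nan, np.inf)
    for le in log_ec50s:
        w = conc / (conc + 10.0**le)
        for b in bottoms:
            for t in tops:
                r = resp - (b + (t - b) * w)
                rss = float(r @ r)
                if rss < best[3]:
                    best = (float(b), float(t), float(le), rss)
    return best


def analytic_agonist_auc(
    baseline: float,
    efficacy: float,
    occupancy: float,
    rise_rate: float,
    decay_rate: float,
    duration: float,
) -> float:
    """Closed-form post-injection AUC of the agonist term
    B·E·occ·(1−e^{−kr u})·e^{−kd u} integrated over u ∈ [0, T]."""
    kd, kr, T = decay_rate, rise_rate, duration
    return (
        baseline
        * efficacy
        * occupancy
        * ((1.0 - math.exp(-kd * T)) / kd - (1.0 - math.exp(-(kr + kd) * T)) / (kr + kd))
    )


def analytic_baseline_auc(
    baseline: float, decay_rate: float, t_start: float, t_end: float
) -> float:
    """Closed-form AUC of B·e^{−kd t} over [t_start, t_end]."""
    kd = decay_rate
    return baseline / kd * (math.exp(-kd * t_start) - math.exp(-kd * t_end))


def exact_rank_permutation_p(group: list[float], control: list[float]) -> float:
    """Exact two-sided permutation p-value of the rank-sum separation
    between two groups (midranks on the pooled data).

    Enumerates every assignment of the pooled values to the two group
    slots; p is the fraction of assignments whose absolute rank-sum
    deviation from its permutation mean is at least the observed one.
    """
    pooled = np.asarray(list(group) + list(control), dtype=float)
    n_g = len(group)
    ranks = stats.rankdata(pooled)
    idx = range(len(pooled))
    observed = abs(ranks[:n_g].sum() - ranks.mean() * n_g)
    count = 0
    total = 0
    for subset in itertools.combinations(idx, n_g):
        stat = abs(ranks[list(subset)].sum() - ranks.mean() * n_g)
        total += 1
        if stat >= observed - 1e-12:
            count += 1
    return count / total


def quadratic_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Centered quadratic OLS via an explicit 3×3 normal-equations solve."""
    dx = x - np.mean(x)
    design = np.column_stack([np.ones_like(dx), dx, dx**2])
    ata = design.T @ design
    atb = design.T @ y
    coef = np.linalg.solve(ata, atb)
    return float(coef[0]), float(coef[1]), float(coef[2])


def logistic_reference(conc: np.ndarray, bottom: float, top: float, ec50: float) -> np.ndarray:
    """Direct evaluation of bottom + (top−bottom)/(1 + EC50/c)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + ec50 / conc)
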