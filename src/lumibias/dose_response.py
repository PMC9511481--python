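"""Three-parameter logistic concentration–response fitting.

Model (Hill slope fixed at 1, the standard three-parameter agonist model):

    response(c) = bottom + (top - bottom) / (1 + EC50 / c)

fitted by least squares in (bottom, top, log10 EC50).  ``top`` is reported
as Emax (in % of the reference agonist's maximal response) and EC50 as the
molar potency.  95% confidence intervals are profile-likelihood intervals —
the printed intervals this mirrors are conspicuously asymmetric, which Wald
intervals cannot produce.

Numerics: for fixed log10 EC50 the model is linear in (bottom, top), since
response = bottom·(1-w) + top·w with w = c/(c+EC50).  The fit is therefore a
deterministic grid over log10 EC50 (0.5-log steps spanning the tested range
plus two decades on each side) with the linear pair solved exactly at each
node, followed by bounded 1-D refinement — a multi-start scheme whose inner
starts are solved to optimality, so it cannot do worse than any explicit
(bottom, top) start grid.

A fit is reported "n.d." (not determined) when the response carries no
usable dose dependence: non-convergence, a top not distinguishable from the
bottom (the 95% profile interval of the span includes 0), or a fitted EC50
above the highest tested concentration.  n.d. propagates to every derived
quantity downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .types import AUCResponse, PipelineOrderError, group_by

logger = logging.getLogger(__name__)

GRID_STEP = 0.5
GRID_PAD_DECADES = 2.0
PROFILE_SEARCH_DECADES = 12.0

STATUS_OK = "ok"
STATUS_ND = "nd"


@dataclass
class ConcentrationResponse:
    """Normalized responses versus concentration for one compound/pathway."""

    compound: str
    pathway: str
    receptor_variant: str
    concentrations: np.ndarray  # molar, one per point
    responses: np.ndarray  # % of reference maximum
    experiment_ids: np.ndarray  # label per point
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.experiment_ids = np.asarray(self.experiment_ids)
        self.replicates = np.asarray(self.replicates)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len({self.concentrations.size, self.responses.size, self.experiment_ids.size}) != 1:
            raise ValueError("point arrays must have equal length")

    @property
    def n_distinct_concentrations(self) -> int:
        return np.unique(self.concentrations).size

    def subset(self, experiment_id) -> "ConcentrationResponse":
        m = self.experiment_ids == experiment_id
        return ConcentrationResponse(
            self.compound,
            self.pathway,
            self.receptor_variant,
            self.concentrations[m],
            self.responses[m],
            self.experiment_ids[m],
            self.replicates[m],
        )


@dataclass
class LogisticFit:
    """Result of a three-parameter logistic fit.

    ``ec50`` is molar; ``emax`` and ``bottom`` are in % of the reference
    maximum.  CI fields are ``None`` when not yet computed or not
    determinable (a profile bound unreached within the search range).
    ``status`` is ``"ok"`` or ``"nd"``; for nd fits the parameter fields are
    ``None`` and ``nd_reason`` explains why.
    """

    ec50: float | None
    emax: float | None
    bottom: float | None
    rss: float | None
    n_points: int
    status: str = STATUS_OK
    nd_reason: str | None = None
    ec50_ci: tuple[float, float] | None = None
    emax_ci: tuple[float, float] | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    @classmethod
    def nd(cls, reason: str, n_points: int = 0) -> "LogisticFit":
        return cls(
            ec50=None, emax=None, bottom=None, rss=None,
            n_points=n_points, status=STATUS_ND, nd_reason=reason,
        )


def from_responses(responses: Sequence[AUCResponse]) -> dict[tuple, ConcentrationResponse]:
    """Group normalized AUC responses into per-(compound, pathway, variant)
    concentration–response datasets."""
    for r in responses:
        if r.response_normalized is None:
            raise PipelineOrderError(
                "responses must be normalized before curve fitting; "
                "run normalize_to_reference first"
            )
    out: dict[tuple, ConcentrationResponse] = {}
    groups = group_by(
        responses,
        lambda r: (r.annotation.compound, r.annotation.pathway, r.annotation.receptor_variant),
    )
    for key, group in groups.items():
        out[key] = ConcentrationResponse(
            compound=key[0],
            pathway=key[1],
            receptor_variant=key[2],
            concentrations=np.array([g.annotation.concentration for g in group]),
            responses=np.array([g.response_normalized for g in group]),
            experiment_ids=np.array([g.annotation.experiment_id for g in group]),
            replicates=np.array([g.annotation.replicate for g in group]),
        )
    return out


def _profile_rss(conc: np.ndarray, resp: np.ndarray, log_ec50: float):
    """Best (bottom, top, RSS) for a fixed log10 EC50 — exact linear solve."""
    w = conc / (conc + 10.0**log_ec50)
    a = np.column_stack([1.0 - w, w])
    coef, _, rank, _ = np.linalg.lstsq(a, resp, rcond=None)
    if rank < 2:  # w constant over the data: bottom/top not separable
        mean = float(np.mean(resp))
        resid = resp - mean
        return mean, mean, float(resid @ resid)
    resid = resp - a @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _fit_log_ec50(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float, float]:
    """Deterministic grid + bounded refinement over log10 EC50."""
    lo = np.log10(conc.min()) - GRID_PAD_DECADES
    hi = np.log10(conc.max()) + GRID_PAD_DECADES
    grid = np.arange(lo, hi + 0.5 * GRID_STEP, GRID_STEP)
    rss_grid = np.array([_profile_rss(conc, resp, x)[2] for x in grid])
    i = int(np.argmin(rss_grid))
    left = grid[max(i - 1, 0)]
    right = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: _profile_rss(conc, resp, x)[2],
        bounds=(left, right),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best_x = float(res.x) if res.fun <= rss_grid[i] else float(grid[i])
    bottom, top, rss = _profile_rss(conc, resp, best_x)
    return best_x, bottom, top, rss


def _rss_threshold(rss: float, n: int, level: float = 0.95) -> float:
    """Profile-likelihood RSS cutoff: RSS·(1 + F(1, n-3; level)/(n-3))."""
    dof = n - 3
    if dof < 1:
        return np.inf
    return rss * (1.0 + stats.f.ppf(level, 1, dof) / dof)


def fit_logistic3(data: ConcentrationResponse) -> LogisticFit:
    """Fit the three-parameter logistic to one concentration–response set.

    Raises ``ValueError`` for fewer than 4 distinct concentrations; returns
    an nd fit for data without usable dose dependence (see module notes).
    """
    if data.n_distinct_concentrations < 4:
        raise ValueError(
            f"{data.compound}/{data.pathway}: need >= 4 distinct concentrations, "
            f"got {data.n_distinct_concentrations}"
        )
    conc = data.concentrations
    resp = data.responses
    n = conc.size
    log_ec50, bottom, top, rss = _fit_log_ec50(conc, resp)

    # span significance: the flat model is the span = 0 profile point
    resid_flat = resp - np.mean(resp)
    rss_flat = float(resid_flat @ resid_flat)
    if rss_flat <= _rss_threshold(rss, n):
        return LogisticFit.nd(
            "top not distinguishable from bottom (no dose dependence)", n
        )
    if log_ec50 > np.log10(conc.max()):
        return LogisticFit.nd(
            f"fitted EC50 (10^{log_ec50:.2f} M) above the highest tested concentration", n
        )
    if not np.isfinite(rss):
        return LogisticFit.nd("fit did not converge", n)
    return LogisticFit(
        ec50=10.0**log_ec50, emax=top, bottom=bottom, rss=rss, n_points=n
    )


def _bracket_and_solve(fun, x0: float, step: float, max_steps: int, direction: int):
    """Walk from x0 until fun changes sign, then root-find; None if unreached."""
    prev = x0
    for k in range(1, max_steps + 1):
        x = x0 + direction * k * step
        if fun(x) >= 0:
            return float(optimize.brentq(fun, min(prev, x), max(prev, x), xtol=1e-12))
        prev = x
    return None


def confidence_intervals(
    fit: LogisticFit,
    data: ConcentrationResponse,
    level: float = 0.95,
    parameters: tuple[str, ...] = ("ec50", "emax"),
) -> LogisticFit:
    """Attach profile-likelihood CIs for EC50 and/or Emax to a fit.

    The interval endpoints are where the profiled RSS crosses
    RSS_min·(1 + F(1, n-3; level)/(n-3)) — the standard F-inversion, exact
    for linear models and near-exact here.  If an endpoint is not reached
    within the search range the CI is reported as not determinable
    (``None``), mirroring printed "n.d." interval entries.  nd fits pass
    through unchanged.
    """
    if not fit.ok:
        return fit
    conc, resp, n = data.concentrations, data.responses, data.concentrations.size
    if fit.rss <= max(1e-12, 1e-14 * float(resp @ resp)):
        # exact fit: the profile threshold collapses onto the estimate
        return replace(
            fit, ec50_ci=(fit.ec50, fit.ec50), emax_ci=(fit.emax, fit.emax)
        )
    threshold = _rss_threshold(fit.rss, n, level)
    out = replace(fit)
    log_ec50 = np.log10(fit.ec50)

    if "ec50" in parameters:
        gfun = lambda x: _profile_rss(conc, resp, x)[2] - threshold
        steps = int(PROFILE_SEARCH_DECADES / 0.25)
        lo = _bracket_and_solve(gfun, log_ec50, 0.25, steps, -1)
        hi = _bracket_and_solve(gfun, log_ec50, 0.25, steps, +1)
        out.ec50_ci = None if (lo is None or hi is None) else (10.0**lo, 10.0**hi)

    if "emax" in parameters:
        span = abs(fit.emax - fit.bottom)
        glo = np.log10(conc.min()) - GRID_PAD_DECADES
        ghi = np.log10(conc.max()) + GRID_PAD_DECADES
        grid = np.arange(glo, ghi + 0.25, GRID_STEP)

        def rss_fixed_top(top: float) -> float:
            def inner(x: float) -> float:
                w = conc / (conc + 10.0**x)
                one_w = 1.0 - w
                denom = float(one_w @ one_w)
                b = float((resp - top * w) @ one_w) / denom if denom > 0 else 0.0
                r = resp - b * one_w - top * w
                return float(r @ r)

            vals = [inner(x) for x in grid]
            i = int(np.argmin(vals))
            res = optimize.minimize_scalar(
                inner,
                bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
                method="bounded",
                options={"xatol": 1e-8},
            )
            return min(float(res.fun), vals[i])

        hfun = lambda top: rss_fixed_top(top) - threshold
        step = max(0.5, 0.05 * max(span, 10.0))
        lo = _bracket_and_solve(hfun, fit.emax, step, 400, -1)
        hi = _bracket_and_solve(hfun, fit.emax, step, 400, +1)
        out.emax_ci = None if (lo is None or hi is None) else (lo, hi)
    return out


def fit_per_experiment(data: ConcentrationResponse) -> dict[str, LogisticFit]:
    """One logistic fit per experiment, each on that experiment's points only.

    Experiments failing the fit preconditions (too few distinct
    concentrations) yield nd fits with a logged reason rather than an error.
    """
    fits: dict[str, LogisticFit] = {}
    for exp_id in sorted(set(data.experiment_ids.tolist())):
        sub = data.subset(exp_id)
        try:
            fits[exp_id] = fit_logistic3(sub)
        except ValueError as exc:
            logger.warning(
                "experiment %s for %s/%s: %s", exp_id, data.compound, data.pathway, exc
            )
            fits[exp_id] = LogisticFit.nd(str(exc), sub.concentrations.size)
    return fits


def logistic3(conc, bottom: float, top: float, ec50: float):
    """Evaluate the three-parameter logistic (exposed for oracles/plots)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) * conc / (conc + ec50)
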