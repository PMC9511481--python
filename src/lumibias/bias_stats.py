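"""Ligand-bias quantification: intrinsic relative activity and β-factors.

For each compound and pathway an intrinsic relative activity is computed
against a reference agonist,

    RAi = (Emax · EC50_ref) / (Emax_ref · EC50)

and the two pathways are combined into the bias factor

    β = log10(RAi_βarr2 / RAi_miniGαq).

β is 0 for the reference agonist by construction; β > 0 means preferential
β-arrestin-2 recruitment over miniGαq (relative to the reference), β < 0 the
opposite.  The reported β-factor is the arithmetic mean of the per-experiment
β values (each experiment's compound fits against the same experiment's
reference fits); a "combined" β from the pooled fits is reported alongside.

Significance of β against 0 is assessed nonparametrically: a Kruskal–Wallis
test across all compounds' per-experiment β sets (the reference contributing
its exact zeros), followed by Dunn's post-hoc comparison of each compound
against the reference group with Holm adjustment.  Wild-type versus mutant
receptor effects are summarized as EC50 fold changes and Emax drops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dose_response import LogisticFit
from .types import PATHWAY_ARR, PATHWAY_GQ

STATUS_OK = "ok"
STATUS_ND = "nd"


@dataclass(frozen=True)
class RAiValue:
    """Pathway-specific intrinsic relative activity versus the reference."""

    compound: str
    pathway: str
    reference: str
    value: float | None
    status: str = STATUS_OK

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclass
class BiasResult:
    """Per-compound bias summary.

    ``beta_per_experiment`` lists β computed experiment-wise;
    ``beta_mean`` is their arithmetic mean (the headline number);
    ``beta_combined`` comes from the pooled ("combined") fits.
    ``p_vs_reference`` is the Holm-adjusted Dunn p-value against the
    reference group, filled by :func:`test_bias_significance`.
    """

    compound: str
    reference: str
    beta_per_experiment: list[float] = field(default_factory=list)
    beta_mean: float | None = None
    beta_combined: float | None = None
    p_vs_reference: float | None = None
    significance: str = ""
    status: str = STATUS_OK
    nd_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@dataclass(frozen=True)
class MutantComparison:
    """WT → mutant change for one compound and pathway."""

    compound: str
    pathway: str
    fold_change_potency: float | None  # EC50_mutant / EC50_WT
    efficacy_drop: float | None  # Emax_WT - Emax_mutant, percentage points
    status: str = STATUS_OK


def compute_rai(
    fit: LogisticFit,
    ref_fit: LogisticFit,
    compound: str = "",
    pathway: str = "",
    reference: str = "",
) -> RAiValue:
    """RAi = (Emax·EC50_ref)/(Emax_ref·EC50); nd inputs give an nd result."""
    if not (fit.ok and ref_fit.ok):
        return RAiValue(compound, pathway, reference, None, STATUS_ND)
    value = (fit.emax * ref_fit.ec50) / (ref_fit.emax * fit.ec50)
    return RAiValue(compound, pathway, reference, value)


def compute_beta(rai_arr2: RAiValue, rai_gq: RAiValue) -> float | None:
    """β = log10(RAi_βarr2 / RAi_miniGαq); ``None`` for nd inputs."""
    if not (rai_arr2.ok and rai_gq.ok):
        return None
    if rai_arr2.compound != rai_gq.compound or rai_arr2.reference != rai_gq.reference:
        raise ValueError(
            "RAi values must share compound and reference: "
            f"{rai_arr2.compound}/{rai_arr2.reference} vs "
            f"{rai_gq.compound}/{rai_gq.reference}"
        )
    if rai_arr2.value <= 0 or rai_gq.value <= 0:
        return None
    return math.log10(rai_arr2.value / rai_gq.value)


def summarize_bias(
    compound: str,
    reference: str,
    per_experiment_fits: dict[str, dict[str, LogisticFit]],
    per_experiment_ref_fits: dict[str, dict[str, LogisticFit]],
    combined_fits: dict[str, LogisticFit],
    combined_ref_fits: dict[str, LogisticFit],
    min_experiments: int = 3,
) -> BiasResult:
    """Assemble per-experiment, averaged and combined β for one compound.

    ``per_experiment_fits`` maps pathway → {experiment_id → fit} for the
    compound, ``per_experiment_ref_fits`` the same for the reference;
    ``combined_*`` map pathway → pooled fit.  Each experiment's β uses that
    experiment's own reference fits, which is exactly why the averaged and
    the combined β can differ.  Fewer than ``min_experiments`` experiments
    with ok fits in both pathways gives an nd result.
    """
    exp_ids = sorted(
        set(per_experiment_fits.get(PATHWAY_ARR, {}))
        & set(per_experiment_fits.get(PATHWAY_GQ, {}))
        & set(per_experiment_ref_fits.get(PATHWAY_ARR, {}))
        & set(per_experiment_ref_fits.get(PATHWAY_GQ, {}))
    )
    betas: list[float] = []
    for e in exp_ids:
        rai_a = compute_rai(
            per_experiment_fits[PATHWAY_ARR][e],
            per_experiment_ref_fits[PATHWAY_ARR][e],
            compound, PATHWAY_ARR, reference,
        )
        rai_g = compute_rai(
            per_experiment_fits[PATHWAY_GQ][e],
            per_experiment_ref_fits[PATHWAY_GQ][e],
            compound, PATHWAY_GQ, reference,
        )
        b = compute_beta(rai_a, rai_g)
        if b is not None:
            betas.append(b)
    rai_a_c = compute_rai(
        combined_fits.get(PATHWAY_ARR, LogisticFit.nd("missing pathway")),
        combined_ref_fits.get(PATHWAY_ARR, LogisticFit.nd("missing pathway")),
        compound, PATHWAY_ARR, reference,
    )
    rai_g_c = compute_rai(
        combined_fits.get(PATHWAY_GQ, LogisticFit.nd("missing pathway")),
        combined_ref_fits.get(PATHWAY_GQ, LogisticFit.nd("missing pathway")),
        compound, PATHWAY_GQ, reference,
    )
    beta_combined = compute_beta(rai_a_c, rai_g_c)

    if len(betas) < min_experiments:
        return BiasResult(
            compound=compound,
            reference=reference,
            beta_per_experiment=betas,
            beta_combined=beta_combined,
            status=STATUS_ND,
            nd_reason=(
                f"only {len(betas)} experiments with determinable β in both "
                f"pathways (need {min_experiments})"
            ),
        )
    return BiasResult(
        compound=compound,
        reference=reference,
        beta_per_experiment=betas,
        beta_mean=float(np.mean(betas)),
        beta_combined=beta_combined,
    )


def kruskal_wallis(groups: list[list[float]]) -> float:
    """Kruskal–Wallis p-value across groups, midranks with tie correction.

    All-identical pooled data (the fully tied null) is reported as p = 1.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal–Wallis needs at least 2 groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def dunn_vs_control(
    groups: dict[str, list[float]], control: str, adjust: str = "holm"
) -> dict[str, float]:
    """Dunn's post-hoc z-test of each group against the control group.

    All groups are pooled and midranked; for each non-control group the
    statistic is z = (R̄_i - R̄_c) / sqrt(σ²(1/n_i + 1/n_c)) with
    σ² = N(N+1)/12 − Σ(t³−t)/(12(N−1)) correcting for ties; the two-sided
    normal p-values are then Holm-adjusted over the set of comparisons
    (``adjust="none"`` disables the adjustment).
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups")
    if len(groups) < 2:
        raise ValueError("Dunn test needs at least 2 groups")
    labels = [k for k in groups if k != control]
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in groups])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    i = 0
    for k in groups:
        n_k = len(groups[k])
        mean_ranks[k] = float(np.mean(ranks[i : i + n_k]))
        sizes[k] = n_k
        i += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    sigma2 = n_total * (n_total + 1) / 12.0 - tie_term
    raw: dict[str, float] = {}
    for k in labels:
        if sigma2 <= 0:  # everything tied: no evidence of any difference
            raw[k] = 1.0
            continue
        se = math.sqrt(sigma2 * (1.0 / sizes[k] + 1.0 / sizes[control]))
        z = (mean_ranks[k] - mean_ranks[control]) / se
        raw[k] = float(2.0 * stats.norm.sf(abs(z)))
    if adjust == "none":
        return raw
    if adjust != "holm":
        raise ValueError(f"unknown adjustment {adjust!r}")
    order = sorted(labels, key=lambda k: raw[k])
    m = len(order)
    adjusted: dict[str, float] = {}
    running = 0.0
    for rank_i, k in enumerate(order):
        running = max(running, min(1.0, (m - rank_i) * raw[k]))
        adjusted[k] = running
    return adjusted


def significance_stars(p: float | None) -> str:
    """Tiered annotation: ** for p < 0.01, * for p < 0.05, else empty."""
    if p is None:
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def test_bias_significance(
    results: list[BiasResult], adjust: str = "holm"
) -> tuple[list[BiasResult], float]:
    """Fill Dunn-vs-reference p-values and stars on a set of bias results.

    Returns the results (p fields filled in place on ok entries) and the
    Kruskal–Wallis omnibus p-value across all groups.  The reference group
    enters with its per-experiment zeros.
    """
    ok_results = [r for r in results if r.ok and r.beta_per_experiment]
    if len(ok_results) < 2:
        raise ValueError("need at least 2 groups (reference + 1 compound)")
    references = {r.reference for r in ok_results}
    if len(references) != 1:
        raise ValueError(f"results mix references: {sorted(references)}")
    reference = references.pop()
    groups = {r.compound: list(r.beta_per_experiment) for r in ok_results}
    if reference not in groups:
        raise ValueError(f"reference {reference!r} has no bias result in the set")
    kw_p = kruskal_wallis(list(groups.values()))
    dunn_p = dunn_vs_control(groups, reference, adjust=adjust)
    for r in results:
        if r.ok and r.compound in dunn_p:
            r.p_vs_reference = dunn_p[r.compound]
            r.significance = significance_stars(r.p_vs_reference)
    return results, kw_p


def compare_variants(fit_wt: LogisticFit, fit_mut: LogisticFit,
                     compound: str = "", pathway: str = "") -> MutantComparison:
    """Potency fold change (EC50_mut/EC50_WT) and efficacy drop (Emax_WT −
    Emax_mut) between receptor variants; nd inputs give an nd comparison."""
    if not (fit_wt.ok and fit_mut.ok):
        return MutantComparison(compound, pathway, None, None, STATUS_ND)
    return MutantComparison(
        compound=compound,
        pathway=pathway,
        fold_change_potency=fit_mut.ec50 / fit_wt.ec50,
        efficacy_drop=fit_wt.emax - fit_mut.emax,
    )
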