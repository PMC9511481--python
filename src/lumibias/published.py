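"""Published functional characterization of the N-benzylphenethylamine
series at the 5-HT2A receptor, used as worked-example inputs.

EC50 (nM, with 95% CI where printed) and Emax (% of the LSD maximum) from
the NanoBiT βarr2 and miniGαq recruitment assays at the wild-type and the
S159A-mutated receptor, 2 h AUC readout, LSD reference.  These cells are
*inputs* to the bias-statistics stage — β-factors, fold changes and
efficacy drops are recomputed from them at run time, which is the pipeline's
printed-value worked example.  ``beta_published`` carries the reported
β-factor (average of three per-experiment values) for comparison only.

``None`` encodes entries printed as "n.d." (not determined).
"""

from __future__ import annotations

from .bias_stats import compute_beta, compute_rai
from .dose_response import LogisticFit
from .types import PATHWAY_ARR, PATHWAY_GQ

REFERENCE = "LSD"

# compound -> pathway -> (ec50_nM, emax_pct)
WT_FUNCTIONAL_DATA: dict[str, dict[str, tuple[float, float]]] = {
    "5-HT": {PATHWAY_ARR: (12.1, 110.0), PATHWAY_GQ: (130.0, 222.0)},
    "LSD": {PATHWAY_ARR: (12.9, 99.7), PATHWAY_GQ: (13.2, 100.0)},
    "4a": {PATHWAY_ARR: (11.1, 112.0), PATHWAY_GQ: (48.8, 28.0)},
    "4b": {PATHWAY_ARR: (11.1, 113.0), PATHWAY_GQ: (44.4, 38.8)},
    "4c": {PATHWAY_ARR: (28.6, 96.6), PATHWAY_GQ: (23.0, 48.7)},
    "4d": {PATHWAY_ARR: (132.0, 121.0), PATHWAY_GQ: (174.0, 47.7)},
    "6a": {PATHWAY_ARR: (2.75, 150.0), PATHWAY_GQ: (8.59, 123.0)},
    "6b": {PATHWAY_ARR: (1.93, 161.0), PATHWAY_GQ: (6.71, 159.0)},
    "6c": {PATHWAY_ARR: (53.2, 114.0), PATHWAY_GQ: (168.0, 72.5)},
    "6d": {PATHWAY_ARR: (17.0, 114.0), PATHWAY_GQ: (45.1, 83.0)},
    "6e": {PATHWAY_ARR: (84.5, 106.0), PATHWAY_GQ: (301.0, 22.5)},
    "6f": {PATHWAY_ARR: (108.0, 82.9), PATHWAY_GQ: (631.0, 18.0)},
}

S159A_FUNCTIONAL_DATA: dict[str, dict[str, tuple[float, float]]] = {
    "5-HT": {PATHWAY_ARR: (661.0, 77.4), PATHWAY_GQ: (1672.0, 49.3)},
    "LSD": {PATHWAY_ARR: (5.19, 99.9), PATHWAY_GQ: (5.38, 99.5)},
    "4a": {PATHWAY_ARR: (172.0, 89.8), PATHWAY_GQ: (154.0, 21.0)},
    "4b": {PATHWAY_ARR: (81.9, 106.0), PATHWAY_GQ: (112.0, 44.7)},
    "6a": {PATHWAY_ARR: (37.7, 114.0), PATHWAY_GQ: (137.0, 70.3)},
    "6c": {PATHWAY_ARR: (661.0, 86.6), PATHWAY_GQ: (1126.0, 20.4)},
    "6e": {PATHWAY_ARR: (939.0, 68.2), PATHWAY_GQ: (2064.0, 12.9)},
    "6f": {PATHWAY_ARR: (1025.0, 90.8), PATHWAY_GQ: (1653.0, 13.8)},
}

# reported β-factor (mean over three experiments); None = n.d.
WT_BETA_PUBLISHED: dict[str, float | None] = {
    "5-HT": 0.576, "LSD": 0.0, "4a": 1.240, "4b": 1.100, "4c": 0.279,
    "4d": 0.558, "6a": 0.619, "6b": 0.526, "6c": 0.669, "6d": 0.638,
    "6e": 1.250, "6f": None,
}


def fit_from_values(ec50_nM: float, emax_pct: float) -> LogisticFit:
    """Wrap published (EC50, Emax) cells as an ok LogisticFit so the bias
    machinery can consume them (bottom 0, no residuals)."""
    return LogisticFit(
        ec50=ec50_nM * 1e-9, emax=emax_pct, bottom=0.0, rss=0.0, n_points=0
    )


def beta_from_published(
    compound: str,
    data: dict[str, dict[str, tuple[float, float]]] | None = None,
    reference: str = REFERENCE,
) -> float | None:
    """Combined bias factor of ``compound`` recomputed from published cells."""
    data = WT_FUNCTIONAL_DATA if data is None else data
    rai = {}
    for pathway in (PATHWAY_ARR, PATHWAY_GQ):
        ec50, emax = data[compound][pathway]
        ref_ec50, ref_emax = data[reference][pathway]
        rai[pathway] = compute_rai(
            fit_from_values(ec50, emax),
            fit_from_values(ref_ec50, ref_emax),
            compound, pathway, reference,
        )
    return compute_beta(rai[PATHWAY_ARR], rai[PATHWAY_GQ])
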