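"""Compute intrinsic relative activities and bias factors (β) per compound,
average the per-experiment β values, and test them against the reference
with Kruskal–Wallis + Dunn's post-hoc comparison (Holm-adjusted)."""

import pandas as pd

from lumibias.bias_stats import summarize_bias
from lumibias.bias_stats import test_bias_significance as fill_significance
from lumibias.dose_response import fit_logistic3, fit_per_experiment, from_responses
from lumibias.types import PATHWAY_ARR, PATHWAY_GQ

from _common import BIAS_CSV, REFERENCE, RESPONSES_CSV, load_responses

def main() -> None:
    datasets = from_responses(load_responses(RESPONSES_CSV))
    compounds = sorted({k[0] for k in datasets})
    per_exp, combined = {}, {}
    for name in compounds:
        per_exp[name], combined[name] = {}, {}
        for pathway in (PATHWAY_ARR, PATHWAY_GQ):
            data = datasets[(name, pathway, "WT")]
            per_exp[name][pathway] = fit_per_experiment(data)
            combined[name][pathway] = fit_logistic3(data)
    results = [
        summarize_bias(name, REFERENCE, per_exp[name], per_exp[REFERENCE],
                       combined[name], combined[REFERENCE])
        for name in compounds
    ]
    results, kw_p = fill_significance(results)
    print(f"Kruskal–Wallis across β groups: p = {kw_p:.4f}")
    rows = []
    for r in results:
        stars = r.significance or "ns"
        betas = ", ".join(f"{b:+.3f}" for b in r.beta_per_experiment)
        print(f"{r.compound:6s} β per experiment [{betas}]  mean "
              f"{r.beta_mean:+.3f}  combined {r.beta_combined:+.3f}  "
              f"p={r.p_vs_reference if r.p_vs_reference is not None else float('nan'):.4f} {stars}"
              if r.ok else f"{r.compound:6s} n.d. ({r.nd_reason})")
        rows.append(dict(
            compound=r.compound, reference=r.reference, status=r.status,
            beta_mean=r.beta_mean, beta_combined=r.beta_combined,
            p_vs_reference=r.p_vs_reference, significance=r.significance,
        ))
    pd.DataFrame(rows).to_csv(BIAS_CSV, index=False, float_format="%.10g")
    print(f"wrote {BIAS_CSV}")

if __name__ == "__main__":
    main()
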