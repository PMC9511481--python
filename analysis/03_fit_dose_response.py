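"""Fit three-parameter logistic concentration–response curves: one pooled
("combined") fit per compound and pathway with 95% profile-likelihood CIs,
plus per-experiment fits that feed the per-experiment bias factors."""

import pandas as pd

from lumibias.dose_response import (
    confidence_intervals,
    fit_logistic3,
    fit_per_experiment,
    from_responses,
)

from _common import FITS_CSV, RESPONSES_CSV, load_responses

def main() -> None:
    datasets = from_responses(load_responses(RESPONSES_CSV))
    rows = []
    for (compound, pathway, variant), data in sorted(datasets.items()):
        pooled = fit_logistic3(data)
        if pooled.ok:
            pooled = confidence_intervals(pooled, data)
        rows.append(dict(
            compound=compound, pathway=pathway, receptor_variant=variant,
            scope="combined", experiment_id="", status=pooled.status,
            ec50_molar=pooled.ec50,
            ec50_ci_lo=pooled.ec50_ci[0] if pooled.ec50_ci else None,
            ec50_ci_hi=pooled.ec50_ci[1] if pooled.ec50_ci else None,
            emax_pct=pooled.emax,
            emax_ci_lo=pooled.emax_ci[0] if pooled.emax_ci else None,
            emax_ci_hi=pooled.emax_ci[1] if pooled.emax_ci else None,
            bottom_pct=pooled.bottom, rss=pooled.rss, n_points=pooled.n_points,
        ))
        if pooled.ok:
            print(f"{compound:6s} {pathway:7s} EC50 "
                  f"{pooled.ec50*1e9:7.2f} nM "
                  f"[{pooled.ec50_ci[0]*1e9:.2f}–{pooled.ec50_ci[1]*1e9:.2f}]  "
                  f"Emax {pooled.emax:6.1f}% "
                  f"[{pooled.emax_ci[0]:.1f}–{pooled.emax_ci[1]:.1f}]")
        else:
            print(f"{compound:6s} {pathway:7s} n.d. ({pooled.nd_reason})")
        for exp_id, f in fit_per_experiment(data).items():
            rows.append(dict(
                compound=compound, pathway=pathway, receptor_variant=variant,
                scope="per_experiment", experiment_id=exp_id, status=f.status,
                ec50_molar=f.ec50, ec50_ci_lo=None, ec50_ci_hi=None,
                emax_pct=f.emax, emax_ci_lo=None, emax_ci_hi=None,
                bottom_pct=f.bottom, rss=f.rss, n_points=f.n_points,
            ))
    pd.DataFrame(rows).to_csv(FITS_CSV, index=False, float_format="%.10g")
    print(f"wrote {FITS_CSV}")

if __name__ == "__main__":
    main()
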