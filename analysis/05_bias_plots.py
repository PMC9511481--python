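"""Build the qualitative bias-plot series: equimolar (βarr2, miniGαq)
response pairs with SEM and a centered quadratic fit per compound.  The
numeric series go to results/; the rendered figure goes to scratch/ (it is
a view of the series, not an analysis product)."""

import pandas as pd

from lumibias.bias_plots import build_series, plot_series
from lumibias.types import PATHWAY_ARR, PATHWAY_GQ, group_by

from _common import REFERENCE, RESPONSES_CSV, SCRATCH, SERIES_CSV, load_responses

def main() -> None:
    responses = load_responses(RESPONSES_CSV)
    by_cp = group_by(responses, lambda r: (r.annotation.compound, r.annotation.pathway))
    compounds = sorted({k[0] for k in by_cp})
    series, rows = [], []
    for name in compounds:
        s = build_series(name, by_cp[(name, PATHWAY_ARR)], by_cp[(name, PATHWAY_GQ)])
        series.append(s)
        a, b, c = s.quad_coeffs
        print(f"{name:6s} quadratic y = {a:.2f} {b:+.3f}(x-x̄) {c:+.5f}(x-x̄)², "
              f"x̄ = {s.x_center:.1f}")
        for p in s.points:
            rows.append(dict(compound=name, concentration_molar=p.concentration,
                             x_barr2_pct=p.x, y_miniGq_pct=p.y,
                             x_sem=p.x_sem, y_sem=p.y_sem,
                             quad_a=a, quad_b=b, quad_c=c, x_center=s.x_center))
    pd.DataFrame(rows).to_csv(SERIES_CSV, index=False, float_format="%.10g")
    print(f"wrote {SERIES_CSV}")
    SCRATCH.mkdir(parents=True, exist_ok=True)
    fig = SCRATCH / "bias_plots.png"
    plot_series(series, REFERENCE, str(fig))
    print(f"rendered {fig}")

if __name__ == "__main__":
    main()
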