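"""Shared paths and small serialization helpers for the analysis drivers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from lumibias.types import AUCResponse, WellAnnotation

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch"

# the raw simulated plate is bulky regenerable data, not an analysis table
PLATE_CSV = SCRATCH / "plate_data.csv"
RESPONSES_CSV = RESULTS / "responses.csv"
FITS_CSV = RESULTS / "fits.csv"
BIAS_CSV = RESULTS / "bias_summary.csv"
SERIES_CSV = RESULTS / "bias_plot_series.csv"

SEED = 1
REFERENCE = "REF"
INJECTION_TIME = 600.0


def save_responses(responses: list[AUCResponse], path: Path) -> None:
    rows = [
        {
            "experiment_id": r.annotation.experiment_id,
            "compound": r.annotation.compound,
            "concentration_molar": r.annotation.concentration,
            "pathway": r.annotation.pathway,
            "receptor_variant": r.annotation.receptor_variant,
            "replicate": r.annotation.replicate,
            "auc_raw": r.auc_raw,
            "auc_corrected": r.auc_corrected,
            "response_normalized": r.response_normalized,
        }
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_responses(path: Path) -> list[AUCResponse]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AUCResponse(
                annotation=WellAnnotation(
                    compound=row.compound,
                    concentration=row.concentration_molar,
                    pathway=row.pathway,
                    receptor_variant=row.receptor_variant,
                    experiment_id=row.experiment_id,
                    replicate=int(row.replicate),
                    is_solvent_control=False,
                ),
                auc_raw=row.auc_raw,
                auc_corrected=row.auc_corrected,
                response_normalized=row.response_normalized,
            )
        )
    return out
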