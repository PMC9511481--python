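"""Process raw traces to normalized AUC responses: interwell correction
(divide by the pre-injection mean), trapezoidal AUC over the 2 h
post-agonist window, solvent-control subtraction, and normalization to the
reference agonist's maximal response (set to 100% per experiment)."""

import numpy as np

from lumibias.io_cli import read_plate_csv
from lumibias.trace_processing import process_study

from _common import INJECTION_TIME, PLATE_CSV, REFERENCE, RESPONSES_CSV, save_responses

def main() -> None:
    experiments = read_plate_csv(PLATE_CSV, injection_time=INJECTION_TIME)
    responses = process_study(experiments, REFERENCE)
    save_responses(responses, RESPONSES_CSV)
    top = [r.response_normalized for r in responses
           if r.annotation.compound == REFERENCE
           and r.annotation.concentration == 2.5e-5]
    print(f"processed {len(experiments)} experiments into "
          f"{len(responses)} normalized well responses")
    print(f"reference plateau responses average "
          f"{np.mean(top):.1f}% (anchored at 100% per experiment)")
    print(f"wrote {RESPONSES_CSV}")

if __name__ == "__main__":
    main()
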