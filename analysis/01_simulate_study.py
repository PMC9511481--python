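"""Simulate the study design: three independent experiments of the two
recruitment assays (βarr2, miniGαq) with a reference agonist, a strongly
βarr2-biased test compound and a high-efficacy test compound, duplicate
wells over the 1 pM – 25 µM decade series, matched solvent controls, and
2 h of post-agonist monitoring.  Writes the raw plate data CSV."""

from lumibias.io_cli import write_plate_csv
from lumibias.synthetic_data import simulate_study, table_like_study_spec

from _common import PLATE_CSV, RESULTS, SCRATCH, SEED

def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    spec = table_like_study_spec(seed=SEED)
    experiments = simulate_study(spec)
    write_plate_csv(experiments, PLATE_CSV)
    n_wells = sum(len(e.wells) for e in experiments)
    n_read = len(experiments[0].wells[0][1].times)
    print(f"simulated {len(experiments)} experiments, {n_wells} wells, "
          f"{n_read} readings per well (seed {SEED})")
    print(f"compound truth: " + ", ".join(
        f"{c.name} (βarr2 EC50 {c.true_ec50['barr2']*1e9:.3g} nM / "
        f"Emax {c.true_emax['barr2']:.3g}%)" for c in spec.compounds))
    print(f"wrote {PLATE_CSV}")

if __name__ == "__main__":
    main()
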