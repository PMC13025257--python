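"""Generate the synthetic study inputs.

Simulates one recurrent case with a planted +10%-per-timepoint nuclear
area drift and rising boundary irregularity, one flat (null) case, and a
three-sample annotated variant table with planted filter decoys and a
shared mutation core.  Raw contour tables go to scratch/sim/ (large,
regenerable); the planted-truth summaries go to results/.

Run from the repository root:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
import json
import math
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from nucleomorph.io import write_contours, write_variant_frame
from nucleomorph.synthetic import (
    TrajectoryPlan,
    VariantPlan,
    generate_case,
    generate_variant_table,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    root = pathlib.Path(__file__).resolve().parents[1]
    scratch = root / "scratch" / "sim"
    results = root / "results"
    scratch.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    rng = np.random.default_rng(args.seed)

    # recurrent-like case: +10% area per timepoint, irregularity rising
    drift = TrajectoryPlan(
        timepoints=("P", "R1", "R2", "R3"),
        radius_multipliers=tuple(math.sqrt(1.1) ** t for t in range(4)),
        irregularity=(0.05, 0.08, 0.11, 0.14),
    )
    specimens, truth = generate_case(drift, rng)
    for label, cs in specimens.items():
        write_contours(cs, scratch / f"drift_{label}.csv")
    truth.to_csv(results / "sim_drift_truth.csv", index=False)

    # non-recurrent-like flat case (null condition)
    flat = TrajectoryPlan(timepoints=("P", "R1", "R2", "R3"))
    specimens_flat, truth_flat = generate_case(flat, rng)
    for label, cs in specimens_flat.items():
        write_contours(cs, scratch / f"flat_{label}.csv")
    truth_flat.to_csv(results / "sim_flat_truth.csv", index=False)

    # variant tables: 70 passing + 10 decoys per rule per sample, 5 shared
    vplan = VariantPlan(n_passing=70, decoys_per_rule=10, shared_core=5,
                        samples=("S1", "S2", "S3"))
    vdf, vtruth = generate_variant_table(vplan, rng)
    write_variant_frame(vdf, scratch / "variants.tsv")
    vtruth.to_csv(results / "sim_variants_truth.csv", index=False)

    summary = {
        "seed": args.seed,
        "cases": {"drift": len(specimens), "flat": len(specimens_flat)},
        "nuclei_per_specimen": drift.nuclei_per_specimen,
        "variant_rows": len(vdf),
        "planted_passing_per_sample": vplan.n_passing + vplan.shared_core,
    }
    (results / "sim_manifest.json").write_text(json.dumps(summary, indent=2))
    print(f"simulated {sum(len(v) for v in specimens.values())} drift-case nuclei, "
          f"{len(vdf)} variant rows (seed {args.seed}) -> scratch/sim, results/")


if __name__ == "__main__":
    main()
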