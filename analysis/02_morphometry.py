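"""Measure the simulated specimens and test their longitudinal evolution.

Reads the contour tables written by 01_simulate.py, computes per-nucleus
shape descriptors and specimen-level summaries (medians, NACV), then
runs the longitudinal framework per case: Kruskal-Wallis omnibus over
timepoints with Bonferroni-adjusted pairwise Mann-Whitney post hocs.
The drift case should show significant consecutive-pair changes; the
flat case should not.

Run after 01_simulate.py:  python analysis/02_morphometry.py
"""

import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from nucleomorph.cohort import friedman_longitudinal, summarize_specimen
from nucleomorph.io import measurements_frame, read_contours

TIMEPOINTS = ("P", "R1", "R2", "R3")


def main() -> None:
    root = pathlib.Path(__file__).resolve().parents[1]
    scratch = root / "scratch" / "sim"
    results = root / "results"
    if not scratch.exists():
        sys.exit("run analysis/01_simulate.py first")

    summary_rows = []
    reports = {}
    for case in ("drift", "flat"):
        samples = []
        for t, label in enumerate(TIMEPOINTS):
            contours = read_contours(scratch / f"{case}_{label}.csv")
            m = measurements_frame(contours)
            s = summarize_specimen(m, f"{case}_{label}", case_id=case,
                                   timepoint=t, group="recurrent_case")
            summary_rows.append({
                "specimen_id": s.specimen_id, "case_id": case, "timepoint": t,
                "n_nuclei": s.n_nuclei, "mean_area": round(s.mean_area, 2),
                "nacv": round(s.nacv, 2),
                "median_area": round(s.medians["area"], 2),
                "median_formfactor": round(s.medians["formfactor"], 4),
                "median_max_feret": round(s.medians["max_feret"], 2),
            })
            samples.append(m["area"].tolist())
        res = friedman_longitudinal(samples, TIMEPOINTS)
        reports[case] = {
            "omnibus": res.method,
            "statistic": round(res.statistic, 2),
            "p": float(res.p_value),
            "pairwise": res.pairwise.to_dict(orient="records"),
            "exploratory": res.exploratory,
        }
        consec = res.pairwise[res.pairwise["consecutive"]]
        n_sig = int((consec["adjusted_p"] < 0.05).sum())
        print(f"{case}: omnibus p = {res.p_value:.3g}; "
              f"{n_sig}/{len(consec)} consecutive pairs significant")

    pd.DataFrame(summary_rows).to_csv(results / "specimen_summaries.csv", index=False)
    (results / "longitudinal_stats.json").write_text(json.dumps(reports, indent=2))
    print("wrote results/specimen_summaries.csv, results/longitudinal_stats.json")


if __name__ == "__main__":
    main()
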