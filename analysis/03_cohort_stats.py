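"""Re-derive every summary statistic from the packaged cohort table.

The per-specimen table (8 non-recurrent tumors, 4 recurrent cases with
serial specimens; Ki-67 %, p53 %, NACV, TMB) supports: group means,
the non-recurrent vs recurrent-case TMB contrast (exact Mann-Whitney),
the 75th-percentile TMB cutoff, and the high/low stratification at the
study cutoffs (Ki-67 > 5%, p53 > 10%, TMB > 6.5 Mut/Mb).

Run:  python analysis/03_cohort_stats.py
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from nucleomorph import study


def main() -> None:
    results = pathlib.Path(__file__).resolve().parents[1] / "results"
    results.mkdir(exist_ok=True)

    means = study.fixture_group_means()
    contrast = study.nrt_vs_rc_tmb()
    strat = study.fixture_stratification()
    p75 = study.tmb_percentile_cutoff()

    print(f"NRT mean TMB {means['nrt_tmb_mean']} vs recurrent-case "
          f"{means['rc_tmb_mean']} Mut/Mb (Mann-Whitney p = {contrast['p']})")
    print(f"Ki-67 means: NRT {means['nrt_ki67_mean']}%, recurrences "
          f"{means['recurrence_ki67_mean']}%, all RC {means['rc_ki67_mean']}%")
    print(f"TMB 75th percentile = {p75:.2f} Mut/Mb (study cutoff 6.5)")
    for name, s in strat.items():
        print(f"{name}: low n={s['n_low']} mean={s['covariate_mean_low']:.2f} | "
              f"high n={s['n_high']} mean={s['covariate_mean_high']:.2f} "
              f"(response {s['comparison']['response']}, "
              f"p={s['comparison']['p_value']:.3f})")

    out = {"group_means": means, "nrt_vs_rc_tmb": contrast,
           "tmb_p75": round(p75, 2), "stratification": strat}
    (results / "cohort_stats.json").write_text(json.dumps(out, indent=2))
    print("wrote results/cohort_stats.json")


if __name__ == "__main__":
    main()
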