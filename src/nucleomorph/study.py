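"""Cohort-fixture analyses: the printed per-specimen table re-derived.

These functions reproduce, from the packaged 25-row cohort fixture,
every summary statistic derivable from it: marker and TMB group means,
the high/low stratification at the study cutoffs (Ki-67 > 5%,
p53 > 10%, TMB > 6.5 Mut/Mb), the TMB 75th percentile, and the
non-recurrent versus recurrent-case Mann-Whitney comparison.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .cohort import (
    mann_whitney,
    percentile_cutoff,
    round_half_away,
    stratify_and_compare,
)
from .synthetic import load_table2_fixture

__all__ = [
    "fixture_group_means",
    "fixture_stratification",
    "nrt_vs_rc_tmb",
    "tmb_percentile_cutoff",
]

KI67_CUTOFF = 5.0
P53_CUTOFF = 10.0
TMB_CUTOFF = 6.5  # printed constant (the recomputed 75th percentile is 6.56)


def fixture_group_means(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Group means of the cohort table at printed precision.

    Groups: non-recurrent tumors (NRT), all recurrent-case specimens,
    recurrences only (non-primary), and recurrent-case primaries.
    """
    df = load_table2_fixture() if df is None else df
    nrt = df["group"] == "non_recurrent"
    rc = df["group"] == "recurrent_case"
    recurrence = rc & (df["timepoint"] > 0)
    primary_rc = rc & (df["timepoint"] == 0)

    def mean(mask, col, decimals):
        vals = df.loc[mask, col].dropna()
        return round_half_away(float(vals.mean()), decimals)

    return {
        "nrt_tmb_mean": mean(nrt, "tmb", 2),
        "rc_tmb_mean": mean(rc, "tmb", 2),
        "nrt_ki67_mean": mean(nrt, "ki67_pct", 1),
        "rc_ki67_mean": mean(rc, "ki67_pct", 1),
        "recurrence_ki67_mean": mean(recurrence, "ki67_pct", 1),
        "primary_rc_ki67_mean": mean(primary_rc, "ki67_pct", 1),
        "n_nrt": int(nrt.sum()),
        "n_rc": int(rc.sum()),
        "n_rc_sequenced": int(df.loc[rc, "tmb"].notna().sum()),
    }


def fixture_stratification(
    df: pd.DataFrame | None = None,
    ki67_cutoff: float = KI67_CUTOFF,
    p53_cutoff: float = P53_CUTOFF,
    tmb_cutoff: float = TMB_CUTOFF,
) -> dict[str, dict]:
    """High/low stratification of the cohort at the study cutoffs.

    For each covariate the response compared is TMB (and NACV as the
    morphometric response available at specimen level in the fixture).
    """
    df = load_table2_fixture() if df is None else df
    out = {}
    for name, cov, cut in [
        ("ki67", "ki67_pct", ki67_cutoff),
        ("p53", "p53_pct", p53_cutoff),
        ("tmb", "tmb", tmb_cutoff),
    ]:
        response = "nacv" if cov == "tmb" else "tmb"
        r = stratify_and_compare(df, cov, cut, response)
        d = {"comparison": dataclasses.asdict(r)}
        # group membership and per-group covariate means use every row
        # with a non-missing covariate (the printed per-group rows)
        vals = df[cov].dropna()
        low, high = vals[vals <= cut], vals[vals > cut]
        d["n_low"] = int(len(low))
        d["n_high"] = int(len(high))
        d["covariate_mean_low"] = float(low.mean())
        d["covariate_mean_high"] = float(high.mean())
        out[name] = d
    return out


def nrt_vs_rc_tmb(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Mann-Whitney U comparison of TMB: NRT vs sequenced RC specimens."""
    df = load_table2_fixture() if df is None else df
    nrt = df.loc[df["group"] == "non_recurrent", "tmb"].dropna()
    rc = df.loc[df["group"] == "recurrent_case", "tmb"].dropna()
    u, p = mann_whitney(nrt, rc)
    return {"U": u, "p": round(p, 3), "n_nrt": len(nrt), "n_rc": len(rc)}


def tmb_percentile_cutoff(df: pd.DataFrame | None = None, q: float = 0.75) -> float:
    """Linear-interpolation quantile of the sequenced TMB values."""
    df = load_table2_fixture() if df is None else df
    return percentile_cutoff(df["tmb"].dropna(), q)
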