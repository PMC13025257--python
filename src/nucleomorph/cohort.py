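"""Specimen-level aggregation and the cohort statistical framework.

The specimen — not the nucleus — is the primary statistical unit: nuclear
measurements are collapsed to specimen-level medians before any group
comparison, avoiding pseudo-replication across the hundreds of nuclei
traced per slide.  On top of that sit the nonparametric tests used for
the chordoma cohort: Shapiro–Wilk normality and Brown–Forsythe (Levene)
variance screening, Kruskal–Wallis across non-recurrent tumors,
Mann–Whitney U for two-group contrasts, and an exploratory
repeated-measures path (Friedman when blocks exist, otherwise
Kruskal–Wallis with pairwise post hocs) with Bonferroni adjustment for
longitudinal recurrence series.

Marker indices (Ki-67, p53) are percentages of positive tumor nuclei;
NACV (nuclear area coefficient of variation, SD/mean x 100) quantifies
size pleomorphism within a specimen, and the between-tumor CV applies
the same ratio across specimen-level medians.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpecimenSummary",
    "MarkerCount",
    "StratificationResult",
    "DegenerateStratificationError",
    "summarize_specimen",
    "nacv",
    "between_tumor_cv",
    "bland_altman",
    "marker_index",
    "percentile_cutoff",
    "stratify_and_compare",
    "mann_whitney",
    "kruskal_wallis",
    "friedman_longitudinal",
    "levene",
    "shapiro_wilk",
    "group_mean_report",
    "round_half_away",
]

DESCRIPTOR_COLUMNS = [
    "area",
    "circumference",
    "equivalent_diameter",
    "formfactor",
    "min_feret",
    "max_feret",
    "max_feret90",
    "feret_asymmetry",
]


class DegenerateStratificationError(ValueError):
    """A stratification cutoff left one group empty."""


@dataclass(frozen=True)
class SpecimenSummary:
    """Per-specimen aggregation; the unit entering every group test."""

    specimen_id: str
    case_id: str
    timepoint: int
    group: str  # {"non_recurrent", "recurrent_case"}
    n_nuclei: int
    medians: dict[str, float]
    mean_area: float
    sd_area: float
    nacv: float


@dataclass(frozen=True)
class MarkerCount:
    specimen_id: str
    marker: str  # {"ki67", "p53"}
    positive: int
    total: int


@dataclass(frozen=True)
class StratificationResult:
    covariate: str
    cutoff: float
    response: str
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    statistic: float
    p_value: float


def _sd(x: np.ndarray) -> float:
    # sample SD, n-1 denominator throughout
    return float(np.std(x, ddof=1))


def nacv(areas: Sequence[float]) -> float:
    """Nuclear area coefficient of variation: 100 * sample SD / mean."""
    a = np.asarray(areas, dtype=float)
    if len(a) < 2:
        raise ValueError("NACV requires at least 2 nuclei")
    mean = float(a.mean())
    if mean <= 0:
        raise ValueError("mean nuclear area must be positive")
    return 100.0 * _sd(a) / mean


def summarize_specimen(
    measurements: pd.DataFrame,
    specimen_id: str,
    case_id: str = "",
    timepoint: int = 0,
    group: str = "non_recurrent",
) -> SpecimenSummary:
    """Collapse a per-nucleus measurement table to one specimen row.

    ``measurements`` holds one row per nucleus with at least an ``area``
    column; medians are taken of every numeric descriptor present.
    """
    if len(measurements) == 0:
        raise ValueError("no nuclei to summarize")
    if "area" not in measurements.columns:
        raise ValueError("measurements must include an 'area' column")
    numeric = measurements.select_dtypes("number")
    medians = {col: float(numeric[col].median()) for col in numeric.columns}
    areas = measurements["area"].to_numpy(dtype=float)
    mean_area = float(areas.mean())
    sd_area = _sd(areas) if len(areas) > 1 else 0.0
    return SpecimenSummary(
        specimen_id=specimen_id,
        case_id=case_id or specimen_id,
        timepoint=timepoint,
        group=group,
        n_nuclei=len(measurements),
        medians=medians,
        mean_area=mean_area,
        sd_area=sd_area,
        nacv=nacv(areas) if len(areas) > 1 else 0.0,
    )


def between_tumor_cv(specimen_medians: Sequence[float]) -> float:
    """Between-tumor CV (%): 100 * SD / mean across specimen-level medians."""
    m = np.asarray(specimen_medians, dtype=float)
    if len(m) < 2:
        raise ValueError("between-tumor CV requires at least 2 specimens")
    return 100.0 * _sd(m) / float(m.mean())


def bland_altman(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, tuple[float, float]]:
    """Replicate-agreement bias and 95% limits of agreement.

    For duplicate sections (a, b): bias = mean(a - b), limits =
    bias +/- 1.96 * SD(a - b).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("Bland-Altman requires at least 2 replicate pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    spread = 1.96 * _sd(d)
    return bias, (bias - spread, bias + spread)


def marker_index(m: MarkerCount) -> float:
    """Percentage of positively stained tumor nuclei."""
    if m.total < 1:
        raise ValueError("total nuclei must be >= 1")
    if not 0 <= m.positive <= m.total:
        raise ValueError("positive count outside [0, total]")
    return 100.0 * m.positive / m.total


def percentile_cutoff(values: Sequence[float], q: float) -> float:
    """Linear-interpolation quantile at sorted position 1 + q*(n-1)."""
    v = np.asarray([x for x in values if not pd.isna(x)], dtype=float)
    if len(v) == 0:
        raise ValueError("no non-missing values")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(v, q))  # linear interpolation is the default


#: largest enumeration size for the exact tied-sample permutation null
_MAX_EXACT_COMBINATIONS = 400_000


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for the rank-sum statistic, ties included.

    Enumerates every assignment of the pooled ranks to the first sample
    and counts rank sums at least as far from the null mean as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    extreme = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= abs(observed - mean) - 1e-9:
            extreme += 1
    return extreme / total


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U and two-sided p.

    Exact null distribution when the combined sample is small
    (n_x + n_y <= 25): the closed-form tie-free distribution when there
    are no ties, otherwise full enumeration of the permutation null over
    the tied ranks.  Larger samples use the normal approximation with
    tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(pooled) <= 25
    u = float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    )
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    elif small and math.comb(len(pooled), len(x)) <= _MAX_EXACT_COMBINATIONS:
        p = _exact_permutation_p(x, y)
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    return u, min(p, 1.0)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all observations identical: no evidence, not an error
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def levene(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Brown–Forsythe (median-centered Levene) variance-homogeneity test."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 observations")
    arrays = [np.asarray(g, float) for g in groups]
    if all(np.ptp(a) == 0 for a in arrays):
        return 0.0, 1.0
    w, p = stats.levene(*arrays, center="median")
    return float(w), float(p)


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (3 <= n <= 5000)."""
    s = np.asarray(sample, dtype=float)
    if not 3 <= len(s) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(s) == 0:
        raise ValueError("W undefined for a constant sample")
    w, p = stats.shapiro(s)
    return float(w), float(p)


@dataclass
class LongitudinalResult:
    """Omnibus + pairwise post hoc output of the longitudinal comparison."""

    method: str  # "friedman" (blocked) or "kruskal_wallis" (unpaired fallback)
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: pair, raw_p, adjusted_p, consecutive
    exploratory: bool = True
    warnings: list[str] = field(default_factory=list)


def friedman_longitudinal(
    samples: Sequence[Sequence[float]],
    timepoint_labels: Sequence[str] | None = None,
    blocks: Sequence[Sequence[float]] | None = None,
) -> LongitudinalResult:
    """Longitudinal comparison across a case's ordered timepoints.

    ``samples`` holds the per-timepoint nucleus-level values.  When
    ``blocks`` is given (per-field-of-view medians aligned across
    timepoints, same length at each timepoint) a genuine Friedman
    repeated-measures test is run on those blocks; otherwise nuclei are
    unpaired and the omnibus degrades to Kruskal–Wallis.  Post hoc
    pairwise Mann–Whitney comparisons over all timepoint pairs are
    Bonferroni-adjusted by the number of pairs.  Output is flagged
    exploratory: the independent-patient count is tiny by design.
    """
    k = len(samples)
    labels = list(timepoint_labels) if timepoint_labels else [str(i) for i in range(k)]
    warnings: list[str] = []
    if k < 2:
        raise ValueError("need at least 2 timepoints")
    if k < 3:
        warnings.append("fewer than 3 timepoints: pairwise-only mode")
        omnibus_stat, omnibus_p = math.nan, math.nan
        method = "pairwise_only"
    elif blocks is not None:
        arr = np.asarray(blocks, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != k:
            raise ValueError("blocks must be (n_blocks, n_timepoints)")
        omnibus_stat, omnibus_p = stats.friedmanchisquare(*arr.T)
        method = "friedman"
    else:
        omnibus_stat, omnibus_p = kruskal_wallis(samples)
        method = "kruskal_wallis"
        warnings.append("no blocks available: unpaired Kruskal-Wallis omnibus")

    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        _, raw = mann_whitney(samples[i], samples[j])
        rows.append(
            {
                "pair": f"{labels[i]} vs {labels[j]}",
                "raw_p": raw,
                "adjusted_p": min(1.0, m * raw),
                "consecutive": j == i + 1,
            }
        )
    return LongitudinalResult(
        method=method,
        statistic=float(omnibus_stat),
        p_value=float(omnibus_p),
        pairwise=pd.DataFrame(rows),
        exploratory=True,
        warnings=warnings,
    )


def stratify_and_compare(
    table: pd.DataFrame,
    covariate: str,
    cutoff: float,
    response: str,
) -> StratificationResult:
    """Split specimens at a strict '>' cutoff and compare the response.

    Rows missing either column are dropped pairwise.  The high group is
    ``covariate > cutoff``; group means plus a two-sided Mann–Whitney U
    on the response are returned.  An empty stratum raises
    :class:`DegenerateStratificationError`.
    """
    sub = table[[covariate, response]].dropna()
    high = sub[sub[covariate] > cutoff][response].to_numpy(dtype=float)
    low = sub[sub[covariate] <= cutoff][response].to_numpy(dtype=float)
    if len(high) == 0 or len(low) == 0:
        raise DegenerateStratificationError(
            f"cutoff {cutoff} on {covariate!r} leaves an empty stratum"
        )
    u, p = mann_whitney(low, high)
    return StratificationResult(
        covariate=covariate,
        cutoff=cutoff,
        response=response,
        n_low=len(low),
        n_high=len(high),
        mean_low=float(low.mean()),
        mean_high=float(high.mean()),
        statistic=u,
        p_value=p,
    )


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero, matching report-table conventions."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def group_mean_report(
    table: pd.DataFrame,
    grouping: Mapping[str, "pd.Series | np.ndarray"],
    response: str,
    decimals: int = 2,
) -> dict[str, float]:
    """Per-group means of a response at printed precision.

    ``grouping`` maps a group label to a boolean row mask; missing
    responses are dropped within each group.  Rounding is half away from
    zero at ``decimals``.
    """
    out: dict[str, float] = {}
    for label, mask in grouping.items():
        vals = table.loc[np.asarray(mask, dtype=bool), response].dropna()
        if len(vals) == 0:
            raise ValueError(f"group {label!r} has no non-missing {response!r}")
        out[label] = round_half_away(float(vals.mean()), decimals)
    return out
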