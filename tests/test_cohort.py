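"""Specimen aggregation and the nonparametric statistical framework."""

import math

import numpy as np
import pandas as pd
import pytest

from nucleomorph import cohort
from nucleomorph.cohort import (
    DegenerateStratificationError,
    MarkerCount,
    bland_altman,
    between_tumor_cv,
    friedman_longitudinal,
    kruskal_wallis,
    levene,
    mann_whitney,
    marker_index,
    nacv,
    percentile_cutoff,
    round_half_away,
    shapiro_wilk,
    stratify_and_compare,
    summarize_specimen,
)
from nucleomorph.synthetic import load_table2_fixture

from conftest import enumerate_mann_whitney_p


class TestSpecimenSummary:
    def test_mean_sd_nacv(self):
        df = pd.DataFrame({"area": [8.0, 10.0, 12.0]})
        s = summarize_specimen(df, "sp1")
        assert s.mean_area == 10.0
        assert s.sd_area == pytest.approx(2.0)
        assert s.nacv == pytest.approx(20.0)

    def test_constant_areas_zero_nacv(self):
        s = summarize_specimen(pd.DataFrame({"area": [5.0] * 10}), "sp")
        assert s.nacv == 0.0

    def test_medians_match_sort_oracle(self, rng):
        df = pd.DataFrame(
            {"area": rng.lognormal(3.0, 0.3, 300), "formfactor": rng.uniform(0.5, 1, 300)}
        )
        s = summarize_specimen(df, "sp")
        for col in df.columns:
            vals = sorted(df[col])
            oracle = 0.5 * (vals[149] + vals[150])
            assert s.medians[col] == pytest.approx(oracle)

    def test_median_order_invariance(self, rng):
        df = pd.DataFrame({"area": rng.lognormal(3.0, 0.3, 101)})
        shuffled = df.sample(frac=1.0, random_state=1)
        assert summarize_specimen(df, "a").medians["area"] == pytest.approx(
            summarize_specimen(shuffled, "a").medians["area"]
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_specimen(pd.DataFrame({"area": []}), "sp")


class TestNacvAndCv:
    def test_simple_value(self):
        assert nacv([8, 10, 12]) == pytest.approx(20.0)

    def test_scale_invariance(self, rng):
        a = rng.lognormal(3.0, 0.4, 50)
        assert nacv(a * 3.7) == pytest.approx(nacv(a))

    def test_lognormal_closed_form(self, rng):
        # CV of lognormal(sigma) is sqrt(exp(sigma^2)-1); pool many draws
        sigma = 0.3
        expected = math.sqrt(math.exp(sigma**2) - 1.0) * 100  # 30.9
        vals = [nacv(rng.lognormal(3.0, sigma, 300)) for _ in range(40)]
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_between_tumor_cv(self):
        assert between_tumor_cv([8, 10, 12]) == pytest.approx(20.0)
        assert between_tumor_cv([5.0, 5.0, 5.0]) == 0.0
        # a formfactor-like set engineered to SD/mean = 0.0228
        m = 0.91
        sd_target = 0.0228 * m
        vals = [m - sd_target, m, m + sd_target]
        assert between_tumor_cv(vals) == pytest.approx(
            100 * np.std(vals, ddof=1) / np.mean(vals)
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            nacv([5.0])
        with pytest.raises(ValueError):
            between_tumor_cv([5.0])


class TestBlandAltman:
    def test_zero_bias_pairs(self):
        bias, _ = bland_altman([(1, 1.2), (2, 1.8)])
        assert bias == pytest.approx(0.0)

    def test_identical_replicates(self):
        bias, (lo, hi) = bland_altman([(3, 3), (4, 4), (5, 5)])
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_planted_offset_recovered(self, rng):
        from nucleomorph.synthetic import NucleusModel, duplicate_sections, generate_contour
        from nucleomorph.geometry import polygon_area

        contours = [generate_contour(NucleusModel(), rng, f"n{i}") for i in range(100)]
        areas = [polygon_area(c) for c in contours]
        replicate = duplicate_sections(contours, rng, offset_um2=0.5, noise_sd=0.3)
        bias, _ = bland_altman(list(zip(replicate, areas)))
        assert bias == pytest.approx(0.5, abs=0.12)


class TestMarkerIndex:
    @pytest.mark.parametrize("pos, tot, expected", [(50, 1000, 5.0), (0, 500, 0.0)])
    def test_index(self, pos, tot, expected):
        assert marker_index(MarkerCount("s", "ki67", pos, tot)) == expected

    def test_positive_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            marker_index(MarkerCount("s", "p53", 11, 10))

    def test_cohort_counting_scale(self):
        # 24,478 nuclei over 23 specimens: mean per-specimen counting effort
        assert round(24478 / 23) == 1064


class TestPercentileCutoff:
    def test_median_odd(self):
        assert percentile_cutoff([1, 2, 3, 4, 5], 0.5) == 3.0

    def test_interpolated(self):
        assert percentile_cutoff([1, 2, 3, 4], 0.75) == pytest.approx(3.25)

    def test_fixture_tmb_75th(self):
        df = load_table2_fixture()
        assert percentile_cutoff(df["tmb"], 0.75) == pytest.approx(6.56, abs=0.005)


class TestMannWhitney:
    def test_small_exact_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.5, 1, ny)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(enumerate_mann_whitney_p(x, y), abs=1e-10)

    def test_tied_small_sample_matches_permutation_oracle(self, rng):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0, 6.0]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(enumerate_mann_whitney_p(x, y), abs=1e-10)

    def test_fixture_nrt_vs_rc_tmb(self):
        df = load_table2_fixture()
        nrt = df.loc[df["group"] == "non_recurrent", "tmb"].dropna()
        rc = df.loc[df["group"] == "recurrent_case", "tmb"].dropna()
        _, p = mann_whitney(nrt, rc)
        assert round(p, 3) == 0.025


class TestOmnibusTests:
    def test_kruskal_two_groups_consistency(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        h, p_kw = kruskal_wallis([x, y])
        assert h > 0
        # k=2 Kruskal-Wallis is the rank-sum test: p-values agree closely
        from scipy.stats import ranksums

        assert p_kw == pytest.approx(ranksums(x, y).pvalue, rel=0.05)

    def test_identical_groups(self):
        h, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0]])
        assert h == 0.0 and p == 1.0

    def test_shifted_groups_power(self, rng):
        hits = 0
        for _ in range(100):
            groups = [rng.normal(d, 1.0, 300) for d in (0.0, 1.0, 2.0)]
            _, p = kruskal_wallis(groups)
            hits += p < 0.001
        assert hits >= 95

    def test_levene_null_calibration(self):
        rejections = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            groups = [r.normal(0, 1, 50) for _ in range(3)]
            _, p = levene(groups)
            rejections += p < 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_levene_power_and_degenerate(self, rng):
        _, p = levene([rng.normal(0, 1, 300), rng.normal(0, 10, 300)])
        assert p < 0.001
        w, p1 = levene([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert w == 0.0 and p1 == 1.0

    def test_shapiro_calibration(self):
        normal_ok = lognormal_rejected = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            _, p_n = shapiro_wilk(r.normal(0, 1, 500))
            _, p_l = shapiro_wilk(r.lognormal(0, 1, 500))
            normal_ok += p_n > 0.05
            lognormal_rejected += p_l < 0.001
        assert normal_ok >= 36  # >= 90%
        assert lognormal_rejected >= 38  # >= 95%

    def test_shapiro_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)


class TestFriedmanLongitudinal:
    def test_null_all_pairs_nonsignificant(self, rng):
        samples = [rng.normal(0, 1, 100) for _ in range(4)]
        res = friedman_longitudinal(samples)
        assert res.method == "kruskal_wallis"
        assert (res.pairwise["adjusted_p"] > 0.05).all()

    def test_bonferroni_definition(self, rng):
        samples = [rng.normal(0, 1, 30) for _ in range(4)]
        res = friedman_longitudinal(samples)
        m = len(res.pairwise)
        assert m == 6
        for _, row in res.pairwise.iterrows():
            assert row["adjusted_p"] == pytest.approx(min(1.0, m * row["raw_p"]))

    def test_planted_drift_detected(self, rng):
        # +10% location per timepoint at n=300: consecutive pairs significant
        samples = [rng.lognormal(math.log(30.0) + 0.1 * t, 0.3, 300) for t in range(4)]
        res = friedman_longitudinal(samples)
        consec = res.pairwise[res.pairwise["consecutive"]]
        assert (consec["adjusted_p"] < 0.001).all()

    def test_blocked_friedman_path(self, rng):
        blocks = rng.normal(0, 1, size=(10, 4)) + np.array([0, 0.5, 1.0, 1.5])
        samples = [blocks[:, t] for t in range(4)]
        res = friedman_longitudinal(samples, blocks=blocks)
        assert res.method == "friedman"
        assert res.p_value < 0.05
        assert res.exploratory

    def test_two_timepoints_falls_back_with_warning(self, rng):
        res = friedman_longitudinal([rng.normal(0, 1, 20), rng.normal(0, 1, 20)])
        assert res.method == "pairwise_only"
        assert res.warnings
        assert len(res.pairwise) == 1


class TestStratification:
    def test_p53_high_group(self):
        df = load_table2_fixture()
        r = stratify_and_compare(df, "p53_pct", 10.0, "nacv")
        assert r.n_high == 6

    def test_tmb_groups(self):
        df = load_table2_fixture()
        r = stratify_and_compare(df, "tmb", 6.5, "nacv")
        assert r.n_high == 6
        assert r.n_low == 16

    def test_degenerate_cutoff_rejected(self):
        df = load_table2_fixture()
        with pytest.raises(DegenerateStratificationError):
            stratify_and_compare(df, "ki67_pct", 1000.0, "nacv")


class TestGroupMeanReport:
    def test_rounding_half_away(self):
        assert round_half_away(2.345, 2) == 2.35
        assert round_half_away(-2.345, 2) == -2.35
        assert round_half_away(1.5, 0) == 2.0

    def test_fixture_group_means(self):
        df = load_table2_fixture()
        nrt = (df["group"] == "non_recurrent").to_numpy()
        rec = ((df["group"] == "recurrent_case") & (df["timepoint"] > 0)).to_numpy()
        out = cohort.group_mean_report(
            df, {"nrt": nrt, "recurrence": rec}, "tmb", decimals=2
        )
        assert out["nrt"] == 1.55
        out_ki = cohort.group_mean_report(
            df, {"recurrence": rec}, "ki67_pct", decimals=1
        )
        assert out_ki["recurrence"] == 7.1

    def test_empty_group_rejected(self):
        df = load_table2_fixture()
        with pytest.raises(ValueError):
            cohort.group_mean_report(df, {"none": np.zeros(len(df), bool)}, "tmb")
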