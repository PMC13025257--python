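# nucleomorph

Quantitative nuclear pleomorphism and mutational burden analysis for
serial tumor specimens, built around a cohort of long-term recurrent and
non-recurrent conventional chordomas.

Chordomas are rare malignant bone tumors with high multifocal recurrence
rates, and routine light microscopy does not reliably separate tumors
that will recur from those that will not. This package implements the
quantitative side of that question as a reusable, tested pipeline:

* **nuclear morphometry** from manually traced contours — area *A*,
  circumference *P*, circle-equivalent diameter 2√(A/π), formfactor
  4πA/P² (1 for a perfect circle), and the Feret family: MinFeret and
  MaxFeret (shortest/longest distance between parallel tangents, computed
  on the convex hull by rotating calipers), MaxFeret90 (the Feret
  diameter perpendicular to the MaxFeret chord), and the asymmetry
  MaxFeret − MaxFeret90;
* **densitometry** on grayscale H&E images — sum intensity, integrated
  optical density (SumDensity = Σ pixel intensity × pixel area), mean
  density, brightness, and a boundary-roughness texture surrogate;
* **specimen-level cohort statistics** — the specimen (not the nucleus)
  is the statistical unit: per-specimen medians, the nuclear area
  coefficient of variation NACV = 100·SD(A)/mean(A), between-tumor CV,
  Bland–Altman replicate QC, Shapiro–Wilk / Brown–Forsythe screening,
  Kruskal–Wallis, exact Mann–Whitney U, and an exploratory longitudinal
  path (Friedman with blocks, else Kruskal–Wallis + Bonferroni-adjusted
  pairwise post hocs);
* **tumor mutational burden** — a seven-rule somatic filter cascade
  (population MAF < 0.001, VAF ≥ 0.1, read depth ≥ 40, impact
  HIGH/MODERATE, AltAF index ≥ 0.15, nonsynonymous, internal-database
  count < 100) with TMB = passing variants / 35 Mb, SNV–InDel spectrum,
  transition/transversion counts, and shared-mutation Venn analysis;
* **synthetic data** — seeded generators for lognormal-size,
  Fourier-perturbed nucleus contours with controllable irregularity
  drift, rendered chromatin images, and variant tables with planted
  pass/fail records — plus the packaged 25-row per-specimen cohort table
  (Ki-67 %, p53 %, NACV, TMB).

## Worked example

The numbered drivers under `analysis/` run the full pipeline; outputs
land in `results/` (bulk intermediates in `scratch/`):

```
python analysis/01_simulate.py --seed 1
python analysis/02_morphometry.py
python analysis/03_cohort_stats.py
python analysis/04_tmb_spectrum.py
```

`03_cohort_stats.py` re-derives the cohort summary statistics from the
packaged per-specimen table and prints:

```
NRT mean TMB 1.55 vs recurrent-case 4.76 Mut/Mb (Mann-Whitney p = 0.025)
Ki-67 means: NRT 4.6%, recurrences 7.1%, all RC 6.5%
TMB 75th percentile = 6.56 Mut/Mb (study cutoff 6.5)
ki67: low n=11 mean=2.19 | high n=14 mean=8.84 (response tmb, p=0.095)
p53: low n=19 mean=1.24 | high n=6 mean=15.97 (response tmb, p=0.484)
tmb: low n=16 mean=1.10 | high n=6 mean=10.23 (response nacv, p=0.858)
```

Reading: non-recurrent tumors (NRT) carry a significantly lower
mutational burden than recurrent-case (RC) specimens (exact Mann–Whitney
p = 0.025), proliferation (Ki-67) is higher in recurrences than in
non-recurrent tumors, and stratifying specimens at the study cutoffs
(Ki-67 > 5 %, p53 > 10 %, TMB > 6.5 Mut/Mb) yields the high/low groups
with the means shown; none of the cross-covariate contrasts reach
significance at this cohort size.

`02_morphometry.py` measures the simulated serial case with a planted
+10 %-per-timepoint nuclear area drift and reports

```
drift: omnibus p = 5.88e-22; 2/3 consecutive pairs significant
flat: omnibus p = 0.785; 0/3 consecutive pairs significant
```

i.e. the longitudinal framework detects the planted drift and stays
quiet on the flat (null) case.

A shell interface to the same library is installed as `nucleomorph`
(`measure`, `summarize`, `compare`, `tmb`, `simulate` subcommands; see
`nucleomorph --help`).

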