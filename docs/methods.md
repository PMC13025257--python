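# Methods

## Morphometry on traced contours

A nucleus is an ordered, closed, counter-clockwise simple polygon with
vertices in micrometers; traced curves are assumed pre-sampled to
vertices (no spline smoothing). Validation removes duplicate
consecutive vertices, normalizes orientation, and rejects
self-intersections and contours below 10⁻⁶ µm² (manual-tracing
artifacts). Area is the shoelace sum, circumference the closed edge
sum.

The equivalent diameter is defined as the circle-equivalent diameter
2√(A/π); this is the standard morphometric convention and is consistent
with the circularity framing of the formfactor 4πA/P², which is bounded
by 1 (isoperimetric inequality) and attains it only in the circle limit.

Feret diameters are computed on the convex hull — for parallel-tangent
(support-function) definitions the hull and raw contour coincide, so
this is a numerical convenience, not an approximation. MaxFeret is the
maximum pairwise hull-vertex distance (the rotating-calipers diameter);
ties resolve to the smallest vertex-index pair so output is
deterministic. MinFeret is the minimum width over hull-edge-normal
directions, where the global minimum width of a convex body is always
attained. MaxFeret90 is the directional Feret width perpendicular to
the MaxFeret chord; MaxFeret − MaxFeret90 (≥ 0) indexes contour
asymmetry.

A caveat on sweep-based verification: the width-versus-angle function of
a polygon has V-shaped (first-order) minima at hull-edge normals, so a
finite angular sweep systematically overshoots the true MinFeret; the
overshoot is negligible for smooth, densely sampled nucleus contours but
reaches ~5·10⁻⁴ relative on sparse spiky polygons. Equivalence tests
against the 3600-direction sweep therefore run on nucleus-like contours;
spiky polygons are checked with one-sided bounds.

## Densitometry

Pixel membership uses the pixel-center test: pixel (row, col) belongs to
a nucleus when its center ((col+0.5)·mpp, (row+0.5)·mpp) lies inside the
polygon, with boundary ties counted inside — a reproducible rasterization
with no partial-pixel weighting. On transmitted-light H&E, dense
chromatin is *dark*, so the working intensity inverts raw gray against
the white level (255 for 8-bit, 65535 for 16-bit); this makes "denser
chromatin ⇒ higher density" literally true. A flag disables inversion
for fluorescence-like inputs. RGB converts to gray by Rec. 601 luma
weights before inversion (deterministic, bit-stable).

Sum intensity is the total working intensity over the region; sum
density (integrated optical density) multiplies by the per-pixel area in
µm²; mean density normalizes by region area; brightness is the mean
working intensity. Roughness — undefined in commercial morphometry
suites' public documentation — is implemented as the explicit surrogate
perimeter / convex-hull-perimeter (≥ 1, scale-invariant, 1 for convex
contours). Absolute density values from this module are surrogates for
proprietary instrument definitions and are not comparable across
software; only standardized within-study comparisons are meaningful.

## Specimen-level statistics

Because hundreds of nuclei are measured per slide, the specimen is the
primary statistical unit: nucleus-level measurements are collapsed to
per-specimen medians (plus mean/SD of area) before any group test,
avoiding pseudo-replication. NACV = 100·SD/mean of nuclear area
(sample SD, n−1 denominator everywhere "SD" appears); the between-tumor
CV applies the same ratio across specimen-level medians. Bland–Altman
replicate QC reports bias = mean(a−b) with 1.96·SD limits of agreement.

Test choices: Shapiro–Wilk for normality (3 ≤ n ≤ 5000), Brown–Forsythe
(median-centered Levene) for variance homogeneity, tie-corrected
Kruskal–Wallis across groups. Mann–Whitney U uses the exact tie-free
null distribution for combined n ≤ 25 without ties; with ties at small n
it enumerates the full permutation null over the midranks (cap 4·10⁵
combinations), and otherwise falls back to the normal approximation with
tie and continuity correction. The exact-permutation branch matters: on
the packaged cohort table the TMB contrast between non-recurrent and
recurrent-case specimens has cross-group ties, and the exact two-sided
p is 0.025 where the asymptotic path would report 0.029.

Longitudinal series within a case are exploratory by construction (few
independent patients, unequal timepoints). Nuclei are not matched
across timepoints, so a true repeated-measures Friedman test is run only
when per-field-of-view medians are available as blocks; otherwise the
omnibus degrades to Kruskal–Wallis across timepoints. In both paths,
pairwise Mann–Whitney post hocs over all timepoint pairs are
Bonferroni-adjusted with m = number of pairs, and results carry an
explicit exploratory flag.

Stratification uses strict ">" cutoffs (Ki-67 > 5 %, p53 > 10 %,
TMB > 6.5 Mut/Mb). Group membership and per-group covariate means use
every specimen with a non-missing covariate; the response comparison
drops missing values pairwise. A not-sequenced TMB is an explicit
sentinel (`NS`), never zero, and is never imputed. Note the TMB cutoff
is carried as the printed constant 6.5 although the 75th percentile of
the 22 sequenced values recomputes to 6.56. Report rounding is half
away from zero at the printed precision; p-values are reported to three
decimals with no correction across distinct descriptor families.

## Variant filtering and TMB

A record passes the cascade iff population MAF < 0.001 ∧ VAF ≥ 0.1 ∧
read depth ≥ 40 ∧ impact ∈ {HIGH, MODERATE} ∧ AltAF index ≥ 0.15 ∧
consequence ≠ synonymous ∧ internal-database count < 100. The passing
set is a pure conjunction (rule-order independent); the exclusion tally
additionally attributes each excluded record to the *first* failing rule
in the listing order above, alongside a marginal per-rule count.
"Read depth" and "AltAF index" are carried as separate columns from VAF
and thresholded independently; the upstream caller's exact definitions
of these indices are not public, so the two-column interpretation is an
explicit input-contract assumption. The table is consumed pre-annotated
(consequence/impact columns); no re-annotation is attempted, and
multi-allelic rows must be pre-split (the reader rejects comma-separated
alts).

TMB = passing count / 35 Mb callable exonic sequence (configurable).
All passing variants count, including InDels, after the synonymous
exclusion. Variant typing: single-base pair → SNV; longer alt sharing
the ref prefix → insertion; shorter alt → deletion; else complex (MNV).
Complex variants are excluded from Ti/Tv but count toward TMB.
Transitions are within-class substitutions (A↔G, C↔T); everything else
is a transversion; Ti + Tv equals the passing SNV count exactly.
Shared-mutation identity is (gene, protein change) when annotated —
"same amino acid change at the same position" — else genomic
coordinates.

## Synthetic data

The generator stands in for traced H&E nuclei, which cannot be shipped.
Contours are star-convex Fourier perturbations of a circle,
r(θ) = R·(1 + Σₖ₌₂ᴷ aₖ cos(kθ + φₖ)) with R lognormal (median
`mean_radius`, shape `radius_sigma`), aₖ ~ N(0, σ_irr/k), φₖ uniform,
polygonized at 256 vertices; self-intersecting draws are redrawn (≤ 100
attempts). The closed-form expected area πE[R²]·(1 + ½Σaₖ²) supports
parameter-recovery tests. Every descriptor responds smoothly and
monotonically to σ_irr, which is what makes the model useful as a
pleomorphism dial.

Defaults, chosen once to match the scale of conventional-chordoma
specimens: mean_radius 3.3 µm (mean area ≈ 36 µm², the low-30s µm²
range of real specimens), radius_sigma 0.15 (per-specimen nuclear-area
CV ≈ 30 %, the NACV scale of the cohort table), σ_irr 0.05 baseline with
K = 8 modes, and 300 nuclei per specimen (the minimum tracing effort
per real slide). The longitudinal power condition plants a +10 %
per-timepoint area drift (radius multiplier √1.1 per step) over 4
timepoints.

What the generator does *not* emulate: tissue architecture (lobules,
fibrous septa), the physaliphorous vacuolation of chordoma cells,
stain/fixation batch effects, or nucleus overlap and sectioning
artifacts. Passing calibration tests therefore demonstrates that the
statistical machinery behaves correctly on data with the assumed
distributional structure — not that real slides meet those assumptions.

The chromatin renderer paints the interior at a base tone darkened
linearly by a density parameter in [0, 1] plus Gaussian clumps, on a
white (255) background; its mask is exactly the shared rasterizer's
output, which pins the mask path and the contour path to each other.

Variant-table plans emit records satisfying every cascade threshold plus
one decoy family per rule, each decoy failing exactly its own rule, so
filter recovery is checkable record-by-record; an optional shared core
plants identical (gene, protein-change) variants across samples for the
Venn analysis. All generators are pure functions of (parameters, seed).

## Numerical and interface choices

Coordinates: contours live in a continuous micron frame (arbitrary
origin); images are 0-based, row-major, origin top-left; the only
conversion is microns_per_pixel, with pixel (row, col) centered at
((col+0.5)·mpp, (row+0.5)·mpp). CLI exit codes: 0 success, 2 input
validation, 3 statistical degeneracy (e.g., an empty stratum). Every
CLI run writes a JSON log (parameters, seed, dialect versions). Config
is a single TOML file; CLI flags take precedence; unknown keys are
rejected.

Problem sizes used by the shipped drivers and the acceptance script —
300 nuclei × 4 timepoints per simulated case, 40 Monte-Carlo seeds for
the power/null calibration, 100–200 polygons for geometric property
checks — are the package's standard desk-scale configuration; all are
parameters, not constants.

## Known limitations

Densitometry values are surrogates (see above); roughness showed no
consistent trend in the motivating cohort and nothing downstream depends
on it. The longitudinal framework treats timepoints as independent
groups when no blocking structure exists, which is conservative for
trend detection. The cohort table's printed group rows contain two
internal inconsistencies that recomputation resolves (a Ki-67-low group
printed as n = 10 whose printed mean matches the recomputed n = 11
grouping; low-group means printed as 1.27 % / 1.13 Mut/Mb that recompute
to 1.24 / 1.10); the package asserts the recomputed values.
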