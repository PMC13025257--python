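"""Synthetic inputs with the statistical structure the analysis assumes.

Real traced H&E nuclei are not distributable, so the generators here
stand in for them: star-convex contours with lognormal size and
Fourier-perturbed boundaries (the irregularity scale sigma_irr drives
every shape descriptor smoothly), rendered chromatin-textured grayscale
images, longitudinal specimen series with planted size/irregularity
drift, duplicate-section replicates, marker counts, and annotated
variant tables with planted pass/fail records for each filter rule.
Every generator is a pure function of (parameters, seed).

The packaged per-specimen cohort fixture (Ki-67 %, p53 %, NACV, TMB for
8 non-recurrent tumors and 4 recurrent cases with serial specimens) is
loaded by :func:`load_table2_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files as _pkg_files

import numpy as np
import pandas as pd
import shapely

from .densitometry import rasterize
from .geometry import Contour, InvalidContourError, validate_contour

__all__ = [
    "NucleusModel",
    "TrajectoryPlan",
    "VariantPlan",
    "generate_contour",
    "render_nucleus",
    "generate_case",
    "generate_variant_table",
    "load_table2_fixture",
    "expected_mean_area",
]


@dataclass(frozen=True)
class NucleusModel:
    """Lognormal-size, Fourier-perturbed star-convex nucleus model.

    Defaults target the conventional-chordoma scale: median radius
    3.3 um (area ~ 34 um^2) with radius_sigma 0.15, giving a per-specimen
    nuclear-area CV around 30% — the scale seen on real specimens.
    """

    mean_radius: float = 3.3  # um, lognormal median
    radius_sigma: float = 0.15  # lognormal shape parameter of the radius
    irregularity: float = 0.05  # sigma_irr, Fourier perturbation scale
    n_modes: int = 8  # highest angular mode K (modes 2..K)
    vertices_per_contour: int = 256


@dataclass(frozen=True)
class TrajectoryPlan:
    """Longitudinal drift plan for one synthetic case.

    ``radius_multipliers`` scale the model's median radius per timepoint
    (a +10%/timepoint *area* drift is multiplier sqrt(1.1)**t);
    ``irregularity`` gives sigma_irr per timepoint.  300 nuclei per
    specimen mirrors the minimum tracing effort per real slide.
    """

    timepoints: tuple[str, ...] = ("P", "R1", "R2", "R3")
    radius_multipliers: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    irregularity: tuple[float, ...] = (0.05, 0.05, 0.05, 0.05)
    nuclei_per_specimen: int = 300
    model: NucleusModel = NucleusModel()
    fields_per_specimen: int = 0  # >0: tag nuclei with field-of-view blocks

    def __post_init__(self) -> None:
        k = len(self.timepoints)
        if k < 1:
            raise ValueError("need at least one timepoint")
        if len(self.radius_multipliers) != k or len(self.irregularity) != k:
            raise ValueError("per-timepoint parameter lengths must match")
        if any(m <= 0 for m in self.radius_multipliers):
            raise ValueError("radius multipliers must be positive")


@dataclass(frozen=True)
class VariantPlan:
    """Planted composition of a synthetic annotated variant table."""

    n_passing: int = 70
    decoys_per_rule: int = 10  # each decoy fails exactly one cascade rule
    shared_core: int = 0  # variants planted identically across all samples
    samples: tuple[str, ...] = ("S1",)


def _draw_contour(model: NucleusModel, rng: np.random.Generator) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, model.vertices_per_contour, endpoint=False)
    radius = model.mean_radius * math.exp(model.radius_sigma * rng.standard_normal())
    r = np.full_like(theta, 1.0)
    for k in range(2, model.n_modes + 1):
        a_k = rng.normal(0.0, model.irregularity / k)
        phi_k = rng.uniform(0.0, 2.0 * math.pi)
        r += a_k * np.cos(k * theta + phi_k)
    r *= radius
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_contour(
    model: NucleusModel, rng: np.random.Generator, nucleus_id: str = "n0"
) -> Contour:
    """One validated nucleus contour; self-intersecting draws are redrawn."""
    for _ in range(100):
        verts = _draw_contour(model, rng)
        if np.any(np.hypot(verts[:, 0], verts[:, 1]) <= 0):
            continue
        try:
            return validate_contour(verts, nucleus_id)
        except InvalidContourError:
            continue
    raise RuntimeError("persistent self-intersection: inadmissible model")


def expected_mean_area(model: NucleusModel) -> float:
    """Closed-form expected contour area of the generative model.

    For r(theta) = R (1 + sum a_k cos(k theta + phi_k)) the enclosed area
    is pi R^2 (1 + 0.5 sum a_k^2); with R lognormal (median m, shape s)
    E[R^2] = m^2 exp(2 s^2) and E[a_k^2] = (sigma_irr/k)^2.
    """
    second_moment = model.mean_radius**2 * math.exp(2.0 * model.radius_sigma**2)
    fourier = 0.5 * sum(
        (model.irregularity / k) ** 2 for k in range(2, model.n_modes + 1)
    )
    return math.pi * second_moment * (1.0 + fourier)


def render_nucleus(
    c: Contour,
    chromatin_density: float,
    clump_count: int = 5,
    rng: np.random.Generator | None = None,
    microns_per_pixel: float = 0.25,
    pad_um: float = 1.0,
    base_tone: int = 200,
) -> tuple[np.ndarray, np.ndarray, Contour]:
    """Render one nucleus as an 8-bit brightfield-like image plus label mask.

    Background is white (255); the interior base tone darkens linearly
    with ``chromatin_density`` in [0, 1] and Gaussian chromatin clumps
    darken it further.  The contour is shifted into the image frame; the
    shifted contour is returned so measurements can use it directly.
    The mask is exactly the rasterization of the shifted contour.
    """
    if not 0.0 <= chromatin_density <= 1.0:
        raise ValueError("chromatin_density must be in [0, 1]")
    rng = rng or np.random.default_rng(0)
    v = c.vertices
    shift = pad_um - v.min(axis=0)
    shifted = validate_contour(v + shift, c.nucleus_id)
    extent = shifted.vertices.max(axis=0) + pad_um
    shape = (
        int(math.ceil(extent[1] / microns_per_pixel)),
        int(math.ceil(extent[0] / microns_per_pixel)),
    )
    region = rasterize(shifted, shape, microns_per_pixel)
    img = np.full(shape, 255.0)
    interior = base_tone - 150.0 * chromatin_density
    values = np.full(region.pixel_count, interior)
    centers_x = (region.cols + 0.5) * microns_per_pixel
    centers_y = (region.rows + 0.5) * microns_per_pixel
    centroid = shifted.vertices.mean(axis=0)
    radius_scale = float(np.abs(shifted.vertices - centroid).max())
    for _ in range(clump_count):
        cx, cy = centroid + rng.uniform(-0.4, 0.4, size=2) * radius_scale
        sigma = rng.uniform(0.15, 0.35) * radius_scale
        depth = rng.uniform(20.0, 60.0) * (0.25 + 0.75 * chromatin_density)
        d2 = (centers_x - cx) ** 2 + (centers_y - cy) ** 2
        values -= depth * np.exp(-d2 / (2.0 * sigma**2))
    img[region.rows, region.cols] = np.clip(values, 0.0, 255.0)
    mask = np.zeros(shape, dtype=np.uint16)
    mask[region.rows, region.cols] = 1
    return img.astype(np.uint8), mask, shifted


def generate_case(
    plan: TrajectoryPlan, rng: np.random.Generator
) -> tuple[dict[str, list[Contour]], pd.DataFrame]:
    """Serial specimens for one case plus the planted-parameter truth table.

    Returns ``{timepoint_label: [contours]}`` and a truth DataFrame with
    the per-timepoint multiplier, sigma_irr, and the closed-form expected
    mean area, enabling parameter-recovery tests.  When
    ``fields_per_specimen`` > 0, nucleus ids carry a field-of-view tag
    ``f<k>`` usable as repeated-measures blocks.
    """
    specimens: dict[str, list[Contour]] = {}
    truth_rows = []
    for t, label in enumerate(plan.timepoints):
        model = NucleusModel(
            mean_radius=plan.model.mean_radius * plan.radius_multipliers[t],
            radius_sigma=plan.model.radius_sigma,
            irregularity=plan.irregularity[t],
            n_modes=plan.model.n_modes,
            vertices_per_contour=plan.model.vertices_per_contour,
        )
        contours = []
        for i in range(plan.nuclei_per_specimen):
            if plan.fields_per_specimen > 0:
                fov = i % plan.fields_per_specimen
                nid = f"{label}_f{fov}_n{i}"
            else:
                nid = f"{label}_n{i}"
            contours.append(generate_contour(model, rng, nid))
        specimens[label] = contours
        truth_rows.append(
            {
                "timepoint": label,
                "radius_multiplier": plan.radius_multipliers[t],
                "irregularity": plan.irregularity[t],
                "expected_mean_area": expected_mean_area(model),
                "n_nuclei": plan.nuclei_per_specimen,
            }
        )
    return specimens, pd.DataFrame(truth_rows)


# -- variant tables ----------------------------------------------------------

_GENES = ["TP53", "PIK3CA", "KRAS", "BRAF", "EGFR", "PTEN", "RB1", "SMARCB1"]
_AA = "ARNDCQEGHILKMFPSTWYV"


def _passing_record(rng: np.random.Generator, sample_id: str, idx: int) -> dict:
    ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
    kind = rng.choice(["snv", "snv", "snv", "ins", "del"])
    if kind == "ins":
        ref, alt = ref, ref + alt
        consequence = "frameshift"
        impact = "HIGH"
    elif kind == "del":
        ref, alt = ref + alt, ref
        consequence = "frameshift"
        impact = "HIGH"
    else:
        consequence = str(rng.choice(["missense", "missense", "missense", "nonsense"]))
        impact = "MODERATE" if consequence == "missense" else "HIGH"
    pos = int(rng.integers(1, 10_000_000))
    aa_pos = int(rng.integers(1, 500))
    return {
        "sample_id": sample_id,
        "chrom": f"chr{int(rng.integers(1, 23))}",
        "pos": pos,
        "ref": str(ref),
        "alt": str(alt),
        "gene": str(rng.choice(_GENES)),
        "protein_change": f"p.{_AA[int(rng.integers(20))]}{aa_pos}{_AA[int(rng.integers(20))]}",
        "consequence": consequence,
        "impact": impact,
        "vaf": round(float(rng.uniform(0.1, 0.6)), 3),
        "alt_af_index": round(float(rng.uniform(0.15, 0.6)), 3),
        "read_depth": int(rng.integers(40, 400)),
        "pop_maf": round(float(rng.uniform(0.0, 0.0009)), 6),
        "internal_db_count": int(rng.integers(0, 100)),
    }


#: per-rule overrides that make a record fail exactly that rule
_DECOY_OVERRIDES = {
    "pop_maf": {"pop_maf": 0.01},
    "vaf": {"vaf": 0.05},
    "read_depth": {"read_depth": 20},
    "impact": {"impact": "LOW", "consequence": "other"},
    "alt_af_index": {"alt_af_index": 0.05},
    # keep impact MODERATE so the synonymous decoy fails only its own rule
    "synonymous": {"consequence": "synonymous", "impact": "MODERATE"},
    "internal_db": {"internal_db_count": 150},
}


def generate_variant_table(
    plan: VariantPlan, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotated variant table plus a truth sidecar.

    Per sample: ``n_passing`` records satisfying every cascade threshold,
    ``decoys_per_rule`` records per rule each failing only that rule, and
    optionally a ``shared_core`` of identical (gene, protein change)
    variants planted in every sample.  The sidecar lists each record's
    planted role (``pass``, ``decoy:<rule>``, ``core``).
    """
    rows, truth = [], []
    core: list[dict] | None = None
    if plan.shared_core > 0:
        core = []
        for i in range(plan.shared_core):
            rec = _passing_record(rng, "core", i)
            while len(rec["ref"]) != 1 or len(rec["alt"]) != 1:
                rec = _passing_record(rng, "core", i)  # keep cores as SNVs
            core.append(rec)
    for sample in plan.samples:
        if core is not None:
            for rec in core:
                r = dict(rec, sample_id=sample)
                rows.append(r)
                truth.append({"sample_id": sample, "role": "core", **_key_of(r)})
        for i in range(plan.n_passing):
            r = _passing_record(rng, sample, i)
            rows.append(r)
            truth.append({"sample_id": sample, "role": "pass", **_key_of(r)})
        for rule, overrides in _DECOY_OVERRIDES.items():
            for i in range(plan.decoys_per_rule):
                base = _passing_record(rng, sample, i)
                if rule in ("impact", "synonymous") and len(base["ref"]) != len(base["alt"]):
                    base["ref"], base["alt"] = "C", "T"  # keep consequence coherent
                r = {**base, **overrides}
                rows.append(r)
                truth.append(
                    {"sample_id": sample, "role": f"decoy:{rule}", **_key_of(r)}
                )
    from .tmb import TSV_COLUMNS

    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    return df, pd.DataFrame(truth)


def _key_of(rec: dict) -> dict:
    return {
        "chrom": rec["chrom"],
        "pos": rec["pos"],
        "ref": rec["ref"],
        "alt": rec["alt"],
        "gene": rec["gene"],
        "protein_change": rec["protein_change"],
    }


def duplicate_sections(
    contours: list[Contour],
    rng: np.random.Generator,
    offset_um2: float = 0.0,
    noise_sd: float = 0.5,
) -> list[float]:
    """Replicate-section areas: each nucleus area re-measured with a planted
    systematic offset (um^2) plus tracing noise, for Bland–Altman QC."""
    from .geometry import polygon_area

    out = []
    for c in contours:
        a = polygon_area(c)
        out.append(a + offset_um2 + rng.normal(0.0, noise_sd))
    return out


# -- packaged fixture --------------------------------------------------------


def load_table2_fixture() -> pd.DataFrame:
    """The printed per-specimen cohort table (25 rows).

    Columns: case_id, specimen, group, timepoint, ki67_pct, p53_pct,
    nacv, tmb — with TMB NaN where the specimen was not sequenced
    (written as the literal ``NS`` sentinel on disk, never zero).
    """
    path = _pkg_files("nucleomorph.data").joinpath("table2_cohort.csv")
    with path.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype={"case_id": str, "specimen": str}, na_values=["NS"])
    df["specimen_id"] = "C" + df["case_id"] + "_" + df["specimen"]
    return df
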