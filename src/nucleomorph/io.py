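"""Readers and writers for the pipeline's file dialects.

Dialects (all UTF-8, '.' decimal separator):

* contour CSV — ``nucleus_id,vertex_index,x_um,y_um``; vertices grouped
  by nucleus, ordered by vertex_index; coordinates in micrometers.
* measurement CSV — one row per nucleus, shape (and optionally density)
  descriptor columns.
* cohort CSV — ``case_id,specimen,group,timepoint,ki67_pct,p53_pct,
  nacv,tmb`` with the literal ``NS`` for a not-sequenced TMB.
* variant TSV — tab-separated with the annotated-variant columns of
  :mod:`nucleomorph.tmb`.
* images — 8/16-bit grayscale or RGB TIFF/PNG; label masks as 16-bit
  single-channel images where value k marks nucleus k.

Coordinate convention, stated once and enforced everywhere: contours
live in a continuous micron frame with arbitrary origin; images are
0-based, row-major, origin top-left; the only conversion between them is
``microns_per_pixel``, with pixel (row, col) centered at
``((col+0.5)*mpp, (row+0.5)*mpp)``.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from skimage import measure as _skmeasure

from .geometry import Contour, measure_shape, validate_contour
from .tmb import FilterConfig, records_from_frame, records_to_frame, VariantRecord

__all__ = [
    "read_contours",
    "write_contours",
    "contours_from_mask",
    "read_image",
    "write_image",
    "measurements_frame",
    "read_cohort",
    "write_cohort",
    "read_variants",
    "write_variants",
    "RunConfig",
    "load_config",
    "write_run_log",
]

DIALECT_VERSIONS = {"contour_csv": 1, "cohort_csv": 1, "variant_tsv": 1}

CONTOUR_COLUMNS = ["nucleus_id", "vertex_index", "x_um", "y_um"]
COHORT_COLUMNS = [
    "case_id", "specimen", "group", "timepoint", "ki67_pct", "p53_pct", "nacv", "tmb",
]


def read_contours(path: str | Path) -> list[Contour]:
    df = pd.read_csv(path, dtype={"nucleus_id": str})
    missing = [c for c in CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contour CSV missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("contour CSV contains no vertices")
    contours = []
    for nid, grp in df.groupby("nucleus_id", sort=True):
        grp = grp.sort_values("vertex_index")
        contours.append(validate_contour(grp[["x_um", "y_um"]].to_numpy(), str(nid)))
    return contours


def write_contours(contours: Iterable[Contour], path: str | Path) -> None:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.vertices):
            rows.append((c.nucleus_id, i, x, y))
    pd.DataFrame(rows, columns=CONTOUR_COLUMNS).to_csv(path, index=False)


def contours_from_mask(mask: np.ndarray, microns_per_pixel: float = 1.0) -> list[Contour]:
    """Extract nucleus boundaries from a label mask as micron contours.

    Each label k > 0 yields one contour traced at the half-level between
    the label and the background, with (row, col) index coordinates
    mapped to pixel-center microns.
    """
    contours = []
    for label in np.unique(mask):
        if label == 0:
            continue
        binary = (mask == label).astype(float)
        traces = _skmeasure.find_contours(binary, 0.5)
        if not traces:
            continue
        trace = max(traces, key=len)  # outer boundary
        xy = np.column_stack(
            [(trace[:, 1] + 0.5) * microns_per_pixel,
             (trace[:, 0] + 0.5) * microns_per_pixel]
        )
        contours.append(validate_contour(xy, str(int(label))))
    return contours


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    else:
        from PIL import Image

        Image.fromarray(image).save(path)


def measurements_frame(contours: Iterable[Contour]) -> pd.DataFrame:
    """Shape descriptors for a set of contours, ordered by nucleus_id."""
    rows = []
    for c in sorted(contours, key=lambda c: c.nucleus_id):
        d = dataclasses.asdict(measure_shape(c))
        rows.append({"nucleus_id": c.nucleus_id, **d})
    return pd.DataFrame(rows)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"case_id": str, "specimen": str}, na_values=["NS"],
        keep_default_na=True,
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    df["specimen_id"] = "C" + df["case_id"] + "_" + df["specimen"]
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    out = df[COHORT_COLUMNS].copy()
    # not-sequenced is an explicit sentinel, never zero
    out["tmb"] = out["tmb"].map(lambda v: "NS" if pd.isna(v) else v)
    out.to_csv(path, index=False)


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return records_from_frame(df)


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    records_to_frame(list(records)).to_csv(path, sep="\t", index=False)


def write_variant_frame(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration; CLI flags override file values."""

    microns_per_pixel: float | None = None
    invert_intensity: bool = True
    cutoff_ki67: float = 5.0
    cutoff_p53: float = 10.0
    cutoff_tmb: float = 6.5
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1
    filter_overrides: dict = dataclasses.field(default_factory=dict)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(**self.filter_overrides)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a TOML run configuration; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.filter_config()  # validate overrides eagerly
    return cfg


def write_run_log(
    path: str | Path, command: str, params: dict, seed: int | None = None
) -> None:
    """Machine-readable reproducibility log for one CLI run."""
    log = {
        "command": command,
        "params": {k: v for k, v in params.items() if not isinstance(v, (bytes,))},
        "seed": seed,
        "dialect_versions": DIALECT_VERSIONS,
    }
    Path(path).write_text(json.dumps(log, indent=2, default=str))
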