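"""Somatic variant filtering, tumor mutational burden, and spectrum.

The filter cascade reduces an annotated whole-exome variant table to
high-confidence nonsynonymous somatic calls.  A record passes iff all of:

* population minor allele frequency (gnomAD-total-style) < 0.001
* variant allele frequency (VAF) >= 0.1
* read depth (reads-index) >= 40
* annotated impact HIGH or MODERATE
* AltAF index >= 0.15
* consequence is not synonymous
* internal-database occurrence count < 100 (germline/artifact screen)

TMB is then the passing-variant count per 35 Mb of callable exonic
sequence.  The spectrum decomposes passing calls into SNV / insertion /
deletion, the SNVs into missense / nonsense / other, and substitutions
into transitions (within a nucleotide class: A<->G, C<->T) versus
transversions (between classes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, fields
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "TmbReport",
    "VariantParseError",
    "classify_variant_type",
    "classify_substitution",
    "apply_filters",
    "compute_tmb",
    "shared_mutations",
    "FILTER_RULES",
]

_BASES = set("ACGT")
_PURINES = set("AG")
CONSEQUENCES = {
    "synonymous",
    "missense",
    "nonsense",
    "splice",
    "frameshift",
    "inframe_indel",
    "other",
}
IMPACTS = {"HIGH", "MODERATE", "LOW", "MODIFIER"}


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant (pre-split, single alt allele)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    protein_change: str | None
    consequence: str
    impact: str
    vaf: float
    alt_af_index: float
    read_depth: int
    pop_maf: float
    internal_db_count: int

    def __post_init__(self) -> None:
        if "," in self.alt:
            raise VariantParseError(
                f"multi-allelic alt {self.alt!r}: rows must be pre-split"
            )
        if not (set(self.ref) <= _BASES and set(self.alt) <= _BASES):
            raise VariantParseError(f"invalid allele {self.ref!r}->{self.alt!r}")
        if self.ref == self.alt:
            raise VariantParseError("ref equals alt")
        if self.pos < 1:
            raise VariantParseError("pos must be >= 1")
        for name in ("vaf", "alt_af_index", "pop_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise VariantParseError(f"{name}={v} outside [0, 1]")
        object.__setattr__(self, "impact", self.impact.upper())
        if self.impact not in IMPACTS:
            raise VariantParseError(f"unknown impact {self.impact!r}")
        if self.consequence not in CONSEQUENCES:
            raise VariantParseError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple:
        """Shared-mutation identity: same amino acid change at the same
        position when annotated, else genomic coordinates."""
        if self.gene and self.protein_change:
            return (self.gene, self.protein_change)
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    max_pop_maf: float = 0.001
    min_vaf: float = 0.1
    min_reads: int = 40
    allowed_impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    min_alt_af_index: float = 0.15
    exclude_synonymous: bool = True
    max_internal_db_count: int = 99  # exclude >= 100
    callable_mb: float = 35.0

    def __post_init__(self) -> None:
        if self.callable_mb <= 0:
            raise ValueError("callable_mb must be positive")


#: rule name -> predicate(record, cfg) returning True when the record PASSES,
#: in the cascade's listing order (fixes "first failing rule" attribution)
FILTER_RULES: dict[str, callable] = {
    "pop_maf": lambda r, c: r.pop_maf < c.max_pop_maf,
    "vaf": lambda r, c: r.vaf >= c.min_vaf,
    "read_depth": lambda r, c: r.read_depth >= c.min_reads,
    "impact": lambda r, c: r.impact in c.allowed_impacts,
    "alt_af_index": lambda r, c: r.alt_af_index >= c.min_alt_af_index,
    "synonymous": lambda r, c: not (c.exclude_synonymous and r.consequence == "synonymous"),
    "internal_db": lambda r, c: r.internal_db_count <= c.max_internal_db_count,
}


@dataclass
class TmbReport:
    sample_id: str
    n_input: int
    n_pass: int
    tmb: float
    first_fail: dict[str, int]
    rule_marginal: dict[str, int]
    spectrum: dict[str, int]  # SNV / insertion / deletion / complex
    snv_classes: dict[str, int]  # missense / nonsense / other
    ti: int
    tv: int


def classify_variant_type(ref: str, alt: str) -> str:
    """SNV / insertion / deletion / complex from the allele pair."""
    if not ref or not alt or not (set(ref) <= _BASES and set(alt) <= _BASES):
        raise VariantParseError(f"invalid alleles {ref!r}->{alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "complex"


def classify_substitution(ref: str, alt: str) -> str:
    """Transition (within purines or within pyrimidines) or transversion."""
    if len(ref) != 1 or len(alt) != 1:
        raise VariantParseError("substitution classes apply to single bases only")
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise VariantParseError(f"invalid substitution {ref}->{alt}")
    return "transition" if (ref in _PURINES) == (alt in _PURINES) else "transversion"


def apply_filters(
    records: Iterable[VariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[VariantRecord], dict[str, dict[str, int]]]:
    """Run the cascade; return (passing records, exclusion tallies).

    The tally carries both a ``first_fail`` count (each excluded record
    attributed to the first rule it fails, in cascade order) and a
    ``rule_marginal`` count (every rule each record fails).  The passing
    set is the conjunction of all rules and is independent of rule order.
    """
    cfg = cfg or FilterConfig()
    passing: list[VariantRecord] = []
    first_fail: Counter = Counter()
    marginal: Counter = Counter()
    for rec in records:
        failed = [name for name, rule in FILTER_RULES.items() if not rule(rec, cfg)]
        if failed:
            first_fail[failed[0]] += 1
            marginal.update(failed)
        else:
            passing.append(rec)
    zero = {name: 0 for name in FILTER_RULES}
    return passing, {
        "first_fail": {**zero, **first_fail},
        "rule_marginal": {**zero, **marginal},
    }


def compute_tmb(
    passing: Sequence[VariantRecord],
    cfg: FilterConfig | None = None,
    sample_id: str = "",
    n_input: int | None = None,
    tally: Mapping[str, Mapping[str, int]] | None = None,
) -> TmbReport:
    """TMB and mutational spectrum over already-filtered records."""
    cfg = cfg or FilterConfig()
    spectrum = Counter({"SNV": 0, "insertion": 0, "deletion": 0, "complex": 0})
    snv_classes = Counter({"missense": 0, "nonsense": 0, "other": 0})
    ti = tv = 0
    for rec in passing:
        vtype = classify_variant_type(rec.ref, rec.alt)
        spectrum[vtype] += 1
        if vtype == "SNV":
            cls = rec.consequence if rec.consequence in ("missense", "nonsense") else "other"
            snv_classes[cls] += 1
            if classify_substitution(rec.ref, rec.alt) == "transition":
                ti += 1
            else:
                tv += 1
    tally = tally or {}
    return TmbReport(
        sample_id=sample_id,
        n_input=n_input if n_input is not None else len(passing),
        n_pass=len(passing),
        tmb=len(passing) / cfg.callable_mb,
        first_fail=dict(tally.get("first_fail", {})),
        rule_marginal=dict(tally.get("rule_marginal", {})),
        spectrum=dict(spectrum),
        snv_classes=dict(snv_classes),
        ti=ti,
        tv=tv,
    )


def tmb_for_sample(
    records: Iterable[VariantRecord],
    cfg: FilterConfig | None = None,
    sample_id: str = "",
) -> TmbReport:
    """Filter + TMB in one step for a single sample's records."""
    recs = list(records)
    cfg = cfg or FilterConfig()
    passing, tally = apply_filters(recs, cfg)
    return compute_tmb(
        passing, cfg, sample_id=sample_id, n_input=len(recs), tally=tally
    )


def shared_mutations(
    sample_sets: Mapping[str, Iterable[VariantRecord | tuple]],
) -> dict[tuple[str, ...], int]:
    """Pairwise and full intersection sizes across >= 2 samples (Venn counts).

    Values may be :class:`VariantRecord` (keyed by amino-acid change when
    annotated, else genomic coordinates) or pre-built key tuples.
    """
    if len(sample_sets) < 2:
        raise ValueError("need at least 2 samples")
    keyed = {
        sid: {v.key if isinstance(v, VariantRecord) else tuple(v) for v in vs}
        for sid, vs in sample_sets.items()
    }
    out: dict[tuple[str, ...], int] = {}
    for a, b in combinations(sorted(keyed), 2):
        out[(a, b)] = len(keyed[a] & keyed[b])
    all_ids = tuple(sorted(keyed))
    if len(all_ids) > 2:
        common = set.intersection(*keyed.values())
        out[all_ids] = len(common)
    return out


# -- tabular I/O -------------------------------------------------------------

TSV_COLUMNS = [f.name for f in fields(VariantRecord)]


def records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    """Build records from the variant-table dialect; optional fields may be
    blank.  Raises :class:`VariantParseError` on missing required columns."""
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise VariantParseError(f"variant table missing columns: {missing}")
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(
            VariantRecord(
                sample_id=str(d["sample_id"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                gene=str(d["gene"]) if pd.notna(d["gene"]) and d["gene"] != "" else None,
                protein_change=(
                    str(d["protein_change"])
                    if pd.notna(d["protein_change"]) and d["protein_change"] != ""
                    else None
                ),
                consequence=str(d["consequence"]),
                impact=str(d["impact"]),
                vaf=float(d["vaf"]),
                alt_af_index=float(d["alt_af_index"]),
                read_depth=int(d["read_depth"]),
                pop_maf=float(d["pop_maf"]),
                internal_db_count=int(d["internal_db_count"]),
            )
        )
    return recs


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f: getattr(r, f) for f in TSV_COLUMNS}
        d["gene"] = d["gene"] or ""
        d["protein_change"] = d["protein_change"] or ""
        rows.append(d)
    return pd.DataFrame(rows, columns=TSV_COLUMNS)
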