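"""The consecutive-filtering engine.

Variants are reduced by applying configured filters one after another:
segregation (pedigree compatibility with missing-genotype tolerance),
consequence type, allelic frequency, genomic region and gene.  Every
filter is a pure set operation — each step's output is a subset of its
input — so the final survivor set does not depend on the order in which
the steps are declared; only the intermediate per-step counts do.

Segregation semantics (the core of the method): for a pattern with
per-sample allowed sets and a tolerance of N missing values, the records
that either fulfil the zygosity criteria or are missing at each
constrained sample are collected first, and of those only the records
with N or fewer missing constrained samples are kept.  ``OTHER``
genotype classes (multi-allelic indices, half calls) never match an
allowed set and never count as missing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .annotations import AnnotatedVariant, AnnotationStore, join
from .errors import ValidationError
from .pedigree import SegregationPattern, validate_pattern
from .variants import GenotypeClass, Region, VariantRecord, VariantTable
from .vocab import normalize_consequence

KG_POPULATIONS = ("ALL", "EUR", "ASN", "AFR", "AMR")
STUDIES = ("KG", "ESP")


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

def record_matches_pattern(
    record: VariantRecord, pattern: SegregationPattern
) -> bool:
    """Allowed-or-missing on every constrained sample, then the N-missing cut."""
    n_missing = 0
    for sample, allowed in pattern.allowed.items():
        cls = record.genotypes[sample]
        if cls is GenotypeClass.MISSING:
            n_missing += 1
            continue
        if cls not in allowed:
            return False
    return n_missing <= pattern.max_missing


def segregation_filter(
    table: VariantTable, pattern: SegregationPattern
) -> VariantTable:
    """Keep the records whose genotypes are compatible with ``pattern``.

    The pattern must validate against the table's roster; all violations
    are reported at once.
    """
    problems = validate_pattern(pattern, table.samples)
    if problems:
        raise ValidationError(
            "segregation pattern invalid for this VCF: " + "; ".join(problems)
        )
    return table.subset(
        [r for r in table.records if record_matches_pattern(r, pattern)]
    )


# ---------------------------------------------------------------------------
# annotation-driven filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyFilterConfig:
    """Which MAF columns to consult and the cut-off to apply.

    A variant survives iff the maximum MAF over the selected
    study/population columns is strictly below ``threshold``, or it has no
    MAF annotation in any selected column (novel variants pass).
    """

    threshold: float
    studies: frozenset[str] = frozenset({"KG", "ESP"})
    populations: frozenset[str] = frozenset(KG_POPULATIONS)

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", frozenset(self.studies))
        object.__setattr__(self, "populations", frozenset(self.populations))
        errors = []
        if not (0.0 <= self.threshold <= 0.5):
            errors.append(f"threshold {self.threshold} outside [0, 0.5]")
        if not self.studies:
            errors.append("study set is empty")
        bad = self.studies - set(STUDIES)
        if bad:
            errors.append(f"unknown studies {sorted(bad)}; valid: {STUDIES}")
        badp = self.populations - set(KG_POPULATIONS)
        if badp:
            errors.append(
                f"unknown populations {sorted(badp)}; valid: {KG_POPULATIONS}"
            )
        if "KG" in self.studies and not self.populations:
            errors.append("KG selected but population set is empty")
        if errors:
            raise ValidationError("; ".join(errors))

    def selected_keys(self) -> list[tuple[str, str]]:
        keys = []
        if "KG" in self.studies:
            keys += [("KG", p) for p in KG_POPULATIONS if p in self.populations]
        if "ESP" in self.studies:
            keys.append(("ESP", "ALL"))
        return keys


def _passes_frequency(row: AnnotatedVariant, cfg: FrequencyFilterConfig) -> bool:
    values = [
        row.annotation.mafs[k]
        for k in cfg.selected_keys()
        if k in row.annotation.mafs
    ]
    if not values:
        return True  # novel variant: no population evidence against it
    return max(values) < cfg.threshold


def frequency_filter(
    rows: Sequence[AnnotatedVariant], cfg: FrequencyFilterConfig
) -> list[AnnotatedVariant]:
    return [r for r in rows if _passes_frequency(r, cfg)]


def consequence_filter(
    rows: Sequence[AnnotatedVariant], allowed_types: Iterable[str]
) -> list[AnnotatedVariant]:
    """Keep variants with at least one transcript effect of an allowed type
    (any-transcript semantics).  Terms are normalized to SO vocabulary."""
    allowed = {normalize_consequence(t) for t in allowed_types}
    if not allowed:
        raise ValidationError("consequence filter requires a non-empty term set")
    return [
        r for r in rows
        if any(e.consequence in allowed for e in r.annotation.effects)
    ]


def gene_filter(
    rows: Sequence[AnnotatedVariant], genes: Iterable[str]
) -> list[AnnotatedVariant]:
    """Keep variants annotated to any of ``genes`` (case-insensitive exact
    match; multi-gene variants match on any of their genes)."""
    wanted = {g.strip().casefold() for g in genes if g.strip()}
    if not wanted:
        raise ValidationError("gene filter requires a non-empty gene set")
    return [
        r for r in rows
        if any(g.casefold() in wanted for g in r.annotation.genes)
    ]


def _region_trees(regions: Sequence[Region]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for reg in regions:
        # IntervalTree is half-open; +1 keeps the 1-based inclusive end.
        trees.setdefault(reg.chrom, IntervalTree()).addi(reg.start, reg.end + 1)
    return trees


def region_filter(
    table: VariantTable, regions: Sequence[Region]
) -> VariantTable:
    """Keep records whose position falls inside at least one region
    (both endpoints inclusive)."""
    if not regions:
        raise ValidationError("region filter requires at least one region")
    trees = _region_trees(regions)
    return table.subset(
        [
            r for r in table.records
            if r.chrom in trees and trees[r.chrom].overlaps_point(r.pos)
        ]
    )


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

class FilterStep:
    """One configured filter; subclasses implement ``keep``."""

    name: str = "step"

    def keep(self, row: AnnotatedVariant) -> bool:  # pragma: no cover
        raise NotImplementedError

    def apply(self, rows: list[AnnotatedVariant]) -> list[AnnotatedVariant]:
        return [r for r in rows if self.keep(r)]

    def describe(self) -> dict:
        return {"name": self.name}


class SegregationStep(FilterStep):
    name = "segregation"

    def __init__(self, pattern: SegregationPattern) -> None:
        self.pattern = pattern

    def keep(self, row: AnnotatedVariant) -> bool:
        return record_matches_pattern(row.variant, self.pattern)

    def describe(self) -> dict:
        return {"name": self.name, "pattern": self.pattern.to_dict()}


class ConsequenceStep(FilterStep):
    name = "consequence"

    def __init__(self, allowed_types: Iterable[str]) -> None:
        self.allowed = frozenset(normalize_consequence(t) for t in allowed_types)
        if not self.allowed:
            raise ValidationError(
                "consequence filter requires a non-empty term set"
            )

    def keep(self, row: AnnotatedVariant) -> bool:
        return any(
            e.consequence in self.allowed for e in row.annotation.effects
        )

    def describe(self) -> dict:
        return {"name": self.name, "allowed_types": sorted(self.allowed)}


class FrequencyStep(FilterStep):
    name = "frequency"

    def __init__(self, cfg: FrequencyFilterConfig) -> None:
        self.cfg = cfg

    def keep(self, row: AnnotatedVariant) -> bool:
        return _passes_frequency(row, self.cfg)

    def describe(self) -> dict:
        return {
            "name": self.name,
            "threshold": self.cfg.threshold,
            "studies": sorted(self.cfg.studies),
            "populations": sorted(self.cfg.populations),
        }


class RegionStep(FilterStep):
    name = "region"

    def __init__(self, regions: Sequence[Region]) -> None:
        if not regions:
            raise ValidationError("region filter requires at least one region")
        self.regions = list(regions)
        self._trees = _region_trees(self.regions)

    def keep(self, row: AnnotatedVariant) -> bool:
        v = row.variant
        return v.chrom in self._trees and self._trees[v.chrom].overlaps_point(v.pos)

    def describe(self) -> dict:
        return {
            "name": self.name,
            "regions": [f"{r.chrom}:{r.start}-{r.end}" for r in self.regions],
        }


class GeneStep(FilterStep):
    name = "gene"

    def __init__(self, genes: Iterable[str]) -> None:
        self.genes = frozenset(g.strip().casefold() for g in genes if g.strip())
        if not self.genes:
            raise ValidationError("gene filter requires a non-empty gene set")

    def keep(self, row: AnnotatedVariant) -> bool:
        return any(g.casefold() in self.genes for g in row.annotation.genes)

    def describe(self) -> dict:
        return {"name": self.name, "genes": sorted(self.genes)}


@dataclass
class FilterCascade:
    """An ordered list of configured filter steps."""

    steps: list[FilterStep] = field(default_factory=list)

    def describe(self) -> list[dict]:
        return [s.describe() for s in self.steps]


@dataclass
class CascadeResult:
    """Survivors plus the per-step bookkeeping of a cascade run."""

    rows: list[AnnotatedVariant]
    step_names: list[str]
    per_step_counts: list[int]  # [input, after step 1, after step 2, ...]

    @property
    def keys(self) -> set:
        return {r.key for r in self.rows}


def run_cascade(
    table: VariantTable,
    store: AnnotationStore,
    cascade: FilterCascade,
) -> CascadeResult:
    """Join the table with its annotations and apply each step in order.

    ``per_step_counts`` starts with the input size and appends one
    surviving count per step; it is non-increasing by construction.
    """
    for step in cascade.steps:
        if isinstance(step, SegregationStep):
            problems = validate_pattern(step.pattern, table.samples)
            if problems:
                raise ValidationError(
                    "segregation pattern invalid for this VCF: "
                    + "; ".join(problems)
                )
    rows = join(table, store)
    counts = [len(rows)]
    names: list[str] = []
    for step in cascade.steps:
        rows = step.apply(rows)
        counts.append(len(rows))
        names.append(step.name)
    return CascadeResult(rows=rows, step_names=names, per_step_counts=counts)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Data-set level statistics: roster, variant counts by type, and the
    distribution over consequence types (a variant counts once per distinct
    term it carries, so the consequence counts may sum to more than the
    variant count)."""

    samples: list[str]
    n_variants: int
    type_counts: dict[str, int]
    consequence_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "samples": self.samples,
            "n_variants": self.n_variants,
            "type_counts": self.type_counts,
            "consequence_counts": self.consequence_counts,
        }


def summarize(table: VariantTable, store: AnnotationStore) -> SummaryStats:
    types = Counter(r.variant_type for r in table.records)
    consequences: Counter[str] = Counter()
    for rec in table.records:
        for term in store.get(rec.key).consequences:
            consequences[term] += 1
    return SummaryStats(
        samples=list(table.samples),
        n_variants=len(table.records),
        type_counts={"SNV": types.get("SNV", 0), "indel": types.get("indel", 0)},
        consequence_counts=dict(sorted(consequences.items())),
    )
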