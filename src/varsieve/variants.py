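"""VCF input, region parsing, and tabular output.

A multi-sample VCF is read into a :class:`VariantTable` of
:class:`VariantRecord` objects.  Per-sample genotypes are reduced to the
five classes a per-site segregation filter can reason about:

====================  =========================================
class                 GT strings
====================  =========================================
``HOM_REF``           ``0/0``
``HET``               ``0/1``, ``1/0`` (phased ``0|1``/``1|0``)
``HOM_ALT``           ``1/1``
``MISSING``           ``./.`` or ``.`` (low quality / coverage)
``OTHER``             anything else (other ALT indices, half calls)
====================  =========================================

Coordinates are VCF-native: 1-based and inclusive everywhere, including
:class:`Region`.  Multi-allelic sites are split into one record per ALT
allele; for each split record, genotype indices that refer to neither the
reference nor that ALT become ``OTHER``.  Indels are taken as-is — inputs
are assumed already normalized (left-aligned, minimal representation).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from cyvcf2 import VCF

from .errors import ValidationError, VcfFormatError

log = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]


class GenotypeClass(Enum):
    """Diploid genotype collapsed to the classes used by the filters."""

    HOM_REF = "0/0"
    HET = "0/1"
    HOM_ALT = "1/1"
    MISSING = "./."
    OTHER = "other"

    def __repr__(self) -> str:  # keeps test output readable
        return self.name


#: The three called genotype classes a pattern may allow.
CALLED_CLASSES = frozenset(
    {GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT}
)


def classify_genotype(alleles: Sequence[int], alt_index: int) -> GenotypeClass:
    """Map allele indices (``-1`` = missing) to a :class:`GenotypeClass`.

    ``alt_index`` is the 1-based index of the ALT allele the current record
    represents, so the same call works on split multi-allelic sites.  Phase
    is irrelevant: the caller passes indices only.
    """
    if len(alleles) == 0 or all(a == -1 for a in alleles):
        return GenotypeClass.MISSING
    if len(alleles) != 2 or any(a == -1 for a in alleles):
        return GenotypeClass.OTHER  # half calls, haploid calls
    s = frozenset(alleles)
    if s == {0}:
        return GenotypeClass.HOM_REF
    if s == {0, alt_index}:
        return GenotypeClass.HET
    if s == {alt_index}:
        return GenotypeClass.HOM_ALT
    return GenotypeClass.OTHER


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant site with per-sample genotype classes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rs_id: str | None
    genotypes: Mapping[str, GenotypeClass]
    raw_line: str | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt must differ at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def variant_type(self) -> str:
        return "SNV" if self.is_snv else "indel"


@dataclass(frozen=True)
class Region:
    """A 1-based, endpoint-inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValidationError(
                f"region start {self.start} exceeds end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


_REGION_RE = re.compile(r"^\s*([\w.]+)\s*:\s*([\d,]+)\s*-\s*([\d,]+)\s*$")


def parse_region(text: str) -> Region:
    """Parse ``"chrom:start-end"`` into a :class:`Region` (whitespace and
    thousands separators tolerated)."""
    m = _REGION_RE.match(text)
    if not m:
        raise ValidationError(
            f"cannot parse region {text!r}; expected 'chrom:start-end'"
        )
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    return Region(chrom, start, end)


@dataclass
class VariantTable:
    """An ordered collection of records plus the sample roster."""

    samples: list[str]
    records: list[VariantRecord]
    raw_header: str | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def subset(self, records: list[VariantRecord]) -> "VariantTable":
        """A new table over the same roster (used by filters)."""
        return VariantTable(self.samples, records, self.raw_header)


def parse_vcf(path: str | Path) -> VariantTable:
    """Read a (plain or bgzipped) multi-sample VCF into a VariantTable.

    Only the GT subfield of FORMAT is interpreted.  Multi-allelic lines are
    split into one record per ALT allele.  A record whose FORMAT lacks GT
    yields MISSING for every sample (with a warning).

    Raises
    ------
    VcfFormatError
        On an unreadable/malformed header or duplicate (chrom,pos,ref,alt).
    """
    path = Path(path)
    if not path.exists():
        raise VcfFormatError(f"VCF file not found: {path}")
    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        raw_header = vcf.raw_header
    except VcfFormatError:
        raise
    except Exception as exc:  # cyvcf2/htslib raise assorted exceptions
        raise VcfFormatError(f"malformed VCF header in {path}: {exc}") from exc

    records: list[VariantRecord] = []
    seen: set[VariantKey] = set()
    no_gt_warned = False
    for v in vcf:
        alts = v.ALT or []
        if not alts:
            continue  # monomorphic / sites-only line: nothing to filter
        has_gt = bool(v.FORMAT) and "GT" in v.FORMAT
        if samples and not has_gt:
            if not no_gt_warned:
                log.warning(
                    "%s:%d has no GT field; genotypes set to MISSING",
                    v.CHROM,
                    v.POS,
                )
                no_gt_warned = True
            gts = [[-1, -1, False]] * len(samples)
        else:
            gts = v.genotypes
        raw = str(v).rstrip("\n")
        for alt_index, alt in enumerate(alts, start=1):
            key = (v.CHROM, v.POS, v.REF.upper(), str(alt).upper())
            if key in seen:
                raise VcfFormatError(
                    f"duplicate variant key {key[0]}:{key[1]} {key[2]}>{key[3]}"
                )
            seen.add(key)
            genotypes = {
                sample: classify_genotype(tuple(g[:-1]), alt_index)
                for sample, g in zip(samples, gts)
            }
            records.append(
                VariantRecord(
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    rs_id=v.ID if v.ID not in (None, ".") else None,
                    genotypes=genotypes,
                    raw_line=raw,
                )
            )
    return VariantTable(samples=samples, records=records, raw_header=raw_header)


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a table back out as VCF.

    Records parsed from a file are passed through with their original data
    lines (shared lines from split multi-allelic records are emitted once);
    in-memory records are rendered as minimal GT-only lines.
    """
    path = Path(path)
    with path.open("w") as fh:
        if table.raw_header:
            fh.write(table.raw_header)
        else:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            contigs: list[str] = []
            for rec in table.records:
                if rec.chrom not in contigs:
                    contigs.append(rec.chrom)
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(table.samples)
                + "\n"
            )
        last_raw: str | None = None
        for rec in table.records:
            if rec.raw_line is not None:
                if rec.raw_line != last_raw:
                    fh.write(rec.raw_line + "\n")
                last_raw = rec.raw_line
            else:
                gts = "\t".join(
                    rec.genotypes[s].value if rec.genotypes[s] is not GenotypeClass.OTHER
                    else "./."
                    for s in table.samples
                )
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t{rec.rs_id or '.'}\t{rec.ref}\t"
                    f"{rec.alt}\t.\t.\t.\tGT\t{gts}\n"
                )


def export_csv(
    rows: Iterable[Mapping[str, object]],
    columns: Sequence[str],
    path: str | Path,
) -> None:
    """Write selected columns of display rows as RFC-4180-style CSV.

    The header is exactly ``columns`` in the given order; cells are written
    so that re-importing yields identical string values.

    Raises
    ------
    ValidationError
        If a requested column is absent from the row schema.
    """
    rows = list(rows)
    if rows:
        available = set(rows[0].keys())
        unknown = [c for c in columns if c not in available]
        if unknown:
            raise ValidationError(
                f"unknown column(s) {unknown}; valid columns: {sorted(available)}"
            )
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([row[c] for c in columns])
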