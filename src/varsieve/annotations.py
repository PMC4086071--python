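"""Local per-variant annotation table.

Annotations live in a tab-delimited file (one row per biallelic variant)
rather than in a live web service, so everything runs offline.  The schema
mirrors the display columns of a prioritization run, and could be populated
from an Ensembl/CellBase export:

=============  ======================================================
column         content
=============  ======================================================
chrom, pos     variant key (1-based position)
ref, alt       alleles
rs_id          dbSNP identifier, or empty
effects        ';'-separated transcript effects; each effect is nine
               ':'-separated sub-fields —
               gene:transcript_id:feature_id:feature_type:biotype:
               consequence:aa_change:sift:polyphen
               (consequence is a Sequence Ontology term; sift/polyphen
               in [0,1] or empty)
kg_all ...     minor allele frequencies per study/population: kg_all,
               kg_eur, kg_asn, kg_afr, kg_amr (1000 Genomes) and esp
               (Exome Sequencing Project); empty = not observed
phenotypes     ';'-separated phenotype strings (opaque display text)
=============  ======================================================

SIFT is more deleterious when *lower*, PolyPhen when *higher*; when a
variant hits several transcripts the most deleterious value is the one
displayed, aggregated over all transcript effects of the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AnnotationError, ValidationError
from .variants import GenotypeClass, VariantKey, VariantRecord, VariantTable
from .vocab import normalize_consequence

#: (study, population) keys the frequency filter can select.
MAF_COLUMNS: dict[str, tuple[str, str]] = {
    "kg_all": ("KG", "ALL"),
    "kg_eur": ("KG", "EUR"),
    "kg_asn": ("KG", "ASN"),
    "kg_afr": ("KG", "AFR"),
    "kg_amr": ("KG", "AMR"),
    "esp": ("ESP", "ALL"),
}

ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "rs_id", "effects",
                      *MAF_COLUMNS, "phenotypes"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at a biallelic site in some population."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


def maf_from_genotype_counts(counts: GenotypeCounts) -> float:
    """Minor allele frequency from genotype counts.

    The alternative-allele frequency is
    ``p = (n_het + 2 * n_hom_alt) / (2 * total)``; the result is folded to
    the minor allele, ``min(p, 1 - p)``, hence always in [0, 0.5] and
    symmetric under swapping the ref/alt roles.
    """
    if min(counts.n_hom_ref, counts.n_het, counts.n_hom_alt) < 0:
        raise ValidationError("genotype counts must be non-negative")
    total = counts.total
    if total == 0:
        raise ValidationError("cannot derive a MAF from zero genotypes")
    p = (counts.n_het + 2 * counts.n_hom_alt) / (2 * total)
    return min(p, 1.0 - p)


def most_deleterious(scores: Sequence[float], index: str) -> float:
    """Collapse several damaging scores to the most deleterious one.

    ``index`` is ``"SIFT"`` (lower = more damaging, so the minimum) or
    ``"POLYPHEN"`` (higher = more damaging, so the maximum).  Idempotent and
    order-invariant.
    """
    if not scores:
        raise ValidationError("most_deleterious requires at least one score")
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValidationError(f"score {s} outside [0, 1]")
    idx = index.upper()
    if idx == "SIFT":
        return min(scores)
    if idx == "POLYPHEN":
        return max(scores)
    raise ValidationError(f"unknown damaging index {index!r}")


@dataclass(frozen=True)
class TranscriptEffect:
    """The predicted effect of a variant on one genomic feature."""

    gene: str
    transcript_id: str
    feature_id: str = ""
    feature_type: str = ""
    biotype: str = ""
    consequence: str = "intergenic_variant"
    aa_change: str | None = None
    sift: float | None = None
    polyphen: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "consequence", normalize_consequence(self.consequence)
        )
        for name in ("sift", "polyphen"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} score {v} outside [0, 1]")


@dataclass(frozen=True)
class AnnotationRecord:
    """All annotations for one variant; ``sift``/``polyphen`` are the
    most-deleterious aggregates over the transcript effects."""

    key: VariantKey
    rs_id: str | None = None
    effects: tuple[TranscriptEffect, ...] = ()
    mafs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    phenotypes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for k, v in self.mafs.items():
            if not (0.0 <= v <= 0.5):
                raise ValidationError(f"MAF {v} for {k} outside [0, 0.5]")

    @property
    def genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for e in self.effects:
            if e.gene and e.gene not in out:
                out.append(e.gene)
        return tuple(out)

    @property
    def consequences(self) -> tuple[str, ...]:
        out: list[str] = []
        for e in self.effects:
            if e.consequence not in out:
                out.append(e.consequence)
        return tuple(out)

    @property
    def sift(self) -> float | None:
        scores = [e.sift for e in self.effects if e.sift is not None]
        return most_deleterious(scores, "SIFT") if scores else None

    @property
    def polyphen(self) -> float | None:
        scores = [e.polyphen for e in self.effects if e.polyphen is not None]
        return most_deleterious(scores, "POLYPHEN") if scores else None


def _empty_record(key: VariantKey) -> AnnotationRecord:
    return AnnotationRecord(key=key)


def encode_effect(e: TranscriptEffect) -> str:
    def num(v: float | None) -> str:
        return "" if v is None else format(v, "g")

    return ":".join(
        [
            e.gene,
            e.transcript_id,
            e.feature_id,
            e.feature_type,
            e.biotype,
            e.consequence,
            e.aa_change or "",
            num(e.sift),
            num(e.polyphen),
        ]
    )


def decode_effect(text: str) -> TranscriptEffect:
    parts = text.split(":")
    if len(parts) != 9:
        raise AnnotationError(
            f"effect {text!r} has {len(parts)} sub-fields, expected 9 "
            "(gene:transcript:feature_id:feature_type:biotype:consequence:"
            "aa_change:sift:polyphen)"
        )
    gene, tx, fid, ftype, biotype, cons, aa, sift, polyphen = parts
    return TranscriptEffect(
        gene=gene,
        transcript_id=tx,
        feature_id=fid,
        feature_type=ftype,
        biotype=biotype,
        consequence=cons,
        aa_change=aa or None,
        sift=float(sift) if sift else None,
        polyphen=float(polyphen) if polyphen else None,
    )


class AnnotationStore:
    """Annotations queryable by (chrom, pos, ref, alt).

    Variants absent from the store yield an empty :class:`AnnotationRecord`
    so joins never drop rows.
    """

    def __init__(self, records: Iterable[AnnotationRecord] = ()) -> None:
        self._by_key: dict[VariantKey, AnnotationRecord] = {}
        for rec in records:
            if rec.key in self._by_key:
                raise AnnotationError(
                    f"duplicate annotation key {rec.key[0]}:{rec.key[1]} "
                    f"{rec.key[2]}>{rec.key[3]}"
                )
            self._by_key[rec.key] = rec

    def __len__(self) -> int:
        return len(self._by_key)

    def get(self, key: VariantKey) -> AnnotationRecord:
        return self._by_key.get(key, _empty_record(key))

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key


def load_annotations(path: str | Path) -> AnnotationStore:
    """Load the annotation TSV described in the module docstring.

    Raises
    ------
    AnnotationError
        On a missing/extra header column, a malformed row (reported with
        its 1-based data row number), or a duplicate variant key.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(
            f"{path}: annotation header is missing column(s) {missing}; "
            f"expected {ANNOTATION_COLUMNS}"
        )
    records: list[AnnotationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            mafs: dict[tuple[str, str], float] = {}
            for col, sp_key in MAF_COLUMNS.items():
                cell = getattr(row, col).strip()
                if cell:
                    mafs[sp_key] = float(cell)
            effects = tuple(
                decode_effect(part)
                for part in row.effects.split(";")
                if part.strip()
            )
            phenotypes = tuple(
                p for p in row.phenotypes.split(";") if p.strip()
            )
            records.append(
                AnnotationRecord(
                    key=(row.chrom, int(row.pos), row.ref.upper(), row.alt.upper()),
                    rs_id=row.rs_id or None,
                    effects=effects,
                    mafs=mafs,
                    phenotypes=phenotypes,
                )
            )
        except (AnnotationError, ValidationError, ValueError) as exc:
            raise AnnotationError(f"{path}: malformed row {i}: {exc}") from exc
    return AnnotationStore(records)


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records back out in the TSV schema (inverse of
    :func:`load_annotations`; used by the simulator)."""
    inv = {v: k for k, v in MAF_COLUMNS.items()}
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for rec in records:
        maf_cells = {col: "" for col in MAF_COLUMNS}
        for sp_key, value in rec.mafs.items():
            maf_cells[inv[sp_key]] = format(value, "g")
        lines.append(
            "\t".join(
                [
                    rec.key[0],
                    str(rec.key[1]),
                    rec.key[2],
                    rec.key[3],
                    rec.rs_id or "",
                    ";".join(encode_effect(e) for e in rec.effects),
                    *[maf_cells[c] for c in MAF_COLUMNS],
                    ";".join(rec.phenotypes),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant joined with its annotation record."""

    variant: VariantRecord
    annotation: AnnotationRecord

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    def display_row(self) -> dict[str, object]:
        """The flat display/export row: position, allelic change, gene,
        per-sample genotypes, dbSNP id, MAFs, consequence types, aggregated
        SIFT/PolyPhen and phenotype."""
        v, a = self.variant, self.annotation
        row: dict[str, object] = {
            "position": f"{v.chrom}:{v.pos}",
            "change": f"{v.ref}>{v.alt}",
            "gene": "|".join(a.genes),
        }
        for sample, cls in v.genotypes.items():
            row[sample] = cls.value
        row["id"] = v.rs_id or a.rs_id or ""
        for col, sp_key in MAF_COLUMNS.items():
            row[f"maf_{col}"] = (
                format(a.mafs[sp_key], "g") if sp_key in a.mafs else ""
            )
        row["consequence"] = "|".join(a.consequences)
        row["sift"] = format(a.sift, "g") if a.sift is not None else ""
        row["polyphen"] = format(a.polyphen, "g") if a.polyphen is not None else ""
        row["phenotype"] = "|".join(a.phenotypes)
        return row


def join(table: VariantTable, store: AnnotationStore) -> list[AnnotatedVariant]:
    """Join every record with its annotation (empty record when absent).

    Strictly additive: never drops or reorders variants.
    """
    return [AnnotatedVariant(rec, store.get(rec.key)) for rec in table.records]


def display_columns(samples: Sequence[str]) -> list[str]:
    """Default export column order for a given sample roster."""
    return (
        ["position", "change", "gene"]
        + list(samples)
        + ["id"]
        + [f"maf_{c}" for c in MAF_COLUMNS]
        + ["consequence", "sift", "polyphen", "phenotype"]
    )
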