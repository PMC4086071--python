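"""Synthetic family exomes with a planted causal variant.

The simulator builds everything a prioritization run consumes — a
multi-sample VCF, a matching annotation TSV and a truth file — so the full
filter cascade can be exercised offline and its sensitivity measured
against a known answer.

What is emulated:

* background variants whose founder genotypes are drawn from
  Hardy–Weinberg proportions at allele frequencies sampled from a
  configurable distribution (by default a 50/50 mixture of rare,
  U(0.0005, 0.05), and common, U(0.05, 0.5), variants so that frequency
  filtering is actually exercised);
* Mendelian transmission from parents to offspring at every background
  site;
* one causal variant whose genotype vector is drawn to satisfy the chosen
  inheritance model (e.g. recessive: carrier parents 0/1, affected 1/1,
  unaffected 0/0 or 0/1), annotated with a configurable consequence type
  and, by default, absent from the population frequency tables (novel);
* per-genotype missingness (``./.``) and genotype errors at configurable
  rates — injected into background variants only, keeping the truth
  record clean, unless ``corrupt_causal`` is set.

Positions are laid out sequentially on synthetic contigs, so nothing
depends on a genome build.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotations import AnnotationRecord, TranscriptEffect, write_annotations
from .errors import ValidationError
from .pedigree import (
    Affection,
    Individual,
    Pedigree,
    PRESETS,
    SegregationPattern,
    Sex,
    pattern_case_control,
)
from .variants import (
    GenotypeClass,
    VariantKey,
    VariantRecord,
    VariantTable,
    parse_vcf,
    write_vcf,
)
from .vocab import normalize_consequence

_CLASS_BY_DOSAGE = {
    0: GenotypeClass.HOM_REF,
    1: GenotypeClass.HET,
    2: GenotypeClass.HOM_ALT,
    -1: GenotypeClass.MISSING,
}

_BACKGROUND_CONSEQUENCES = [
    ("intron_variant", 0.36),
    ("missense_variant", 0.20),
    ("synonymous_variant", 0.12),
    ("upstream_gene_variant", 0.07),
    ("downstream_gene_variant", 0.07),
    ("3_prime_UTR_variant", 0.06),
    ("5_prime_UTR_variant", 0.03),
    ("splice_region_variant", 0.03),
    ("non_coding_transcript_exon_variant", 0.03),
    ("stop_gained", 0.015),
    ("frameshift_variant", 0.015),
]

_CONTIGS = [str(c) for c in range(1, 23)]


def default_pedigree() -> Pedigree:
    """A nuclear family: carrier parents, affected proband, unaffected sib."""
    return Pedigree.from_individuals(
        [
            Individual("FATHER", sex=Sex.MALE, affected=Affection.UNAFFECTED),
            Individual("MOTHER", sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
            Individual(
                "PROBAND", father="FATHER", mother="MOTHER",
                affected=Affection.AFFECTED,
            ),
            Individual(
                "SIBLING", father="FATHER", mother="MOTHER",
                affected=Affection.UNAFFECTED,
            ),
        ]
    )


@dataclass
class SimulationConfig:
    """Study conditions for one simulated family data set."""

    pedigree: Pedigree = field(default_factory=default_pedigree)
    model: str = "recessive"  # recessive | dominant | de_novo | case_control
    n_background: int = 10_000
    maf_distribution: str | tuple = "mixture"
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    causal_consequence: str = "missense_variant"
    causal_maf: float | None = None  # None = novel variant
    corrupt_causal: bool = False
    indel_fraction: float = 0.1
    unannotated_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        errors = []
        for name in ("missing_rate", "mendel_error_rate", "indel_fraction",
                     "unannotated_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name}={v} outside [0, 1]")
        if self.n_background < 0:
            errors.append(f"n_background must be >= 0, got {self.n_background}")
        if self.model not in (*PRESETS, "case_control"):
            errors.append(
                f"model must be one of {(*PRESETS, 'case_control')}, "
                f"got {self.model!r}"
            )
        if self.causal_maf is not None and not (0.0 <= self.causal_maf <= 0.5):
            errors.append(f"causal_maf={self.causal_maf} outside [0, 0.5]")
        try:
            normalize_consequence(self.causal_consequence)
        except ValidationError as exc:
            errors.append(str(exc))
        if errors:
            raise ValidationError("; ".join(errors))


@dataclass(frozen=True)
class TruthRecord:
    """Where the causal variant is and which genotypes were planted."""

    causal_key: VariantKey
    model: str
    causal_gene: str
    expected_genotypes: Mapping[str, GenotypeClass]

    def to_dict(self) -> dict:
        return {
            "causal_key": list(self.causal_key),
            "model": self.model,
            "causal_gene": self.causal_gene,
            "expected_genotypes": {
                s: c.name for s, c in self.expected_genotypes.items()
            },
        }


@dataclass
class SimulationResult:
    table: VariantTable
    annotations: list[AnnotationRecord]
    truth: TruthRecord
    vcf_path: Path | None = None
    annotation_path: Path | None = None
    truth_path: Path | None = None


def compiled_pattern(cfg: SimulationConfig) -> SegregationPattern:
    """The preset pattern matching the simulated model."""
    if cfg.model == "case_control":
        return pattern_case_control(
            cases=cfg.pedigree.affected_ids(),
            controls=cfg.pedigree.unaffected_ids(),
            model="recessive",
        )
    return PRESETS[cfg.model](cfg.pedigree)


def _draw_frequencies(rng: np.random.Generator, n: int,
                      dist: str | tuple) -> np.ndarray:
    if dist == "mixture":
        rare = rng.uniform(0.0005, 0.05, size=n)
        common = rng.uniform(0.05, 0.5, size=n)
        pick = rng.random(n) < 0.5
        return np.where(pick, rare, common)
    if isinstance(dist, tuple) and len(dist) == 3 and dist[0] == "uniform":
        return rng.uniform(float(dist[1]), float(dist[2]), size=n)
    raise ValidationError(
        f"unknown maf_distribution {dist!r}; use 'mixture' or "
        "('uniform', low, high)"
    )


def _topological_order(ped: Pedigree) -> list[Individual]:
    ordered: list[Individual] = []
    placed: set[str] = set()
    pending = list(ped)
    while pending:
        progressed = False
        rest = []
        for ind in pending:
            parents_ready = all(
                p is None or p not in ped.individuals or p in placed
                for p in (ind.father, ind.mother)
            )
            if parents_ready:
                ordered.append(ind)
                placed.add(ind.id)
                progressed = True
            else:
                rest.append(ind)
        pending = rest
        if not progressed:  # unreachable: Pedigree is validated acyclic
            raise ValidationError("pedigree ordering failed")
    return ordered


def _background_dosages(
    rng: np.random.Generator,
    ped: Pedigree,
    freqs: np.ndarray,
) -> dict[str, np.ndarray]:
    """Founders from Hardy–Weinberg, offspring by Mendelian transmission."""
    n = len(freqs)
    dosage: dict[str, np.ndarray] = {}
    for ind in _topological_order(ped):
        has_father = ind.father in dosage
        has_mother = ind.mother in dosage
        if has_father and has_mother:
            from_father = (rng.random(n) < dosage[ind.father] / 2.0).astype(np.int8)
            from_mother = (rng.random(n) < dosage[ind.mother] / 2.0).astype(np.int8)
            dosage[ind.id] = from_father + from_mother
        else:
            dosage[ind.id] = rng.binomial(2, freqs).astype(np.int8)
    return dosage


_PREFERRED = {
    frozenset({GenotypeClass.HOM_ALT}): GenotypeClass.HOM_ALT,
    frozenset({GenotypeClass.HET}): GenotypeClass.HET,
    frozenset({GenotypeClass.HOM_REF}): GenotypeClass.HOM_REF,
    frozenset({GenotypeClass.HET, GenotypeClass.HOM_ALT}): GenotypeClass.HET,
}


def _causal_genotypes(
    rng: np.random.Generator,
    samples: Sequence[str],
    pattern: SegregationPattern,
) -> dict[str, GenotypeClass]:
    out: dict[str, GenotypeClass] = {}
    for s in samples:
        allowed = pattern.allowed.get(s)
        if allowed is None:
            out[s] = GenotypeClass.HOM_REF  # unconstrained bystander
        elif allowed in _PREFERRED:
            out[s] = _PREFERRED[allowed]
        else:
            choices = sorted(allowed, key=lambda c: c.name)
            out[s] = choices[rng.integers(0, len(choices))]
    return out


def _alleles(rng: np.random.Generator, is_indel: bool) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[rng.integers(0, 4)]
    if not is_indel:
        # draw alt from the three non-ref bases
        others = bases.replace(ref, "")
        alt = others[rng.integers(0, 3)]
        return ref, alt
    extra = "".join(bases[rng.integers(0, 4)] for _ in range(1 + rng.integers(0, 3)))
    if rng.random() < 0.5:
        return ref, ref + extra  # insertion
    return ref + extra, ref  # deletion


def _perturb(
    rng: np.random.Generator,
    dosages: np.ndarray,
    missing_rate: float,
    mendel_error_rate: float,
) -> np.ndarray:
    """Genotype errors first, then missingness (missing wins)."""
    out = dosages.copy()
    if mendel_error_rate > 0:
        err = rng.random(out.shape) < mendel_error_rate
        shift = rng.integers(1, 3, size=out.shape)
        out = np.where(err, (out + shift) % 3, out)
    if missing_rate > 0:
        out = np.where(rng.random(out.shape) < missing_rate, -1, out)
    return out.astype(np.int8)


def simulate_family(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
    prefix: str = "sim",
) -> SimulationResult:
    """Materialize one simulated data set.

    When ``out_dir`` is given, writes ``<prefix>.vcf``,
    ``<prefix>.annotations.tsv`` and ``<prefix>.truth.json`` there; the
    in-memory table/annotations/truth are returned either way.  Identical
    configs produce byte-identical files.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ped = cfg.pedigree
    samples = [ind.id for ind in ped]
    pattern = compiled_pattern(cfg)

    n_bg = cfg.n_background
    freqs = _draw_frequencies(rng, n_bg, cfg.maf_distribution)
    dosage_by_sample = _background_dosages(rng, ped, freqs)
    bg = np.stack(
        [dosage_by_sample[s] for s in samples], axis=1
    ) if n_bg else np.zeros((0, len(samples)), dtype=np.int8)

    causal_index = int(rng.integers(0, n_bg + 1))
    causal_gts = _causal_genotypes(rng, samples, pattern)

    is_indel = rng.random(n_bg + 1) < cfg.indel_fraction
    allele_pairs = [_alleles(rng, bool(b)) for b in is_indel]
    consequence_terms = [t for t, _ in _BACKGROUND_CONSEQUENCES]
    weights = np.array([w for _, w in _BACKGROUND_CONSEQUENCES])
    weights = weights / weights.sum()
    bg_consequences = rng.choice(len(consequence_terms), size=n_bg, p=weights)
    bg_extra_effects = rng.integers(0, 3, size=n_bg)
    bg_unannotated = rng.random(n_bg) < cfg.unannotated_rate
    pop_wobble = rng.lognormal(mean=0.0, sigma=0.15, size=(n_bg, 5))
    sift_scores = rng.uniform(0.0, 1.0, size=n_bg)
    polyphen_scores = rng.uniform(0.0, 1.0, size=n_bg)
    causal_sift = float(rng.uniform(0.0, 0.05))
    causal_polyphen = float(rng.uniform(0.9, 1.0))

    bg_noisy = _perturb(rng, bg, cfg.missing_rate, cfg.mendel_error_rate)
    if cfg.corrupt_causal:
        causal_row = np.array(
            [
                {v: k for k, v in _CLASS_BY_DOSAGE.items()}[causal_gts[s]]
                for s in samples
            ],
            dtype=np.int8,
        )[None, :]
        causal_row = _perturb(
            rng, causal_row, cfg.missing_rate, cfg.mendel_error_rate
        )
        causal_classes = {
            s: _CLASS_BY_DOSAGE[int(d)]
            for s, d in zip(samples, causal_row[0])
        }
    else:
        causal_classes = dict(causal_gts)

    n_total = n_bg + 1
    per_contig = -(-n_total // len(_CONTIGS))  # ceil

    records: list[VariantRecord] = []
    annotations: list[AnnotationRecord] = []
    truth: TruthRecord | None = None
    rs_counter = 100
    bg_i = 0
    for i in range(n_total):
        contig = _CONTIGS[i // per_contig]
        pos = 10_000 + 100 * (i % per_contig)
        ref, alt = allele_pairs[i]
        key: VariantKey = (contig, pos, ref, alt)
        gene = f"GENE{i // 8:05d}"
        if i == causal_index:
            gene = "GENE_CAUSAL"
            effects = [
                TranscriptEffect(
                    gene=gene,
                    transcript_id=f"TX{i:06d}.1",
                    feature_id=f"EX{i:06d}",
                    feature_type="exon",
                    biotype="protein_coding",
                    consequence=normalize_consequence(cfg.causal_consequence),
                    aa_change="p.Arg100Trp",
                    sift=round(causal_sift, 3),
                    polyphen=round(causal_polyphen, 3),
                )
            ]
            mafs = (
                {("KG", "ALL"): round(cfg.causal_maf, 6)}
                if cfg.causal_maf is not None
                else {}
            )
            records.append(
                VariantRecord(contig, pos, ref, alt, None, dict(causal_classes))
            )
            annotations.append(
                AnnotationRecord(
                    key=key,
                    rs_id=None,
                    effects=tuple(effects),
                    mafs=mafs,
                    phenotypes=("simulated disease phenotype",),
                )
            )
            truth = TruthRecord(
                causal_key=key,
                model=cfg.model,
                causal_gene=gene,
                expected_genotypes=dict(causal_gts),
            )
            continue

        j = bg_i
        bg_i += 1
        classes = {
            s: _CLASS_BY_DOSAGE[int(d)]
            for s, d in zip(samples, bg_noisy[j])
        }
        term = consequence_terms[bg_consequences[j]]
        rs_id = None
        mafs = {}
        if not bg_unannotated[j]:
            rs_counter += 1
            rs_id = f"rs{rs_counter}"
            maf = float(min(freqs[j], 1.0 - freqs[j]))
            mafs[("KG", "ALL")] = round(maf, 6)
            for p_i, pop in enumerate(("EUR", "ASN", "AFR", "AMR")):
                mafs[("KG", pop)] = round(
                    float(np.clip(maf * pop_wobble[j, p_i], 0.0, 0.5)), 6
                )
            mafs[("ESP", "ALL")] = round(
                float(np.clip(maf * pop_wobble[j, 4], 0.0, 0.5)), 6
            )
        effects = [
            TranscriptEffect(
                gene=gene,
                transcript_id=f"TX{i:06d}.1",
                feature_id=f"EX{i:06d}" if term == "missense_variant" else f"FT{i:06d}",
                feature_type="exon" if term == "missense_variant" else "transcript",
                biotype="protein_coding",
                consequence=term,
                aa_change="p.Ala10Val" if term == "missense_variant" else None,
                sift=round(float(sift_scores[j]), 3)
                if term == "missense_variant" else None,
                polyphen=round(float(polyphen_scores[j]), 3)
                if term == "missense_variant" else None,
            )
        ]
        for k in range(int(bg_extra_effects[j])):
            effects.append(
                TranscriptEffect(
                    gene=gene,
                    transcript_id=f"TX{i:06d}.{k + 2}",
                    feature_id=f"FT{i:06d}x{k}",
                    feature_type="transcript",
                    biotype="protein_coding",
                    consequence="intron_variant",
                )
            )
        records.append(VariantRecord(contig, pos, ref, alt, rs_id, classes))
        annotations.append(
            AnnotationRecord(
                key=key, rs_id=rs_id, effects=tuple(effects), mafs=mafs
            )
        )

    assert truth is not None
    table = VariantTable(samples=samples, records=records)
    result = SimulationResult(table=table, annotations=annotations, truth=truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.vcf_path = out_dir / f"{prefix}.vcf"
        result.annotation_path = out_dir / f"{prefix}.annotations.tsv"
        result.truth_path = out_dir / f"{prefix}.truth.json"
        write_vcf(table, result.vcf_path)
        write_annotations(annotations, result.annotation_path)
        result.truth_path.write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    return result


def expected_survivors(
    vcf_path: str | Path, pattern: SegregationPattern
) -> set[VariantKey]:
    """Brute-force re-check of the segregation semantics, used in tests as
    an oracle independent of the filter engine.

    For each record: every constrained sample must be within its allowed
    set or missing, and the number of missing constrained samples must not
    exceed the tolerance.
    """
    table = parse_vcf(vcf_path)
    keys: set[VariantKey] = set()
    for rec in table.records:
        missing = [
            s for s in pattern.allowed
            if rec.genotypes[s] is GenotypeClass.MISSING
        ]
        ok = all(
            rec.genotypes[s] is GenotypeClass.MISSING
            or rec.genotypes[s] in allowed
            for s, allowed in pattern.allowed.items()
        )
        if ok and len(missing) <= pattern.max_missing:
            keys.add(rec.key)
    return keys
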