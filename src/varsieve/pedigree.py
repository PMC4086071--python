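"""Pedigrees and their compilation into segregation patterns.

The central object is :class:`SegregationPattern`: for each constrained
sample, the set of called genotype classes compatible with the disease
model, plus the maximum number of constrained samples allowed to be
missing.  Any pedigree and inheritance mode — including incomplete
penetrance and case-control designs — reduces to such a pattern; the
presets here are conveniences that compile the common Mendelian models.
X-linked models have no preset but can be expressed manually through
per-sample allowed sets.

Under autosomal-recessive inheritance the canonical nuclear family looks
like: both parents obligate carriers (0/1), the affected child homozygous
for the alternative allele (1/1), and any unaffected sibling 0/0 or 0/1.
A pattern built this way automatically discards Mendelian inconsistencies
at the constrained trio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ModelError, ValidationError
from .variants import CALLED_CLASSES, GenotypeClass

_ALL3 = frozenset(CALLED_CLASSES)


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None = None
    mother: str | None = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN


@dataclass
class Pedigree:
    """Individuals keyed by sample id, with acyclic parentage."""

    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValidationError("pedigree must contain at least one individual")
        for ind in self.individuals.values():
            if ind.father is not None and ind.father == ind.mother:
                raise ValidationError(
                    f"{ind.id}: father and mother must be distinct individuals"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self.individuals}

        def visit(iid: str) -> None:
            color[iid] = GREY
            ind = self.individuals[iid]
            for parent in (ind.father, ind.mother):
                if parent is None or parent not in self.individuals:
                    continue
                if color[parent] == GREY:
                    raise ValidationError(
                        f"pedigree contains a parentage cycle through {parent!r}"
                    )
                if color[parent] == WHITE:
                    visit(parent)
            color[iid] = BLACK

        for iid in self.individuals:
            if color[iid] == WHITE:
                visit(iid)

    def __iter__(self):
        return iter(self.individuals.values())

    def affected_ids(self) -> list[str]:
        return [i.id for i in self if i.affected is Affection.AFFECTED]

    def unaffected_ids(self) -> list[str]:
        return [i.id for i in self if i.affected is Affection.UNAFFECTED]

    @classmethod
    def from_individuals(cls, individuals: Iterable[Individual]) -> "Pedigree":
        return cls({ind.id: ind for ind in individuals})


_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}


def read_ped(path: str | Path) -> Pedigree:
    """Read a PED-like whitespace-delimited file.

    Columns: family, individual, father, mother, sex (1=male, 2=female),
    phenotype (1=unaffected, 2=affected, 0/-9=unknown).  ``0`` means
    "no parent".  Extra columns are ignored; lines starting with '#' too.
    """
    individuals: list[Individual] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise ValidationError(
                f"{path}:{lineno}: expected >= 6 whitespace-delimited columns "
                f"(fam id father mother sex phenotype), got {len(cols)}"
            )
        _, iid, father, mother, sex, pheno = cols[:6]
        individuals.append(
            Individual(
                id=iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=_SEX.get(sex, Sex.UNKNOWN),
                affected=_PHENO.get(pheno, Affection.UNKNOWN),
            )
        )
    return Pedigree.from_individuals(individuals)


@dataclass(frozen=True)
class SegregationPattern:
    """Per-sample allowed genotype classes + missing-genotype tolerance.

    A record passes the segregation filter iff every constrained sample's
    genotype class is in its allowed set *or* is MISSING, and at most
    ``max_missing`` constrained samples are MISSING.  Samples absent from
    ``allowed`` are unconstrained and ignored entirely.
    """

    allowed: Mapping[str, frozenset[GenotypeClass]]
    max_missing: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "allowed",
            {s: frozenset(v) for s, v in self.allowed.items()},
        )
        for sample, classes in self.allowed.items():
            if not classes:
                raise ValidationError(f"empty allowed set for sample {sample!r}")
            bad = classes - CALLED_CLASSES
            if bad:
                raise ValidationError(
                    f"allowed set for {sample!r} may only contain called "
                    f"classes (HOM_REF/HET/HOM_ALT), got {sorted(c.name for c in bad)}"
                )
        if self.max_missing < 0:
            raise ValidationError("max_missing must be >= 0")
        if self.allowed and self.max_missing > len(self.allowed):
            raise ValidationError(
                f"max_missing={self.max_missing} exceeds the number of "
                f"constrained samples ({len(self.allowed)})"
            )

    def with_max_missing(self, n: int) -> "SegregationPattern":
        return SegregationPattern(dict(self.allowed), n)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "allowed": {
                s: sorted(c.name for c in classes)
                for s, classes in self.allowed.items()
            },
            "max_missing": self.max_missing,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegregationPattern":
        try:
            allowed = {
                s: frozenset(GenotypeClass[name] for name in names)
                for s, names in d["allowed"].items()
            }
        except KeyError as exc:
            raise ValidationError(f"bad pattern document: {exc}") from exc
        return cls(allowed, int(d.get("max_missing", 0)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegregationPattern":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _compile(constraints: dict[str, frozenset[GenotypeClass]],
             max_missing: int = 0) -> SegregationPattern:
    """Drop unconstrained samples and guard against contradictions."""
    allowed = {}
    for sample, classes in constraints.items():
        if not classes:
            raise ModelError(
                f"model constraints are contradictory for sample {sample!r} "
                "(no genotype satisfies them)"
            )
        if classes == _ALL3:
            continue  # unconstrained: leave out of the pattern
        allowed[sample] = classes
    return SegregationPattern(allowed, max_missing)


def pattern_autosomal_recessive(ped: Pedigree) -> SegregationPattern:
    """Autosomal-recessive preset.

    Parents of affected individuals are obligate carriers ({HET}); affected
    individuals are {HOM_ALT}; unaffected individuals are {HOM_REF, HET}.
    """
    affected = ped.affected_ids()
    if not affected:
        raise ModelError("recessive model requires at least one affected individual")
    constraints: dict[str, frozenset[GenotypeClass]] = {
        i.id: _ALL3 for i in ped
    }
    for iid in affected:
        constraints[iid] = constraints[iid] & {GenotypeClass.HOM_ALT}
    for iid in ped.unaffected_ids():
        constraints[iid] = constraints[iid] & {
            GenotypeClass.HOM_REF,
            GenotypeClass.HET,
        }
    for iid in affected:
        ind = ped.individuals[iid]
        for parent in (ind.father, ind.mother):
            if parent is not None and parent in ped.individuals:
                constraints[parent] = constraints[parent] & {GenotypeClass.HET}
    return _compile(constraints)


def pattern_dominant(
    ped: Pedigree, penetrance: str = "complete"
) -> SegregationPattern:
    """Autosomal-dominant preset.

    Affected individuals carry at least one alternative allele
    ({HET, HOM_ALT}).  Unaffected individuals are {HOM_REF} under complete
    penetrance and unconstrained under incomplete penetrance (a carrier may
    fail to express the phenotype).
    """
    if penetrance not in ("complete", "incomplete"):
        raise ValidationError(
            f"penetrance must be 'complete' or 'incomplete', got {penetrance!r}"
        )
    affected = ped.affected_ids()
    if not affected:
        raise ModelError("dominant model requires at least one affected individual")
    constraints: dict[str, frozenset[GenotypeClass]] = {i.id: _ALL3 for i in ped}
    for iid in affected:
        constraints[iid] = constraints[iid] & {
            GenotypeClass.HET,
            GenotypeClass.HOM_ALT,
        }
    if penetrance == "complete":
        for iid in ped.unaffected_ids():
            constraints[iid] = constraints[iid] & {GenotypeClass.HOM_REF}
    return _compile(constraints)


def pattern_de_novo(ped: Pedigree) -> SegregationPattern:
    """De novo preset: the variant is new in the affected individual.

    Both parents of every affected individual must be in the pedigree and
    are {HOM_REF}; affected individuals are {HET, HOM_ALT}; every other
    unaffected individual is {HOM_REF} as well — nobody else can carry an
    allele that arose in the proband.
    """
    affected = ped.affected_ids()
    if not affected:
        raise ModelError("de novo model requires at least one affected individual")
    constraints: dict[str, frozenset[GenotypeClass]] = {i.id: _ALL3 for i in ped}
    for iid in affected:
        ind = ped.individuals[iid]
        if (
            ind.father is None
            or ind.mother is None
            or ind.father not in ped.individuals
            or ind.mother not in ped.individuals
        ):
            raise ModelError(
                f"de novo model requires both parents of {iid!r} in the pedigree"
            )
        constraints[iid] = constraints[iid] & {
            GenotypeClass.HET,
            GenotypeClass.HOM_ALT,
        }
    for iid in ped.unaffected_ids():
        constraints[iid] = constraints[iid] & {GenotypeClass.HOM_REF}
    return _compile(constraints)


def pattern_case_control(
    cases: Sequence[str], controls: Sequence[str], model: str = "recessive"
) -> SegregationPattern:
    """Case-control preset over unrelated samples.

    ``recessive`` encodes a loss-of-function configuration: 1/1 for cases
    versus 0/1 or 0/0 for controls.  ``dominant``: cases {HET, HOM_ALT},
    controls {HOM_REF}.
    """
    errors = []
    if not cases:
        errors.append("cases list is empty")
    if not controls:
        errors.append("controls list is empty")
    overlap = set(cases) & set(controls)
    if overlap:
        errors.append(f"samples in both cases and controls: {sorted(overlap)}")
    if model not in ("recessive", "dominant"):
        errors.append(f"model must be 'recessive' or 'dominant', got {model!r}")
    if errors:
        raise ValidationError("; ".join(errors))
    if model == "recessive":
        case_set = frozenset({GenotypeClass.HOM_ALT})
        control_set = frozenset({GenotypeClass.HOM_REF, GenotypeClass.HET})
    else:
        case_set = frozenset({GenotypeClass.HET, GenotypeClass.HOM_ALT})
        control_set = frozenset({GenotypeClass.HOM_REF})
    allowed: dict[str, frozenset[GenotypeClass]] = {}
    for s in cases:
        allowed[s] = case_set
    for s in controls:
        allowed[s] = control_set
    return SegregationPattern(allowed)


def validate_pattern(
    pattern: SegregationPattern, roster: Sequence[str]
) -> list[str]:
    """Check a pattern against a VCF sample roster.

    Returns a list of human-readable violations (empty when valid); all
    problems are reported at once rather than failing on the first.
    """
    problems: list[str] = []
    roster_set = set(roster)
    for sample, classes in pattern.allowed.items():
        if sample not in roster_set:
            problems.append(
                f"constrained sample {sample!r} is not in the VCF roster "
                f"{sorted(roster_set)}"
            )
        if not classes:
            problems.append(f"empty allowed set for sample {sample!r}")
    if pattern.allowed and pattern.max_missing > len(pattern.allowed):
        problems.append(
            f"max_missing={pattern.max_missing} exceeds the number of "
            f"constrained samples ({len(pattern.allowed)})"
        )
    return problems


PRESETS = {
    "recessive": pattern_autosomal_recessive,
    "dominant": pattern_dominant,
    "de_novo": pattern_de_novo,
}
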