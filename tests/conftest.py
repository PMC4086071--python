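import itertools

import pytest
from hypothesis import settings

from varsieve import (
    Affection,
    GenotypeClass,
    Individual,
    Pedigree,
    Sex,
    VariantRecord,
    VariantTable,
)

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

HOM_REF = GenotypeClass.HOM_REF
HET = GenotypeClass.HET
HOM_ALT = GenotypeClass.HOM_ALT
MISSING = GenotypeClass.MISSING
OTHER = GenotypeClass.OTHER


@pytest.fixture
def trio_sib_pedigree() -> Pedigree:
    """Carrier parents, affected proband, unaffected sibling."""
    return Pedigree.from_individuals(
        [
            Individual("FATHER", sex=Sex.MALE, affected=Affection.UNAFFECTED),
            Individual("MOTHER", sex=Sex.FEMALE, affected=Affection.UNAFFECTED),
            Individual("PROBAND", father="FATHER", mother="MOTHER",
                       affected=Affection.AFFECTED),
            Individual("SIBLING", father="FATHER", mother="MOTHER",
                       affected=Affection.UNAFFECTED),
        ]
    )


def make_table(samples, genotype_rows, chrom="1", start_pos=100):
    """Build an in-memory VariantTable from rows of genotype classes."""
    records = [
        VariantRecord(
            chrom=chrom,
            pos=start_pos + i,
            ref="A",
            alt="G",
            rs_id=None,
            genotypes=dict(zip(samples, row)),
        )
        for i, row in enumerate(genotype_rows)
    ]
    return VariantTable(samples=list(samples), records=records)


def all_genotype_vectors(n, classes=(HOM_REF, HET, HOM_ALT, MISSING)):
    """Every genotype-class vector of length n over the given classes."""
    return list(itertools.product(classes, repeat=n))


def write_vcf_text(path, samples, lines):
    """Write a minimal VCF from raw data-line strings (tab-joined)."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + "".join(line + "\n" for line in lines))
    return path
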