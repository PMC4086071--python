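"""Controlled vocabulary of variant consequence types.

Consequence terms follow the Sequence Ontology (SO) names used by Ensembl's
effect predictor.  Legacy display labels from older annotation pipelines
("non-synonymous", "stop lost") are accepted as aliases and normalized to
their SO equivalents, so that a filter configured with either spelling
behaves identically.
"""

from __future__ import annotations

from .errors import ValidationError

#: Sequence Ontology consequence terms the package recognizes.
SO_TERMS: frozenset[str] = frozenset(
    {
        "transcript_ablation",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
        "inframe_insertion",
        "inframe_deletion",
        "missense_variant",
        "protein_altering_variant",
        "splice_region_variant",
        "incomplete_terminal_codon_variant",
        "stop_retained_variant",
        "synonymous_variant",
        "coding_sequence_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "non_coding_transcript_exon_variant",
        "intron_variant",
        "non_coding_transcript_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "TF_binding_site_variant",
        "regulatory_region_variant",
        "intergenic_variant",
    }
)

#: Legacy / loose labels mapped onto SO terms.
ALIASES: dict[str, str] = {
    "non-synonymous": "missense_variant",
    "non synonymous": "missense_variant",
    "non_synonymous": "missense_variant",
    "nonsynonymous": "missense_variant",
    "stop lost": "stop_lost",
    "stop gained": "stop_gained",
    "stop-lost": "stop_lost",
    "stop-gained": "stop_gained",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "frameshift": "frameshift_variant",
    "intronic": "intron_variant",
}

#: The default "severe effect" shortlist a prioritization run starts from.
DEFAULT_CONSEQUENCES: frozenset[str] = frozenset({"missense_variant", "stop_lost"})


def normalize_consequence(term: str) -> str:
    """Return the canonical SO term for ``term``.

    Raises
    ------
    ValidationError
        If the term is neither an SO term nor a known alias.
    """
    t = term.strip()
    if t in SO_TERMS:
        return t
    key = t.lower()
    if key in ALIASES:
        return ALIASES[key]
    raise ValidationError(
        f"unknown consequence term {term!r}; expected a Sequence Ontology term "
        f"such as {sorted(SO_TERMS)[:3]} ... or a legacy alias {sorted(ALIASES)}"
    )
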