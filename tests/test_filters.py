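"""Filter semantics: segregation with missing tolerance, annotation-driven
filters, cascade algebra, and the data-set summary."""

import itertools

import pytest
from hypothesis import given, strategies as st

from varsieve import (
    AnnotationRecord,
    AnnotationStore,
    ConsequenceStep,
    FilterCascade,
    FrequencyFilterConfig,
    FrequencyStep,
    GeneStep,
    Region,
    RegionStep,
    SegregationPattern,
    SegregationStep,
    TranscriptEffect,
    ValidationError,
    consequence_filter,
    frequency_filter,
    gene_filter,
    join,
    region_filter,
    run_cascade,
    segregation_filter,
    summarize,
)

from conftest import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    OTHER,
    all_genotype_vectors,
    make_table,
)

TRIO_SIB = ["FATHER", "MOTHER", "PROBAND", "SIBLING"]
RECESSIVE = SegregationPattern(
    {
        "FATHER": {HET},
        "MOTHER": {HET},
        "PROBAND": {HOM_ALT},
        "SIBLING": {HOM_REF, HET},
    }
)


class TestSegregationFilter:
    def test_recessive_configuration_retained(self):
        table = make_table(TRIO_SIB, [(HET, HET, HOM_ALT, HOM_REF)])
        assert len(segregation_filter(table, RECESSIVE)) == 1

    def test_allowed_set_violation_discarded(self):
        table = make_table(TRIO_SIB, [(HET, HET, HET, HOM_REF)])
        assert len(segregation_filter(table, RECESSIVE)) == 0

    def test_missing_tolerance_counts_missing_samples(self):
        table = make_table(
            TRIO_SIB,
            [
                (HET, HET, MISSING, HOM_REF),      # 1 missing
                (MISSING, MISSING, HOM_ALT, HOM_REF),  # 2 missing
            ],
        )
        pat1 = RECESSIVE.with_max_missing(1)
        kept = segregation_filter(table, pat1)
        assert [r.pos for r in kept.records] == [100]
        assert len(segregation_filter(table, RECESSIVE.with_max_missing(2))) == 2
        assert len(segregation_filter(table, RECESSIVE)) == 0

    def test_other_never_matches_nor_counts_as_missing(self):
        table = make_table(TRIO_SIB, [(OTHER, HET, HOM_ALT, HOM_REF)])
        for n in range(5):
            assert len(segregation_filter(table, RECESSIVE.with_max_missing(n))) == 0

    def test_unconstrained_samples_ignored(self):
        pat = SegregationPattern({"PROBAND": {HOM_ALT}})
        table = make_table(TRIO_SIB, [(OTHER, MISSING, HOM_ALT, HET)])
        assert len(segregation_filter(table, pat)) == 1

    def test_pattern_must_validate_against_roster(self):
        pat = SegregationPattern({"GHOST": {HET}})
        table = make_table(TRIO_SIB, [(HET, HET, HOM_ALT, HOM_REF)])
        with pytest.raises(ValidationError, match="GHOST"):
            segregation_filter(table, pat)

    def test_order_preserved(self):
        rows = [
            (HET, HET, HOM_ALT, HET),
            (HET, HET, HET, HET),
            (HET, HET, HOM_ALT, HOM_REF),
        ]
        table = make_table(TRIO_SIB, rows)
        kept = segregation_filter(table, RECESSIVE)
        assert [r.pos for r in kept.records] == [100, 102]

    @given(st.integers(0, 3))
    def test_missing_tolerance_is_monotone(self, n):
        """survivors(N) is a subset of survivors(N+1)."""
        table = make_table(
            TRIO_SIB, all_genotype_vectors(4), start_pos=1
        )
        keys_n = {r.key for r in segregation_filter(
            table, RECESSIVE.with_max_missing(n))}
        keys_n1 = {r.key for r in segregation_filter(
            table, RECESSIVE.with_max_missing(n + 1))}
        assert keys_n <= keys_n1


def _annotated(tmp_key, effects=(), mafs=None):
    table = make_table(["s"], [(HET,)], start_pos=tmp_key)
    ann = AnnotationRecord(
        key=table.records[0].key, effects=tuple(effects), mafs=mafs or {}
    )
    return join(table, AnnotationStore([ann]))


class TestConsequenceFilter:
    def _rows(self, *terms):
        effects = [
            TranscriptEffect(gene="G", transcript_id=f"T{i}", consequence=t)
            for i, t in enumerate(terms)
        ]
        return _annotated(1, effects)

    def test_any_transcript_semantics(self):
        rows = self._rows("missense_variant", "intron_variant")
        assert consequence_filter(rows, {"missense_variant", "stop_lost"}) == rows

    def test_empty_intersection_discarded(self):
        rows = self._rows("synonymous_variant")
        assert consequence_filter(rows, {"missense_variant", "stop_lost"}) == []

    def test_allowed_equal_to_term_set_retained(self):
        rows = self._rows("missense_variant", "intron_variant")
        assert (
            consequence_filter(rows, {"missense_variant", "intron_variant"})
            == rows
        )

    def test_legacy_aliases_accepted(self):
        rows = self._rows("missense_variant")
        assert consequence_filter(rows, {"non-synonymous", "stop lost"}) == rows

    def test_unknown_term_named_in_error(self):
        with pytest.raises(ValidationError, match="bogus_term"):
            consequence_filter(self._rows("missense_variant"), {"bogus_term"})

    def test_growing_allowed_set_grows_survivors(self):
        rows = self._rows("synonymous_variant") + self._rows("missense_variant")
        small = consequence_filter(rows, {"missense_variant"})
        large = consequence_filter(
            rows, {"missense_variant", "synonymous_variant"}
        )
        assert {r.key for r in small} <= {r.key for r in large}


class TestFrequencyFilter:
    def test_high_maf_discarded(self):
        rows = _annotated(1, mafs={("KG", "ALL"): 0.20})
        assert frequency_filter(rows, FrequencyFilterConfig(0.01)) == []

    def test_novel_variant_retained(self):
        rows = _annotated(1)
        assert frequency_filter(rows, FrequencyFilterConfig(0.0)) == rows

    def test_max_over_selected_columns(self):
        rows = _annotated(1, mafs={("KG", "ALL"): 0.005, ("ESP", "ALL"): 0.02})
        both = FrequencyFilterConfig(0.01, studies={"KG", "ESP"})
        kg_only = FrequencyFilterConfig(0.01, studies={"KG"})
        assert frequency_filter(rows, both) == []
        assert frequency_filter(rows, kg_only) == rows

    def test_comparison_is_strict(self):
        rows = _annotated(1, mafs={("KG", "ALL"): 0.01})
        assert frequency_filter(rows, FrequencyFilterConfig(0.01)) == []

    def test_population_subset(self):
        rows = _annotated(1, mafs={("KG", "AFR"): 0.3, ("KG", "EUR"): 0.001})
        eur = FrequencyFilterConfig(0.01, studies={"KG"}, populations={"EUR"})
        afr = FrequencyFilterConfig(0.01, studies={"KG"}, populations={"AFR"})
        assert frequency_filter(rows, eur) == rows
        assert frequency_filter(rows, afr) == []

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"threshold": 0.7},
            {"threshold": 0.01, "studies": frozenset()},
            {"threshold": 0.01, "studies": frozenset({"HAPMAP"})},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValidationError):
            FrequencyFilterConfig(**kwargs)

    @given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
    def test_threshold_monotonicity(self, t_low, t_high):
        if t_low > t_high:
            t_low, t_high = t_high, t_low
        rows = (
            _annotated(1, mafs={("KG", "ALL"): 0.004})
            + _annotated(2, mafs={("KG", "ALL"): 0.2})
            + _annotated(3)
        )
        low = frequency_filter(rows, FrequencyFilterConfig(t_low))
        high = frequency_filter(rows, FrequencyFilterConfig(t_high))
        assert {r.key for r in low} <= {r.key for r in high}


class TestRegionAndGeneFilters:
    def test_region_containment_and_inclusive_endpoints(self):
        table = make_table(["s"], [(HET,)] * 3, start_pos=499)
        # positions 499, 500, 501
        kept = region_filter(table, [Region("1", 500, 501)])
        assert [r.pos for r in kept.records] == [500, 501]
        end_hit = region_filter(table, [Region("1", 400, 499)])
        assert [r.pos for r in end_hit.records] == [499]

    def test_wrong_chromosome_discarded(self):
        table = make_table(["s"], [(HET,)], chrom="2")
        assert len(region_filter(table, [Region("1", 1, 10 ** 9)])) == 0

    def test_multiple_regions_union(self):
        table = make_table(["s"], [(HET,)] * 5, start_pos=100)
        kept = region_filter(
            table, [Region("1", 100, 100), Region("1", 103, 104)]
        )
        assert [r.pos for r in kept.records] == [100, 103, 104]

    def test_empty_region_list_invalid(self):
        table = make_table(["s"], [(HET,)])
        with pytest.raises(ValidationError):
            region_filter(table, [])

    def test_gene_membership_case_insensitive(self):
        rows = _annotated(
            1,
            [TranscriptEffect(gene="BCKDK", transcript_id="T",
                              consequence="missense_variant")],
        )
        assert gene_filter(rows, {"bckdk"}) == rows
        assert gene_filter(rows, {"BCKDK"}) == rows
        assert gene_filter(rows, {"OTHERGENE"}) == []

    def test_multi_gene_variant_matches_any(self):
        rows = _annotated(
            1,
            [
                TranscriptEffect(gene="GENEA", transcript_id="T1",
                                 consequence="intron_variant"),
                TranscriptEffect(gene="GENEB", transcript_id="T2",
                                 consequence="intron_variant"),
            ],
        )
        assert gene_filter(rows, {"geneb"}) == rows


def _fixture_for_cascade():
    """A small table whose variants differ on every filtered property."""
    rows = [
        (HET, HET, HOM_ALT, HOM_REF),   # segregates
        (HET, HET, HOM_ALT, HET),       # segregates
        (HOM_REF, HET, HOM_ALT, HET),   # fails segregation
        (HET, HET, HET, HOM_REF),       # fails segregation
        (HET, HET, HOM_ALT, HOM_REF),   # segregates
        (HET, HET, HOM_ALT, HOM_REF),   # segregates
    ]
    table = make_table(TRIO_SIB, rows, start_pos=100)
    anns = []
    specs = [
        ("missense_variant", None, "GENE1"),
        ("synonymous_variant", 0.001, "GENE1"),
        ("missense_variant", 0.001, "GENE2"),
        ("missense_variant", None, "GENE2"),
        ("missense_variant", 0.3, "GENE2"),
        ("stop_lost", 0.001, "GENE3"),
    ]
    for rec, (term, maf, gene) in zip(table.records, specs):
        anns.append(
            AnnotationRecord(
                key=rec.key,
                effects=(TranscriptEffect(gene=gene, transcript_id="T",
                                          consequence=term),),
                mafs={("KG", "ALL"): maf} if maf is not None else {},
            )
        )
    return table, AnnotationStore(anns)


def _steps():
    return [
        SegregationStep(RECESSIVE),
        ConsequenceStep({"missense_variant", "stop_lost"}),
        FrequencyStep(FrequencyFilterConfig(0.01)),
        RegionStep([Region("1", 100, 104)]),
        GeneStep({"GENE1", "GENE3"}),
    ]


class TestCascade:
    def test_empty_cascade_is_identity(self):
        table, store = _fixture_for_cascade()
        res = run_cascade(table, store, FilterCascade([]))
        assert res.per_step_counts == [6]
        assert [r.key for r in res.rows] == [r.key for r in table.records]

    def test_counts_non_increasing_and_subset_per_step(self):
        table, store = _fixture_for_cascade()
        res = run_cascade(table, store, FilterCascade(_steps()))
        assert res.per_step_counts[0] == 6
        assert all(
            a >= b
            for a, b in zip(res.per_step_counts, res.per_step_counts[1:])
        )
        assert res.step_names == [
            "segregation", "consequence", "frequency", "region", "gene",
        ]
        # only variant 0 passes everything
        assert [r.variant.pos for r in res.rows] == [100]

    def test_final_set_invariant_under_step_order(self):
        table, store = _fixture_for_cascade()
        reference = run_cascade(table, store, FilterCascade(_steps())).keys
        for perm in itertools.permutations(_steps()):
            assert run_cascade(table, store, FilterCascade(list(perm))).keys \
                == reference

    def test_segregation_step_validated_against_roster(self):
        table, store = _fixture_for_cascade()
        bad = FilterCascade([SegregationStep(SegregationPattern({"X": {HET}}))])
        with pytest.raises(ValidationError, match="'X'"):
            run_cascade(table, store, bad)


class TestSummarize:
    def test_empty_table(self):
        table = make_table(["a", "b"], [])
        stats = summarize(table, AnnotationStore())
        assert stats.samples == ["a", "b"]
        assert stats.n_variants == 0
        assert stats.type_counts == {"SNV": 0, "indel": 0}
        assert stats.consequence_counts == {}

    def test_type_and_consequence_counts(self):
        from varsieve import VariantRecord, VariantTable

        records = [
            VariantRecord("1", p, ref, alt, None, {"s": HET})
            for p, ref, alt in [
                (1, "A", "G"), (2, "C", "T"), (3, "G", "A"), (4, "AT", "A"),
            ]
        ]
        table = VariantTable(["s"], records)
        anns = [
            AnnotationRecord(
                key=records[0].key,
                effects=(
                    TranscriptEffect(gene="G", transcript_id="T1",
                                     consequence="missense_variant"),
                    TranscriptEffect(gene="G", transcript_id="T2",
                                     consequence="intron_variant"),
                ),
            ),
            AnnotationRecord(
                key=records[1].key,
                effects=(TranscriptEffect(gene="G", transcript_id="T",
                                          consequence="missense_variant"),),
            ),
        ]
        stats = summarize(table, AnnotationStore(anns))
        assert stats.type_counts == {"SNV": 3, "indel": 1}
        assert stats.consequence_counts == {
            "intron_variant": 1,
            "missense_variant": 2,
        }
        # a variant counts once per distinct term, so sums may exceed n
        assert sum(stats.consequence_counts.values()) == 3
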