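# varsieve

Pedigree-aware consecutive filtering for exome variant prioritization.

In whole-exome studies of familial and sporadic disease, a sequencing run
yields tens of thousands of candidate variants per sample, and the causal
mutation has to be found against that background of ordinary individual
variability. `varsieve` narrows a multi-sample VCF down to a handful of
candidates by applying successive, intersective filters:

1. **Segregation** — any pedigree and inheritance model is expressed as a
   per-sample set of allowed genotype classes (`0/0`, `0/1`, `1/1`), with a
   tolerance for missing calls (`./.`). Presets compile autosomal-recessive,
   autosomal-dominant (complete or incomplete penetrance), de novo and
   case-control designs into such patterns; arbitrary patterns can be given
   directly as YAML.
2. **Consequence type** — keep variants with a predicted severe effect on at
   least one transcript (Sequence Ontology terms; `missense_variant` and
   `stop_lost` are the classic starting shortlist).
3. **Allelic frequency** — discard variants whose minor allele frequency
   (MAF) in reference populations (1000 Genomes ALL/EUR/ASN/AFR/AMR, ESP)
   reaches a threshold; variants with no population record pass as novel.
4. **Regions** and **genes** — restrict to linkage intervals or genes of
   interest.

Annotations (gene, per-transcript effects, dbSNP ids, per-population MAFs,
SIFT/PolyPhen scores, phenotype strings) come from a local tab-delimited
table (schema documented in `varsieve/annotations.py`, worked example in
`examples/annotations.tsv`), so everything runs offline.

## The segregation model

For a pattern *P* mapping each constrained sample *s* to an allowed set
*A(s)* ⊆ {0/0, 0/1, 1/1} with missing tolerance *N*, a variant is retained
iff

* for every constrained sample, the genotype class is in *A(s)* **or** is
  missing (`./.`), and
* the number of constrained samples with a missing class is ≤ *N*.

Under autosomal-recessive inheritance in a nuclear family this is the
familiar configuration: both parents carriers (0/1), the affected child
1/1, unaffected siblings 0/0 or 0/1 — which automatically discards
Mendelian-inconsistent sites. The same machinery covers case-control
designs (e.g. 1/1 for cases versus 0/1 or 0/0 for controls for a
loss-of-function mutation). MAFs are derived from genotype counts as
p = (n_het + 2·n_homalt) / (2·n_total), folded to min(p, 1−p); when a
variant hits several transcripts, the most deleterious score is displayed
(minimum SIFT, maximum PolyPhen).

## Worked example

`examples/` contains a four-sample family VCF (carrier parents, affected
proband, unaffected sibling), the matching annotation table and PED file.

```sh
varsieve filter \
    --vcf examples/family.vcf \
    --annotations examples/annotations.tsv \
    --ped examples/family.ped --model recessive \
    --consequence non-synonymous --consequence "stop lost" \
    --maf-threshold 0.01 \
    --out-csv candidates.csv --out-report report.json
```

prints

```
steps: segregation, consequence, frequency
surviving variants per step: 8 -> 3 -> 2 -> 1
wrote 1 variants to candidates.csv
```

Of the 8 input variants, 3 are compatible with recessive segregation, 2 of
those are missense, and exactly one is also rare — the planted candidate, a
novel homozygous missense change in ITGAM:

```
position,change,gene,FATHER,MOTHER,PROBAND,SIBLING,id,...,consequence,sift,polyphen,phenotype
16:31120622,C>T,ITGAM,0/1,0/1,1/1,0/0,,...,missense_variant,0.01,0.99,
```

`report.json` records the per-step survivor counts and the full effective
configuration; re-running from that configuration reproduces the identical
output. `varsieve summary` prints data-set statistics (roster, variant
counts by type and consequence term), and `varsieve simulate` generates
synthetic family data sets with a planted causal variant under a chosen
inheritance model (Hardy–Weinberg background, configurable missingness and
genotype-error rates) plus matching annotations and a truth file.

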