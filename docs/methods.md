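# Methods

## The filtering model

`varsieve` treats variant prioritization as successive set intersection
over the records of a multi-sample VCF. Each configured filter is a pure
predicate on a (variant, annotation) pair; a cascade applies them in the
declared order and records the surviving count after each step. Because
every step only removes records, the final survivor set is invariant
under re-ordering of the steps — the order affects only the intermediate
counts shown to the user. This property is enforced by tests over all
permutations of configured cascades.

### Genotype classes

Per-sample genotypes are collapsed to five classes: `HOM_REF` (0/0),
`HET` (0/1 or 1/0; phase is ignored), `HOM_ALT` (1/1), `MISSING` (./.
or ., i.e. low-quality/low-coverage positions), and `OTHER` for anything
else — genotype indices pointing at a different ALT allele of a split
multi-allelic site, half calls such as `0/.`, and haploid calls.
`OTHER` never satisfies an allowed set and never counts toward the
missing tolerance: the segregation model deliberately reasons only about
the three called diploid classes and explicit missingness.

Multi-allelic VCF lines are split into one record per ALT allele, keyed
by (chrom, pos, ref, alt); indels are accepted as-is and assumed already
normalized (left-aligned, minimal representation). Coordinates are
VCF-native — 1-based and endpoint-inclusive — everywhere, including
region filters.

### Segregation with missing tolerance

A segregation pattern maps each constrained sample to a non-empty subset
of {HOM_REF, HET, HOM_ALT} plus an integer tolerance `max_missing`.
A record survives iff every constrained sample's class is allowed or
missing, and at most `max_missing` constrained samples are missing.
Samples absent from the pattern are ignored entirely, including for the
missing count. Survivor sets are therefore nested in `max_missing`
(monotone relaxation), which the suite checks exhaustively.

Presets compile pedigrees into patterns:

* **recessive** — parents of affected individuals {HET} (obligate
  carriers), affected {HOM_ALT}, unaffected {HOM_REF, HET};
* **dominant** — affected {HET, HOM_ALT}; unaffected {HOM_REF} under
  complete penetrance, unconstrained under incomplete penetrance (the
  relaxation is monotone per sample);
* **de novo** — both parents of each affected individual required and
  {HOM_REF}; affected {HET, HOM_ALT}; every other unaffected individual
  {HOM_REF}, since nobody else can carry an allele that arose in the
  proband;
* **case-control** — recessive: cases {HOM_ALT} versus controls
  {HOM_REF, HET} (the loss-of-function configuration); dominant: cases
  {HET, HOM_ALT} versus controls {HOM_REF}.

Individuals of unknown affection status are left unconstrained.
Contradictory combinations (e.g. an affected individual who is also a
parent of an affected individual under the recessive preset, where
{HOM_ALT} ∩ {HET} = ∅) raise a model error rather than silently
producing an unsatisfiable pattern; such pedigrees can still be analyzed
with a hand-written pattern.

A per-sample allowed-set model cannot express *joint* constraints across
samples. The recessive preset happens to exclude every
Mendelian-inconsistent called vector at the constrained trio (verified by
exhaustive enumeration), but the dominant preset does not — e.g. father
0/1, mother 0/0, child 1/1 passes the per-sample sets although it is
impossible under transmission — and the de novo preset *selects*
transmission-violating vectors by design. This is an inherent limitation
of per-site, per-sample filtering, shared with the interactive tools this
package is modeled on; compound heterozygotes are likewise out of scope
because the filter is strictly per-site.

### Annotation-driven filters

* **Consequence**: any-transcript semantics — a variant survives if at
  least one of its transcript effects carries an allowed Sequence
  Ontology term. Legacy labels ("non-synonymous", "stop lost") are
  normalized to SO terms (`missense_variant`, `stop_lost`) so either
  spelling configures the same filter.
* **Frequency**: the comparison is *strict* (`max MAF < threshold`
  passes) over the maximum of the selected study/population columns
  (1000 Genomes ALL/EUR/ASN/AFR/AMR and ESP), and a variant with no MAF
  record in any selected column passes — a novel variant has no
  population evidence against it. Both choices are the conservative
  reading for prioritizing rare causal candidates; survivors shrink
  weakly as the threshold decreases.
* **Region**: interval containment with inclusive endpoints, via an
  interval tree per chromosome.
* **Gene**: case-insensitive exact name match; variants annotated to
  several genes match on any of them (gene names are displayed
  pipe-separated).

### Derived quantities

MAF from genotype counts: p = (n_het + 2·n_homalt)/(2·n_total), folded
to min(p, 1−p) — always in [0, 0.5] and symmetric under swapping the
ref/alt roles. Damaging-score aggregation over a record's transcript
effects takes the most deleterious value: minimum for SIFT, maximum for
PolyPhen (both scores live in [0, 1] with opposite orientations). The
aggregation runs over all transcript effects of the record.

## Synthetic data generator

The generator emulates the inputs of a small family exome study:

* background allele frequencies drawn from a 50/50 mixture of
  U(0.0005, 0.05) (rare) and U(0.05, 0.5) (common), so the frequency
  filter is actually exercised; configurable to a single uniform band;
* founder genotypes from Hardy–Weinberg proportions, offspring by
  faithful single-locus Mendelian transmission;
* one causal variant whose genotype vector is drawn to satisfy the
  chosen model's preset pattern (recessive: parents 0/1, affected 1/1,
  unaffected 0/0 or 0/1 at random); it is novel by default (no rs id, no
  MAF record) and annotated with a configurable consequence
  (`missense_variant` by default) and damaging scores in the pathogenic
  range (SIFT < 0.05, PolyPhen > 0.9);
* per-genotype missingness and genotype-error rates (defaults 0 — the
  reference study condition is noise-free; tests that probe the missing
  tolerance turn them up explicitly). Noise hits background variants
  only, keeping the truth record clean, unless `corrupt_causal` is set —
  that flag exists precisely to exercise the missing-tolerance path;
* about 10 % of variants are indels and about 3 % carry no population
  annotation, mimicking novel background variation;
* positions laid out sequentially on 22 synthetic contigs, so nothing
  depends on a genome build; everything is reproducible from the seed
  (identical configs produce byte-identical files).

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, locus-specific mutation/error profiles, realistic
site-frequency spectra, sequencing reads or quality scores, and
population structure within the MAF columns (per-population values are
the global frequency with lognormal wobble). Passing tests therefore
demonstrate the correctness of the filtering semantics on faithfully
Mendelian data, not calibrated performance on real exomes.

## Numerical and design choices

* Filtering is exact set logic on exact genotype classes; the only
  floating-point comparisons are the strict MAF cut and score bounds.
* The annotation TSV stores numbers in `%g` format; round-trips are
  cell-identical for values written by the package.
* Problem sizes in the validation suite: the exhaustive oracle
  comparison enumerates all 4^n genotype vectors for n = 3–5 over 200
  random patterns; cascade recovery uses 20 simulated families of
  10 000 background variants each — large enough that segregation alone
  leaves a non-trivial background, small enough that the whole suite
  runs in well under a minute per family.
* CLI validation collects *all* configuration problems before exiting,
  so a user fixes one invocation, not one flag at a time. The JSON
  report embeds the full effective configuration and suffices to re-run
  an identical analysis.

## Known limitations

* Per-site filtering only: no compound-heterozygote or gene-burden
  logic, no kinship checking, no phasing.
* X-linked presets are not provided (expressible manually).
* The VCF INFO field is not interpreted; only GT is read.
* No annotation is computed in-package; the local table is trusted
  as given.
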