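# Methods

## The copy-loss model

`lofcall` treats a gene copy (haplotype) as *lost* in an individual when it
carries at least one high-confidence (HC) loss-of-function allele anywhere
in the gene. All downstream quantities derive from this rule:

* **Variant zygosity** is the alt-allele count of a biallelic call:
  0 (non-carrier), 1 (heterozygous), 2 (homozygous), with missing
  propagated.
* **Gene copy loss** (phased): evaluate the two haplotypes independently;
  copies lost = number of haplotypes carrying ≥1 HC LoF allele. The
  per-sample *mechanism* refines this: `HOMOZYGOUS` (some single variant is
  hom), `COMPOUND_HET` (two hets in trans, no hom), `HOM_AND_CH` (both),
  `MULTI_CIS` (≥2 hets all on one haplotype), `SINGLE_HET`, `NONE`, or
  `MISSING` (every call in the gene missing).
* **Gene copy loss** (unphased): cis/trans is unknowable, so a homozygous
  variant is the only proof of a two-copy loss. Any het carriage without a
  hom yields 1 copy lost; with ≥2 hets the mechanism is reported as
  `MULTI_CIS` with an `ambiguous` flag, which is the conservative reading
  (the alternative, trans, would claim a knockout that the data cannot
  support). Compound hets are never called from unphased data.

Mixed-phase data are handled conservatively per (sample, gene): if any
non-missing call at the gene's variants is unphased for that sample, the
unphased rule applies to that cell.

A **compound-het event** is recorded per (sample, gene) containing a trans
het pair. When more than two hets qualify, the reported pair is the
lowest-position het on each haplotype (ties broken on variant id), making
output deterministic; the full trans-pair list is available via
`lofcall.calling.trans_pairs`.

**Mechanism partition.** Over the whole cohort, each gene with ≥1 two-copy
sample is labelled `hom_only`, `ch_only`, or `both` (the latter includes
any single sample with both a hom variant and a trans pair). The labels
are disjoint and cover exactly the genes with a knockout.

**Frequencies** attached to matrix rows are sample-state fractions — e.g.
het frequency = (#samples with entry 1) / (#non-missing samples) — because
that is what the matrix consumers (association tools) collapse on. A
separate alt-allele frequency, (het + 2·hom) / (2·non-missing), is emitted
for the allele-frequency listing. Rows with no non-missing sample report
no frequency (NaN).

## Annotation parsing

The `CSQ` INFO field is parsed against the layout declared in the VCF
header (`Format: ...` sub-field list); `Gene`, `SYMBOL`, `Consequence`,
`LoF` and `LoF_flags` are required, `Allele`/`Feature` optional. LoF class
tokens other than `HC`/`LC` are demoted to no-class with a warning. A
variant is HC if *any* transcript consequence is HC (a `canonical`-only
policy is available), and it contributes independently to every gene some
consequence marks HC. HC consequences carrying `LoF_flags` are kept by
default (`keep_flagged=False` drops them).

Multi-allelic records are split on read: for each alt, genotype alleles are
remapped so the focal alt is 1 and everything else 0, and consequences
follow their alt via the VEP allele token (alt base for SNVs, trimmed
for simple indels, `-` for deletions). Haploid/hemizygous calls are
treated as homozygous for copy-loss purposes (logged); the model makes no
special provision for sex chromosomes beyond this.

## IMPUTE2 preprocessing

Two quality filters apply to imputed genotypes, matching standard
imputation QC practice:

* `min_info` (default 0.9): variants are retained when their INFO score is
  *strictly above* the threshold.
* `prob_cutoff` (default 0.05): a genotype call is accepted when the best
  probability of its triple is ≥ 1 − cutoff; otherwise the call is set
  missing. Ties break toward missing. The cutoff is therefore a
  *distance from certainty* — the natural reading of cutoffs quoted in the
  0.01–0.1 range, where a probability *floor* of 0.05 would be vacuous.
  The 0.05 default is the midpoint of that commonly examined range and is
  deliberately marked heuristic: both parameters should be tuned against a
  sequencing gold standard when one is available (`compare_callsets`
  exists for exactly that).

Phase is always taken from the `.haps` file; the probability triple decides
only missingness. When the argmax genotype disagrees with the haplotype
pair the haplotypes win and the conflict is logged.

## Trio validation and call-set comparison

A proband CH event is a **true transmission** when one parent carries one
variant of the pair and the other parent carries the other (≥1 alt allele;
parental phase is not required, matching array data). An event where a
parent is missing at both variants is counted false with a `missing_data`
flag — never silently dropped — and summary rates are reported both
including and excluding such events, since the choice of denominator is a
judgement call. A variant carried by neither parent sets a `de_novo` flag.

`compare_callsets` counts, per shared sample, variants called in a truth
cohort but not a test cohort (FN) and the converse (FP), keyed on
(chrom, pos, ref, alt) only; `two_copy_only=True` restricts to homozygous
calls. FP/FN are symmetric under swapping the cohorts.

## The synthetic generators

The generators exist to make every claim above testable with exact,
by-construction truth:

* **Cohort** (`generate_cohort`): defaults 200 samples × 300 genes, 2–4
  variants per gene, one knockout scenario per (gene, sample) cell planted
  at exactly `round(rate · cells)` cells — homozygous 1%, trans CH pair 1%,
  cis pair 0.5%, single het 3%. The first two variants of each gene are
  forced HC (so any gene can host a pair); others are HC with probability
  0.8. LC variants carry random rare het alleles (allele frequency
  log-uniform on 10⁻⁴–5·10⁻³, mimicking the rarity of deleterious alleles)
  that a correct pipeline must ignore. Optional missingness masks only
  alt-free HC calls, so planted scenarios survive and the truth of every
  masked cell remains derivable. Emitted truth: both matrices, per-cell
  mechanisms, the CH event list, and the gene-level mechanism partition.
* **Trios** (`generate_trios`): defaults 250 families, one planted CH per
  family. Offspring haplotype A is a copy of one paternal haplotype and B
  of one maternal haplotype, chosen per gene with no recombination within
  a gene (genes are short relative to recombination distances). A planted
  CH gives each parent one LoF allele of a distinct variant in the same
  gene on the transmitted haplotype. Parental genotype *errors* replace a
  call, with probability `genotype_error_rate`, by a random rare genotype
  (each allele Bernoulli(0.05)) — applied after transmission so the
  proband's calls are untouched. Replacement rather than allele-flipping
  was chosen because flipping a het preserves carrier status and would
  leave the validation rate at 100% even at error rate 1. Expected true-
  transmission rate ≈ [(1−e) + e(1−0.95²)]², monotone decreasing in e.
* **IMPUTE2** (`generate_impute2`): 150 variants × 200 samples by default;
  haplotypes drawn at allele frequencies uniform on 0.05–0.5 (common
  variants, so all three genotypes occur); each probability triple puts
  1 − noise on the true genotype with noise uniform on [0, 0.15], split
  70/30 over the other genotypes so exact ties cannot arise from the
  model; INFO scores Beta(1, 1). Probabilities and INFO scores are rounded
  to the 4 decimals actually written to the files, and the truth carries
  those rounded values, so threshold recounts are exact.

All generators are bit-reproducible given a config and seed.

What passing these tests shows — and does not. The simulations validate
the *logic*: phase handling, cis/trans discrimination, matrix and
frequency bookkeeping, transmission arithmetic, filter thresholds. They do
not emulate LD structure, annotation errors, phasing switch errors,
reference-panel effects or population stratification, so performance on
real cohorts is bounded by the upstream phasing/imputation/annotation
quality, not by anything measured here.

## Numerical and design choices

* Variant ordering is deterministic everywhere: (chrom, pos, ref, alt)
  with natural chromosome ordering; genes sort by gene id; no reliance on
  input hash order.
* Matrices use dense int8 storage with −1 as the missing sentinel;
  `-1`/`NA` conversion happens only at the I/O boundary. A gene entry is
  missing only if *all* of the gene's variant calls are missing for that
  sample; otherwise the non-missing calls drive the verdict.
* The same variant annotated for several genes yields one matrix row per
  (variant, gene) context in the gene matrix, and one row per variant in
  the variant matrix.
* Probability triples must sum to 1 within 10⁻³ (accommodating the
  precision of text-format genotype files); negative probabilities are
  fatal.
* The `.info` report is strictly key/value and round-trips through
  `parse_info_report`; it reports mean, median, min and max per-sample
  counts, covering both "average" and "median" reporting conventions.
* Pipeline outputs are staged in a temporary directory and moved into
  place on success, so a failed run leaves no partial outputs.
* Problem sizes in the acceptance script (20 cohort seeds at 200 × 300,
  250 families, 3 seeds per error rate, the 3 × 3 filter grid) were chosen
  as the smallest sizes at which every planted-event class is well
  represented (hundreds of events per class) while the whole script runs
  in well under a minute per section.

## Known limitations

* CH detection requires phased input; phase switch errors in the upstream
  phaser translate directly into cis/trans misclassification and are not
  modelled or corrected here.
* Copy-number variation is invisible: a deletion spanning a gene is not an
  HC LoF *variant* in the CSQ sense and will not be counted as a lost
  copy.
* The `canonical` transcript policy depends on a `CANONICAL` sub-field
  being present in the annotation; dialects that encode it differently
  fall back to excluding the consequence.
* Hemizygous genotypes are treated as homozygous, which is correct for
  male X outside the PAR but approximate elsewhere.
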