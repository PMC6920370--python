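# Methods

## The problem

In a cohort of unrelated families each segregating a distinct rare
Mendelian disease, a causal variant must satisfy three independent kinds of
evidence: it must track the affection status of the family under some
transmission model; it must be rare in reference populations; and it must
plausibly damage a protein. `raredx` implements that three-stage cascade,
plus two extensions that rescue the cases the plain cascade misses —
a misclassification-tolerant relabeling search for families whose clinical
labels are partly wrong, and a variant-density scan that localizes causal
events (such as short-tandem-repeat expansions) that are invisible to SNV
calling but betray themselves through a co-segregating haplotype block.

## Segregation filters

Five predicates are evaluated per family over a multi-sample VCF, given the
family's affection labels:

* **dominant** — every sequenced affected carries ≥ 1 alternate allele; no
  sequenced unaffected carries any.
* **recessive (homozygous)** — affecteds are hom-alt, unaffecteds are not,
  and every sequenced parent of an affected is a carrier (this excludes
  apparently-homozygous de novo artifacts).
* **compound heterozygous** — two distinct heterozygous variants in the
  same gene, each affected het for both; where an affected has both parents
  sequenced the two variants must come from different parents (trans), and
  a pair both of whose variants are traceable to the same parent is
  rejected as cis. Without parental data, pairs are reported flagged
  `phase_unknown` rather than discarded.
* **X-linked recessive** — affected males carry (diploid callers may code a
  hemizygote 0/1 or 1/1; both count), affected females are hom-alt,
  unaffected males carry nothing, unaffected females are not hom-alt.
  Unknown-sex individuals are unconstrained.
* **de novo** — affecteds with both parents sequenced carry an allele that
  neither parent carries; additionally no sequenced unaffected in the
  family carries it (stricter than minimal trio logic — the extended family
  serves as controls).

**Cross-family controls.** Under the rare-disease/rare-variant assumption,
every sequenced individual outside the analyzed family is a healthy
control: any observed alternate allele outside the family removes the
variant before the model predicates run.

**Missing genotypes.** A missing call never *violates* a predicate (30×
WGS has dropout), but every predicate requires positive support from at
least one affected individual's observed genotype. Partially missing calls
(e.g. `0/.`) can hide an allele and therefore cannot violate a carrier
requirement, while any observed alternate allele in a control is a real
violation. Individuals with unknown affection status constrain nothing.

Two implementations of the predicates coexist: per-record reference
functions, and a genotype-matrix engine used for cohort-scale scans and
for the relabeling search (where the same matrices are reused across
thousands of label assignments). A property test asserts they are the same
filter on random cohorts.

## Frequency, database and predictor filters

* **Population frequency.** A variant is removed when, over the five
  1000 Genomes super-populations (AFR, AMR, EAS, EUR, SAS), any clause of
  the rule fires: ≥ 1 population at frequency ≥ 0.05, ≥ 2 at ≥ 0.03, ≥ 3 at
  ≥ 0.025, or ≥ 4 at ≥ 0.02. Populations absent from the annotation count
  as unobserved. The rule is monotone in every frequency and configurable
  (`--freq-rule k:t,...`).
* **Databases.** The default policy removes a variant only on frequency
  evidence (the rule above, or an ESP frequency at/above the
  single-population threshold); bare dbSNP membership does not remove,
  because known pathogenic alleles carry rs identifiers too. A strict
  policy that removes any dbSNP member is selectable. Which reading is
  right is genuinely ambiguous; both are provided.
* **Deleteriousness.** Eight in-silico predictors (SIFT, PolyPhen, LRT,
  MutationTaster, MutationAssessor, FATHMM, MetaSVM, MetaLR) vote.
  A missense variant is deleterious when damaging calls strictly outnumber
  tolerated calls among non-missing calls (ties lose; the margin is a
  parameter). Nonsense, frameshift and canonical-splice variants are
  deleterious unconditionally — the predictors only score amino-acid
  substitutions. Non-frameshift indels need one damaging call; synonymous
  and noncoding variants are never deleterious.

Stages run in the order segregation → frequency/database → predictor vote;
each stage only shrinks the set, and the per-stage counts per model are the
run's `FilterTrace` (monotonicity is asserted at runtime). A
`frequency_first` flag reorders computation for efficiency; the final set
is identical because the stages are independent per-variant predicates,
and a test asserts this.

## Misclassification-tolerant search

Rare-disease phenotyping is unreliable: mild, late-onset or self-reported
phenotypes put cases among the controls and vice versa. Every individual's
label therefore carries a confidence flag (`firm`/`soft`; PED column 7,
default soft), and the search enumerates all relabelings that flip up to
`max_flips` soft labels of sequenced individuals, in ascending flip count,
re-running the full cascade under each. A candidate is reported once, at
the minimal flip count k that rescues it, together with every flip set of
that size that does so; ranking is (minimal k, number of distinct flip
sets, genomic coordinate). A combinatorial guard (default 10⁵ assignments)
refuses unbounded searches. With `max_flips = 0` the search reduces exactly
to the plain cascade.

## Density scan for hidden loci

A pathogenic repeat expansion produces no SNV record, but the founder
haplotype it rides on carries rare variants that co-segregate perfectly
with the disease and survive the segregation and frequency stages. The
scan consumes exactly those stage-2 survivors (not the predictor vote —
the linked variants are bystanders, not candidates):

1. per chromosome, a one-sided binomial test of the observed count against
   a uniform-by-length null, Benjamini–Hochberg corrected across
   chromosomes; chromosomes with q < α (default 0.05) are flagged;
2. on each flagged chromosome, sliding-window counts (1 Mb window, 0.5 Mb
   step); the peak window is the maximal-count window (ties → smallest
   start), the enriched run is the contiguous stretch of windows around the
   peak with count ≥ half the peak, and the peak center is the median
   position of the variants inside the peak window, rounded to 1 kb;
3. the candidate interval is the peak center ± 1 Mb (configurable), and
   genes overlapping it are ranked by distance of their midpoint from the
   center.

The run/center definitions are explicit conventions of this package: the
enrichment that motivates them is visually obvious in real data, and the
formalization (binomial + BH + median-of-peak-window) is the package's
choice of a defensible, testable rule.

## De novo CNV segments

CNV segments arrive pre-called per sample (read-depth calling is upstream
and out of scope). A child segment is *inherited* when a parental segment
of the same state (loss/gain) matches it under reciprocal overlap —
overlap/len(child) ≥ t and overlap/len(parent) ≥ t, t = 0.5 by default —
and *de novo* otherwise. Only same-state overlaps count; the threshold is
exposed because no canonical value exists. Genes overlapping a segment by
≥ 1 bp are attached (half-open coordinates; an abutting gene is excluded).

## Functional classification

For self-contained cohorts a minimal classifier assigns variant effects
against a toy gene model (exons + coding span on a supplied reference):
± 2 intronic bases flanking a coding exon → splicing; in-CDS indels are
frameshift iff net length mod 3 ≠ 0; in-CDS SNVs are classified by codon
translation (synonymous / missense / nonsense), strand-aware. It is
validated against a brute-force oracle that translates the entire coding
sequence before and after every possible substitution. It is deliberately
not a transcript-aware annotator; production cohorts bring their own
annotation table.

## The synthetic cohort generator

The generator makes the pipeline's assumptions true by construction and
records everything planted in a truth manifest, so that end-to-end tests
have ground truth. Default study conditions: 16 families totalling 79
sequenced individuals (4 trios, 4 quartets, 3 five-member recessive
sibships, 3 six-member three-generation families, one 8-member family with
collateral relatives, one 10-member three-generation family with six
affected and four healthy members), and 20,000 decoy variants.

* **Decoys.** Sites are placed uniformly per chromosome length
  (GRCh37-scale lengths). Each variant draws a base frequency from a
  mixture — 60% common (Beta(0.8, 4)) and 40% rare (log-uniform on
  10⁻⁴–10⁻²) — and per-super-population frequencies as correlated
  log-normal perturbations of that base, so the multi-population frequency
  rule has non-trivial behavior. Founder genotypes are drawn from
  Hardy–Weinberg at the EAS frequency (the emulated cohort is East Asian)
  and dropped through each pedigree independently per variant by Mendelian
  transmission. Functional classes are mostly noncoding/synonymous (70%),
  22% missense, and ~5% truncating/splice; common decoys are usually in
  dbSNP/ESP, rare ones rarely.
* **Causal planting.** One scenario per cohort (dominant, recessive-hom,
  compound-het, X-linked, de novo, LD block, de novo CNV) is planted in a
  family whose structure suits the mode; causal genotypes satisfy the mode
  under the *truth* labels, the allele is absent from every other family,
  and the annotation is novel (no population frequencies, not in
  databases) with damaging-truth predictor calls (each tool damaging with
  probability 0.9, missing with 0.05; benign-truth variants damaging with
  probability 0.1).
* **LD-block scenario.** ~100 rare variants on one founder haplotype
  spanning 16 Mb of chr14, transmitted as a single unit with the disease
  (no recombination within the block). The hidden locus sits within ± 2 Mb
  of the block center and is *not* emitted as a variant; variant positions
  are drawn from a 50/50 mixture of uniform-over-block and
  Normal(locus, 1 Mb), emulating the denser ancestral-haplotype sharing
  near the causal locus that makes the density peak informative. The gene
  table plants a target gene at the locus among decoy tiles.
* **CNV scenario.** A terminal 10 Mb loss (chr3:0–10,350,000) present only
  in the child, plus 5 decoy CNVs per parent which the child inherits with
  ± 2 kb breakpoint jitter (as independent per-sample calling would
  produce).
* **Imperfections.** Whole-call missingness at 1% and alt-allele dropout
  at 0.1% per allele. Genotype error is modeled as dropout (allele loss)
  rather than allele gain: in a joint-called family cohort the dominant
  error mode for a rare allele is losing it, and a gain-type model would
  scatter false alternate alleles over the ~75 cross-family controls and
  remove essentially every rare variant. Label errors are injected on
  request (flipping affected soft labels in the target family, never the
  designated proband) and recorded in the manifest.
* **Determinism.** One master seed; per-purpose and per-family RNG
  substreams are spawned from a single `SeedSequence`, so outputs are
  byte-identical across runs of the same seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium from a recombination map
(each decoy is dropped independently; only the planted block is a
haplotype), population demography and relatedness between families,
transcript-level annotation consistency (decoy classes are drawn, not
derived from sequence), base-calling artifacts that *add* alleles, and
CNV/SV calling noise. Results on real cohorts depend on upstream callers
and annotators in ways these cohorts cannot probe.

## Numerical and design choices

* Genotype matrices are `int8` with −1 for a missing allele slot; a
  multiallelic site splits into biallelic records with other-alt alleles
  mapped to missing slots, conserving each sample's multiset of non-ref
  alleles.
* Binomial tails come from `scipy.stats.binomtest`, BH correction from
  `scipy.stats.false_discovery_control`; both are checked against exact
  computations in tests.
* Ties: the peak window takes the smallest start; candidate ranking and
  flip-set ordering are lexicographic; report output is fully ordered so
  identical inputs give byte-identical reports.
* Degenerate inputs: zero variants yield an empty enrichment result with a
  warning; a window scan needs ≥ 1 variant; pedigrees must contain an
  affected member; requesting the de novo model without a sequenced parent
  pair is a configuration error, not an empty result.
* Problem sizes in the validation suite — 50 cohorts per inheritance mode,
  20 for the label-noise/LD-block/CNV checks, 1,000 random small cohorts
  for the oracle comparison — were chosen to give stable pass/fail margins
  at the default study conditions while keeping a full run in minutes on
  one core.

## Known limitations

* Compound-het phasing uses parental carrier status only; a parent
  carrying both variants makes the pair's phase ambiguous rather than
  resolved, and no population phasing is attempted.
* The X-linked filter treats diploid-coded hemizygotes permissively and
  applies no pseudo-autosomal-region logic.
* The density scan's localization precision is bounded by the half-width
  convention (± 1 Mb); a locus at the edge of a diffuse block can fall
  outside the interval.
* The relabeling search scales as Σ C(s, k); families with many
  soft-labeled members need the firm/soft column or a lower `max_flips`.
* No statistical linkage (LOD), penetrance modeling, or
  genotype-likelihood-aware de novo calling.
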