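# Methods

## Model

A tumor's MSI status is inferred from its somatic mutation catalog alone.
The statistical object is the per-tumor feature vector of mutation rates
normalized by the capture length in Mb: *T.sns*, *S.sns*, *T.ind*,
*S.ind*, *T*, *S*, the three ratios *S.sns/T.sns*, *S.ind/T.ind*, *S/T*,
and the cancer-type label. The modeling assumptions are:

* mismatch-repair deficiency raises the rate of somatic length changes in
  simple repeats (*S.ind*) by more than an order of magnitude relative to
  MMR-proficient tumors, and also raises overall SNS rates;
* substitution and microindel calling have different error profiles, so
  the two classes are never pooled before normalization;
* the denominator is the *targeted* sequence length — mutations called
  outside the capture design are excluded (and tallied), since counting
  them against the targeted length would inflate every rate;
* POLE-proofreading deficiency produces the complementary signature —
  extreme *T.sns* with low *S.ind* — and is flagged, never folded into
  the MSI call.

The default classifiers are single-split stumps on *S.ind* with packaged
cutoffs 0.395/Mb (exome regime) and 0.909/Mb (whole-genome regime; simple
repeats are denser genome-wide, so the same biology yields a higher rate).
All decision inequalities are strict: a value exactly at a cutoff is the
negative outcome. The POLE flag requires *T.sns* > 60/Mb **and**
*S.ind* < 0.18/Mb, both strict.

## Coordinate conventions

Internally every interval is 0-based half-open; conversions happen only at
file boundaries. MAF records are 1-based inclusive: an SNS or deletion
spanning 1-based `[start, end]` maps to half-open `[start−1, end)`; an
insertion (MAF convention `end = start + 1`, the two flanking bases) maps
to the same `[start−1, end)` span covering both flanks. BED and
`simpleRepeats` inputs are already half-open and pass through unchanged.
`chr` prefixes are stripped on read so UCSC- and Ensembl-style naming
interoperate.

## Repeat annotation

Simple repeats are the union of (i) homopolymer runs of length ≥ 5 scanned
from the reference sequence — case-insensitive, with `N` breaking any run,
since an ambiguity base is not evidence of a repeat — and (ii) di-, tri-
and tetranucleotide tandem repeats taken from a `simpleRepeats`-style
table, filtered on its `period` column only. The merged track is sorted
and non-overlapping; overlap queries are binary searches (O(log n) per
query). A mutation is "in repeat" if its span overlaps any repeat base
(any-overlap rule: a length change touching a repeat changes the repeat's
length). Two variations are exposed but off by default, because nothing in
the method's definition requires them: a symmetric `pad` around the span
before the overlap test, and a strict-inside rule for insertions
(`insertion_rule="within"`), under which an insertion counts only when
both flanking bases lie in the repeat.

Zero-denominator ratios (e.g. *S.ind/T.ind* for a tumor with no indels)
are missing values, never 0 or ∞: fabricating 0 would bias retraining,
and the default classifier never consults a ratio.

## Tree induction and cross-validation

Retraining uses a documented C4.5-flavored procedure rather than a
bit-exact clone of any toolkit: greedy top-down induction scoring
candidate splits by information-gain ratio; numeric candidates are the
midpoints between consecutive distinct sorted values (ties in score break
toward the smallest threshold); the categorical cancer type enters as
one-vs-rest splits. Growth stops when a node is pure, when a split would
create a child smaller than `min_leaf` (default 2), at `max_depth`
(default 5), or at zero gain. Bottom-up pruning then replaces any subtree
by its majority-class leaf whenever that does not increase training
error — this is what collapses the tree to a stump on well-separated
data. Samples missing a feature are left out of that feature's split
scoring and are routed down the `>` branch during induction and pruning;
at prediction time a missing required feature is an error naming the
sample and feature (the packaged stumps require only *S.ind*). Induction
is deterministic; the `seed` parameter exists for interface symmetry.

Cross-validation stratifies folds by class (per-class shuffle, round-robin
deal, fully determined by the seed) and reports concordance pooled over
test folds: 100 × correct / n. Laboratory MSI-L and MSS labels are always
grouped as non-MSI-H before any comparison, reflecting their clinical and
mutational similarity.

## Evaluation machinery

* **Fisher's exact test** (one-sided, enrichment of the top-left cell) is
  the exact hypergeometric tail via `scipy.stats.fisher_exact`; the test
  suite checks it against full enumeration over all tables with margins
  ≤ 12 at 10⁻¹² relative error.
* **ROC/AUC** ranks samples by raw *S.ind* and uses the pair-count
  definition (ties ½) via `sklearn.metrics`; the suite cross-checks a
  brute-force pair-counting oracle.
* **Capture-subset robustness**: each replicate draws whole target
  regions without replacement until the accumulated length first reaches
  the requested length; the last region may overshoot and the achieved
  length becomes the rate denominator. Sampling whole regions (rather
  than base windows) avoids fabricating breakpoints; at full length the
  experiment reproduces the full-data calls exactly, which the suite
  asserts.
* **Repeat density** is reported per consecutive group of target regions
  (default 1,000 regions per group) as distinct repeat intervals
  overlapping the group per Kb of grouped region length.

## Synthetic-data generator

The generator emulates a capture-sequenced tumor cohort: exon-like target
regions (150–1,500 bp) over five synthetic chromosomes; repeat intervals
planted inside regions at a configurable density (default 5.6/Kb of
capture, exome-like); and three tumor classes with per-Mb rate means —
non-MSI-H (T.sns 3.0, S.ind 0.05), MSI-H (T.sns 30, S.ind 1.5) and
POLE-like (T.sns 80, S.ind 0.05). Per-sample counts are
negative-binomial with dispersion parameter 10 (real tumor burdens are
overdispersed; CV ≈ 32% at these settings). Each class also has an
off-repeat microindel rate (0.3, 3.0 and 0.5/Mb respectively) so that
*T.ind* exceeds *S.ind* and the indel ratio is informative. In-repeat
mutations are placed uniformly on repeat bases and the rest uniformly on
repeat-free capture bases, so a feature computation over the generated
files recovers each sample's drawn counts exactly — this is asserted in
the tests. The default capture is 30 Mb (exome scale): several
class-separation guarantees (e.g. "a pure non-MSI-H cohort is never
called MSI-H") hold only when a single stray repeat indel cannot move
*S.ind* near the 0.395 cutoff, which requires an exome-scale denominator.

What the generator does **not** emulate: sequencing depth and caller
error (mutations are placed, not called), mutational signatures and
trinucleotide context, inter-sample contamination, regional variation in
repeat density beyond placement noise, and correlation between cancer
type and class. Passing tests therefore demonstrate the correctness of
the counting, normalization, induction and evaluation machinery under the
assumed class structure — not the clinical accuracy of the cutoffs on
real cohorts, which depends on variant-calling quality.

A separate reference-sequence generator plants homopolymers (5–12 bp,
with non-matching flanks so planted runs are maximal exactly as planted)
and 2–4 bp tandem arrays in random sequence, returning the truth track
for scanner validation.

## Problem sizes and numerical choices

The test suite and the acceptance script run synthetic cohorts of 17–160
samples over 1.5–30 Mb captures, tree induction at n = 400, the Fisher
enumeration over all ≈5,500 small tables, and 10–20 subset replicates;
the whole suite completes in well under a minute on one CPU. Equality
thresholds throughout use strict inequalities as stated above; sample
standard deviations use n−1 except subset-experiment spread (population
form, so a single replicate reports 0); class-tie majority votes in
leaves break toward MSI-H deterministically.

## Known limitations

* The retrainer is not a bit-exact J48/C4.5 reimplementation (no
  confidence-interval pruning, no fractional instances for missing
  values); the packaged cutoffs are constants, so this affects only
  retraining, which need be principled and reproducible rather than
  Weka-identical.
* The benchmark panel records the hypermutation condition (*T.sns* >
  60/Mb) as a boolean because exact burdens are not part of the panel;
  panel POLE flags combine that boolean with the recorded *S.ind*.
* MSI-L is never a predicted class; the classifier is binary by design.
* Variant calling, BAM handling and depth down-sampling are out of scope:
  the package starts from a somatic mutation list.
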