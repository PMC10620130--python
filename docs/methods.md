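# Methods

## Scope and data model

The package implements the computational core of a multi-omics tumour-cohort
analysis: chromosome-level CIN scoring with Simple/Complex classification,
windowed chromothripsis detection, allele-specific-expression classification
of somatic mutations, threshold-based expression/miRNA integration, and
exact two-group statistics. Upstream steps — alignment, variant calling,
allele-specific segmentation (FACETS or similar), expression quantification
and differential-expression model fitting — are out of scope; their tabular
outputs are the inputs here.

Coordinates are 0-based half-open internally; segment files default to the
SEG convention (1-based inclusive) with a BED-style dialect accepted behind
a flag, and the round-trip file → internal → file is the identity.
Chromosome names are normalised (leading `chr` stripped, `23` → `X`). The
default genome model is b37, autosomes 1–22 plus X; DNA coordinates in the
motivating study were on b37 while RNA used GRCh38, but all interval
arithmetic here concerns the copy-number side, so a single build is used.
Segments need not tile a chromosome: allele-specific segmenters emit gaps,
which carry no state.

## Affected-chromosome CIN score

For each chromosome of a sample:

- **CNV-affected** — some segment of length ≥ `min_aberrant_len_bp`
  (default 0) has total copy number different from the baseline;
- **cnLOH-affected** — some such segment has total copy number equal to the
  baseline and minor-allele copy number 0.

The per-sample summary partitions affected chromosomes into CNV-only /
cnLOH-only / both (the categories are disjoint; a chromosome with both
kinds of segment counts once, in *both*), and the total is their sum. A
sample with total ≥ `complexity_threshold` (default 10) is **Complex**,
otherwise **Simple**; the threshold is inclusive and no rounding is
involved since the counts are integers.

Design choices where the convention was genuinely open:

- **Baseline copy number is 2 (diploid) by default**, not sample ploidy:
  near-tetraploid samples in practice show high affected-chromosome totals
  under a diploid reference, which matches how such cohorts are scored. A
  `nearest_integer_ploidy` mode is available.
- **Chromosome X** is eligible for CNV counting in all samples, but is
  excluded from cnLOH counting in male samples (a single X is hemizygous,
  not LOH); the behaviour can be forced either way through
  `count_x_for_cnloh`.
- **No minimum segment length** by default: any aberrant segment flags its
  chromosome. The length filter exists for noise robustness on real data.

## Comparator CIN metrics

Given per-segment log-ratios (taken from the input when present, otherwise
derived as log₂(max(total_cn, 0.5)/baseline); the 0.5 floor keeps
homozygous deletions finite):

- `cna_segment_count` — segments with |log-ratio| above
  `log_ratio_threshold` (default 0.2);
- `breakpoint_count` — adjacent same-chromosome segment pairs whose total
  copy number differs;
- `fga` — summed length of above-threshold segments divided by the genome
  length of the build (bounded to [0, 1]);
- `tai` — length-weighted mean |log-ratio| over **all** segments; a masked
  variant restricted to above-threshold segments is behind a flag, since
  both conventions circulate.

FGA and TAI are invariant under splitting a segment into equal-state
pieces; the breakpoint count is invariant under such splits because an
equal-state split introduces no copy-number change.

## Chromothripsis detection

Per chromosome, adjacent segments in sorted order are compared — across
gaps, since segmenter output is gapped and no maximum-gap rule is imposed —
and each pair with differing state contributes one switch at the left
segment's end. The default state is total copy number; an allele-specific
mode also counts transitions in the minor allele (e.g. into cnLOH). The
score is the maximum number of switch positions inside any half-open
window `[x, x + 50 Mb)`; this maximum is computed exactly, because any
window can be slid right until its left edge touches a switch position
without losing one, so anchoring at the positions suffices. A chromosome
reaching 10 switches in a window is positive with high confidence.
Chromosomes with zero switches are omitted from reports unless requested.

## ASE classification

Somatic variants first pass the evidence filter (tumour depth ≥ 50,
control depth ≥ 30, tumour MAF ≥ 0.03, supporting reads ≥ 5; all
inclusive). Each variant joined to RNA evidence is assigned exactly one
category, in this order: **not covered** when no RNA read overlaps the
locus; **gene not expressed** when the gene's TPM < 2; **mutated allele
expressed** when RNA VAF > 0.03; **mutated allele not expressed**
otherwise (VAF ≤ 0.03). The deliberately asymmetric comparisons — TPM
inclusive at 2, VAF strict at 0.03 — follow the classification rules as
stated, and the boundary observations (TPM exactly 2 → expressed gene;
VAF exactly 0.03 → allele not expressed) are pinned in tests. "Not
covered" is an explicit class rather than a dropped row so counts stay
auditable, but it is excluded from the denominator of the per-sample
proportions. Because averaging per-sample proportions and pooling
variants give different cohort figures, the cohort summary reports both.
TMB is mutations per Mb of the sequenced target (the target size is a
required argument — there is no hidden exome-size constant), low when
strictly below 5/Mb.

## Expression and miRNA integration

DE statistics (adjusted p, q, log₂ fold changes, group medians) are
consumed, never computed. mRNA background: a gene is removed only when its
median TPM is below 2 in **both** groups. mRNA DE: adjusted p < 0.05 and
|log₂FC| > 1, both strict. miRNA background: the adopted reading of the
"before and after normalisation … in both groups" rule is the most
conservative one — removal only when all four medians (raw and normalised,
each group) are below 45; `raw_only` / `norm_only` readings are selectable.
miRNA DE: q ≤ 0.05 and |log₂FC| ≥ 1, both inclusive — the contrast with
the strict mRNA rule is kept deliberately, with a switch to harmonise.
Pairing emits (miRNA, gene) exactly when both are DE, an interaction of
allowed confidence (experimentally observed or highly predicted, by
default) links them, and their fold changes have strictly opposite signs;
zero fold change pairs with nothing. Fold-change signs are
metastatic-over-non-metastatic throughout.

## Exact Mann–Whitney

For pooled sample sizes up to 25 the two-sided p-value is exact under the
permutation null: with midranks assigned to the pooled values, the
distribution of the rank sum over all C(n_a+n_b, n_a) group assignments is
obtained by a subset-sum counting recurrence over doubled midranks
(doubling makes them integers, so ties are handled exactly), and the
p-value doubles the smaller tail of the U distribution, capped at 1. This
convention is well defined with ties at these sample sizes; since exact
conventions differ between implementations, published p-values from other
tools are treated as significance bounds rather than equalities. Above 25
pooled observations the tie-corrected normal approximation
(`scipy.stats.mannwhitneyu`) is used. Group medians use the midpoint
convention for even sizes.

## Synthetic-data generator

Ground truth is planted constructively — values satisfy their class's
defining inequalities with a margin sampled away from the boundaries — not
drawn from fitted distributions, because no distributional parameters for
the raw data are available. Consequences: passing tests demonstrate the
correctness of the rule implementations and their invariances, not
robustness to real-data noise (segmentation artefacts, purity, mappability
bias), which the generator does not emulate. Boundary-case observations
are available behind a flag with documented expected classes.

Segment profiles assign disjoint roles to chromosomes: CNV-only (a planted
gain), cnLOH-only (a copy-neutral LOH segment), both, chromothriptic
(alternating 2↔3 segments), all else diploid heterozygous. Segment
boundaries are jittered from a seeded generator; identical seeds give
byte-identical output files. A chromothriptic chromosome with ≥ 1 switch
necessarily carries non-diploid segments and therefore also counts as
CNV-affected in the ground-truth summary. A segment-noise mode randomly
splits segments into equal-state pieces, which provably changes no CIN
count and no chromothripsis call and is used by the invariance tests.

Chromothriptic breakpoints: for spans up to the detection window the k
breakpoints are spread evenly over the half-open span, so they always fit
one window. For spans beyond the window, breakpoints are packed into
clusters of at most threshold − 1 at sites more than one window apart, so
no window reaches the threshold. This dispersal is geometrically possible
only while k ≤ (threshold − 1) × number of cluster sites: by pigeonhole,
any 28 or more breakpoints inside a 120 Mb span must place 10 inside some
50 Mb window (three disjoint 50 Mb windows cover the span), and such
chromosomes are detected regardless of placement. The planted ground-truth
label is always computed from the actually planted positions, so
generator and detector can never silently disagree.

The bundled fixture tables encode a 21-sample high-risk GIST cohort: the
per-sample affected-chromosome counts with ploidy and mitotic count, and
the chromothriptic chromosomes of the five high-confidence samples with
their switch counts. Re-scoring profiles planted from the count table
reproduces every total and label (11 of 21 Complex; non-metastatic median
6, range 1–20; metastatic range 7–23).

## Problem sizes and numerics

The oracle suites run 150–200 random instances per property: random small
profiles on a 5-chromosome toy genome against a per-segment scan, random
breakpoint sets against an exhaustive 1-bp-anchor window scan, and random
two-group data with ties (pooled n ≤ 12) against full enumeration of
assignments; these sizes make full enumeration cheap while covering the
tie and boundary structure. Proportions are exact rational counts; the
only floating-point tolerances are pytest's default approx on FGA/TAI
(invariance under splits) and 1e-12 on proportion sums. All randomness is
seeded; the hypothesis suites are derandomised.

## Known limitations

- The generator's cosmetic realism is minimal (no segment-length
  distributions fitted to data, no log-ratio noise, no purity effects).
- Structural-variant-based chromothripsis criteria (breakpoint clustering,
  fragment joins, heterozygosity retention) are not implemented; only the
  windowed switch-count rule is.
- VCF ingestion of variants is not provided; variants arrive as TSV with
  explicit depth/allele-count columns.
- Arm-level event calling, recurrence analysis across samples, and
  purity/ploidy estimation are out of scope.
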