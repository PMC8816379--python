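# Methods

`amniomics` re-implements, as a tested library, a paired cross-omics
analysis of the human fetal membrane at term: amnion vs choriodecidua
methylation and expression differences within the zone of intact
morphology (ZIM) and the zone of altered morphology (ZAM, the
physiological rupture site), their integration, and the downstream
sequence-level analyses (term enrichment, miRNA seed scanning, in-silico
COBRA).  This note describes the models, the numerical choices, and what
the synthetic benchmark does and does not establish.

## Paired differential methylation

For each probe, the statistic is the mean over patients of the
within-patient methylation difference Δβ = mean_i(β_A,i − β_C,i), with a
two-sided paired Student t-test on the per-patient differences
(`p = 1` for zero-variance differences — a conservative policy that keeps
constant probes in the table instead of producing NaNs).

Significance alone does not select a probe.  A Monte-Carlo sign-flip null
provides per-chromosome Δβ limits (m, M): in each iteration the two
tissue labels are flipped independently within each patient (equivalently
each patient's difference vector changes sign as a block, preserving the
paired correlation structure), the null Δβ is recomputed for every probe,
and the per-chromosome minimum and maximum are recorded.  A probe is
selected iff `p < alpha` (default 0.05) **and** Δβ < m or Δβ > M on its
chromosome.  Two aggregations over iterations are offered:

* `extreme` (default): m = min of minima, M = max of maxima.  Appropriate
  for null-calibration questions, but the extremes grow with the
  iteration count, and on data that *do* contain effects the identity
  sign pattern (probability 2^-n per iteration, ~2 expected hits in 1000
  iterations at n = 9) drives M to the largest observed Δβ itself — so no
  true effect can exceed it.  Extreme aggregation is therefore a
  specificity instrument, not a sensitivity one.
* `quantile`: m and M are empirical quantiles of the per-iteration
  minima/maxima.  The default level is 0.01/0.99.  At n = 9 pairs the
  null of the per-chromosome maxima is discrete with an outermost atom of
  mass 2/512 ≈ 0.0039 (the two fully aligned sign vectors); a level of
  0.005 sits almost exactly on that atom and the empirical quantile at
  1000 iterations is unstable, whereas 0.01 falls between the atom masses
  (0.0039 < 0.01 < 20/512 ≈ 0.039) and is reproducible.

Both the aggregation and the iteration count are recorded in the limits
table.  Selected probes are lifted to gene calls by an any-probe rule: a
gene is `mA>mC` if at least one of its selected probes has Δβ > 0 and
`mA<mC` if at least one has Δβ < 0 (a gene may be both; probes annotated
to several genes count for each; intergenic probes are dropped).
Coordinates are 0-based half-open throughout, including the BED export.

## Paired differential expression

Per gene, log2 FC is the mean over patients of the paired log2
difference; a two-sided paired t-test with Benjamini–Hochberg adjustment
across all tested genes classifies genes as up/down when
|log2 FC| ≥ 2.8 (inclusive boundary) and adjusted p < 0.01, both
configurable.  A multi-group post-hoc test is not meaningful for this
two-group paired design, so the paired t-test is the test of record.
Linear-scale input is log2-transformed after a positivity check.

## Integration

The four per-zone direction sets are partitioned exactly by membership
pattern (15 regions); zone-specific sets are unions of regions involving
only that zone's sets.  The cross-omics step intersects gene calls with
expression classes under the inverse-correlation convention:
`hyperA_upC` = hypermethylated in the amnion ∩ classified down (i.e.
higher in the choriodecidua), and conversely.  Gene symbols join
case-insensitively with an optional synonym map; methylome genes absent
from the expression universe are reported as `untested`, not silently
intersected.

## Term enrichment

Over-representation of a study set against any gene→term table uses the
upper-tail hypergeometric probability P(X ≥ k) (scipy's log-space
survival function), with Bonferroni (default), BH, or no correction.
The population defaults to the platform's tested genes rather than the
genome; terms with zero population hits are excluded from both testing
and the Bonferroni multiplier.  The engine is deliberately DAG-free: no
GO-hierarchy propagation or semantic collapsing is performed, and any
term vocabulary (e.g. disease terms) can be supplied.

## miRNA seed scanning and concordance

Canonical seed sites only: the 6mer core is the reverse complement of
mature positions 2–7; 7mer-m8 adds the position-8 complement, 7mer-A1
adds an A anchor opposite position 1 (an A regardless of the mature
base), 8mer adds both.  Overlapping matches are reported once at the
highest-specificity type.  No context scores, conservation or free-energy
terms are computed — the prediction is used qualitatively.  Candidate
nomination excludes 6mers by default and flags a (miRNA, target) pair as
concordant when the miRNA gene is hypermethylated (presumed silenced) in
the tissue where the target is over-expressed.  Probe→miRNA-gene
assignment is by an explicit map, not a distance heuristic.  miRNA-gene
probe differences are tested with the exact Wilcoxon signed-rank test.

The bundled `tlr4_3utr_synthetic.fasta` is a **synthetic** 2,223-nt
stand-in for the TLR4 3'UTR (matching the transcript's UTR length) with
one canonical site planted for each of let-7a and miR-125b; it exercises
the scanner end-to-end but is not the genomic sequence.

## In-silico COBRA

Bisulfite conversion maps every top-strand cytosine to thymine except
methylated CpG cytosines (IUPAC codes pass through).  Virtual PCR matches
conversion-specific primers exactly against the converted strand and
requires unique binding.  Digestion cuts at every non-overlapping
occurrence of the recognition site (Taq I preset: TCGA, cut after
position 1).  Because TCGA contains a CpG, a fully unmethylated template
loses every site and yields a single fragment — the chemistry invariant
the property tests sweep.  Only the top strand is modelled; partial
digestion and mismatch-tolerant priming are out of scope.

## Small-sample statistics

* Wilcoxon matched-pairs signed-rank: exact two-sided p for n ≤ 25 via
  the full sign-assignment distribution of W+ computed by convolution on
  doubled mid-ranks (handles ties); normal approximation with
  Var = Σr²/4 above.  Zero differences are dropped (Wilcoxon's
  convention) with Pratt handling behind a flag; all-zero input returns
  p = 1 with a warning.
* Kruskal–Wallis with tie correction (scipy) plus Dunn's post-hoc on
  pooled mid-ranks, Bonferroni over pairs by default.
* qPCR standard-curve quantification: least-squares line of Ct on log10
  quantity (slope must be negative), inverted per gene, target quantity
  normalised to the geometric mean of two housekeeping quantities.
* Reporter-ratio normalisation: signal/reference scaled to the control
  condition.

## Synthetic cohort generator

The generator emulates the study design: 9 patients × 2 tissues × 2
zones, with planted effects in the ZAM comparison only (the ZIM
comparison is null), so zone-specific integration has a known truth.
Defaults: 2,000 probes in blocks of 4 per gene over 400 genes (surplus
probes intergenic), 5% differential probes planted gene-block-wise with a
0.3 β-unit shift against 0.05 β-units of noise, 5% differential genes
with a 4 log2-unit shift against 0.5 log2 units of noise, and half the
expression-differential genes drawn from the methylation-differential
genes with inverse orientation to give a known cross-omics overlap.

β values are built on the logit scale: probe means are set in β units,
noise SD is rescaled by the delta method (sd_logit = sd_β / (μ(1−μ))) so
its β-scale magnitude matches the configured value, patient random
intercepts (SD 0.2 logit units) are shared across a patient's samples,
and the inverse logit maps into (0, 1) with no censoring.  The second-
order bias of the back-transformation is < 0.01 β units at these noise
levels, which the generator's own recovery test bounds at ±0.05.

What the generator does **not** emulate: probe-wise heteroscedasticity of
real arrays beyond the μ(1−μ) profile, cross-hybridisation, batch and
cell-composition structure, correlated probes within a gene beyond the
shared mean shift, and any relationship between methylation level and
expression level other than the planted direction coupling.  Passing the
recovery benchmarks therefore shows the pipeline's statistics are
correctly implemented and calibrated under the declared design — not that
the original array counts are reproducible, which additionally depends on
unpublished normalisation and Monte-Carlo settings.

## Benchmark problem sizes

The test-suite and benchmark cohorts use 400–600 probes over 100–150
genes (9 pairs, 1000 Monte-Carlo iterations, 20 seeds), sizes at which
the planted-effect recovery rates are stable while the whole suite runs
in seconds; all statistics are vectorised and scale linearly in probes ×
iterations, so full-array sizes run in minutes with identical code
paths.

## Known limitations

* The Monte-Carlo selection step's original iteration count, permutation
  unit and aggregation are not published; both aggregations are
  implemented and recorded, but published probe counts are not an
  attainable target.
* Gene-level calls use the any-probe rule; a stricter multi-probe rule
  would change gene counts.
* Enrichment reproduces the screening logic, not any specific annotation
  release, so term-level bar charts are not comparable across releases.
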