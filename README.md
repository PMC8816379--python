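# amniomics

Paired cross-omics analysis of the two layers of the human fetal membrane
— the amnion and the choriodecidua — sampled from the zone of intact
morphology (ZIM) and the zone of altered morphology (ZAM, the
physiological rupture site overlying the cervix).  The package is aimed
at epigenomics/regulatory-genomics analysts working with paired 450K-style
methylation arrays and paired expression arrays who want the full chain
from probe-level statistics to regulatory hypotheses as reusable,
testable code:

* **Differential methylation** — per-probe Δβ = mean_i(β_A,i − β_C,i)
  with a paired Student t-test, plus per-chromosome Monte-Carlo Δβ limits
  (m, M) from a within-patient tissue-label sign-flip null; a probe is
  selected iff p < α and Δβ ∉ [m, M], then lifted to direction-labelled
  gene calls (mA>mC / mA<mC).
* **Differential expression** — paired log2 FC with Benjamini–Hochberg
  adjustment and the |log2 FC| ≥ 2.8, adj. p < 0.01 screening filter.
* **Integration** — exact four-way Venn partitioning of per-zone
  direction sets, zone-specific gene sets, and the inverse-correlation
  cross-omics intersections (hypermethylated in one layer, over-expressed
  in the other).
* **Enrichment** — upper-tail hypergeometric over-representation,
  P(X ≥ k) for k of n study genes against K of N population genes, with
  Bonferroni/BH/none correction; term-vocabulary agnostic.
* **miRNA regulation** — canonical seed-site scanning (8mer, 7mer-m8,
  7mer-A1, 6mer) of 3'UTRs and a methylation–expression concordance
  screen nominating miRNA→target pairs.
* **In-silico COBRA** — bisulfite conversion under a methylation state,
  virtual PCR and restriction digestion (Taq I preset), predicting
  methylation-dependent fragment patterns.
* **Small-sample statistics** — exact Wilcoxon matched-pairs signed-rank,
  Kruskal–Wallis + Dunn, qPCR standard-curve quantification, reporter
  ratio normalisation.
* **Synthetic cohorts** — a seeded generator for the full paired design
  (9 patients × 2 tissues × 2 zones) with planted, ground-truthed
  methylation and expression effects.

See `docs/methods.md` for the statistical details and design decisions.

## Worked example

Fit both omics layers on a synthetic ZAM cohort and intersect them:

```python
from amniomics import (CohortConfig, generate_cohort,
                       PairedMethylationModel, PairedExpressionModel,
                       cross_omics)

cfg = CohortConfig(seed=0, n_probes=600, n_genes=150)
beta, expr, manifest, truth = generate_cohort(cfg)

meth = PairedMethylationModel(beta, manifest, zone="ZAM").fit(
    alpha=0.05, n_iterations=1000, aggregation="quantile", seed=0)
print(meth.summary())

de = PairedExpressionModel(expr, zone="ZAM").fit(fc_threshold=2.8, alpha=0.01)
print(de.summary())

cross = cross_omics(meth.gene_calls, de.table)
print(sorted(cross.hyperA_upC))
```

which prints

```
Paired differential methylation (amnion - choriodecidua, zone ZAM)
  probes tested:        600
  pairs:                9
  alpha:                0.05
  limits:               quantile over 1000 iterations
  probes selected:      31
  genes mA>mC:          7
  genes mA<mC:          1

Paired differential expression (amnion - choriodecidua, zone ZAM)
  genes tested:   150
  |log2 FC| >=    2.8
  adj. p <        0.01 (Benjamini-Hochberg)
  up-regulated:   1
  down-regulated: 7

['GENE0000', 'GENE0053', 'GENE0088', 'GENE0100']
```

31 of the 600 probes pass both the paired-test and the permutation-limit
gate, giving 7 genes more methylated in the amnion and 1 more methylated
in the choriodecidua; 8 genes pass the expression screen; the final list
is the genes hypermethylated in the amnion whose expression is higher in
the choriodecidua — here exactly the 4 planted inverse-correlation genes
(`truth.expected_cross_omics()`).

The same stages are available from the shell:

```bash
amniomics simulate --seed 0 --out-dir cohort/
amniomics diffmeth --beta cohort/beta.csv --sample-sheet cohort/samples.tsv \
    --manifest cohort/manifest.tsv --zone ZAM --out selected.tsv
amniomics run --config pipeline.yaml        # full chained pipeline
```

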