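# hccpipe

Analysis pipeline for bulk expression cohorts of hepatocellular carcinoma
(HCC) and for dual-stain histology of fibrotic tumors. It is aimed at
computational biologists studying why cytotoxic CD8+ T cells are excluded
from some tumors: the package discovers stage-associated gene programs,
derives a T-cell-exclusion gene signature, refines it to a module conserved
across cancer indications, classifies tumor immune phenotypes from that
module, and quantifies fibrosis and T-cell localization in trichrome/CD8
double-stained images. A synthetic-data module generates every input with
ground truth, so the whole pipeline is testable without patient data.

## What it computes

- **Preprocessing.** Genes with fewer than 10 reads across the dataset are
  dropped; counts become log2(count + 1); every sample column is centered at
  median 0.
- **Stage association.** Per-gene one-way ANOVA of expression against tumor
  stage (T1/T2/T3), Benjamini–Hochberg FDR, selection at FDR < 25% and
  log2 between-mean variance > −3; selected genes are clustered (Ward
  linkage on 1 − Pearson r) into trend clusters and scored per sample as
  the average of per-gene z-scores.
- **Exclusion signature.** Per-gene two-sample t-tests between peri-tumoral
  (T-cell-excluded) and intra-tumoral samples; selection at FDR < 12.5%,
  |log2 fold-change| > 1, up in peri.
- **Enrichment.** One-sided Fisher's exact (hypergeometric) test of a gene
  list against GMT gene sets, BH-adjusted, significant at adjusted p < 10%.
- **Module refinement.** Per-indication Pearson correlation matrices over
  the candidate genes; a reference matrix R = cell-wise minimum across
  indications; clustering R splits the candidates into a conserved module
  (module1) and the remainder.
- **Phenotype classification.** Module-1 signature score thresholded
  (Youden's J, fit on an exploratory cohort and frozen for validation) to
  call peri vs intra phenotype, reported as sensitivity/specificity.
- **Histology quantification.** Fibrotic clusters segmented by
  B − (R+G)/2 thresholding with morphological cleanup and size filtering;
  fibrosis reported as % positive area of tissue; CD8 cells detected and
  split into trapped (≤5 µm from fibrosis, or inside) vs infiltrated
  (>5 µm) via a Euclidean distance transform.

## Worked example

```python
import hccpipe as h

cohort = h.simulate_cohort(seed=17)          # staged NB counts + truth
expr = h.preprocess_counts(cohort.counts)    # filter, log2, median-center
stats = h.anova_per_gene(expr, cohort.annotation)
genes = h.select_stage_genes(stats)
clusters = h.cluster_genes(expr, genes, k=3)
for label, members in clusters.clusters.items():
    score = h.signature_score(expr, members)
    means, verdict = h.trend_summary(score, cohort.annotation,
                                     ("cirrhosis", "T1", "T2", "T3"))
    print(label, len(members), verdict, [round(v, 2) for v in means])
```

prints (seed 17):

```
1 101 increasing [-1.16, -0.47, 0.32, 1.1]
2 100 decreasing [1.16, 0.36, -0.33, -1.01]
3 100 up_then_down [0.09, 1.13, 0.08, -0.94]
```

i.e. the three planted trend clusters are recovered (about 100 genes each)
and their per-group mean signature scores reproduce the planted shapes:
monotone decline from cirrhosis to T3, a T1 peak that subsides, and a
steady rise.

The same stages are scriptable from the shell:

```sh
hccpipe simulate cohort --seed 17 --out data/
hccpipe preprocess --counts data/counts.tsv --out data/expr.tsv
hccpipe stage-assoc --expr data/expr.tsv --ann data/annotation.tsv \
    --k 3 --out clusters.json
hccpipe run --config config.yaml   # full pipeline with a YAML config
```

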