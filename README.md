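# scn3a-bench

Gene-specific benchmarking of missense pathogenicity predictors on curated
*SCN3A* (Nav1.3) variants.

## The problem

*SCN3A* encodes the voltage-gated sodium channel Nav1.3; missense variants
cause developmental and epileptic encephalopathies (DEE), focal epilepsies
and cortical malformations such as polymicrogyria. In-silico predictors
(SIFT, PolyPhen-2, AlphaMissense, meta-predictors like ClinPred and
BayesDel, …) are trained genome-wide, and their published cutoffs are often
poorly placed for an individual gene. This package benchmarks nineteen such
tools on a curated *SCN3A* cohort and calibrates gene-specific thresholds,
for clinical geneticists and methods developers who need reproducible,
per-gene performance numbers.

## What it computes

Given a curated cohort (pathogenic cases vs benign/likely-benign controls),
a dbNSFP-style score matrix, a Nav1.3 topology table and a tool registry:

1. **Curation** — HGVS protein parsing, validation, deduplication of
   recurrent variants, cohort summaries.
2. **Subregional enrichment** — variants are mapped onto the channel's four
   domains × six transmembrane segments; enrichment of pathogenic variants
   in transmembrane regions is tested with Fisher's exact test
   (minimum-likelihood two-sided p), as are location-vs-phenotype
   associations (seizures, polymicrogyria) among carriers.
3. **Default-threshold benchmark** — per-tool confusion matrices at the
   recommended cutoff; accuracy, balanced accuracy, sensitivity,
   specificity, PPV, NPV, F-score and

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

   with tools ranked by balanced accuracy = (sensitivity + specificity)/2.
4. **Score comparisons** — per tool, pathogenic vs benign scores compared
   with a normality-gated test (Shapiro–Wilk → Student/Welch t or Wilcoxon
   rank-sum; exact rank-sum enumeration at small n).
5. **ROC calibration** — Mann–Whitney AUC with DeLong variance
   (var = S₁₀/m + S₀₁/n from placement values), Wald 95% CI and p vs 0.5;
   the threshold maximizing Youden's J = sens + spec − 1 defines the
   gene-specific operating point, reported with its full metric suite.
6. **Synthetic cohorts** — a seeded generator with known ground truth
   (class-conditional score models, configurable transmembrane enrichment
   and missingness) exports inputs in exactly the formats the pipeline
   reads, so every stage is testable offline.

## Worked example

```python
import scn3a_bench as sb

dataset = sb.load_curated_cases()          # packaged curated case table
print(sb.summarize_cohort(dataset)["n_patients"])        # 37
print(sb.summarize_cohort(dataset)["pathogenic_unique"]) # 20
```

The 37 reported patients deduplicate to 20 unique pathogenic variants (one
hotspot accounts for 11 patients). Benchmarking a study-shaped synthetic
cohort (20 pathogenic / 45 benign, 19 tools) at recommended thresholds:

```
$ python examples/03_benchmark_default_thresholds.py
 rank             tool  tp  fn  tn  fp  balanced_accuracy  sensitivity  specificity    mcc
    1    AlphaMissense  20   0  45   0             1.0000       1.0000       1.0000 1.0000
    ...
    6            ESM1b  20   0  38   7             0.9222       1.0000       0.8444 0.7909
```

Each row is one tool's confusion matrix on the 65 deduplicated variants;
ESM1b here calls every pathogenic variant deleterious (sensitivity 1.0) but
mislabels 7 of 45 benign variants (specificity 0.84), so its balanced
accuracy is 0.92. Threshold calibration
(`examples/04_calibrate_thresholds.py`) prints each tool's DeLong AUC with
95% CI and the Youden-optimal gene-specific cutoff with the metrics
achieved there.

A thin CLI wraps the same pipeline:

```bash
scn3a-bench simulate --seed 7 --out cohort/
scn3a-bench run --patients cohort/patients.tsv --variants cohort/variants.tsv \
    --scores cohort/scores.tsv --topology cohort/topology.tsv --out reports/
```

## Layout

- `src/scn3a_bench/` — library modules (dataset, topology, enrichment,
  registry, predictions, metrics, roc, score_statistics, synthetic,
  pipeline, cli) and packaged data (curated case table, Nav1.3 topology,
  19-tool registry).
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, assumptions, numerical conventions,
  limitations.
- `tests/` — unit, property-based (hypothesis) and acceptance suites.

The packaged topology table is an approximate UniProt-style annotation of
the Nav1.3 architecture; structure-critical analyses should supply their
own boundaries via `--topology`.
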