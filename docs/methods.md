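# Methods

This note documents the statistical procedures, conventions and design
choices behind `scn3a-bench`, and what the synthetic-data tests do and do
not establish about real data.

## Cohort curation

Variants are missense substitutions on the canonical Nav1.3 protein,
identified by protein HGVS (`p.Ile875Thr`); one- and three-letter residue
codes are accepted and canonicalized to three-letter. Curation labels
collapse to the binary design: {pathogenic, likely pathogenic} →
`pathogenic`, {benign, likely benign} → `benign`. Recurrent variants across
patients are deduplicated for all variant-level analyses (deterministic
order: ascending residue, then alphabetical alternate residue); the same
change carrying conflicting labels is a hard error. Missing clinical cells
("–", ".", empty) parse to missing, never to `False`.

The packaged case table records 37 reported patients. Two clinical flags
are derived where the table carries them implicitly: a DEE or focal-epilepsy
diagnosis implies seizures (an explicit "without EP" tag implies none;
anything else stays missing), and an MRI note containing "PMG" sets the
polymicrogyria flag. The canonical transcript used for residue numbering is
not standardized across sources; the fixture assumes internally consistent
numbering and the topology table is an explicit, overridable input.

## Topology and enrichment

Nav1.3 (2000 aa) has four homologous domains (DI–DIV), each with six
membrane-spanning segments S1–S6; S1–S6 are classed transmembrane,
loops/linkers/termini are "other". The packaged table is an **approximate**
UniProt-style annotation assembled from the canonical Nav channel
architecture — adequate for demonstrating the workflow, but users with
structure-critical questions should supply residue boundaries from a
primary annotation (`load_topology` validates any replacement against the
coverage invariant: sorted, non-overlapping, gap-free over the protein).

Enrichment uses Fisher's exact test on the 2×2 table (class × TM/other).
The two-sided p follows the minimum-likelihood convention: all tables with
the observed margins whose hypergeometric point probability does not exceed
the observed one (relative tie tolerance 1 + 1e-7) contribute. The sample
odds ratio a·d/(b·c) is reported with ∞/0 for single zero cells, alongside
a Haldane–Anscombe corrected OR (+0.5 per cell). Phenotype associations
(seizures, polymicrogyria) reuse the same machinery among
pathogenic-variant carriers; the analysis unit is configurable —
**patients** (default, matching the carrier-level framing of the clinical
question) or unique **variants**. Observations missing the phenotype flag
are dropped with a logged count.

Which benign comparator to use (curated benign/likely-benign list vs a
broader population-variant set) is a genuine design fork; the shipped
analyses compare curated vs curated, and any position list can be passed to
`tm_enrichment` for the population reading.

## Tool registry and classification

Each of the 19 predictors carries: orientation (`higher_damaging` vs
`lower_damaging` — SIFT, SIFT4G, PROVEAN and ESM1b are lower-damaging),
a recommended genome-wide threshold on the raw scale, a categorical map to
deleterious/tolerated, and a documented score range. A score exactly at the
threshold counts deleterious. Published cutoffs drift between tool
versions, so the registry YAML is the single source of truth and fully
overridable; results at "recommended thresholds" are only as comparable as
the cutoffs supplied.

dbNSFP-style ingestion: ";"-separated multi-transcript cells collapse to
the most damaging value under the tool's orientation (the common clinical
convention); "." is missing; missingness is explicit (NaN/None), never a
sentinel value. Variants missing a tool's output are excluded from that
tool's confusion matrix and ROC listwise per tool, with per-tool coverage
counts reported — per-tool n may therefore differ.

## Metric suite

From a confusion matrix with pathogenic as the positive class: accuracy,
sensitivity, specificity, PPV, NPV, F = 2PR/(P+R), and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Balanced accuracy (sens + spec)/2 is the primary ranking metric because of
the 20/45 class imbalance; raw accuracy is reported alongside, explicitly
labeled. Any metric with a zero denominator is *undefined* (None) rather
than 0 — silent zeros would corrupt rankings — and a tool with undefined
balanced accuracy ranks last (ties broken by MCC, then name). Machine
output carries 4-decimal rounding for display only; computation never uses
rounded values.

## Score comparisons

Per tool, pathogenic vs benign scores are compared with a test selected by
a fixed policy (`auto`): Shapiro–Wilk normality per group at α = 0.05; if
both pass, a two-sided F-ratio variance test decides Student's t
(homogeneous) vs Welch's t; if either fails, the Wilcoxon rank-sum test.
The F-ratio test is a deliberate, swappable choice (normality already holds
on that branch); the selection trace (both Shapiro p-values, variance-test
p) is recorded so the policy is auditable. A `force_wilcoxon` policy is
available for the convention of comparing every tool nonparametrically.
Rank-sum p-values are exact (full enumeration) when both groups have
n ≤ 10 and the pooled sample is tie-free; otherwise the midrank
tie-corrected normal approximation with continuity correction (the default
of the common R implementation). Tests are two-sided; no multiple-testing
correction is applied across tools by default, mirroring common benchmark
practice — a correction hook exists but is off.

## ROC analysis and DeLong inference

All ROC computation happens on the oriented scale (larger = more
damaging). The AUC is the Mann–Whitney probability
P(score_pos > score_neg) + ½·P(tie), computed via midranks (identical to
exhaustive pair counting). DeLong's estimator gives the variance from
per-observation placement values: var = S₁₀/m + S₀₁/n with sample
variances of the positive and negative placements. The Wald CI at the
requested level is truncated to [0, 1]; the p-value vs 0.5 is the
two-sided normal test. When the variance is exactly zero (perfect
separation at small n) the CI collapses to the point estimate and the
result is flagged `degenerate` — near the AUC → 1 boundary the Wald
interval is anti-conservative, which is why coverage simulations (below)
use a moderate-separation model.

Tools whose score comparison is not significant at α are excluded from ROC
analysis with an explicit flag (never silently dropped).

## Youden calibration

Candidate thresholds are the midpoints of consecutive distinct oriented
score values plus ±∞ sentinels (convention configurable to
observed-values). The optimum maximizes J = sens + spec − 1; ties break
toward higher specificity, then the lower threshold, and all tied
thresholds are reported. The winning threshold is mapped back to the
tool's raw scale (negated for lower-damaging tools), and the full
confusion matrix and metric suite at the optimum are reported.
Recalibrated thresholds from a 20/45 cohort carry substantial sampling
uncertainty and should be treated as gene-level guidance, not fixed
clinical cutoffs.

## Synthetic cohorts and what the tests show

The generator emulates the study conditions: 20 pathogenic / 45 benign
unique variants by default, 19 tools with class-conditional score models
(beta or range-clipped normal, inside each tool's documented range),
categorical labels emitted by thresholding at the recommended cutoff,
configurable per-tool missingness, and residue positions drawn from
transmembrane vs other regions with configurable fractions (defaults 0.55
pathogenic — the curated table's TM share under the packaged topology —
and 0.20 benign). Model separations are graded so the structure-aware deep
models and meta-predictors separate best and M-CAP over-calls at its
default threshold, reproducing the qualitative ordering of the curated
benchmark. One global seed feeds a splittable generator with an
independent stream per tool, so regeneration is bit-identical and adding a
tool never perturbs existing columns.

`true_auc` is a Monte-Carlo oracle for P(pos more damaging than neg) with
reported standard error. Recovery checks exercised by the test suite:

- **DeLong CI coverage** at n = 200/200 over 500 seeded cohorts, at a
  moderate-separation model (true AUC ≈ 0.95, the benchmark's median
  regime) where Wald asymptotics apply; nominal 95% within ±3%.
- **Youden threshold recovery**: with beta class densities crossing at a
  known score, the recovered optimum converges to the crossing (median
  absolute error ≲ 0.01 at n = 2000/2000).
- **Enrichment recovery**: configured TM fractions 0.9 vs 0.2 at
  n = 200/200 are detected at p < 0.001 in ≥ 99% of 200 seeds.

Problem sizes (500/200 seeded repeats, n = 200/200 cohorts, 2000/2000 for
threshold recovery, 10⁵ Monte-Carlo pairs) were chosen to make the binomial
noise of each recovery rate small relative to its acceptance band.

What passing these tests does **not** show: the synthetic score models are
independent across tools and within classes, while real predictor scores
are strongly correlated (many tools share features or ingest each other);
synthetic amino-acid changes are uniform over positions and substitutions,
ignoring mutational spectra; clinical flags are independent of position.
Conclusions about the relative ranking of real tools therefore come only
from real score tables, not from the synthetic defaults.

## Numerical conventions

- Ties in scores: half-credit in the AUC kernel; midranks in placements
  and rank sums.
- Equality with a classification threshold counts deleterious.
- Report floats serialize at 6 significant digits; JSON reports are
  deterministic (sorted keys, atomic writes).
- Degenerate inputs: single-class ROC input, empty confusion input and
  out-of-range positions raise typed errors; constant pooled samples in a
  comparison yield p = 1 with a `degenerate` flag.
- Seeds: every stochastic routine takes an explicit seed; streams are
  derived via `SeedSequence` with CRC-keyed labels.

## Known limitations

- The packaged topology boundaries are approximate (see above).
- No genomic-coordinate lifting, transcript annotation or external
  database access; scores are ingested from precomputed tables only.
- No pairwise DeLong tests between tools, partial AUC or ROC smoothing;
  the AUC is tested against 0.5 only.
- Confidence intervals are not provided for single-tool metrics at default
  thresholds (a bootstrap hook exists but is off by default).
- The DeLong Wald CI is unreliable when the empirical AUC reaches 0 or 1;
  such results are flagged rather than corrected.
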