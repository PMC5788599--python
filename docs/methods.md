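# Methods

`lfqdiff` implements a label-free quantitative (LFQ) shotgun-proteomics
differential-abundance analysis for completely paired two-condition
designs, together with a ground-truth synthetic-evidence generator that
makes every stage testable without raw LC-MS/MS data. This note records
the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic benchmark does and does not show.

## Study design and data model

The unit of observation is a *run*: one LC-MS/MS injection of one
sample. Designs are completely paired: each (biological replicate,
technical replicate) slot is measured once under `control` and once
under `treated`. The default shape is 2 biological x 5 technical
replicates per condition — 20 runs, ten abundance measurements per
condition — which is the standard small-cohort cell-line layout this
package targets. Pairing for the paired t-test is by replicate slot:
the i-th control measurement (ordered by biological then technical
index) is matched with the i-th treated measurement. Technical
replicates are treated as exchangeable measurements of their biological
sample; no nested variance model is fitted.

Evidence arrives as one row per (protein, run) carrying spectral count,
summed peptide intensity, observed/observable peptide counts, an
identification score, a decoy flag, and an upstream filter flag.

## Quantitation

Three spectral indices are implemented per run:

* **NSAF** — `(SpC_i / L_i) / sum_j (SpC_j / L_j)`, over proteins with
  nonzero counts; sums to 1 per run by construction.
* **emPAI** — `10^(N_obs,i / N_obsble,i) - 1`; observable peptide
  counts are taken from the input table (no in-silico digestion).
* **SI_N** — `(SI_i / sum_j SI_j) / L_i`, where `SI_i` is the summed
  peptide intensity. The variant is fixed as per-run total-intensity
  normalisation followed by length division; averaging across
  replicates is deliberately left to the statistics layer rather than
  folded into the index.

Proteins without evidence in a run are *missing* (`NaN`), which is kept
strictly distinct from an observed zero throughout the quantitation
layer; converting missing to zero is a statistical decision made by the
workflows.

**Target-decoy filtering.** Per run, rows are ranked by score
(descending; ties broken by protein id for determinism) and the largest
prefix whose decoy/target ratio stays at or below the threshold
(default 1%) is retained; decoys are removed from all outputs. The
plain ratio estimator is the default; the conservative `+1` numerator
is available as a switch. Filtering is per run because detection is a
run-level property (a protein may pass in some injections and not
others). Rows flagged as already rejected upstream never enter the
filtered output but remain in the *unfiltered list*, which is retained
because the imputation strategy (workflow C) reaches back into it.

**Normalisation.** Global technical biases are removed by total-sum
scaling: each run's non-missing values are divided by the run total and
rescaled by the grand mean of run totals so magnitudes stay comparable
across methods; median scaling is available as an option. The
operation is idempotent to round-off. The rescale by the grand mean
makes the output invariant to per-run multipliers only up to one global
factor; all downstream statistics (fold changes, rank tests, t-tests on
proportionally scaled data) are invariant to that factor. Whether
normalisation happens before or after index computation is exposed via
the call order; the default pipeline normalises after.

## Statistical workflows

For each protein, the ten control and ten treated measurements are
compared. A protein is *testable* when it is detected in at least
`min_condition_detections` (default 1) runs of each condition;
one-condition proteins are reported as detection-status changes
(gained/lost on treatment) with undefined fold change, and proteins
detected nowhere at the required depth are untestable.

* **Workflow A** — missing values set to zero; classical paired t-test
  on every testable protein; one BH family over all raw p-values.
* **Workflow B** — missing set to zero; Shapiro–Wilk gate at
  `alpha_sw = 0.05`; paired t-test on the normally distributed (ND)
  set, two-group Kruskal–Wallis (tie-corrected, chi-square with 1 df)
  on the not-normally-distributed (NND) set; BH applied *within each
  branch separately* before the branches are combined.
* **Workflow C** — as B, after imputing missing values: a cell missing
  in the filtered matrix but present in that run's unfiltered list is
  recomputed from the sub-threshold row using the same index formula,
  the same stored per-run denominator and the same normalisation
  factor as the filtered matrix; cells absent even from the unfiltered
  list are set to zero (below detection limit). Detection classes are
  assessed on the pre-imputation missingness pattern, so a protein
  seen only sub-threshold in one condition still reports as a status
  change rather than acquiring a synthetic fold change.

**Normality gate.** The Shapiro–Wilk test is applied to each
condition's 10-value vector after the workflow's fill policy, and both
must pass for the protein to be ND — the t-test's normality assumption
applies per sample. Applying the gate to paired differences instead is
exposed as `sw_target="differences"`. Constant vectors and vectors
shorter than 3 are routed to NND, where the rank test is defined.

**Degenerate cases.** Zero-variance paired differences give an
undefined p-value and class `untestable` rather than p = 0: constant
zero-filled vectors must not manufacture significance. An all-tied
Kruskal–Wallis input returns p = 1 by convention.

**BH correction.** `q_(i) = min_{k>=i} m p_(k)/k` capped at 1, with m
counting only defined p-values; undefined entries pass through as
undefined. The implementation delegates to statsmodels' `fdr_bh` and is
checked against a brute-force transcription of the step-up definition.
One BH family is formed per analysis per branch; families are never
pooled across samples.

**Volcano classification.** `up` iff `q < 0.05` and `FC >= 2.5`;
`down` iff `q < 0.05` and `FC <= 0.4`, with `FC` the ratio of treated
to control condition means. The FC gates are inclusive and the FDR gate
strict, matching the convention the thresholds are quoted in. The
plot-ready table uses `log10 FC` against `-log2` of the *uncorrected*
p-value; the q-gate-vs-p-axis asymmetry is intentional and reproduced
as such.

## Synthetic data generator

The generator emulates the paired study the statistics assume, with
known ground truth.

* **Responders.** Defaults: 5% up, 2% down. Fold-change law: log-normal
  with median 4 and sigma 0.25 on the log scale, floored at 1.25
  (reciprocal for down-responders), or a fixed value; benchmarks use
  fixed 4-fold effects.
* **Abundance laws.** Base abundances are log-normal (median 100
  arbitrary units, sigma 0.7). Normal-family proteins draw run
  abundances from Normal(mu, (cv*mu)^2) truncated at zero (by redraw);
  contaminated-family proteins from the mixture
  `0.8 N(mu, (cv mu)^2) + 0.2 N(mu, (5 cv mu)^2)`. With the default
  50/50 family split this reproduces the empirical situation in which
  roughly half the proteins fail a Shapiro–Wilk check, without
  modelling instrument physics; the mixture is a stand-in, not an
  inference about any particular instrument's error law. Default
  `noise_cv = 0.2`.
* **Channels.** Spectral counts are Poisson with mean
  `abundance * length * 4e-4` (about 20 spectra for a median protein),
  so count-based indices carry shot noise; summed intensity is
  proportional to abundance, so SI_N carries the abundance noise
  directly. Each run has a log-normal efficiency factor (sigma 0.1)
  applied to both channels, which per-run normalisation removes.
* **Scores and decoys.** Confidently identified targets score
  N(6, 1); decoys — and target rows destined for filter dropout —
  score from the null law N(0, 1). Decoys appear in a run with
  probability 0.3. At a 1% protein FDR this makes the target-decoy
  stage meaningful (it removes decoys and sub-threshold rows) without
  discarding well-identified targets.
* **Missingness.** Mechanism 1 (*below limit*): the evidence row is
  absent entirely. Mechanism 2 (*filter dropout*): the row exists,
  flagged as failing identification filtering, visible only in the
  unfiltered list — exactly the case workflow C's imputation targets.
  Both are attached per cell, independently across runs; run-level
  batch missingness is a documented non-feature.
* **Determinism.** One sub-stream per protein, seeded by a stable hash
  of (seed, protein id): regenerating with additional proteins leaves
  existing rows byte-identical, and identical inputs reproduce
  identical tables.

What passing the synthetic benchmark does *not* show: the generator has
no peptide-level structure, no retention-time or m/z dimension, no
correlated batch effects, no intensity-dependent missingness curve, and
its contaminated-normal law is one convenient heavy-tailed choice.
Results on real data depend on upstream search and protein grouping,
which are out of scope here (evidence arrives pre-grouped).

## Benchmark problem sizes

The shipped acceptance checks run: 2,000 target proteins (plus 2,000
decoys) per study, the 2x5 paired design, 20 independent simulations
per benchmark. At these sizes the null-study false-discovery
proportion, the 4-fold-responder sensitivity of workflow A (>= 0.9),
and the imputation benefit of workflow C over A under 30% filter
dropout are all stable; the BH oracle comparison uses random vectors of
up to 1,000 p-values.

## Reporting

IRG (interferon-regulated gene) annotation is a case-folded exact join
against a local two-column table — a deliberate replacement for live
database queries, which version-drift and are not reproducible at desk
scale. No alias resolution is attempted. Overlap statistics between two
samples' significant gene sets report the shared count, per-set
fractions and Jaccard index. When simulation truth is available,
reports include sensitivity (direction-matched volcano calls among true
responders) and the realized false-discovery proportion
`FDP = (calls - true positives) / max(1, calls)`.

## Known limitations

* No moderated-variance (shrinkage) testing; the workflows are the
  classical tests by design.
* Wilcoxon and Friedman tests are deliberately not offered (underpowered
  at ten paired measurements).
* No protein grouping / peptide-to-protein inference.
* The byte-identity of workflows A and B on all-ND data holds for the
  statistical columns; the provenance columns (workflow label, branch
  label) differ by construction.
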