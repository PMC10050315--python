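# Methods

## Event model and data dialect

The unit record is one blockage event: the blockage ratio
I_b/I_0 ∈ (0, 1] and the dwell time in milliseconds, optionally with an
onset time in seconds. Tables are CSV/TSV with columns
`glycan, ib_over_i0, dwell_ms[, t_start_s]`; the dialect is deliberately
minimal because upstream event callers export richer, tool-specific
schemas that this package does not reproduce. Reads are strict by default:
a row violating the invariants aborts the parse (lenient mode drops and
counts such rows instead), because silent data loss hides upstream
processing errors. Events with I_b/I_0 > 0.99 correspond to an essentially
unoccupied pore and are excluded by `filter_events` before any statistic is
computed.

Event frequency is the event count divided by the recording duration when
the metadata carries one, else by the span of onset times. The denominator
convention is stated here because measured data sheets rarely make it
explicit; for Poisson arrivals both estimators converge to the rate.

## Synthetic event generator

Each glycan's event cloud is a weighted mixture of Gaussian components:
Gaussian in I_b/I_0 (truncated by rejection to (0, 0.99], so generated data
pass the unoccupied-pore filter unchanged) and Gaussian in log10(dwell_ms).
Dwell is modelled on the log scale because measured dwell histograms are
right-skewed in linear time and near-Gaussian on a log axis; the
characteristic dwell reported everywhere is the back-transformed peak
position 10^μ. Arrivals are a homogeneous Poisson process (exponential
inter-arrival gaps) whose rate is proportional to concentration.

The built-in library carries single-component models for a panel of tagged
glycans with these characteristic means (I_b/I_0, dwell ms): 6SL-MPB
0.42/0.93 (arrival rate 13.7 s⁻¹), 3SL-MPB 0.54/0.88, 3S3FL-MPB 0.43/0.96,
6S3FL-MPB 0.37/1.07, 6S2FL-MPB 0.38/1.23, LNT-DPE-6SL 0.288/0.98,
LNnT-DPE-6SL —/0.94, LeA-DPE-6SL —/1.01, 6SL-TPE —/2.22.

Calibration choices where measurements leave gaps:

* **Dispersions.** Most populations have no published spread. The one
  published dwell dispersion (0.94 ± 0.17 ms) implies a CV ≈ 0.18, i.e.
  σ ≈ 0.078 on the log10 axis; the default is σ_logdwell = 0.08. The
  default σ_ratio = 0.03 makes populations 0.12 apart in I_b/I_0 (the
  6SL/3SL pair) overlap visibly yet remain separable, matching the
  qualitative appearance of measured scatter plots. The two tetrasaccharide
  models use their own published dwell CVs (0.17/0.94 and 0.21/0.98).
* **Unreported means.** Three models lack a published mean I_b/I_0:
  LNnT-DPE-6SL is set to 0.31 with a broader σ_ratio = 0.05 (its cloud is
  described as more dispersed than LNT's, which centres at 0.288),
  LeA-DPE-6SL to 0.35 and 6SL-TPE to 0.30. These are calibration choices,
  not measured facts, and no acceptance-facing quantity depends on them.
* **Multi-modal populations.** Some tags produce multi-population clouds;
  the component type supports arbitrary mixtures, but the built-in models
  are single-component because no per-component statistics are published.

What the generator does *not* emulate: waveform shape, voltage dependence,
inter-event correlations, drift, and heavy-tailed dwell outliers from pore
clogging. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated population model, not instrument-level
realism; recovery tolerances on real data will be wider.

## EPDFs and mixture deconvolution

EPDFs are normalized 2-D histograms over (I_b/I_0, log10 dwell). Default
grid: 50 × 50 equal-width bins, ratio axis fixed to [0, 1], log-dwell axis
spanning the pooled data range padded by 5% per side. 2,500 bins balance
resolution against small-count noise at the ~10⁴-event scale this package
targets. Every bin receives additive mass ε = 10⁻⁹ before renormalisation:
the divergence is undefined on empty bins, and ε this small does not move
the optimum at any tested scale.

The objective is the symmetrized (Jeffreys) KL divergence — the two-term
sum KL(f_mix‖f̂) + KL(f̂‖f_mix) — in natural log (the minimizer is
base-invariant). The estimator is projected gradient descent on the weight
simplex: Euclidean simplex projection, backtracking line search (accept on
decrease, halve otherwise, re-grow between iterations), deterministic start
at the uniform vector, stop when the objective improves by < 10⁻⁸ or after
10⁴ iterations. Convexity of J in w makes the starting point immaterial;
the uniform start makes runs reproducible. `grid_search_weights`
exhaustively scans the simplex lattice (guarded to N ≤ 4) and serves as the
independent oracle in the tests; the two routes agree to within the lattice
resolution on every tested instance.

Degenerate inputs: identical component EPDFs make the optimum a face of the
simplex rather than a point — any weight split among identical components
achieves the same divergence, and the returned point is then
start-dependent by construction. Empty tables and events outside the grid
are errors, not silently dropped.

## Feature engineering and subset-size selection

Equal-frequency boundaries cut each axis at the k-quantile order
statistics, with each cut midway between the bracketing order statistics;
with all-distinct values every marginal stripe holds n/k ± 1 pooled events.
Ties can collapse cuts; this is flagged (`degenerate`), not repaired. The
dwell axis is cut on log10(dwell) for consistency with the rest of the
package, and the cuts are reported back in milliseconds. Cells are
half-open [lo, hi) with the last stripe closed above.

Subsets are formed by a seeded random permutation followed by contiguous
chunks of exactly the subset size (remainder dropped and reported). Random
rather than chronological chunks make subsets exchangeable, which the
KL-based size evaluation implicitly assumes. The subset-size curve reports,
per candidate size, the mean one-sided KL(subset ‖ overall) between each
subset's EPDF and the full table's EPDF on a shared grid; the subset is the
first argument because it is the candidate being judged against the
reference distribution. The working default — 20 subsets of 2,000 events
from a 40,000-event table at k = 3 — gives the canonical 80 × 9 feature
matrix for a four-glycan panel.

## Classification protocol

Each glycan's feature rows form one stratum. Per cycle: a fresh stratified
split sends ceil(20%) of each class to test (16/4 with 20 rows), a fresh
estimator is trained and the held-out rows predicted. One experiment = 100
cycles, accumulating 400 test-set predictions per class; the full
evaluation = 10 replicate experiments, each rebuilding the feature matrix
with a new subset partition, summing confusion matrices (4,000 accumulated
predictions per class) and averaging scores across replicates. Scores are
macro-averaged F1/Precision/Recall computed on the accumulated predictions
of an experiment; macro averaging is the natural choice for
balanced-by-construction classes. A "test set" is one feature row; its
prediction is correct iff the predicted class matches its label.

Model specs (fixed hyperparameters): SVM with RBF kernel, C = 1.0, no
iteration limit (C is a neutral default, recorded in the spec);
multinomial naive Bayes with Laplace smoothing α = 1.0, fed pseudo-counts
(features × subset size) because multinomial likelihoods are count-based;
random forest with 25 trees, switchable to 80 for hard-to-separate panels;
AdaBoost with 100 decision-tree weak learners using scikit-learn's current
boosting variant (the classic real-valued SAMME.R update no longer exists
in modern scikit-learn); logistic regression with liblinear (ridge/L2,
C = 1.0) wrapped one-vs-rest, liblinear being binary-only in current
scikit-learn. Determinism: every estimator receives a seed derived from
(base seed, cycle index), so a full report is a pure function of inputs and
seeds.

Tuning evaluates mean macro F1 over a (k, subset size) grid with a reduced
budget of 10 cycles per point by default (the full protocol per point is
optional); ties break toward smaller k, then smaller size. Grid points
leaving fewer than 5 subsets per class are skipped and reported, since the
20% split needs at least one test row per class.

## Pipeline reproducibility

The pipeline config (YAML/JSON, pydantic-validated, unknown keys rejected)
drives simulate → filter → deconvolve and/or featurize+classify. All stage
seeds derive from one root seed via SHA-256 of (seed, stage name, index),
so partial re-runs are consistent; the manifest records every seed, every
written file with its checksum, and the effective config with all defaults
filled. Identical configs produce byte-identical outputs.

## Problem sizes

Package defaults mirror the study conditions: 40,000 events per reference
glycan, 10,000-event mixtures, 2,000-event subsets, 100 × 10 evaluation
cycles. The test suite exercises the full protocol accounting at these
sizes and uses smaller panels (8,000–10,000 events, reduced cycles) for
behavioural checks where the property under test does not depend on scale;
each test states its sizes inline.

## Known limitations

* Single-component library models cannot reproduce multi-population tags.
* The weight estimator's accuracy degrades as component signatures overlap;
  for near-identical components the problem is ill-conditioned (see
  degenerate case above).
* The equal-frequency tie policy can yield unequal stripes on heavily
  quantised data (e.g. dwell times at coarse sampling resolution).
* Classification scores on synthetic panels reflect the chosen population
  separations; they are an upper bound on what equally-sized real panels
  with instrument noise would give.
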