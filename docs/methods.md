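# Methods

This note documents the modeling and numerical choices behind
`ecgorigin`: what each stage computes, which parameters matter, what the
synthetic world does and does not emulate, and where the design was
genuinely open.

## Signal model and preprocessing

A recording is one PVC/VT beat context: a 12 × T voltage matrix sampled
at 2,000 Hz with a known (or detectable) lead-II R-wave peak.  Voltage
units are arbitrary-but-consistent; the downstream tree ensembles are
invariant to per-feature monotone rescaling, so no unit conversion is
attempted.

**Denoising.** Each lead is independently decomposed with a periodized
orthogonal coiflet-5 DWT.  The decomposition depth is the standard
maximum useful level `floor(log2(n / (L−1)))` for filter length L = 30,
capped at 8 (deeper levels act on sub-2 Hz content and add nothing for
beat-length records).  The noise scale σ is estimated from the finest
detail band by MAD/0.6745; every detail band d is *soft*-thresholded at
σ·t*, where t* minimizes Stein's unbiased risk estimate
`SURE(t) = n − 2·#{|dᵢ/σ| ≤ t} + Σ min((dᵢ/σ)², t²)` over the candidate
set {|dᵢ/σ|}.  The approximation band is untouched, which preserves
baseline morphology exactly (constants and the zero signal are fixed
points).  Soft thresholding is the standard companion of the SURE rule.
The transform is implemented in-package (`_wavelet`) because no wavelet
library is available in the deployment environment; the filter-bank
constants are the published coiflet-5 table, verified against the
defining orthonormality and vanishing-moment conditions (which they
satisfy to ~1e-9, the precision of the published values — hence exact
reconstruction to ~1e-7 rather than machine precision).  Series shorter
than 30 samples fall back to identity with a warning.  Whether denoising
precedes or follows windowing was an open choice; the default is
denoise-the-full-recording-then-window.

**Windowing.** A window of W samples straddles the reference line with
`pre = floor(W/2)` samples before it; the reference sample itself is the
first sample of the "after" side, so window offsets run −pre..−1,
+1..+post with no offset 0.  This convention fixes the reporting of
important features ("the 10th point after the reference line" is offset
+10).  Windows overrunning a record boundary are filled by edge-value
padding, never rejected, so the 1,000-sample search maximum is always
admissible.  The split around the peak is a package choice (the beat
straddles the R wave); it is configurable through `WindowConfig`.

**Reference location.** The annotated R-peak index is always preferred.
The fallback detector is argmax |lead II| with a first-maximizer tie
rule — adequate because each recording contains exactly one QRS complex.

## Cohort construction

Splitting is at the *patient* level, stratified by the finest-scheme
label (one assignment then serves all four schemes).  Within a stratum
of n patients the cohort sizes are largest-remainder rounded, ties
toward the earlier cohort in (train, validation, test) order, plus a
minimum-one guarantee for validation and test whenever n ≥ 3 (taken
from training).  This rule reproduces both published anchor points:
545 → 436/55/54 and 5 → 3/1/1.  Strata with fewer than 3 patients go to
training with a warning — held-out coverage for such a class is
impossible, which mirrors the clinical situation for rare sites.

Recordings inherit their patient's cohort.  Because patients contribute
unequal beat counts, per-class recording shares can deviate from
80/10/10; deviations beyond 2 percentage points are warned about, not
corrected (re-curating recordings within a patient is out of scope).

Training-cohort oversampling duplicates minority-class recordings with
replacement (seeded) until every class matches the majority class
count.  Plain duplication was chosen over jitter/SMOTE-style synthesis:
tree ensembles treat duplicates as sample weights, and the reference
protocol specifies only "oversampling".  Validation and test sets are
never resampled.

## Window search and the model registry

The window search is an exhaustive scan (default 200..1,000 step 10
samples) scored by a fixed 100-tree random forest — hyperparameters
deliberately frozen so the scan measures the window, not the model.
Ties break toward the smallest window (cheaper features).  The
per-scheme defaults shipped in `DEFAULT_SCHEME_WINDOWS` (250/550/360/320
samples for schemes 1–4) are outcomes on the reference clinical
validation cohorts and are provided as conveniences, not asserted.

The registry enumerates 21 runnable families — ensembles: bagging,
random forest, AdaBoost, gradient boosting, histogram ("extreme")
gradient boosting, extremely randomized trees; base learners: decision
tree, k-NN, nearest centroid, four naive-Bayes variants, LDA, QDA,
multinomial logistic, MLP, ridge, SGD-linear, passive-aggressive,
linear SVM — standalone and under each of the three multiclass
meta-wrappers, plus two inert deep-model stubs (residual CNN,
LSTM-with-attention) that are listed but never run.  The exact
historical enumeration to "98 combinations" is not reconstructible from
its description, so the registry is configuration-driven (JSON) and its
count is reported, never asserted.  Families requiring nonnegative
inputs (multinomial/complement NB) are fitted behind a min-max scaler;
scale-sensitive families (MLP, SGD, SVM, k-NN) behind a standardizer;
tree families see raw voltages.

Hyper-grids are small, documented defaults (the original grids are
unpublished); selection maximizes weighted-average F1 on the validation
cohort, ties to the first-listed combination.  The winner configuration
is extremely-randomized trees with 100 trees and **all features
considered at each split**: with random thresholds this costs little,
and it keeps impurity importance concentrated on informative window
samples instead of crediting noise splits — with `max_features='sqrt'`
only ~38 of the ~3,800 window features are visible per split, so
spurious splits accumulate importance mass.

Ranking models by *test-cohort* accuracy (the faithful historical
protocol) leaks test information into selection; `compare_models` logs
a prominent warning and the default selection policy is validation F1.

## Evaluation

Metrics are one-vs-rest per class; 0/0 ratios are reported as undefined
(NaN), never zeroed, and weighted averages renormalize over defined
classes.  Adjusted accuracy replaces the 0/1 correctness indicator with
a credit matrix: diagonal 1, `sibling_weight` (default 0.5) for two
distinct classes sharing their immediate parent in the hierarchy
(e.g. the two RVOT septal subdivisions, the two left fascicles), 0
otherwise.  The original study's exact credit assignments are
unpublished; the sibling rule is this package's documented stand-in and
the matrix is fully overridable from CSV.  With sibling weight 0 the
adjusted accuracy reduces to plain accuracy exactly.

Confidence intervals are percentile bootstrap (B = 2,000 default,
seeded), resampling evaluated recordings; percentile rather than BCa is
the minimal faithful reading of "bootstrapping with 2,000 replications".
If a metric is undefined on more than 10% of replicates the CI is
reported undefined with a diagnostic.  The rank-of-truth histogram
records at which probability rank the true site appeared (1..3, >3).

## The synthetic world

The generator tests pipeline mechanics, not cardiac physiology.  Each
class template is a 12-lead Q-R-S triplet of Gaussian lobes (QRS width
0.1 s, lead-II R lobe the strict extremum so the fallback detector
works); classes differ by an additive morphology field (per-sample
s.d. 0.2 per unit `separation`) confined to configurable discriminative
leads and offsets — lead II excepted, as the alignment lead.  Template
distances are exactly linear in `separation`.  Every patient carries a
smooth morphology jitter (s.d. 0.02, Gaussian-smoothed, shared across
that patient's recordings); each recording adds white measurement noise
(s.d. 0.05, the scale of residual noise on a filtered clinical ECG) and
a ±40-sample beat displacement with the R index recorded truthfully.
The patient jitter is what makes patient-disjoint splitting measurable:
recording-level splits would leak patient identity.

The frozen benchmark: 10 classes, counts (100, 80, 60, 45, 35, 25, 18,
12, 6, 2) — a clinical-shaped imbalance capped at 50:1 — across 49
patients, 2,400-sample records at 2 kHz, seed 1234.  Default separation
1.0 makes class differences (~0.2 mV per discriminative sample) large
against noise (0.05 mV), so the end-to-end benchmark accuracy is
expected ≥ 0.95; at separation 0 it collapses to chance.  A green
benchmark therefore establishes that the pipeline routes information
correctly (no leakage, correct alignment, correct bookkeeping) — it
says nothing about accuracy on real ECGs, where class overlap, drift,
electrode placement and rhythm context are the real difficulties, none
of which are emulated.

## Numerical details and limitations

* Odd-length signals are edge-padded by one sample per DWT level and
  truncated on reconstruction.
* The morphology smoother is Nadaraya–Watson regression over the sample
  index with a Gaussian kernel (default bandwidth 5 samples ≈ 2.5 ms);
  bandwidth → 0 recovers the pointwise mean.
* Degenerate inputs: empty datasets yield 0-row feature matrices with
  full column metadata; empty confusion input yields a zero matrix;
  single-candidate window searches are valid.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  datasets and byte-identical report JSON.
* WFDB input requires the optional `wfdb` package; without it the CSV
  dialect is the interface.
* Known bookkeeping quirks of the reference cohort table (its per-site
  patient and recording columns do not sum to the headline totals) are
  shipped as printed and not reconciled.
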