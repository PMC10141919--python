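# Methods

This note documents the models, the synthetic data, and the numerical
and design choices behind `flowsense`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signals and preprocessing

The data model is a wear session with four channels at the wristband's
native rates — HR 1 Hz (bpm), TEMP 4 Hz (°C), EDA 4 Hz (µS), ACC 32 Hz
(triaxial, g, quantised to 1/64 g counts) — and an ordered list of
non-overlapping baseline/task segments. Segment boundaries and survey
responses live in an `annotations.csv` sidecar because the device
records neither.

The device needs time to stabilise after donning, so a fixed head trim
is applied once per session: 20 s of TEMP, EDA and ACC (80, 80 and 640
samples) and 10 s of HR (10 samples; HR is already a 10 s trailing
moving average, so only its warm-up is artifactual). Trimming at every
segment instead would discard valid data; a `trimmed` flag refuses
double application. Segments are cut as half-open intervals
[start, end) via indices `floor(t·rate)`, which never double-counts a
boundary sample. Each task is paired with the nearest *preceding*
baseline in its activity (the conservative reading of a pre/post
baseline design); `mean_of_pre_post` pools both baselines instead.

## Features

Per task, five statistics per scalar stream (HR, TEMP, EDA, ACC_X,
ACC_Y, ACC_Z) give 30 features with frozen names `<stat>_<channel>`:

* `mean_diff`, `median_diff`, `sd_diff` — task minus baseline; the sd
  uses the n−1 denominator. `sd_diff_HR` doubles as the time-domain
  heart-rate-variability proxy.
* `skewness` — Fisher–Pearson g₁ = m₃/m₂^1.5 on task samples only.
* `kurtosis` — excess g₂ = m₄/m₂² − 3 (platykurtic ⇒ negative), from
  biased central moments. No small-sample bias correction is applied:
  with hundreds to tens of thousands of samples per task the correction
  is negligible, and the g-statistics keep the sign conventions used in
  interpretation. A `kurtosis="raw"` switch (g₂ + 3) exists for
  sensitivity analysis.

Zero-variance streams (e.g. a channel pinned at a sensor floor) return
skewness and kurtosis 0 with a warning rather than NaN, so downstream
designs stay finite; the same convention catches variance so small the
moment ratios underflow. Shape moments are computed on centred data to
avoid precision loss when variation is tiny relative to the level.

## Rating Scale Model

The nine Flow State Scale items (one per element of flow, Likert coded
0..4 with 0 = strongly disagree) are measured with the polytomous Rasch
Rating Scale Model:

    P(X_ni = k) ∝ exp( k(β_n − δ_i) − Σ_{j≤k} τ_j ),   k = 0..M

with person measure β_n, item difficulty δ_i and thresholds τ shared by
all items; identification by mean(δ) = 0 and Σ τ = 0. At β = δ_i the
two extreme categories are equally likely, so δ_i is the centre of the
item's rating scale.

**Estimation** is joint maximum likelihood (JMLE) with alternating
damped Newton steps (per-parameter steps clipped to ±1 logit),
convergence at a maximal parameter change below 1e-4 logits, default
cap 200 sweeps. Persons/items with extreme raw scores are excluded
from estimation and afterwards assigned the measure whose expected
score equals the raw score moved 0.25 score points inward — every row
gets a finite measure. No (N−1)/N bias correction is applied by
default; JMLE difficulty estimates are slightly spread at small N,
which none of the package's decisions are sensitive to. Unobserved
categories are collapsed to contiguous codes with a warning. Standard
errors are the information-based 1/√ΣW with W the model variance of a
response.

**Diagnostics** follow standard Rasch practice: outfit_i = mean z²,
infit_i = Σ(x−E)²/ΣW (expectation 1; above 1.5 flagged as misfit);
PCA of the item×item *correlation* matrix of standardized residuals so
the eigenvalues are in item units and comparable to the conventional
cutoff of 2; separation reliability
(var(measures) − mean SE²)/var(measures), clipped to [0,1]. A
deterministic, perfectly ordered item overfits (mean squares < 1); an
item riding an independent second trait loads with its partners on the
first residual component.

The binary **full-flow label** is rating the transformation of time —
the hardest element in the hierarchy — at "agree" (3) or above.

## Two-level stepwise selection

The inferential model forces participant identity (reference-cell
dummies, first participant as reference) into a logistic regression
before any feature is considered, then enters candidates forward-only:
at each step every remaining feature is added one at a time, the best
is judged by likelihood-ratio test, and it enters iff p < 0.10 (a 90%
confidence entry criterion; deliberately liberal, with overfitting
assessed later by between-participant cross-validation). Ties break by
larger χ², then candidate order. Fitting is Newton maximum likelihood
(statsmodels), tolerance 1e-8.

A candidate whose trial fit is quasi-separated is barred from entry:
its ML estimate does not exist and its LRT statistic is an artifact of
where the optimizer stopped. Without this rule the greedy procedure at
n = 60 almost always walks into a degenerate separated model with
meaningless Wald output. Separation is detected via the optimizer's own
diagnostics plus fitted probabilities indistinguishable from the labels
or coefficients beyond ±50.

## Classifier evaluation

The classifiers (plain ML logistic regression; Gaussian naive Bayes
with per-feature class-conditional normals, training-frequency priors
and variance smoothing 1e-9 × max feature variance) use only the
selected features — never participant dummies, since the
between-participant scheme evaluates exactly the unseen-person case.

Out-of-fold probabilities are pooled (concatenated) across folds; the
confusion matrix (cutoff 0.5), support-weighted precision/recall/F1
(weighted recall ≡ accuracy) and the Mann–Whitney AUC (ties ½) are
computed on the pooled predictions. Pooling, rather than per-fold
averaging, is what makes a 60-task confusion matrix possible under
5-fold-by-participant validation. "Participant-stratified 10-fold" is
interpreted as folds balanced jointly on participant and label: each
(participant, label) cell is dealt round-robin across folds with a
separate running offset per label, seeded. An ROC table enumerates all
distinct thresholds so a specificity-first operating point can be
chosen without hard-coding one.

Permutation importance shuffles one feature column at a time (default
1000 shuffles, seeded; the test suite uses 100) and reports the mean
and SD of the AUC reduction. Transfer prediction applies frozen
coefficients to a new study's feature table without refitting.

## Synthetic studies

The generator emulates two designs with known ground truth:

* five participants × two activities, each 5-min baseline + six tasks
  (1–17 min, mean 375 s via a Beta(2, ·) on the range) + 5-min
  baseline — 60 tasks, target flow prevalence 22/60;
* one participant, ten single-task sessions of 10–83 min.

Each task draws a latent intensity z ~ N(0,1); the truth label is
z > Φ⁻¹(1 − prevalence). Survey responses are sampled from the Rating
Scale Model at β = 1.91 + 2.5(z − cut) with a difficulty hierarchy
ending at the transformation of time; the intercept puts that item at
its 50% endorsement point exactly at the truth threshold, making the
observed label agree with the truth ~87% of the time — the label is an
instrument reading, not the truth itself.

Signals are built so that flow changes distribution *shape*, not
magnitude. Every segment — baseline or task, flow or not — receives
level wander, a temperature drift of random sign, movement bursts of
random sign and y-axis regime excursions to a random side; an overall
per-segment movement-intensity multiplier keeps variance features
non-systematic. Flow biases the directions: the temperature drift turns
upward (vasodilation ⇒ positive median shift, left-skewed task
distribution), x-axis bursts turn positive (right skew), y-regimes
favor the low side with a little extra regime time (left skew,
platykurtic). Heart rate and EDA carry only small additive shifts under
person-level offsets of 6 bpm / 1 µS, so their features stay
uninformative across persons. Effect magnitudes are synthetic choices
(the source literature reports directions, not raw-signal sizes),
fixed once at design time.

What the generator does **not** emulate: real E4 noise spectra, EDA
tonic/phasic decomposition, motion artifacts, circadian temperature
structure, or any coupling between channels. Passing tests therefore
demonstrate that the pipeline recovers the *kind* of structure it
assumes, not that real wrist data contain that structure.

## Small-sample caveats

* With 30 candidates at entry α = 0.10, the stepwise procedure admits
  roughly three spurious features per study alongside the planted
  ones; this is a property of the method, not a defect of the
  implementation, and the cross-validated metrics price it in.
* All five planted features rarely enter *jointly* at n = 60: once
  three or four are in, the conditional evidence for the rest shrinks.
  Recovery properties are therefore stated per feature.
* Leave-one-out with an unpenalized logistic on ten tasks and five
  features is unstable (training folds can separate); the naive Bayes
  analog is the steadier of the two in that regime. The acceptance
  script transfers only the first five entered features to the
  daily-use study, since ten observations cannot support more.

## Problem sizes

The shipped configuration uses the full study geometries above.
Simulation-based checks run at N = 200–500 persons for measurement
recovery, 40 replicates for the residual-PCA behavior and 50 seeded
replicates for selection recovery; these sizes give stable pass/fail
behavior for the stated thresholds.
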