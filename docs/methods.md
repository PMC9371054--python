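# Methods

## The problem

Motor-imagery (MI) brain–computer interfaces classify single EEG trials
into imagined-movement classes from the event-related desynchronization
(ERD) of the sensorimotor μ (8–12 Hz) and β (12–40 Hz) rhythms.  Two
artifact families degrade this signal: ocular (EOG) potentials, which
are large, low-frequency and frontal-dominant; and volume conduction,
the passive spread of every source's field to many electrodes, which
inflates inter-channel correlations and masks genuine functional
connectivity (FC).  Critically, how much either artifact hurts — and
whether removing it helps — varies strongly across subjects, which is
why roughly a quarter of users stay below the ~70 % accuracy usually
taken as the usability floor ("BCI inefficiency").

This package implements *subject-dependent artifact removal* (SD-AR):
rather than applying a fixed cleanup to everyone, each subject's
pipeline is chosen among four scenarios by the classification accuracy
it achieves for that subject:

| η | scenario |
|---|----------------------------------|
| 0 | raw data |
| 1 | ICA ocular cleanup |
| 2 | surface Laplacian |
| 3 | ICA cleanup, then surface Laplacian |

Two forced baselines are always reported alongside: *Raw* (η = 0 for
everyone) and *Ind-AR* (η = 3 for everyone, subject-independent
removal).

## Pipeline stages

### Surface Laplacian (spherical splines)

Electrode positions are taken on the unit sphere and the potential
field is interpolated with spherical splines whose kernels are
truncated Legendre series

    g(x) = (1/4π) Σ_{n=1..o} (2n+1) P_n(x) / (n(n+1))^ρ,
    h(x) = (1/4π) Σ_{n=1..o} (2n+1) P_n(x) / (n(n+1))^(ρ−1),

with x = cos of the inter-electrode angle.  Defaults: order o = 10,
smoothness ρ = 4, Tikhonov regularization λ = 1e−5 on the Gram matrix
G.  Per time sample the spline coefficients are solved against
G + λI with the constant-offset (common-mode) term removed exactly,
and the Laplacian is read out through H.  Consequences asserted in
tests: a spatially constant field maps to zero (to ~1e−12 of the input
scale), the operator is linear, and spatially broad (volume-conducted)
patterns are strongly attenuated while focal ones survive.  We do not
apply head-radius unit calibration: every downstream feature is
z-scored before classification, so the overall scale cancels.

Legendre polynomials are generated with the three-term Bonnet
recurrence; the test oracle recomputes the same series independently
through `scipy.special.eval_legendre` and demands agreement to 1e−12.

### ICA ocular cleanup

The data model is a linear mixture X = WS of statistically independent
non-Gaussian sources.  Stages, in order:

1. **1 Hz high-pass** (zero-phase 5th-order Butterworth).  Slow drifts
   ruin ICA estimation; since the lowest analysis band starts at 8 Hz,
   this cannot affect the features.
2. **FastICA** (scikit-learn, Gaussian contrast `exp(−u²/2)`, parallel
   updates) on whitened, trial-concatenated data, with as many
   components as channels — capped at the numerical rank of the data.
   The cap matters on the second pass: after removing a component the
   data are rank-deficient, and a full-rank refit blows up the
   whitening and destroys the reconstruction.
3. **Scoring**: each component's Pearson correlation with the artifact
   references, computed per trial and aggregated as the mean absolute
   correlation (robust to sign flips across trials).  References are
   the recorded EOG traces when available, otherwise the three most
   anterior electrodes.  References are used for scoring only; they
   are never mixed into the output.
4. **3σ rejection**: scores are pooled across components and
   references; components whose maximum score exceeds mean + 3·SD are
   zeroed and the data reconstructed through the mixing matrix.
   Degenerate (zero-spread) score sets reject nothing.
5. The fit → score → threshold → reconstruct cycle runs **twice**
   (second pass on the first pass's output), catching ocular energy
   the first unmixing split across components.  The pass count is a
   parameter.

On synthetic data with a known injected blink (150 µV) the two-pass
rule rejects exactly the blink component and reduces the frontal-channel
RMS error to the clean ground truth by ~85 % (the acceptance suite
requires ≥ 50 % over a 10-seed grid).

### Functional-connectivity features

Trials are cropped to the post-cue window (default 0.5–3.5 s; 0.5–2.5 s
for the synthetic 3 s epochs), band-passed (zero-phase, 5th-order
Butterworth) into four rhythms — μ 8–12, β_low 12–15, β_mid 15–20,
β_high 18–40 Hz (the β_mid/β_high overlap is deliberate and kept) —
and every channel pair is reduced to one scalar per band:

* **pearson** — sample correlation;
* **motifs** — fraction of time points with coinciding ordinal patterns
  (rank order of 3 consecutive samples, lag 1; ties broken
  earlier-index-smaller, so the mapping is deterministic);
* **gfc** — Gaussian-kernel similarity `mean_t exp(−(x_t−x'_t)²/2σ²)`;
  σ is the median of |x_i(t) − x_j(t)| pooled over all pairs and
  samples of the trial (per band) — the median heuristic; a per-pair σ
  is available by flag;
* **coherence** — Welch cross-spectral coherence magnitude
  |E S_xy| / √(E S_xx · E S_yy) (Hann windows of min(256, T/4) samples,
  50 % overlap), averaged over the in-band bins — averaging, not the
  maximum, because the feature layout requires one scalar per pair per
  band;
* **plv** — phase-locking value from analytic-signal (Hilbert) phases.

The upper-triangular values (i < j, row-major) of each band are
concatenated in fixed band order: 4·C(C−1)/2 features per trial
(C = 22 → 924; C = 64 → 8064).  Analytic anchors asserted in tests:
identical inputs give exactly 1 for every measure; independent inputs
give motif coincidence ≈ 1/6 and PLV ≈ 1/√n_independent.

### Classification and metrics

A linear discriminant (SVD solver, tolerant of features ≫ samples)
preceded by per-feature z-scoring fitted on training data only.
Schemes: stratified 10-fold CV, ten random stratified 80/20
train/test splits, or a fixed held-out test set.  Reported metrics:
accuracy (pooled confusion diagonal), Cohen's κ (computed from the
pooled confusion; cross-checked against scikit-learn), and ROC AUC
(rank-based; macro one-vs-rest beyond two classes).  One caveat worth
knowing: the SVD solver ignores directions with *zero* within-class
variance, so a synthetic feature that is exactly constant per class is
dropped rather than exploited; real features always carry within-class
spread.

### Scenario selection

For one subject, `run_sdar` splits the trials once (stratified 80/20),
fits the estimation stages (ICA) on the training portion only while
applying the learned cleanup to all trials, estimates each scenario's
accuracy by stratified CV inside the training portion (nested, so the
selection never sees the held-out trials — an instrumentation test
replaces the test trials with noise and demands bit-identical
selection), picks the argmax with ties going to the smallest η (least
processing), and reports the selected scenario plus both forced
baselines on the held-out trials.  A `select_on_test` flag reproduces
the permissive protocol that tunes on the reported score, for studying
that bias; it is never the default.

### Skill groups and relevance

Subjects are clustered into three ordered groups (GI best … GIII
worst) by k-means (10 restarts, fixed seed) on one classifier metric
computed under the Raw scenario; identical metric values across
subjects are an error rather than a silent single cluster.  Link
relevance is the absolute LDA coefficient vector (element-wise max
across discriminants in the multiclass case), min–max normalized to
[0, 1], with the three β sub-band blocks merged element-wise by
maximum — giving C(C−1) values (μ block + merged β block).  Group
summaries stack the members' vectors and report per-link maxima and
the links above a 0.9 threshold.

## The synthetic generator

Every test runs on generated data with full ground truth (sources,
mixing, noise, artifact traces all recorded; the energy budget
`data = mixing·sources + noise` closes to 1e−15).

* **Montage**: deterministic Fibonacci spiral on the upper hemisphere
  (+y anterior); the three most anterior electrodes are the designated
  frontal references.
* **Sources**: μ and β band-limited noise sources in left/right
  sensorimotor locations plus occipital and frontal-midline broadband
  background.  Class 0 attenuates the left-hemisphere μ amplitude by
  the ERD depth (default 0.5; β attenuated by its square root), class 1
  the right.
* **Inter-trial variability**: every source amplitude is jittered per
  trial by a lognormal factor exp(0.4·N(0,1)).  This is the single most
  important realism ingredient: without it single-trial classification
  saturates at 100 % and scenario selection degenerates into ties.
  With it, per-subject accuracies land in the realistic 60–95 % range.
* **Volume conduction**: mixing gains decay as a Gaussian kernel of
  great-circle distance (default width 0.8 rad), broad enough that raw
  inter-channel correlations are pervasive and the Laplacian's link
  reduction is visible.
* **Blinks**: biexponential pulses (50 ms rise, 150 ms decay), Poisson
  onsets (default 0.5 /s), topography peaking at the most anterior
  electrodes; amplitude in µV is the severity knob.  The clean
  pre-injection data and the blink trace are kept for error
  measurement.
* **SNR** (default 10 dB; 5 dB in the cohort studies) is the ratio of
  mixed source power to additive white sensor-noise power.

What the generator does **not** emulate: realistic head-model forward
fields (BEM/FEM), muscle/ECG/line artifacts, non-stationarity across a
session, 1/f background spectra, or inter-session variability.
Passing tests therefore demonstrate correctness of the algorithms and
the claimed qualitative behaviors under controlled conditions — not
performance on any real recording.

### Verified cohorts

Whether contamination hurts a *given* subject — and which scenario
best repairs it — depends on the realization.  `benchmark_cohort`
therefore verifies each subject's severity label before accepting it:
candidates are drawn deterministically from a seed stream, their four
scenario accuracies are measured by a fixed CV oracle, and an
artifact-heavy candidate (600 µV, 1.5 /s blinks with a broad 0.8 rad
field, on broadly mixed 1.0 rad signal) is accepted only when an ICA
scenario wins by ≥ 5 accuracy points; a clean candidate (focal 0.45 rad
mixing, no artifacts, no frontal background source — so the
frontal-referenced 3σ rule finds nothing to remove) is accepted when a
non-ICA scenario wins.  Failing candidates are redrawn (up to 8; then
the best is kept).  The broad-vs-focal contrast is what separates the
scenarios physically: a broad ocular field also hurts broadly-mixed
signal that the Laplacian alone would over-sharpen, while focal clean
signal leaves nothing for either cleanup to fix.

## Problem sizes and numerical choices

Default study sizes — 16 channels, 250 Hz, 40–60 trials of 3 s, 5
subjects per cohort, 10-seed grids — were chosen so the full property
suite demonstrates every claim on a single CPU in minutes while
keeping ≥ 20 samples per CV fold.  Other numerics: all filtering is
zero-phase (phase measures must not be distorted by filter delay);
FastICA tolerance 1e−4 with 500 iterations and convergence warnings
demoted (the best iterate is still informative); rank detection uses a
1e−8 relative singular-value cutoff; k-means uses 10 restarts; every
stochastic stage takes an explicit integer seed and the whole
simulate → select → group chain is bit-reproducible (asserted).

## Known limitations

* The GDF reader is exercised against the documented real-data layout
  but not against a real recording in the test suite (no GDF writer
  exists in the stack); the MAT reader is tested on a synthetic
  container in the same layout, labelled as such.
* Scenario selection inherits the variance of its CV estimate; with
  ~50 training trials, scenario differences under ~4 accuracy points
  are inside the selection noise, and the selector will tie-break to
  less processing.
* Relevance maps are coefficient-based; they localize discriminative
  links under the linear model only and are not causal statements
  about cortical sources.
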