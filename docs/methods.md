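# Methods

`betamod` quantifies movement-related beta-band dynamics from cued motor-task
EEG and links them to clinical, neurophysiological, and structural markers of
fatigue in multiple sclerosis. This note documents the models, the numerical
choices, and what the synthetic-data generator does and does not emulate.

## The beta modulation-depth statistic

During a cued pinch movement, sensorimotor and frontal beta (13.5–25 Hz)
power transiently drops below baseline (event-related desynchronization,
ERD) and rebounds above it after the movement (event-related
synchronization, ERS). The pipeline estimates, per trial and subject:

1. **Spatial sharpening.** Epochs (−0.5 to 1.5 s around the cue, 61
   channels, 256 Hz) are transformed to current source density: a spherical
   spline with a constant term (order `m = 4`, regularization
   `λ = 1e−5`, Legendre series truncated at degree 50) is fit to the scalp
   potentials per time point and the negative surface Laplacian evaluated at
   each electrode. The output is reference-free: adding any constant across
   channels leaves it unchanged to numerical precision.
2. **Time–frequency decomposition.** Complex Morlet wavelets on a 1–90 Hz
   grid in 0.5 Hz steps (179 bins), sampled on a 10 ms grid. Cycle counts
   grow linearly from 3 at 1 Hz to 10 at 90 Hz — the linear mapping is a
   package choice; only the endpoints are prescribed by the protocol the
   pipeline reproduces. Kernels are amplitude-normalized so that a
   unit-amplitude sinusoid at a wavelet's centre frequency yields power ≈ 1.
   No padding is applied; samples within one wavelet half-width
   (`n_cycles / 2f`) of an epoch edge are flagged per frequency. At 13.5 Hz
   the analysis windows (0–1.0 s) are comfortably edge-clean.
3. **Whole-trial normalization.** Band-averaged power `P(ch, t)` is
   normalized per trial and channel as `(P − μ)/μ` with `μ` the mean over
   the *entire* epoch. The time-mean of the result is exactly zero — an
   identity the tests assert at 1e−10.
4. **Personalized ROIs.** Within each of three printed candidate regions
   (frontal, "left sensorimotor", "right sensorimotor" — the printed
   sensorimotor lists carry electrodes of the opposite scalp side; they are
   implemented verbatim under their printed names), the electrode with the
   largest trial-averaged modulation depth is found and grouped with its six
   nearest montage neighbours (3-D chord distance on the unit sphere;
   neighbour search ranges over all 61 electrodes, with a config flag to
   restrict it to the region). Depth ties break by distance to the region
   centroid, then lexicographically.
5. **Metric extraction.** On the ROI-mean normalized time course, per trial:
   peak ERD = minimum in [0, 0.7) s, peak ERS = maximum in [0.7, 1.0] s
   (the 0.7 s sample belongs to the ERS window only), modulation depth =
   ERS − ERD, plus latencies and the epoch-mean. Subject-level values are
   means over kept trials. Subjects with no discernible dip-plus-rebound in
   any ROI (trial-averaged ERD > −0.2 or ERS < +0.2 everywhere; thresholds
   configurable) are excluded.

## EMG chain

Per-trial EMG is rectified as `|x − mean(x)|` over the 1.5 s post-cue
segment (the pre-cue segment is processed identically but used only for
baseline statistics), smoothed with a zero-phase second-order Butterworth
low-pass designed at 20 × 1.25 = 25 Hz — one forward–backward pass squares
the magnitude response, which puts the effective −3 dB point of the realized
filter at 25·(√2 − 1)^¼ ≈ 20.06 Hz — and normalized by the session maximum.
Visual onset marking is replaced by a deterministic rule: onset is the first
post-cue crossing of baseline mean + 3 SD sustained ≥ 25 ms; offset is the
last supra-threshold sample; trials with no such run, or with an envelope
peak below 5 baseline SDs, are dropped ("no clear EMG peak"). EEG/EMG
exclusion is applied jointly (shared trial ids). The EMG sampling rate is
not part of the reproduced protocol; the default is 1024 Hz.

## Synthetic-data generator

The generator emulates the study's design: three groups (fatigued MS,
non-fatigued MS, healthy controls; default sizes 19/22/18), 300 cued trials
per subject, 61-channel epochs at 256 Hz, one EMG trace per trial, and a
per-subject feature table.

**EEG model.** Each trial is spatially correlated 1/f background noise
(channel covariance decaying exponentially with electrode distance;
Cholesky-mixed; fitted log–log PSD slope −1 ± 0.3 over 2–45 Hz) plus three
regional beta sources. Each source is a cosine carrier — one frequency per
trial, drawn uniformly over 13.5–25 Hz and shared across sources with
independent phases, so regional powers add incoherently across trials
without within-trial beat oscillations — multiplied by the square root of a
squared-amplitude envelope `q(t)` (baseline 1, Gaussian dip at the ERD
latency, Gaussian bump at the ERS latency) and by a Gaussian spatial
topography (width 0.9 chord units) centred on Fz, C4, and C3. Fz rather
than FCz anchors the frontal source so its CSD footprint stays off the
vertex electrodes shared by both sensorimotor candidate lists.

**Calibration.** The target quantities (per-group peak ERD/ERS, Table-style
group means as defaults) are defined *through* the analysis pipeline, so the
generator solves for its envelope coefficients by running that very
pipeline: (i) background band power and source amplitudes realizing the
configured snr (default 30) are measured once per scenario on seeded probe
trials; (ii) the six envelope coefficients are solved jointly by bounded
least squares against the subject's six targets, on noise-free probe trials
whose relative source phases rotate uniformly so cross terms cancel (the
data-driven ROI memberships are frozen within a solve and refreshed between
rounds — spatial leakage couples the three regions, which is why a joint
solve is required); (iii) because the pipeline's subject-level statistic
averages *per-trial* extrema, which trial noise inflates relative to the
noise-free extrema, a fixed-seed 96-trial mini-session measures the
inflation and the noise-free targets are shifted to compensate (up to two
rounds). All stages are seeded and bit-reproducible. Infeasible targets
(e.g. ERD deeper than the background floor allows) raise a parameter error
naming the residual.

**Feature tables.** Group marginals follow the study's printed descriptives
where available, otherwise plausible clinical values. Cross-correlations are
induced by a one-factor Gaussian copula anchored on the subject's latent
severity factor (which also drives the regional ERD/ERS targets, fully
correlated — the printed ERD SDs are an order of magnitude smaller than the
ERS SDs, so the depth SD is essentially their sum). The latent loading for
each configured pooled Spearman target (FSS −0.54 over patients, ICF +0.49
and caudate volume +0.35 over everyone) is found by seeded Monte-Carlo
bisection, since the pooled coefficient mixes the within-group coupling with
the between-group mean separation. Fatigue labels derive from the simulated
FSS at the cut-off of 4 (draws are resampled to respect the cut-off).
Healthy controls carry explicit missing values on patient-only scales;
patients additionally lose a random TMS/FA predictor with probability 0.32,
reproducing the study's complete-case count (~28 of 41).

**What a green test does not establish.** The generator produces
artifact-free, stationary-background epochs with deterministic envelopes: no
ocular/muscle artifacts, no ICA mixing, no bad channels, no trial-to-trial
envelope variability, no force data, and no MRI/TMS physics (those enter
only as table columns). Recovery of the planted parameters therefore
validates the pipeline's numerics and bookkeeping, not its robustness to
real-world contamination.

## Statistics layer

Kruskal–Wallis (tie-corrected, χ² reference) with Dunn's post-hoc z tests
(tie-corrected pooled variance, Bonferroni over all pairs; raw p also
reported); Spearman ρ with seeded 1000-resample percentile bootstrap CIs
(pairwise-complete deletion); mediation by the product of OLS coefficients
with bias-corrected (BC, not BCa) percentile bootstrap CIs and two-sided
bootstrap sign p-values (listwise deletion; TE = DE + IE holds exactly on
the point estimates); OLS of FSS on z-scored beta depth and MADRS with
standardized β, t, and model F on (2, n−3) df; Pearson chi-square without
continuity correction for sex tables. Note that bias-corrected bootstrap
intervals for a product of coefficients are known to be slightly
anti-conservative under the null: simulated null coverage is ≈0.92 rather
than 0.95 (scipy's independent BCa bootstrap shows the same behaviour on the
same statistic), so borderline mediation claims should be read accordingly. Bonferroni across the three primary
EEG measures (ERD, ERS, depth) is exposed as familywise α/3. When the
grouping factor has three levels, mediation is run pairwise with dummy
coding.

## Fatigue classifier

Elastic-net penalized logistic regression under stratified 5-fold nested
cross-validation, repeated 50 times with fresh splits. The inner 5-fold CV
searches α ∈ {0.1, …, 1.0} × 100 log-spaced λ values spanning four decades
down from the data-driven λ_max (the smallest λ zeroing all coefficients at
the given α); the pair minimizing the summed inner-fold binomial deviance is
refit on the outer-train fold. Continuous predictors are z-scored strictly
inside each training fold; binary columns (sex) pass through. Held-out
predictions are pooled per repeat for ROC-AUC, PR-AUC, accuracy,
sensitivity, specificity, balanced accuracy (threshold 0.5 — the threshold
is a package choice; balanced accuracy is reported alongside because
accuracy is sensitive to class imbalance), and the Brier score; aggregates
are means with percentile 95% intervals over repeats. Selection frequency is
the fraction of outer refits with a nonzero coefficient; predictors with
mean selection frequency > 0.50 enter a descriptive ridge-logistic refit
(default λ = 0.01, raised a decade at a time if separation persists) with
odds ratios, stratified (within-class) bootstrap percentile CIs, and
McFadden/Cox–Snell/Nagelkerke pseudo-R². The solver is a glmnet-style
IRLS + coordinate-descent path compiled with numba; sklearn's L2 logistic
regression serves as an independent cross-check in the tests. Outcome coding
defaults to fatigued = 1 (the source protocol prints both codings; signs are
reported explicitly). Sex is penalized like every other predictor. Degenerate
single-class inner folds trigger a logged seed bump and re-split.

## Numerical and design notes

- Montage positions are an idealized spherical 10-10 construction; real cap
  geometry deviates slightly, which is irrelevant for synthetic work but
  means CSD values on real data should use measured positions.
- The per-trial subtract-and-divide normalization makes all beta metrics
  scale-free; the generator's snr parameter (default 30, beta baseline power
  over background band power at a source centre, measured post-CSD) controls
  the depth of achievable ERD: at snr → ∞ the normalized floor approaches
  −1, at low snr deep targets become infeasible and calibration raises.
- Latency recovery is limited by the 10 ms grid plus wavelet smoothing
  (σ_t ≈ 36 ms at 20 Hz); the generator's Gaussian envelopes are symmetric,
  so smoothing does not bias the peak location.
- Between- vs within-subject variance of modulation depth is not constrained
  by the reproduced protocol; the generator puts all depth variance between
  subjects (one latent severity factor per region, regional factors coupled
  at 0.8) and none in the envelope across trials.
- Bootstrap and permutation routines consume `numpy.random.default_rng`
  seeds; identical seeds give identical CIs, selection frequencies, and
  simulated cohorts.
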