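# betamod

Movement-related beta ERD/ERS analysis and multimodal fatigue modelling for
cued motor-task EEG studies in multiple sclerosis.

## The problem

Fatigue is among the most disabling symptoms of MS and has no objective
biomarker. During a cued pinch movement, beta-band (13.5–25 Hz) power over
frontal and sensorimotor cortex transiently drops (event-related
desynchronization, ERD) and then rebounds above baseline after the movement
(event-related synchronization, ERS). The peak-to-peak excursion of this
dip-and-rebound — the **beta modulation depth** — is reduced in fatigued
patients, correlates with fatigue severity and intracortical facilitation,
and contributes to multimodal classifiers of fatigue status. `betamod`
implements the full quantification pipeline plus the surrounding statistics,
for methodologists who want a tested, seeded, reusable implementation.

## What it computes

For each subject, on cue-locked epochs `x(trial, channel, t)`,
t ∈ [−0.5, 1.5) s at 256 Hz over 61 scalp channels:

1. **CSD**: spherical-spline surface Laplacian (Perrin-style, order m = 4,
   λ = 1e−5), reference-free and spatially sharpened.
2. **TFR**: complex Morlet wavelet power, 1–90 Hz in 0.5 Hz steps
   (179 bins), 3→10 cycles linear in frequency, 10 ms time grid.
3. **Normalization**: band-averaged power P(ch, t) → (P − μ)/μ with μ the
   whole-epoch mean, per trial and channel (time-mean exactly 0).
4. **Personalized ROI**: within each of three candidate regions, the
   electrode with the largest trial-averaged modulation depth plus its six
   nearest neighbours.
5. **Metrics** per trial on the ROI-mean course: peak ERD = min over
   [0, 0.7) s, peak ERS = max over [0.7, 1.0] s, modulation depth =
   ERS − ERD, latencies, mean beta.

Around this sit: an EMG chain (rectification about the trial mean, zero-phase
Butterworth envelope with the 25 %-adjusted cutoff giving an effective −3 dB
point at 20 Hz, threshold onset/duration, trial exclusion), a statistics
layer (Kruskal–Wallis + Dunn–Bonferroni, bootstrap Spearman, BC-bootstrap
mediation, the FSS ∼ depth + MADRS regression, chi-square), an elastic-net
logistic fatigue classifier under repeated stratified nested CV with
stability selection and a ridge refit, and a seeded synthetic-data generator
that emulates the study design (group-specific ERD/ERS targets realized
through the pipeline itself, 1/f background EEG, EMG bursts with
group-specific reaction times, and a feature table with configurable group
means and pooled rank-correlation structure).

## Worked example

```python
from betamod import analyze_session
from betamod.simulate import SimScenario, mean_subject, generate_session

scenario = SimScenario(seed=1, n_trials=120)
record = mean_subject(scenario, "MS-F")          # group-mean ground truth
eeg, emg = generate_session(scenario, record)    # 120 epochs + EMG traces
result = analyze_session(eeg, emg)               # CSD -> TFR -> ROI metrics
print(result.metrics["frontal"].subject["modulation_depth"])
```

Running `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
prints (numbers from that exact run):

```
MS-F: frontal modulation depth 3.640 (target 3.53), kept trials 114/120
MS-NF: frontal modulation depth 4.179 (target 4.20), kept trials 117/120
HC: frontal modulation depth 4.129 (target 4.08), kept trials 117/120
KW on frontal depth: H=21.89 p=0.0000; FSS~depth rho=-0.67 CI=(-0.79,-0.47); FSS regression betas={depth: -0.62, MADRS: +0.36}
nested CV (n=27, p=25): ROC-AUC 0.986 [0.973, 0.999], Brier 0.051
```

Reading this: the pipeline recovers each group's planted frontal modulation
depth within sampling error at 120 trials (the EMG exclusion keeps ~95 % of
trials, matching the emulated study's rate); on a full simulated cohort the
groups separate strongly on frontal depth, fatigue severity correlates
negatively with depth across patients, and depth predicts fatigue
independently of depression; the nested-CV classifier on the patients'
complete cases discriminates fatigued from non-fatigued subjects. These are
properties of the synthetic cohort, which is built to carry the group
structure the pipeline is designed to detect.

`scripts/acceptance.py` re-runs the pipeline end-to-end from scratch —
simulation, spectral analysis, ROI metrics, statistics, classifier — under
the given seed and writes its manifest to `--out`.

## Layout

```
src/betamod/
  montage.py        61-channel 10-10 montage geometry, candidate regions
  containers.py     EpochedEEG / EMGTraces with NPZ + text I/O
  simulate.py       synthetic sessions, cohorts, feature tables (seeded)
  preprocess.py     FIR band-pass + notch, epoching, EMG chain
  spectral.py       spherical-spline CSD, Morlet TFR, baseline normalization
  beta_metrics.py   personalized ROIs, ERD/ERS/depth extraction, exclusion
  stats.py          KW/Dunn, bootstrap Spearman, mediation, regression
  fatigue.py        elastic-net nested CV, stability selection, ridge refit
  pipeline.py       analyze_session: epochs -> metrics in one call
docs/methods.md     models, assumptions, numerical choices, limitations
```
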