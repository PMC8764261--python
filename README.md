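# emodyn

**Dynamic mutual-information brain networks for EEG music-emotion
classification.**

`emodyn` is a reusable, tested pipeline for studying how emotions evoked by
music appear in the *connectivity* of the brain rather than in single
channels.  Multichannel EEG is decomposed into the canonical frequency
bands (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz); a sliding window is
moved across each band-limited signal and, within every window, the mutual
information between every pair of channels is estimated, giving a
time-resolved *dynamic brain network*.  Each windowed network is
proportionally thresholded and summarized by its graph topology — average
clustering coefficient and characteristic path length — and those
time-courses become the features from which valence/arousal emotion
classes are decoded.

It is aimed at researchers working with DEAP-style affective-EEG designs
(multiple subjects × multiple music trials, self-assessed 1–9
valence/arousal/dominance/liking ratings) who want every stage — from raw
multichannel signals to a cross-validated classification report — as
inspectable, seeded, reproducible code.  Because affective-EEG corpora
cannot be redistributed, the package ships a first-class synthetic-EEG
generator that emulates the study structure with *known* class-dependent
connectivity, so every stage of the pipeline is testable end to end.

## The method

For band $b$ and window $w$, the association between channels $i, j$ is the
plug-in mutual information over 16 equal-frequency (quantile) bins:

$$\hat I(x_i, x_j) = \sum_{u,v} \hat p_{uv}\,\ln\frac{\hat p_{uv}}{\hat p_{u\cdot}\,\hat p_{\cdot v}} \quad \text{(nats)},$$

yielding a connectivity tensor indexed (band × window × channel × channel).
Pearson correlation and the phase-locking value
$\mathrm{PLV} = |\langle e^{i(\phi_i-\phi_j)}\rangle|$ (phases from the
Hilbert analytic signal) are drop-in alternative estimators.  Each slice is
binarized by keeping the strongest 15 % of edges, and the graph metric
series are reduced to mean/SD/slope per band — 60 features per trial with
the default five bands.

Classification uses Fisher linear discriminant analysis implemented from
first principles: the two-class projection $w \propto S_w^{-1}(\mu_1 -
\mu_2)$ with the decision threshold at the midpoint of the projected class
means, extended to the four valence-arousal quadrants (HVHA/HVLA/LVHA/LVLA)
by pairwise voting.  SVM, MLP, k-NN, logistic-regression and
random-forest learners plug in behind the same fit/predict contract.

Around that core the package provides the full experimental chain:
zero-phase Butterworth filtering, common-average re-referencing, ICA-based
ocular-artifact removal (with a regression fallback), epoching with
baseline correction, empirical mode decomposition with the Hilbert
transform, Welch band-power / differential-asymmetry / band-energy /
mental-workload (frontal-θ over parietal-α) features, the 620-column full
and 108-column reduced PSD feature schemes, music feature-event detection,
entropy and Gini impurity scoring, ridge-based recursive feature
elimination, leave-one-block-out / leave-one-subject-out / stratified k-fold
cross-validation, paired feature-set comparison, and label-correlation
subject selection.

## Worked example

Simulate a six-subject study with the default arousal-dominant planted
connectivity, preprocess it, build MI dynamic networks, and evaluate LDA
with leave-one-subject-out cross-validation:

```python
import emodyn as e

cfg = e.SimConfig(n_subjects=6, trials_per_subject=16, trial_duration=16.0)
reports = e.run_emotion_study(cfg, seed=0)
for task, rep in reports.items():
    print(f"{task:8s} macro accuracy = {rep.macro_accuracy:.3f}")
print(reports["quadrant"].confusion)
```

prints

```
quadrant macro accuracy = 0.792
valence  macro accuracy = 0.854
arousal  macro accuracy = 0.990
[[18  0  7  0]
 [ 0 20  1  3]
 [ 4  0 17  2]
 [ 0  3  0 21]]
```

Four-quadrant accuracy is far above the 0.25 chance level, and the binary
arousal task is recovered almost perfectly while valence is harder — the
expected signature of the generator's default coupling, whose arousal
effect (β-band fronto-central clique, shared-variance κ 0.85 vs 0.15) is
deliberately stronger than its valence effect (α-band prefrontal clique,
κ 0.70 vs 0.25).  The confusion matrix (rows = true class HVHA/HVLA/LVHA/
LVLA, columns = predicted) shows errors concentrated within arousal levels,
i.e. valence confusions.

The same pipeline is available from the shell, stage by stage or in one
command:

```sh
emodyn run-all --seed 1 --out runs/demo            # defaults: 8 subjects x 20 trials
emodyn simulate --config my_study.toml --seed 1 --out runs/sim
```

Every output directory contains the fully resolved configuration and a
log, so any artifact is regenerable from its stored config and seed.

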