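# Methods

This note documents the models, estimators and numerical choices behind
`emodyn`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem left them open.

## Data model and label mapping

Ratings follow the DEAP convention: valence, arousal, dominance and liking
on a continuous 1–9 self-assessment scale.  Classes derive from a midpoint
split, default 5 (the scale midpoint used throughout the DEAP literature);
a rating exactly at the midpoint counts as *high*, so the four quadrant
classes HVHA/HVLA/LVHA/LVLA partition the rating square exactly and
`quadrantize(v, a)` always agrees with `binarize` applied per axis.
Dominance and liking are stored and validated but not used as
classification targets.  (Some DEAP-style designs collect a fifth label
dimension such as familiarity; this package standardizes on the four
rating axes above.)

Montage regions (frontal/central/parietal/temporal/occipital) are explicit
per-channel tags rather than being parsed from names at use time, so fully
synthetic montages work; `infer_region`/`infer_pairs` label standard
10-20/10-10 names (odd digits left, even right, homologue = digit + 1).
The 15-electrode frontal+central montage used by the reduced feature
scheme is a reconstruction: nine frontal (Fp1/2, AF3/4, F3/4, F7/8, Fz)
and six fronto-central/central (FC1/2, FC5/6, C3/4) electrodes with six
homologous pairs (Fp1–Fp2, AF3–AF4, F3–F4, F7–F8, FC1–FC2, C3–C4); which
exact electrodes constitute the 15/6 design is not fixed by the dimension
arithmetic alone, only the counts are.  A standard 62-channel extended
10-10 cap backs the full scheme.

## Synthetic affective EEG

The generator's defaults emulate the DEAP study structure: 32 subjects ×
40 trials, 128 Hz, 60 s per trial, 16 channels spanning all five scalp
regions.  Each channel is a sum of

* **band-limited sources** — white noise through the same zero-phase
  4th-order Butterworth band-pass used downstream, normalized to unit RMS
  and scaled per band (δ 8, θ 7, α 10, β 6, γ 4 µV RMS — a 1/f-flavoured
  amplitude profile with the usual alpha prominence).  Filtered noise
  rather than sinusoids keeps MI and PLV estimates non-degenerate and the
  spectra realistic;
* **pink background noise** — 1/f (exponent 1.0) spectral shaping, 3 µV
  RMS;
* **blink artifacts** — 0.3 s raised-cosine pulses, Poisson-timed at
  12/min, 80 µV at frontal sites, projected with an exponentially decaying
  front-to-back topography (weight $e^{-d}$ with depth 0 frontal, 1
  central, 1.5 temporal, 2 parietal, 3 occipital; frontal:occipital
  amplitude ratio ≈ 20).

**Planted connectivity.** Emotion classes differ by which channel groups
share a band-limited source.  A coupling entry (i, j, band, κ) makes both
channels mix the group's shared source with weight √κ and their private
source with weight √(1−κ), so **κ is the shared-variance fraction and the
planted band-limited correlation between clique members equals κ** (κ = 1
means identical signals).  Entries in the same band form cliques via
connected components, one shared source per component.  The defaults are
arousal-dominant: high arousal strengthens a β-band fronto-central clique
(F3, F4, C3, C4) from κ 0.15 to 0.85; high valence an α-band prefrontal
clique (Fp1, Fp2, F7, F8) from κ 0.25 to 0.70.  Network topology is
therefore expected to discriminate arousal better than valence, and the
end-to-end tests assert exactly that asymmetry.

Ratings are the class centroid (HVHA → (7,7), HVLA → (7,3), LVHA → (3,7),
LVLA → (3,3)) plus a per-subject bias (SD 0.3) and Gaussian noise (SD
0.8), clipped — not resampled — to [1, 9]; at these SDs clipping bias is
negligible and the quadrant map of the noisy ratings agrees with the
planted class ≳ 95 % of the time.  Per-subject multiplicative gain is
log-normal (σ 0.1).

Every draw comes from `SeedSequence([seed, subject, trial, stream])`, so
datasets are bit-reproducible and regenerating a subject subset never
reshuffles other subjects.

**What the generator does not emulate:** volume conduction and a head
model (couplings are planted directly, not through a leadfield), muscle
and line-noise artifacts, non-stationarity within a trial beyond the
windowed estimator's own variance, and real music audio (the stimulus is
abstracted to the trial epoch; `detect_music_events` accepts any sampled
envelope).  Passing tests therefore demonstrate that the pipeline recovers
*planted* connectivity structure under realistic noise, spectra and
artifacts — not that real EEG carries such structure.

## Preprocessing

All filtering is zero-phase (forward–backward 4th-order Butterworth,
`sosfiltfilt`), preserving alignment across bands — the windowed MI/PLV
estimators assume no inter-band delay.  The effective roll-off (≈ 48
dB/octave) comfortably exceeds a 20 dB-per-octave stopband requirement.
Gamma is capped at 45 Hz to stay below 50/60 Hz mains.

Ocular cleanup runs FastICA on the common-average-referenced data and
zeroes components whose absolute correlation with a frontal 0.5–4 Hz
reference reaches 0.7 or whose excess kurtosis exceeds 10, then
reconstructs.  Two numerical points matter: (1) the component count is
capped at the numerical rank of the data — common-average referencing
makes the data rank-deficient by one, and whitening across a null
direction destroys the reconstruction; (2) FastICA's convergence criterion
is rarely met on EEG whose background is near-Gaussian (a Gaussian
subspace has no preferred rotation), but the spiky blink component is
still extracted, so the estimate is used and only hard failures (or < 8
channels) fall back to regressing out the frontal slow reference.  The
regression fallback also removes genuine frontal slow activity; it is the
fallback, not the default, for that reason.

Epoching cuts non-overlapping windows, subtracts the per-channel mean of
the first 0.5 s (the default baseline window) and drops a trailing partial
epoch.

**EMD.** Sifting uses cubic-spline envelopes through local extrema with
the signal endpoints as additional anchors (taming edge swings at the cost
of slight end effects).  A sift stops when the mean-envelope RMS falls
below 0.05 × the component RMS (or after 64 sifts); decomposition stops
at a monotone residue, too few extrema, or 10 IMFs.  The decomposition is
exactly additive by construction — IMFs plus residue reproduce the input
to machine precision — and on well-separated tones each IMF's extrema and
zero-crossing counts differ by at most one.  EMD is provided as an
alternative decomposition; the default pipeline path is the linear
band-pass bank.

## Connectivity and graphs

Mutual information is the plug-in estimate over equal-frequency (quantile)
bins, default 16.  Quantile bins make the marginals uniform by
construction, so MI(x, x) is a stable ln(16) for continuous signals and
the estimate needs no bandwidth choice.  The plug-in estimator has a
positive bias of roughly $(B-1)^2/2N$ nats (≈ 0.22 at the default 4 s ×
128 Hz window); the bias is common to all pairs and cancels in the
thresholding ranking, which is all the network construction uses.
Constant inputs are degenerate: the estimators warn and return 0.

The sliding window defaults to 4 s with a 2 s step — at least four cycles
of the slowest (1 Hz) band edge per window and 512 samples for the
histogram, while still resolving within-trial dynamics.

Each (band, window) slice is binarized by *proportional thresholding*:
keep the `round(ρ·n(n−1)/2)` strongest edges, default ρ = 0.15, ties
broken by ascending (i, j) so the edge set is deterministic.  Density
matching across trials is standard practice where absolute association
scales differ between subjects.  Graph metrics follow the Watts–Strogatz
definitions: average clustering with degree-<2 nodes contributing 0, and
characteristic path length as the mean shortest-path distance over
*reachable* ordered pairs with an explicit fragmentation flag — closest to
"average path length" while remaining defined on fragmented graphs (an
edgeless graph reports 0 with the flag set).  Per band the four metric
series (clustering, path length, achieved density, mean degree) are
summarized by mean, SD and least-squares slope over windows: 5 × 4 × 3 =
60 features per trial.  With proportional thresholding the density and
mean-degree columns are near-constant; they are kept for estimator modes
where the achieved density can differ (ties, degenerate windows) and are
harmless to the regularized discriminant.

## Features

Welch band power uses Hann windows, 2 s segments, 50 % overlap, and
trapezoidal integration of the PSD over the closed band interval.  The
full PSD scheme yields 10 columns per channel (5 absolute + 5 relative
band powers; 62 channels → 620); the reduced scheme yields 6 per selected
frontal/central channel (5 band powers + total 1–45 Hz power) plus 3
differential-asymmetry columns per homologous pair (θ, α, γ; 15 channels +
6 pairs → 108).  The asymmetry bands are the emotion-relevant bands minus
delta, whose asymmetry is blink-contaminated; asymmetry is the log-ratio
ln(left) − ln(right) for scale invariance.  The mental-workload index is
frontal-θ power over parietal-α power — the classic spectral signature of
load (frontal theta rises, parietal alpha desynchronizes) written as a
single ratio.

Music feature events are mutation points of a stimulus envelope: novelty
is the positive part of the first difference of a 100 ms moving-average
smoothed envelope, an event fires where novelty exceeds its mean by z
times the SD of the *signed* first difference, and a refractory period
(default 0.5 s) suppresses near-duplicates.  Using the signed-difference
SD keeps the threshold scale-invariant while placing z = 5 far enough into
the Gaussian tail that featureless noise produces no events; thresholding
on the SD of the rectified novelty itself would fire on a few tenths of a
percent of noise samples, which is not a usable default.

Recursive feature elimination standardizes the features, scores them by
the weight magnitudes of a ridge regression on signed class indicators
(λ = 1; ridge because its weights — and hence the elimination order — are
stable), and removes one feature per round (exact reproducibility at this
scale; the step size is configurable).  Ties are broken by feature-name
order.  Entropy (−Σ p ln p, nats) and Gini impurity (1 − Σ p²) are the
standard definitions, validated on proper probability vectors.

## Classification and evaluation

Fisher LDA regularizes the pooled within-class scatter with ε = 10⁻⁶ ×
its mean diagonal before inversion, so duplicated or collinear columns are
harmless.  Multi-class problems use pairwise voting over two-class
machines — staying with the two-class projection mechanism rather than
switching to the multi-class eigen-formulation — with ties broken by the
aggregate signed projected margin, then class order.  Macro accuracy is
the unweighted mean of per-fold accuracies.  Leave-one-block-out treats
samples as a condition × block grid and leaves one block out per fold
(6 conditions × 10 blocks → 10 folds of 6); leave-one-subject-out folds by
subject; stratified k-fold shuffles with the scheme seed.  Fold
construction is asserted leak-free (folds partition the samples, no
train/test overlap) on every evaluation.  Feature-set comparisons reuse
identical folds and report per-fold accuracy deltas with a two-sided
paired t-test.

Subject selection scores each subject by the mean Pearson correlation of
their trial-label vector with every other subject's and keeps subjects at
or above the group-mean score (with a small numerical tolerance so an
all-equal cohort keeps everyone), topping up to `min_keep` by score if too
few qualify.  The at-or-above-mean cut is this package's rule; only the
selection *idea* (keep the emotionally most typical subjects) is given by
the problem.

## Evaluation scale

The test suite and the acceptance script run everything at a reduced,
CPU-friendly scale chosen once: per-trial checks use 16 s single trials;
the DEAP-structure sample-count check uses 32 × 40 trials at 2 s; the
end-to-end recovery study uses ten seeded datasets of 6 subjects × 16
trials × 16 s each, evaluated with leave-one-subject-out LDA.  The
generator's *defaults* remain the full study structure (32 × 40 × 60 s);
scale parameters are explicit inputs everywhere, so nothing in the code
privileges the reduced sizes.

## Known limitations

* The MI estimator is the plug-in histogram estimate; absolute MI values
  carry the bin bias discussed above and should be compared, not
  interpreted as unbiased information measures.
* Directed connectivity (Granger causality, directed transfer functions)
  and weighted graph metrics are out of scope; the tensor is symmetric.
* The ICA flagging rule can occasionally zero a genuine frontal
  slow-activity component on blink-free data (it correlates with the
  frontal reference by construction); at the default artifact rates this
  costs little variance, but artifact-free pipelines can disable ocular
  cleanup.
* LDA's pairwise voting does not produce calibrated class probabilities;
  plugin learners should be used where probabilities are needed.
* The generator's stationarity means the network *slope* features carry
  no planted signal; they are retained because real dynamics would load on
  them.
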