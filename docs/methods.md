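# Methods

`erpdecode` implements a moving-window multivariate decoding analysis for
epoched EEG, together with the group-level permutation statistics that make
such an analysis interpretable, and a synthetic study generator that
provides ground truth for every stage. This note describes the models, the
parameters that matter, the numerical choices, and what the synthetic
studies do and do not establish.

## The decoding model

Epochs span −100…+1000 ms around stimulus onset (defaults: 64 channels,
512 Hz, 563 samples). The epoch is tiled with consecutive, non-overlapping
10-ms windows — `floor(10 · fs / 1000)` samples each (5 at 512 Hz), the
trailing partial window dropped, giving 112 windows that cover the
prestimulus baseline as well as the first second of stimulus processing.
Within each window the feature vector of a trial is the full spatiotemporal
pattern: all channels × all samples in the window (320 features at the
defaults), channel-major. A per-channel window-mean variant
(`feature_mode="channel_mean"`) is available.

Two decoders are supported, both linear, both libsvm-backed:

* **SVM classification** of binary Yes/No responses. Performance is the
  mean held-out accuracy of stratified k-fold cross-validation (default
  10-fold), with fold assignment re-randomised over repetitions (default
  10). Classes are balanced beforehand by randomly subsampling the
  majority class to the minority count; without this step, 50% would not
  be the chance level for participants with skewed response rates.
* **SVR regression** on 0–100 ratings. Per repetition, held-out
  predictions are pooled across the k folds, correlated with the true
  ratings (Pearson), and Fisher-Z transformed (z = atanh r); the mean z
  over repetitions is reported. Ratings stay on their native scale;
  predictions are not clipped before correlating.

Features are z-scored per feature using training-fold statistics only, so
no information leaks from test folds. The regularization constant is fixed
(C = 1) and there is no inner tuning loop: the analysis establishes the
*presence* of predictive information by significance testing, not a
maximally accurate classifier — optimising C against the data being tested
would inflate exactly the quantity the null distribution is meant to
calibrate.

**Empirical null.** Each participant × window also gets a shuffled-label
score: labels (or ratings) are permuted uniformly at random across trials —
once per CV repetition by default — and the identical CV machinery is
re-run. This preserves everything about the data except the
label–epoch assignment, which makes it the correct chance reference even
where k-fold CV on small samples has a slight negative accuracy bias.

**Eligibility.** A participant enters a classification analysis only with
at least 20 trials of *each* class (too few Yes responses leave nothing to
train on), and a regression analysis only with sufficiently variable
ratings (SD ≥ 1 rating unit and ≥ 5 distinct values — the variability rule
is stated qualitatively in the literature this follows; these concrete
thresholds are this package's choice). Trials with no button press and
trials rejected in preprocessing are excluded throughout.

**Determinism.** Every stochastic sub-step (fold shuffles, label shuffles,
class balancing, permutation signs) derives its seed from the master seed
plus a key path that includes the window's identity, so windows can be
evaluated in any order — or a subgrid re-evaluated later — with results
identical to a serial full-grid run.

## Preprocessing retained at the epoch level

Only two steps operate on epochs; filtering, re-referencing, ICA and
channel interpolation are assumed done upstream on continuous data.

1. **Baseline subtraction**: per trial × channel, the mean voltage over
   the 100-ms prestimulus interval is subtracted. Double correction is an
   error.
2. **Amplitude rejection**: trials with |voltage| > 150 μV at any
   channel/sample are flagged rejected. Rejection is applied *after*
   baseline correction, so the criterion tests baseline-corrected
   amplitudes; the ordering is a convention of this package (common
   practice), not something the upstream description fixes.

Sample conventions: sample 0 is the first sample at/after the epoch start;
t = 0 belongs to the post-stimulus side; ms intervals are closed on the
left, open on the right.

## Group inference

Per window, a one-tailed paired-samples t-test compares true vs
shuffled-label scores across participants (H1: true > null, df = n−1).
Zero-variance difference vectors are flagged degenerate (p = 0 if the
constant difference is positive, else 1).

Familywise error over the ~112 windows is controlled with a cluster-mass
permutation test: clusters are maximal runs of contiguous windows with
uncorrected p < 0.05 *and* t > 0; the cluster statistic is the sum of t
over member windows; the null distribution is the maximum cluster mass
under random sign flips of each participant's whole difference series
(exchangeable under the null hypothesis that true and shuffled-label
decoding are interchangeable), default 1000 permutations. Cluster p-values
use the add-one estimator (1 + #{null ≥ observed}) / (1 + N) so they are
never exactly zero; `exhaustive=True` enumerates all 2^n sign assignments
instead (feasible for small n, and used to validate the sampled version).
The forming threshold, the mass statistic and the sign-flip scheme are the
standard formulation for paired/one-sample designs; the upstream
description names the method without these constants.

**Feature-weight topographies.** For a (significant) cluster, the linear
model is refit per participant × window on all eligible balanced trials
(single fit, not fold-averaged); absolute weights are averaged over the
window's samples per channel, z-standardised across channels (mean 0,
SD 1 within participant), averaged over the cluster's windows, and tested
per channel across participants with a one-tailed one-sample t against 0,
flagged at p < 0.05 uncorrected. Raw weights are used, not
activation-pattern transforms; with correlated noise a linear model's
weights partly reflect noise whitening, so these maps rank channel
*importance to the prediction* and must not be read as source
localisation.

## Behavioral arm

Per participant × dimension the behavioral table holds Yes/No counts and
the mean 0–100 rating, with vaping-status group (never/current/past).
Group differences are tested with one-way ANOVAs followed by
Bonferroni-corrected classical (equal-variance) pairwise t-tests
(p × number of pairs, capped at 1); the dependent variable is run three
ways — Yes counts, No counts, mean ratings — and labelled. Image-level
consistency between the two response modalities is checked by correlating,
across images, the number of Yes responses with the mean rating (and
likewise No responses, which is the mirror image when no responses are
missing).

## The synthetic study generator

The generator emulates the *structure* of a product-evaluation EEG study:
38 participants (12 never / 16 currently / 10 past vaping), 120 images ×
3 question dimensions = 360 trials, 64 channels at 512 Hz.

A single latent appeal variable per participant × image drives everything:

    latent[p, i] = group_mean[g(p)] + person[p] + image[i] + idio[p, i]

with group means (−0.9, +0.8, −0.4 for never/current/past; SD 0.5 between
participants), image effects (SD 0.5) shared across participants, and
idiosyncratic terms (SD 0.5). Through the default rating transform
(rating = clip(30 + 22·latent + N(0, 10), 0, 100)) these group means land
near the observed real-data pattern of mean ratings (≈10 / 48 / 22 for
never/current/past), and the shared image effect produces the positive
image-level correlation between Yes counts and ratings.

* **Responses**: Yes with probability logistic((latent_d − θ_d)/τ), where
  latent_d adds per-dimension jitter (SD 0.4) and θ = 0.25/0.0/0.5 for
  appealing/curiosity/wanting (wanting hardest to endorse), τ = 0.6.
* **Ratings**: the affine transform above, rounded and clipped to [0, 100].
* **EEG**: epochs are ongoing-noise surrogates — spatially correlated
  1/f^α noise (α = 1, channel correlation ρ^|i−j| with ρ = 0.5, 80% of
  variance) plus white sensor noise (20%), scaled to 10 μV per-channel SD.
  Pink noise is synthesised spectrally (complex-normal coefficients shaped
  to the target spectrum at a fast FFT length, truncated to the epoch).
  Two deterministic components are injected, amplitude-modulated by the
  same latent appeal: a strong late one (440–860 ms) at
  `signal_amplitude` μV per unit latent and a weak early one (100–300 ms)
  at 0.4× that, both on a unit-norm occipital/parieto-occipital channel
  pattern with a half-cosine envelope (zero at the window edges, so
  decodability does not jump discontinuously at window borders).

Because responses, ratings and EEG amplitude share the latent variable,
trials answered Yes carry larger injected amplitudes and all three
behavioral measures are mutually consistent — the property the decoding
stages are supposed to recover.

**On the amplitude scale.** `signal_amplitude` is expressed per unit of
latent appeal, but the decodable quantity is the *class contrast*: the
difference in mean latent between Yes and No trials, which the logistic
response model dilutes to ≈0.6 latent units at the defaults, spread over a
unit-norm pattern (≈0.35/channel) and a half-cosine envelope. The default
(1.5 μV) therefore yields a realistic, *hard* decoding problem near the
detection floor; the recovery and topography tests use 25–60 μV per unit
latent so that a 20-participant study recovers the component decisively,
and the calibration tests use 0. These are per-unit-latent scales, not
single-trial ERP amplitudes.

**What the generator does not emulate**: eye/muscle artifacts, channel
drop-outs, non-stationary noise, source geometry (no head model — the
spatial pattern is an abstract channel weighting), serial dependence
between trials, or realistic reaction-time structure. Passing tests
therefore establish the *statistical machinery* (calibration, error
control, recovery, localization), not robustness to real-world artifact
structure.

## Problem sizes used by the calibration checks

The chance-calibration and error-control checks run at a reduced,
desk-scale size: 30 evenly spaced
windows of the 112-window grid, 3-fold CV × 1 repetition, 20 participants;
the familywise-error simulation uses 100 independent null studies with 60
balanced trials each and 500 cluster permutations. Monte-Carlo standard
errors treat participants (or studies) as the independent replication
unit, since windows share trials.

## Known limitations

* The SVR null distribution is only asymptotically centred on zero;
  with very few trials or folds the pooled-prediction correlation has
  visible variance (SD ≈ 0.1 at 120 trials), which is why chance is
  always established empirically rather than assumed.
* Cluster-level inference licenses statements about the *cluster*, not
  about individual windows inside it; the reported per-window mask is the
  conventional display, not window-wise inference.
* Feature-weight maps rank prediction importance, not neural sources.
* The behavioral ANOVA uses classical equal-variance post hocs;
  heteroscedastic groups would call for a Welch variant (configurable).
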