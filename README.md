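# erpdecode

Moving-window multivariate decoding of epoched EEG, built for studies that
ask *when* a stimulus property or an upcoming decision becomes readable
from single-trial brain activity — for example, whether young people's
Yes/No judgements of e-cigarette product images (appeal, curiosity,
wanting) and their 0–100 product ratings can be predicted from the first
second of neural processing.

The package provides, as a library with a thin CLI on top:

* **`erpdecode.epochs`** — an epoched-EEG data model
  (trials × channels × samples, μV) with trial metadata, prestimulus
  baseline subtraction, ±150 μV amplitude rejection, per-dimension trial
  selection, and a lossless on-disk container (JSON header + float32).
* **`erpdecode.mvpa`** — per-participant decoding: the epoch is tiled with
  10-ms windows; within each window a linear SVM classifies Yes/No
  responses (mean accuracy over 10×10-fold stratified CV, classes balanced
  by subsampling) or a linear SVR predicts ratings (Fisher-Z of the
  correlation between pooled held-out predictions and truth,
  z = atanh r). Shuffled-label re-runs of the identical machinery give
  each participant an empirical chance series.
* **`erpdecode.group`** — group inference: per-window one-tailed paired
  t-tests of true vs shuffled-label performance, corrected across windows
  by a cluster-mass permutation test (sign-flipping of participant
  difference series, add-one p-values, exhaustive enumeration available),
  plus feature-weight topographies (channel-standardised absolute weights)
  for significant clusters.
* **`erpdecode.behavior`** — group descriptives, one-way ANOVAs with
  Bonferroni post hocs, and image-level choice–rating correlations.
* **`erpdecode.simulate`** — a synthetic study generator: spatially
  correlated 1/f noise epochs with two injected components (weak
  100–300 ms, strong 440–860 ms) whose amplitude, the Yes/No responses and
  the ratings all derive from one latent appeal variable per
  participant × image — so every stage has a known ground truth.
* **`erpdecode.calibration`** — signal-free end-to-end checks: empirical
  chance levels of both decoders and the familywise error rate of the
  corrected pipeline.

In brief, per participant *s*, window *w* and CV fold the classifier is a
soft-margin linear SVM (C = 1, features z-scored with training-fold
statistics); decodability is established not by accuracy magnitude but by
the group-level contrast Δ(s, w) = acc_true(s, w) − acc_shuffled(s, w),
tested with one-tailed paired t and cluster-mass permutation
(max-statistic null over sign flips, p = (1 + #{M_perm ≥ M_obs})/(1 + N)).

## Worked example

```bash
python examples/03_group_inference.py
```

simulates a 10-participant study (120 images, 32 channels) with a strong
late component injected at 440–860 ms on the last four channels, decodes
every eligible participant, and runs the corrected group test:

```
10 of 10 participants eligible (≥ 20 trials per class)

clusters (forming threshold p<0.05, one-tailed):
     456..   827 ms  mass  224.1  p = 0.001 *
corrected-significant windows span 456-827 ms (injected: 440-860 ms)

top channels by standardized |weight| in the first cluster:
   CH28  z = +1.85 *
   CH31  z = +0.76 *
   CH30  z = +0.44 *
   CH27  z = +0.30 *
   CH29  z = +0.21
   CH20  z = +0.05
(generator injected on: CH28, CH29, CH30, CH31)
```

The significant cluster covers the injected interval (its edges are soft
because the component has a half-cosine envelope and carries little energy
there), and the weight topography ranks the four channels carrying the
simulated signal on top — with CH27 illustrating the nominal false-positive
rate of the uncorrected per-channel test.
`examples/01`, `02` and `04` walk through the generator, a single
participant's decoding time course, and the behavioral statistics.

The same pipeline runs from the shell via a JSON config:

```bash
erpdecode simulate -c run.json
erpdecode decode   -c run.json --mode svm --dimension all
erpdecode group    -c run.json --mode svm --dimension all
erpdecode behavior -c run.json
erpdecode report   -c run.json
```

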