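# Methods

`fidgetlab` studies the automatic recognition of fidgety movements (FMs) —
the small-amplitude, moderate-speed, multidirectional spontaneous movements
of infants around 10–20 weeks post-term whose absence predicts neurological
disorders — from two sensing modalities: four limb-mounted 6-channel IMUs
(3-axis acceleration + angular velocity, 200 Hz native) and a 33-keypoint
3-D pose track at 30 Hz. Because real clinical recordings of this kind are
not publicly available, the package ships a synthetic-cohort generator that
reproduces the *statistical structure* of such a study — most importantly
the subject-identity confounds that cause shortcut learning — so that the
preprocessing, the three classifier families, and the disentanglement
evaluation are all testable end to end.

## The synthetic cohort generator

Each subject is a draw from explicit distributions
(`fidgetlab.config.CohortConfig` holds every constant with units):

* **Recording durations** follow a truncated normal, mean 447.62 s,
  SD 112.77 s, truncated to [137, 936] s. Cohorts default to 95 subjects
  with an at-risk prevalence of 6/95.
* **Gross movement** (the large, slow motor background that FMs ride on)
  is, per limb, a 3-component latent built from four sinusoids drawn in
  0.1–0.7 Hz plus heavily smoothed noise, normalized to unit RMS and scaled
  to 2 m/s² (accelerometers), 1 rad/s (gyros, via the latent's derivative)
  and 5 cm (pose). Keeping the gross spectrum well below 2 Hz is what makes
  the fidgety band observable at all; early designs with gross content up
  to 1 Hz leaked enough spectral energy into 2–6 Hz to mask the bursts.
* **Fidgety bursts** are band-limited oscillations (default 2–6 Hz) with
  amplitude 20% of the gross amplitude — the top of the "small relative to
  gross movement" range the model assumes — rendered as 1–3 s tones with a
  flat-topped Tukey envelope, placed by a renewal process at 30–40
  bursts/min so that fidgety periods are near-continuously oscillatory
  (clinically, continual FMs pause only for a second or two). Each burst
  has a primary limb (weight 1) and spreads to the others (weight 0.5),
  mirroring how FMs progress through the body.
* **Annotations** alternate FM+/FM− segments with exponential durations
  (mean 15 s for FM+, scaled to make FM time cover 63.6%), plus
  Poisson-placed invalid periods covering ~5% of the record. After
  windowing, this yields the ≈64/36 FM+/FM− window balance the protocol
  assumes.
* **Identity confounds**, applied with strength `confound_strength`
  ∈ [0, 1]: per-sensor placement rotations (10° jitter SD), per-channel
  baseline offsets (0.5 m/s², 0.2 rad/s), body scale and movement-vigor
  scale (lognormal, σ = 0.15 and 0.6), a mat-position offset for the pose,
  subject-specific burst-frequency centers, and subject-specific channel
  patterns blended with the canonical ones. When confounded, non-fidgety
  periods additionally contain *distractor* oscillations in the subject's
  second band at 0.75× the FM amplitude, so no population-level spectral
  rule separates the classes on an unseen subject — within a subject the
  classes stay separable, which is exactly the structure that rewards
  shortcut learning. The per-burst frequency SD is deliberately wide
  (0.6 Hz) so identity is expressed mainly through amplitude, orientation
  and offsets rather than through frequency alone; a movement
  representation then need not identify the subject.
* **Noise** defaults are 0.001 m/s² (IMU) and 1 mm (pose), understood as
  effective noise after device-side filtering; the fidgety bursts are
  resolvable by the sensors, as they must be for a cue that clinicians can
  see with the naked eye.
* Per-sensor clock offsets (SD 0.05 s) are synchronization artifacts, not
  identity, and are corrected by the alignment stage.

What the generator does **not** emulate: real tracking dropouts and outliers
(an optional quiet-period pose-jitter mode exists but is off by default),
gravity components and sensor saturation, infant posture/biomechanics, and
any clinical scoring beyond the binary risk flag. A passing test suite
therefore shows that the *pipeline and the statistical machinery* behave as
designed under the stated structure — not that any classifier would reach a
particular accuracy on clinical data.

## Preprocessing

IMU streams are aligned to the pose reference clock by maximizing the
normalized cross-correlation of movement-intensity traces (mean-removed RMS
across channels) over integer lags in ±2 s, ties toward zero; resampled to
100 Hz by linear interpolation; pose stays at its native 30 Hz. Annotations
become per-frame labels on the 100 Hz grid (half-open intervals, invalid
precedence). Non-overlapping 1-s windows anchored at integer seconds take
the modal frame label if it reaches 60% of frames — ties and sub-threshold
windows are excluded, invalid-majority windows discarded — yielding per-IMU
100×6 and pose 30×99 frames. The majority is computed on the 100 Hz grid
(the finest common grid); the threshold is ≥ 0.6 and configurable.

## Hand-crafted features

29 descriptors per channel (23 time-domain, 6 spectral), concatenated to
696 / 2871 / 3567 dimensions for IMU / pose / both. Definitional choices
are documented in `fidgetlab.hcf`; notable ones: spectra are un-windowed
FFTs of the mean-removed segment normalized so spectral energy equals the
time-domain energy of the mean-removed signal (Parseval, tested); sample
entropy uses m = 2, r = 0.2·SD, Chebyshev distance, 0 for constant signals
and capped at log n when no template matches; permutation entropy is order
3, delay 1, normalized to [0, 1]. The random-forest search space is a
documented stand-in (the published one is not available); candidates are
scored with subject-grouped inner validation and the winner refit.

## The CNN and the adversarial disentanglement

The multi-branch CNN (one branch per sensor stream; 4 IMU / 1 pose / 5
both) defaults to two conv layers (32, 64 filters, kernel 5), max-pool 2,
flatten, and a 128–64–2 dense head with dropout 0.3 and l2 1e-4, trained
with Adam at 1e-4 for 100 epochs, batch 64. The best epoch maximizes the
mean of train and test accuracy — this test-set peeking reproduces the
study protocol deliberately and is flagged here. Subject-disjoint splits
are enforced with a hard error. Both models run on a small reverse-mode
autodiff core (`fidgetlab._nn`) written for this package and verified
against finite differences.

CSAD feeds the backbone features to two β-VAEs producing a movement code
z_m and a subject code z_s; a movement MLP classifies FM from z_m, a
subject MLP classifies training-subject identity from z_s, adversarial
MLPs try to decode FM from z_s and subject from z_m, and a joint decoder
reconstructs the backbone features from [z_m, z_s] (RMSE). Optimization
alternates per batch: adversary steps on frozen codes, then a main step on
the weighted objective. Defaults follow the architecture as described
(negative adversary cross-entropy, λ_adv 0.5, β 1.0, latent 64/64);
experience at desk scale motivated several config switches, all
off-by-default:

* `adv_objective="confusion"`: the encoder minimizes the adversary's
  cross-entropy toward a *uniform* target instead of maximizing its
  true-label cross-entropy. Pure CE maximization has a degenerate optimum —
  anti-predictive codes that keep subject clusters intact while the
  adversary is confidently wrong — which we observed reliably; the
  confusion objective's optimum is genuinely uninformative codes.
* adversarial heads own their hidden layers (a linear probe on a trunk the
  encoder controls is too easy to fool), `adv_steps`/`adv_lr_scale` let the
  adversary track the moving codes, and `adv_warmup_frac` ramps λ_adv so
  task features form before the scrubbing pressure peaks.
* `rec_detach_movement` routes the reconstruction gradient through z_s
  only, removing the decoder's incentive to park identity in z_m.
* `task_weight_movement` stabilizes the FM head against strong adversarial
  pressure.

Downstream representations use the posterior mean; subject heads cover
training-fold subjects only.

## Evaluation

Subject-level stratified folds (at-risk subjects dealt round-robin, then
sizes balanced within one); accuracy, macro-F1 (AF1), sensitivity,
specificity and precision in percent with FM+ positive; Friedman rank test
with tie correction and Nemenyi post-hoc from the studentized-range
distribution; Bonferroni-corrected α reported to four decimals (0.05 over
nine approach×modality configurations gives 0.0056).

Average Neighborhood Entropy (ANE): for each sample, the Shannon entropy
(bits) of the label proportions among its k nearest neighbors (k = 10,
Euclidean, exact search, self excluded, distance ties broken by index),
averaged over samples. Bounded by log₂(min(k, L)); low subject-label ANE
means subject clusters.

## The scaled-down recovery study

`fidgetlab.evaluation.recovery_study` reproduces the study's central
finding at desk scale: 10 subjects × 60 s, IMU modality, one fold of the
stratified 5-fold split (8 train / 2 test subjects), a confounded cohort
(strength 1) and its clean twin (strength 0). Problem sizes and training
schedules are chosen for a single CPU: compact branches (16/32 filters,
kernel 9 — a receptive field covering one cycle at the band center — with a
jerk first-difference input encoding that spectrally rebalances the slow
gross movement against the fidgety band), learning rate 1e-3, batch 32,
30 CNN epochs, and for CSAD 70 epochs with latents 8/8, β 0.05, confusion
objective at λ_adv 3 ramped over half of training, reconstruction detached
from z_m and movement-task weight 2.

Expected signature, verified by the acceptance tests over three seeds:
every approach shows a train−test accuracy gap above 15 points when
confounded and recovers (test within 10 points of train) when clean; the
CNN embedding clusters by subject while the movement code's subject-ANE
exceeds it; the concurrent adversarial probe decodes training-subject
identity close to the 1/n chance level. One caveat is intrinsic to any
world whose train−test gap is driven by subject-conditional cues: a
representation that supports within-subject movement rules cannot be made
perfectly identity-free, so a fully converged fresh probe still recovers
some identity from z_m; the packaged probe quantifies what the adversarial
game itself leaves decodable.

## Numerical choices and degenerate inputs

Zero-variance signals yield zero for variance-normalized descriptors;
empty or sub-window recordings produce empty datasets with warnings;
posterior log-variances are clipped to ±10 before the KL; Friedman tie
corrections that zero the denominator return a zero statistic; precision
with no positive predictions is 0 with a warning. All randomness derives
from one root seed via SHA-256 labelled sub-seeds (31-bit), so every stage
can be re-run in isolation.
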