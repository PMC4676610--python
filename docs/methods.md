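# Methods

This note documents the models, conventions, and design choices behind
gaitguard: what the synthetic data emulates, how each feature is defined,
how the forest and the trial protocol are specified, and where the design
was genuinely open.

## The problem

A smartphone classifier distinguishes sitting from walking using 50 Hz
accelerometer and gyroscope streams. Users have incentives to deceive it —
shaking a phone while seated to log "activity", or walking smoothly so a
monitored activity goes undetected. The defence studied here is
adversarial retraining: let a subject cheat, fold the deceptive sensor data
(labeled with the *true* activity) back into training, and repeat until
cheating fails. The cross-subject question is whether deceptive data from a
few subjects makes the classifier robust to the deception of *others*.
Because no raw sensor recordings of such experiments are publicly
available, the package generates its own cohort synthetically and treats
the qualitative behavioral anchors — near-certain first-round deception,
declining success under retraining, expert-over-baseline dominance — as the
properties its tests enforce.

## Synthetic IMU model

Each subject is a parameter bundle: gait fundamental (step frequency,
uniform on 1.4–2.2 Hz), vertical gait amplitude (2–4 m/s²), harmonic
weights for components k = 1–3, resting accelerometer noise (0.05–0.15
m/s²), a gyro gain coupling rotation to the gait template (0.25–0.55), a
fidget rate (0.05–0.2 events/s), and a habitual phone orientation. Ranges
are simulator choices tuned once so that normal sitting and walking are
cleanly separable per subject while baseline classifiers remain fully
deceivable (the two calibration properties below).

**Gravity and orientation.** The accelerometer always contains gravity:
|g(t)| = 9.81 m/s² exactly, pointed by the subject's habitual carry
orientation plus a small per-session static jitter (sd 0.02 rad tilt, 0.05
rad azimuth) plus slow in-session wobble (two sub-Hz sinusoids). Modeling
orientation as a *subject* trait rather than a per-session draw matters:
with one session per class in training, any session-constant quantity (an
axis mean, a planar-angle mean) would otherwise separate the classes
perfectly in training and arbitrarily on fresh streams, making trial
outcomes flip all-or-nothing on the orientation draw. The wobble amplitude
for sitting scales with the subject's resting noise so the documented
noise-free limit (zero noise, no fidgets ⇒ constant-magnitude gravity, zero
gyro) holds exactly.

**Normal activities.** Sitting = gravity + white noise + sparse
Gaussian-windowed fidget bumps. Walking = gravity + a vertical harmonic
stack at k·f plus weaker lateral components at f (so the dominant spectral
line is the step frequency), correlated gyro oscillation scaled by the gyro
gain, and heavier noise.

**Deceptive strategies.** Fake-walking kinds superimpose motion on a seated
base; every accelerometer axis and the gyro are excited (multiplicative
direction jitter keeps all components bounded away from zero — a hand shake
never leaves an axis still, and a single quiet channel would trivially
expose the cheat):

- `shake_linear` — bounce along a mostly-vertical direction with a second
  harmonic;
- `shake_circular` — exact quadrature between X and Y (circle drawing);
- `shake_rotational` — gyro-dominant wrist rotation, with gravity swinging
  across the accelerometer axes;
- `pocket_torso` — a gait-template imitation from torso rocking.

Fake-sitting kinds modify a walking base: `smooth_walk` attenuates and
low-pass-filters the dynamic part by `smoothing` s (gain (1−s) plus a
one-pole filter with coefficient s; the gyro is suppressed less, by 0.7·s,
since rotation is harder to cancel by hand), `pace_shift` multiplies the
step frequency by `pace_factor`, and `hand_damped` walks at a reduced
amplitude.

**The adaptive adversary.** `adapt_strategy` scores the incumbent strategy
plus n candidates (perturbations of the incumbent with log-normal jitter,
and novel draws over the allowed kinds and parameter ranges) by their
success rate on a short probe stream classified frame-by-frame, and returns
the argmax; ties keep the earliest candidate, hence the incumbent. Because
the candidate distribution is identical in every round while the classifier
only accumulates training data, the achievable maximum success is
non-increasing in expectation — this is what produces the declining success
curves without any scripted schedule.

## Features (260 per frame)

Frames are 200 samples (4 s) with 75% overlap (hop 50 = 1 s); trailing
partial frames are discarded. Per sensor and axis: mean, abs-mean, RMS;
standard deviation, skewness, excess kurtosis (biased 1/n moment
estimators, defined as 0 when the variance is 0); the same four moments of
the unscaled first difference; min, max, abs-min, abs-max; counts of the
z-scored signal in 6 unit bins spanning [−3, 3] (out-of-range samples are
clipped into the end bins so counts always sum to the frame length; a
zero-variance signal puts all mass in the [0, 1) bin); magnitudes of the
unnormalized length-200 DFT at 1-based components 2–20 (0.25–4.75 Hz).
Per sensor: the mean over the frame of the per-sample 3-axis Euclidean
magnitude (orientation-free energy summary); for each axis pair the mean
and abs-mean of (a) the full cross-correlation sequence over all lags
−199…199, each lag normalized by the geometric mean of the two windows'
zero-lag energies (defined as 0 if either axis has zero variance), and (b)
the planar angle series θ_AB(t) = atan2(B(t), A(t)).

Two of these definitions — the "angular cross-correlation" and the
"overall mean" — have no canonical definition in the activity-recognition
literature; the readings above (planar-angle summary; magnitude mean) are
explicit stand-ins chosen to yield exactly 6 and 1 features respectively,
and are localized in the schema so either can be swapped without
renumbering the remaining features.

## The forest

200 trees by default, each grown on a bootstrap resample of the training
set (uniform with replacement, same size); at every node 16 of the 260
features are drawn without replacement and the split maximizing entropy
information gain over midpoint thresholds between consecutive distinct
values is taken. Nodes stop when pure, smaller than 2·min_leaf (min_leaf =
1), at the optional depth cap, or when no split has positive gain — i.e.
fully grown trees, the common random-forest default. Determinism
conventions: split ties break toward the lower feature index then the lower
threshold; prediction ties toward the first class label ("sitting"
alphabetically). The ensemble's confidence is the vote fraction of the
winning class, which is why the trees are hand-grown: off-the-shelf
ensembles average leaf probabilities instead of counting votes, and do not
pin down the tie-break conventions the JSON round-trip and the
exhaustive-search oracle tests rely on. The split criterion is an enum so a
Gini alternative can be added without interface change.

Models serialize to versioned JSON (nested node records, full float
precision); parsing restores a predictor with bit-identical predictions.

## Trial protocol

Evaluations happen once per second, each classifying the most recent
complete 4-s frame, so the first evaluation is at t = 4 s and — with the
1-s hop — evaluations and frames are one-to-one afterwards; warm-up seconds
before the first complete frame are not counted. A trial ends when either
detected class reaches 150 or after 300 evaluations (5 minutes), whichever
comes first. Success rate is the fraction of evaluations whose output
differed from the true activity; strictly above 50% counts as success.

The personal experiment trains on one sitting and one walking session, then
loops: adapt a fake-walking strategy, run the trial; adapt a fake-sitting
strategy, run the trial; if the round succeeds, retrain and continue, else
stop (10 rounds maximum). Two ambiguities in the protocol are exposed as
configuration rather than resolved silently:

- *End rule.* "Not successful in a deceptive activity trial" can mean any
  failed trial ends the experiment (strict, the default) or only a round
  with both trials failed (lenient, `end_rule="lenient"`).
- *Retraining data.* Retraining can use all deceptive frames accumulated so
  far (cumulative, the default — consistent with the growing-dataset
  framing and with the global expert training) or only the last round's
  (`retrain_mode="last_round"`).

Deceptive frames from *failed* trials are also kept in the cumulative
record: the data was observed either way, and the cross-subject evaluation
needs deceptive frames even from subjects who never succeeded.

## Evaluation

For each number of training subjects n = 1 … cohort−1 and each repeat, a
random train/test subject partition is drawn (at n = cohort−1, repeats
enumerate the held-out subject instead, using the cohort fully). The
baseline classifier trains on a bootstrap of the training subjects' normal
frames; the expert on a bootstrap of the pooled normal + deceptive frames
of the *same* partition, down-sampled to the same size (the baseline pool's
size — the conservative direction, since that pool is always available).
Accuracy on deceptive data counts a frame correct when the prediction
equals the subject's true activity. Sensitivity/specificity use walking as
the positive class (a documented convention; the protocol does not fix
one). Undefined ratios (empty denominators) are reported as NaN, never 0.

`embed_2d` is a 2-component maximum-likelihood factor analysis on
standardized features (zero-variance columns dropped), used to visualize
normal-vs-deceptive frame clusters and their drift across trials;
standardization is the default because the 260 features span wildly
different scales.

## Problem sizes and calibration

The test suite and the acceptance script run the full protocol at reduced
problem sizes — 60-s sessions and trials (30-evaluation class cap), 20-tree
forests, an 8-subject cohort, 8 adversary candidates with 8-s probes, 5
sweep repeats — chosen so the complete battery finishes in a few minutes on
one CPU while leaving every rule of the protocol intact; the stop-rule and
framing checks still use the full 5-minute / 300-evaluation geometry, which
is cheap with stub classifiers. Under these conditions the two calibration
properties hold with margin: mean round-1 deception success is ≈ 98–99%
(declining to ≈ 0–20% after one retraining and to ≈ 0 at failure), and
held-out normal-activity accuracy is ≈ 99–100%.

## What passing tests do and do not show

The generator reproduces the *structure* of the phenomenon — deceivable
baselines, cross-subject generalization of deceptive signatures, no harm on
normal data — but its streams are far cleaner than human motion: strategies
are stationary sinusoid families rather than nonstationary improvisation,
within-subject variability is low, and every subject eventually fails
because the strategy space is bounded. Consequently the synthetic
baseline-vs-expert gap (≈ 2% vs ≈ 95–100% on deceptive frames) is wider
than anything to be expected on real recordings, and absolute accuracies
here say nothing about real-world performance; only the ordinal findings
transfer. Numerical edge cases are pinned by convention (zero-variance
moments and correlations, histogram clipping, split and vote tie-breaks) so
that independently written implementations can agree bit-for-bit.
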