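# Methods

`kinectcpt` scores a motion-capture variant of the continuous performance
test (CPT): letters appear one at a time, the examinee raises the dominant
hand after every letter and must stay still after the forbidden letter
`X`.  Because the sensor records the whole hand trajectory rather than a
key press, the engine can time the movement onset precisely, measure how
long a reaction takes to complete, and — crucially — quantify *partial*
failures of inhibition that a keyboard cannot see.  This note documents
the models, the thresholds, and the deliberate design choices behind the
implementation.

## Task designs

Two presets are built in.  The revised design presents 60 letters over
about 3 minutes — 12 `X` (no-go) stimuli and 48 go stimuli — with
inter-stimulus intervals (ISIs) drawn from {2, 3, 5} s.  The legacy design
presents 360 letters with ISIs from {1, 2, 4} s over roughly 15 minutes.
Several scheduling details are open in the task description and are fixed
here as generator policy:

* each ISI is drawn independently and uniformly from the design's ISI set
  (configurable weights are exposed on `DesignSpec`);
* `X` positions are drawn uniformly at random **excluding the first
  stimulus**, so every no-go trial has a preceding trial to normalise its
  commission index against;
* go letters are drawn uniformly from A–Z excluding X;
* the first onset is at schedule time zero; recordings carry a 2 s rest
  lead-in, so session schedules are shifted copies of the design schedule.
* the legacy preset keeps the revised design's 20% no-go proportion
  (72 of 360), as its own split is not specified.

Schedules are deterministic in `(design, seed)` and serialise to JSON
byte-identically.

## Trajectory model and segmentation

Streams are timestamped 3-D positions of one hand joint in the camera
frame (x lateral, y vertical/up, z depth, metres) at a nominal 30 Hz, with
a per-sample `tracked` flag.  Policy decisions:

* **windows** are half-open `[onset, next onset)`; the final window runs to
  the end of the stream.  This partitions the session with no double
  counting, and segmentation is pure bookkeeping — identical inputs give
  identical windows.
* **rest baseline** per trial = median tracked position over the 0.25 s
  before stimulus onset; if that buffer holds no tracked samples the
  fallback is the session-global median x/z and 10th-percentile height.
  A short pre-onset buffer travels with each window so that movements
  that began *before* the stimulus can be recognised.
* **gap policy**: untracked runs shorter than 0.2 s (~6 frames) may be
  linearly interpolated; trials with more than 0.5 s of tracking loss are
  `invalid_trial` and excluded from every median — stillness cannot be
  certified from missing data.

## Movement-onset detection

"The hand starts to rise" is operationalised as a sustained
vertical-velocity threshold with hysteresis:

1. positions are smoothed with a centred 5-sample moving average (~0.17 s;
   disable with `smooth_window=1`) to keep 30 Hz sensor jitter out of the
   velocity signal;
2. vertical velocity is the central difference of height over time;
3. a **rise episode** opens at the first of `k = 3` consecutive samples
   with `v_y ≥ v_min = 0.15 m/s`, closes when `v_y` falls below
   `0.4 · v_min`, and *qualifies* only if the hand rises at least
   `rise_min = 0.05 m` above baseline within the episode — this rejects
   jitter bursts;
4. the reported onset is **backtracked** from the threshold crossing to
   the last preceding sample with `v_y ≤ 0.02 m/s`.  A pure threshold
   report would lag the true movement start by the time the minimum-jerk
   velocity profile needs to reach 0.15 m/s (~1–2 frames); backtracking
   removes that lag, and on noise-free synthetic raises the scored RT is
   within one sample interval of the programmed latency.

Each qualifying episode counts one reaction (`n_reactions`); an episode
that begins inside the pre-onset buffer marks the trial `premature`.  The
peak is the maximum height after onset; the return is the first sample
after the peak back inside the `0.05 m` rest band.

The defaults (0.15 m/s, 3 samples, 0.05 m, 40% release) were chosen once
for a seated child raising a hand ~0.3 m in ~0.35 s under ~2 mm sensor
noise at 30 Hz: the minimum-jerk peak velocity of such a raise is
~1.4 m/s, an order of magnitude above `v_min`, while smoothed jitter
velocities stay well below it.  All thresholds are exposed in
`ScoringParams`.

## Per-trial measures

* **RT** (go trials): movement onset minus stimulus onset.  Premature
  trials and omissions contribute no RT.
* **CT** (go trials): return-to-rest minus onset; absent when the hand
  never returns within the window (partial omission).
* **displacement**: 3-D path length — the sum of Euclidean distances
  between consecutive tracked samples.  "Length of the hand displacement"
  is read as trajectory length, not peak excursion; the peak-excursion
  alternative is kept as `displacement_metric="peak"` for sensitivity
  analyses.
* **commission index** (no-go trials): displacement during the X window
  divided by the maximum displacement in the two neighbouring trial
  windows (the previous one only when the X closes the session).  The
  neighbour windows are their full trial windows — they already partition
  time, so no second window length needs inventing.  The index is
  undefined when the best neighbour moved less than `d_min = 0.05 m`.
  It is scale-invariant and monotone in the X-trial excursion.

Event classes: go trials are `premature_reaction` (precedence first), then
`multiple_reaction` (≥ 2 episodes), then `full_reaction` / 
`partial_omission` / `omission`; no-go trials are cut on the continuous
index at `c_lo = 0.1` and `c_hi = 0.5` into `correct_inhibition`,
`inhibited_commission`, and `commission`.  The cuts only label events —
participant medians always use the continuous index — and both are
configuration, since the boundary between an aborted and a completed
reaction is a reporting convention, not a measurable constant.

A participant is summarised by the **median** RT, CT and commission index
(even-count medians are the mean of the central pair).  A fully compliant
revised-design session yields 48 RT/CT observations and 12 index
observations.

## Synthetic participants

The simulator exists so the whole pipeline is testable without hardware or
clinical data; it generates what the scoring engine consumes, from latent
traits (inattention, hyperactivity, impulsivity on the 0–100 SWAN web
scale):

* **raises** follow a minimum-jerk profile (0.30 m in 0.35 s, 0.1 s hold,
  0.35 s return) — the standard smooth point-to-point reach model, which
  produces realistic velocity peaks for the detector;
* **RT** is shifted-lognormal, `0.15 + exp(N(log 0.45 + β_imp·(imp−50) +
  β_hyp·(hyp−50), 0.3²))` s with `β_imp = −0.004`, `β_hyp = −0.002` per
  trait unit: the canonical positive-skew RT family, with median RT
  falling from ~0.70 s to ~0.52 s across the impulsivity range — the
  direction and rough magnitude of the faster-when-impulsive pattern the
  instrument is meant to detect;
* **omissions** occur with probability `0.01 + 0.001·inattention`;
* **no-go excursions** have amplitude `(0.02 + 0.0012·impulsivity)` m
  times a lognormal(0, 0.5²) jitter, clipped to the raise height, so
  impulsive profiles produce larger aborted movements and occasional full
  commissions;
* isotropic Gaussian sensor noise (sd 2 mm, a typical skeletal-tracking
  jitter at close range) is added to every sample;
* **SWAN items** equal their factor's trait plus N(0, 10²) noise clamped
  to [0, 100] — a single-factor-per-item model, sufficient for factor
  scores to recover traits, and *not* a claim about real SWAN
  psychometrics.

What the simulator does **not** emulate: postural drift, secondary-joint
motion, hand-dominance effects, age/sex structure, learning or fatigue
across the session, and any ADHD-subtype mixture.  Passing tests
therefore certify the *engine* — detection, timing, ratios, statistics —
not the clinical validity of the measures on real children.

## Psychometrics

Factor scores are item **means** (items 1–9 inattention, 10–15
hyperactivity, 16–18 impulsivity), keeping factors on the 0–100 item
scale; sums would only rescale them and leave every correlation
unchanged.  The validity report correlates per-participant medians with
the three factors, Pearson by default with two-sided p-values from the
t transform on n − 2 degrees of freedom (Spearman optional), cells
computed pairwise-complete with per-cell n, no multiple-testing
adjustment by default (a Holm flag is provided).

## Calibration experiments

Two Monte-Carlo properties are checked at fixed problem sizes, chosen so
each completes in minutes on one core:

* **parameter recovery** — 100 replicate cohorts of n = 200 under the
  default negative impulsivity→RT slope; the Pearson correlation between
  median RT and the true impulsivity trait is negative in ≥ 99% of
  replicates (observed mean r ≈ −0.75);
* **type-I calibration** — 200 replicate cohorts of n = 30 (the design's
  natural cohort size) with every trait slope zeroed; the p < 0.05 rate
  for the RT–impulsivity cell must lie in 5% ± 3%.

## Numerical and degenerate-input conventions

Ties in the ISI/letter draws are resolved by the seeded generator;
velocity at stream edges uses one-sided differences; a single-sample
window has zero path length; a window with < 2 tracked samples raises an
invalid-trial signal rather than guessing; onsets backtracked into the
pre-stimulus buffer are clamped to the stimulus onset so RT is never
negative; correlation cells with fewer than 3 complete pairs are reported
as not-computable rather than NaN-propagating.

## Known limitations

The onset detector is tuned for discrete raise gestures; continuous
fidgeting inflates `n_reactions` and can shadow a true reaction.  The
commission index is undefined when both neighbouring trials are
motionless (e.g. flanking omissions), which concentrates exactly in the
inattentive profiles that produce omissions.  The 30 Hz sampling bounds
RT resolution to ~33 ms.  Path length grows with recording noise; the
default smoothing keeps the motionless-window noise floor near 0.05–0.1 m
per 3 s window, visible as a nonzero commission-index floor.
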