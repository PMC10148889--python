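# Methods

This note documents the models, conventions, and design choices behind the
package, in the order data flow through it: synthetic generation → ethogram
classification → photometry normalization and event-locking → avoidance
scoring → statistics. Units are cm, seconds, and fractional ΔF/F
throughout (1% ΔF/F = 0.01).

## Synthetic data: what it emulates, and what it does not

No animal data ship with the package, so every analysis is exercised on
generated inputs with exact ground truth. The generator is a first-class,
tested module, and its defaults define the study conditions used by the
analysis scripts, the test suite, and the acceptance script.

### Tube-test bouts

A bout is a script of labeled episodes (body push, nose push, resist,
retreat, idle) with an actor and a time span, rendered to nose/tailbase
keypoint tracks for two mice in tube coordinates (x along the 30 cm tube;
mouse A enters at x = 0 facing +x, mouse B opposite). Pose capture is
30 frames/s — typical for behavior video, and chosen so that sub-second
analysis windows and the optional 15 Hz software low-pass are meaningful.
i.i.d. Gaussian jitter (default sd 0.05 cm; tested up to 0.1 cm) models
keypoint noise; the likelihood column is emitted as 1.0 (dropout is a
config option on the reader side, where low-confidence frames are
interpolated).

Kinematics are chosen so the classifier's rule predicates hold on exactly
the scripted frames:

- At rest the two noses sit 0.4 cm apart, so the nose-overlap predicate
  needs no approach phase (approach movements would otherwise cross the
  velocity thresholds and create unscripted events).
- A pusher advances nose and tailbase at 4 cm/s. The pushed partner's nose
  yields in lockstep (overlap is maintained) while its tailbase gives
  ground at 0.5 cm/s — below the retreat threshold, so the "partner is not
  retreating" conjunct holds, and below the displacement minimum for
  episodes shorter than 4 s, so the partner *resists* (holds ground). A
  scripted push therefore implies a resist event by the partner, and a
  scripted resist implies a body push by the partner; both appear in the
  ground-truth event list so precision is scored against complete truth.
- A retreating mouse backs away at 4 cm/s — like the push speed, two
  noise-sigma above threshold at the highest supported jitter.
- Between episodes, displaced keypoints glide back to their resting posts
  in two phases: series moving away from the partner return first at
  1.5 cm/s; then the one nose that was displaced backward returns, creeping
  over its final 1.4 cm at 0.5 cm/s. The staggering guarantees no keypoint
  is ever simultaneously overlapping the partner's nose and moving near the
  2 cm/s push threshold, where coordinate noise could otherwise trigger
  spurious push events. Scripts must leave enough inter-episode time for
  these glides; the validator rejects scripts that do not (and, as a
  special case, any per-actor episode overlap).

What this does *not* emulate: 2-D body posture, keypoint identity swaps,
occlusion dropout, or irregular naturalistic velocity profiles. Passing
recovery tests therefore demonstrates that the classifier implements its
rules faithfully and robustly to coordinate noise — not that the rules
themselves capture every real tube-test interaction.

### Photometry

Two channels at 100 samples/s (post-demodulation rate; acquisition-side
lock-in demodulation is out of scope):

    signal  = F0 · e^(−t/τ_bleach) · (1 + Σ transients) + artifact + ε₁
    control = F0 · e^(−t/τ_bleach) · (1 + g · artifact / F0) + ε₂

Transients use the kernel k(t) = (1 − e^(−t/τ_rise)) e^(−t/τ_decay) with
τ_rise = 0.2 s and τ_decay = 1.5 s — GCaMP6s-like dynamics (the sensor's
published kinetics are of this order; the indicator name alone does not
pin them down). Each event's sampled kernel is normalized by its own grid
maximum, so the true peak ΔF/F of an event is exactly its amplitude
parameter; the analytic peak normalization would differ by a few 1e−6 at
100 samples/s, which matters for closed-form tests. Per-event amplitudes
may be negative (needed to model per-animal offsets around a zero group
mean without clipping bias); the scalar default amplitude is non-negative.

The motion artifact is Gaussian noise smoothed with a 2 s kernel
(≈ 0.08 Hz), scaled to 2% of F0, and added to both channels with gain
ratio 1. The timescale matters: a drift-like sub-0.1 Hz artifact is what
the 10 s sliding-median window is designed to track and remove, whereas
artifact power near 0.3–1 Hz passes through both the median and the
baseline subtraction and lands directly in the event amplitude statistic.
The default models the slow regime; `artifact_tau_s` exposes the choice.

Measurement noise is white, sd 0.5% of F0 per channel. This level keeps a
healthy but transient-sparse recording above the 1% ΔF/F spread QC
threshold (at 0.2% the QC rule would flag normal recordings as
expressionless) and is the level at which amplitude recovery is validated.
Bleaching τ defaults to 3000 s (slow within a 150 s trial).

### OFSI sessions and cohorts

Each animal gets two 150 s trials in a 44 × 44 cm arena (arena size is a
convention; chamber 10 × 6.5 cm at the far wall, 24 × 14 cm interaction
zone centered on it, 9 × 9 cm corner zones on the opposite wall). A
session realizes a requested occupancy profile by construction: scheduled
zone visits (confined reflected random walks inside a safety margin)
joined by straight travel segments, with corner trips routed through a
waypoint so a path can never clip the other corner zone. Dwell lengths are
corrected for the travel frames spent inside the zone, so realized
occupancy lands within a couple of frames of the request; the trial-2
interaction-zone entry count equals `n_entries` exactly (zero requested
interaction time forces zero entries). Requests whose zone times plus
travel allowance exceed the trial are rejected.

Cohort defaults (per-trial interaction s, corner s, trial-2 entries):
resilient (45, 60; 8, 8; 6), control (45, 55; 8, 10; 6), susceptible
(45, 10; 10, 45; 3), each jittered ±10% per animal. Entry-locked transient
peak amplitudes are 0.05 / 0.01 / 0.00 ΔF/F for resilient / susceptible /
control — the resilient-selective activation pattern — plus a per-animal
offset (sd 0.005, half the susceptible effect; gives the mixed model a
genuine random-effect structure) and per-event jitter (sd 0.002).

The trajectories are random walks, not mice: no thigmotaxis, grooming
bouts, or speed–turning coupling. Classification accuracy on these cohorts
validates the score arithmetic and its sign conventions, not the ethology.

## Ethogram classification

Velocities: low-confidence keypoints (< 0.6) are linearly interpolated
(contiguous gaps > 1 s invalidate the bout); positions are smoothed by a
centered moving average of 5 frames (truncated at edges); central
differences × fps give cm/s; the sign convention multiplies by the mouse's
facing so positive always means toward the partner.

The four predicates are evaluated per frame and per mouse exactly as
listed in the README. Two of them are epoch-level: a candidate retreat run
(frames with tailbase velocity ≤ −2 cm/s) counts only if its net backward
displacement reaches 2 cm, and a resist spans the partner's push epoch
when the focal animal's displacement over that epoch stays below 2 cm.
Run-length encoding, merging of gaps < 0.3 s, and a 0.2 s minimum duration
produce the event list; body push takes precedence over nose push on any
frame. The numeric thresholds are conventions exposed in
`EthogramConfig` — the scoring protocol this implements specifies that
thresholds exist, not their values. "Resist" in particular is undefined in
that protocol and is implemented as the documented holding-ground
interpretation above.

A frame-wise brute-force reimplementation of the same rules (plain Python
loops in `tests/oracles.py`) must produce identical intervals on random
bouts; this guards the vectorized implementation.

Wins: rear paws are not tracked, so the loser is detected by its tailbase
exiting the tube span on its own entry side by > 1 cm while the partner's
tailbase is still inside; the first such frame decides, and a simultaneous
double exit is no-decision. Ranks are daily win counts (round robin);
two-way ties break by head-to-head, anything else shares a rank and is
flagged unresolved. Stability is the first day of four consecutive
identical rank permutations.

## Photometry analysis

The isosbestic fit is affine (slope + intercept) least squares over the
whole recording; affine absorbs LED-power and offset differences between
channels and makes the normalization invariant to rescaling of the
control. Note one consequence verified in the tests: with many transients
the intercept absorbs the session-mean transient activity, so *absolute*
ΔF/F peaks are biased low by that mean — event-locked analysis is
unaffected because every trace is baseline-shifted, but raw peak readouts
must be taken baseline-relative.

The sliding median uses a centered window of ± 5 s, truncated at the
recording edges (not reflected; affects only the first and last 5 s). The
QC spread uses linear-interpolation percentiles — the convention matters
because exclusion sits on a hard 1% threshold — and exclusion is
spread < 0.01, i.e. a spread of exactly 0.01 is retained.

Event windows are sampled by nearest-sample alignment to onset (no
resampling). Baseline windows are [−1, 0] s (tube) and [−1.5, −1.0) s
(post-CSDS); amplitude is the mean over [0, 4] s of the baseline-shifted
trace. Tube mode includes only bouts strictly longer than 15 s ("longer
than 15 s" read as strict) and has no refractory rule; post-CSDS mode
excludes events < 3 s after *any* prior event in the stream, included or
not. Exclusions carry reason codes (short_bout, refractory,
window_out_of_range) and are logged in the run manifest.

With τ_rise = 0.2 s and τ_decay = 1.5 s, the [0, 4] s mean of the
peak-normalized kernel is 0.4595; an injected peak difference δ therefore
appears in the amplitude statistic as 0.4595 δ, and recovery is always
assessed against that closed-form expectation
(`kernel_amplitude_fraction`). Under the default artifact, per-event
amplitudes carry ≈ 0.005 ΔF/F of correlated noise — the dominant error
term in cohort-level contrasts (single-run recovery errors of 5–15% are
typical; the calibration script quantifies this).

## Avoidance scoring

Components are z-scored across the *scored* cohort only — stressed
animals; unstressed controls are never scored (switchable). Sample
standard deviation uses n − 1; with that convention a two-animal cohort
yields components of ±1/√2, not ±1. Corner durations sum both corner
zones. Zone membership uses the centroid with closed boundaries; an entry
is an outside→inside transition, with a trajectory that starts inside
counting as an entry at t = 0 (the same detector serves partner entries in
the forced-interaction task). Animals with a zero trial-1 denominator are
flagged and excluded from the z-population rather than failing the cohort.
A composite of exactly 0 is labeled resilient with a tie flag (only
"above zero" is defined as susceptible).

## Statistics

Welch's t and the iterative two-sided Grubbs filter are implemented from
their closed forms (Grubbs critical value from the t quantile at
α/(2n); iteration removes the single most extreme point until nothing
exceeds the critical value or n = 3, applied per experimental group).
Fisher's exact test delegates to scipy and is checked against exhaustive
hypergeometric enumeration. Bonferroni is min(1, m·p).

The group mixed model is `amplitude ~ group + (1 | mouse)`, REML via
statsmodels MixedLM (optimizer fallback chain bfgs → powell → lbfgs → nm;
the first-choice optimizer occasionally converges to a degenerate point on
small balanced designs, which the fallback ordering avoids). The reported
degrees of freedom use the residual convention n_events − n_fixed_params,
matching how integer dfs are conventionally reported for these event-level
contrasts; p-values come from the t distribution at that df. Calibration:
the injected δ = 0.04 design (10 mice × 8 events per group, mouse sd 0.01,
residual sd 0.01) is recovered to ~1–2% on average, and the null rejection
rate at α = 0.05 sits near 0.05–0.06 — slightly anticonservative, as
expected for Wald tests with moderate cluster counts. Repeated-measures
two-way ANOVA is a thin delegation to statsmodels AnovaRM and is exercised
only in integration tests.

## Pipelines and reproducibility

Both workflows generate their raw data, write it in the exchange formats
(DeepLabCut-style CSV, photometry CSV/HDF5, tidy tables), read it back
through the same readers a user would call on real data, and analyze the
re-read copies — so the format round trip is on the tested path. A run
manifest records the config snapshot, seed, file checksums, per-stage row
counts, and every reason-coded exclusion; identical seeds give identical
manifests and output checksums. All randomness flows from
`numpy.random.SeedSequence` children of the single run seed.

Problem sizes in the shipped scripts and tests — 60-bout round-robin
studies, 30-animal cohorts, 200-bout recovery runs, 50-cohort
classification sweeps, 100-simulation recovery and 1000-replicate null
calibration for the mixed model — are chosen so the full suite completes
in about a minute on one CPU while keeping Monte-Carlo error comfortably
inside the tolerances being asserted.

## Known limitations

- The bout renderer is 1-D and piecewise-linear; it cannot script
  simultaneous independent episodes for both mice (the validator enforces
  global episode spacing), and win-by-exit must be scripted as a long
  closing retreat.
- The sliding median only removes artifact slower than roughly a tenth of
  its window; faster artifact contaminates single-channel amplitudes, as
  quantified in the calibration script. The isosbestic path removes shared
  artifact of any speed but requires the control channel.
- The avoidance score's z-normalization makes labels cohort-relative:
  the same animal can change label in a different cohort. This mirrors the
  score's definition, not a defect.
- The mixed model reports a single random-intercept structure; random
  slopes, crossed effects, and small-sample df corrections
  (Satterthwaite/Kenward-Roger) are out of scope.
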