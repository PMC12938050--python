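# Methods

## Scope and data model

`huddlekit` consumes post-tracking output only: per-frame 2-D keypoints for
exactly four animals. An animal's position is its **body-center** keypoint —
the only single point that is stable across postures — and its heading is
`nose − body center` where a nose keypoint exists. Coordinates are continuous
centimetres in the image convention (origin top-left, x rightward, y
downward); frame indices are 0-based and all ranges half-open. Identity
correction, pose refinement and video decoding are out of scope: the package
assumes tracks whose identities have been verified upstream, which is also
why analyses are typically restricted to a verified leading portion of a
recording (`analyzed_range`).

Missing detections are *invalid* frames. `interpolate_gaps` fills interior
invalid runs of at most `max_gap` frames (default 15, i.e. 0.5 s at 30 fps)
by linear interpolation; longer runs and runs touching either end are left
invalid — no extrapolation, and valid frames are never altered.

### Kinematics

Per-frame speed is a central difference on the body center (one-sided at the
ends); a frame's speed is invalid if any frame in its stencil is invalid.
Path length sums consecutive valid raw steps. The **maximum** speed is read
from a 5-frame median-filtered copy of the positions: without the filter,
single-frame tracking jitter dominates the max. The filter is applied only
for that readout; per-frame speeds and path lengths stay raw so they remain
consistent with the underlying track.

## Huddle definitions

All criteria live in `HuddleCriteria` (defaults: distance 5 cm, duration
60 s, entry radius 3.5 cm, entry sustain 1 s). Distance comparisons are
strict (`<`); a frame exactly at threshold is outside.

Instantaneous candidate configurations per frame:

* **DYAD** — some pair's distance < 5 cm (the closest qualifying pair is the
  candidate membership);
* **TRIAD** — some 3-subset whose three pairwise distances average < 5 cm
  (tightest qualifying triple wins);
* **QUARTET** — the mean over the four animals of each animal's largest
  distance to another member < 5 cm. This reads "mean of the most separated
  pairs" as one worst partner per animal; the alternative reading — the mean
  of the three largest of the six pairwise distances — is available as
  `quartet_rule="pair_top3"`. The default is the per-animal reading because
  it weights every animal's isolation once, but on near-regular
  configurations the two differ only in a narrow band (a square of side s
  qualifies iff s·√2 < 5 under the default).

Duration gating is top-down: quartet runs meeting the minimum duration are
fixed first, then triad runs on the remaining frames, then dyad runs. A
short excursion to a higher state inside a sustained lower state therefore
demotes into the lower state instead of fragmenting it, and a growth
sequence whose early stages are individually shorter than the criterion is
absorbed by whichever stage does satisfy it. No gap bridging by default
(`bridge_gap = 0`).

Events are maximal constant-state runs split further at membership changes,
with hysteresis — the previous member set is kept while it still qualifies —
so near-tied candidates do not fragment events; a growth step (dyad → triad)
closes the event and opens a child linked by `parent_id`. The event centroid
is the members' body-center centroid averaged over the event. Two disjoint
simultaneous dyads are representable (`dyad_multiplicity_frames`) but the
state series records a single DYAD.

The **huddling fraction** divides huddling frames by *all* frames of the
analyzed range: invalid frames count as non-huddling time, so the fraction
is conservative with respect to tracking loss.

### Spatial enrichment

The arena is a 4 × 4 grid of equal cells (4 corners, 8 edges, 4 centers);
cells are half-open `[low, high)` except the last cell per axis, so every
in-arena point maps to exactly one cell. Per mouse, the proportion of its
events (events whose member set contains it) with a corner centroid is
compared to the uniform expectation 4/16 = 0.25 with a one-sample Wilcoxon
signed-rank test; summarizing at the animal level reduces the dependence
among events from the same group. Mice with zero events are excluded and
reported, and the test is skipped (reported `None`) when fewer than three
animals have proportions different from 0.25.

## Circular-shift permutation null

Each iteration draws an independent uniform offset in `[0, n_frames)` per
animal (0 included; its probability is 1/n and excluding it buys nothing),
rotates positions and validity, and recomputes the huddling fraction under
identical criteria. Rotation preserves each animal's position multiset and
all speeds except at the single wrap seam, so the null keeps individual
locomotor statistics while destroying cross-animal alignment. Empirical
p-values use the +1-corrected rank formula and are therefore never zero;
the two-sided p doubles the smaller tail, capped at 1. The one-sided
criterion (observed above 95% of the null) drives the `above_chance` flag.

**Calibration.** The type-I error of the test is checked on simulated
control groups. Under the full 5 cm / 1 min criteria a control recording's
huddling fraction is identically zero, as is every shifted version — the
test then never rejects and its error rate is trivially zero. The
calibration therefore drops the duration gate (`min_duration = 0`), making
the statistic (fraction of time the minimum dyadic distance is below 5 cm)
continuous under the null; with 199 shifts over 200 independent 10-minute
control recordings the one-sided rejection rate at α = 0.05 falls in
[0.01, 0.09]. The observed rate sits slightly below the nominal 0.045 that
the discrete rank formula allows, consistent with the mild conservativeness
of circular-shift tests on serially dependent series.

## Markov model of group states

Group state is sampled instantaneously at the start of each 60 s interval
(majority voting within the interval is deliberately not the default: the
sampled chain then has a clean interpretation as a snapshot process).
Transition counts accumulate within-sequence adjacent pairs only — never
across recordings — and rows are normalized by their own sums. Never-visited
rows are surfaced as undefined (all-zero), not imputed; Laplace smoothing is
available (`alpha`) for simulation studies only. Sampling can be anchored at
the analyzed-range start (default for transition estimation) or at the first
huddle onset (`anchor_frame`), which is the natural anchor for time-in-state
summaries.

## Pre-huddle dynamics

The huddle **center** is the two members' body-center centroid averaged over
the first 10 s after onset and held fixed; the definition needs a time
anchor and the early event is when the configuration is tightest around its
eventual location. **Entry** is the start of the sustained (≥ 1 s) run
within 3.5 cm of that center that is in effect at onset — a brief dip inside
does not count, and a resident's run may reach back long before the event.
If a member is outside the radius exactly at onset, its first sustained run
after onset is used. First entry = initiator; ties at the same frame break
toward the animal closer to the center. Events where a member never
satisfies the rule are excluded from role analysis and reported.

Features over the 150 pre-onset frames: central-difference speed, distance
to the center, and the cosine between the head vector and the direction to
the center (NaN without a nose keypoint). Windows truncated by the analyzed
range are flagged `short` and excluded from pooled fits.

### HMM fitting and selection

Pooled (speed, distance) sequences — one per event × role — are z-scored
over the whole pool and fitted with diagonal-covariance Gaussian HMMs
(hmmlearn EM, variance floor 1e-4 standardized, tolerance 1e-6, max 500
iterations, 10 seeded restarts keeping the best log-likelihood). Free
parameters per K-state model: (K−1) start probabilities + K(K−1)
transitions + 2·K·d emission terms; AIC = 2k − 2ℓ, BIC = k·ln n − 2ℓ with n
the pooled time-point count. BIC selects K (and breaks any disagreement
with AIC, being the more conservative of the two); both are reported for
every K. States are labeled post hoc: the higher-mean-speed state is
*approaching*, the lower *stationing*. Constant-feature pools are flagged
`degenerate` rather than rejected — the variance floor keeps EM defined.

wPersistence = Σₛ πₛ·Pₛₛ with π the normalized left eigenvector of P at
eigenvalue 1; if no unit eigenvalue is found (reducible/periodic chains) the
row-averaged long-run occupancy of P^1000 is used and flagged. The statistic
is in [0, 1], equalling 1 iff every π-supported state has Pₛₛ = 1.

The clustered bootstrap resamples animals (identified per recording) with
replacement, keeps *all* sequences of a sampled animal as a unit, refits the
K = 2 model per replicate (fewer restarts — 3 by default — since the pooled
fit shows the likelihood surface is benign), and reports the median and
percentile 95% CI of wPersistence. Replicates landing on fewer than two
sequences are redrawn and counted. State-time ratios use the Viterbi path
(posterior-argmax via `decode_windows` callers if preferred) and a one-frame
pseudocount: log((approaching + 1)/(stationing + 1)).

Downstream mixed-effects models on the emitted tables (displacement by role,
role prediction from the log ratio) are the province of standard GLMM
routines; the package's responsibility ends at the tidy tables.

## Generic tests

Two-sample comparisons are screened for normality with a one-sample KS test
against a normal fitted to each group (α = 0.05, either group rejecting →
rank-sum; constant groups force the rank-sum path with a warning; the choice
is overridable). Effect conventions, always carried in the result:
rank-biserial r = 1 − 2U/(n₁n₂) for the rank-sum, Cohen's d with pooled SD
for Welch's t, r = |Z|/√n for the signed-rank. Exact rank-test p-values up
to n = 25 without ties, normal approximation with tie correction otherwise.
KS families are Holm step-down adjusted (monotone, never below raw). Event
counts are compared with a log-link Poisson regression on condition; an
all-zero reference group is reported non-estimable rather than offset.

## The simulator: what it emulates and what it does not

The generator reproduces the *statistical structure* the analyses assume —
not thermoregulatory, olfactory or social-force mechanism. Defaults are the
study conditions: 4 agents (2 labeled M, 2 F; sex is cosmetic metadata with
no dynamic effect), 76.2 cm square arena, 30 fps, 1 h.

* **Wander** — heading-persistent random walk: wrapped-Gaussian turns
  (sd 0.5 rad/frame), speeds truncated-normal (mean 6, sd 3 cm/s, ≥ 0),
  reflecting walls. Chosen over Brownian motion for realistic path-length
  statistics. Control phenotypes are pure wander; their incidental
  proximity is brief by construction (speeds are essentially never zero),
  so the 5 cm / 1 min criteria fire on ≥ 95% of control hours exactly never
  — the calibration the detection threshold choice relies on.
* **Scheduled huddles** (impaired) — event count Poisson at `huddle_rate`
  (default 3/h), uniform starts packed sequentially (collisions push events
  later; events that no longer fit are dropped, which at the default rate
  perturbs the realized rate negligibly), corner-biased sites
  (`corner_bias` 0.8), durations uniform in 240–480 s *including* growth.
  Members join in a random growth order: the first (the scripted initiator)
  stations 10 s before onset, the second at onset, later members every 75 s.
  The stagger deliberately exceeds the 60 s duration criterion so each
  growth stage is itself a detectable sustained state — staging faster than
  the criterion would make the early stages undetectable by definition and
  cap span recovery around Jaccard 0.8. Stationed members sit on a 1.8 cm
  ring around the site with AR(1) positional jitter (marginal sd 0.3 cm,
  ρ = 0.98): huddled animals are nearly motionless frame to frame, which
  keeps the impaired phenotype's travelled distance *below* controls while
  leaving maximum speeds comparable. Approaches run straight at 15 cm/s,
  beginning early enough to arrive 2 s before the member's scheduled start;
  an agent that cannot reach its site in time raises an error rather than
  silently missing its huddle.
* **Ground truth** — per-frame per-agent regime (wander/approach/station),
  per-frame group state derived from the schedule (number of members whose
  scheduled span covers the frame), and the schedule itself. Detector
  validation scores each scheduled span against the best-overlapping
  detected bout by Jaccard overlap.

Deterministic per seed; noise arrays are pre-drawn from one generator per
simulation. Not emulated, hence not demonstrated by passing tests: tracking
noise and identity swaps, resting/grooming bouts (controls here move
continuously, so simulated travel distances exceed real mouse hours),
thigmotaxis in wandering, social attraction outside scheduled events, and
any sex effect. The single-step `step_agent` API draws stationing jitter
independently per call; only the full simulation carries the AR(1) state.

## Problem sizes used in the shipped checks

Simulation-backed checks run at: 50 impaired hours for detector recovery;
200 ten-minute control recordings × 199 shifts for permutation calibration;
10⁴-step chains for Markov recovery; 10⁴ pooled time points for HMM
selection/decoding; ≥ 50 scripted dyadic events for role assignment;
10⁶-step Monte-Carlo chains for the wPersistence oracle. The acceptance
script uses 20 recovery hours, 100 calibration recordings and a B = 100
bootstrap; all sizes are the package's own choices balancing Monte-Carlo
error against turnaround.

## Known limitations

* The quartet compactness rule has two defensible readings (above); results
  near the 5 cm boundary can differ between them.
* Minute-binned distance summaries report both mean and median per bin; the
  mean is primary.
* The permutation null preserves within-animal dynamics only up to the wrap
  seam; for recordings dominated by a single long stationary bout the null
  is conservative (shifted copies still overlap spatially).
* hmmlearn's EM can terminate with a tiny negative final-step delta; fits
  carry a `converged` flag and the best restart is returned regardless.
* The clustered bootstrap treats animals within a recording as the
  exchangeable unit; it does not model group-level dependence beyond that.
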