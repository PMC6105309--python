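# Methods

This note documents the models implemented in `puffcrus`, the parameters
that matter, the numerical conventions chosen where the procedure left them
open, and what the synthetic-data generator does and does not emulate.

## Task generative model

Stimuli are censored Poisson trains.  The total puff rate of 2.5 events/s
is read as a **total** rate split between the sides by the 1:4 ratio
(majority 2.0 Hz, minority 0.5 Hz); the alternative reading (2.5 Hz per
side) is inconsistent with the stated generative framing and is not
implemented.  Censoring is left-to-right thinning: a proposal is kept only
if it falls at least 200 ms (`min_ipi`) after the previously retained
same-side event — the start-boundary puff seeds the thinning — and at
least 200 ms before the end boundary, so the full train including both
bilateral boundary puffs respects the refractory constraint.  Thinning was
chosen over resampling because it is deterministic given a seed.  Because
censoring removes proportionally more majority-side proposals, the
realized majority:minority count ratio is ≈3.1 rather than 4 at the
default rates (verified against an independent event-by-event renewal
simulator).

Cue durations are 1.5 s / 3.8 s with probabilities 0.15 / 0.85.  The
correct side is the side with more interior (non-boundary) puffs; tie
trials are redrawn so every trial has a defined correct side.  Choices are
drawn sequentially from the history logistic model; the evidence scale
divisor defaults to the session-wide max |#R−#L| ("scaled from −1 to 1"),
which also makes the GLM invariant to uniformly doubling all counts.
Trial timing on the session timeline uses a 2.5 s pre-cue baseline
(covering the start tone and 1 s delay), 0.2 s post-cue delay, a decision
lick 0.2–0.8 s into the decision phase, 3 s reward consumption, and
inter-trial intervals of 3.5 s (correct) / 6 s (error).

Lick trains are the least constrained part of the generative model: the
decision lick is followed on correct trials by consumption licking
(default 7 Hz, exposed as `consumption_lick_rate`) and on errors by
cessation, plus a low spontaneous inter-trial lick rate (default 0.3 Hz)
so that lick-bout events exist in both outcome contexts.  These rates are
free parameters, not measured quantities.

## Synthetic neural activity

Somatic ΔF/F is a firing-rate drive converted to per-frame Poisson event
counts, convolved with a single-exponential calcium kernel, scaled by a
per-cell gain, and corrupted by Gaussian noise.  Kernel time constants
default to τ = 1.0 s for somata (slow Purkinje calcium extrusion) and
τ = 0.2 s for dendrites.  Response classes: linear cue-period ramps
(up/down, peak drive 10 Hz), per-puff impulse responses (2 expected events
per puff) on one side or on the signed difference, a choice-dependent
offset in the final 500 ms of the cue, and nulls.  The default population
mixture places 70% of cells in the ramp classes, matching the dominance of
time-modulated cells in the recorded population.  `sampling="expected"`
bypasses Poisson sampling for noiseless kernel-identity tests.

Dendritic traces are discrete events (outcome-conditioned rates in the
800 ms post-decision window, defaults 2.5 Hz after errors vs 0.5 Hz after
rewards, plus 0.05 Hz spontaneous) convolved with the fast kernel; the
ground-truth event trains are returned for deconvolution testing.

Movies are `background + Σ footprint·(cell_baseline + trace) + noise`,
optionally jittered by an integer-pixel random-walk rigid trajectory.  A
non-zero `cell_baseline` (resting fluorescence) matters: frames in which
all cells are silent otherwise contain no spatial structure for template
matching.  Footprints are disks on a jittered grid whose pitch keeps ≥3 px
between neighbors, because a 3×3 median filter can bridge a 1-px gap and
fuse the correlation-image components of two strongly correlated cells.

**What the generator does not emulate:** training/shaping and anti-biasing
procedures, photon statistics and optics, sub-pixel or non-rigid motion,
neuropil contamination, overlapping footprints, and electrophysiology.
Passing tests therefore demonstrate correctness of the analysis chain
under the assumed statistical structure, not robustness to every artifact
of real recordings.

## Behavioral fits

All fits use decided trials only (no-decision-lick trials are excluded).
Logistic fits are unpenalized maximum likelihood; perfect separation or a
non-identified fit (|coefficient| > 50 or SE > 100 logit units) is
reported as a failure, never silently regularized.  The psychometric 4PL
is least-squares on unweighted per-level choice proportions.  The
five-bin evidence regression uses trials of the primary (3.8 s) cue
duration, interior puffs only, and an intercept.  The Jeffreys CI is the
equal-tailed Beta(k+½, n−k+½) interval with lo=0 at k=0 and hi=1 at k=n.

The bootstrap inactivation test resamples baseline **design rows** (with
history terms already attached) with replacement, refits, and reports the
one-sided exceedance fraction per coefficient; both tails and
min(2·tail, 1) are exposed because the original convention reports a
one-sided fraction without naming its sidedness.  Bootstrap refit failures
are counted, with a warning above 5%.  Bootstrap confidence bounds
throughout the package use the 5th/95th percentiles of the resampled
statistic, following the source convention for the modulation-fraction
interval.

## Imaging pipeline conventions

Choices made where the procedure is under-specified:

- Template matching: integer-pixel rigid shifts by maximal circular
  cross-correlation of mean-subtracted images, search radius 15 px,
  template = mean of the first 500 frames.  Shifts are defined relative to
  the template, so a motion-blurred default template can introduce a
  constant offset; supplying a clean template recovers planted shifts
  exactly.  Pixels within the max |shift| border band are removed from all
  ROIs.
- Correlation image: 3×3 median filter; threshold statistics (mean, SD)
  over the whole filtered image; 8-connected components.  Note the seed's
  own pixels correlate with the seed trace even in pure noise; for compact
  blob-shaped seeds this artifact survives the median filter, and
  rejection of structure-free movies then relies on the 0.5–3.5× size
  gate (thin, dendrite-like seeds are rejected outright).
- Merging operates on raw (pre-ΔF/F) traces, processes candidate pairs in
  descending correlation order, and repeats both stages to a fixpoint,
  which makes the result deterministic and idempotent.  Centroid distance
  uses `um_per_px` metadata, defaulting to 1.18 µm/px with a warning.
- ΔF/F: the trailing 12 s minimum window includes the current sample and
  truncates at the trace start (the first frame's baseline is its own
  filtered value).  F₀ ≤ 0 is an error: inputs must be raw positive
  intensities.
- Movement indices: mouth/lick use |trace − 0.5 s-median baseline|,
  other features |derivative|, each normalized to [0, 1]; constant traces
  return all-zero indices with a `degenerate` flag.  Onsets are upward
  crossings of mean + 2.5 SD.

## Somatic statistics

The modulation comparison uses a 2 s window immediately before the cue and
a 2 s window centered at the cue midpoint ("middle of the cue period" has
no tighter anchor), computed on the trial-averaged signal per cell.
Somatic analyses are restricted to 3.8 s-cue trials.  The pre-decision
window is the 500 ms before the decision phase (end of the delay).  The
puff-triggered t½ uses trials with <3 same-side interior puffs, a 400 ms
pre-puff baseline, peak search restricted to 0–1 s post-puff, and linear
interpolation between frames.  The evidence linear model includes an
intercept (not stated in the source procedure; standard OLS practice) and
reports per-cell p-values uncorrected, with a Benjamini–Hochberg column
where applicable.  Note that the choice-held shuffle deliberately
preserves choice-mediated associations: for cells whose evidence coding
drives choice, shuffled category rates fall toward the choice-explained
level, not to the nominal test level.

## Decoding

The classifier is a standardized linear logistic model (scikit-learn,
C = 1.0 — weak L2 regularization, exposed as a parameter) inside each
stratified CV fold; per-feature standardization makes decoding invariant
to affine rescaling of individual cells.  Choice/evidence decoding uses
400 ms bins from −2 s to +4 s around cue onset with k = 5; evidence
magnitude strata for the independence shuffle are quartiles of |#R−#L| by
default (fixed-width bins available), with ties joining the upper bin.
Outcome decoding uses the 800 ms before/after the decision, 1,000
class-matched batches (equal error/correct counts, subsampled without
replacement), k = 3.

## Dendritic events

Deconvolution solves min ½‖y − Ks‖² + λ‖s‖₀ with K the AR(1) convolution
matrix, by (1) candidate detection on the whitened innovation
d(t) = y(t) − γ·y(t−1), (2) non-negative least-squares amplitude refit on
the candidate support (processed in independent clusters separated by more
than the kernel's effective length), and (3) backward pruning of the
weakest events while removal costs less than λ.  γ defaults to
exp(−1/(τ·frame_rate)).  λ is noise-scaled by default, λ = (2.5σ)²/2 with
σ a robust MAD estimate of the innovation noise, and is exposed as
`sparsity`.  On noiseless traces with ≤3 events the support matches an
exhaustive L0 search exactly.  The 0.1 binarization threshold is in the
trace's ΔF/F units and is applied to refit amplitudes (events ≥ threshold
are retained).

Outcome responses use floor(0.8 s × frame rate) frames (22 at 28 Hz),
recorded in the output.  Lick bouts use the 250 ms gap rule per side; an
isolated lick is both a start and a stop.  Events in the inter-trial
interval inherit the preceding trial's outcome context.  Difficulty
stratification uses rank-based terciles of |#R−#L| (quantile edges on the
small discrete support can produce empty strata); raw ΔF/F, not
deconvolved events, is the default activity measure for outcome analyses,
with events available via the deconvolution API.

## Problem sizes

Test and acceptance computations use desk-scale sizes chosen to estimate
each quantity with adequate precision: 20,000 draws for the duration
mixture and GLM recovery, 850–1,000 cells for population fractions and
null calibration (binomial SE ≤ 1.7 percentage points), 100–250-trial
sessions for decoding, and 100–1,000 bootstrap/batch resamples where the
full 10,000 would not change the conclusion.
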