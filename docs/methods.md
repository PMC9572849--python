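# Methods

## The analysis in brief

The pipeline quantifies how a push-and-pull (P&P) handcart session is
executed, per participant and per circuit traversal, and contrasts two
clinically defined groups. A session is ten traversals (5 series × 2
attempts) of an 8-waypoint circuit, with 2 s pauses between attempts
and 20 s between series. Inputs are six force channels (x, y, z per
handle side at 100 Hz), six surface-EMG channels (latissimus dorsi,
pectoralis major, flexor carpi ulnaris, bilateral), a per-muscle MVC
trial, an ordered waypoint-event stream, and a participant
characteristics table.

## Cohort scoring and classification

DASS scale totals are plain sums of 14 item responses (0–3 each).
Cut-offs are inclusive and default to stress ≥ 15, anxiety ≥ 8,
depression ≥ 10, apathy ≥ 14. The published description of the
motivating cohort lists the DASS cut-offs in the order "Depression,
Anxiety, Stress = 15, 8, 10", but the accompanying participant table's
flagged totals are only consistent with the mapping used here (stress
totals of 13–14 unflagged and 15–16 flagged; anxiety 8–9 flagged;
a depression total of 11 flagged). The thresholds are configurable for
users who prefer the literal reading; the inclusive comparison is
forced by the apathy wording ("equal to or higher than") and by the
flagged boundary cases. Depression's behaviour exactly at 10 is not
testable from the bundled table (no total of 9 or 10 occurs).

Group 1 requires zero high totals, zero active trigger points (VRS 3–4)
and normal thoracolumbar mobility; Group 2 requires at least two high
totals, at least two active trigger points and reduced mobility; all
other participants are unclassified. Applied verbatim to the bundled
table these criteria yield Group 1 = {1, 9} and Group 2 = {6, 7, 11,
13}; the study that produced the table described Group 2 as three
individuals, so it evidently applied an additional, unstated exclusion
to participant 13. No exclusion is guessed here; the verbatim result
is reported and asserted in the tests. Similarly, the recomputed mean
age (34.7 y) and height (186.65 cm) differ slightly from the published
"35.0 ± 5.8" and "186.0 ± 8.8", while mean body weight (94.9 kg)
matches exactly; only the weight statistic is treated as a
reproduction check. Standard deviations use the n−1 denominator; a
single-record cohort reports SD 0 with a warning.

## Signal processing

The per-side resultant force is the Euclidean norm of the three
components, so it is non-negative, rotation-invariant and homogeneous.

The EMG chain is a conventional surface-EMG envelope pipeline chosen
because the acquisition description only says the signals were
"filtered and normalized": 4th-order Butterworth band-pass 20–450 Hz
applied forward-backward (zero phase), full-wave rectification, and a
100 ms moving-average envelope (RMS optional). When the sampling rate
cannot honour the upper edge (e.g. 100 Hz data), the edge is clipped
to 0.95 × Nyquist with a warning; the defaults are recorded in output
metadata. The MVC is the maximum of the *identically processed* trial
envelope — normalizing envelope by envelope rather than raw peak —
with the first and last envelope-window excluded so transients cannot
pose as the contraction peak. The passband is not perfectly flat: at
2 kHz sampling a 50 Hz in-band sine's envelope settles at 2/π within
about 1% (forward-backward filtering squares the ~0.5% edge
attenuation), which is why the analytic envelope checks use a 2%
tolerance.

## Segmentation and the relative-moment scale

Eight events per traversal (waypoints 1…7 and the return to 1) define
six overlapping phases; consecutive phases share two events. The
analysis window is the last 30% of the first leg plus the first 70% of
the second. All features are computed on this window (a config switch
computes them on the full phase instead, for sensitivity analysis).

Relative moments map window time onto [−1, 1] piecewise-linearly with
0 exactly at the middle waypoint. The −1 anchor sits at the *window*
start, not the phase start — the source description conflates the two
("−1 … e.g. P1"), but anchoring on the window is the only reading
under which the depicted parameters live on the analysis window — and
the two branches necessarily have different slopes (0.3 vs 0.7 leg
fractions). Window endpoints map to sample indices by
[ceil(t_a·fs), floor(t_b·fs)], making windows reproducible across
implementations; argmax/argmin ties resolve to the first occurrence.

## Features

Per window and side: mean, SD (n−1), max, min, trapezoidal time
integral (exact for piecewise-linear signals sampled at breakpoints),
relative moments of max and min, maximal absolute difference of
consecutive extrema (0 with fewer than two extrema), and local
max/min counts. The counting criterion is not specified by the
motivating study; on unsmoothed 100 Hz force data a bare 3-point rule
is noise-dominated, so extrema must have prominence ≥ 5% of the window
range and be ≥ 0.1 s apart (both configurable, both recorded in output
metadata). Same-kind neighbours are merged keeping the more extreme
one, so the reported sequence alternates and the two counts differ by
at most one. The implementation uses scipy's peak machinery; the test
suite cross-checks it against an O(n²) oracle that reimplements
candidate detection, prominence and tallest-first separation directly
from their definitions.

Per phase: overall duration (end − start), position-related task time
(start to middle; about half the overall duration since a phase spans
two legs), and the relative moment of the middle event, which is 0 by
construction under this mapping and is emitted for table fidelity.
Parameter bookkeeping follows the 10-per-side + 3-time-domain reading
(the source alternately counts "two" or "three" time parameters; all
three are emitted, and the constant one is excluded from the contrast
table, whose published layout has 22 force/time rows).

The integral is reported in (force units)·s over the analysis window.
The published table's integral magnitudes (~290/550) cannot be
reconciled with its own force means (~3.2) and durations (~18 s),
which imply ~58 per window; whether the published values were summed
across phases or series is unknowable from the text, so the
self-consistent per-window definition is used and no absolute-scale
reproduction is claimed.

## Group contrasts

Group means pool all (participant, traversal, phase) cells with equal
weight (a participant-means-first option exists for sensitivity); the
published aggregation scheme is unstated. Contrasts are percent
differences with Group 1 (or traversals 1–2) as reference — the
formula implied by every reproducible published row. "Series 9–10"
indexes the ten traversals (attempt level), the only reading
compatible with a 5-series protocol. Machine-readable output keeps
full precision; the text rendering rounds to 6 significant digits.
No hypothesis tests are computed because the design reports none.

## The synthetic session generator

The generator is a declared statistical stand-in, not a biomechanical
model: no cart dynamics, friction, posture or limb kinematics. It
emulates (i) the protocol timing — mean leg duration 8.87 s (so a
two-leg phase is ~17.7 s and a session lands near 11–12 minutes),
lognormal leg-duration jitter (CV 0.08), the pause structure, event
streams with the exact waypoint grammar; (ii) per-side resultant force
as baseline (1.3 force units) + one Gaussian exertion bump per
interior waypoint (amplitude 6, σ 1 s, lognormal CV 0.10, centred at
the waypoint plus the configured relative-moment offset) + Poisson
micro-peak bumps (amplitude 0.5–1.2, σ 0.08–0.2 s) + sensor noise
(SD 0.05 per component), decomposed into components through a slowly
wandering direction with a small vertical share (0.18), matching the
observation that the vertical component contributes least; (iii) EMG
as band-limited noise amplitude-modulated by the exertion envelope.
The force scale constants put the per-window mean near 3.2 and the
maximum near 7.4 force units, the scale of the published group means
(force units are unlabeled there and are treated as opaque).

Two calibrations are built into the generator's contract: MVC trials
are rescaled so the processed envelope maximum equals the configured
MVC exactly, and EMG channels are rescaled so the mean MVC-normalized
envelope over the active portion equals the configured MAV target —
both against the package's own preprocessing chain with the same
parameter set the analysis uses. This makes MVC and MAV recovery exact
up to window effects, which is intended: those knobs define the
generator's targets, and recovery tests then probe the analysis path,
not the generator's luck.

Knob-to-parameter mapping and its limits: `effort_scale` multiplies
all force amplitudes, so window integrals scale ~linearly with it;
`asymmetry` is the right/left amplitude ratio; `peak_timing_shift`
places the dominant bump at a chosen relative moment (recovered
essentially unbiased); `fatigue_drift` is a shared log-linear
per-traversal factor on amplitudes and leg durations, the simplest
mechanism able to produce the published negative late-vs-early drift
signs; `micro_peak_rate` is the expected number of *injected*
micro-peaks per analysis window. The recovered count of
prominence-filtered alternating extrema is a monotone but smaller
function of that rate (roughly 0.5–0.6 of it at the defaults), because
micro-peaks riding the main bump's steep flanks lose prominence and
pairs without a prominent valley between them merge; the count knob is
therefore treated as ordinal (more injected → more counted), which is
what the recovery checks assert. Reference configurations for the two
groups encode the published contrast pattern (effort ratio 1.9, slight
right-dominance and earlier peaks in Group 1, more micro-peaks and a
stronger drift in Group 2; Group 2's base leg duration 9.69 s is set
so its drift-pooled mean duration sits ~2–4% above Group 1's, the
published relation).

One seed drives a documented stream split (schedule, per-side force,
direction, one stream per EMG channel, per-participant spawns), so
identical config + seed reproduces recordings bit-for-bit and adding a
participant does not perturb the others.

What passing recovery tests do and do not show: they demonstrate that
the pipeline recovers known group effects of realistic magnitude from
signals with protocol-faithful structure, seeded noise and drift. They
do not validate performance on real electromyographic or force data —
real EMG at 100 Hz sampling is severely band-limited, real forces
contain cart-dynamics structure the bump model lacks, and real
left/right channels are physiologically correlated (the published EMG
table's identical left/right arm values, likely a channel duplication,
are deliberately not emulated).

## Sizes and numerical choices

Monte-Carlo validation uses 20 cohorts of 2 + 3 participants with
full-protocol sessions (~70 000 samples × 12 channels each), the
cohort sizes of the motivating study; the recovery study fixes both
groups to identical configurations except the knob under test so each
recovered quantity maps onto one knob. Unit tests use a shortened
protocol (2 traversals, 3 s legs). CSV readers parse floats in
round-trip mode so write-then-read is exact; relative-moment window
membership uses a 1e-9 relative tolerance; filter application refuses
series shorter than the filtfilt transient.

## Known limitations

* The integral's absolute scale cannot be tied to the published
  values (see above); only ratios and signs are meaningful targets.
* Extrema counts depend on the declared prominence/separation
  criterion; published counts were produced by an unknown criterion.
* The cohort classification reproduces four Group 2 members where the
  source reports three (unstated exclusion; documented, not guessed).
* The simulator's EMG is a calibrated envelope carrier, not a
  physiological motor-unit model; spectral EMG features would be
  meaningless on it and are out of scope.
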