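# Methods

`coroflow` automates the measurement of coronary blood flow from murine
transthoracic Doppler echocardiography (TTDE).  This note records the
models, heuristics, parameters and numerical choices behind each stage,
and what the synthetic validation does and does not demonstrate.

## The measurement problem

A TTDE recording of the left main coronary artery shows a spectral
Doppler window (time × velocity, brightness = signal power) above an ECG
trace.  Murine coronary flow is diastole-dominant: each beat has a small
systolic bump followed by a large diastolic peak that decays until the
next QRS.  The clinically relevant quantities are the per-cycle peak
velocity (PV), the velocity-time integral (VTI, the area under the
envelope in mm), heart rate (HR), and — combined with the vessel
diameter D from color-mode imaging —

    CBF [mL/min] = (π/4) · D² · VTI · HR / 1000,

with the hyperemia/baseline ratios CFVR (peak velocities) and CFR (CBF)
as reserve indices.  Reduced reserve indicates coronary microvascular
disease.

## Video stitching

Consoles paint the spectrogram with a sweeping cursor that wraps from
the right to the left edge.  `detect_sweep_resets` finds wraps by
tracking the band of changed columns between consecutive frames: a reset
is a frame whose change band starts in the left quarter of the window
while the previous paint activity had reached the right quarter.  The
frame immediately before each reset is a fully painted sweep; stitching
concatenates those frames in time order.  A trailing partial sweep
cannot be distinguished from an unfinished paint and is discarded; with
no resets at all the last frame is taken as the single completed sweep.
The synthetic scroll renderer emits one trailing frame after the final
completed sweep in which the cursor wraps onto a background band, so
that every completed sweep is delimited by an observable reset and
stitch∘render is the identity.

Row coordinates are 0-based from the top and intervals half-open.  The
Doppler/ECG row layout comes from a JSON sidecar; auto-detecting a
vendor's window chrome is out of scope.

## Envelope extraction

The Doppler region is Gaussian-smoothed (σ = 1 px), dilated with a
horizontal 1×3 linear element, and thresholded at the Otsu level (exact
256-bin between-class-variance maximizer; plateau ties resolve to the
smallest maximizing threshold for determinism).  The dilation element is
deliberately short: it closes single-column dropouts, while a longer
element acts as a morphological closing that permanently fills the
narrow dip at diastolic onset and biases the diastolic velocity and
slope by up to ~10%.

A signed `threshold_offset` replaces interactive threshold adjustment: a
negative offset admits fainter cycles, a positive one suppresses noise.
The mask is antitone in the offset by construction.

Noise removal deletes every 8-connected component whose nearest pixel is
more than 10 rows from the baseline (nearest-pixel distance, not
centroid).  This removes "top noise" — bright artifact hanging from the
top of the window — and floating speckle while never clipping the flow
envelope, which always reaches the baseline.  Background pockets of at
most 64 px not connected to the image border are filled.  Rows below the
baseline are cleared: reverse flow is out of scope.  The envelope
velocity of a column is `(baseline_row − topmost_foreground_row) ·
scale_max_v / rows_above_baseline`; empty columns read 0 mm/s.

## ECG segmentation

The ECG band is reduced to a per-column deflection height (topmost
bright pixel above the band bottom, median-subtracted).  Local maxima
above 0.4 of the global maximum, at least 8 px apart, are QRS
candidates.  Two distance heuristics against the median inter-peak
interval M correct them: intervals below 0.5·M are deduplicated (the
later peak of the closest pair is dropped, M recomputed), and intervals
above 1.6·M are filled with round(gap/M) − 1 equally spaced peaks
flagged `inserted` so reports can distinguish estimated boundaries.

One subtlety: when many beats are missed, the raw median interval is
itself an integer multiple of the beat interval, and no gap would exceed
1.6·M.  The base interval is therefore refined by scoring median/k for
k = 1..3 on how nearly all intervals are integer multiples of it,
preferring the smallest k unless a larger one fits at least 25% better.
The correction is idempotent and recovers a regular grid corrupted by
random duplications and deletions in ≥ 99% of seeded trials.  Cycles are
the half-open spans between consecutive corrected peaks; partial data
outside the first/last peak is discarded.

## Landmarks and per-cycle parameters

On each cycle's box-smoothed trace (window 5 px) five landmarks are
located: diastolic onset (deepest local minimum between the first
systolic local maximum and the global peak), the diastolic peak (global
maximum), the decay point, peak diastolic deceleration (minimum of the
centered first difference of velocity after the peak), and cycle end.
Landmark columns found on the smoothed trace are snapped to the raw
extremum within half a window, because box smoothing drags an asymmetric
extremum toward its shallower limb; landmark velocities are read from
the raw trace.

The decay point separates the slow diastolic decay from the terminal
plunge into the next systole.  Where the discrete acceleration genuinely
changes sign near peak deceleration (the envelope shoulders before the
plunge — the usual case in noisy recordings), the start of the
negative-acceleration run containing peak deceleration is used, and a
shoulder is only believed if its positive excursion reaches 15% of the
peak deceleration so quantization flicker cannot masquerade as one.  On
a cleanly monotone decay no sign change exists; the deceleration knee —
the minimum of the acceleration's derivative, at least two smoothing
windows past the peak so the peak's own curvature is excluded — marks
the same transition.

The eleven parameters follow from the landmarks: PV, diastolic velocity,
decay velocity; systolic rise time (cycle start → systolic bump),
diastolic rise time (onset → peak), decay times 1 (peak → decay point)
and 2 (decay point → end); the four matching slopes in mm/s² (the
systolic slope is measured from zero velocity at the QRS, where the
envelope leaves the baseline, to the bump maximum); HR = 60000 / cycle
duration; and VTI as the column sum of velocity times column width
(exact for the column sampling; ms·mm/s → mm via /1000).  Cycles with no
systolic bump leave the systolic metrics undefined (NaN) rather than
fabricated; flat or degenerate cycles are reported but flagged and
excluded from summaries.

## Unrepresentative-cycle rejection

Cycles in which the artery drifted out of the sample volume have
abnormally low PV and VTI.  A cycle is rejected when either value falls
below 0.6 of the center (median by default — it resists the very
outliers being removed; the mean is available) of the currently kept
set; the rule iterates to a fixed point (≤ 3 iterations by default,
max_iterations = 1 gives a single pass).  Rejections record their
reason and appear in the output tables with a kept/rejected flag.
Summaries report per-metric mean and sample SD (n−1), excluding
undefined values pairwise with counts.

## Color-mode diameter

The vessel appears as a bright near-vertical band crossing the marked
center line.  Frames are cropped around the center line, rotated by the
probe angle (bilinear interpolation) so the vessel stands vertical, and
thresholded with the same Otsu machinery as the Doppler envelope.  A
component is accepted only if its area is ≥ 100 px and its centroid lies
within 15 px of the measurement axis — the guard against speckle and
ventricular filling, for which the paper-trail gives no quantitative
rule; these are this package's defaults.  The diameter is the mean over
rows of the wall-to-wall width (first to last foreground column + 1)
times mm/px from the probe depth span, with the outer 20% of the
component's rows trimmed to avoid corner-clipped partial widths.  The
six summary statistics are min, max, mean, median, mode (on values
rounded to 0.01 mm, smallest modal value on ties) and sample SD (0 for
a single frame).

## The synthetic generator

No public dataset accompanies this kind of analysis, so validation rests
on seeded synthetic recordings with analytic truth.  Each cycle's
envelope is piecewise-linear through six vertices — cycle start (v = 0),
systolic bump (at 85% of the systolic portion), diastolic onset, peak
(25% into diastole), decay point (67% into diastole), cycle end (2% of
peak velocity) — so every parameter, including the exact VTI integral,
is known in closed form.  Default amplitudes and proportions follow
published murine TTDE values: baseline PV ≈ 290 mm/s at ≈ 364 BPM with
VTI ≈ 22 mm, hyperemia PV ≈ 850 mm/s with VTI ≈ 61 mm; diastolic
velocity 0.25·PV, decay velocity 0.65·PV, with the terminal decay slope
steeper than the first.  Beat-to-beat variability is 3% Gaussian jitter
on duration and amplitude.  Strips render at 0.5 ms/px with a 220-px
Doppler region (baseline at row 200) over a 44-px ECG band carrying one
7-px triangular QRS spike per cycle boundary (n_cycles + 1 spikes,
counting both ends; a 16-px zero-flow pad keeps every spike interior).
Speckle is additive truncated Gaussian (SD 8 by default); "top noise"
blobs are bright disks in the top rows, painted into the image but never
into the truth; faint cycles render at reduced intensity; unrepresentative
cycles scale the whole waveform (default 0.4).  Color-mode frames hold
one bright band of exact perpendicular width at a probe angle, inset
from the window edges, with a center-line marker tick; the study
conditions use 12 px (0.47 mm) baseline and 16 px (0.63 mm) hyperemia at
a 2–12 mm depth span over 256 px, a ~33% hyperemic dilation.

What the generator does not emulate: physical speckle statistics,
Doppler aliasing, wall-filter artifacts, intra-beat envelope dropout,
probe motion, or ECG morphology beyond the QRS spike.  Passing tests
therefore demonstrate correctness of the geometry, calibration,
segmentation and arithmetic of the pipeline under realistic waveform
shapes and the artifact taxonomy above — not robustness to every
clinical acquisition pathology.

## Problem sizes and tolerances

The validation suite uses 8–14-cycle strips (≈ 2600–4700 columns), 500
corrupted ECG grids, and 6–51-frame color-mode clips; a full strip
analyzes in ≈ 0.2 s.  Measured against analytic truth across 20 seeded
strips of both conditions, median absolute relative errors are ≈ 0.5%
(PV), ≈ 0.1% (HR), ≈ 1.5% (VTI) and ≤ 3% (all slopes); envelope
precision/recall ≈ 0.985/1.0 with planted top noise; diameter error
< 0.1 px over probe angles 0–30°; recovered CFVR within ≈ 0.2% and CBF
within ≈ 2% of truth.  `scripts/acceptance.py` recomputes all of these
from scratch for any seed.

## Known limitations

- AVI decoding requires an external conversion to PNG frames.
- Only above-baseline (antegrade) flow is traced.
- The systolic rise-time endpoints and the decay-1/decay-2 split are
  package conventions (documented above); other programs define them
  differently, so absolute times/slopes are comparable only within a
  convention.
- Combined Doppler + color-mode flow uses per-recording aggregation
  (mean diameter, mean HR/VTI over kept cycles), not per-cycle pairing.
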