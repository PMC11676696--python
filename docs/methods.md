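# Methods

## Signal model and conventions

A recording is a uniformly sampled 100 Hz six-channel inertial time series:
tri-axial acceleration in g (sensor range ±16 g) and tri-axial angular
velocity in °/s (±2000 °/s), with an optional 10 Hz GPS sub-track on the
same clock. Axes follow a fixed project-wide convention: **x** forward
(direction of travel), **y** mediolateral, **z** vertical
(gravity-aligned at rest). A trunk sensor worn between the shoulder blades
does not advertise its axis orientation, so this convention is an
implementation choice; every operation that depends on it (channel
selection for peak counting, the sync-tap axis) is configurable.

Cycling-task intervals are half-open `[start, end)`: a boundary instant
belongs to the later interval. Coasting is defined as riding without
turning the pedals for *more than one second*, so shorter coasting
intervals are rejected at validation (predicted tracks produced by merging
classifier windows relax this, since a single 2.5 s window is a legitimate
model output). Gaps in a label track are allowed and surface as the
sentinel `unlabelled`, because real race footage has unlabelled
transitions.

## Band-pass filtering

Both the peak counter and the feature extractor use a sixth-order
Butterworth band-pass, chosen for its maximally flat passband. "Sixth
order" means the band-pass transfer function itself has order six (a
third-order low-pass prototype); conventions differ, so this is stated
explicitly. Cutoffs are 2–3 Hz for cycling and running and 0.5–1.4 Hz for
swimming, reflecting each movement's cadence band.

Filtering is applied forward–backward (`sosfiltfilt`) so event times keep
zero phase lag against externally synchronised video. Two consequences are
documented rather than hidden: the forward–backward pass squares the
magnitude response (sharper effective roll-off than a single sixth-order
pass), and the signal is padded by reflection over roughly three periods
of the lower cutoff to suppress start-up transients. Signals must be
longer than three times the filter order.

## Peak counting

Candidate events are the local extrema of the filtered profile channel —
maxima only for cycling and running (one vertical oscillation per pedal
stroke or step), maxima *and* minima for swimming (trunk roll alternates
with left/right arm entry, so the roll channel oscillates at half the
stroke rate). Candidates closer together than the discipline's minimum
interval (swim 0.5 s, cycle 0.3 s, run 0.25 s) are resolved greedily in
favour of the larger-magnitude extremum. The suppression radius is one
sample short of the minimum interval: when the true event spacing sits
exactly at the minimum (e.g. a 1 Hz roll with a 0.5 s swim interval),
quantisation jitter of ±1 sample must not delete real events. Event
spacing is therefore guaranteed only to within one sample of the stated
minimum. No amplitude or prominence threshold is applied by default — the
detection contract is interval-only — but an optional prominence gate
exists for noisy field data.

Cadence series bin events into half-open epochs of configurable length;
`ceil(duration/epoch)` epochs cover the session and every event in the
covered span lands in exactly one epoch. Count accuracy is
`100·(1 − |detected − truth|/truth)` floored at zero; the per-epoch RMSE
uses 60 s epochs (cadence is conventionally per minute) with a trailing
partial epoch dropped from the RMSE but kept in totals; relative error is
the absolute total-count error in percent.

The video-sync detector looks for the deliberate five-strike signature on
the forward axis: supra-threshold spikes (default 4 g, 0.3 s minimum gap —
the strikes are "distinct", so both are configurable) and returns the time
of the last of the first five, the anchor for aligning sensor and video
clocks.

## Spectral features and task classification

The six channels are band-pass filtered with the cycling filter (the same
method as peak counting; a config switch disables the pre-filter for
experimentation) and cut into rectangular 250-sample (2.5 s) windows with
no overlap. Rectangular windows keep the arithmetic exact: each window
yields a one-sided magnitude spectrum of 126 bins per channel, 756
features per window. Features are the STFT magnitudes only — no
time-domain features are added. Standardisation is per-feature z-scoring
fitted on training windows only; zero-variance features map to zero.

Ground-truth labels live on a 0.1 s grid (25 steps per window) and each
window takes the modal label of the steps it covers; `unlabelled` steps do
not vote, fully unlabelled windows stay `unlabelled`, and exact ties break
towards the label occurring earliest in the window (deterministic and
independent of label dictionary order).

The classifier is an XGBoost gradient-boosted tree ensemble with default
parameters (100 trees at this version) and a fixed seed, single-threaded
for determinism — a deliberately untuned proof of concept. The hold-out
protocol designates training participants, splits each of their sessions
80/20 by contiguous window blocks in seeded-random order (window-level
random sampling would leak information between temporally adjacent
windows), and keeps all remaining participants entirely unseen. Binary
evaluation treats `out_of_saddle` as positive; coasting truth windows are
excluded, since distinguishing coasting from seated pedalling is not
claimed, and a coasting prediction counts as a negative.

## Synthetic sessions

The generator emulates what the analysis needs from real recordings, not
trunk biomechanics in full. Single-discipline sessions place a harmonic
waveform Σₕ wₕ·sin(2π·h·f·t) on the primary channel — f = cadence/60 on
the vertical axis for running and cycling, f = cadence/120 on the
mediolateral axis for swimming — plus a 1 g gravity baseline on the
vertical channel, attenuated phase-shifted copies on secondary channels,
gyroscope oscillations, and independent Gaussian noise per channel
(defaults 0.08 g accelerometer, 5 °/s gyroscope). Ground-truth event times
are the analytic extremum times of the noise-free waveform, so event
counts are exact integers. Default harmonic weights (1, 0.3, 0.1) keep one
maximum and one minimum per cycle after band-pass filtering across the
supported cadence ranges. Default cadences follow observed triathlon
means: swim ≈ 79 strokes/min, cycle ≈ 157.5 pedal strokes/min,
run ≈ 172 strides/min. Amplitudes (0.1–1.5 g) are order-of-magnitude
choices, not measurements.

Scheduled cycling sessions switch regimes per block: seated pedalling is a
0.3 g vertical oscillation at the pedal frequency (~2.6 Hz); standing
efforts double the vertical amplitude, shift the vertical baseline by
+0.15 g, and add a 0.6 g mediolateral rocking component at half the pedal
frequency (~1.3 Hz) whose second harmonic falls inside the 2–3 Hz analysis
band; coasting is road noise only, with no pedal events. The rocking
signature follows the biomechanics of standing riding (torso-transmitted
side-to-side forces) but is a modelling choice, not a measured spectrum.
Two schedule builders cover the data-collection styles of interest:
balanced schedules of equal 20 s task blocks, and race-style schedules
with long seated stretches, short standing efforts and occasional coasting
(~90% seated at the defaults). An optional quantum rounds block durations
to the 2.5 s window grid; leaving it off produces window-straddling blocks
whose blurred features reproduce the known failure mode — short (2–4 s)
standing efforts are detected with markedly lower sensitivity than 20 s
blocks.

What passing tests on these sessions do **not** show: robustness to
sensor detachment, posture drift, swell and chop in open water, gradients
and surface vibration spectra of real roads, or inter-athlete waveform
variability. The generator's spectra are cleanly separable by class;
real-world coasting vs seated pedalling, in particular, is known to be
hard and carries no claim here.

## GPS and maps

Synthetic GPS tracks follow an idealised course (closed 2:1 rectangle of
configurable perimeter, or an out-and-back line) at constant speed with
optional Gaussian position jitter, converted to lat/lon by a local
flat-earth approximation — adequate at course scale (kilometres). Map
exports are GeoJSON FeatureCollections of LineString segments with style
properties (red = out-of-saddle, green = in-saddle, grey =
coasting/unlabelled; cadence maps alternate green/blue), chosen over an
interactive HTML page because the artifact is diff-able and testable.
Cadence-map intervals must be whole multiples of the cadence epoch; the
rolling average is a trailing simple moving average that shortens at the
start.

## Benchmark problem sizes

The bundled benchmarks use six 8 min swim sessions (71–87 strokes/min),
five 15 min cycling sessions (150–165 pedal strokes/min), six 10 min run
sessions (166–178 strides/min), and twelve ~20 min scheduled riders (six
balanced, six race-style with 20 s efforts; three of each train the
model). Session seeds derive deterministically from one base seed;
cadences are evenly spaced over each stated range. Training riders are
evaluated on their held-out 20% blocks, excluded riders on their full
sessions.

## Known limitations

* Axis conventions and per-discipline channel choices are assumptions;
  field deployments should verify them against the worn orientation.
* The accuracy formula and RMSE epoching reproduce the reporting style of
  count-level validation work but cannot be cross-checked against any
  original field data.
* The classifier is untuned by design; no claim is made about coasting
  recognition.
* The generator's difficulty is a modelling choice; its defaults are the
  package's study conditions, and all acceptance-style results are
  conditional on them.
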