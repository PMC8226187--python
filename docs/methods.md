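# Methods

This note documents the models, conventions and numerical choices behind
`duetphase`, in the order of the processing chain: score and simulator,
virtual agent, onset-level analysis, recurrence analysis, body-level
analysis, experience measures, and orchestration.

## The compositional schedule

The performed material is a 12-note cycle played in sixteenth notes at a
dotted-quarter pulse of 72 BPM (one beat = six sixteenths, so one sixteenth
lasts 60/(72·6) ≈ 138.89 ms and one cycle spans two beats, 1.667 s).  The
schedule alternates **stable** bars — both performers at the same rate,
relative phase held at k sixteenths — and **shifting** bars in which the
second performer plays slightly faster until exactly one sixteenth has been
gained.  With 12 relations the schedule is 25 bars: stable at offsets
0,1,…,12(≡0) interleaved with 12 shifts.  Stable bars hold 8 pattern
repetitions (96 onsets, 13.33 s); the shift duration defaults to 10 s per
sixteenth and is configurable up to the 30–60 s a concert performance would
use.  The short default matters for the synchronization-index analysis: a
drift of 2π/12 across the default 10-s SI window gives SI = sin(Δ/2)/(Δ/2) ≈
0.9886 < 0.99, so the 0.99 segmentation threshold cleanly separates stable
from shifting bars; much longer shifts make the drift per window smaller
and the threshold must be raised accordingly (this sensitivity is inherent
to threshold segmentation, not to this implementation).

The simulation omits the solo opening bar of the traditional instruction
(relative phase is undefined with one player) and starts at the first unison
bar.  Acceleration within a shifting bar is linear in rate.  Pitches default
to 12 distinct placeholder MIDI numbers; no analysis reads pitch.

## Simulator

The timekeeper emits sixteenths at the nominal tempo with two noise sources:
per-onset Gaussian jitter (SD 8 ms, truncated at ±3 SD, clamped at t ≥ 0) and
a reflected tempo random walk (step SD 0.2 BPM per onset, bounded to ±3 BPM).
The human performers' true jitter magnitudes are not observable from the
analysis side, so these are plausible sensorimotor-synchronization values
exposed in `PerformerParams`.  The shifter is generated in phase space: its
cycle phase is the timekeeper's (pre-jitter) phase plus the scheduled offset
ramp Δ(t), and its onsets are the crossings of 2πk/12 — this guarantees the
noiseless phase gain per shifting bar is exactly 2π/12 and that stable bars
contain exactly 96 timekeeper onsets regardless of drift (the schedule lives
on the sixteenth-index grid).  One seeded generator per simulate call is
split into independent per-signal substreams (`numpy` `SeedSequence.spawn`),
making every output bit-reproducible under a fixed seed.

Motion synthesis emulates what the body-level layer assumes and nothing
more: head position oscillates along a per-performer dominant axis at the
beat frequency (1.2 Hz at 72 BPM), phase-locked to that performer's own
part, plus isotropic Gaussian noise (SD 0.3 of the 2 cm amplitude); gaze
points forward (the partner sits at 60°, 1.8 m) and is pulled smoothly
toward the partner's head during shifting bars; chair-pressure sway is a
slow bounded walk per channel with one net-nonzero step change at the middle
transition; the pupil trace carries Poisson-timed blink gaps of 60–200 ms.
What the generator does **not** emulate: expressive timing hierarchies,
pitch errors, anticipatory head cues, saccade dynamics, or any influence of
the partner's behavior on a performer's own timing.  Passing tests therefore
validate the analysis chain's conventions and numerics on signals with the
right first-order structure, not the full richness of real performances.
One consequence is documented rather than hidden: the real study found
*higher* IOI variability when the human played against the virtual agent —
a human-in-the-loop effect.  Here the timekeeper is generated independently
of its partner, so the jitter-free agent's bottom part is in fact *smoother*
(≈2–3 ms vs ≈11–12 ms IOI SD), and the comparison test asserts exactly that.

## Virtual agent

The agent is a single Kuramoto oscillator in cycle phase with an added
first-order frequency attractor:

    θ̇ = ω + K·sin(θ_live + Δ(t) − θ),
    ω̇ = γ·(ω₀ − ω) + K_f·sin(θ_live + Δ(t) − θ),

with ω₀ = 2π·0.6 rad/s (the cycle rate at 72 BPM), K = 0.5 rad/s, γ = 0.05
s⁻¹, and frequency-coupling gain K_f = K/10 by default (K_f = 0 recovers
phase-only coupling).  Integration is explicit Euler at dt = 10 ms; halving
dt moves the end-of-run phase by far less than 10⁻³ rad on the default
scenario, and phase monotonicity is guarded at render time.  The live phase
is estimated causally from onsets: 2πk/12 at onset k, extrapolated at the
median rate of the last 12 IOIs, and never more than one sixteenth past the
last heard onset — the cap keeps the estimate non-decreasing when jitter
would otherwise make an onset snap the phase backwards.  Steady-state
locking follows the standard closed form: for a constant live detuning Δω
the locked phase error satisfies sin e = γΔω/(γK + K_f).  Free-run
relaxation is exponential, ω(t) − ω₀ ∝ e^{−γt}; from 80 BPM the residual
after 5/γ is 8·e⁻⁵ ≈ 0.054 BPM.  (From the extreme of a 50–100 BPM start
range the 5/γ residual is up to 0.19 BPM, so the "any start" convergence
property is checked at 6/γ where the bound 28·e⁻⁶ ≈ 0.07 BPM holds.)
Rendering emits prerecorded note k at the wall time θ crosses 2πk/12 and
returns the monotone time-warp map for re-timing motion traces.

## Onset-level analysis

Cycle phase is piecewise linear through onsets (2πk/12 at onset k), sampled
at fs = 20 Hz — far above the phase bandwidth, and making the 0.3 s RQA
delay an integer 6 samples.  SI uses a 10-s centered window with 0.05-s hop,
truncated (never padded) at the edges.  Segmentation labels SI ≥ 0.99 runs
stable, merges runs shorter than 2 s into the longer neighbour (earlier on
ties), and annotates stable segments with the modal offset in sixteenths.
Tempo is reported both as the arithmetic mean of instantaneous 60/(6·IOI)
and as 60/(6·median IOI); IOI variability is the sample SD in ms.

## Recurrence analysis

Phase series are circular, so they are mapped to (cos φ, sin φ) pairs before
delay embedding — the 0/2π wrap then introduces no artificial distances.
Defaults follow the phase-series convention: m = 4, τ = 0.3 s, ε = 0.55,
minimum diagonal/vertical line 0.3 s (6 samples at 20 Hz); sway uses m = 5,
τ = 0.35 s.  A Theiler band of half-width m·τ around the main diagonal is
excluded from every count (trivial tangential recurrences otherwise
dominate).  The joint recurrence plot is the elementwise AND of the two
performers' phase-trajectory plots; embedding the scalar relative-phase
series instead is available as a mode switch, since either reading of
"joint RQA of the relative phase" is defensible.  RR is the recurrent
fraction off-Theiler; DET the fraction of recurrent points on diagonals of
length ≥ lmin; TT the mean vertical length among verticals ≥ vmin (0 when
none survive — the joint plot of two fast phase ramps has essentially no
verticals, so TT ≈ 0 there is expected, whereas the relative-phase mode
produces large blocks in stable bars).  All three metrics are verified
against a brute-force O(n²) line census on random matrices.  The windowed
variant evaluates fully interior diagonal windows (10 s, step 1 s).
Radius calibration bisects on [0, max distance] — RR is monotone in the
radius — to the 10% target within ±0.5 points.

Embedding-parameter selection: the delay is the first minimum of average
mutual information.  The default MI estimator is Gaussian rank-copula MI
(−½·ln(1−ρ²) on normal scores), which is smooth in the lag and puts a
sinusoid's first minimum exactly at a quarter period; an equiquantile
histogram estimator (⌊√(n/5)⌋ bins) is available, but binned MI of
deterministic signals is jagged in the lag and its "first local minimum" is
an artifact of bin crossings rather than dynamics.  The selection rule is:
if MI at lag 1 already sits below 1/e of the lag-0 value the series
decorrelates within a sample and lag 1 is returned (broadband noise);
otherwise the first strict local minimum; failing that, the first 1/e
crossing.  The dimension is the smallest m with a false-nearest-neighbour
fraction below 1% under both Kennel criteria (distance-ratio tolerance 15,
attractor-size tolerance 2).

## Body-level analysis

PCA is per performer (centered, SVD, sign fixed by the largest loading,
z-scored scores); coherence is then computed between the two PC1 series.
The wavelet is the analytic Morlet with ω₀ = 6, 12 voices per octave over
0.125–4 Hz.  Coherence follows the smoothed-cross-spectrum construction:
|S(WₓW_y*/s)|² / (S(|Wₓ|²/s)·S(|W_y|²/s)) with S a Gaussian in time of SD
equal to one scale (applied spectrally on a zero-padded grid) and a boxcar
over 0.6 octave in scale.  The time-smoothing width is the conventional
choice for this construction; a narrower kernel (e.g. half a scale) leaves
too few independent samples per smoothing window and biases the coherence
of independent noise toward ~0.5, destroying the null contrast.  The cone
of influence excludes points within √2·scale of either edge; band summaries
(default 0.9–1.5 Hz) use coherence-weighted circular statistics, with mean
angles reported in degrees in (−180°, 180°].  A caution for interpretation:
a single strong shared tone saturates coherence over roughly ±2 voices, so
peak-frequency localization is only meaningful when the series carry
broadband noise alongside the oscillation (the simulator's default noise
provides this).

Gaze angle is arccos⟨gaze, u⟩ with u the unit own-head→partner-head vector;
missing samples propagate.  Sway analysis sums the four pressure channels,
z-scores, embeds, and reports both the normalized unthresholded distance
plot (∈ [0,1], zero diagonal) and calibrated-radius metrics.  Mocap gaps
shorter than 0.25 s are linearly interpolated; nod events are annotation
I/O only (the field practice is manual annotation), aligned to the nearest
segment boundary.

## Experience measures

Questionnaires are defined structurally — item counts, 1–7 bounds, subscale
keys — because the published instruments' item texts are licensed and the
analysis only needs means; reverse-keyed items are handled through a
user-supplied key map (item → 8 − item).  Pupil preprocessing flags samples
whose dilation speed deviates from the median by more than 3 MADs, closes
short valid islands (≤ 0.3 s) bracketed by flagged samples — a blink's flat
bottom has near-zero speed and would otherwise survive — interpolates gaps
under 0.5 s, leaves longer gaps missing, and z-scores.  Pupil values are
normalized within condition only; comparisons across lighting conditions
are not meaningful and are not offered.

## Orchestration

`report.run` executes simulate/analyze/full runs from one validated config;
every output carries a config hash, the seed, and the package version, and
identical config+seed reproduces byte-identical reports.  For the full-run
analyses the head PC1 is decimated to 20 Hz before coherence and sway to
10 Hz before recurrence — both signals are band-limited well below these
rates, and the recurrence matrix is O(n²) in samples.  `compare_conditions`
refuses to compare reports produced under different analysis parameters and
differences are reported against a designated ground-truth condition
(defaulting to the one labelled "human").  Layer 3 enters a report only
when questionnaire data are supplied; the simulator does not invent
subjective ratings.

## Problem sizes

The test suite and the acceptance script run full-length performances
(25 bars, ≈293 s, ≈2100 onsets per part) for schedule-level checks, and
shorter configurations (1–3 relations) where only the mechanics are under
test; recurrence oracle checks use matrices up to 50×50, Monte-Carlo nulls
use 20 seeds.  These sizes make every check deterministic or tightly
concentrated while keeping the whole suite in the tens of seconds.

## Known limitations

- The simulator's performers do not react to each other; adaptation
  phenomena (including the elevated human IOI variability against an
  unresponsive partner) are out of its generative scope.
- SI-threshold segmentation is sensitive to the window/threshold pair;
  the defaults are matched to the default shift duration.
- The Kuramoto gains are engineering choices (the modelled system's real
  coupling constants are unobservable); all are exposed in `AgentParams`.
- MIDI support covers SMF formats 0/1 with note and tempo events only.
- TT is 0 by construction on joint plots of monotone phase ramps; use the
  relative-phase embedding mode when vertical structure is of interest.
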