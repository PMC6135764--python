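# Methods

This note documents the models, thresholds and numerical choices behind
`loomassay`, and what validation on synthetic data does and does not
establish about real recordings.

## Looming stimulus model

An object of half-length *l* approaching at speed *v* subtends
θ(t) = 2·tan⁻¹(l / v·t) at time-to-collision *t*.  Only the ratio *l/v*
(units of time; default 40 ms, i.e. a 1 cm object at 25 cm/s) shapes the
curve, so `LoomingParams` is parameterized by `l_over_v_ms` directly and
treats *l* and *v* as optional convenience inputs.  The profile generator
anchors the virtual collision time t\* = (l/v) / tan(θ_max/2) so that the
angle reaches its maximum (78°) exactly at the end of the 450 ms expansion,
samples at the 144 Hz monitor refresh, holds for 50 ms, and never emits an
angle above the maximum.  With the defaults the first sample is ≈ 9.2° and
t\* ≈ 49.4 ms.

Inter-stimulus spacing of the open-loop protocol (20 presentations across a
5 min block) is modeled as even 15 s periods with the onset at the start of
each period; the spacing is configurable because only the count and the
block duration are pinned down.  The luminance-matched dot control is
modeled as a schedule event plus its luminance endpoint (260 → 35 lux,
86.5% decrease); dots are never rasterized because the tracking camera is
infrared-filtered and the analysis never sees the monitor.

## Closed-loop trigger logic

A trigger compares the fly's displacement over the trailing 500 ms window
with a mode threshold (low: < 1 mm; high: > 7.5 mm; very high: > 10 mm) and
enforces a 15 s refractory period.  After the refractory expires the
threshold must be "crossed anew": the detector fires on a rising edge of the
condition, and if the condition has been continuously true across the whole
refractory period it re-arms one frame after expiry.  A perfectly still fly
in low mode therefore triggers with a spacing of exactly refractory + one
frame, while a fly hovering at threshold cannot fire twice without the
condition going false in between or a full refractory elapsing.  The online
detector (`ClosedLoopDetector.step`) and the whole-trajectory replay
(`closed_loop_triggers`) are the same state machine, so offline replay of a
closed-loop session reproduces the online trigger times bit for bit.

## Tracking

Background: per-pixel temporal median over ≤ 200 evenly spaced frames —
robust whenever the fly occupies a pixel less than half the time.  For
near-stationary recordings the median cannot separate fly from floor, so
`track_video` accepts an explicit background image.  Segmentation: pixels at
least 25 gray levels darker than background (configurable), largest
connected component above a minimum area, ellipse from second-order moments.
The centroid is intensity-weighted over the blob, which recovers sub-pixel
positions on optically blurred (or anti-aliased synthetic) flies; on
rendered ground truth at 276×260 px (≈ 7.8 px/mm) the centroid RMSE is
≈ 0.002 mm and recovered speed correlates > 0.99 with the generating speed.
Motion energy counts ROI pixels whose intensity changes strictly more than
10 levels between consecutive frames; the ROI is centered on the *previous*
frame's centroid so a jump out of the window still registers maximal change,
and is clipped silently at image borders.  Invalid frames are linearly
interpolated and flagged; more than 20% invalid aborts the video.
Coordinates are arena-centered millimeters with +y toward the stimulus
screen (azimuth 90°); head–tail disambiguation is deliberately absent
because every orientation measure in scope is displacement-based.

## Ethogram thresholds

All classifier constants are fixed, auditable config values: 500 ms bins;
walking = bin speed strictly > 4 mm/s; freezing = not walking and bin motion
strictly < 50 px/s; everything else (low translation, high local motion) is
grooming.  Jumps are strict crossings of 75 mm/s on raw per-frame speed,
merged over consecutive frames, and a bin containing a jump is never labeled
freeze.  A pause is ≥ 10 consecutive frames below the walking threshold —
the frame count, not its ≈ 160 ms duration, is the normative criterion —
searched in a configurable [onset, onset + 1 s] window.  Trial responses are
assigned with precedence jump > freeze > flee > none, where the freeze/flee
decision reads the 500 ms window starting at looming offset, classified by
the same bin rules (windows flanking a looming need not align with the fixed
bin grid).  A fly frozen both before and after a looming counts as a
freezing response — frozen flies still startle to each stimulus, so they are
still responding — and those same trials define the startle profile, whose
motion transient peaks at the end of the expansion.  Optogenetic
stimulations count as successful when the frozen time inside the pulse
strictly exceeds 25% of its duration.

## Statistics

**Freezing by speed.**  Transition trials (pre-stimulus state not freezing)
are binned by mean speed over the 500 ms before onset (default edges
0, 2, …, 24 mm/s); each bin reports the freezing fraction with a two-sided
95% Wilson score interval (well behaved at small n and extreme p) and the
SD of the speeds it pooled.  Empty bins are omitted rather than reported as
zeros.  Whether grooming pre-states belong in the denominator is not
settled; all non-freezing pre-states are included here.

**Deceleration fit.**  The mean peri-looming speed trace is fitted with
f(x) = a^(bx − c) + d.  As written the family is over-parameterized: only
β = b·ln a, γ = c·ln a and d are identifiable, the base being a pure gauge.
The fitter therefore estimates (β, γ, d) by variable projection — for fixed
β the optimal amplitude/offset pair is a closed-form linear solve, reducing
the problem to a 1-D search over β (log-spaced grid, parabolic refinement,
bounded scalar polish) — and reports (b, c) in a caller-chosen base
(default e).  This is deterministic, has no starting-point luck, and refits
thousands of traces per second, which the randomization test needs.  A
constant trace returns the degenerate member (b = 0, c = 0, d = trace − 1)
with zero residual; non-finite outcomes are flagged, never silent.
Shifting the time axis by Δ moves c by b·Δ, so c is only comparable between
fits sharing a time origin.

**Randomization test.**  The statistic is |c_A − c_B| from fits to the two
group-mean traces; the null redistributes trial labels (default 5000
shuffles) and refits both means per shuffle with the identical vectorized
estimator, and p uses the add-one estimator (1 + #{null ≥ obs}) / (1 + N).
Groups are ordered canonically before pooling so the result cannot depend on
argument order, and a fixed seed reproduces p exactly.  More than 5% fit
failures across shuffles aborts with diagnostics.  Calibration: across 500
null simulations (500 shuffles each) the rejection rate at α = 0.05 stays
within 0.05 ± 0.02.

Standard hypothesis tests (rank-sum, χ², Kruskal–Wallis) are delegated to
scipy behind thin wrappers and only smoke-tested.

## Synthetic flies

The simulator is the test oracle: it emits a 60 Hz trajectory plus a
ground-truth record (per-frame state, commanded speed and motion-emission
rate, jump times, pause intervals, intended per-stimulus response) that is
consistent with the trajectory by construction.  Its laws and defaults:

* **Walking**: mean-reverting (OU) speed, mean 10 mm/s, SD 3 mm/s, 1 s
  relaxation, floored at 4.5 mm/s so walking bins stay unambiguous; heading
  diffuses at 0.15 rad/frame.  Baselines of ≈ 9–13 mm/s are realistic for
  this assay, and the floor/SD keep high-speed closed-loop triggers
  attainable.  Grooming (0.5 mm/s, high local motion) alternates with
  walking via per-bin transition probabilities (0.06 in, 0.25 out).
* **Boundary**: the wall reflects walkers; escaping flies instead slide
  along the wall tangent (thigmotaxis), which preserves commanded speed and
  keeps escape paths directed rather than bouncing back toward the screen.
* **Looming responses**: jump with p = 0.06; otherwise freeze with
  p(speed) = 0.8 · expit(−0.5·(speed − 6)) evaluated on the pre-stimulus
  500 ms mean; otherwise a walking fly flees, pausing first with
  speed-independent p = 0.5 (12–18 frames), then runs at 1.7× speed for
  1.5 s with heading drawn von Mises around 270° (κ = 2).  Freeze bouts are
  a heavy-tailed mixture (70% exponential mean 240 s, else mean 8 s,
  minimum 2 s), giving the characteristic bimodal time-frozen distribution.
  A frozen fly startles to each looming: a motion transient in the
  300–500 ms window ramping to its peak at the end of the expansion
  (450 ms), after which it remains frozen.  Control (dot) stimuli use the
  same laws scaled by 0.05 and evoke no escapes or startles.
* **Motion emissions**: state-dependent rates (walk 250 + 30·speed px/s,
  groom 400, pause 150, freeze 10) emitted as per-frame Poisson counts;
  `motion_noise=False` emits the deterministic rates, the "zero-noise"
  condition used for exact-recovery tests.
* **Rendering**: 8-bit frames, light floor (200), dark 3 × 1.5 mm fly
  ellipse (60) with ≈ 1 px analytic soft edge, at a reduced 276 × 260 px
  resolution.  Temporal Gaussian pixel noise defaults to σ = 1.5 levels:
  the frame-difference noise floor (SD ≈ 2.1) then sits far below the
  strict >10-level active-pixel rule (< 1 px/s of spurious motion), which
  is the regime the 50 px/s freezing threshold presupposes.  Appreciably
  larger temporal noise (σ ≈ 5) would flood a 100 × 100 ROI with thousands
  of spurious active pixels per second and is not a usable operating point
  for this detector.

These parameters are study conditions chosen once for realism; they are
deliberately **not** fitted to any published percentages, and analyses of
synthetic cohorts are validated against the generating laws, never against
real-data numbers.  What passing tests show: the pipeline recovers the
generator's states, events and response laws essentially exactly at zero
emission noise and within a few percent at default noise.  What they do not
show: robustness to real-video nuisances absent from the generator —
uneven illumination, shadows, reflections at the arena wall, occlusion,
grooming postures that mimic freezing, or motion blur.

## Problem sizes and tolerances

Validation runs use scaled-down but fully representative inputs: 10 s clips
at 276 × 260 px for render-and-recover (centroid RMSE threshold 0.2 mm),
20-fly × 10 min trajectory-level cohorts for ethogram recovery (≥ 99%
bin-label agreement without emission noise, ≥ 95% with), 100-replicate fit
recovery (exact parameters to 1e-3 relative without noise; mean |Δc| < 0.1
time units at 5% trace noise), 500 × 500-shuffle null calibration for the
randomization test, and 200 cohorts of 300 trials for Wilson-CI coverage
(≥ 90% of bins).  Oracle-equivalence checks (motion counting, pause
scanning, trigger replay) are exact, not tolerance-based.

## Known limitations

Single-animal assumption throughout; no identity tracking, posture or wing
analysis.  The segmentation threshold and blob-size defaults are declared
conventions, not reconstructions of any particular rig.  The 50 px/s
freezing threshold is resolution-dependent (≈ 5% of a fly's pixel area at
the native 1104 × 1040 resolution) and is exposed in config rather than
auto-scaled.  The deceleration parameter c is gauge- and origin-dependent
(see above); only within-analysis comparisons are meaningful.  Closed-loop
simulation couples triggers to the evolving trajectory, but real rigs add
acquisition latency that is not modeled.
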