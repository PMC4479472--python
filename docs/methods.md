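# Methods

This note documents the models, algorithms and design choices behind
`apcdetect`: what each stage assumes, which parameters matter and why the
defaults are what they are, what the synthetic data generator does and
does not emulate, and the package's known limitations.

## The detection problem

A head-mounted tri-axial accelerometer on a diving pinniped records the
superposition of (i) the gravity component of head orientation, which
changes slowly, (ii) rhythmic swimming strokes at roughly 1–1.5 Hz,
(iii) fast, energetic head movements during prey strikes and handling,
and (iv) sensor noise, all hard-clipped at the logger's gain limit
(±3 g). Attempted prey captures (APC) — chases ending in a capture or a
missed lunge — produce bursts of high-frequency head movement whose
short-window variance rises well above the swimming baseline. The
detector therefore: high-pass filters each axis, computes a moving
variance per dive, finds variance peaks above a threshold, and merges
peaks closer together than a minimum interval into single APCs, on the
reasoning that one capture (strike plus handling) produces several peaks
in quick succession while distinct prey items are further apart.

## Signal-processing choices

* **High-pass filter** — 4th-order Butterworth, 3 Hz cutoff, applied
  forward-backward (`sosfiltfilt`). Zero-phase filtering matters: event
  times are matched to video windows, and a causal filter would delay
  every detection by a signal-dependent lag. The effective magnitude
  response is the square of the single-pass response; the test suite
  checks measured tone attenuation against this analytic curve.
* **Moving variance** — centred window of 1.5 s (30 samples at 20 Hz),
  sample variance with the n−1 denominator, computed by a cumulative-sum
  scheme and clamped at zero against round-off. Positions whose window
  would run past the dive's data are excluded rather than padded, so a
  dive shorter than the window yields no variance series (logged).
  Centred windows keep variance peaks aligned with their bursts, which
  the time-based event matching relies on.
* **Peaks** — strict local maxima above the threshold; plateaus of equal
  values count once, at their first sample; series endpoints are never
  peaks. These conventions are pinned by an independent brute-force
  oracle in the tests.
* **Grouping** — a chain rule: consecutive peaks with gap ≤ the minimum
  interval join one APC; a gap above it starts a new APC. Chains can
  therefore extend transitively; this is intentional (a long handling
  bout is one event) but has consequences for parameter monotonicity
  (see *Limitations*).
* **Per-APC features** — duration and integral area are measured over
  the supra-threshold extents of the variance curve containing the
  group's peaks (merged across peaks), not merely first-to-last peak
  time. The integral is trapezoidal over time (units g²·s) by default;
  `integral_mode="sample_sum"` instead sums the raw variance samples
  (units g²) for compatibility with reports that quote the area that
  way. The switch only rescales the feature; it does not affect
  detection or matching.

## Dive segmentation

Depth is zero-offset corrected by subtracting a centred rolling minimum
(default window 600 s — it must span at least one surfacing, i.e. exceed
the longest dive) and flooring at zero. This removes constant and slowly
drifting pressure offsets and is verified by injecting a known offset
and recovering it. Dives are contiguous excursions below the 2 m
surface-exclusion depth whose maximum exceeds 15 m; descent ends where
vertical speed first falls below 10% of the dive's peak vertical speed,
ascent starts symmetrically from the end, and the bottom phase is the
remainder (zero-length for a V-dive). The 10% fraction is configurable;
a relative threshold adapts to fast and slow divers without a new
parameter per deployment.

## Matching and error metrics

Matching is per dive and time-based: a detection matches the annotated
event whose window contains its first-peak time. Per event the earliest
matching detection is the TP; additional matches are FPs (the detector
over-counted one capture), as are detections inside no window. Events
with no detection are FNs. Abandoned chases (no capture lunge) are not
APCs: they are excluded before matching and leave a dive prey-absent. A
dive with neither events nor detections contributes exactly one TN —
TN is only meaningful at dive level, which is also why accuracy and
specificity are not computed. Overlapping annotation windows (rare, but
video events can abut) are disambiguated deterministically: nearest
event start wins, ties to the earlier event, and the case is logged.

Percentages are carried at full precision and rounded to one decimal
only in reports. The FP rate is computed as 100 − precision, making the
complement identity exact in floating point; this equals the
FP/(TP+FP) definition algebraically. Per-animal aggregation is
counts-first: pool an animal's confusion counts over its dives, compute
one metric per animal, then take the unweighted mean ± SD across animals
so each animal is one data point regardless of how many dives it
contributed. Undefined metrics (zero denominators) propagate as explicit
`None` with a reason, never as silent zeros, and are excluded (and
counted) in aggregation.

## Holdout optimisation

Each animal's annotated dives are partitioned once into training and
testing subsets. The split is a seeded permutation split — shuffle and
take `round(n/2)` for training — rather than an independent coin flip
per dive: the realised proportion then stays within ~1 dive of 50%
(48.6–51.4% for cohorts of a few dozen dives), matching how realised
holdout proportions are reported, while remaining uniform over balanced
assignments. The grid search evaluates every
(threshold, interval) pair on the training dives only; each result row
carries a subset provenance tag and the selector refuses rows not tagged
`training`, so leakage is structurally prevented rather than merely
avoided. Selection maximises detection; candidates within a 2-percentage-
point tie window (absolute) are resolved by highest precision, and
residual ties go to the lowest threshold, then the shortest interval —
the most sensitive, most generic setting. The variance series per dive
is cached across the grid, since threshold and interval only affect the
peak/grouping stages.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes:

| quantity | default | basis |
|---|---|---|
| dive maximum depth | U(61, 86) m | benthic shelf foraging range |
| prey events per dive | round(N(2.6, 1.6)) clipped to 1–7 | reported per-dive counts |
| success probability | 0.93 | reported video success rates |
| successful APC duration | N(4.1, 2.7) s, clipped 1–9 s | reported durations |
| unsuccessful APC duration | N(2.7, 1.2) s, clipped 1–6 s | reported durations |
| sub-bursts per successful APC | ≈ duration/1.5, max 8 | reported 1–8 peaks with handling |
| burst carrier | 6 Hz, Hanning envelope | above the 3 Hz cutoff, below Nyquist |
| burst amplitude | 1.5 g × U(0.9, 1.1) per event | free choice; strong but sub-clip |
| axis scaling | surge 1.0, sway 0.9, heave 0.5 | heave strikes are weakest |
| stroke baseline | 0.25 g at 1.2 Hz | typical stroking below the cutoff |
| orientation drift | 0.4 g at 0.01 Hz + static offset | removed by the high-pass stage |
| sensor noise | white, sd 0.05 g | typical logger noise floor |
| inter-event spacing | U(25, 60) s | 1–7 events over a multi-minute bottom phase |
| surface interval / descent rate | 60 s / 1.5 m s⁻¹ | plausible benthic-dive schedule |

Annotation windows span each event's burst train padded by 1 s of chase
lead-in and handling tail, because the 1.5 s variance window smears
peaks up to ~0.75 s outside the burst itself; real video windows
likewise start at the chase, before the strike. Distractors (non-feeding
head movements) are single 1–2 s bursts scheduled into the same
event chain, so they never overlap APC windows. Dives are trapezoidal
with the bottom phase sized to its event chain; an explicitly requested
duration too short for the schedule raises a packing error instead of
truncating. Per-dive draws come from a child generator seeded
`(seed, 1000 + dive_index)` in a documented order, so tests can re-derive
them independently of signal synthesis; identical configs give
byte-identical files.

What the generator does *not* emulate — and hence what passing tests do
not show about field data: hydrodynamic noise and burst-shape diversity,
amplitude overlap between captures and distractors (real non-feeding
head movements are not cleanly separable, which is why field FP rates
are tens of percent while the clean synthetic benchmark reaches 0%),
search-swimming sway that raises baseline variance, clock drift between
instruments (only constant offsets are modelled), duty-cycled video
coverage, and any prey-type signal in the acceleration (none was found
in real data either). Results on synthetic deployments validate the
machinery — filtering, segmentation, detection, matching, bookkeeping,
selection — not field-realistic error magnitudes.

## Numerical and degenerate-input conventions

Uniform-sampling tolerance on file input is half a sample period; the
first offending row is named in the error. Depth upsampling preserves
original samples bit-exactly and interpolates linearly in between
(exact on affine profiles). Stream alignment trims to the common window
on a shared grid and refuses non-overlapping or too-short overlaps.
Clip-limit violations, inverted event windows, unknown categories,
negative counts and out-of-order phase boundaries all raise at
construction time. Zero-denominator metrics are explicit `None`s.
A dive shorter than the variance window detects nothing and logs why.

## Limitations

* Count-monotonicity in the variance threshold is **not** a theorem
  under chain grouping: deleting an interior peak can split a chain into
  two groups. With realistic event spacing (wider than the largest grid
  interval) chains never span events and the package's grid-wide
  monotonicity checks pass; on data with events packed closer than the
  minimum interval, raising the threshold can genuinely increase the
  APC count. Monotonicity in the minimum interval, by contrast, is exact.
* Within one event, sub-bursts share one amplitude; real handling bouts
  vary within events, which would soften detection thresholds'
  all-or-nothing effect per event.
* The rolling-minimum zero-offset correction assumes the animal surfaces
  at least once per correction window and that surface readings are the
  window minimum; strongly non-monotone sensor drift would need a more
  elaborate corrector.
* Formal mixed-effects inference on generic-vs-specific parameter
  differences is out of scope; the package reports paired per-animal
  descriptive differences instead.
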