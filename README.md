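# apcdetect

Detection and video validation of **attempted prey captures (APC)** from
head-mounted tri-axial accelerometers on diving pinnipeds.

Free-ranging marine predators cannot be watched while they hunt, so
foraging is inferred from animal-borne sensors. A small accelerometer
glued to a seal's head records the rapid strike and prey-handling
movements that accompany each capture attempt; an animal-borne video
camera, deployed on a subset of animals, supplies the ground truth needed
to measure how well the accelerometer alone detects those events. This
package implements that whole workflow for biologging researchers:
signal processing, per-dive event detection, event-level validation
against annotated video, error metrics, and holdout tuning of the
detector's parameters — plus a synthetic deployment generator so every
stage is testable without field data.

## Method

For one acceleration axis `a(t)` (surge, sway or heave, sampled at 20 Hz,
clipped at ±3 g) within one dive (depth > 2 m, dives defined by a 15 m
threshold on the zero-offset-corrected 1 Hz depth record, linearly
interpolated to 20 Hz):

1. **High-pass filter**: zero-phase 4th-order Butterworth, cutoff 3 Hz —
   removes gravity/orientation and swimming strokes (~1.2 Hz), keeps
   strike/handling bursts.
2. **Moving variance**: sample variance `s²(t)` in a centred 1.5 s window.
3. **Peak detection**: local maxima of `s²(t)` strictly above a variance
   threshold `v` (g²).
4. **Grouping**: consecutive peaks ≤ `τ` s apart (the minimum interval)
   form one APC; a larger gap starts a new APC.
5. **Features**: per APC, the time of its first peak, its duration and
   trapezoidal integral area over the supra-threshold extents, and its
   peak count.

A detection is a **true positive** if its first-peak time falls inside an
annotated video event window (chase start → handling end); extra
detections matched to the same event, and detections inside no window,
are **false positives**; unmatched events are **false negatives**; a dive
empty on both sources is one **true negative**. Metrics follow the
event-validation conventions:

```
detection = 100·TP/(TP+FN)      (sensitivity/recall)
precision = 100·TP/(TP+FP)
FP rate   = 100·FP/(TP+FP) = 100 − precision
```

The two free parameters `(v, τ)` are tuned per animal by a seeded 50/50
dive-level holdout: a grid search over `v ∈ {0.1, 0.2, 0.4, 0.8}` g²
(heave drops 0.8) × `τ ∈ {5, 10, 20}` s on the training dives maximises
detection, with candidates within 2 percentage points resolved by highest
precision; generic one-size-fits-all parameters are `(0.1 g², 5 s)`. All
reported metrics come from the testing dives only, pooled counts-first
per animal, then averaged across animals (mean ± SD, each animal one
point). Dive-level foraging classification (a foraging dive has ≥ 1 APC)
yields the foraging-dive identification error.

## Worked example

```python
from apcdetect import CaptureValidation
from apcdetect.synthetic import SimConfig

study = CaptureValidation.from_simulation(
    n_animals=4, seed=1, axes=("surge", "heave"),
    config=SimConfig(seed=0, n_dives=12, distractor_rate=0.5),
)
results = study.fit(seed=1)
print(results.summary())
```

prints

```
Accelerometer APC validation — testing subset, mean (SD) across animals
animals: 4; axes: surge, heave; split seed 1; tie window 2%

Axis    Parameters           Detection %     FP rate %   Precision %  Total APC
surge   Generic              100.0 (0.0)    14.9 (7.3)    85.1 (7.3)         70
surge   Animal-specific      100.0 (0.0)    14.9 (7.3)    85.1 (7.3)         70
heave   Generic               86.3 (5.7)     9.9 (4.0)    90.1 (4.0)         57
heave   Animal-specific       86.3 (5.7)     9.9 (4.0)    90.1 (4.0)         57

animal-specific parameters [surge]: A1: 0.1/5s, A2: 0.1/5s, A3: 0.1/5s, A4: 0.1/5s
animal-specific parameters [heave]: A1: 0.1/5s, A2: 0.1/5s, A3: 0.1/5s, A4: 0.1/5s
foraging dives (surge, generic): video 24, accelerometer 24 -> underestimate 0.0%
```

Each simulated animal dives 12 times with on average 2.6 prey events per
dive plus non-feeding head-movement distractors (0.5/dive). On surge the
detector finds every injected capture (detection 100%) while the
distractors it flags make up ~15% of detections (FP rate); on heave the
bursts are weaker, so some captures drop below the 0.1 g² threshold
(detection 86%) but fewer distractors trigger it. The grid search
recovers the generic parameters (0.1 g², 5 s) for every animal, and
dive-level foraging classification agrees perfectly with video here.

The same stages are available from the shell:

```
apcdetect simulate --seed 1 --n-dives 10 --out deploy/
apcdetect detect --accel deploy/accel.csv --depth deploy/depth.csv \
    --axis surge --variance-threshold 0.1 --min-interval 5 --out apc.csv
apcdetect run-all --seed 1 --n-animals 4 --out run/
```

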