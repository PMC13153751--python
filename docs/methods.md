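# Methods

## Problem and approach

Grip strength — maximal isometric hand force, measured in kg with a
Jamar-style dynamometer — is a widely used clinical biomarker for
sarcopenia and frailty, but measuring it requires a dedicated
instrument. `gripsense` implements a pipeline that estimates grip
strength from how a person performs three short touchscreen tasks on a
phone held in the working hand:

* **tap** — ten circular targets (14.6 mm) appear one after another and
  are tapped away;
* **flick** — a small ball (7.3 mm) is flicked toward a goal target ten
  times;
* **drag** — an outward Archimedean spiral (4.4 mm stroke) is traced
  once from the center.

During the tasks the device's accelerometer, gyroscope and orientation
sensors record at 60 Hz. Each *set* (two dynamometer squeezes, averaged
into the ground truth, followed by one execution of each task) becomes
one training row per task; a *unified* row concatenates the three tasks'
features. Regression models map the feature rows to grip in kg.

## Sensor preprocessing

1. **Regridding and interpolation.** Inertial streams are regridded to a
   uniform 60 Hz base; missing values (dropped frames or NaNs) are
   filled per channel by linear interpolation, with nearest-value
   extension at the boundaries. Interpolation is idempotent.
2. **Low-pass filtering.** A 4th-order Butterworth low-pass with a 20 Hz
   cutoff, applied forward-backward (zero phase), realized as
   second-order sections: the cutoff sits at 2/3 of the 30 Hz Nyquist
   frequency, where a transfer-function realization would be
   ill-conditioned. Filtering is applied to the full stream before
   windowing. Order and cutoff are configurable.
3. **Event windows.** Around each input event three windows are taken:
   the 10 frames immediately before the event, the average value at the
   event time (a one-frame-wide interval centered on the anchor), and
   the 10 frames immediately after. Events too close to a stream edge
   are completed by repeating the terminal frame, and the padding count
   is recorded, so every sub-event yields a complete feature set.

## Features

Per anchor, each of the 9 sensor channels contributes the max, min,
range, mean, and mean absolute consecutive-frame difference for the pre
and post windows, plus the during-input channel value: 99 statistics.
Behavioral features are per-sub-event quantities aggregated by their
mean over an execution (one grip value maps to one execution, which
fixes the row unit; the within-execution aggregator is a design choice,
and standard deviations can be emitted as well):

* tap — spatial error (mm to the target center, taken at touch-down),
  elimination time, touch duration, contact area;
* flick — stroke direction as the unit vector from the first to the
  last sample of the stroke (x and y components), elimination time,
  stroke duration, contact area; zero-length strokes have no direction
  and are excluded from the aggregate with a logged count;
* drag — tracing accuracy (mean distance from each touch sample to the
  nearest spiral centerline point), speed and acceleration magnitudes
  (mean and max) from central finite differences of the raw touch path,
  contact area, total duration.

Touch paths are deliberately *not* low-pass filtered — the 20 Hz filter
is a sensor-stream operation. Contact area stays in device-normalized
units because no physical unit is defined for it; the per-stroke mean is
used (switchable). Feature names are versioned through a schema hash
embedded in feature-matrix headers, and fitted models refuse matrices
whose hash does not match.

## Spiral geometry

The drag reference curve is the Archimedean spiral r(θ) = pitch·θ/2π.
Only the stroke width and the chirality convention (clockwise for the
right hand) are fixed by the task; pitch (8 mm) and turn count (3) are
package defaults chosen to fit the 72.9 × 152.0 mm screen with margin.
`spiral_point` parameterizes the curve by arc-length fraction using the
closed-form arc length of the Archimedean spiral inverted by Newton
iteration. `distance_to_spiral` seeds each query from a dense θ grid and
refines with a safeguarded, trust-region-clamped Newton step on the
derivative of the squared distance; the result is accurate to well below
0.01 mm and fully vectorized, which matters because every drag sample
queries it. Tests cross-check it against brute-force minimization over
10⁵ centerline samples. Left-hand sessions are mirrored into the
right-hand convention by x ↦ width − x on touch points and targets and a
chirality flip (an involution that leaves timestamps and sensor streams
untouched).

## Synthetic cohort generator

No public dataset accompanies this problem, so the generator is a
first-class, tested component that emulates the study design: by default
21 participants × 5 days × 10 consecutive sets (1050 rows per task).

**Latent grip.** G = μ + uᵢ + vᵢd − fatigue_slope·(s−1), truncated at
1 kg, with uᵢ ~ N(0, user_sd²) between users and vᵢd ~ N(0, day_sd²)
between days. The within-day slope models the fatigue deliberately
induced by squeezing a dynamometer before every set; its default
(0.3 kg/set) is a free parameter, not an empirical value. Defaults
μ = 30 kg, user_sd = 4 kg concentrate the cohort around 25–35 kg. Two
dynamometer readings add independent N(0, 0.5²) noise; the ground truth
is their mean.

**Grip→behavior coupling.** Each behavioral channel c (timings, spatial
and tracing error, contact area, device jitter amplitude) is driven by

    b = coupling · (−z + w_ic) + (1 − coupling) · ε,

where z = (G − μ)/grip_population_sd is standardized grip, w_ic is the
user's idiosyncratic offset in how grip maps to that channel (plus
smaller per-day offsets and a scalar day state shared across channels),
and ε is fresh noise. Channels respond log-linearly (value =
base·exp(sensitivity·b)), keeping them positive; weaker grip means
slower, less accurate, shakier interaction, and smaller contact area.
The noise ε mixes a per-execution state (weight 0.8) with per-sub-event
scatter: the shared state does not average out across a task's ten
sub-events, giving every single task an irreducible error floor, while
the three tasks' states are independent — so the unified model can
genuinely outperform each single-task model, which is the qualitative
structure the analysis expects. At coupling = 0 behavior carries no
grip information at all; in particular, sensor posture baselines are
re-drawn every set rather than per participant, because any persistent
per-user signature would let a model identify the user and predict
their mean grip even without coupling.

**Streams.** Sensor streams are baseline + smoothed jitter (amplitude
grip-coupled) + white noise, with a small missing-value rate (1%)
exercising the interpolation path. Touch streams are synthesized
consistently with the task layouts at 60 Hz. Seeding is counter-based
(`SeedSequence(master, spawn_key=(participant, day, set))`), so
enlarging a cohort never perturbs existing participants.

What the generator does **not** emulate: real biomechanics, device-
specific sensor spectra, heteroscedastic touch noise, left-hand users,
learning effects across days. Passing tests therefore demonstrate that
the pipeline recovers the statistical structure it assumes — not that
the published human-data accuracy is attainable, which cannot be
verified without the (undeposited) study data.

## Models and validation

Four regressors, all behind a z-score standardizer fitted on training
rows only: random forest (200 trees, depth 20, √p features per split,
random_state 42), RBF-kernel SVR (C = 100, gamma = "scale"), gradient
boosting (100 estimators, learning rate 0.1, depth 5), and k-NN (9
neighbors, distance-weighted, Manhattan metric). Unstated
hyperparameters stay at scikit-learn defaults and are recorded in the
run manifest. Constant features get scale 1 (center = the constant).
Grid search minimizes mean cross-validated MAPE with ties broken by the
order of the grid specification.

Validation schemes: shuffled 5-fold cross-validation; leave-one-user-out
(one fold per participant); and few-day calibration, where the training
set is all other participants plus the target's chronologically first
d ∈ 1..4 days (an onboarding scenario; an option instead averages all
C(5, d) day subsets). d = 0 is identical to the leave-one-user-out fold.
Metrics are MAE (kg), MAPE (%, denominator = true grip, which the
generator keeps ≥ 1 kg) and R², computed per fold and aggregated as
mean (SD) across folds — not pooled — matching how per-fold spreads are
conventionally reported. A mean-predictor baseline is always evaluated
alongside: with no real data, *relative* improvement over baseline is
the meaningful yardstick.

The raw NASA-TLX overall workload is the unweighted mean of the six
subscale ratings (0–10 scale), reported to 2 decimals.

## Problem sizes and numerical choices

End-to-end statistical checks use scaled-down cohorts chosen as a
package decision for single-CPU runtimes: 12 × 5 × 10 for the
task-scope comparison (the study's per-day design with fewer
participants — at a few hundred rows estimation noise swamps the
modest unified-over-tap margin, so this check needs the larger size),
12 × 5 × 4 for the leave-one-user-out and calibration comparisons, and
8 × 3 × 4 for the zero-coupling null (10 seeds each); the design-count
and signal-recovery checks run the full 21 × 5 × 10 design. The
scope-ordering comparison uses gradient boosting: RBF-SVR concatenating all three tasks' features
(313 columns) suffers kernel distance dilution from the many
uninformative dimensions, which can offset the averaging gain, whereas
tree boosting selects informative features and exposes the unified
model's advantage directly. The leave-one-user-out and calibration
comparisons use SVR, the strongest single model in this family.

Floats are serialized with 12 significant digits (round trips well
within 1e-9 relative); reports are JSON with sorted keys so identical
runs are byte-identical. All estimators run single-threaded with fixed
random states.

## Known limitations

* The spiral's pitch and turn count, the flick goal distance (25 mm),
  and the within-execution aggregator are explicit package choices; the
  task design leaves them open.
* Whether filtering should precede or follow window extraction is
  undocumented in the protocol this follows; filtering first was chosen
  and the alternative is a one-line change flagged for sensitivity
  analysis.
* MAPE is scale-dependent at low grip values; the generator truncates
  latent grip at 1 kg, and real low-grip populations would need a
  different error metric.
* The published human-data error magnitudes are not reproducible here
  by construction; only directions and relative improvements are
  testable against the synthetic cohort.
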