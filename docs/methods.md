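# Methods

## Measurement model

The elbow is treated as the junction of two rigid segments instrumented
with one electromagnetic sensor each (humerus and forearm) plus a stylus
sensor for digitization. A sensor pose is a timestamped position (mm) and
scalar-first unit quaternion; streams are nominally 60 Hz and are paired
across sensors by nearest timestamp, rejecting gaps larger than half a
sample period.

Five landmarks — greater tubercle, medial and lateral epicondyles (humerus
sensor), radial and ulnar styloids (forearm sensor) — are digitized by
averaging the stylus tip expressed in the host sensor's frame over a short
window. The stylus tip is taken to be the stylus sensor origin (an optional
constant tip offset is supported; pivot calibration is out of scope). The
radial styloid is treated as rigid with the forearm sensor, which is valid
because the protocols lock the forearm in supination.

The anatomical frames follow the landmark construction given in the README.
Two conventions deserve note:

- **Cross products and normalization.** The frame construction is only
  well-defined with explicit cross products and unit-normalized axes; the
  argument order (landmark offset × longitudinal axis) is chosen so that
  with the arm straight the two y-axes coincide and the flexion angle is
  exactly 0°, rising to ~135° at deep flexion. Both frames come out
  right-handed.
- **Angle evaluation.** Flexion is the arc-cosine of the dot product of
  the two y-axes. It is evaluated as `atan2(|u×v|, u·v)`, which is the
  same function of unit vectors but numerically well-conditioned near 0°
  and 180°, where a literal `acos` of a rounded dot product loses roughly
  half the available precision. The angle is unsigned ([0°, 180°]):
  hyperextension folds onto small positive angles, a known limitation of
  the acos definition.

Degenerate landmark geometry (triangle area ≤ 1 mm²) raises an error in the
scalar API; in time-series processing such samples are excluded and logged
instead, so one corrupt frame does not abort a trial.

## Plateau detection

Holds are detected as maximal runs where the centered rolling-window SD of
the angle stays at or below a threshold. Defaults: 0.5 s window, 1.5°
threshold, 2.0 s minimum duration — sized to accept ~3 s holds measured
with ~0.2° sensor-level angle jitter while rejecting ramps at tens of
degrees per second. Each plateau is summarized by the mean (not a snapshot
sample) and sample SD of its angles; the mean matches the convention of
reporting a single angle per hold. Plateaus are matched to nominal target
angles (default 0/45/90/135°) within a 10° tolerance; when two plateaus
claim the same nominal, the closer wins, ties going to the earlier one.

## Agreement statistics

- **Differences** are always method − reference, so positive bias means
  the EMS reads high.
- **Bland–Altman** limits are mean ± 1.96·SD with the n−1 SD; the fixed
  1.96 multiplier (not a t quantile) is the convention for 95% limits of
  agreement. `limits_from_summary` applies the same arithmetic to reported
  summary statistics.
- **Pearson** r carries the exact two-sided p from the t transform on n−2
  degrees of freedom, plus a strength label (slight/fair/moderate/
  substantial/almost perfect in 0.2-wide bands of |r|, edges belonging to
  the lower band).
- **ICC** follows Shrout–Fleiss: one-way random (measurements nested in
  targets; intra-rater use) and two-way random with absolute agreement
  (raters crossed with targets; inter-rater use), each in single and
  average-of-k form. CIs use the F-distribution constructions with
  Satterthwaite degrees of freedom for the two-way model. Estimates are
  reported exactly as the ANOVA formulas give them — average-of-k forms
  can fall below −1 on noise-only data — while the CI is clamped to
  [−1, 1] and widened, if necessary, to bracket the estimate. A constant
  matrix raises (ICC undefined); identical columns with distinct targets
  return exactly 1.

## Simulator

The simulator is a planar hinge: the humeral shaft is fixed along +z with
the epicondylar axis along x, and the forearm segment rotates rigidly about
that axis. Supination is locked and no carrying-angle obliquity is modelled
— the measured quantity is the single acos angle, which this geometry spans
exactly. Default segment geometry: humerus 300 mm, forearm 250 mm,
epicondylar half-width 30 mm, wrist half-width 25 mm, sensors offset 20 mm
from the bone axis with fixed non-trivial mounting rotations so every
transform path is exercised.

A trial is a ramp-and-hold trajectory: 3 s holds joined by 1 s
cosine-eased ramps, sampled at 60 Hz. Stochastic terms, all per-trial
seeded:

| term | default | meaning |
|---|---|---|
| `pos_noise_rms` | 0.76 mm | per-sample sensor position noise, isotropic; per-axis σ = RMS/√3 so the 3-D norm RMS matches |
| `ori_noise_rms` | 0.15° | per-sample rotation by \|N(0,σ²)\| about a uniform random axis |
| `hold_sd_deg` | 1.0° | examiner hold-placement error, one draw per hold |
| `digitization_noise_mm` | 0.76 mm | stylus tip scatter during registration (60 samples averaged) |
| `artifact_gain` | 0.08 | in-vivo only: per-hold forearm-sensor rotation with SD = gain × true angle |
| `xray_noise_sd_deg` | 1.0° | reading error of the radiographic reference |

The position/orientation noise levels are the tracker's stated RMS
accuracy; the 1° hold SD represents a careful examiner working against
pre-marked goniometer targets. The soft-tissue artifact models brace
displacement from biceps contraction as a zero-mean rotation about the
flexion axis, constant within a hold and proportional to flexion; the gain
0.08 is a tuning choice (no quantitative artifact model exists to adopt)
set so simulated in-vivo flexion differences spread on the order of 10°
while extension differences stay near the sensor floor. The radiographic
reference is truth plus small Gaussian error, not an image simulation.

Because the commanded hold at 0° can be slightly negative (hyperextension)
and the angle definition is unsigned, the recorded truth is the absolute
commanded angle; this reproduces the positive mean bias real bench tests
show at 0°.

In-vivo experiments draw six subjects' true extremes from a normal
population (extension 2.7 ± 2.0°, flexion 130.8 ± 4.5°, extension clipped
at 0°) and measure each subject repeatedly per rater (default 2 raters × 3
repeats → 36 paired EMS/radiograph readings). What the simulator does NOT
emulate: magnetic-field distortion, marker occlusion, pro/supination,
carrying angle, muscle-model artifact dynamics, or any image formation —
so passing tests demonstrate the correctness of the computational pipeline
and the statistical machinery under the stated noise structure, not the
behaviour of real tissue.

## Experiment harness and problem sizes

`run_validation_experiment` reproduces the two study designs: the bench
protocol (default 2 raters × 10 reps × 4 angles, 80 plateau measurements)
and the in-vivo protocol (6 subjects × 2 raters × 3 reps, 36 pairs). These
defaults match the validation studies this pipeline targets and run in
about a second. Intra-rater ICCs use the per-rater nominal × repetition
matrix (one-way); inter-rater ICCs use the (nominal, repetition) × rater
matrix (two-way random) — the layout is a design choice, as reliability
reports rarely state it. Per-trial seeds are the experiment seed plus the
trial index; identical configurations therefore produce byte-identical
outputs.

## Numerical and I/O choices

- Quaternions are normalized on ingest; read policy for files: silently
  renormalize deviations ≤ 1e-6, warn up to 1e-3, reject beyond (corrupt
  data rather than serialization rounding).
- CSVs are written at 17 significant digits and parsed with round-trip
  float precision, so write→read is lossless.
- Angle series tolerate 1e-9 out-of-range rounding and clip to [0, 180].
- Report tables round only at the rendering layer (1 dp for angles, 3 dp
  for dimensionless coefficients); all internal values are unrounded.

## Known limitations

- Hyperextension is unsigned; a signed convention would need an extra
  reference axis the landmark set does not provide.
- The plateau detector assumes a uniform sample rate and a hold at least
  as long as the minimum duration; brief touches are ignored by design.
- The one-way/two-way ICC matrix layouts above are one reasonable reading
  of common reporting practice; alternative layouts (e.g. rater means as
  columns) give slightly different inter-rater values.
- The soft-tissue artifact is phenomenological; its gain controls the
  simulated in-vivo error spread directly and should not be interpreted
  as a tissue property.
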