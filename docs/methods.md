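# Methods

## Model and assumptions

The pipeline treats the cranium, upper jaw (palatoquadrate) and lower jaw
(Meckel's cartilage) as rigid bodies — reasonable for shark jaws, whose
tessellated cartilage is very stiff — each carrying ≥3 non-collinear
implanted markers (4 on the cranium).  Input is tracked 3D marker
positions in mm at 320 or 330 Hz; everything upstream (video acquisition,
image-based tracking, CT-based marker reference coordinates) is out of
scope, and no interpolation of missing markers is performed: a frame with
fewer than three visible markers of a body simply has no pose.

### Pose fitting

Per frame and body, the pose minimises Σᵢ‖R pᵢ + t − qᵢ‖² over proper
rigid transforms (Kabsch via SVD of the cross-covariance, sign correction
on the smallest singular direction so det R = +1, which also resolves the
reflection ambiguity of planar three-marker sets).  This is the
maximum-likelihood estimate under isotropic Gaussian marker noise.  The
fit residual (RMSD, mm) is recorded per frame as a quality diagnostic.

### Joint coordinate systems

An anatomical coordinate system (ACS) is built from a config-supplied
origin and two hint directions: X = x̂_hint normalised, Y = ẑ_hint × X
normalised, Z = X × Y (right-handed; the z hint need not be orthogonal to
the long axis).  The JCS angle series is the z-y-x Euler decomposition
(R = R_z R_y R_x, active rotations, column vectors, θ_y ∈ [−90°, 90°]) of
the distal ACS expressed in the proximal (cranial) ACS.  Channels are
unwrapped along time with a 180° jump threshold (jaw motions stay far
below ±180°, so channel-wise unwrapping is safe) and zeroed by
subtracting the reference-frame angles (default: frame 0); for the small
angles involved this is indistinguishable from pre-composing a reference
offset.  At gimbal lock (|cos θ_y| < 1e-7, never approached by jaw
motions of ≤ ~23°) the convention θ_x = 0 with θ_z absorbing the sum is
applied and the frame flagged.

Sign semantics: depression negative / elevation positive on θ_z for both
jaws; inversion positive / eversion negative on θ_x for both jaws, which
works because the upper-jaw long axis points caudally while the lower-jaw
long axis points cranially; θ_y is mapped to a "joint moves laterally
positive" channel via a per-jaw sign (+1 lower, −1 upper).  The ACS
placement itself (origin at the jaw joint, exact axis directions) is
config-driven: anatomy stays in the configuration, not in the math core.

### Events and summaries

Gape is the Euclidean distance between two body-attached landmarks (the
jaw tips).  Peak gape (maximum, ties to the earliest frame) defines
t = 0 ms.  Initial jaw depression is the frame after the last ventilatory
closure before peak gape, where "closed" means gape ≤ 2% of the trial's
maximum (a small, configurable numeric proxy for jaw closure; a trial
whose gape never closes is flagged).  Expansive-phase onset is the first
frame at/after initial depression with gape ≥ 10% of maximum
(configurable).  Channel extrema are taken over the analysis window
[initial depression, trial end]: eversion is the LAR minimum, inversion
the maximum *after* the eversion extremum (inversion follows eversion
with jaw closing; this guards against picking a pre-strike maximum),
depression the θ_z minimum; ties go to the earliest frame.  Timings are
(frame − peak frame)/rate × 1000 ms.  Across trials each quantity is
reported as mean ± s.e.m. (sample s.d., n−1 denominator, over √n); all
trials are pooled rather than averaging per individual first.

### Precision statistic

For every within-body marker pair, the sample s.d. over frames of the
inter-marker distance; a rigid body moved without noise gives exactly 0.
For i.i.d. per-coordinate noise of s.d. σ, the difference of two marker
errors projected on the inter-marker axis gives a pair-distance s.d. of
σ√2 (first order in σ/distance).  The report pools all pair s.d. values
and gives their arithmetic grand mean together with both the s.d. and the
s.e.m. of the pooled values, since "mean ± x" conventions differ between
studies; the pair count is generic.

## Smoothing and extremum bias

With 0.1 mm marker noise on ~15 mm marker triangles, per-frame JCS angle
noise is roughly 0.5° per axis.  The extremum of an unsmoothed noisy
channel is biased *outward* by approximately the expected maximum of the
noise over the frames near the true peak — order 0.5–1°, comparable to
the across-trial s.e.m. being estimated.  Event detection therefore
optionally low-pass filters the angle channels and the gape series with a
zero-phase 4th-order Butterworth filter (filtfilt, so peaks are not
shifted in time).  The default cutoff is 20 Hz: jaw-strike pulses of
~110–240 ms duration concentrate below ~10 Hz and lose < 0.1% of their
peak, while noise variance drops by ~8×, leaving a residual extremum bias
of ~0.1–0.2°.  The library default is smoothing **off** (the raw-channel
analysis is always available and the angle CSVs always contain unsmoothed
values); the configuration emitted for synthetic studies enables it.

## Synthetic data generator

The generator emulates the study conditions: 3 individuals ×
4 trials, 320 Hz, ~2 s per trial, 0.1 mm isotropic marker noise
(calibrated against a 0.12 mm grand-mean pair-distance precision via
σ = 0.12/√2), a static cranium during the strike (optional slow drift is
available), and per-trial pulse magnitudes/timings drawn from study
tables whose defaults are the across-trial means: eversion −8.0° (trial
s.d. 1.1), inversion 11.2° (1.5), upper eversion −12.3° (0.9), lower
depression −22.7° (0.6), upper depression −15.7° (1.8); timings −19 ms
(7), +87 ms (6), 0 ms (1.6), +6 ms (2), +55 ms (5) relative to peak gape.

Design choices, each made once:

* **Raised-cosine pulses** (compact support, smooth, drawn amplitude =
  exact extremum) model the pulse-like channel traces; real angle traces
  are not exactly of this family.
* **Geometry**: cranium markers on a ~20 mm tetrahedron, jaw markers on
  ~15 mm triangles ~40 mm from the joint — consistent with a ~6.5 cm
  cranium, so noise-to-lever-arm ratios are realistic.  Both jaw ACSs sit
  at the joint, world-aligned at rest; gape landmarks are the jaw tips,
  *on each jaw's long axis*, which makes gape exactly independent of the
  LAR channels.
* **Two-stage timing draw**: hinge (depression) channels are drawn first
  and determine the realized noise-free peak-gape frame; LAR pulse times
  are then drawn relative to that frame, so LAR timing recovery is
  anchored to the same event the analysis uses.
* **Gape-peak calibration**: the upper-jaw depression (protrusion, which
  closes the mouth as the upper tip chases the lower tip) has its pulse
  duration solved deterministically so the nominal noise-free gape
  derivative vanishes at the pulse time origin.  Of the two roots the
  faster is used: an accelerating protrusion gives a sharp, unambiguous
  gape maximum, whereas the slower root balances opening against closing
  for tens of ms and yields a flat-topped, ill-defined peak.
* **Sustain pulse**: a broad half-amplitude depression pulse starting
  4 ms after the strike peak keeps the lower jaw depressed through
  closing (the mouth closes by upper-jaw protrusion, and gape reaches ~0
  again near +100 ms), without altering the drawn depression extremum.
* **Ventilation**: three small (−1.5°) pre-strike depression bumps make
  the gape open and fully close rhythmically, so "frame after the last
  ventilatory closure" is a genuine event.  Eversion begins before
  initial depression, as observed in vivo.
* **Seeds**: per-trial seeds are base_seed + trial index; magnitude and
  timing draws are independent (their true trial-to-trial covariance is
  unknown).

What passing recovery tests therefore show: the full chain of
conventions (axes, rotation order, signs, zeroing, event definitions,
timing arithmetic) inverts correctly, and estimation noise at realistic
marker precision does not bias across-trial means beyond ~0.4° / ~1 ms.
What they do not show: robustness to non-rigid deformation, tracking
outliers, marker occlusion structure, or motion outside the pulse family.

## Problem sizes and numerics

Default validation studies use 12 trials × 640 frames; precision studies
3 × 5,000 frames.  Collinearity is declared when the second singular
value of the centered marker coordinates falls below 1e-8 of the first.
Rotation matrices are validated to 1e-6 orthogonality before Euler
decomposition.  Marker CSVs are written with 17 significant digits and
parsed with correctly-rounded float conversion, so write→read is the
identity; analysis outputs use fixed 6-decimal formatting, so re-running
a study is byte-identical.

## Known limitations

* Single-joint chains only (each JCS shares the cranium as proximal
  body); hyoid-arch elements would need their own JCS definitions.
* Gape is a landmark-pair distance; angular gape metrics are not
  implemented.
* JCS translations are retained in the pose series but not decomposed
  along JCS axes; no helical-axis or quaternion reporting.
* The s.e.m. pools all trials; per-individual nesting (mixed models) is
  out of scope.
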