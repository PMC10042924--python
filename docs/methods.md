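# Methods

This note records the model behind `clearspeech`, the main design decisions,
and the package's limitations. Formulas use 1-based landmark indices in the
68-point iBUG convention.

## 1. Coordinate spaces and normalization

Landmark frames live in one of two spaces. *Pixel* space is image-native
(y down). *Normalized* space is face-centric: the nose tip l34 is at the
origin and the segment L from the nose tip to the midpoint of the two eye
centroids (mean of l37–l42 and of l43–l48) points along +y with |L| = 1.

`normalize_frame` removes a similarity transform (translation, rotation,
uniform scale) and returns its parameters; `denormalize_frame` inverts it via
p = s·R(−θ)·q + t. Two deliberate choices:

- **Pure rotation, no reflection.** Normalization never mirrors the face, so a
  frame that is already normalized maps to itself with identity parameters
  (idempotence), and round-trips are exact to < 1e-9.
- **Degenerate geometry is an error.** If the eye midpoint coincides with the
  nose tip the scale is undefined; `InvalidGeometryError` is raised rather
  than guessing.

All cue measurement, curve fitting, change-field computation, and fold
correction operate in normalized space; only rendering and lip-reader
preprocessing touch pixels.

## 2. Visual cues

Per normalized frame: V = |l52 − l58| (vertical lip stretch), H = |l55 − l49|
(horizontal lip stretch), jaw lowering |l9 − l34|, eccentricity
e = √(1 − b/a) with (b, a) = (min, max) of (V, H), and area (π/4)·V·H.
Distances are Euclidean. Note the eccentricity definition uses the axis
*ratio* b/a directly (not the squared ratio of the standard ellipse formula):
it is a lip-rounding proxy with fixed endpoints, 0 for V = H and 1 for a
closed mouth. When both stretches are zero, e is defined as 1 (the
closed-lips limit), logged at info level.

## 3. Trajectories and temporal smoothing

A word clip of n frames is modelled as 136 independent degree-3 polynomials
over normalized time t ∈ [0, 1] (t = i/(n−1)), least-squares fitted with
`numpy.polynomial`. The degree drops to n − 1 for clips shorter than 4
frames so the system stays determined. This one representation serves three
needs:

- temporal smoothing of detector jitter (fit + resample at the same times —
  a projection, so smoothing twice equals smoothing once);
- frame-by-frame alignment of plain and clear clips of different length
  (resample the plain fit at the clear clip's times);
- duration scaling under the displacement factor.

The output length rule is `n_out = max(2, n_plain + round(df · (n_clear −
n_plain)))` with round-half-away-from-zero; e.g. 9 plain / 12 clear frames at
DF 2 → 15 frames.

## 4. Change fields

For an aligned pair, with p_mid the plain mid-vowel coordinate vector, the
field stores per coordinate two degree-3 curves:

- animation ratio α(t) = plain(t) / p_mid,
- relative change c(t) = (clear(t) − plain(t)) / p_mid,

and applies to a novel plain clip's mid-vowel frame m_in as
`dest(t) = m_in · (α(t) + df · c(t))` on a grid of `n_out` frames. This
composition makes DF = 0 exactly the (smoothed) plain animation, DF = 1 the
transferred clear style, and scales both the spatial displacement and the
duration change linearly in DF. Ratio transfer (rather than additive
transfer) adapts the displacement to the receiving face's own proportions.

**Near-zero anchors.** Ratios blow up where |p_mid| < 1e-3 (e.g. x
coordinates on the facial midline, the nose tip itself). Those coordinates
fall back to additive channels, `dest = m_in + anim(t) + df · change(t)`,
stored alongside the ratio channels; the fallback mask is saved with the
field. The 1e-3 threshold is in normalized units (the nose-to-eye distance
is 1), i.e. ~0.1 % of the face scale — small enough that real articulation
is never misrouted, large enough to keep ratio magnitudes bounded by ~1000.

**Averaging.** The *average* target is the equal-weight mean of per-pair
fields. Because all fields share the normalized-time axis, averaging the
polynomial coefficients equals averaging the curves pointwise. A coordinate
is fallback in the average if it is fallback in any contributing field;
`delta_frames` is the mean duration difference. The error of an averaged
field, measured on the landmark positions it produces, shrinks ≈ 1/√N in the
number of contributing pairs (verified in the acceptance suite).

**Fold correction.** Large DFs can produce impossible geometry: a lip
landmark above the nose tip, or an inner lower-lip landmark above its paired
upper landmark (pairs (l64, l66), (l63, l67), (l62, l68) — the geometric
vertical pairs of the inner ring, whose bottom half runs right-to-left).
Folded frames are smoothed by a circular 1-D Gaussian (σ = 1 landmark,
width 5) along the outer (l49–l60) and inner (l61–l68) lip rings, repeated up
to 10 times; the convolution preserves each ring's centroid and contracts
excursions. If the fold persists a `FoldWarning` is emitted and the best
effort returned.

## 5. Rendering

A Delaunay triangulation is built once on the source mid-vowel landmarks plus
eight border anchors (image corners and edge midpoints, pinning the
background); every destination frame reuses the topology. Each destination
triangle is mapped by its own affine transform back to the source (inverse
mapping with barycentric rasterization and bilinear sampling, so the output
has no holes), and triangles whose vertices did not move are copied verbatim
— making the identity warp bit-exact, a property the test suite relies on.
Destination landmark frames are temporally smoothed, then carried to pixel
space with the source frame's normalization parameters, so a single
high-resolution mid-vowel image drives the whole clip.

## 6. Synthetic corpus

The generator exists so every stage is testable without recordings, detectors
or model weights. A canonical symmetric 68-point face template is **affine in
three articulatory parameters** (v, h, jaw) chosen so the measured cues equal
the injected values exactly: the outer lip ring is an ellipse with full axes
(h, v), the inner ring a smaller concentric ellipse, and the jaw curve an
ellipse through the chin at distance `jaw` from the nose. Trig values at the
cardinal ring angles are snapped to exact zeros so cue limits (e = 1 at
V = 0) are hit exactly.

**Motion profile.** A clip interpolates from a rest pose to the word's peak
pose and back along a cubic bump q(t) = t(1 − t)(1 + gt), with g chosen so
the maximum falls exactly on the annotated mid-vowel frame. A cubic (rather
than, say, a raised cosine) is a design decision: the face template is affine
in its parameters, so noiseless synthetic motion is then *exactly* a degree-3
polynomial per coordinate — the generator is closed under the pipeline's
curve fitting, and properties like "DF 0 is the identity" and "DF 1
self-reconstruction" hold to machine precision instead of drowning in fit
residual at 9-frame clips.

**Design.** Six /kVd/ words spanning the tense/lax pairs /i-ɪ/, /ɑ-ʌ/,
/u-ʊ/, with per-word mid-vowel cue targets; 18 talkers (10 tagged F, 8 M) by
default, each contributing 15 plain and 12 clear repetitions per word; plain
clips 9 frames, clear clips 12 (the duration-scaling worked example);
landmark jitter σ = 0.01 normalized units; per-talker multiplicative cue
idiosyncrasy (SD 0.05) and clear-speech gains drawn around v ×1.25, h ×1.10,
jaw ×1.10. Rounded vowels *tighten* horizontally in clear style (h ÷1.06),
back vowels widen only mildly — mirroring the direction of reported clear-
speech kinematics (longer, larger vertical/jaw displacement, rounding
enhanced where contrastive).

The word table's cue separations were calibrated once against the geometry of
the task: tense/lax separations must exceed the clear-speech exaggeration
step, otherwise plain tense words score *below chance* (an unrealistic
corpus). With the shipped values the landscape is qualitatively realistic —
plain speech mid-range, clear and DF 1 near ceiling, DF 2–3 destroying lax
identity — without being fitted to any specific accuracy number.

All randomness flows from explicit seeds through `numpy.random.SeedSequence`;
corpora, modification runs, and manifests are byte-deterministic.

## 7. Evaluation

Clip preparation mirrors common lip-reading front ends: 29 frames selected at
regular spacing (`floor(i·n/29)`, padding short clips with the last frame),
per-frame similarity alignment to the mean template face shape, a 96×96 crop
centered on the mouth landmarks, BT.601 gray conversion. Word identification
is a nearest-centroid classifier over the five cue trajectories resampled to
a 20-point grid and z-scored with training statistics (ties break
lexicographically, keeping evaluation deterministic). It sits behind a
minimal `predict(trajectory) → word` interface so a learned lip reader can
be substituted without touching the evaluation or reporting code.

Accuracy is aggregated by condition (plain, clear, DFx-mode) and vowel
tensity with binomial standard errors; per-condition confusion matrices are
written alongside.

## 8. What the generator does *not* emulate

- Appearance realism: rendered faces are flat-shaded geometric rasters; no
  texture, lighting, teeth, or tongue. The warp therefore demonstrates
  geometric correctness, not photorealism.
- Coarticulation and consonant dynamics: the /k/ and /d/ contexts are a
  shared rest pose; only the vowel gesture is modelled.
- Detector error structure: jitter is i.i.d. Gaussian, not the correlated,
  pose-dependent error of real landmark detectors.
- Audio, and any audio-visual interaction.

## 9. Numerical choices worth knowing

- Round-half-away-from-zero (not banker's rounding) for frame counts, so the
  printed worked example 3 × 2 + 9 = 15 is reproduced for all inputs.
- `ANCHOR_EPS = 1e-3` normalized units for the ratio/additive fallback split.
- Identity triangles (max vertex displacement < 1e-9 px) are copied verbatim
  in the warp; degenerate destination triangles (|2·area| < 1e-12) are
  skipped with a warning.
- Classifier z-scoring floors feature standard deviations at 1e-12 (replaced
  by 1) to keep constant features harmless.
- Trajectory JSON stores coordinates rounded to 12 decimals — far below any
  physical precision, but enough to keep files compact and round-trips
  lossless at the tolerances the pipeline uses.

## 10. Limitations

The intelligibility numbers produced on the synthetic corpus characterize the
*pipeline*, not human perception: absolute accuracies depend on the generator's
separability and the simple centroid classifier. Only the qualitative
orderings (clear ≥ plain, DF 1 ≥ plain for tense vowels; exaggeration
eventually harming lax vowels) are claimed, and those are what the acceptance
suite locks down. Applying the package to real video additionally requires an
external 68-point landmark detector and, for rendering, a source video of
sufficient resolution; both plug in at documented seams (`LandmarkTrajectory`
construction and `generate_video`'s source image).
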