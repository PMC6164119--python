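# Methods

This note documents the models, defaults and design choices behind each
module, what the synthetic generators emulate, and what the tests do and do
not establish about real recordings.

## Session forms and the response dialect

A session is described by a JSON configuration document (title, 3-digit
sample codes, randomization and repeat-question flags, an optional ranking
block, and an ordered question list).  Questions carry one of three scale
kinds with fixed numeric ranges:

| scale kind     | range    | rationale |
|----------------|----------|-----------|
| `face`         | [0, 100] | continuous hedonic face scale; the smallest conventional range containing all example values (13–94) |
| `continuous15` | [0, 15]  | the 15-point nonstructured line scale of descriptive tests, stored as a float |
| `categorical`  | level index | ≥ 2 declared levels |

Validation rejects duplicate sample codes, empty question lists, dangling
conditional-question targets and conditional cycles at build time, so an
emitted document can never describe an unrunnable session.

Response files are tab-delimited with fixed literal tokens (`Assessment`,
`Sample`, `Progress`, a `Time: HH:MM:SS` stamp) and an optional `Rank` line
alternating `Sample <label>` / `Position <n>` fields.  `parse` and `write`
are exact inverses on valid inputs, which the suite checks by property-based
round-tripping.  Timestamps are timezone-naive times of day; the session
date belongs to the enclosing file/folder metadata, not to records.

Per-participant presentation order is a uniform permutation keyed by a
SHA-256 hash of `(seed, participant_id)`, making orders reproducible across
platforms and independent across participants.  A balanced crossover design
(e.g. a Williams square) is deliberately not imposed; it can be layered on
top by supplying explicit orders.

## Video photoplethysmography

The pulse signal is the spatial mean of the green channel inside a facial
ROI, one sample per frame (the camera's default profile is 1640 x 1232 px at
30 fps).  Preprocessing removes a linear trend and applies a zero-phase
4th-order Butterworth band-pass over 0.7–4.0 Hz (42–240 bpm), the
conventional physiological pulse band.  Heart rate is 60 x the dominant
frequency of a Welch periodogram (10-s Hann segments, 50 % overlap,
zero-padded to 2^16 points) with parabolic interpolation of the log-power
peak; a peak must exceed 3 x the in-band median power or a "no pulse"
condition is raised.  Sliding-window application of the same estimator
produces heart-rate-over-time tracks; windows must be at least 10 s for the
spectral estimate to be meaningful.

Blood pressure cannot be read directly from a PPG spectrum, so the vitals
stage is a *trainable* ridge regressor from a fixed 10-element feature
vector (dominant frequency, peak power and half-power bandwidth, amplitude
statistics, inter-beat-interval mean/variability, rise/fall times) to
(HR, SP, DP).  Predictions are post-processed to guarantee SP > DP > 0.
The estimator shipped here is fit only on synthetic calibration data in the
tests; it demonstrates the I/O contract and is **not clinically validated**.

No frame-drop handling beyond the caller's control is attempted; clips are
assumed regularly sampled at the stated fps.

## Thermal co-registration and skin temperature

Skin temperature is defined as the maximum temperature inside a facial
region of the thermal raster.  The region is found in the visible image with
a fixed fallback chain — eye band, then whole face, then "no subject"
(frame skipped and logged).  The bundled `ContrastDetector` segments the
subject as the largest connected component differing from the border
background and looks for a darker horizontal band in the upper half of the
face; it is a classical reference implementation adequate for synthetic and
controlled scenes, and any callable returning a box can replace it (the
detection interface is deliberately pluggable).

Visible-to-thermal mapping is affine.  The default calibration assumes
axis-aligned optics: per-axis scale equal to the size ratio of the two
images plus a configurable pixel offset (the rig-specific offset must be
measured once per hardware setup).  Landmark calibration fits the affine by
least squares over >= 3 matched point pairs and reports the RMS residual.
The ROI is mapped by inverse-transforming thermal pixel centres and keeping
those that land inside the (half-open) box; the maximum of the covered
pixels is the reported temperature, tagged with the ROI kind so eye-box and
whole-face readings remain distinguishable downstream.  No emissivity or
atmospheric correction is applied — rasters are taken to be already in
degrees C from upstream radiometric decoding.

## Emotion tables

The external facial-expression software's export format is proprietary, so
the package defines its own documented CSV dialect carrying the eight
emotion intensities (each in [0, 1]), valence in [-1, 1], arousal in [0, 1],
head orientation in degrees about the three axes, and gaze direction encoded
as an angle in degrees.  Ingestion validates ranges row by row; summaries
are component-wise means over fixed time windows, timestamped at window
centres.  Means of bounded components stay in range, so summaries are valid
vectors by construction.

## Multivariate fusion

Per-sample means across participants of the conscious variables (liking
scales, face scale FS) and subconscious variables (HR, SP, DP, skin
temperature IR, emotions, valence/arousal, head pose) form the feature
matrix.  PCA is computed by explicit eigendecomposition of the correlation
matrix: variables mix units, so z-scoring (ddof = 1) is the default;
covariance PCA is available via `standardize=False`.  Explained percentages
are eigenvalue/trace x 100 and sum to exactly 100 over all components;
each loading vector is oriented so its largest-magnitude element is
positive, making signs reproducible run to run.  Constant columns are
dropped with a warning (they carry no correlation information); a matrix of
identical rows yields all-zero explained variances rather than a division
error.

"Euclidean linkage" is ambiguous (Euclidean is a metric, not a linkage
rule), so clustering is agglomerative with Euclidean distances and
*average* linkage by default — single, complete and Ward are selectable.
Clustering operates on the first two PC scores by default, i.e. on the same
plane the biplot shows.  Missing samples in any source are an error unless
column-mean imputation is explicitly enabled.

GDir enters the numeric fusion only if the caller encodes it numerically
(the default tables use an angle); categorical gaze codings are excluded
from PCA by default.

## Synthetic generators and what they do(n't) show

All fixtures are generated, none downloaded, and every generator returns
its ground truth:

* **Face video** — an elliptical skin-tone face on a grey background whose
  green channel is modulated sinusoidally at the target rate, plus a slow
  out-of-band drift and per-pixel Gaussian noise.  SNR is defined on the
  spatially averaged signal: per-pixel noise of SD sigma averages down by
  sqrt(n_face_pixels), so sigma is scaled up accordingly.  Frames are
  float32 so sub-quantisation modulations survive.  Defaults follow the
  capture profile (1640 x 1232 at 30 fps); the heart-rate sweep in the
  acceptance checks uses 80 x 64 frames over 30 s per clip, a size chosen
  to keep 40-clip sweeps cheap while leaving thousands of averaged pixels.
* **Thermal pairs** — visible frames in three scene classes (eyes visible /
  occluded / no subject) paired with a half-resolution raster in which the
  planted hottest pixel equals the true temperature exactly; background sits
  near 26 degC, facial skin near 33.2 degC, and raster noise is 0.02 degC SD.
* **Sessions** — the default scenario mirrors an image-viewing study: 59
  participants, 9 stimuli in three valence classes (positive/neutral/
  negative).  Liking is a truncated normal per stimulus (class means 82/50/20
  on the face scale, SD 8); rankings are each participant's own top draws;
  emotion frames are truncated normals around class-specific intensity
  profiles (SD 0.15) with a small fixed per-stimulus jitter so same-class
  stimuli are not identical; HR and skin temperature get class-dependent
  offsets (+2/+0/+5 bpm, +0.25/0/-0.25 degC).  A 30-participant, 9-sample
  tasting variant is provided for the beer-style design.

These scenes are parametric, not photorealistic.  Passing tests therefore
establish that the *algorithms* are correct against known ground truth —
exact extraction arithmetic, filter and spectral behaviour, registration
geometry, recovery of planted structure — not that the detector or the PPG
pipeline is robust to real-world lighting, motion, occlusion or skin-tone
variation, and not that the vitals regressor generalises to human data.
Published explained-variance figures from real studies depend on raw data
that are not distributed and are consequently not reproduced here; the
oracle-equivalence and planted-recovery checks stand in for them.

## Numerical choices and degenerate inputs

* Band edges strictly inside (0, Nyquist); violations are errors, not clips.
* HR peak interpolation is parabolic in log power; peaks at the band edge
  are clamped to the band.
* Flat PPG signals yield a defined all-zero feature vector flagged
  low-quality rather than an error.
* Registration matrices must be invertible; the landmark fit reports its
  residual and the round-trip property (landmarks reproduce targets within
  the residual) is tested.
* Ties in the temperature maximum are irrelevant (max is well defined);
  boundary pixels follow the half-open box convention.
* The acceptance problem sizes are 40 clips x 30 s for the heart-rate sweep,
  1000 random rasters for the extraction oracle, 20 random 9 x 20 matrices
  for the PCA oracle and 100 replicates of the 59 x 9 session for cluster
  recovery.
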