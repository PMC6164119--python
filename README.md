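# biosense

Sensory scientists increasingly pair the traditional questionnaire — liking
scales, ranking tasks — with nonintrusive biometrics captured while a
panelist tastes a sample or views a stimulus: heart rate and blood pressure
from facial video (remote photoplethysmography), skin temperature from
paired visible/infrared-thermal frames, and facial-expression intensities
from external classification software.  `biosense` is an open toolkit for
that integrated workflow: it builds and validates session configuration
files, reads and writes the tab-delimited response files such sessions
produce, extracts the physiological signals from the recordings, and fuses
conscious and subconscious responses into a multivariate analysis.

## What it computes

* **Session I/O** — a JSON session-config schema (sample codes,
  randomization, ranking, categorical / 15-point continuous / 0–100 face
  scales, conditional questions, media attachments) and an exact
  parser/writer pair for the app's response dialect.
* **Heart rate (HR)** — the green-channel PPG principle: the spatial mean
  of the green channel in a face ROI is detrended, band-passed over
  0.7–4.0 Hz, and HR = 60·f₀ where f₀ is the dominant Welch-spectrum peak
  (parabolic interpolation).  A trainable ridge regressor maps PPG features
  to (HR, SP, DP); the blood-pressure output is not clinically validated.
* **Skin temperature (IR)** — eye-region detection in the visible image
  (whole-face fallback), affine visible→thermal co-registration, and
  IR = max temperature inside the co-registered region, per frame.
* **Multivariate fusion** — per-sample means of all variables, PCA on the
  correlation matrix (explained variance per component, deterministic sign
  convention, biplot), and agglomerative clustering with Euclidean
  distances on the leading PC scores.
* **Synthetic generators** — face videos with a planted pulse, thermal
  pairs with planted temperatures, and full multi-participant sessions
  with planted valence structure, each returning its ground truth, so the
  entire pipeline is testable without any study data.

## Worked example

```python
from biosense import multivariate, rppg, session_io, synthetic

# 1. Parse a response file in the app dialect
records, rank = session_io.parse_response_file(session_io.example_response_text())
print(f"{len(records)} assessments, max={max(r.value for r in records):.0f}")

# 2. Recover a planted 72-bpm pulse from a noisy synthetic clip
clip, truth = synthetic.generate_face_video(72, 30, snr_db=5, seed=42,
                                            frame_size=(64, 80))
sig = rppg.preprocess(rppg.extract_green_signal(clip, rppg.FaceROI(*truth["face_box"])))
print(f"HR = {rppg.estimate_heart_rate(sig):.1f} bpm")

# 3. Simulate a 59-participant image session and fuse + decompose it
data = synthetic.generate_session(synthetic.image_scenario(seed=42))
fm = multivariate.assemble_features(*synthetic.session_feature_sources(data))
res = multivariate.pca(fm)
print(f"PC1 = {res.explained_pct[0]:.2f}%, PC2 = {res.explained_pct[1]:.2f}%, "
      f"total = {res.explained_pct[:2].sum():.2f}%")
cut = multivariate.cluster(res).cut_by_count(3)
for cid in sorted(set(cut.values())):
    print(f"cluster {cid}: " + ", ".join(sorted(l for l, c in cut.items() if c == cid)))
```

Output:

```
9 assessments, max=94
HR = 72.0 bpm
PC1 = 62.15%, PC2 = 25.50%, total = 87.64%
cluster 1: Dark room, Dentist, Spider
cluster 2: Door, Stairs, Wheel
cluster 3: Baby, Beach, Dog
```

The parsed file is the bundled nine-image example (face-scale values 13–94
plus a three-position ranking).  The heart-rate line shows the pipeline
recovering the planted rate at 5 dB SNR.  The PCA lines report how much of
the between-stimulus variance the first two components capture for this
simulated session, and the three-cluster cut groups the stimuli exactly by
their planted valence class (negative / neutral / positive).

A CLI mirrors the library: `biosense parse`, `biosense config build`,
`biosense hr`, `biosense temp`, `biosense emotions`, `biosense pca`,
`biosense cluster`, `biosense simulate`.  Run `biosense --help`.

## Scope notes

The facial-expression classifier itself, proprietary radiometric file
decoding, cloud/app deployment, and clinically validated blood pressure are
out of scope; see `docs/methods.md` for the models, defaults, and the
limits of what the synthetic benchmarks establish.
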