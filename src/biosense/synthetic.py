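"""Synthetic fixtures for every pipeline stage, with ground truth attached.

No human-subject data ship with this package, so each stage is exercised
against generated scenes whose true parameters are known exactly:

* :func:`generate_face_video` — an elliptical "face" whose green channel is
  modulated sinusoidally at the requested heart rate, plus slow baseline
  drift and Gaussian pixel noise at a requested SNR.
* :func:`generate_thermal_sequence` — paired visible/thermal frames at the
  2-s capture interval, with the eye region the hottest part of the scene
  and three scene classes (eyes visible / eyes occluded / no subject) to
  exercise the detector's fallback chain.
* :func:`generate_session` — a full multi-participant session: response
  files in the app's tab-delimited dialect, per-stimulus emotion tables
  correlated with each stimulus's planted valence class, and per-participant
  heart-rate and skin-temperature draws.

Every generator is deterministic for a fixed integer seed and returns its
ground truth alongside the artifact.  The faces are parametric shapes, not
photorealistic renders: sufficient for green-channel extraction and the
reference contrast detector, which is exactly what the downstream tests
need.  Defaults mirror the integrated camera's capture profile (1640 x 1232
px at 30 fps; thermal pairs every 2 s) and the image-study design (59
participants, 9 stimuli in 3 valence classes).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import session_io
from .emotions import EMOTION_NAMES
from .rppg import CAPTURE_PROFILE, VideoClip
from .session_io import (
    QuestionSpec,
    RankingSpec,
    RankRecord,
    ResponseRecord,
    SessionConfig,
)
from .thermal import ThermalPair

__all__ = [
    "ScenarioSpec",
    "SessionData",
    "generate_face_video",
    "generate_thermal_sequence",
    "generate_session",
    "session_feature_sources",
    "image_scenario",
    "beer_scenario",
]

_SKIN_RGB = np.array([204.0, 161.0, 140.0])
_BACKGROUND_RGB = np.array([80.0, 80.0, 80.0])
_EYE_RGB = np.array([38.0, 28.0, 28.0])


def _face_geometry(height: int, width: int):
    """Centre and semi-axes of the synthetic face ellipse."""
    cy, cx = height / 2.0, width / 2.0
    ry, rx = 0.42 * height, 0.30 * width
    return cy, cx, ry, rx


def _face_mask(height: int, width: int) -> np.ndarray:
    cy, cx, ry, rx = _face_geometry(height, width)
    y, x = np.mgrid[0:height, 0:width]
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def _eye_band(height: int, width: int) -> tuple[slice, slice]:
    """Row/column slices of the dark eye band within the face."""
    cy, cx, ry, rx = _face_geometry(height, width)
    y0 = int(cy - 0.45 * ry)
    y1 = max(y0 + 2, int(cy - 0.20 * ry))
    x0 = int(cx - 0.55 * rx)
    x1 = max(x0 + 2, int(cx + 0.55 * rx))
    return slice(y0, y1), slice(x0, x1)


def generate_face_video(
    hr_bpm: float,
    duration_s: float,
    fps: float = CAPTURE_PROFILE["fps"],
    snr_db: float = np.inf,
    seed: int = 0,
    frame_size: tuple[int, int] = (CAPTURE_PROFILE["height"], CAPTURE_PROFILE["width"]),
    pulse_amplitude: float = 3.0,
    drift_amplitude: float = 4.0,
) -> tuple[VideoClip, dict]:
    """Synthesise a face clip with a green-channel pulse at ``hr_bpm``.

    The pulse is a sinusoid of amplitude ``pulse_amplitude`` (intensity
    units on the 0-255 scale) added to the green channel of every face
    pixel, on top of a slow out-of-band baseline drift.  ``snr_db`` sets the
    power ratio of the pulse to the pixel noise *after spatial averaging over
    the face*: per-pixel noise of standard deviation ``sigma`` averages down
    by ``sqrt(n_face_pixels)``, so ``sigma`` is scaled up accordingly.
    Frames are float32 so that sub-quantisation modulations survive.

    Returns the clip and a ground-truth dict with the injected rate, the
    face bounding box (usable as the extraction ROI) and the noise level.
    """
    if not (42.0 <= hr_bpm <= 240.0):
        raise ValueError(f"hr_bpm {hr_bpm} outside the plausible 42-240 bpm band")
    if duration_s < 10.0:
        import warnings

        warnings.warn("clips shorter than 10 s give unreliable HR estimates")
    height, width = frame_size
    n_frames = max(2, int(round(duration_s * fps)))
    rng = np.random.default_rng(seed)
    mask = _face_mask(height, width)
    n_face = int(mask.sum())
    base = np.where(mask[..., None], _SKIN_RGB, _BACKGROUND_RGB).astype(np.float32)

    f0 = hr_bpm / 60.0
    t = np.arange(n_frames) / fps
    pulse = pulse_amplitude * np.sin(2 * np.pi * f0 * t)
    drift = drift_amplitude * np.sin(2 * np.pi * 0.05 * t) + 0.1 * t

    if np.isinf(snr_db):
        sigma = 0.0
    else:
        # SNR is defined on the spatially averaged signal
        sigma = (pulse_amplitude / np.sqrt(2.0)) * 10 ** (-snr_db / 20.0) * np.sqrt(n_face)

    frames = np.empty((n_frames, height, width, 3), dtype=np.float32)
    for i in range(n_frames):
        frame = base.copy()
        frame[mask, 1] += pulse[i] + drift[i]
        if sigma > 0:
            frame += rng.normal(0.0, sigma, size=frame.shape).astype(np.float32)
        frames[i] = frame

    ys, xs = np.where(mask)
    roi = (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
    truth = {
        "hr_bpm": float(hr_bpm),
        "pulse_hz": f0,
        "face_box": roi,
        "pixel_noise_sd": float(sigma),
        "n_face_pixels": n_face,
    }
    return VideoClip(frames=frames, fps=fps), truth


def generate_thermal_sequence(
    n_pairs: int = 10,
    eye_temps: Optional[Sequence[float]] = None,
    scene_classes: Optional[Sequence[str]] = None,
    interval_s: float = 2.0,
    visible_size: tuple[int, int] = (120, 160),
    thermal_scale: float = 0.5,
    noise_sd_c: float = 0.02,
    seed: int = 0,
) -> tuple[list[ThermalPair], dict]:
    """Paired visible/thermal frames at the 2-s capture interval.

    ``eye_temps`` is the true eye-region temperature per frame (degrees C;
    default a 34.0 to 35.8 ramp).  ``scene_classes`` picks per frame from
    ``"eyes"`` (face with visible dark eye band), ``"occluded"`` (face
    without an eye band) and ``"empty"`` (background only); the planted
    hottest pixel equals the true temperature exactly in both non-empty
    classes, so a correct pipeline recovers ``eye_temps`` up to raster
    noise.  The thermal raster is ``thermal_scale`` times the visible
    resolution with zero geometric offset, matching the default
    calibration.
    """
    if eye_temps is None:
        eye_temps = np.linspace(34.0, 35.8, n_pairs)
    eye_temps = np.asarray(eye_temps, dtype=float)
    if len(eye_temps) != n_pairs:
        raise ValueError("eye_temps length must match n_pairs")
    if scene_classes is None:
        scene_classes = ["eyes"] * n_pairs
    if len(scene_classes) != n_pairs:
        raise ValueError("scene_classes length must match n_pairs")

    rng = np.random.default_rng(seed)
    hv, wv = visible_size
    ht, wt = int(round(hv * thermal_scale)), int(round(wv * thermal_scale))
    mask_v = _face_mask(hv, wv)
    mask_t = _face_mask(ht, wt)
    eye_v = _eye_band(hv, wv)
    eye_t = _eye_band(ht, wt)

    pairs, truths = [], []
    for i, cls in enumerate(scene_classes):
        if cls == "empty":
            visible = np.broadcast_to(_BACKGROUND_RGB, (hv, wv, 3)).copy()
        else:
            visible = np.where(mask_v[..., None], _SKIN_RGB, _BACKGROUND_RGB)
        thermal = 26.0 + rng.normal(0.0, noise_sd_c, size=(ht, wt))
        if cls in ("eyes", "occluded"):
            thermal[mask_t] = 33.2 + rng.normal(0.0, noise_sd_c, size=int(mask_t.sum()))
            if cls == "eyes":
                visible[eye_v[0], eye_v[1]] = _EYE_RGB
                hot = thermal[eye_t[0], eye_t[1]]
                hot[...] = eye_temps[i] - np.abs(
                    rng.normal(0.0, noise_sd_c, size=hot.shape)
                )
                cy = (eye_t[0].start + eye_t[0].stop) // 2
                cx = (eye_t[1].start + eye_t[1].stop) // 2
                thermal[cy, cx] = eye_temps[i]
            else:
                # forehead hot spot keeps the planted max recoverable via face fallback
                cy = int(0.35 * ht)
                cx = wt // 2
                thermal[cy, cx] = eye_temps[i]
        elif cls != "empty":
            raise ValueError(f"unknown scene class {cls!r}")
        visible = np.clip(
            visible + rng.normal(0.0, 1.0, size=visible.shape), 0, 255
        ).astype(np.uint8)
        pairs.append(ThermalPair(visible=visible, thermal=thermal, timestamp=i * interval_s))
        truths.append({"class": cls, "temp_c": float(eye_temps[i]) if cls != "empty" else None})
    truth = {"frames": truths, "interval_s": interval_s, "thermal_scale": thermal_scale}
    return pairs, truth


class ScenarioSpec(BaseModel):
    """Study design for a full synthetic session.

    Defaults emulate the image-stimulus design: 59 participants rating 9
    stimuli (three positive, three neutral, three negative) on the 0-100
    face scale, with emotion responses drawn from class-dependent mixtures.
    For tasting designs see :func:`beer_scenario`.
    """

    n_participants: int = Field(default=59, ge=1)
    sample_labels: list[str] = Field(
        default=[
            "Baby", "Dog", "Beach",
            "Door", "Wheel", "Stairs",
            "Spider", "Dark room", "Dentist",
        ]
    )
    valence_classes: list[str] = Field(
        default=["positive"] * 3 + ["neutral"] * 3 + ["negative"] * 3
    )
    liking_means: Optional[list[float]] = None  # face-scale units; default per class
    liking_sd: float = Field(default=8.0, ge=0)
    emotion_sd: float = Field(default=0.15, ge=0)
    hr_base_bpm: float = 72.0
    hr_sd_bpm: float = Field(default=3.0, ge=0)
    ir_base_c: float = 34.5
    ir_sd_c: float = Field(default=0.2, ge=0)
    rank_top: int = Field(default=3, ge=1)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        k = len(self.sample_labels)
        if k < 1:
            raise ValueError("need at least one sample")
        if len(set(self.sample_labels)) != k:
            raise ValueError("sample labels must be unique")
        if len(self.valence_classes) != k:
            raise ValueError("valence_classes must match sample count")
        for c in self.valence_classes:
            if c not in ("positive", "neutral", "negative"):
                raise ValueError(f"unknown valence class {c!r}")
        if self.liking_means is not None and len(self.liking_means) != k:
            raise ValueError("liking_means must match sample count")
        if self.rank_top > k:
            raise ValueError("cannot rank more samples than exist")
        return self

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)


# class-level response profiles: liking mean (face scale), emotion intensity
# means for (happy, neutral, sad, scared, surprised, angry, contempt,
# disgusted), valence, arousal, HR offset (bpm) and IR offset (degrees C)
_CLASS_PROFILES = {
    "positive": {
        "liking": 82.0,
        "emotions": (0.62, 0.22, 0.03, 0.02, 0.10, 0.02, 0.02, 0.02),
        "valence": 0.55, "arousal": 0.55, "hr": 2.0, "ir": 0.25,
    },
    "neutral": {
        "liking": 50.0,
        "emotions": (0.10, 0.70, 0.05, 0.03, 0.04, 0.03, 0.04, 0.03),
        "valence": 0.0, "arousal": 0.30, "hr": 0.0, "ir": 0.0,
    },
    "negative": {
        "liking": 20.0,
        "emotions": (0.03, 0.15, 0.18, 0.22, 0.10, 0.18, 0.06, 0.28),
        "valence": -0.55, "arousal": 0.65, "hr": 5.0, "ir": -0.25,
    },
}


@dataclass
class SessionData:
    """Artifacts of one simulated session plus the generating truth."""

    config: SessionConfig
    response_files: dict[str, str]
    emotion_tables: dict[tuple[str, str], pd.DataFrame]
    vitals: pd.DataFrame
    temperatures: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Draw from N(mean, sd) truncated to [lo, hi] by redraw, clip fallback."""
    if sd == 0:
        return np.clip(np.broadcast_to(np.asarray(mean, dtype=float), size or ()), lo, hi).copy()
    x = np.atleast_1d(rng.normal(mean, sd, size=size))
    for _ in range(20):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x = np.where(bad, rng.normal(mean, sd, size=x.shape), x)
    x = np.clip(x, lo, hi)
    return x if size is not None else float(x[0])


def _emotion_frames(rng, profile, sd, n_frames=7, frame_dt=1.0, t0=0.0) -> pd.DataFrame:
    rows = []
    for j in range(n_frames):
        raw = _truncated_normal(
            rng, np.asarray(profile["emotions"]), sd, 0.0, 1.0, size=(8,)
        )
        rows.append(
            {
                "timestamp": t0 + j * frame_dt,
                **dict(zip(EMOTION_NAMES, raw)),
                "valence": float(_truncated_normal(rng, profile["valence"], sd, -1, 1)),
                "arousal": float(_truncated_normal(rng, profile["arousal"], sd, 0, 1)),
                "head_x": float(rng.normal(0, 3)),
                "head_y": float(rng.normal(0, 3)),
                "head_z": float(rng.normal(0, 3)),
                "gaze_dir": float(rng.normal(0, 10)),
            }
        )
    return pd.DataFrame(rows)


def generate_session(spec: ScenarioSpec) -> SessionData:
    """Simulate a full session for every participant in ``spec``.

    Per participant: face-scale liking for each stimulus drawn from a normal
    truncated to [0, 100] around the stimulus's class (or explicit) mean, a
    ranking of the top ``rank_top`` stimuli consistent with that
    participant's own draws, a 7-row emotion table per stimulus drawn around
    the class emotion profile, and single HR/SP/DP and skin-temperature
    draws per stimulus.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_samples
    codes = [f"{101 + 7 * i:03d}" for i in range(k)]
    config = SessionConfig(
        title="Synthetic stimulus session",
        sample_codes=codes,
        randomize=True,
        repeat_questions=True,
        ranking=RankingSpec(position=k, n_samples=spec.rank_top),
        questions=[
            QuestionSpec(id="fs", descriptor="How does this sample make you feel?",
                         scale_kind="face")
        ],
        seed=spec.seed,
    )
    liking_means = spec.liking_means or [
        _CLASS_PROFILES[c]["liking"] for c in spec.valence_classes
    ]
    # small fixed per-sample jitter so same-class stimuli are not identical
    sample_jitter = rng.normal(0.0, 0.03, size=(k, 8))

    response_files: dict[str, str] = {}
    emotion_tables: dict[tuple[str, str], pd.DataFrame] = {}
    vit_rows, temp_rows, liking_rows = [], [], []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:03d}"
        order = session_io.randomize_presentation(list(range(k)), pid, spec.seed)
        records = []
        t0 = _dt.datetime(2000, 1, 1, 10, 0, 0)
        likes = {}
        for slot, si in enumerate(order):
            label = spec.sample_labels[si]
            cls = spec.valence_classes[si]
            profile = dict(_CLASS_PROFILES[cls])
            profile["emotions"] = np.clip(
                np.asarray(profile["emotions"]) + sample_jitter[si], 0, 1
            )
            value = float(
                _truncated_normal(rng, liking_means[si], spec.liking_sd, 0.0, 100.0)
            )
            likes[label] = value
            stamp = (t0 + _dt.timedelta(seconds=90 * slot + int(rng.integers(0, 30)))).time()
            records.append(
                ResponseRecord(
                    assessment_kind="Image", sample_label=label,
                    question_kind="Face scale", value=value, timestamp=stamp,
                )
            )
            emotion_tables[(pid, label)] = _emotion_frames(
                rng, profile, spec.emotion_sd, t0=10.0 * slot
            )
            hr = spec.hr_base_bpm + profile["hr"] + rng.normal(0, spec.hr_sd_bpm)
            sp = 118.0 + 0.3 * (hr - spec.hr_base_bpm) + rng.normal(0, 3)
            dp = 78.0 + 0.15 * (hr - spec.hr_base_bpm) + rng.normal(0, 2)
            vit_rows.append(
                {"participant": pid, "sample": label, "HR": hr, "SP": sp,
                 "DP": min(dp, sp - 5.0)}
            )
            temp_rows.append(
                {
                    "participant": pid, "sample": label,
                    "IR": spec.ir_base_c + profile["ir"] + rng.normal(0, spec.ir_sd_c),
                }
            )
            liking_rows.append({"participant": pid, "sample": label, "FS": value})
        ranked = sorted(likes, key=likes.get, reverse=True)[: spec.rank_top]
        rank = RankRecord(entries=[(lab, i + 1) for i, lab in enumerate(ranked)])
        response_files[pid] = session_io.write_response_file(records, rank)

    truth = {
        "liking_means": dict(zip(spec.sample_labels, liking_means)),
        "valence_classes": dict(zip(spec.sample_labels, spec.valence_classes)),
        "codes": dict(zip(spec.sample_labels, codes)),
    }
    return SessionData(
        config=config,
        response_files=response_files,
        emotion_tables=emotion_tables,
        vitals=pd.DataFrame(vit_rows),
        temperatures=pd.DataFrame(temp_rows),
        truth=truth,
    )


def session_feature_sources(
    data: SessionData,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tidy (participant, sample) source tables for feature assembly.

    The self-report table is rebuilt by *parsing* the generated response
    files, so the full write-parse path is exercised; emotion tables are
    collapsed to per-stimulus means.
    """
    resp_rows = []
    for pid, text in data.response_files.items():
        records, _ = session_io.parse_response_file(text)
        for rec in records:
            resp_rows.append(
                {"participant": pid, "sample": rec.sample_label, "FS": rec.value}
            )
    emo_rows = []
    for (pid, label), frames in data.emotion_tables.items():
        means = frames.drop(columns=["timestamp", "head_x", "head_y", "head_z", "gaze_dir"]).mean()
        emo_rows.append({"participant": pid, "sample": label, **means.to_dict()})
    return (
        pd.DataFrame(resp_rows),
        data.vitals,
        data.temperatures,
        pd.DataFrame(emo_rows),
    )


def image_scenario(seed: int, n_participants: int = 59) -> ScenarioSpec:
    """The default 9-image, 3-valence-class viewing design."""
    return ScenarioSpec(seed=seed, n_participants=n_participants)


def beer_scenario(seed: int, n_participants: int = 30) -> ScenarioSpec:
    """A 9-sample tasting design (labels are beer styles, no valence planting)."""
    return ScenarioSpec(
        seed=seed,
        n_participants=n_participants,
        sample_labels=[
            "Porter", "Aged ale", "Kolsch", "Lager", "American lager",
            "Pilsner", "Lambic cassis", "Lambic framboise", "Lambic kriek",
        ],
        valence_classes=["neutral"] * 9,
        liking_means=[68.0, 60.0, 55.0, 52.0, 48.0, 50.0, 62.0, 64.0, 58.0],
    )
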