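"""Ingestion and summarisation of facial-expression tables.

Facial-expression classification is done by external commercial software;
this module only defines a documented CSV dialect for its exports and
validates/summarises them for downstream fusion.

CSV dialect (header required, one row per analysed frame):

====================  =========================================
column                meaning / range
====================  =========================================
timestamp             seconds from session start
happy .. disgusted    eight emotion intensities, each in [0, 1]
valence               [-1, 1]
arousal               [0, 1]
head_x head_y head_z  head orientation, degrees
gaze_dir              gaze direction angle, degrees
====================  =========================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field

__all__ = [
    "EMOTION_NAMES",
    "EMOTION_COLUMNS",
    "EmotionVector",
    "read_emotion_table",
    "write_emotion_table",
    "summarize_emotions",
    "vectors_to_frame",
]

#: The eight emotion intensities reported by the external classifier.
EMOTION_NAMES = (
    "happy", "neutral", "sad", "scared",
    "surprised", "angry", "contempt", "disgusted",
)

#: Full column set of the CSV dialect, in canonical order.
EMOTION_COLUMNS = (
    "timestamp", *EMOTION_NAMES,
    "valence", "arousal", "head_x", "head_y", "head_z", "gaze_dir",
)


class EmotionVector(BaseModel):
    """One frame's emotion intensities, affect dimensions and head pose."""

    timestamp: float
    happy: float = Field(ge=0, le=1)
    neutral: float = Field(ge=0, le=1)
    sad: float = Field(ge=0, le=1)
    scared: float = Field(ge=0, le=1)
    surprised: float = Field(ge=0, le=1)
    angry: float = Field(ge=0, le=1)
    contempt: float = Field(ge=0, le=1)
    disgusted: float = Field(ge=0, le=1)
    valence: float = Field(ge=-1, le=1)
    arousal: float = Field(ge=0, le=1)
    head_x: float = 0.0
    head_y: float = 0.0
    head_z: float = 0.0
    gaze_dir: float = 0.0


def read_emotion_table(source: str | Path) -> list[EmotionVector]:
    """Read and validate an emotion CSV.

    Raises a :class:`ValueError` naming any missing column, and reports the
    1-based data row number of the first out-of-range value.
    """
    df = pd.read_csv(source)
    missing = [c for c in EMOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"emotion table is missing column(s): {', '.join(missing)}")
    vectors = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            vectors.append(EmotionVector(**{c: getattr(row, c) for c in EMOTION_COLUMNS}))
        except Exception as exc:
            raise ValueError(f"row {i}: {exc}") from None
    return vectors


def vectors_to_frame(vectors: Sequence[EmotionVector]) -> pd.DataFrame:
    """Stack vectors into a DataFrame in canonical column order."""
    return pd.DataFrame([v.model_dump() for v in vectors], columns=list(EMOTION_COLUMNS))


def write_emotion_table(vectors: Sequence[EmotionVector], path: str | Path) -> None:
    """Write vectors back to the CSV dialect (inverse of :func:`read_emotion_table`)."""
    vectors_to_frame(vectors).to_csv(path, index=False)


def summarize_emotions(
    vectors: Sequence[EmotionVector], window: float
) -> list[EmotionVector]:
    """Component-wise means over consecutive time windows.

    Frames are binned by ``floor(timestamp / window)``; each output vector is
    the arithmetic mean of its bin's components, timestamped at the bin
    centre.  Means of in-range components are necessarily in range, so the
    outputs are valid vectors.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not vectors:
        raise ValueError("no vectors to summarise")
    df = vectors_to_frame(vectors)
    bins = (df["timestamp"] // window).astype(int)
    out = []
    for b, grp in df.groupby(bins, sort=True):
        mean = grp.mean()
        mean["timestamp"] = (b + 0.5) * window
        out.append(EmotionVector(**mean.to_dict()))
    return out
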