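"""Skin-temperature extraction from paired visible/thermal frames.

The thermal camera records a per-pixel temperature raster (degrees C) every
~2 s alongside a higher-resolution visible image.  Skin temperature is read
as the *maximum* temperature inside a facial region of interest: the region
is found in the visible image (eye band preferred, whole face as fallback),
mapped into thermal coordinates through an affine co-registration, and the
maximum of the covered thermal pixels is taken.

The detector is pluggable: any callable ``image -> DetectedROI`` can be
supplied.  The built-in :class:`ContrastDetector` is a classical
segmentation/contrast detector adequate for synthetic and well-controlled
scenes; it is not a trained cascade classifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "ThermalPair",
    "DetectedROI",
    "Registration",
    "TemperatureSeries",
    "NoSubjectError",
    "ContrastDetector",
    "detect_roi",
    "register",
    "default_calibration",
    "landmark_calibration",
    "max_temperature",
    "temperature_series",
    "read_temperature_raster",
]

logger = logging.getLogger(__name__)

#: Plausible skin-temperature window in degrees C used for sanity flagging.
PLAUSIBLE_RANGE_C = (0.0, 60.0)


class NoSubjectError(RuntimeError):
    """No face found in the visible image."""


@dataclass
class ThermalPair:
    """A visible frame with its co-captured temperature raster.

    ``thermal`` holds per-pixel temperatures in degrees C (already decoded
    upstream from the camera's radiometric format).  ``timestamp`` is seconds
    from session start; pairs are typically ~2 s apart.
    """

    visible: np.ndarray
    thermal: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.visible = np.asarray(self.visible)
        self.thermal = np.asarray(self.thermal, dtype=float)
        if self.visible.ndim != 3 or self.visible.shape[-1] != 3:
            raise ValueError("visible image must be (H, W, 3)")
        if self.thermal.ndim != 2:
            raise ValueError("thermal raster must be 2-D")
        if not np.all(np.isfinite(self.thermal)):
            raise ValueError("temperatures must be finite")

    @property
    def plausible(self) -> bool:
        lo, hi = PLAUSIBLE_RANGE_C
        return bool((self.thermal.min() >= lo) and (self.thermal.max() <= hi))


@dataclass(frozen=True)
class DetectedROI:
    """Detection result in visible-image coordinates; half-open box."""

    x: int
    y: int
    w: int
    h: int
    kind: str  # "eyes" or "face"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("eyes", "face"):
            raise ValueError(f"kind must be 'eyes' or 'face', got {self.kind!r}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI must have positive area")


@dataclass
class Registration:
    """Affine map from visible (x, y) to thermal (x, y) coordinates."""

    matrix: np.ndarray  # 2x3
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("registration matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("registration transform is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of visible (x, y) points to thermal coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "Registration":
        A = self.matrix[:, :2]
        b = self.matrix[:, 2]
        Ainv = np.linalg.inv(A)
        return Registration(
            matrix=np.hstack([Ainv, (-Ainv @ b)[:, None]]), residual=self.residual
        )


@dataclass
class TemperatureSeries:
    """Per-frame maximum skin temperature track."""

    timestamps: np.ndarray
    temperatures: np.ndarray
    roi_kinds: list[str]
    failures: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if len(self.timestamps) != len(self.temperatures):
            raise ValueError("timestamps and temperatures must align")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)


def _luminance(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    return img @ np.array([0.299, 0.587, 0.114])


class ContrastDetector:
    """Reference eye/face detector for synthetic and controlled scenes.

    Segments the subject as the largest connected region that differs from
    the border background, then searches the upper half of the face for a
    horizontal band darker than the surrounding skin (the eye line).

    Parameters
    ----------
    background_tol:
        Max absolute luminance difference from the median border pixel for a
        pixel to count as background.
    min_face_fraction:
        Minimum fraction of the image a face region must cover.
    eye_contrast:
        Minimum luminance drop (relative to face median) for an eye row.
    """

    def __init__(
        self,
        background_tol: float = 12.0,
        min_face_fraction: float = 0.02,
        eye_contrast: float = 25.0,
    ) -> None:
        self.background_tol = background_tol
        self.min_face_fraction = min_face_fraction
        self.eye_contrast = eye_contrast

    def __call__(self, image: np.ndarray) -> DetectedROI:
        lum = _luminance(image)
        h, w = lum.shape
        border = np.concatenate([lum[0], lum[-1], lum[:, 0], lum[:, -1]])
        bg = np.median(border)
        fg = np.abs(lum - bg) > self.background_tol
        labels = measure.label(fg)
        if labels.max() == 0:
            raise NoSubjectError("no foreground region found")
        regions = measure.regionprops(labels)
        best = max(regions, key=lambda r: r.area)
        if best.area < self.min_face_fraction * h * w:
            raise NoSubjectError("foreground region too small to be a face")
        y0, x0, y1, x1 = best.bbox
        face = DetectedROI(
            x=x0, y=y0, w=x1 - x0, h=y1 - y0, kind="face",
            confidence=min(1.0, best.area / ((y1 - y0) * (x1 - x0))),
        )
        eyes = self._find_eye_band(lum, labels == best.label, face)
        return eyes if eyes is not None else face

    def _find_eye_band(
        self, lum: np.ndarray, face_mask: np.ndarray, face: DetectedROI
    ) -> Optional[DetectedROI]:
        # eye line sits in the upper half of the face; look for dark rows
        top = face.y
        mid = face.y + face.h // 2
        skin_median = np.median(lum[face_mask])
        dark = (skin_median - lum > self.eye_contrast) & face_mask
        band = dark[top:mid]
        rows = np.where(band.any(axis=1))[0]
        if len(rows) == 0:
            return None
        y0, y1 = top + rows[0], top + rows[-1] + 1
        cols = np.where(dark[y0:y1].any(axis=0))[0]
        x0, x1 = cols[0], cols[-1] + 1
        # pad a little so the box covers the full eye region
        pad_y = max(1, (y1 - y0) // 4)
        pad_x = max(1, (x1 - x0) // 10)
        h_img, w_img = lum.shape
        y0, y1 = max(0, y0 - pad_y), min(h_img, y1 + pad_y)
        x0, x1 = max(0, x0 - pad_x), min(w_img, x1 + pad_x)
        frac_dark = dark[y0:y1, x0:x1].mean()
        return DetectedROI(
            x=int(x0), y=int(y0), w=int(x1 - x0), h=int(y1 - y0),
            kind="eyes", confidence=float(min(1.0, 2 * frac_dark)),
        )


def detect_roi(
    visible: np.ndarray,
    detector: Optional[Callable[[np.ndarray], DetectedROI]] = None,
) -> DetectedROI:
    """Find the eye region, falling back to the whole face.

    The fallback order is fixed: eyes if the detector can resolve them, the
    face box otherwise, and :class:`NoSubjectError` when nothing is found.
    """
    detector = detector or ContrastDetector()
    return detector(np.asarray(visible))


def default_calibration(offset: tuple[float, float] = (0.0, 0.0)) -> dict:
    """Axis-aligned calibration: per-axis scale from image sizes plus an offset.

    The visible/thermal geometric offset is hardware-specific; measure it for
    your rig and pass it here (thermal pixels).
    """
    return {"mode": "scale", "offset": tuple(offset)}


def landmark_calibration(
    visible_points: Sequence[tuple[float, float]],
    thermal_points: Sequence[tuple[float, float]],
) -> dict:
    """Calibration from matched landmark pairs (>= 3), fit by least squares."""
    vis = np.asarray(visible_points, dtype=float)
    thm = np.asarray(thermal_points, dtype=float)
    if vis.shape != thm.shape or vis.ndim != 2 or vis.shape[1] != 2:
        raise ValueError("landmark point sets must both be (N, 2)")
    if len(vis) < 3:
        raise ValueError(f"need >= 3 landmark pairs, got {len(vis)}")
    return {"mode": "landmarks", "visible": vis, "thermal": thm}


def register(pair: ThermalPair, calibration: Optional[dict] = None) -> Registration:
    """Affine co-registration of the visible image onto the thermal raster.

    With the default calibration the transform is an axis-aligned scale
    (thermal size / visible size per axis) plus the configured offset; with
    landmark calibration it is the least-squares affine over the point pairs,
    with the RMS landmark residual reported.
    """
    calibration = calibration or default_calibration()
    if calibration["mode"] == "scale":
        hv, wv = pair.visible.shape[:2]
        ht, wt = pair.thermal.shape
        ox, oy = calibration.get("offset", (0.0, 0.0))
        matrix = np.array([[wt / wv, 0.0, ox], [0.0, ht / hv, oy]])
        return Registration(matrix=matrix, residual=0.0)
    if calibration["mode"] == "landmarks":
        vis, thm = calibration["visible"], calibration["thermal"]
        design = np.hstack([vis, np.ones((len(vis), 1))])
        coeffs, *_ = np.linalg.lstsq(design, thm, rcond=None)
        matrix = coeffs.T  # rows: [a, b, tx], [c, d, ty]
        pred = design @ coeffs
        residual = float(np.sqrt(np.mean(np.sum((pred - thm) ** 2, axis=1))))
        return Registration(matrix=matrix, residual=residual)
    raise ValueError(f"unknown calibration mode {calibration['mode']!r}")


def _roi_mask_on_thermal(
    roi: DetectedROI, reg: Registration, thermal_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of thermal pixels whose centres map back inside the ROI."""
    ht, wt = thermal_shape
    inv = reg.inverse()
    xs, ys = np.meshgrid(np.arange(wt) + 0.5, np.arange(ht) + 0.5)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    back = inv.apply(pts)
    inside = (
        (back[:, 0] >= roi.x)
        & (back[:, 0] < roi.x + roi.w)
        & (back[:, 1] >= roi.y)
        & (back[:, 1] < roi.y + roi.h)
    )
    return inside.reshape(ht, wt)


def max_temperature(pair: ThermalPair, roi: DetectedROI, reg: Registration) -> float:
    """Maximum temperature (degrees C) within the co-registered ROI."""
    mask = _roi_mask_on_thermal(roi, reg, pair.thermal.shape)
    if not mask.any():
        raise ValueError("ROI maps to an empty region of the thermal raster")
    return float(pair.thermal[mask].max())


def temperature_series(
    pairs: Sequence[ThermalPair],
    detector: Optional[Callable[[np.ndarray], DetectedROI]] = None,
    calibration: Optional[dict] = None,
) -> TemperatureSeries:
    """Max-temperature track over a sequence of visible/thermal pairs.

    Frames where detection fails are skipped and logged; if every frame
    fails, an error summarising the failures is raised.
    """
    if not pairs:
        raise ValueError("need at least one visible/thermal pair")
    times, temps, kinds, failures = [], [], [], []
    for pair in pairs:
        try:
            roi = detect_roi(pair.visible, detector)
            reg = register(pair, calibration)
            temp = max_temperature(pair, roi, reg)
        except (NoSubjectError, ValueError) as exc:
            logger.warning("frame at t=%.1fs skipped: %s", pair.timestamp, exc)
            failures.append((pair.timestamp, str(exc)))
            continue
        times.append(pair.timestamp)
        temps.append(temp)
        kinds.append(roi.kind)
    if not times:
        raise RuntimeError(
            f"no frame yielded a detection; failures: {failures}"
        )
    return TemperatureSeries(
        timestamps=np.array(times),
        temperatures=np.array(temps),
        roi_kinds=kinds,
        failures=failures,
    )


def read_temperature_raster(path: str | Path, sidecar: Optional[str | Path] = None) -> np.ndarray:
    """Load a temperature raster in degrees C from CSV or 16-bit TIFF.

    TIFF rasters store raw counts; the sidecar JSON must provide ``scale``
    and ``offset`` such that C = raw * scale + offset.  CSV rasters are
    assumed to be in degrees C already.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, delimiter=",", dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path), dtype=float)
        if sidecar is None:
            raise ValueError("TIFF rasters require a sidecar JSON with scale/offset")
        meta = json.loads(Path(sidecar).read_text())
        return raw * float(meta["scale"]) + float(meta["offset"])
    raise ValueError(f"unsupported raster format {path.suffix!r}")
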