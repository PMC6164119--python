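"""Remote photoplethysmography: heart rate and vitals from facial video.

The cardiac pulse modulates the amount of blood in facial skin, which in turn
modulates how much green light the skin reflects.  Averaging the green channel
over a facial region of interest therefore yields a weak periodic signal at
the pulse frequency.  The pipeline here is the classical green-channel method:

1. :func:`extract_green_signal` — spatial mean of the green channel in a face
   ROI, one sample per frame.
2. :func:`preprocess` — linear detrend plus a zero-phase 4th-order Butterworth
   band-pass over the physiological pulse band, 0.7-4.0 Hz (42-240 bpm).
3. :func:`estimate_heart_rate` — Welch periodogram (10 s Hann segments, 50 %
   overlap, heavily zero-padded) with parabolic interpolation of the dominant
   in-band peak; HR = 60 x peak frequency.
4. :func:`extract_features` / :func:`fit_vitals_model` — a fixed-length
   spectral/morphological feature vector feeding a trainable ridge regressor
   that maps PPG features to mean heart rate and systolic/diastolic blood
   pressure.  The shipped estimator is calibrated on synthetic data only and
   is **not** clinically validated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.linear_model import Ridge

__all__ = [
    "DEFAULT_BAND",
    "CAPTURE_PROFILE",
    "VideoClip",
    "FaceROI",
    "PPGSignal",
    "PPGFeatures",
    "VitalsEstimate",
    "VitalsModel",
    "NoPulseError",
    "read_video",
    "extract_green_signal",
    "preprocess",
    "estimate_heart_rate",
    "heart_rate_track",
    "extract_features",
    "fit_vitals_model",
    "predict_vitals",
]

#: Physiological pulse band in Hz (42-240 bpm).
DEFAULT_BAND = (0.7, 4.0)

#: Default capture profile of the integrated camera: width, height, fps.
CAPTURE_PROFILE = {"width": 1640, "height": 1232, "fps": 30.0}


class NoPulseError(RuntimeError):
    """Raised when no spectral peak rises above the in-band noise floor."""


@dataclass
class VideoClip:
    """A frame sequence with its frame rate.

    ``frames`` is (T, H, W, 3), uint8 or float, RGB channel order.
    """

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, H, W, 3), got {self.frames.shape}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.fps

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class FaceROI:
    """Axis-aligned box (x, y, w, h); origin top-left, 0-based, half-open."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI must have positive area")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_within(self, height: int, width: int) -> None:
        if self.x + self.w > width or self.y + self.h > height:
            raise ValueError(
                f"ROI {self} exceeds frame bounds {height}x{width}"
            )

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)


@dataclass
class PPGSignal:
    """Green-intensity time series at the video frame rate."""

    samples: np.ndarray
    rate: float
    detrended: bool = False
    band: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPG samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


FEATURE_NAMES = (
    "dominant_freq_hz",
    "peak_power",
    "peak_bandwidth_hz",
    "amplitude_std",
    "amplitude_rms",
    "amplitude_p2p",
    "ibi_mean_s",
    "ibi_sd_s",
    "rise_time_s",
    "fall_time_s",
)


@dataclass
class PPGFeatures:
    """Fixed-length feature vector summarising a preprocessed PPG signal."""

    values: np.ndarray
    low_quality: bool = False
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} features, got {self.values.shape}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


@dataclass(frozen=True)
class VitalsEstimate:
    """Heart rate (bpm) and optional systolic/diastolic pressure (mmHg)."""

    hr: float
    sp: Optional[float] = None
    dp: Optional[float] = None
    window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sp is not None and self.dp is not None:
            if not (self.sp > self.dp > 0):
                raise ValueError(f"need SP > DP > 0, got SP={self.sp}, DP={self.dp}")


def read_video(path: str | Path, fps: Optional[float] = None) -> VideoClip:
    """Load a clip from a directory of frame images or a video container.

    A directory is read as lexicographically sorted frames (``fps`` required).
    Container formats go through imageio and need an ffmpeg plugin, which may
    not be installed; a clear error is raised in that case.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        if fps is None:
            raise ValueError("fps is required when reading a frame directory")
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
        )
        if not files:
            raise ValueError(f"no frame images found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
        return VideoClip(frames=frames, fps=fps)
    try:
        frames = iio.imread(path, plugin="pyav") if fps else iio.imread(path)
    except Exception as exc:  # pragma: no cover - depends on installed plugins
        raise RuntimeError(
            f"could not decode {path}; for container formats an imageio ffmpeg/pyav "
            "plugin is required, or supply a directory of frame images"
        ) from exc
    meta_fps = fps
    if meta_fps is None:  # pragma: no cover
        meta = iio.immeta(path)
        meta_fps = float(meta.get("fps", CAPTURE_PROFILE["fps"]))
    return VideoClip(frames=np.asarray(frames), fps=meta_fps)


def extract_green_signal(clip: VideoClip, roi: FaceROI) -> PPGSignal:
    """Spatial mean of the green channel inside ``roi``, one sample per frame."""
    if clip.frames.shape[0] < 2:
        raise ValueError("need at least 2 frames to form a signal")
    roi.validate_within(*clip.frame_shape)
    ys, xs = roi.slices()
    samples = clip.frames[:, ys, xs, 1].astype(float).mean(axis=(1, 2))
    return PPGSignal(samples=samples, rate=clip.fps)


def preprocess(
    sig: PPGSignal, band: tuple[float, float] = DEFAULT_BAND, order: int = 4
) -> PPGSignal:
    """Linear detrend followed by a zero-phase Butterworth band-pass."""
    low, high = band
    nyq = sig.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must lie strictly within (0, {nyq}) Hz")
    x = sps.detrend(sig.samples, type="linear")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sig.rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return PPGSignal(samples=y, rate=sig.rate, detrended=True, band=band)


def _welch_spectrum(
    sig: PPGSignal, segment_s: float = 10.0, nfft: int = 1 << 16
) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(int(round(segment_s * sig.rate)), len(sig.samples))
    freqs, psd = sps.welch(
        sig.samples,
        fs=sig.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=max(nfft, nperseg),
        detrend=False,
    )
    return freqs, psd


def _parabolic_refine(freqs: np.ndarray, psd: np.ndarray, i: int) -> float:
    """Refine a discrete spectral peak by fitting a parabola to log power."""
    if i <= 0 or i >= len(psd) - 1:
        return freqs[i]
    with np.errstate(divide="ignore"):
        a, b, c = np.log(psd[i - 1 : i + 2] + 1e-300)
    denom = a - 2 * b + c
    if denom == 0:
        return freqs[i]
    delta = 0.5 * (a - c) / denom
    return freqs[i] + delta * (freqs[1] - freqs[0])


def estimate_heart_rate(
    sig: PPGSignal,
    band: Optional[tuple[float, float]] = None,
    min_peak_snr: float = 3.0,
) -> float:
    """Heart rate in bpm from the dominant in-band spectral peak.

    ``min_peak_snr`` is the required ratio of peak power to the in-band
    median; below it a :class:`NoPulseError` is raised.
    """
    band = band or sig.band or DEFAULT_BAND
    if sig.duration < 10.0:
        warnings.warn("signal shorter than 10 s; HR estimate may be unreliable")
    freqs, psd = _welch_spectrum(sig)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise NoPulseError("no spectral support inside the pulse band")
    in_band = np.where(mask)[0]
    i = in_band[np.argmax(psd[in_band])]
    noise_floor = np.median(psd[in_band])
    if noise_floor <= 0 or psd[i] < min_peak_snr * noise_floor:
        raise NoPulseError("no spectral peak above the in-band noise floor")
    f0 = _parabolic_refine(freqs, psd, i)
    return float(np.clip(f0, band[0], band[1]) * 60.0)


def heart_rate_track(
    sig: PPGSignal,
    window_s: float = 15.0,
    step_s: float = 5.0,
    band: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window HR estimates.

    Returns ``(times, bpm)`` with times at window centres, enabling
    heart-rate-over-time curves for a tasting session.  Windows where no
    pulse is detected yield NaN.
    """
    if window_s < 10.0:
        raise ValueError("window must be at least 10 s")
    n_win = int(round(window_s * sig.rate))
    n_step = max(1, int(round(step_s * sig.rate)))
    if n_win > len(sig.samples):
        raise ValueError("window longer than signal")
    times, rates = [], []
    for start in range(0, len(sig.samples) - n_win + 1, n_step):
        chunk = PPGSignal(
            samples=sig.samples[start : start + n_win],
            rate=sig.rate,
            detrended=sig.detrended,
            band=sig.band,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                rates.append(estimate_heart_rate(chunk, band=band))
            except NoPulseError:
                rates.append(np.nan)
        times.append((start + n_win / 2) / sig.rate)
    return np.asarray(times), np.asarray(rates)


def extract_features(sig: PPGSignal, band: Optional[tuple[float, float]] = None) -> PPGFeatures:
    """Deterministic fixed-length feature vector for the vitals regressor.

    Spectral features come from the Welch periodogram; beat morphology
    (inter-beat intervals, rise/fall times) from peak/trough detection on the
    filtered waveform.  A flat signal yields all-zero amplitude features and
    is flagged ``low_quality``.
    """
    band = band or sig.band or DEFAULT_BAND
    x = sig.samples
    amp_std = float(np.std(x))
    if amp_std < 1e-12:
        return PPGFeatures(values=np.zeros(len(FEATURE_NAMES)), low_quality=True)

    freqs, psd = _welch_spectrum(sig)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    in_band = np.where(mask)[0]
    i = in_band[np.argmax(psd[in_band])]
    f0 = _parabolic_refine(freqs, psd, i)
    peak_power = float(psd[i])
    # half-power bandwidth around the dominant peak
    half = peak_power / 2.0
    lo_i = i
    while lo_i > in_band[0] and psd[lo_i] > half:
        lo_i -= 1
    hi_i = i
    while hi_i < in_band[-1] and psd[hi_i] > half:
        hi_i += 1
    bandwidth = float(freqs[hi_i] - freqs[lo_i])

    min_dist = max(1, int(sig.rate / band[1]))
    peaks, _ = sps.find_peaks(x, distance=min_dist, prominence=amp_std)
    troughs, _ = sps.find_peaks(-x, distance=min_dist, prominence=amp_std)
    if len(peaks) >= 2:
        ibis = np.diff(peaks) / sig.rate
        ibi_mean, ibi_sd = float(np.mean(ibis)), float(np.std(ibis))
    else:
        ibi_mean = ibi_sd = 0.0
    rise, fall = _rise_fall_times(peaks, troughs, sig.rate)
    values = np.array(
        [
            float(np.clip(f0, band[0], band[1])),
            peak_power,
            bandwidth,
            amp_std,
            float(np.sqrt(np.mean(x**2))),
            float(np.ptp(x)),
            ibi_mean,
            ibi_sd,
            rise,
            fall,
        ]
    )
    return PPGFeatures(values=values, low_quality=len(peaks) < 2)


def _rise_fall_times(peaks: np.ndarray, troughs: np.ndarray, rate: float) -> tuple[float, float]:
    """Mean trough-to-peak (rise) and peak-to-trough (fall) durations."""
    if len(peaks) == 0 or len(troughs) == 0:
        return 0.0, 0.0
    rises, falls = [], []
    for p in peaks:
        before = troughs[troughs < p]
        after = troughs[troughs > p]
        if len(before):
            rises.append((p - before[-1]) / rate)
        if len(after):
            falls.append((after[0] - p) / rate)
    return (
        float(np.mean(rises)) if rises else 0.0,
        float(np.mean(falls)) if falls else 0.0,
    )


MODEL_FORMAT_VERSION = 1


@dataclass
class VitalsModel:
    """Ridge regressor mapping PPG features to (HR, SP, DP).

    Trained on whatever calibration data the caller provides; the synthetic
    calibration shipped with this package is for demonstration and testing
    only and carries no clinical validity.
    """

    coef: np.ndarray = field(repr=False)
    intercept: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...] = FEATURE_NAMES
    alpha: float = 1.0

    def save(self, path: str | Path) -> None:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "alpha": self.alpha,
            "feature_names": list(self.feature_names),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VitalsModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
        return cls(
            coef=np.asarray(doc["coef"], dtype=float),
            intercept=np.asarray(doc["intercept"], dtype=float),
            feature_names=tuple(doc["feature_names"]),
            alpha=float(doc["alpha"]),
        )


def fit_vitals_model(
    features: Sequence[PPGFeatures],
    targets: Sequence[VitalsEstimate],
    alpha: float = 1.0,
) -> VitalsModel:
    """Fit the (HR, SP, DP) ridge regressor on paired calibration data."""
    if len(features) != len(targets):
        raise ValueError("features and targets must have equal length")
    if len(features) < 10:
        raise ValueError(f"need >= 10 training examples, got {len(features)}")
    X = np.stack([f.values for f in features])
    Y = np.array([[t.hr, t.sp, t.dp] for t in targets], dtype=float)
    if np.isnan(Y[:, 1:]).any():
        raise ValueError("all training targets must include SP and DP")
    if np.allclose(Y.std(axis=0), 0):
        warnings.warn("constant targets: fitting a constant model")
    reg = Ridge(alpha=alpha).fit(X, Y)
    return VitalsModel(
        coef=np.asarray(reg.coef_), intercept=np.asarray(reg.intercept_), alpha=alpha
    )


def predict_vitals(
    model: VitalsModel,
    features: PPGFeatures,
    window: tuple[float, float] = (0.0, 0.0),
) -> VitalsEstimate:
    """Predict (HR, SP, DP) for one feature vector.

    If the raw regression output violates SP > DP the two are pulled apart
    symmetrically around their midpoint by a minimal 1 mmHg gap.
    """
    hr, sp, dp = model.coef @ features.values + model.intercept
    sp, dp = float(sp), float(dp)
    if sp <= dp:
        mid = (sp + dp) / 2.0
        sp, dp = mid + 0.5, mid - 0.5
    dp = max(dp, 1.0)
    sp = max(sp, dp + 1.0)
    return VitalsEstimate(hr=float(hr), sp=sp, dp=dp, window=window)
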