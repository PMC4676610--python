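"""Sliding-window framing and the 260-feature motion descriptor.

A 50 Hz stream is cut into 200-sample (4 s) frames with 75% overlap; from
each frame, 130 features are computed per sensor (accelerometer and
gyroscope): per-axis descriptive statistics, first-difference moments,
extremes, z-score histogram counts, magnitudes of DFT components 2-20,
an orientation-free overall magnitude mean, and cross-correlation and
planar-angle summaries for each axis pair.

Conventions for degenerate inputs (zero-variance axes) are fixed so that
every feature is always finite: skewness and excess kurtosis are 0 when the
standard deviation is 0, the z-score histogram then puts all samples in the
central [0, 1) bin, and cross-correlation features are 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as _sig
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SAMPLE_RATE, SensorStream

FRAME_LEN = 200  # samples (4 s at 50 Hz)
OVERLAP = 0.75  # fraction of the frame shared with its neighbour

_AXES = ("x", "y", "z")
_PAIRS = (("x", "y"), ("y", "z"), ("z", "x"))
_SENSORS = ("acc", "gyr")

GROUPS = (
    "basic",
    "moments",
    "deriv_moments",
    "extremes",
    "histogram",
    "fourier",
    "overall_mean",
    "cross_corr",
    "angular_cross_corr",
)


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    sensor: str  # "acc" | "gyr"
    group: str
    axis: str | None  # "x"/"y"/"z", a pair like "xy", or None


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named layout of the 260-dimensional feature vector."""

    specs: tuple[FeatureSpec, ...]

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def count(self, sensor: str | None = None, group: str | None = None) -> int:
        return sum(
            1
            for s in self.specs
            if (sensor is None or s.sensor == sensor) and (group is None or s.group == group)
        )

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256("|".join(self.names).encode()).hexdigest()[:16]


def _sensor_specs(sensor: str) -> list[FeatureSpec]:
    sp: list[FeatureSpec] = []

    def add(group: str, axis: str | None, stat: str) -> None:
        axis_tag = f"_{axis}" if axis else ""
        sp.append(FeatureSpec(f"{sensor}{axis_tag}_{stat}", sensor, group, axis))

    for ax in _AXES:
        for stat in ("mean", "absmean", "rms"):
            add("basic", ax, stat)
    for ax in _AXES:
        for stat in ("sd", "skew", "kurt"):
            add("moments", ax, stat)
    for ax in _AXES:
        for stat in ("dmean", "dsd", "dskew", "dkurt"):
            add("deriv_moments", ax, stat)
    for ax in _AXES:
        for stat in ("min", "max", "absmin", "absmax"):
            add("extremes", ax, stat)
    for ax in _AXES:
        for b in range(6):
            add("histogram", ax, f"zhist{b}")
    for ax in _AXES:
        for k in range(2, 21):  # 1-based DFT components 2..20
            add("fourier", ax, f"fft{k}")
    add("overall_mean", None, "mag_mean")
    for a, b in _PAIRS:
        for stat in ("xcorr_mean", "xcorr_absmean"):
            add("cross_corr", a + b, stat)
    for a, b in _PAIRS:
        for stat in ("angcorr_mean", "angcorr_absmean"):
            add("angular_cross_corr", a + b, stat)
    return sp


@lru_cache(maxsize=1)
def feature_schema() -> FeatureSchema:
    """The fixed 260-entry feature schema (130 per sensor)."""
    return FeatureSchema(tuple(_sensor_specs("acc") + _sensor_specs("gyr")))


@dataclass
class Frame:
    """One fixed-length window of raw samples from both sensors."""

    start_index: int
    accel: np.ndarray  # (frame_len, 3)
    gyro: np.ndarray  # (frame_len, 3)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if (
            self.accel.ndim != 2
            or self.accel.shape[1] != 3
            or self.accel.shape != self.gyro.shape
            or self.accel.shape[0] < 2
        ):
            raise ValueError("accel and gyro windows must be equal (L>=2, 3) arrays")


def frame_stream(
    stream: SensorStream, frame_len: int = FRAME_LEN, overlap: float = OVERLAP
) -> list[Frame]:
    """Cut a stream into fully contained overlapping frames.

    The hop ``frame_len * (1 - overlap)`` must be a whole number of samples;
    trailing samples that do not fill a frame are discarded. A stream shorter
    than ``frame_len`` yields an empty list.
    """
    if frame_len < 2:
        raise ValueError("frame_len must be >= 2")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    hop_f = frame_len * (1.0 - overlap)
    hop = int(round(hop_f))
    if hop < 1 or abs(hop - hop_f) > 1e-9:
        raise ValueError(f"hop {hop_f} is not a whole number of samples")
    n = stream.n_samples
    return [
        Frame(s, stream.accel[s : s + frame_len], stream.gyro[s : s + frame_len])
        for s in range(0, n - frame_len + 1, hop)
    ]


def _moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean, sd, skewness, excess kurtosis with biased (1/n) estimators.

    Skewness and kurtosis are 0 for zero-variance input.
    """
    mean = x.mean(axis=1)
    c = x - mean[:, None, :]
    var = (c**2).mean(axis=1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(sd > 0, (c**3).mean(axis=1) / np.where(sd > 0, sd, 1) ** 3, 0.0)
        kurt = np.where(var > 0, (c**4).mean(axis=1) / np.where(var > 0, var, 1) ** 2 - 3.0, 0.0)
    return mean, sd, skew, kurt


def _sensor_features(W: np.ndarray) -> np.ndarray:
    """Features for one sensor over a batch of frames: (m, L, 3) -> (m, 130)."""
    m, L, _ = W.shape
    absW = np.abs(W)
    mean, sd, skew, kurt = _moments(W)
    out = [
        _interleave(mean, absW.mean(axis=1), np.sqrt((W**2).mean(axis=1))),  # basic
        _interleave(sd, skew, kurt),  # moments
        _interleave(*_moments(np.diff(W, axis=1))),  # deriv moments
        _interleave(W.min(axis=1), W.max(axis=1), absW.min(axis=1), absW.max(axis=1)),
    ]

    # z-score histogram: 6 unit bins over [-3, 3]; out-of-range clipped into
    # the end bins; sd == 0 puts everything in the [0, 1) bin
    z = (W - mean[:, None, :]) / np.where(sd > 0, sd, 1.0)[:, None, :]
    idx = np.clip(np.floor(z + 3.0), 0, 5).astype(int)
    hist = np.stack([(idx == b).sum(axis=1) for b in range(6)], axis=2)  # (m, 3, 6)
    out.append(hist.reshape(m, 18).astype(float))

    # unnormalized DFT magnitudes, 1-based components 2..20 (0-based 1..19)
    F = np.abs(np.fft.rfft(W, axis=1))[:, 1:20, :]  # (m, 19, 3)
    out.append(F.transpose(0, 2, 1).reshape(m, 57))

    out.append(np.sqrt((W**2).sum(axis=2)).mean(axis=1)[:, None])  # overall mean

    # full cross-correlation over all lags, normalized by zero-lag energies;
    # 0 when either axis has zero variance
    energy = (W**2).sum(axis=1)  # (m, 3)
    xc = np.empty((m, 6))
    for p, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        seq = _sig.fftconvolve(W[:, :, i], W[:, ::-1, j], mode="full", axes=1)
        denom = np.sqrt(energy[:, i] * energy[:, j])
        ok = (sd[:, i] > 0) & (sd[:, j] > 0) & (denom > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            seq = np.where(ok[:, None], seq / np.where(denom > 0, denom, 1.0)[:, None], 0.0)
        xc[:, 2 * p] = seq.mean(axis=1)
        xc[:, 2 * p + 1] = np.abs(seq).mean(axis=1)
    out.append(xc)

    # planar angle series theta_AB(t) = atan2(B, A) per axis pair
    ang = np.empty((m, 6))
    for p, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        theta = np.arctan2(W[:, :, j], W[:, :, i])
        ang[:, 2 * p] = theta.mean(axis=1)
        ang[:, 2 * p + 1] = np.abs(theta).mean(axis=1)
    out.append(ang)

    return np.concatenate(out, axis=1)


def _interleave(*stats: np.ndarray) -> np.ndarray:
    """Stack per-axis stats axis-major: x-stats, y-stats, z-stats."""
    return np.stack(stats, axis=2).reshape(stats[0].shape[0], -1)


def extract_features_batch(
    accel: np.ndarray, gyro: np.ndarray
) -> np.ndarray:
    """Feature matrix for batches of aligned accel/gyro windows (m, L, 3)."""
    return np.concatenate([_sensor_features(accel), _sensor_features(gyro)], axis=1)


def extract_features(frame: Frame) -> np.ndarray:
    """The 260-dimensional feature vector of one frame, schema-ordered."""
    return extract_features_batch(frame.accel[None], frame.gyro[None])[0]


@dataclass
class LabeledFrameSet:
    """A feature matrix with per-row provenance (the training-set container)."""

    X: np.ndarray  # (n, 260)
    y: np.ndarray  # activity labels
    honesty: np.ndarray
    subject_id: np.ndarray
    trial_id: np.ndarray
    frame_start: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = self.X.shape[0]
        for name in ("y", "honesty", "subject_id", "trial_id"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} rows")
            setattr(self, name, arr)
        self.frame_start = np.asarray(self.frame_start, dtype=int)
        if self.frame_start.shape[0] != n:
            raise ValueError("frame_start length mismatch")

    def __len__(self) -> int:
        return self.X.shape[0]

    @classmethod
    def empty(cls, n_features: int | None = None) -> "LabeledFrameSet":
        d = n_features if n_features is not None else len(feature_schema())
        e = np.empty(0, dtype=object)
        return cls(np.empty((0, d)), e, e.copy(), e.copy(), e.copy(), np.empty(0, dtype=int))

    @staticmethod
    def concat(parts: list["LabeledFrameSet"]) -> "LabeledFrameSet":
        if not parts:
            return LabeledFrameSet.empty()
        return LabeledFrameSet(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.honesty for p in parts]),
            np.concatenate([p.subject_id for p in parts]),
            np.concatenate([p.trial_id for p in parts]),
            np.concatenate([p.frame_start for p in parts]),
        )

    def subset(self, mask: np.ndarray) -> "LabeledFrameSet":
        return LabeledFrameSet(
            self.X[mask],
            self.y[mask],
            self.honesty[mask],
            self.subject_id[mask],
            self.trial_id[mask],
            self.frame_start[mask],
        )


def extract_dataset(
    streams: list[SensorStream],
    frame_len: int = FRAME_LEN,
    overlap: float = OVERLAP,
) -> LabeledFrameSet:
    """Frame every stream and stack the features with provenance columns.

    Row order is stream order, then frame order within each stream. All
    streams must share the 50 Hz sampling rate.
    """
    parts: list[LabeledFrameSet] = []
    for k, stream in enumerate(streams):
        if abs(stream.sample_rate - SAMPLE_RATE) > 1e-9:
            raise ValueError(
                f"stream {k} sampled at {stream.sample_rate} Hz, expected {SAMPLE_RATE}"
            )
        frames = frame_stream(stream, frame_len, overlap)
        if not frames:
            continue
        acc = np.stack([f.accel for f in frames])
        gyr = np.stack([f.gyro for f in frames])
        X = extract_features_batch(acc, gyr)
        n = len(frames)
        trial = stream.trial_id if stream.trial_id is not None else str(k)
        parts.append(
            LabeledFrameSet(
                X,
                np.full(n, stream.true_activity, dtype=object),
                np.full(n, stream.honesty, dtype=object),
                np.full(n, stream.subject_id, dtype=object),
                np.full(n, trial, dtype=object),
                np.array([f.start_index for f in frames]),
            )
        )
    return LabeledFrameSet.concat(parts)


class FrameFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: sensor streams -> feature matrix.

    ``transform`` accepts a list of :class:`SensorStream` and returns the
    stacked (n_frames, 260) matrix, so it composes with sklearn pipelines
    whose downstream estimator is a frame classifier.
    """

    def __init__(self, frame_len: int = FRAME_LEN, overlap: float = OVERLAP):
        self.frame_len = frame_len
        self.overlap = overlap

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X) -> np.ndarray:
        streams = [X] if isinstance(X, SensorStream) else list(X)
        return extract_dataset(streams, self.frame_len, self.overlap).X

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_schema().names, dtype=object)
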