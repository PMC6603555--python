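"""Accelerometer stream container, orientation-independent features, resampling.

All internal units are g (1 g = 9.80665 m/s^2) and integer milliseconds from
stream start.  The three features defined here — total magnitude, the
linear-to-total acceleration ratio, and the angle between two mean acceleration
vectors — are invariant under any fixed rigid rotation of the device, which is
what makes the downstream detector independent of where and how the sensor is
worn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "G_MS2",
    "SUPPORTED_RATES",
    "POSITIONS",
    "AccelStream",
    "magnitude",
    "estimate_gravity",
    "gravity_alpha",
    "fall_ratio",
    "vector_angle",
    "resample",
]

G_MS2 = 9.80665
#: sampling rates the target accelerometer supports
SUPPORTED_RATES = (8, 50, 100, 250, 333, 500)
POSITIONS = ("chest", "waist", "pocket", "unknown")

#: denominator guard for the free-fall ratio, in g
RATIO_EPS = 1e-3


class StreamValidationError(ValueError):
    """Raised when a stream violates the sampling contract."""


@dataclass
class AccelStream:
    """Uniformly sampled triaxial acceleration, in g.

    Parameters
    ----------
    t_ms : (n,) int64 array
        Sample times in milliseconds from stream start, strictly increasing,
        spaced by ``1000 / rate_hz`` within +-1 ms.
    xyz : (n, 3) float64 array
        Per-axis acceleration in g.
    rate_hz : int
        One of :data:`SUPPORTED_RATES`.
    position : str
        Body position of the device (``chest``/``waist``/``pocket``/``unknown``).
    subject_id : str
        Free-form subject identifier.
    """

    t_ms: np.ndarray
    xyz: np.ndarray
    rate_hz: int
    position: str = "unknown"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.rate_hz not in SUPPORTED_RATES:
            raise StreamValidationError(
                f"rate_hz={self.rate_hz} not in supported set {SUPPORTED_RATES}"
            )
        if self.position not in POSITIONS:
            raise StreamValidationError(f"unknown position {self.position!r}")
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise StreamValidationError("xyz must have shape (n, 3)")
        if self.t_ms.shape[0] != self.xyz.shape[0]:
            raise StreamValidationError("t_ms and xyz length mismatch")
        if len(self) == 0:
            raise StreamValidationError("empty stream")
        if not np.all(np.isfinite(self.xyz)):
            raise StreamValidationError("non-finite acceleration values")
        if self.t_ms[0] < 0:
            raise StreamValidationError("negative start time")
        if len(self) > 1:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                raise StreamValidationError("t_ms not strictly increasing")
            nominal = 1000.0 / self.rate_hz
            if np.any(np.abs(dt - nominal) > 1.0 + 1e-9):
                raise StreamValidationError(
                    f"sample spacing deviates more than 1 ms from {nominal:.3f} ms"
                )

    def __len__(self) -> int:
        return int(self.t_ms.shape[0])

    @property
    def duration_ms(self) -> int:
        return int(self.t_ms[-1] - self.t_ms[0])

    def with_xyz(self, xyz: np.ndarray) -> "AccelStream":
        """Copy of the stream with replaced axis data (same timing/metadata)."""
        return replace(self, xyz=np.asarray(xyz, dtype=np.float64))

    @classmethod
    def from_arrays(
        cls,
        xyz: np.ndarray,
        rate_hz: int,
        position: str = "unknown",
        subject_id: str = "",
        t0_ms: int = 0,
    ) -> "AccelStream":
        """Build a stream from axis data alone, synthesizing nominal timestamps."""
        n = np.asarray(xyz).shape[0]
        t = t0_ms + np.round(np.arange(n) * (1000.0 / rate_hz)).astype(np.int64)
        return cls(t, xyz, rate_hz, position, subject_id)


def magnitude(xyz: np.ndarray) -> np.ndarray | float:
    """Euclidean norm of acceleration, in g.  Accepts a triple or an (n,3) array."""
    a = np.asarray(xyz, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite acceleration input")
    out = np.sqrt(np.sum(a * a, axis=-1))
    return float(out) if out.ndim == 0 else out


def gravity_alpha(rate_hz: float, cutoff_hz: float = 0.3) -> float:
    """First-order IIR coefficient for a low-pass with the given cutoff.

    ``g[n] = alpha * g[n-1] + (1 - alpha) * a[n]`` with
    ``alpha = exp(-2 pi f_c / f_s)``; at 100 Hz and 0.3 Hz cutoff the time
    constant is about 0.53 s, slow enough to ride through a fall's sub-second
    free-fall phase while still tracking posture changes.
    """
    return math.exp(-2.0 * math.pi * cutoff_hz / rate_hz)


def estimate_gravity(stream: AccelStream, cutoff_hz: float = 0.3) -> np.ndarray:
    """Per-sample gravity estimate via a causal per-axis low-pass recursion.

    Initialized at the first sample (``g[0] = a[0]``), so the estimate is valid
    immediately on quasi-static starts and converges geometrically after steps.
    Returns an (n, 3) array in g.
    """
    if len(stream) == 0:  # defensive; the container forbids this
        raise ValueError("empty stream")
    from scipy.signal import lfilter

    a = stream.xyz
    alpha = gravity_alpha(stream.rate_hz, cutoff_hz)
    b, aa = [1.0 - alpha], [1.0, -alpha]
    # zi chosen so that y[0] == a[0]
    zi = alpha * a[0][None, :]
    g, _ = lfilter(b, aa, a, axis=0, zi=zi)
    return g


def fall_ratio(xyz: np.ndarray, gravity: np.ndarray) -> np.ndarray | float:
    """Ratio of linear-acceleration magnitude to total magnitude.

    ``|a - g| / max(|a|, 1e-3 g)``.  At rest this is ~0.  During free fall the
    total magnitude collapses toward 0 g while the linear magnitude tends to
    1 g, so the ratio spikes; the detector's Falling transition fires when it
    exceeds a threshold.  The epsilon guard keeps the feature finite at exact
    free fall.
    """
    a = np.asarray(xyz, dtype=np.float64)
    g = np.asarray(gravity, dtype=np.float64)
    lin = np.sqrt(np.sum((a - g) ** 2, axis=-1))
    tot = np.sqrt(np.sum(a * a, axis=-1))
    out = lin / np.maximum(tot, RATIO_EPS)
    return float(out) if out.ndim == 0 else out


def vector_angle(v1, v2) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180].

    The normalized dot product is clamped to [-1, 1] before the arccos so that
    rounding noise on (anti)parallel vectors cannot produce NaN.
    """
    x1, y1, z1 = float(v1[0]), float(v1[1]), float(v1[2])
    x2, y2, z2 = float(v2[0]), float(v2[1]), float(v2[2])
    n1 = math.sqrt(x1 * x1 + y1 * y1 + z1 * z1)
    n2 = math.sqrt(x2 * x2 + y2 * y2 + z2 * z2)
    if n1 == 0.0:
        raise ValueError("zero-length first vector in vector_angle")
    if n2 == 0.0:
        raise ValueError("zero-length second vector in vector_angle")
    c = (x1 * x2 + y1 * y2 + z1 * z2) / (n1 * n2)
    c = min(1.0, max(-1.0, c))
    return math.degrees(math.acos(c))


def resample(stream: AccelStream, target_rate: int) -> AccelStream:
    """Convert a stream to a lower supported sampling rate.

    Integer rate ratios (e.g. 100 -> 50 Hz) use exact decimation keeping the
    first sample; non-integer ratios (e.g. 100 -> 8 Hz) linearly interpolate
    onto a uniform grid spanning the same duration.  Upsampling is out of
    scope and rejected.
    """
    if target_rate not in SUPPORTED_RATES:
        raise StreamValidationError(f"target rate {target_rate} not supported")
    if target_rate > stream.rate_hz:
        raise ValueError(
            f"upsampling {stream.rate_hz} -> {target_rate} Hz is not supported"
        )
    if target_rate == stream.rate_hz:
        return stream
    if stream.rate_hz % target_rate == 0:
        step = stream.rate_hz // target_rate
        return replace(
            stream,
            t_ms=stream.t_ms[::step].copy(),
            xyz=stream.xyz[::step].copy(),
            rate_hz=target_rate,
        )
    duration = int(stream.t_ms[-1] - stream.t_ms[0])
    n_out = int(math.floor(duration * target_rate / 1000.0)) + 1
    rel = np.round(np.arange(n_out) * (1000.0 / target_rate))
    t_out = stream.t_ms[0] + rel.astype(np.int64)
    t_exact = stream.t_ms[0] + np.arange(n_out) * (1000.0 / target_rate)
    xyz = np.empty((n_out, 3), dtype=np.float64)
    t_in = stream.t_ms.astype(np.float64)
    for k in range(3):
        xyz[:, k] = np.interp(t_exact, t_in, stream.xyz[:, k])
    return replace(stream, t_ms=t_out, xyz=xyz, rate_hz=target_rate)
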