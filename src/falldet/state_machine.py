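"""Five-state fall detector: Stable, Unstable, Falling, Impact/Watcher.

The detector runs sample by sample with O(1) memory and identical logic for
every body position — all transition features (total magnitude, the
linear-to-total acceleration ratio, and the angle between the falling-phase
mean vector and a frozen pre-fall reference vector) are invariant under rigid
rotation of the device, so no calibration step is needed when the sensor is
moved between chest, waist and pocket.

Transition rules
----------------
Stable -> Unstable      ``|  |a| - 1 g | > unstable_mag_dev``
Unstable -> Falling     ``|a - g| / max(|a|, eps) > fall_ratio_min``
Falling -> Impact       ``|a| > impact_mag_min`` AND the angle between the
                        running mean acceleration of the Falling phase and the
                        mean over the pre-fall buffer frozen at Falling entry
                        exceeds ``impact_angle_min``
Impact (watcher)        after 5 s without movement a fall is broadcast; any
                        sample with ``| |a| - 1 g | > watcher_move_dev`` after
                        a short post-impact settling interval restarts the
                        machine in Unstable
Falling, no impact      back to Unstable after ``falling_timeout_s``
Unstable, quiet         back to Stable after ``unstable_quiet_s`` without a
                        magnitude excursion
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from enum import IntEnum
from typing import Optional

import numpy as np

from . import _kernel
from .signal_core import AccelStream, RATIO_EPS, gravity_alpha

__all__ = [
    "ThresholdSet",
    "TUNABLE_FIELDS",
    "REFERENCE_THRESHOLDS",
    "State",
    "DetectorState",
    "FallEvent",
    "step",
    "process_stream",
]


class State(IntEnum):
    STABLE = _kernel.STABLE
    UNSTABLE = _kernel.UNSTABLE
    FALLING = _kernel.FALLING
    WATCHER = _kernel.WATCHER


#: ThresholdSet fields explored by the optimizer; the rest are timing constants.
TUNABLE_FIELDS = (
    "unstable_mag_dev",
    "fall_ratio_min",
    "impact_mag_min",
    "impact_angle_min",
    "watcher_move_dev",
)


@dataclass(frozen=True)
class ThresholdSet:
    """Tunable transition thresholds plus fixed timing constants.

    Units: accelerations in g, angles in degrees, durations in seconds.
    ``watcher_duration_s`` is fixed at 5 s by the detector's design (a fall is
    broadcast only after five movement-free seconds).
    """

    unstable_mag_dev: float
    fall_ratio_min: float
    impact_mag_min: float
    impact_angle_min: float
    watcher_move_dev: float
    watcher_duration_s: float = 5.0
    pre_fall_window_s: float = 0.4
    falling_timeout_s: float = 1.0
    unstable_quiet_s: float = 2.0
    impact_settle_s: float = 0.5

    def __post_init__(self) -> None:
        for name in TUNABLE_FIELDS + (
            "watcher_duration_s",
            "pre_fall_window_s",
            "falling_timeout_s",
            "unstable_quiet_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.impact_angle_min < 180.0:
            raise ValueError("impact_angle_min must lie in (0, 180) degrees")
        if self.impact_settle_s < 0:
            raise ValueError("impact_settle_s must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


#: packaged reference thresholds, calibrated on the synthetic movement corpus
REFERENCE_THRESHOLDS = ThresholdSet(
    unstable_mag_dev=0.25,
    fall_ratio_min=1.2,
    impact_mag_min=1.8,
    impact_angle_min=40.0,
    watcher_move_dev=0.4,
)


@dataclass(frozen=True)
class FallEvent:
    """A broadcast fall alert with the timestamps of each traversed state."""

    t_broadcast_ms: int
    t_unstable_ms: int
    t_falling_ms: int
    t_impact_ms: int
    peak_impact_g: float
    impact_angle_deg: float

    def __post_init__(self) -> None:
        if not (
            self.t_unstable_ms
            <= self.t_falling_ms
            <= self.t_impact_ms
            < self.t_broadcast_ms
        ):
            raise ValueError("fall event timestamps out of order")

    def to_dict(self) -> dict:
        return asdict(self)


class DetectorState:
    """Mutable per-stream detector state for the incremental :func:`step` API.

    Holds the gravity low-pass state, the rolling pre-fall buffer, the
    falling-phase accumulator and the watcher timer.  One instance per stream;
    call :meth:`reset` to reuse it on a new stream.
    """

    def __init__(self, rate_hz: int, cutoff_hz: float = 0.3,
                 pre_fall_window_s: float = 0.4) -> None:
        self.rate_hz = int(rate_hz)
        self.alpha = gravity_alpha(rate_hz, cutoff_hz)
        self.w_pre = max(1, int(round(pre_fall_window_s * rate_hz)))
        self.reset()

    def reset(self) -> None:
        self.current = State.STABLE
        self._g = None  # gravity triple, None until first sample
        self._buf = np.zeros((self.w_pre, 3))
        self._buf_n = 0
        self._buf_i = 0
        self._pf = (0.0, 0.0, 0.0)
        self._fs = (0.0, 0.0, 0.0)
        self._fn = 0
        self._t_unstable = -1
        self._t_falling = -1
        self._t_impact = -1
        self._falling_entry = -1
        self._watcher_entry = -1
        self._last_active = -1
        self._peak = 0.0
        self._angle = 0.0
        self._last_t: Optional[int] = None


def step(state: DetectorState, t_ms: int, xyz, thresholds: ThresholdSet
         ) -> Optional[FallEvent]:
    """Advance the detector by one sample; returns a FallEvent on broadcast.

    Mirrors the compiled kernel branch for branch (the suite asserts
    equivalence).  Raises on out-of-order timestamps.
    """
    t = int(t_ms)
    if state._last_t is not None and t <= state._last_t:
        raise ValueError(f"out-of-order timestamp {t} after {state._last_t}")
    state._last_t = t
    ax, ay, az = float(xyz[0]), float(xyz[1]), float(xyz[2])
    if not (math.isfinite(ax) and math.isfinite(ay) and math.isfinite(az)):
        raise ValueError("non-finite acceleration sample")
    alpha = state.alpha
    if state._g is None:
        gx, gy, gz = ax, ay, az
    else:
        gx = alpha * state._g[0] + (1.0 - alpha) * ax
        gy = alpha * state._g[1] + (1.0 - alpha) * ay
        gz = alpha * state._g[2] + (1.0 - alpha) * az
    state._g = (gx, gy, gz)
    mag = math.sqrt(ax * ax + ay * ay + az * az)
    dev = abs(mag - 1.0)
    ts = thresholds
    watcher_ms = int(round(ts.watcher_duration_s * 1000))
    settle_ms = int(round(ts.impact_settle_s * 1000))
    timeout_ms = int(round(ts.falling_timeout_s * 1000))
    quiet_ms = int(round(ts.unstable_quiet_s * 1000))
    event = None
    if state.current == State.STABLE:
        if dev > ts.unstable_mag_dev:
            state.current = State.UNSTABLE
            state._t_unstable = t
            state._last_active = t
    elif state.current == State.UNSTABLE:
        if dev > ts.unstable_mag_dev:
            state._last_active = t
        lx, ly, lz = ax - gx, ay - gy, az - gz
        lin = math.sqrt(lx * lx + ly * ly + lz * lz)
        denom = mag if mag > RATIO_EPS else RATIO_EPS
        ratio = lin / denom
        if ratio > ts.fall_ratio_min:
            state.current = State.FALLING
            state._t_falling = t
            state._falling_entry = t
            m = state._buf_n
            if m > 0:
                sx = sy = sz = 0.0
                for k in range(m):
                    sx += state._buf[k, 0]
                    sy += state._buf[k, 1]
                    sz += state._buf[k, 2]
                state._pf = (sx / m, sy / m, sz / m)
            else:
                state._pf = (gx, gy, gz)
            state._fs = (ax, ay, az)
            state._fn = 1
        elif t - state._last_active >= quiet_ms:
            state.current = State.STABLE
    elif state.current == State.FALLING:
        fsx = state._fs[0] + ax
        fsy = state._fs[1] + ay
        fsz = state._fs[2] + az
        state._fs = (fsx, fsy, fsz)
        state._fn += 1
        fired = False
        if mag > ts.impact_mag_min:
            fn = state._fn
            mx, my, mz = fsx / fn, fsy / fn, fsz / fn
            pfx, pfy, pfz = state._pf
            n1 = math.sqrt(mx * mx + my * my + mz * mz)
            n2 = math.sqrt(pfx * pfx + pfy * pfy + pfz * pfz)
            if n1 > 0.0 and n2 > 0.0:
                c = (mx * pfx + my * pfy + mz * pfz) / (n1 * n2)
                c = min(1.0, max(-1.0, c))
                ang = math.degrees(math.acos(c))
            else:
                ang = 0.0
            if ang > ts.impact_angle_min:
                state.current = State.WATCHER
                state._t_impact = t
                state._watcher_entry = t
                state._peak = mag
                state._angle = ang
                fired = True
        if not fired and t - state._falling_entry >= timeout_ms:
            state.current = State.UNSTABLE
            state._last_active = t
    else:  # WATCHER
        if mag > state._peak:
            state._peak = mag
        if t - state._watcher_entry >= watcher_ms:
            event = FallEvent(
                t_broadcast_ms=t,
                t_unstable_ms=state._t_unstable,
                t_falling_ms=state._t_falling,
                t_impact_ms=state._t_impact,
                peak_impact_g=state._peak,
                impact_angle_deg=state._angle,
            )
            state.current = State.STABLE
        elif t - state._watcher_entry > settle_ms and dev > ts.watcher_move_dev:
            state.current = State.UNSTABLE
            state._t_unstable = t
            state._last_active = t
    # push into the pre-fall ring buffer after dispatch
    state._buf[state._buf_i, 0] = ax
    state._buf[state._buf_i, 1] = ay
    state._buf[state._buf_i, 2] = az
    state._buf_i = (state._buf_i + 1) % state.w_pre
    if state._buf_n < state.w_pre:
        state._buf_n += 1
    return event


def process_stream(
    stream: AccelStream,
    thresholds: ThresholdSet,
    engine: str = "auto",
    return_states: bool = False,
    cutoff_hz: float = 0.3,
):
    """Run the detector over a whole stream.

    Deterministic batch driver equal to folding :func:`step` over the samples.
    ``engine`` selects the compiled kernel (``"auto"``/``"numba"``) or the
    pure-Python incremental path (``"python"``).  Returns the list of
    :class:`FallEvent`; with ``return_states=True`` also the per-sample state
    trace (int8 array of :class:`State` codes).
    """
    if engine not in ("auto", "numba", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "python":
        det = DetectorState(stream.rate_hz, cutoff_hz, thresholds.pre_fall_window_s)
        events = []
        trace = np.zeros(len(stream), dtype=np.int8)
        for i in range(len(stream)):
            ev = step(det, int(stream.t_ms[i]), stream.xyz[i], thresholds)
            trace[i] = int(det.current)
            if ev is not None:
                events.append(ev)
    else:
        alpha = gravity_alpha(stream.rate_hz, cutoff_hz)
        ev_arr, trace = _kernel.run_fsm(
            stream.t_ms, stream.xyz, thresholds, stream.rate_hz, alpha,
            engine=engine,
        )
        events = [
            FallEvent(
                t_broadcast_ms=int(row[0]),
                t_unstable_ms=int(row[1]),
                t_falling_ms=int(row[2]),
                t_impact_ms=int(row[3]),
                peak_impact_g=float(row[4]),
                impact_angle_deg=float(row[5]),
            )
            for row in ev_arr
        ]
    if return_states:
        return events, trace
    return events
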