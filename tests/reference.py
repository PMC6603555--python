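"""Independent brute-force reference detector used as a test oracle.

Unlike the incremental implementation, this one precomputes every feature
over full arrays (gravity by filtering the whole stream, running means from
prefix sums, window means from prefix-sum differences) and then simulates the
transition rules literally, state by state.  It shares no code with
``falldet.state_machine`` beyond the threshold container.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import lfilter

from falldet.signal_core import AccelStream


def brute_force_events(stream: AccelStream, ts, cutoff_hz: float = 0.3):
    """Full-array literal simulation; returns list of event tuples
    (t_broadcast, t_unstable, t_falling, t_impact, peak_g, angle_deg)."""
    a = stream.xyz
    t = stream.t_ms
    n = len(stream)
    alpha = math.exp(-2.0 * math.pi * cutoff_hz / stream.rate_hz)
    g, _ = lfilter([1 - alpha], [1, -alpha], a, axis=0,
                   zi=alpha * a[0][None, :])
    mag = np.linalg.norm(a, axis=1)
    dev = np.abs(mag - 1.0)
    lin = np.linalg.norm(a - g, axis=1)
    ratio = lin / np.maximum(mag, 1e-3)
    csum = np.cumsum(a, axis=0)
    w = max(1, int(round(ts.pre_fall_window_s * stream.rate_hz)))
    watcher_ms = int(round(ts.watcher_duration_s * 1000))
    settle_ms = int(round(ts.impact_settle_s * 1000))
    timeout_ms = int(round(ts.falling_timeout_s * 1000))
    quiet_ms = int(round(ts.unstable_quiet_s * 1000))

    def window_mean(i):
        # mean of the w samples strictly before i (fewer near the start)
        m = min(i, w)
        if m == 0:
            return g[i]
        hi = csum[i - 1]
        lo = csum[i - m - 1] if i - m - 1 >= 0 else np.zeros(3)
        return (hi - lo) / m

    def angle(v1, v2):
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0.0 or n2 == 0.0:
            return 0.0
        c = float(np.dot(v1, v2) / (n1 * n2))
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    STABLE, UNSTABLE, FALLING, WATCHER = 0, 1, 2, 3
    state = STABLE
    events = []
    t_unst = t_fall = t_imp = -1
    fall_entry_i = -1
    watch_entry_i = -1
    last_active = -1
    prefall = None
    angle_imp = 0.0
    for i in range(n):
        ti = int(t[i])
        if state == STABLE:
            if dev[i] > ts.unstable_mag_dev:
                state = UNSTABLE
                t_unst = ti
                last_active = ti
        elif state == UNSTABLE:
            if dev[i] > ts.unstable_mag_dev:
                last_active = ti
            if ratio[i] > ts.fall_ratio_min:
                state = FALLING
                t_fall = ti
                fall_entry_i = i
                prefall = window_mean(i)
            elif ti - last_active >= quiet_ms:
                state = STABLE
        elif state == FALLING:
            fired = False
            if mag[i] > ts.impact_mag_min:
                lo = csum[fall_entry_i - 1] if fall_entry_i >= 1 else np.zeros(3)
                fall_mean = (csum[i] - lo) / (i - fall_entry_i + 1)
                ang = angle(fall_mean, prefall)
                if ang > ts.impact_angle_min:
                    state = WATCHER
                    t_imp = ti
                    watch_entry_i = i
                    angle_imp = ang
                    fired = True
            if not fired and ti - int(t[fall_entry_i]) >= timeout_ms:
                state = UNSTABLE
                last_active = ti
        else:  # WATCHER
            entry_t = int(t[watch_entry_i])
            if ti - entry_t >= watcher_ms:
                peak = float(np.max(mag[watch_entry_i:i + 1]))
                events.append((ti, t_unst, t_fall, t_imp, peak, angle_imp))
                state = STABLE
            elif ti - entry_t > settle_ms and dev[i] > ts.watcher_move_dev:
                state = UNSTABLE
                t_unst = ti
                last_active = ti
    return events


def make_random_stream(seed: int, rate_hz: int = 100,
                       max_duration_s: float = 10.0) -> AccelStream:
    """Random piecewise test signal mixing quiet, noisy, free-fall-like dips,
    spikes and orientation flips, built to exercise every transition."""
    rng = np.random.default_rng(seed)
    total = rng.uniform(2.0, max_duration_s)
    chunks = []
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    t_used = 0.0
    while t_used < total:
        kind = rng.choice(["still", "noise", "dip", "spike", "flip"])
        dur = float(rng.uniform(0.05, 1.5))
        dur = min(dur, total - t_used)
        n = max(1, int(round(dur * rate_hz)))
        if kind == "still":
            mag = np.full(n, 1.0) + rng.normal(0, 0.01, n)
        elif kind == "noise":
            mag = 1.0 + rng.normal(0, rng.uniform(0.05, 0.4), n)
        elif kind == "dip":
            mag = np.full(n, rng.uniform(0.02, 0.7)) + rng.normal(0, 0.02, n)
        elif kind == "spike":
            mag = np.full(n, rng.uniform(1.5, 5.0)) + rng.normal(0, 0.1, n)
        else:  # flip: new orientation
            theta = rng.uniform(0, math.pi)
            p = rng.normal(size=3)
            p -= np.dot(p, d) * d
            p /= np.linalg.norm(p)
            d = math.cos(theta) * d + math.sin(theta) * p
            mag = np.full(n, 1.0) + rng.normal(0, 0.02, n)
        chunks.append(np.abs(mag)[:, None] * d)
        t_used += n / rate_hz
    xyz = np.vstack(chunks)
    return AccelStream.from_arrays(xyz, rate_hz)
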