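"""Compiled detector core.

The five-state detector is written once as a plain scalar loop over arrays
(:func:`_fsm_loop`) and compiled with numba when available; the incremental
:func:`falldet.state_machine.step` API mirrors it branch for branch and the
test suite asserts event-level equivalence of both against an independent
full-array reference.  A batch entry point evaluates one threshold set over a
whole clip corpus in a single compiled call, which is what makes the
randomized threshold search tractable.

State encoding: 0 Stable, 1 Unstable, 2 Falling, 3 Impact/Watcher.
Event rows: (t_broadcast, t_unstable, t_falling, t_impact, peak_g, angle_deg).
"""

from __future__ import annotations

import math

import numpy as np

STABLE, UNSTABLE, FALLING, WATCHER = 0, 1, 2, 3
EVENT_WIDTH = 6


def _fsm_loop(
    t_ms,
    a,
    alpha,
    w_pre,
    unstable_mag_dev,
    fall_ratio_min,
    impact_mag_min,
    impact_angle_min,
    watcher_move_dev,
    watcher_ms,
    settle_ms,
    falling_timeout_ms,
    quiet_ms,
    ratio_eps,
    events,
    states,
):
    n = t_ms.shape[0]
    state = STABLE
    gx = gy = gz = 0.0
    # pre-fall ring buffer of raw triples
    buf = np.zeros((w_pre, 3))
    buf_n = 0
    buf_i = 0
    pfx = pfy = pfz = 0.0  # frozen pre-fall mean
    fsx = fsy = fsz = 0.0  # falling-phase running sum
    fn = 0
    t_unstable = -1
    t_falling = -1
    t_impact = -1
    falling_entry = -1
    watcher_entry = -1
    last_active = -1
    peak = 0.0
    angle_at_impact = 0.0
    n_ev = 0
    for i in range(n):
        t = t_ms[i]
        ax = a[i, 0]
        ay = a[i, 1]
        az = a[i, 2]
        if i == 0:
            gx = ax
            gy = ay
            gz = az
        else:
            gx = alpha * gx + (1.0 - alpha) * ax
            gy = alpha * gy + (1.0 - alpha) * ay
            gz = alpha * gz + (1.0 - alpha) * az
        mag = math.sqrt(ax * ax + ay * ay + az * az)
        dev = abs(mag - 1.0)
        if state == STABLE:
            if dev > unstable_mag_dev:
                state = UNSTABLE
                t_unstable = t
                last_active = t
        elif state == UNSTABLE:
            if dev > unstable_mag_dev:
                last_active = t
            lx = ax - gx
            ly = ay - gy
            lz = az - gz
            lin = math.sqrt(lx * lx + ly * ly + lz * lz)
            denom = mag if mag > ratio_eps else ratio_eps
            ratio = lin / denom
            if ratio > fall_ratio_min:
                state = FALLING
                t_falling = t
                falling_entry = t
                # freeze the pre-fall reference: mean over the ring buffer
                sx = 0.0
                sy = 0.0
                sz = 0.0
                m = buf_n
                for k in range(m):
                    sx += buf[k, 0]
                    sy += buf[k, 1]
                    sz += buf[k, 2]
                if m > 0:
                    pfx = sx / m
                    pfy = sy / m
                    pfz = sz / m
                else:
                    pfx = gx
                    pfy = gy
                    pfz = gz
                fsx = ax
                fsy = ay
                fsz = az
                fn = 1
            elif t - last_active >= quiet_ms:
                state = STABLE
        elif state == FALLING:
            fsx += ax
            fsy += ay
            fsz += az
            fn += 1
            fired = False
            if mag > impact_mag_min:
                mx = fsx / fn
                my = fsy / fn
                mz = fsz / fn
                n1 = math.sqrt(mx * mx + my * my + mz * mz)
                n2 = math.sqrt(pfx * pfx + pfy * pfy + pfz * pfz)
                if n1 > 0.0 and n2 > 0.0:
                    c = (mx * pfx + my * pfy + mz * pfz) / (n1 * n2)
                    if c > 1.0:
                        c = 1.0
                    elif c < -1.0:
                        c = -1.0
                    ang = math.degrees(math.acos(c))
                else:
                    ang = 0.0
                if ang > impact_angle_min:
                    state = WATCHER
                    t_impact = t
                    watcher_entry = t
                    peak = mag
                    angle_at_impact = ang
                    fired = True
            if not fired and t - falling_entry >= falling_timeout_ms:
                state = UNSTABLE
                last_active = t
        else:  # WATCHER
            if mag > peak:
                peak = mag
            if t - watcher_entry >= watcher_ms:
                events[n_ev, 0] = t
                events[n_ev, 1] = t_unstable
                events[n_ev, 2] = t_falling
                events[n_ev, 3] = t_impact
                events[n_ev, 4] = peak
                events[n_ev, 5] = angle_at_impact
                n_ev += 1
                state = STABLE
            elif t - watcher_entry > settle_ms and dev > watcher_move_dev:
                state = UNSTABLE
                t_unstable = t
                last_active = t
        states[i] = state
        # ring-buffer push happens after the transition dispatch so the frozen
        # pre-fall mean never includes the sample that entered Falling
        buf[buf_i, 0] = ax
        buf[buf_i, 1] = ay
        buf[buf_i, 2] = az
        buf_i += 1
        if buf_i == w_pre:
            buf_i = 0
        if buf_n < w_pre:
            buf_n += 1
    return n_ev


def _max_events(t_ms, watcher_ms: int) -> int:
    # broadcasts are at least one watcher duration apart
    if t_ms.shape[0] == 0:
        return 1
    span = int(t_ms[-1] - t_ms[0])
    return span // max(1, int(watcher_ms)) + 2


def _make_batch(fsm):
    def _batch(flat_t, flat_a, offsets, alpha, w_pre, umd, frm, imm, iam,
               wmd, w_ms, s_ms, ft_ms, q_ms, eps, fired):
        n_clips = offsets.shape[0] - 1
        for c in range(n_clips):
            lo = offsets[c]
            hi = offsets[c + 1]
            n = hi - lo
            span = flat_t[hi - 1] - flat_t[lo]
            max_ev = span // max(1, w_ms) + 2
            events = np.zeros((max_ev, 6))
            states = np.zeros(n, dtype=np.int8)
            fired[c] = fsm(
                flat_t[lo:hi], flat_a[lo:hi], alpha, w_pre, umd, frm,
                imm, iam, wmd, w_ms, s_ms, ft_ms, q_ms, eps,
                events, states,
            )

    return _batch


try:  # pragma: no cover - import guard
    from numba import njit

    _fsm_loop_jit = njit(cache=False)(_fsm_loop)
    _batch_count_jit = njit(cache=False)(_make_batch(_fsm_loop_jit))
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _fsm_loop_jit = _fsm_loop
    _batch_count_jit = _make_batch(_fsm_loop)
    HAVE_NUMBA = False


def fsm_params(thresholds, rate_hz: int, alpha: float) -> tuple:
    """Pack a ThresholdSet into the scalar argument tuple of the kernel."""
    w_pre = max(1, int(round(thresholds.pre_fall_window_s * rate_hz)))
    return (
        alpha,
        w_pre,
        float(thresholds.unstable_mag_dev),
        float(thresholds.fall_ratio_min),
        float(thresholds.impact_mag_min),
        float(thresholds.impact_angle_min),
        float(thresholds.watcher_move_dev),
        int(round(thresholds.watcher_duration_s * 1000)),
        int(round(thresholds.impact_settle_s * 1000)),
        int(round(thresholds.falling_timeout_s * 1000)),
        int(round(thresholds.unstable_quiet_s * 1000)),
        1e-3,
    )


def run_fsm(t_ms, xyz, thresholds, rate_hz, alpha, engine="auto"):
    """Run the detector over one stream; returns (events array, states array)."""
    params = fsm_params(thresholds, rate_hz, alpha)
    events = np.zeros((_max_events(t_ms, params[7]), EVENT_WIDTH))
    states = np.zeros(t_ms.shape[0], dtype=np.int8)
    fn = _fsm_loop_jit if (engine in ("auto", "numba") and HAVE_NUMBA) else _fsm_loop
    n_ev = fn(np.ascontiguousarray(t_ms), np.ascontiguousarray(xyz), *params,
              events, states)
    return events[:n_ev], states


def count_events_batch(flat_t, flat_a, offsets, thresholds, rate_hz, alpha):
    """Number of emitted events per clip for one threshold set.

    ``flat_t``/``flat_a`` are clip streams concatenated along axis 0 with
    ``offsets`` delimiting clip ``c`` as ``[offsets[c], offsets[c+1])``.
    """
    params = fsm_params(thresholds, rate_hz, alpha)
    fired = np.zeros(offsets.shape[0] - 1, dtype=np.int64)
    _batch_count_jit(np.ascontiguousarray(flat_t), np.ascontiguousarray(flat_a),
                     np.ascontiguousarray(offsets), *params, fired)
    return fired
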