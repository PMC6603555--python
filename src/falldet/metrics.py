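"""Event-label matching and evaluation statistics.

Clip-level scoring treats every labeled movement clip as one binary trial
(fall / non-fall); continuous scoring matches broadcast events against
labeled fall windows in a long recording, where true negatives are undefined
and false alarms are reported both as a count and as a rate per wear day
(16.5 h of daily usage by default).

Headline statistics::

    Sens   = TP / (TP + FN) * 100 %
    Spec   = TN / (TN + FP) * 100 %
    J      = Sens + Spec - 100 %          (Youden index)
    Prec   = TP / (TP + FP) * 100 %
    F      = 2 * Prec * Sens / (Prec + Sens)
    FA/day = FP / (hours / day_hours)

ROC points are (1 - Spec/100, Sens/100); TOC (total operating characteristic)
points plot hits against hits + false alarms, so the diagonal marks "no false
alarms" and a horizontal line marks the total number of falls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "DAY_HOURS",
    "ConfusionCounts",
    "MetricsReport",
    "UndefinedMetricError",
    "round_half_up",
    "j_index",
    "compute_metrics",
    "match_events_clip",
    "match_events_continuous",
    "toc_points",
    "roc_points",
    "plot_toc",
    "plot_roc",
]

#: assumed daily wear time, in hours
DAY_HOURS = 16.5


class UndefinedMetricError(ZeroDivisionError):
    """A requested ratio has a zero denominator (e.g. sensitivity with no falls)."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, used only at presentation time."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN event counts; ``tn=None`` flags continuous scoring."""

    tp: int = 0
    fp: int = 0
    tn: Optional[int] = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        tn = None if (self.tn is None or other.tn is None) else self.tn + other.tn
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               tn, self.fn + other.fn)


def j_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """Youden index in percent: sensitivity + specificity - 100 (may be negative)."""
    for v in (sensitivity_pct, specificity_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("sensitivity/specificity must lie in [0, 100]")
    return sensitivity_pct + specificity_pct - 100.0


@dataclass(frozen=True)
class MetricsReport:
    """Full-precision evaluation statistics; round only for display."""

    counts: ConfusionCounts
    sensitivity_pct: float
    specificity_pct: Optional[float]
    j_index_pct: Optional[float]
    precision_pct: Optional[float]
    f_score_pct: Optional[float]
    fa_count: int
    fa_per_day: Optional[float]
    hours_of_data: Optional[float]
    day_hours: float = DAY_HOURS

    def rounded(self, ndigits: int = 1) -> dict:
        """Presentation dict with half-up rounding to ``ndigits`` decimals."""
        out = {}
        for name in ("sensitivity_pct", "specificity_pct", "j_index_pct",
                     "precision_pct", "f_score_pct", "fa_per_day"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, ndigits)
        out["fa_count"] = self.fa_count
        out["hours_of_data"] = self.hours_of_data
        return out

    def to_dict(self) -> dict:
        d = self.rounded()
        d["counts"] = {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn}
        return d


def compute_metrics(
    counts: ConfusionCounts,
    hours: Optional[float] = None,
    day_hours: float = DAY_HOURS,
) -> MetricsReport:
    """Evaluation statistics from confusion counts.

    Specificity and the J-index are reported only when true negatives are
    defined (clip-level scoring); FA/day only when ``hours`` is given.
    """
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    sens = counts.tp / (counts.tp + counts.fn) * 100.0
    if counts.tn is None:
        spec = jv = None
    else:
        if counts.tn + counts.fp == 0:
            raise UndefinedMetricError("specificity undefined: no negative cases")
        spec = counts.tn / (counts.tn + counts.fp) * 100.0
        jv = j_index(sens, spec)
    if counts.tp + counts.fp == 0:
        prec = fscore = None
    else:
        prec = counts.tp / (counts.tp + counts.fp) * 100.0
        fscore = (
            0.0 if prec + sens == 0.0 else 2.0 * prec * sens / (prec + sens)
        )
    fa_per_day = None
    if hours is not None:
        if hours <= 0:
            raise ValueError("hours of data must be positive")
        fa_per_day = counts.fp / (hours / day_hours)
    return MetricsReport(
        counts=counts,
        sensitivity_pct=sens,
        specificity_pct=spec,
        j_index_pct=jv,
        precision_pct=prec,
        f_score_pct=fscore,
        fa_count=counts.fp,
        fa_per_day=fa_per_day,
        hours_of_data=hours,
        day_hours=day_hours,
    )


def match_events_clip(
    events_by_clip: Mapping[str, Sequence],
    labels: Mapping[str, bool],
) -> ConfusionCounts:
    """Clip-level confusion counts: one binary decision per labeled clip.

    A fall clip with at least one broadcast event is a TP, otherwise an FN; a
    non-fall clip with at least one event is an FP, otherwise a TN.  Every
    clip with events must carry a label.
    """
    unknown = set(events_by_clip) - set(labels)
    if unknown:
        raise KeyError(f"clips without labels: {sorted(unknown)[:5]}")
    tp = fp = tn = fn = 0
    for clip_id, is_fall in labels.items():
        fired = len(events_by_clip.get(clip_id, ())) > 0
        if is_fall:
            tp += fired
            fn += not fired
        else:
            fp += fired
            tn += not fired
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _event_time_ms(ev) -> int:
    return int(getattr(ev, "t_impact_ms", ev))


def match_events_continuous(
    events: Sequence,
    fall_windows: Sequence[tuple],
    tolerance_s: float = 2.0,
) -> ConfusionCounts:
    """Match broadcast events against labeled fall windows of a long recording.

    ``events`` are FallEvents (matched on their impact time) or plain impact
    times in ms; ``fall_windows`` are non-overlapping, time-sorted
    ``(start_ms, end_ms)`` intervals.  A window containing at least one event
    within ``[start - tol, end + tol]`` is a TP (extra events inside the same
    window are not double-counted); an event matching no window is an FP; a
    window with no event is an FN.  TN is undefined (``None``) for continuous
    scoring.
    """
    windows = [(int(s), int(e)) for s, e in fall_windows]
    for (s, e) in windows:
        if e < s:
            raise ValueError("fall window with end before start")
    for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
        if s1 < s0:
            raise ValueError("fall windows must be time-sorted")
        if s1 <= e0:
            raise ValueError("fall windows must be non-overlapping")
    tol = int(round(tolerance_s * 1000))
    times = sorted(_event_time_ms(ev) for ev in events)
    matched = [False] * len(windows)
    fp = 0
    for t in times:
        hit = False
        for w, (s, e) in enumerate(windows):
            if s - tol <= t <= e + tol:
                matched[w] = True
                hit = True
                break
        if not hit:
            fp += 1
    tp = sum(matched)
    fn = len(windows) - tp
    return ConfusionCounts(tp=tp, fp=fp, tn=None, fn=fn)


def toc_points(results: Sequence[tuple]) -> list[tuple]:
    """TOC points (hits + false alarms, hits) from per-threshold-set (tp, fp)."""
    if len(results) == 0:
        raise ValueError("no results for TOC construction")
    return [(int(tp) + int(fp), int(tp)) for tp, fp in results]


def roc_points(results: Sequence[tuple]) -> list[tuple]:
    """ROC points (1 - spec/100, sens/100) from per-set (sens_pct, spec_pct)."""
    if len(results) == 0:
        raise ValueError("no results for ROC construction")
    return [((100.0 - spec) / 100.0, sens / 100.0) for sens, spec in results]


def plot_roc(points: Sequence[tuple], ax=None, **kwargs):
    """Scatter the ROC operating points on [0,1]x[0,1] axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    ax.plot(xs, ys, "o", **kwargs)
    ax.plot([0, 1], [0, 1], ":", color="0.6", lw=1)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def plot_toc(points: Sequence[tuple], total_falls: int, ax=None, **kwargs):
    """Scatter TOC points with the no-false-alarm diagonal and the fall ceiling."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    ax.plot(xs, ys, "o", **kwargs)
    lim = max(xs + [total_falls]) * 1.1 + 1
    ax.plot([0, lim], [0, lim], ":", color="0.6", lw=1, label="no false alarms")
    ax.axhline(total_falls, color="0.3", lw=1, ls="--", label="total dataset falls")
    ax.set_xlabel("hits + false alarms")
    ax.set_ylabel("hits (true positives)")
    ax.legend(loc="lower right", fontsize=8)
    return ax
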