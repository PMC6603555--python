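"""Randomized threshold search with stratified resampling and level selection.

The detector's transition thresholds are not fitted by gradient methods —
each candidate is a random draw inside per-parameter bounds, "trained" by
evaluating and ranking it on a class-balanced train partition, and kept or
discarded by its Youden J-index.  The full pipeline:

1. repeat a stratified 70/30 train/test split of the labeled clip corpus
   ``n_splits`` times;
2. for each split, randomly undersample the majority class of the train set
   ``n_undersamples`` times (down to the minority count);
3. for each undersampled set, draw ``n_random_sets`` random threshold sets
   within the bounds;
4. rank them on the balanced train set by J-index and keep the ``n_keep``
   best, remembering the split's test partition;
5. evaluate the kept sets on that test partition;
6. pool everything and return the ``n_keep`` candidates with the best test
   J-index.

From the 10 best candidates three operating points are then picked off the
ROC: maximum J (medium sensitivity), maximum specificity (low) and maximum
sensitivity (high) — a user-selectable trade-off between detection rate and
false alarms.

Exposed in a model/results idiom: build a :class:`ThresholdOptimizer` from a
clip corpus, call :meth:`~ThresholdOptimizer.fit`, inspect the returned
:class:`OptimizationResults` (leaderboard, ``summary()``, ``select_levels()``,
``plot_roc()``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .metrics import ConfusionCounts, compute_metrics, j_index, roc_points
from .signal_core import gravity_alpha, resample
from .state_machine import ThresholdSet, TUNABLE_FIELDS

__all__ = [
    "ThresholdBounds",
    "DEFAULT_BOUNDS",
    "OptimizationConfig",
    "CandidateResult",
    "SensitivityLevels",
    "ThresholdOptimizer",
    "OptimizationResults",
    "stratified_splits",
    "undersample_majority",
    "sample_threshold_sets",
    "evaluate_candidate",
    "run_optimization",
    "select_levels",
]


@dataclass(frozen=True)
class ThresholdBounds:
    """Admissible (low, high) interval per tunable threshold field."""

    unstable_mag_dev: tuple = (0.15, 0.45)
    fall_ratio_min: tuple = (0.8, 1.8)
    impact_mag_min: tuple = (1.3, 1.9)
    impact_angle_min: tuple = (30.0, 55.0)
    watcher_move_dev: tuple = (0.15, 0.5)

    def __post_init__(self) -> None:
        for name in TUNABLE_FIELDS:
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"{name} bounds must be finite")
            if not 0 < lo <= hi:
                raise ValueError(f"{name} bounds must satisfy 0 < low <= high")

    def to_dict(self) -> dict:
        return {k: list(getattr(self, k)) for k in TUNABLE_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdBounds":
        return cls(**{k: tuple(v) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ThresholdBounds":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_BOUNDS = ThresholdBounds()


@dataclass(frozen=True)
class OptimizationConfig:
    """Search-pipeline configuration (defaults follow the published procedure)."""

    n_splits: int = 10
    train_ratio: float = 0.7
    n_undersamples: int = 10
    n_random_sets: int = 100
    n_keep: int = 50
    seed: int = 0
    rate_hz: int = 100

    def __post_init__(self) -> None:
        for name in ("n_splits", "n_undersamples", "n_random_sets", "n_keep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.train_ratio < 1.0:
            raise ValueError("train_ratio must lie in (0, 1)")
        if self.rate_hz not in (50, 100):
            raise ValueError("optimization runs at 100 or 50 Hz")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizationConfig":
        return cls(**d)


@dataclass(frozen=True)
class CandidateResult:
    """One retained threshold set with its train/test operating points."""

    thresholds: ThresholdSet
    train_j: float
    test_j: float
    test_sens: float
    test_spec: float
    split_id: int
    undersample_id: int


@dataclass(frozen=True)
class SensitivityLevels:
    """The low/medium/high operating points selected from the candidate ROC."""

    low: CandidateResult
    medium: CandidateResult
    high: CandidateResult

    def __post_init__(self) -> None:
        if not (self.high.test_sens >= self.medium.test_sens
                >= self.low.test_sens):
            raise ValueError("level sensitivities must be ordered "
                             "high >= medium >= low")

    def __getitem__(self, name: str) -> CandidateResult:
        if name not in ("low", "medium", "high"):
            raise KeyError(name)
        return getattr(self, name)

    def to_dict(self) -> dict:
        out = {}
        for name in ("low", "medium", "high"):
            c = self[name]
            out[name] = {
                "thresholds": c.thresholds.to_dict(),
                "test_sens": c.test_sens,
                "test_spec": c.test_spec,
                "test_j": c.test_j,
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# pipeline primitives

def _round_half_up_int(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_splits(labels: np.ndarray, config: OptimizationConfig,
                      rng: np.random.Generator):
    """Repeated stratified train/test index partitions.

    Each split places ``round(train_ratio * n_c)`` clips of each class ``c``
    in the train set; repetitions are drawn independently.
    """
    labels = np.asarray(labels, dtype=bool)
    out = []
    for c in (True, False):
        if int(np.sum(labels == c)) < 2:
            raise ValueError("each class needs at least 2 clips to split")
    for _ in range(config.n_splits):
        train_idx = []
        test_idx = []
        for c in (True, False):
            idx = np.flatnonzero(labels == c)
            n_train = _round_half_up_int(config.train_ratio * idx.size)
            perm = rng.permutation(idx)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        out.append((np.sort(np.concatenate(train_idx)),
                    np.sort(np.concatenate(test_idx))))
    return out


def undersample_majority(indices: np.ndarray, labels: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Randomly reduce the majority class to the minority count (no replacement)."""
    indices = np.asarray(indices)
    lab = np.asarray(labels, dtype=bool)[indices]
    pos = indices[lab]
    neg = indices[~lab]
    if pos.size == neg.size:
        return np.sort(indices)
    major, minor = (pos, neg) if pos.size > neg.size else (neg, pos)
    kept = rng.choice(major, size=minor.size, replace=False)
    return np.sort(np.concatenate([minor, kept]))


def sample_threshold_sets(bounds: ThresholdBounds, n: int,
                          rng: np.random.Generator) -> list[ThresholdSet]:
    """Draw ``n`` threshold sets uniformly and independently within bounds.

    Fixed timing constants (watcher duration, pre-fall window, timeouts) are
    left at their defaults.
    """
    sets = []
    for _ in range(n):
        draws = {name: float(rng.uniform(*getattr(bounds, name)))
                 for name in TUNABLE_FIELDS}
        sets.append(ThresholdSet(**draws))
    return sets


# ---------------------------------------------------------------------------
# corpus evaluation

class _CorpusArrays:
    """Clip streams resampled once and flattened for the batch kernel."""

    def __init__(self, clips, rate_hz: int, cutoff_hz: float = 0.3) -> None:
        streams = [resample(c.stream, rate_hz) for c in clips]
        self.labels = np.array([c.is_fall for c in clips])
        self.rate_hz = rate_hz
        self.alpha = gravity_alpha(rate_hz, cutoff_hz)
        self.flat_t = np.concatenate([s.t_ms for s in streams])
        self.flat_a = np.vstack([s.xyz for s in streams])
        lens = np.array([len(s) for s in streams], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
        self.n_clips = len(streams)

    def fires(self, thresholds: ThresholdSet,
              subset: Optional[np.ndarray] = None) -> np.ndarray:
        fired = _kernel.count_events_batch(
            self.flat_t, self.flat_a, self.offsets, thresholds,
            self.rate_hz, self.alpha,
        ) > 0
        return fired if subset is None else fired[subset]

    def counts(self, thresholds: ThresholdSet,
               subset: Optional[np.ndarray] = None) -> ConfusionCounts:
        fired = self.fires(thresholds)
        lab = self.labels
        if subset is not None:
            fired = fired[subset]
            lab = lab[subset]
        tp = int(np.sum(fired & lab))
        fp = int(np.sum(fired & ~lab))
        fn = int(np.sum(~fired & lab))
        tn = int(np.sum(~fired & ~lab))
        return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_candidate(thresholds: ThresholdSet, clips,
                       rate_hz: int = 100) -> ConfusionCounts:
    """Clip-level confusion counts of one threshold set over labeled clips."""
    arrays = clips if isinstance(clips, _CorpusArrays) else _CorpusArrays(
        list(clips), rate_hz)
    return arrays.counts(thresholds)


def _j_of(counts: ConfusionCounts) -> tuple[float, float, float]:
    rep = compute_metrics(counts)
    return rep.j_index_pct, rep.sensitivity_pct, rep.specificity_pct


# ---------------------------------------------------------------------------
# model / results

class ThresholdOptimizer:
    """Randomized threshold-search model over a labeled clip corpus.

    Parameters
    ----------
    clips : sequence of LabeledClip (or a ClipCorpus)
        The labeled training corpus; both classes must be present.
    bounds : ThresholdBounds
        Per-parameter admissible intervals for the random draws.
    config : OptimizationConfig
        Resampling and search sizes; ``config.rate_hz`` selects the
        evaluation sampling rate (clips are resampled once up front).
    """

    def __init__(self, clips, bounds: ThresholdBounds = DEFAULT_BOUNDS,
                 config: OptimizationConfig = OptimizationConfig()) -> None:
        self.clips = list(clips)
        if len(self.clips) == 0:
            raise ValueError("empty clip corpus")
        self.bounds = bounds
        self.config = config
        self._arrays = _CorpusArrays(self.clips, config.rate_hz)
        labels = self._arrays.labels
        if labels.all() or (~labels).all():
            raise ValueError("corpus must contain both falls and non-falls")

    def fit(self, seed: Optional[int] = None) -> "OptimizationResults":
        """Run the full search; reproducible from the seed."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        master = np.random.SeedSequence(cfg.seed)
        ss_split, ss_under, ss_sets = master.spawn(3)
        split_rng = np.random.default_rng(ss_split)
        under_children = ss_under.spawn(cfg.n_splits * cfg.n_undersamples)
        sets_children = ss_sets.spawn(cfg.n_splits * cfg.n_undersamples)
        labels = self._arrays.labels
        splits = stratified_splits(labels, cfg, split_rng)
        pool: list[CandidateResult] = []
        n_train_evals = 0
        n_test_evals = 0
        for s, (train_idx, test_idx) in enumerate(splits):
            for u in range(cfg.n_undersamples):
                k = s * cfg.n_undersamples + u
                under_rng = np.random.default_rng(under_children[k])
                sets_rng = np.random.default_rng(sets_children[k])
                balanced = undersample_majority(train_idx, labels, under_rng)
                candidates = sample_threshold_sets(
                    self.bounds, cfg.n_random_sets, sets_rng)
                trained = []
                for ts in candidates:
                    tj, _, _ = _j_of(self._arrays.counts(ts, balanced))
                    trained.append((tj, ts))
                    n_train_evals += 1
                trained.sort(key=lambda x: -x[0])
                for tj, ts in trained[:cfg.n_keep]:
                    test_j, sens, spec = _j_of(
                        self._arrays.counts(ts, test_idx))
                    n_test_evals += 1
                    pool.append(CandidateResult(
                        thresholds=ts, train_j=tj, test_j=test_j,
                        test_sens=sens, test_spec=spec,
                        split_id=s, undersample_id=u,
                    ))
        pool.sort(key=lambda c: -c.test_j)
        return OptimizationResults(
            model=self, config=cfg, candidates=pool[:cfg.n_keep],
            n_train_evaluations=n_train_evals,
            n_test_evaluations=n_test_evals,
        )


@dataclass
class OptimizationResults:
    """Outcome of a threshold search: the retained candidate leaderboard."""

    model: ThresholdOptimizer
    config: OptimizationConfig
    candidates: list[CandidateResult]
    n_train_evaluations: int
    n_test_evaluations: int

    def top(self, n: int = 10) -> list[CandidateResult]:
        return self.candidates[:n]

    def select_levels(self, top_n: int = 10) -> SensitivityLevels:
        return select_levels(self.top(top_n))

    def summary(self) -> pd.DataFrame:
        """Leaderboard table: rank, test metrics and the threshold fields."""
        rows = []
        for rank, c in enumerate(self.candidates, start=1):
            row = {"rank": rank, "test_j": c.test_j, "test_sens": c.test_sens,
                   "test_spec": c.test_spec, "train_j": c.train_j,
                   "split_id": c.split_id, "undersample_id": c.undersample_id}
            for name in TUNABLE_FIELDS:
                row[name] = getattr(c.thresholds, name)
            rows.append(row)
        return pd.DataFrame(rows)

    def roc(self, top_n: int = 10) -> list[tuple]:
        return roc_points([(c.test_sens, c.test_spec) for c in self.top(top_n)])

    def plot_roc(self, top_n: int = 10, ax=None):
        from .metrics import plot_roc as _plot
        ax = _plot(self.roc(top_n), ax=ax)
        levels = self.select_levels(top_n)
        for name, marker in (("low", "s"), ("medium", "o"), ("high", "^")):
            c = levels[name]
            ax.plot((100 - c.test_spec) / 100, c.test_sens / 100, marker,
                    color="k", ms=9, label=f"{name} sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        return ax


def run_optimization(clips, bounds: ThresholdBounds = DEFAULT_BOUNDS,
                     config: OptimizationConfig = OptimizationConfig()
                     ) -> OptimizationResults:
    """Functional wrapper: build the optimizer and fit it in one call."""
    return ThresholdOptimizer(clips, bounds, config).fit()


def _argbest(cands: Sequence[CandidateResult], primary, secondary):
    best = 0
    for i in range(1, len(cands)):
        a, b = cands[i], cands[best]
        if (primary(a), secondary(a)) > (primary(b), secondary(b)):
            best = i
    return cands[best]


def select_levels(candidates: Sequence[CandidateResult]) -> SensitivityLevels:
    """Pick the low/medium/high operating points from the candidate ROC.

    Medium is the optimal ROC point (maximum Youden J), low the maximum
    specificity, high the maximum sensitivity; ties break on the other
    coordinate, then on candidate order.
    """
    cands = list(candidates)
    if len(cands) < 3:
        raise ValueError("need at least 3 candidates to pick three levels")
    medium = _argbest(cands, lambda c: c.test_j, lambda c: c.test_sens)
    low = _argbest(cands, lambda c: c.test_spec, lambda c: c.test_sens)
    high = _argbest(cands, lambda c: c.test_sens, lambda c: c.test_spec)
    return SensitivityLevels(low=low, medium=medium, high=high)
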