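"""Seeded synthetic wearable-accelerometer data.

The original clip corpus (39 movement types, three body positions) and the
continuous ~40-minute validation sessions this package was designed around are
not publicly deposited, so everything here is generated: each movement is a
piecewise magnitude profile with band-limited noise riding on a unit gravity
direction that tilts at scripted orientation changes, then rotated by a random
device-mounting rotation.  This is not a biomechanical simulation — it is
built to exercise every detector transition and the known false-alarm
archetypes (hard table drops, falls with recovery) with controlled, verifiable
feature trajectories.

Fall clips always contain the four canonical phases: a free-fall interval
(total magnitude 0.1-0.6 g for 100-500 ms), an impact spike (2-6 g, <=100 ms),
an orientation change of at least 60 degrees, and at least 5 s of post-impact
stillness.  Recovery-type non-falls share the first three phases but truncate
the stillness below the 5 s watcher duration.  Table-drop non-falls get a hard
spike with a small orientation change, the dominant false-alarm source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import round_half_up
from .signal_core import AccelStream, SUPPORTED_RATES

__all__ = [
    "MovementSpec",
    "CATALOGUE",
    "DS1_COUNTS",
    "LabeledClip",
    "ClipCorpus",
    "SessionPlan",
    "make_clip",
    "make_ds1_corpus",
    "make_ds2_session",
    "DS2_ACTIVITIES",
    "DS2_FALL_GROUPS",
]

# ---------------------------------------------------------------------------
# geometry helpers

_POSITION_DIR = {
    "chest": np.array([0.0, 0.0, 1.0]),
    "waist": np.array([0.26, 0.0, 0.9656]),
    "pocket": np.array([0.5, 0.0, 0.866]),
    "unknown": np.array([0.0, 0.0, 1.0]),
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rand_perp(rng: np.random.Generator, d: np.ndarray) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, d) * d
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _tilted(rng: np.random.Generator, d: np.ndarray, lo_deg: float,
            hi_deg: float) -> np.ndarray:
    theta = math.radians(rng.uniform(lo_deg, hi_deg))
    p = _rand_perp(rng, d)
    return _unit(math.cos(theta) * d + math.sin(theta) * p)


def _slerp(d0: np.ndarray, d1: np.ndarray, n: int) -> np.ndarray:
    c = float(np.clip(np.dot(d0, d1), -1.0, 1.0))
    omega = math.acos(c)
    if n <= 1:
        return np.tile(d1, (max(n, 1), 1))
    ts = np.linspace(0.0, 1.0, n)
    if omega < 1e-8:
        return np.tile(d0, (n, 1))
    s = np.sin(omega)
    out = (np.sin((1 - ts) * omega)[:, None] * d0 +
           np.sin(ts * omega)[:, None] * d1) / s
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# signal assembly

_NOISE_ALPHA = 0.7  # first-order low-pass coefficient for the magnitude noise


class _ClipBuilder:
    """Accumulates piecewise (magnitude, direction) segments for one clip."""

    def __init__(self, rng: np.random.Generator, rate_hz: int,
                 d0: np.ndarray) -> None:
        self.rng = rng
        self.rate = rate_hz
        self.d = d0.copy()
        self._mag: list[np.ndarray] = []
        self._dirs: list[np.ndarray] = []
        self._sigma: list[np.ndarray] = []
        self._lo: list[np.ndarray] = []
        self._hi: list[np.ndarray] = []
        self.marks: dict[str, int] = {}
        self._n = 0

    def _samples(self, dur_s: float) -> int:
        return max(1, int(round(dur_s * self.rate)))

    def _push(self, mag, dirs, sigma, lo, hi):
        n = mag.shape[0]
        self._mag.append(mag)
        self._dirs.append(dirs)
        self._sigma.append(np.full(n, sigma))
        self._lo.append(np.full(n, lo))
        self._hi.append(np.full(n, hi))
        self._n += n

    def mark(self, name: str) -> None:
        self.marks[name] = int(round(self._n * 1000.0 / self.rate))

    @property
    def t_now_ms(self) -> int:
        return int(round(self._n * 1000.0 / self.rate))

    def still(self, dur_s, sigma=0.02, level=1.0, lo=0.6, hi=1.6):
        n = self._samples(dur_s)
        self._push(np.full(n, level), np.tile(self.d, (n, 1)), sigma, lo, hi)

    def osc(self, dur_s, amp, freq_hz, sigma, lo, hi):
        n = self._samples(dur_s)
        t = np.arange(n) / self.rate
        phase = self.rng.uniform(0, 2 * math.pi)
        mag = 1.0 + amp * np.sin(2 * math.pi * freq_hz * t + phase)
        self._push(mag, np.tile(self.d, (n, 1)), sigma, lo, hi)

    def transition(self, dur_s, d_to, bump=0.2, sigma=0.04):
        """Slow posture change: direction slerps to ``d_to``, magnitude bumps."""
        n = self._samples(dur_s)
        t = np.linspace(0, 1, n)
        mag = 1.0 + bump * np.sin(math.pi * t)
        self._push(mag, _slerp(self.d, d_to, n), sigma, 0.6, 1.7)
        self.d = np.asarray(d_to, dtype=float)

    def freefall(self, dur_s, mag_lo, mag_hi, d_ff):
        n = self._samples(dur_s)
        level = self.rng.uniform(mag_lo, mag_hi)
        self._push(np.full(n, level), _slerp(self.d, d_ff, n), 0.02,
                   max(0.05, mag_lo - 0.05), mag_hi + 0.1)

    def impact(self, dur_s, peak, d_new):
        n = self._samples(dur_s)
        mag = peak * self.rng.uniform(0.88, 1.0, size=n)
        self._push(mag, np.tile(np.asarray(d_new, float), (n, 1)), 0.05,
                   peak * 0.8, peak * 1.05)
        self.d = np.asarray(d_new, dtype=float)

    def render(self, mount_rotation: Optional[np.ndarray] = None) -> np.ndarray:
        mag = np.concatenate(self._mag)
        dirs = np.vstack(self._dirs)
        sigma = np.concatenate(self._sigma)
        lo = np.concatenate(self._lo)
        hi = np.concatenate(self._hi)
        white = self.rng.normal(size=mag.shape[0])
        from scipy.signal import lfilter
        a = _NOISE_ALPHA
        band = lfilter([1 - a], [1, -a], white)
        band *= math.sqrt((1 + a) / (1 - a))  # restore unit variance
        total = np.clip(mag + sigma * band, lo, hi)
        xyz = total[:, None] * dirs
        if mount_rotation is not None:
            xyz = xyz @ mount_rotation.T
        return xyz


# ---------------------------------------------------------------------------
# movement archetypes

def _pre(b: _ClipBuilder, rng, kind: str) -> None:
    if kind == "stand":
        b.still(rng.uniform(0.8, 1.5), sigma=0.02)
    elif kind == "sit":
        b.still(rng.uniform(0.8, 1.5), sigma=0.02)
    elif kind == "walk":
        b.osc(rng.uniform(1.5, 3.0), 0.22, rng.uniform(1.8, 2.2), 0.03,
              0.65, 1.7)
        b.still(0.4, sigma=0.02)
    elif kind == "sit2stand":
        b.still(0.8, sigma=0.02)
        b.transition(rng.uniform(1.2, 1.8), _tilted(rng, b.d, 5, 15),
                     bump=0.2, sigma=0.04)
    else:
        raise ValueError(f"unknown pre-activity {kind!r}")


def _fall_core(b: _ClipBuilder, rng, tilt, still_rng, peak=(2.5, 5.5)) -> None:
    """Free fall -> impact with orientation change -> post-impact stillness."""
    d_before = b.d.copy()
    d_ff = _tilted(rng, d_before, 45, 90)
    d_new = _tilted(rng, d_before, tilt[0], tilt[1])
    b.mark("freefall_start")
    b.freefall(rng.uniform(0.15, 0.45), 0.12, 0.30, d_ff)
    b.mark("impact")
    b.impact(rng.uniform(0.06, 0.10), rng.uniform(*peak), d_new)
    b.still(rng.uniform(*still_rng), sigma=0.03)


def _arch_fall(b, rng, p):
    _pre(b, rng, p.get("pre", "stand"))
    _fall_core(b, rng, p.get("tilt", (60, 120)), (5.5, 7.0))


def _arch_fall_recovery(b, rng, p):
    _pre(b, rng, p.get("pre", "stand"))
    _fall_core(b, rng, p.get("tilt", (60, 110)), (2.0, 3.5))
    b.mark("recovery_start")
    d_up = _tilted(rng, _POSITION_DIR["chest"], 0, 10)
    b.osc(rng.uniform(1.5, 2.5), 0.7, rng.uniform(1.0, 1.6), 0.05, 0.3, 2.0)
    b.transition(rng.uniform(1.0, 1.6), d_up, bump=0.25)
    b.still(1.0, sigma=0.02)


def _arch_drop_quick(b, rng, p):
    b.still(rng.uniform(0.8, 1.5), sigma=0.02)
    d_before = b.d.copy()
    d_ff = _tilted(rng, d_before, 45, 90)
    d_new = _tilted(rng, d_before, 5, 22)
    b.mark("freefall_start")
    b.freefall(rng.uniform(0.08, 0.16), 0.08, 0.18, d_ff)
    b.mark("impact")
    b.impact(rng.uniform(0.04, 0.08), rng.uniform(2.5, 5.0), d_new)
    b.still(rng.uniform(5.0, 8.0), sigma=0.01)  # sensor left on the table


def _arch_drop_slow(b, rng, p):
    b.still(rng.uniform(0.8, 1.5), sigma=0.02)
    d_new = _tilted(rng, b.d, 5, 25)
    b.transition(rng.uniform(1.0, 1.6), d_new, bump=0.12, sigma=0.04)
    b.impact(rng.uniform(0.04, 0.08), rng.uniform(1.1, 1.4), d_new)
    b.still(rng.uniform(4.0, 8.0), sigma=0.01)


def _arch_stumble(b, rng, p):
    b.osc(1.5, 0.22, 2.0, 0.03, 0.65, 1.7)
    n_dip = rng.uniform(0.12, 0.2)
    d_j = _tilted(rng, b.d, 3, 12)
    b.freefall(n_dip, 0.55, 0.7, d_j)
    b.impact(rng.uniform(0.04, 0.06), rng.uniform(1.5, 2.1),
             _tilted(rng, b.d, 3, 15))
    b.osc(1.5, 0.22, 2.0, 0.03, 0.65, 1.7)


def _arch_walk(b, rng, p):
    sig = 0.03 * p.get("noise_scale", 1.0)
    b.osc(p.get("dur", rng.uniform(4.0, 7.0)), 0.22, rng.uniform(1.8, 2.2),
          sig, 0.65, 1.7)


def _arch_run(b, rng, p):
    sig = 0.06 * p.get("noise_scale", 1.0)
    b.osc(p.get("dur", rng.uniform(4.0, 7.0)), 0.4, rng.uniform(2.5, 3.0),
          sig, 0.5, 1.95)


def _arch_still(b, rng, p):
    if p.get("lying"):
        b.d = _tilted(rng, b.d, 80, 100)
    b.still(p.get("dur", rng.uniform(5.0, 9.0)), sigma=p.get("sigma", 0.02))


def _arch_posture_seq(b, rng, p):
    """Sequences of sit/stand/lay/bend transitions with scripted waits."""
    for item in p["plan"]:
        kind = item[0]
        if kind == "wait":
            b.still(item[1], sigma=0.02)
        elif kind == "walk":
            b.osc(item[1], 0.22, rng.uniform(1.8, 2.2), 0.03, 0.65, 1.7)
        elif kind == "tilt":
            lo, hi = item[1]
            b.transition(rng.uniform(1.3, 1.9), _tilted(rng, b.d, lo, hi),
                         bump=item[2] if len(item) > 2 else 0.22)
        else:
            raise ValueError(f"unknown plan item {kind!r}")


def _arch_jolts(b, rng, p):
    """Cough/sneeze/body-lift: small magnitude bumps around 1 g."""
    b.still(1.0, sigma=0.02)
    for _ in range(p.get("n_jolts", 3)):
        n = b._samples(0.3)
        t = np.linspace(0, 1, n)
        amp = rng.uniform(0.15, p.get("amp", 0.3))
        mag = 1.0 + amp * np.sin(math.pi * t)
        b._push(mag, np.tile(b.d, (n, 1)), 0.03, 0.6, 1.6)
        b.still(rng.uniform(0.4, 0.8), sigma=0.02)
    b.still(1.0, sigma=0.02)


_ARCHETYPES: dict[str, Callable] = {
    "fall": _arch_fall,
    "fall_recovery": _arch_fall_recovery,
    "drop_quick": _arch_drop_quick,
    "drop_slow": _arch_drop_slow,
    "stumble": _arch_stumble,
    "walk": _arch_walk,
    "run": _arch_run,
    "still": _arch_still,
    "posture_seq": _arch_posture_seq,
    "jolts": _arch_jolts,
}


# ---------------------------------------------------------------------------
# movement catalogue (the clip-corpus taxonomy with its per-type clip counts)

@dataclass(frozen=True)
class MovementSpec:
    """One movement type of the clip corpus."""

    name: str
    label: str  # "fall" | "non-fall"
    archetype: str
    params: dict = field(default_factory=dict)
    fa_archetype: bool = False  # table-drop style false-alarm source

    @property
    def is_fall(self) -> bool:
        return self.label == "fall"


def _spec(name, label, archetype, count, params=None, fa=False):
    return (MovementSpec(name, label, archetype, params or {}, fa), count)


_SIT = {"plan": [("tilt", (8, 18)), ("wait", 2.0)]}

_RAW_CATALOGUE = [
    # --- non-fall movements -------------------------------------------------
    _spec("While seated slowly drop sensor on the table", "non-fall",
          "drop_slow", 99, fa=True),
    _spec("While seated quickly drop sensor on the table", "non-fall",
          "drop_quick", 68, fa=True),
    _spec("While standing quickly drop sensor on the table", "non-fall",
          "drop_quick", 73, fa=True),
    _spec("While standing slowly drop sensor on the table", "non-fall",
          "drop_slow", 82, fa=True),
    _spec("Stumble", "non-fall", "stumble", 67),
    _spec("Sit on a lower chair, wait 10 s and get up", "non-fall",
          "posture_seq", 63,
          {"plan": [("wait", 1.0), ("tilt", (10, 25), 0.3), ("wait", 10.0),
                    ("tilt", (10, 25), 0.3), ("wait", 1.0)]}),
    _spec("Left lateral fall with recovery", "non-fall", "fall_recovery", 67,
          {"tilt": (75, 110)}),
    _spec("Walking and sitting on a chair", "non-fall", "posture_seq", 65,
          {"plan": [("walk", 3.0), ("tilt", (8, 18)), ("wait", 2.0)]}),
    _spec("Lay, wait 10 s, stand, wait 10 s", "non-fall", "posture_seq", 70,
          {"plan": [("tilt", (80, 100)), ("wait", 10.0), ("tilt", (80, 100)),
                    ("wait", 10.0)]}),
    _spec("Forward Fall with recovery", "non-fall", "fall_recovery", 67,
          {"tilt": (60, 100)}),
    _spec("Backward fall with recovery", "non-fall", "fall_recovery", 67,
          {"tilt": (60, 100)}),
    _spec("Catch an object from the floor while walking", "non-fall",
          "posture_seq", 67,
          {"plan": [("walk", 2.0), ("tilt", (40, 60), 0.3), ("tilt", (40, 60), 0.3),
                    ("walk", 2.0)]}),
    _spec("Walk a few meters", "non-fall", "walk", 68),
    _spec("Cough and sneeze", "non-fall", "jolts", 67, {"n_jolts": 4}),
    _spec("Sit, wait 10 s, stand, wait 10 s", "non-fall", "posture_seq", 70,
          {"plan": [("wait", 1.0), ("tilt", (8, 18)), ("wait", 10.0),
                    ("tilt", (8, 18)), ("wait", 10.0)]}),
    _spec("Run a few meters", "non-fall", "run", 67),
    _spec("Right lateral fall with recovery", "non-fall", "fall_recovery", 66,
          {"tilt": (75, 110)}),
    _spec("While seated slightly lift the body", "non-fall", "jolts", 31,
          {"n_jolts": 2, "amp": 0.25}),
    _spec("Sitting on a chair", "non-fall", "still", 34),
    _spec("Laying on a bed", "non-fall", "still", 31, {"lying": True}),
    _spec("Bend and pick an object from the floor", "non-fall", "posture_seq",
          18, {"plan": [("wait", 1.0), ("tilt", (40, 60), 0.3),
                        ("tilt", (40, 60), 0.3), ("wait", 1.0)]}),
    _spec("Get up from laying and stand", "non-fall", "posture_seq", 59,
          {"plan": [("tilt", (80, 100)), ("wait", 1.5), ("tilt", (80, 100)),
                    ("wait", 1.5)]}),
    _spec("Get up from laying and sit", "non-fall", "posture_seq", 30,
          {"plan": [("tilt", (80, 100)), ("wait", 1.5), ("tilt", (60, 80)),
                    ("wait", 1.5)]}),
    _spec("Walk", "non-fall", "walk", 3),
    # --- fall movements -----------------------------------------------------
    _spec("Sited on a chair, stand up, walk and fall", "fall", "fall", 64,
          {"pre": "walk"}),
    _spec("Backward fall ending lying", "fall", "fall", 70, {"tilt": (80, 120)}),
    _spec("Forward fall with rotation, ending in lateral left position",
          "fall", "fall", 67, {"tilt": (75, 115)}),
    _spec("Backward fall ending sitting", "fall", "fall", 67, {"tilt": (60, 80)}),
    _spec("Forward fall with rotation, ending in lateral right position",
          "fall", "fall", 67, {"tilt": (75, 115)}),
    _spec("Walk few meters and then right lateral fall", "fall", "fall", 67,
          {"pre": "walk", "tilt": (75, 115)}),
    _spec("Lateral fall to the left ending lying flat", "fall", "fall", 67,
          {"tilt": (80, 120)}),
    _spec("Lateral fall to the right ending lying flat", "fall", "fall", 67,
          {"tilt": (80, 120)}),
    _spec("Backward fall ending in lateral position", "fall", "fall", 66,
          {"tilt": (75, 115)}),
    _spec("Walk few meters and fall backwards", "fall", "fall", 66,
          {"pre": "walk"}),
    _spec("Walk few meters and left lateral falls", "fall", "fall", 67,
          {"pre": "walk", "tilt": (75, 115)}),
    _spec("Forward fall on the knees", "fall", "fall", 70, {"tilt": (60, 80)}),
    _spec("Forward fall ending lying flat", "fall", "fall", 67,
          {"tilt": (80, 120)}),
    _spec("Forward fall with forward arm protection", "fall", "fall", 70,
          {"tilt": (70, 110)}),
    _spec("Walk few meters and fall forward", "fall", "fall", 67,
          {"pre": "walk"}),
]

CATALOGUE: dict[str, MovementSpec] = {s.name: s for s, _ in _RAW_CATALOGUE}
#: default per-type clip counts of the emulated training corpus
DS1_COUNTS: dict[str, int] = {s.name: c for s, c in _RAW_CATALOGUE}


# ---------------------------------------------------------------------------
# clips and corpora

@dataclass
class LabeledClip:
    """A generated movement clip with its label and ground-truth phase times."""

    clip_id: str
    spec_name: str
    label: str  # "fall" | "non-fall"
    position: str
    seed: int
    stream: AccelStream
    truth: dict

    @property
    def is_fall(self) -> bool:
        return self.label == "fall"


def make_clip(
    spec_name: str,
    position: str = "waist",
    rate_hz: int = 100,
    seed: int = 0,
    clip_id: Optional[str] = None,
) -> LabeledClip:
    """Generate one movement clip; fully deterministic per seed."""
    if spec_name not in CATALOGUE:
        raise KeyError(f"unknown movement spec {spec_name!r}")
    if rate_hz not in SUPPORTED_RATES:
        raise ValueError(f"rate {rate_hz} not supported")
    spec = CATALOGUE[spec_name]
    rng = np.random.default_rng(seed)
    d0 = _tilted(rng, _POSITION_DIR[position], 0, 8)
    b = _ClipBuilder(rng, rate_hz, d0)
    params = dict(spec.params)
    if position == "pocket" and spec.archetype in ("walk", "run"):
        # pocket wear picks up extra leg-swing noise during gait
        params["noise_scale"] = 1.8
    _ARCHETYPES[spec.archetype](b, rng, params)
    xyz = b.render(mount_rotation=_random_rotation(rng))
    stream = AccelStream.from_arrays(xyz, rate_hz, position=position,
                                     subject_id=f"synth-{seed}")
    truth = {"label": spec.label, **b.marks}
    return LabeledClip(
        clip_id=clip_id or f"{spec_name[:24].replace(' ', '_')}-{seed}",
        spec_name=spec_name,
        label=spec.label,
        position=position,
        seed=seed,
        stream=stream,
        truth=truth,
    )


class ClipCorpus:
    """A labeled clip collection; streams are generated lazily and cached."""

    def __init__(self, descriptors: list[dict], rate_hz: int) -> None:
        self._desc = descriptors
        self.rate_hz = rate_hz
        self._cache: dict[int, LabeledClip] = {}

    def __len__(self) -> int:
        return len(self._desc)

    def clip(self, i: int) -> LabeledClip:
        if i not in self._cache:
            d = self._desc[i]
            self._cache[i] = make_clip(
                d["spec"], d["position"], self.rate_hz, d["seed"],
                clip_id=d["clip_id"],
            )
        return self._cache[i]

    def __iter__(self):
        return (self.clip(i) for i in range(len(self)))

    @property
    def labels(self) -> np.ndarray:
        """Boolean fall labels, available without materializing streams."""
        return np.array([d["label"] == "fall" for d in self._desc])

    @property
    def clip_ids(self) -> list[str]:
        return [d["clip_id"] for d in self._desc]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"clip_id": d["clip_id"], "spec": d["spec"], "label": d["label"],
              "position": d["position"], "seed": d["seed"]}
             for d in self._desc]
        )

    def subset(self, indices: Sequence[int]) -> "ClipCorpus":
        sub = ClipCorpus([self._desc[i] for i in indices], self.rate_hz)
        for j, i in enumerate(indices):
            if i in self._cache:
                sub._cache[j] = self._cache[i]
        return sub


def make_ds1_corpus(
    counts: Optional[dict] = None,
    scale: Optional[float] = None,
    rate_hz: int = 100,
    seed: int = 0,
    positions: Sequence[str] = ("chest", "waist", "pocket"),
) -> ClipCorpus:
    """Labeled clip corpus mirroring the training-set movement taxonomy.

    Default per-type counts follow the published taxonomy (1399 non-falls,
    1009 falls).  ``scale`` shrinks every row by the given factor with half-up
    rounding; ``counts`` overrides rows explicitly.  Positions are cycled
    across the three wear locations.
    """
    if counts is None:
        counts = dict(DS1_COUNTS)
    else:
        unknown = set(counts) - set(CATALOGUE)
        if unknown:
            raise KeyError(f"unknown movement specs: {sorted(unknown)[:5]}")
        counts = {**{k: 0 for k in DS1_COUNTS}, **counts}
    if scale is not None:
        counts = {k: int(round_half_up(v * scale, 0)) for k, v in counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("clip counts must be nonnegative")
    master = np.random.default_rng(seed)
    desc = []
    i = 0
    for name in DS1_COUNTS:  # fixed catalogue order keeps seeds stable
        for _ in range(counts.get(name, 0)):
            child = int(master.integers(0, 2**31 - 1))
            desc.append({
                "clip_id": f"clip{i:05d}",
                "spec": name,
                "label": CATALOGUE[name].label,
                "position": positions[i % len(positions)],
                "seed": child,
            })
            i += 1
    return ClipCorpus(desc, rate_hz)


# ---------------------------------------------------------------------------
# continuous sessions

#: the six scripted ambulatory activities, 6 minutes each
DS2_ACTIVITIES = ("standing still", "sitting", "walking", "running",
                  "standing with freedom of movements", "laying")

DS2_FALL_GROUPS = {
    1: ("forward fall", "backward fall", "sit-stand transfer fall",
        "stand-sit transfer fall"),
    2: ("stumble and fall forward", "lateral fall", "vertical fall (faint)",
        "walk then forward fall"),
}

_FALL_KIND_PARAMS = {
    "forward fall": {"pre": "stand", "tilt": (70, 110)},
    "backward fall": {"pre": "stand", "tilt": (70, 110)},
    "sit-stand transfer fall": {"pre": "sit2stand", "tilt": (60, 95)},
    "stand-sit transfer fall": {"pre": "stand", "tilt": (60, 85)},
    "stumble and fall forward": {"pre": "walk", "tilt": (70, 110)},
    "lateral fall": {"pre": "stand", "tilt": (75, 115)},
    "vertical fall (faint)": {"pre": "stand", "tilt": (60, 95)},
    "walk then forward fall": {"pre": "walk", "tilt": (70, 110)},
}


@dataclass(frozen=True)
class SessionPlan:
    """Schedule of one continuous validation session."""

    group: int = 1
    position: str = "waist"
    activity_min: float = 6.0
    subject_id: str = "synth-subject"

    def __post_init__(self) -> None:
        if self.group not in DS2_FALL_GROUPS:
            raise ValueError("group must be 1 or 2")


def _activity_segment(b: _ClipBuilder, rng, name: str, dur_s: float,
                      position: str) -> None:
    noise_scale = 1.8 if position == "pocket" else 1.0
    if name == "standing still":
        b.still(dur_s, sigma=0.02)
    elif name == "sitting":
        b.transition(1.5, _tilted(rng, b.d, 8, 18))
        b.still(dur_s - 3.0, sigma=0.02)
        b.transition(1.5, _tilted(rng, b.d, 8, 18))
    elif name == "walking":
        b.osc(dur_s, 0.22, rng.uniform(1.8, 2.2), 0.03 * noise_scale, 0.65, 1.7)
    elif name == "running":
        b.osc(dur_s, 0.4, rng.uniform(2.5, 3.0), 0.06 * noise_scale, 0.5, 1.95)
    elif name == "standing with freedom of movements":
        b.osc(dur_s, 0.12, rng.uniform(0.6, 1.2), 0.06, 0.6, 1.7)
    elif name == "laying":
        b.transition(2.0, _tilted(rng, b.d, 80, 100))
        b.still(dur_s - 4.0, sigma=0.015)
        b.transition(2.0, _tilted(rng, b.d, 80, 100))
    else:
        raise ValueError(f"unknown activity {name!r}")


def make_ds2_session(plan: SessionPlan = SessionPlan(), rate_hz: int = 100,
                     seed: int = 0):
    """Continuous ~40-minute session: six activities with four falls interleaved.

    Returns ``(stream, windows, kinds)`` where ``windows`` is a list of
    ``(start_ms, end_ms)`` ground-truth fall intervals (ends 6 s after the
    planted impact) and ``kinds`` the fall type per window.
    """
    rng = np.random.default_rng(seed)
    d0 = _tilted(rng, _POSITION_DIR[plan.position], 0, 8)
    b = _ClipBuilder(rng, rate_hz, d0)
    falls = DS2_FALL_GROUPS[plan.group]
    windows = []
    kinds = []
    dur_s = plan.activity_min * 60.0
    for i, activity in enumerate(DS2_ACTIVITIES):
        if i > 0:
            # instruction pause between protocol tasks
            b.still(rng.uniform(30.0, 45.0), sigma=0.03)
        _activity_segment(b, rng, activity, dur_s, plan.position)
        if i < len(falls):
            kind = falls[i]
            start = b.t_now_ms
            p = _FALL_KIND_PARAMS[kind]
            _pre(b, rng, p["pre"])
            _fall_core(b, rng, p["tilt"], (5.5, 7.0))
            impact = b.marks["impact"]  # marks are absolute session times
            windows.append((start, impact + 6000))
            kinds.append(kind)
            # recover and carry on with the protocol
            b.osc(rng.uniform(1.5, 2.5), 0.7, rng.uniform(1.0, 1.6), 0.05,
                  0.3, 2.0)
            b.transition(1.5, _tilted(rng, _POSITION_DIR[plan.position], 0, 8),
                         bump=0.25)
    xyz = b.render(mount_rotation=_random_rotation(rng))
    stream = AccelStream.from_arrays(xyz, rate_hz, position=plan.position,
                                     subject_id=plan.subject_id)
    return stream, windows, kinds
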