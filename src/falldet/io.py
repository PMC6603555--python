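"""File formats: stream CSV, event exports, corpus directories, configs.

Stream CSV layout::

    # rate_hz=100
    # position=waist
    # subject=s01
    timestamp_ms,ax_g,ay_g,az_g
    0,0.0,0.0,1.0
    ...

UTF-8 throughout, '.' decimal separator, rows in time order.  The comment
headers are optional on read (rate then defaults to 100 Hz and must be passed
explicitly if different).
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signal_core import AccelStream
from .state_machine import FallEvent
from .synthetic import ClipCorpus, make_clip

__all__ = [
    "read_stream_csv",
    "write_stream_csv",
    "write_events_csv",
    "read_events_csv",
    "write_events_jsonl",
    "read_events_jsonl",
    "write_corpus_dir",
    "read_corpus_dir",
    "write_fall_windows_csv",
    "read_fall_windows_csv",
    "sha256_of",
]

EVENT_CSV_FIELDS = ("t_broadcast_ms", "t_impact_ms", "peak_impact_g",
                    "impact_angle_deg")


def sha256_of(path) -> str:
    """Hex digest of a file, for run-audit logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_stream_csv(stream: AccelStream, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# rate_hz={stream.rate_hz}\n")
        fh.write(f"# position={stream.position}\n")
        fh.write(f"# subject={stream.subject_id}\n")
        w = csv.writer(fh)
        w.writerow(["timestamp_ms", "ax_g", "ay_g", "az_g"])
        for t, (x, y, z) in zip(stream.t_ms, stream.xyz):
            w.writerow([int(t), repr(float(x)), repr(float(y)), repr(float(z))])


def read_stream_csv(path, rate_hz: Optional[int] = None) -> AccelStream:
    """Parse a stream CSV; malformed rows raise with their line number."""
    meta = {"rate_hz": None, "position": "unknown", "subject": ""}
    rows_t: list[int] = []
    rows_a: list[tuple] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    k = k.strip()
                    if k in meta:
                        meta[k] = v.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if not header_seen:
                if parts[0] != "timestamp_ms":
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'timestamp_ms,...'")
                header_seen = True
                continue
            try:
                rows_t.append(int(parts[0]))
                rows_a.append((float(parts[1]), float(parts[2]),
                               float(parts[3])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
    rate = rate_hz or (int(meta["rate_hz"]) if meta["rate_hz"] else 100)
    return AccelStream(
        np.array(rows_t, dtype=np.int64), np.array(rows_a, dtype=np.float64),
        rate, meta["position"] if meta["position"] else "unknown",
        meta["subject"],
    )


def write_events_csv(events: Sequence[FallEvent], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_CSV_FIELDS)
        for ev in events:
            w.writerow([ev.t_broadcast_ms, ev.t_impact_ms,
                        repr(ev.peak_impact_g), repr(ev.impact_angle_deg)])


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events_jsonl(events: Sequence[FallEvent], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")


def read_events_jsonl(path) -> list[FallEvent]:
    events = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(FallEvent(**json.loads(line)))
    return events


def write_corpus_dir(corpus: ClipCorpus, out_dir) -> Path:
    """One stream CSV per clip plus a manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for clip in corpus:
        write_stream_csv(clip.stream, out / f"{clip.clip_id}.csv")
    corpus.manifest().to_csv(out / "manifest.csv", index=False)
    return out


def read_corpus_dir(in_dir):
    """Load a corpus directory; returns (list of clips, manifest frame).

    Clips are lightweight records with ``stream``, ``label``/``is_fall``,
    ``clip_id`` — the shape the optimizer expects.
    """
    from .synthetic import LabeledClip

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    clips = []
    for row in manifest.itertuples():
        stream = read_stream_csv(in_dir / f"{row.clip_id}.csv")
        clips.append(LabeledClip(
            clip_id=str(row.clip_id), spec_name=str(row.spec),
            label=str(row.label), position=str(row.position),
            seed=int(row.seed), stream=stream, truth={"label": str(row.label)},
        ))
    return clips, manifest


def write_fall_windows_csv(windows, kinds, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_ms", "end_ms", "kind"])
        for (s, e), kind in zip(windows, kinds):
            w.writerow([int(s), int(e), kind])


def read_fall_windows_csv(path):
    df = pd.read_csv(path)
    windows = list(zip(df["start_ms"].astype(int), df["end_ms"].astype(int)))
    return windows, list(df["kind"].astype(str))
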