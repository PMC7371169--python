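"""CSV readers/writers for recordings, label tracks and dataset manifests.

All files are plain RFC-4180 CSV with "." as the decimal separator.
Recordings carry a ``t`` column plus the nine sensor channels; label tracks
are ``start_s, end_s, behaviour`` with half-open intervals; a manifest is a
single CSV listing one row per individual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ChannelCountError,
    NonMonotoneTimeError,
    OverlapError,
    RateMismatchError,
    UnknownBehaviourError,
    ValidationError,
)
from .ethogram import BEHAVIOURS
from .synth import (
    CHANNELS,
    InertialRecording,
    LabelInterval,
    LabelTrack,
    RecordingMeta,
)

_FLOAT_FMT = "%.12g"  # round-trips doubles to well under 1e-9 relative


def write_recording(recording: InertialRecording, path) -> None:
    df = pd.DataFrame(recording.samples, columns=list(CHANNELS))
    df.insert(0, "t", recording.t)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording(path, meta: RecordingMeta | None = None) -> InertialRecording:
    """Read a recording CSV, validating channel layout and time base.

    The sampling rate is inferred from the median time step; when ``meta``
    declares a rate it must agree within 1%.
    """
    df = pd.read_csv(path)
    expected = ("t",) + CHANNELS
    if tuple(df.columns) != expected:
        raise ChannelCountError(
            f"{path}: expected columns {expected}, got {tuple(df.columns)}"
        )
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise NonMonotoneTimeError(
            f"{path}: time not strictly increasing at row {bad + 1} "
            f"(t={t[bad]} followed by t={t[bad + 1]})"
        )
    inferred_rate = 1.0 / float(np.median(dt))
    if meta is not None and abs(inferred_rate - meta.sampling_rate) \
            > 0.01 * meta.sampling_rate:
        raise RateMismatchError(
            f"{path}: inferred rate {inferred_rate:.3f} Hz differs from "
            f"declared {meta.sampling_rate} Hz by more than 1%"
        )
    if meta is None:
        meta = RecordingMeta("unknown", "unknown", sampling_rate=inferred_rate)
    return InertialRecording(meta, t, df[list(CHANNELS)].to_numpy(dtype=float))


def write_labels(track: LabelTrack, path) -> None:
    df = pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.behaviour) for iv in track],
        columns=["start_s", "end_s", "behaviour"],
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels(path, recording_duration: float | None = None) -> LabelTrack:
    """Read a label CSV; sort, clip to the recording, and validate."""
    df = pd.read_csv(path)
    required = ("start_s", "end_s", "behaviour")
    if tuple(df.columns) != required:
        raise ValidationError(
            f"{path}: expected columns {required}, got {tuple(df.columns)}"
        )
    rows = sorted(
        (float(r.start_s), float(r.end_s), str(r.behaviour))
        for r in df.itertuples()
    )
    intervals = []
    prev = None
    for start, end, name in rows:
        if name not in BEHAVIOURS:
            raise UnknownBehaviourError(
                f"{path}: unknown behaviour {name!r} in [{start}, {end})"
            )
        if recording_duration is not None:
            start = max(start, 0.0)
            end = min(end, recording_duration)
            if end <= start:
                continue
        if prev is not None and start < prev[1] - 1e-12:
            raise OverlapError(
                f"{path}: intervals overlap: [{prev[0]}, {prev[1]}) "
                f"{prev[2]!r} and [{start}, {end}) {name!r}"
            )
        prev = (start, end, name)
        intervals.append(LabelInterval(start, end, name))
    return LabelTrack(intervals)


@dataclass(frozen=True)
class ManifestEntry:
    individual_id: str
    group_id: str
    recording_path: str
    label_path: str


@dataclass
class DatasetManifest:
    """Index of a dataset: one (recording, labels) file pair per individual."""

    entries: list[ManifestEntry]
    sampling_rate: float = 50.0
    classes: tuple[str, ...] = BEHAVIOURS

    def __post_init__(self):
        ids = [e.individual_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate individual_ids: {dupes}")


def write_manifest(manifest: DatasetManifest, path) -> None:
    df = pd.DataFrame(
        [(e.individual_id, e.group_id, e.recording_path, e.label_path,
          manifest.sampling_rate) for e in manifest.entries],
        columns=["individual_id", "group_id", "recording_path", "label_path",
                 "sampling_rate"],
    )
    df.to_csv(path, index=False)


def read_manifest(path) -> DatasetManifest:
    path = Path(path)
    df = pd.read_csv(path)
    entries = []
    rates = set()
    for r in df.itertuples():
        for p in (r.recording_path, r.label_path):
            if not (path.parent / p).exists():
                raise ValidationError(f"manifest references missing file {p}")
        entries.append(ManifestEntry(str(r.individual_id), str(r.group_id),
                                     str(r.recording_path), str(r.label_path)))
        rates.add(float(r.sampling_rate))
    if len(rates) > 1:
        raise ValidationError(f"manifest mixes sampling rates: {sorted(rates)}")
    rate = rates.pop() if rates else 50.0
    return DatasetManifest(entries, sampling_rate=rate)


def save_dataset(cohort, out_dir) -> Path:
    """Write a cohort's recordings, labels and manifest under ``out_dir``.

    Returns the manifest path. Paths inside the manifest are relative to it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    rate = None
    for recording, track in cohort:
        ind = recording.meta.individual_id
        rec_name = f"{ind}_recording.csv"
        lab_name = f"{ind}_labels.csv"
        write_recording(recording, out_dir / rec_name)
        write_labels(track, out_dir / lab_name)
        entries.append(ManifestEntry(ind, recording.meta.group_id,
                                     rec_name, lab_name))
        rate = recording.meta.sampling_rate
    manifest = DatasetManifest(entries, sampling_rate=rate or 50.0)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path


def load_dataset(manifest_path) -> list[tuple[InertialRecording, LabelTrack]]:
    """Load every (recording, labels) pair referenced by a manifest."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    out = []
    for e in manifest.entries:
        meta = RecordingMeta(e.individual_id, e.group_id,
                             manifest.sampling_rate)
        rec = read_recording(manifest_path.parent / e.recording_path, meta)
        labels = read_labels(manifest_path.parent / e.label_path,
                             rec.duration)
        out.append((rec, labels))
    return out


def log_run(out_dir, config: dict, seed: int) -> Path:
    """Persist the resolved configuration and master seed for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.json"
    with open(path, "w") as fh:
        json.dump({"seed": seed, "config": config}, fh, indent=2, default=str)
    return path
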