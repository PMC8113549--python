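"""Syllable annotation I/O and song-bout segmentation.

Adult zebra finch song decomposes into three levels: syllables (individual
vocal elements separated by silent gaps longer than ~5 ms), motifs
(stereotyped syllable sequences), and song bouts (introductory notes followed
by one or more motif renditions with inter-motif intervals shorter than
500 ms).  This module reads tabular annotation logs — one row per syllable
rendition with a label, onset and offset in seconds, and optional acoustic
features — and groups the annotated stream into bouts using silence
thresholds.

Gap conventions
---------------
A *gap* is ``next.onset - current.offset``.  Silences of more than 100 ms are
treated as song boundaries; events flanked by such silence on both sides are
dropped as probable calls; a gap of 500 ms or more starts a new bout.  The
5 ms minimum inter-syllable gap is a validation floor: closer events trigger
a warning rather than a merge, because the upstream annotations are treated
as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AnnotationError",
    "SyllableEvent",
    "Recording",
    "SongBout",
    "SegmentationConfig",
    "parse_annotations",
    "read_annotations",
    "parse_label_track",
    "write_annotations",
    "segment_bouts",
    "drop_isolated_calls",
]

#: Default column names for delimited annotation logs.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "recording_id": "recording_id",
    "label": "label",
    "onset": "onset_s",
    "offset": "offset_s",
    "pitch": "pitch_hz",
    "entropy": "entropy",
}


class AnnotationError(ValueError):
    """Raised when an annotation file or event stream violates an invariant."""


@dataclass(frozen=True)
class SyllableEvent:
    """A single annotated vocal element.

    Parameters
    ----------
    label : str
        Syllable label.  Spectrally similar variants (e.g. ``h`` vs ``h'``)
        are distinct labels, assigned upstream.
    onset, offset : float
        Event boundaries in seconds; ``offset > onset >= 0``.
    pitch : float, optional
        Fundamental frequency of the rendition in Hz.
    entropy : float, optional
        Wiener entropy of the rendition (dimensionless, typically <= 0).
    """

    label: str
    onset: float
    offset: float
    pitch: float | None = None
    entropy: float | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise AnnotationError("event label must be non-empty")
        if self.onset < 0:
            raise AnnotationError(f"onset must be >= 0, got {self.onset}")
        if self.offset <= self.onset:
            raise AnnotationError(
                f"offset must exceed onset ({self.label}: "
                f"{self.onset}..{self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SegmentationConfig:
    """Silence thresholds (seconds) for bout segmentation and call removal.

    ``min_syllable_gap`` is the validation floor between annotated syllables;
    ``boundary_gap`` marks a song boundary ("/" in transition matrices);
    ``call_isolation_gap`` is the two-sided silence that flags a call;
    ``bout_gap`` splits bouts (within-bout inter-motif intervals are shorter
    than 500 ms, so a gap >= 500 ms starts a new bout).
    """

    min_syllable_gap: float = 0.005
    bout_gap: float = 0.5
    boundary_gap: float = 0.1
    call_isolation_gap: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.min_syllable_gap < self.boundary_gap <= self.bout_gap):
            raise AnnotationError(
                "require 0 < min_syllable_gap < boundary_gap <= bout_gap, got "
                f"{self.min_syllable_gap}, {self.boundary_gap}, {self.bout_gap}"
            )
        if self.call_isolation_gap <= 0:
            raise AnnotationError("call_isolation_gap must be positive")


@dataclass
class Recording:
    """An ordered, validated stream of syllable events from one recording."""

    recording_id: str
    events: list[SyllableEvent] = field(default_factory=list)
    timepoint: str = "baseline"
    subject_id: str = ""

    def __post_init__(self) -> None:
        validate_events(self.events)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class SongBout:
    """A maximal run of events with all internal gaps below the bout gap."""

    events: list[SyllableEvent]
    recording_id: str = ""

    def __post_init__(self) -> None:
        if not self.events:
            raise AnnotationError("a song bout must contain at least one event")

    @property
    def label_sequence(self) -> list[str]:
        return [e.label for e in self.events]

    @property
    def onset(self) -> float:
        return self.events[0].onset

    @property
    def offset(self) -> float:
        return self.events[-1].offset

    def __len__(self) -> int:
        return len(self.events)


def validate_events(
    events: Sequence[SyllableEvent], min_gap: float = 0.005
) -> None:
    """Check that events are sorted by onset and non-overlapping.

    Gaps below ``min_gap`` (default 5 ms) draw a warning only: annotations
    are upstream ground truth and are never auto-merged.
    """
    for i in range(1, len(events)):
        gap = events[i].onset - events[i - 1].offset
        if gap < 0:
            raise AnnotationError(
                f"events {i - 1} ({events[i - 1].label}) and {i} "
                f"({events[i].label}) overlap (gap {gap:.4f}s)"
            )
        if gap < min_gap:
            warnings.warn(
                f"gap of {gap * 1e3:.1f} ms between events {i - 1} and {i} "
                f"is below the {min_gap * 1e3:.0f} ms floor",
                stacklevel=3,
            )


def _events_from_frame(df: pd.DataFrame, schema: Mapping[str, str]) -> list[SyllableEvent]:
    events = []
    errors = []
    has_pitch = schema["pitch"] in df.columns
    has_entropy = schema["entropy"] in df.columns
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        rec = row._asdict() if hasattr(row, "_asdict") else dict(row)
        try:
            pitch = float(rec[schema["pitch"]]) if has_pitch and pd.notna(rec[schema["pitch"]]) else None
            entropy = float(rec[schema["entropy"]]) if has_entropy and pd.notna(rec[schema["entropy"]]) else None
            events.append(
                SyllableEvent(
                    label=str(rec[schema["label"]]),
                    onset=float(rec[schema["onset"]]),
                    offset=float(rec[schema["offset"]]),
                    pitch=pitch,
                    entropy=entropy,
                )
            )
        except (AnnotationError, TypeError, ValueError) as exc:
            errors.append(f"row {row_no}: {exc}")
    if errors:
        raise AnnotationError(
            "invalid annotation rows:\n  " + "\n  ".join(errors)
        )
    return events


def read_annotations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    timepoint: str = "baseline",
) -> list[Recording]:
    """Read a delimited annotation log into one Recording per recording id.

    The file must have a header; the delimiter is sniffed (TSV or CSV)
    unless ``sep`` is given.  Required columns (renameable through
    ``schema``): label, onset_s, offset_s; recording_id, pitch_hz and
    entropy are optional.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        warnings.warn(f"annotation file {path} is empty", stacklevel=2)
        return [Recording(recording_id=path.stem, events=[], timepoint=timepoint)]
    df = pd.read_csv(path, sep=sep, engine="python")
    for key in ("label", "onset", "offset"):
        if schema[key] not in df.columns:
            raise AnnotationError(
                f"column '{schema[key]}' (for {key}) not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    id_col = schema["recording_id"]
    recordings = []
    if id_col in df.columns:
        groups = [(str(rid), g) for rid, g in df.groupby(id_col, sort=False)]
    else:
        groups = [(path.stem, df)]
    for rid, g in groups:
        g = g.sort_values(schema["onset"], kind="stable")
        recordings.append(
            Recording(rid, _events_from_frame(g, schema), timepoint=timepoint)
        )
    return recordings


def parse_annotations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    timepoint: str = "baseline",
) -> Recording:
    """Read an annotation log that holds a single recording."""
    recs = read_annotations(path, schema=schema, sep=sep, timepoint=timepoint)
    if len(recs) > 1:
        raise AnnotationError(
            f"{path} holds {len(recs)} recording ids; use read_annotations()"
        )
    return recs[0]


def parse_label_track(
    path: str | Path, recording_id: str | None = None, timepoint: str = "baseline"
) -> Recording:
    """Import a headerless three-column label track (onset, offset, label)."""
    path = Path(path)
    events = []
    errors = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                if len(parts) < 3:
                    raise ValueError(f"expected 3 columns, got {len(parts)}")
                events.append(
                    SyllableEvent(parts[2], float(parts[0]), float(parts[1]))
                )
            except (AnnotationError, ValueError) as exc:
                errors.append(f"row {row_no}: {exc}")
    if errors:
        raise AnnotationError("invalid label-track rows:\n  " + "\n  ".join(errors))
    events.sort(key=lambda e: e.onset)
    return Recording(recording_id or path.stem, events, timepoint=timepoint)


def write_annotations(recordings: Iterable[Recording], path: str | Path) -> None:
    """Write recordings as a TSV annotation log (the module's file dialect)."""
    rows = []
    for rec in recordings:
        for e in rec.events:
            rows.append(
                {
                    "recording_id": rec.recording_id,
                    "label": e.label,
                    "onset_s": e.onset,
                    "offset_s": e.offset,
                    "pitch_hz": e.pitch,
                    "entropy": e.entropy,
                }
            )
    pd.DataFrame(
        rows,
        columns=["recording_id", "label", "onset_s", "offset_s", "pitch_hz", "entropy"],
    ).to_csv(path, sep="\t", index=False)


def segment_bouts(
    rec: Recording, cfg: SegmentationConfig | None = None
) -> list[SongBout]:
    """Partition a recording's events into song bouts.

    A new bout starts wherever the silent gap reaches ``cfg.bout_gap``
    (within-bout intervals are strictly shorter than 500 ms by the bout
    definition).  Concatenating the bouts' sequences reproduces the
    recording's sequence.
    """
    cfg = cfg or SegmentationConfig()
    bouts: list[SongBout] = []
    current: list[SyllableEvent] = []
    for event in rec.events:
        if current and event.onset - current[-1].offset >= cfg.bout_gap:
            bouts.append(SongBout(current, rec.recording_id))
            current = []
        current.append(event)
    if current:
        bouts.append(SongBout(current, rec.recording_id))
    return bouts


def drop_isolated_calls(
    events: Sequence[SyllableEvent], cfg: SegmentationConfig | None = None
) -> list[SyllableEvent]:
    """Remove events flanked by silence longer than the call-isolation gap.

    Syllables preceded *and* followed by more than 100 ms of silence likely
    reflect calls rather than song syllables.  The recording's start and end
    count as infinite silence, so a lone event is treated as a call.
    """
    cfg = cfg or SegmentationConfig()
    kept = []
    n = len(events)
    for i, event in enumerate(events):
        gap_before = (
            event.onset - events[i - 1].offset if i > 0 else float("inf")
        )
        gap_after = (
            events[i + 1].onset - event.offset if i < n - 1 else float("inf")
        )
        if gap_before > cfg.call_isolation_gap and gap_after > cfg.call_isolation_gap:
            continue
        kept.append(event)
    return kept


def shift_events(events: Sequence[SyllableEvent], delta: float) -> list[SyllableEvent]:
    """Return events with onsets/offsets shifted by ``delta`` seconds."""
    return [replace(e, onset=e.onset + delta, offset=e.offset + delta) for e in events]
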