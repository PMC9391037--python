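"""Scored movement events, bout merging, and per-session rate/duration summaries.

A scored movement is an interval on a 30 Hz session timeline during which the
fetal jaws are separated (orofacial) or the head is away from baseline (head).
Movements of one kind separated by gaps of at most 500 ms (15 frames) belong to
the same *movement unit* (bout); the constituent movements of a unit are its
"syllables". Units truncated by loss of view are flagged partial: they count
toward unit numbers and rates but are excluded from duration and syllable-number
statistics.

Time is kept in integer frames (exactly 30 Hz) internally; seconds appear only
at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

FRAME_RATE = 30
#: 500 ms at 30 Hz; gaps of exactly this many frames still merge.
DEFAULT_MERGE_GAP_FRAMES = 15

Kind = Literal["orofacial", "head"]
KINDS: tuple[Kind, Kind] = ("orofacial", "head")


def frames_to_seconds(frames: int | float) -> float:
    """Convert a frame count on the 30 Hz timeline to seconds (frames / 30)."""
    return frames / FRAME_RATE


def seconds_to_frames(seconds: float) -> int:
    """Convert seconds to the nearest frame index on the 30 Hz timeline."""
    return int(round(seconds * FRAME_RATE))


@dataclass(frozen=True)
class MovementEvent:
    """One raw scored movement interval, closed on both ends in frames."""

    session_id: str
    pregnancy_id: str
    gestational_day: int
    kind: Kind
    onset: int
    offset: int
    partial: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown movement kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError(f"negative onset frame {self.onset}")
        if self.offset < self.onset:
            raise ValueError(
                f"offset {self.offset} precedes onset {self.onset} "
                f"(session {self.session_id})"
            )

    @property
    def duration_s(self) -> float:
        return frames_to_seconds(self.offset - self.onset)


@dataclass(frozen=True)
class MovementUnit:
    """A merged bout of same-kind events with gaps <= the merge threshold."""

    events: tuple[MovementEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a movement unit needs at least one event")
        kinds = {e.kind for e in self.events}
        if len(kinds) > 1:
            raise ValueError(f"unit mixes movement kinds {sorted(kinds)}")

    @property
    def kind(self) -> Kind:
        return self.events[0].kind

    @property
    def onset(self) -> int:
        return self.events[0].onset

    @property
    def offset(self) -> int:
        return self.events[-1].offset

    @property
    def duration_s(self) -> float:
        return frames_to_seconds(self.offset - self.onset)

    @property
    def syllable_count(self) -> int:
        """Number of constituent movements (the bout's 'syllables')."""
        return len(self.events)

    @property
    def partial(self) -> bool:
        return any(e.partial for e in self.events)


@dataclass
class Session:
    """One imaging session: usable footage span plus the merged unit streams."""

    session_id: str
    pregnancy_id: str
    gestational_day: int
    visible_time_s: float
    orofacial_units: list[MovementUnit] = field(default_factory=list)
    head_units: list[MovementUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.visible_time_s <= 0:
            raise ValueError(
                f"session {self.session_id}: visible_time_s must be positive"
            )
        span = self.span_frames
        for unit in list(self.orofacial_units) + list(self.head_units):
            if unit.onset < 0 or unit.offset > span:
                raise ValueError(
                    f"session {self.session_id}: unit [{unit.onset}, {unit.offset}] "
                    f"outside visible span [0, {span}] frames"
                )

    @property
    def span_frames(self) -> int:
        return int(round(self.visible_time_s * FRAME_RATE))

    def units(self, kind: Kind) -> list[MovementUnit]:
        if kind == "orofacial":
            return self.orofacial_units
        if kind == "head":
            return self.head_units
        raise ValueError(f"unknown movement kind {kind!r}")


def merge_events(
    events: Sequence[MovementEvent],
    gap_threshold_frames: int = DEFAULT_MERGE_GAP_FRAMES,
) -> list[MovementUnit]:
    """Merge same-kind events separated by gaps <= ``gap_threshold_frames``.

    The gap between consecutive events is ``next.onset - prev.offset`` in
    frames; a gap exactly at the threshold (500 ms = 15 frames by default)
    still merges. Input events must be sorted by onset and non-overlapping
    within their kind.
    """
    if gap_threshold_frames < 0:
        raise ValueError("gap_threshold_frames must be non-negative")
    events = list(events)
    if not events:
        return []
    kinds = {e.kind for e in events}
    if len(kinds) > 1:
        raise ValueError(f"merge_events expects events of one kind, got {sorted(kinds)}")
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset < prev.onset:
            raise ValueError(
                f"events not sorted by onset: [{prev.onset}, {prev.offset}] "
                f"followed by [{nxt.onset}, {nxt.offset}]"
            )
        if nxt.onset < prev.offset:
            raise ValueError(
                f"overlapping same-kind events: [{prev.onset}, {prev.offset}] "
                f"and [{nxt.onset}, {nxt.offset}]"
            )
    units: list[MovementUnit] = []
    current = [events[0]]
    for nxt in events[1:]:
        if nxt.onset - current[-1].offset <= gap_threshold_frames:
            current.append(nxt)
        else:
            units.append(MovementUnit(tuple(current)))
            current = [nxt]
    units.append(MovementUnit(tuple(current)))
    return units


def movement_rate(session: Session, kind: Kind) -> float:
    """Movement units per hour of face-visible footage.

    Partial units are included in the count; only duration/syllable statistics
    exclude them.
    """
    if session.visible_time_s <= 0:
        raise ValueError("movement_rate needs positive visible time")
    n_units = len(session.units(kind))
    return n_units / (session.visible_time_s / 3600.0)


def unit_durations(
    units: Iterable[MovementUnit], exclude_partial: bool = True
) -> list[float]:
    """Durations (s) of units, dropping partially captured units by default."""
    return [u.duration_s for u in units if not (exclude_partial and u.partial)]


def unit_syllable_counts(
    units: Iterable[MovementUnit], exclude_partial: bool = True
) -> list[int]:
    """Syllable counts of units, dropping partially captured units by default."""
    return [u.syllable_count for u in units if not (exclude_partial and u.partial)]
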