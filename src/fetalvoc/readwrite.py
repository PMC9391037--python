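"""Delimited-text readers/writers for events, units, sessions, calls, and profiles.

All tables are comma-delimited UTF-8 with a header row. Times are stored in
seconds and converted to integer frames (nearest frame at 30 Hz) on ingest;
in-memory computation is frame-based throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .callclass import CallRecord
from .events import (
    DEFAULT_MERGE_GAP_FRAMES,
    KINDS,
    MovementEvent,
    Session,
    frames_to_seconds,
    merge_events,
    seconds_to_frames,
)
from .profiles import CallTemplate, TemporalProfile
from .states import StateSequence

EVENT_COLUMNS = [
    "session_id", "pregnancy_id", "gestational_day", "kind",
    "onset_s", "offset_s", "partial",
]
SESSION_COLUMNS = ["session_id", "pregnancy_id", "gestational_day", "visible_time_s"]


def read_events(path: str | Path) -> list[MovementEvent]:
    """Read a movement-event table, reporting malformed rows by line number."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    events, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            kind = str(row["kind"])
            if kind not in KINDS:
                raise ValueError(f"unknown kind {kind!r}")
            onset = seconds_to_frames(float(row["onset_s"]))
            offset = seconds_to_frames(float(row["offset_s"]))
            events.append(
                MovementEvent(
                    session_id=str(row["session_id"]),
                    pregnancy_id=str(row["pregnancy_id"]),
                    gestational_day=int(row["gestational_day"]),
                    kind=kind,  # type: ignore[arg-type]
                    onset=onset,
                    offset=offset,
                    partial=bool(int(row["partial"])),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed rows:\n" + "\n".join(errors))
    return events


def write_events(events: Iterable[MovementEvent], path: str | Path) -> None:
    rows = [
        {
            "session_id": e.session_id,
            "pregnancy_id": e.pregnancy_id,
            "gestational_day": e.gestational_day,
            "kind": e.kind,
            "onset_s": frames_to_seconds(e.onset),
            "offset_s": frames_to_seconds(e.offset),
            "partial": int(e.partial),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def sessions_to_events(sessions: Iterable[Session]) -> list[MovementEvent]:
    events = []
    for s in sessions:
        for unit in list(s.orofacial_units) + list(s.head_units):
            events.extend(unit.events)
    return events


def write_session_meta(sessions: Iterable[Session], path: str | Path) -> None:
    rows = [
        {
            "session_id": s.session_id,
            "pregnancy_id": s.pregnancy_id,
            "gestational_day": s.gestational_day,
            "visible_time_s": s.visible_time_s,
        }
        for s in sessions
    ]
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def build_sessions(
    events: Sequence[MovementEvent],
    session_meta: pd.DataFrame,
    merge_gap_frames: int = DEFAULT_MERGE_GAP_FRAMES,
) -> list[Session]:
    """Assemble sessions from raw events: group, sort, and merge into units."""
    missing = [c for c in SESSION_COLUMNS if c not in session_meta.columns]
    if missing:
        raise ValueError(f"session metadata missing columns {missing}")
    by_session: dict[str, dict[str, list[MovementEvent]]] = {}
    for e in events:
        by_session.setdefault(e.session_id, {k: [] for k in KINDS})[e.kind].append(e)
    sessions = []
    for _, row in session_meta.iterrows():
        sid = str(row["session_id"])
        streams = by_session.get(sid, {k: [] for k in KINDS})
        units = {
            kind: merge_events(
                sorted(streams[kind], key=lambda e: e.onset), merge_gap_frames
            )
            for kind in KINDS
        }
        sessions.append(
            Session(
                session_id=sid,
                pregnancy_id=str(row["pregnancy_id"]),
                gestational_day=int(row["gestational_day"]),
                visible_time_s=float(row["visible_time_s"]),
                orofacial_units=units["orofacial"],
                head_units=units["head"],
            )
        )
    return sessions


def read_sessions(
    events_path: str | Path,
    session_meta_path: str | Path,
    merge_gap_frames: int = DEFAULT_MERGE_GAP_FRAMES,
) -> list[Session]:
    events = read_events(events_path)
    meta = pd.read_csv(session_meta_path)
    return build_sessions(events, meta, merge_gap_frames)


def write_units(sessions: Iterable[Session], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for kind in KINDS:
            for u in s.units(kind):
                rows.append(
                    {
                        "session_id": s.session_id,
                        "pregnancy_id": s.pregnancy_id,
                        "gestational_day": s.gestational_day,
                        "kind": kind,
                        "onset_s": frames_to_seconds(u.onset),
                        "offset_s": frames_to_seconds(u.offset),
                        "syllable_count": u.syllable_count,
                        "duration_s": u.duration_s,
                        "partial": int(u.partial),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_state_sequences(
    sequences: Iterable[StateSequence], path: str | Path
) -> None:
    rows = [
        {
            "session_id": seq.session_id,
            "state": f"S{occ.state}",
            "anchor_s": frames_to_seconds(occ.anchor_frame),
        }
        for seq in sequences
        for occ in seq.occurrences
    ]
    pd.DataFrame(rows, columns=["session_id", "state", "anchor_s"]).to_csv(
        path, index=False
    )


def read_calls(path: str | Path) -> list[CallRecord]:
    df = pd.read_csv(path)
    required = ["call_id", "type_label", "duration_s", "syllable_count", "modality"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    calls, errors = [], []
    for idx, row in df.iterrows():
        try:
            calls.append(
                CallRecord(
                    call_id=str(row["call_id"]),
                    type_label=str(row["type_label"]),
                    duration_s=float(row["duration_s"]),
                    syllable_count=int(row["syllable_count"]),
                    modality=str(row["modality"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx + 2}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed rows:\n" + "\n".join(errors))
    return calls


def write_calls(calls: Iterable[CallRecord], path: str | Path) -> None:
    rows = [
        {
            "call_id": c.call_id,
            "type_label": c.type_label,
            "duration_s": c.duration_s,
            "syllable_count": c.syllable_count,
            "modality": c.modality,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_profiles(profiles: Sequence[TemporalProfile], directory: str | Path) -> None:
    """One (frame, value) file per profile plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for p in profiles:
        fname = f"{p.profile_id or id(p)}.csv"
        pd.DataFrame(
            {"frame": np.arange(len(p)), "value": p.values}
        ).to_csv(directory / fname, index=False)
        manifest.append(
            {
                "profile_id": p.profile_id,
                "session_id": p.session_id,
                "source": p.source,
                "gestational_day": p.gestational_day,
                "manual_syllables": p.syllable_count,
                "path": fname,
            }
        )
    pd.DataFrame(manifest).to_csv(directory / "manifest.csv", index=False)


def read_profiles(directory: str | Path) -> list[TemporalProfile]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    profiles = []
    for _, row in manifest.iterrows():
        values = pd.read_csv(directory / str(row["path"]))["value"].to_numpy()
        profiles.append(
            TemporalProfile(
                values=values,
                source=str(row["source"]),
                syllable_count=int(row["manual_syllables"]),
                profile_id=str(row["profile_id"]),
                session_id=str(row["session_id"]),
                gestational_day=int(row["gestational_day"]),
            )
        )
    return profiles


def write_templates(templates: Sequence[CallTemplate], path: str | Path) -> None:
    payload = {
        str(t.syllable_count): [float(v) for v in t.values] for t in templates
    }
    Path(path).write_text(json.dumps(payload))


def read_templates(path: str | Path) -> list[CallTemplate]:
    payload = json.loads(Path(path).read_text())
    return [
        CallTemplate(syllable_count=int(k), values=np.asarray(v, dtype=float))
        for k, v in sorted(payload.items(), key=lambda kv: int(kv[0]))
    ]
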