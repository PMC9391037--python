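"""Call-signature criteria: duration x syllable boxes, likelihoods, percent match.

Infant call types carry duration/syllable-number signatures: contact calls are
long multi-syllable calls (3.69-6.5 s, 5-9 syllables), twitters short with few
syllables (0.96-1.5 s, 2-3), and licks bimodal (short 0.33-3.77 s with 1-6
syllables, or long 6.67-14.29 s with 10-16). A fetal movement unit "matches" a
call type when its duration and syllable count fall inside the type's box
(closed bounds, any union member). Partially captured units are excluded from
all duration/syllable statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .events import MovementUnit, Session


@dataclass(frozen=True)
class CallRecord:
    call_id: str
    type_label: str  # 'contact' | 'twitter' | 'lick' | 'other'
    duration_s: float
    syllable_count: int
    modality: str = "audio"  # 'audio' | 'video'

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"call {self.call_id}: duration must be positive")
        if self.syllable_count < 1:
            raise ValueError(f"call {self.call_id}: syllable_count must be >= 1")


@dataclass(frozen=True)
class CriteriaBox:
    """Union of closed duration-range x syllable-range boxes defining a call type."""

    name: str
    members: tuple[tuple[float, float, int, int], ...]  # (dur_lo, dur_hi, syl_lo, syl_hi)

    def __post_init__(self) -> None:
        for dur_lo, dur_hi, syl_lo, syl_hi in self.members:
            if dur_lo > dur_hi or syl_lo > syl_hi:
                raise ValueError(f"box {self.name}: lo > hi in a member")

    def contains(self, duration_s: float, syllable_count: int) -> bool:
        return any(
            dur_lo <= duration_s <= dur_hi and syl_lo <= syllable_count <= syl_hi
            for dur_lo, dur_hi, syl_lo, syl_hi in self.members
        )


#: Study-fixed signature boxes.
CONTACT_BOX = CriteriaBox("contact", ((3.69, 6.5, 5, 9),))
TWITTER_BOX = CriteriaBox("twitter", ((0.96, 1.5, 2, 3),))
LICK_BOX = CriteriaBox("lick", ((0.33, 3.77, 1, 6), (6.67, 14.29, 10, 16)))
DEFAULT_BOXES = {b.name: b for b in (CONTACT_BOX, TWITTER_BOX, LICK_BOX)}


def count_syllables(unit: MovementUnit) -> int:
    """Number of constituent movements of a complete (non-partial) unit."""
    if unit.partial:
        raise ValueError(
            "syllable counts are undefined for partially captured units"
        )
    return unit.syllable_count


def type_likelihood(
    calls: Sequence[CallRecord], box: CriteriaBox, target_type: str
) -> float:
    """Fraction of in-box calls that are of the target type; NaN if box empty."""
    in_box = [c for c in calls if box.contains(c.duration_s, c.syllable_count)]
    if not in_box:
        return float("nan")
    return sum(c.type_label == target_type for c in in_box) / len(in_box)


def box_capture(
    calls: Sequence[CallRecord], box: CriteriaBox, target_type: str
) -> float:
    """Fraction of target-type calls the box captures; NaN without targets."""
    targets = [c for c in calls if c.type_label == target_type]
    if not targets:
        return float("nan")
    return sum(
        box.contains(c.duration_s, c.syllable_count) for c in targets
    ) / len(targets)


def percent_match(
    session_or_units: Session | Iterable[MovementUnit],
    box: CriteriaBox,
    kind: str = "orofacial",
) -> float:
    """Percentage of complete units whose duration and syllables fall in the box.

    Accepts a session (uses its units of ``kind``) or a unit list directly;
    sessions with no complete units yield NaN.
    """
    if isinstance(session_or_units, Session):
        units = session_or_units.units(kind)
    else:
        units = list(session_or_units)
    complete = [u for u in units if not u.partial]
    if not complete:
        return float("nan")
    n_match = sum(
        box.contains(u.duration_s, u.syllable_count) for u in complete
    )
    return 100.0 * n_match / len(complete)


def adjust_audio_durations(
    paired: Sequence[tuple[float, float]], audio_only: Sequence[float]
) -> list[float]:
    """Reconcile audio-derived call durations with the video timeline.

    ``paired`` holds (audio_duration, video_duration) for calls captured in
    both modalities; the median discrepancy (video - audio) is added to every
    audio-only duration.
    """
    if not paired:
        raise ValueError("adjust_audio_durations needs at least one paired call")
    delta = float(np.median([v - a for a, v in paired]))
    return [a + delta for a in audio_only]


def boxes_disjoint(
    box_a: CriteriaBox,
    box_b: CriteriaBox,
    syllable_grid: tuple[int, int] = (1, 16),
) -> bool:
    """Exhaustive check that no (duration, syllable) point lies in both boxes.

    Scans every integer syllable count in ``syllable_grid`` and, for each,
    every pair of member duration intervals (closed bounds): two closed
    intervals intersect iff max(lo) <= min(hi), and the intersection endpoints
    are themselves witnesses, so checking interval intersection per shared
    syllable value is exhaustive.
    """
    for s in range(syllable_grid[0], syllable_grid[1] + 1):
        for a_lo, a_hi, a_slo, a_shi in box_a.members:
            if not a_slo <= s <= a_shi:
                continue
            for b_lo, b_hi, b_slo, b_shi in box_b.members:
                if not b_slo <= s <= b_shi:
                    continue
                if max(a_lo, b_lo) <= min(a_hi, b_hi):
                    return False
    return True


def derive_criteria(
    calls: Sequence[CallRecord],
    target_type: str,
    min_capture: float = 0.5,
    duration_step: float = 0.01,
) -> CriteriaBox:
    """Grid search for the single box best separating a call type.

    Candidate duration bounds are the observed call durations snapped to
    ``duration_step``; candidate syllable bounds the observed counts. Among
    boxes capturing at least ``min_capture`` of the target-type calls, the one
    maximizing target-type likelihood is kept (ties: larger capture, then
    smaller duration span).
    """
    targets = [c for c in calls if c.type_label == target_type]
    if not targets:
        raise ValueError(f"no calls of type {target_type!r}")
    durs = np.round([c.duration_s for c in calls], int(-np.log10(duration_step)))
    sylls = np.array([c.syllable_count for c in calls])
    is_target = np.array([c.type_label == target_type for c in calls])
    dur_bounds = np.unique(durs)
    syl_bounds = np.unique(sylls)
    n_target = is_target.sum()
    best = None  # (likelihood, capture, -span, box)
    for s_lo in syl_bounds:
        for s_hi in syl_bounds[syl_bounds >= s_lo]:
            syl_ok = (sylls >= s_lo) & (sylls <= s_hi)
            for d_lo in dur_bounds:
                for d_hi in dur_bounds[dur_bounds >= d_lo]:
                    in_box = syl_ok & (durs >= d_lo) & (durs <= d_hi)
                    n_in = in_box.sum()
                    if n_in == 0:
                        continue
                    captured = (in_box & is_target).sum()
                    if captured / n_target < min_capture:
                        continue
                    key = (captured / n_in, captured / n_target, -(d_hi - d_lo))
                    if best is None or key > best[0]:
                        best = (
                            key,
                            CriteriaBox(
                                target_type,
                                ((float(d_lo), float(d_hi), int(s_lo), int(s_hi)),),
                            ),
                        )
    if best is None:
        raise ValueError("no candidate box satisfies the capture constraint")
    return best[1]
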