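"""Five-state orofacial/head co-occurrence coding and first-order Markov summaries.

Each movement occurrence is one of five behavioral states:

* S1 - orofacial movement with no overlapping head movement
* S2 - head movement with no overlapping orofacial movement
* S3 - orofacial movement followed by an overlapping head movement (head onset
  at least one frame after the orofacial onset and strictly before its offset)
* S4 - head movement followed by an overlapping orofacial movement
* S5 - orofacial and head movements initiated in the same frame

An overlapping orofacial-head pair collapses into a single occurrence (S3, S4,
or S5); a unit overlapping several units of the other kind pairs with the
earliest and its remaining overlaps are ignored, so every unit contributes to
exactly one occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import greedy_pairs
from .events import MovementUnit, Session

N_STATES = 5
STATE_LABELS = ("S1", "S2", "S3", "S4", "S5")

_ORO = 0
_HEAD = 1


@dataclass(frozen=True)
class StateOccurrence:
    """One state occurrence, anchored at the earlier onset of its unit(s)."""

    state: int  # 1..5
    anchor_frame: int


@dataclass
class StateSequence:
    session_id: str
    occurrences: list[StateOccurrence]

    def __post_init__(self) -> None:
        for occ in self.occurrences:
            if not 1 <= occ.state <= N_STATES:
                raise ValueError(f"state {occ.state} outside S1..S5")
        anchors = [o.anchor_frame for o in self.occurrences]
        if anchors != sorted(anchors):
            raise ValueError("occurrences must be ordered by anchor frame")

    @property
    def states(self) -> list[int]:
        return [o.state for o in self.occurrences]

    def __len__(self) -> int:
        return len(self.occurrences)


@dataclass(frozen=True)
class StateDistribution:
    """Empirical frequencies over the 5 states; flagged empty when no occurrences."""

    p: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} components, got shape {p.shape}")
        if not self.empty:
            if np.any(p < 0):
                raise ValueError("negative state frequency")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"state frequencies sum to {p.sum()}, not 1")


def _pair_units(
    orofacial_units: Sequence[MovementUnit], head_units: Sequence[MovementUnit]
):
    """Merged sorted unit arrays plus the greedy pair assignment."""
    onsets = np.array(
        [u.onset for u in orofacial_units] + [u.onset for u in head_units],
        dtype=np.int64,
    )
    offsets = np.array(
        [u.offset for u in orofacial_units] + [u.offset for u in head_units],
        dtype=np.int64,
    )
    kinds = np.array(
        [_ORO] * len(orofacial_units) + [_HEAD] * len(head_units), dtype=np.int64
    )
    # deterministic order: onset, then orofacial before head
    order = np.lexsort((kinds, onsets))
    onsets, offsets, kinds = onsets[order], offsets[order], kinds[order]
    partner = greedy_pairs(onsets, offsets, kinds)
    return onsets, offsets, kinds, partner


def classify_states(
    orofacial_units: Sequence[MovementUnit],
    head_units: Sequence[MovementUnit],
    session_id: str = "",
) -> StateSequence:
    """Assign every movement occurrence to one of the 5 co-occurrence states.

    Units must be sorted by onset within each kind. Partial units are included:
    state counting uses all scored units.
    """
    for name, units in (("orofacial", orofacial_units), ("head", head_units)):
        on = [u.onset for u in units]
        if on != sorted(on):
            raise ValueError(f"{name} units not sorted by onset")
    onsets, offsets, kinds, partner = _pair_units(orofacial_units, head_units)
    occurrences: list[StateOccurrence] = []
    for i in range(onsets.size):
        j = partner[i]
        if j >= 0 and j < i:
            continue  # pair already emitted from its anchor
        if j < 0:
            state = 1 if kinds[i] == _ORO else 2
        elif onsets[j] == onsets[i]:
            state = 5
        elif kinds[i] == _ORO:
            state = 3  # orofacial leads, head onset strictly inside
        else:
            state = 4  # head leads, orofacial onset strictly inside
        occurrences.append(StateOccurrence(state, int(onsets[i])))
    occurrences.sort(key=lambda o: (o.anchor_frame, o.state))
    return StateSequence(session_id, occurrences)


def session_states(session: Session) -> StateSequence:
    return classify_states(
        session.orofacial_units, session.head_units, session.session_id
    )


def count_overlap_pairs(
    orofacial_units: Sequence[MovementUnit], head_units: Sequence[MovementUnit]
) -> int:
    """Number of overlapping orofacial-head pairs (S3 + S4 + S5 occurrences)."""
    if not orofacial_units or not head_units:
        return 0
    _, _, _, partner = _pair_units(orofacial_units, head_units)
    return int((partner >= 0).sum()) // 2


def state_distribution(seq: StateSequence) -> StateDistribution:
    """Empirical state frequencies; an empty sequence yields a flagged-empty result."""
    if len(seq) == 0:
        return StateDistribution(np.zeros(N_STATES), empty=True)
    counts = np.bincount(np.array(seq.states) - 1, minlength=N_STATES).astype(float)
    return StateDistribution(counts / counts.sum())


def transition_matrix(seq: StateSequence) -> np.ndarray:
    """Row-normalized first-order transition frequencies.

    ``m[i, j]`` is the frequency of S(i+1) -> S(j+1) among transitions leaving
    S(i+1); rows never observed as sources stay all-zero.
    """
    m = np.zeros((N_STATES, N_STATES), dtype=float)
    states = seq.states
    for a, b in zip(states, states[1:]):
        m[a - 1, b - 1] += 1.0
    row_sums = m.sum(axis=1, keepdims=True)
    np.divide(m, row_sums, out=m, where=row_sums > 0)
    return m
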