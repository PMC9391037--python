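"""Shannon entropy and Kullback-Leibler divergence of session state distributions.

Per-session behavioral variability is the base-2 Shannon entropy of the 5-state
occurrence distribution, H(X) = -sum_i P(X=i) log2 P(X=i) with 0 log 0 := 0;
the ceiling for 5 states is log2(5) ~ 2.32 bits. Developmental divergence is
KL(P|Q) = sum_i P_i log2(P_i / Q_i), where P is the early-gestation baseline
(mean state distribution of the sessions at gestational days 93-99) and Q the
session under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .states import N_STATES, StateDistribution, session_states, state_distribution
from .events import Session

MAX_ENTROPY_BITS = math.log2(N_STATES)

_SUM_TOL = 1e-6


def _validated(p: StateDistribution | np.ndarray, name: str) -> np.ndarray:
    v = p.p if isinstance(p, StateDistribution) else np.asarray(p, dtype=float)
    if np.any(v < 0):
        raise ValueError(f"{name} has negative components")
    if abs(v.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} sums to {v.sum()}, not 1")
    return v / v.sum()


def shannon_entropy(p: StateDistribution | np.ndarray) -> float:
    """Base-2 Shannon entropy with the convention 0 log 0 = 0."""
    v = _validated(p, "distribution")
    nz = v[v > 0]
    return float(-(nz * np.log2(nz)).sum())


def kl_divergence(
    p: StateDistribution | np.ndarray,
    q: StateDistribution | np.ndarray,
    smoothing: float = 0.0,
) -> float:
    """KL(P|Q) = sum_i P_i log2(P_i/Q_i), with 0 log(0/q) := 0.

    Returns ``math.inf`` when some P_i > 0 has Q_i = 0. ``smoothing`` > 0
    additively smooths both distributions (add-alpha, renormalized) before the
    computation; it is off by default and exists only for baselines with empty
    cells.
    """
    pv = _validated(p, "P")
    qv = _validated(q, "Q")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    if smoothing > 0:
        pv = (pv + smoothing) / (1.0 + N_STATES * smoothing)
        qv = (qv + smoothing) / (1.0 + N_STATES * smoothing)
    support = pv > 0
    if np.any(qv[support] == 0):
        return math.inf
    return float((pv[support] * np.log2(pv[support] / qv[support])).sum())


def baseline_distribution(
    sessions: Sequence[Session], day_range: tuple[int, int] = (93, 99)
) -> StateDistribution:
    """Mean per-session state distribution over the early-gestation window.

    The average is over per-session distributions (sessions weigh equally
    regardless of how many occurrences they contain), renormalized.
    """
    lo, hi = day_range
    dists = [
        state_distribution(session_states(s))
        for s in sessions
        if lo <= s.gestational_day <= hi
    ]
    dists = [d for d in dists if not d.empty]
    if not dists:
        raise ValueError(f"no non-empty sessions in day range [{lo}, {hi}]")
    mean = np.mean([d.p for d in dists], axis=0)
    return StateDistribution(mean / mean.sum())


@dataclass(frozen=True)
class EntropyPoint:
    session_id: str
    gestational_day: int
    h_bits: float


@dataclass(frozen=True)
class DivergencePoint:
    session_id: str
    gestational_day: int
    kl_bits: float


def session_entropies(sessions: Sequence[Session]) -> list[EntropyPoint]:
    """Per-session Shannon entropy; sessions without occurrences are skipped."""
    points = []
    for s in sessions:
        dist = state_distribution(session_states(s))
        if dist.empty:
            continue
        points.append(EntropyPoint(s.session_id, s.gestational_day, shannon_entropy(dist)))
    return points


def session_divergences(
    sessions: Sequence[Session],
    baseline_day_range: tuple[int, int] = (93, 99),
    smoothing: float = 0.0,
) -> list[DivergencePoint]:
    """Divergence of each session's state distribution from the baseline.

    Computed as KL(session | baseline) = sum_i Q_i log2(Q_i / P_i) with Q the
    session and P the early-gestation baseline: the direction that stays
    finite whenever the baseline has full support, so sessions that have lost
    whole states (the hallmark of late gestation) still receive a finite,
    large divergence.
    """
    baseline = baseline_distribution(sessions, baseline_day_range)
    points = []
    for s in sessions:
        dist = state_distribution(session_states(s))
        if dist.empty:
            continue
        points.append(
            DivergencePoint(
                s.session_id,
                s.gestational_day,
                kl_divergence(dist, baseline, smoothing=smoothing),
            )
        )
    return points
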