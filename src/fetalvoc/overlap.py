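"""Orofacial-head overlap fraction and its duration/latency-preserving permutation null.

Percent overlap in a session is the number of overlapping orofacial-head
instances (states S3 + S4 + S5) divided by the total number of movement units.
The permutation null independently rebuilds each session's two streams by
resampling, with replacement, the observed unit durations and inter-unit
latencies (the gap preceding each unit, with the initial offset from time zero
pooled in), laying alternating latency-duration segments end to end. Unit
counts and both marginal distributions are preserved while any temporal
coupling between the streams is destroyed; overlap that survives this shuffle
is attributable to chance co-occurrence alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._kernels import greedy_pairs
from .events import MovementEvent, MovementUnit, Session
from .states import count_overlap_pairs
from .trends import PolyFit, fit_polynomial


@dataclass(frozen=True)
class OverlapPoint:
    session_id: str
    gestational_day: int
    pct_overlap: float  # fraction in [0, 1]


@dataclass(frozen=True)
class PermutationEnvelope:
    """Pointwise 2.5/97.5 percentile envelope of per-day shuffled overlap."""

    days: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_reps: int
    seed: int
    slopes: np.ndarray  # per-replicate fitted linear slopes
    slope_ci: tuple[float, float]
    mean_fit: PolyFit
    mean_line_slope: float
    mean_line_p: float


def percent_overlap(session: Session) -> float:
    """(#S3 + #S4 + #S5 occurrences) / (#orofacial + #head units); NaN if empty."""
    n_total = len(session.orofacial_units) + len(session.head_units)
    if n_total == 0:
        return float("nan")
    pairs = count_overlap_pairs(session.orofacial_units, session.head_units)
    return pairs / n_total


def session_overlaps(sessions: Sequence[Session]) -> list[OverlapPoint]:
    return [
        OverlapPoint(s.session_id, s.gestational_day, percent_overlap(s))
        for s in sessions
    ]


def average_by_day(
    days: Sequence[int], values: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of values per unique gestational day, NaNs ignored."""
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    grid = np.unique(days)
    means = np.array(
        [np.nanmean(values[days == d]) if np.any(np.isfinite(values[days == d])) else np.nan
         for d in grid]
    )
    return grid, means


def _stream_arrays(units: Sequence[MovementUnit]) -> tuple[np.ndarray, np.ndarray]:
    on = np.array([u.onset for u in units], dtype=np.int64)
    off = np.array([u.offset for u in units], dtype=np.int64)
    return on, off


def _shuffle_stream(
    on: np.ndarray, off: np.ndarray, span: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Resample durations and latencies with replacement; rebuild from time 0.

    Latencies are the n gaps preceding each unit (first unit: offset from 0).
    Units whose rebuilt interval crosses the session span are dropped.
    """
    n = on.size
    if n == 0:
        return on.copy(), off.copy()
    durations = off - on
    latencies = np.empty(n, dtype=np.int64)
    latencies[0] = on[0]
    latencies[1:] = on[1:] - off[:-1]
    dur_s = durations[rng.integers(0, n, n)]
    lat_s = latencies[rng.integers(0, n, n)]
    new_on = np.cumsum(lat_s) + np.concatenate(([0], np.cumsum(dur_s[:-1])))
    new_off = new_on + dur_s
    keep = new_off <= span
    return new_on[keep], new_off[keep]


def _overlap_fraction_arrays(
    on_o: np.ndarray, off_o: np.ndarray, on_h: np.ndarray, off_h: np.ndarray
) -> float:
    n_total = on_o.size + on_h.size
    if n_total == 0:
        return float("nan")
    onsets = np.concatenate([on_o, on_h])
    offsets = np.concatenate([off_o, off_h])
    kinds = np.concatenate(
        [np.zeros(on_o.size, np.int64), np.ones(on_h.size, np.int64)]
    )
    order = np.lexsort((kinds, onsets))
    partner = greedy_pairs(onsets[order], offsets[order], kinds[order])
    return (int((partner >= 0).sum()) // 2) / n_total


def shuffle_session(session: Session, rng_seed: int | np.random.Generator) -> Session:
    """One duration/latency-preserving shuffle of both movement streams.

    Requires at least one unit of each kind to have an effect; otherwise the
    session is returned unchanged. Shuffled units are opaque single-event
    intervals (syllable structure is irrelevant to overlap).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if not session.orofacial_units or not session.head_units:
        return session
    span = session.span_frames
    new_streams = {}
    for kind in ("orofacial", "head"):
        on, off = _stream_arrays(session.units(kind))
        new_on, new_off = _shuffle_stream(on, off, span, rng)
        new_streams[kind] = [
            MovementUnit(
                (
                    MovementEvent(
                        session.session_id,
                        session.pregnancy_id,
                        session.gestational_day,
                        kind,
                        int(a),
                        int(b),
                    ),
                )
            )
            for a, b in zip(new_on, new_off)
        ]
    return Session(
        session_id=session.session_id,
        pregnancy_id=session.pregnancy_id,
        gestational_day=session.gestational_day,
        visible_time_s=session.visible_time_s,
        orofacial_units=new_streams["orofacial"],
        head_units=new_streams["head"],
    )


def permutation_envelope(
    sessions: Sequence[Session],
    n_reps: int = 1000,
    seed: int = 0,
    fit_degree: int = 1,
    envelope_alpha: float = 0.05,
) -> PermutationEnvelope:
    """Permutation null for the gestational overlap trend.

    Every replicate shuffles every session, computes per-session percent
    overlap, averages per gestational day, and fits a polynomial of
    ``fit_degree`` (the degree chosen on the observed data; linear in the
    study). The envelope is the pointwise 2.5/97.5 percentile band (for the
    default alpha) over replicates, and the mean regression line is the fit to
    the replicate-mean per-day curve, whose nullity p-value is reported.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    arrays = []
    days = []
    for s in sessions:
        on_o, off_o = _stream_arrays(s.orofacial_units)
        on_h, off_h = _stream_arrays(s.head_units)
        arrays.append((on_o, off_o, on_h, off_h, s.span_frames))
        days.append(s.gestational_day)
    days = np.asarray(days)
    grid = np.unique(days)
    curves = np.empty((n_reps, grid.size))
    slopes = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])  # substream per replicate
        fracs = np.empty(len(arrays))
        for k, (on_o, off_o, on_h, off_h, span) in enumerate(arrays):
            if on_o.size == 0 or on_h.size == 0:
                fracs[k] = _overlap_fraction_arrays(on_o, off_o, on_h, off_h)
                continue
            s_on_o, s_off_o = _shuffle_stream(on_o, off_o, span, rng)
            s_on_h, s_off_h = _shuffle_stream(on_h, off_h, span, rng)
            fracs[k] = _overlap_fraction_arrays(s_on_o, s_off_o, s_on_h, s_off_h)
        _, curve = average_by_day(days, fracs)
        curves[r] = curve
        ok = np.isfinite(curve)
        slopes[r] = np.polyfit(grid[ok], curve[ok], 1)[0]
    lo_q, hi_q = 100 * envelope_alpha / 2, 100 * (1 - envelope_alpha / 2)
    mean_curve = np.nanmean(curves, axis=0)
    lower = np.nanpercentile(curves, lo_q, axis=0)
    upper = np.nanpercentile(curves, hi_q, axis=0)
    slope_ci = (
        float(np.percentile(slopes, lo_q)),
        float(np.percentile(slopes, hi_q)),
    )
    ok = np.isfinite(mean_curve)
    mean_fit = fit_polynomial(grid[ok], mean_curve[ok], fit_degree)
    lin = stats.linregress(grid[ok], mean_curve[ok])
    return PermutationEnvelope(
        days=grid,
        mean=mean_curve,
        lower=lower,
        upper=upper,
        n_reps=n_reps,
        seed=seed,
        slopes=slopes,
        slope_ci=slope_ci,
        mean_fit=mean_fit,
        mean_line_slope=float(lin.slope),
        mean_line_p=float(lin.pvalue),
    )
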