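"""Mouth-opening temporal profiles: conditioning, DTW similarity, DBA templates.

A temporal profile is the frame-wise mouth-opening magnitude of one movement
unit or call, sampled at 30 Hz. Profiles are z-scored (amplitude carries no
information under ultrasound), smoothed — Savitzky-Golay (degree 3, window 9)
for fetal traces, cubic smoothing splines for infant exemplars (p = 0.999) and
templates (p = 0.1) — and compared by dynamic time warping with local cost
|a_i - b_j| over the symmetric step set {(1,0), (0,1), (1,1)}, endpoints
matched, no path-length normalization. Contact-call templates are DTW
barycenter averages (DBA) of same-syllable-count infant profiles; each fetal
profile keeps the cost of its best-matching template.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

from ._kernels import dtw_cost_kernel, dtw_matrix

FRAME_RATE = 30


@dataclass
class TemporalProfile:
    """One mouth-opening trace; ``syllable_count`` is the manual count on record."""

    values: np.ndarray
    source: str = "fetal"  # 'fetal' | 'infant'
    syllable_count: int = 0
    quality_ok: bool = True
    profile_id: str = ""
    session_id: str = ""
    gestational_day: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("profile needs a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile contains missing or non-finite samples")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CallTemplate:
    syllable_count: int
    values: np.ndarray


@dataclass(frozen=True)
class DtwMatch:
    profile_id: str
    session_id: str
    gestational_day: int
    best_template_syllables: int
    cost: float


def zscore(values: np.ndarray) -> np.ndarray:
    """Remove amplitude: (v - mean) / sd. Constant traces are rejected."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant profile")
    return (v - v.mean()) / sd


def smooth_savgol(
    profile: TemporalProfile | np.ndarray, poly_degree: int = 3, window: int = 9
) -> TemporalProfile | np.ndarray:
    """Savitzky-Golay local-polynomial smoothing, same length as the input."""
    if window % 2 == 0 or window <= poly_degree:
        raise ValueError("window must be odd and larger than poly_degree")
    values = profile.values if isinstance(profile, TemporalProfile) else np.asarray(profile, float)
    if values.size < window:
        raise ValueError(
            f"profile of length {values.size} too short for window {window}"
        )
    smoothed = signal.savgol_filter(values, window, poly_degree)
    if isinstance(profile, TemporalProfile):
        return replace(profile, values=smoothed)
    return smoothed


def smooth_spline(
    profile: TemporalProfile | np.ndarray, smoothing: float
) -> TemporalProfile | np.ndarray:
    """Cubic smoothing spline evaluated on the sample grid.

    ``smoothing`` is the csaps-style parameter p in [0, 1] for the objective
    p * sum (y - g)^2 + (1 - p) * integral g''^2: p = 1 interpolates, p -> 0
    tends to the least-squares line. Internally mapped to the penalized-spline
    weight lam = (1 - p) / p on the unit-spaced sample grid.
    """
    if not 0.0 <= smoothing <= 1.0:
        raise ValueError("smoothing parameter must lie in [0, 1]")
    values = profile.values if isinstance(profile, TemporalProfile) else np.asarray(profile, float)
    if values.size < 4:
        raise ValueError("smoothing spline needs at least 4 samples")
    x = np.arange(values.size, dtype=float)
    if smoothing == 0.0:
        smoothed = np.polyval(np.polyfit(x, values, 1), x)
    else:
        lam = (1.0 - smoothing) / smoothing
        smoothed = make_smoothing_spline(x, values, lam=lam)(x)
    if isinstance(profile, TemporalProfile):
        return replace(profile, values=smoothed)
    return smoothed


def _resample(values: np.ndarray, factor: int) -> np.ndarray:
    """Uniform linear-interpolation refinement by an integer factor."""
    n = values.size
    fine = np.linspace(0.0, n - 1.0, (n - 1) * factor + 1)
    return np.interp(fine, np.arange(n, dtype=float), values)


def dtw_cost(
    a: TemporalProfile | np.ndarray,
    b: TemporalProfile | np.ndarray,
    resample_factor: int = 1,
    normalize: bool = False,
) -> float:
    """Minimal cumulative |a_i - b_j| over monotone warping paths.

    ``resample_factor`` > 1 linearly interpolates both sequences onto a
    ``factor``-times finer uniform grid before the dynamic program (a
    continuous-DTW approximation); the default is plain discrete DTW.
    ``normalize`` divides by len(a) + len(b), giving a per-step dissimilarity
    comparable across profiles of different durations.
    """
    av = a.values if isinstance(a, TemporalProfile) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, TemporalProfile) else np.asarray(b, dtype=float)
    if av.size < 1 or bv.size < 1:
        raise ValueError("dtw_cost needs non-empty sequences")
    if resample_factor < 1:
        raise ValueError("resample_factor must be >= 1")
    if resample_factor > 1:
        av = _resample(av, resample_factor)
        bv = _resample(bv, resample_factor)
    cost = float(dtw_cost_kernel(np.ascontiguousarray(av), np.ascontiguousarray(bv)))
    if normalize:
        cost /= av.size + bv.size
    return cost


def dtw_path(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """One optimal warping path (ties broken diagonal-first), end to end."""
    a = np.ascontiguousarray(np.asarray(a, dtype=float))
    b = np.ascontiguousarray(np.asarray(b, dtype=float))
    acc = dtw_matrix(a, b)
    i, j = a.size - 1, b.size - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (
                (acc[i - 1, j - 1], i - 1, j - 1),
                (acc[i - 1, j], i - 1, j),
                (acc[i, j - 1], i, j - 1),
            )
            _, i, j = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return path


def dba_barycenter(
    sequences: Sequence[np.ndarray], n_iter: int = 10
) -> np.ndarray:
    """DTW barycenter average of a set of sequences.

    Starts from the medoid (minimal total DTW cost to the rest), then
    repeatedly aligns every sequence to the current average and replaces each
    average sample by the mean of its aligned samples, stopping after
    ``n_iter`` rounds or as soon as the total DTW cost stops decreasing. The
    lowest-cost average seen is returned.
    """
    seqs = [np.asarray(s, dtype=float) for s in sequences]
    if not seqs:
        raise ValueError("dba_barycenter needs at least one sequence")
    if len(seqs) == 1:
        return seqs[0].copy()

    def total_cost(center: np.ndarray) -> float:
        return sum(dtw_cost(center, s) for s in seqs)

    costs = [total_cost(s) for s in seqs]
    center = seqs[int(np.argmin(costs))].copy()
    best_center, best_cost = center.copy(), min(costs)
    for _ in range(n_iter):
        sums = np.zeros_like(center)
        counts = np.zeros(center.size)
        for s in seqs:
            for i, j in dtw_path(center, s):
                sums[i] += s[j]
                counts[i] += 1
        center = sums / counts
        cost = total_cost(center)
        if cost >= best_cost:
            break
        best_center, best_cost = center.copy(), cost
    return best_center


def dba_template(
    profiles: Sequence[TemporalProfile],
    n_iter: int = 10,
    template_smoothing: float = 0.1,
) -> CallTemplate:
    """Barycenter-average same-syllable-count profiles into a smoothed template."""
    if not profiles:
        raise ValueError("dba_template needs at least one profile")
    counts = {p.syllable_count for p in profiles}
    if len(counts) > 1:
        raise ValueError(f"profiles mix syllable counts {sorted(counts)}")
    center = dba_barycenter([p.values for p in profiles], n_iter=n_iter)
    if center.size >= 4:
        center = smooth_spline(center, template_smoothing)
    return CallTemplate(syllable_count=counts.pop(), values=center)


def build_templates(
    profiles: Sequence[TemporalProfile],
    n_iter: int = 10,
    template_smoothing: float = 0.1,
) -> list[CallTemplate]:
    """One template per syllable count present among the given infant profiles."""
    by_count: dict[int, list[TemporalProfile]] = {}
    for p in profiles:
        by_count.setdefault(p.syllable_count, []).append(p)
    return [
        dba_template(group, n_iter=n_iter, template_smoothing=template_smoothing)
        for _, group in sorted(by_count.items())
    ]


def match_to_templates(
    profile: TemporalProfile,
    templates: Sequence[CallTemplate],
    normalize: bool = True,
) -> DtwMatch:
    """Best (lowest-cost) template for a profile; ties favor fewer syllables.

    The retained score is length-normalized by default so that it measures
    shape dissimilarity rather than profile duration and is comparable
    across gestational ages.
    """
    if not templates:
        raise ValueError("match_to_templates needs at least one template")
    best_cost, best_syll = np.inf, None
    for t in sorted(templates, key=lambda t: t.syllable_count):
        c = dtw_cost(profile.values, t.values, normalize=normalize)
        if c < best_cost:
            best_cost, best_syll = c, t.syllable_count
    return DtwMatch(
        profile_id=profile.profile_id,
        session_id=profile.session_id,
        gestational_day=profile.gestational_day,
        best_template_syllables=best_syll,
        cost=float(best_cost),
    )


def session_median_dtw(matches: Sequence[DtwMatch]) -> dict[str, float]:
    """Median retained DTW cost per session; sessions without matches are absent."""
    by_session: dict[str, list[float]] = {}
    for m in matches:
        by_session.setdefault(m.session_id, []).append(m.cost)
    return {sid: float(np.median(costs)) for sid, costs in by_session.items()}


def count_profile_syllables(
    values: np.ndarray, prominence: float = 0.5, min_distance_frames: int = 4
) -> int:
    """Automated syllable count: prominent peaks of the z-scored trace.

    One open-close cycle contributes one prominent peak; ``prominence`` is in
    z-score units.
    """
    v = np.asarray(values, dtype=float)
    if v.std() == 0:
        return 0
    z = zscore(v)
    peaks, _ = find_peaks(z, prominence=prominence, distance=min_distance_frames)
    return int(peaks.size)


def quality_gate(
    profiles: Sequence[TemporalProfile],
    min_length: int = 9,
    prominence: float = 0.5,
    smooth_window: int = 9,
    smooth_degree: int = 3,
) -> list[TemporalProfile]:
    """Keep profiles usable for matching, with ``quality_ok`` set accordingly.

    A profile passes when it is at least ``min_length`` samples (the smoothing
    window, below which the filter is inapplicable) and the automated syllable
    count of its denoised trace (Savitzky-Golay, then prominent-peak counting)
    agrees with the manual count on record.
    """
    gated = []
    for p in profiles:
        ok = len(p) >= max(min_length, smooth_window)
        if ok:
            denoised = smooth_savgol(p.values, smooth_degree, smooth_window)
            ok = count_profile_syllables(denoised, prominence=prominence) == p.syllable_count
        gated.append(replace(p, quality_ok=ok))
    return gated
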