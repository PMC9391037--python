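"""Synthetic cohorts and call-shaped profiles with the structure the analyses assume.

The generator emulates the study design: four pregnancies imaged every few
days from gestational day 93 to 146 (64 sessions), orofacial and head movement
units on a 30 Hz timeline, and mouth-opening waveforms built from 1-16
raised-cosine open-close cycles. Defaults encode the qualitative developmental
shapes the analyses are meant to detect — an inverse-U orofacial rate, a
linearly declining head rate, orofacial-head coupling that decays toward term,
and unit durations/syllable counts that grow toward the infant contact-call
signature — without claiming the study's parameter values.

All randomness flows from one master seed through named substreams, so every
artifact is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .callclass import CallRecord
from .events import FRAME_RATE, MovementEvent, MovementUnit, Session
from .profiles import TemporalProfile

Schedule = Callable[[float], float]


def _as_schedule(v: float | Schedule) -> Schedule:
    return v if callable(v) else (lambda day, _v=float(v): _v)


def default_orofacial_rate(day: float) -> float:
    """Inverse-U movement rate (units/hour): ~25 at E93, peak ~60 near E119."""
    return max(5.0, 60.0 - 0.052 * (day - 119.0) ** 2)


def default_head_rate(day: float) -> float:
    """Linearly declining head rate: 55/hour at E93 down to 12/hour at E146."""
    return max(3.0, 55.0 - (43.0 / 53.0) * (day - 93.0))


def default_coupling(day: float) -> float:
    """Orofacial-head coupling probability: 0.8 at E93 declining to 0.05 at E146."""
    return float(np.clip(0.8 - 0.75 * (day - 93.0) / 53.0, 0.0, 1.0))


def _day_frac(day: float) -> float:
    return float(np.clip((day - 93.0) / 53.0, 0.0, 1.0))


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for a synthetic imaging cohort."""

    n_pregnancies: int = 4
    sessions_per_pregnancy: int = 16
    day_range: tuple[int, int] = (93, 146)
    visible_time_s: float = 1200.0
    orofacial_rate_schedule: float | Schedule = default_orofacial_rate
    head_rate_schedule: float | Schedule = default_head_rate
    coupling_schedule: float | Schedule = default_coupling
    #: (orofacial-lead, head-lead, synchronous) split for coupled pairs
    lead_mix: tuple[float, float, float] = (0.45, 0.45, 0.10)
    #: mean syllables per orofacial unit at E93 and E146 (linear in between)
    syllable_mean_range: tuple[float, float] = (2.0, 5.0)
    #: mean open-close cycle duration (s) at E93 and E146
    cycle_duration_range: tuple[float, float] = (0.35, 0.55)
    cycle_duration_sd: float = 0.08
    #: intra-unit gap between cycles, frames (must stay <= merge threshold)
    intra_gap_frames: tuple[int, int] = (2, 14)
    head_duration_mean_s: float = 1.0
    head_duration_sd_s: float = 0.3
    partial_prob: float = 0.05
    #: minimum gap between same-kind units, frames (> merge threshold)
    inter_unit_gap_frames: int = 16

    def __post_init__(self) -> None:
        if not 90 <= self.day_range[0] <= self.day_range[1] <= 146:
            raise ValueError("day_range must lie within [90, 146]")
        if self.partial_prob < 0 or self.partial_prob > 1:
            raise ValueError("partial_prob must be in [0, 1]")
        if abs(sum(self.lead_mix) - 1.0) > 1e-9:
            raise ValueError("lead_mix must sum to 1")


@dataclass(frozen=True)
class ProfileSpec:
    """Parameters for one synthetic mouth-opening waveform."""

    call_type: str = "contact"
    syllable_count: int = 5
    cycle_duration_mean_s: float = 0.55
    cycle_duration_sd_s: float = 0.08
    inter_cycle_gap_s: tuple[float, float] = (0.1, 0.4)  # must stay < 0.5 s
    noise_sd: float = 0.05
    warp_amplitude: float = 0.3
    #: sd of the per-cycle amplitude jitter; 0 keeps every cycle at unit height.
    #: Unlike time warping, amplitude irregularity is NOT absorbed by DTW, so
    #: it controls genuine shape distance from the call templates.
    amplitude_jitter: float = 0.0
    #: sd of a slow random baseline drift (incomplete jaw closures, posture
    #: shifts). Call templates return to baseline between syllables, so drift
    #: is another warp-proof source of shape distance.
    baseline_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.syllable_count < 1:
            raise ValueError("syllable_count must be >= 1")
        if self.inter_cycle_gap_s[1] >= 0.5:
            raise ValueError("inter-cycle gaps must stay below 0.5 s")


def _session_days(spec: CohortSpec) -> list[int]:
    lo, hi = spec.day_range
    return [int(round(d)) for d in np.linspace(lo, hi, spec.sessions_per_pregnancy)]


def _unit_blueprints(
    n: int, day: float, spec: CohortSpec, rng: np.random.Generator
) -> list[tuple[list[int], list[int]]]:
    """(cycle durations, intra gaps) in frames for n orofacial units."""
    frac = _day_frac(day)
    syl_mean = spec.syllable_mean_range[0] + frac * (
        spec.syllable_mean_range[1] - spec.syllable_mean_range[0]
    )
    cyc_mean = spec.cycle_duration_range[0] + frac * (
        spec.cycle_duration_range[1] - spec.cycle_duration_range[0]
    )
    blueprints = []
    for _ in range(n):
        k = int(np.clip(1 + rng.poisson(max(syl_mean - 1.0, 0.0)), 1, 16))
        cycles = np.clip(
            rng.normal(cyc_mean, spec.cycle_duration_sd, k), 0.15, 0.95
        )
        cyc_frames = [max(2, int(round(c * FRAME_RATE))) for c in cycles]
        gaps = list(
            rng.integers(spec.intra_gap_frames[0], spec.intra_gap_frames[1] + 1, k - 1)
        )
        blueprints.append((cyc_frames, [int(g) for g in gaps]))
    return blueprints


def _place_stream(
    durations: Sequence[int], span: int, min_gap: int, rng: np.random.Generator
) -> list[int]:
    """Non-overlapping onsets with >= min_gap frames between consecutive units."""
    n = len(durations)
    if n == 0:
        return []
    required = int(sum(durations)) + min_gap * (n - 1)
    extra = span - required
    if extra < 0:
        raise ValueError(
            f"infeasible packing: {n} units need {required} frames, span is {span}"
        )
    weights = rng.dirichlet(np.ones(n + 1))
    slack = np.floor(weights * extra).astype(int)
    onsets = []
    t = int(slack[0])
    for i, d in enumerate(durations):
        if i > 0:
            t += min_gap + int(slack[i])
        onsets.append(t)
        t += int(d)
    return onsets


def _events_for_unit(
    onset: int,
    cycles: Sequence[int],
    gaps: Sequence[int],
    kind: str,
    partial: bool,
    session_id: str,
    pregnancy_id: str,
    day: int,
) -> MovementUnit:
    events = []
    t = onset
    for i, c in enumerate(cycles):
        events.append(
            MovementEvent(
                session_id, pregnancy_id, day, kind, t, t + c,
                partial=partial and i == 0,
            )
        )
        t += c
        if i < len(gaps):
            t += gaps[i]
    return MovementUnit(tuple(events))


def _coupled_onset(
    o_on: int, o_off: int, d_h: int, mode: int, rng: np.random.Generator
) -> int | None:
    """Head onset for a coupled pair: 0 oro-lead, 1 head-lead, 2 synchronous."""
    if mode == 0:
        if o_off - o_on < 2:
            return None
        return int(rng.integers(o_on + 1, o_off))  # strictly inside
    if mode == 1:
        lo = max(0, o_on - d_h + 1)
        if lo > o_on - 1:
            return None
        return int(rng.integers(lo, o_on))  # oro onset strictly inside head
    return o_on  # synchronous


def _generate_session(
    spec: CohortSpec,
    pregnancy_id: str,
    day: int,
    session_id: str,
    rng: np.random.Generator,
) -> Session:
    span = int(round(spec.visible_time_s * FRAME_RATE))
    hours = spec.visible_time_s / 3600.0
    rate_o = _as_schedule(spec.orofacial_rate_schedule)(day)
    rate_h = _as_schedule(spec.head_rate_schedule)(day)
    c = float(np.clip(_as_schedule(spec.coupling_schedule)(day), 0.0, 1.0))

    n_o = rng.poisson(rate_o * hours)
    blueprints = _unit_blueprints(n_o, day, spec, rng)
    durations_o = [sum(cyc) + sum(g) for cyc, g in blueprints]
    onsets_o = _place_stream(durations_o, span, spec.inter_unit_gap_frames, rng)
    oro_units = [
        _events_for_unit(
            on, cyc, gaps, "orofacial", bool(rng.random() < spec.partial_prob),
            session_id, pregnancy_id, day,
        )
        for on, (cyc, gaps) in zip(onsets_o, blueprints)
    ]
    oro_intervals = [(u.onset, u.offset) for u in oro_units]

    n_h = rng.poisson(rate_h * hours)
    durations_h = [
        max(3, int(round(d * FRAME_RATE)))
        for d in np.clip(
            rng.normal(spec.head_duration_mean_s, spec.head_duration_sd_s, n_h),
            0.2, 2.5,
        )
    ]
    head_intervals: list[tuple[int, int]] = []
    min_gap = spec.inter_unit_gap_frames

    def fits(on: int, off: int) -> bool:
        if on < 0 or off > span:
            return False
        return all(
            off + min_gap <= a or b + min_gap <= on for a, b in head_intervals
        )

    lead_p = np.array(spec.lead_mix)
    for d_h in durations_h:
        placed = False
        if oro_intervals and rng.random() < c:
            for _ in range(20):  # coupled placement with rejection
                o_on, o_off = oro_intervals[rng.integers(len(oro_intervals))]
                mode = int(rng.choice(3, p=lead_p))
                on = _coupled_onset(o_on, o_off, d_h, mode, rng)
                if on is not None and fits(on, on + d_h):
                    head_intervals.append((on, on + d_h))
                    placed = True
                    break
        if not placed:
            for _ in range(50):  # independent placement
                on = int(rng.integers(0, max(1, span - d_h)))
                if fits(on, on + d_h):
                    head_intervals.append((on, on + d_h))
                    placed = True
                    break
        # units that cannot be packed are dropped
    head_intervals.sort()
    head_units = [
        _events_for_unit(
            on, [off - on], [], "head", bool(rng.random() < spec.partial_prob),
            session_id, pregnancy_id, day,
        )
        for on, off in head_intervals
    ]
    return Session(
        session_id=session_id,
        pregnancy_id=pregnancy_id,
        gestational_day=day,
        visible_time_s=spec.visible_time_s,
        orofacial_units=sorted(oro_units, key=lambda u: u.onset),
        head_units=head_units,
    )


def generate_cohort(spec: CohortSpec, seed: int) -> list[Session]:
    """Generate all sessions of the cohort, fully reproducible from the seed."""
    sessions = []
    days = _session_days(spec)
    for p in range(spec.n_pregnancies):
        pregnancy_id = f"P{p + 1}"
        for s_idx, day in enumerate(days):
            rng = np.random.default_rng([seed, p, s_idx])
            session_id = f"{pregnancy_id}_E{day}_{s_idx:02d}"
            sessions.append(
                _generate_session(spec, pregnancy_id, day, session_id, rng)
            )
    return sessions


def generate_profile(
    spec: ProfileSpec, rng: int | np.random.Generator
) -> TemporalProfile:
    """One waveform of ``syllable_count`` raised-cosine open-close cycles.

    Cycles are separated by sub-500 ms flat gaps, time-warped by a smooth
    monotone distortion, and perturbed by additive Gaussian noise. The true
    cycle count is carried in ``syllable_count`` for quality-gate tests.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pieces = [np.zeros(2)]
    for i in range(spec.syllable_count):
        dur = float(
            np.clip(
                rng.normal(spec.cycle_duration_mean_s, spec.cycle_duration_sd_s),
                0.15, 1.0,
            )
        )
        n = max(5, int(round(dur * FRAME_RATE)))
        t = np.arange(n) / (n - 1)
        amp = 1.0
        if spec.amplitude_jitter > 0:
            amp = max(0.15, 1.0 + rng.normal(0.0, spec.amplitude_jitter))
        pieces.append(amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t)))
        if i < spec.syllable_count - 1:
            gap = rng.uniform(*spec.inter_cycle_gap_s)
            pieces.append(np.zeros(max(1, int(round(gap * FRAME_RATE)))))
    pieces.append(np.zeros(2))
    values = np.concatenate(pieces)
    n = values.size
    if spec.warp_amplitude > 0:
        a = float(np.clip(rng.normal(0.0, spec.warp_amplitude), -0.9, 0.9))
        u = np.arange(n) / (n - 1)
        g = u + (a / (2.0 * np.pi)) * np.sin(2.0 * np.pi * u)  # monotone for |a|<1
        values = np.interp(g * (n - 1), np.arange(n, dtype=float), values)
    if spec.baseline_drift > 0:
        rough = rng.normal(0.0, 1.0, n)
        ksize = min(15, n)  # ~0.5 s smoothing scale
        drift = np.convolve(rough, np.ones(ksize) / ksize, mode="same")
        sd = drift.std()
        if sd > 0:
            values = values + spec.baseline_drift * drift / sd
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, n)
    return TemporalProfile(
        values=values,
        source="infant" if spec.call_type != "fetal" else "fetal",
        syllable_count=spec.syllable_count,
    )


#: Infant contact-call video sample sizes per syllable count (1-7 syllables).
INFANT_TEMPLATE_COUNTS = {1: 2, 2: 3, 3: 5, 4: 5, 5: 2, 6: 4, 7: 4}


def generate_infant_call_profiles(
    counts: dict[int, int] | None = None,
    seed: int = 0,
    noise_sd: float = 0.05,
    warp_amplitude: float = 0.15,
) -> list[TemporalProfile]:
    """Infant contact-call profiles grouped by syllable count, for DBA templates."""
    counts = INFANT_TEMPLATE_COUNTS if counts is None else counts
    profiles = []
    for k, n in sorted(counts.items()):
        for i in range(n):
            rng = np.random.default_rng([seed, k, i])
            spec = ProfileSpec(
                call_type="contact",
                syllable_count=k,
                noise_sd=noise_sd,
                warp_amplitude=warp_amplitude,
            )
            p = generate_profile(spec, rng)
            p.source = "infant"
            p.profile_id = f"infant_k{k}_{i}"
            profiles.append(p)
    return profiles


def generate_fetal_profiles(
    sessions: Sequence[Session],
    seed: int = 0,
    noise_sd_range: tuple[float, float] = (0.35, 0.06),
    warp_range: tuple[float, float] = (0.6, 0.15),
    amplitude_jitter_range: tuple[float, float] = (0.8, 0.05),
    drift_range: tuple[float, float] = (0.6, 0.03),
    max_per_session: int = 12,
    syllable_cap: int = 7,
) -> list[TemporalProfile]:
    """Fetal mouth-opening profiles whose template distance shrinks with age.

    One profile per complete orofacial unit (capped per session). Additive
    noise, time warp, and per-cycle amplitude irregularity all interpolate
    from the early- to the late-gestation value, so early profiles are
    genuinely unlike the stereotyped infant call shapes while late profiles
    approach them — the trajectory the DTW analysis is designed to detect.
    """
    profiles = []
    for s_idx, s in enumerate(sessions):
        frac = _day_frac(s.gestational_day)
        noise = noise_sd_range[0] + frac * (noise_sd_range[1] - noise_sd_range[0])
        warp = warp_range[0] + frac * (warp_range[1] - warp_range[0])
        jitter = amplitude_jitter_range[0] + frac * (
            amplitude_jitter_range[1] - amplitude_jitter_range[0]
        )
        drift = drift_range[0] + frac * (drift_range[1] - drift_range[0])
        complete = [u for u in s.orofacial_units if not u.partial]
        for u_idx, unit in enumerate(complete[:max_per_session]):
            rng = np.random.default_rng([seed, s_idx, u_idx])
            k = int(np.clip(unit.syllable_count, 1, syllable_cap))
            spec = ProfileSpec(
                call_type="fetal",
                syllable_count=k,
                cycle_duration_mean_s=0.35 + 0.2 * frac,
                noise_sd=noise,
                warp_amplitude=warp,
                amplitude_jitter=jitter,
                baseline_drift=drift,
            )
            p = generate_profile(spec, rng)
            p.source = "fetal"
            p.profile_id = f"{s.session_id}_u{u_idx}"
            p.session_id = s.session_id
            p.gestational_day = s.gestational_day
            profiles.append(p)
    return profiles


def generate_infant_calls(
    n_per_type: dict[str, int] | None = None, seed: int = 0
) -> list[CallRecord]:
    """Labeled infant call records (type, duration, syllables).

    Defaults emulate the postnatal-day-1 sample: contact calls with median
    duration near 3.69 s and median 5 syllables, short twitters with 2-3
    syllables, and bimodal licks (short/few or long/many syllables).
    """
    n_per_type = {"contact": 120, "twitter": 60, "lick": 37} if n_per_type is None else n_per_type
    calls = []
    for t_idx, (type_label, n) in enumerate(sorted(n_per_type.items())):
        rng = np.random.default_rng([seed, t_idx])
        for i in range(n):
            if type_label == "contact":
                dur = float(np.clip(rng.normal(3.69, 0.8), 1.0, 6.5))
                syl = int(np.clip(round(rng.normal(5.0, 1.3)), 1, 9))
            elif type_label == "twitter":
                dur = float(np.clip(rng.normal(1.2, 0.18), 0.5, 2.2))
                syl = 2 if rng.random() < 0.55 else 3
            elif type_label == "lick":
                if rng.random() < 0.7:  # short licks
                    dur = float(np.clip(rng.normal(1.8, 0.9), 0.2, 4.5))
                    syl = int(np.clip(1 + rng.poisson(1.5), 1, 7))
                else:  # long licks
                    dur = float(np.clip(rng.normal(10.5, 2.0), 5.0, 15.0))
                    syl = int(np.clip(round(rng.normal(13.0, 1.8)), 8, 17))
            else:
                dur = float(np.clip(rng.normal(2.0, 1.0), 0.3, 8.0))
                syl = int(np.clip(1 + rng.poisson(2.0), 1, 12))
            calls.append(
                CallRecord(
                    call_id=f"{type_label}_{i:03d}",
                    type_label=type_label,
                    duration_s=dur,
                    syllable_count=syl,
                    modality="audio" if rng.random() < 0.75 else "video",
                )
            )
    return calls
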