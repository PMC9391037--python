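"""End-to-end orchestration: cohort -> states -> trends -> matching -> signatures.

``run_pipeline`` executes every analysis stage on a cohort (synthetic by
default, or sessions supplied by the caller), returning a result bundle and
optionally writing all tables, fits, and a parameter manifest to a directory.
All randomness funnels through the config seed; two runs with the same config
produce identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .callclass import (
    CallRecord,
    DEFAULT_BOXES,
    box_capture,
    percent_match,
    type_likelihood,
)
from .events import Session, movement_rate, unit_durations, unit_syllable_counts
from .infotheory import (
    baseline_distribution,
    session_divergences,
    session_entropies,
)
from .overlap import (
    PermutationEnvelope,
    average_by_day,
    permutation_envelope,
    session_overlaps,
)
from .profiles import (
    CallTemplate,
    DtwMatch,
    TemporalProfile,
    build_templates,
    match_to_templates,
    quality_gate,
    session_median_dtw,
    smooth_savgol,
    smooth_spline,
    zscore,
)
from .readwrite import (
    write_calls,
    write_events,
    write_session_meta,
    write_state_sequences,
    write_templates,
    write_units,
    sessions_to_events,
)
from .states import session_states, state_distribution, transition_matrix
from .synthetic import (
    CohortSpec,
    generate_cohort,
    generate_fetal_profiles,
    generate_infant_call_profiles,
    generate_infant_calls,
)
from .trends import (
    PolyFit,
    RegressionResult,
    fit_polynomial,
    fit_polynomial_auto,
    regress_with_pregnancy,
    select_poly_degree_aic,
)

log = logging.getLogger("fetalvoc")


@dataclass
class PipelineConfig:
    """Study parameters; the defaults are the analysis constants of record."""

    frame_rate: int = 30  # fixed by the recording hardware
    merge_gap_frames: int = 15  # 500 ms at 30 Hz
    baseline_day_range: tuple[int, int] = (93, 99)
    savgol_degree: int = 3
    savgol_window: int = 9
    exemplar_spline_smoothing: float = 0.999
    template_spline_smoothing: float = 0.1
    permutation_reps: int = 1000
    envelope_alpha: float = 0.05
    #: additive smoothing for KL, applied only when the baseline has empty
    #: cells (otherwise every session sharing that state diverges infinitely)
    kl_smoothing: float = 1e-3
    dtw_resample_factor: int = 1
    max_poly_degree: int = 10
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        if self.frame_rate != 30:
            raise ValueError("the analysis timeline is fixed at 30 Hz")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"] = {
            k: v for k, v in d["cohort"].items() if not callable(v)
        }
        Path(path).write_text(yaml.safe_dump(d, default_flow_style=None))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        cohort = d.pop("cohort", {})
        known = {f.name for f in dataclasses.fields(CohortSpec)}
        spec = CohortSpec(
            **{k: (tuple(v) if isinstance(v, list) else v)
               for k, v in cohort.items() if k in known}
        )
        known_cfg = {f.name for f in dataclasses.fields(cls)}
        d = {k: (tuple(v) if isinstance(v, list) else v)
             for k, v in d.items() if k in known_cfg}
        return cls(cohort=spec, **d)


@dataclass
class PipelineResult:
    sessions: list[Session]
    session_table: pd.DataFrame  # per-session: day, pregnancy, rates, H, KL, overlap...
    state_distributions: dict[str, np.ndarray]
    transition_matrices: dict[str, np.ndarray]
    entropy_fit: PolyFit
    entropy_regression: RegressionResult
    kl_fit: PolyFit
    kl_regression: RegressionResult
    rate_fits: dict[str, PolyFit]
    overlap_fit: PolyFit
    overlap_regression: RegressionResult
    envelope: PermutationEnvelope
    templates: list[CallTemplate]
    matches: list[DtwMatch]
    dtw_regression: RegressionResult | None
    duration_fit: PolyFit
    syllable_fit: PolyFit
    match_regressions: dict[str, RegressionResult]
    infant_calls: list[CallRecord]
    call_likelihoods: dict[str, float]
    ns: dict[str, int]


def condition_fetal_profile(
    p: TemporalProfile, config: PipelineConfig
) -> TemporalProfile:
    """z-score then Savitzky-Golay smooth a fetal trace for DTW matching."""
    out = dataclasses.replace(p, values=zscore(p.values))
    return smooth_savgol(out, config.savgol_degree, config.savgol_window)


def condition_infant_profile(
    p: TemporalProfile, config: PipelineConfig
) -> TemporalProfile:
    """z-score then near-interpolating spline smooth an infant exemplar."""
    out = dataclasses.replace(p, values=zscore(p.values))
    return smooth_spline(out, config.exemplar_spline_smoothing)


def match_fetal_profiles(
    fetal: Sequence[TemporalProfile],
    templates: Sequence[CallTemplate],
    config: PipelineConfig,
) -> list[DtwMatch]:
    conditioned = [condition_fetal_profile(p, config) for p in fetal]
    return [match_to_templates(p, templates) for p in conditioned]


def run_pipeline(
    config: PipelineConfig | None = None,
    sessions: Sequence[Session] | None = None,
    fetal_profiles: Sequence[TemporalProfile] | None = None,
    infant_profiles: Sequence[TemporalProfile] | None = None,
    infant_calls: Sequence[CallRecord] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every analysis stage; see the module docstring."""
    config = config or PipelineConfig()
    ns: dict[str, int] = {}

    # --- cohort ---------------------------------------------------------
    if sessions is None:
        sessions = generate_cohort(config.cohort, config.seed)
    sessions = list(sessions)
    ns["sessions"] = len(sessions)
    ns["orofacial_units"] = sum(len(s.orofacial_units) for s in sessions)
    ns["head_units"] = sum(len(s.head_units) for s in sessions)
    log.info("cohort: %d sessions, %d orofacial units, %d head units",
             ns["sessions"], ns["orofacial_units"], ns["head_units"])

    # --- state coding + information theory ------------------------------
    sequences = {s.session_id: session_states(s) for s in sessions}
    dists = {sid: state_distribution(seq).p for sid, seq in sequences.items()}
    trans = {sid: transition_matrix(seq) for sid, seq in sequences.items()}
    entropy_pts = session_entropies(sessions)
    baseline = baseline_distribution(sessions, config.baseline_day_range)
    kl_smoothing = 0.0 if np.all(baseline.p > 0) else config.kl_smoothing
    if kl_smoothing:
        log.info("baseline has empty state cells; KL uses additive "
                 "smoothing %g", kl_smoothing)
    kl_pts = session_divergences(
        sessions, config.baseline_day_range, smoothing=kl_smoothing
    )
    ns["state_occurrences"] = sum(len(seq) for seq in sequences.values())

    days_h = [p.gestational_day for p in entropy_pts]
    h_vals = [p.h_bits for p in entropy_pts]
    def _degree_cap(xs) -> int:
        return max(1, min(config.max_poly_degree, len(np.unique(xs)) - 2))

    entropy_fit = fit_polynomial_auto(days_h, h_vals, _degree_cap(days_h))
    by_sid = {s.session_id: s for s in sessions}
    entropy_reg = regress_with_pregnancy(
        h_vals, days_h, [by_sid[p.session_id].pregnancy_id for p in entropy_pts]
    )
    kl_finite = [p for p in kl_pts if math.isfinite(p.kl_bits)]
    ns["kl_finite_sessions"] = len(kl_finite)
    kl_days = [p.gestational_day for p in kl_finite]
    kl_fit = fit_polynomial_auto(
        kl_days, [p.kl_bits for p in kl_finite], _degree_cap(kl_days)
    )
    kl_reg = regress_with_pregnancy(
        [p.kl_bits for p in kl_finite],
        [p.gestational_day for p in kl_finite],
        [by_sid[p.session_id].pregnancy_id for p in kl_finite],
    )

    # --- rates and overlap ----------------------------------------------
    days = np.array([s.gestational_day for s in sessions])
    rate_fits = {}
    rates = {}
    for kind in ("orofacial", "head"):
        rates[kind] = np.array([movement_rate(s, kind) for s in sessions])
        rate_fits[kind] = fit_polynomial_auto(
            days, rates[kind], _degree_cap(days)
        )
    overlap_pts = session_overlaps(sessions)
    ov = np.array([p.pct_overlap for p in overlap_pts])
    grid, ov_by_day = average_by_day(days, ov)
    ok = np.isfinite(ov_by_day)
    ov_degree = select_poly_degree_aic(
        grid[ok], ov_by_day[ok], _degree_cap(grid[ok])
    )
    overlap_fit = fit_polynomial(grid[ok], ov_by_day[ok], ov_degree)
    finite = np.isfinite(ov)
    overlap_reg = regress_with_pregnancy(
        ov[finite], days[finite],
        np.array([s.pregnancy_id for s in sessions])[finite],
    )
    envelope = permutation_envelope(
        sessions,
        n_reps=config.permutation_reps,
        seed=config.seed,
        fit_degree=ov_degree,
        envelope_alpha=config.envelope_alpha,
    )

    # --- temporal-profile matching --------------------------------------
    if infant_profiles is None:
        infant_profiles = generate_infant_call_profiles(seed=config.seed)
    if fetal_profiles is None:
        fetal_profiles = generate_fetal_profiles(sessions, seed=config.seed)
    ns["fetal_profiles"] = len(fetal_profiles)
    infant_conditioned = [
        condition_infant_profile(p, config) for p in infant_profiles
    ]
    templates = build_templates(
        infant_conditioned,
        template_smoothing=config.template_spline_smoothing,
    )
    gated = [
        p for p in quality_gate(fetal_profiles, min_length=config.savgol_window)
        if p.quality_ok
    ]
    ns["fetal_profiles_retained"] = len(gated)
    matches = match_fetal_profiles(gated, templates, config)
    medians = session_median_dtw(matches)
    ns["sessions_with_dtw_median"] = len(medians)
    log.info("profiles: %d generated, %d retained, medians for %d sessions",
             ns["fetal_profiles"], len(gated), len(medians))
    if len(medians) >= 3:
        med_sids = list(medians)
        dtw_reg = regress_with_pregnancy(
            [medians[sid] for sid in med_sids],
            [by_sid[sid].gestational_day for sid in med_sids],
            [by_sid[sid].pregnancy_id for sid in med_sids],
        )
    else:
        dtw_reg = None

    # --- duration / syllable trends (complete units only) ----------------
    dur_med, syl_med, dur_days = [], [], []
    for s in sessions:
        d = unit_durations(s.orofacial_units, exclude_partial=True)
        if not d:
            continue
        dur_med.append(float(np.median(d)))
        syl_med.append(float(np.median(
            unit_syllable_counts(s.orofacial_units, exclude_partial=True)
        )))
        dur_days.append(s.gestational_day)
    trend_max = _degree_cap(dur_days)
    duration_fit = fit_polynomial_auto(dur_days, dur_med, trend_max)
    syllable_fit = fit_polynomial_auto(dur_days, syl_med, trend_max)

    # --- call-signature matching -----------------------------------------
    match_regs = {}
    match_cols = {}
    for name, box in DEFAULT_BOXES.items():
        pm = np.array([percent_match(s, box) for s in sessions])
        match_cols[name] = pm
        finite = np.isfinite(pm)
        match_regs[name] = regress_with_pregnancy(
            pm[finite], days[finite],
            np.array([s.pregnancy_id for s in sessions])[finite],
        )
    if infant_calls is None:
        infant_calls = generate_infant_calls(seed=config.seed)
    infant_calls = list(infant_calls)
    ns["infant_calls"] = len(infant_calls)
    likelihoods = {
        name: type_likelihood(infant_calls, box, name)
        for name, box in DEFAULT_BOXES.items()
    }
    # the lick union is characterized by how many licks it captures
    likelihoods["lick_capture"] = box_capture(
        infant_calls, DEFAULT_BOXES["lick"], "lick"
    )

    # --- assemble ---------------------------------------------------------
    h_by_sid = {p.session_id: p.h_bits for p in entropy_pts}
    kl_by_sid = {p.session_id: p.kl_bits for p in kl_pts}
    session_table = pd.DataFrame(
        {
            "session_id": [s.session_id for s in sessions],
            "pregnancy_id": [s.pregnancy_id for s in sessions],
            "gestational_day": days,
            "orofacial_rate_per_h": rates["orofacial"],
            "head_rate_per_h": rates["head"],
            "entropy_bits": [h_by_sid.get(s.session_id, np.nan) for s in sessions],
            "kl_bits": [kl_by_sid.get(s.session_id, np.nan) for s in sessions],
            "pct_overlap": ov,
            "median_dtw": [medians.get(s.session_id, np.nan) for s in sessions],
            **{f"pct_match_{k}": v for k, v in match_cols.items()},
        }
    )
    result = PipelineResult(
        sessions=sessions,
        session_table=session_table,
        state_distributions=dists,
        transition_matrices=trans,
        entropy_fit=entropy_fit,
        entropy_regression=entropy_reg,
        kl_fit=kl_fit,
        kl_regression=kl_reg,
        rate_fits=rate_fits,
        overlap_fit=overlap_fit,
        overlap_regression=overlap_reg,
        envelope=envelope,
        templates=templates,
        matches=matches,
        dtw_regression=dtw_reg,
        duration_fit=duration_fit,
        syllable_fit=syllable_fit,
        match_regressions=match_regs,
        infant_calls=infant_calls,
        call_likelihoods=likelihoods,
        ns=ns,
    )
    if outdir is not None:
        write_results(result, config, Path(outdir), sequences)
    return result


def _fit_dict(fit: PolyFit) -> dict:
    return {
        "degree": fit.degree,
        "coefficients": [float(c) for c in fit.coefficients],
        "aic": float(fit.aic),
        "rss": float(fit.rss),
        "x_domain": list(fit.x_domain),
    }


def _reg_dict(reg: RegressionResult | None) -> dict | None:
    if reg is None:
        return None
    return {
        "slope": reg.slope, "se": reg.se, "t": reg.t, "f": reg.f, "p": reg.p,
        "df": [reg.df_num, reg.df_den], "covariates": list(reg.covariate_set),
    }


def write_results(
    result: PipelineResult,
    config: PipelineConfig,
    outdir: Path,
    sequences: dict | None = None,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_events(sessions_to_events(result.sessions), outdir / "events.csv")
    write_session_meta(result.sessions, outdir / "sessions.csv")
    write_units(result.sessions, outdir / "units.csv")
    if sequences:
        write_state_sequences(sequences.values(), outdir / "state_sequences.csv")
    result.session_table.to_csv(outdir / "session_table.csv", index=False)
    pd.DataFrame(
        {
            "day": result.envelope.days,
            "mean": result.envelope.mean,
            "lower": result.envelope.lower,
            "upper": result.envelope.upper,
        }
    ).to_csv(outdir / "permutation_envelope.csv", index=False)
    write_templates(result.templates, outdir / "templates.json")
    write_calls(result.infant_calls, outdir / "infant_calls.csv")
    fits = {
        "entropy": _fit_dict(result.entropy_fit),
        "kl": _fit_dict(result.kl_fit),
        "orofacial_rate": _fit_dict(result.rate_fits["orofacial"]),
        "head_rate": _fit_dict(result.rate_fits["head"]),
        "overlap": _fit_dict(result.overlap_fit),
        "duration_median": _fit_dict(result.duration_fit),
        "syllable_median": _fit_dict(result.syllable_fit),
    }
    regs = {
        "entropy": _reg_dict(result.entropy_regression),
        "kl": _reg_dict(result.kl_regression),
        "overlap": _reg_dict(result.overlap_regression),
        "median_dtw": _reg_dict(result.dtw_regression),
        **{f"pct_match_{k}": _reg_dict(v) for k, v in result.match_regressions.items()},
    }
    manifest = {
        "fetalvoc_version": __version__,
        "config": json.loads(json.dumps(
            {k: v for k, v in dataclasses.asdict(config).items() if k != "cohort"},
            default=str,
        )),
        "ns": result.ns,
        "call_likelihoods": {
            k: (None if not math.isfinite(v) else v)
            for k, v in result.call_likelihoods.items()
        },
        "fits": fits,
        "regressions": regs,
        "envelope": {
            "n_reps": result.envelope.n_reps,
            "seed": result.envelope.seed,
            "slope_ci": list(result.envelope.slope_ci),
            "mean_line_slope": result.envelope.mean_line_slope,
            "mean_line_p": result.envelope.mean_line_p,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
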