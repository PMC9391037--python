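"""The synthetic cohort/profile generator: determinism, construction, recovery."""

import numpy as np
import pytest

from fetalvoc.callclass import CONTACT_BOX
from fetalvoc.overlap import percent_overlap
from fetalvoc.profiles import count_profile_syllables
from fetalvoc.synthetic import (
    CohortSpec,
    ProfileSpec,
    generate_cohort,
    generate_fetal_profiles,
    generate_infant_call_profiles,
    generate_infant_calls,
    generate_profile,
)


def _cohort_signature(sessions):
    return [
        (
            s.session_id,
            tuple((u.onset, u.offset, u.syllable_count) for u in s.orofacial_units),
            tuple((u.onset, u.offset) for u in s.head_units),
        )
        for s in sessions
    ]


def test_same_seed_reproduces_cohort_exactly():
    spec = CohortSpec(n_pregnancies=2, sessions_per_pregnancy=4)
    assert _cohort_signature(generate_cohort(spec, 5)) == _cohort_signature(
        generate_cohort(spec, 5)
    )
    assert _cohort_signature(generate_cohort(spec, 5)) != _cohort_signature(
        generate_cohort(spec, 6)
    )


def test_cohort_shape_and_validity():
    sessions = generate_cohort(CohortSpec(), seed=2)
    assert len(sessions) == 64
    assert len({s.pregnancy_id for s in sessions}) == 4
    days = sorted({s.gestational_day for s in sessions})
    assert days[0] == 93 and days[-1] == 146
    for s in sessions:
        for units in (s.orofacial_units, s.head_units):
            for a, b in zip(units, units[1:]):
                assert b.onset > a.offset  # same-kind units never overlap


def test_full_coupling_produces_high_overlap():
    spec = CohortSpec(
        coupling_schedule=1.0,
        head_rate_schedule=20.0,
        orofacial_rate_schedule=40.0,
    )
    sessions = generate_cohort(spec, seed=4)
    fracs, bounds = [], []
    for s in sessions:
        n_o, n_h = len(s.orofacial_units), len(s.head_units)
        if n_o and n_h:
            fracs.append(percent_overlap(s))
            bounds.append(min(n_o, n_h) / (n_o + n_h))
    # nearly every head unit is an overlap instance
    assert np.mean(fracs) >= 0.8 * np.mean(bounds)


def test_zero_coupling_matches_analytic_coincidence_rate():
    """With independent streams, expected pair count per session is close to
    the renewal-coincidence approximation n_o*n_h*(mean_do + mean_dh)/span."""
    spec = CohortSpec(coupling_schedule=0.0)
    sessions = generate_cohort(spec, seed=9)
    observed = expected = 0.0
    for s in sessions:
        n_o, n_h = len(s.orofacial_units), len(s.head_units)
        if not (n_o and n_h):
            continue
        d_o = np.mean([u.offset - u.onset for u in s.orofacial_units])
        d_h = np.mean([u.offset - u.onset for u in s.head_units])
        expected += n_o * n_h * (d_o + d_h) / s.span_frames
        observed += percent_overlap(s) * (n_o + n_h)
    assert observed == pytest.approx(expected, rel=0.35)
    # and far below the fully coupled construction
    assert observed < 0.5 * sum(
        min(len(s.orofacial_units), len(s.head_units)) for s in sessions
    )


def test_infeasible_packing_is_rejected():
    spec = CohortSpec(visible_time_s=30.0, orofacial_rate_schedule=100000.0)
    with pytest.raises(ValueError, match="infeasible packing"):
        generate_cohort(spec, seed=0)


@pytest.mark.parametrize("k", [1, 4, 7])
def test_clean_profile_carries_ground_truth(k):
    spec = ProfileSpec(syllable_count=k, noise_sd=0.0, warp_amplitude=0.0)
    p = generate_profile(spec, 3)
    assert p.syllable_count == k
    assert count_profile_syllables(p.values) == k
    # same seed, same waveform
    np.testing.assert_array_equal(p.values, generate_profile(spec, 3).values)


def test_profile_gaps_stay_below_call_separator():
    with pytest.raises(ValueError, match="0.5"):
        ProfileSpec(inter_cycle_gap_s=(0.3, 0.6))


def test_contact_profile_durations_near_signature():
    durs = [
        len(generate_profile(ProfileSpec(syllable_count=5), i)) / 30.0
        for i in range(200)
    ]
    assert 3.0 <= float(np.median(durs)) <= 4.5


def test_infant_calls_hit_signature_medians():
    calls = generate_infant_calls(seed=0)
    contact = [c for c in calls if c.type_label == "contact"]
    assert len(contact) == 120
    assert np.median([c.duration_s for c in contact]) == pytest.approx(3.69, abs=0.35)
    assert np.median([c.syllable_count for c in contact]) == 5
    twitter = [c for c in calls if c.type_label == "twitter"]
    assert 0.96 <= np.median([c.duration_s for c in twitter]) <= 1.5
    lick_durs = [c.duration_s for c in calls if c.type_label == "lick"]
    # bimodal: both short and long licks occur
    assert min(lick_durs) < 3.0 and max(lick_durs) > 7.0
    # determinism and per-type n control
    again = generate_infant_calls(seed=0)
    assert [(c.call_id, c.duration_s) for c in again] == [
        (c.call_id, c.duration_s) for c in calls
    ]
    none = generate_infant_calls({"contact": 0, "twitter": 5}, seed=1)
    assert not [c for c in none if c.type_label == "contact"]
    assert len(none) == 5


def test_contact_fraction_rises_with_gestation():
    from fetalvoc.callclass import percent_match

    sessions = generate_cohort(CohortSpec(), seed=13)
    early = [s for s in sessions if s.gestational_day <= 110]
    late = [s for s in sessions if s.gestational_day >= 130]
    pm_early = np.nanmean([percent_match(s, CONTACT_BOX) for s in early])
    pm_late = np.nanmean([percent_match(s, CONTACT_BOX) for s in late])
    assert pm_late > pm_early


def test_fetal_profiles_round_trip_through_io(tmp_path, default_cohort):
    from fetalvoc.readwrite import read_profiles, write_profiles

    profiles = generate_fetal_profiles(default_cohort[:4], seed=21)
    write_profiles(profiles, tmp_path / "profiles")
    back = read_profiles(tmp_path / "profiles")
    assert len(back) == len(profiles)
    for a, b in zip(profiles, back):
        assert a.profile_id == b.profile_id
        assert a.syllable_count == b.syllable_count
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def test_infant_template_profiles_cover_counts():
    profiles = generate_infant_call_profiles(seed=1)
    by_count = {}
    for p in profiles:
        by_count[p.syllable_count] = by_count.get(p.syllable_count, 0) + 1
    assert by_count == {1: 2, 2: 3, 3: 5, 4: 5, 5: 2, 6: 4, 7: 4}
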