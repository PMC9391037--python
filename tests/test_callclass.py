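"""Call-signature boxes, likelihoods, percent match, and duration reconciliation."""

import math

import numpy as np
import pytest

from fetalvoc.callclass import (
    CONTACT_BOX,
    LICK_BOX,
    TWITTER_BOX,
    CallRecord,
    CriteriaBox,
    adjust_audio_durations,
    box_capture,
    boxes_disjoint,
    count_syllables,
    derive_criteria,
    percent_match,
    type_likelihood,
)

from conftest import make_session, make_unit


def call(type_label, dur, syl, cid="c"):
    return CallRecord(cid, type_label, dur, syl)


def test_count_syllables_and_partial_rejection():
    unit = make_unit(0, 100)
    assert count_syllables(unit) == 1
    with pytest.raises(ValueError, match="partial"):
        count_syllables(make_unit(0, 100, partial=True))


def test_count_syllables_consistent_with_merging():
    from fetalvoc.events import merge_events
    from conftest import make_event

    events = [make_event(20 * i, 20 * i + 10) for i in range(7)]  # 10-frame gaps
    (unit,) = merge_events(events, 15)
    assert count_syllables(unit) == 7


def test_type_likelihood_examples_and_enumeration_oracle(rng):
    box = CriteriaBox("test", ((1.0, 2.0, 2, 4),))
    pure = [call("contact", 1.5, 3, f"a{i}") for i in range(5)]
    assert type_likelihood(pure, box, "contact") == 1.0
    assert type_likelihood(pure, box, "twitter") == 0.0
    # mixed population vs direct counting
    calls = [
        call(rng.choice(["contact", "lick"]), rng.uniform(0.5, 2.5), rng.integers(1, 6), str(i))
        for i in range(200)
    ]
    inside = [c for c in calls if box.contains(c.duration_s, c.syllable_count)]
    expected = sum(c.type_label == "contact" for c in inside) / len(inside)
    assert type_likelihood(calls, box, "contact") == pytest.approx(expected)
    # empty occupancy is flagged undefined
    assert math.isnan(type_likelihood(pure, CriteriaBox("far", ((50, 60, 2, 4),)), "contact"))


def test_box_capture():
    calls = [call("lick", 1.0, 2), call("lick", 5.0, 8), call("contact", 4.0, 6)]
    assert box_capture(calls, LICK_BOX, "lick") == pytest.approx(0.5)
    assert math.isnan(box_capture(calls, LICK_BOX, "twitter"))


def test_criteria_bounds_are_closed():
    assert CONTACT_BOX.contains(3.69, 5)  # both lower bounds exactly
    assert CONTACT_BOX.contains(6.5, 9)  # both upper bounds exactly
    assert not CONTACT_BOX.contains(3.6899, 5)
    assert not CONTACT_BOX.contains(4.0, 4)
    assert LICK_BOX.contains(0.33, 1) and LICK_BOX.contains(14.29, 16)
    assert not LICK_BOX.contains(5.0, 8)  # between the union members


def test_percent_match_in_box_unit():
    # 5 cycles spanning 4.0 s and 6 syllables... build a 5-syllable 4 s unit
    from fetalvoc.events import MovementUnit
    from conftest import make_event

    events = tuple(make_event(25 * i, 25 * i + 15) for i in range(5))
    unit = MovementUnit(events)  # frames 0..115 -> 3.833 s, 5 syllables
    assert CONTACT_BOX.contains(unit.duration_s, unit.syllable_count)
    session = make_session(visible_time_s=600.0)
    session.orofacial_units = [unit]
    assert percent_match(session, CONTACT_BOX) == 100.0


def test_percent_match_counts_only_complete_units():
    session = make_session(visible_time_s=600.0)
    inbox = make_unit(0, int(4.0 * 30))  # 4.0 s single event -> 1 syllable
    session.orofacial_units = [inbox]
    # single-syllable 4 s unit misses the contact box (needs 5-9 syllables)
    assert percent_match(session, CONTACT_BOX) == 0.0
    # 1.0 s, 2 syllables twitter example
    from fetalvoc.events import MovementUnit
    from conftest import make_event

    twitterish = MovementUnit((make_event(0, 14), make_event(20, 30)))
    session.orofacial_units = [twitterish]
    assert percent_match(session, TWITTER_BOX) == 100.0
    assert percent_match(session, CONTACT_BOX) == 0.0
    # all-partial sessions are flagged
    session.orofacial_units = [make_unit(0, 100, partial=True)]
    assert math.isnan(percent_match(session, CONTACT_BOX))


def test_adjust_audio_durations():
    paired = [(1.0, 1.2), (2.0, 2.2), (3.0, 3.2)]
    assert adjust_audio_durations(paired, [5.0, 6.0]) == pytest.approx([5.2, 6.2])
    assert adjust_audio_durations([(1.0, 1.0)], [5.0]) == [5.0]
    # median oracle on mixed discrepancies
    paired = [(1.0, 1.1), (1.0, 1.5), (1.0, 1.2)]
    expected = 5.0 + float(np.median([0.1, 0.5, 0.2]))
    assert adjust_audio_durations(paired, [5.0])[0] == pytest.approx(expected)
    with pytest.raises(ValueError):
        adjust_audio_durations([], [1.0])


def test_boxes_disjoint_detects_contact_lick_sliver():
    """The printed contact and short-lick boxes genuinely share a sliver:
    durations [3.69, 3.77] s with 5 or 6 syllables lie in both."""
    assert CONTACT_BOX.contains(3.7, 5) and LICK_BOX.contains(3.7, 5)
    assert not boxes_disjoint(CONTACT_BOX, LICK_BOX)
    # contact and twitter boxes are disjoint (durations cannot meet)
    assert boxes_disjoint(CONTACT_BOX, TWITTER_BOX)
    assert boxes_disjoint(TWITTER_BOX, CriteriaBox("far", ((10.0, 12.0, 2, 3),)))


def test_likelihood_monotone_under_target_pure_refinement():
    calls = [
        call("contact", 4.0, 6, "a"),
        call("contact", 5.0, 7, "b"),
        call("lick", 1.0, 6, "c"),
    ]
    parent = CriteriaBox("p", ((0.5, 6.5, 1, 9),))
    refined = CriteriaBox("r", ((3.5, 6.5, 5, 9),))  # contains only contacts
    assert type_likelihood(calls, refined, "contact") >= type_likelihood(
        calls, parent, "contact"
    )


def test_derive_criteria_separates_clean_types():
    rng = np.random.default_rng(8)
    calls = [
        call("contact", rng.uniform(4.0, 6.0), int(rng.integers(5, 9)), f"c{i}")
        for i in range(40)
    ] + [
        call("twitter", rng.uniform(0.9, 1.6), int(rng.integers(2, 4)), f"t{i}")
        for i in range(40)
    ]
    box = derive_criteria(calls, "contact", min_capture=0.8)
    assert type_likelihood(calls, box, "contact") == 1.0
    assert box_capture(calls, box, "contact") >= 0.8


def test_call_record_validation():
    with pytest.raises(ValueError, match="duration"):
        call("contact", 0.0, 5)
    with pytest.raises(ValueError, match="syllable"):
        call("contact", 1.0, 0)
    with pytest.raises(ValueError, match="lo > hi"):
        CriteriaBox("bad", ((2.0, 1.0, 1, 2),))
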