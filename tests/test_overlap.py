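"""Percent overlap and the duration/latency-preserving permutation null."""

import numpy as np
import pytest

from fetalvoc.overlap import (
    _overlap_fraction_arrays,
    _shuffle_stream,
    average_by_day,
    percent_overlap,
    permutation_envelope,
    shuffle_session,
)
from fetalvoc.states import count_overlap_pairs

from conftest import make_session


@pytest.mark.parametrize(
    "oro, head, expected",
    [
        ([(0, 100)], [(50, 160)], 0.5),  # one overlapping pair of two units
        ([(0, 50), (100, 150)], [(200, 250), (300, 350)], 0.0),
        # 3 orofacial + 2 head with 2 overlapping pairs -> 2/5
        ([(0, 100), (200, 300), (400, 500)], [(50, 160), (250, 360)], 0.4),
    ],
)
def test_percent_overlap_examples(oro, head, expected):
    assert percent_overlap(make_session(oro, head)) == pytest.approx(expected)


def test_percent_overlap_empty_session_is_flagged():
    assert np.isnan(percent_overlap(make_session()))


def test_shuffle_preserves_unit_counts_and_marginals():
    session = make_session(
        oro_intervals=[(0, 60), (200, 290), (500, 530)],
        head_intervals=[(100, 160), (400, 420)],
        visible_time_s=600.0,
    )
    shuffled = shuffle_session(session, 7)
    assert len(shuffled.orofacial_units) == 3
    assert len(shuffled.head_units) == 2
    # durations drawn from the original multiset
    orig = {60, 90, 30}
    for u in shuffled.orofacial_units:
        assert u.offset - u.onset in orig
    # same seed -> identical output; different seed -> generally different
    again = shuffle_session(session, 7)
    assert [(u.onset, u.offset) for u in again.orofacial_units] == [
        (u.onset, u.offset) for u in shuffled.orofacial_units
    ]


def test_shuffle_returns_session_unchanged_without_both_kinds():
    session = make_session(oro_intervals=[(0, 50)])
    assert shuffle_session(session, 0) is session


def test_shuffled_duration_distribution_matches_original(rng):
    """Monte-Carlo: resampled durations reproduce the original marginal."""
    on = np.array([0, 100, 250, 400], dtype=np.int64)
    off = on + np.array([10, 30, 10, 50], dtype=np.int64)
    counts = {10: 0, 30: 0, 50: 0}
    n_draws = 0
    for _ in range(3000):
        new_on, new_off = _shuffle_stream(on, off, span=10**9, rng=rng)
        for d in new_off - new_on:
            counts[int(d)] += 1
            n_draws += 1
    # expected multiset frequencies 0.5 / 0.25 / 0.25
    assert counts[10] / n_draws == pytest.approx(0.5, abs=0.03)
    assert counts[30] / n_draws == pytest.approx(0.25, abs=0.03)
    assert counts[50] / n_draws == pytest.approx(0.25, abs=0.03)


def test_shuffle_truncates_at_session_span(rng):
    on = np.array([0], dtype=np.int64)
    off = np.array([90], dtype=np.int64)
    new_on, new_off = _shuffle_stream(on, off, span=50, rng=rng)
    assert new_on.size == 0  # the only possible rebuild crosses the span


def test_object_and_array_shuffles_agree():
    session = make_session(
        oro_intervals=[(0, 60), (200, 290)],
        head_intervals=[(100, 160), (400, 420)],
        visible_time_s=600.0,
    )
    shuffled = shuffle_session(session, 99)
    rng = np.random.default_rng(99)
    for kind in ("orofacial", "head"):
        units = session.units(kind)
        on = np.array([u.onset for u in units], dtype=np.int64)
        off = np.array([u.offset for u in units], dtype=np.int64)
        exp_on, exp_off = _shuffle_stream(on, off, session.span_frames, rng)
        got = shuffled.units(kind)
        np.testing.assert_array_equal([u.onset for u in got], exp_on)
        np.testing.assert_array_equal([u.offset for u in got], exp_off)


def test_overlap_fraction_fast_path_agrees_with_state_coding(rng):
    for _ in range(30):
        n_o, n_h = rng.integers(1, 12, 2)
        session = make_session(
            sorted(
                (int(a), int(a) + int(d))
                for a, d in zip(rng.integers(0, 5000, n_o), rng.integers(2, 80, n_o))
            ),
            sorted(
                (int(a), int(a) + int(d))
                for a, d in zip(rng.integers(0, 5000, n_h), rng.integers(2, 80, n_h))
            ),
            visible_time_s=600.0,
        )
        expected = percent_overlap(session)
        on_o = np.array([u.onset for u in session.orofacial_units], np.int64)
        off_o = np.array([u.offset for u in session.orofacial_units], np.int64)
        on_h = np.array([u.onset for u in session.head_units], np.int64)
        off_h = np.array([u.offset for u in session.head_units], np.int64)
        assert _overlap_fraction_arrays(on_o, off_o, on_h, off_h) == pytest.approx(
            expected
        )


def test_average_by_day_ignores_nan():
    days = [93, 93, 95, 95]
    vals = [0.2, 0.4, np.nan, 0.6]
    grid, means = average_by_day(days, vals)
    np.testing.assert_array_equal(grid, [93, 95])
    np.testing.assert_allclose(means, [0.3, 0.6])


def _tiny_cohort():
    sessions = []
    rng = np.random.default_rng(0)
    for p in range(2):
        for i, day in enumerate((95, 110, 125, 140)):
            n = 6
            oro = sorted(int(a) for a in rng.integers(0, 15000, n))
            head = sorted(int(a) for a in rng.integers(0, 15000, n))
            sessions.append(
                make_session(
                    [(a, a + 30) for a in oro],
                    [(a, a + 20) for a in head],
                    visible_time_s=600.0,
                    session=f"P{p}_{day}",
                    pregnancy=f"P{p}",
                    day=day,
                )
            )
    return sessions


def test_envelope_single_replicate_collapses():
    sessions = _tiny_cohort()
    env = permutation_envelope(sessions, n_reps=1, seed=3)
    np.testing.assert_allclose(env.mean, env.lower)
    np.testing.assert_allclose(env.mean, env.upper)


def test_envelope_is_ordered_and_deterministic():
    sessions = _tiny_cohort()
    env1 = permutation_envelope(sessions, n_reps=50, seed=5)
    env2 = permutation_envelope(sessions, n_reps=50, seed=5)
    np.testing.assert_array_equal(env1.mean, env2.mean)
    np.testing.assert_array_equal(env1.slopes, env2.slopes)
    assert np.all(env1.lower <= env1.mean + 1e-12)
    assert np.all(env1.mean <= env1.upper + 1e-12)
    assert env1.slope_ci[0] <= env1.slope_ci[1]
    assert 0 <= env1.mean_line_p <= 1
    with pytest.raises(ValueError):
        permutation_envelope(sessions, n_reps=0)
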