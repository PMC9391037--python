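"""Profile conditioning, DTW, DBA templates, and template matching."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from fetalvoc.profiles import (
    CallTemplate,
    TemporalProfile,
    count_profile_syllables,
    dba_barycenter,
    dba_template,
    dtw_cost,
    dtw_path,
    match_to_templates,
    quality_gate,
    session_median_dtw,
    smooth_savgol,
    smooth_spline,
    zscore,
)
from fetalvoc.synthetic import ProfileSpec, generate_profile


# ---------------------------------------------------------------- smoothing
def test_savgol_preserves_cubics_and_constants():
    t = np.linspace(-1, 1, 50)
    cubic = 0.3 * t**3 - t**2 + 2 * t + 1
    np.testing.assert_allclose(smooth_savgol(cubic), cubic, atol=1e-9)
    np.testing.assert_allclose(smooth_savgol(np.full(20, 2.5)), 2.5, atol=1e-12)


def test_savgol_matches_direct_sliding_leastsquares(rng):
    """Interior samples equal the center of a local cubic least-squares fit."""
    y = np.sin(np.linspace(0, 6, 60)) + rng.normal(0, 0.2, 60)
    out = smooth_savgol(y, poly_degree=3, window=9)
    half = 4
    for i in range(half, 60 - half):
        seg = y[i - half : i + half + 1]
        coef = np.polyfit(np.arange(-half, half + 1), seg, 3)
        assert out[i] == pytest.approx(np.polyval(coef, 0), abs=1e-9)


def test_savgol_rejects_bad_parameters():
    with pytest.raises(ValueError, match="odd"):
        smooth_savgol(np.arange(20.0), window=8)
    with pytest.raises(ValueError, match="too short"):
        smooth_savgol(np.arange(5.0), window=9)


def test_spline_smoothing_limits():
    rng = np.random.default_rng(0)
    y = rng.normal(0, 1, 30)
    # p = 1 interpolates the data at the knots
    np.testing.assert_allclose(smooth_spline(y, 1.0), y, atol=1e-8)
    # p = 0 is the least-squares line
    x = np.arange(30.0)
    line = np.polyval(np.polyfit(x, y, 1), x)
    np.testing.assert_allclose(smooth_spline(y, 0.0), line, atol=1e-8)
    # p -> 0 tends to the same line
    np.testing.assert_allclose(smooth_spline(y, 1e-9), line, atol=1e-3)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        smooth_spline(y, 1.5)


def test_spline_matches_penalized_objective_minimizer():
    """Oracle: numerically minimize p*RSS + (1-p)*int(g'')^2 over natural
    cubic splines pinned at the sample grid."""
    rng = np.random.default_rng(3)
    y = np.sin(np.linspace(0, 3, 12)) + rng.normal(0, 0.3, 12)
    x = np.arange(12.0)
    p = 0.2

    def bending_energy(g):
        cs = CubicSpline(x, g, bc_type="natural")
        m = cs(x, 2)  # second derivative at the knots, piecewise linear
        h = np.diff(x)
        return float(np.sum(h / 3.0 * (m[:-1] ** 2 + m[:-1] * m[1:] + m[1:] ** 2)))

    def objective(g):
        return p * np.sum((y - g) ** 2) + (1 - p) * bending_energy(g)

    res = minimize(objective, y, method="BFGS", options={"gtol": 1e-12, "maxiter": 2000})
    np.testing.assert_allclose(smooth_spline(y, p), res.x, atol=1e-5)


# ---------------------------------------------------------------- DTW
def brute_force_dtw(a, b):
    """Exhaustive enumeration of monotone warping paths (tiny inputs only)."""
    best = [np.inf]

    def walk(i, j, acc):
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = acc
            return
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, acc)
        if i + 1 < len(a):
            walk(i + 1, j, acc)
        if j + 1 < len(b):
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def test_dtw_identity_symmetry_reversal(rng):
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(2, 30))
        b = rng.normal(0, 1, rng.integers(2, 30))
        assert dtw_cost(a, a) == pytest.approx(0.0, abs=1e-12)
        assert dtw_cost(a, b) == pytest.approx(dtw_cost(b, a))
        # joint time reversal leaves the cost unchanged
        assert dtw_cost(a[::-1], b[::-1]) == pytest.approx(dtw_cost(a, b))
        assert dtw_cost(a, b) >= 0


def test_dtw_matches_bruteforce_enumeration(rng):
    assert dtw_cost([0.0, 1.0, 2.0], [0.0, 2.0]) == pytest.approx(
        brute_force_dtw([0.0, 1.0, 2.0], [0.0, 2.0])
    )
    for _ in range(50):
        a = rng.normal(0, 1, rng.integers(2, 7))
        b = rng.normal(0, 1, rng.integers(2, 7))
        assert dtw_cost(a, b) == pytest.approx(brute_force_dtw(a, b))


def test_dtw_path_is_valid_and_consistent(rng):
    a = rng.normal(0, 1, 12)
    b = rng.normal(0, 1, 9)
    path = dtw_path(a, b)
    assert path[0] == (0, 0) and path[-1] == (11, 8)
    for (i0, j0), (i1, j1) in zip(path, path[1:]):
        assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}
    assert sum(abs(a[i] - b[j]) for i, j in path) == pytest.approx(dtw_cost(a, b))


def test_dtw_normalization_and_resampling():
    a = np.array([0.0, 1.0, 0.0, 1.0])
    b = np.array([0.0, 0.5, 1.0])
    assert dtw_cost(a, b, normalize=True) == pytest.approx(dtw_cost(a, b) / 7)
    # refined sequences of a straight line still match exactly
    line = np.linspace(0, 1, 5)
    assert dtw_cost(line, line, resample_factor=4) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        dtw_cost(a, np.array([]))


# ---------------------------------------------------------------- DBA
def test_dba_fixed_points():
    p = np.sin(np.linspace(0, 3, 40))
    # a single sequence is its own barycenter
    np.testing.assert_allclose(dba_barycenter([p]), p)
    # k identical sequences reproduce the sequence for any k
    for k in (2, 5):
        np.testing.assert_allclose(dba_barycenter([p.copy() for _ in range(k)]), p)


def test_dba_cost_not_worse_than_medoid(rng):
    seqs = [np.sin(np.linspace(0, 3, 30)) + rng.normal(0, 0.3, 30) for _ in range(6)]
    center = dba_barycenter(seqs)
    total = sum(dtw_cost(center, s) for s in seqs)
    medoid_total = min(sum(dtw_cost(c, s) for s in seqs) for c in seqs)
    assert total <= medoid_total + 1e-9


def test_dba_template_checks_syllable_counts():
    a = TemporalProfile(np.sin(np.linspace(0, 3, 30)), syllable_count=2)
    b = TemporalProfile(np.sin(np.linspace(0, 3, 30)), syllable_count=3)
    with pytest.raises(ValueError, match="mix"):
        dba_template([a, b])
    with pytest.raises(ValueError, match="at least one"):
        dba_template([])
    t = dba_template([a])
    assert t.syllable_count == 2


# ---------------------------------------------------------------- matching
def _templates():
    return [
        CallTemplate(k, np.sin(np.linspace(0, k * np.pi, 20 + 10 * k)))
        for k in range(1, 4)
    ]


def test_match_returns_zero_cost_for_exact_template():
    templates = _templates()
    p = TemporalProfile(templates[1].values.copy(), profile_id="x")
    m = match_to_templates(p, templates)
    assert m.best_template_syllables == 2
    assert m.cost == pytest.approx(0.0, abs=1e-12)


def test_match_argmin_agrees_with_explicit_loop(rng):
    templates = _templates()
    for _ in range(20):
        p = TemporalProfile(rng.normal(0, 1, 35))
        m = match_to_templates(p, templates)
        costs = {
            t.syllable_count: dtw_cost(p.values, t.values, normalize=True)
            for t in templates
        }
        assert m.cost == pytest.approx(min(costs.values()))
        assert costs[m.best_template_syllables] == pytest.approx(m.cost)


def test_match_tie_breaks_toward_fewer_syllables():
    v = np.sin(np.linspace(0, 3, 25))
    templates = [CallTemplate(5, v.copy()), CallTemplate(2, v.copy())]
    m = match_to_templates(TemporalProfile(v.copy()), templates)
    assert m.best_template_syllables == 2
    with pytest.raises(ValueError):
        match_to_templates(TemporalProfile(v), [])


def test_session_median_matches_sort_oracle(rng):
    from fetalvoc.profiles import DtwMatch

    matches = []
    per_session = {"a": [1.0, 2.0, 3.0], "b": [4.0], "c": [1.0, 2.0, 3.0, 10.0]}
    for sid, costs in per_session.items():
        for c in costs:
            matches.append(DtwMatch("p", sid, 100, 1, c))
    med = session_median_dtw(matches)
    assert med["a"] == 2.0
    assert med["b"] == 4.0
    # even count: mean of the central pair after sorting
    s = sorted(per_session["c"])
    assert med["c"] == pytest.approx(0.5 * (s[1] + s[2]))


# ---------------------------------------------------------------- gating
@pytest.mark.parametrize("k", [1, 3, 5, 7])
def test_clean_profiles_count_their_cycles(k):
    spec = ProfileSpec(syllable_count=k, noise_sd=0.0, warp_amplitude=0.0)
    p = generate_profile(spec, np.random.default_rng(7))
    assert count_profile_syllables(p.values) == k


def test_quality_gate_checks_length_and_count_agreement():
    good = generate_profile(
        ProfileSpec(syllable_count=3, noise_sd=0.0, warp_amplitude=0.0),
        np.random.default_rng(1),
    )
    short = TemporalProfile(np.array([0.0, 1.0, 0.0]), syllable_count=1)
    mislabeled = TemporalProfile(good.values.copy(), syllable_count=6)
    gated = quality_gate([good, short, mislabeled])
    assert [p.quality_ok for p in gated] == [True, False, False]


def test_zscore_and_validation():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    z = zscore(v)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="constant"):
        zscore(np.ones(5))
    with pytest.raises(ValueError, match="length"):
        TemporalProfile(np.array([1.0]))
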