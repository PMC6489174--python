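"""Closed-form model: printed anchors, limits, estimator round trips."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from truncal.analytic import (
    AnalyticQuery,
    CoincidenceProfile,
    coincidence_profile,
    equidistant_pattern_n,
    estimate_f,
    expected_coincidence,
    monte_carlo_oracle,
    p_finite_branches,
    p_single_bifurcation,
    p_truncal,
    samples_needed,
)

F_GRID = np.linspace(0.01, 0.99, 99)


@pytest.mark.parametrize(
    "f, n, expected",
    [(0.5, 1, 0.5), (0.0, 7, 1.0), (0.1, 2, 0.99)],
)
def test_single_bifurcation_values(f, n, expected):
    assert p_single_bifurcation(f, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "f, n, M, expected",
    [
        (0.5, 2, 1, 0.75),  # reduces to the single-bifurcation form
        (0.5, 2, 2, 0.6875),  # 1 - 0.25 - (0.25)^2 by hand
    ],
)
def test_finite_branches_values(f, n, M, expected):
    assert p_finite_branches(f, n, M) == pytest.approx(expected, abs=1e-12)


def test_finite_branches_converges_to_geometric_limit():
    assert p_finite_branches(0.5, 2, 50) == pytest.approx(
        p_truncal(0.5, 2), abs=1e-12
    )
    assert p_finite_branches(0.5, 2, "inf") == p_truncal(0.5, 2)


@pytest.mark.parametrize(
    "f, n, expected",
    [
        (0.1, 3, 0.27 / 0.271),  # > 98% with three samples
        (0.5, 6, 62 / 63),  # > 98% with six samples
        (0.3, 1, 0.0),  # one sample always sits in one branch
        (0.9, 1, 0.0),
        (1.0, 5, 0.0),
        (0.0, 1, 0.0),  # analytic limits at f=0
        (0.0, 2, 1.0),
    ],
)
def test_truncal_probability_values(f, n, expected):
    assert p_truncal(f, n) == pytest.approx(expected, abs=1e-12)
    assert p_truncal(0.1, 3) > 0.98


@pytest.mark.parametrize("bad_call", [
    lambda: p_single_bifurcation(-0.1, 2),
    lambda: p_single_bifurcation(1.5, 2),
    lambda: p_single_bifurcation(0.5, 0),
    lambda: p_finite_branches(0.5, 2, 0),
    lambda: p_truncal(float("nan"), 2),
    lambda: samples_needed(0.5, 1.0),
    lambda: samples_needed(0.0, 0.9),
    lambda: equidistant_pattern_n(1.0),
    lambda: AnalyticQuery(0.5, 2, "three"),
])
def test_domain_errors(bad_call):
    with pytest.raises(ValueError):
        bad_call()


def test_query_accepts_infinite_branch_count():
    assert AnalyticQuery(0.5, 2, "inf").M == math.inf
    assert AnalyticQuery(0.5, 2).M == math.inf


@given(
    f=st.floats(0.01, 0.99),
    n=st.integers(1, 40),
    M=st.integers(1, 30),
)
def test_finite_branch_properties(f, n, M):
    """M=1 reduces to the single bifurcation; more branches only hurt;
    the geometric limit is approached from above within (1-f)^(nM)."""
    p1 = p_finite_branches(f, n, 1)
    assert p1 == pytest.approx(p_single_bifurcation(f, n), abs=1e-12)
    pm = p_finite_branches(f, n, M)
    assert pm <= p1 + 1e-12
    assert pm >= p_finite_branches(f, n, M + 1) - 1e-12
    limit = p_truncal(f, n)
    assert pm >= limit - 1e-12
    assert abs(pm - limit) <= (1.0 - f) ** (n * M) + 1e-12


def test_equation_consistency_on_grid():
    """Exhaustive grid check of the reduction, ordering and error bound."""
    for f in F_GRID:
        for n in range(1, 41):
            assert p_finite_branches(f, n, 1) == pytest.approx(
                p_single_bifurcation(f, n), abs=1e-12
            )
            for M in (2, 5, 20):
                gap = p_finite_branches(f, n, M) - p_truncal(f, n)
                assert -1e-12 <= gap <= (1.0 - f) ** (n * M) + 1e-12


def test_truncal_probability_increases_with_samples():
    for f in F_GRID:
        assert p_truncal(f, 1) == 0.0
        previous = 0.0
        for n in range(2, 41):
            current = p_truncal(f, n)
            # strictly increasing until it saturates at 1 in float precision
            assert current > previous or (current == previous == 1.0)
            previous = current


@pytest.mark.parametrize(
    "f, target, expected",
    [(0.1, 0.98, 3), (0.5, 0.98, 6), (0.9, 0.98, 38)],
)
def test_samples_needed_anchors(f, target, expected):
    n = samples_needed(f, target)
    assert n == expected
    assert p_truncal(f, n) > target
    assert p_truncal(f, n - 1) <= target if n > 1 else True


def test_samples_needed_monotone():
    assert samples_needed(0.3, 0.98) <= samples_needed(0.6, 0.98)
    assert samples_needed(0.5, 0.9) <= samples_needed(0.5, 0.99)


@pytest.mark.parametrize("f, expected", [(0.9, 10), (0.5, 2), (0.0, 1)])
def test_equidistant_pattern_n(f, expected):
    assert equidistant_pattern_n(f) == expected


def test_coincidence_profile_identical_sets():
    prof = coincidence_profile([{1, 2, 3}] * 4)
    assert prof.n_total == 4
    assert prof.ratios == {2: 1.0, 3: 1.0}


def test_coincidence_profile_hand_enumeration():
    # grand intersection {A}; of the three pairs only two intersect to {A}
    prof = coincidence_profile([{"A", "B"}, {"A", "B"}, {"A"}])
    assert prof.ratios == {2: pytest.approx(2 / 3)}


def test_coincidence_profile_disjoint_beyond_trunk():
    # private mutations never co-occur: every subset already hits the trunk
    sets = [{0, 10}, {0, 11}, {0, 12}, {0, 13}]
    prof = coincidence_profile(sets)
    assert all(r == 1.0 for r in prof.ratios.values())


def test_coincidence_profile_needs_three_sets():
    with pytest.raises(ValueError):
        coincidence_profile([{0}, {0}])


def test_coincidence_profile_subsampled_matches_exact():
    sets = [{0, 1}, {0, 1}, {0, 2}, {0}, {0, 1, 2}]
    exact = coincidence_profile(sets)
    sampled = coincidence_profile(sets, max_exact=3, n_subsets=4000, seed=1)
    for i, r in exact.ratios.items():
        assert sampled.ratios[i] == pytest.approx(r, abs=0.05)


@pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
@pytest.mark.parametrize("n_total", [4, 6, 10])
def test_estimate_f_round_trip(f, n_total):
    fit = estimate_f(expected_coincidence(f, n_total))
    assert not fit.degenerate
    assert fit.f_hat == pytest.approx(f, abs=1e-4)
    assert fit.residual < 1e-10


def test_estimate_f_degenerate_on_full_concordance():
    prof = CoincidenceProfile(n_total=5, ratios={2: 1.0, 3: 1.0, 4: 1.0})
    fit = estimate_f(prof)
    assert fit.degenerate
    assert fit.f_hat <= 1e-3


def test_estimate_f_rejects_empty_profile():
    with pytest.raises(ValueError):
        estimate_f(CoincidenceProfile(n_total=5, ratios={}))


def test_oracle_matches_closed_form():
    res = monte_carlo_oracle(0.5, 2, 2, reps=100_000, seed=1)
    assert abs(res.estimate - 0.6875) <= 3 * res.se
    res1 = monte_carlo_oracle(0.5, 1, 1, reps=10_000, seed=2)
    assert abs(res1.estimate - 0.5) <= 3 * res1.se


def test_oracle_boundaries():
    assert monte_carlo_oracle(0.0, 3, 5, reps=1000, seed=0).estimate == 1.0
    assert monte_carlo_oracle(1.0, 3, 5, reps=1000, seed=0).estimate == 0.0


def test_oracle_many_samples_high_f():
    res = monte_carlo_oracle(0.9, 38, 200, reps=100_000, seed=3)
    assert res.estimate > 0.98 - 3 * res.se
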