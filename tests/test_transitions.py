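"""Median-to-probability conversion and transition-matrix assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    build_transition_matrix,
    monthly_risk,
    param_range,
    prob_from_rate,
    probability_table,
    rate_from_prob,
)


class TestMonthlyRisk:
    @pytest.mark.parametrize(
        "median, expected",
        [
            (14, 0.048),  # OPD DFS -> PD
            (22, 0.031),  # OPD DFS -> D
            (8, 0.083),  # OPD PD -> D (post-progression median 22 - 14)
            (15, 0.045),
            (24, 0.028),
            (9, 0.074),
            (1, 0.5),  # a one-cycle median halves the cohort each month
        ],
    )
    def test_published_values_at_3_decimals(self, median, expected):
        assert round(monthly_risk(median), 3) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0, -3, float("nan"), float("inf")])
    def test_rejects_nonpositive_median(self, bad):
        with pytest.raises(ValueError):
            monthly_risk(bad)

    @settings(derandomize=True)
    @given(st.floats(0.05, 1000), st.floats(0.05, 1000))
    def test_strictly_decreasing_in_median_and_in_unit_interval(self, m1, m2):
        p1, p2 = monthly_risk(m1), monthly_risk(m2)
        assert 0 < p1 < 1
        if m2 > m1 * (1 + 1e-9):
            assert p1 > p2


class TestRateProbConversion:
    def test_known_points(self):
        assert prob_from_rate(0.0) == 0.0
        assert prob_from_rate(math.log(2)) == pytest.approx(0.5)
        assert round(prob_from_rate(math.log(2) / 22), 3) == pytest.approx(0.031)

    @settings(derandomize=True)
    @given(st.floats(0, 6))
    def test_roundtrip_identity(self, rate):
        assert rate_from_prob(prob_from_rate(rate)) == pytest.approx(rate, abs=1e-12)

    def test_unit_probability_is_infinite_rate(self):
        with pytest.raises(ValueError):
            rate_from_prob(1.0)


class TestBuildTransitionMatrix:
    def test_replicates_median_derived_rows(self):
        tm = build_transition_matrix(14, 22)
        assert round(tm.p_dfs_dfs, 3) == 0.921
        assert round(tm.p_dfs_pd, 3) == 0.048
        assert round(tm.p_dfs_d, 3) == 0.031
        assert round(tm.p_pd_d, 3) == 0.083

    def test_zero_post_progression_survival_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(10, 10)

    def test_sub_half_cycle_post_progression_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            build_transition_matrix(10, 10.3)

    def test_short_medians_rejected_by_direct_arithmetic_only(self):
        # direct per-median risks overcount DFS exits at sub-cycle medians
        with pytest.raises(ValueError, match="too short"):
            build_transition_matrix(0.625, 1.625)
        tm = build_transition_matrix(0.625, 1.625, competing_risks=True)
        assert tm.p_dfs_pd + tm.p_dfs_d <= 1.0

    @settings(derandomize=True)
    @given(
        st.floats(2.0, 200),
        st.floats(1.0, 200),
        st.booleans(),
    )
    def test_row_stochastic_for_any_valid_medians(self, m_dfs, extra, competing):
        m_os = m_dfs + extra
        tm = build_transition_matrix(m_dfs, m_os, competing_risks=competing)
        P = tm.matrix
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((P >= 0) & (P <= 1))
        # structural zeros: no recovery from PD, death absorbing
        assert P[1, 0] == 0 and P[2, 0] == 0 and P[2, 1] == 0 and P[2, 2] == 1

    def test_competing_risks_preserves_total_dfs_exit(self):
        tm = build_transition_matrix(14, 22, competing_risks=True)
        assert tm.p_dfs_pd + tm.p_dfs_d == pytest.approx(monthly_risk(14), abs=1e-14)
        # death gets the cause-specific share of the exit rate
        assert tm.p_dfs_d / (tm.p_dfs_pd + tm.p_dfs_d) == pytest.approx(14 / 22)


class TestParamRange:
    @pytest.mark.parametrize(
        "baseline, cap, expected",
        [
            (0.921, 1.0, (0.737, 1.0)),
            (0.048, 1.0, (0.038, 0.058)),
            (0.0, 1.0, (0.0, 0.0)),
            (100.0, None, (80.0, 120.0)),  # costs uncapped
        ],
    )
    def test_bounds(self, baseline, cap, expected):
        lo, hi = param_range(baseline, 0.20, cap=cap)
        assert (round(lo, 3), round(hi, 3)) == expected

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            param_range(-0.1)


# all ten baseline probabilities and their one-way bounds, per strategy
PUBLISHED_TABLE = {
    (14, 22): [
        ("p_dfs_dfs", 0.921, 0.737, 1.0),
        ("p_dfs_pd", 0.048, 0.038, 0.058),
        ("p_dfs_d", 0.031, 0.025, 0.037),
        ("p_pd_pd", 0.917, 0.734, 1.0),
        ("p_pd_d", 0.083, 0.066, 0.100),
    ],
    (15, 24): [
        ("p_dfs_dfs", 0.927, 0.742, 1.0),
        ("p_dfs_pd", 0.045, 0.036, 0.054),
        ("p_dfs_d", 0.028, 0.022, 0.034),
        ("p_pd_pd", 0.926, 0.741, 1.0),
        ("p_pd_d", 0.074, 0.059, 0.089),
    ],
}


@pytest.mark.parametrize("medians", list(PUBLISHED_TABLE))
def test_probability_table_reproduces_published_values(medians):
    """Both strategy blocks, from the two medians alone, to 3 decimals."""
    df = probability_table(*medians).set_index("transition")
    for name, base, lo, hi in PUBLISHED_TABLE[medians]:
        row = df.loc[name]
        assert row["baseline"] == pytest.approx(base, abs=5e-4)
        assert row["lower"] == pytest.approx(lo, abs=5e-4)
        assert row["upper"] == pytest.approx(hi, abs=5e-4)
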