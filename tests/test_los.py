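"""Unit and property tests for the geometric LOS / marketing-impact algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sheltersim import los

positive_odds = st.floats(min_value=1e-6, max_value=1e3)
multipliers = st.floats(min_value=1e-3, max_value=50.0)


class TestBaselineAlgebra:
    @pytest.mark.parametrize(
        "d, p", [(1.0, 0.5), (0.5, 1 / 3), (0.0385, 0.0371)],
    )
    def test_adoption_probability_worked_values(self, d, p):
        assert los.adoption_probability(d) == pytest.approx(p, abs=5e-4)

    @pytest.mark.parametrize("d, q", [(1.0, 0.5), (0.5, 2 / 3), (1e-9, 1.0)])
    def test_nonadoption_probability_worked_values(self, d, q):
        assert los.nonadoption_probability(d) == pytest.approx(q, abs=1e-6)

    @pytest.mark.parametrize("d, l", [(1.0, 2.0), (0.5, 3.0), (1 / 26, 27.0)])
    def test_expected_los_worked_values(self, d, l):
        assert los.expected_los(d) == pytest.approx(l, rel=1e-12)

    @pytest.mark.parametrize("l, d", [(2.0, 1.0), (27.0, 1 / 26), (3.0, 0.5)])
    def test_los_to_odds_worked_values(self, l, d):
        assert los.los_to_odds(l) == pytest.approx(d, rel=1e-12)
        # an expected LOS of 27 days implies daily odds 0.0385
        assert round(los.los_to_odds(27.0), 4) == 0.0385

    @given(positive_odds)
    def test_probability_normalization(self, d):
        p = los.adoption_probability(d)
        q = los.nonadoption_probability(d)
        assert p + q == pytest.approx(1.0, abs=1e-15)
        assert 0.0 < p < 1.0

    @given(st.floats(min_value=2.0, max_value=1e6))
    def test_los_odds_round_trip(self, l):
        assert los.expected_los(los.los_to_odds(l)) == pytest.approx(l, rel=1e-9)

    @pytest.mark.parametrize("func", [los.adoption_probability, los.expected_los])
    @pytest.mark.parametrize("bad", [0.0, -0.5])
    def test_nonpositive_odds_rejected(self, func, bad):
        with pytest.raises(ValueError):
            func(bad)

    @pytest.mark.parametrize("bad", [1.0, 0.5, -3.0])
    def test_los_at_most_one_day_rejected(self, bad):
        with pytest.raises(ValueError):
            los.los_to_odds(bad)

    def test_sub_two_day_los_warns(self):
        with pytest.warns(UserWarning):
            assert los.los_to_odds(1.5) == pytest.approx(2.0)

    def test_geometric_sampling_recovers_expected_los(self):
        """Simulated geometric stays (success prob P) average to L."""
        rng = np.random.default_rng(2024)
        d = 1 / 26
        p = los.adoption_probability(d)
        draws = rng.geometric(p, size=100_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - los.expected_los(d)) < 3 * se


def brute_force_marketed_los(a: float, d: float) -> float:
    """Expectation of the two-regime geometric stay, by direct summation.

    Day 1 is adopted with probability P(AD); day k >= 2 requires surviving
    day 1 (prob Q(AD)) and k-2 baseline days (prob Q(D) each) before a
    baseline adoption (prob P(D)).  Truncated when the remaining tail is
    negligible.
    """
    p1 = a * d / (1 + a * d)
    q1 = 1 / (1 + a * d)
    p = d / (1 + d)
    q = 1 / (1 + d)
    total = 1.0 * p1
    survive = q1
    k = 2
    while survive * (k + 2.0 / p) > 1e-13:
        total += k * survive * p
        survive *= q
        k += 1
        assert k < 10_000
    return total


class TestMarketingImpact:
    @pytest.mark.parametrize(
        "a, d, expected",
        [
            (1.0, 0.7, 0.0),
            (1.6, 1.0, -0.6 / 2.6),
            (4.0, 1 / 29, -3.0 / (1 + 4 / 29)),
            (1.6, 1e-6, -0.6),
        ],
    )
    def test_one_day_impact_worked_values(self, a, d, expected):
        assert los.one_day_impact(a, d) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize(
        "a, d", [(1.6, 1.0), (4.0, 1.0), (2.0, 0.3), (0.5, 0.5), (1.2, 1 / 26)]
    )
    def test_marketed_los_matches_brute_force_expectation(self, a, d):
        assert los.marketed_los_one_day(a, d) == pytest.approx(
            brute_force_marketed_los(a, d), abs=1e-8
        )

    @given(multipliers, positive_odds)
    def test_impact_is_marketed_minus_baseline_los(self, a, d):
        lhs = los.marketed_los_one_day(a, d) - los.expected_los(d)
        assert lhs == pytest.approx(los.one_day_impact(a, d), rel=1e-9, abs=1e-9)

    @given(
        st.floats(min_value=1.0 + 1e-6, max_value=50.0),
        positive_odds,
        st.floats(min_value=1e-6, max_value=10.0),
    )
    def test_impact_magnitude_grows_with_baseline_los(self, a, d, delta):
        """For a boost A > 1, X is strictly increasing in D (|X| in L)."""
        assert los.one_day_impact(a, d + delta) > los.one_day_impact(a, d)

    @given(multipliers, positive_odds)
    def test_impact_sign_flips_at_unit_multiplier(self, a, d):
        x = los.one_day_impact(a, d)
        z = los.windowed_impact(a, d)
        if a > 1:
            assert x < 0 and z < 0
        elif a < 1:
            assert x > 0 and z > 0
        else:
            assert x == 0 and z == 0

    @pytest.mark.parametrize("lam", [0.01, 1.0, 10.0])
    @pytest.mark.parametrize("a, expected", [(1.0, 0.0), (1.6, -0.6), (5.0, -4.0)])
    def test_exponential_impact_is_rate_independent(self, lam, a, expected):
        assert los.exponential_rate_impact(a, lam) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        for func in (los.one_day_impact, los.windowed_odds, los.windowed_impact):
            with pytest.raises(ValueError):
                func(0.0, 1.0)
            with pytest.raises(ValueError):
                func(2.0, -1.0)
        with pytest.raises(ValueError):
            los.exponential_rate_impact(1.5, 0.0)


class TestWindowedModel:
    @pytest.mark.parametrize(
        "a, d, expected", [(1.0, 0.7, 0.7), (2.0, 1.0, 3.0), (3.0, 0.1, 0.331)]
    )
    def test_windowed_odds_worked_values(self, a, d, expected):
        assert los.windowed_odds(a, d) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(min_value=1.0 + 1e-6, max_value=20.0), positive_odds)
    def test_windowed_odds_exceed_proportional_odds_for_boosts(self, a, d):
        assert los.windowed_odds(a, d) > a * d * (1 - 1e-12)

    @pytest.mark.parametrize("a, d, expected", [(1.0, 0.4, 0.0), (2.0, 1.0, -0.5)])
    def test_windowed_impact_worked_values(self, a, d, expected):
        assert los.windowed_impact(a, d) == pytest.approx(expected, abs=1e-12)

    @given(multipliers, positive_odds)
    def test_windowed_impact_printed_forms_agree(self, a, d):
        """((1+D)^(1-A) - 1)/D equals (1 + 1/D)/(1+D)^A - 1/D."""
        alt = (1 + 1 / d) / (1 + d) ** a - 1 / d
        assert los.windowed_impact(a, d) == pytest.approx(alt, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("a", [1.2, 1.6, 2.0, 5.0])
    def test_small_odds_limits(self, a):
        """Both impact formulations approach 1 - A as D -> 0."""
        assert abs(los.one_day_impact(a, 1e-8) - (1 - a)) < 1e-6
        assert abs(los.windowed_impact(a, 1e-8) - (1 - a)) < 1e-6

    def test_windowed_matches_one_day_for_small_odds(self):
        # Z - X = A(1-A)D/2 + O(D^2): agreement at A = 1.6 is within 1e-3
        # at D = 1e-3, and the gap shrinks linearly in D everywhere
        assert abs(los.windowed_impact(1.6, 1e-3) - los.one_day_impact(1.6, 1e-3)) < 1e-3
        for a in np.linspace(1.2, 5.0, 12):
            for d in (1e-3, 1e-4):
                diff = los.windowed_impact(a, d) - los.one_day_impact(a, d)
                assert abs(diff) <= a * (a - 1) * d
            ratio = abs(
                los.windowed_impact(a, 1e-4) - los.one_day_impact(a, 1e-4)
            ) / abs(los.windowed_impact(a, 1e-3) - los.one_day_impact(a, 1e-3))
            assert ratio == pytest.approx(0.1, rel=0.05)


class TestImpactCurve:
    def test_matches_pointwise_impacts(self):
        table = los.impact_curve([1.6, 4.0], [2.0, 30.0], variant="one_day")
        assert list(table.columns) == [
            "variant", "A", "baseline_L", "baseline_D", "impact_per_day",
        ]
        assert len(table) == 4
        by_key = {
            (row.A, row.baseline_L): row.impact_per_day for row in table.itertuples()
        }
        assert by_key[(1.6, 2.0)] == pytest.approx(-0.2308, abs=5e-4)
        assert by_key[(1.6, 30.0)] == pytest.approx(-0.5686, abs=5e-4)
        assert by_key[(4.0, 2.0)] == pytest.approx(-0.60, abs=5e-4)
        assert by_key[(4.0, 30.0)] == pytest.approx(-2.636, abs=5e-4)

    def test_unit_multiplier_rows_are_zero(self):
        for variant in ("one_day", "windowed"):
            table = los.impact_curve([1.0], np.arange(2, 31, 0.5), variant=variant)
            assert np.allclose(table["impact_per_day"], 0.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            los.impact_curve([], [2.0])
        with pytest.raises(ValueError):
            los.impact_curve([1.5], [])
        with pytest.raises(ValueError):
            los.impact_curve([1.5], [2.0], variant="weekly")
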