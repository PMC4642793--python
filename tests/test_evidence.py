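"""Evidence layer: modes, HDIs, directional odds, Bayes factors, categories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from respmix.evidence import (
    directional_odds,
    evidence_table,
    hdi,
    jeffreys_category,
    posterior_mode,
    read_evidence_csv,
    savage_dickey_bf10,
    write_evidence_csv,
)

STD_NORMAL_AT_ZERO = 1 / math.sqrt(2 * math.pi)  # 0.39894


class TestPosteriorMode:
    def test_normal_mode_recovered(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.83, 0.1, 50000)
        assert abs(posterior_mode(draws) - 0.83) < 0.05

    def test_symmetric_mode_near_mean(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(2.0, 1.0, 20000)
        assert abs(posterior_mode(draws) - draws.mean()) < 0.1

    def test_constant_draws(self):
        assert posterior_mode(np.full(500, 3.25)) == 3.25

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            posterior_mode(np.arange(50))


class TestHdi:
    def test_standard_normal_endpoints(self):
        rng = np.random.default_rng(2)
        lo, hi = hdi(rng.standard_normal(100000), 0.95)
        assert abs(lo + 1.96) < 0.05 and abs(hi - 1.96) < 0.05

    def test_uniform_width(self):
        rng = np.random.default_rng(3)
        lo, hi = hdi(rng.random(100000), 0.95)
        assert abs((hi - lo) - 0.95) < 0.02

    def test_exhaustive_mass_returns_range(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        assert hdi(x, 0.9999) == (x.min(), x.max())

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(200), 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), mass=st.floats(0.5, 0.99))
    def test_never_wider_than_equal_tailed(self, seed, mass):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 1.0, 2000)  # skewed sample
        lo, hi = hdi(x, mass)
        q_lo, q_hi = np.quantile(x, [(1 - mass) / 2, (1 + mass) / 2])
        assert hi - lo <= (q_hi - q_lo) + 1e-9

    def test_matches_equal_tailed_for_symmetric_samples(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100000)
        lo, hi = hdi(x, 0.9)
        q_lo, q_hi = np.quantile(x, [0.05, 0.95])
        assert abs(lo - q_lo) < 0.05 and abs(hi - q_hi) < 0.05


class TestDirectionalOdds:
    def test_direct_count(self):
        # 3 negative draws to 1 positive
        res = directional_odds(np.tile([-1.0, -2.0, -3.0, 1.0], 25))
        assert res.value == pytest.approx(3.0)
        assert res.sign == "-"
        assert not res.saturated

    def test_tie(self):
        res = directional_odds(np.tile([-1.0, 1.0], 50))
        assert res == (1.0, "tie", False)

    def test_zeros_split_between_sides(self):
        draws = np.tile([1.0, 1.0, 0.0, 0.0, -1.0], 20)  # p+ = 0.6
        res = directional_odds(draws)
        assert res.value == pytest.approx(0.6 / 0.4)
        assert res.sign == "+"

    def test_one_sided_draws_are_floored_and_flagged(self):
        res = directional_odds(np.abs(np.random.default_rng(0).standard_normal(200)) + 0.1)
        assert res.saturated
        assert res.value == pytest.approx(1.0 / (1.0 / 400))

    def test_matches_counting_oracle_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.normal(rng.normal(), 1.0, size=rng.integers(100, 500))
            res = directional_odds(x)
            p_plus = (np.sum(x > 0) + 0.5 * np.sum(x == 0)) / len(x)
            p_minus = 1 - p_plus
            if p_plus == p_minus:
                assert res == (1.0, "tie", False)
            else:
                floor = 1 / (2 * len(x))
                expected = max(p_plus, p_minus) / max(min(p_plus, p_minus), floor)
                assert res.value == pytest.approx(expected)
                assert res.sign == ("+" if p_plus > p_minus else "-")


class TestSavageDickey:
    def test_posterior_equal_to_prior_gives_unit_bf(self):
        rng = np.random.default_rng(8)
        bf = savage_dickey_bf10(rng.standard_normal(50000), STD_NORMAL_AT_ZERO)
        assert abs(bf - 1.0) < 0.1

    def test_concentrated_null_posterior(self):
        rng = np.random.default_rng(9)
        draws = rng.normal(0.0, 0.25, 50000)
        bf = savage_dickey_bf10(draws, STD_NORMAL_AT_ZERO)
        # analytic: 0.39894 / N(0 | 0, 0.25) = 0.25
        assert bf == pytest.approx(0.25, rel=0.1)

    def test_displaced_posterior_is_decisive(self):
        rng = np.random.default_rng(10)
        draws = rng.normal(2.0, 0.5, 50000)
        bf = savage_dickey_bf10(draws, STD_NORMAL_AT_ZERO)
        analytic = STD_NORMAL_AT_ZERO / norm.pdf(0.0, 2.0, 0.5)
        assert bf == pytest.approx(analytic, rel=0.1)
        assert jeffreys_category(bf).startswith("decisive")

    def test_degenerate_zero_draws_flagged(self):
        with pytest.warns(UserWarning, match="saturated"):
            bf = savage_dickey_bf10(np.zeros(2000), STD_NORMAL_AT_ZERO)
        assert bf < 0.01

    def test_requires_many_draws(self):
        with pytest.raises(ValueError, match="at least"):
            savage_dickey_bf10(np.random.default_rng(0).standard_normal(500), 0.4)


class TestJeffreysCategories:
    @pytest.mark.parametrize(
        "bf, label",
        [
            (150.0, "decisive evidence for H1"),
            (50.0, "very strong evidence for H1"),
            (15.0, "strong evidence for H1"),
            (5.0, "substantial evidence for H1"),
            (2.0, "anecdotal evidence for H1"),
            (1.0, "no evidence"),
            (0.5, "anecdotal evidence for H0"),
            (0.15, "substantial evidence for H0"),
            (0.05, "strong evidence for H0"),
            (0.02, "very strong evidence for H0"),
            (0.005, "decisive evidence for H0"),
            # printed-table pairs
            (3.24, "substantial evidence for H1"),
            (1.82, "anecdotal evidence for H1"),
            (0.82, "anecdotal evidence for H0"),
        ],
    )
    def test_category_table(self, bf, label):
        assert jeffreys_category(bf) == label

    @pytest.mark.parametrize(
        "bf, label",
        [
            (3.0, "substantial evidence for H1"),
            (10.0, "strong evidence for H1"),
            (100.0, "decisive evidence for H1"),
            (1 / 3, "substantial evidence for H0"),
            (1 / 10, "strong evidence for H0"),
            (1 / 100, "decisive evidence for H0"),
        ],
    )
    def test_boundaries_assigned_to_stronger_category(self, bf, label):
        assert jeffreys_category(bf) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            jeffreys_category(0.0)

    def test_monotone_evidence_ordering(self):
        """Sweeping BF upward never weakens the evidence grade for H1."""
        order = ["decisive evidence for H0", "very strong evidence for H0",
                 "strong evidence for H0", "substantial evidence for H0",
                 "anecdotal evidence for H0", "no evidence",
                 "anecdotal evidence for H1", "substantial evidence for H1",
                 "strong evidence for H1", "very strong evidence for H1",
                 "decisive evidence for H1"]
        grid = np.logspace(-3, 3, 400)
        ranks = [order.index(jeffreys_category(b)) for b in grid]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))


class TestEvidenceTable:
    def test_constant_zero_draws(self):
        rows = evidence_table({"x": np.zeros(2000)}, STD_NORMAL_AT_ZERO, include_bf=True)
        row = rows[0]
        assert row.mode == 0.0
        assert row.or_sign == "tie"
        assert row.bf10_saturated and row.bf10 < 0.01

    def test_sorted_by_mode(self):
        rng = np.random.default_rng(11)
        draws = {
            "a": rng.normal(1.0, 0.1, 2000),
            "b": rng.normal(-1.0, 0.1, 2000),
            "c": rng.normal(0.0, 0.1, 2000),
        }
        rows = evidence_table(draws)
        assert [r.name for r in rows] == ["b", "c", "a"]

    def test_sorted_by_bf(self):
        rng = np.random.default_rng(12)
        draws = {
            "null": rng.normal(0.0, 0.3, 5000),
            "effect": rng.normal(1.5, 0.3, 5000),
        }
        rows = evidence_table(draws, STD_NORMAL_AT_ZERO, include_bf=True, sort_by="bf10")
        assert [r.name for r in rows] == ["null", "effect"]
        assert rows[0].category.endswith("H0")

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        rows = evidence_table(
            {"a": rng.normal(0.5, 0.2, 5000), "b": rng.normal(-0.2, 0.2, 5000)},
            STD_NORMAL_AT_ZERO, include_bf=True,
        )
        p = tmp_path / "tab.csv"
        write_evidence_csv(rows, p)
        back = read_evidence_csv(p)
        assert back == rows
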