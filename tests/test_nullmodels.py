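"""Null models: regional-pool draws, independent swap, SES."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporocarp import (
    BinaryCommunityMatrix,
    CommunityTable,
    NullDistribution,
    RegionalPool,
    TraitTable,
    attach_community_traits,
    independent_swap,
    regional_pool_null,
    ses,
    swap_null,
    to_binary_matrix,
)
from conftest import random_binary_matrix


class TestRegionalPoolNull:
    def test_draw_of_whole_stratum_is_constant(self, pool_log123):
        null = regional_pool_null(pool_log123, "ST", richness=3, n_rand=50, seed=0)
        np.testing.assert_allclose(null.values, 2.0)
        assert null.sd == 0.0

    def test_moments_match_exhaustive_enumeration(self, pool_log123):
        """Enumeration oracle: richness-2 draws from {1,2,3} have means
        {1.5, 2.0, 2.5}, so E = 2.0 and population sd = sqrt(1/6)."""
        pairs = list(itertools.combinations([1.0, 2.0, 3.0], 2))
        means = np.array([np.mean(p) for p in pairs])
        exact_mean, exact_sd = means.mean(), means.std()
        assert exact_mean == pytest.approx(2.0)
        assert exact_sd == pytest.approx(np.sqrt(1.0 / 6.0))

        n_rand = 10_000
        null = regional_pool_null(pool_log123, "ST", richness=2, n_rand=n_rand, seed=1)
        se_mean = exact_sd / np.sqrt(n_rand)
        assert abs(null.mean - exact_mean) < 3 * se_mean
        # se of the sd estimate ~ sd / sqrt(2 (n-1))
        assert abs(null.sd - exact_sd) < 3 * exact_sd / np.sqrt(2 * (n_rand - 1))

    def test_richness_one_recovers_pool_moments(self, pool_log123):
        null = regional_pool_null(pool_log123, "ST", richness=1, n_rand=20_000, seed=2)
        pool_vals = np.array([1.0, 2.0, 3.0])
        assert null.mean == pytest.approx(pool_vals.mean(), abs=0.02)
        assert null.sd == pytest.approx(pool_vals.std(), abs=0.02)

    def test_richness_exceeding_stratum_raises(self, pool_log123):
        with pytest.raises(ValueError, match="without replacement"):
            regional_pool_null(pool_log123, "ST", richness=4, n_rand=10)

    def test_seed_determinism(self, pool_log123):
        a = regional_pool_null(pool_log123, "ST", 2, n_rand=100, seed=7)
        b = regional_pool_null(pool_log123, "ST", 2, n_rand=100, seed=7)
        np.testing.assert_array_equal(a.values, b.values)


class TestIndependentSwap:
    def test_identity_matrix_single_swap(self):
        m = np.eye(2, dtype=np.int8)
        out = independent_swap(m, n_swaps=1, seed=0)
        np.testing.assert_array_equal(out, [[0, 1], [1, 0]])

    def test_zero_swaps_is_identity(self):
        m = random_binary_matrix(np.random.default_rng(0), 10, 8)
        np.testing.assert_array_equal(independent_swap(m, 0, seed=1), m)

    def test_all_ones_unchanged_with_warning(self, caplog):
        m = np.ones((3, 3), dtype=np.int8)
        with caplog.at_level("WARNING"):
            out = independent_swap(m, n_swaps=1, seed=0)
        np.testing.assert_array_equal(out, m)
        assert "attempt budget" in caplog.text

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_marginals_conserved_for_any_chain_length(self, n_swaps, seed):
        rng = np.random.default_rng(seed)
        m = random_binary_matrix(rng, 12, 9)
        out = independent_swap(m, n_swaps, seed=seed)
        np.testing.assert_array_equal(out.sum(axis=1), m.sum(axis=1))
        np.testing.assert_array_equal(out.sum(axis=0), m.sum(axis=0))

    def test_seed_determinism(self):
        m = random_binary_matrix(np.random.default_rng(3), 20, 15)
        a = independent_swap(m, 200, seed=11)
        b = independent_swap(m, 200, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_wrapped_matrix_preserves_labels(self, toy_community, toy_traits):
        matrix = to_binary_matrix(toy_community, toy_traits, "ST", 2009)
        out = independent_swap(matrix, 5, seed=0)
        assert out.species == matrix.species
        assert out.plots == matrix.plots


def _chain_community(n_species=4, n_plots=3):
    """Small fully-typed community for swap_null tests."""
    rows = [
        ("p1", "a"), ("p1", "b"), ("p2", "a"), ("p2", "c"),
        ("p3", "b"), ("p3", "c"), ("p3", "d"), ("p1", "d"),
    ]
    table = CommunityTable(pd.DataFrame({
        "plot_id": [r[0] for r in rows],
        "species_id": [r[1] for r in rows],
        "year": 2009,
        "count": 2,
    }))
    traits = TraitTable(pd.DataFrame({
        "species_id": ["a", "b", "c", "d"],
        "guild": ["ST"] * 4,
        "cap_diameter_mm": [10.0, 20.0, 40.0, 80.0],
    }))
    return table, attach_community_traits(traits, table)


class TestSwapNull:
    def test_identical_traits_give_constant_null(self):
        table, _ = _chain_community()
        traits = TraitTable(pd.DataFrame({
            "species_id": ["a", "b", "c", "d"],
            "guild": ["ST"] * 4,
            "cap_diameter_mm": [30.0] * 4,
        }))
        traits = attach_community_traits(traits, table)
        matrix = to_binary_matrix(table, traits, "ST", 2009)
        nulls = swap_null(matrix, traits, "mean_log_size", n_rand=20, seed=0)
        s = ses(np.log10(900.0), nulls["p1"])
        assert s.flag == "zero_null_sd"
        assert np.isnan(s.ses)

    def test_checkerboard_two_state_chain(self):
        """2x2 checkerboard with traits {a, b}: consecutive thin=1 samples
        alternate between the two states, so each plot's null values hit the
        two trait values with frequency 1/2 each."""
        matrix = BinaryCommunityMatrix(
            np.eye(2, dtype=np.int8), ["s1", "s2"], ["p1", "p2"], "ST", 2009
        )
        traits = TraitTable(pd.DataFrame({
            "species_id": ["s1", "s2"], "guild": ["ST", "ST"],
            "cap_diameter_mm": [10.0, 100.0],
        }))
        n_rand = 200
        nulls = swap_null(matrix, traits, "mean_log_size",
                          n_rand=n_rand, burn_in=0, thin=1, seed=0)
        vals = nulls["p1"].values
        a, b = 2.0, 4.0  # log10 of 100 and 10000
        assert set(np.round(vals, 12)) == {a, b}
        freq_a = np.mean(vals == a)
        assert abs(freq_a - 0.5) <= 3 * 0.5 / np.sqrt(n_rand) + 1.0 / n_rand

    def test_richness_one_plot_uniform_over_traits(self):
        """Permutation matrices with equal occupancies: by symmetry the
        single occupant of a plot is uniform over the species."""
        matrix = BinaryCommunityMatrix(
            np.eye(3, dtype=np.int8), ["s1", "s2", "s3"],
            ["p1", "p2", "p3"], "ST", 2009,
        )
        traits = TraitTable(pd.DataFrame({
            "species_id": ["s1", "s2", "s3"], "guild": ["ST"] * 3,
            "cap_diameter_mm": [10.0, 100.0, 1000.0],
        }))
        n_rand = 3000
        nulls = swap_null(matrix, traits, "mean_log_size",
                          n_rand=n_rand, burn_in=10, thin=3, seed=4)
        vals = nulls["p1"].values
        freqs = np.array([np.mean(np.isclose(vals, v)) for v in (2.0, 4.0, 6.0)])
        assert freqs.sum() == pytest.approx(1.0)
        # binomial tolerance around 1/3 (thinned samples are correlated, so
        # allow several standard errors)
        assert np.all(np.abs(freqs - 1 / 3) < 6 * np.sqrt((1 / 3) * (2 / 3) / n_rand))

    def test_degenerate_matrix_returns_none(self, caplog):
        matrix = BinaryCommunityMatrix(
            np.ones((1, 3), dtype=np.int8), ["s1"], ["p1", "p2", "p3"], "ST", 2009
        )
        traits = TraitTable(pd.DataFrame({
            "species_id": ["s1"], "guild": ["ST"], "cap_diameter_mm": [10.0],
        }))
        with caplog.at_level("WARNING"):
            assert swap_null(matrix, traits, "mean_log_size", n_rand=10, seed=0) is None

    def test_seed_determinism(self):
        table, traits = _chain_community()
        matrix = to_binary_matrix(table, traits, "ST", 2009)
        a = swap_null(matrix, traits, "mean_log_size", n_rand=25, seed=9)
        b = swap_null(matrix, traits, "mean_log_size", n_rand=25, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_restart_mode_also_conserves_marginals_implicitly(self):
        # restart mode must produce valid distributions of the same shape
        table, traits = _chain_community()
        matrix = to_binary_matrix(table, traits, "ST", 2009)
        out = swap_null(matrix, traits, "mean_log_size", n_rand=10, seed=0,
                        mode="restart")
        assert out.values.shape == (10, 3)


class TestSES:
    def test_centred_observation_scores_zero(self):
        null = NullDistribution("m", np.array([3.0, 4.0, 5.0, 6.0, 7.0]))
        assert ses(5.0, null).ses == pytest.approx(0.0)

    def test_two_sd_above(self):
        null = NullDistribution("m", np.array([4.0, 5.0, 6.0]))  # mean 5, sd 1
        assert ses(7.0, null).ses == pytest.approx(2.0)

    def test_constant_null_flagged_undefined(self):
        null = NullDistribution("m", np.full(10, 3.3))
        s = ses(1.0, null)
        assert s.flag == "zero_null_sd"
        assert np.isnan(s.ses)

    def test_empty_null_raises(self):
        with pytest.raises(ValueError):
            ses(1.0, NullDistribution("m", np.array([])))

    def test_sample_sd_uses_n_minus_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        null = NullDistribution("m", vals)
        assert null.sd == pytest.approx(np.std(vals, ddof=1))


def test_regional_ses_calibrated_under_neutral_draws(pool_log123):
    """Observed assemblages drawn from the pool itself give SES ~ N(0, 1)."""
    rng = np.random.default_rng(12)
    pool_sizes = np.array([1.0, 2.0, 3.0])
    n_plots = 300
    ses_vals = []
    for i in range(n_plots):
        obs = rng.choice(pool_sizes, size=2, replace=False).mean()
        null = regional_pool_null(pool_log123, "ST", 2, n_rand=100, seed=rng)
        ses_vals.append(ses(obs, null).ses)
    ses_vals = np.asarray(ses_vals)
    assert abs(np.mean(ses_vals)) < 0.15
    assert 0.8 < np.std(ses_vals) < 1.25
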