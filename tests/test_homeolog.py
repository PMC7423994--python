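"""Homeolog bias posterior: conjugate oracle, symmetries, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polyexpr.homeolog import (
    CATEGORY_GROUPS,
    CATEGORY_TABLE,
    HomeologBiasModel,
    assign_categories,
    assign_category,
    bias_balance_test,
    classify_bias,
    compare_forms,
    posterior_density,
    theta_posterior,
)


class TestConjugateOracle:
    @pytest.mark.parametrize("sa, sb", [(32, 154), (5, 0), (0, 7), (3, 2), (200, 180)])
    def test_grid_matches_beta_density(self, sa, sb):
        """With q=0 the grid posterior equals Beta(1+sum_A, 1+sum_B) at every node."""
        grid, dens = posterior_density(sa, sb)
        exact = stats.beta.pdf(grid, 1 + sa, 1 + sb)
        mask = exact > 1e-12
        assert np.max(np.abs(dens[mask] - exact[mask]) / exact[mask]) < 1e-8

    def test_informative_prior(self):
        grid, dens = posterior_density(10, 5, prior_a=2.0, prior_b=3.0)
        exact = stats.beta.pdf(grid, 12, 8)
        mask = exact > 1e-12
        assert np.max(np.abs(dens[mask] - exact[mask]) / exact[mask]) < 1e-8

    def test_single_replicate_beta_6_1_mean(self):
        bp = theta_posterior([5], [0])
        assert bp.theta_mean == pytest.approx(6 / 7, abs=1e-6)

    def test_symmetric_counts_mean_half(self):
        bp = theta_posterior([3, 3], [3, 3])
        assert bp.theta_mean == pytest.approx(0.5, abs=1e-12)

    def test_strong_b_bias_beta_cdf_oracle(self):
        """x_A=(10,12,9), x_B=(50,48,55): posterior mass below 0.5 > 0.999."""
        bp = theta_posterior([10, 12, 9], [50, 48, 55])
        assert bp.bias_class == "biased_B"
        assert stats.beta.cdf(0.5, 32, 154) > 0.999  # oracle confirms the call
        assert bp.ci_high < 0.5


class TestGridAgainstFineIntegration:
    def test_q_positive_matches_10x_finer_grid(self):
        """Posterior means with q>0 agree with 10x finer quadrature within 1e-4."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            sa, sb = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            if sa + sb == 0:
                sa = 1
            qa, qb = rng.uniform(0, 0.2, 2)
            coarse = theta_posterior([sa], [sb], qa, qb, grid_points=2001)
            fine = theta_posterior([sa], [sb], qa, qb, grid_points=20001)
            assert abs(coarse.theta_mean - fine.theta_mean) < 1e-4


@settings(max_examples=60, deadline=None)
@given(
    sa=st.integers(0, 500),
    sb=st.integers(0, 500),
    qa=st.floats(0.0, 0.3),
    qb=st.floats(0.0, 0.3),
)
def test_label_exchange_symmetry(sa, sb, qa, qb):
    """Swapping A/B counts and qA/qB maps theta_mean to 1 - theta_mean."""
    if sa + sb == 0:
        sa = 1
    fwd = theta_posterior([sa], [sb], qa, qb, grid_points=501)
    rev = theta_posterior([sb], [sa], qb, qa, grid_points=501)
    assert fwd.theta_mean == pytest.approx(1 - rev.theta_mean, abs=1e-9)
    assert fwd.ci_low == pytest.approx(1 - rev.ci_high, abs=1e-6)
    swap = {"biased_A": "biased_B", "biased_B": "biased_A", "unbiased": "unbiased"}
    assert fwd.bias_class == swap[rev.bias_class]


def test_posterior_mean_monotone_in_sum_A():
    means = [theta_posterior([sa], [20], grid_points=501).theta_mean
             for sa in range(0, 60, 5)]
    assert all(a < b for a, b in zip(means, means[1:]))


@pytest.mark.parametrize(
    "lo, hi, mean, expected",
    [
        (0.48, 0.53, 0.505, "unbiased"),
        (0.51, 0.60, 0.55, "biased_A"),
        (0.40, 0.49, 0.45, "biased_B"),
        (0.50, 0.60, 0.55, "unbiased"),  # boundary: 0.5 inside closed interval
    ],
)
def test_classify_bias(lo, hi, mean, expected):
    assert classify_bias(mean, lo, hi) == expected


def test_all_zero_locus_raises():
    with pytest.raises(ValueError, match="zero"):
        theta_posterior([0, 0], [0, 0])


class TestModelFit:
    def test_low_count_loci_excluded_and_logged(self):
        df = pd.DataFrame(
            {
                "locus_id": ["l1", "l1", "l2", "l2"],
                "replicate": [1, 2, 1, 2],
                "count_A": [40, 45, 2, 1],
                "count_B": [38, 41, 1, 0],
            }
        )
        res = HomeologBiasModel(df, min_total=10).fit()
        assert list(res.posteriors.index) == ["l1"]
        assert list(res.excluded["locus_id"]) == ["l2"]

    def test_per_locus_q_table(self):
        df = pd.DataFrame(
            {
                "locus_id": ["l1"] * 2 + ["l2"] * 2,
                "replicate": [1, 2, 1, 2],
                "count_A": [60, 55, 60, 55],
                "count_B": [40, 45, 40, 45],
            }
        )
        q = pd.DataFrame({"locus_id": ["l1", "l2"], "qA": [0.0, 0.3], "qB": [0.0, 0.0]})
        res = HomeologBiasModel(df, q=q).fit()
        # misassignment from A to B hides true bias: correcting for a large
        # qA pushes the theta estimate up
        assert res.posteriors.loc["l2", "theta_mean"] > res.posteriors.loc["l1", "theta_mean"]

    def test_summary_contains_counts(self):
        df = pd.DataFrame(
            {
                "locus_id": ["l1"] * 3,
                "replicate": [1, 2, 3],
                "count_A": [100, 110, 90],
                "count_B": [10, 8, 12],
            }
        )
        res = HomeologBiasModel(df).fit()
        text = res.summary()
        assert "biased_A" in text and "loci analysed" in text


class TestCategories:
    def test_full_table(self):
        """All nine (parental DE x bias) cells map to the documented category."""
        expected = {
            ("no_de", "unbiased"): (1, "parental_legacy"),
            ("A_higher", "biased_A"): (2, "parental_legacy"),
            ("B_higher", "biased_B"): (3, "parental_legacy"),
            ("A_higher", "unbiased"): (4, "absence_of_bias"),
            ("B_higher", "unbiased"): (5, "absence_of_bias"),
            ("no_de", "biased_A"): (6, "novel_bias"),
            ("no_de", "biased_B"): (7, "novel_bias"),
            ("A_higher", "biased_B"): (8, "novel_bias"),
            ("B_higher", "biased_A"): (9, "novel_bias"),
        }
        for key, val in expected.items():
            assert assign_category(*key) == val
        assert set(CATEGORY_TABLE.values()) == set(range(1, 10))
        assert len(CATEGORY_GROUPS) == 9

    def test_vectorised_skips_missing(self):
        de = pd.Series({"l1": "no_de", "l2": "A_higher"})
        bias = pd.Series({"l1": "biased_A", "l3": "unbiased"})
        out = assign_categories(de, bias)
        assert list(out.index) == ["l1"]
        assert out.loc["l1", "category"] == 6
        assert out.attrs["n_skipped"] == 2


class TestCompareForms:
    def test_identical_calls_diagonal(self):
        calls = pd.Series({"l1": "unbiased", "l2": "biased_A", "l3": "biased_B"})
        tab, maternal = compare_forms(calls, calls, "B", "A")
        assert tab.to_numpy().sum() == 3
        off = tab.to_numpy().sum() - np.trace(tab.to_numpy())
        assert off == 0 and maternal == []

    def test_maternal_specific_membership(self):
        # form1 maternal parent is A: biased_A in form1 + unbiased in form2 counts
        c1 = pd.Series({"l1": "biased_A", "l2": "biased_A", "l3": "unbiased"})
        c2 = pd.Series({"l1": "unbiased", "l2": "biased_B", "l3": "biased_B"})
        tab, maternal = compare_forms(c1, c2, maternal_of_form1="A", maternal_of_form2="B")
        assert "l1" in maternal          # maternal-biased in form1, unbiased in form2
        assert "l2" not in maternal      # direction switch -> table only
        assert "l3" in maternal          # maternal-biased in form2, unbiased in form1
        assert tab.loc["biased_A", "biased_B"] == 1


class TestBalanceTest:
    def test_equal_counts(self):
        chi2, p = bias_balance_test(100, 100)
        assert chi2 == 0 and p == 1

    @pytest.mark.parametrize(
        "a, b, expected",
        [(444, 545, 2 * 50.5**2 / 494.5), (416, 515, 2 * 49.5**2 / 465.5)],
    )
    def test_closed_form(self, a, b, expected):
        chi2, p = bias_balance_test(a, b)
        assert chi2 == pytest.approx(expected)
        assert p == pytest.approx(stats.chi2.sf(expected, df=1))

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            bias_balance_test(0, 0)


def test_parameter_recovery_on_simulated_data(small_sim):
    """Three-way classification recovers the simulated truth at small scale."""
    sim = small_sim
    res = HomeologBiasModel(sim.homeolog_counts, q=(0.02, 0.02)).fit()
    truth = sim.truth.loc[res.posteriors.index]
    pred = res.posteriors["bias_class"]
    strong = (truth["true_bias_class"] != "unbiased") & (
        (truth["true_theta"] - 0.5).abs() >= 0.15
    )
    assert (pred[strong] == truth.loc[strong, "true_bias_class"]).mean() >= 0.9
    null = truth["true_bias_class"] == "unbiased"
    assert (pred[null] != "unbiased").mean() <= 0.075
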