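"""Fairlie decomposition: additivity, linear limits, enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from csdecomp import (Cohort, DecompositionSpec, ModelSpec,
                      aggregate_decomposition, detailed_decomposition,
                      draw_subsample, fit, generate_cohort, match_by_rank,
                      reference_fit, sensitivity_rerun, sequential_contributions)

from conftest import binary_cov, make_spec


def decomp(reference="public", replications=30, seed=0, **kw):
    return DecompositionSpec(reference=reference, replications=replications,
                             seed=seed, **kw)


# --- subsampling and matching ---------------------------------------------


class TestDrawSubsample:
    def test_full_size_draw_is_a_permutation(self):
        rng = np.random.default_rng(0)
        idx = draw_subsample(np.arange(10), 10, rng)
        assert sorted(idx) == list(range(10))

    def test_same_substream_gives_identical_indices(self):
        a = draw_subsample(np.arange(100), 30, np.random.default_rng(42))
        b = draw_subsample(np.arange(100), 30, np.random.default_rng(42))
        assert (a == b).all()

    def test_oversized_target_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            draw_subsample(np.arange(5), 6, np.random.default_rng(0))

    def test_inclusion_frequency_is_hypergeometric_uniform(self):
        """Across many draws each index is included with probability k/n."""
        n, k, draws = 10, 4, 10_000
        counts = np.zeros(n)
        rng = np.random.default_rng(7)
        for _ in range(draws):
            counts[draw_subsample(np.arange(n), k, rng)] += 1
        p = k / n
        se = np.sqrt(p * (1 - p) / draws)
        assert np.all(np.abs(counts / draws - p) < 4 * se)


class TestMatchByRank:
    def test_sorted_distinct_vectors_pair_identically(self):
        rng = np.random.default_rng(0)
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.15, 0.25, 0.35])
        ia, ib = match_by_rank(a, b, rng)
        assert (ia == ib).all() and (ia == [0, 1, 2]).all()

    def test_single_element(self):
        ia, ib = match_by_rank(np.array([0.5]), np.array([0.9]),
                               np.random.default_rng(1))
        assert ia[0] == 0 and ib[0] == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            match_by_rank(np.zeros(3), np.zeros(4), np.random.default_rng(0))

    def test_all_equal_probabilities_give_uniform_random_bijection(self):
        """With ties everywhere, element 0's partner is uniform over seeds."""
        n, seeds = 3, 1000
        partner_counts = np.zeros(n)
        a = np.full(n, 0.5)
        b = np.full(n, 0.5)
        for s in range(seeds):
            ia, ib = match_by_rank(a, b, np.random.default_rng(s))
            partner = ib[np.flatnonzero(ia == 0)[0]]
            partner_counts[partner] += 1
        p = 1 / n
        se = np.sqrt(p * (1 - p) / seeds)
        assert np.all(np.abs(partner_counts / seeds - p) < 4 * se)

    def test_pairing_is_a_bijection(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(50), rng.random(50)
        ia, ib = match_by_rank(a, b, rng)
        assert sorted(ia) == list(range(50)) and sorted(ib) == list(range(50))


# --- sequential switching against exhaustive path enumeration -------------


def enumerate_path_contributions(X_a, X_b, beta, blocks, F):
    """Brute-force mean per-block contribution over all switching orders.

    Independent oracle: for each permutation, walk the path through the
    2^K lattice of switched-block subsets and record each block's step.
    """
    K = len(blocks)

    def mean_F(switched):
        Z = X_a.copy()
        for k in switched:
            Z[:, blocks[k]] = X_b[:, blocks[k]]
        return F(Z @ beta).mean()

    totals = np.zeros(K)
    orders = list(itertools.permutations(range(K)))
    for order in orders:
        done = []
        for k in order:
            before = mean_F(done)
            done.append(k)
            totals[k] += before - mean_F(done)
    return totals / len(orders)


class TestSequentialContributions:
    @pytest.fixture
    def four_pairs(self):
        # intercept + two binary covariates, 4 matched pairs
        X_a = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=float)
        X_b = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 0], [1, 0, 0]], dtype=float)
        beta = np.array([-0.3, 0.9, 0.5])
        return X_a, X_b, beta

    def test_identical_block_values_contribute_zero(self, four_pairs):
        X_a, _, beta = four_pairs
        pairing = (np.arange(4), np.arange(4))
        out = sequential_contributions(pairing, X_a, X_a.copy(), beta,
                                       [0, 1], [[1], [2]])
        assert np.allclose(out, 0.0, atol=1e-15)

    def test_single_block_equals_full_explained_term(self, four_pairs):
        X_a, X_b, beta = four_pairs
        pairing = (np.arange(4), np.arange(4))
        out = sequential_contributions(pairing, X_a, X_b, beta, [0], [[1, 2]])
        expected = norm.cdf(X_a @ beta).mean() - norm.cdf(X_b @ beta).mean()
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_both_orderings_average_to_path_enumeration(self, four_pairs):
        X_a, X_b, beta = four_pairs
        pairing = (np.arange(4), np.arange(4))
        blocks = [[1], [2]]
        averaged = np.mean([
            sequential_contributions(pairing, X_a, X_b, beta, order, blocks)
            for order in ([0, 1], [1, 0])
        ], axis=0)
        oracle = enumerate_path_contributions(X_a, X_b, beta, blocks, norm.cdf)
        assert np.allclose(averaged, oracle, atol=1e-12)

    def test_contributions_telescope_to_matched_explained(self, four_pairs):
        X_a, X_b, beta = four_pairs
        pairing = (np.array([2, 0, 3, 1]), np.array([1, 3, 0, 2]))
        out = sequential_contributions(pairing, X_a, X_b, beta, [1, 0],
                                       [[1], [2]])
        explained = (norm.cdf(X_a[pairing[0]] @ beta).mean()
                     - norm.cdf(X_b[pairing[1]] @ beta).mean())
        assert out.sum() == pytest.approx(explained, abs=1e-14)

    def test_bad_ordering_rejected(self, four_pairs):
        X_a, X_b, beta = four_pairs
        with pytest.raises(ValueError, match="permutation"):
            sequential_contributions((np.arange(4), np.arange(4)), X_a, X_b,
                                     beta, [0, 0], [[1], [2]])


# --- aggregate decomposition ----------------------------------------------


class TestAggregateDecomposition:
    def test_six_row_fixture_matches_direct_enumeration(self, tiny_cohort):
        """Fixed beta=(0,1) probit: explained from direct evaluation."""
        res = fit(tiny_cohort, ModelSpec("y", ("x",), include_private=False))
        res.params[:] = [0.0, 1.0]
        agg = aggregate_decomposition(res, tiny_cohort, "y")
        x = tiny_cohort.data["x"].to_numpy(float)
        explained_oracle = (norm.cdf(x[:3]).mean() - norm.cdf(x[3:]).mean())
        assert agg.explained == pytest.approx(explained_oracle, abs=1e-12)
        assert agg.gap == pytest.approx(2 / 3 - 1 / 3, abs=1e-12)
        assert agg.unexplained == pytest.approx(agg.gap - agg.explained,
                                                abs=1e-15)

    def test_symmetric_groups_have_near_zero_gap(self):
        spec = make_spec(4000, 4000, [binary_cov("x", 0.4, 0.4)],
                         {"intercept": -0.8, "x": 0.7}, seed=31)
        cohort = generate_cohort(spec)
        mspec = ModelSpec("elcs", ("x",))
        res = reference_fit(cohort, mspec, decomp("public"))
        agg = aggregate_decomposition(res, cohort, "elcs")
        rate = 0.25
        mc_se = np.sqrt(2 * rate * (1 - rate) / 4000)
        assert abs(agg.gap) < 4 * mc_se
        assert abs(agg.explained) < 4 * mc_se

    def test_identity_link_equals_linear_oaxaca_blinder(self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"), link="identity")
        res = reference_fit(small_cohort, mspec, decomp("public"))
        agg = aggregate_decomposition(res, small_cohort, "elcs")
        df = small_cohort.data
        pub, pri = df["group"] == "public", df["group"] == "private"
        linear = sum(
            res.params[c] * (df.loc[pub, c].mean() - df.loc[pri, c].mean())
            for c in ("x1", "x2"))
        assert agg.explained == pytest.approx(linear, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_additivity_is_exact_for_any_reference_fit(self, seed):
        spec = make_spec(60, 40, [binary_cov("x", 0.3, 0.7)],
                         {"intercept": -0.4, "x": 0.6},
                         group_effect=0.2, seed=seed)
        cohort = generate_cohort(spec)
        mspec = ModelSpec("elcs", ("x",))
        for ref in ("public", "private", "pooled"):
            try:
                res = reference_fit(cohort, mspec, decomp(ref))
            except Exception:
                continue  # tiny samples may separate; additivity is the claim
            agg = aggregate_decomposition(res, cohort, "elcs")
            assert agg.explained + agg.unexplained == pytest.approx(
                agg.gap, abs=1e-15)


# --- detailed decomposition ------------------------------------------------


class TestDetailedDecomposition:
    def test_detailed_additivity_and_residual(self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"))
        result = detailed_decomposition(small_cohort, "elcs", mspec,
                                        decomp(replications=40, seed=2))
        total = result.table["contribution"].sum()
        assert total == pytest.approx(result.aggregate.explained, abs=1e-10)
        pct = result.table["pct_of_gap"].dropna()
        expected_pct = (result.table["contribution"].dropna()
                        / result.aggregate.gap * 100)
        assert np.allclose(pct, expected_pct.loc[pct.index])

    def test_reproducible_given_seed(self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"))
        a = detailed_decomposition(small_cohort, "elcs", mspec,
                                   decomp(replications=15, seed=9))
        b = detailed_decomposition(small_cohort, "elcs", mspec,
                                   decomp(replications=15, seed=9))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_identity_link_fixed_order_matches_linear_detailed_exactly(self):
        """Equal group sizes, identity link: per-covariate contributions are
        the classical (mean difference x coefficient) terms, any ordering."""
        spec = make_spec(300, 300,
                         [binary_cov("x1", 0.3, 0.6), binary_cov("x2", 0.2, 0.5)],
                         {"intercept": 0.3, "x1": 0.1, "x2": 0.15},
                         link="identity", seed=41)
        cohort = generate_cohort(spec)
        mspec = ModelSpec("elcs", ("x1", "x2"), link="identity")
        result = detailed_decomposition(
            cohort, "elcs", mspec,
            decomp(replications=1, seed=0, randomize_order=False,
                   fixed_order=("x2", "x1")))
        res = reference_fit(cohort, mspec, decomp("public"))
        df = cohort.data
        pub, pri = df["group"] == "public", df["group"] == "private"
        for c in ("x1", "x2"):
            linear = res.params[c] * (df.loc[pub, c].mean()
                                      - df.loc[pri, c].mean())
            assert result.table.loc[c, "contribution"] == pytest.approx(
                linear, abs=1e-12)
        assert result.table.loc["(residual)", "contribution"] == pytest.approx(
            0.0, abs=1e-12)

    def test_identity_link_contributions_are_order_invariant(self):
        spec = make_spec(200, 200,
                         [binary_cov("x1", 0.3, 0.6), binary_cov("x2", 0.2, 0.5)],
                         {"intercept": 0.3, "x1": 0.1, "x2": 0.15},
                         link="identity", seed=43)
        cohort = generate_cohort(spec)
        mspec = ModelSpec("elcs", ("x1", "x2"), link="identity")
        results = [
            detailed_decomposition(
                cohort, "elcs", mspec,
                decomp(replications=1, seed=0, randomize_order=False,
                       fixed_order=order))
            for order in (("x1", "x2"), ("x2", "x1"))
        ]
        pd.testing.assert_series_equal(results[0].table["contribution"],
                                       results[1].table["contribution"])

    def test_label_swap_negates_gap_and_components(self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"))
        res = reference_fit(small_cohort, mspec, decomp("public"))
        agg = aggregate_decomposition(res, small_cohort, "elcs")

        swapped_df = small_cohort.data.copy()
        swapped_df["group"] = swapped_df["group"].map(
            {"public": "private", "private": "public"})
        swapped = Cohort(swapped_df, small_cohort.outcome_names)
        res_swapped = reference_fit(swapped, mspec, decomp("private"))
        agg_swapped = aggregate_decomposition(res_swapped, swapped, "elcs")

        assert agg_swapped.gap == pytest.approx(-agg.gap, abs=1e-12)
        assert agg_swapped.explained == pytest.approx(-agg.explained, abs=1e-10)
        assert agg_swapped.unexplained == pytest.approx(-agg.unexplained,
                                                        abs=1e-10)

    def test_all_references_share_the_same_raw_gap(self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"))
        gaps, splits = [], []
        for ref in ("public", "private", "pooled"):
            result = detailed_decomposition(small_cohort, "elcs", mspec,
                                            decomp(ref, replications=10, seed=3))
            gaps.append(result.aggregate.gap)
            splits.append(result.aggregate.explained)
        assert gaps[0] == pytest.approx(gaps[1], abs=1e-15)
        assert gaps[1] == pytest.approx(gaps[2], abs=1e-15)
        assert len({round(s, 12) for s in splits}) > 1  # splits do differ

    def test_pooled_group_dummy_variant_runs_and_splits_differently(
            self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"))
        without = detailed_decomposition(
            small_cohort, "elcs", mspec, decomp("pooled", replications=5, seed=1))
        with_dummy = detailed_decomposition(
            small_cohort, "elcs", mspec,
            decomp("pooled", replications=5, seed=1,
                   pooled_includes_group_dummy=True))
        assert with_dummy.aggregate.gap == pytest.approx(
            without.aggregate.gap, abs=1e-15)
        assert with_dummy.aggregate.explained != pytest.approx(
            without.aggregate.explained, abs=1e-12)

    def test_residual_shrinks_with_more_replications(self):
        # unequal groups: the residual reflects subsampling noise, which
        # averages out as replications accumulate (at equal sizes the
        # subsample is the whole group and the residual is already ~0)
        spec = make_spec(900, 400,
                         [binary_cov("x1", 0.3, 0.6), binary_cov("x2", 0.2, 0.5)],
                         {"intercept": -1.0, "x1": 0.8, "x2": 0.6},
                         seed=51)
        cohort = generate_cohort(spec)
        mspec = ModelSpec("elcs", ("x1", "x2"))
        resid = {}
        for R in (5, 200):
            vals = []
            for seed in range(5):
                result = detailed_decomposition(cohort, "elcs", mspec,
                                                decomp(replications=R, seed=seed))
                vals.append(abs(result.table.loc["(residual)", "contribution"]))
            resid[R] = np.median(vals)
        assert resid[200] < resid[5]

    def test_replication_and_delta_standard_errors_same_scale(self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"))
        rep = detailed_decomposition(small_cohort, "elcs", mspec,
                                     decomp(replications=200, seed=4))
        delta = detailed_decomposition(
            small_cohort, "elcs", mspec,
            decomp(replications=50, seed=4, se_method="delta"))
        # different estimands (MC error vs sampling error); both finite, and
        # the delta-method SE should dominate the R=200 Monte-Carlo SE
        for c in ("x1", "x2"):
            assert np.isfinite(delta.table.loc[c, "se"])
            assert delta.table.loc[c, "se"] > 0


class TestSensitivityRerun:
    def test_empty_drop_reproduces_detailed_decomposition(self, small_cohort):
        mspec = ModelSpec("elcs", ("x1", "x2"))
        dspec = decomp(replications=10, seed=6)
        base = detailed_decomposition(small_cohort, "elcs", mspec, dspec)
        rerun = sensitivity_rerun(small_cohort, "elcs", mspec, dspec, ())
        pd.testing.assert_frame_equal(base.table, rerun.table)

    def test_dropping_gap_driver_reduces_explained_share(self):
        """If one covariate drives most of the gap, removing it from the
        model cuts the explained share."""
        spec = make_spec(8000, 8000,
                         [binary_cov("age_high", 0.2, 0.6),
                          binary_cov("other", 0.3, 0.4)],
                         {"intercept": -1.2, "age_high": 0.9, "other": 0.4},
                         seed=61)
        cohort = generate_cohort(spec)
        mspec = ModelSpec("elcs", ("age_high", "other"))
        dspec = decomp(replications=30, seed=7)
        full = detailed_decomposition(cohort, "elcs", mspec, dspec)
        reduced = sensitivity_rerun(cohort, "elcs", mspec, dspec, ("age_high",))
        assert reduced.dropped_terms == ("age_high",)
        assert (reduced.aggregate.explained_share
                < 0.7 * full.aggregate.explained_share)

    def test_dropping_countervailing_covariate_raises_explained_share(self):
        """A risk factor more prevalent in the low-rate group pulls the
        explained share down; excluding it raises the share."""
        spec = make_spec(8000, 8000,
                         [binary_cov("age_high", 0.2, 0.7),
                          binary_cov("clinical", 0.15, 0.05)],
                         {"intercept": -1.2, "age_high": 0.8, "clinical": 0.5},
                         seed=62)
        cohort = generate_cohort(spec)
        mspec = ModelSpec("elcs", ("age_high", "clinical"))
        dspec = decomp(replications=30, seed=8)
        full = detailed_decomposition(cohort, "elcs", mspec, dspec)
        reduced = sensitivity_rerun(cohort, "elcs", mspec, dspec, ("clinical",))
        assert (reduced.aggregate.explained_share
                > full.aggregate.explained_share)

    def test_dropping_all_covariates_errors(self, small_cohort):
        from csdecomp import ConfigError
        mspec = ModelSpec("elcs", ("x1", "x2"), include_private=False)
        with pytest.raises(ConfigError):
            sensitivity_rerun(small_cohort, "elcs", mspec, decomp(),
                              ("x1", "x2"))
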