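"""FDR, component detection, TFNBS scoring and the permutation FWE null."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcmod.edge_glm import build_design
from fcmod.inference import (
    TFNBSParams,
    bh_fdr,
    components_at_threshold,
    permutation_fwe,
    tail_statistic,
    tfnbs_scores,
    tfnbs_scores_direct,
)
from fcmod.synthetic_data import EffectSpec, default_planted_edges, simulate_fc
from tests.conftest import all_pairs_mask, make_mask, stat_matrix


def brute_force_bh(p, q):
    """Step-up by trying every cutoff k: reject the k smallest p-values for
    the largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    rejected = np.zeros(m, bool)
    rejected[order[:k_star]] = True
    # adjusted p by direct min-over-tail definition
    adj = np.empty(m)
    sorted_p = p[order]
    for k in range(m):
        adj[order[k]] = min(1.0, min(m * sorted_p[j] / (j + 1) for j in range(k, m)))
    return rejected, adj


class TestBhFdr:
    def test_all_small_p_rejected(self):
        res = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert res.rejected.all()

    def test_null_extreme_and_singleton(self):
        res = bh_fdr([1.0, 1.0, 1.0])
        assert not res.rejected.any()
        np.testing.assert_array_equal(res.p_adjusted, 1.0)
        one = bh_fdr([0.04], q=0.05)
        assert one.rejected[0] and one.p_adjusted[0] == pytest.approx(0.04)

    def test_adjusted_at_least_raw(self):
        p = np.random.default_rng(0).random(100)
        res = bh_fdr(p)
        assert np.all(res.p_adjusted >= p - 1e-15)
        np.testing.assert_array_equal(res.rejected, res.p_adjusted <= res.q)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.2, 1.3])

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.lists(st.sampled_from([0.001, 0.01, 0.04, 0.049, 0.05, 0.2, 0.5, 1.0]),
                    min_size=1, max_size=12))
    def test_matches_brute_force_step_up(self, p):
        res = bh_fdr(p, q=0.05)
        rej, adj = brute_force_bh(p, 0.05)
        np.testing.assert_array_equal(res.rejected, rej)
        np.testing.assert_allclose(res.p_adjusted, adj, atol=1e-12)


class TestComponents:
    def test_node_sharing_definition(self):
        # AB and BC share node B; DE is separate
        t = stat_matrix(5, {(0, 1): 3.0, (1, 2): 2.5, (3, 4): 2.2})
        mask = make_mask([(0, 1), (1, 2), (3, 4)], 5)
        recs = components_at_threshold(t, mask, T=2.0)
        extents = sorted(r.extent for r in recs)
        assert extents == [1, 2]
        recs_hi = components_at_threshold(t, mask, T=2.7)
        assert len(recs_hi) == 1 and recs_hi[0].member_edges == {(0, 1)}

    def test_left_tail_keeps_negative_statistics(self):
        t = stat_matrix(3, {(0, 1): -3.0, (1, 2): 2.0})
        mask = make_mask([(0, 1), (1, 2)], 3)
        recs = components_at_threshold(t, mask, T=2.5, tail="left")
        assert len(recs) == 1 and recs[0].member_edges == {(0, 1)}

    def test_union_of_components_is_suprathreshold_set(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 12
            mask = all_pairs_mask(n)
            t = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            vals = rng.normal(0, 2, iu[0].size)
            t[iu] = vals
            t = t + t.T
            T = rng.uniform(0.5, 3.0)
            kept = {e for e in mask.edges if abs(t[e]) >= T - 1e-9}
            union = set().union(*[r.member_edges for r in
                                  components_at_threshold(t, mask, T)], set())
            assert union == kept


class TestTfnbsScores:
    def test_isolated_edge_direct_summation(self):
        t = stat_matrix(2, {(0, 1): 3.0})
        score = tfnbs_scores(t, make_mask([(0, 1)], 2))[0, 1]
        assert score == pytest.approx(0.001 * sum(k**2 for k in range(1, 31)),
                                      abs=1e-12)
        assert score == pytest.approx(9.455, abs=1e-10)

    def test_two_edges_sharing_node_hand_summation(self):
        t = stat_matrix(3, {(0, 1): 2.0, (1, 2): 1.0})
        s = tfnbs_scores(t, make_mask([(0, 1), (1, 2)], 3))
        shared = np.sqrt(2) * 0.001 * 385
        assert s[1, 2] == pytest.approx(shared, abs=1e-12)
        assert s[0, 1] == pytest.approx(shared + 0.001 * 2485, abs=1e-12)

    def test_below_first_threshold_scores_zero(self):
        t = stat_matrix(2, {(0, 1): 0.05})
        assert tfnbs_scores(t, make_mask([(0, 1)], 2))[0, 1] == 0.0

    def test_all_negative_under_right_tail_is_zero_matrix(self):
        t = stat_matrix(3, {(0, 1): -2.0, (1, 2): -1.0})
        s = tfnbs_scores(t, make_mask([(0, 1), (1, 2)], 3),
                         TFNBSParams(tail="right"))
        assert np.nansum(s) == 0.0

    @pytest.mark.parametrize("s_val", [1.0, 2.0, 3.0, 5.0])
    def test_isolated_edge_closed_form_limit(self, s_val):
        t = stat_matrix(2, {(0, 1): s_val})
        score = tfnbs_scores(t, make_mask([(0, 1)], 2))[0, 1]
        assert abs(score - s_val**3 / 3) <= s_val**2 * 0.1

    def test_fast_scorer_equals_direct_summation(self):
        rng = np.random.default_rng(2)
        for tail in ("two", "left", "right"):
            for _ in range(5):
                n = 10
                mask = all_pairs_mask(n)
                t = np.zeros((n, n))
                iu = np.triu_indices(n, 1)
                t[iu] = rng.normal(0, 1.5, iu[0].size)
                t = t + t.T
                params = TFNBSParams(tail=tail)
                np.testing.assert_allclose(
                    tfnbs_scores(t, mask, params),
                    tfnbs_scores_direct(t, mask, params), atol=1e-10)

    def test_monotone_in_single_edge_statistic(self):
        rng = np.random.default_rng(3)
        n = 8
        mask = all_pairs_mask(n)
        iu = np.triu_indices(n, 1)
        t = np.zeros((n, n))
        t[iu] = rng.uniform(0, 3, iu[0].size)
        t = t + t.T
        base = tfnbs_scores(t, mask, TFNBSParams(tail="right"))
        bumped = t.copy()
        bumped[2, 5] = bumped[5, 2] = bumped[2, 5] + 1.0
        raised = tfnbs_scores(bumped, mask, TFNBSParams(tail="right"))
        finite = np.isfinite(base)
        assert np.all(raised[finite] >= base[finite] - 1e-12)


@pytest.fixture(scope="module")
def planted(study_cohort):
    effects = EffectSpec(affected_edges=default_planted_edges(),
                         beta_interaction=-0.05, noise_sd=0.1)
    return simulate_fc(study_cohort, 8, effects, seed=4)


class TestPermutationFwe:
    def test_planted_network_attains_minimal_p(self, study_cohort, planted):
        X = build_design(study_cohort, "full")
        mask = all_pairs_mask(8)
        res = permutation_fwe(planted.fc_observed, X, "group_x_psqi", mask,
                              TFNBSParams(tail="left", n_perm=200, seed=5))
        min_p = res.min_p()
        assert min_p <= 0.05
        iu = np.triu_indices(8, 1)
        argmin = np.nanargmin(res.p_fwe[iu])
        assert (iu[0][argmin], iu[1][argmin]) in default_planted_edges()
        for i, j in default_planted_edges():
            assert res.p_fwe[i, j] <= 0.05

    def test_p_monotone_nonincreasing_in_score(self, study_cohort, planted):
        X = build_design(study_cohort, "full")
        mask = all_pairs_mask(8)
        res = permutation_fwe(planted.fc_observed, X, "group_x_psqi", mask,
                              TFNBSParams(tail="left", n_perm=100, seed=6))
        iu = np.triu_indices(8, 1)
        order = np.argsort(res.score[iu])
        p_sorted = res.p_fwe[iu][order]
        assert np.all(np.diff(p_sorted) <= 1e-12)
        assert np.all((res.p_fwe[iu] > 0) & (res.p_fwe[iu] <= 1))

    def test_deterministic_replay(self, study_cohort, planted):
        X = build_design(study_cohort, "full")
        mask = all_pairs_mask(8)
        params = TFNBSParams(tail="left", n_perm=50, seed=7)
        a = permutation_fwe(planted.fc_observed, X, "group_x_psqi", mask, params)
        b = permutation_fwe(planted.fc_observed, X, "group_x_psqi", mask, params)
        np.testing.assert_array_equal(a.null_max, b.null_max)
        np.testing.assert_array_equal(np.nan_to_num(a.p_fwe), np.nan_to_num(b.p_fwe))

    def test_single_permutation_p_values(self, study_cohort, planted):
        X = build_design(study_cohort, "full")
        mask = all_pairs_mask(8)
        res = permutation_fwe(planted.fc_observed, X, "group_x_psqi", mask,
                              TFNBSParams(tail="left", n_perm=1, seed=8))
        iu = np.triu_indices(8, 1)
        assert set(np.round(res.p_fwe[iu], 12)) <= {0.5, 1.0}

    def test_simple_scheme_runs_and_differs(self, study_cohort, planted):
        X = build_design(study_cohort, "full")
        mask = all_pairs_mask(8)
        fl = permutation_fwe(planted.fc_observed, X, "group_x_psqi", mask,
                             TFNBSParams(tail="left", n_perm=50, seed=9))
        sp = permutation_fwe(planted.fc_observed, X, "group_x_psqi", mask,
                             TFNBSParams(tail="left", n_perm=50, seed=9,
                                         scheme="simple"))
        assert not np.array_equal(fl.null_max, sp.null_max)


def test_tail_statistic_conventions():
    t = np.array([-2.0, 0.5])
    np.testing.assert_array_equal(tail_statistic(t, "two"), [2.0, 0.5])
    np.testing.assert_array_equal(tail_statistic(t, "left"), [2.0, -0.5])
    np.testing.assert_array_equal(tail_statistic(t, "right"), t)
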