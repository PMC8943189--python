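import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemiconn.core_io import Connectome, ValidationError, split_hemispheres
from hemiconn.synthetic_cohort import GeneratorConfig, simulate_cohort
from hemiconn.tfnbs import (
    StatMatrix,
    TfnbsParams,
    TfnbsResult,
    paired_edge_statistic,
    permutation_fwe,
    significant_edges,
    tfnbs_transform,
)

from _oracles import component_extent_scores


def _mirror_weights(toy_connectome):
    """Mirror-symmetrized toy weights (lh block copied onto rh block)."""
    w = toy_connectome.weights.copy()
    for i, j in ((0, 1), (0, 2), (1, 2)):
        w[i + 3, j + 3] = w[j + 3, i + 3] = w[i, j]
    for i in range(3):
        w[i + 3, 6] = w[6, i + 3] = w[i, 6]
    return w


def _pairs_from_edge_values(toy_connectome, values_ipsi, values_contra, sides=None):
    """Build hemispheric pairs whose region (a, b) edge carries the given
    per-subject ipsi/contra weights; all other edges mirror-symmetric, so
    only that edge has a nonzero hemispheric difference."""
    pairs = []
    n = len(values_ipsi)
    sides = sides or ["right"] * n
    base = _mirror_weights(toy_connectome)
    for vi, vc, side in zip(values_ipsi, values_contra, sides):
        w = base.copy()
        i_ipsi, j_ipsi = (3, 4) if side == "right" else (0, 1)
        i_con, j_con = (0, 1) if side == "right" else (3, 4)
        w[i_ipsi, j_ipsi] = w[j_ipsi, i_ipsi] = vi
        w[i_con, j_con] = w[j_con, i_con] = vc
        conn = Connectome(toy_connectome.nodes, w)
        pairs.append(split_hemispheres(conn, side))
    return pairs


class TestPairedEdgeStatistic:
    def test_identical_hemispheres_give_zero_t(self, toy_connectome):
        conn = Connectome(toy_connectome.nodes, _mirror_weights(toy_connectome))
        pairs = [split_hemispheres(conn, s) for s in ("left", "right", "left", "right")]
        stat = paired_edge_statistic(pairs)
        assert np.all(stat.t_values == 0)

    def test_intercept_t_matches_ols_oracle(self, toy_connectome):
        """Five subjects, single manipulated edge, d=(1,2,3,2,1) with side
        (-1,-1,+1,+1,+1): the intercept t must match an explicit OLS fit."""
        import statsmodels.api as sm

        d = [1.0, 2.0, 3.0, 2.0, 1.0]
        sides = ["left", "left", "right", "right", "right"]
        base = 10.0
        pairs = _pairs_from_edge_values(
            toy_connectome, [base] * 5, [base + x for x in d], sides
        )
        stat = paired_edge_statistic(pairs)
        side = np.array([-1.0, -1.0, 1.0, 1.0, 1.0])
        fit = sm.OLS(np.array(d), sm.add_constant(side - side.mean())).fit()
        edge = stat.labels.index("a"), stat.labels.index("b")
        assert stat.t_values[edge] == pytest.approx(fit.tvalues[0], rel=1e-10)

    def test_direction_swap_truncates_opposite_effects(self, toy_connectome):
        pairs = _pairs_from_edge_values(
            toy_connectome, [10.0] * 5, [14.0, 15.0, 16.0, 15.0, 14.0],
            ["left", "left", "right", "right", "right"],
        )
        up = paired_edge_statistic(pairs, direction="contra_gt_ipsi")
        down = paired_edge_statistic(pairs, direction="ipsi_gt_contra")
        edge = up.labels.index("a"), up.labels.index("b")
        assert up.t_values[edge] > 0
        assert down.t_values[edge] == 0

    def test_requires_three_subjects(self, toy_connectome):
        pairs = _pairs_from_edge_values(toy_connectome, [1.0, 2.0], [1.0, 2.0], ["left", "right"])
        with pytest.raises(ValidationError, match=">= 3"):
            paired_edge_statistic(pairs)


class TestTfnbsTransform:
    def test_all_zero_stats_give_all_zero_scores(self):
        scores = tfnbs_transform(np.zeros((6, 6)), TfnbsParams())
        assert np.all(scores == 0)

    @pytest.mark.parametrize("mode", ["component", "incident"])
    def test_isolated_edge_closed_form(self, mode):
        """Single edge t=2 with unit extent: score -> integral of h^3 from 0
        to 2 = 4.0; within 0.5% at n_steps=1000."""
        t = np.zeros((5, 5))
        t[0, 1] = t[1, 0] = 2.0
        params = TfnbsParams(n_steps=1000, extent_mode=mode)
        score = tfnbs_transform(t, params)[0, 1]
        assert score == pytest.approx(4.0, rel=0.005)

    @pytest.mark.parametrize("mode", ["component", "incident"])
    def test_scaling_as_c_to_h_plus_one(self, mode):
        rng = np.random.default_rng(7)
        t = np.triu(rng.random((6, 6)), 1)
        t = t + t.T
        params = TfnbsParams(n_steps=200, extent_mode=mode)
        c = 3.5
        s1 = tfnbs_transform(t, params)
        s2 = tfnbs_transform(c * t, params)
        # adaptive grid: thresholds scale with the map, extents unchanged
        assert np.allclose(s2, c**4 * s1, rtol=1e-9)

    @pytest.mark.parametrize("mode", ["component", "incident"])
    def test_adjacent_edges_score_higher_than_disjoint(self, mode):
        disjoint = np.zeros((4, 4))
        disjoint[0, 1] = disjoint[1, 0] = 2.0
        disjoint[2, 3] = disjoint[3, 2] = 2.0
        adjacent = np.zeros((4, 4))
        adjacent[0, 1] = adjacent[1, 0] = 2.0
        adjacent[1, 2] = adjacent[2, 1] = 2.0
        params = TfnbsParams(n_steps=500, extent_mode=mode)
        s_dis = tfnbs_transform(disjoint, params)[0, 1]
        s_adj = tfnbs_transform(adjacent, params)[0, 1]
        assert s_adj > s_dis

    def test_component_mode_matches_library_component_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            t = np.triu((rng.random((8, 8)) < 0.4) * rng.random((8, 8)) * 3, 1)
            t = t + t.T
            params = TfnbsParams(n_steps=50, extent_mode="component")
            mine = tfnbs_transform(t, params)
            oracle = component_extent_scores(t, 50, 0.4, 3.0)
            assert np.allclose(mine, oracle, rtol=1e-9, atol=1e-12)

    def test_negative_statistic_rejected(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = -1.0
        with pytest.raises(ValidationError, match="negative"):
            tfnbs_transform(t)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        bump=st.floats(min_value=0.0, max_value=3.0),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_monotone_in_single_edge_statistic(self, bump, seed):
        """Raising one edge's t never decreases that edge's score."""
        rng = np.random.default_rng(seed)
        t = np.triu((rng.random((6, 6)) < 0.5) * rng.random((6, 6)), 1)
        t = t + t.T
        params = TfnbsParams(n_steps=100)
        before = tfnbs_transform(t, params)[0, 1]
        t2 = t.copy()
        t2[0, 1] = t2[1, 0] = t[0, 1] + bump
        after = tfnbs_transform(t2, params)[0, 1]
        assert after >= before - 1e-9 * max(before, 1.0)


@pytest.fixture(scope="module")
def effect_cohort():
    cfg = GeneratorConfig(seed=42, subgroup_weights=(1, 0, 0, 0))
    cohort = simulate_cohort(cfg)
    pairs = [
        split_hemispheres(s.connectome_a, s.clinical.lesion_side)
        for s in cohort.subjects
    ]
    return cohort, pairs


class TestPermutationFwe:
    def test_p_floor_and_result_invariants(self, effect_cohort):
        _, pairs = effect_cohort
        params = TfnbsParams(n_perm=199, seed=3)
        res = permutation_fwe(pairs, params)
        iu = np.triu_indices(40, k=1)
        p = res.p_fwe[iu]
        assert p.min() >= 1 / 200 and p.max() <= 1.0
        assert np.all(res.scores >= 0)
        # monotone: larger score implies smaller-or-equal p
        order = np.argsort(-res.scores[iu])
        assert np.all(np.diff(p[order]) >= 0)

    def test_injected_effect_edges_attain_smallest_p(self, effect_cohort):
        cohort, pairs = effect_cohort
        res = permutation_fwe(pairs, TfnbsParams(n_perm=300, seed=5))
        truth = set()
        for s in cohort.subjects:
            truth |= {tuple(e) for e in s.truth.affected_edges}
        labels = res.labels
        iu, ju = np.triu_indices(40, k=1)
        ranked = sorted(
            zip(res.p_fwe[iu, ju], [tuple(sorted((labels[i], labels[j]))) for i, j in zip(iu, ju)])
        )
        top = {edge for _, edge in ranked[: len(truth)]}
        assert len(top & truth) / len(truth) > 0.8

    def test_constant_covariate_equals_pure_sign_flip(self, toy_connectome):
        """With a constant side covariate Freedman-Lane must reduce to pure
        sign flipping: identical null maxima at a fixed seed."""
        rng = np.random.default_rng(0)
        values_c = list(10 + rng.random(6) * 2)
        pairs = _pairs_from_edge_values(
            toy_connectome, [10.0] * 6, values_c, ["right"] * 6
        )
        params = TfnbsParams(n_perm=50, seed=9)
        res = permutation_fwe(pairs, params)  # side constant -> covariate dropped

        # manual pure sign-flip reference with the same rng stream
        from hemiconn.tfnbs import _difference_matrix, _edge_scores, _intercept_t

        d, regions, iu, ju = _difference_matrix(pairs)
        rng2 = np.random.default_rng(9)
        ref = []
        for _ in range(50):
            signs = rng2.integers(0, 2, size=len(d)) * 2.0 - 1.0
            t = np.maximum(_intercept_t(signs[:, None] * d, None), 0.0)
            ref.append(_edge_scores(t, iu, ju, len(regions), params).max())
        assert np.allclose(res.null_max, ref)

    def test_excess_permutations_warn(self, toy_connectome):
        pairs = _pairs_from_edge_values(
            toy_connectome, [10.0, 10.0, 10.0], [11.0, 12.0, 10.5],
            ["left", "right", "right"],
        )
        with pytest.warns(UserWarning, match="sign patterns"):
            permutation_fwe(pairs, TfnbsParams(n_perm=16, seed=0))


class TestSignificantEdges:
    def _result(self, p, score):
        labels = ["a", "b", "c"]
        t = np.zeros((3, 3))
        return TfnbsResult(labels, score, p, t, np.zeros(10), "contra_gt_ipsi", TfnbsParams())

    def test_all_p_one_gives_empty_list(self):
        res = self._result(np.ones((3, 3)), np.zeros((3, 3)))
        assert significant_edges(res) == []

    def test_threshold_and_ordering(self):
        p = np.ones((3, 3))
        s = np.zeros((3, 3))
        p[0, 1] = p[1, 0] = 0.04
        p[0, 2] = p[2, 0] = 0.01
        s[0, 1] = s[1, 0] = 5.0
        s[0, 2] = s[2, 0] = 9.0
        res = self._result(p, s)
        rows = significant_edges(res, alpha=0.05)
        assert [(r[0], r[1]) for r in rows] == [("a", "c"), ("a", "b")]

    def test_alpha_zero_returns_empty(self):
        p = np.ones((3, 3)) * 0.001
        res = self._result(p, np.ones((3, 3)))
        assert significant_edges(res, alpha=0.0) == []
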