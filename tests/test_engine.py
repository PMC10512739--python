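"""Block subsampling, vote-rate algebra, and the full SHV loop."""

import numpy as np
import pytest

from shv import (
    ShvConfig,
    SubjectFeatures,
    VoxelMask,
    block_subsample_voxels,
    cluster_vote_rate,
    effective_vote_ratio,
    run_shv,
    score_vector,
    select_lambda,
    select_qualified_loops,
    subsample_trials,
    top_n_selector,
    voxel_vote_rate,
)
from shv.sparse_logistic import GroupFit

from _oracles import cluster_vote_rate_naive, voxel_vote_rate_naive
from conftest import make_separable_subject


class TestBlockSubsampling:
    def test_single_full_block(self, rng):
        mask = VoxelMask.full((3, 3, 3))
        with pytest.warns(RuntimeWarning, match="one block"):
            out = block_subsample_voxels(mask, 0.9, (3, 3, 3), rng)
        assert out.size == 27  # the one block covers (and overshoots) the target

    def test_high_alpha_returns_nearly_all(self, rng):
        mask = VoxelMask.full((6, 6, 3))
        out = block_subsample_voxels(mask, 0.999, (3, 3, 3), rng)
        assert out.size == mask.n_voxels

    def test_target_is_reached_not_overshot_by_a_block(self, rng):
        mask = VoxelMask.full((9, 9, 9))
        for _ in range(10):
            out = block_subsample_voxels(mask, 0.1, (3, 3, 3), rng)
            target = 0.1 * mask.n_voxels
            assert out.size >= target
            assert out.size - 27 < target  # dropping the last block falls short

    def test_returned_indices_are_whole_blocks(self, rng):
        mask = VoxelMask.full((6, 6, 6))
        out = block_subsample_voxels(mask, 0.3, (3, 3, 3), rng)
        blocks = {tuple(c // 3) for c in mask.coords[out]}
        assert out.size == 27 * len(blocks)

    def test_inclusion_frequency_uniform(self, rng):
        """Interior blocks are drawn uniformly: per-voxel inclusion
        frequencies agree within 3 binomial standard errors."""
        mask = VoxelMask.full((6, 6, 6))  # 8 full blocks
        n_rep = 2000
        counts = np.zeros(mask.n_voxels)
        for _ in range(n_rep):
            counts[block_subsample_voxels(mask, 0.3, (3, 3, 3), rng)] += 1
        freq = counts / n_rep
        # 0.3 * 216 = 64.8 -> 3 of 8 blocks drawn each time
        expected = 3 / 8
        se = np.sqrt(expected * (1 - expected) / n_rep)
        assert (np.abs(freq - expected) < 3.5 * se + 0.01).all()

    def test_tiny_alpha_single_block_warns(self, rng):
        mask = VoxelMask.full((6, 6, 6))
        with pytest.warns(RuntimeWarning, match="one block"):
            out = block_subsample_voxels(mask, 0.001, (3, 3, 3), rng)
        assert out.size == 27


class TestTrialSubsampling:
    def test_balanced_split_arithmetic(self, rng):
        y = np.array([1] * 20 + [-1] * 20)
        train, test = subsample_trials(y, 0.9, rng)
        assert train.size == 36 and test.size == 4
        assert (y[train] == 1).sum() == 18 and (y[test] == 1).sum() == 2

    def test_near_full_leaves_one_per_class(self, rng):
        y = np.array([1] * 5 + [-1] * 5)
        train, test = subsample_trials(y, 0.99, rng)
        assert test.size == 2
        assert set(y[test]) == {1, -1}

    def test_train_test_disjoint_cover(self, rng):
        y = np.array([1] * 7 + [-1] * 9)
        train, test = subsample_trials(y, 0.7, rng)
        assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(16))

    def test_inclusion_frequency_matches_alpha(self, rng):
        y = np.array([1] * 10 + [-1] * 10)
        n_rep = 4000
        counts = np.zeros(20)
        for _ in range(n_rep):
            train, _ = subsample_trials(y, 0.8, rng)
            counts[train] += 1
        freq = counts / n_rep
        se = np.sqrt(0.8 * 0.2 / n_rep)
        assert (np.abs(freq - 0.8) < 4 * se).all()

    def test_tiny_class_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            subsample_trials(np.array([1, -1, -1]), 0.5, rng)


def _fit(W, ids):
    return GroupFit(W=W, b=np.zeros(W.shape[1]), lam=0.0,
                    cluster_ids=np.asarray(ids), objective_trace=np.array([0.0]))


class TestVoteAlgebra:
    def test_score_vector_single_fit_absolute(self):
        fit = _fit(np.array([[2.0], [-3.0]]), [1, 4])
        s = score_vector([fit], 0, n_clusters=6)
        assert np.array_equal(s, [0, 2, 0, 0, 3, 0])

    def test_score_vector_averages_absolutes(self):
        f1 = _fit(np.array([[2.0]]), [0])
        f2 = _fit(np.array([[-2.0]]), [0])
        s = score_vector([f1, f2], 0, n_clusters=2)
        assert s[0] == 2.0  # |+2| and |-2| average to 2, not 0

    def test_score_vector_matches_loop_oracle(self, rng):
        fits = [_fit(rng.standard_normal((4, 3)), [0, 2, 5, 7]) for _ in range(3)]
        s = score_vector(fits, 1, n_clusters=8)
        expect = np.zeros(8)
        for j, cid in enumerate([0, 2, 5, 7]):
            expect[cid] = np.mean([abs(f.W[j, 1]) for f in fits])
        assert np.allclose(s, expect)

    def test_selector_all_zero(self):
        assert top_n_selector(np.zeros(5), 3).sum() == 0

    def test_selector_fewer_nonzeros_than_requested(self):
        sel = top_n_selector(np.array([0.0, 2.0, 0.0, 1.0]), 4)
        assert sel.sum() == 2 and sel[1] == 1 and sel[3] == 1

    def test_selector_tie_breaks_to_lower_id(self):
        sel = top_n_selector(np.array([5.0, 3.0, 3.0, 1.0]), 2)
        assert np.array_equal(sel, [1, 1, 0, 0])

    def test_qualified_loops_all_when_alpha_one(self, rng):
        acc = rng.random(10)
        assert np.array_equal(select_qualified_loops(acc, 1.0), np.arange(10))

    def test_qualified_loops_count_floor(self, rng):
        acc = rng.random(200)
        assert select_qualified_loops(acc, 0.3).size == 60

    def test_qualified_loops_sort_oracle(self, rng):
        acc = rng.random(37)
        got = select_qualified_loops(acc, 0.25)
        expect = np.sort(np.argsort(-acc, kind="stable")[: int(0.25 * 37)])
        assert np.array_equal(got, expect)

    def test_min_precision_filters(self):
        acc = np.array([0.9, 0.4, 0.8, 0.3])
        got = select_qualified_loops(acc, 1.0, min_precision=0.75)
        assert np.array_equal(got, [0, 2])

    def test_min_precision_keeps_best_when_all_fail(self):
        with pytest.warns(RuntimeWarning, match="single best"):
            got = select_qualified_loops(np.array([0.2, 0.5, 0.4]), 1.0, min_precision=0.9)
        assert np.array_equal(got, [1])

    def test_cluster_vote_rate_unanimous(self):
        scores = np.zeros((4, 6))
        scores[:, [1, 3]] = [2.0, 1.0]
        phi = cluster_vote_rate([scores, scores, scores], n_sel=2)
        assert np.array_equal(phi, [0, 1, 0, 1, 0, 0])

    def test_cluster_vote_rate_single_subject_binary(self, rng):
        scores = rng.random((5, 7))
        phi = cluster_vote_rate([scores], n_sel=3)
        assert set(np.unique(phi)) <= {0.0, 1.0}
        assert phi.sum() <= 3

    def test_cluster_vote_rate_matches_nested_oracle(self, rng):
        selected = [rng.random((rng.integers(2, 6), 9)) * (rng.random((1, 9)) > 0.3)
                    for _ in range(3)]
        got = cluster_vote_rate(selected, n_sel=3)
        expect = cluster_vote_rate_naive(selected, 3)
        assert np.allclose(got, expect)
        # entries are multiples of 1/N_S
        assert np.allclose(got * 3, np.round(got * 3))

    def test_voxel_vote_rate_half(self, toy_parcellation):
        sel_yes = np.zeros(6); sel_yes[0] = 1
        sel_no = np.zeros(6)
        loops = [(np.array([0]), sel_yes), (np.array([0]), sel_no)]
        rate = voxel_vote_rate(loops, toy_parcellation)
        assert rate[0] == 0.5 and rate[1] == 0.0

    def test_voxel_vote_rate_always_selected(self, toy_parcellation):
        sel = np.zeros(6); sel[2] = 1
        loops = [(np.array([20, 21]), sel), (np.array([20]), sel), (np.array([25]), sel)]
        rate = voxel_vote_rate(loops, toy_parcellation)
        assert rate[20] == 1.0 and rate[21] == 1.0 and rate[25] == 1.0

    def test_voxel_vote_rate_matches_indicator_oracle(self, rng, toy_parcellation):
        loops = []
        for _ in range(5):
            sampled = rng.choice(60, size=rng.integers(5, 30), replace=False)
            sel = (rng.random(6) > 0.5).astype(float)
            loops.append((sampled, sel))
        got = voxel_vote_rate(loops, toy_parcellation)
        expect = voxel_vote_rate_naive(loops, toy_parcellation.labels)
        assert np.allclose(got, expect)

    def test_evr_product_and_zeroing(self, toy_parcellation):
        vv = np.linspace(0, 1, 60)
        phi = np.array([0.0, 1.0, 2 / 3, 0.5, 0.0, 1.0])
        evr = effective_vote_ratio(vv, phi, toy_parcellation)
        assert (evr[toy_parcellation.labels == 0] == 0).all()
        v = 25  # cluster 2
        assert np.isclose(evr[v], vv[v] * 2 / 3)
        assert np.isclose(effective_vote_ratio(np.full(60, 0.8), phi, toy_parcellation)[v],
                          0.8 * 2 / 3)


@pytest.fixture
def tiny_group(rng, toy_parcellation):
    subjects = [
        make_separable_subject(rng, toy_parcellation, informative=(0, 3),
                               n_trials=24, noise=0.2, subject_id=f"s{i}")
        for i in range(3)
    ]
    mask = VoxelMask.full((5, 4, 3))
    return subjects, toy_parcellation, mask


class TestRunShv:
    def test_deterministic_under_seed(self, tiny_group):
        subjects, parc, mask = tiny_group
        cfg = ShvConfig(n_k=4, n_l=2, alpha_col=0.4, alpha_row=0.8, alpha_k=0.5,
                        n_sel=2, seed=5, block_size=(2, 2, 2), fit_tol=1e-8)
        r1 = run_shv(subjects, parc, cfg, 1.0, mask=mask)
        r2 = run_shv(subjects, parc, cfg, 1.0, mask=mask)
        assert np.array_equal(r1.scores, r2.scores)
        assert np.array_equal(r1.evr, r2.evr)
        assert np.array_equal(r1.cluster_votes, r2.cluster_votes)

    def test_vote_rate_inequalities(self, tiny_group):
        subjects, parc, mask = tiny_group
        cfg = ShvConfig(n_k=6, n_l=2, alpha_col=0.4, alpha_row=0.8, alpha_k=0.5,
                        n_sel=2, seed=9, block_size=(2, 2, 2), fit_tol=1e-8)
        res = run_shv(subjects, parc, cfg, 1.0, mask=mask)
        phi_c = res.cluster_votes
        assert ((0 <= phi_c) & (phi_c <= 1)).all()
        assert np.allclose(phi_c * len(subjects), np.round(phi_c * len(subjects)))
        assert (phi_c > 0).sum() <= cfg.n_sel * len(subjects)
        for i in range(len(subjects)):
            vv, evr = res.voxel_votes[i], res.evr[i]
            assert ((0 <= evr) & (evr <= vv + 1e-12) & (vv <= 1)).all()
            assert (evr <= phi_c[parc.labels] + 1e-12).all()

    def test_separable_toy_selects_informative_clusters(self, tiny_group):
        subjects, parc, mask = tiny_group
        cfg = ShvConfig(n_k=8, n_l=3, alpha_col=0.6, alpha_row=0.8, alpha_k=0.5,
                        n_sel=2, seed=2, block_size=(2, 2, 2), fit_tol=1e-8)
        res = run_shv(subjects, parc, cfg, 0.5, mask=mask)
        top2 = np.lexsort((np.arange(6), -res.cluster_votes))[:2]
        assert set(top2.tolist()) == {0, 3}
        # EVR concentrates on the informative clusters
        informative = np.isin(parc.labels, [0, 3])
        assert res.mean_evr[informative].mean() > res.mean_evr[~informative].mean()

    def test_scrambled_labels_near_chance_overall(self, tiny_group, rng):
        subjects, parc, mask = tiny_group
        null = [SubjectFeatures(X=s.X, y=rng.permutation(s.y), subject_id=s.subject_id)
                for s in subjects]
        cfg = ShvConfig(n_k=6, n_l=3, alpha_col=0.5, alpha_row=0.8, alpha_k=1.0,
                        n_sel=2, seed=4, block_size=(2, 2, 2), fit_tol=1e-6)
        res = run_shv(null, parc, cfg, 2.0, mask=mask)
        assert 0.35 < res.test_acc.mean() < 0.65

    def test_select_lambda_prefers_discriminative_penalty(self, tiny_group):
        subjects, parc, mask = tiny_group
        from shv import average_features, lambda_max

        feats = [average_features(s, parc, np.arange(parc.n_voxels)) for s in subjects]
        lmax = lambda_max(feats, [s.y for s in subjects])
        cfg = ShvConfig(n_k=4, n_l=2, alpha_col=0.5, alpha_row=0.8, alpha_k=0.5,
                        n_sel=2, seed=3, block_size=(2, 2, 2),
                        lambda_grid=(0.05 * lmax, 10 * lmax), fit_tol=1e-8)
        best, r_bar, results = select_lambda(subjects, parc, cfg, mask=mask)
        assert best == 0.05 * lmax  # the huge penalty predicts at chance
        assert r_bar[best] > r_bar[10 * lmax]
        # R_bar recomputed from stored accuracies matches
        res = results[best]
        expect = np.mean([res.test_acc[i, res.qualified_loops[i]].mean()
                          for i in range(len(subjects))])
        assert np.isclose(r_bar[best], expect)

    def test_shared_plan_across_candidates(self, tiny_group):
        subjects, parc, mask = tiny_group
        cfg = ShvConfig(n_k=3, n_l=2, alpha_col=0.5, alpha_row=0.8, alpha_k=1.0,
                        n_sel=2, seed=8, block_size=(2, 2, 2),
                        lambda_grid=(0.1, 1.0), fit_tol=1e-6)
        _, _, results = select_lambda(subjects, parc, cfg, mask=mask)
        a, b = results[0.1], results[1.0]
        for k in range(cfg.n_k):
            assert np.array_equal(a.voxel_sets[k], b.voxel_sets[k])
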