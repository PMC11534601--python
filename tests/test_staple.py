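"""STAPLE consensus fusion: EM contract, oracle equality, recovery."""
import numpy as np
import pytest

from m3sl.errors import AlignmentError, DegenerateInputError
from m3sl.metrics import confusion_counts, f_measure
from m3sl.staple import binarize_consensus, majority_vote, staple
from m3sl.types import BinaryMask

from conftest import simulated_raters


def brute_force_staple(votes, prior, init_pq=0.99, eps=1e-5, tol=1e-6, max_iter=100):
    """Independent per-voxel EM oracle written element-by-element from the
    update equations; returns the (p, q) trajectory and final posteriors."""
    R, n = votes.shape
    p = [init_pq] * R
    q = [init_pq] * R
    trajectory = []
    W = [0.0] * n
    for _ in range(max_iter):
        for i in range(n):
            a = prior
            b = 1.0 - prior
            for j in range(R):
                if votes[j, i]:
                    a *= p[j]
                    b *= 1.0 - q[j]
                else:
                    a *= 1.0 - p[j]
                    b *= q[j]
            W[i] = a / (a + b)
        sum_w = sum(W)
        sum_nw = sum(1.0 - w for w in W)
        p_new, q_new = [], []
        for j in range(R):
            num_p = sum(W[i] for i in range(n) if votes[j, i])
            num_q = sum(1.0 - W[i] for i in range(n) if not votes[j, i])
            p_new.append(min(max(num_p / sum_w, eps), 1.0 - eps))
            q_new.append(min(max(num_q / sum_nw, eps), 1.0 - eps))
        delta = max(
            max(abs(a - b) for a, b in zip(p_new, p)),
            max(abs(a - b) for a, b in zip(q_new, q)),
        )
        p, q = p_new, q_new
        trajectory.append((list(p), list(q)))
        if delta < tol:
            break
    return trajectory, p, q


class TestStapleContract:
    def test_unanimous_raters_yield_confident_consensus(self):
        grid = np.zeros((6, 6, 6), bool)
        grid[2:4, 2:4, 2:4] = True
        masks = [BinaryMask(data=grid.copy(), role="bronze") for _ in range(3)]
        res = staple(masks)
        assert res.consensus_prob[grid].min() > 0.99
        assert res.consensus_prob[~grid].max() < 0.01
        for perf in res.performances:
            assert perf.p == pytest.approx(1 - 1e-5)
            assert perf.q == pytest.approx(1 - 1e-5)

    def test_complementary_raters_are_a_symmetric_fixed_point(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[:2] = True
        masks = [
            BinaryMask(data=grid, role="bronze"),
            BinaryMask(data=~grid, role="bronze"),
        ]
        res = staple(masks, prior=0.5)
        np.testing.assert_allclose(res.consensus_prob, 0.5, atol=1e-9)

    def test_fewer_than_two_masks_rejected(self):
        m = BinaryMask(data=np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError, match=">= 2"):
            staple([m])

    def test_mismatched_shapes_rejected(self):
        a = BinaryMask(data=np.ones((3, 3, 3), bool))
        b = BinaryMask(data=np.ones((4, 4, 4), bool))
        with pytest.raises(AlignmentError):
            staple([a, b])

    def test_all_empty_union_rejected(self):
        masks = [BinaryMask(data=np.zeros((4, 4, 4), bool)) for _ in range(3)]
        with pytest.raises(DegenerateInputError, match="empty"):
            staple(masks)

    def test_permuting_raters_permutes_performances(self, rng):
        truth = np.zeros((10, 10, 10), bool)
        truth[3:7, 3:7, 3:7] = True
        masks = simulated_raters(truth, [(0.9, 0.99), (0.8, 0.98), (0.7, 0.97)], seed=4)
        res = staple(masks)
        res_perm = staple([masks[2], masks[0], masks[1]])
        np.testing.assert_allclose(
            res.consensus_prob, res_perm.consensus_prob, atol=1e-12
        )
        assert res_perm.performances[0].p == pytest.approx(res.performances[2].p)
        assert res_perm.performances[1].p == pytest.approx(res.performances[0].p)

    def test_loglikelihood_nondecreasing(self, rng):
        truth = np.zeros((12, 12, 12), bool)
        truth[4:9, 4:9, 4:9] = True
        masks = simulated_raters(truth, [(0.9, 0.97), (0.75, 0.99), (0.6, 0.95)], seed=9)
        res = staple(masks)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)


class TestStapleOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_em_trajectory_matches_brute_force_on_tiny_grids(self, seed):
        r = np.random.default_rng(seed)
        grid_masks = [r.random((4, 4, 4)) < 0.3 for _ in range(3)]
        if not np.any(np.logical_or.reduce(grid_masks)):
            grid_masks[0][0, 0, 0] = True
        masks = [BinaryMask(data=g, role="bronze") for g in grid_masks]
        prior = 0.4
        res = staple(masks, prior=prior, margin=5)
        votes = np.stack([g.ravel() for g in grid_masks])
        _, p_oracle, q_oracle = brute_force_staple(votes, prior)
        for perf, po, qo in zip(res.performances, p_oracle, q_oracle):
            assert perf.p == pytest.approx(po, abs=1e-10)
            assert perf.q == pytest.approx(qo, abs=1e-10)

    def test_bounding_box_equals_dense_computation(self, rng):
        truth = np.zeros((20, 20, 20), bool)
        truth[8:12, 8:12, 8:12] = True
        masks = simulated_raters(truth, [(0.9, 0.999), (0.8, 0.999)], seed=2)
        tight = staple(masks, margin=1)
        dense = staple(masks, margin=50)
        np.testing.assert_allclose(
            tight.consensus_prob, dense.consensus_prob, atol=1e-12
        )

    def test_agrees_with_simpleitk_reference(self):
        """Cross-check the fused posterior against an independent STAPLE
        implementation on a small fixture."""
        sitk = pytest.importorskip("SimpleITK")
        truth = np.zeros((12, 12, 12), bool)
        truth[3:9, 3:9, 3:9] = True
        masks = simulated_raters(truth, [(0.95, 0.99), (0.85, 0.98), (0.9, 0.97)], seed=5)
        # ITK's STAPLE fixes the prior at the mean foreground fraction of
        # the inputs; match that convention for the comparison
        votes = np.stack([m.data for m in masks])
        res = staple(masks, prior=float(votes.mean()))
        imgs = [sitk.GetImageFromArray(m.data.astype(np.uint8)) for m in masks]
        ref = sitk.GetArrayFromImage(sitk.STAPLE(imgs, 1.0))
        assert np.abs(res.consensus_prob - ref).max() < 1e-4


class TestParameterRecovery:
    SPECS = [(0.90, 0.99), (0.75, 0.995), (0.85, 0.98)]

    def test_recovery_within_tolerance_across_seeds(self):
        """Sensitivity within +-0.05 and specificity within +-0.01 of the
        generating values, on >= 10^4-voxel grids over 5 seeds."""
        p_errs, q_errs = [], []
        for seed in range(5):
            truth = np.zeros((40, 40, 40), bool)
            truth[10:20, 10:20, 10:20] = True
            masks = simulated_raters(truth, self.SPECS, seed=seed)
            res = staple(masks)
            for perf, (p_true, q_true) in zip(res.performances, self.SPECS):
                p_errs.append(abs(perf.p - p_true))
                q_errs.append(abs(perf.q - q_true))
        assert float(np.mean(p_errs)) <= 0.05
        assert max(q_errs) <= 0.01

    def test_silver_f_beats_best_single_rater(self):
        truth = np.zeros((40, 40, 40), bool)
        truth[10:20, 10:20, 10:20] = True
        gt = BinaryMask(data=truth, role="gold")
        masks = simulated_raters(truth, self.SPECS, seed=0)
        silver = binarize_consensus(staple(masks))
        f_silver = f_measure(confusion_counts(silver, gt))
        f_raters = [f_measure(confusion_counts(m, gt)) for m in masks]
        assert f_silver >= max(f_raters)


class TestBinarizeConsensus:
    def test_unanimous_at_half_threshold_returns_input(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[1:3, 1:3, 1:3] = True
        masks = [BinaryMask(data=grid.copy()) for _ in range(3)]
        out = binarize_consensus(staple(masks), 0.5)
        np.testing.assert_array_equal(out.data, grid)
        assert out.role == "silver"

    def test_tie_rule_is_inclusive(self):
        from m3sl.staple import StapleResult

        res = StapleResult(
            consensus_prob=np.full((3, 3, 3), 0.5),
            performances=[],
            iterations=1,
            converged=True,
            prior=0.5,
            loglik_trace=[],
        )
        out = binarize_consensus(res, 0.5)
        assert out.data.all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_outside_open_interval_rejected(self, bad):
        from m3sl.staple import StapleResult

        res = StapleResult(
            consensus_prob=np.zeros((2, 2, 2)), performances=[], iterations=0,
            converged=True, prior=0.5, loglik_trace=[],
        )
        with pytest.raises(ValueError):
            binarize_consensus(res, bad)


class TestMajorityVote:
    def test_identical_masks_fixed_point(self):
        grid = np.zeros((4, 4, 4), bool)
        grid[0] = True
        masks = [BinaryMask(data=grid.copy()) for _ in range(3)]
        np.testing.assert_array_equal(majority_vote(masks).data, grid)

    def test_two_of_three_votes_true(self):
        a = np.zeros((2, 2, 2), bool)
        b = np.zeros((2, 2, 2), bool)
        c = np.zeros((2, 2, 2), bool)
        a[0, 0, 0] = b[0, 0, 0] = True
        out = majority_vote([BinaryMask(data=g) for g in (a, b, c)])
        assert out.data[0, 0, 0] and out.data.sum() == 1

    def test_agrees_with_staple_for_good_symmetric_raters(self):
        truth = np.zeros((30, 30, 30), bool)
        truth[8:22, 8:22, 8:22] = True
        masks = simulated_raters(truth, [(0.92, 0.95)] * 3, seed=7)
        mv = majority_vote(masks)
        st_mask = binarize_consensus(staple(masks))
        assert (mv.data == st_mask.data).mean() >= 0.95
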