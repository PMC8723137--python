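"""Reranking, thresholding, fusion, ranking and the statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from voxscreen.errors import InputError
from voxscreen.screening import (
    PairingRecord,
    ScoredPose,
    combine_scores,
    dock_pairing_score,
    mean_test,
    poisson_rate_test,
    rank_candidates,
    ratio_std,
    rerank_poses,
    rescore_max,
    summarize_topn,
    threshold_pairings,
    vs_pairing_score,
)


def make_poses(pred_fnats, dock_scores=None, vs_scores=None):
    n = len(pred_fnats)
    dock_scores = dock_scores or [0.0] * n
    vs_scores = vs_scores or [None] * n
    return [
        ScoredPose(pose_rank=i + 1, dock_score=d, pred_fnat=p, vs_score=v)
        for i, (p, d, v) in enumerate(zip(pred_fnats, dock_scores, vs_scores))
    ]


def make_pairing(antigen="ag", antibody="ab", cognate=False, **scores):
    rec = PairingRecord(antigen_id=antigen, antibody_id=antibody, is_cognate=cognate)
    for k, v in scores.items():
        setattr(rec, k, v)
    return rec


class TestRerank:
    def test_descending_by_prediction(self):
        poses = make_poses([0.1, 0.9, 0.5])
        assert [p.pose_rank for p in rerank_poses(poses)] == [2, 3, 1]

    def test_ties_keep_docking_order(self):
        poses = make_poses([0.5, 0.5, 0.5])
        assert [p.pose_rank for p in rerank_poses(poses)] == [1, 2, 3]

    def test_matches_sort_oracle(self, rng):
        scores = rng.uniform(size=200)
        poses = make_poses(list(scores))
        expected = [
            p.pose_rank
            for p in sorted(poses, key=lambda q: (-q.pred_fnat, q.pose_rank))
        ]
        assert [p.pose_rank for p in rerank_poses(poses)] == expected

    def test_unscored_pose_rejected(self):
        poses = make_poses([0.5, None])
        with pytest.raises(InputError):
            rerank_poses(poses)


class TestRescoreMax:
    def test_simple_and_single(self):
        assert rescore_max(make_pairing(poses=make_poses([0.2, 0.8, 0.3]))) == 0.8
        assert rescore_max(make_pairing(poses=make_poses([0.42]))) == 0.42

    def test_500_random_oracle(self, rng):
        scores = rng.uniform(size=500)
        rec = make_pairing(poses=make_poses(list(scores)))
        assert rescore_max(rec) == pytest.approx(scores.max())


class TestThreshold:
    def _pairings(self, keys):
        return [
            make_pairing(antibody=f"ab{i}", poses=make_poses([k]))
            for i, k in enumerate(keys)
        ]

    def test_discard_80_of_10_keeps_two_largest(self, rng):
        keys = list(rng.uniform(size=10))
        kept = threshold_pairings(self._pairings(keys), 0.8)
        assert len(kept) == 2
        assert sorted(rescore_max(p) for p in kept) == sorted(keys)[-2:]

    def test_ceiling_rule_on_five_items(self):
        kept = threshold_pairings(self._pairings([0.1, 0.2, 0.3, 0.4, 0.5]), 0.6)
        assert len(kept) == math.ceil(0.4 * 5) == 2

    def test_zero_fraction_is_identity(self):
        pairings = self._pairings([0.3, 0.1, 0.2])
        assert set(id(p) for p in threshold_pairings(pairings, 0.0)) == set(
            id(p) for p in pairings
        )

    def test_partition_matches_oracle(self, rng):
        keys = list(rng.uniform(size=100))
        pairings = self._pairings(keys)
        for f in (0.4, 0.6, 0.8):
            kept = threshold_pairings(pairings, f)
            n_keep = math.ceil((1 - f) * 100)
            assert len(kept) == n_keep
            kept_keys = sorted(rescore_max(p) for p in kept)
            assert kept_keys == sorted(keys)[-n_keep:]
            assert min(kept_keys) >= max(k for k in keys if k not in kept_keys)


class TestPairingScores:
    def test_top10_mean_and_shortfall(self):
        poses = make_poses([0.9] * 12, vs_scores=[0.5] * 12)
        assert vs_pairing_score(poses, k=10) == pytest.approx(0.5)
        seven = make_poses([0.9] * 7, vs_scores=list(np.linspace(0, 1, 7)))
        assert vs_pairing_score(seven, k=10) == pytest.approx(np.linspace(0, 1, 7).mean())

    def test_random_oracle(self, rng):
        vs = list(rng.uniform(size=30))
        poses = make_poses([0.9] * 30, vs_scores=vs)
        assert vs_pairing_score(poses, k=10) == pytest.approx(np.mean(vs[:10]))

    def test_dock_score_of_rank_one(self):
        poses = make_poses([0.1, 0.2], dock_scores=[17.0, 4.0])
        assert dock_pairing_score(poses) == 17.0
        with pytest.raises(InputError):
            dock_pairing_score([ScoredPose(pose_rank=2, dock_score=1.0)])


class TestCombine:
    def _candidates(self, vs, dock):
        return [
            make_pairing(antibody=f"ab{i}", vs_pairing_score=v, dock_pairing_score=d)
            for i, (v, d) in enumerate(zip(vs, dock))
        ]

    def test_two_candidate_extremes(self):
        cands = self._candidates([0.0, 1.0], [10.0, 20.0])
        combine_scores(cands)
        assert [c.combined_score for c in cands] == [0.0, 1.0]

    def test_affine_rescaling_invariance(self, rng):
        vs = list(rng.uniform(size=20))
        dock = list(rng.uniform(size=20))
        a = self._candidates(vs, dock)
        b = self._candidates(vs, [7.3 * d - 11.0 for d in dock])
        combine_scores(a)
        combine_scores(b)
        np.testing.assert_allclose(
            [c.combined_score for c in a], [c.combined_score for c in b], atol=1e-12
        )

    def test_oracle_recomputation_and_degenerate_channel(self, rng):
        vs = list(rng.uniform(size=50))
        dock = [3.0] * 50  # degenerate docking channel
        cands = self._candidates(vs, dock)
        combine_scores(cands)
        lo, hi = min(vs), max(vs)
        for c, v in zip(cands, vs):
            expected = 0.5 * ((v - lo) / (hi - lo) + 0.5)
            assert c.combined_score == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= c.combined_score <= 1.0


class TestRanking:
    def _screen(self, cognate_score, decoy_scores):
        cands = [make_pairing(antibody="cog", cognate=True,
                              combined_score=cognate_score)]
        cands += [
            make_pairing(antibody=f"d{i}", combined_score=s)
            for i, s in enumerate(decoy_scores)
        ]
        return rank_candidates("ag", cands)

    def test_top_scored_cognate_counts_for_top2pct(self):
        result = self._screen(1.0, list(np.linspace(0, 0.9, 50)))
        assert result.cognate_rank == 1
        rates = summarize_topn([result])
        assert rates[0.02]["rate"] == 1.0

    def test_ties_resolved_pessimistically(self):
        result = self._screen(0.5, [0.5, 0.5, 0.1])
        assert result.cognate_rank == 3

    def test_ceiling_boundary_rank6_of_51_succeeds_at_10pct(self):
        decoys = [1.0] * 5 + [0.0] * 45
        result = self._screen(0.5, decoys)
        assert result.cognate_rank == 6
        assert math.ceil(0.1 * 51) == 6
        assert summarize_topn([result])[0.10]["rate"] == 1.0
        # rank 7 fails
        result7 = self._screen(0.5, [1.0] * 6 + [0.0] * 44)
        assert summarize_topn([result7])[0.10]["rate"] == 0.0

    def test_missing_cognate_rejected(self):
        cands = [make_pairing(antibody="d0", combined_score=0.1)]
        with pytest.raises(InputError):
            rank_candidates("ag", cands)


class TestStatistics:
    def test_ratio_std_closed_forms(self):
        assert ratio_std(0, 50) == 0.0
        assert ratio_std(100, 100) == pytest.approx(0.1)
        with pytest.raises(InputError):
            ratio_std(1, 0)

    def test_ratio_std_tracks_binomial_se_for_small_ratios(self):
        c, n = 5, 200
        binom_se = math.sqrt((c / n) * (1 - c / n) / n)
        assert ratio_std(c, n) == pytest.approx(binom_se, rel=0.05)

    def test_poisson_symmetric_counts_give_p_one(self):
        assert poisson_rate_test(7, 100, 7, 100) == pytest.approx(1.0)
        assert poisson_rate_test(0, 10, 0, 10) == 1.0

    def test_poisson_matches_exact_binomial_tail(self):
        p = poisson_rate_test(50, 100, 10, 100)
        assert p < 0.001
        oracle = stats.binomtest(50, 60, 0.5, alternative="two-sided").pvalue
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_mean_test_identical_samples(self):
        assert mean_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_mean_test_is_welch(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(1, 3, 25)
        assert mean_test(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )
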