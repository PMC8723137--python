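"""Clustering, splits, samplers, pose selection and the training loop."""

import collections

import numpy as np
import pytest

from voxscreen.errors import InputError
from voxscreen.gridding import ChannelMap, GridSpec
from voxscreen.models import FnatBinning, fnat_bin_index
from voxscreen.synthetic import make_decoy_pool
from voxscreen.training import (
    PoseRecord,
    TrainConfig,
    TrainExample,
    balanced_vs_batches,
    cdr_identity,
    cluster_cdr_sequences,
    make_folds,
    sample_decoys,
    select_vs_training_poses,
    stratified_re_batches,
    train,
)


def levenshtein(a, b):
    """Independent O(nm) dynamic-programming edit-distance oracle."""
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb))
    return dp[len(b)]


class TestCdrIdentity:
    def test_reference_values(self):
        assert cdr_identity("GFTISSARD", "GFTISSARD") == 1.0
        assert cdr_identity("AAAA", "AAAT") == 0.75

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            cdr_identity("", "AA")

    def test_unequal_lengths_match_dp_oracle(self, rng):
        alpha = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(200):
            a = "".join(rng.choice(list(alpha), size=rng.integers(3, 25)))
            b = "".join(rng.choice(list(alpha), size=rng.integers(3, 25)))
            expected = (
                sum(x == y for x, y in zip(a, b)) / len(a)
                if len(a) == len(b)
                else 1.0 - levenshtein(a, b) / max(len(a), len(b))
            )
            assert cdr_identity(a, b) == pytest.approx(expected, abs=1e-12)


class TestClustering:
    def test_identical_sequences_cluster_together(self):
        c = cluster_cdr_sequences({"a": "GFTISS", "b": "GFTISS"})
        assert c.clusters["a"] == c.clusters["b"]

    def test_disjoint_sequences_separate(self):
        c = cluster_cdr_sequences({"a": "AAAAAA", "b": "WWWWWW"})
        assert c.clusters["a"] != c.clusters["b"]

    def test_planted_families_recovered(self, rng):
        pool = make_decoy_pool("A" * 24, n_families=5, family_size=10, rng=rng)
        clusters = cluster_cdr_sequences(pool, cutoff=0.9)
        assert clusters.n_clusters == 5
        by_family = collections.defaultdict(set)
        for aid, cid in clusters.clusters.items():
            by_family[aid.split("_")[0]].add(cid)
        assert all(len(cids) == 1 for cids in by_family.values())


class TestFolds:
    def _clusters(self, n):
        return cluster_cdr_sequences(
            {f"ab{i}": chr(65 + i) * 20 for i in range(n)}, cutoff=0.9
        )

    def test_ten_clusters_k10_one_per_fold(self, rng):
        plan = make_folds(self._clusters(10), k=10, rng=rng)
        assert sorted(len(plan.test_clusters(f)) for f in range(10)) == [1] * 10

    def test_partitions_disjoint_and_balanced(self, rng):
        plan = make_folds(self._clusters(17), k=5, rng=rng)
        plan.check()
        sizes = [len(plan.test_clusters(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        for fold in range(5):
            test_abs = set(plan.antibodies_in(plan.test_clusters(fold)))
            for vs in range(2):
                train_abs = set(
                    plan.antibodies_in(plan.train_clusters(fold, validation_set=vs))
                )
                val_abs = set(plan.antibodies_in(plan.validation_sets[fold][vs]))
                assert not (test_abs & train_abs)
                assert not (test_abs & val_abs)
                assert not (train_abs & val_abs)

    def test_json_roundtrip(self, rng):
        from voxscreen.training import SplitPlan

        plan = make_folds(self._clusters(12), k=4, rng=rng)
        back = SplitPlan.from_json(plan.to_json())
        assert back.fold_of_cluster == plan.fold_of_cluster
        assert back.validation_sets == plan.validation_sets
        assert back.cluster.clusters == plan.cluster.clusters

    def test_k_exceeding_clusters_rejected(self, rng):
        with pytest.raises(InputError):
            make_folds(self._clusters(3), k=10, rng=rng)


class TestSampleDecoys:
    def _pool(self, rng, n=100):
        alpha = list("ARNDCQEGHILKMFPSTWYV")
        return {f"d{i}": "".join(rng.choice(alpha, size=24)) for i in range(n)}

    def test_draws_distinct_eligible_ids(self, rng):
        pool = self._pool(rng)
        cognate = "W" * 24
        picks = sample_decoys("ag1", "cog", cognate, pool, n=50, rng=rng)
        assert len(picks) == len(set(picks)) == 50
        assert all(cdr_identity(pool[p], cognate) < 0.9 for p in picks)

    def test_cognate_never_sampled(self, rng):
        pool = self._pool(rng, 60)
        pool["cog"] = "W" * 24
        picks = sample_decoys("ag1", "cog", "W" * 24, pool, n=50, rng=rng)
        assert "cog" not in picks

    def test_seeded_determinism(self, rng):
        pool = self._pool(rng)
        a = sample_decoys("ag1", "cog", "W" * 24, pool, n=50,
                          rng=np.random.default_rng(5))
        b = sample_decoys("ag1", "cog", "W" * 24, pool, n=50,
                          rng=np.random.default_rng(5))
        assert a == b

    def test_shortfall_reports_error(self, rng):
        pool = {"a": "W" * 24, "b": "A" * 24}
        with pytest.raises(InputError, match="eligible"):
            sample_decoys("ag1", "cog", "W" * 24, pool, n=2, rng=rng)


class TestSamplers:
    def _pool(self):
        recs = []
        for b in range(11):
            fnat = 0.0 if b == 0 else b / 10 - 0.05
            for i in range(3 + 5 * b):  # heavily imbalanced bins
                recs.append(PoseRecord("p", len(recs) + 1, 0.0, fnat=fnat))
        return recs

    def test_single_occupied_bin_dominates(self):
        recs = [PoseRecord("p", i, 0.0, fnat=0.55) for i in range(1, 4)]
        stream = stratified_re_batches(recs, FnatBinning(), 8, np.random.default_rng(0))
        batch = next(stream)
        assert all(r.fnat == 0.55 for r in batch)

    def test_seeded_stream_reproducible(self):
        for _ in range(2):
            stream = stratified_re_batches(
                self._pool(), FnatBinning(), 16, np.random.default_rng(3)
            )
            ids = [r.pose_rank for _ in range(5) for r in next(stream)]
            if _ == 0:
                first = ids
        assert ids == first

    def test_balanced_batches_exact_balance(self):
        pos = [PoseRecord("p", i, 0.0, fnat=0.9) for i in range(5)]
        neg = [PoseRecord("p", i, 0.0, fnat=0.0) for i in range(50)]
        stream = balanced_vs_batches(pos, neg, 12, np.random.default_rng(0))
        for _ in range(10):
            p, n = next(stream)
            assert len(p) == len(n) == 6
        with pytest.raises(InputError):
            next(balanced_vs_batches(pos, neg, 7, np.random.default_rng(0)))


class TestVsPoseSelection:
    def test_cap_at_fifty_positives(self):
        poses = [PoseRecord("p", i + 1, 0.0, fnat=0.71 + 0.003 * i) for i in range(60)]
        out = select_vs_training_poses(poses, None)
        assert len(out.positives) == 50
        worst_kept = min(p.fnat for p in out.positives)
        assert all(p.fnat <= worst_kept for p in poses if p not in out.positives)

    def test_boundary_gates_are_strict(self):
        poses = [
            PoseRecord("p", 1, 0.0, fnat=0.7),    # excluded: not > 0.7
            PoseRecord("p", 2, 0.0, fnat=0.1),    # excluded: not < 0.1
            PoseRecord("p", 3, 0.0, fnat=0.09),
        ]
        out = select_vs_training_poses(poses, None)
        assert out.positives == []
        assert [p.pose_rank for p in out.cognate_negatives] == [3]

    def test_matches_brute_force_filter(self, rng):
        fnats = rng.uniform(size=300)
        poses = [PoseRecord("p", i + 1, 0.0, fnat=float(f)) for i, f in enumerate(fnats)]
        decoy = PoseRecord("d", 1, 0.0)
        out = select_vs_training_poses(poses, decoy)
        expected_pos = sorted(
            [p for p in poses if p.fnat > 0.7], key=lambda p: (-p.fnat, p.pose_rank)
        )[:50]
        expected_neg = sorted(
            [p for p in poses if p.fnat < 0.1], key=lambda p: (p.fnat, p.pose_rank)
        )[:5]
        assert out.positives == expected_pos
        assert out.cognate_negatives == expected_neg
        assert out.decoy_negatives == [decoy]


class TestTrainLoop:
    """Mechanics only; learnability is exercised in the acceptance suite."""

    SPEC = GridSpec(radius=3.0, resolution=0.75)  # 8^3 micro-grids

    def _examples(self, rng, n, task):
        out = []
        for i in range(n):
            label = float(rng.uniform()) if task == "re" else float(i % 2)
            offset = 1.5 * label  # geometry encodes the label crudely
            coords = np.array([[0.0, 0, 0], [offset, 0, 0], [0, offset, 0]])
            coords += rng.normal(0, 0.1, coords.shape)
            out.append(
                TrainExample(
                    coords=coords,
                    channel_idx=np.array([0, 4, 4]),
                    centre=np.zeros(3),
                    label=label,
                )
            )
        return out

    def _config(self, task, steps=12):
        return TrainConfig(
            task=task, arch="tiny_test", steps=steps, batch_size=4, lr=1e-3,
            eval_interval=4, augment=False, grid_spec=self.SPEC,
        )

    def test_same_seed_identical_validation_metrics(self, rng):
        examples = self._examples(rng, 24, "re")
        val = self._examples(np.random.default_rng(1), 8, "re")
        logs = []
        for _ in range(2):
            res = train(examples, val, self._config("re"), rng=np.random.default_rng(2))
            logs.append([row["val_metric"] for row in res.log])
        assert logs[0] == logs[1]

    def test_snapshot_is_argmax_over_recorded_evaluations(self, rng):
        examples = self._examples(rng, 24, "re")
        val = self._examples(np.random.default_rng(1), 8, "re")
        res = train(examples, val, self._config("re", steps=20), rng=rng)
        best = min(res.log, key=lambda r: r["val_loss"])
        assert res.best_step == best["step"]

    def test_vs_training_runs_with_balanced_batches(self, rng):
        examples = self._examples(rng, 24, "vs")
        pos = [e for e in examples if e.label == 1.0]
        neg = [e for e in examples if e.label == 0.0]
        val = self._examples(np.random.default_rng(1), 8, "vs")
        res = train((pos, neg), val, self._config("vs"), rng=rng)
        assert res.model.config.head == "vs_binary"
        assert 0.0 <= res.best_metric <= 1.0

    def test_config_json_roundtrip(self):
        cfg = self._config("re")
        back = TrainConfig.from_json(cfg.to_json())
        assert back.grid_spec == cfg.grid_spec
        assert back.task == cfg.task and back.steps == cfg.steps
        assert back.channels == cfg.channels
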