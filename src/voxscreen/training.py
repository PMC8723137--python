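"""Training-set assembly, clustered splits and the training loop.

Pose selection for the binder classifier follows the screening pipeline's
rules: per cognate pairing up to 50 poses with fnat > 0.7 as positives
(descending fnat), exactly five poses with fnat < 0.1 as cognate negatives,
and per non-cognate pairing the single top pose after rescorer reranking as
a decoy negative.  The rescorer is trained with stratified sampling across
occupied fnat bins; the classifier with exactly class-balanced batches.

Leakage control: antibodies are clustered greedily by CDR-sequence identity
at a 90% cutoff and whole clusters are assigned to train/validation/test,
so near-identical antibodies never straddle a split.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np
from sklearn.metrics import average_precision_score

from . import nn
from .errors import ConfigurationError, InputError, VoxscreenError
from .gridding import ChannelMap, GridSpec, augment_coords, rasterize
from .models import (
    HEAD_RE,
    HEAD_VS,
    FnatBinning,
    VoxNet,
    build_model,
    fnat_bin_index,
)

__all__ = [
    "PoseRecord",
    "Cluster",
    "SplitPlan",
    "VsTrainingSet",
    "TrainExample",
    "TrainConfig",
    "TrainResult",
    "cdr_identity",
    "cluster_cdr_sequences",
    "make_folds",
    "sample_decoys",
    "stratified_re_batches",
    "balanced_vs_batches",
    "select_vs_training_poses",
    "train",
]


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class PoseRecord:
    """One docking pose of one antibody-antigen pairing."""

    pairing_id: str
    pose_rank: int
    dock_score: float
    fnat: Optional[float] = None
    grid_ref: Optional[object] = None


@dataclass
class VsTrainingSet:
    """Binder-classifier training poses with their selection gates applied."""

    positives: List[PoseRecord] = field(default_factory=list)
    cognate_negatives: List[PoseRecord] = field(default_factory=list)
    decoy_negatives: List[PoseRecord] = field(default_factory=list)

    def validate(self) -> None:
        if any(p.fnat is None or p.fnat <= 0.7 for p in self.positives):
            raise InputError("positive poses must have fnat > 0.7")
        if any(p.fnat is None or p.fnat >= 0.1 for p in self.cognate_negatives):
            raise InputError("cognate negatives must have fnat < 0.1")


# ---------------------------------------------------------------------------
# CDR identity and clustering


def cdr_identity(seq_a: str, seq_b: str) -> float:
    """Pairwise CDR sequence identity in [0, 1].

    Equal lengths: matching positions / length.  Unequal lengths:
    1 - Levenshtein / max(len).
    """
    if not seq_a or not seq_b:
        raise InputError("empty CDR sequence")
    if len(seq_a) == len(seq_b):
        matches = sum(x == y for x, y in zip(seq_a, seq_b))
        return matches / len(seq_a)
    dist = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(seq_a), len(seq_b))


@dataclass
class Cluster:
    """Greedy single-linkage-to-representative clustering of antibody ids."""

    clusters: Dict[str, int]
    identity_cutoff: float = 0.9

    def members(self, cluster_id: int) -> List[str]:
        return sorted(k for k, v in self.clusters.items() if v == cluster_id)

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))


def cluster_cdr_sequences(
    seqs: Mapping[str, str], cutoff: float = 0.9
) -> Cluster:
    """Greedy incremental clustering by CDR identity (CD-HIT style).

    Sequences are processed by descending length then lexicographic id; each
    joins the first existing cluster whose representative (founder) has
    identity >= cutoff, else founds a new cluster.  Word-filter heuristics
    of CD-HIT are not replicated: exact identities are computed throughout,
    which is the right trade at desk scale.
    """
    if not seqs:
        raise InputError("no sequences to cluster")
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    reps: List[Tuple[int, str]] = []  # (cluster_id, representative sequence)
    assignment: Dict[str, int] = {}
    for sid in order:
        seq = seqs[sid]
        for cid, rep in reps:
            if cdr_identity(seq, rep) >= cutoff:
                assignment[sid] = cid
                break
        else:
            cid = len(reps)
            reps.append((cid, seq))
            assignment[sid] = cid
    return Cluster(clusters=assignment, identity_cutoff=cutoff)


# ---------------------------------------------------------------------------
# Fold construction


@dataclass
class SplitPlan:
    """Cluster-level k-fold assignment with per-fold validation carvings.

    ``validation_sets[fold]`` holds two disjoint cluster subsets (roughly
    10% of that fold's training clusters each), supporting an ensemble of
    two architectures x two validation sets per fold.  No cluster ever
    appears in more than one of train/validation/test for a given fold.
    """

    cluster: Cluster
    fold_of_cluster: Dict[int, int]
    n_folds: int
    validation_sets: Dict[int, List[List[int]]]

    def test_clusters(self, fold: int) -> List[int]:
        return sorted(c for c, f in self.fold_of_cluster.items() if f == fold)

    def train_clusters(self, fold: int, validation_set: Optional[int] = None) -> List[int]:
        held = set(self.test_clusters(fold))
        if validation_set is not None:
            held |= set(self.validation_sets[fold][validation_set])
        return sorted(c for c in self.fold_of_cluster if c not in held)

    def antibodies_in(self, cluster_ids: Iterable[int]) -> List[str]:
        wanted = set(cluster_ids)
        return sorted(a for a, c in self.cluster.clusters.items() if c in wanted)

    def check(self) -> None:
        """Assert split hygiene: partitions are disjoint at cluster level."""
        for fold in range(self.n_folds):
            test = set(self.test_clusters(fold))
            for vs in self.validation_sets[fold]:
                if test & set(vs):
                    raise VoxscreenError("validation clusters overlap test clusters")
            v0, v1 = (set(v) for v in self.validation_sets[fold])
            if v0 & v1:
                raise VoxscreenError("the two validation carvings overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "identity_cutoff": self.cluster.identity_cutoff,
                "clusters": self.cluster.clusters,
                "fold_of_cluster": {str(k): v for k, v in self.fold_of_cluster.items()},
                "n_folds": self.n_folds,
                "validation_sets": {
                    str(k): v for k, v in self.validation_sets.items()
                },
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SplitPlan":
        d = json.loads(s)
        return cls(
            cluster=Cluster(
                clusters={k: int(v) for k, v in d["clusters"].items()},
                identity_cutoff=float(d["identity_cutoff"]),
            ),
            fold_of_cluster={int(k): int(v) for k, v in d["fold_of_cluster"].items()},
            n_folds=int(d["n_folds"]),
            validation_sets={
                int(k): [[int(c) for c in vs] for vs in v]
                for k, v in d["validation_sets"].items()
            },
        )


def make_folds(
    clusters: Cluster,
    k: int = 10,
    rng: Optional[np.random.Generator] = None,
    val_fraction: float = 0.1,
    n_validation_sets: int = 2,
) -> SplitPlan:
    """Assign clusters to k folds (sizes differ by at most one cluster) and
    carve ``n_validation_sets`` disjoint validation subsets per fold from
    that fold's training clusters."""
    if rng is None:
        rng = np.random.default_rng(0)
    ids = sorted(set(clusters.clusters.values()))
    if k > len(ids):
        raise InputError(f"k={k} exceeds the number of clusters ({len(ids)})")
    perm = list(rng.permutation(ids))
    fold_of_cluster = {int(c): i % k for i, c in enumerate(perm)}
    validation_sets: Dict[int, List[List[int]]] = {}
    for fold in range(k):
        train = [c for c in ids if fold_of_cluster[c] != fold]
        n_val = max(1, int(np.ceil(val_fraction * len(train))))
        if n_validation_sets * n_val > len(train):
            raise InputError("not enough training clusters to carve validation sets")
        shuffled = list(rng.permutation(train))
        validation_sets[fold] = [
            sorted(int(c) for c in shuffled[i * n_val:(i + 1) * n_val])
            for i in range(n_validation_sets)
        ]
    plan = SplitPlan(
        cluster=clusters,
        fold_of_cluster=fold_of_cluster,
        n_folds=k,
        validation_sets=validation_sets,
    )
    plan.check()
    return plan


# ---------------------------------------------------------------------------
# Decoy sampling


def sample_decoys(
    antigen_id: str,
    cognate_id: str,
    cognate_seq: str,
    pool: Mapping[str, str],
    n: int = 50,
    max_identity: float = 0.9,
    rng: Optional[np.random.Generator] = None,
) -> List[str]:
    """Sample ``n`` non-cognate antibody ids for one antigen.

    Candidates sharing >= ``max_identity`` CDR identity with the cognate
    antibody (including the cognate itself) are excluded before sampling.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    eligible = sorted(
        aid for aid, seq in pool.items()
        if aid != cognate_id and cdr_identity(seq, cognate_seq) < max_identity
    )
    if len(eligible) < n:
        raise InputError(
            f"antigen {antigen_id}: decoy pool has only {len(eligible)} eligible "
            f"antibodies after the identity filter, need {n}"
        )
    picks = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(picks)]


# ---------------------------------------------------------------------------
# Samplers


def stratified_re_batches(
    pool: Sequence,
    binning: FnatBinning,
    batch_size: int,
    rng: np.random.Generator,
    fnat_of=lambda rec: rec.fnat,
) -> Iterator[List]:
    """Endless batch stream sampling fnat bins at equal rates.

    Each example is drawn by first selecting a bin uniformly among occupied
    bins, then a pose uniformly within it (with replacement).  Empty bins
    are simply excluded.  Used at train time only; testing applies the
    model to all poses without stratification.
    """
    if not pool:
        raise InputError("empty pose pool")
    by_bin: Dict[int, List] = {}
    for rec in pool:
        f = fnat_of(rec)
        if f is None:
            raise InputError("stratified sampling requires fnat labels")
        by_bin.setdefault(fnat_bin_index(f, binning), []).append(rec)
    bins = sorted(by_bin)
    while True:
        batch = []
        for _ in range(batch_size):
            b = bins[rng.integers(len(bins))]
            members = by_bin[b]
            batch.append(members[rng.integers(len(members))])
        yield batch


def balanced_vs_batches(
    positives: Sequence,
    negatives: Sequence,
    batch_size: int,
    rng: np.random.Generator,
) -> Iterator[Tuple[List, List]]:
    """Endless stream of exactly class-balanced batches (batch_size even)."""
    if batch_size % 2:
        raise InputError("balanced batches require an even batch size")
    if not positives or not negatives:
        raise InputError("both classes must be non-empty")
    half = batch_size // 2
    while True:
        pos = [positives[i] for i in rng.integers(len(positives), size=half)]
        neg = [negatives[i] for i in rng.integers(len(negatives), size=half)]
        yield pos, neg


# ---------------------------------------------------------------------------
# Binder-classifier pose selection


def select_vs_training_poses(
    cognate_poses: Sequence[PoseRecord],
    decoy_top_pose: Optional[PoseRecord],
    max_positives: int = 50,
    n_cognate_negatives: int = 5,
) -> VsTrainingSet:
    """Apply the binder-classifier pose-selection gates for one pairing.

    Positives: up to ``max_positives`` poses with fnat strictly above 0.7,
    by descending fnat.  Cognate negatives: ``n_cognate_negatives`` poses
    with fnat strictly below 0.1, by ascending fnat (fewer if unavailable).
    The decoy pairing contributes its top rescorer-reranked pose as a
    negative.
    """
    labelled = [p for p in cognate_poses if p.fnat is not None]
    if len(labelled) != len(cognate_poses):
        raise InputError("all cognate poses must carry fnat")
    positives = sorted(
        (p for p in labelled if p.fnat > 0.7),
        key=lambda p: (-p.fnat, p.pose_rank),
    )[:max_positives]
    negatives = sorted(
        (p for p in labelled if p.fnat < 0.1),
        key=lambda p: (p.fnat, p.pose_rank),
    )[:n_cognate_negatives]
    out = VsTrainingSet(
        positives=positives,
        cognate_negatives=negatives,
        decoy_negatives=[decoy_top_pose] if decoy_top_pose is not None else [],
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Training loop


@dataclass(frozen=True)
class TrainExample:
    """One training pose, pre-classified for fast re-gridding.

    ``coords``/``channel_idx`` are per-atom; gridding happens per draw so
    train-time augmentation (random rotation about the centre plus <=2 A
    per-axis shifts) resamples the discretisation every epoch.
    """

    coords: np.ndarray
    channel_idx: np.ndarray
    centre: np.ndarray
    label: float
    pairing_id: str = ""
    pose_rank: int = 0

    @property
    def fnat(self) -> float:
        return self.label


@dataclass
class TrainConfig:
    """Tunable training knobs.

    Defaults mirror the reference protocol (200k rescorer steps / 50k
    classifier steps); the desk-scale profile used throughout the tests and
    examples passes a few thousand steps with the ``tiny_test``
    architecture on reduced grids.
    """

    task: str = "re"  # "re" | "vs"
    arch: str = "tiny_test"
    steps: int = 200_000
    batch_size: int = 16
    lr: float = 1e-3
    eval_interval: int = 250
    augment: bool = True
    max_shift: float = 2.0
    grid_spec: GridSpec = field(default_factory=GridSpec)
    channels: ChannelMap = field(default_factory=ChannelMap.default)
    binning: FnatBinning = field(default_factory=FnatBinning)
    snapshot_metric: Optional[str] = None  # default: val_loss (re), AP (vs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "arch": self.arch,
                "steps": self.steps,
                "batch_size": self.batch_size,
                "lr": self.lr,
                "eval_interval": self.eval_interval,
                "augment": self.augment,
                "max_shift": self.max_shift,
                "grid_spec": self.grid_spec.to_dict(),
                "channel_map": json.loads(self.channels.to_json()),
                "binning": list(self.binning.representatives),
                "snapshot_metric": self.snapshot_metric,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TrainConfig":
        d = json.loads(s)
        return cls(
            task=d["task"],
            arch=d["arch"],
            steps=int(d["steps"]),
            batch_size=int(d["batch_size"]),
            lr=float(d["lr"]),
            eval_interval=int(d["eval_interval"]),
            augment=bool(d["augment"]),
            max_shift=float(d["max_shift"]),
            grid_spec=GridSpec.from_dict(d["grid_spec"]),
            channels=ChannelMap(
                rules=tuple((p, e, int(c)) for p, e, c in d["channel_map"]["rules"])
            ),
            binning=FnatBinning(representatives=tuple(d["binning"])),
            snapshot_metric=d["snapshot_metric"],
        )


@dataclass
class TrainResult:
    model: VoxNet
    log: List[dict]
    best_step: int
    best_metric: float


def _grid_batch(
    examples: Sequence[TrainExample],
    config: TrainConfig,
    rng: Optional[np.random.Generator],
) -> np.ndarray:
    side = config.grid_spec.side_voxels
    out = np.empty(
        (len(examples), config.channels.n_channels, side, side, side), dtype=np.float64
    )
    for i, ex in enumerate(examples):
        coords = ex.coords
        if rng is not None and config.augment:
            coords = augment_coords(coords, ex.centre, rng, config.max_shift)
        values, _ = rasterize(
            coords, ex.channel_idx, ex.centre, config.grid_spec,
            config.channels.n_channels,
        )
        out[i] = values
    return out


def _evaluate(
    model: VoxNet, config: TrainConfig, val_grids: np.ndarray, val_labels: np.ndarray
) -> Tuple[float, float]:
    """(validation loss, validation metric); metric is -loss for the
    rescorer and average precision for the classifier."""
    logits = model.logits(val_grids)
    if config.task == "re":
        classes = np.array(
            [fnat_bin_index(f, config.binning) for f in val_labels], dtype=int
        )
        loss, _ = nn.softmax_cross_entropy(logits, classes)
        return loss, -loss
    loss, _ = nn.sigmoid_bce(logits[:, 0], val_labels.astype(float))
    ap = float(average_precision_score(val_labels.astype(int), logits[:, 0]))
    return loss, ap


def train(
    train_set,
    val_set: Sequence[TrainExample],
    config: TrainConfig,
    rng: Optional[np.random.Generator] = None,
) -> TrainResult:
    """Train a rescorer or binder classifier with snapshot selection.

    ``train_set`` is a sequence of :class:`TrainExample` for the rescorer
    (stratified bin sampling is applied here) or a ``(positives,
    negatives)`` pair of such sequences for the classifier (batches are
    exactly class-balanced).  Validation is evaluated every
    ``eval_interval`` steps and the returned model carries the snapshot
    with the best validation metric: lowest loss for the rescorer, highest
    average precision for the classifier.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if config.task not in ("re", "vs"):
        raise ConfigurationError(f"unknown task {config.task!r}")
    head = HEAD_RE if config.task == "re" else HEAD_VS
    model = build_model(
        config.arch, head, config.grid_spec, config.channels, config.binning, rng
    )
    opt = nn.RAdam(model.net, lr=config.lr)

    if config.task == "re":
        batches = stratified_re_batches(
            list(train_set), config.binning, config.batch_size, rng
        )
    else:
        positives, negatives = train_set
        batches = balanced_vs_batches(positives, negatives, config.batch_size, rng)

    val_grids = _grid_batch(list(val_set), config, rng=None)
    val_labels = np.array([ex.label for ex in val_set])

    maximize = config.task == "vs" if config.snapshot_metric is None else (
        config.snapshot_metric == "average_precision"
    )
    best_metric = -np.inf
    best_state = model.net.state_dict()
    best_step = 0
    log: List[dict] = []

    for step in range(1, config.steps + 1):
        if config.task == "re":
            batch = next(batches)
            grids = _grid_batch(batch, config, rng)
            classes = np.array(
                [fnat_bin_index(ex.label, config.binning) for ex in batch], dtype=int
            )
            logits = model.logits(grids, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, classes)
        else:
            pos, neg = next(batches)
            batch = list(pos) + list(neg)
            grids = _grid_batch(batch, config, rng)
            targets = np.array([1.0] * len(pos) + [0.0] * len(neg))
            logits = model.logits(grids, train=True)
            loss, dlogits = nn.sigmoid_bce(logits[:, 0], targets)
            dlogits = dlogits[:, None]
        if not np.isfinite(loss):
            raise VoxscreenError(
                f"training diverged at step {step}: loss={loss!r}; "
                f"last validation metric {log[-1] if log else None}"
            )
        model.net.backward(dlogits.astype(np.float32))
        opt.step()

        if step % config.eval_interval == 0 or step == config.steps:
            val_loss, val_metric = _evaluate(model, config, val_grids, val_labels)
            signed = val_metric if maximize else -val_loss
            log.append(
                {"step": step, "train_loss": float(loss),
                 "val_loss": float(val_loss), "val_metric": float(val_metric)}
            )
            if signed > best_metric:
                best_metric = signed
                best_state = model.net.state_dict()
                best_step = step

    model.net.load_state_dict(best_state)
    return TrainResult(model=model, log=log, best_step=best_step, best_metric=best_metric)
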