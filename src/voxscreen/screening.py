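"""Pose reranking, pairing scores, score fusion and screening evaluation.

Per pairing: poses are reranked by predicted fnat; the maximum predicted
fnat over the pose set (``rescore_max``) flags pairings likely to contain a
good pose and is used to discard the bottom 40/60/80% of pairings; the
binder pairing score averages the (ensemble-averaged) classifier scores of
the top 10 reranked poses; the docking baseline uses the docking score of
the original top-ranked pose.  Per antigen, the classifier and docking
channels are min-max normalized and averaged into the combined score, and
candidates are ranked to locate the cognate binder.

Evaluation conventions (pinned by boundary fixtures in the tests): the
cognate's rank resolves ties pessimistically (equal-scored decoys are
placed ahead of it) and top-q membership uses the ceiling rule,
rank <= ceil(q * n_candidates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "ScoredPose",
    "PairingRecord",
    "ScreenResult",
    "rerank_poses",
    "rescore_max",
    "threshold_pairings",
    "vs_pairing_score",
    "dock_pairing_score",
    "combine_scores",
    "rank_candidates",
    "summarize_topn",
    "ratio_std",
    "poisson_rate_test",
    "mean_test",
    "write_screen_results",
]


@dataclass
class ScoredPose:
    """One pose with its per-stage scores."""

    pose_rank: int
    dock_score: float
    pred_fnat: Optional[float] = None
    vs_score: Optional[float] = None


@dataclass
class PairingRecord:
    """One antibody-antigen pairing across the screening pipeline."""

    antigen_id: str
    antibody_id: str
    is_cognate: bool
    poses: List[ScoredPose] = field(default_factory=list)
    rescore_max: Optional[float] = None
    vs_pairing_score: Optional[float] = None
    dock_pairing_score: Optional[float] = None
    combined_score: Optional[float] = None


@dataclass
class ScreenResult:
    """Ranked candidates for one antigen and where the cognate landed."""

    antigen_id: str
    ranking: List[Tuple[str, float]]  # (antibody_id, score), best first
    cognate_rank: int
    cognate_percentile: float


# ---------------------------------------------------------------------------
# Pose-level operations


def rerank_poses(
    poses: Sequence[ScoredPose], key: str = "pred_fnat"
) -> List[ScoredPose]:
    """Stable sort by ``key`` descending; ties keep original docking order."""
    vals = [getattr(p, key) for p in poses]
    if any(v is None for v in vals):
        raise InputError(f"rerank_poses: unscored pose (missing {key})")
    return sorted(poses, key=lambda p: (-getattr(p, key), p.pose_rank))


def rescore_max(pairing: PairingRecord) -> float:
    """Highest predicted fnat over the pairing's scored poses."""
    scores = [p.pred_fnat for p in pairing.poses if p.pred_fnat is not None]
    if not scores:
        raise InputError("no rescored poses")
    return float(max(scores))


def threshold_pairings(
    pairings: Sequence[PairingRecord],
    discard_fraction: float,
    key=rescore_max,
) -> List[PairingRecord]:
    """Retain the top ceil((1-f) * n) pairings by ``key``.

    Used with ``rescore_max`` to discard the bottom 40/60/80% of pairings;
    the same routine applies to the docking-score-of-top-pose baseline by
    passing a different key.
    """
    if not pairings:
        raise InputError("no pairings to threshold")
    if not (0.0 <= discard_fraction < 1.0):
        raise InputError("discard_fraction must lie in [0, 1)")
    keyed = [(key(p), i, p) for i, p in enumerate(pairings)]
    keyed.sort(key=lambda t: (-t[0], t[1]))
    n_keep = math.ceil((1.0 - discard_fraction) * len(pairings))
    return [p for _, _, p in keyed[:n_keep]]


def vs_pairing_score(reranked_poses: Sequence[ScoredPose], k: int = 10) -> float:
    """Mean classifier score over the top min(k, available) reranked poses.

    Poses must already be reranked by predicted fnat; per-pose scores are
    expected to be ensemble-averaged already.
    """
    if not reranked_poses:
        raise InputError("no poses to score")
    top = list(reranked_poses)[:k]
    scores = [p.vs_score for p in top]
    if any(s is None for s in scores):
        raise InputError("vs_pairing_score: pose without classifier score")
    return float(np.mean(scores))


def dock_pairing_score(poses: Sequence[ScoredPose]) -> float:
    """Docking score of the original top-ranked pose (docking order)."""
    for p in poses:
        if p.pose_rank == 1:
            return float(p.dock_score)
    raise InputError("no pose with pose_rank 1")


# ---------------------------------------------------------------------------
# Fusion and ranking


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.full(len(values), 0.5)
    return (values - lo) / (hi - lo)


def combine_scores(candidates: Sequence[PairingRecord]) -> None:
    """Min-max fuse classifier and docking pairing scores within one antigen.

    Each channel is mapped to (x - min)/(max - min) over the antigen's
    candidates and the two channels are averaged; a degenerate channel
    (max == min) contributes 0.5 for every candidate.  Scores are written
    onto ``combined_score`` in place.
    """
    if not candidates:
        raise InputError("no candidates to combine")
    vs = np.array([c.vs_pairing_score for c in candidates], dtype=float)
    dock = np.array([c.dock_pairing_score for c in candidates], dtype=float)
    if np.any(np.isnan(vs)) or np.any(np.isnan(dock)):
        raise InputError("candidates missing pairing scores")
    combined = 0.5 * (_minmax(vs) + _minmax(dock))
    for c, s in zip(candidates, combined):
        c.combined_score = float(s)


def rank_candidates(
    antigen_id: str,
    candidates: Sequence[PairingRecord],
    score_key: str = "combined_score",
) -> ScreenResult:
    """Rank one antigen's candidates by a pairing score, best first.

    The cognate's rank is pessimistic: decoys with equal scores are placed
    ahead of it.
    """
    cognates = [c for c in candidates if c.is_cognate]
    if len(cognates) != 1:
        raise InputError(
            f"antigen {antigen_id}: expected exactly one cognate, got {len(cognates)}"
        )
    scores = [getattr(c, score_key) for c in candidates]
    if any(s is None for s in scores):
        raise InputError(f"candidates missing {score_key}")
    order = sorted(
        zip(candidates, scores), key=lambda t: (-t[1], t[0].is_cognate, t[0].antibody_id)
    )
    ranking = [(c.antibody_id, float(s)) for c, s in order]
    cog_score = float(getattr(cognates[0], score_key))
    cognate_rank = 1 + sum(
        1 for c, s in zip(candidates, scores)
        if not c.is_cognate and s >= cog_score
    )
    return ScreenResult(
        antigen_id=antigen_id,
        ranking=ranking,
        cognate_rank=cognate_rank,
        cognate_percentile=cognate_rank / len(candidates),
    )


def summarize_topn(
    results: Sequence[ScreenResult],
    fractions: Sequence[float] = (0.02, 0.05, 0.10, 0.20),
) -> Dict[float, Dict[str, float]]:
    """Fraction of antigens whose cognate ranks in the top q of candidates.

    Success at level q means cognate_rank <= ceil(q * n_candidates)
    (ceiling rule).  Each rate comes with its sqrt(c)/n standard-deviation
    approximation.
    """
    if not results:
        raise InputError("no screen results")
    out: Dict[float, Dict[str, float]] = {}
    n = len(results)
    for q in fractions:
        c = sum(
            1 for r in results
            if r.cognate_rank <= math.ceil(q * len(r.ranking))
        )
        out[q] = {"rate": c / n, "std": ratio_std(c, n), "successes": c, "n": n}
    return out


# ---------------------------------------------------------------------------
# Statistics


def ratio_std(c: int, n: int) -> float:
    """Poisson-count approximation of the SD of a success ratio: sqrt(c)/n."""
    if n <= 0:
        raise InputError("n must be positive")
    if c < 0:
        raise InputError("c must be non-negative")
    return math.sqrt(c) / n


def poisson_rate_test(c1: int, n1: float, c2: int, n2: float) -> float:
    """Two-sided equality test of two Poisson rates (counts c over exposure n).

    Realized as the exact conditional binomial test: given the total count,
    c1 ~ Binomial(c1 + c2, n1/(n1+n2)) under the null.  Both counts zero
    gives p = 1.
    """
    if min(c1, c2) < 0 or min(n1, n2) <= 0:
        raise InputError("counts must be >= 0 and exposures > 0")
    if c1 == 0 and c2 == 0:
        return 1.0
    from statsmodels.stats.rates import test_poisson_2indep

    res = test_poisson_2indep(
        c1, n1, c2, n2, method="exact-cond", alternative="two-sided"
    )
    return float(res.pvalue)


def mean_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Welch t-test for a difference in means."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("need at least two values per sample")
    if np.allclose(a.mean(), b.mean()) and a.std() == 0 and b.std() == 0:
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# Output writers


def write_screen_results(
    results: Sequence[ScreenResult],
    summary: Mapping[float, Mapping[str, float]],
    out_dir,
    extra: Optional[dict] = None,
) -> None:
    """Write per-antigen ranking TSVs and a JSON summary of top-N% rates."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for r in results:
        df = pd.DataFrame(r.ranking, columns=["antibody_id", "score"])
        df["rank"] = np.arange(1, len(df) + 1)
        df.to_csv(os.path.join(out_dir, f"{r.antigen_id}.tsv"), sep="\t", index=False)
    payload = {
        "top_fractions": {
            str(q): dict(v) for q, v in summary.items()
        },
        "n_antigens": len(results),
    }
    if extra:
        payload.update(extra)
    with open(os.path.join(out_dir, "summary.json"), "w") as f:
        json.dump(payload, f, indent=2)
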