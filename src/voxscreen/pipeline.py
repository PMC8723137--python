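"""End-to-end screening orchestration.

Glues the stages together for one antigen's candidate antibodies: discard
poses without a valid interaction centre, voxelize, rescore every pose,
rerank, score the top reranked poses with the binder-classifier ensemble,
attach the docking baseline, fuse per antigen and rank.  Works on
in-memory pose sets (synthetic screens) or on a manifest of PDB pose files
(the ``screen`` command).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError
from .gridding import ChannelMap, GridSpec, atom_channels, rasterize
from .models import VoxNet, batch_pred_fnat, batch_vs_scores, ensemble_score
from .pose_metrics import interaction_centre
from .screening import (
    PairingRecord,
    ScoredPose,
    ScreenResult,
    combine_scores,
    dock_pairing_score,
    rank_candidates,
    rerank_poses,
    rescore_max,
    summarize_topn,
    threshold_pairings,
    vs_pairing_score,
)
from .structures import AnnotatedComplex, read_complex, read_cdr_table

__all__ = [
    "PoseInput",
    "score_pairing",
    "screen_antigen",
    "run_screen_from_manifest",
    "run_synthetic_screen",
]


@dataclass
class PoseInput:
    """One candidate pose ready for featurization."""

    pose_rank: int
    dock_score: float
    coords: np.ndarray
    channel_idx: np.ndarray
    centre_point: Optional[np.ndarray]  # None when the centre is invalid


def pose_inputs_from_poses(
    poses: Sequence[AnnotatedComplex],
    table: pd.DataFrame,
    channels: ChannelMap,
) -> List[PoseInput]:
    """Build pose inputs from annotated poses plus their docking table."""
    out = []
    for pose, row in zip(poses, table.itertuples(index=False)):
        centre = interaction_centre(pose)
        ch_idx = atom_channels(pose.atoms, pose.role_of_chain, channels)
        out.append(
            PoseInput(
                pose_rank=int(row.pose_rank),
                dock_score=float(row.dock_score),
                coords=pose.coords,
                channel_idx=ch_idx,
                centre_point=centre.point if centre.valid else None,
            )
        )
    return out


def _grids_for(
    inputs: Sequence[PoseInput], spec: GridSpec, n_channels: int
) -> np.ndarray:
    side = spec.side_voxels
    out = np.empty((len(inputs), n_channels, side, side, side))
    for i, pi in enumerate(inputs):
        out[i], _ = rasterize(pi.coords, pi.channel_idx, pi.centre_point, spec, n_channels)
    return out


def score_pairing(
    antigen_id: str,
    antibody_id: str,
    is_cognate: bool,
    pose_inputs: Sequence[PoseInput],
    re_model: VoxNet,
    vs_models: Sequence[VoxNet],
    top_k: int = 10,
    batch_size: int = 64,
) -> PairingRecord:
    """Score one pairing: rescore all valid poses, rerank, classify the top
    ``top_k`` reranked poses with the ensemble, attach the docking baseline.

    Poses without a valid interaction centre are discarded up front.  The
    classifier is evaluated on the reranked top poses only — exactly the
    poses whose scores enter the pairing score.
    """
    usable = [p for p in pose_inputs if p.centre_point is not None]
    if not usable:
        raise InputError(f"{antigen_id}/{antibody_id}: no pose with a valid centre")
    spec = re_model.grid_spec
    n_ch = re_model.channels.n_channels

    preds = np.empty(len(usable))
    for lo in range(0, len(usable), batch_size):
        chunk = usable[lo:lo + batch_size]
        preds[lo:lo + len(chunk)] = batch_pred_fnat(
            re_model, _grids_for(chunk, spec, n_ch)
        )
    scored = [
        ScoredPose(pose_rank=p.pose_rank, dock_score=p.dock_score, pred_fnat=float(f))
        for p, f in zip(usable, preds)
    ]
    reranked = rerank_poses(scored, key="pred_fnat")
    by_rank = {p.pose_rank: i for i, p in enumerate(usable)}
    top = reranked[:top_k]
    top_grids = _grids_for([usable[by_rank[p.pose_rank]] for p in top], spec, n_ch)
    member_scores = np.stack(
        [batch_vs_scores(m, top_grids) for m in vs_models]
    )  # (n_members, n_top)
    for j, pose in enumerate(top):
        pose.vs_score = ensemble_score(member_scores[:, j])

    record = PairingRecord(
        antigen_id=antigen_id,
        antibody_id=antibody_id,
        is_cognate=is_cognate,
        poses=reranked,
    )
    record.rescore_max = rescore_max(record)
    record.vs_pairing_score = vs_pairing_score(reranked, k=top_k)
    # the docking baseline uses the engine's own top pose, whether or not
    # that pose survived the interaction-centre filter
    record.dock_pairing_score = dock_pairing_score(
        [ScoredPose(pose_rank=p.pose_rank, dock_score=p.dock_score)
         for p in pose_inputs]
    )
    return record


def screen_antigen(
    antigen_id: str,
    candidates: Sequence[PairingRecord],
    score_key: str = "combined_score",
) -> ScreenResult:
    """Fuse scores within one antigen and rank its candidates."""
    combine_scores(candidates)
    return rank_candidates(antigen_id, candidates, score_key=score_key)


def run_synthetic_screen(
    re_model: VoxNet,
    vs_models: Sequence[VoxNet],
    n_antigens: int = 50,
    n_decoys: int = 50,
    n_poses: int = 16,
    rng: Optional[np.random.Generator] = None,
    top_k: int = 10,
    discard_fraction: Optional[float] = None,
    return_records: bool = False,
):
    """Screen synthetic antigens end to end with trained models.

    Per antigen: one native complex, a cognate pose ensemble with an fnat
    spectrum, and ``n_decoys`` non-binder pairings whose antibody ids are
    drawn from a CDR-family decoy pool through the identity-gated sampler.
    Pairings are rescored, reranked, classified, fused with docking scores
    and ranked; with ``discard_fraction`` the bottom pairings by max
    predicted fnat are dropped first (antigens losing their cognate drop
    out of the summary).  Returns (results, summary); with
    ``return_records`` also the per-antigen pairing records, so baselines
    (e.g. docking-score-only ranking) can reuse the same screen.
    """
    from .structures import cdr_concat_sequence
    from .synthetic import (
        make_decoy_pool,
        make_native_complex,
        make_nonbinder_pose_set,
        make_pose_set,
    )
    from .training import sample_decoys

    if rng is None:
        rng = np.random.default_rng(0)
    channels = re_model.channels
    records_by_antigen: Dict[str, List[PairingRecord]] = {}
    for a in range(n_antigens):
        antigen_id = f"ag{a:03d}"
        native, contacts = make_native_complex(rng=rng)
        cognate_cdr = cdr_concat_sequence(native)
        pool = make_decoy_pool(
            cognate_cdr, n_families=5, family_size=max(2, (n_decoys + 9) // 5), rng=rng
        )
        decoy_ids = sample_decoys(antigen_id, "cognate", cognate_cdr, pool,
                                  n=n_decoys, rng=rng)
        records = []
        cognate_set = make_pose_set(native, contacts, n_poses=n_poses, rng=rng)
        inputs = pose_inputs_from_poses(cognate_set.poses, cognate_set.table, channels)
        records.append(
            score_pairing(antigen_id, "cognate", True, inputs, re_model, vs_models,
                          top_k=top_k)
        )
        for decoy_id in decoy_ids:
            ps = make_nonbinder_pose_set(native, n_poses=n_poses, rng=rng)
            inputs = pose_inputs_from_poses(ps.poses, ps.table, channels)
            records.append(
                score_pairing(antigen_id, decoy_id, False, inputs, re_model,
                              vs_models, top_k=top_k)
            )
        records_by_antigen[antigen_id] = records

    if discard_fraction:
        all_records = [r for recs in records_by_antigen.values() for r in recs]
        kept = {id(r) for r in threshold_pairings(all_records, discard_fraction)}
        records_by_antigen = {
            ag: [r for r in recs if id(r) in kept]
            for ag, recs in records_by_antigen.items()
        }

    results = []
    for ag, recs in records_by_antigen.items():
        if not any(r.is_cognate for r in recs) or len(recs) < 2:
            continue
        results.append(screen_antigen(ag, recs))
    if not results:
        raise InputError("no antigen retained its cognate candidate")
    if return_records:
        return results, summarize_topn(results), records_by_antigen
    return results, summarize_topn(results)


def run_screen_from_manifest(
    manifest_path,
    re_model: VoxNet,
    vs_models: Sequence[VoxNet],
    out_dir,
    discard_fraction: Optional[float] = None,
    top_k: int = 10,
) -> Tuple[List[ScreenResult], Dict[float, Dict[str, float]]]:
    """Screen every antigen in a manifest of pose PDB files.

    Manifest TSV columns: antigen_id, antibody_id, is_cognate, pose_path,
    dock_score_table (paths relative to the manifest).  Pose files are
    multi-model PDBs, one MODEL per pose in docking order.  With
    ``discard_fraction`` the bottom pairings by max predicted fnat are
    dropped before ranking (antigens losing their cognate are excluded
    from the summary).
    """
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = os.path.dirname(os.path.abspath(manifest_path))
    channels = re_model.channels
    records_by_antigen: Dict[str, List[PairingRecord]] = {}
    from .structures import n_models

    for row in manifest.itertuples(index=False):
        pose_path = os.path.join(base, str(row.pose_path))
        table = pd.read_csv(os.path.join(base, str(row.dock_score_table)), sep="\t")
        poses = []
        for m in range(1, n_models(pose_path) + 1):
            pose = read_complex(pose_path, model=m)
            from .structures import relative_surface_exposure

            pose.rel_exposure = relative_surface_exposure(pose, partner_split=True)
            poses.append(pose)
        inputs = pose_inputs_from_poses(poses, table, channels)
        rec = score_pairing(
            str(row.antigen_id), str(row.antibody_id), bool(row.is_cognate),
            inputs, re_model, vs_models, top_k=top_k,
        )
        records_by_antigen.setdefault(str(row.antigen_id), []).append(rec)

    all_records = [r for recs in records_by_antigen.values() for r in recs]
    if discard_fraction:
        kept = set(
            id(r) for r in threshold_pairings(all_records, discard_fraction)
        )
        records_by_antigen = {
            ag: [r for r in recs if id(r) in kept]
            for ag, recs in records_by_antigen.items()
        }

    results = []
    for ag, recs in records_by_antigen.items():
        if not any(r.is_cognate for r in recs) or len(recs) < 2:
            continue
        results.append(screen_antigen(ag, recs))
    if not results:
        raise InputError("no antigen retained a cognate candidate")
    summary = summarize_topn(results)
    from .screening import write_screen_results

    write_screen_results(results, summary, out_dir)
    return results, summary
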