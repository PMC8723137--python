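"""Pose-quality metrics against a native complex.

fnat is the fraction of the native (crystal) interface's residue-residue
contacts that are recapitulated in a docked pose; together with interface
and ligand RMSD it yields the community "CAPRI acceptable" criterion
(fnat > 0.1 and iRMSD < 4 A or LRMSD < 10 A).  The interaction centre —
midpoint of the two partners' mean interface-atom coordinates — is the grid
origin for voxelization; poses with no cross-partner interaction under 4 A
are discarded.

The residue-residue contact cutoff for fnat defaults to 5.0 A (heavy atoms,
CAPRI convention) and is configurable; the 4.0 A cutoff of the epitope and
interaction-centre definitions is deliberately a separate parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import InputError
from .structures import AnnotatedComplex, ResidueKey

__all__ = [
    "ContactSet",
    "PoseQuality",
    "InteractionCentre",
    "native_contacts",
    "compute_fnat",
    "capri_class",
    "interface_rmsd",
    "ligand_rmsd",
    "interaction_centre",
    "write_pose_quality_table",
    "FNAT_CONTACT_CUTOFF",
    "CENTRE_CUTOFF",
]

FNAT_CONTACT_CUTOFF = 5.0
CENTRE_CUTOFF = 4.0


@dataclass(frozen=True)
class ContactSet:
    """Native antibody-antigen residue contact pairs at a given cutoff."""

    pairs: FrozenSet[Tuple[ResidueKey, ResidueKey]]
    cutoff: float

    def __post_init__(self):
        if self.cutoff <= 0:
            raise InputError("contact cutoff must be positive")

    def __len__(self):
        return len(self.pairs)


@dataclass(frozen=True)
class PoseQuality:
    """Quality labels of one docked pose."""

    fnat: float
    irmsd: Optional[float] = None
    lrmsd: Optional[float] = None
    capri_acceptable: Optional[bool] = None


@dataclass(frozen=True)
class InteractionCentre:
    point: np.ndarray
    n_contributing_atoms: int
    valid: bool


def _heavy_coords_by_residue(
    complex_: AnnotatedComplex,
) -> Dict[ResidueKey, np.ndarray]:
    out: Dict[ResidueKey, List[np.ndarray]] = {}
    for a in complex_.atoms:
        if a.is_heavy:
            out.setdefault(a.residue_key, []).append(a.coords)
    return {k: np.array(v) for k, v in out.items()}


def native_contacts(
    native: AnnotatedComplex, contact_cutoff: float = FNAT_CONTACT_CUTOFF
) -> ContactSet:
    """All (antibody residue, antigen residue) pairs with any heavy-atom
    distance strictly below the cutoff in the native complex."""
    coords = native.coords[native.heavy_mask]
    is_ab = native.antibody_mask[native.heavy_mask]
    keys = [a.residue_key for a in native.atoms if a.is_heavy]
    ab_idx = np.where(is_ab)[0]
    ag_idx = np.where(~is_ab)[0]
    if ab_idx.size == 0 or ag_idx.size == 0:
        raise InputError("native complex must contain both partners")
    tree = cKDTree(coords[ag_idx])
    pairs: Set[Tuple[ResidueKey, ResidueKey]] = set()
    hits = tree.query_ball_point(coords[ab_idx], r=contact_cutoff)
    ag_coords = coords[ag_idx]
    for i, neigh in zip(ab_idx, hits):
        if not neigh:
            continue
        d = np.linalg.norm(ag_coords[neigh] - coords[i], axis=1)
        for j, dj in zip(neigh, d):
            if dj < contact_cutoff:  # strict
                pairs.add((keys[i], keys[ag_idx[j]]))
    return ContactSet(pairs=frozenset(pairs), cutoff=contact_cutoff)


def compute_fnat(native_contacts_: ContactSet, pose: AnnotatedComplex) -> float:
    """Fraction of native contacts recapitulated in the pose.

    Contacts are re-evaluated in the pose at the native cutoff.  Residue
    correspondence is by residue key (rigid-body docking preserves
    numbering).
    """
    if len(native_contacts_) == 0:
        raise InputError("native contact set is empty; fnat undefined")
    by_res = _heavy_coords_by_residue(pose)
    missing = {
        k for pair in native_contacts_.pairs for k in pair if k not in by_res
    }
    if missing:
        raise InputError(f"pose lacks residues of native contacts: {sorted(missing)[:5]}")
    cutoff = native_contacts_.cutoff
    kept = 0
    for ab_key, ag_key in native_contacts_.pairs:
        d = cdist(by_res[ab_key], by_res[ag_key])
        if d.min() < cutoff:
            kept += 1
    return kept / len(native_contacts_)


def capri_class(
    fnat: float, irmsd: Optional[float] = None, lrmsd: Optional[float] = None
) -> bool:
    """CAPRI acceptability: fnat > 0.1 and (iRMSD < 4 A or LRMSD < 10 A)."""
    if irmsd is None and lrmsd is None:
        raise InputError("capri_class needs at least one RMSD")
    rmsd_ok = (irmsd is not None and irmsd < 4.0) or (lrmsd is not None and lrmsd < 10.0)
    return fnat > 0.1 and rmsd_ok


def _ca_coords(complex_: AnnotatedComplex, keys) -> np.ndarray:
    by_key = {}
    for a in complex_.atoms:
        if a.name == "CA" and a.residue_key not in by_key:
            by_key[a.residue_key] = a.coords
    missing = [k for k in keys if k not in by_key]
    if missing:
        raise InputError(f"missing CA atoms for residues {missing[:5]}")
    return np.array([by_key[k] for k in keys])


def _superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``."""
    if len(mobile) < 3:
        raise InputError("need at least 3 atoms for superposition")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def _interface_residue_keys(
    native: AnnotatedComplex, cutoff: float = 10.0
) -> List[ResidueKey]:
    """Native residues with any heavy atom within ``cutoff`` of the partner."""
    coords = native.coords[native.heavy_mask]
    is_ab = native.antibody_mask[native.heavy_mask]
    keys = [a.residue_key for a in native.atoms if a.is_heavy]
    ab, ag = coords[is_ab], coords[~is_ab]
    out, seen = [], set()
    tree_ab, tree_ag = cKDTree(ab), cKDTree(ag)
    d_to_partner = np.empty(len(coords))
    d_to_partner[is_ab] = tree_ag.query(ab, k=1)[0]
    d_to_partner[~is_ab] = tree_ab.query(ag, k=1)[0]
    for key, d in zip(keys, d_to_partner):
        if d < cutoff and key not in seen:
            seen.add(key)
            out.append(key)
    return out


def interface_rmsd(native: AnnotatedComplex, pose: AnnotatedComplex) -> float:
    """C-alpha RMSD over native interface residues (10 A criterion) after
    superposing the pose's interface onto the native's."""
    keys = _interface_residue_keys(native)
    nat = _ca_coords(native, keys)
    mob = _superpose(_ca_coords(pose, keys), nat)
    return float(np.sqrt(np.mean(np.sum((mob - nat) ** 2, axis=1))))


def ligand_rmsd(native: AnnotatedComplex, pose: AnnotatedComplex) -> float:
    """C-alpha RMSD of the antibody after superposing the antigens."""
    ag_keys = [k for k in native.residue_keys() if not native.is_antibody_residue(k)]
    ab_keys = [k for k in native.residue_keys() if native.is_antibody_residue(k)]
    nat_ag, pose_ag = _ca_coords(native, ag_keys), _ca_coords(pose, ag_keys)
    if len(nat_ag) < 3:
        raise InputError("need at least 3 antigen CA atoms")
    mc, tc = pose_ag.mean(axis=0), nat_ag.mean(axis=0)
    rot, _ = Rotation.align_vectors(nat_ag - tc, pose_ag - mc)
    pose_ab = rot.apply(_ca_coords(pose, ab_keys) - mc) + tc
    nat_ab = _ca_coords(native, ab_keys)
    return float(np.sqrt(np.mean(np.sum((pose_ab - nat_ab) ** 2, axis=1))))


def interaction_centre(
    pose: AnnotatedComplex,
    cutoff: float = CENTRE_CUTOFF,
    exposure_threshold: float = 0.15,
) -> InteractionCentre:
    """Grid origin of a pose.

    Mean of the surface-exposed antibody atoms within ``cutoff`` of the
    antigen and of the surface-exposed antigen atoms within ``cutoff`` of
    the antibody, averaged.  Poses with no qualifying atoms on either side
    are invalid and discarded upstream.  Requires ``pose.rel_exposure``
    (computed per separated partner; rigid docking lets the native
    partner-split exposure be reused across poses).
    """
    if pose.rel_exposure is None:
        raise InputError("pose.rel_exposure missing; compute partner-split exposure first")
    exposed = {k for k, v in pose.rel_exposure.items() if v >= exposure_threshold}
    heavy = pose.heavy_mask
    on_exposed = np.array([a.residue_key in exposed for a in pose.atoms])
    is_ab = pose.antibody_mask
    ab_mask = heavy & is_ab
    ag_mask = heavy & ~is_ab
    ab_all, ag_all = pose.coords[ab_mask], pose.coords[ag_mask]
    ab_exp = pose.coords[ab_mask & on_exposed]
    ag_exp = pose.coords[ag_mask & on_exposed]
    if len(ab_exp) == 0 or len(ag_exp) == 0:
        return InteractionCentre(np.full(3, np.nan), 0, False)
    tree_ag = cKDTree(ag_exp)
    tree_ab = cKDTree(ab_exp)
    ab_sel = ab_exp[tree_ag.query(ab_exp, k=1)[0] < cutoff]
    ag_sel = ag_exp[tree_ab.query(ag_exp, k=1)[0] < cutoff]
    if len(ab_sel) == 0 or len(ag_sel) == 0:
        return InteractionCentre(np.full(3, np.nan), 0, False)
    centre = 0.5 * (ab_sel.mean(axis=0) + ag_sel.mean(axis=0))
    return InteractionCentre(centre, len(ab_sel) + len(ag_sel), True)


def write_pose_quality_table(records, path) -> None:
    """Write per-pose quality labels as TSV.

    ``records``: iterable of dicts with keys pairing_id, pose_rank, fnat,
    irmsd, lrmsd, capri_acceptable.
    """
    df = pd.DataFrame(
        list(records),
        columns=["pairing_id", "pose_rank", "fnat", "irmsd", "lrmsd", "capri_acceptable"],
    )
    df.to_csv(path, sep="\t", index=False)
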