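"""Synthetic antibody-antigen complexes, pose ensembles and decoy pools.

The generator builds pseudo-protein two-body complexes on a C-alpha-scale
lattice (3.8 A backbone spacing): the binding interface is a rectangular
patch of residue pairs, antibody over antigen, with a probe pseudo-side-
chain atom reaching into the gap so that exactly the planted residue pairs
are in contact at the fnat cutoff (5 A) and at the epitope/centre cutoff
(4 A).  Pose ensembles perturb the antibody rigidly:

* tilts about a horizontal axis through a random patch corner peel the
  interface off gradually, sweeping fnat from 1 towards 1/k;
* register shifts by one lattice vector break every native pair while
  keeping non-native contacts, giving fnat = 0 poses with a valid
  interaction centre (note these look like a perfect interface on a grid:
  they model wrong-register docks and are deliberately unlearnable);
* off-site placements dock the antibody patch onto the antigen tail —
  fnat = 0 with a valid centre and geometry a grid model can recognise;
* far translations give contact-free poses that exercise the discard path;
* clash placements (antibody pushed into the antigen) provide non-binder
  geometry for classifier training and decoy pairings.

Synthetic docking scores are ``a + b * fnat + noise`` for cognate poses
(informative but imperfect baseline ranking) and a lower-offset noise draw
for non-binders.  The geometry is deliberately non-physical (no rotamers,
no energetics); it exists so that every pipeline invariant is exercisable
without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InputError, VoxscreenError
from .gridding import ChannelMap, GridSpec, atom_channels
from .pose_metrics import (
    ContactSet,
    compute_fnat,
    interaction_centre,
    native_contacts,
)
from .structures import (
    AnnotatedComplex,
    Atom,
    relative_surface_exposure,
)
from .training import TrainExample

__all__ = [
    "SyntheticComplexSpec",
    "PoseSet",
    "make_native_complex",
    "make_pose_set",
    "make_nonbinder_pose_set",
    "make_decoy_pool",
    "make_grid_learnability_task",
    "write_fixture_bundle",
    "BACKBONE_SPACING",
    "PLANE_GAP",
]

BACKBONE_SPACING = 3.8  # A, consecutive C-alpha distance
PLANE_GAP = 4.7         # A, antibody C-alpha plane above the antigen plane
PROBE_DROP = 0.9        # A, probe pseudo-side-chain below the antibody plane
JITTER = 0.05           # A, per-coordinate uniform jitter (margins tolerate it)
FAR_SHIFT = 50.0        # A, translation that voids the interaction centre

AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL"
).split()
AA1 = "ARNDCQEGHILKMFPSTWYV"

#: residue types used for interface-patch pseudo-residues: small reference
#: maxima keep single-pseudo-atom residues safely above the 0.15 relative
#: exposure threshold that the epitope and interaction-centre rules apply
AA3_SMALL = "GLY ALA SER CYS THR PRO ASP ASN".split()

_TAIL_ELEMENTS = (("N", "N"), ("O", "O"), ("SD", "S"))


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Geometry of one synthetic complex.

    The interface patch is ``patch_nx x patch_ny`` residue pairs (all
    planted contacts); each chain carries a short non-interface tail for
    element diversity and realistic chain length.
    """

    patch_nx: int = 4
    patch_ny: int = 3
    ab_tail: int = 6
    ag_tail: int = 6
    light_chain_len: int = 10
    jitter: float = JITTER

    @property
    def n_planted_contacts(self) -> int:
        return self.patch_nx * self.patch_ny

    @property
    def cdr_layout(self) -> Dict[str, Dict[str, Tuple[int, int]]]:
        """Per-chain CDR residue ranges (1-based, author numbering)."""
        return {
            "H": {"H1": (1, 4), "H2": (5, 8), "H3": (9, 14)},
            "L": {"L1": (1, 4), "L2": (5, 7), "L3": (8, 10)},
        }


def _serpentine(nx: int, ny: int) -> List[Tuple[int, int]]:
    """Row-by-row serpentine through an nx x ny lattice; consecutive cells
    are lattice neighbours, preserving the backbone spacing."""
    out = []
    for iy in range(ny):
        xs = range(nx) if iy % 2 == 0 else range(nx - 1, -1, -1)
        out.extend((ix, iy) for ix in xs)
    return out


def make_native_complex(
    spec: SyntheticComplexSpec = SyntheticComplexSpec(),
    rng: Optional[np.random.Generator] = None,
    validate: bool = True,
) -> Tuple[AnnotatedComplex, ContactSet]:
    """Generate a native complex with exactly the planted contacts.

    Returns the annotated complex (partner-split exposure and CDR
    annotation attached) and the planted contact set at the 5 A fnat
    cutoff.  With ``validate`` the planted pairs are cross-checked against
    a fresh contact computation; a spec whose geometry cannot realise its
    planted contacts raises.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if spec.patch_nx < 1 or spec.patch_ny < 1:
        raise InputError("patch must contain at least one residue pair")
    s = BACKBONE_SPACING
    path = _serpentine(spec.patch_nx, spec.patch_ny)
    jit = lambda: rng.uniform(-spec.jitter, spec.jitter, size=3)

    atoms: List[Atom] = []
    serial = 1

    def add_atom(name, element, xyz, chain, res_id, res_name):
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial, element=element, name=name,
                coords=np.asarray(xyz, float) + jit(),
                residue_key=(chain, res_id, ""), residue_name=res_name,
                is_heavy=True,
            )
        )
        serial += 1

    def chain_seq(n, n_patch=0):
        patch = [AA3_SMALL[i] for i in rng.integers(len(AA3_SMALL), size=n_patch)]
        tail = [AA3[i] for i in rng.integers(len(AA3), size=n - n_patch)]
        return patch + tail

    # --- antigen chain A: patch then tail along +/-x at z = 0
    ag_names = chain_seq(len(path) + spec.ag_tail, n_patch=len(path))
    for idx, (ix, iy) in enumerate(path):
        add_atom("CA", "C", (ix * s, iy * s, 0.0), "A", idx + 1, ag_names[idx])
    end_x, end_y = path[-1]
    direction = 1 if spec.patch_ny % 2 == 1 else -1  # continue the serpentine
    for j in range(1, spec.ag_tail + 1):
        rid = len(path) + j
        x = (end_x + direction * j) * s
        add_atom("CA", "C", (x, end_y * s, 0.0), "A", rid, ag_names[rid - 1])
        name, elem = _TAIL_ELEMENTS[j % len(_TAIL_ELEMENTS)]
        add_atom(name, elem, (x, end_y * s - 1.3, 0.0), "A", rid, ag_names[rid - 1])

    # --- antibody heavy chain H: mirrored patch at z = PLANE_GAP, probe CB
    h_names = chain_seq(len(path) + spec.ab_tail, n_patch=len(path))
    for idx, (ix, iy) in enumerate(path):
        add_atom("CA", "C", (ix * s, iy * s, PLANE_GAP), "H", idx + 1, h_names[idx])
        add_atom("CB", "C", (ix * s, iy * s, PLANE_GAP - PROBE_DROP), "H", idx + 1, h_names[idx])
    for j in range(1, spec.ab_tail + 1):
        rid = len(path) + j
        z = PLANE_GAP + j * s
        add_atom("CA", "C", (end_x * s, end_y * s, z), "H", rid, h_names[rid - 1])
        name, elem = _TAIL_ELEMENTS[j % len(_TAIL_ELEMENTS)]
        add_atom(name, elem, (end_x * s, end_y * s + 1.3, z), "H", rid, h_names[rid - 1])

    # --- antibody light chain L: vertical tail next to the heavy tail,
    # starting one lattice step above the interface so it never contacts A
    l_names = chain_seq(spec.light_chain_len)
    for j in range(spec.light_chain_len):
        z = PLANE_GAP + (j + 1) * s
        xyz = ((end_x + 1) * s, end_y * s, z)
        add_atom("CA", "C", xyz, "L", j + 1, l_names[j])
        name, elem = _TAIL_ELEMENTS[j % len(_TAIL_ELEMENTS)]
        add_atom(name, elem, ((end_x + 1) * s, end_y * s - 1.3, z), "L", j + 1, l_names[j])

    complex_ = AnnotatedComplex(
        atoms=atoms,
        role_of_chain={"H": "antibody_heavy", "L": "antibody_light", "A": "antigen"},
    )
    complex_.rel_exposure = relative_surface_exposure(complex_, partner_split=True)

    annotation: Dict[Tuple[str, int, str], str] = {}
    for chain, loops in spec.cdr_layout.items():
        for label, (lo, hi) in loops.items():
            for key in complex_.chain_residues(chain):
                if lo <= key[1] <= hi:
                    annotation[key] = label
    complex_.cdr_annotation = annotation

    planted = ContactSet(
        pairs=frozenset(
            (("H", idx + 1, ""), ("A", idx + 1, "")) for idx in range(len(path))
        ),
        cutoff=5.0,
    )
    if validate:
        measured = native_contacts(complex_, 5.0)
        if measured.pairs != planted.pairs:
            raise VoxscreenError(
                "infeasible synthetic spec: measured contacts differ from planted "
                f"({len(measured.pairs)} vs {len(planted.pairs)})"
            )
    return complex_, planted


# ---------------------------------------------------------------------------
# Pose ensembles


@dataclass
class PoseSet:
    """Rigid poses of one pairing with their synthetic docking-score table.

    ``table`` columns: pose_rank (1 = best docking score), dock_score,
    fnat (NaN for non-binder pairings), kind, magnitude.  ``poses`` is
    ordered by pose_rank.
    """

    poses: List[AnnotatedComplex]
    table: pd.DataFrame


def _transform_antibody(
    native: AnnotatedComplex, rot: Rotation, pivot: np.ndarray, shift: np.ndarray
) -> AnnotatedComplex:
    coords = native.coords.copy()
    ab = native.antibody_mask
    coords[ab] = rot.apply(coords[ab] - pivot) + pivot + shift
    pose = native.with_coords(coords)
    pose.rel_exposure = dict(native.rel_exposure)  # rigid bodies: per-partner SASA unchanged
    pose.cdr_annotation = dict(native.cdr_annotation) if native.cdr_annotation else None
    return pose


def _patch_corners(spec: SyntheticComplexSpec) -> np.ndarray:
    s = BACKBONE_SPACING
    return np.array(
        [
            [0.0, 0.0, PLANE_GAP],
            [(spec.patch_nx - 1) * s, 0.0, PLANE_GAP],
            [0.0, (spec.patch_ny - 1) * s, PLANE_GAP],
            [(spec.patch_nx - 1) * s, (spec.patch_ny - 1) * s, PLANE_GAP],
        ]
    )


def make_pose_set(
    native: AnnotatedComplex,
    contacts: ContactSet,
    n_poses: int = 500,
    rng: Optional[np.random.Generator] = None,
    spec: SyntheticComplexSpec = SyntheticComplexSpec(),
    max_tilt_deg: float = 35.0,
    far_fraction: float = 0.04,
    register_fraction: float = 0.10,
    offsite_fraction: float = 0.04,
    dock_offset: float = 10.0,
    dock_slope: float = 8.0,
    dock_noise: float = 2.0,
) -> PoseSet:
    """Rigid pose ensemble of a cognate pairing with an fnat spectrum.

    Tilt poses sweep fnat from 1 downwards, register shifts contribute
    fnat = 0 poses with a valid centre, far translations contribute poses
    the pipeline must discard.  Docking scores are
    ``dock_offset + dock_slope * fnat + N(0, dock_noise)``; poses are
    ranked by docking score (rank 1 = highest), emulating a docking
    engine's imperfect but informative ordering.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_far = int(round(far_fraction * n_poses))
    n_reg = int(round(register_fraction * n_poses))
    n_off = int(round(offsite_fraction * n_poses))
    n_tilt = n_poses - n_far - n_reg - n_off - 1  # one identity pose
    if n_tilt < 0:
        raise InputError("n_poses too small for the schedule")
    corners = _patch_corners(spec)
    s = BACKBONE_SPACING

    rows = []
    poses = []

    def emit(pose, fnat, kind, magnitude):
        poses.append(pose)
        rows.append({"fnat": fnat, "kind": kind, "magnitude": magnitude})

    emit(native.with_coords(native.coords.copy()), 1.0, "identity", 0.0)
    poses[-1].rel_exposure = dict(native.rel_exposure)
    poses[-1].cdr_annotation = dict(native.cdr_annotation)

    centroid = corners.mean(axis=0)
    tilts = np.linspace(0.0, np.deg2rad(max_tilt_deg), n_tilt + 1)[1:]
    for theta in tilts:
        pivot = corners[rng.integers(len(corners))]
        # axis perpendicular to pivot->centroid so +theta peels the patch
        # away from the antigen; jittered so peel directions vary
        d = centroid - pivot
        d[2] = 0.0
        if np.linalg.norm(d) < 1e-9:
            d = np.array([1.0, 0.0, 0.0])
        d /= np.linalg.norm(d)
        axis = np.cross(d, [0.0, 0.0, 1.0])
        jitter_rot = Rotation.from_rotvec([0.0, 0.0, rng.uniform(-0.3, 0.3)])
        rot = Rotation.from_rotvec(theta * jitter_rot.apply(axis))
        shift = np.append(rng.uniform(-0.3, 0.3, size=2), 0.0)
        pose = _transform_antibody(native, rot, pivot, shift)
        emit(pose, compute_fnat(contacts, pose), "tilt", float(theta))

    for _ in range(n_reg):
        axis_xy = rng.integers(2)
        sign = 1 if rng.integers(2) else -1
        shift = np.zeros(3)
        shift[axis_xy] = sign * s
        theta = rng.uniform(0, np.deg2rad(5.0))
        azim = rng.uniform(0, 2 * np.pi)
        rot = Rotation.from_rotvec(theta * np.array([np.cos(azim), np.sin(azim), 0.0]))
        pose = _transform_antibody(native, rot, corners[rng.integers(len(corners))], shift)
        emit(pose, compute_fnat(contacts, pose), "register", float(s + theta))

    # off-site: slide the antibody patch out along the tail direction by at
    # least the patch width, so no antibody residue sits over the patch any
    # more and the trailing row docks onto the antigen tail: fnat = 0 with a
    # valid centre and a line-contact geometry distinct from the interface
    if n_off and spec.ag_tail < spec.patch_nx:
        raise InputError("off-site poses need ag_tail >= patch_nx")
    tail_sign = 1 if spec.patch_ny % 2 == 1 else -1  # serpentine exit side
    for _ in range(n_off):
        j = int(rng.integers(spec.patch_nx, spec.ag_tail + 1))
        shift = np.array([tail_sign * j * s + rng.uniform(-0.3, 0.3),
                          rng.uniform(-0.3, 0.3), 0.0])
        theta = rng.uniform(0, np.deg2rad(5.0))
        azim = rng.uniform(0, 2 * np.pi)
        rot = Rotation.from_rotvec(theta * np.array([np.cos(azim), np.sin(azim), 0.0]))
        pose = _transform_antibody(native, rot, corners[3], shift)
        emit(pose, compute_fnat(contacts, pose), "offsite", float(j * s))

    for _ in range(n_far):
        shift = np.array([0.0, 0.0, FAR_SHIFT + rng.uniform(0, 10)])
        pose = _transform_antibody(native, Rotation.identity(), corners[0], shift)
        emit(pose, 0.0, "far", float(shift[2]))

    table = pd.DataFrame(rows)
    table["dock_score"] = (
        dock_offset
        + dock_slope * table["fnat"].to_numpy()
        + rng.normal(0.0, dock_noise, size=len(table))
    )
    order = np.argsort(-table["dock_score"].to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "pose_rank", np.arange(1, len(table) + 1))
    poses = [poses[i] for i in order]
    return PoseSet(poses=poses, table=table)


def make_nonbinder_pose_set(
    native: AnnotatedComplex,
    n_poses: int,
    rng: Optional[np.random.Generator] = None,
    gap_fraction: float = 0.1,
    dock_offset: float = 15.5,
    dock_noise: float = 2.0,
) -> PoseSet:
    """Pose ensemble of a non-binder (decoy) pairing.

    Clash placements push the antibody patch into or through the antigen
    plane (valid interaction centre, wrong geometry); a small fraction of
    gapped placements has no contact at all and is discarded by the
    pipeline.  fnat is NaN: no native complex exists for a decoy pairing.
    The docking-score offset sits below a well-docked cognate's top pose
    but the top-pose distributions overlap, so ranking candidates by
    docking score alone is informative yet clearly imperfect — the regime
    in which score fusion has room to help.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows, poses = [], []
    n_gap = int(round(gap_fraction * n_poses))
    for i in range(n_poses):
        if i < n_gap:
            dz = rng.uniform(4.0, 12.0)  # gap: min separation > centre cutoff
            kind = "gap"
        else:
            dz = -PLANE_GAP + rng.uniform(-0.5, 1.5)  # clash: interpenetration
            kind = "clash"
        shift = np.array([rng.uniform(-1.0, 1.0), rng.uniform(-1.0, 1.0), dz])
        theta = rng.uniform(0, np.deg2rad(10.0))
        azim = rng.uniform(0, 2 * np.pi)
        rot = Rotation.from_rotvec(theta * np.array([np.cos(azim), np.sin(azim), 0.0]))
        pivot = native.coords[native.antibody_mask].mean(axis=0)
        pose = _transform_antibody(native, rot, pivot, shift)
        poses.append(pose)
        rows.append({"fnat": np.nan, "kind": kind, "magnitude": float(abs(dz))})
    table = pd.DataFrame(rows)
    table["dock_score"] = dock_offset + rng.normal(0.0, dock_noise, size=len(table))
    order = np.argsort(-table["dock_score"].to_numpy(), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "pose_rank", np.arange(1, len(table) + 1))
    return PoseSet(poses=[poses[i] for i in order], table=table)


# ---------------------------------------------------------------------------
# Decoy antibody pools


def make_decoy_pool(
    cognate_cdr: str,
    n_families: int = 5,
    family_size: int = 10,
    rng: Optional[np.random.Generator] = None,
    cross_max: float = 0.45,
    cognate_max: float = 0.7,
) -> Dict[str, str]:
    """CDR strings for a decoy antibody pool with planted family structure.

    Families are tight (within-family pairwise identity >= 0.95), mutually
    distant (cross-family identity <= 0.5) and all well below 90% identity
    to the cognate, so the decoy sampler's identity gate never trips on
    them by construction — and clustering recovers exactly the families.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    L = len(cognate_cdr)
    if L < 4:
        raise InputError("cognate CDR too short")
    n_mut = int(0.025 * L)  # pairwise within-family identity stays >= 0.95
    centers: List[str] = []
    guard = 0
    while len(centers) < n_families:
        guard += 1
        if guard > 10_000:
            raise VoxscreenError("could not place decoy families; relax constraints")
        cand = "".join(AA1[i] for i in rng.integers(len(AA1), size=L))
        from .training import cdr_identity

        if cdr_identity(cand, cognate_cdr) > cognate_max:
            continue
        if any(cdr_identity(cand, c) > cross_max for c in centers):
            continue
        centers.append(cand)
    pool: Dict[str, str] = {}
    for f, center in enumerate(centers):
        for m in range(family_size):
            seq = list(center)
            for pos in rng.choice(L, size=n_mut, replace=False) if n_mut else []:
                seq[pos] = AA1[rng.integers(len(AA1))]
            pool[f"fam{f}_{m}"] = "".join(seq)
    return pool


# ---------------------------------------------------------------------------
# Grid-level learnability tasks


def make_grid_learnability_task(
    n_examples: int,
    grid_spec: GridSpec = GridSpec(radius=9.0, resolution=0.75),
    rng: Optional[np.random.Generator] = None,
    task: str = "re",
    channels: Optional[ChannelMap] = None,
    poses_per_complex: int = 40,
) -> Tuple[List[TrainExample], pd.DataFrame]:
    """Desk-scale surrogate training task on reduced grids.

    ``task="re"``: the label is the pose's true fnat, geometrically encoded
    in the inter-partner voxel proximity (all 11 fnat bins are populated).
    Tilt poses sweep bins 1..10; the zero bin comes from near-miss poses
    (antibody lifted just past the contact cutoff), whose grids show a
    visible gap — the fnat = 0 condition expressed in voxel proximity.
    Near-miss poses have no sub-4 A interaction, so their grids are centred
    on the midpoint of the closest cross-partner atom pair instead of the
    pipeline's interaction centre.
    ``task="vs"``: binder class 1 = complementary interface (fnat > 0.7),
    class 0 = planted clash or peeled-off (fnat < 0.1) geometry, balanced.
    Returns per-pose atom-level examples (gridded lazily during training so
    augmentation can resample the discretisation) plus a metadata table.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if task not in ("re", "vs"):
        raise InputError("task must be 're' or 'vs'")
    channels = channels or ChannelMap.default()
    spec = SyntheticComplexSpec()
    examples: List[TrainExample] = []
    meta = []

    while len(examples) < n_examples:
        native, contacts = make_native_complex(spec, rng)
        ch_idx = atom_channels(native.atoms, native.role_of_chain, channels)
        n_want = min(poses_per_complex, n_examples - len(examples))
        if task == "re":
            # register/off-site docks also have fnat = 0, but their grids
            # still show bulk contact; for a task whose labels must be
            # recoverable from voxel proximity, the zero bin uses lifted
            # near-miss poses instead
            n_lift = max(1, round(0.12 * n_want))
            pose_set = make_pose_set(
                native, contacts, n_poses=max(8, n_want - n_lift), rng=rng,
                spec=spec, far_fraction=0.0, register_fraction=0.0,
                offsite_fraction=0.0,
            )
            sel = zip(pose_set.poses, pose_set.table["fnat"])
            items = [(pose, float(f), f) for pose, f in sel][:n_want - n_lift]
            for _ in range(n_lift):
                dz = rng.uniform(1.4, 2.6)
                shift = np.array([rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5), dz])
                pose = _transform_antibody(native, Rotation.identity(),
                                           np.zeros(3), shift)
                assert compute_fnat(contacts, pose) == 0.0
                items.append((pose, 0.0, 0.0))
        else:
            n_bind = max(4, n_want) // 2
            binders = make_pose_set(
                native, contacts, n_poses=4 * n_bind, rng=rng, spec=spec,
                far_fraction=0.0, register_fraction=0.0, max_tilt_deg=30.0,
            )
            pos = [
                (pose, 1.0, f)
                for pose, f in zip(binders.poses, binders.table["fnat"])
                if f > 0.7
            ][:n_bind]
            lowf = [
                (pose, 0.0, f)
                for pose, f in zip(binders.poses, binders.table["fnat"])
                if f < 0.1
            ][: n_bind // 2]
            clashes = make_nonbinder_pose_set(
                native, n_poses=n_bind - len(lowf), rng=rng, gap_fraction=0.0
            )
            items = pos + lowf + [
                (pose, 0.0, np.nan) for pose in clashes.poses
            ]
        for pose, label, fnat in items:
            centre = interaction_centre(pose)
            if centre.valid:
                point = centre.point
            else:
                # near-miss pose: centre on the closest cross-partner pair
                ab = pose.coords[pose.antibody_mask]
                ag = pose.coords[~pose.antibody_mask]
                d = np.linalg.norm(ab[:, None, :] - ag[None, :, :], axis=2)
                i, j = np.unravel_index(np.argmin(d), d.shape)
                if d[i, j] > 8.0:
                    continue  # too far apart to featurize meaningfully
                point = 0.5 * (ab[i] + ag[j])
            examples.append(
                TrainExample(
                    coords=pose.coords.copy(),
                    channel_idx=ch_idx.copy(),
                    centre=point.copy(),
                    label=float(label),
                )
            )
            meta.append({"label": float(label), "fnat": float(fnat)})
    return examples[:n_examples], pd.DataFrame(meta[:n_examples])


# ---------------------------------------------------------------------------
# Fixture bundles for the CLI


def write_fixture_bundle(
    out_dir,
    n_antigens: int = 3,
    n_decoys: int = 4,
    n_poses: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Emit a complete on-disk screening fixture.

    Layout per antigen: ``native_<ag>.pdb``, per-pairing multi-model pose
    PDBs, per-pairing docking-score TSVs, a CDR range table and a manifest
    TSV the ``screen`` command consumes.  Returns the manifest.
    """
    import os

    from .structures import write_complex
    from biotite.structure.io.pdb import PDBFile
    import biotite.structure as struc

    if rng is None:
        rng = np.random.default_rng(0)
    os.makedirs(out_dir, exist_ok=True)
    spec = SyntheticComplexSpec()
    manifest_rows = []
    for a in range(n_antigens):
        ag_id = f"ag{a:03d}"
        native, contacts = make_native_complex(spec, rng)
        native_path = os.path.join(out_dir, f"native_{ag_id}.pdb")
        write_complex(native, native_path)
        pairings = [(f"{ag_id}_cognate", True)] + [
            (f"{ag_id}_decoy{d}", False) for d in range(n_decoys)
        ]
        for ab_id, is_cognate in pairings:
            if is_cognate:
                ps = make_pose_set(native, contacts, n_poses=n_poses, rng=rng, spec=spec)
            else:
                ps = make_nonbinder_pose_set(native, n_poses=n_poses, rng=rng)
            pose_path = os.path.join(out_dir, f"poses_{ab_id}.pdb")
            stack = struc.stack(
                [_pose_atom_array(p) for p in ps.poses]
            )
            pdb = PDBFile()
            pdb.set_structure(stack)
            pdb.write(pose_path)
            table_path = os.path.join(out_dir, f"dock_{ab_id}.tsv")
            ps.table[["pose_rank", "dock_score"]].to_csv(table_path, sep="\t", index=False)
            manifest_rows.append(
                {
                    "antigen_id": ag_id,
                    "antibody_id": ab_id,
                    "is_cognate": int(is_cognate),
                    "native_path": os.path.basename(native_path),
                    "pose_path": os.path.basename(pose_path),
                    "dock_score_table": os.path.basename(table_path),
                }
            )
        cdr_rows = [
            {"chain": chain, "cdr_label": lbl, "start_res": lo, "end_res": hi}
            for chain, loops in spec.cdr_layout.items()
            for lbl, (lo, hi) in loops.items()
        ]
        pd.DataFrame(cdr_rows).to_csv(
            os.path.join(out_dir, "cdr_ranges.tsv"), sep="\t", index=False
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest


def _pose_atom_array(pose: AnnotatedComplex):
    from .structures import _to_atom_array

    return _to_atom_array(pose.atoms)
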