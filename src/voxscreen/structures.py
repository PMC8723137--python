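"""Antibody-antigen structures: PDB I/O, surface exposure, epitope/paratope.

An :class:`AnnotatedComplex` holds one antibody-antigen pair as a flat atom
list plus chain-role, relative-surface-exposure and (optional) CDR
annotations.  The interface definitions follow the standard docking-pipeline
rules: an antigen residue belongs to the epitope when it is surface exposed
and any of its atoms lies strictly within the contact cutoff (default 4 A)
of an atom of a surface-exposed antibody residue; the allowed docking
interface additionally includes exposed antigen residues within the
expansion cutoff of the epitope.  The paratope is either the mirror-image
contact definition or the IMGT CDR loops plus two flanking residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigurationError, InputError

__all__ = [
    "Atom",
    "AnnotatedComplex",
    "InterfaceDefinition",
    "ANTIBODY_ROLES",
    "ROLES",
    "read_complex",
    "write_complex",
    "relative_surface_exposure",
    "surface_residues",
    "define_epitope",
    "define_paratope_from_contacts",
    "define_paratope_from_cdrs",
    "cdr_concat_sequence",
    "imgt_cdr_annotation",
    "read_cdr_table",
    "CDR_ORDER",
]

ResidueKey = Tuple[str, int, str]

ROLE_ANTIBODY_HEAVY = "antibody_heavy"
ROLE_ANTIBODY_LIGHT = "antibody_light"
ROLE_ANTIGEN = "antigen"
ANTIBODY_ROLES = frozenset({ROLE_ANTIBODY_HEAVY, ROLE_ANTIBODY_LIGHT})
ROLES = frozenset({ROLE_ANTIBODY_HEAVY, ROLE_ANTIBODY_LIGHT, ROLE_ANTIGEN})

#: fixed CDR concatenation order (heavy loops then light loops)
CDR_ORDER = ("H1", "H2", "H3", "L1", "L2", "L3")

#: IMGT loop boundaries on IMGT-numbered chains
IMGT_CDR_RANGES = {"1": (27, 38), "2": (56, 65), "3": (105, 117)}

# Theoretical maximum accessible surface areas (A^2) per residue type
# (Tien et al. 2013), used to normalise absolute SASA to relative exposure.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
GENERIC_MAX_ASA = 200.0

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    """One atom of a complex.

    ``residue_key`` is the (chain id, residue number, insertion code) triple
    that identifies the parent residue across poses of a rigid-body docking
    run.
    """

    serial: int
    element: str
    name: str
    coords: np.ndarray
    residue_key: ResidueKey
    residue_name: str
    is_heavy: bool

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise InputError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.element:
            raise InputError(f"atom {self.serial}: empty element")
        if self.is_heavy != (self.element.upper() not in ("H", "D")):
            raise InputError(f"atom {self.serial}: is_heavy inconsistent with element")


@dataclass
class AnnotatedComplex:
    """Atoms of one antibody-antigen pair with chain roles and annotations."""

    atoms: List[Atom]
    role_of_chain: Dict[str, str]
    rel_exposure: Optional[Dict[ResidueKey, float]] = None
    cdr_annotation: Optional[Dict[ResidueKey, str]] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        for chain, role in self.role_of_chain.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown role {role!r} for chain {chain!r}")
        chains = {a.residue_key[0] for a in self.atoms}
        missing = chains - set(self.role_of_chain)
        if missing:
            raise ConfigurationError(f"chains without role: {sorted(missing)}")
        if not any(self.role_of_chain.get(c) == ROLE_ANTIGEN for c in chains):
            raise InputError("complex has no antigen atoms")
        if not any(self.role_of_chain.get(c) in ANTIBODY_ROLES for c in chains):
            raise InputError("complex has no antibody atoms")

    # -- array views -------------------------------------------------------

    def _arrays(self):
        """Cached numpy views over the atom list."""
        if "coords" not in self._cache:
            self._cache["coords"] = np.array([a.coords for a in self.atoms])
            self._cache["heavy"] = np.array([a.is_heavy for a in self.atoms])
            self._cache["is_ab"] = np.array(
                [self.role_of_chain[a.residue_key[0]] in ANTIBODY_ROLES for a in self.atoms]
            )
        return self._cache

    @property
    def coords(self) -> np.ndarray:
        return self._arrays()["coords"]

    @property
    def heavy_mask(self) -> np.ndarray:
        return self._arrays()["heavy"]

    @property
    def antibody_mask(self) -> np.ndarray:
        return self._arrays()["is_ab"]

    def residue_keys(self) -> List[ResidueKey]:
        """Residue keys in order of first appearance."""
        seen, out = set(), []
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                out.append(a.residue_key)
        return out

    def chain_residues(self, chain: str) -> List[ResidueKey]:
        """Residues of one chain in sequence order (residue number, then
        insertion code) — invariant to atom order in the source file."""
        keys = {k for k in self.residue_keys() if k[0] == chain}
        return sorted(keys, key=lambda k: (k[1], k[2]))

    def residue_name_of(self, key: ResidueKey) -> str:
        if "resname" not in self._cache:
            self._cache["resname"] = {a.residue_key: a.residue_name for a in self.atoms}
        return self._cache["resname"][key]

    def atoms_of_residue(self, key: ResidueKey) -> List[Atom]:
        if "by_res" not in self._cache:
            by_res: Dict[ResidueKey, List[Atom]] = {}
            for a in self.atoms:
                by_res.setdefault(a.residue_key, []).append(a)
            self._cache["by_res"] = by_res
        return self._cache["by_res"][key]

    def is_antibody_residue(self, key: ResidueKey) -> bool:
        return self.role_of_chain[key[0]] in ANTIBODY_ROLES

    def with_coords(self, coords: np.ndarray) -> "AnnotatedComplex":
        """A copy of this complex with replaced atom coordinates."""
        coords = np.asarray(coords, float)
        if coords.shape != (len(self.atoms), 3):
            raise InputError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        return AnnotatedComplex(
            atoms=atoms,
            role_of_chain=dict(self.role_of_chain),
            rel_exposure=dict(self.rel_exposure) if self.rel_exposure else None,
            cdr_annotation=dict(self.cdr_annotation) if self.cdr_annotation else None,
        )


@dataclass
class InterfaceDefinition:
    """Epitope atoms, allowed docking interface and paratope residues."""

    epitope_atoms: Set[int]
    docking_interface_atoms: Set[int]
    paratope_residues: Set[ResidueKey]

    def __post_init__(self):
        if not self.epitope_atoms <= self.docking_interface_atoms:
            raise InputError("epitope atoms must be a subset of the docking interface")


# ---------------------------------------------------------------------------
# PDB I/O


def _structure_to_atoms(array: struc.AtomArray) -> List[Atom]:
    atoms = []
    serials = (
        array.atom_id if "atom_id" in array.get_annotation_categories()
        else np.arange(1, array.array_length() + 1)
    )
    for i in range(array.array_length()):
        element = str(array.element[i]).strip() or "C"
        atoms.append(
            Atom(
                serial=int(serials[i]),
                element=element,
                name=str(array.atom_name[i]).strip(),
                coords=np.asarray(array.coord[i], dtype=float),
                residue_key=(
                    str(array.chain_id[i]),
                    int(array.res_id[i]),
                    str(array.ins_code[i]).strip(),
                ),
                residue_name=str(array.res_name[i]).strip(),
                is_heavy=element.upper() not in ("H", "D"),
            )
        )
    return atoms


def _infer_roles(chains: Iterable[str]) -> Dict[str, str]:
    roles = {}
    for c in chains:
        if c.upper() == "H":
            roles[c] = ROLE_ANTIBODY_HEAVY
        elif c.upper() == "L":
            roles[c] = ROLE_ANTIBODY_LIGHT
        else:
            roles[c] = ROLE_ANTIGEN
    return roles


def read_complex(
    pdb_path,
    chain_map: Optional[Mapping[str, str]] = None,
    model: int = 1,
) -> AnnotatedComplex:
    """Read one antibody-antigen complex from a PDB file.

    Alternate locations are resolved to the highest-occupancy copy, waters
    and hetero small molecules are dropped, hydrogens are retained but
    flagged.  ``chain_map`` assigns each chain a role; when omitted, chains
    named H/L are taken as the antibody and every other chain as antigen.
    Multi-MODEL files are read one model at a time (``model`` selects which),
    so a file of docked poses can be consumed pose by pose.
    """
    pdb = PDBFile.read(pdb_path)
    array = pdb.get_structure(model=model, altloc="occupancy", extra_fields=["atom_id"])
    keep = ~array.hetero & ~np.isin(array.res_name, sorted(_WATER_NAMES))
    array = array[keep]
    if array.array_length() == 0:
        raise InputError(f"{pdb_path}: no polymer atoms after filtering")
    chains = sorted(set(str(c) for c in array.chain_id))
    if chain_map is None:
        roles = _infer_roles(chains)
    else:
        missing = [c for c in chains if c not in chain_map]
        if missing:
            raise ConfigurationError(f"{pdb_path}: chains {missing} missing from chain_map")
        roles = {c: chain_map[c] for c in chains}
    return AnnotatedComplex(atoms=_structure_to_atoms(array), role_of_chain=roles)


def n_models(pdb_path) -> int:
    """Number of MODEL records in a PDB file (1 for single-model files)."""
    return PDBFile.read(pdb_path).get_model_count()


def _to_atom_array(atoms: Sequence[Atom]) -> struc.AtomArray:
    n = len(atoms)
    array = struc.AtomArray(n)
    array.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    array.chain_id = np.array([a.residue_key[0] for a in atoms], dtype="U4")
    array.res_id = np.array([a.residue_key[1] for a in atoms], dtype=int)
    array.ins_code = np.array([a.residue_key[2] for a in atoms], dtype="U1")
    array.res_name = np.array([a.residue_name for a in atoms], dtype="U5")
    array.atom_name = np.array([a.name for a in atoms], dtype="U6")
    array.element = np.array([a.element.upper() for a in atoms], dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    array.set_annotation("occupancy", np.ones(n))
    array.set_annotation("b_factor", np.zeros(n))
    return array


def write_complex(complex_: AnnotatedComplex, path) -> None:
    """Write a complex as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(complex_.atoms))
    pdb.write(path)


# ---------------------------------------------------------------------------
# Surface exposure


def _residue_sasa(atoms: Sequence[Atom], point_number: int) -> Dict[ResidueKey, float]:
    array = _to_atom_array(atoms)
    heavy = np.array([a.is_heavy for a in atoms])
    per_atom = struc.sasa(
        array, atom_filter=heavy, vdw_radii="Single", point_number=point_number
    )
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    out: Dict[ResidueKey, float] = {}
    for a, s in zip(atoms, per_atom):
        out[a.residue_key] = out.get(a.residue_key, 0.0) + float(s)
    return out


def relative_surface_exposure(
    complex_: AnnotatedComplex,
    partner_split: bool = True,
    point_number: int = 300,
) -> Dict[ResidueKey, float]:
    """Per-residue relative solvent exposure in [0, 1].

    Shrake-Rupley SASA of each residue divided by its residue-type reference
    maximum, clipped to [0, 1].  With ``partner_split`` the antibody and the
    antigen are evaluated as separate isolated structures, which is how
    surface residues are determined before epitope/paratope definition (an
    interface residue buried in the complex is still "surface" on the lone
    partner).
    """
    heavy_present = any(a.is_heavy for a in complex_.atoms)
    if not heavy_present:
        raise InputError("no heavy atoms present for SASA computation")
    if partner_split:
        ab_atoms = [a for a in complex_.atoms if complex_.is_antibody_residue(a.residue_key)]
        ag_atoms = [a for a in complex_.atoms if not complex_.is_antibody_residue(a.residue_key)]
        sasa_map = _residue_sasa(ab_atoms, point_number)
        sasa_map.update(_residue_sasa(ag_atoms, point_number))
    else:
        sasa_map = _residue_sasa(complex_.atoms, point_number)

    out: Dict[ResidueKey, float] = {}
    unknown: Set[str] = set()
    for key in complex_.residue_keys():
        name = complex_.residue_name_of(key)
        ref = MAX_ASA.get(name)
        if ref is None:
            unknown.add(name)
            ref = GENERIC_MAX_ASA
        out[key] = float(np.clip(sasa_map.get(key, 0.0) / ref, 0.0, 1.0))
    if unknown:
        warnings.warn(
            f"unknown residue types {sorted(unknown)}: using generic reference "
            f"maximum {GENERIC_MAX_ASA} A^2",
            stacklevel=2,
        )
    return out


def surface_residues(
    complex_: AnnotatedComplex, exposure_threshold: float = 0.15
) -> Set[ResidueKey]:
    """Residues whose relative exposure reaches the threshold."""
    if complex_.rel_exposure is None:
        raise InputError(
            "rel_exposure not set; call relative_surface_exposure(partner_split=True) first"
        )
    return {k for k, v in complex_.rel_exposure.items() if v >= exposure_threshold}


# ---------------------------------------------------------------------------
# Epitope / paratope


def _contacting_residues(
    complex_: AnnotatedComplex,
    query_is_antibody: bool,
    exposure_threshold: float,
    contact_cutoff: float,
) -> Set[ResidueKey]:
    """Exposed residues on one side with any heavy atom strictly within
    ``contact_cutoff`` of a heavy atom of an exposed residue on the other side."""
    surf = surface_residues(complex_, exposure_threshold)
    side = [
        a for a in complex_.atoms
        if a.is_heavy and a.residue_key in surf
        and complex_.is_antibody_residue(a.residue_key) != query_is_antibody
    ]
    query = [
        a for a in complex_.atoms
        if a.is_heavy and a.residue_key in surf
        and complex_.is_antibody_residue(a.residue_key) == query_is_antibody
    ]
    if not side or not query:
        return set()
    tree = cKDTree(np.array([a.coords for a in side]))
    hits = tree.query_ball_point(np.array([a.coords for a in query]), r=contact_cutoff)
    out: Set[ResidueKey] = set()
    side_coords = np.array([a.coords for a in side])
    for atom, idx in zip(query, hits):
        if not idx:
            continue
        # strict "<" at the cutoff: query_ball_point is "<=", re-check
        d = np.linalg.norm(side_coords[idx] - atom.coords, axis=1)
        if np.any(d < contact_cutoff):
            out.add(atom.residue_key)
    return out


def define_epitope(
    complex_: AnnotatedComplex,
    exposure_threshold: float = 0.15,
    contact_cutoff: float = 4.0,
    expansion_cutoff: float = 4.0,
) -> InterfaceDefinition:
    """Epitope and allowed docking interface on the antigen.

    The epitope is every atom of a surface-exposed antigen residue having
    any heavy atom strictly within ``contact_cutoff`` of a heavy atom of a
    surface-exposed antibody residue.  The allowed docking interface also
    includes all atoms of exposed antigen residues within
    ``expansion_cutoff`` of any epitope atom, modelling realistic access to
    the epitope.
    """
    epi_res = _contacting_residues(
        complex_, query_is_antibody=False,
        exposure_threshold=exposure_threshold, contact_cutoff=contact_cutoff,
    )
    if not epi_res:
        raise InputError("empty epitope: no antigen-antibody contacts under the cutoffs")
    para_res = _contacting_residues(
        complex_, query_is_antibody=True,
        exposure_threshold=exposure_threshold, contact_cutoff=contact_cutoff,
    )
    epitope_atoms = {
        a.serial for a in complex_.atoms if a.residue_key in epi_res
    }
    # expansion: exposed antigen residues with any heavy atom near an epitope atom
    surf = surface_residues(complex_, exposure_threshold)
    epi_coords = np.array(
        [a.coords for a in complex_.atoms if a.serial in epitope_atoms and a.is_heavy]
    )
    tree = cKDTree(epi_coords)
    expanded = set(epi_res)
    for key in surf:
        if complex_.is_antibody_residue(key) or key in expanded:
            continue
        coords = np.array([a.coords for a in complex_.atoms_of_residue(key) if a.is_heavy])
        if coords.size and np.any(
            np.array(tree.query(coords, k=1)[0]) < expansion_cutoff
        ):
            expanded.add(key)
    interface_atoms = {
        a.serial for a in complex_.atoms if a.residue_key in expanded
    }
    return InterfaceDefinition(
        epitope_atoms=epitope_atoms,
        docking_interface_atoms=interface_atoms,
        paratope_residues=para_res,
    )


def define_paratope_from_contacts(
    complex_: AnnotatedComplex,
    exposure_threshold: float = 0.15,
    contact_cutoff: float = 4.0,
) -> Set[ResidueKey]:
    """Paratope as the contact mirror image of the epitope definition."""
    para = _contacting_residues(
        complex_, query_is_antibody=True,
        exposure_threshold=exposure_threshold, contact_cutoff=contact_cutoff,
    )
    if not para:
        raise InputError("empty paratope: no antibody-antigen contacts under the cutoffs")
    return para


def define_paratope_from_cdrs(
    complex_: AnnotatedComplex, flank: int = 2
) -> Set[ResidueKey]:
    """Paratope as the annotated CDR loops plus ``flank`` residues either side.

    Flanks are sequence-adjacent residues in chain order, clipped at chain
    termini.  Requires ``cdr_annotation`` (IMGT-numbered chains can be
    annotated with :func:`imgt_cdr_annotation`, or supply an explicit range
    table via :func:`read_cdr_table`).
    """
    if complex_.cdr_annotation is None:
        raise InputError(
            "cdr_annotation missing: supply IMGT numbering or a CDR range table"
        )
    out: Set[ResidueKey] = set()
    for chain in {k[0] for k in complex_.cdr_annotation}:
        order = complex_.chain_residues(chain)
        index = {k: i for i, k in enumerate(order)}
        # expand each contiguous annotated run by `flank` on both sides
        positions = sorted(index[k] for k in complex_.cdr_annotation if k[0] == chain)
        for pos in positions:
            lo = max(0, pos - flank)
            hi = min(len(order) - 1, pos + flank)
            out.update(order[lo:hi + 1])
    bad = [k for k in out if not complex_.is_antibody_residue(k)]
    if bad:
        raise InputError(f"CDR annotation on non-antibody chains: {sorted({k[0] for k in bad})}")
    return out


def cdr_concat_sequence(complex_: AnnotatedComplex) -> str:
    """One-letter sequence of H1,H2,H3,L1,L2,L3 concatenated in that order.

    Residues within each loop follow chain order; non-standard residues map
    to 'X'.  All six loops must be annotated.
    """
    if complex_.cdr_annotation is None:
        raise InputError("cdr_annotation missing")
    by_label: Dict[str, List[ResidueKey]] = {lbl: [] for lbl in CDR_ORDER}
    for key, label in complex_.cdr_annotation.items():
        if label not in by_label:
            raise InputError(f"unknown CDR label {label!r}")
        by_label[label].append(key)
    missing = [lbl for lbl in CDR_ORDER if not by_label[lbl]]
    if missing:
        raise InputError(f"CDR loops not annotated: {missing}")
    parts = []
    for label in CDR_ORDER:
        keys = by_label[label]
        chain_order = {k: i for i, k in enumerate(complex_.chain_residues(keys[0][0]))}
        for key in sorted(keys, key=lambda k: chain_order[k]):
            parts.append(THREE_TO_ONE.get(complex_.residue_name_of(key), "X"))
    return "".join(parts)


# ---------------------------------------------------------------------------
# CDR annotation sources


def imgt_cdr_annotation(complex_: AnnotatedComplex) -> Dict[ResidueKey, str]:
    """CDR labels for chains whose residue numbers are already IMGT.

    Maps residues 27-38 to CDR1, 56-65 to CDR2 and 105-117 to CDR3 on every
    antibody chain, prefixed H/L by chain role.  IMGT numbering itself is
    not assigned here.
    """
    out: Dict[ResidueKey, str] = {}
    for key in complex_.residue_keys():
        role = complex_.role_of_chain[key[0]]
        if role not in ANTIBODY_ROLES:
            continue
        prefix = "H" if role == ROLE_ANTIBODY_HEAVY else "L"
        for loop, (lo, hi) in IMGT_CDR_RANGES.items():
            if lo <= key[1] <= hi:
                out[key] = prefix + loop
    return out


def read_cdr_table(path, complex_: AnnotatedComplex) -> Dict[ResidueKey, str]:
    """Read an explicit CDR range table (TSV: chain, cdr_label, start_res, end_res)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "cdr_label": str})
    required = {"chain", "cdr_label", "start_res", "end_res"}
    if not required <= set(df.columns):
        raise InputError(f"CDR table needs columns {sorted(required)}")
    out: Dict[ResidueKey, str] = {}
    for row in df.itertuples(index=False):
        for key in complex_.chain_residues(str(row.chain)):
            if int(row.start_res) <= key[1] <= int(row.end_res):
                out[key] = str(row.cdr_label)
    return out
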