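"""Structure I/O, surface exposure and epitope/paratope definitions."""

import numpy as np
import pytest

from voxscreen.errors import ConfigurationError, InputError
from voxscreen.structures import (
    Atom,
    AnnotatedComplex,
    cdr_concat_sequence,
    define_epitope,
    define_paratope_from_cdrs,
    define_paratope_from_contacts,
    read_complex,
    relative_surface_exposure,
    surface_residues,
    write_complex,
)
from voxscreen.synthetic import make_native_complex

from conftest import make_toy_complex


def _pdb_line(serial, name, res, chain, res_id, x, y, z, occ=1.0, altloc=" ", element="C"):
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{res:3s} {chain}{res_id:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}\n"
    )


class TestReadComplex:
    def test_two_chain_toy(self, tmp_path):
        lines = []
        serial = 1
        for chain in ("H", "A"):
            for r in range(1, 11):
                lines.append(_pdb_line(serial, "CA", "ALA", chain, r, r * 3.8, 0.0,
                                       0.0 if chain == "A" else 5.0))
                serial += 1
        path = tmp_path / "toy.pdb"
        path.write_text("".join(lines) + "END\n")
        cx = read_complex(path)
        assert set(cx.role_of_chain.values()) == {"antibody_heavy", "antigen"}
        assert len(cx.residue_keys()) == 20
        assert len(cx.atoms) == 20

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "ALA", "H", 1, 0.0, 0.0, 0.0, occ=0.4, altloc="A"),
            _pdb_line(2, "CA", "ALA", "H", 1, 9.0, 0.0, 0.0, occ=0.6, altloc="B"),
            _pdb_line(3, "CA", "GLY", "A", 1, 0.0, 0.0, 5.0),
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("".join(lines) + "END\n")
        cx = read_complex(path)
        h_atoms = [a for a in cx.atoms if a.residue_key[0] == "H"]
        assert len(h_atoms) == 1
        assert h_atoms[0].coords[0] == pytest.approx(9.0)

    def test_waters_dropped_hydrogens_flagged(self, tmp_path):
        lines = [
            _pdb_line(1, "CA", "ALA", "H", 1, 0.0, 0.0, 0.0),
            _pdb_line(2, "H", "ALA", "H", 1, 0.5, 0.0, 0.0, element="H"),
            _pdb_line(3, "CA", "GLY", "A", 1, 0.0, 0.0, 5.0),
            "HETATM    4  O   HOH A 101      9.000   9.000   9.000  1.00  0.00           O\n",
        ]
        path = tmp_path / "w.pdb"
        path.write_text("".join(lines) + "END\n")
        cx = read_complex(path)
        assert all(a.residue_name != "HOH" for a in cx.atoms)
        hydrogens = [a for a in cx.atoms if not a.is_heavy]
        assert len(hydrogens) == 1 and hydrogens[0].element.upper() == "H"

    def test_missing_chain_in_map_is_configuration_error(self, tmp_path):
        path = tmp_path / "c.pdb"
        path.write_text(
            _pdb_line(1, "CA", "ALA", "X", 1, 0.0, 0.0, 0.0)
            + _pdb_line(2, "CA", "GLY", "A", 1, 0.0, 0.0, 5.0) + "END\n"
        )
        with pytest.raises(ConfigurationError):
            read_complex(path, chain_map={"A": "antigen"})

    def test_synthetic_roundtrip(self, tmp_path, native_pair):
        native, _ = native_pair
        path = tmp_path / "native.pdb"
        write_complex(native, path)
        back = read_complex(path)
        assert len(back.atoms) == len(native.atoms)
        np.testing.assert_allclose(back.coords, native.coords, atol=1e-3)


class TestSurfaceExposure:
    def test_extended_tripeptide_middle_exposed(self):
        # crude extended Gly-Gly-Gly backbone: N, CA, C, O per residue
        atoms, serial = [], 1
        for r in range(3):
            x = r * 3.8
            for name, elem, off in (
                ("N", "N", (-1.2, 0.4, 0.0)),
                ("CA", "C", (0.0, 0.0, 0.0)),
                ("C", "C", (1.2, 0.4, 0.0)),
                ("O", "O", (1.4, 1.6, 0.0)),
            ):
                atoms.append(Atom(serial, elem, name,
                                  np.array([x + off[0], off[1], off[2]]),
                                  ("H", r + 1, ""), "GLY", True))
                serial += 1
        atoms.append(Atom(serial, "C", "CA", np.array([50.0, 50.0, 50.0]),
                          ("A", 1, ""), "GLY", True))
        cx = AnnotatedComplex(
            atoms=atoms,
            role_of_chain={"H": "antibody_heavy", "A": "antigen"},
        )
        exposure = relative_surface_exposure(cx, partner_split=True)
        assert exposure[("H", 2, "")] >= 0.8

    def test_buried_centre_of_dense_ball(self):
        # residue 1 at the centre of a 2 A-spaced carbon lattice
        shell = [
            (x, y, z)
            for x in np.arange(-6, 6.1, 2)
            for y in np.arange(-6, 6.1, 2)
            for z in np.arange(-6, 6.1, 2)
            if (x, y, z) != (0.0, 0.0, 0.0)
        ]
        cx = make_toy_complex(ab_coords=[(80, 80, 80)], ag_coords=[(0, 0, 0)] + shell)
        exposure = relative_surface_exposure(cx, partner_split=True)
        assert exposure[("A", 1, "")] < 0.05

    def test_partner_split_not_below_complex_value_at_interface(self, native_pair):
        native, _ = native_pair
        split = relative_surface_exposure(native, partner_split=True)
        joint = relative_surface_exposure(native, partner_split=False)
        # interface patch residues: the partner occludes them in the complex
        for key in [("A", i, "") for i in range(1, 13)]:
            assert split[key] >= joint[key] - 0.02

    def test_unknown_residue_warns_and_uses_generic(self):
        cx = make_toy_complex(ab_coords=[(0, 0, 0)], ag_coords=[(50, 0, 0)])
        cx.atoms[0] = Atom(1, "C", "CA", np.zeros(3), ("H", 1, ""), "XYZ", True)
        cx._cache.clear()
        with pytest.warns(UserWarning, match="generic"):
            relative_surface_exposure(cx)


class TestEpitope:
    @pytest.mark.parametrize("distance,expected", [(3.9, True), (4.1, False)])
    def test_contact_cutoff_is_strict(self, distance, expected):
        cx = make_toy_complex(ab_coords=[(0, 0, 0)], ag_coords=[(distance, 0, 0)])
        if expected:
            iface = define_epitope(cx)
            ag_serials = {a.serial for a in cx.atoms if a.residue_key[0] == "A"}
            assert iface.epitope_atoms == ag_serials
        else:
            with pytest.raises(InputError):
                define_epitope(cx)

    def test_buried_residue_excluded_despite_proximity(self):
        cx = make_toy_complex(ab_coords=[(0, 0, 0)], ag_coords=[(3.0, 0, 0)])
        cx.rel_exposure[("A", 1, "")] = 0.01  # below the exposure threshold
        with pytest.raises(InputError):
            define_epitope(cx)

    def test_epitope_matches_brute_force_scan(self, native_pair):
        native, _ = native_pair
        iface = define_epitope(native)
        surf = surface_residues(native, 0.15)
        expected = set()
        for a in native.atoms:
            if native.is_antibody_residue(a.residue_key) or a.residue_key not in surf:
                continue
            for b in native.atoms:
                if not native.is_antibody_residue(b.residue_key):
                    continue
                if b.residue_key in surf and np.linalg.norm(a.coords - b.coords) < 4.0:
                    expected.add(a.residue_key)
                    break
        got = {a.residue_key for a in native.atoms if a.serial in iface.epitope_atoms}
        assert got == expected
        assert iface.epitope_atoms <= iface.docking_interface_atoms

    def test_epitope_monotone_in_cutoff(self, native_pair):
        native, _ = native_pair
        sizes = [
            len(define_epitope(native, contact_cutoff=c).epitope_atoms)
            for c in (4.0, 5.0, 6.0)
        ]
        assert sizes == sorted(sizes)

    def test_paratope_is_contact_mirror(self, native_pair):
        native, _ = native_pair
        para = define_paratope_from_contacts(native)
        iface = define_epitope(native)
        assert para == iface.paratope_residues
        assert all(native.is_antibody_residue(k) for k in para)


class TestCdrParatope:
    def _chain_complex(self, n=20, cdr_range=(8, 12)):
        cx = make_toy_complex(
            ab_coords=[(i * 3.8, 0, 0) for i in range(n)],
            ag_coords=[(0, 0, 4.0)],
        )
        cx.cdr_annotation = {
            ("H", r, ""): "H1" for r in range(cdr_range[0], cdr_range[1] + 1)
        }
        return cx

    def test_flank_expansion(self):
        para = define_paratope_from_cdrs(self._chain_complex(), flank=2)
        assert para == {("H", r, "") for r in range(6, 15)}

    def test_no_underflow_at_chain_start(self):
        para = define_paratope_from_cdrs(self._chain_complex(cdr_range=(1, 3)), flank=2)
        assert para == {("H", r, "") for r in range(1, 6)}

    def test_six_loop_window_oracle(self, native_pair):
        native, _ = native_pair
        para = define_paratope_from_cdrs(native, flank=2)
        expected = set()
        for chain in ("H", "L"):
            order = native.chain_residues(chain)
            idx = {k: i for i, k in enumerate(order)}
            for key, _label in native.cdr_annotation.items():
                if key[0] != chain:
                    continue
                i = idx[key]
                expected.update(order[max(0, i - 2):i + 3])
        assert para == expected

    def test_missing_annotation_is_input_error(self, native_pair):
        native, _ = native_pair
        bare = AnnotatedComplex(
            atoms=list(native.atoms), role_of_chain=dict(native.role_of_chain)
        )
        with pytest.raises(InputError):
            define_paratope_from_cdrs(bare)


class TestCdrSequence:
    def test_fixed_order_concatenation(self):
        cx = make_toy_complex(
            ab_coords=[(i * 3.8, 0, 0) for i in range(6)],
            ag_coords=[(0, 0, 4.0)],
        )
        names = ["GLY", "PHE", "THR", "ILE", "SER", "SER"]
        cx.atoms = [
            Atom(a.serial, a.element, a.name, a.coords, a.residue_key,
                 names[i] if a.residue_key[0] == "H" else a.residue_name, True)
            for i, a in enumerate(cx.atoms[:6])
        ] + cx.atoms[6:]
        cx._cache.clear()
        cx.cdr_annotation = {}
        for i, lbl in enumerate(["H1", "H2", "H3"]):
            cx.cdr_annotation[("H", 2 * i + 1, "")] = lbl
            cx.cdr_annotation[("H", 2 * i + 2, "")] = lbl
        with pytest.raises(InputError, match="L1"):
            cdr_concat_sequence(cx)  # light loops unannotated

    def test_synthetic_sequence_and_atom_order_invariance(self, native_pair, rng):
        native, _ = native_pair
        seq = cdr_concat_sequence(native)
        assert len(seq) == 24 and set(seq) <= set("ARNDCQEGHILKMFPSTWYVX")
        shuffled = AnnotatedComplex(
            atoms=[native.atoms[i] for i in rng.permutation(len(native.atoms))],
            role_of_chain=dict(native.role_of_chain),
        )
        shuffled.cdr_annotation = dict(native.cdr_annotation)
        assert cdr_concat_sequence(shuffled) == seq
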