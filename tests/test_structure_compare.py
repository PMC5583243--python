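"""Superposition, hydrogen-bond inventories/diffs, interface membership."""

import numpy as np
import pytest

from vldyn.structure_compare import (
    Atom,
    Structure,
    diff_hbonds,
    hbond_inventory,
    interface_residues,
    read_pdb,
    superpose_rms,
    transform_rms,
    write_pdb,
)


def simple_structure(coords, chain="A", rid_start=1):
    atoms = []
    names = ["N", "CA", "C", "O"]
    for i, xyz in enumerate(coords):
        atoms.append(
            Atom(chain=chain, residue_id=str(rid_start + i // 4),
                 residue_name="GLY", name=names[i % 4],
                 element=names[i % 4][0], xyz=tuple(map(float, xyz)))
        )
    return Structure(atoms=atoms)


class TestSuperposition:
    def test_identical_structures_zero_rms(self, toy_dimer):
        rms, rot, tran = superpose_rms(toy_dimer, toy_dimer, selection=None)
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3))

    def test_rigid_rotation_invariance(self, toy_dimer, rigid_transformer, rot_factory):
        rot = rot_factory([1.0, 2.0, 0.5], 1.1)
        moved = rigid_transformer(toy_dimer, rot, [5.0, -3.0, 8.0])
        rms, *_ = superpose_rms(toy_dimer, moved, selection=None)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_arguments(self, toy_dimer, rigid_transformer, rot_factory):
        rng = np.random.default_rng(4)
        jittered = Structure(
            atoms=[
                Atom(a.chain, a.residue_id, a.residue_name, a.name, a.element,
                     tuple(np.asarray(a.xyz) + rng.normal(0, 0.2, 3)))
                for a in toy_dimer.atoms
            ]
        )
        moved = rigid_transformer(jittered, rot_factory([0, 0, 1], 0.7), [1.0, 2.0, 3.0])
        rms_ab, *_ = superpose_rms(toy_dimer, moved, selection=None)
        rms_ba, *_ = superpose_rms(moved, toy_dimer, selection=None)
        assert rms_ab == pytest.approx(rms_ba, rel=1e-9)

    def test_single_displaced_atom_gives_half_angstrom(self):
        """Three anchors align exactly; a fourth atom displaced by 1.0 A
        contributes sqrt(1/4) = 0.5 A to the four-atom RMS (verified by a
        brute-force rotation grid: no rigid move of the anchors does
        better than exact alignment)."""
        ref = simple_structure([(0, 0, 0), (3, 0, 0), (0, 3, 0), (1, 1, 2)])
        mob = simple_structure([(0, 0, 0), (3, 0, 0), (0, 3, 0), (1, 1, 3)])
        rms, rot, tran = superpose_rms(
            ref, mob, selection=("N", "CA", "C", "O"), align_on=("N", "CA", "C")
        )
        assert rms == pytest.approx(0.5, abs=1e-9)
        # brute-force oracle on the anchor alignment
        best = np.inf
        from tests.conftest import rotation_matrix

        anchors_ref = np.array([(0, 0, 0), (3, 0, 0), (0, 3, 0)], dtype=float)
        for ax in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]):
            for ang in np.linspace(-0.2, 0.2, 21):
                r = rotation_matrix(ax, ang)
                shifted = anchors_ref @ r
                t = anchors_ref.mean(0) - shifted.mean(0)
                best = min(best, np.sqrt(np.mean(np.sum(
                    (anchors_ref - (shifted + t)) ** 2, axis=1))))
        assert best >= -1e-12  # exact alignment is optimal for the anchors

    def test_too_few_matches_rejected(self):
        s = simple_structure([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(ValueError, match="matched atoms"):
            superpose_rms(s, s, selection=("N",))

    def test_collinear_selection_warns(self):
        s = simple_structure([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
        with pytest.warns(UserWarning, match="collinear"):
            superpose_rms(s, s, selection=None)


class TestHBonds:
    def test_no_polar_atoms_empty(self):
        s = Structure(atoms=[
            Atom("A", "1", "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            Atom("A", "2", "ALA", "CA", "C", (3.0, 0.0, 0.0)),
        ])
        assert hbond_inventory(s) == []

    def test_collinear_pair_detected(self, toy_dimer):
        bonds = hbond_inventory(toy_dimer)
        keys = {(b.donor, b.acceptor) for b in bonds}
        assert (("A", "94", "N"), ("B", "55", "O")) in keys
        bond = next(b for b in bonds if b.donor == ("A", "94", "N")
                    and b.acceptor == ("B", "55", "O"))
        assert bond.length == pytest.approx(2.9, abs=1e-9)
        assert bond.interchain

    def test_beyond_cutoff_no_bond(self, toy_dimer):
        stretched = Structure(atoms=[
            Atom(a.chain, a.residue_id, a.residue_name, a.name, a.element,
                 (a.xyz[0], a.xyz[1], a.xyz[2] + (0.7 if a.chain == "B" else 0.0)))
            for a in toy_dimer.atoms
        ])  # donor-acceptor now 3.6 A
        keys = {(b.donor, b.acceptor) for b in hbond_inventory(stretched)}
        assert (("A", "94", "N"), ("B", "55", "O")) not in keys

    def test_bent_hydrogen_rejected(self):
        # D-H...A angle of ~90 degrees fails the 120-degree criterion
        s = Structure(atoms=[
            Atom("A", "1", "GLY", "N", "N", (0.0, 0.0, 0.0)),
            Atom("A", "1", "GLY", "H", "H", (1.0, 0.0, 0.0)),
            Atom("B", "2", "GLY", "O", "O", (1.0, 2.9, 0.0)),
            Atom("B", "2", "GLY", "C", "C", (1.0, 3.9, 1.0)),
        ])
        bonds = [b for b in hbond_inventory(s) if b.donor == ("A", "1", "N")]
        assert bonds == []


class TestDiffHbonds:
    def test_identical_structures_empty_diff(self, toy_dimer):
        diff = diff_hbonds(toy_dimer, toy_dimer)
        assert diff == {"lost": [], "gained": [], "changed": []}

    def test_lost_bond_detected(self, toy_dimer):
        mutant = Structure(atoms=[
            a for a in toy_dimer.atoms
            if not (a.chain == "A" and a.residue_id == "94" and a.name == "H")
        ] + [
            Atom("A", "94", "HIS", "H", "H", (0.9, 0.0, -0.4))  # points away
        ])
        diff = diff_hbonds(toy_dimer, mutant)
        lost_keys = {(b.donor, b.acceptor) for b in diff["lost"]}
        assert (("A", "94", "N"), ("B", "55", "O")) in lost_keys

    def test_length_change_detected(self, toy_dimer):
        moved = Structure(atoms=[
            Atom(a.chain, a.residue_id, a.residue_name, a.name, a.element,
                 (a.xyz[0], a.xyz[1], a.xyz[2] + (0.4 if a.chain == "B" else 0.0)))
            for a in toy_dimer.atoms
        ])  # 2.9 -> 3.3 A, still a bond
        diff = diff_hbonds(toy_dimer, moved)
        changed = {(b.donor, b.acceptor): d for b, d in diff["changed"]}
        key = (("A", "94", "N"), ("B", "55", "O"))
        assert key in changed
        assert changed[key] == pytest.approx(0.4, abs=0.01)


class TestInterface:
    def test_distant_chains_empty(self):
        a = simple_structure([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)], chain="A")
        b = simple_structure([(100, 0, 0), (101, 0, 0), (102, 0, 0), (103, 0, 0)], chain="B")
        s = Structure(atoms=a.atoms + b.atoms)
        out = interface_residues(s, "A", "B")
        assert out == {"A": set(), "B": set()}

    def test_contacting_residues_found(self, toy_dimer):
        out = interface_residues(toy_dimer, "A", "B")
        assert "94" in out["A"]
        assert "55" in out["B"]
        assert "56" not in out["B"]  # the decoy residue 30 A away

    def test_newly_interfacial_residue(self, toy_dimer):
        """A residue moved from >5 A to 4.5 A of the partner chain joins
        the interface, mirroring a side-chain repositioning mutation."""
        before = interface_residues(toy_dimer, "A", "B")
        assert "56" not in before["B"]
        moved = Structure(atoms=[
            Atom(a.chain, a.residue_id, a.residue_name, a.name, a.element,
                 ((3.0, 0.2, 1.0) if (a.chain, a.residue_id, a.name) == ("B", "56", "N")
                  else a.xyz))
            for a in toy_dimer.atoms
        ])  # N of B/56 now ~4.4 A from A/95 CA
        after = interface_residues(moved, "A", "B")
        assert "56" in after["B"]

    def test_monotone_in_cutoff(self, toy_dimer):
        small = interface_residues(toy_dimer, "A", "B", cutoff=3.5)
        large = interface_residues(toy_dimer, "A", "B", cutoff=6.0)
        assert small["A"] <= large["A"] and small["B"] <= large["B"]

    def test_missing_chain_rejected(self, toy_dimer):
        with pytest.raises(ValueError, match="chain"):
            interface_residues(toy_dimer, "A", "Z")


class TestPDBIO:
    def test_write_read_round_trip(self, toy_dimer, tmp_path):
        path = tmp_path / "toy.pdb"
        write_pdb(toy_dimer, path)
        back = read_pdb(path)
        assert len(back.atoms) == len(toy_dimer.atoms)
        assert back.chains == ["A", "B"]
        a0 = toy_dimer.atoms[0]
        b0 = back.get(a0.chain, a0.residue_id, a0.name)
        assert np.allclose(b0.xyz, a0.xyz, atol=1e-3)

    def test_duplicate_atom_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Structure(atoms=[
                Atom("A", "1", "GLY", "N", "N", (0.0, 0.0, 0.0)),
                Atom("A", "1", "GLY", "N", "N", (1.0, 0.0, 0.0)),
            ])
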