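import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import specshell as sp
from specshell.structure_shell import (
    Atom,
    CorrespondenceError,
    Residue,
    StructureError,
    kabsch_transform,
)

from conftest import horn_quaternion_fit, random_rotation

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.508  1.00  0.00           C
ATOM      3  CA  GLY A   2      13.200   9.900  -4.100  1.00  0.00           C
HETATM    4  C1  AKG A  10      10.000  10.000 -10.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.40  0.00           C
TER
END
"""


def _ca_structure(coords, start=1, chain="A"):
    residues = tuple(
        Residue(chain, start + i, "", "ALA",
                (Atom("CA", "C", tuple(map(float, xyz)), "polymer"),), "polymer")
        for i, xyz in enumerate(coords)
    )
    return sp.Structure(residues=residues)


def _identity_corr(n, offset=0):
    return sp.ResidueCorrespondence(pairs=tuple((i + offset, i + offset) for i in range(1, n + 1)))


class TestReadStructure:
    def test_minimal_synthetic_pdb(self, tmp_path):
        p = tmp_path / "min.pdb"
        p.write_text(MINIMAL_PDB)
        struct = sp.read_structure(p)
        assert len(struct.polymer_residues()) == 2
        assert len(struct.hetero_residues()) == 1
        assert struct.hetero_residues()[0].name == "AKG"

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        struct = sp.read_structure(p)
        (res,) = struct.polymer_residues()
        assert len(res.atoms) == 1
        assert res.atoms[0].coord == pytest.approx((1.0, 2.0, 3.0))

    def test_write_read_round_trip_three_decimals(self, tmp_path, rng):
        coords = rng.uniform(-50, 50, size=(10, 3)).round(3)
        struct = _ca_structure(coords)
        p = tmp_path / "rt.pdb"
        sp.write_structure(struct, p)
        back = sp.read_structure(p)
        got = np.array([r.atoms[0].coord for r in back.polymer_residues()])
        assert np.allclose(got, coords, atol=5e-4)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(StructureError):
            sp.read_structure(p)


class TestKabsch:
    def test_identity_on_equal_structures(self, rng):
        coords = rng.uniform(-10, 10, size=(6, 3))
        s = _ca_structure(coords)
        sup = sp.kabsch_superpose(s, s, _identity_corr(6))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(sup.translation, 0.0, atol=1e-10)
        assert sup.n_atoms == 6

    def test_pure_translation_recovered(self, rng):
        fixed = rng.uniform(-10, 10, size=(5, 3))
        mobile = fixed + np.array([1.0, 2.0, 3.0])
        sup = sp.kabsch_superpose(
            _ca_structure(mobile), _ca_structure(fixed), _identity_corr(5)
        )
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, [-1.0, -2.0, -3.0], atol=1e-9)

    def test_90_degree_rotation_recovered(self):
        fixed = np.array(
            [[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [1.0, 1.0, 0.5]]
        )
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mobile = fixed @ Rz.T  # rotate fixed by +90 deg about z
        R, t, rmsd = kabsch_transform(mobile, fixed)
        assert rmsd < 1e-8
        assert np.allclose(R, Rz.T, atol=1e-8)  # inverse rotation recovered

    def test_rmsd_self_consistent_with_applied_transform(self, rng):
        for _ in range(20):
            P = rng.uniform(-10, 10, size=(8, 3))
            Q = rng.uniform(-10, 10, size=(8, 3))
            R, t, rmsd = kabsch_transform(P, Q)
            brute = np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1)))
            assert rmsd == pytest.approx(brute, abs=1e-12)

    def test_rmsd_invariant_under_common_rigid_motion(self, rng):
        P = rng.uniform(-10, 10, size=(7, 3))
        Q = rng.uniform(-10, 10, size=(7, 3))
        _, _, base = kabsch_transform(P, Q)
        for _ in range(10):
            R = random_rotation(rng)
            t = rng.uniform(-20, 20, size=3)
            _, _, moved = kabsch_transform(P @ R.T + t, Q @ R.T + t)
            assert moved == pytest.approx(base, abs=1e-9)

    def test_proper_rotation_for_mirror_image_input(self, rng):
        P = rng.uniform(-10, 10, size=(6, 3))
        Q = P.copy()
        Q[:, 0] = -Q[:, 0]  # reflected target
        R, _, _ = kabsch_transform(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_quaternion_oracle_agreement(self, rng):
        """SVD route equals Horn's quaternion eigen-route on random inputs."""
        for _ in range(50):
            n = int(rng.integers(4, 12))
            P = rng.uniform(-10, 10, size=(n, 3))
            Q = rng.uniform(-10, 10, size=(n, 3))
            _, _, rmsd = kabsch_transform(P, Q)
            _, _, oracle = horn_quaternion_fit(P, Q)
            assert abs(rmsd - oracle) < 1e-9

    def test_collinear_points_rejected(self):
        P = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(CorrespondenceError):
            kabsch_transform(P, P)

    def test_too_few_pairs_rejected(self, rng):
        s = _ca_structure(rng.uniform(-5, 5, size=(4, 3)))
        corr = sp.ResidueCorrespondence(pairs=((1, 1), (2, 2)))
        with pytest.raises(CorrespondenceError):
            sp.kabsch_superpose(s, s, corr)

    def test_pairs_missing_atom_dropped_and_counted(self, rng):
        coords = rng.uniform(-10, 10, size=(5, 3))
        s = _ca_structure(coords)
        corr = sp.ResidueCorrespondence(pairs=tuple((i, i) for i in range(1, 8)))
        sup = sp.kabsch_superpose(s, s, corr)  # pairs 6,7 have no residues
        assert sup.n_atoms == 5


class TestLigandShell:
    def _struct_with_residue_at(self, distance):
        residues = (
            Residue("A", 1, "", "ALA",
                    (Atom("CA", "C", (distance, 0.0, 0.0), "polymer"),), "polymer"),
            Residue("A", 2, "", "AKG",
                    (Atom("C1", "C", (0.0, 0.0, 0.0), "hetero"),), "hetero"),
        )
        return sp.Structure(residues=residues)

    def test_boundary_distance_inclusive(self):
        struct = self._struct_with_residue_at(7.9)
        shell = sp.ligand_shell(struct, "AKG", cutoff=8.0)
        assert shell.member_numbers == {1}

    def test_below_cutoff_excluded(self):
        struct = self._struct_with_residue_at(7.9)
        shell = sp.ligand_shell(struct, "AKG", cutoff=7.5)
        assert shell.member_numbers == set()

    def test_exact_cutoff_included(self):
        struct = self._struct_with_residue_at(8.0)
        shell = sp.ligand_shell(struct, "AKG", cutoff=8.0)
        assert shell.member_numbers == {1}

    def test_planted_shell_recovered(self):
        template, _, truth = sp.gen_structure_pair(
            sp.StructureSpec(
                n_residues=25,
                shell_distances={3: 3.0, 7: 4.5, 11: 6.0, 15: 7.0, 19: 7.9},
            ),
            seed=5,
        )
        shell = sp.ligand_shell(template, "AKG", cutoff=8.0)
        assert sorted(shell.member_numbers) == truth["shell_positions"]

    def test_membership_monotone_in_cutoff(self):
        template, _, _ = sp.gen_structure_pair(
            sp.StructureSpec(n_residues=30,
                             shell_distances={2: 3.0, 9: 6.0, 14: 7.9}),
            seed=6,
        )
        previous = set()
        for cutoff in (2.0, 4.0, 6.0, 8.0, 15.0, 40.0):
            members = sp.ligand_shell(template, "AKG", cutoff=cutoff).member_numbers
            assert previous <= members
            previous = members

    def test_waters_and_ions_never_members(self):
        residues = (
            Residue("A", 1, "", "HOH",
                    (Atom("O", "O", (1.0, 0.0, 0.0), "hetero"),), "hetero"),
            Residue("A", 2, "", "MG",
                    (Atom("MG", "MG", (1.5, 0.0, 0.0), "hetero"),), "hetero"),
            Residue("A", 3, "", "ALA",
                    (Atom("CA", "C", (2.0, 0.0, 0.0), "polymer"),), "polymer"),
            Residue("A", 9, "", "AKG",
                    (Atom("C1", "C", (0.0, 0.0, 0.0), "hetero"),), "hetero"),
        )
        shell = sp.ligand_shell(sp.Structure(residues=residues), "AKG", cutoff=8.0)
        assert shell.member_numbers == {3}

    def test_ambiguous_selector_rejected(self):
        residues = (
            Residue("A", 1, "", "AKG",
                    (Atom("C1", "C", (0.0, 0.0, 0.0), "hetero"),), "hetero"),
            Residue("A", 2, "", "AKG",
                    (Atom("C1", "C", (5.0, 0.0, 0.0), "hetero"),), "hetero"),
            Residue("A", 3, "", "ALA",
                    (Atom("CA", "C", (2.0, 0.0, 0.0), "polymer"),), "polymer"),
        )
        struct = sp.Structure(residues=residues)
        with pytest.raises(StructureError):
            sp.ligand_shell(struct, "AKG", cutoff=8.0)
        # narrowing by residue number makes it unique
        shell = sp.ligand_shell(struct, "AKG", ligand_number=1, cutoff=8.0)
        assert shell.member_numbers == {3}


class TestShellMapping:
    def test_single_pair_mapped(self):
        template, _, _ = sp.gen_structure_pair(
            sp.StructureSpec(n_residues=5, shell_distances={1: 4.0}), seed=0
        )
        shell = sp.ligand_shell(template, "AKG", cutoff=8.0)
        corr = sp.ResidueCorrespondence(pairs=((1, 186),))
        mapped, unmapped = sp.map_shell_to_target(shell, corr)
        assert mapped == {186}
        assert unmapped == []

    def test_unpaired_member_reported(self):
        template, _, _ = sp.gen_structure_pair(
            sp.StructureSpec(n_residues=5, shell_distances={1: 4.0}), seed=0
        )
        shell = sp.ligand_shell(template, "AKG", cutoff=8.0)
        corr = sp.ResidueCorrespondence(pairs=((4, 99),))
        mapped, unmapped = sp.map_shell_to_target(shell, corr)
        assert mapped == set()
        assert unmapped == [1]

    def test_mapping_equals_exhaustive_lookup(self, rng):
        template, _, truth = sp.gen_structure_pair(
            sp.StructureSpec(
                n_residues=30,
                shell_distances={4: 3.0, 9: 5.0, 17: 6.0, 22: 7.0, 29: 7.9},
            ),
            seed=11,
        )
        shell = sp.ligand_shell(template, "AKG", cutoff=8.0)
        pairs = tuple(
            (i, i + 150) for i in range(1, 31) if int(rng.integers(0, 2))
        )
        corr = sp.ResidueCorrespondence(pairs=pairs)
        mapped, unmapped = sp.map_shell_to_target(shell, corr)
        lookup = dict(pairs)
        expected = {lookup[n] for n in shell.member_numbers if n in lookup}
        assert mapped == expected
        assert set(unmapped) == {n for n in shell.member_numbers if n not in lookup}


class TestCorrespondenceFromAlignment:
    def test_mutually_nongap_columns_only(self):
        corr = sp.correspondence_from_pairwise_alignment("AC-EF", "A-DEF")
        assert corr.pairs == ((1, 1), (3, 3), (4, 4))

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet="AC-", min_size=1, max_size=20))
    def test_identical_alignments_pair_every_residue(self, seq):
        corr = sp.correspondence_from_pairwise_alignment(seq, seq)
        n_res = len(seq.replace("-", ""))
        assert len(corr.pairs) == n_res
        assert all(a == b for a, b in corr.pairs)
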