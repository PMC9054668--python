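import math

import numpy as np
import pytest

from oxtrsim import contacts as C
from oxtrsim.errors import PDBParseError, ResidueLookupError, StructureError
from oxtrsim.synth import synth_helix_pdb

ATOM_LINE = (
    "ATOM      7  CB  ALA A 218      11.104  22.506   3.001  1.00 15.20"
    "           C"
)


def brute_force_neighbors(atoms, chain, resnum, cutoff=5.5):
    """Independent all-pairs scan over side-chain heavy atoms."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    center, others = [], {}
    for a in atoms:
        if a.element == "H" or a.atom_name in backbone:
            continue
        if a.chain_id == chain and a.residue_number == resnum:
            center.append(a)
        else:
            others.setdefault((a.chain_id, a.residue_number), []).append(a)
    found = {}
    for key, group in others.items():
        best = math.inf
        for a in center:
            for b in group:
                d = math.dist(a.xyz, b.xyz)
                best = min(best, d)
        if best <= cutoff:
            found[key] = best
    return found


def random_fixture(rng, n_res=14, chains=("A",)):
    """Random residues scattered in a box; each has backbone + side chain."""
    names = ["ALA", "LEU", "THR", "SER", "VAL", "GLY", "ILE"]
    sidechains = {
        "ALA": ["CB"], "LEU": ["CB", "CG", "CD1", "CD2"],
        "THR": ["CB", "OG1", "CG2"], "SER": ["CB", "OG"], "GLY": [],
        "VAL": ["CB", "CG1", "CG2"], "ILE": ["CB", "CG1", "CG2", "CD1"],
    }
    atoms, serial = [], 1
    for ch in chains:
        for i in range(1, n_res + 1):
            resname = names[int(rng.integers(len(names)))]
            origin = rng.uniform(0, 18, size=3)
            for name in ["N", "CA", "C", "O"] + sidechains[resname]:
                pos = origin + rng.uniform(-1.2, 1.2, size=3)
                elem = name[0]
                atoms.append(C.AtomRecord(
                    serial=serial, atom_name=name, alt_loc="",
                    residue_name=resname, chain_id=ch, residue_number=i,
                    xyz=tuple(np.round(pos, 3)), occupancy=1.0, element=elem,
                ))
                serial += 1
    return atoms


class TestParse:
    def test_single_atom_line_fields(self):
        (a,) = C.parse_coordinates(ATOM_LINE)
        assert a.serial == 7
        assert a.atom_name == "CB"
        assert a.residue_name == "ALA"
        assert a.chain_id == "A"
        assert a.residue_number == 218
        assert a.xyz == (11.104, 22.506, 3.001)
        assert a.occupancy == 1.00
        assert a.element == "C"
        assert not a.het

    def test_altloc_highest_occupancy_wins(self):
        lines = [
            "ATOM      1  CB ATHR A  10       1.000   0.000   0.000  0.40"
            "  0.00           C",
            "ATOM      2  CB BTHR A  10       2.000   0.000   0.000  0.60"
            "  0.00           C",
        ]
        (a,) = C.parse_coordinates("\n".join(lines))
        assert a.alt_loc == "B" and a.xyz[0] == 2.0

    def test_altloc_tie_prefers_a(self):
        lines = [
            "ATOM      1  CB BTHR A  10       2.000   0.000   0.000  0.50"
            "  0.00           C",
            "ATOM      2  CB ATHR A  10       1.000   0.000   0.000  0.50"
            "  0.00           C",
        ]
        (a,) = C.parse_coordinates("\n".join(lines))
        assert a.alt_loc == "A" and a.xyz[0] == 1.0

    def test_malformed_line_reports_number(self):
        text = ATOM_LINE + "\nATOM      2  CA  ALA A  1x       bad line"
        with pytest.raises(PDBParseError) as exc:
            C.parse_coordinates(text)
        assert exc.value.line_number == 2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            C.parse_coordinates("")
        with pytest.raises(ValueError):
            C.parse_coordinates("REMARK nothing here\nEND\n")

    def test_element_inferred_when_missing(self):
        line = ATOM_LINE[:76].rstrip()
        (a,) = C.parse_coordinates(line)
        assert a.element == "C"
        (h,) = C.parse_coordinates(
            "ATOM      1 1HB  ALA A   1       0.000   0.000   0.000  1.00"
            "  0.00"
        )
        assert h.element == "H" and h.is_hydrogen

    def test_write_parse_round_trip(self):
        rng = np.random.default_rng(12)
        atoms = random_fixture(rng)
        back = C.parse_coordinates(C.write_pdb(atoms))
        assert len(back) == len(atoms)
        for a, b in zip(atoms, back):
            assert a.atom_name == b.atom_name
            assert a.residue_name == b.residue_name
            assert a.residue_number == b.residue_number
            assert np.allclose(a.xyz, b.xyz, atol=5e-4)


class TestNeighborResidues:
    def test_two_glycines_no_neighbors(self):
        text = "\n".join([
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00"
            "  0.00           N",
            "ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00"
            "  0.00           C",
            "ATOM      3  C   GLY A   1       2.000   0.000   0.000  1.00"
            "  0.00           C",
            "ATOM      4  N   GLY A   2       3.000   0.000   0.000  1.00"
            "  0.00           N",
            "ATOM      5  CA  GLY A   2       3.500   0.000   0.000  1.00"
            "  0.00           C",
            "ATOM      6  C   GLY A   2       4.000   0.000   0.000  1.00"
            "  0.00           C",
        ])
        atoms = C.parse_coordinates(text)
        rep = C.neighbor_residues(atoms, "A", 1)
        assert rep.partners == ()

    def test_missing_center_raises(self):
        atoms = C.parse_coordinates(ATOM_LINE)
        with pytest.raises(ResidueLookupError, match="999"):
            C.neighbor_residues(atoms, "A", 999)

    def test_helix_i3_i4_pattern(self):
        atoms = C.parse_coordinates(synth_helix_pdb(15, "L"))
        rep = C.neighbor_residues(atoms, "A", 8)
        assert {p.residue_number for p in rep.partners} == {4, 5, 11, 12}
        assert all(p.scope == "intra_chain" for p in rep.partners)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            atoms = random_fixture(rng)
            resnum = int(rng.integers(1, 15))
            expected = brute_force_neighbors(atoms, "A", resnum)
            rep = C.neighbor_residues(atoms, "A", resnum)
            got = {(p.chain_id, p.residue_number): p.min_distance
                   for p in rep.partners}
            assert set(got) == set(expected)
            for key in got:
                assert got[key] == pytest.approx(expected[key], abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        atoms = random_fixture(rng)
        for resnum in range(1, 15):
            rep = C.neighbor_residues(atoms, "A", resnum)
            for p in rep.partners:
                back = C.neighbor_residues(atoms, p.chain_id,
                                           p.residue_number)
                q = back.partner("A", resnum)
                assert q is not None
                assert q.min_distance == p.min_distance

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(14)
        atoms = random_fixture(rng)
        rep = C.contact_environment(atoms, "A", 5)
        shuffled = list(atoms)
        rng.shuffle(shuffled)
        rep2 = C.contact_environment(shuffled, "A", 5)
        assert rep.partners == rep2.partners


def _residue(resname, resnum, named_positions, chain="A", start_serial=1):
    atoms = []
    for i, (name, pos) in enumerate(named_positions):
        elem = "H" if name.startswith("H") else name[0]
        atoms.append(C.AtomRecord(
            serial=start_serial + i, atom_name=name, alt_loc="",
            residue_name=resname, chain_id=chain, residue_number=resnum,
            xyz=pos, occupancy=1.0, element=elem,
        ))
    return atoms


class TestClassify:
    def test_thr_og1_near_backbone_o_is_hbond(self):
        thr = _residue("THR", 1, [
            ("N", (0, 0, 0)), ("CA", (1.5, 0, 0)), ("C", (2.2, 1.3, 0)),
            ("O", (1.8, 2.4, 0)), ("CB", (2.0, -1.4, 0)),
            ("OG1", (3.4, -1.5, 0)), ("CG2", (1.4, -2.7, 0.4)),
        ])
        # partner backbone O 3.0 A from OG1; side chains also proximal
        ala = _residue("ALA", 2, [
            ("N", (8, 0, 0)), ("CA", (7.0, 0.8, 0)), ("C", (7.5, 2.0, 0)),
            ("O", (6.4, -1.5, 0)), ("CB", (5.8, 0.4, 2.0)),
        ], start_serial=10)
        atoms = thr + ala
        rep = C.contact_environment(atoms, "A", 1)
        p = rep.partner("A", 2)
        assert p is not None
        assert "hbond" in p.classes
        d = math.dist((3.4, -1.5, 0), (6.4, -1.5, 0))
        assert d == pytest.approx(3.0)

    def test_thr_cg2_near_leu_cd1_is_hydrophobic(self):
        thr = _residue("THR", 1, [
            ("N", (0, 0, 0)), ("CA", (1.5, 0, 0)), ("C", (2.2, 1.3, 0)),
            ("O", (1.8, 2.4, 0)), ("CB", (2.0, -1.4, 0)),
            ("OG1", (3.0, -2.2, 0.7)), ("CG2", (2.4, -2.0, -1.3)),
        ])
        leu = _residue("LEU", 5, [
            ("N", (8, 0, 0)), ("CA", (7.0, 0.8, 0)), ("C", (7.5, 2.0, 0)),
            ("O", (8.6, 2.4, 0)), ("CB", (6.2, -0.4, -1.0)),
            ("CG", (6.0, -1.6, -1.4)), ("CD1", (6.4, -2.0, -1.3)),
            ("CD2", (5.2, -2.4, -2.3)),
        ], start_serial=10)
        atoms = thr + leu
        rep = C.contact_environment(atoms, "A", 1)
        p = rep.partner("A", 5)
        assert p is not None
        assert "hydrophobic" in p.classes
        assert math.dist((2.4, -2.0, -1.3), (6.4, -2.0, -1.3)) == \
            pytest.approx(4.0)

    def test_ala_to_thr_increases_classified_partners(self):
        pattern = "LLLLLLLALLLLLLL"  # ALA at residue 8
        atoms = C.parse_coordinates(synth_helix_pdb(15, pattern))
        before = C.contact_environment(atoms, "A", 8)
        mutated = C.mutate_ala_thr(atoms, "A", 8)
        after = C.contact_environment(mutated, "A", 8)

        def n_classified(rep):
            return sum(1 for p in rep.partners
                       if p.classes != ("proximal_only",))

        assert n_classified(after) > n_classified(before)
        assert len(after.partners) > len(before.partners)


class TestMutate:
    @pytest.fixture()
    def ala_helix(self):
        return C.parse_coordinates(synth_helix_pdb(15, "LLLLLLLALLLLLLL"))

    def test_round_trip_exact(self, ala_helix):
        mutated = C.mutate_ala_thr(ala_helix, "A", 8)
        reverted = C.mutate_ala_thr(mutated, "A", 8)
        orig = [(a.atom_name, a.residue_name, a.xyz) for a in ala_helix]
        back = [(a.atom_name, a.residue_name, a.xyz) for a in reverted]
        assert orig == back

    def test_built_geometry(self, ala_helix):
        mutated = C.mutate_ala_thr(ala_helix, "A", 8)
        res = C.residues(mutated)[("A", 8)]
        coords = {a.atom_name: np.array(a.xyz) for a in res}
        assert res[0].residue_name == "THR"
        assert np.linalg.norm(coords["OG1"] - coords["CB"]) == \
            pytest.approx(1.43, abs=1e-3)
        assert np.linalg.norm(coords["CG2"] - coords["CB"]) == \
            pytest.approx(1.52, abs=1e-3)
        # tetrahedral angle at CB
        v1 = coords["CA"] - coords["CB"]
        v2 = coords["OG1"] - coords["CB"]
        ang = math.degrees(math.acos(
            float(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))
        ))
        assert ang == pytest.approx(109.47, abs=0.1)
        # chi1 dihedral N-CA-CB-OG1 = -60
        n, ca, cb, og1 = (coords[k] for k in ("N", "CA", "CB", "OG1"))
        b1, b2, b3 = ca - n, cb - ca, og1 - cb
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        chi = math.degrees(math.atan2(
            float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))),
            float(n1 @ n2),
        ))
        assert chi == pytest.approx(-60.0, abs=0.1)

    def test_new_contact_gained(self, ala_helix):
        before = C.neighbor_residues(ala_helix, "A", 8)
        after = C.neighbor_residues(C.mutate_ala_thr(ala_helix, "A", 8),
                                    "A", 8)
        assert len(after.partners) >= len(before.partners) + 1

    def test_wrong_residue_type_raises(self, ala_helix):
        with pytest.raises(ValueError):
            C.mutate_ala_thr(ala_helix, "A", 7)  # LEU

    def test_missing_backbone_raises(self):
        atoms = _residue("ALA", 1, [("N", (0, 0, 0)), ("CA", (1.5, 0, 0)),
                                    ("CB", (2.0, -1.4, 0))])
        with pytest.raises(StructureError):
            C.mutate_ala_thr(atoms, "A", 1)

    def test_missing_residue_raises(self, ala_helix):
        with pytest.raises(ResidueLookupError):
            C.mutate_ala_thr(ala_helix, "B", 8)


class TestInterface:
    def test_single_chain_raises(self):
        atoms = C.parse_coordinates(synth_helix_pdb(15, "L"))
        with pytest.raises(ValueError, match="neighbor_residues"):
            C.interface_contacts(atoms, 8)

    def test_separated_dimer_no_contacts(self):
        atoms = C.parse_coordinates(
            synth_helix_pdb(15, "A", chains=2, axis_sep=12.0, facing=False)
        )
        reps = C.interface_contacts(atoms, 8)
        assert all(r.partners == () for r in reps.values())

    def test_facing_dimer_has_contacts(self):
        atoms = C.parse_coordinates(
            synth_helix_pdb(15, "L", chains=2, axis_sep=8.0, facing=True)
        )
        reps = C.interface_contacts(atoms, 8)
        assert len(reps["A"].partners) >= 1
        assert all(p.scope == "inter_chain" for p in reps["A"].partners)
        assert all(p.chain_id == "B" for p in reps["A"].partners)

    def test_thr_centers_at_least_as_many_classified_as_ala(self):
        pat = "LLLLLLLALLLLLLL"
        ala = C.parse_coordinates(
            synth_helix_pdb(15, pat, chains=2, axis_sep=8.0, facing=True)
        )
        thr = C.mutate_ala_thr(C.mutate_ala_thr(ala, "A", 8), "B", 8)

        def n_classified(reps):
            return sum(
                1 for r in reps.values() for p in r.partners
                if p.classes != ("proximal_only",)
            )

        assert n_classified(C.interface_contacts(thr, 8)) >= \
            n_classified(C.interface_contacts(ala, 8))
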