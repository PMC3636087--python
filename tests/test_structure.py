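"""Structure parsing, dihedrals, neighbor counts, interface classification."""

import math

import numpy as np
import pytest

import polyspec as ps
from polyspec.structure import Residue, StructureModel, dihedral


def two_residue_model(d):
    """Two CB-bearing residues separated by ``d`` Angstrom."""
    def res(num, x):
        return Residue("A", num, "", "ALA", {
            "N": np.array([x, 1.4, 0.0]),
            "CA": np.array([x, 0.0, 0.0]),
            "C": np.array([x, -1.4, 0.0]),
            "CB": np.array([x, 0.0, 1.5]),
        })
    return StructureModel(chains={"A": [res(1, 0.0), res(2, d)]})


def random_rigid_motion(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=20.0, size=3)


class TestReadWrite:
    def test_round_trip_preserves_coordinates(self, tmp_path, default_bundle):
        cid, model = next(iter(default_bundle.structures.items()))
        p = tmp_path / "m.pdb"
        ps.write_structure(model, p)
        back = ps.read_structure(p, required_chains=["H", "G"])
        assert set(back.chains) == set(model.chains)
        for chain in model.chains:
            orig, rd = model.chains[chain], back.chains[chain]
            assert len(orig) == len(rd)
            for a, b in zip(orig, rd):
                assert a.name == b.name
                for name, xyz in a.atoms.items():
                    assert np.allclose(xyz, b.atoms[name], atol=1.5e-3)

    def test_missing_chain_is_configuration_error(self, tmp_path, default_bundle):
        model = next(iter(default_bundle.structures.values()))
        p = tmp_path / "m.pdb"
        ps.write_structure(model, p)
        with pytest.raises(ps.structure.StructureError):
            ps.read_structure(p, required_chains=["Z"])

    def test_residue_without_ca_excluded_from_dihedrals(self, tmp_path):
        bb = ps.build_chain(np.full(4, -120.0), np.full(4, 130.0))
        residues = []
        for i in range(4):
            atoms = {"N": bb[i, 0], "CA": bb[i, 1], "C": bb[i, 2]}
            if i == 1:
                del atoms["CA"]
            residues.append(Residue("A", i + 1, "", "ALA", atoms))
        model = StructureModel(chains={"A": residues})
        recs = ps.compute_dihedrals(model, "A")
        assert recs[1].phi is None and recs[1].psi is None
        # neighbors of the broken residue lose the shared dihedral only
        assert recs[0].psi is None and recs[2].phi is None


class TestDihedrals:
    def test_built_strand_reproduces_angles(self):
        bb = ps.build_chain(np.full(10, -120.0), np.full(10, 130.0))
        model = StructureModel(chains={"A": [
            Residue("A", i + 1, "", "ALA",
                    {"N": bb[i, 0], "CA": bb[i, 1], "C": bb[i, 2]})
            for i in range(10)
        ]})
        recs = ps.compute_dihedrals(model, "A")
        assert recs[0].phi is None and recs[-1].psi is None
        for r in recs[1:-1]:
            assert r.phi == pytest.approx(-120.0, abs=0.5)
            assert r.psi == pytest.approx(130.0, abs=0.5)
            assert r.ss_label == "beta"

    def test_helix_labeled_other(self):
        bb = ps.build_chain(np.full(8, -57.0), np.full(8, -47.0))
        model = StructureModel(chains={"A": [
            Residue("A", i + 1, "", "ALA",
                    {"N": bb[i, 0], "CA": bb[i, 1], "C": bb[i, 2]})
            for i in range(8)
        ]})
        recs = ps.compute_dihedrals(model, "A")
        assert all(r.ss_label == "other" for r in recs[1:-1])

    def test_rigid_motion_invariance(self, default_bundle):
        model = next(iter(default_bundle.structures.values()))
        rng = np.random.default_rng(0)
        rot, trans = random_rigid_motion(rng)
        moved = model.transformed(rot, trans)
        for a, b in zip(ps.compute_dihedrals(model, "H"),
                        ps.compute_dihedrals(moved, "H")):
            if a.phi is not None:
                assert abs(a.phi - b.phi) < 1e-6
            if a.psi is not None:
                assert abs(a.psi - b.psi) < 1e-6

    def test_chain_break_undefines_dihedrals(self):
        bb = ps.build_chain(np.full(4, -120.0), np.full(4, 130.0))
        residues = [Residue("A", i + 1, "", "ALA",
                            {"N": bb[i, 0], "CA": bb[i, 1], "C": bb[i, 2]})
                    for i in range(4)]
        for atom in residues[2].atoms:
            residues[2].atoms[atom] = residues[2].atoms[atom] + np.array([50.0, 0, 0])
        for atom in residues[3].atoms:
            residues[3].atoms[atom] = residues[3].atoms[atom] + np.array([50.0, 0, 0])
        recs = ps.compute_dihedrals(StructureModel(chains={"A": residues}), "A")
        assert recs[1].psi is None and recs[2].phi is None
        assert recs[2].psi is not None  # the far fragment is intact


class TestNeighborCount:
    def test_isolated_residue_scores_zero(self):
        model = two_residue_model(50.0)
        model.chains["A"] = model.chains["A"][:1]
        (b,) = ps.neighbor_count(model)
        assert b.neighbor_count == 0.0

    @pytest.mark.parametrize("d,expected", [(3.0, 1.0), (12.0, 0.0), (7.2, 0.5)])
    def test_falloff_values(self, d, expected):
        scores = ps.neighbor_count(two_residue_model(d))
        for b in scores:
            assert b.neighbor_count == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_rigid_invariance(self):
        model = two_residue_model(6.5)
        s = ps.neighbor_count(model)
        assert s[0].neighbor_count == pytest.approx(s[1].neighbor_count)
        rot, trans = random_rigid_motion(np.random.default_rng(1))
        s2 = ps.neighbor_count(model.transformed(rot, trans))
        assert s2[0].neighbor_count == pytest.approx(s[0].neighbor_count, abs=1e-9)

    def test_glycine_uses_calpha_center(self):
        model = two_residue_model(3.0)
        gly = model.chains["A"][1]
        gly.name = "GLY"
        del gly.atoms["CB"]
        scores = ps.neighbor_count(model)
        d = np.linalg.norm(model.chains["A"][0].atoms["CB"] - gly.atoms["CA"])
        expected = ps.neighbor_weight(float(d))
        assert scores[0].neighbor_count == pytest.approx(expected)


class TestInterface:
    def test_planted_contacts_detected(self, default_bundle):
        for cid, model in default_bundle.structures.items():
            truth = set(default_bundle.truth["interface_columns"][cid])
            det = {a.key[1] for a in ps.classify_interface(model, ["H"], ["G"])
                   if a.is_interface}
            assert truth <= det
            # spillover can only implicate the immediate periphery of a site
            assert all(any(abs(e - t) <= 2 for t in truth) for e in det - truth)

    def test_no_antigen_means_zero_deltas(self, default_bundle):
        model = next(iter(default_bundle.structures.values()))
        bare = model.without_chains(["G"])
        annos = ps.classify_interface(bare, ["H"], ["G"])
        assert all(a.delta_neighbor == 0.0 for a in annos)
        assert not any(a.is_interface for a in annos)

    def test_threshold_is_strict_at_exactly_one(self):
        annos = ps.annotate_interface({("H", 1, ""): 1.0, ("H", 2, ""): 1.0000001})
        flags = {k[1]: a.is_interface for k, a in zip([a.key for a in annos], annos)}
        assert flags[1] is False and flags[2] is True

    def test_label_independence_under_chain_rename(self, default_bundle):
        model = next(iter(default_bundle.structures.values()))
        renamed = StructureModel(chains={
            "H": model.chains["H"],
            "Q": [Residue("Q", r.number, r.icode, r.name, dict(r.atoms))
                  for r in model.chains["G"]],
        })
        a1 = {a.key[1]: a.is_interface
              for a in ps.classify_interface(model, ["H"], ["G"])}
        a2 = {a.key[1]: a.is_interface
              for a in ps.classify_interface(renamed, ["H"], ["Q"])}
        assert a1 == a2

    def test_overlapping_chain_sets_rejected(self, default_bundle):
        model = next(iter(default_bundle.structures.values()))
        with pytest.raises(ps.structure.StructureError):
            ps.classify_interface(model, ["H"], ["H"])


def test_dihedral_function_sign_convention():
    # trans (180) and cis (0) configurations of four points
    p = [np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 0.0]),
         np.array([1.0, 0.0, 0.0]), np.array([1.0, -1.0, 0.0])]
    assert abs(dihedral(*p)) == pytest.approx(180.0)
    p[3] = np.array([1.0, 1.0, 0.0])
    assert dihedral(*p) == pytest.approx(0.0)
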