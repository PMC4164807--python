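"""PDB handling, binding-site geometry, superposition, and annotation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import etrace as et
from etrace.structure import StructureError, superpose_chains
from etrace.trace import Status

from conftest import brute_force_site


def rigid(coords, seed, translation=(1.0, -2.0, 3.0)):
    rot = Rotation.random(random_state=seed).as_matrix()
    return coords @ rot.T + np.asarray(translation)


class TestReadPdb:
    def test_round_trip_of_generated_complex(self, tmp_path, toy_complex):
        structure, _ = toy_complex
        path = tmp_path / "toy.pdb"
        et.write_pdb(structure, path)
        again = et.read_pdb(path)
        assert again.chain_ids == structure.chain_ids
        assert again.n_atoms() == structure.n_atoms()
        orig = structure.chain("A").residues
        back = again.chain("A").residues
        assert [(r.name, r.seqnum) for r in back] == [(r.name, r.seqnum) for r in orig]
        # coordinates survive at the file's 3-decimal precision
        for ro, rb in zip(orig, back):
            assert np.allclose(ro.coords, rb.coords, atol=1.5e-3)

    def test_water_only_file_warns(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(
            "HETATM    1  O   HOH A 401       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="no protein"):
            st = et.read_pdb(p)
        assert all(r.is_water for c in st.chains for r in c.residues)

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       1.0x0   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(StructureError, match="line 2"):
            et.read_pdb(p)


class TestSelectChain:
    def test_keeps_only_requested_chain(self, toy_complex):
        structure, _ = toy_complex
        sel = et.select_chain(structure, "A")
        assert sel.chain_ids == ["A"]
        assert len(sel.chains[0].residues) == 20

    def test_missing_chain_lists_available(self, toy_complex):
        structure, _ = toy_complex
        with pytest.raises(StructureError, match="'A', 'L'"):
            et.select_chain(structure, "Z")


class TestLigandSelection:
    def test_default_rule_is_nonwater_hetatm(self, toy_complex):
        structure, _ = toy_complex
        lig = et.ligand_selection(structure)
        assert {r.name for r, _ in lig.atoms} == {"LIG"}

    def test_chain_override(self, toy_complex):
        structure, _ = toy_complex
        lig = et.ligand_selection(structure, chain="L")
        assert len(lig.atoms) == 1

    def test_empty_selection_rejected(self, toy_complex):
        structure, _ = toy_complex
        with pytest.raises(StructureError, match="empty ligand"):
            et.ligand_selection(structure, resnames=["ZZZ"])


class TestBindingSite:
    def test_planted_single_contact(self, toy_complex):
        structure, truth = toy_complex
        site = et.binding_site(
            et.select_chain(structure, "A"), et.ligand_selection(structure)
        )
        assert site.resnums == truth.resnums

    def test_exact_cutoff_is_inclusive(self):
        spec = et.ToyComplexSpec(
            n_residues=10, geometry="straight",
            ligand_placements=((4, 5.0, (0.0, 0.0, 1.0)),), seed=1,
        )
        structure, truth = et.simulate_complex(spec)
        site = et.binding_site(
            et.select_chain(structure, "A"), et.ligand_selection(structure), cutoff=5.0
        )
        assert 4 in site.resnums and 4 in truth.resnums

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        placements = tuple(
            (int(t), float(d), tuple(rng.normal(size=3)))
            for t, d in zip(rng.integers(1, 51, size=3), rng.uniform(2, 8, size=3))
        )
        spec = et.ToyComplexSpec(n_residues=50, ligand_placements=placements, seed=seed)
        structure, _ = et.simulate_complex(spec)
        lig = et.ligand_selection(structure)
        site = et.binding_site(et.select_chain(structure, "A"), lig, cutoff=5.0)
        assert site.resnums == brute_force_site(structure, lig.coords, 5.0)

    def test_monotone_in_cutoff(self, toy_complex):
        structure, _ = toy_complex
        chain = et.select_chain(structure, "A")
        lig = et.ligand_selection(structure)
        previous: set[int] = set()
        for cutoff in (2.0, 4.0, 5.0, 7.0, 10.0):
            current = set(et.binding_site(chain, lig, cutoff=cutoff).resnums)
            assert previous <= current
            previous = current

    def test_chain_selection_commutes(self, toy_complex):
        structure, _ = toy_complex
        lig = et.ligand_selection(structure)
        direct = et.binding_site(structure, lig)
        selected = et.binding_site(et.select_chain(structure, "A"), lig)
        assert direct.resnums == selected.resnums


class TestMatchCalphas:
    def test_self_match_pairs_everything(self, toy_complex):
        structure, _ = toy_complex
        chain = structure.chain("A")
        ca, cb, pairs = et.match_calphas(chain, chain)
        assert len(pairs) == 20
        assert np.allclose(ca, cb)

    def test_interior_deletion_reduces_pairs(self, toy_complex):
        structure, _ = toy_complex
        chain = structure.chain("A")
        from etrace.structure import Chain

        shortened = Chain(id="A", residues=chain.residues[:8] + chain.residues[13:])
        _, _, pairs = et.match_calphas(chain, shortened)
        assert len(pairs) == 15

    def test_too_few_residues_rejected(self, toy_complex):
        structure, _ = toy_complex
        from etrace.structure import Chain

        tiny = Chain(id="A", residues=structure.chain("A").residues[:2])
        with pytest.raises(StructureError, match="at least 3"):
            et.match_calphas(tiny, tiny)


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        p = np.random.default_rng(0).normal(size=(12, 3))
        result = et.kabsch_superpose(p, p)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_recovered_exactly(self, seed):
        p = np.random.default_rng(seed).normal(size=(10, 3))
        q = rigid(p, seed)
        result = et.kabsch_superpose(p, q)
        assert result.rmsd <= 1e-9
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)
        assert np.allclose(result.transform(q), p, atol=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        p, q = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
        assert et.kabsch_superpose(p, q).rmsd == pytest.approx(
            et.kabsch_superpose(q, p).rmsd, abs=1e-9
        )

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        p, q = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        ours = et.kabsch_superpose(p, q)
        rot, rssd = Rotation.align_vectors(p - p.mean(0), q - q.mean(0))
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(p)), abs=1e-9)
        assert np.allclose(ours.rotation, rot.as_matrix(), atol=1e-6)

    def test_matches_quaternion_grid_oracle(self):
        """Optimal RMSD is no worse than any rotation from a dense random
        quaternion sample, and within the sample's resolution of its best."""
        rng = np.random.default_rng(12)
        p, q = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        ours = et.kabsch_superpose(p, q).rmsd
        p0, q0 = p - p.mean(0), q - q.mean(0)
        sampled = Rotation.random(20000, random_state=99)
        best = min(
            float(np.sqrt(np.mean(np.sum((q0 @ m.T - p0) ** 2, axis=1))))
            for m in sampled.as_matrix()
        )
        assert ours <= best + 1e-12
        assert best - ours < 0.05

    def test_degenerate_collinear_points_still_valid(self):
        p = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        q = rigid(p, 3)
        result = et.kabsch_superpose(p, q)
        assert result.rmsd <= 1e-9
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(StructureError):
            et.kabsch_superpose(np.empty((0, 3)), np.empty((0, 3)))

    def test_superpose_chains_on_rigid_copy(self, tmp_path, toy_complex):
        structure, _ = toy_complex
        chain = structure.chain("A")
        from etrace.structure import Atom, Chain, Residue, Structure

        moved_res = []
        for res in chain.residues:
            coords = rigid(res.coords, 7)
            atoms = [
                Atom(a.name, a.element, *xyz)
                for a, xyz in zip(res.atoms, coords)
            ]
            moved_res.append(Residue(res.name, res.seqnum, atoms=atoms))
        moved = Structure(id="moved", chains=[Chain(id="A", residues=moved_res)])
        result = superpose_chains(structure.chain("A"), moved.chains[0])
        assert result.n_pairs == 20
        assert result.rmsd <= 1e-6


class TestAnnotation:
    def make_map(self, pairs):
        return et.ResidueStatusMap(
            "q", [(n, "A", s) for n, s in sorted(pairs.items())]
        )

    def test_statuses_joined_onto_site(self):
        site = et.BindingSite(
            entries=[(32, "ASP", 3.1), (70, "PRO", 4.2)], cutoff=5.0
        )
        smap = self.make_map({32: Status.CONSERVED, 70: Status.GROUP_SPECIFIC})
        df = et.annotate_binding_site(site, smap)
        assert df.set_index("resnum")["status"].to_dict() == {
            32: "conserved", 70: "group-specific"
        }

    def test_missing_statuses_reported_unmapped(self):
        site = et.BindingSite(entries=[(5, "GLY", 2.0)], cutoff=5.0)
        df = et.annotate_binding_site(site, self.make_map({1: Status.CONSERVED}))
        assert df["status"].tolist() == ["UNMAPPED"]

    def test_empty_site_gives_empty_table(self):
        df = et.annotate_binding_site(
            et.BindingSite(entries=[], cutoff=5.0), self.make_map({})
        )
        assert len(df) == 0

    def test_flap_intersection_inclusive_ends(self):
        site = et.BindingSite(
            entries=[(n, "ALA", 3.0) for n in (60, 67, 70, 77, 80)], cutoff=5.0
        )
        assert et.flap_intersection(site, 67, 77) == [67, 70, 77]
        assert et.flap_intersection(site, 90, 99) == []
        assert et.flap_intersection(site, 1, 9999) == site.resnums

    def test_annotated_pdb_bfactors_encode_statuses(self, tmp_path, toy_complex):
        structure, _ = toy_complex
        smap = self.make_map(
            {1: Status.CONSERVED, 2: Status.GROUP_SPECIFIC, 3: Status.NEUTRAL}
        )
        path = tmp_path / "ann.pdb"
        et.write_annotated_pdb(structure, smap, path)
        again = et.read_pdb(path)
        codes = {
            r.seqnum: {round(a.bfactor, 2) for a in r.atoms}
            for r in again.chain("A").residues
        }
        assert codes[1] == {99.99}
        assert codes[2] == {50.0}
        assert codes[3] == {0.0}
        assert codes[4] == {25.0}  # unmapped
        ligand = again.chain("L").residues[0]
        assert {round(a.bfactor, 2) for a in ligand.atoms} == {25.0}
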