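"""Binding sites, identical-sequence matching, Kabsch and ensembles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from overlaybench import chem_properties as cp
from overlaybench import ensemble_builder as eb
from overlaybench import structure_io as sio
from overlaybench import synthetic_fixtures as sf


def _residue(name, num, center):
    center = np.asarray(center, dtype=float)
    return sio.Residue(
        residue_name=name, residue_number=num, insertion_code="",
        backbone={
            "N": center + (1.46, 0, 0),
            "CA": center.copy(),
            "C": center + (-1.52, 0, 0),
            "O": center + (-1.52, 1.23, 0),
        },
    )


def _ligand_at(origin, entry="tst1", het="LIG"):
    return sio.LigandInstance(
        entry_id=entry, residue_name=het, chain_id="A", residue_number=301,
        atoms=[sio.Atom("C", *origin)],
    )


class TestExtractBindingSite:
    def _entry(self, residue_centers):
        residues = [
            _residue("GLY", i + 1, c) for i, c in enumerate(residue_centers)
        ]
        return sio.StructureEntry(
            entry_id="tst1", resolution=2.0, release_date=None,
            chains=[sio.ProteinChain("A", residues)],
            ligand_candidates=[],
        )

    def test_residue_at_the_inner_boundary_is_included(self):
        # nearest backbone atom (C at center - 1.52) ends up at 6.4
        entry = self._entry([(6.4 + 1.52, 0, 0)])
        site = eb.extract_binding_site(_ligand_at((0, 0, 0)), entry)
        assert [r.residue_number for r in site.chains[0].residues] == [1]

    def test_residue_beyond_the_radius_is_excluded(self):
        entry = self._entry([(6.6 + 1.52, 0, 0), (5.0, 0, 0)])
        site = eb.extract_binding_site(_ligand_at((0, 0, 0)), entry)
        assert [r.residue_number for r in site.chains[0].residues] == [2]

    def test_isolated_ligand_is_an_error(self):
        entry = self._entry([(30.0, 0, 0)])
        with pytest.raises(eb.DegenerateGeometry):
            eb.extract_binding_site(_ligand_at((0, 0, 0)), entry)

    def test_signature_follows_residue_order(self, ensemble_scenario):
        entry_id = "a101"
        entry = sio.parse_structure(
            ensemble_scenario.structures[entry_id], entry_id=entry_id
        )
        row = next(
            r for r in ensemble_scenario.manifest["complexes"]
            if r["entry_id"] == entry_id
        )
        site = eb.extract_binding_site(entry.ligand_candidates[0], entry)
        selected = [r.residue_number for c in site.chains for r in c.residues]
        assert selected == row["pocket_residues"]
        assert site.signature_str == "".join(
            row["sequence"][n - 1] for n in row["pocket_residues"]
        )


class TestChainBijectionMatching:
    def _two_chain_entry(self, entry_id, swap):
        # two chains around one ligand; ``swap`` exchanges the chain ids
        ligand = _ligand_at((0, 0, 0), entry=entry_id)
        chain_1 = [
            _residue(n, i + 1, (4.0, 2.0 * i - 2, 0))
            for i, n in enumerate(("GLY", "ALA", "SER"))
        ]
        chain_2 = [
            _residue(n, i + 1, (-4.0, 2.0 * i - 2, 0))
            for i, n in enumerate(("LEU", "VAL", "THR"))
        ]
        ids = ("B", "A") if swap else ("A", "B")
        return sio.StructureEntry(
            entry_id=entry_id, resolution=2.0, release_date=None,
            chains=[
                sio.ProteinChain(ids[0], chain_1),
                sio.ProteinChain(ids[1], chain_2),
            ],
            ligand_candidates=[ligand],
        )

    def test_swapped_chains_still_match_via_bijection(self):
        entry_a = self._two_chain_entry("tsta", swap=False)
        entry_b = self._two_chain_entry("tstb", swap=True)
        index = eb.SiteIndex()
        site_a = eb.extract_binding_site(
            entry_a.ligand_candidates[0], entry_a)
        site_b = eb.extract_binding_site(
            entry_b.ligand_candidates[0], entry_b)
        index.add(site_a)
        index.add(site_b)
        hits = index.find_identical_sites(site_a)
        assert {h.ligand.entry_id for h in hits} == {"tsta", "tstb"}
        # brute force: some chain bijection pairs equal sequences
        sigs_a = sorted(c.sequence for c in site_a.chains)
        sigs_b = sorted(c.sequence for c in site_b.chains)
        assert sigs_a == sigs_b

    def test_mutated_pocket_does_not_match(self):
        entry_a = self._two_chain_entry("tsta", swap=False)
        entry_c = self._two_chain_entry("tstc", swap=False)
        entry_c.chains[0].residues[1] = _residue("TRP", 2, (4.0, 0, 0))
        index = eb.SiteIndex()
        site_c = eb.extract_binding_site(
            entry_c.ligand_candidates[0], entry_c)
        index.add(site_c)
        site_a = eb.extract_binding_site(
            entry_a.ligand_candidates[0], entry_a)
        assert index.find_identical_sites(site_a) == []


class TestKabsch:
    def test_identical_point_sets(self):
        pts = np.random.default_rng(3).normal(size=(12, 3))
        rot, trans, rmsd = eb.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0.0, atol=1e-10)

    def test_recovers_a_known_rigid_transform(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(20, 3)) * 5
        true_rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        mov = ref @ true_rot.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = eb.kabsch_superpose(ref, mov)
        assert rmsd < 1e-6
        assert np.allclose(mov @ rot.T + trans, ref, atol=1e-6)

    def test_matches_an_independent_svd_oracle_on_noisy_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ref = rng.normal(size=(15, 3)) * 4
            mov = ref + rng.normal(size=ref.shape) * 0.3
            _, _, rmsd = eb.kabsch_superpose(ref, mov)
            oracle_rot, oracle_rssd = Rotation.align_vectors(
                ref - ref.mean(axis=0), mov - mov.mean(axis=0)
            )
            oracle_rmsd = oracle_rssd / np.sqrt(len(ref))
            assert rmsd == pytest.approx(oracle_rmsd, abs=1e-9)

    def test_too_few_or_collinear_points_are_errors(self):
        with pytest.raises(eb.DegenerateGeometry):
            eb.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack(
            [np.arange(5.0), np.zeros(5), np.zeros(5)]
        )
        with pytest.raises(eb.DegenerateGeometry):
            eb.kabsch_superpose(line, line)


class TestDeduplicateMembers:
    def _member(self, entry, smiles, rmsd):
        lig = _ligand_at((0, 0, 0), entry=entry)
        lig.smiles = smiles
        return eb.EnsembleMember(lig, np.zeros((1, 3)), rmsd)

    def _ensemble(self, members):
        return eb.LigandEnsemble(
            name="LIG_A_301-tst1", search_ligand=members[0].ligand,
            members=members,
        )

    def test_lowest_rmsd_wins_per_smiles(self):
        ens = self._ensemble([
            self._member("tst1", "c1ccccc1", 0.0),
            self._member("tst2", "CCO", 0.5),
            self._member("tst3", "CCO", 0.2),
        ])
        eb.deduplicate_members(ens)
        assert [m.ligand.entry_id for m in ens.members] == ["tst1", "tst3"]
        assert not ens.removed

    def test_rmsd_tie_keeps_smallest_ligand_key(self):
        ens = self._ensemble([
            self._member("tst1", "c1ccccc1", 0.0),
            self._member("tstz", "CCO", 0.4),
            self._member("tsta", "CCO", 0.4),
        ])
        eb.deduplicate_members(ens)
        assert [m.ligand.entry_id for m in ens.members] == ["tst1", "tsta"]

    def test_singleton_after_dedup_is_removed(self):
        ens = self._ensemble([
            self._member("tst1", "c1ccccc1", 0.0),
            self._member("tst2", "c1ccccc1", 0.3),
        ])
        eb.deduplicate_members(ens)
        assert ens.removed
        assert len(ens.members) == 1

    def test_all_unique_ensemble_is_unchanged(self):
        ens = self._ensemble([
            self._member("tst1", "c1ccccc1", 0.0),
            self._member("tst2", "CCO", 0.3),
        ])
        eb.deduplicate_members(ens)
        assert len(ens.members) == 2 and not ens.removed


@pytest.fixture(scope="module")
def built():
    entries, ref_poses, transforms = sf.make_rigid_copy_entries(seed=11)
    entry_map = {e.entry_id: e for e in entries}
    ligands = []
    for entry in entries:
        ligands += cp.perceive_all(entry.ligand_candidates)
    ensembles = eb.build_all_ensembles(ligands, entry_map)
    return ensembles, ref_poses, transforms


class TestRigidCopyRecovery:
    """Exact rigid copies must superimpose to numerical precision."""

    def test_backbone_rmsds_vanish(self, built):
        ensembles, _, _ = built
        assert len(ensembles) == 3
        for ens in ensembles:
            assert ens.size == 3
            for member in ens.members:
                assert member.backbone_rmsd < 1e-6

    def test_ligand_poses_coincide_with_ground_truth_overlay(self, built):
        ensembles, ref_poses, transforms = built
        for ens in ensembles:
            rot, trans = transforms[ens.search_ligand.entry_id]
            for member in ens.members:
                expected = ref_poses[member.ligand.key_str] @ rot.T + trans
                assert np.abs(member.coords - expected).max() < 1e-6

    def test_membership_invariant_under_extra_rigid_motion(self, built):
        ensembles, _, _ = built
        names = {e.name for e in ensembles}
        entries2, _, _ = sf.make_rigid_copy_entries(seed=77)
        entry_map = {e.entry_id: e for e in entries2}
        ligands = []
        for entry in entries2:
            ligands += cp.perceive_all(entry.ligand_candidates)
        names2 = {e.name for e in eb.build_all_ensembles(ligands, entry_map)}
        assert names == names2


class TestEnsembleNaming:
    def test_name_format_and_search_ligand_membership(self, ensemble_run):
        names = {e.name for e in ensemble_run.ensembles}
        assert "ANT_A_301-a105" in names
        for ens in ensemble_run.ensembles:
            member_keys = [m.ligand.key for m in ens.members]
            assert ens.search_ligand.key in member_keys
            assert all(m.backbone_rmsd >= 0 for m in ens.members)
            assert len(ens.complexes) == len(ens.members)
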