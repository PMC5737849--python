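import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydration import consensus as cs
from hydration import structures as st
from hydration.synth import SharedSiteSpec, make_crystal_assembly, make_toy_system


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        tr = cs.kabsch_superpose(pts, pts)
        assert tr.fit_rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_known_rotation_recovered(self, rng):
        pts = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        tr = cs.kabsch_superpose(pts, moved)
        assert tr.fit_rmsd < 1e-9
        np.testing.assert_allclose(tr.apply(moved), pts, atol=1e-9)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_mirror_image_gets_proper_rotation(self, rng):
        pts = rng.normal(size=(8, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tr = cs.kabsch_superpose(pts, mirrored)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-6)
        assert tr.fit_rmsd > 0

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent cross-check against scipy's Kabsch implementation."""
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        tr = cs.kabsch_superpose(a, b)
        rot, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        expected_rmsd = rssd / np.sqrt(len(a))
        assert tr.fit_rmsd == pytest.approx(expected_rmsd, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cs.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestChainRMSD:
    def test_duplicated_chain_zero(self):
        model, _ = make_crystal_assembly(2, [], seed=1)
        mat, mean = cs.pairwise_chain_rmsd(model, ["A", "B"])
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_jittered_copies_match_numerical_oracle(self):
        sigma = 0.5
        model, _ = make_crystal_assembly(2, [], seed=7,
                                         atom_jitter_sigma=sigma)
        _, mean = cs.pairwise_chain_rmsd(model, ["A", "B"], atom_filter="heavy")
        # oracle: direct computation on the known correspondence after kabsch
        maps = {c: cs._atom_map(model, c, "heavy") for c in ("A", "B")}
        xa, xb = cs._common_coords(model, maps["A"], model, maps["B"])
        oracle = cs.kabsch_superpose(xa, xb).fit_rmsd
        assert mean == pytest.approx(oracle, abs=1e-12)
        # scale check: two copies with RMS displacement sigma each differ by
        # an expected RMSD of sqrt(2)*sigma ~ 0.71, minus what the rigid fit
        # absorbs; allow a generous band around that
        assert 0.45 < mean < 0.95

    def test_matrix_matches_pairwise_kabsch(self):
        model, _ = make_crystal_assembly(3, [], seed=3, atom_jitter_sigma=0.3)
        chains = ["A", "B", "C"]
        mat, _ = cs.pairwise_chain_rmsd(model, chains)
        maps = {c: cs._atom_map(model, c, "backbone") for c in chains}
        xa, xb = cs._common_coords(model, maps["A"], model, maps["C"])
        assert mat[0, 2] == pytest.approx(cs.kabsch_superpose(xa, xb).fit_rmsd)


class TestEnsembleRMSD:
    def test_copies_give_zero(self):
        model = make_toy_system(6, include_rna=False)
        ensemble = [model, model]
        assert cs.ensemble_vs_model_rmsd(ensemble, model, ["A"]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_single_pair_reduces_to_kabsch(self):
        model, _ = make_crystal_assembly(2, [], seed=9, atom_jitter_sigma=0.4)
        # ensemble: chain A extracted as its own model
        a_atoms = [a for a in model.atoms if a.chain_id == "A"]
        member = st.StructureModel(atoms=a_atoms)
        got = cs.ensemble_vs_model_rmsd([member], model, ["B"])
        maps_a = cs._atom_map(member, "A", "backbone")
        maps_b = cs._atom_map(model, "B", "backbone")
        xa, xb = cs._common_coords(member, maps_a, model, maps_b)
        assert got == pytest.approx(cs.kabsch_superpose(xa, xb).fit_rmsd)


class TestConsensusClustering:
    def test_site_in_all_copies(self):
        model, truth = make_crystal_assembly(
            6, [SharedSiteSpec(present_in=6, jitter_sigma=0.3)], seed=21)
        sites = cs.pool_and_cluster_waters(model)
        assert sites and sites[0].presence_count == 6

    def test_partial_presence(self):
        model, truth = make_crystal_assembly(
            6, [SharedSiteSpec(present_in=3, jitter_sigma=0.3)], seed=22)
        sites = cs.pool_and_cluster_waters(model)
        assert sites and sites[0].presence_count == 3
        assert sites[0].chains_present == truth.presence_map[0]

    def test_multiple_sites_not_merged(self):
        model, truth = make_crystal_assembly(
            6, [SharedSiteSpec(6, 0.2), SharedSiteSpec(4, 0.2)], seed=23)
        sites = cs.pool_and_cluster_waters(model)
        counts = sorted((s.presence_count for s in sites), reverse=True)
        assert counts[:2] == [6, 4]

    def test_each_water_in_at_most_one_cluster(self):
        model, _ = make_crystal_assembly(
            6, [SharedSiteSpec(6, 0.3), SharedSiteSpec(3, 0.3)], seed=24,
            n_extra_waters_per_copy=2)
        sites = cs.pool_and_cluster_waters(model)
        total_members = sum(len(s.member_waters) for s in sites)
        n_waters = sum(1 for a in model.atoms if a.is_water)
        assert total_members <= n_waters
        for s in sites:
            for _c, _num, d in s.member_waters:
                assert d <= 1.2 + 1e-9

    def test_presence_invariant_under_chain_relabeling(self):
        model, _ = make_crystal_assembly(
            4, [SharedSiteSpec(3, 0.2)], seed=25)
        sites1 = cs.pool_and_cluster_waters(model)
        # relabel chains in reverse
        perm = {"A": "D", "B": "C", "C": "B", "D": "A"}
        relabeled = st.StructureModel(atoms=[
            st.Atom(a.serial, a.name, a.element, a.residue_name,
                    a.residue_number, perm.get(a.chain_id, a.chain_id),
                    a.position.copy())
            for a in model.atoms])
        sites2 = cs.pool_and_cluster_waters(relabeled)
        assert sorted(s.presence_count for s in sites1) == \
            sorted(s.presence_count for s in sites2)

    def test_deterministic(self):
        model, _ = make_crystal_assembly(5, [SharedSiteSpec(4, 0.25)], seed=26)
        s1 = cs.pool_and_cluster_waters(model)
        s2 = cs.pool_and_cluster_waters(model)
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.centroid, b.centroid)

    def test_bad_cutoff(self):
        model, _ = make_crystal_assembly(2, [], seed=1)
        with pytest.raises(ValueError):
            cs.pool_and_cluster_waters(model, cluster_cutoff=0.0)


class TestAnnotation:
    def test_coordinating_atoms_listed(self):
        # a water 2.8 Å from both a serine OG and a backbone O must list both
        atoms = [
            st.Atom(1, "CA", "C", "SER", 5, "A", np.array([0.0, 0.0, 0.0])),
            st.Atom(2, "CB", "C", "SER", 5, "A", np.array([1.45, 0.0, 0.0])),
            st.Atom(3, "OG", "O", "SER", 5, "A", np.array([2.9, 0.0, 0.0])),
            st.Atom(4, "C", "C", "SER", 5, "A", np.array([0.0, 4.0, 0.0])),
            st.Atom(5, "O", "O", "SER", 5, "A", np.array([2.9, 4.4, 0.0])),
            st.Atom(6, "O", "O", "HOH", 100, "W", np.array([4.4, 2.2, 0.0])),
        ]
        model = st.StructureModel(atoms=atoms)
        d_og = np.linalg.norm(atoms[5].position - atoms[2].position)
        d_o = np.linalg.norm(atoms[5].position - atoms[4].position)
        assert d_og < 3.5 and d_o < 3.5
        site = cs.ConsensusSite(centroid=atoms[5].position.copy(),
                                member_waters=[("A", 100, 0.0)],
                                chains_present={"A"})
        out = cs.annotate_coordinating_atoms(model, site)
        assert out.coordinating_labels["A"] == ["S5(O)", "S5(OG)"]
        assert out.label == "S5(O)/S5(OG)"

    def test_lonely_water_gets_empty_label(self):
        atoms = [
            st.Atom(1, "CA", "C", "GLY", 1, "A", np.zeros(3)),
            st.Atom(2, "O", "O", "HOH", 50, "W", np.array([20.0, 0.0, 0.0])),
        ]
        model = st.StructureModel(atoms=atoms)
        site = cs.ConsensusSite(centroid=np.array([20.0, 0.0, 0.0]),
                                member_waters=[("A", 50, 0.0)],
                                chains_present={"A"})
        out = cs.annotate_coordinating_atoms(model, site)
        assert out.label == ""

    def test_assembly_site_annotated_consistently(self):
        model, _ = make_crystal_assembly(
            6, [SharedSiteSpec(6, 0.1)], seed=31)
        sites = cs.pool_and_cluster_waters(model)
        out = cs.annotate_coordinating_atoms(model, sites[0])
        assert out.label  # shared anchor atom named in the majority of copies
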