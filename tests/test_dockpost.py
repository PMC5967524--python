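"""Pose IO, superposition, interfaces, clustering, propensities and SASA."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosphodelta import dockpost
from phosphodelta import simulate


def toy_structure(coords, chains=None, res_ids=None, radii=None, atom_names=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return dockpost.Structure(
        chains=np.array(chains if chains is not None else ["A"] * n),
        res_ids=np.array(res_ids if res_ids is not None else np.arange(1, n + 1)),
        res_names=np.array(["GLY"] * n),
        atom_names=np.array(atom_names if atom_names is not None else ["CA"] * n),
        elements=np.array(["C"] * n),
        coords=coords,
        radii=np.array(radii if radii is not None else [1.8] * n),
    )


def quaternion_rmsd_oracle(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via the Horn quaternion eigenvalue method."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K).max()
    n = len(a)
    msd = max(0.0, ((a**2).sum() + (b**2).sum() - 2 * lam) / n)
    return math.sqrt(msd)


def brute_force_interface(pose, receptor_chain, ligand_chain, cutoff=5.0):
    """O(n^2) all-pairs contact scan."""
    rec = pose.subset(pose.mask(receptor_chain))
    lig = pose.subset(pose.mask(ligand_chain))
    pairs = set()
    for i in range(len(rec)):
        for j in range(len(lig)):
            if np.linalg.norm(rec.coords[i] - lig.coords[j]) < cutoff:
                pairs.add((int(rec.res_ids[i]), int(lig.res_ids[j])))
    return pairs


class TestPoseIO:
    def test_roundtrip_two_chain_pose(self, tmp_path):
        pose = toy_structure(
            [[0, 0, 0], [3, 0, 0], [20, 0, 0]],
            chains=["A", "A", "B"],
            res_ids=[1, 2, 1],
        )
        path = tmp_path / "pose.pdb"
        dockpost.write_pose_pdb(pose, path)
        back = dockpost.read_pose(path, "A", "B")
        assert np.allclose(back.coords, pose.coords, atol=1e-3)
        assert list(back.chains) == ["A", "A", "B"]
        assert list(back.res_ids) == [1, 2, 1]

    def test_missing_chain_named_in_error(self, tmp_path):
        pose = toy_structure([[0, 0, 0], [3, 0, 0]], chains=["A", "A"])
        path = tmp_path / "pose.pdb"
        dockpost.write_pose_pdb(pose, path)
        with pytest.raises(ValueError, match="'B'"):
            dockpost.read_pose(path, "A", "B")

    def test_hetatm_ignored_by_default(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY B   1       9.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    3  O   HOH A  99       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        pose = dockpost.read_pose(path, "A", "B")
        assert len(pose) == 2


class TestSuperpose:
    def test_identity(self):
        pose = toy_structure([[0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 5]])
        moved, rmsd = dockpost.superpose(pose, pose)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(moved.coords, pose.coords, atol=1e-12)

    def test_pure_rotation_recovered(self):
        coords = np.array([[1, 0, 0], [0, 2, 0], [0, 0, 3], [1, 1, 1]], dtype=float)
        theta = math.pi / 2
        R = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        reference = toy_structure(coords @ R.T + np.array([5.0, -2.0, 1.0]))
        moved, rmsd = dockpost.superpose(toy_structure(coords), reference)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_copy_matches_quaternion_oracle(self, rng):
        coords = rng.normal(size=(30, 3)) * 5
        angle = 1.1
        R = np.array(
            [[math.cos(angle), 0, math.sin(angle)],
             [0, 1, 0],
             [-math.sin(angle), 0, math.cos(angle)]]
        )
        noisy = coords @ R.T + rng.normal(scale=0.4, size=(30, 3)) + 3.0
        _, rmsd = dockpost.superpose(toy_structure(coords), toy_structure(noisy))
        assert rmsd == pytest.approx(quaternion_rmsd_oracle(coords, noisy), abs=1e-8)

    def test_too_few_atoms(self):
        a = toy_structure([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            dockpost.superpose(a, a)


class TestCenterOfMass:
    def test_examples(self, rng):
        pose = toy_structure([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(dockpost.center_of_mass(pose, "A"), [1, 0, 0])
        single = toy_structure([[4.2, -1.0, 7.5]])
        assert np.allclose(dockpost.center_of_mass(single, "A"), [4.2, -1.0, 7.5])
        coords = rng.normal(size=(100, 3))
        assert np.allclose(
            dockpost.center_of_mass(toy_structure(coords), "A"), coords.mean(axis=0)
        )

    def test_empty_chain(self):
        with pytest.raises(ValueError):
            dockpost.center_of_mass(toy_structure([[0, 0, 0]]), "Z")


class TestDistanceFilter:
    def make_pose(self, separation):
        return toy_structure(
            [[0, 0, 0], [separation, 0, 0]], chains=["A", "B"], res_ids=[118, 81]
        )

    @pytest.mark.parametrize("sep,kept", [(9.9, True), (10.0, True), (10.1, False)])
    def test_inclusive_boundary(self, sep, kept):
        poses = [self.make_pose(sep)]
        out, distances = dockpost.distance_filter(
            poses, ("B", 81, "CA"), ("A", 118, "CA")
        )
        assert (len(out) == 1) is kept
        assert distances[0] == pytest.approx(sep)

    def test_infinite_cutoff_is_identity_and_monotone(self):
        poses = [self.make_pose(s) for s in (2.0, 9.0, 11.0, 30.0)]
        all_kept, _ = dockpost.distance_filter(
            poses, ("B", 81, "CA"), ("A", 118, "CA"), cutoff=math.inf
        )
        assert all_kept == poses
        at10, _ = dockpost.distance_filter(poses, ("B", 81, "CA"), ("A", 118, "CA"), cutoff=10)
        at12, _ = dockpost.distance_filter(poses, ("B", 81, "CA"), ("A", 118, "CA"), cutoff=12)
        assert set(map(id, at10)) <= set(map(id, at12))

    def test_missing_atom_errors_without_fallback(self):
        pose = self.make_pose(5.0)
        with pytest.raises(ValueError, match="missing"):
            dockpost.pose_distance(pose, ("B", 81, "CB"), ("A", 118, "CA"))
        d = dockpost.pose_distance(
            pose, ("B", 81, "CB"), ("A", 118, "CA"), fallback_centroid=True
        )
        assert d == pytest.approx(5.0)


class TestInterface:
    @pytest.mark.parametrize("sep,inside", [(4.9, True), (5.1, False)])
    def test_strict_cutoff(self, sep, inside):
        pose = toy_structure([[0, 0, 0], [sep, 0, 0]], chains=["A", "B"], res_ids=[1, 1])
        contacts = dockpost.interface(pose, "A", "B")
        assert ((1, 1) in contacts.contacts) is inside

    def test_random_pose_matches_brute_force(self, rng):
        n = 60
        coords = rng.uniform(-12, 12, size=(n, 3))
        chains = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        res_ids = list(np.arange(1, n // 2 + 1)) + list(np.arange(1, n - n // 2 + 1))
        pose = toy_structure(coords, chains=chains, res_ids=res_ids)
        ours = dockpost.interface(pose, "A", "B").contacts
        assert ours == brute_force_interface(pose, "A", "B")


class TestContactSimilarity:
    def C(self, pairs):
        return dockpost.ContactSet(contacts=frozenset(pairs))

    def test_examples(self):
        a = self.C({(1, 1), (1, 2), (2, 2)})
        b = self.C({(1, 1), (1, 2)})
        assert dockpost.contact_similarity(a, a) == 1.0
        assert dockpost.contact_similarity(a, self.C({(9, 9)})) == 0.0
        assert dockpost.contact_similarity(a, b) == pytest.approx(2 / 3)
        assert dockpost.contact_similarity(self.C(set()), self.C(set())) == 1.0
        assert dockpost.contact_similarity(self.C(set()), b) == 0.0

    @given(
        st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=20),
        st.sets(st.tuples(st.integers(0, 8), st.integers(0, 8)), max_size=20),
    )
    def test_symmetric_and_bounded(self, pa, pb):
        a, b = self.C(pa), self.C(pb)
        s = dockpost.contact_similarity(a, b)
        assert s == dockpost.contact_similarity(b, a)
        assert 0.0 <= s <= 1.0


class TestClustering:
    def C(self, pairs):
        return dockpost.ContactSet(contacts=frozenset(pairs))

    def test_identical_sets_one_cluster(self):
        sets = [self.C({(1, 1), (2, 1)})] * 5
        labels = dockpost.cluster_poses(sets)
        assert set(labels) == {0}

    def test_dissimilar_sets_singletons(self):
        sets = [self.C({(i, i)}) for i in range(4)]
        labels = dockpost.cluster_poses(sets)
        assert len(set(labels)) == 4

    def test_planted_families_recovered_and_deterministic(self):
        config = simulate.SimulationConfig(seed=5, n_poses=24, fraction_near_site=0.25)
        poses, truth = simulate.gen_poses(config)
        contacts = [dockpost.interface(p, "A", "B") for p in poses]
        labels = dockpost.cluster_poses(contacts)
        labels2 = dockpost.cluster_poses(contacts)
        assert np.array_equal(labels, labels2)
        assert len(set(labels)) == len(set(truth.families))
        # cluster labels refine the planted families exactly
        for fam in set(truth.families):
            fam_labels = {l for l, f in zip(labels, truth.families) if f == fam}
            assert len(fam_labels) == 1


class TestPropensity:
    def test_uniform_ensemble_is_zero(self):
        prof = dockpost.propensity([{1} for _ in range(8)])
        row = prof[prof["residue"] == 1].iloc[0]
        assert row["count"] == 8 and row["propensity"] == pytest.approx(0.0)

    def test_never_in_interface_gets_floor(self):
        prof = dockpost.propensity([{1}] * 8, residues=[1, 2])
        absent = prof[prof["residue"] == 2].iloc[0]
        assert absent["count"] == 0
        assert absent["propensity"] == pytest.approx(math.log2(1 / 9))

    def test_counts_match_recount_and_permutation_invariance(self, rng):
        sets = [set(map(int, rng.choice(20, size=rng.integers(1, 6), replace=False)))
                for _ in range(15)]
        prof = dockpost.propensity(sets)
        for _, row in prof.iterrows():
            assert row["count"] == sum(1 for s in sets if row["residue"] in s)
        shuffled = [sets[i] for i in rng.permutation(len(sets))]
        prof2 = dockpost.propensity(shuffled)
        assert prof.equals(prof2)


class TestSASA:
    def test_isolated_atom_analytic_sphere(self):
        st_ = toy_structure([[0, 0, 0]], radii=[1.6])
        result = dockpost.sasa(st_)
        assert result.table["sasa"].iloc[0] == pytest.approx(
            4 * math.pi * 3.0**2, rel=0.01
        )

    def test_fully_enclosed_atom_is_zero(self):
        st_ = toy_structure(
            [[0, 0, 0], [0.1, 0, 0]], res_ids=[1, 2], radii=[1.0, 3.0]
        )
        result = dockpost.sasa(st_)
        assert result.residue("A", 1)["sasa"] == 0.0

    def test_disjoint_atoms_additive(self):
        coords = [[0, 0, 0], [50, 0, 0], [0, 50, 0]]
        radii = [1.5, 1.8, 2.0]
        result = dockpost.sasa(toy_structure(coords, radii=radii))
        for area, r in zip(result.atom_areas, radii):
            assert area == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=0.01)

    def test_refinement_convergence_on_toy_cluster(self, rng):
        coords = rng.normal(scale=2.0, size=(5, 3))
        st_ = toy_structure(coords)
        coarse = dockpost.sasa(st_, n_points=960).table["sasa"]
        fine = dockpost.sasa(st_, n_points=10000).table["sasa"]
        assert np.allclose(coarse, fine, rtol=0.02, atol=0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dockpost.sasa(toy_structure([[0, 0, 0]]), n_points=5)


class TestRestraintSelection:
    def test_exposed_seed_selected_buried_neighbour_excluded(self):
        # seed residue 1 exposed; residue 2 buried in a cage of large atoms
        cage = [[3 + dx, dy, dz] for dx, dy, dz in
                [(0.9, 0, 0), (-0.9, 0, 0), (0, 0.9, 0), (0, -0.9, 0), (0, 0, 0.9), (0, 0, -0.9)]]
        coords = [[0, 0, 0], [3, 0, 0]] + cage
        res_ids = [1, 2] + [10 + i for i in range(6)]
        radii = [1.8, 0.8] + [2.4] * 6
        st_ = toy_structure(coords, res_ids=res_ids, radii=radii)
        selected = dockpost.restraint_selection(st_, "A", [1], radius=10.0)
        assert 1 in selected
        assert 2 not in selected

    def test_matches_brute_force_recomputation(self):
        config = simulate.SimulationConfig(seed=2, n_poses=1, fraction_near_site=1.0)
        poses, truth = simulate.gen_poses(config)
        pose = poses[0].subset(poses[0].mask("A"))
        seed_res = [truth.catalytic_residue]
        result = dockpost.sasa(pose)
        selected = dockpost.restraint_selection(pose, "A", seed_res, radius=10.0)
        # brute force: distance + relative-accessibility rule re-applied by hand
        expected = []
        seed_coords = pose.coords[np.isin(pose.res_ids, seed_res)]
        for res_id in pose.residue_ids("A"):
            atom_coords = pose.coords[pose.res_ids == res_id]
            dmin = min(
                np.linalg.norm(a - s) for a in atom_coords for s in seed_coords
            )
            row = result.residue("A", res_id)
            if dmin <= 10.0 and (row["rel_main"] >= 0.15 or row["rel_side"] >= 0.15):
                expected.append(res_id)
        assert selected == expected

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            dockpost.restraint_selection(toy_structure([[0, 0, 0]]), "A", [])
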