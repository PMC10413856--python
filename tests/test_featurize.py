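"""Feature builders: shells, residue minima, waters, PCA, occupancy."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from unbindml import (
    FeatureDescriptor,
    FeatureMatrix,
    Trajectory,
    WaterSiteSpec,
    build_toy_topology,
    make_toy_receptor_trajectory,
    pca_residue_contributions,
    residue_min_features,
    shell_pair_features,
    water_features,
    water_site_occupancy,
    xyz_pca_features,
)
from unbindml.featurize import ShellPairFeaturizer, WaterFeaturizer
from unbindml.errors import ConfigurationError, StructuralError

from conftest import small_receptor_spec


def _ensemble(n_trajs=3, n_frames=30, seed=0):
    spec = small_receptor_spec(seed=seed)
    trajs = [
        make_toy_receptor_trajectory(
            small_receptor_spec(seed=seed + k), n_frames
        )
        for k in range(n_trajs)
    ]
    return trajs, trajs[0].frame(0)


class TestDescriptors:
    def test_kind_field_consistency_enforced(self):
        with pytest.raises(ConfigurationError):
            FeatureDescriptor(kind="pair_distance", ligand_atom_id=1)
        with pytest.raises(ConfigurationError):
            FeatureDescriptor(
                kind="pca_component", component_index=0, residue_id=3
            )
        d = FeatureDescriptor(kind="water_distance", water_molecule_id=9)
        assert d.label() == "wat(9)"


class TestShellFeatures:
    def _toy(self):
        # 3 ligand atoms near 2 protein atoms; 2 protein atoms far away
        top = build_toy_topology(n_protein=4, n_ligand=3, n_waters=1)
        frame = np.array(
            [
                [0.0, 0, 0], [2.0, 0, 0],          # inside 3 Å of ligand
                [30.0, 0, 0], [40.0, 0, 0],        # far
                [1.0, 1.0, 0], [1.0, -1.0, 0], [0.0, 1.5, 0],   # ligand
                [200.0, 0, 0],                      # water
            ]
        )
        coords = np.stack([frame, frame + 0.1])
        return Trajectory(top, coords, np.array([0.0, 0.01]))

    def test_feature_count_is_ligand_times_selected(self):
        traj = self._toy()
        fm = shell_pair_features([traj], traj.frame(0), cutoff=3.0)
        assert fm.n_features == 3 * 2
        kinds = {d.kind for d in fm.descriptors}
        assert kinds == {"pair_distance"}

    def test_3A_selection_nested_in_6A(self, receptor_traj):
        ref = receptor_traj.frame(0)
        top = receptor_traj.topology
        f3 = ShellPairFeaturizer(cutoff=3.0).fit(ref, top)
        f6 = ShellPairFeaturizer(cutoff=6.0).fit(ref, top)
        assert set(map(tuple, f3.pairs_)) <= set(map(tuple, f6.pairs_))

    def test_augment_range_adds_residues_beyond_cutoff(self):
        traj = self._toy()
        # residue 1 = protein atoms 0-3 (all four), so augmenting adds the far ones
        fm = shell_pair_features(
            [traj], traj.frame(0), cutoff=3.0, augment_residue_range=(1, 1)
        )
        assert fm.n_features == 3 * 4

    def test_matches_brute_force_enumeration(self, receptor_traj):
        ref = receptor_traj.frame(0)
        top = receptor_traj.topology
        fm = shell_pair_features([receptor_traj], ref, cutoff=6.0)
        lig, prot = top.ligand_heavy, top.protein_heavy
        dref = cdist(ref[lig], ref[prot])
        selected = prot[dref.min(axis=0) < 6.0]
        assert fm.n_features == len(lig) * len(selected)
        # spot-check values per frame against direct norms
        for k, d in enumerate(fm.descriptors[: 10]):
            a, p = d.ligand_atom_id, d.protein_atom_id
            expect = np.linalg.norm(
                receptor_traj.coordinates[:, a] - receptor_traj.coordinates[:, p],
                axis=1,
            )
            np.testing.assert_allclose(fm.values[0, :, k], expect, atol=1e-9)

    def test_strict_pair_semantics_subset_of_shell(self, receptor_traj):
        ref = receptor_traj.frame(0)
        top = receptor_traj.topology
        shell = ShellPairFeaturizer(cutoff=4.0, semantics="shell").fit(ref, top)
        strict = ShellPairFeaturizer(cutoff=4.0, semantics="pair").fit(ref, top)
        assert set(map(tuple, strict.pairs_)) <= set(map(tuple, shell.pairs_))

    def test_empty_selection_rejected(self):
        traj = self._toy()
        with pytest.raises(ConfigurationError):
            shell_pair_features([traj], traj.frame(0), cutoff=0.1)


class TestResidueMinFeatures:
    def test_per_residue_minimum_and_oracle(self, receptor_traj):
        fm = residue_min_features([receptor_traj])
        top = receptor_traj.topology
        lig, prot = top.ligand_heavy, top.protein_heavy
        assert fm.n_features == len(np.unique(top.residue_ids[prot]))
        for f in range(0, receptor_traj.n_frames, 11):
            frame = receptor_traj.coordinates[f]
            d = cdist(frame[lig], frame[prot]).min(axis=0)
            for k, desc in enumerate(fm.descriptors):
                mask = top.residue_ids[prot] == desc.residue_id
                assert fm.values[0, f, k] == pytest.approx(
                    d[mask].min(), abs=1e-9
                )

    def test_min_switches_identity_per_frame(self):
        top = build_toy_topology(n_protein=2, n_ligand=1, n_waters=1)
        f1 = np.array([[0.0, 0, 0], [10.0, 0, 0], [4.0, 0, 0], [99.0] * 3])
        f2 = np.array([[0.0, 0, 0], [10.0, 0, 0], [8.0, 0, 0], [99.0] * 3])
        traj = Trajectory(top, np.stack([f1, f2]), np.array([0.0, 0.01]))
        fm = residue_min_features([traj])
        assert fm.values[0, 0, 0] == pytest.approx(4.0)  # closest: atom 0
        assert fm.values[0, 1, 0] == pytest.approx(2.0)  # closest: atom 1

    def test_residue_min_bounded_by_pair_features(self, receptor_traj):
        rmin = residue_min_features([receptor_traj])
        pairs = shell_pair_features(
            [receptor_traj], receptor_traj.frame(0), cutoff=6.0
        )
        rid_to_col = {d.residue_id: k for k, d in enumerate(rmin.descriptors)}
        for k, d in enumerate(pairs.descriptors):
            col = rid_to_col[d.residue_id]
            assert np.all(
                rmin.values[0, :, col] <= pairs.values[0, :, k] + 1e-9
            )


class TestWaterFeatures:
    def test_selection_and_identity_tracking(self):
        spec = small_receptor_spec(seed=6)
        traj = make_toy_receptor_trajectory(spec, 50)
        fm = water_features([traj], traj.frame(0), n_waters=2)
        assert fm.n_features == 2
        ids = {d.water_molecule_id for d in fm.descriptors}
        # the two anchored waters are the only ones near the ligand
        mols = traj.topology.water_molecules()
        near = sorted(mols)[:2]
        assert ids == set(near)

    def test_tracked_water_distance_grows_as_it_drifts(self):
        top = build_toy_topology(n_protein=4, n_ligand=1, n_waters=2)
        frames = []
        for f in range(5):
            frame = np.zeros((top.n_atoms, 3))
            frame[:4] = [[10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 0]]
            frame[4] = [0, 0, 0]                        # ligand
            frame[5] = [2.0 + f, 0, 0]                  # drifting water
            frame[6] = [0, 50.0, 0]                     # far water
            frames.append(frame)
        traj = Trajectory(top, np.array(frames), np.arange(5) * 0.01)
        fm = water_features([traj], traj.frame(0), n_waters=1)
        np.testing.assert_allclose(fm.values[0, :, 0], 2.0 + np.arange(5))

    def test_too_few_waters_error_names_the_count(self, receptor_traj):
        with pytest.raises(ConfigurationError, match="10"):
            WaterFeaturizer(n_waters=11).fit(
                receptor_traj.frame(0), receptor_traj.topology
            )

    def test_values_match_oracle(self, receptor_traj):
        fm = water_features([receptor_traj], receptor_traj.frame(0), n_waters=3)
        top = receptor_traj.topology
        lig = top.ligand_heavy
        mols = top.water_molecules()
        for k, d in enumerate(fm.descriptors):
            atoms = mols[d.water_molecule_id]
            for f in range(0, receptor_traj.n_frames, 13):
                frame = receptor_traj.coordinates[f]
                expect = cdist(frame[atoms], frame[lig]).min()
                assert fm.values[0, f, k] == pytest.approx(expect, abs=1e-9)


class TestXYZPCA:
    def test_rank_limited_motion_and_orthonormality(self):
        rng = np.random.default_rng(0)
        top = build_toy_topology(n_protein=8, n_ligand=1, n_waters=1)
        base = rng.normal(size=(top.n_atoms, 3)) * 5
        # motion confined to a 2-D subspace of one atom's coordinates
        frames = []
        for t in range(40):
            f = base.copy()
            f[0, 0] += np.sin(t * 0.7) * 2
            f[1, 1] += np.cos(t * 0.7) * 1
            frames.append(f)
        traj = Trajectory(top, np.array(frames), np.arange(40) * 0.01)
        with pytest.warns(UserWarning, match="truncating"):
            fm, model = xyz_pca_features(
                [traj], traj.frame(0), n_components=100, superpose=False
            )
        ev = model.explained_variance
        assert ev[0] > ev[1] > 1e-6
        assert np.all(ev[2:] < 1e-6 * ev[0])
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_projections_match_svd_oracle(self, receptor_traj):
        fm, model = xyz_pca_features(
            [receptor_traj], receptor_traj.frame(0), n_components=5
        )
        # independent oracle: centered SVD of the superposed coordinates
        from unbindml import Selection, superpose_frames

        sup = superpose_frames(
            receptor_traj,
            receptor_traj.frame(0),
            Selection(role="protein", heavy_only=True),
        )
        flat = sup.coordinates[:, receptor_traj.topology.protein_heavy, :]
        flat = flat.reshape(sup.n_frames, -1)
        centered = flat - flat.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[:5].T
        for c in range(5):
            got = fm.values[0, :, c]
            assert np.allclose(got, proj[:, c], atol=1e-6) or np.allclose(
                got, -proj[:, c], atol=1e-6
            )

    def test_total_variance_preserved(self, receptor_traj):
        from unbindml.featurize import XYZPCAFeaturizer

        fz = XYZPCAFeaturizer(n_components=100)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fz.fit([receptor_traj], receptor_traj.frame(0))
        assert fz.model_.explained_variance.sum() == pytest.approx(
            fz.total_variance_ * len(receptor_traj.times)
            / (len(receptor_traj.times) - 1),
            rel=1e-6,
        )


class TestResidueContributions:
    def test_single_residue_motion_dominates_component_one(self):
        top = build_toy_topology(n_protein=8, n_ligand=1, n_waters=1)
        rng = np.random.default_rng(1)
        base = rng.normal(size=(top.n_atoms, 3)) * 5
        frames = []
        for t in range(60):
            f = base.copy()
            f[0] += rng.normal(scale=1.0, size=3)  # residue 1 moves
            frames.append(f)
        traj = Trajectory(top, np.array(frames), np.arange(60) * 0.01)
        _, model = xyz_pca_features(
            [traj], traj.frame(0), n_components=3, superpose=False
        )
        contrib = pca_residue_contributions(model, top)
        np.testing.assert_allclose(contrib.sum(axis=1), 1.0, atol=1e-8)
        assert contrib.loc[0, 1] > 0.99  # component 0, residue 1

    def test_variance_ratio_recovered(self):
        # two residues moving along one axis with 4:1 variance ratio
        top = build_toy_topology(n_protein=8, n_ligand=1, n_waters=1)
        rng = np.random.default_rng(2)
        base = np.arange(top.n_atoms * 3, dtype=float).reshape(-1, 3)
        frames = []
        for t in range(4000):
            f = base.copy()
            z = rng.standard_normal()
            f[0, 0] += 2.0 * z          # residue 1, sd 2
            f[4, 0] += 1.0 * z          # residue 2, sd 1 (same latent mode)
            frames.append(f)
        traj = Trajectory(top, np.array(frames), np.arange(4000) * 0.01)
        _, model = xyz_pca_features(
            [traj], traj.frame(0), n_components=1, superpose=False
        )
        contrib = pca_residue_contributions(model, top)
        ratio = contrib.loc[0, 1] / contrib.loc[0, 2]
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_topology_mismatch_rejected(self, receptor_traj):
        _, model = xyz_pca_features(
            [receptor_traj], receptor_traj.frame(0), n_components=2
        )
        other = build_toy_topology(n_protein=2, n_ligand=1, n_waters=1)
        with pytest.raises(StructuralError):
            pca_residue_contributions(model, other)


class TestWaterSiteOccupancy:
    def _traj(self, occupied_frames, n_frames=100):
        top = build_toy_topology(n_protein=4, n_ligand=1, n_waters=2)
        frames = np.zeros((n_frames, top.n_atoms, 3))
        frames[:, :4] = [[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]]
        frames[:, 4] = [50, 50, 50]
        frames[:, 5] = [200.0, 0, 0]  # inert far water
        frames[:, 6] = [200.0, 50, 0]
        for f in occupied_frames:
            frames[f, 5] = [2.0, 0, 0]  # within 3.5 Å of site atom 0
        times = np.arange(n_frames) * 0.01
        return Trajectory(top, frames, times)

    def test_always_and_never(self):
        always = self._traj(range(100))
        never = self._traj([])
        site = WaterSiteSpec(site_atom_id=0)
        assert water_site_occupancy(always, site).occupancy == 1.0
        assert water_site_occupancy(never, site).occupancy == 0.0

    def test_93_of_100_frames(self):
        traj = self._traj(range(93))
        res = water_site_occupancy(traj, WaterSiteSpec(site_atom_id=0))
        assert res.occupancy == pytest.approx(0.93, abs=1e-12)
        # a single continuous 93-frame residence segment for that molecule
        rid = sorted(traj.topology.water_molecules())[0]
        assert res.segments[rid] == [93]

    def test_segment_lengths_reflect_swaps(self):
        traj = self._traj(list(range(0, 10)) + list(range(20, 25)))
        res = water_site_occupancy(traj, WaterSiteSpec(site_atom_id=0))
        rid = sorted(traj.topology.water_molecules())[0]
        assert res.segments[rid] == [10, 5]

    def test_bad_site_atom_raises(self):
        traj = self._traj([])
        with pytest.raises(IndexError):
            water_site_occupancy(traj, WaterSiteSpec(site_atom_id=10_000))


class TestFeatureMatrix:
    def test_hdf5_round_trip(self, tmp_path, receptor_traj):
        fm = residue_min_features([receptor_traj], labels=["IN"])
        path = tmp_path / "fm.h5"
        fm.save(path)
        back = FeatureMatrix.load(path)
        np.testing.assert_array_equal(back.values, fm.values)
        assert back.descriptors == fm.descriptors
        assert list(back.labels) == ["IN"]

    def test_concat_appends_columns(self, receptor_traj):
        a = residue_min_features([receptor_traj])
        b = water_features([receptor_traj], receptor_traj.frame(0), n_waters=2)
        c = a.concat(b)
        assert c.n_features == a.n_features + 2
        assert c.descriptors[-1].kind == "water_distance"

    def test_undecided_labels_rejected(self, receptor_traj):
        with pytest.raises(StructuralError):
            residue_min_features([receptor_traj], labels=["UNDECIDED"])
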