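import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from fragdecomp.ensemble import (featurize, filter_frames, fit_gmm,
                                 rank_conformers, reduce_dimensionality,
                                 representative_conformations)
from fragdecomp.mol_io import Trajectory
from fragdecomp.synthetic import GeneratorSpec, make_clustered_trajectory, \
    make_complex, make_peptide


@pytest.fixture(scope="module")
def clustered():
    cx, _, _ = make_complex(seed=4)
    spec = GeneratorSpec(n_frames=120, n_clusters=3, seed=4)
    traj, labels, manifest = make_clustered_trajectory(cx, spec)
    return traj, labels, manifest


class TestFeaturize:
    def test_shape(self, clustered):
        traj, _, _ = clustered
        X = featurize(traj, selection="all", align=False)
        assert X.shape == (len(traj), traj.frames[0].n_atoms * 3)

    def test_constant_trajectory_zero_variance(self):
        pep = make_peptide(3)
        traj = Trajectory([pep.with_coords(pep.coords(), frame_index=i,
                                           time_ns=float(i))
                           for i in range(4)])
        X = featurize(traj, align=False)
        assert np.abs(X.std(axis=0)).max() == 0.0

    def test_alignment_removes_planted_rigid_motion(self, rng):
        pep = make_peptide(4)
        base = pep.coords()
        frames = []
        for i in range(6):
            # pure rigid motion: random rotation + translation per frame
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w),
                 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z),
                 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w),
                 1 - 2 * (x * x + y * y)]])
            frames.append(pep.with_coords(
                base @ rot.T + rng.normal(size=3) * 5,
                frame_index=i, time_ns=float(i)))
        X = featurize(Trajectory(frames), align=True)
        assert np.abs(X.std(axis=0)).max() <= 1e-6

    def test_empty_selection_rejected(self, clustered):
        traj, _, _ = clustered
        with pytest.raises(ValueError):
            featurize(traj, selection=[])


class TestFilterFrames:
    def test_clean_input_identity(self, clustered):
        traj, _, _ = clustered
        kept, dropped = filter_frames(traj)
        assert len(kept) == len(traj) and dropped == {}

    def test_nan_frame_dropped(self):
        pep = make_peptide(3)
        frames = [pep.with_coords(pep.coords(), frame_index=i,
                                  time_ns=float(i)) for i in range(3)]
        frames[1].atoms[0].coords[:] = np.nan  # corrupt in place
        kept, dropped = filter_frames(frames)
        assert len(kept) == 2
        assert dropped == {1: "non-finite coordinates"}

    def test_topology_mismatch_dropped(self):
        frames = [make_peptide(3), make_peptide(4), make_peptide(3)]
        kept, dropped = filter_frames(frames)
        assert len(kept) == 2
        assert dropped[1] == "topology mismatch"

    def test_all_dropped_raises(self):
        pep = make_peptide(2)
        frame = pep.with_coords(pep.coords())
        frame.atoms[0].coords[:] = np.inf
        with pytest.raises(ValueError, match="all frames"):
            filter_frames([frame])


class TestReduceDimensionality:
    def test_blobs_stay_separated(self, rng):
        centers = np.array([[0.0] * 30, [15.0] * 30, [-15.0] * 30])
        labels = np.repeat([0, 1, 2], 40)
        X = centers[labels] + rng.normal(size=(120, 30))
        emb = reduce_dimensionality(X, "linear_projection", n_dims=2, seed=0)
        assert silhouette_score(emb, labels) > 0.8

    def test_duplicate_frames_map_together(self, rng):
        X = rng.normal(size=(20, 12))
        X[7] = X[3]
        emb = reduce_dimensionality(X, "linear_projection", n_dims=2, seed=0)
        assert np.abs(emb[7] - emb[3]).max() <= 1e-9

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(30, 12))
        a = reduce_dimensionality(X, "linear_projection", n_dims=3, seed=7)
        b = reduce_dimensionality(X, "linear_projection", n_dims=3, seed=7)
        assert np.array_equal(a, b)

    def test_nonlinear_path_runs_and_is_seeded(self, rng):
        X = np.repeat(np.eye(3), 12, axis=0)[:, :3]
        X = np.hstack([X] * 4) * 10 + rng.normal(size=(36, 12)) * 0.1
        a = reduce_dimensionality(X, "neighbor_graph_nonlinear", 2, seed=1)
        b = reduce_dimensionality(X, "neighbor_graph_nonlinear", 2, seed=1)
        assert a.shape == (36, 2)
        assert np.allclose(a, b)

    def test_argument_errors(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError):
            reduce_dimensionality(X, n_dims=10)
        with pytest.raises(ValueError):
            reduce_dimensionality(rng.normal(size=(2, 10)), n_dims=3)


class TestFitGmm:
    def test_recovers_planted_partition(self, clustered):
        traj, labels, _ = clustered
        X = featurize(traj, align=True)
        emb = reduce_dimensionality(X, "linear_projection", n_dims=2, seed=0)
        model = fit_gmm(emb, k=3, seed=0)
        assert adjusted_rand_score(labels, model.labels) >= 0.95

    def test_k_one_gives_single_label(self, rng):
        emb = rng.normal(size=(40, 2))
        model = fit_gmm(emb, k=1, seed=0)
        assert set(model.labels.tolist()) == {0}

    def test_responsibilities_normalised(self, clustered):
        traj, _, _ = clustered
        X = featurize(traj, align=True)
        emb = reduce_dimensionality(X, n_dims=2, seed=0)
        model = fit_gmm(emb, k=3, seed=0)
        assert np.abs(model.responsibilities.sum(axis=1) - 1.0).max() <= 1e-9

    def test_auto_selects_planted_k_and_records_trace(self, clustered):
        traj, _, _ = clustered
        X = featurize(traj, align=True)
        emb = reduce_dimensionality(X, n_dims=2, seed=0)
        model = fit_gmm(emb, k="auto", seed=0)
        assert model.n_clusters == 3
        assert set(model.selection_criterion_trace) == set(range(1, 9))

    def test_k_above_frame_count_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gmm(rng.normal(size=(5, 2)), k=10, seed=0)


class TestRepresentativeConformations:
    def test_duplicate_frame_cluster_is_that_frame(self):
        pep = make_peptide(3)
        traj = Trajectory([pep.with_coords(pep.coords(), frame_index=i,
                                           time_ns=float(i))
                           for i in range(4)])
        from fragdecomp.ensemble import EnsembleModel

        model = EnsembleModel(labels=np.zeros(4, dtype=int), n_clusters=1,
                              embedding=np.zeros((4, 2)), seed=0)
        rep, = representative_conformations(traj, model, align=False)
        assert np.array_equal(rep.structure.coords(), pep.coords())
        assert rep.member_frames == [0, 1, 2, 3]

    def test_two_frame_midpoint_without_alignment(self):
        pep = make_peptide(3)
        c0 = pep.coords()
        c1 = c0.copy()
        c1[0] += np.array([2.0, 0.0, 0.0])
        traj = Trajectory([pep.with_coords(c0, frame_index=0, time_ns=0.0),
                           pep.with_coords(c1, frame_index=1, time_ns=1.0)])
        from fragdecomp.ensemble import EnsembleModel

        model = EnsembleModel(labels=np.zeros(2, dtype=int), n_clusters=1,
                              embedding=np.zeros((2, 2)), seed=0)
        rep, = representative_conformations(traj, model, align=False)
        assert rep.structure.coords()[0] == pytest.approx(
            c0[0] + np.array([1.0, 0.0, 0.0]))

    def test_average_equals_column_means(self, clustered):
        traj, labels, _ = clustered
        from fragdecomp.ensemble import EnsembleModel

        model = EnsembleModel(labels=labels, n_clusters=3,
                              embedding=np.zeros((len(traj), 2)), seed=0)
        reps = representative_conformations(traj, model, align=False)
        coords = traj.coords()
        for rep in reps:
            oracle = coords[rep.member_frames].mean(axis=0)
            assert np.abs(rep.structure.coords() - oracle).max() <= 1e-12

    def test_empty_cluster_skipped_with_warning(self):
        pep = make_peptide(2)
        traj = Trajectory([pep.with_coords(pep.coords(), frame_index=i,
                                           time_ns=float(i))
                           for i in range(3)])
        from fragdecomp.ensemble import EnsembleModel

        model = EnsembleModel(labels=np.zeros(3, dtype=int), n_clusters=2,
                              embedding=np.zeros((3, 2)), seed=0)
        with pytest.warns(UserWarning, match="no member frames"):
            reps = representative_conformations(traj, model, align=False)
        assert len(reps) == 1


class TestRankConformers:
    def test_seven_conformer_site_extrema(self):
        # per-conformation totals of a seven-member ensemble
        energies = {"conf 0": -48.4, "conf 1": -49.8, "conf 2": -50.0,
                    "conf 3": -52.7, "conf 4": -54.0, "conf 5": -54.3,
                    "final": -54.8}
        ranking = rank_conformers(energies)
        assert ranking.min_energy == -54.8 and ranking.max_energy == -48.4
        assert [e for _, e in ranking.ordered] == sorted(energies.values())

    def test_single_entry_is_both_extrema(self):
        ranking = rank_conformers({"only": -50.0})
        assert ranking.min_label == ranking.max_label == "only"

    def test_ties_broken_by_label(self):
        ranking = rank_conformers({"b": -1.0, "a": -1.0})
        assert ranking.min_label == "a" and ranking.max_label == "b"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_conformers({})
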