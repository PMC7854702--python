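import collections

import numpy as np
import pytest

from phytosaxs import bead_models as bm
from phytosaxs import saxs_core as sc
from phytosaxs import shape_classify as scl
from phytosaxs import synthetic_data as sd


@pytest.fixture(scope="module")
def bent_rod():
    return bm.generate_shape(
        "bent_rod", {"length": 120.0, "diameter": 30.0, "bend_angle": 130.0},
        800, seed=21)


def _random_rigid(coords, seed, mirror=False):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    out = coords.copy()
    if mirror:
        out = out * np.array([1.0, 1.0, -1.0])
    return out @ q.T + rng.normal(0, 30, 3)


class TestAlign:
    def test_canonical_pose_is_fixed_point(self, bent_rod):
        once = scl.align_principal_axes(bent_rod)
        twice = scl.align_principal_axes(once)
        assert np.abs(twice.coords - once.coords).max() < 1e-9

    def test_random_rigid_motion_is_undone(self, bent_rod):
        ref = scl.align_principal_axes(bent_rod)
        moved = bm.BeadModel(coords=_random_rigid(bent_rod.coords, seed=5))
        aligned = scl.align_principal_axes(moved, reference=ref)
        rmsd = np.sqrt(((aligned.coords - ref.coords) ** 2).sum(axis=1).mean())
        assert rmsd < scl.DEFAULT_VOXEL_SIZE / 2

    def test_mirror_image_recovered_with_enantiomer_handling(self, bent_rod):
        ref = scl.align_principal_axes(bent_rod)
        mirrored = bm.BeadModel(coords=_random_rigid(bent_rod.coords, seed=6,
                                                     mirror=True))
        with_flip = scl.align_principal_axes(mirrored, reference=ref,
                                             enantiomer=True)
        extent = scl.shared_extent([ref])
        ref_occ = scl._binary_occupancy(ref.coords, extent[0],
                                        scl.DEFAULT_VOXEL_SIZE, extent[1])
        overlap_flip = scl._overlap(with_flip.coords, ref_occ, extent[0],
                                    scl.DEFAULT_VOXEL_SIZE)
        without = scl.align_principal_axes(mirrored, reference=ref,
                                           enantiomer=False)
        overlap_no = scl._overlap(without.coords, ref_occ, extent[0],
                                  scl.DEFAULT_VOXEL_SIZE)
        assert overlap_flip >= overlap_no

    def test_collinear_model_rejected(self):
        line = bm.BeadModel(coords=np.column_stack([np.arange(10.0),
                                                    np.zeros(10), np.zeros(10)]))
        with pytest.raises(ValueError, match="collinear"):
            scl.align_principal_axes(line)


class TestVoxelize:
    def test_single_bead_density(self):
        model = bm.BeadModel(coords=[[3.0, 3.0, 3.0]])
        grid = scl.voxelize(model, 6.0, (np.zeros(3), (2, 2, 2)))
        assert grid.density[0, 0, 0] == pytest.approx(1.0 / 216.0)
        assert grid.density.sum() == pytest.approx(1.0 / 216.0)

    def test_face_bead_goes_to_higher_index_voxel(self):
        model = bm.BeadModel(coords=[[6.0, 1.0, 1.0]])
        grid = scl.voxelize(model, 6.0, (np.zeros(3), (2, 2, 2)))
        assert grid.density[1, 0, 0] > 0
        assert grid.density[0, 0, 0] == 0

    def test_conservation(self, bent_rod):
        grid = scl.voxelize(scl.align_principal_axes(bent_rod))
        assert grid.n_beads == pytest.approx(bent_rod.n_beads)

    def test_bead_outside_extent_rejected(self):
        model = bm.BeadModel(coords=[[100.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="extent"):
            scl.voxelize(model, 6.0, (np.zeros(3), (2, 2, 2)))


class TestEmbedding:
    def _grids(self, vectors):
        return [
            scl.VoxelGrid(origin=np.zeros(3), voxel_size=6.0,
                          density=np.asarray(v, dtype=float))
            for v in vectors
        ]

    def test_identical_grids_rejected(self):
        v = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="variance"):
            scl.embed_pca(self._grids([v, v, v, v]))

    def test_rank_one_variation_loads_on_pc1(self, rng):
        base = rng.uniform(0, 1, (3, 3, 3))
        direction = rng.uniform(-1, 1, (3, 3, 3))
        grids = self._grids([base + t * direction for t in np.linspace(0, 1, 8)])
        emb = scl.embed_pca(grids)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_two_planted_families_separate_on_pc1(self):
        models, truth = sd.make_model_ensemble(
            families=sd.default_families(n_beads=1500)[:2],
            n_per_family=30, jitter_sigma=1.5, seed=8)
        aligned = [scl.align_principal_axes(m) for m in models]
        extent = scl.shared_extent(aligned)
        emb = scl.embed_pca([scl.voxelize(m, 6.0, extent) for m in aligned])
        pc1_a = emb.coords[truth == 0, 0]
        pc1_b = emb.coords[truth == 1, 0]
        assert pc1_a.max() < pc1_b.min() or pc1_b.max() < pc1_a.min()


class TestKMeans:
    def _embedding(self, coords):
        return scl.Embedding(coords=np.asarray(coords, dtype=float),
                             explained_variance_ratio=np.array([0.7, 0.3]),
                             component_axes=np.zeros((2, 8)),
                             mean_vector=np.zeros(8))

    def test_k_equals_m_gives_zero_inertia(self, rng):
        emb = self._embedding(rng.uniform(-1, 1, (6, 2)))
        ass = scl.cluster_kmeans(emb, k=6, seed=0, n_restarts=10)
        assert ass.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(ass.labels.tolist())) == 6

    def test_separated_blobs_recovered(self, rng):
        blob_a = rng.normal(0, 0.1, (20, 2))
        blob_b = rng.normal(10, 0.1, (20, 2))
        emb = self._embedding(np.vstack([blob_a, blob_b]))
        ass = scl.cluster_kmeans(emb, k=2, seed=1)
        assert len(set(ass.labels[:20].tolist())) == 1
        assert len(set(ass.labels[20:].tolist())) == 1
        assert ass.labels[0] != ass.labels[-1]

    def test_fixed_seed_is_deterministic(self, rng):
        emb = self._embedding(rng.uniform(-1, 1, (30, 2)))
        a = scl.cluster_kmeans(emb, k=4, seed=3)
        b = scl.cluster_kmeans(emb, k=4, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_more_clusters_than_points_rejected(self, rng):
        emb = self._embedding(rng.uniform(-1, 1, (3, 2)))
        with pytest.raises(ValueError):
            scl.cluster_kmeans(emb, k=5)


class TestAveraging:
    def test_singleton_cluster_occupancy_is_binary_mask(self, bent_rod):
        ref = scl.align_principal_axes(bent_rod)
        avg = scl.average_models([bent_rod], ref)
        assert set(np.unique(avg.occupancy)) <= {0.0, 1.0}
        grid = scl.voxelize(ref, 6.0, (avg.origin, avg.occupancy.shape))
        assert np.array_equal(avg.mask, grid.density > 0)

    def test_rigid_copies_average_to_binary_occupancy(self, bent_rod):
        ref = scl.align_principal_axes(bent_rod)
        copies = [bm.BeadModel(coords=_random_rigid(bent_rod.coords, seed=s))
                  for s in range(5)]
        avg = scl.average_models(copies, ref)
        # every member realigns onto the reference, so occupancy is 0/1 up
        # to beads sitting within numerical alignment error of a voxel edge
        occupied = avg.occupancy[avg.occupancy > 0]
        binary = np.isin(occupied, [1.0])
        assert binary.mean() >= 0.98

    def test_two_disjoint_half_shapes(self):
        a = bm.BeadModel(coords=np.random.default_rng(1).uniform(0, 12, (50, 3)))
        ref = scl.align_principal_axes(a)
        avg = scl.AveragedShape(
            occupancy=np.array([[[0.5, 1.0], [0.0, 0.5]]]),
            threshold=0.5, n_members=2, reference_index=0)
        assert avg.mask.sum() == 3  # 0.5 kept at threshold 0.5


@pytest.fixture(scope="module")
def small_ensemble():
    return sd.make_model_ensemble(
        families=sd.default_families(n_beads=1500),
        n_per_family=15, jitter_sigma=1.5, seed=33)


class TestPipeline:
    def test_group_sizes_partition_the_ensemble(self, small_ensemble):
        models, truth = small_ensemble
        report = scl.classify_ensemble(models, k=5, seed=2, n_restarts=20)
        assert sum(report.group_sizes) == len(models)

    def test_rerun_is_deterministic(self, small_ensemble):
        models, _ = small_ensemble
        a = scl.classify_ensemble(models, k=5, seed=2, n_restarts=20)
        b = scl.classify_ensemble(models, k=5, seed=2, n_restarts=20)
        assert np.array_equal(a.assignment.labels, b.assignment.labels)

    def test_planted_families_recovered_with_high_purity(self, small_ensemble):
        models, truth = small_ensemble
        report = scl.classify_ensemble(models, k=5, seed=2, n_restarts=20)
        correct = 0
        for c in set(report.assignment.labels.tolist()):
            members = truth[report.assignment.labels == c]
            correct += collections.Counter(members).most_common(1)[0][1]
        assert correct / len(models) >= 0.9

    def test_global_rigid_motion_leaves_embedding_unchanged(self, small_ensemble):
        models, _ = small_ensemble
        moved = [bm.BeadModel(coords=_random_rigid(m.coords, seed=77))
                 for m in models]
        aligned_a = [scl.align_principal_axes(m) for m in models]
        aligned_b = [scl.align_principal_axes(m) for m in moved]
        extent = scl.shared_extent(aligned_a + aligned_b)
        emb_a = scl.embed_pca([scl.voxelize(m, 6.0, extent) for m in aligned_a])
        emb_b = scl.embed_pca([scl.voxelize(m, 6.0, extent) for m in aligned_b])
        # limited by beads within numerical alignment error of a voxel edge
        assert np.abs(emb_a.coords - emb_b.coords).max() < 1e-3

    def test_report_written(self, small_ensemble, tmp_path):
        models, _ = small_ensemble
        scl.classify_ensemble(models[:10], k=3, seed=2, n_restarts=5,
                              out_dir=tmp_path)
        assert (tmp_path / "pc_scatter.csv").exists()
        assert (tmp_path / "run_report.json").exists()
        assert list(tmp_path.glob("group_*.ccp4"))


class TestDrCountSurvey:
    @staticmethod
    def _profile():
        s = np.linspace(1e-3, 0.05, 80)
        pair = bm.BeadModel(coords=[[0, 0, 0], [0, 0, 20.0]])
        return bm.debye_intensity(pair, s, mode="exact")

    def test_parabolic_engine_minimized_at_thousand(self):
        profile = self._profile()

        def engine(prof, count, seed):
            # separation error grows quadratically away from 1000 DRs
            d = 20.0 + (count - 1000) ** 2 * 1e-4
            return bm.BeadModel(coords=[[0, 0, 0], [0, 0, d]])

        best, curve = scl.optimize_dr_count(profile, engine, n_repeats=3)
        assert best == 1000
        assert set(curve) == set(range(900, 1201, 25))

    def test_flat_engine_breaks_ties_toward_smaller_count(self):
        profile = self._profile()

        def engine(prof, count, seed):
            return bm.BeadModel(coords=[[0, 0, 0], [0, 0, 20.0]])

        best, _ = scl.optimize_dr_count(profile, engine, n_repeats=2)
        assert best == 900

    def test_noisy_engine_recovers_planted_minimum(self):
        profile = self._profile()
        hits = 0
        trials = 25
        for trial in range(trials):
            def engine(prof, count, seed, _trial=trial):
                rng = np.random.default_rng(seed)
                d = 20.0 + (count - 1000) ** 2 * 1e-4 + rng.normal(0, 0.05)
                return bm.BeadModel(coords=[[0, 0, 0], [0, 0, d]])

            best, _ = scl.optimize_dr_count(profile, engine, n_repeats=14,
                                            seed=trial)
            hits += best == 1000
        assert hits / trials >= 0.9

    def test_engine_failure_reported_with_context(self):
        profile = self._profile()

        def engine(prof, count, seed):
            raise RuntimeError("annealing diverged")

        with pytest.raises(RuntimeError, match="dr_count=900"):
            scl.optimize_dr_count(profile, engine, n_repeats=1)
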