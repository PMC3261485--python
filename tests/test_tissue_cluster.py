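"""Feature-space tissue segmentation: density surface, k-means, restriction,
tissue assignment and back-mapping."""

import itertools

import numpy as np
import pytest

import corddti as c
from conftest import make_maps


def blob_instance(rng, centers, n_per=100, sd=0.05):
    pts = np.vstack([ctr + sd * rng.standard_normal((n_per, 2)) for ctr in centers])
    return make_maps(pts[:, 0], pts[:, 1])


def brute_force_kmeans_inertia(points, k=3):
    """Global optimum of the k-means objective by exhaustive labeling."""
    points = np.asarray(points, float)
    n = len(points)
    labelings = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int8)
    onehot = np.eye(k)[labelings]                       # (M, n, k)
    counts = onehot.sum(axis=1)                          # (M, k)
    valid = (counts > 0).all(axis=1)
    onehot, counts = onehot[valid], counts[valid]
    sums = np.einsum("mnk,nd->mkd", onehot, points)
    # inertia = sum |x|^2 - sum_c |sum_c|^2 / n_c
    sq = (points**2).sum()
    inertia = sq - ((sums**2).sum(axis=2) / counts).sum(axis=1)
    return inertia.min()


class TestDensitySurface:
    def test_counts_conserved(self, noisefree_maps):
        maps = noisefree_maps["cervical"]
        surf = c.build_density_surface(maps, bins=50)
        assert surf.total == len(maps)

    def test_identical_voxels_fill_single_bin(self):
        maps = make_maps(np.full(40, 1.5), np.full(40, 0.5))
        surf = c.build_density_surface(maps, bins=20)
        assert (surf.counts > 0).sum() == 1
        assert surf.counts.max() == 40

    def test_noisefree_phantom_shows_three_tissue_modes(self, noisefree_maps):
        surf = c.build_density_surface(noisefree_maps["lumbar"], bins=50)
        assert len(surf.local_maxima()) >= 3

    def test_bad_bins_rejected(self, noisefree_maps):
        with pytest.raises(ValueError):
            c.build_density_surface(noisefree_maps["cervical"], bins=0)


class TestKMeansPartition:
    def test_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        centers = [(1.0, 0.7), (1.8, 0.45), (3.0, 0.1)]
        maps = blob_instance(rng, centers)
        model = c.kmeans_partition(maps, k=3, seed=0)
        # each blob of 100 is one cluster, centroids near blob means
        assert sorted(np.bincount(model.labels).tolist()) == [100, 100, 100]
        got = model.centroids[np.argsort(model.centroids[:, 0])]
        for (mx, fy), ctr in zip(centers, got):
            assert np.hypot(ctr[0] - mx, ctr[1] - fy) < 3 * 0.05 / np.sqrt(100)

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(7)
        centers = [(0.0, 0.0), (3.0, 0.0), (0.0, 3.0)]
        pts = np.vstack([ctr + 0.3 * rng.standard_normal((4, 2)) for ctr in centers])[:10]
        maps = make_maps(pts[:, 0], pts[:, 1])
        model = c.kmeans_partition(maps, k=3, seed=0)
        inertia = sum(
            ((pts[model.labels == k_] - model.centroids[k_]) ** 2).sum()
            for k_ in range(3)
        )
        assert inertia == pytest.approx(brute_force_kmeans_inertia(pts, 3), rel=1e-9)

    def test_deterministic_given_seed(self, noisefree_maps):
        a = c.kmeans_partition(noisefree_maps["thoracic"], seed=5)
        b = c.kmeans_partition(noisefree_maps["thoracic"], seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.centroids, b.centroids)

    def test_k1_centroid_is_grand_mean(self):
        rng = np.random.default_rng(1)
        maps = make_maps(rng.uniform(0, 3, 50), rng.uniform(0, 1, 50))
        model = c.kmeans_partition(maps, k=1, seed=0)
        assert np.allclose(model.centroids[0], [maps.md.mean(), maps.fa.mean()])

    def test_memberships_partition_the_voxel_set(self, noisefree_maps):
        model = c.kmeans_partition(noisefree_maps["cervical"], seed=0)
        assert len(model.labels) == len(noisefree_maps["cervical"])
        assert set(np.unique(model.labels)) == {0, 1, 2}

    def test_too_few_distinct_points_rejected(self):
        maps = make_maps([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            c.kmeans_partition(maps, k=3, seed=0)


class TestRestriction:
    def test_voxel_at_centroid_retained(self):
        maps = blob_instance(np.random.default_rng(0), [(1.0, 0.7), (1.8, 0.45), (3.0, 0.1)])
        model = c.kmeans_partition(maps, seed=0)
        model = c.restrict_clusters(model, 0.2)
        nearest = np.argmin(
            np.linalg.norm(maps_features(model) - model.centroids[model.labels], axis=1)
        )
        assert model.retained[nearest]

    def test_half_distance_voxel_excluded_at_20pct(self):
        # two tight blobs plus one voxel midway: 0.5 x inter-centroid distance
        md = np.r_[np.full(50, 1.0), np.full(50, 2.0), 1.5]
        fa = np.r_[np.full(50, 0.7), np.full(50, 0.2), 0.45]
        md[:50] += np.linspace(0, 1e-4, 50)  # break exact duplication
        fa[50:100] += np.linspace(0, 1e-4, 50)
        maps = make_maps(np.r_[md, 3.0], np.r_[fa, 0.05])
        model = c.kmeans_partition(maps, k=3, seed=0)
        model = c.restrict_clusters(model, 0.2)
        assert not model.retained[100]  # the midway voxel

    def test_monotone_in_threshold(self, noisefree_maps):
        base = c.kmeans_partition(noisefree_maps["lumbar"], seed=1)
        r1 = c.restrict_clusters(base, 0.1).retained
        r2 = c.restrict_clusters(base, 0.2).retained
        r4 = c.restrict_clusters(base, 0.4).retained
        assert np.all(r1 <= r2) and np.all(r2 <= r4)

    def test_vanishing_threshold_excludes_almost_all(self, noisefree_maps):
        base = c.kmeans_partition(noisefree_maps["thoracic"], seed=1)
        model = c.restrict_clusters(base, 1e-12)
        assert model.retained.mean() < 0.05

    def test_nonpositive_threshold_rejected(self, noisefree_maps):
        base = c.kmeans_partition(noisefree_maps["thoracic"], seed=1)
        with pytest.raises(ValueError):
            c.restrict_clusters(base, 0.0)


def maps_features(model):
    return model.features


class TestAssignTissues:
    def _model(self, centroids, counts):
        labels = np.concatenate([np.full(n, k) for k, n in enumerate(counts)])
        feats = np.asarray(centroids, float)[labels]
        return c.ClusterModel(
            centroids=np.asarray(centroids, float),
            labels=labels,
            features=feats,
            coords=np.zeros((len(labels), 3), int),
            shape=(1, 1, 1),
            retained=np.ones(len(labels), bool),
        )

    def test_healthy_cord_centroids_assigned_correctly(self):
        # centroid geometry as reported for the cervical cord
        model = self._model([(0.97, 0.70), (1.8, 0.45), (3.06, 0.28)], [500, 200, 80])
        model = c.assign_tissues(model)
        assert model.tissue_names == ("WM", "GM", "CSF")

    def test_assignment_invariant_to_cluster_order(self):
        model = self._model([(3.06, 0.28), (0.97, 0.70), (1.8, 0.45)], [80, 500, 200])
        model = c.assign_tissues(model)
        assert model.tissue_names == ("CSF", "WM", "GM")

    def test_unexpected_count_order_warns_but_labels_by_geometry(self):
        model = self._model([(0.97, 0.70), (1.8, 0.45), (3.06, 0.28)], [80, 200, 500])
        with pytest.warns(UserWarning, match="cluster sizes"):
            model = c.assign_tissues(model)
        assert model.tissue_names == ("WM", "GM", "CSF")

    def test_coincident_centroids_rejected(self):
        model = self._model([(1.0, 0.5), (1.0, 0.5), (3.0, 0.1)], [5, 5, 5])
        with pytest.raises(ValueError, match="degenerate"):
            c.assign_tissues(model)


class TestBackmap:
    def test_noisefree_accuracy_at_least_90pct(self, phantoms, noisefree_maps):
        hits = total = 0
        for region, maps in noisefree_maps.items():
            model = c.segment_tissues(maps, seed=1)
            vol = c.backmap(model)
            coords = model.coords[model.retained]
            idx = tuple(coords.T)
            hits += int((vol.labels[idx] == phantoms[region].labels[idx]).sum())
            total += len(coords)
        assert hits / total >= 0.90

    def test_labels_only_inside_roi(self, phantoms, noisefree_maps):
        region = "cervical"
        model = c.segment_tissues(noisefree_maps[region], seed=1)
        vol = c.backmap(model)
        assert np.all(vol.labels[~phantoms[region].roi_mask] == 0)
        assert np.all(vol.labels[phantoms[region].roi_mask] > 0)

    def test_all_excluded_when_threshold_vanishes(self, noisefree_maps):
        from corddti.phantom import EXCLUDED

        model = c.kmeans_partition(noisefree_maps["thoracic"], seed=1)
        model = c.restrict_clusters(model, 1e-12)
        model = c.assign_tissues(model)
        vol = c.backmap(model)
        inside = vol.labels[tuple(model.coords.T)]
        assert (inside == EXCLUDED).mean() > 0.95


class TestParameterRecovery:
    def test_resolvable_tissue_centroids_recover_generator_values(self, phantoms, noisefree_maps):
        """Post-restriction cluster means recover the generator (MD, FA) for
        every tissue that has a substantial pure-voxel population in the
        region: WM in the cervical cord, GM in the lumbar enlargement, CSF
        everywhere (tolerance 0.1 on MD, 0.05 on FA)."""
        cases = [("cervical", "WM"), ("lumbar", "GM"),
                 ("cervical", "CSF"), ("thoracic", "CSF"), ("lumbar", "CSF")]
        for region, tissue in cases:
            ph = phantoms[region]
            model = c.segment_tissues(noisefree_maps[region], seed=1)
            md, fa, _ = model.tissue_centroids()[tissue]
            assert abs(md - ph.tissues[tissue].md) <= 0.1, (region, tissue)
            assert abs(fa - ph.tissues[tissue].fa) <= 0.05, (region, tissue)
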