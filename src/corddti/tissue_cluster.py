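"""Tissue segmentation by k-means in (MD, FA) feature space.

Cord voxels form a continuum in the FA-versus-MD plane: anisotropic white
matter (high FA, low MD), grey matter (lower FA, low MD) and CSF (near
isotropic, high MD), with partial-volume voxels strung between the pure
modes.  The pipeline is:

1. a 2-D voxel-density histogram over (MD, FA), a diagnostic surface whose
   peaks confirm the expected three clusters;
2. k-means (k = 3) on the raw (MD in 1e-3 mm^2/s, FA) coordinates — both
   axes are order one, so no rescaling is applied by default;
3. a partial-volume restriction that keeps, in each cluster, only voxels
   within 20% of the distance from the cluster's centroid to the nearest
   other centroid, discarding the in-between voxels most affected by
   partial-volume mixing;
4. tissue assignment from centroid geometry (CSF = highest MD; of the rest,
   WM = higher FA) with warnings when cluster sizes are not ordered
   WM >= GM >= CSF as expected anatomically;
5. back-mapping of the retained labels onto the image grid.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .phantom import EXCLUDED, TISSUE_CODES
from .tensorfit import ScalarMaps


@dataclass
class DensitySurface:
    """2-D voxel-count histogram over (MD, FA)."""

    counts: np.ndarray     # (bins_md, bins_fa)
    md_edges: np.ndarray
    fa_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def local_maxima(self) -> list[tuple[int, int]]:
        """Bins strictly larger than all 8 neighbours (nonzero only)."""
        c = np.pad(self.counts, 1)
        peaks = []
        for i in range(1, c.shape[0] - 1):
            for j in range(1, c.shape[1] - 1):
                if c[i, j] <= 0:
                    continue
                nb = c[i - 1 : i + 2, j - 1 : j + 2].copy()
                nb[1, 1] = -1
                if c[i, j] > nb.max():
                    peaks.append((i - 1, j - 1))
        return peaks


@dataclass
class ClusterModel:
    """k-means partition of ROI voxels in (MD, FA) space.

    ``features`` are the (MD, FA) pairs, ``labels`` the cluster index per
    voxel, ``retained`` the post-restriction mask, and ``tissue_names`` the
    per-cluster tissue identity once assigned.
    """

    centroids: np.ndarray                  # (k, 2): (MD, FA)
    labels: np.ndarray                     # (n,)
    features: np.ndarray                   # (n, 2)
    coords: np.ndarray                     # (n, 3)
    shape: tuple[int, int, int]
    retained: np.ndarray                   # (n,) bool
    threshold_frac: float | None = None
    thresholds: np.ndarray | None = None   # (k,) retention radii
    tissue_names: tuple[str, ...] | None = None
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def pre_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    @property
    def retained_counts(self) -> np.ndarray:
        return np.bincount(self.labels[self.retained], minlength=self.k)

    def retention_fraction(self) -> np.ndarray:
        """Per-cluster retained / pre-restriction voxel fraction."""
        pre = self.pre_counts
        return np.where(pre > 0, self.retained_counts / np.maximum(pre, 1), 0.0)

    def tissue_centroids(self) -> dict[str, tuple[float, float, int]]:
        """Mean (MD, FA) of retained voxels per tissue, with voxel count."""
        if self.tissue_names is None:
            raise ValueError("tissues not assigned yet")
        out: dict[str, tuple[float, float, int]] = {}
        for c, name in enumerate(self.tissue_names):
            sel = (self.labels == c) & self.retained
            if sel.any():
                md, fa = self.features[sel].mean(axis=0)
                out[name] = (float(md), float(fa), int(sel.sum()))
        return out


@dataclass
class TissueLabelVolume:
    """Per-voxel tissue code on the source grid.

    Codes: 0 background, 1 WM, 2 GM, 3 CSF, 4 excluded-by-restriction.
    """

    labels: np.ndarray  # (nx, ny, nz) uint8
    voxel_size: tuple[float, float, float] | None = None


def build_density_surface(maps: ScalarMaps, bins: int = 50) -> DensitySurface:
    """Histogram the ROI voxels over [0, max MD] x [0, 1]."""
    if bins <= 0:
        raise ValueError("bins must be positive")
    if len(maps) == 0:
        raise ValueError("no voxels to histogram")
    md_max = max(float(maps.md.max()), 1e-12)
    counts, md_edges, fa_edges = np.histogram2d(
        maps.md, maps.fa, bins=bins, range=[[0.0, md_max], [0.0, 1.0]]
    )
    return DensitySurface(counts=counts, md_edges=md_edges, fa_edges=fa_edges)


def kmeans_partition(maps: ScalarMaps, k: int = 3, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Partition ROI voxels into k clusters in (MD, FA) space.

    Lloyd's algorithm with k-means++ initialization and ``n_init`` restarts,
    keeping the best inertia; deterministic given ``seed``.
    """
    features = np.column_stack([maps.md, maps.fa])
    if len(features) < k:
        raise ValueError("fewer voxels than clusters")
    if len(np.unique(features, axis=0)) < k:
        raise ValueError("fewer distinct points than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(features)
    return ClusterModel(
        centroids=km.cluster_centers_.copy(),
        labels=labels,
        features=features,
        coords=maps.coords,
        shape=maps.shape,
        retained=np.ones(len(features), dtype=bool),
        seed=seed,
    )


def restrict_clusters(model: ClusterModel, threshold_frac: float = 0.2) -> ClusterModel:
    """Apply the partial-volume restriction.

    For each cluster c the retention radius is ``threshold_frac`` times the
    distance from centroid c to its nearest other centroid; a voxel is
    retained iff it lies within its own cluster's radius.  Voxels between
    centroids — those most affected by partial-volume mixing — are excluded.
    """
    if threshold_frac <= 0:
        raise ValueError("threshold_frac must be positive")
    pairwise = np.linalg.norm(model.centroids[:, None] - model.centroids[None, :], axis=-1)
    np.fill_diagonal(pairwise, np.inf)
    thresholds = threshold_frac * pairwise.min(axis=1)
    dist_own = np.linalg.norm(model.features - model.centroids[model.labels], axis=1)
    retained = dist_own <= thresholds[model.labels]
    return dataclasses.replace(
        model,
        retained=retained,
        threshold_frac=threshold_frac,
        thresholds=thresholds,
    )


def assign_tissues(model: ClusterModel) -> ClusterModel:
    """Assign WM / GM / CSF identities to the three clusters.

    CSF is the cluster with the highest centroid MD; of the remaining two,
    WM is the one with higher centroid FA and GM the other.  Anatomically WM
    should also be the largest cluster and CSF the smallest (within a
    whole-cord ROI); violations of that ordering are warned about, not
    treated as errors, since the MD/FA geometry alone is unambiguous.
    """
    if model.k != 3:
        raise ValueError("tissue assignment requires k = 3")
    cent = model.centroids
    for i in range(3):
        for j in range(i + 1, 3):
            if np.allclose(cent[i], cent[j]):
                raise ValueError("degenerate clustering: coincident centroids")
    order = np.argsort(cent[:, 0])  # by MD ascending
    csf = int(order[-1])
    rest = [int(order[0]), int(order[1])]
    wm = rest[int(np.argmax(cent[rest, 1]))]
    gm = rest[0] if wm == rest[1] else rest[1]
    names = [""] * 3
    names[wm], names[gm], names[csf] = "WM", "GM", "CSF"

    counts = model.pre_counts
    if not (counts[wm] >= counts[gm] >= counts[csf]):
        warnings.warn(
            "cluster sizes not ordered WM >= GM >= CSF "
            f"(WM={counts[wm]}, GM={counts[gm]}, CSF={counts[csf]}); "
            "tissue identities were assigned from centroid MD/FA geometry",
            stacklevel=2,
        )
    return dataclasses.replace(model, tissue_names=tuple(names))


def backmap(model: ClusterModel, maps: ScalarMaps | None = None) -> TissueLabelVolume:
    """Map cluster tissue labels back onto the image grid.

    Retained voxels carry their tissue code; voxels excluded by the
    restriction are coded separately; everything outside the ROI is
    background.
    """
    if model.tissue_names is None:
        raise ValueError("assign tissues before back-mapping")
    coords = model.coords if maps is None else maps.coords
    vol = np.zeros(model.shape, dtype=np.uint8)
    codes = np.array([TISSUE_CODES[name] for name in model.tissue_names], dtype=np.uint8)
    idx = tuple(coords.T)
    vol[idx] = np.where(model.retained, codes[model.labels], EXCLUDED)
    return TissueLabelVolume(labels=vol)


def segment_tissues(
    maps: ScalarMaps,
    seed: int = 0,
    threshold_frac: float = 0.2,
    n_init: int = 10,
) -> ClusterModel:
    """Full feature-space segmentation: cluster, restrict, assign."""
    model = kmeans_partition(maps, k=3, seed=seed, n_init=n_init)
    model = restrict_clusters(model, threshold_frac=threshold_frac)
    return assign_tissues(model)
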