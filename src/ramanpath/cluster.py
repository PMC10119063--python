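"""Ward hierarchical clustering of map spectra and false-color HCA maps.

Agglomerative clustering with Ward's minimum-variance criterion segments a
hyperspectral map into spectroscopically distinct regions (7 clusters for
Raman tissue maps, 5 for the FTIR preset).  The cluster covering the cell
nuclei is identified by its pronounced nucleic-acid bands and feeds the
downstream PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core import HyperMap, Spectrum

__all__ = [
    "HCAResult",
    "hca",
    "cluster_mean_spectra",
    "render_hca_map",
    "DEFAULT_HCA_PALETTE",
]

#: Default 7-color palette for HCA maps (RGB, 0-255).
DEFAULT_HCA_PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 25, 75),
    (60, 180, 75),
    (0, 130, 200),
    (245, 130, 48),
    (145, 30, 180),
    (255, 225, 25),
    (70, 240, 240),
    (240, 50, 230),
    (128, 128, 128),
)


@dataclass
class HCAResult:
    """Ward linkage over map pixels, cut at k clusters.

    ``linkage`` is the scipy (n-1, 4) merge table; ``labels`` assigns every
    pixel a cluster id 1..k (shaped like the map); ``cluster_means`` holds
    the mean preprocessed spectrum per cluster, keyed by cluster id.
    """

    linkage: np.ndarray
    labels: np.ndarray
    k: int
    cluster_means: dict[int, Spectrum]


def hca(hmap: HyperMap, k: int = 7) -> HCAResult:
    """Ward's-method HCA of all pixel spectra, cut to exactly k clusters.

    Distances are Euclidean on the (preprocessed) intensities; merge heights
    are nondecreasing by construction of the Ward criterion.  Deterministic
    for a given pixel order.
    """
    X = hmap.as_matrix()
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty map")
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    Z = linkage(X, method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = flat.reshape(hmap.shape)
    means = _means_by_label(hmap, labels)
    return HCAResult(linkage=Z, labels=labels, k=k, cluster_means=means)


def _means_by_label(hmap: HyperMap, labels: np.ndarray) -> dict[int, Spectrum]:
    X = hmap.as_matrix()
    flat = labels.ravel()
    out: dict[int, Spectrum] = {}
    for cid in np.unique(flat):
        mask = flat == cid
        out[int(cid)] = Spectrum(hmap.axis, X[mask].mean(axis=0))
    return out


def cluster_mean_spectra(hmap: HyperMap, labels: np.ndarray) -> dict[int, Spectrum]:
    """Arithmetic mean spectrum of each cluster present in ``labels``.

    Cluster ids absent from the label image are excluded with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != hmap.shape:
        raise ValueError("labels shape must match map shape")
    present = set(int(c) for c in np.unique(labels))
    expected = set(range(1, max(present) + 1)) if present else set()
    missing = expected - present
    if missing:
        warnings.warn(f"clusters {sorted(missing)} are empty and were excluded")
    return _means_by_label(hmap, labels)


def render_hca_map(
    labels: np.ndarray,
    palette: tuple[tuple[int, int, int], ...] | None = None,
) -> np.ndarray:
    """False-color (H, W, 3) uint8 image with one color per cluster id."""
    labels = np.asarray(labels)
    pal = palette if palette is not None else DEFAULT_HCA_PALETTE
    ids = np.unique(labels)
    if len(ids) > len(pal):
        raise ValueError(f"palette has {len(pal)} colors for {len(ids)} clusters")
    img = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for i, cid in enumerate(sorted(int(c) for c in ids)):
        img[labels == cid] = pal[i]
    return img
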