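"""PCA of second-derivative spectra from cell-nuclei pixels.

The HCA segmentation localises the cancer-cell nuclei; the spectra of those
pixels, across tumor groups, are differentiated twice (to suppress baseline)
and decomposed by principal component analysis.  The leading component
separates conventional PDAC from AVAC/IPMC along the nucleic-acid
phosphodiester region (1240-1080 cm^-1) and the CH2/CH3 deformation bands
(1447/1410 cm^-1) that track DNA methylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HyperMap, SpectralAxis, Spectrum
from .prep import second_derivative

__all__ = ["PCAResult", "select_nuclei_spectra", "pca_matrix", "pca_second_derivative"]


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA model.

    Loadings are orthonormal rows; each is oriented so its maximum-magnitude
    element is positive (principal-axis signs are otherwise arbitrary).
    """

    scores: np.ndarray  # (n, c)
    loadings: np.ndarray  # (c, axis length)
    explained_variance_fraction: np.ndarray  # (c,)
    mean: np.ndarray  # feature mean used for centering
    group_labels: np.ndarray | None = None
    axis: SpectralAxis | None = None


def select_nuclei_spectra(
    hmap: HyperMap,
    hca_labels: np.ndarray,
    nuclei_cluster_ids: set[int] | list[int] | tuple[int, ...],
    group_label: int | str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spectra of the pixels belonging to the named HCA clusters.

    Returns ``(spectra, groups)`` where ``groups`` tags every returned
    spectrum with ``group_label`` (or the map's class code layer if None).
    """
    ids = set(int(i) for i in nuclei_cluster_ids)
    if not ids:
        raise ValueError("no nuclei cluster ids given")
    labels = np.asarray(hca_labels)
    if labels.shape != hmap.shape:
        raise ValueError("hca_labels shape must match map shape")
    mask = np.isin(labels, sorted(ids)).ravel()
    if not mask.any():
        raise ValueError(f"no pixels carry cluster ids {sorted(ids)}")
    spectra = hmap.as_matrix()[mask]
    if group_label is not None:
        groups = np.full(mask.sum(), group_label)
    elif hmap.class_labels is not None:
        groups = hmap.class_labels.ravel()[mask]
    else:
        groups = np.full(mask.sum(), -1)
    return spectra, groups


def pca_matrix(X: np.ndarray, n_components: int = 3) -> PCAResult:
    """Mean-centered covariance PCA of an (n, p) matrix via SVD."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} spectra for {n_components} components"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data == eigendecomposition of the covariance.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    k = n_components
    loadings = Vt[:k].copy()
    scores = U[:, :k] * s[:k]
    # Orient each loading so its max-|.| element is positive.
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    frac = var[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=frac,
        mean=mean,
    )


def pca_second_derivative(
    spectra: np.ndarray,
    axis: SpectralAxis,
    n_components: int = 3,
    group_labels: np.ndarray | None = None,
    sg_polyorder: int = 3,
    sg_window: int = 17,
) -> PCAResult:
    """PCA on the SG second derivatives of the given spectra.

    Differentiation (same 17-point, 3rd-order filter as the smoothing step)
    removes baseline influence before the decomposition.
    """
    X = np.asarray(spectra, dtype=float)
    D = np.vstack(
        [
            second_derivative(Spectrum(axis, row), sg_polyorder, sg_window).intensities
            for row in X
        ]
    )
    result = pca_matrix(D, n_components)
    result.group_labels = None if group_labels is None else np.asarray(group_labels)
    result.axis = axis
    return result
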