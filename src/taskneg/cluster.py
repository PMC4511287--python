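"""Monte-Carlo cluster-extent thresholding.

Voxelwise thresholding at a lenient p leaves isolated false positives; the
standard remedy is to keep only clusters larger than a minimum extent
calibrated on null data.  The estimator here follows the classic AlphaSim
recipe: fill the analysis mask with white Gaussian noise, smooth it to the
nominal spatial smoothness, re-standardize, threshold two-tailed at the
voxel p, record the maximum cluster size, and repeat.  The minimum
significant cluster size is the smallest extent whose family-wise
false-positive frequency is at most alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from taskneg.preprocess import smooth_gaussian

__all__ = ["ClusterThresholdResult", "label_clusters", "estimate_min_cluster_size"]


class ClusterError(ValueError):
    pass


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ClusterThresholdResult:
    min_cluster_size: int  # voxels
    voxel_p: float  # two-tailed
    alpha: float  # corrected (family-wise) level
    iterations: int
    null_max_sizes: np.ndarray  # (iterations,) max cluster size per null map
    fwhm_mm: float
    connectivity: int
    seed: int

    def familywise_rate(self, k: int | None = None) -> float:
        """Fraction of null maps with a cluster of at least k voxels."""
        k = self.min_cluster_size if k is None else k
        return float(np.mean(self.null_max_sizes >= k))


def label_clusters(binary: np.ndarray, connectivity: int = 6) -> list[np.ndarray]:
    """Connected components of a 3D binary map under face (6), edge (18) or
    corner (26) adjacency.  Returns one index array (voxels x 3) per
    cluster, largest first."""
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 3:
        raise ClusterError("cluster labeling expects a 3D map")
    if connectivity not in _STRUCTURES:
        raise ClusterError("connectivity must be 6, 18 or 26")
    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    clusters = [np.argwhere(labels == i) for i in range(1, n + 1)]
    clusters.sort(key=len, reverse=True)
    return clusters


def max_cluster_size(binary: np.ndarray, connectivity: int = 6) -> int:
    labels, n = ndimage.label(np.asarray(binary).astype(bool), structure=_STRUCTURES[connectivity])
    if n == 0:
        return 0
    return int(np.max(np.bincount(labels.ravel())[1:]))


def estimate_min_cluster_size(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_size: tuple[float, float, float],
    voxel_p: float = 0.01,
    alpha: float = 0.05,
    iterations: int = 1000,
    seed: int = 0,
    connectivity: int = 6,
) -> ClusterThresholdResult:
    """Monte-Carlo estimate of the minimum significant cluster extent.

    Per iteration: white N(0,1) noise on the mask's bounding grid, Gaussian
    smoothing to ``fwhm_mm``, re-standardization to unit variance inside the
    mask, two-tailed thresholding at ``voxel_p`` (|z| criterion), and the
    maximum in-mask cluster size under the chosen adjacency.  The returned
    size is the smallest k with P(max cluster >= k) <= alpha over the null
    ensemble.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3 or not mask.any():
        raise ClusterError("mask must be a non-empty 3D binary volume")
    if not 0 < voxel_p < 1:
        raise ClusterError("voxel_p must be in (0, 1)")
    if iterations < 100:
        raise ClusterError("need at least 100 iterations")
    if alpha < 1.0 / iterations:
        raise ClusterError(
            f"alpha={alpha} is below 1/iterations={1.0 / iterations:.2g}; "
            "increase iterations"
        )
    rng = np.random.default_rng(seed)
    zthr = stats.norm.ppf(1.0 - voxel_p / 2.0)
    maxima = np.empty(iterations, dtype=int)
    for i in range(iterations):
        noise = rng.standard_normal(mask.shape)
        if fwhm_mm > 0:
            noise = smooth_gaussian(noise, fwhm_mm, voxel_size)
        inm = noise[mask]
        z = (noise - inm.mean()) / inm.std()
        supra = (np.abs(z) > zthr) & mask
        maxima[i] = max_cluster_size(supra, connectivity)
    # smallest k whose family-wise false-positive fraction is <= alpha
    for k in range(1, int(maxima.max()) + 2):
        if np.mean(maxima >= k) <= alpha:
            break
    return ClusterThresholdResult(
        min_cluster_size=int(k),
        voxel_p=voxel_p,
        alpha=alpha,
        iterations=iterations,
        null_max_sizes=maxima,
        fwhm_mm=fwhm_mm,
        connectivity=connectivity,
        seed=seed,
    )


def apply_cluster_threshold(
    tmap: np.ndarray,
    mask: np.ndarray,
    t_thresh: float,
    min_cluster_size: int,
    connectivity: int = 6,
) -> np.ndarray:
    """Binary map of suprathreshold voxels (|t| > t_thresh) surviving the
    cluster-extent criterion."""
    supra = (np.abs(tmap) > t_thresh) & np.asarray(mask).astype(bool)
    out = np.zeros_like(supra)
    for voxels in label_clusters(supra, connectivity):
        if len(voxels) < min_cluster_size:
            break  # clusters sorted largest-first
        out[tuple(voxels.T)] = True
    return out
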