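"""Cluster-quality measures: adjusted Rand index and spherical silhouette.

The adjusted Rand index is the chance-corrected pairwise agreement between
two partitions (1 = identical up to relabelling, 0 expected under random
labelling).  The silhouette coefficient is computed with the geodesic
distance on the unit sphere, d(x, y) = arccos(x'y), so that it measures the
quality of *directional* clusters.  In both measures the noise cluster is
treated as an ordinary label: allocating an observation to noise carries
information about the recovered structure.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import comb

from .io import DirectionalDataset

__all__ = ["adjusted_rand_index", "spherical_silhouette", "noise_cluster_size"]


def _as_codes(labels: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels, dtype=object).astype(str), return_inverse=True)
    return codes


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Adjusted Rand index between two partitions of the same items.

    Computed from the contingency table under the permutation model:

        ARI = (sum_ij C(n_ij,2) - E) / (max - E),

    with E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.
    """
    a = _as_codes(a)
    b = _as_codes(b)
    if a.size != b.size:
        raise ValueError("partitions must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    table = np.zeros((a.max() + 1, b.max() + 1), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all-one-cluster or all-singletons): agreement is total
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def spherical_silhouette(data: DirectionalDataset, labels: Sequence) -> float:
    """Mean silhouette with great-circle (arc length) distances.

    For observation i with mean within-cluster distance a_i and smallest
    mean distance to another cluster b_i, the silhouette is
    (b_i - a_i) / max(a_i, b_i); observations in singleton clusters score 0
    (Rousseeuw's convention).  Requires at least two clusters.
    """
    codes = _as_codes(labels)
    if codes.size != data.n:
        raise ValueError("labels length must match number of observations")
    n_clusters = codes.max() + 1
    if n_clusters < 2:
        raise ValueError("silhouette requires at least two clusters")

    d = np.arccos(np.clip(data.x @ data.x.T, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)  # rounding in x@x.T would otherwise leave ~1e-8 self-distances
    sizes = np.bincount(codes, minlength=n_clusters)
    # sums of distances from each point to each cluster
    cluster_sums = np.zeros((data.n, n_clusters))
    for k in range(n_clusters):
        cluster_sums[:, k] = d[:, codes == k].sum(axis=1)

    s = np.zeros(data.n)
    for i in range(data.n):
        k = codes[i]
        if sizes[k] == 1:
            continue
        a = cluster_sums[i, k] / (sizes[k] - 1)
        others = [cluster_sums[i, c] / sizes[c] for c in range(n_clusters) if c != k and sizes[c] > 0]
        b = min(others)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def noise_cluster_size(labels: Sequence, noise_label: str = "noise") -> int:
    """Number of observations carrying the noise label."""
    return int(sum(1 for l in labels if str(l) == noise_label))
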