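"""Gap-statistic selection of the number of genetic clusters.

Hierarchical (Ward) clustering on an individual-level distance matrix, with
the number of clusters K chosen by the Tibshirani gap statistic: the observed
log pooled within-cluster dispersion is compared with its expectation under
uniform reference data drawn in the bounding box of the classical-MDS
embedding of the observed distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .popgen import DistanceMatrix, mds_embed

__all__ = ["ClusterSelection", "select_k_gap"]

_EPS = 1e-12


@dataclass(frozen=True)
class ClusterSelection:
    """Result of a gap-statistic scan over K.

    ``gap[K] = mean_ref(log Wk_ref) - log Wk_obs``; ``best_k`` is the
    smallest K whose gap lies within one standard error of the maximal gap
    (the "firstSEmax" convention — parsimonious, and robust to the gap
    curve dipping before the true K, which the sequential one-SE stopping
    rule is not).
    """

    best_k: int
    k_values: tuple[int, ...]
    observed_log_wk: tuple[float, ...]
    reference_log_wk: tuple[float, ...]
    gap: tuple[float, ...]
    se: tuple[float, ...]
    labels_by_k: dict[int, tuple[int, ...]]


def _pooled_within_dispersion(d2: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum over clusters of (sum of within-cluster squared distances)/(2 n_r)."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1:
            w += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return w


def _ward_labels(dist: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(squareform(dist, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def select_k_gap(
    d: DistanceMatrix,
    k_min: int = 1,
    k_max: int = 6,
    n_ref: int = 100,
    seed: int = 0,
) -> ClusterSelection:
    """Choose the number of clusters by the gap statistic on ``d``.

    Reference datasets are uniform draws in the axis-aligned bounding box of
    the classical-MDS embedding of ``d`` (full rank), clustered the same way
    (Ward linkage, squared-distance pooled dispersion). Deterministic for a
    given seed. ``k_max`` is truncated (with a warning) when it exceeds the
    number of individuals.
    """
    import logging

    if not (k_max >= k_min >= 1):
        raise ValueError("need k_max >= k_min >= 1")
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    n = d.n
    if k_max > n:
        logging.getLogger(__name__).warning("k_max %d > n individuals %d; truncating", k_max, n)
        k_max = n
    ks = list(range(k_min, k_max + 1))
    dist = np.asarray(d.values, dtype=float)
    d2 = dist**2

    # observed curve
    labels_by_k: dict[int, tuple[int, ...]] = {}
    obs_log_wk = []
    for k in ks:
        labels = np.ones(n, dtype=int) if k == 1 else _ward_labels(dist, k)
        labels_by_k[k] = tuple(int(x) for x in labels)
        obs_log_wk.append(np.log(max(_pooled_within_dispersion(d2, labels), _EPS)))

    # reference curves from uniform draws in the MDS bounding box
    emb = mds_embed(d, dims=max(n - 1, 1)).to_numpy()
    lo, hi = emb.min(axis=0), emb.max(axis=0)
    rng = np.random.default_rng(seed)
    ref_log_wk = np.empty((n_ref, len(ks)))
    for b in range(n_ref):
        pts = rng.uniform(lo, hi, size=emb.shape)
        rdist = squareform(pdist(pts))
        rd2 = rdist**2
        for ki, k in enumerate(ks):
            labels = np.ones(n, dtype=int) if k == 1 else _ward_labels(rdist, k)
            ref_log_wk[b, ki] = np.log(max(_pooled_within_dispersion(rd2, labels), _EPS))

    mean_ref = ref_log_wk.mean(axis=0)
    sd_ref = ref_log_wk.std(axis=0, ddof=0)
    se = sd_ref * np.sqrt(1.0 + 1.0 / n_ref)
    gap = mean_ref - np.asarray(obs_log_wk)

    i_max = int(np.argmax(gap))
    best_k = ks[-1]
    for i in range(len(ks)):
        if gap[i] >= gap[i_max] - se[i_max]:
            best_k = ks[i]
            break
    return ClusterSelection(
        best_k=int(best_k),
        k_values=tuple(ks),
        observed_log_wk=tuple(float(x) for x in obs_log_wk),
        reference_log_wk=tuple(float(x) for x in mean_ref),
        gap=tuple(float(x) for x in gap),
        se=tuple(float(x) for x in se),
        labels_by_k=labels_by_k,
    )
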