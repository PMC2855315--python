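"""Outlier removal: reject measurements that fail to cluster with their odorant.

Repeated measurements of one odorant should form a tight cluster in the
normalized 120-feature space; instrument instability occasionally produces a
signature that lands nearer another odorant's cluster.  The default criterion
is held-out nearest-centroid assignment: each sample is assigned to the
nearest class centroid, its own class's centroid computed with the sample
held out, and it is kept iff it is assigned to its own odorant.  A k-means
variant (k = number of odorants, clusters mapped to their plurality class)
is available behind ``method='kmeans'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FULLY_NORMALIZED, FeatureMatrix


@dataclass
class QCResult:
    """Outcome of the clustering QC."""

    keep_mask: np.ndarray  # bool per sample
    assigned: list[str]  # assigned class per sample
    cluster_accuracy: float  # fraction assigned to their own class
    flags: dict[int, str] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return int((~self.keep_mask).sum())


def cluster_qc(
    matrix: FeatureMatrix,
    labels: list[str] | None = None,
    method: str = "centroid",
    seed: int = 0,
) -> QCResult:
    """Assess how well each signature clusters with its own odorant class.

    Requires a fully normalized matrix and at least two classes.  Samples
    from singleton classes are kept automatically (their held-out own-class
    centroid is undefined) and flagged.
    """
    if matrix.state != FULLY_NORMALIZED:
        raise ValueError("cluster_qc requires a fully normalized matrix")
    labels = list(labels) if labels is not None else list(matrix.odorant_ids)
    if len(labels) != matrix.n_samples:
        raise ValueError("labels length does not match matrix rows")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("cluster QC needs at least 2 classes")
    if method == "centroid":
        return _centroid_qc(matrix.values, labels, classes)
    if method == "kmeans":
        return _kmeans_qc(matrix.values, labels, classes, seed)
    raise ValueError(f"unknown QC method {method!r}")


def _centroid_qc(X: np.ndarray, labels: list[str], classes: list[str]) -> QCResult:
    idx = {c: i for i, c in enumerate(classes)}
    lab = np.array([idx[l] for l in labels])
    sums = np.zeros((len(classes), X.shape[1]))
    counts = np.zeros(len(classes))
    np.add.at(sums, lab, X)
    np.add.at(counts, lab, 1.0)

    keep = np.ones(len(labels), dtype=bool)
    assigned: list[str] = []
    flags: dict[int, str] = {}
    for i in range(len(labels)):
        own = lab[i]
        if counts[own] < 2:
            assigned.append(classes[own])
            flags[i] = "singleton_class_kept"
            continue
        centroids = sums / counts[:, None]
        centroids[own] = (sums[own] - X[i]) / (counts[own] - 1.0)
        dists = np.linalg.norm(centroids - X[i], axis=1)
        best = int(np.argmin(dists))
        assigned.append(classes[best])
        keep[i] = best == own
    accuracy = float(np.mean([a == l for a, l in zip(assigned, labels)]))
    return QCResult(keep_mask=keep, assigned=assigned,
                    cluster_accuracy=accuracy, flags=flags)


def _kmeans_qc(
    X: np.ndarray, labels: list[str], classes: list[str], seed: int
) -> QCResult:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=len(classes), n_init=10, random_state=seed)
    cluster_of = km.fit_predict(X)
    # map each cluster to the plurality class among its members
    majority: dict[int, str] = {}
    for c in np.unique(cluster_of):
        members = [labels[i] for i in np.flatnonzero(cluster_of == c)]
        majority[int(c)] = max(set(members), key=members.count)
    assigned = [majority[int(c)] for c in cluster_of]
    keep = np.array([a == l for a, l in zip(assigned, labels)])
    return QCResult(keep_mask=keep, assigned=assigned,
                    cluster_accuracy=float(keep.mean()))


def apply_mask(matrix: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    """Retain the rows where ``mask`` is true, preserving order and ids."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (matrix.n_samples,):
        raise ValueError("mask length does not match matrix rows")
    if not mask.any():
        raise ValueError("no samples retained")
    return matrix.subset(np.flatnonzero(mask))
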