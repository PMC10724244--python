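"""Companion validity metrics for comparing candidate labellings.

Alongside H+ (internal, rank-based), this module provides the standard
metrics practitioners put next to it: mean silhouette width and
within-cluster sum of squares (internal), and the Adjusted Rand Index
(external, needs ground truth).  :func:`k_sweep_report` tabulates all of
them over a family of candidate labellings (e.g. cuts of a dendrogram at
k = 2..10) so the "peak of 1 - H+ at the true k" diagnostic can be read off
directly.

ARI and silhouette are small, standard formulas implemented here directly
(keeping the package's runtime dependency surface minimal); the test suite
cross-checks them against scikit-learn.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DissimilarityMatrix, PartitionLabels, discordance
from .exceptions import DegeneratePartitionError, InputError

__all__ = [
    "adjusted_rand_index",
    "mean_silhouette",
    "wcss",
    "k_sweep_report",
]


def _contingency(truth: PartitionLabels, predicted: PartitionLabels) -> np.ndarray:
    if truth.n != predicted.n:
        raise InputError(
            f"label vectors differ in length: {truth.n} vs {predicted.n}"
        )
    table = np.zeros((truth.k, predicted.k), dtype=np.int64)
    np.add.at(table, (truth.codes, predicted.codes), 1)
    return table


def adjusted_rand_index(truth, predicted) -> float:
    """Pair-counting Adjusted Rand Index between two partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2) and
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.  1 for identical
    partitions, ~0 for independent ones, negative for worse-than-chance.
    """
    truth = PartitionLabels.coerce(truth)
    predicted = PartitionLabels.coerce(predicted)
    table = _contingency(truth, predicted)
    n = truth.n

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-in-one / all-singleton)
        return 1.0 if np.array_equal(truth.codes, predicted.codes) else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def mean_silhouette(D: DissimilarityMatrix, labels) -> float:
    """Mean silhouette width s_i = (b_i - a_i) / max(a_i, b_i) over observations.

    a_i is the mean dissimilarity to the observation's own cluster (excluding
    itself), b_i the smallest mean dissimilarity to any other cluster.
    Singleton-cluster observations get s_i = 0 by convention.
    """
    labels = PartitionLabels.coerce(labels)
    if labels.n != D.n:
        raise InputError(
            f"label vector length {labels.n} does not match matrix size {D.n}"
        )
    if labels.k < 2:
        raise DegeneratePartitionError("silhouette needs k >= 2 clusters")
    V = D.values
    # mean distance from every observation to every cluster
    sums = np.zeros((D.n, labels.k))
    for j in range(labels.k):
        sums[:, j] = V[:, labels.codes == j].sum(axis=1)
    counts = labels.counts
    own = labels.codes
    sil = np.zeros(D.n)
    for i in range(D.n):
        c = own[i]
        if counts[c] == 1:
            continue  # singleton: 0
        a = sums[i, c] / (counts[c] - 1)
        other = [sums[i, j] / counts[j] for j in range(labels.k) if j != c]
        b = min(other)
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def wcss(D: DissimilarityMatrix, labels) -> float:
    """Within-cluster sum of squares from pairwise dissimilarities.

    Uses the centroid identity sum_i ||x_i - c||^2 = (1/n_j) sum_{i<i'} d_ii'^2,
    exact for Euclidean dissimilarities and a scale-dependent dispersion
    analogue for the others.
    """
    labels = PartitionLabels.coerce(labels)
    if labels.n != D.n:
        raise InputError(
            f"label vector length {labels.n} does not match matrix size {D.n}"
        )
    total = 0.0
    sq = D.values**2
    for j in range(labels.k):
        members = np.flatnonzero(labels.codes == j)
        if members.size < 2:
            continue
        block = sq[np.ix_(members, members)]
        total += block.sum() / (2.0 * members.size)  # full block double-counts
    return float(total)


def k_sweep_report(
    D: DissimilarityMatrix,
    label_sets: dict,
    truth=None,
) -> pd.DataFrame:
    """Validity report across candidate labellings, one row per entry.

    ``label_sets`` maps an identifier (typically k) to a label vector.
    Columns: k, h_plus, one_minus_h_plus, mean_silhouette, wcss and — when
    ``truth`` is supplied — ari.  A labelling on which H+ or silhouette is
    degenerate yields NaN in those columns plus an ``error`` note instead of
    aborting the sweep.
    """
    if len(label_sets) < 1:
        raise InputError("need at least one candidate label set")
    if truth is not None:
        truth = PartitionLabels.coerce(truth)
    rows = []
    for name, raw in label_sets.items():
        labels = PartitionLabels.coerce(raw)
        row = {"labels": name, "k": labels.k, "error": ""}
        try:
            res = discordance(D, labels)
            row["h_plus"] = res.h_plus
            row["one_minus_h_plus"] = 1.0 - res.h_plus
        except DegeneratePartitionError as err:
            row["h_plus"] = row["one_minus_h_plus"] = np.nan
            row["error"] = str(err)
        try:
            row["mean_silhouette"] = mean_silhouette(D, labels)
        except DegeneratePartitionError as err:
            row["mean_silhouette"] = np.nan
            row["error"] = row["error"] or str(err)
        row["wcss"] = wcss(D, labels)
        if truth is not None:
            row["ari"] = adjusted_rand_index(truth, labels)
        rows.append(row)
    return pd.DataFrame(rows)
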