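"""Exact discordance statistics: s, G+, H+ and the within-distance fraction alpha.

Given a symmetric dissimilarity matrix ``D`` over ``n`` observations and a
cluster labelling ``L``, every one of the ``N_d = n(n-1)/2`` unique pairwise
dissimilarities is either *within*-cluster (both endpoints share a label) or
*between*-cluster.  The raw discordance count

    s = #{ (w, b) in D_W x D_B : w > b }

counts how often a within-cluster distance strictly exceeds a between-cluster
one.  Two normalisations of ``s`` are provided:

* ``G+ = s / (N_d (N_d - 1) / 2)`` — the classical discordance index.  Its
  expectation is ``~ 2 alpha (1 - alpha) P(w > b)`` where
  ``alpha = |D_W| / N_d``, so it depends on group balance even for a fixed
  data-generating process.
* ``H+ = s / (|D_W| |D_B|)`` — an unbiased estimator of ``P(w > b)``, the
  probability that a within distance exceeds a between distance.  It is a
  normalised Mann-Whitney statistic between the two distance sets and does
  not depend on alpha.

Values near 0 mean concordant (tight, separated) clusters; values near 1 mean
the labelling is anti-correlated with the dissimilarity structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform

from .exceptions import DegeneratePartitionError, InputError

__all__ = [
    "DissimilarityMatrix",
    "PartitionLabels",
    "DistanceSplit",
    "DiscordanceResult",
    "split_distances",
    "count_s",
    "count_s_brute_force",
    "g_plus",
    "h_plus",
    "discordance",
    "alpha_from_balance",
    "expected_g_plus",
    "penalized_h_plus",
]

#: relative tolerance for accepting (and averaging away) asymmetry on ingestion
SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric n x n dissimilarity matrix with a zero diagonal.

    Only the upper triangle is semantically meaningful; construction
    symmetrises small numerical asymmetry and zeroes the diagonal, rejecting
    anything beyond tolerance.
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError(f"dissimilarity matrix must be square, got shape {v.shape}")
        n = v.shape[0]
        if n < 2:
            raise InputError(f"need at least 2 observations, got n={n}")
        if not np.all(np.isfinite(v)):
            raise InputError("dissimilarity matrix contains non-finite entries")
        scale = max(float(np.abs(v).max()), 1.0)
        if not np.allclose(v, v.T, rtol=SYMMETRY_RTOL, atol=SYMMETRY_RTOL * scale):
            raise InputError("matrix is asymmetric beyond tolerance")
        if np.abs(np.diag(v)).max() > SYMMETRY_RTOL * scale:
            raise InputError("diagonal entries must be zero")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_distances(self) -> int:
        """N_d = n(n-1)/2, the number of unique observation pairs."""
        n = self.n
        return n * (n - 1) // 2

    def condensed(self) -> np.ndarray:
        """Upper triangle in row-major i<j order (scipy condensed form)."""
        return squareform(self.values, checks=False)

    @classmethod
    def from_condensed(cls, vec: Sequence[float]) -> "DissimilarityMatrix":
        """Build from an upper-triangle vector of length n(n-1)/2."""
        vec = np.asarray(vec, dtype=float).ravel()
        m = vec.size
        n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        if n * (n - 1) // 2 != m:
            raise InputError(
                f"condensed vector length {m} is not a triangular number n(n-1)/2"
            )
        return cls(squareform(vec, checks=False))


class PartitionLabels:
    """Cluster assignment per observation.

    Labels are arbitrary hashable values; ``codes`` are their 0..k-1 integer
    encoding (first-appearance order), ``counts`` the per-cluster sizes and
    ``balance`` the per-cluster proportions b_j = counts_j / n.
    """

    def __init__(self, labels: Sequence):
        labels = list(labels)
        if len(labels) == 0:
            raise InputError("empty label vector")
        self.labels = labels
        uniq, codes = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
        # reorder clusters by first appearance for stable, input-driven output
        order = np.argsort([codes.tolist().index(c) for c in range(len(uniq))])
        rank = np.empty(len(uniq), dtype=int)
        rank[order] = np.arange(len(uniq))
        self.codes = rank[codes]
        self.classes = [uniq[i] for i in order]
        self.counts = np.bincount(self.codes, minlength=len(uniq))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def balance(self) -> np.ndarray:
        return self.counts / self.n

    @classmethod
    def coerce(cls, labels) -> "PartitionLabels":
        return labels if isinstance(labels, cls) else cls(labels)


@dataclass(frozen=True)
class DistanceSplit:
    """The within/between partition of the condensed distance vector."""

    within: np.ndarray
    between: np.ndarray

    @property
    def n_within(self) -> int:
        return self.within.size

    @property
    def n_between(self) -> int:
        return self.between.size

    @property
    def n_distances(self) -> int:
        return self.within.size + self.between.size

    @property
    def alpha(self) -> float:
        """Fraction of all pairwise distances that are within-cluster."""
        return self.n_within / self.n_distances


@dataclass(frozen=True)
class DiscordanceResult:
    s: int
    g_plus: float
    h_plus: float
    alpha: float
    n_within: int
    n_between: int
    n_distances: int
    ties: int = 0

    def to_dict(self) -> dict:
        return {
            "s": self.s,
            "g_plus": self.g_plus,
            "h_plus": self.h_plus,
            "alpha": self.alpha,
            "n_within": self.n_within,
            "n_between": self.n_between,
            "n_distances": self.n_distances,
            "ties": self.ties,
        }


def _adjacency_condensed(labels: PartitionLabels) -> np.ndarray:
    codes = labels.codes
    iu, ju = np.triu_indices(labels.n, k=1)
    return codes[iu] == codes[ju]


def split_distances(D: DissimilarityMatrix, labels) -> DistanceSplit:
    """Partition D's upper triangle into within- and between-cluster sets."""
    labels = PartitionLabels.coerce(labels)
    if labels.n != D.n:
        raise InputError(
            f"label vector length {labels.n} does not match matrix size {D.n}"
        )
    d = D.condensed()
    same = _adjacency_condensed(labels)
    return DistanceSplit(within=d[same], between=d[~same])


def count_s(within, between, *, return_ties: bool = False):
    """Number of (w, b) cross pairs with w strictly greater than b.

    Sorts the between set once and locates each within value by binary
    search: O((|D_W| + |D_B|) log |D_B|) instead of the quadratic double
    loop.  Ties (w == b) contribute zero; their count is available as a
    diagnostic for heavily tied (e.g. binary-metric) inputs.
    """
    w = np.asarray(within, dtype=float).ravel()
    b = np.sort(np.asarray(between, dtype=float).ravel())
    if w.size == 0 or b.size == 0:
        return (0, 0) if return_ties else 0
    lo = np.searchsorted(b, w, side="left")  # strictly smaller between values
    s = int(lo.sum())
    if return_ties:
        hi = np.searchsorted(b, w, side="right")
        return s, int((hi - lo).sum())
    return s


def count_s_brute_force(within, between) -> int:
    """Quadratic reference implementation of :func:`count_s` (test oracle)."""
    return int(sum(1 for w in within for b in between if w > b))


def g_plus(s: int, n_distances: int) -> float:
    """G+ = s / (N_d (N_d - 1) / 2)."""
    if n_distances < 2:
        raise InputError(f"G+ needs at least 2 distances, got N_d={n_distances}")
    return s / (n_distances * (n_distances - 1) / 2)


def h_plus(s: int, n_within: int, n_between: int) -> float:
    """H+ = s / (|D_W| |D_B|), the empirical P(within > between)."""
    if n_within == 0:
        raise DegeneratePartitionError(
            "no within-cluster distances (every cluster is a singleton); H+ undefined"
        )
    if n_between == 0:
        raise DegeneratePartitionError(
            "no between-cluster distances (single cluster, k=1); H+ undefined"
        )
    return s / (n_within * n_between)


def discordance(D: DissimilarityMatrix, labels) -> DiscordanceResult:
    """Exact s, G+, H+ and alpha for a dissimilarity matrix and labelling.

    Raises :class:`DegeneratePartitionError` when H+ is undefined (k=1 or
    all-singleton labels); the exception's ``partial`` dict still carries
    s, g_plus and alpha.
    """
    split = split_distances(D, labels)
    s, ties = count_s(split.within, split.between, return_ties=True)
    gp = g_plus(s, split.n_distances)
    try:
        hp = h_plus(s, split.n_within, split.n_between)
    except DegeneratePartitionError as err:
        err.partial = {"s": s, "g_plus": gp, "alpha": split.alpha}
        raise
    return DiscordanceResult(
        s=s,
        g_plus=gp,
        h_plus=hp,
        alpha=split.alpha,
        n_within=split.n_within,
        n_between=split.n_between,
        n_distances=split.n_distances,
        ties=ties,
    )


def alpha_from_balance(n: int, balance) -> float:
    """Within-distance fraction implied by group balance.

    alpha = (1/(n-1)) * sum_j b_j (n b_j - 1); each cluster of size n*b_j
    contributes its n*b_j (n*b_j - 1)/2 internal pairs out of N_d.  Agrees
    exactly with the empirical alpha when n*b_j are the integer cluster
    sizes; fractional n*b_j give the continuous extension of the formula.
    """
    if n < 2:
        raise InputError(f"need n >= 2, got {n}")
    b = np.asarray(balance, dtype=float).ravel()
    if b.size == 0 or np.any(b <= 0):
        raise InputError("balance entries must be positive")
    if abs(b.sum() - 1.0) > 1e-8:
        raise InputError(f"balance must sum to 1, got {b.sum()!r}")
    return float(np.sum(b * (n * b - 1)) / (n - 1))


def expected_g_plus(alpha: float, n_distances: int, p_exceed: float = 0.5) -> float:
    """Expected G+ given alpha and P(within > between).

    E[G+] = (N_d / (N_d - 1)) * 2 alpha (1 - alpha) * P(within > between),
    which makes the balance-dependence of G+ explicit: even at the null
    P = 1/2, E[G+] varies with alpha.
    """
    if n_distances < 2:
        raise InputError(f"need N_d >= 2, got {n_distances}")
    if not (0.0 <= alpha <= 1.0 and 0.0 <= p_exceed <= 1.0):
        raise InputError("alpha and p_exceed must lie in [0, 1]")
    nd = n_distances
    return (nd / (nd - 1)) * 2.0 * alpha * (1.0 - alpha) * p_exceed


def penalized_h_plus(h: float, alpha: float, mode: str = "max") -> float:
    """Experimental degeneracy-penalised H+.

    ``h / max(alpha, 1-alpha)`` penalises dumping observations into one huge
    cluster (alpha -> 1); ``h / min(alpha, 1-alpha)`` penalises shattering
    into many tiny clusters (alpha -> 0).  The min variant can exceed 1.
    """
    if mode not in ("max", "min"):
        raise InputError(f"mode must be 'max' or 'min', got {mode!r}")
    if not 0.0 <= h <= 1.0:
        raise InputError(f"h must lie in [0, 1], got {h}")
    if not 0.0 < alpha < 1.0:
        raise DegeneratePartitionError(
            f"alpha={alpha} admits no cross pairs; penalised H+ undefined"
        )
    denom = max(alpha, 1 - alpha) if mode == "max" else min(alpha, 1 - alpha)
    return h / denom
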