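import numpy as np
import pytest

from hplus import DissimilarityMatrix, PartitionLabels


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hand_example():
    """n=3, labels (A,A,B), d12=1, d13=5, d23=6: within={1}, between={5,6}."""
    D = DissimilarityMatrix(np.array([
        [0.0, 1.0, 5.0],
        [1.0, 0.0, 6.0],
        [5.0, 6.0, 0.0],
    ]))
    return D, PartitionLabels(["A", "A", "B"])


def random_dissimilarity(rng, n):
    """Random symmetric zero-diagonal matrix (not necessarily metric)."""
    M = rng.uniform(0.1, 10.0, size=(n, n))
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 0.0)
    return DissimilarityMatrix(M)


def random_labelled_instance(rng, max_n=25, k_max=4):
    """Small random (D, labels) pair with a non-degenerate partition."""
    n = int(rng.integers(3, max_n + 1))
    while True:
        labels = rng.integers(0, min(k_max, n - 1) + 1, size=n)
        if 2 <= len(np.unique(labels)) and np.any(np.bincount(labels) >= 2):
            # at least one within and one between distance
            counts = np.bincount(labels)
            if counts[counts > 0].max() >= 2:
                break
    return random_dissimilarity(rng, n), PartitionLabels(labels.tolist())


def split_truth_candidates(labels):
    """Candidate labellings at k=2..6 by merging/splitting 3 truth groups.

    Merging the last two groups gives k=2; splitting groups in half (by
    position) gives k=4, 5, 6.  Used for the "1 - H+ peaks at the true k"
    diagnostic.
    """
    base = np.asarray(PartitionLabels.coerce(labels).codes)
    k3 = base.copy()
    k2 = np.where(base == 2, 1, base)
    out = {2: k2, 3: k3}
    current = k3.copy()
    next_code = 3
    for g in range(3):
        members = np.flatnonzero(base == g)
        half = members[: members.size // 2]
        current = current.copy()
        current[half] = next_code
        next_code += 1
        out[3 + g + 1] = current
    return {k: v.tolist() for k, v in out.items()}
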