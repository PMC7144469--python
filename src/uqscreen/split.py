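"""Fold assignment: random k-fold CV and balanced agglomerative clustering.

Random CV shuffles compounds into k near-equal folds.  The BAC split instead
clusters compounds by structural similarity (average-linkage agglomerative
clustering on 1 − Tanimoto distance) and packs whole clusters onto folds, so
test compounds are structurally dissimilar from the training set.  Random CV
therefore measures memorization-friendly interpolation while BAC probes
extrapolation to novel chemotypes — the mechanism that makes BAC estimates
pessimistic relative to random CV.

BAC procedure: the average-linkage dendrogram is decomposed into subtrees by
recursive capacity splitting — any subtree larger than the fold capacity
ceil(n/k) is replaced by its two children, so clusters are split only when
they cannot fit a fold and well-separated clusters stay whole.  The
resulting chunks are packed largest-first onto the currently smallest fold,
ties to the lowest fold index; a final fix-up guarantees no empty fold for
n ≥ k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .featurize import FingerprintMatrix, tanimoto_matrix

__all__ = ["SplitAssignment", "random_cv_folds", "bac_folds"]


@dataclass
class SplitAssignment:
    compound_ids: list[str]
    fold: np.ndarray  # int fold index per compound, in [0, k)
    k: int
    method: str  # "random_cv" | "bac"
    seed: int

    def __post_init__(self):
        self.fold = np.asarray(self.fold, dtype=np.int64)
        if self.fold.shape != (len(self.compound_ids),):
            raise ValueError("one fold index per compound required")
        if self.fold.min(initial=0) < 0 or (len(self.fold) and self.fold.max() >= self.k):
            raise ValueError("fold indices must lie in [0, k)")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold != fold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"compound_id": self.compound_ids, "fold": self.fold})


def random_cv_folds(
    compound_ids: list[str] | int, k: int, seed: int
) -> SplitAssignment:
    """Shuffle n compounds into k folds whose sizes differ by at most 1."""
    if isinstance(compound_ids, int):
        compound_ids = [f"CPD{i:06d}" for i in range(compound_ids)]
    n = len(compound_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} compounds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold = np.empty(n, dtype=np.int64)
    fold[perm] = np.arange(n) % k
    return SplitAssignment(list(compound_ids), fold, k, "random_cv", seed)


def _cap_chunks(bits: np.ndarray, cap: int) -> list[np.ndarray]:
    """Average-linkage dendrogram subtrees, recursively split to size ≤ cap.

    Splitting a subtree into its two children is the minimal way to break an
    oversized cluster, so structurally coherent clusters are preserved
    whenever they fit a fold.
    """
    dist = 1.0 - tanimoto_matrix(bits)
    np.fill_diagonal(dist, 0.0)
    # squareform requires exact symmetry; Tanimoto is symmetric up to fp error
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    chunks: list[np.ndarray] = []
    stack = [to_tree(Z)]
    while stack:
        node = stack.pop()
        if node.get_count() > cap:
            stack.append(node.get_right())
            stack.append(node.get_left())
        else:
            chunks.append(np.array(node.pre_order(lambda leaf: leaf.id), dtype=int))
    return chunks


def bac_folds(fps: FingerprintMatrix, k: int, seed: int) -> SplitAssignment:
    """Balanced agglomerative clustering fold assignment.

    Whole clusters (dendrogram subtrees no larger than ceil(n/k)) are packed
    greedily, largest first, onto the currently smallest fold; only clusters
    exceeding the capacity are split, and then into their dendrogram
    children.  Deterministic given the fingerprint matrix; the seed is
    recorded in the assignment for provenance.
    """
    n = len(fps)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} compounds")

    cap = -(-n // k)  # ceil(n/k)
    chunks = _cap_chunks(fps.bits, cap)

    # largest-first onto the currently smallest fold; ties → lowest index
    order = sorted(range(len(chunks)), key=lambda i: (-chunks[i].size, i))
    fold = np.empty(n, dtype=np.int64)
    fold_sizes = np.zeros(k, dtype=np.int64)
    for i in order:
        target = int(np.argmin(fold_sizes))
        fold[chunks[i]] = target
        fold_sizes[target] += chunks[i].size

    # last-resort fix-up: whole-cluster packing can leave a fold empty
    while (fold_sizes == 0).any():
        empty = int(np.argmin(fold_sizes))
        donor = int(np.argmax(fold_sizes))
        movable = np.flatnonzero(fold == donor)
        fold[movable[-1]] = empty
        fold_sizes[donor] -= 1
        fold_sizes[empty] += 1

    return SplitAssignment(list(fps.compound_ids), fold, k, "bac", seed)
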