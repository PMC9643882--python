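"""Kennard-Stone sample selection and the per-group one-third hold-out.

The Kennard-Stone algorithm picks samples by max-min Euclidean distance; it
is run within each group on the raw (unpreprocessed) absorbance, and the
selected samples form the prediction (test) set.  Because the selection is
deterministic, the split is identical across preprocessing methods and
variable subsets — the whole model comparison shares one partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .synth import SpectraSet


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row indices covering all samples."""

    train_idx: np.ndarray
    test_idx: np.ndarray


def kennard_stone(X: np.ndarray, k: int) -> list[int]:
    """Ordered Kennard-Stone selection of ``k`` rows of ``X``.

    Starts from the pair at maximum Euclidean distance, then repeatedly adds
    the point maximizing the minimum distance to the selected set.  Ties are
    broken by lowest index; duplicate rows are permitted.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("Kennard-Stone requires k >= 2")
    if k > n:
        raise ValueError(f"cannot select {k} of {n} samples")

    D = cdist(X, X)
    # initial pair: max distance, lexicographically smallest on ties
    flat = np.argmax(D)
    best = D.flat[flat]
    ii, jj = np.where(D == best)
    pairs = sorted((min(a, b), max(a, b)) for a, b in zip(ii, jj) if a != b)
    if not pairs:  # all rows identical
        selected = [0, 1]
    else:
        selected = list(pairs[0])

    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    while len(selected) < k:
        cand = np.where(mask)[0]
        nxt = cand[np.argmax(min_dist[cand])]
        selected.append(int(nxt))
        mask[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def kennard_stone_split(
    X: np.ndarray,
    groups: np.ndarray,
    test_fraction: float = 1 / 3,
) -> SplitIndices:
    """Per-group Kennard-Stone hold-out: within each group, KS selects
    ``round(group size * test_fraction)`` samples as the test set.

    ``groups`` is any per-sample grouping vector (class labels for the
    identification task, adulteration levels for the quantification tasks).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    test: list[int] = []
    for g in _stable_unique(groups):
        idx = np.where(groups == g)[0]
        if idx.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        k = int(round(idx.size * test_fraction))
        k = max(2, k)
        picked = kennard_stone(X[idx], k)
        test.extend(int(idx[i]) for i in picked)
    test_idx = np.array(sorted(test), dtype=int)
    train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
    return SplitIndices(train_idx=train_idx, test_idx=test_idx)


def stratified_ks_split(spectra: SpectraSet, test_fraction: float = 1 / 3) -> SplitIndices:
    """The identification split: one third of each class, chosen by
    Kennard-Stone on the raw absorbance, held out as the prediction set."""
    return kennard_stone_split(spectra.absorbance, spectra.class_labels, test_fraction)


def _stable_unique(values: np.ndarray) -> list:
    seen: list = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen
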