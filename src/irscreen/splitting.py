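"""Kennard-Stone representative sample selection and the 70/15/15 split.

Kennard-Stone is the deterministic max-min-distance algorithm chemometrics
uses to carve representative calibration subsets: the first two picks are
the most distant pair; every later pick maximizes its minimum Euclidean
distance to the already-selected set.  The training set takes the first
(most representative) ranks so that it spans the data cloud; validation and
test follow in rank order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .spectra import SpectralDataset


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/validation/test index sets over samples."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if np.unique(all_idx).size != all_idx.size:
            raise ValueError("split subsets are not disjoint")

    @property
    def n_total(self) -> int:
        return self.train_idx.size + self.val_idx.size + self.test_idx.size


def kennard_stone(X: np.ndarray, n_select: int) -> list[int]:
    """Ordered Kennard-Stone ranking of ``n_select`` rows of ``X``.

    The first two indices are the pair at maximal Euclidean distance; each
    subsequent index maximizes the minimum distance to all already-selected
    rows.  Deterministic; ties break toward the lowest index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_select < 2:
        raise ValueError(f"n_select must be >= 2, got {n_select}")
    if n_select > n:
        raise ValueError(f"n_select={n_select} exceeds n_samples={n}")
    D = cdist(X, X)
    # max-distance pair; np.argmax scans row-major, so the first maximal
    # entry already realises the (lowest-i, then lowest-j) tie-break
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_select:
        masked = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(masked))  # argmax returns the first (lowest) index on ties
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def split_sizes(n: int, f_train: float = 0.70, f_val: float = 0.15, f_test: float = 0.15):
    """(n_train, n_val, n_test): val/test rounded to nearest, remainder to train."""
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_val = int(np.floor(f_val * n + 0.5))
    n_test = int(np.floor(f_test * n + 0.5))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"degenerate split sizes for n={n}: "
                         f"({n_train}, {n_val}, {n_test})")
    return n_train, n_val, n_test


def split_dataset(
    ds: SpectralDataset,
    f_train: float = 0.70,
    f_val: float = 0.15,
    f_test: float = 0.15,
) -> SplitResult:
    """Kennard-Stone 70/15/15 split of an averaged (one row per sample) dataset.

    The KS ranking is computed on the rows as given — pass preprocessed
    spectra.  The first ``n_train`` ranks form the training set, the next
    ``n_val`` the validation set, the remainder the test set.
    """
    if not ds.is_averaged:
        raise ValueError("split requires an averaged dataset (one row per sample)")
    n = ds.n_rows
    n_train, n_val, n_test = split_sizes(n, f_train, f_val, f_test)
    order = kennard_stone(ds.absorbance, n)
    order = np.asarray(order)
    return SplitResult(
        train_idx=np.sort(order[:n_train]),
        val_idx=np.sort(order[n_train : n_train + n_val]),
        test_idx=np.sort(order[n_train + n_val :]),
    )
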