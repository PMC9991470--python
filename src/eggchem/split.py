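"""Kennard-Stone maximin selection of representative training samples.

The first two selections are the most distant pair; every later
selection maximizes its minimum Euclidean distance to the already
selected samples.  Deterministic: ties break toward the lowest index.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import CLASS_LABELS
from .preprocess import ProfileTable, exploration_matrix

logger = logging.getLogger(__name__)

#: Above this size the pairwise distance matrix is not materialized.
_DENSE_LIMIT = 2000


def _max_distance_pair(X: np.ndarray) -> tuple[int, int]:
    """Indices (i, j), i < j, of the most distant pair; lexicographically
    smallest pair on ties."""
    n = len(X)
    if n <= _DENSE_LIMIT:
        sq = np.sum(X**2, axis=1)
        D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        np.fill_diagonal(D, -np.inf)
        i, j = np.unravel_index(int(np.argmax(D)), D.shape)
        return (i, j) if i < j else (j, i)
    best = (-np.inf, 0, 1)
    for i in range(n - 1):  # streamed: one row of distances at a time
        d = np.sum((X[i + 1 :] - X[i]) ** 2, axis=1)
        j = int(np.argmax(d))
        if d[j] > best[0]:
            best = (float(d[j]), i, i + 1 + j)
    return best[1], best[2]


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Ordered maximin selection of ``n_select`` row indices of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n = len(X)
    if np.any(np.isnan(X)):
        raise ValueError("X contains NaNs")
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")

    i0, j0 = _max_distance_pair(X)
    selected = [i0, j0]
    in_set = np.zeros(n, dtype=bool)
    in_set[[i0, j0]] = True
    # squared min distance from every sample to the selected set
    min_d = np.minimum(
        np.sum((X - X[i0]) ** 2, axis=1), np.sum((X - X[j0]) ** 2, axis=1)
    )
    while len(selected) < n_select:
        min_d[in_set] = -np.inf
        nxt = int(np.argmax(min_d))  # first occurrence = lowest index on ties
        selected.append(nxt)
        in_set[nxt] = True
        np.minimum(min_d, np.sum((X - X[nxt]) ** 2, axis=1), out=min_d)
    return np.asarray(selected, dtype=int)


@dataclass
class SplitResult:
    """Per-class train/test assignment from Kennard-Stone selection.

    ``train_ids`` preserves selection order.  Index arrays refer to row
    positions in the table the split was computed from.
    """

    train_ids: dict[str, list[str]]
    test_ids: dict[str, list[str]]
    train_indices: np.ndarray
    test_indices: np.ndarray
    metric: str = "euclidean"
    representation: str = "rowwise+autoscale(all)"
    extra: dict = field(default_factory=dict)

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_test(self) -> int:
        return len(self.test_indices)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "representation": self.representation,
            "train_ids": {c: list(v) for c, v in self.train_ids.items()},
            "test_ids": {c: list(v) for c, v in self.test_ids.items()},
            "train_indices": [int(i) for i in self.train_indices],
            "test_indices": [int(i) for i in self.test_indices],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SplitResult":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
            train_indices=np.asarray(d["train_indices"], dtype=int),
            test_indices=np.asarray(d["test_indices"], dtype=int),
            metric=d.get("metric", "euclidean"),
            representation=d.get("representation", ""),
        )


def split_per_class(
    table: ProfileTable,
    n_train_per_class: int | dict,
    X: np.ndarray | None = None,
    representation: str | None = None,
) -> SplitResult:
    """Kennard-Stone selection run separately within each class.

    ``X`` optionally supplies the representation used for distances
    (row-aligned with the table); by default the weight-rescaled,
    all-sample-autoscaled matrix is computed from the table, so raw
    magnitude differences between elements do not dominate.
    """
    if isinstance(n_train_per_class, int):
        n_train_per_class = {c: n_train_per_class for c in CLASS_LABELS}
    if X is None:
        X, _ = exploration_matrix(table)
        representation = representation or "rowwise+autoscale(all)"
    else:
        X = np.asarray(X, dtype=float)
        representation = representation or "caller-supplied"
    if X.shape[0] != table.n_samples:
        raise ValueError("representation matrix must align with table rows")

    train_ids: dict[str, list[str]] = {}
    test_ids: dict[str, list[str]] = {}
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in CLASS_LABELS:
        idx = table.class_indices(label)
        n_train = n_train_per_class.get(label, 0)
        if n_train > len(idx):
            raise ValueError(
                f"class {label!r} has {len(idx)} samples, cannot select "
                f"{n_train} for training"
            )
        order = kennard_stone(X[idx], n_train)
        chosen = idx[order]
        rest = idx[~np.isin(idx, chosen)]
        if len(rest) == 0:
            warnings.warn(
                f"class {label!r}: all samples selected for training; "
                "test set is empty",
                stacklevel=2,
            )
        train_ids[label] = [str(s) for s in table.sample_ids[chosen]]
        test_ids[label] = [str(s) for s in table.sample_ids[rest]]
        train_idx.extend(int(i) for i in chosen)
        test_idx.extend(int(i) for i in rest)
        logger.info(
            "split class %s: %d train / %d test", label, len(chosen), len(rest)
        )
    return SplitResult(
        train_ids=train_ids,
        test_ids=test_ids,
        train_indices=np.asarray(train_idx, dtype=int),
        test_indices=np.asarray(test_idx, dtype=int),
        representation=representation,
    )
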