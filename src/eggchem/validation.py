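"""Model validation: confusion-matrix metrics, Monte Carlo cross
validation (MCCV) and grid search for parameter selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .models import encode_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive class = free-range."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tabulate binary confusion counts.

    Labels may be class names or the +/-1 coding; anything else raises.
    """
    t = encode_labels(y_true)
    p = encode_labels(y_pred)
    if len(t) != len(p):
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == -1))),
        tn=int(np.sum((t == -1) & (p == -1))),
        fp=int(np.sum((t == -1) & (p == 1))),
    )


def _pct(numer: int, denom: int) -> float:
    """Exact percentage rounded to 1 decimal, half up."""
    q = Decimal(100 * numer) / Decimal(denom)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity and accuracy as fractions plus their
    1-decimal percentage presentation (half-up rounding).

    A metric whose defining denominator is empty is ``None`` rather than
    a silent 0/0.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    sensitivity_pct: float | None
    specificity_pct: float | None
    accuracy_pct: float | None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
        }


def metrics(c: ConfusionCounts) -> Metrics:
    """Sens = TP/(TP+FN), Spec = TN/(TN+FP), Accu = (TP+TN)/n."""
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0:
        logger.warning("no positive samples: sensitivity undefined")
    if neg == 0:
        logger.warning("no negative samples: specificity undefined")
    sens = c.tp / pos if pos else None
    spec = c.tn / neg if neg else None
    accu = (c.tp + c.tn) / c.n if c.n else None
    return Metrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=accu,
        sensitivity_pct=_pct(c.tp, pos) if pos else None,
        specificity_pct=_pct(c.tn, neg) if neg else None,
        accuracy_pct=_pct(c.tp + c.tn, c.n) if c.n else None,
    )


# ---------------------------------------------------------------------------
# Monte Carlo cross validation
# ---------------------------------------------------------------------------


def mccv_splits(
    y,
    n_splits: int = 100,
    train_frac: float = 0.7,
    seed=None,
    stratified: bool = True,
    max_retries: int = 100,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/validation index pairs.

    Stratified draws hold the train fraction within each class (validation
    size = floor((1 - train_frac) * n_class) per class), which also
    guarantees both classes appear in every training set.  Unstratified
    draws are redrawn (and logged) if a training set misses a class.
    """
    y = encode_labels(y)
    n = len(y)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    splits = []
    classes = np.unique(y)
    for _ in range(n_splits):
        if stratified:
            val_parts = []
            for c in classes:
                idx = np.flatnonzero(y == c)
                n_val = int(np.floor((1 - train_frac) * len(idx)))
                val_parts.append(rng.choice(idx, size=n_val, replace=False))
            val = np.sort(np.concatenate(val_parts))
        else:
            n_val = int(np.floor((1 - train_frac) * n))
            for attempt in range(max_retries):
                val = np.sort(rng.choice(n, size=n_val, replace=False))
                train_y = y[np.setdiff1d(np.arange(n), val)]
                if set(classes) <= set(train_y):
                    break
                logger.info("redrawing split: a class vanished from training")
            else:
                raise RuntimeError(
                    f"could not draw a split with both classes in training "
                    f"after {max_retries} tries"
                )
        if len(val) == 0:
            raise ValueError("validation set is empty at this train_frac")
        train = np.setdiff1d(np.arange(n), val)
        splits.append((train, val))
    return splits


def mccv_error(
    make_model,
    X,
    y,
    n_splits: int = 100,
    train_frac: float = 0.7,
    seed=None,
    stratified: bool = True,
    splits=None,
    return_per_split: bool = False,
):
    """Pooled misclassification fraction over random train/validation splits.

    ``make_model()`` must return a fresh estimator with ``fit(X, y)`` and
    ``predict(X) -> +/-1`` per call, so any internal scaling is refit
    inside every split (no information leaks from validation samples).
    A pre-built ``splits`` list lets grid searches share one split
    sequence across candidates.
    """
    X = np.asarray(X, dtype=float)
    y = encode_labels(y)
    if splits is None:
        splits = mccv_splits(
            y, n_splits=n_splits, train_frac=train_frac, seed=seed,
            stratified=stratified,
        )
    n_wrong = 0
    n_total = 0
    per_split = []
    for train, val in splits:
        model = make_model()
        model.fit(X[train], y[train])
        pred = np.asarray(model.predict(X[val]))
        wrong = int(np.sum(pred != y[val]))
        n_wrong += wrong
        n_total += len(val)
        per_split.append(wrong / len(val))
    err = n_wrong / n_total
    if return_per_split:
        return err, np.asarray(per_split)
    return err


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass
class MCCVGrid:
    """MCCV error surface over candidate parameters.

    ``candidates`` are parameter dicts in *simplicity order*: on ties the
    earliest minimal candidate is selected (smallest LV count; smallest
    gamma, then largest sigma2).
    """

    candidates: list[dict]
    errors: np.ndarray
    n_splits: int
    train_frac: float
    seed: object
    selected_index: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        if np.any((self.errors < 0) | (self.errors > 1)):
            raise ValueError("error rates must lie in [0, 1]")
        if self.errors[self.selected_index] != self.errors.min():
            raise ValueError("selected candidate must attain the minimum error")

    @property
    def selected_params(self) -> dict:
        return dict(self.candidates[self.selected_index])

    @property
    def min_error(self) -> float:
        return float(self.errors[self.selected_index])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.candidates)
        df["mccv_error"] = self.errors
        df["selected"] = False
        df.loc[self.selected_index, "selected"] = True
        return df

    def to_dict(self) -> dict:
        return {
            "candidates": [dict(c) for c in self.candidates],
            "errors": [float(e) for e in self.errors],
            "n_splits": self.n_splits,
            "train_frac": self.train_frac,
            "seed": self.seed,
            "selected_index": int(self.selected_index),
            "selected_params": self.selected_params,
        }


def default_lv_grid(max_lv: int = 10) -> list[dict]:
    """Latent-variable counts 1..max_lv, simplest first."""
    return [{"n_components": k} for k in range(1, max_lv + 1)]


def default_lssvm_grid(
    sigma2=(10.0, 50.0, 100.0, 300.0, 500.0, 700.0, 1000.0, 3000.0),
    gamma=(0.5, 1.0, 5.0, 10.0, 50.0, 100.0),
) -> list[dict]:
    """(sigma2, gamma) cross product ordered smallest-gamma-first and,
    within a gamma, largest-sigma2-first (the tie-break preference)."""
    return [
        {"sigma2": float(s2), "gamma": float(g)}
        for g in sorted(gamma)
        for s2 in sorted(sigma2, reverse=True)
    ]


def grid_search(
    model_factory,
    X,
    y,
    grid: list[dict],
    n_splits: int = 100,
    train_frac: float = 0.7,
    seed=None,
    stratified: bool = True,
) -> MCCVGrid:
    """Evaluate every candidate with a shared MCCV split sequence.

    ``model_factory(**params)`` builds an estimator for one candidate.
    Sharing splits makes candidate comparisons paired and deterministic
    given the seed.
    """
    if not grid:
        raise ValueError("parameter grid must not be empty")
    y = encode_labels(y)
    splits = mccv_splits(
        y, n_splits=n_splits, train_frac=train_frac, seed=seed,
        stratified=stratified,
    )
    errors = np.empty(len(grid))
    for i, params in enumerate(grid):
        errors[i] = mccv_error(
            lambda params=params: model_factory(**params), X, y, splits=splits
        )
        logger.debug("candidate %s -> MCCVER %.4f", params, errors[i])
    selected = int(np.argmin(errors))  # first minimum = simplest on ties
    logger.info(
        "grid search: selected %s (MCCVER %.4f over %d splits)",
        grid[selected], errors[selected], len(splits),
    )
    return MCCVGrid(
        candidates=grid,
        errors=errors,
        n_splits=n_splits,
        train_frac=train_frac,
        seed=seed,
        selected_index=selected,
    )
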