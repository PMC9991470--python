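"""Robust outlier screening via projection-pursuit outlyingness.

For each sample the outlyingness is the maximum, over random unit
directions, of the absolute deviation from the projected data's median,
standardized by 1.4826 x MAD (the normal-consistent robust scale).
Samples whose value exceeds a fixed cutoff (default 3, a 3-sigma rule)
are flagged; screening runs separately within each class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CLASS_LABELS
from .preprocess import ProfileTable

logger = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826


class DegenerateProjectionsError(ValueError):
    """All projection directions had zero MAD (e.g. identical samples)."""


@dataclass
class OutlyingnessReport:
    """Per-sample outlyingness diagnostics for one screened group."""

    sample_ids: np.ndarray
    values: np.ndarray
    flags: np.ndarray
    cutoff: float
    n_projections: int
    seed: int | None
    class_label: str | None = None
    n_degenerate_directions: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.flags = np.asarray(self.flags, dtype=bool)
        if np.any(self.values < 0):
            raise ValueError("outlyingness values must be >= 0")
        if not np.array_equal(self.flags, self.values > self.cutoff):
            raise ValueError("flags must equal (value > cutoff)")

    @property
    def flagged_ids(self) -> list[str]:
        return [str(s) for s in np.asarray(self.sample_ids)[self.flags]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": np.asarray(self.sample_ids, dtype=object),
                "class": self.class_label,
                "outlyingness": self.values,
                "flagged": self.flags,
            }
        )

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "cutoff": self.cutoff,
            "n_projections": self.n_projections,
            "seed": self.seed,
            "n_degenerate_directions": self.n_degenerate_directions,
            "sample_ids": [str(s) for s in self.sample_ids],
            "outlyingness": [float(v) for v in self.values],
            "flagged_ids": self.flagged_ids,
        }


def _random_directions(n_projections: int, p: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((n_projections, p))
    norms = np.linalg.norm(A, axis=1)
    # a zero vector has probability 0; regenerate defensively anyway
    while np.any(norms == 0):  # pragma: no cover
        bad = norms == 0
        A[bad] = rng.standard_normal((int(bad.sum()), p))
        norms = np.linalg.norm(A, axis=1)
    return A / norms[:, np.newaxis]


def sde_outlyingness(
    X: np.ndarray,
    n_projections: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_n_degenerate: bool = False,
):
    """Random-projection outlyingness of each row of ``X``.

    Directions are standard-normal vectors normalized to the unit sphere.
    Projections whose MAD is zero carry no scale information and are
    skipped (and counted); if every direction is degenerate a
    :class:`DegenerateProjectionsError` is raised.  Deterministic given
    ``seed``.  The estimate is a lower bound of the supremum over all
    directions; in one dimension it is exact.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if p < 1 or n_projections < 1:
        raise ValueError("need p >= 1 and n_projections >= 1")
    if np.any(~np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if rng is None:
        rng = np.random.default_rng(seed)
    A = _random_directions(n_projections, p, rng)
    proj = X @ A.T  # n x n_projections
    med = np.median(proj, axis=0)
    mad = np.median(np.abs(proj - med), axis=0)
    valid = mad > 0
    n_degenerate = int(np.sum(~valid))
    if not np.any(valid):
        raise DegenerateProjectionsError(
            "every projection direction has zero MAD; the data carry no "
            "robust scale (are all samples identical?)"
        )
    Z = np.abs(proj[:, valid] - med[valid]) / (MAD_CONSISTENCY * mad[valid])
    values = Z.max(axis=1)
    if return_n_degenerate:
        return values, n_degenerate
    return values


def flag_outliers(
    values,
    cutoff: float = 3.0,
    sample_ids=None,
    n_projections: int = 0,
    seed: int | None = None,
    class_label: str | None = None,
    n_degenerate_directions: int = 0,
) -> OutlyingnessReport:
    """Flag samples whose outlyingness strictly exceeds ``cutoff``."""
    values = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("outlyingness values must be finite")
    if sample_ids is None:
        sample_ids = np.arange(len(values))
    return OutlyingnessReport(
        sample_ids=np.asarray(sample_ids, dtype=object),
        values=values,
        flags=values > cutoff,
        cutoff=cutoff,
        n_projections=n_projections,
        seed=seed,
        class_label=class_label,
        n_degenerate_directions=n_degenerate_directions,
    )


def screen_by_class(
    table: ProfileTable,
    n_projections: int = 1000,
    cutoff: float = 3.0,
    seed: int | None = None,
    X: np.ndarray | None = None,
) -> tuple[ProfileTable, dict[str, OutlyingnessReport]]:
    """Run outlyingness screening independently within each class and drop
    flagged samples.

    ``X`` optionally supplies the matrix screened (row-aligned with the
    table) so callers can screen on a rescaled representation while
    keeping the table in concentration units; default is the table's own
    values.  Each class gets an independent child seed derived from
    ``seed``.
    """
    if X is None:
        X = table.values
    X = np.asarray(X, dtype=float)
    if X.shape[0] != table.n_samples:
        raise ValueError("screening matrix must align with table rows")
    for label in CLASS_LABELS:
        if len(table.class_indices(label)) < 3:
            raise ValueError(
                f"class {label!r} has fewer than 3 samples; cannot screen"
            )

    reports: dict[str, OutlyingnessReport] = {}
    keep = np.ones(table.n_samples, dtype=bool)
    children = np.random.SeedSequence(seed).spawn(len(CLASS_LABELS))
    for label, child in zip(CLASS_LABELS, children):
        idx = table.class_indices(label)
        rng = np.random.default_rng(child)
        values, n_deg = sde_outlyingness(
            X[idx], n_projections=n_projections, rng=rng, return_n_degenerate=True
        )
        report = flag_outliers(
            values,
            cutoff=cutoff,
            sample_ids=table.sample_ids[idx],
            n_projections=n_projections,
            seed=seed,
            class_label=label,
            n_degenerate_directions=n_deg,
        )
        reports[label] = report
        keep[idx[report.flags]] = False
        logger.info(
            "screened class %s: %d of %d flagged (%s)",
            label,
            int(report.flags.sum()),
            len(idx),
            ", ".join(report.flagged_ids) or "none",
        )
    return table.subset(np.flatnonzero(keep)), reports
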