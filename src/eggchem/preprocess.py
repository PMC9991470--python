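"""Profile tables, CSV I/O, detection limits, and the two-stage rescaling
(row-wise division by sample weight, column-wise autoscaling).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CLASS_LABELS, ElementPanel, default_panel

logger = logging.getLogger(__name__)

_META_COLUMNS = ("sample_id", "class", "area", "weight_g")


class SchemaError(ValueError):
    """Raised when a profile CSV does not match the declared schema."""


class ZeroVarianceError(ValueError):
    """Raised when autoscaling meets a constant column."""


@dataclass
class ProfileTable:
    """Samples-by-elements concentration table with per-sample metadata.

    ``values`` holds one row per sample in panel element order.  Values are
    concentrations (ug/g) unless ``metadata['autoscaled']`` is set, in which
    case they are dimensionless scaled values and the non-negativity
    invariant is suspended.
    """

    sample_ids: np.ndarray
    classes: np.ndarray
    areas: np.ndarray
    weights_g: np.ndarray
    values: np.ndarray
    panel: ElementPanel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.classes = np.asarray(self.classes, dtype=object)
        self.areas = np.asarray(self.areas, dtype=object)
        self.weights_g = np.asarray(self.weights_g, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, self.panel.n_elements):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {self.panel.n_elements} elements"
            )
        if not (len(self.classes) == len(self.areas) == len(self.weights_g) == n):
            raise SchemaError("metadata arrays must have one entry per sample")
        unknown = set(self.classes) - set(CLASS_LABELS)
        if unknown:
            raise SchemaError(f"unknown class labels: {sorted(unknown)}")
        if np.any(~np.isfinite(self.weights_g)) or np.any(self.weights_g <= 0):
            bad = self.sample_ids[~(self.weights_g > 0)]
            raise SchemaError(f"nonpositive weight for samples {list(bad)}")
        if not self.metadata.get("autoscaled", False):
            if np.any(self.values < 0):
                i, j = np.argwhere(self.values < 0)[0]
                raise SchemaError(
                    f"negative concentration at sample "
                    f"{self.sample_ids[i]!r}, element {self.panel.symbols[j]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_indices(self, label: str) -> np.ndarray:
        """Row positions of samples belonging to ``label``."""
        return np.flatnonzero(self.classes == label)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.classes == c)) for c in CLASS_LABELS}

    def subset(self, indices) -> "ProfileTable":
        """New table with the given row positions, metadata carried over."""
        idx = np.asarray(indices)
        return ProfileTable(
            sample_ids=self.sample_ids[idx],
            classes=self.classes[idx],
            areas=self.areas[idx],
            weights_g=self.weights_g[idx],
            values=self.values[idx],
            panel=self.panel,
            metadata=dict(self.metadata),
        )

    def copy(self) -> "ProfileTable":
        t = self.subset(np.arange(self.n_samples))
        t.values = t.values.copy()
        return t

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "class": self.classes,
                "area": self.areas,
                "weight_g": self.weights_g,
            }
        )
        for j, sym in enumerate(self.panel.symbols):
            df[sym] = self.values[:, j]
        return df

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProfileTable):
            return NotImplemented
        return (
            list(self.sample_ids) == list(other.sample_ids)
            and list(self.classes) == list(other.classes)
            and list(self.areas) == list(other.areas)
            and np.array_equal(self.weights_g, other.weights_g)
            and np.array_equal(self.values, other.values)
            and self.panel == other.panel
        )


def read_profiles(path, panel: ElementPanel | None = None) -> ProfileTable:
    """Read a profile table from CSV.

    The schema is ``sample_id,class,area,weight_g,<element...>`` with the
    element columns in panel order.  Errors name the offending column or
    row so malformed files are diagnosable.
    """
    panel = panel or default_panel()
    try:
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "class": str, "area": str},
            float_precision="round_trip",
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas messages vary
        raise SchemaError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    missing += [s for s in panel.symbols if s not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("weight_g", *panel.symbols):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) > 0:
            raise SchemaError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} "
                f"in column {col!r}, row {bad[0] + 2}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise SchemaError(f"{path}: missing value in column {col!r}, row {row + 2}")
        df[col] = coerced
    try:
        return ProfileTable(
            sample_ids=df["sample_id"].to_numpy(dtype=object),
            classes=df["class"].to_numpy(dtype=object),
            areas=df["area"].to_numpy(dtype=object),
            weights_g=df["weight_g"].to_numpy(dtype=float),
            values=df[list(panel.symbols)].to_numpy(dtype=float),
            panel=panel,
        )
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_profiles(table: ProfileTable, path, sidecar: bool = True) -> None:
    """Write a profile table to CSV (repr-precision floats, lossless round
    trip) plus an optional JSON provenance sidecar built from its metadata.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_dataframe().to_csv(path, index=False)
    if sidecar and table.metadata:
        side = path.with_suffix(".json")
        with open(side, "w", encoding="utf-8") as fh:
            json.dump(table.metadata, fh, indent=2, sort_keys=True)


def estimate_detection_limit(blank_signals, expected_replicates: int | None = 11) -> float:
    """Detection limit as 3x the sample SD of replicate blank measurements.

    By default exactly 11 replicates are required; pass
    ``expected_replicates=None`` to accept any count >= 2.
    """
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.ndim != 1 or len(blanks) < 2:
        raise ValueError("need at least 2 blank replicates")
    if expected_replicates is not None and len(blanks) != expected_replicates:
        raise ValueError(
            f"expected {expected_replicates} blank replicates, got {len(blanks)}"
        )
    if np.any(~np.isfinite(blanks)):
        raise ValueError("blank replicates must be finite")
    return float(3.0 * np.std(blanks, ddof=1))


def censor_below_dl(table: ProfileTable, panel: ElementPanel | None = None) -> ProfileTable:
    """Replace concentrations strictly below the detection limit with 0.

    Values exactly at the detection limit are retained.  The number of
    censored cells is logged and recorded in the table metadata.
    """
    panel = panel or table.panel
    dl = np.asarray(panel.detection_limits, dtype=float)
    out = table.copy()
    mask = out.values < dl[np.newaxis, :]
    n_censored = int(mask.sum())
    out.values[mask] = 0.0
    out.metadata["censored_cells"] = n_censored
    logger.info("censored %d cells below detection limit", n_censored)
    return out


def rescale_rowwise(table: ProfileTable) -> ProfileTable:
    """Divide each sample's concentration row by its sample weight (g).

    Weights are retained in the output so the operation is invertible.
    """
    if np.any(table.weights_g <= 0):
        raise ValueError("row-wise rescaling requires strictly positive weights")
    out = table.copy()
    out.values = out.values / out.weights_g[:, np.newaxis]
    out.metadata["row_rescaled"] = True
    return out


@dataclass(frozen=True)
class ScalingParams:
    """Column centers/scales fitted on a stated reference subset."""

    elements: tuple[str, ...]
    center: tuple[float, ...]
    scale: tuple[float, ...]
    reference_ids: tuple[str, ...]
    row_rescaled: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale):
            raise ZeroVarianceError("all scales must be > 0")

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "center": list(self.center),
            "scale": list(self.scale),
            "reference_ids": list(self.reference_ids),
            "row_rescaled": self.row_rescaled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            elements=tuple(d["elements"]),
            center=tuple(d["center"]),
            scale=tuple(d["scale"]),
            reference_ids=tuple(d["reference_ids"]),
            row_rescaled=bool(d.get("row_rescaled", False)),
        )


def fit_column_scaler(X: np.ndarray, columns=None) -> tuple[np.ndarray, np.ndarray]:
    """Mean/SD (ddof=1) per column of a plain matrix; error on constants.

    Low-level helper behind :func:`autoscale_fit`, also used wherever
    scaling must be refit inside resampling loops without table overhead.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 reference samples to fit a scaler")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        j = int(np.flatnonzero(scale == 0)[0])
        name = columns[j] if columns is not None else f"column {j}"
        raise ZeroVarianceError(
            f"zero variance in {name} on the scaling reference subset"
        )
    return center, scale


def autoscale_fit(table: ProfileTable, reference=None) -> ScalingParams:
    """Fit per-element center (mean) and scale (SD, n-1 denominator).

    ``reference`` selects the rows used to compute the statistics (row
    positions); default is all samples.  A zero-variance element raises
    :class:`ZeroVarianceError` naming the element — callers must decide
    how to proceed, there is no silent fallback.
    """
    if reference is None:
        reference = np.arange(table.n_samples)
    reference = np.asarray(reference)
    X = table.values[reference]
    center, scale = fit_column_scaler(X, columns=table.panel.symbols)
    return ScalingParams(
        elements=tuple(table.panel.symbols),
        center=tuple(float(c) for c in center),
        scale=tuple(float(s) for s in scale),
        reference_ids=tuple(str(s) for s in table.sample_ids[reference]),
        row_rescaled=bool(table.metadata.get("row_rescaled", False)),
    )


def autoscale_apply(table: ProfileTable, params: ScalingParams) -> ProfileTable:
    """Apply fitted column scaling: (x - center) / scale per element."""
    if tuple(table.panel.symbols) != params.elements:
        raise SchemaError("scaling params were fitted for a different panel")
    out = table.copy()
    center = np.asarray(params.center)
    scale = np.asarray(params.scale)
    out.metadata["autoscaled"] = True
    out.values = (out.values - center) / scale
    return out


def autoscale_invert(table: ProfileTable, params: ScalingParams) -> ProfileTable:
    """Undo :func:`autoscale_apply` with the same params."""
    if tuple(table.panel.symbols) != params.elements:
        raise SchemaError("scaling params were fitted for a different panel")
    out = table.copy()
    out.values = out.values * np.asarray(params.scale) + np.asarray(params.center)
    out.metadata.pop("autoscaled", None)
    # re-run invariant checks now that values are concentrations again
    return ProfileTable(
        sample_ids=out.sample_ids,
        classes=out.classes,
        areas=out.areas,
        weights_g=out.weights_g,
        values=out.values,
        panel=out.panel,
        metadata=out.metadata,
    )


def exploration_matrix(table: ProfileTable) -> tuple[np.ndarray, ScalingParams]:
    """Weight-rescaled, all-sample-autoscaled matrix used by the
    exploratory stages (outlier screening, PCA, train/test splitting)."""
    rw = rescale_rowwise(table)
    params = autoscale_fit(rw)
    return autoscale_apply(rw, params).values, params
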