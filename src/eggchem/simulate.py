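"""Synthetic eggshell profile generator.

Draws per-class element concentrations with zero-truncated-normal
marginals matching the packaged class-conditional means/SDs, averages
triplicate measurements, censors below the detection limit, and can
plant gross outliers for recovery experiments.

By default elements share a low-dimensional latent factor structure
(``GeneratorConfig.correlation``), mimicking the strong inter-element
correlation of real eggshell digests, where a couple of principal
components carry most of the variance.  This matters downstream: the
projection-pursuit outlier screen uses a fixed cutoff of 3, which is
only meaningful when the within-class data have a low effective
dimension.  Set ``correlation=0`` for fully independent elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import (
    CLASS_LABELS,
    ClassDistribution,
    ElementPanel,
    default_areas,
    default_distributions,
    default_panel,
)
from .preprocess import ProfileTable


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic profile generator.

    ``n_per_class`` maps class label to sample count (each >= 2).  Sample
    weights are drawn from N(weight_mean_g, weight_sd_g) truncated at
    ``weight_min_g``.  Each sample is measured ``n_replicates`` times with
    multiplicative noise of coefficient of variation ``replicate_cv`` and
    the replicates are averaged.
    """

    n_per_class: dict = field(
        default_factory=lambda: {"free-range": 127, "caged": 122}
    )
    seed: int | None = None
    weight_mean_g: float = 1.0
    weight_sd_g: float = 0.02
    weight_min_g: float = 0.5
    n_replicates: int = 3
    replicate_cv: float = 0.02
    #: Shared-factor communality in [0, 1): fraction of each element's
    #: (latent, pre-truncation) variance carried by common factors.
    #: 0 means fully independent elements.
    correlation: float = 0.98
    n_factors: int = 2

    def __post_init__(self) -> None:
        for label, n in self.n_per_class.items():
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown class label {label!r}")
            if n < 2:
                raise ValueError(f"n per class must be >= 2, got {n} for {label}")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.replicate_cv < 0:
            raise ValueError("replicate CV must be >= 0")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_per_class": dict(self.n_per_class),
            "seed": self.seed,
            "weight_mean_g": self.weight_mean_g,
            "weight_sd_g": self.weight_sd_g,
            "weight_min_g": self.weight_min_g,
            "n_replicates": self.n_replicates,
            "replicate_cv": self.replicate_cv,
            "correlation": self.correlation,
            "n_factors": self.n_factors,
        }


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    lower: float = 0.0,
) -> np.ndarray:
    """Sample N(mean, sd) conditioned on being >= ``lower`` by rejection.

    Rejection (rather than clipping) keeps the sampled moments close to
    the nominal ones whenever the truncation point is a couple of SDs
    below the mean.  SD = 0 returns the constant ``mean`` (which must
    satisfy the bound).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        if mean < lower:
            raise ValueError("degenerate distribution below truncation bound")
        return np.full(size, float(mean))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[draw >= lower]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _factor_directions(p: int, n_factors: int) -> np.ndarray:
    """Deterministic unit-norm factor-direction vector per element."""
    theta = 2.0 * np.pi * np.arange(p) / p
    if n_factors == 1:
        return np.ones((p, 1))
    cols = [np.cos(theta), np.sin(theta)]
    for f in range(2, n_factors):
        cols.append(np.cos(f * theta + 0.5 * f))
    G = np.column_stack(cols[:n_factors])
    norms = np.linalg.norm(G, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ValueError("degenerate factor directions for this (p, n_factors)")
    return G / norms


def _draw_concentrations(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    sds: np.ndarray,
    correlation: float,
    n_factors: int,
) -> np.ndarray:
    """Rows with truncated-normal marginals and optional shared factors.

    Latent per-element scores are ``z = L f + sqrt(1 - h^2) e`` with unit
    marginal variance (``h^2`` = ``correlation``); concentrations are
    ``mean + sd * z`` and whole rows are redrawn (rejection, not
    clipping) until every coordinate is non-negative.  With
    ``correlation = 0`` this reproduces independent zero-truncated
    normals exactly.
    """
    p = len(means)
    L = np.sqrt(correlation) * _factor_directions(p, n_factors)
    resid = np.sqrt(1.0 - correlation)
    out = np.empty((n, p))
    filled = 0
    stalled = 0
    while filled < n:
        m = n - filled
        F = rng.standard_normal((m, n_factors))
        E = rng.standard_normal((m, p))
        x = means + sds * (F @ L.T + resid * E)
        keep = x[np.all(x >= 0, axis=1)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
        stalled = stalled + 1 if len(keep) == 0 else 0
        if stalled > 1000:
            raise RuntimeError(
                "rejection sampler stalled; distribution mass is almost "
                "entirely below zero"
            )
    return out


def generate_profiles(
    panel: ElementPanel | None = None,
    dists: dict[str, ClassDistribution] | None = None,
    cfg: GeneratorConfig | None = None,
    areas: list[str] | None = None,
) -> ProfileTable:
    """Generate a synthetic :class:`ProfileTable`.

    Per sample: draw a true concentration per element from the class
    distribution (zero-truncated normal; nondetect elements are exact
    zeros), simulate replicate measurements with multiplicative noise,
    average them, then censor averages strictly below the detection
    limit to 0.  Producing areas are assigned round-robin.
    """
    panel = panel or default_panel()
    dists = dists if dists is not None else default_distributions()
    cfg = cfg or GeneratorConfig()
    areas = areas if areas is not None else default_areas()
    missing = [c for c in cfg.n_per_class if c not in dists]
    if missing:
        raise ValueError(f"no distribution provided for classes {missing}")

    rng = np.random.default_rng(cfg.seed)
    dl = np.asarray(panel.detection_limits)

    ids: list[str] = []
    labels: list[str] = []
    sample_areas: list[str] = []
    weights: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    prefix = {"free-range": "FR", "caged": "CG"}

    for label in CLASS_LABELS:
        if label not in cfg.n_per_class:
            continue
        n = cfg.n_per_class[label]
        dist = dists[label].aligned_to(panel)
        w = truncated_normal(
            rng, cfg.weight_mean_g, cfg.weight_sd_g, n, lower=cfg.weight_min_g
        )
        true_conc = _draw_concentrations(
            rng,
            n,
            np.asarray(dist.means, dtype=float),
            np.asarray(dist.sds, dtype=float),
            cfg.correlation,
            cfg.n_factors,
        )
        if cfg.replicate_cv > 0:
            noise = rng.normal(
                0.0, cfg.replicate_cv, size=(n, cfg.n_replicates, panel.n_elements)
            )
            reps = true_conc[:, np.newaxis, :] * (1.0 + noise)
            np.maximum(reps, 0.0, out=reps)
            conc = reps.mean(axis=1)
        else:
            conc = true_conc.copy()
        conc[conc < dl[np.newaxis, :]] = 0.0

        ids.extend(f"{prefix[label]}-{i + 1:03d}" for i in range(n))
        labels.extend([label] * n)
        sample_areas.extend(
            areas[i % len(areas)] if areas else "" for i in range(n)
        )
        weights.append(w)
        blocks.append(conc)

    return ProfileTable(
        sample_ids=np.array(ids, dtype=object),
        classes=np.array(labels, dtype=object),
        areas=np.array(sample_areas, dtype=object),
        weights_g=np.concatenate(weights),
        values=np.vstack(blocks),
        panel=panel,
        metadata={"generator": cfg.to_dict(), "seed": cfg.seed},
    )


def pooled_within_class_sd(table: ProfileTable) -> np.ndarray:
    """Per-element pooled within-class SD across the two classes."""
    num = np.zeros(table.panel.n_elements)
    dof = 0
    for label in CLASS_LABELS:
        idx = table.class_indices(label)
        if len(idx) < 2:
            continue
        X = table.values[idx]
        num += (len(idx) - 1) * X.var(axis=0, ddof=1)
        dof += len(idx) - 1
    if dof == 0:
        raise ValueError("need at least one class with >= 2 samples")
    return np.sqrt(num / dof)


def plant_outliers(
    table: ProfileTable,
    k: int | dict,
    displacement: float,
    seed: int | None = None,
) -> tuple[ProfileTable, np.ndarray]:
    """Displace ``k`` randomly chosen samples per class by ``displacement``
    pooled-SD units along a random direction.

    ``k`` may be an int (same count in both classes) or a mapping from
    class label to count.  Each planted sample gets its own random unit
    direction; the per-element shift is ``displacement * u_j * sd_j``
    with ``sd_j`` the pooled within-class SD, and shifted values are
    clipped at 0 to keep concentrations physical.  Returns the modified
    table and a boolean truth-flag array.
    """
    if isinstance(k, int):
        k = {label: k for label in CLASS_LABELS}
    for label, kc in k.items():
        if kc < 0:
            raise ValueError("outlier count must be >= 0")
        if kc > len(table.class_indices(label)):
            raise ValueError(
                f"cannot plant {kc} outliers in class {label!r} of size "
                f"{len(table.class_indices(label))}"
            )
    flags = np.zeros(table.n_samples, dtype=bool)
    if all(kc == 0 for kc in k.values()):
        return table.copy(), flags
    if not displacement > 0:
        raise ValueError("displacement must be > 0")

    rng = np.random.default_rng(seed)
    sd = pooled_within_class_sd(table)
    out = table.copy()
    for label in CLASS_LABELS:
        kc = k.get(label, 0)
        if kc == 0:
            continue
        idx = table.class_indices(label)
        chosen = rng.choice(idx, size=kc, replace=False)
        for i in chosen:
            u = rng.standard_normal(table.panel.n_elements)
            u /= np.linalg.norm(u)
            out.values[i] = np.maximum(out.values[i] + displacement * u * sd, 0.0)
            flags[i] = True
    out.metadata["planted_outliers"] = {
        "k": {label: int(kc) for label, kc in k.items()},
        "displacement": displacement,
        "seed": seed,
        "sample_ids": [str(s) for s in out.sample_ids[flags]],
    }
    return out, flags
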