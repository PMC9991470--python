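"""End-to-end workflow: generate/read profiles, rescale, screen outliers
per class, Kennard-Stone split per class, MCCV parameter selection, final
model fits, and test-set evaluation — all from one config with one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .models import (
    MODEL_FAMILIES,
    LSSVMClassifier,
    LSSVMModel,
    PLSDAClassifier,
    PLSDAModel,
    encode_labels,
    pca_fit,
)
from .outliers import screen_by_class
from .panel import CLASS_LABELS
from .preprocess import (
    ProfileTable,
    exploration_matrix,
    read_profiles,
    rescale_rowwise,
    write_profiles,
)
from .simulate import GeneratorConfig, generate_profiles, plant_outliers
from .split import SplitResult, split_per_class
from .validation import (
    confusion,
    default_lssvm_grid,
    default_lv_grid,
    grid_search,
    metrics,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips through YAML.

    Exactly one of ``input_csv`` / ``generator`` must be set.  All stage
    seeds are derived from the single global ``seed``.
    """

    seed: int = 20190101
    input_csv: str | None = None
    generator: dict | None = field(
        default_factory=lambda: {
            "n_per_class": {"free-range": 127, "caged": 122},
            "planted_outliers": {"free-range": 2, "caged": 1},
            "displacement": 10.0,
        }
    )
    outlier_screen: dict = field(
        default_factory=lambda: {"n_projections": 1000, "cutoff": 3.0}
    )
    split: dict = field(default_factory=lambda: {"n_train_per_class": 80})
    mccv: dict = field(
        default_factory=lambda: {
            "n_splits": 100,
            "train_frac": 0.7,
            "stratified": True,
        }
    )
    models: list = field(
        default_factory=lambda: [{"family": "plsda"}, {"family": "lssvm"}]
    )
    out_dir: str = "eggchem-run"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigError(
                "config must set exactly one of 'input_csv' or 'generator'"
            )
        if self.outlier_screen.get("n_projections", 1000) < 1:
            raise ConfigError("outlier_screen.n_projections must be >= 1")
        if self.outlier_screen.get("cutoff", 3.0) <= 0:
            raise ConfigError("outlier_screen.cutoff must be > 0")
        if self.split.get("n_train_per_class", 80) < 2:
            raise ConfigError("split.n_train_per_class must be >= 2")
        if not 0 < self.mccv.get("train_frac", 0.7) < 1:
            raise ConfigError("mccv.train_frac must be in (0, 1)")
        if self.mccv.get("n_splits", 100) < 1:
            raise ConfigError("mccv.n_splits must be >= 1")
        for spec in self.models:
            fam = spec.get("family")
            if fam not in MODEL_FAMILIES:
                raise ConfigError(
                    f"unknown model family {fam!r}; "
                    f"choose from {sorted(MODEL_FAMILIES)}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage_seeds(seed: int, n_models: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(4 + n_models)
    return [int(s) for s in state]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def save_classifier(clf, path) -> None:
    """Serialize a fitted classifier (model + its training-set scaler)."""
    payload = {
        "family": "plsda" if isinstance(clf, PLSDAClassifier) else "lssvm",
        "params": clf.get_params(),
        "scaler": {"center": clf.center_.tolist(), "scale": clf.scale_.tolist()},
        "model": clf.model_.to_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(payload), fh, indent=2)


def load_classifier(path):
    """Rebuild a fitted classifier saved by :func:`save_classifier`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    family = payload["family"]
    clf = MODEL_FAMILIES[family](**payload["params"])
    clf.center_ = np.asarray(payload["scaler"]["center"], dtype=float)
    clf.scale_ = np.asarray(payload["scaler"]["scale"], dtype=float)
    model_cls = PLSDAModel if family == "plsda" else LSSVMModel
    clf.model_ = model_cls.from_dict(payload["model"])
    return clf


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    stages: dict
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonify(
            {"config": self.config, "stages": self.stages, "manifest": self.manifest}
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_grid(family: str) -> list[dict]:
    return default_lv_grid() if family == "plsda" else default_lssvm_grid()


def run_pipeline(config: PipelineConfig, out_dir=None) -> RunReport:
    """Execute the full workflow and write every intermediate artifact.

    Stage order: read/generate -> row-wise weight rescale + all-sample
    autoscale -> per-class outlier screen -> per-class Kennard-Stone
    split -> MCCV parameter selection (scaling refit inside each split)
    -> final fit on the training set -> test-set confusion and metrics.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, len(config.models))
    stages: dict = {}
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    # -- stage 1: input ----------------------------------------------------
    truth_flags = None
    if config.input_csv is not None:
        table = read_profiles(config.input_csv)
        logger.info("loaded %d profiles from %s", table.n_samples, config.input_csv)
    else:
        gen = dict(config.generator)
        planted = gen.pop("planted_outliers", None)
        displacement = gen.pop("displacement", 10.0)
        cfg = GeneratorConfig(**{**gen, "seed": seeds[0]})
        table = generate_profiles(cfg=cfg)
        if planted and any(planted.values()):
            table, truth_flags = plant_outliers(
                table, planted, displacement, seed=seeds[1]
            )
        logger.info("generated %d synthetic profiles", table.n_samples)
    write_profiles(table, out / "profiles.csv")
    emit(out / "profiles.csv")
    if (out / "profiles.json").exists():
        emit(out / "profiles.json")
    stages["input"] = {
        "n_samples": table.n_samples,
        "class_counts": table.class_counts(),
        "seed": config.seed,
        "planted_outlier_ids": (
            [str(s) for s in table.sample_ids[truth_flags]]
            if truth_flags is not None
            else []
        ),
    }

    # -- stage 2: exploratory scaling + PCA --------------------------------
    X_explore, explore_params = exploration_matrix(table)
    pca = pca_fit(X_explore)
    evr = pca.explained_variance_ratio
    stages["pca"] = {
        "explained_variance_ratio": evr,
        "pc1_pc2_pct": float(100.0 * evr[:2].sum()),
    }
    scores = pca.scores[:, :2]
    with open(out / "pca_scores.csv", "w", encoding="utf-8") as fh:
        fh.write("sample_id,class,pc1,pc2\n")
        for sid, cls, (a, b) in zip(table.sample_ids, table.classes, scores):
            fh.write(f"{sid},{cls},{a!r},{b!r}\n")
    emit(out / "pca_scores.csv")

    # -- stage 3: per-class outlier screen ---------------------------------
    screen_cfg = config.outlier_screen
    clean, reports = screen_by_class(
        table,
        n_projections=screen_cfg.get("n_projections", 1000),
        cutoff=screen_cfg.get("cutoff", 3.0),
        seed=seeds[2],
        X=X_explore,
    )
    for label, rep in reports.items():
        path = out / f"outlyingness_{label}.csv"
        rep.to_frame().to_csv(path, index=False)
        emit(path)
    write_profiles(clean, out / "screened.csv", sidecar=False)
    emit(out / "screened.csv")
    stages["screen"] = {
        "cutoff": screen_cfg.get("cutoff", 3.0),
        "n_projections": screen_cfg.get("n_projections", 1000),
        "per_class": {
            label: {
                "n_in": len(rep.values),
                "n_flagged": int(rep.flags.sum()),
                "flagged_ids": rep.flagged_ids,
            }
            for label, rep in reports.items()
        },
        "class_counts_after": clean.class_counts(),
    }

    # -- stage 4: per-class Kennard-Stone split ----------------------------
    split = split_per_class(clean, config.split.get("n_train_per_class", 80))
    split.to_json(out / "split.json")
    emit(out / "split.json")
    stages["split"] = {
        "n_train": split.n_train,
        "n_test": split.n_test,
        "per_class": {
            label: {
                "n_train": len(split.train_ids[label]),
                "n_test": len(split.test_ids[label]),
            }
            for label in CLASS_LABELS
        },
    }

    # -- stage 5: models ---------------------------------------------------
    rw = rescale_rowwise(clean)
    X_all = rw.values
    y_all = encode_labels(clean.classes)
    Xtr, ytr = X_all[split.train_indices], y_all[split.train_indices]
    Xte, yte = X_all[split.test_indices], y_all[split.test_indices]
    stages["models"] = {}
    for i, spec in enumerate(config.models):
        family = spec["family"]
        grid = spec.get("grid") or _default_grid(family)
        gs = grid_search(
            MODEL_FAMILIES[family],
            Xtr,
            ytr,
            grid,
            n_splits=config.mccv.get("n_splits", 100),
            train_frac=config.mccv.get("train_frac", 0.7),
            seed=seeds[4 + i],
            stratified=config.mccv.get("stratified", True),
        )
        gs.to_frame().to_csv(out / f"grid_{family}.csv", index=False)
        emit(out / f"grid_{family}.csv")
        clf = MODEL_FAMILIES[family](**gs.selected_params).fit(Xtr, ytr)
        save_classifier(clf, out / f"model_{family}.json")
        emit(out / f"model_{family}.json")
        pred = clf.predict(Xte)
        counts = confusion(yte, pred)
        stages["models"][family] = {
            "selected_params": gs.selected_params,
            "mccv_error": gs.min_error,
            "mccv_seed": seeds[4 + i],
            "confusion": counts.to_dict(),
            "metrics": metrics(counts).to_dict(),
            "scaler_reference": "training set only",
        }
        logger.info(
            "%s: test accuracy %.1f%%",
            family,
            stages["models"][family]["metrics"]["accuracy_pct"],
        )

    manifest = {p.name: _sha256(p) for p in written}
    report = RunReport(config=config.to_dict(), stages=stages, manifest=manifest)
    report.to_json(out / "report.json")
    return report
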