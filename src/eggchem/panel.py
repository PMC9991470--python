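"""Analytical panel definitions: elements, wavelengths, detection limits,
and class-conditional concentration distributions.

The default panel (16 mineral elements measured in eggshell digests by
ICP-AES) ships with the package as a YAML file and is the single source of
truth for element ordering throughout the pipeline.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import yaml

#: Number of elements every panel must carry.
N_ELEMENTS = 16

#: The two husbandry classes. Free-range is the "positive" class.
POSITIVE_CLASS = "free-range"
NEGATIVE_CLASS = "caged"
CLASS_LABELS = (POSITIVE_CLASS, NEGATIVE_CLASS)

#: Numeric class coding used by the classifiers.
CLASS_CODES = {POSITIVE_CLASS: 1, NEGATIVE_CLASS: -1}


class PanelError(ValueError):
    """Raised for malformed panels or distributions."""


@dataclass(frozen=True)
class ElementPanel:
    """Ordered element panel with per-element wavelength and detection limit.

    Parameters
    ----------
    symbols
        Element symbols in measurement order (exactly 16, unique).
    wavelengths_nm
        Analytical emission wavelength per element, nm (strictly positive).
    detection_limits
        Detection limit per element, in concentration units (ug/g),
        strictly positive.
    """

    symbols: tuple[str, ...]
    wavelengths_nm: tuple[float, ...]
    detection_limits: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != N_ELEMENTS:
            raise PanelError(
                f"panel must have exactly {N_ELEMENTS} elements, "
                f"got {len(self.symbols)}"
            )
        if len(set(self.symbols)) != len(self.symbols):
            raise PanelError("element symbols must be unique")
        if len(self.wavelengths_nm) != len(self.symbols):
            raise PanelError("one wavelength required per element")
        if len(self.detection_limits) != len(self.symbols):
            raise PanelError("one detection limit required per element")
        for name, values in (
            ("wavelength", self.wavelengths_nm),
            ("detection limit", self.detection_limits),
        ):
            for sym, v in zip(self.symbols, values):
                if not v > 0:
                    raise PanelError(f"{name} for {sym} must be > 0, got {v}")

    @property
    def n_elements(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        """Position of ``symbol`` in the panel order."""
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise PanelError(f"element {symbol!r} not in panel") from None

    def to_dict(self) -> dict:
        return {
            "elements": [
                {"symbol": s, "wavelength_nm": w, "detection_limit": d}
                for s, w, d in zip(
                    self.symbols, self.wavelengths_nm, self.detection_limits
                )
            ]
        }


@dataclass(frozen=True)
class ClassDistribution:
    """Per-element concentration distribution for one husbandry class.

    Each element is modelled as normal with the given mean/SD, truncated
    at zero.  Elements flagged ``nondetect`` never rise above the
    detection limit and are stored as exact zeros (mean and SD are
    forced to 0 for them).
    """

    elements: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    nondetect: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.elements)
        if not (len(self.means) == len(self.sds) == len(self.nondetect) == n):
            raise PanelError("distribution fields must align with elements")
        for sym, m, s, nd in zip(
            self.elements, self.means, self.sds, self.nondetect
        ):
            if s < 0:
                raise PanelError(f"SD for {sym} must be >= 0, got {s}")
            if nd and (m != 0 or s != 0):
                raise PanelError(
                    f"nondetect element {sym} must store mean = SD = 0"
                )

    def aligned_to(self, panel: ElementPanel) -> "ClassDistribution":
        """Reorder to the panel's element order (error on mismatch)."""
        if set(self.elements) != set(panel.symbols):
            missing = set(panel.symbols) - set(self.elements)
            extra = set(self.elements) - set(panel.symbols)
            raise PanelError(
                f"distribution does not match panel elements "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        order = [self.elements.index(s) for s in panel.symbols]
        return ClassDistribution(
            elements=tuple(panel.symbols),
            means=tuple(self.means[i] for i in order),
            sds=tuple(self.sds[i] for i in order),
            nondetect=tuple(self.nondetect[i] for i in order),
        )


def _parse_panel_config(raw: dict) -> tuple[ElementPanel, dict, list[str]]:
    elements = raw.get("elements")
    if not elements:
        raise PanelError("panel config missing 'elements'")
    panel = ElementPanel(
        symbols=tuple(e["symbol"] for e in elements),
        wavelengths_nm=tuple(float(e["wavelength_nm"]) for e in elements),
        detection_limits=tuple(float(e["detection_limit"]) for e in elements),
    )
    dists: dict[str, ClassDistribution] = {}
    for label, per_elem in raw.get("class_distributions", {}).items():
        if label not in CLASS_LABELS:
            raise PanelError(f"unknown class label {label!r} in config")
        syms, means, sds, nds = [], [], [], []
        for sym, spec in per_elem.items():
            nd = bool(spec.get("nondetect", False))
            syms.append(sym)
            means.append(0.0 if nd else float(spec["mean"]))
            sds.append(0.0 if nd else float(spec["sd"]))
            nds.append(nd)
        dist = ClassDistribution(
            elements=tuple(syms),
            means=tuple(means),
            sds=tuple(sds),
            nondetect=tuple(nds),
        )
        dists[label] = dist.aligned_to(panel)
    areas = list(raw.get("producing_areas", []))
    return panel, dists, areas


def load_panel_config(path: str) -> tuple[ElementPanel, dict, list[str]]:
    """Load (panel, class distributions, producing areas) from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _parse_panel_config(raw)


@lru_cache(maxsize=1)
def _default_config() -> tuple[ElementPanel, dict, list[str]]:
    ref = importlib.resources.files("eggchem.data") / "default_panel.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _parse_panel_config(raw)


def default_panel() -> ElementPanel:
    """The packaged 16-element panel."""
    return _default_config()[0]


def default_distributions() -> dict[str, ClassDistribution]:
    """Packaged class-conditional distributions for both classes."""
    return dict(_default_config()[1])


def default_areas() -> list[str]:
    """Packaged list of producing-area names."""
    return list(_default_config()[2])
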