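"""Anatomical model definitions and configuration I/O.

Two built-in layered models ("model1", "model2") represent average adult
anatomical profiles of the human back: epidermis, dermis, adipose and
muscle resting on bone, loaded by a 10-mm-diameter circular pressure patch.
The printed source table for these parameters is typographically garbled;
the defaults below are the documented best-effort parse and every value is
overridable through the YAML configuration, so the parse is non-binding.

Geometry convention: axisymmetric (r, z) with z = 0 at the skin surface and
z increasing with depth; the 120 mm x 120 mm surface plane of the original
three-dimensional domain maps to a disc of radius 60 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence, Tuple

import yaml

from .materials import MaterialParams, reduce_stiffness

__all__ = [
    "SOFT_LAYERS",
    "LAYER_ORDER",
    "LayerSpec",
    "AnatomyModel",
    "LoadCase",
    "ConfigError",
    "builtin_model",
    "sensor_material",
    "default_load_cases",
    "make_variants",
    "load_config",
    "save_config",
]

SOFT_LAYERS: Tuple[str, ...] = ("epidermis", "dermis", "adipose", "muscle")
LAYER_ORDER: Tuple[str, ...] = SOFT_LAYERS + ("bone",)

#: Documented default parse of the model table: per layer
#: (thickness model1, thickness model2, E model1, E model2, nu, linear).
_TABLE = {
    "epidermis": (0.1, 0.07, 1500.0, 1500.0, 0.48, False),
    "dermis": (1.5, 0.8, 35.0, 35.0, 0.48, False),
    "adipose": (4.4, 3.0, 2.0, 2.0, 0.48, False),
    # muscle: identical reference element counts in both models imply a shared
    # geometry; thickness 6.6 mm and E = 21 kPa (mid-range skeletal muscle)
    # reproduce the adipose-dominant depth profile of the strain field
    "muscle": (6.6, 6.6, 21.0, 21.0, 0.48, False),
    "bone": (5.0, 5.0, 6480.0, 6480.0, 0.33, True),
}

#: Reference 3-D element counts of the source models (metadata only; the
#: axisymmetric meshes here are resolution-controlled instead).
REFERENCE_ELEMENT_COUNTS = {
    "epidermis": (40318, 46901),
    "dermis": (29802, 20774),
    "adipose": (64423, 48869),
    "muscle": (98980, 98980),
    "bone": (37890, 37890),
}


class ConfigError(ValueError):
    """Configuration schema violation; message carries the field path."""


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: name, thickness (mm), and its material."""

    name: str
    thickness: float
    material: MaterialParams
    target_element_count: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ConfigError(f"layers.{self.name}.thickness_mm: must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class LoadCase:
    """A single static load: uniform normal pressure over the indenter patch."""

    pressure: float  # kPa
    contact_mode: str = "traction_patch"  # or "rigid_punch"

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ConfigError(f"loads.pressures_kPa: pressure must be >= 0, got {self.pressure}")
        if self.contact_mode not in ("traction_patch", "rigid_punch"):
            raise ConfigError(f"loads.contact_mode: unknown mode {self.contact_mode!r}")


@dataclass(frozen=True)
class AnatomyModel:
    """Ordered layer stack plus domain / indenter / ROI geometry."""

    model_id: str
    layers: Tuple[LayerSpec, ...]
    domain_half_width: float = 60.0  # mm, disc radius
    indenter_radius: float = 5.0  # mm (10 mm diameter patch)
    roi_radius: float = 15.0  # mm (30 mm diameter zone)
    stiffness_factor: float = 1.0

    def __post_init__(self) -> None:
        names = [ly.name for ly in self.layers]
        if len(names) != len(set(names)):
            raise ConfigError("layers: duplicate layer names")
        if names and names[-1] != "bone" and "bone" in names:
            raise ConfigError("layers: bone must be the deepest layer")
        if self.roi_radius < self.indenter_radius:
            raise ConfigError("geometry.roi_radius_mm: must not be smaller than the indenter radius")
        if self.roi_radius > self.domain_half_width:
            raise ConfigError("geometry.roi_radius_mm: must not exceed the domain radius")
        if not (0.0 < self.stiffness_factor <= 1.0):
            raise ConfigError("stiffness_factor must lie in (0, 1]")

    @property
    def soft_layers(self) -> Tuple[LayerSpec, ...]:
        return tuple(ly for ly in self.layers if not ly.material.is_linear)

    @property
    def total_depth(self) -> float:
        return sum(ly.thickness for ly in self.layers)

    def layer(self, name: str) -> LayerSpec:
        for ly in self.layers:
            if ly.name == name:
                return ly
        raise KeyError(name)


def sensor_material() -> MaterialParams:
    """Material of the load-delivering sensor (metadata; the sensor body is
    not meshed — its role is uniform pressure delivery over the patch)."""
    return MaterialParams(name="sensor", E=1300.0, nu=0.45, is_linear=True)


def builtin_model(model_id: str) -> AnatomyModel:
    """Return one of the two documented default anatomical models."""
    if model_id not in ("model1", "model2"):
        raise ConfigError(f"model_id: unknown model {model_id!r} (expected model1 or model2)")
    col = 0 if model_id == "model1" else 1
    layers = []
    for name in LAYER_ORDER:
        t1, t2, e1, e2, nu, linear = _TABLE[name]
        counts = REFERENCE_ELEMENT_COUNTS[name]
        layers.append(
            LayerSpec(
                name=name,
                thickness=(t1, t2)[col],
                material=MaterialParams(name=name, E=(e1, e2)[col], nu=nu, is_linear=linear),
                target_element_count=counts[col],
            )
        )
    return AnatomyModel(model_id=model_id, layers=tuple(layers))


def default_load_cases() -> List[LoadCase]:
    """The four studied pressure magnitudes (kPa)."""
    return [LoadCase(pressure=p) for p in (2.0, 6.0, 8.0, 10.0)]


def make_variants(base: AnatomyModel, fractions: Sequence[float]) -> List[AnatomyModel]:
    """Stiffness-softened variants: soft-layer E scaled by (1 - f); bone kept."""
    out = []
    for f in fractions:
        if not (0.0 <= f < 1.0):
            raise ConfigError(f"variants.stiffness_reductions: fraction {f} outside [0, 1)")
        layers = tuple(
            ly if ly.material.is_linear else replace(ly, material=reduce_stiffness(ly.material, f))
            for ly in base.layers
        )
        out.append(replace(base, layers=layers, stiffness_factor=1.0 - f))
    return out


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_GEOM_KEYS = {"domain_half_width_mm", "indenter_radius_mm", "roi_radius_mm"}
_LAYER_KEYS = {"thickness_mm", "E_kPa", "nu", "prony", "linear"}
_LOAD_KEYS = {"pressures_kPa", "contact_mode"}
_TOP_KEYS = {"model_id", "geometry", "layers", "loads", "variants", "solver", "seed"}


def _require_mapping(obj, path: str) -> Mapping:
    if not isinstance(obj, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(obj).__name__}")
    return obj


def _reject_unknown(obj: Mapping, allowed: set, path: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _number(obj: Mapping, key: str, path: str, default=None, positive=False):
    if key not in obj:
        if default is not None:
            return default
        raise ConfigError(f"{path}.{key}: missing required value")
    v = obj[key]
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {v!r}")
    if positive and v <= 0:
        raise ConfigError(f"{path}.{key}: must be > 0, got {v}")
    return float(v)


def load_config(path: str | Path):
    """Read and validate a model configuration file.

    Returns ``(model, load_cases, extras)`` where ``extras`` carries the
    optional ``variants`` fraction list, ``solver`` override mapping and
    ``seed``.  Unknown keys at any level are rejected with the field path.
    """
    path = Path(path)
    raw = _require_mapping(yaml.safe_load(path.read_text()), "config")
    _reject_unknown(raw, _TOP_KEYS, "config")

    model_id = raw.get("model_id", "custom")
    geom = _require_mapping(raw.get("geometry", {}), "geometry")
    _reject_unknown(geom, _GEOM_KEYS, "geometry")

    layers_cfg = _require_mapping(raw.get("layers", {}), "layers")
    missing = [n for n in LAYER_ORDER if n not in layers_cfg]
    if missing:
        raise ConfigError(f"layers: missing layer(s) {missing}")
    _reject_unknown(layers_cfg, set(LAYER_ORDER), "layers")

    layers = []
    for name in LAYER_ORDER:
        lc = _require_mapping(layers_cfg[name], f"layers.{name}")
        _reject_unknown(lc, _LAYER_KEYS, f"layers.{name}")
        thickness = _number(lc, "thickness_mm", f"layers.{name}", positive=True)
        E = _number(lc, "E_kPa", f"layers.{name}", positive=True)
        nu = _number(lc, "nu", f"layers.{name}")
        linear = bool(lc.get("linear", name == "bone"))
        prony = tuple(
            (float(g), float(t)) for g, t in (lc.get("prony") or [])
        )
        try:
            mat = MaterialParams(name=name, E=E, nu=nu, prony=prony, is_linear=linear)
        except ValueError as exc:
            raise ConfigError(f"layers.{name}: {exc}") from exc
        layers.append(LayerSpec(name=name, thickness=thickness, material=mat))

    model = AnatomyModel(
        model_id=model_id,
        layers=tuple(layers),
        domain_half_width=_number(geom, "domain_half_width_mm", "geometry", default=60.0, positive=True),
        indenter_radius=_number(geom, "indenter_radius_mm", "geometry", default=5.0, positive=True),
        roi_radius=_number(geom, "roi_radius_mm", "geometry", default=15.0, positive=True),
    )

    loads_cfg = _require_mapping(raw.get("loads", {}), "loads")
    _reject_unknown(loads_cfg, _LOAD_KEYS, "loads")
    pressures = loads_cfg.get("pressures_kPa", [2.0, 6.0, 8.0, 10.0])
    if not isinstance(pressures, (list, tuple)) or not pressures:
        raise ConfigError("loads.pressures_kPa: expected a non-empty list")
    mode = loads_cfg.get("contact_mode", "traction_patch")
    load_cases = [LoadCase(pressure=float(p), contact_mode=mode) for p in pressures]

    variants_cfg = _require_mapping(raw.get("variants", {}), "variants")
    _reject_unknown(variants_cfg, {"stiffness_reductions"}, "variants")
    extras = {
        "variants": [float(f) for f in variants_cfg.get("stiffness_reductions", [])],
        "solver": dict(raw.get("solver") or {}),
        "seed": int(raw.get("seed", 0)),
    }
    return model, load_cases, extras


def save_config(
    model: AnatomyModel,
    load_cases: Iterable[LoadCase] = (),
    path: str | Path | None = None,
    variants: Sequence[float] = (),
    seed: int = 0,
) -> str:
    """Serialize a model (plus loads/variants) to YAML; inverse of load_config."""
    cases = list(load_cases) or default_load_cases()
    doc = {
        "model_id": model.model_id,
        "geometry": {
            "domain_half_width_mm": model.domain_half_width,
            "indenter_radius_mm": model.indenter_radius,
            "roi_radius_mm": model.roi_radius,
        },
        "layers": {
            ly.name: {
                "thickness_mm": ly.thickness,
                "E_kPa": ly.material.E,
                "nu": ly.material.nu,
                **({"prony": [list(p) for p in ly.material.prony]} if ly.material.prony else {}),
                **({"linear": True} if ly.material.is_linear else {}),
            }
            for ly in model.layers
        },
        "loads": {
            "pressures_kPa": [lc.pressure for lc in cases],
            "contact_mode": cases[0].contact_mode,
        },
        "variants": {"stiffness_reductions": list(variants)},
        "seed": seed,
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
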