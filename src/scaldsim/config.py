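"""Numerics configuration and plain-text (YAML) config overrides."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .materials import DamageKinetics, PerfusionModel, PorridgeModel, TissueLayer

__all__ = ["NumericsConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and sampling parameters.

    dx : node spacing, m (default 10 um).
    dt : time step, s (default 2e-4 s; stable for all default materials).
    sample_interval : trace sampling period, s.
    porridge_properties : ``"local"`` re-evaluates the porridge property
        polynomials each step at the local node temperature; ``"frozen"``
        evaluates them once at the initial spill temperature (useful for
        sensitivity studies and for constant-property verification runs).
    basal_sampling : where the basal-layer temperature driving the damage
        integral is read.  ``"interface"`` (default) interpolates the
        temperature at the epidermis-dermis junction from the two adjacent
        cell centers; ``"last_epidermis"`` / ``"first_dermis"`` read the
        single cell center half a spacing above / below the junction.
    """

    dx: float = 10e-6
    dt: float = 2e-4
    sample_interval: float = 0.05
    porridge_properties: str = "local"
    basal_sampling: str = "interface"

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0 or self.sample_interval <= 0:
            raise ValueError("dx, dt and sample_interval must be positive")
        if self.porridge_properties not in ("local", "frozen"):
            raise ValueError("porridge_properties must be 'local' or 'frozen'")
        if self.basal_sampling not in ("interface", "last_epidermis", "first_dermis"):
            raise ValueError(
                "basal_sampling must be 'interface', 'last_epidermis' or 'first_dermis'"
            )

    def replace(self, **kwargs) -> "NumericsConfig":
        return replace(self, **kwargs)


_SECTION_TYPES = {
    "numerics": NumericsConfig,
    "perfusion": PerfusionModel,
    "kinetics": DamageKinetics,
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into model objects.

    Recognized top-level sections (all optional):

    - ``numerics``: fields of :class:`NumericsConfig`
    - ``perfusion``: fields of :class:`PerfusionModel`
    - ``kinetics``: fields of :class:`DamageKinetics`
    - ``porridge``: fields of :class:`PorridgeModel` (polynomial coefficient
      triples ordered ``[T^2, T^1, T^0]``)
    - ``layers``: list of tissue-layer mappings (name, k, rho, c, thickness)

    Returns a dict with the corresponding objects under the same keys;
    missing sections are absent.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    for key, cls in _SECTION_TYPES.items():
        if key in raw:
            kwargs = dict(raw[key])
            for name in ("perfused_layers",):
                if name in kwargs:
                    kwargs[name] = tuple(kwargs[name])
            out[key] = cls(**_coerce_floats(cls, kwargs))
    if "porridge" in raw:
        kwargs = dict(raw["porridge"])
        for name in ("k_coeffs", "rho_coeffs", "c_coeffs"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        out["porridge"] = PorridgeModel(**kwargs)
    if "layers" in raw:
        out["layers"] = [TissueLayer.from_dict(d) for d in raw["layers"]]
    return out


def dump_config(path: str | Path, **sections) -> None:
    """Serialize model objects back to a YAML config file."""
    raw: dict = {}
    for key, obj in sections.items():
        if key == "layers":
            raw[key] = [layer.to_dict() for layer in obj]
        else:
            raw[key] = {
                f.name: _plain(getattr(obj, f.name)) for f in fields(obj)
            }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _coerce_floats(cls, kwargs: dict) -> dict:
    # YAML 1.1 reads exponents without a sign ("3.1e98") as strings;
    # coerce anything destined for a float field
    float_fields = {f.name for f in fields(cls) if f.type in ("float", float)}
    return {
        k: float(v) if k in float_fields and isinstance(v, str) else v
        for k, v in kwargs.items()
    }


def _plain(value):
    if isinstance(value, tuple):
        return list(value)
    return value
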