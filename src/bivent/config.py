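"""Structured configuration: one YAML document covering geometry,
materials, circulation, pump, solver and run settings.

Unknown keys and invalid values produce actionable error messages naming
the section, the offending key and the accepted alternatives.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .circulation import CircuitParams, LVADCurveSet, synthetic_lvad_curves
from .fem import SolverConfig
from .geometry import GeometryConfig
from .materials import ActiveParams, PassiveParams

#: named material presets; "chf_reference" carries the calibrated
#: chronic-heart-failure constants shipped with the package
MATERIAL_PRESETS = {
    "chf_reference": PassiveParams(),
}


class ConfigFileError(ValueError):
    pass


def _build(section: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigFileError(
            f"[{section}] unknown key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(valid)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigFileError(f"[{section}] {exc}") from exc


@dataclasses.dataclass
class RunSettings:
    rpm: str = "off"
    n_cycles: int = 3
    dt: float = 0.01
    output_dir: str = "bivent_out"
    write_vtu: bool = False


@dataclasses.dataclass
class Setup:
    geometry: GeometryConfig
    passive: PassiveParams
    active: ActiveParams
    circuit: CircuitParams
    solver: SolverConfig
    run: RunSettings
    curves: LVADCurveSet


def load_config(path_or_dict) -> Setup:
    """Parse and validate a configuration file (or pre-parsed mapping)."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    known = {"geometry", "materials", "circuit", "pump", "solver", "run"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigFileError(
            f"unknown top-level section(s) {sorted(unknown)}; valid "
            f"sections: {sorted(known)}")

    materials = dict(raw.get("materials", {}))
    preset = materials.pop("preset", "chf_reference")
    if preset not in MATERIAL_PRESETS:
        raise ConfigFileError(
            f"[materials] unknown preset {preset!r}; available: "
            f"{sorted(MATERIAL_PRESETS)}")
    passive_over = dict(materials.pop("passive", {}))
    active_over = dict(materials.pop("active", {}))
    if materials:
        raise ConfigFileError(
            f"[materials] unknown key(s) {sorted(materials)}; valid: "
            "['preset', 'passive', 'active']")
    base = MATERIAL_PRESETS[preset]
    passive = _build("materials.passive", PassiveParams,
                     {**dataclasses.asdict(base), **passive_over})
    active = _build("materials.active", ActiveParams, active_over)

    pump = dict(raw.get("pump", {}))
    csv = pump.pop("curves_csv", None)
    if pump:
        raise ConfigFileError(
            f"[pump] unknown key(s) {sorted(pump)}; valid: ['curves_csv']")
    curves = LVADCurveSet.from_csv(csv) if csv else synthetic_lvad_curves()

    return Setup(
        geometry=_build("geometry", GeometryConfig, raw.get("geometry", {})),
        passive=passive, active=active,
        circuit=_build("circuit", CircuitParams, raw.get("circuit", {})),
        solver=_build("solver", SolverConfig, raw.get("solver", {})),
        run=_build("run", RunSettings, raw.get("run", {})),
        curves=curves)


def fast_preset() -> dict:
    """A reduced-resolution configuration for quick runs and tests."""
    return {
        "geometry": {"n_circ": 8, "n_long": 3, "n_trans": 2,
                     "n_trans_rv": 2},
        "run": {"n_cycles": 2, "dt": 0.02},
    }
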