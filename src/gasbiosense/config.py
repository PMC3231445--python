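"""Scenario configuration: a single YAML file with unit-tagged quantities.

Every physical quantity in a scenario file is a string carrying an
explicit unit (e.g. ``"0.39 M/atm"``, ``"2.5 um"``); bare numbers are
accepted only for intrinsically dimensionless fields (ppm mixing ratio,
pH, pKa, temperature metadata, option ratios).  Unknown keys anywhere in
the file are rejected so that typos cannot silently drop a parameter.

A built-in preset, ``methanethiol_cytc``, encodes the reference
methanethiol / cytochrome-c sensor scenario: 100 ppm analyte at 1 atm,
k_H = 0.39 M/atm, pKa 10.3, D = 1.3 × 10⁻⁹ m²/s (methanol approximation),
pH 7 phosphate buffer, 10 mM receptor in a 2.5 μm sensing layer under a
200 nm gelatin cover, Δε = 22 mM⁻¹cm⁻¹, k = 2.8 × 10⁻³ μM⁻¹s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import yaml

from .kinetics import SensorSpec, WindowPolicy
from .partition import AnalyteSpec, GasSample
from .prediction import PredictionOptions
from .quantities import Quantity, parse_quantity
from .speciation import MediumSpec

__all__ = ["ScenarioConfig", "ConfigError", "load_scenario", "preset", "PRESETS"]


class ConfigError(ValueError):
    """Malformed scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully-resolved scenario: all specs plus chain options."""

    analyte: AnalyteSpec
    gas: GasSample
    medium: MediumSpec
    sensor: SensorSpec
    rate_constant: Quantity
    options: PredictionOptions = field(default_factory=PredictionOptions)
    window_policy: WindowPolicy = field(default_factory=WindowPolicy)
    seed: int = 0

    def to_dict(self) -> dict:
        """Round-trippable plain-dict form (quantities as tagged strings)."""
        return {
            "analyte": {
                "name": self.analyte.name,
                "henry_constant": str(self.analyte.henry_constant),
                "pKa": self.analyte.pKa,
                "diffusion_coefficient": str(self.analyte.diffusion_coefficient),
                "notes": self.analyte.notes,
            },
            "gas": {
                "mixing_ratio_ppm": self.gas.mixing_ratio_ppm,
                "total_pressure": str(self.gas.total_pressure),
                "temperature_C": self.gas.temperature_c,
            },
            "medium": {"pH": self.medium.pH, "description": self.medium.description},
            "sensor": {
                "receptor_concentration": str(self.sensor.receptor_concentration),
                "sensing_layer_thickness": str(self.sensor.sensing_layer_thickness),
                "cover_layer_thickness": str(self.sensor.cover_layer_thickness),
                "effective_delta_epsilon": str(self.sensor.effective_delta_epsilon),
            },
            "kinetics": {"rate_constant": str(self.rate_constant)},
            "options": {
                "rounding_mode": self.options.rounding_mode,
                "speciation_method": self.options.speciation_method,
                "diffusion_fraction": self.options.diffusion_fraction,
                "t_ref_s": self.options.t_ref_s,
                "observation_timescale_s": self.options.observation_timescale_s,
                "limitation_threshold_ratio": self.options.limitation_threshold_ratio,
                "gel_partition_factor": self.options.gel_partition_factor,
                "tortuosity": self.options.tortuosity,
                "window_settle_s": self.window_policy.settle_s,
                "window_min_fit_duration_s": self.window_policy.min_fit_duration_s,
                "seed": self.seed,
            },
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _take(section: dict, name: str, keys: dict) -> dict:
    """Pop known keys with defaults; reject anything left over."""
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping, got {type(section).__name__}")
    section = dict(section)
    out = {}
    missing = []
    for key, default in keys.items():
        if key in section:
            out[key] = section.pop(key)
        elif default is ...:
            missing.append(key)
        else:
            out[key] = default
    if missing:
        raise ConfigError(f"section {name!r} missing required keys: {missing}")
    if section:
        raise ConfigError(f"section {name!r} has unknown keys: {sorted(section)}")
    return out


def scenario_from_dict(payload: dict) -> ScenarioConfig:
    if not isinstance(payload, dict):
        raise ConfigError("scenario config must be a mapping at top level")
    payload = dict(payload)
    sections = {}
    for name in ("analyte", "gas", "medium", "sensor", "kinetics"):
        if name not in payload:
            raise ConfigError(f"scenario config missing section {name!r}")
        sections[name] = payload.pop(name)
    opts_raw = payload.pop("options", {}) or {}
    if payload:
        raise ConfigError(f"scenario config has unknown sections: {sorted(payload)}")

    a = _take(sections["analyte"], "analyte", {
        "name": ..., "henry_constant": ..., "pKa": ...,
        "diffusion_coefficient": ..., "notes": "",
    })
    analyte = AnalyteSpec(
        name=str(a["name"]),
        henry_constant=parse_quantity(a["henry_constant"]),
        pKa=float(a["pKa"]),
        diffusion_coefficient=parse_quantity(a["diffusion_coefficient"]),
        notes=str(a["notes"]),
    )
    g = _take(sections["gas"], "gas", {
        "mixing_ratio_ppm": ..., "total_pressure": "1 atm", "temperature_C": 25.0,
    })
    gas = GasSample(
        mixing_ratio_ppm=float(g["mixing_ratio_ppm"]),
        total_pressure=parse_quantity(g["total_pressure"]),
        temperature_c=float(g["temperature_C"]),
    )
    m = _take(sections["medium"], "medium", {"pH": ..., "description": ""})
    medium = MediumSpec(pH=float(m["pH"]), description=str(m["description"]))
    s = _take(sections["sensor"], "sensor", {
        "receptor_concentration": ..., "sensing_layer_thickness": ...,
        "cover_layer_thickness": ..., "effective_delta_epsilon": ...,
    })
    sensor = SensorSpec(
        receptor_concentration=parse_quantity(s["receptor_concentration"]),
        sensing_layer_thickness=parse_quantity(s["sensing_layer_thickness"]),
        cover_layer_thickness=parse_quantity(s["cover_layer_thickness"]),
        effective_delta_epsilon=parse_quantity(s["effective_delta_epsilon"]),
    )
    kin = _take(sections["kinetics"], "kinetics", {"rate_constant": ...})
    rate_constant = parse_quantity(kin["rate_constant"])

    opt_defaults = {f.name: getattr(PredictionOptions(), f.name)
                    for f in dc_fields(PredictionOptions)}
    o = _take(opts_raw, "options", {
        **opt_defaults,
        "window_settle_s": WindowPolicy().settle_s,
        "window_min_fit_duration_s": WindowPolicy().min_fit_duration_s,
        "seed": 0,
    })
    options = PredictionOptions(**{k: o[k] for k in opt_defaults})
    window = WindowPolicy(
        settle_s=float(o["window_settle_s"]),
        min_fit_duration_s=float(o["window_min_fit_duration_s"]),
    )
    return ScenarioConfig(
        analyte=analyte, gas=gas, medium=medium, sensor=sensor,
        rate_constant=rate_constant, options=options,
        window_policy=window, seed=int(o["seed"]),
    )


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a YAML scenario file."""
    with open(path) as fh:
        try:
            payload = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML in {path}: {exc}") from exc
    return scenario_from_dict(payload)


def _methanethiol_cytc() -> ScenarioConfig:
    return scenario_from_dict({
        "analyte": {
            "name": "methanethiol",
            "henry_constant": "0.39 M/atm",
            "pKa": 10.3,
            "diffusion_coefficient": "1.3e-9 m^2/s",
            "notes": "D approximated by methanol (aqueous, tabulated)",
        },
        "gas": {"mixing_ratio_ppm": 100.0, "total_pressure": "1 atm",
                "temperature_C": 25.0},
        "medium": {"pH": 7.0, "description": "10 mM sodium phosphate buffer"},
        "sensor": {
            "receptor_concentration": "10 mM",
            "sensing_layer_thickness": "2.5 um",
            "cover_layer_thickness": "200 nm",
            "effective_delta_epsilon": "22 mM^-1 cm^-1",
        },
        "kinetics": {"rate_constant": "2.8e-3 uM^-1 s^-1"},
    })


PRESETS = {"methanethiol_cytc": _methanethiol_cytc}


def preset(name: str = "methanethiol_cytc") -> ScenarioConfig:
    """Return a built-in scenario preset by name."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
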