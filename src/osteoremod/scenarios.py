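"""Scenario presets, configuration loading and synthetic test fixtures.

The three study conditions are collapsed to their identified energy
levels: sedentary animals remain at the homeostatic energy W0, the
intermittent-running group is driven at W1 (moderate overload, net
formation) and the continuous-running group at W3 (sustained overload,
net resorption).  The within-session structure of the running protocols is
not time-resolved; each scenario is represented by its constant energy
level for the full 56-day (8-week) protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .geometry import (
    BoneGeometry,
    DensityProfileParams,
    MaterialParams,
    Mesh,
    build_mesh,
    density_profile,
    initial_density_field,
)
from .mechanics import DENSITY_FLOOR
from .remodeling import ActivityParams, DelayParams, ModulationParams

_TABLE3 = ActivityParams()

#: scenario name -> driving energy level (mJ)
SCENARIO_ENERGIES = {
    "sedentary": _TABLE3.W0,
    "intermittent": _TABLE3.W1,
    "continuous": _TABLE3.W3,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully resolved configuration of one remodeling run."""

    name: Literal["sedentary", "intermittent", "continuous", "custom"] = "custom"
    scenario_energy: float = _TABLE3.W0     # mJ
    duration: float = 56.0                  # days
    dt: float = 0.1                         # days
    coupling_interval: float = 1.0          # days between mechanics re-solves
    energy_mode: Literal["global", "local"] = "global"
    mesh_size: float = 0.1                  # mm
    snapshot_interval: float = 1.0          # days
    body_mass: float = 350.0                # g
    density_floor: float = DENSITY_FLOOR
    front_threshold: float = 0.56
    seed: int = 0                           # reserved; the model is deterministic
    output_dir: str | None = None
    geometry: BoneGeometry = field(default_factory=BoneGeometry)
    profile: DensityProfileParams = field(default_factory=DensityProfileParams)
    material: MaterialParams = field(default_factory=MaterialParams)
    activity: ActivityParams = field(default_factory=ActivityParams)
    modulation: ModulationParams = field(default_factory=ModulationParams)
    delay: DelayParams = field(default_factory=DelayParams)

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0 or self.scenario_energy <= 0:
            raise ValueError("duration, dt and scenario_energy must be positive")
        if self.coupling_interval <= 0 or self.snapshot_interval <= 0:
            raise ValueError("coupling and snapshot intervals must be positive")


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """Named preset with the scenario's identified energy level."""
    if name not in SCENARIO_ENERGIES:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIO_ENERGIES)}")
    return ScenarioConfig(name=name, scenario_energy=SCENARIO_ENERGIES[name], **overrides)


_SCALAR_KEYS = {
    "name", "scenario_energy_mJ", "duration_days", "dt_days",
    "coupling_interval_days", "energy_mode", "mesh_size_mm",
    "snapshot_interval_days", "body_mass_g", "density_floor",
    "front_threshold", "seed", "output_dir", "delay",
    "delay_coefficient", "n_interpolation",
}

_KEY_TO_FIELD = {
    "scenario_energy_mJ": "scenario_energy",
    "duration_days": "duration",
    "dt_days": "dt",
    "coupling_interval_days": "coupling_interval",
    "mesh_size_mm": "mesh_size",
    "snapshot_interval_days": "snapshot_interval",
    "body_mass_g": "body_mass",
}


def load_config(path) -> ScenarioConfig:
    """Read a YAML (or JSON) run configuration.

    Keys carry explicit unit suffixes (``scenario_energy_mJ``,
    ``duration_days``, ...).  Unknown keys are rejected by name; omitted
    keys fall back to the documented defaults.  A ``name`` of one of the
    scenario presets resolves that scenario's energy level unless
    ``scenario_energy_mJ`` is given explicitly.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = set(data) - _SCALAR_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")

    kwargs = {}
    name = data.get("name", "custom")
    if name != "custom":
        if name not in SCENARIO_ENERGIES:
            raise ValueError(f"unknown scenario name {name!r}")
        kwargs["scenario_energy"] = SCENARIO_ENERGIES[name]
    kwargs["name"] = name
    for key, fieldname in _KEY_TO_FIELD.items():
        if key in data:
            kwargs[fieldname] = float(data[key])
    for key in ("energy_mode", "density_floor", "front_threshold", "seed", "output_dir"):
        if key in data:
            kwargs[key] = data[key]
    if "delay" in data or "delay_coefficient" in data:
        kwargs["delay"] = DelayParams(
            mode=data.get("delay", "none"),
            coefficient=data.get("delay_coefficient"),
        )
    if "n_interpolation" in data:
        kwargs["modulation"] = ModulationParams(n_interpolation=data["n_interpolation"])
    return ScenarioConfig(**kwargs)


@dataclass(frozen=True)
class FixtureSpec:
    """Synthetic density-field specification for tests and oracles."""

    profile_kind: Literal["arctan", "shifted", "two_ring", "uniform"] = "arctan"
    shift: float = 0.0              # mm; positive moves the interface outward
    noise_amplitude: float = 0.0
    seed: int = 0
    uniform_value: float = 1.0
    inner_density: float = 0.5      # two_ring
    outer_density: float = 1.0
    ring_radius: float = 0.5        # mm
    mesh_size: float = 0.1
    geometry: BoneGeometry = field(default_factory=BoneGeometry)
    profile: DensityProfileParams = field(default_factory=DensityProfileParams)

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")


def make_fixture(spec: FixtureSpec):
    """Build ``(density_field, mesh)`` for a fixture specification.

    Shifted fixtures translate the arctan profile radially; noise adds a
    smooth seeded perturbation (a few low-order radial cosine modes), so
    the field stays deterministic for a fixed seed.
    """
    mesh = build_mesh(spec.geometry, spec.mesh_size)
    r = mesh.element_r
    if spec.profile_kind == "uniform":
        rho = np.full(mesh.n_elements, float(spec.uniform_value))
    elif spec.profile_kind == "two_ring":
        rho = np.where(r < spec.ring_radius, spec.inner_density, spec.outer_density)
    elif spec.profile_kind in ("arctan", "shifted"):
        shifted_r = np.clip(r - spec.shift, 0.0, None)
        rho = np.asarray(density_profile(shifted_r, spec.profile), dtype=float)
    else:
        raise ValueError(f"unknown profile_kind {spec.profile_kind!r}")
    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        coeffs = rng.standard_normal(4)
        R = spec.geometry.outer_radius
        pert = sum(
            c * np.cos((k + 1) * np.pi * r / R) for k, c in enumerate(coeffs)
        ) / np.sqrt(len(coeffs))
        rho = rho + spec.noise_amplitude * pert
    if np.any(rho <= 0) or np.any(rho > 1.1):
        raise ValueError("fixture produced out-of-range densities")
    return rho, mesh
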