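"""YAML configuration files mirroring :class:`SimulationConfig` fields."""

from __future__ import annotations

from pathlib import Path

import yaml

from .synthetic_electrolyte import ObstacleSpec, SimulationConfig, SlabSpec

__all__ = ["load_config", "dump_config"]


def load_config(path: str | Path, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    Top-level keys mirror the dataclass fields exactly; ``slab`` and
    ``obstacle`` are nested mappings mirroring :class:`SlabSpec` and
    :class:`ObstacleSpec`.  Keyword overrides (e.g. a CLI ``--seed``)
    take precedence over the file.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "slab" in data and data["slab"] is not None:
        data["slab"] = SlabSpec(**data["slab"])
    if "obstacle" in data and data["obstacle"] is not None:
        obs = dict(data["obstacle"])
        if "center" in obs:
            obs["center"] = tuple(obs["center"])
        data["obstacle"] = ObstacleSpec(**obs)
    if "box_lengths" in data:
        data["box_lengths"] = tuple(data["box_lengths"])
    data.update(overrides)
    return SimulationConfig(**data)


def dump_config(config: SimulationConfig, path: str | Path) -> Path:
    """Write a config back to YAML (field names mirror the dataclass)."""
    data: dict = {
        "seed": config.seed,
        "n_steps": config.n_steps,
        "box_lengths": list(config.box_lengths),
        "concentration": config.concentration,
        "temperature": config.temperature,
        "voltage": config.voltage,
        "timestep": config.timestep,
        "save_every": config.save_every,
        "equilibration_steps": config.equilibration_steps,
    }
    if config.diffusion_coefficients is not None:
        data["diffusion_coefficients"] = dict(config.diffusion_coefficients)
    if config.slab is not None:
        data["slab"] = {
            "pore_diameter": config.slab.pore_diameter,
            "center_z": config.slab.center_z,
            "thickness": config.slab.thickness,
        }
    if config.obstacle is not None:
        data["obstacle"] = {
            "radius": config.obstacle.radius,
            "center": list(config.obstacle.center),
            "label": config.obstacle.label,
        }
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
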