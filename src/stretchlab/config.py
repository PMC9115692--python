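"""Device configuration files: material and geometry profiles.

A config is a small TOML or YAML mapping with optional ``material`` and
``geometry`` tables, e.g.::

    [material]
    profile = "VHB4910"     # or explicit c10/c20/c30/eps0/pr

    [geometry]
    t_init = 1e-3
    lam_p = 3.0
    electrode_radius = 5.85e-3
    frame_radius = 30e-3

The only built-in material profile is ``VHB4910`` (the published
parameter set); explicit keys override profile values.
"""

from __future__ import annotations

import tomllib
from dataclasses import replace
from pathlib import Path

import yaml

from .actuation import MembraneGeometry
from .materials import VHB4910, YeohMaterial

__all__ = ["MATERIAL_PROFILES", "load_config", "load_material", "load_geometry"]

MATERIAL_PROFILES: dict[str, YeohMaterial] = {"VHB4910": VHB4910}


def _read_mapping(path) -> dict:
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def load_material(data: dict | None) -> YeohMaterial:
    if not data:
        return VHB4910
    data = dict(data)
    profile = data.pop("profile", "VHB4910")
    if profile not in MATERIAL_PROFILES:
        raise ValueError(
            f"unknown material profile {profile!r}; known: {sorted(MATERIAL_PROFILES)}"
        )
    return replace(MATERIAL_PROFILES[profile], **data)


def load_geometry(data: dict | None) -> MembraneGeometry:
    return MembraneGeometry(**(data or {}))


def load_config(path=None) -> tuple[YeohMaterial, MembraneGeometry]:
    """Material and geometry from a config file; defaults when path is None."""
    if path is None:
        return VHB4910, MembraneGeometry()
    data = _read_mapping(path)
    return load_material(data.get("material")), load_geometry(data.get("geometry"))
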