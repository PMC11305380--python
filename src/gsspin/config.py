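"""Runtime configuration: radii, polyhedra, cut-offs and thresholds.

A single :class:`Settings` object bundles everything the assignment pipeline
needs, with a stable fingerprint so every report can state exactly which
tables produced it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .chem_core import load_covalent_radii
from .errors import ConfigError
from .geometry import DEFAULT_BOND_TOLERANCE, ReferencePolyhedron, load_polyhedra
from .spin_rules import CutoffTable, load_cutoffs


@dataclass
class Settings:
    radii: dict[str, float]
    library: list[ReferencePolyhedron]
    cutoffs: CutoffTable
    bond_tolerance: float = DEFAULT_BOND_TOLERANCE
    geometry_threshold: float = 3.0

    def fingerprint(self) -> str:
        """SHA-256 over a canonical serialization of every table in use."""
        payload = {
            "radii": {k: round(v, 10) for k, v in sorted(self.radii.items())},
            "polyhedra": [
                {"name": p.name, "cn": p.cn,
                 "directions": [[round(float(x), 10) for x in row] for row in p.directions]}
                for p in self.library
            ],
            "cutoffs": {f"{m}|{g}": round(v, 10)
                        for (m, g), v in sorted(self.cutoffs.cutoffs.items())},
            "overrides": {f"{n}|{g}": m for (n, g), m
                          in sorted(self.cutoffs.lowest_spin_overrides.items())},
            "cutoff_version": self.cutoffs.version,
            "bond_tolerance": self.bond_tolerance,
            "geometry_threshold": self.geometry_threshold,
        }
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()


def default_settings() -> Settings:
    return Settings(radii=load_covalent_radii(), library=load_polyhedra(),
                    cutoffs=load_cutoffs())


def load_settings(path: Optional[str] = None) -> Settings:
    """Load a YAML config with optional sections overriding the defaults.

    Recognized keys: ``radii`` (path), ``polyhedra`` (path), ``cutoffs``
    (path), ``bond_tolerance``, ``geometry_threshold``.
    """
    if path is None:
        return default_settings()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must be a YAML mapping")
    settings = Settings(
        radii=load_covalent_radii(raw.get("radii")),
        library=load_polyhedra(raw.get("polyhedra")),
        cutoffs=load_cutoffs(raw.get("cutoffs")),
    )
    if "bond_tolerance" in raw:
        settings.bond_tolerance = float(raw["bond_tolerance"])
        if settings.bond_tolerance < 0:
            raise ConfigError("bond_tolerance must be >= 0")
    if "geometry_threshold" in raw:
        settings.geometry_threshold = float(raw["geometry_threshold"])
        if settings.geometry_threshold <= 0:
            raise ConfigError("geometry_threshold must be positive")
    return settings
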