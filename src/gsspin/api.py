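"""High-level assignment pipeline: structure in, spin assignment out."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chem_core import ComplexRecord
from .config import Settings, default_settings
from .descriptors import relative_metal_radius
from .geometry import classify_geometry, detect_coordination_sphere, geometry_deviation_filter
from .spin_rules import assign_spin


@dataclass
class AssignmentReport:
    """Everything one assignment produced, serializable to JSON."""

    identifier: str
    metal: str
    oxidation_state: int
    d_electron_count: int
    coordination_number: int
    geometry: str
    cshm: float
    all_measures: dict[str, float]
    geometry_reliable: bool
    r_rel: float
    multiplicity: int
    spin_label: str
    rule_trace: list[str]
    config_fingerprint: str
    ml_multiplicity: Optional[int] = None
    ml_probabilities: Optional[dict[str, float]] = None

    def to_dict(self) -> dict:
        out = {
            "identifier": self.identifier,
            "metal": self.metal,
            "oxidation_state": self.oxidation_state,
            "d_electron_count": self.d_electron_count,
            "coordination_number": self.coordination_number,
            "geometry": self.geometry,
            "cshm": round(self.cshm, 6),
            "all_measures": {k: round(v, 6) for k, v in self.all_measures.items()},
            "geometry_reliable": self.geometry_reliable,
            "r_rel": round(self.r_rel, 6),
            "multiplicity": self.multiplicity,
            "spin_label": self.spin_label,
            "rule_trace": self.rule_trace,
            "config_fingerprint": self.config_fingerprint,
        }
        if self.ml_multiplicity is not None:
            out["ml_multiplicity"] = self.ml_multiplicity
            out["ml_probabilities"] = self.ml_probabilities
        return out


def assign_ground_state_spin(
    complex_: ComplexRecord,
    settings: Optional[Settings] = None,
    model=None,
) -> AssignmentReport:
    """Run sphere detection -> geometry -> r_rel -> decision tree.

    If ``model`` (a fitted random forest over F_TM+CE) is supplied, its
    prediction and class probabilities are attached alongside the empirical
    assignment.
    """
    settings = settings or default_settings()
    sphere = detect_coordination_sphere(complex_, settings.radii,
                                        settings.bond_tolerance)
    assignment = classify_geometry(sphere, settings.library)
    reliable = geometry_deviation_filter(assignment, settings.geometry_threshold)
    r_rel = relative_metal_radius(sphere, settings.radii[complex_.metal.symbol])
    spin = assign_spin(complex_.metal, assignment, r_rel.value, settings.cutoffs)

    ml_mult = None
    ml_probs = None
    if model is not None:
        from .descriptors import F_TM_CE, build_features

        fv = build_features(complex_.metal, assignment, r_rel.value, F_TM_CE,
                            settings.library)
        x = fv.values.reshape(1, -1)
        ml_mult = int(model.predict(x)[0])
        ml_probs = {str(int(c)): float(p)
                    for c, p in zip(model.classes_, model.predict_proba(x)[0])}

    return AssignmentReport(
        identifier=complex_.identifier,
        metal=complex_.metal.symbol,
        oxidation_state=complex_.metal.oxidation_state,
        d_electron_count=complex_.metal.d_electron_count,
        coordination_number=sphere.coordination_number,
        geometry=assignment.geometry,
        cshm=assignment.cshm,
        all_measures=assignment.all_measures,
        geometry_reliable=reliable,
        r_rel=r_rel.value,
        multiplicity=spin.multiplicity,
        spin_label=spin.spin_label,
        rule_trace=spin.rule_trace,
        config_fingerprint=settings.fingerprint(),
        ml_multiplicity=ml_mult,
        ml_probabilities=ml_probs,
    )
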