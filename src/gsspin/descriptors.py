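"""Interpretable descriptors: the relative metal radius and feature vectors.

The relative metal radius condenses the first coordination sphere into one
dimensionless number,

    r_rel = (1 / CN) * sum_i ( d(M - A_i) - r_A_i ) / r_M,

the mean apparent radius the metal exhibits toward its donors, expressed in
units of its own covalent radius. r_rel == 1 when every bond equals the
covalent-radius sum; high-spin complexes, whose antibonding-orbital
population lengthens metal-ligand bonds, show systematically larger values
than low-spin ones, which is what makes it a spin-state discriminator.

Three feature vectors feed the statistical models: F_TM = (Z, OS, N_d)
describes the metal center, F_CE = (CN, CG, r_rel) the coordination
environment (CG is the ordinal geometry code from the polyhedron library),
and F_TM+CE their 6-slot concatenation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem_core import MetalCenter
from .errors import IncompleteInputError, ValidationError
from .geometry import CoordinationSphere, GeometryAssignment, ReferencePolyhedron, geometry_code

F_TM = "F_TM"
F_CE = "F_CE"
F_TM_CE = "F_TM+CE"

FEATURE_NAMES = {
    F_TM: ("Z", "OS", "N_d"),
    F_CE: ("CN", "CG", "r_rel"),
    F_TM_CE: ("Z", "OS", "N_d", "CN", "CG", "r_rel"),
}


@dataclass
class RelativeMetalRadius:
    value: float
    per_donor_terms: np.ndarray

    def __float__(self) -> float:
        return self.value


def relative_metal_radius(sphere: CoordinationSphere, r_m: float) -> RelativeMetalRadius:
    """Compute r_rel from a detected coordination sphere.

    Each donor contributes (d(M-A_i) - r_A_i) / r_M; the value is the mean
    over the coordination number. Donor order does not matter.
    """
    if r_m <= 0:
        raise ValidationError("metal covalent radius must be positive")
    if sphere.coordination_number < 1:
        raise ValidationError("need at least one donor")
    d = sphere.distances
    r_a = np.array([donor.covalent_radius for donor in sphere.donors], dtype=float)
    if np.any(d <= 0):
        raise ValidationError("zero metal-donor distance")
    terms = (d - r_a) / r_m
    return RelativeMetalRadius(value=float(terms.mean()), per_donor_terms=terms)


@dataclass
class FeatureVector:
    kind: str
    values: np.ndarray
    names: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def build_features(
    metal: MetalCenter,
    geometry: Optional[GeometryAssignment],
    r_rel: Optional[float],
    kind: str,
    library: Optional[Sequence[ReferencePolyhedron]] = None,
) -> FeatureVector:
    """Assemble F_TM, F_CE or F_TM+CE for one complex.

    Geometry, the library (for the ordinal geometry code) and r_rel are only
    required for the kinds that include coordination-environment slots.
    """
    if kind not in FEATURE_NAMES:
        raise ValidationError(f"unknown feature kind {kind!r}; expected one of {sorted(FEATURE_NAMES)}")

    tm = (float(metal.element.atomic_number),
          float(metal.oxidation_state),
          float(metal.d_electron_count))

    if kind == F_TM:
        values = tm
    else:
        if geometry is None or r_rel is None or library is None:
            raise IncompleteInputError(
                f"{kind} needs a geometry assignment, a polyhedron library and r_rel"
            )
        ce = (float(geometry.coordination_number),
              float(geometry_code(geometry.geometry, library)),
              float(r_rel))
        values = ce if kind == F_CE else tm + ce

    return FeatureVector(kind=kind, values=np.array(values, dtype=float),
                         names=FEATURE_NAMES[kind])
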