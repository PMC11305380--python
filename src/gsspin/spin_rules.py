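"""Rule-based ground-state spin assignment for first-row TM complexes.

The decision tree encodes the empirical regularities of mononuclear Cr, Mn,
Fe, Co and Ni complexes:

  R1  d-counts 0-3 and 9-10 have no spin-state freedom; the multiplicity is
      fixed by the unpaired-electron count.
  R2  Zero-valent centers (and Mn(I)) bind strong-field ligands such as
      carbonyls and phosphines and sit in the lowest parity-consistent spin
      state (singlet for even d-counts, doublet for odd).
  R3  Co(III) octahedral (d6) is always a singlet; Ni(III) (d7) is always a
      doublet, regardless of geometry.
  R4  Coordination numbers of 2, or greater than 6, imply a weak ligand
      field (sterically enforced in the former, crowding-diluted in the
      latter) and give high spin.
  R5  Geometries with genuine spin-state variability (octahedral, square
      planar, square pyramidal, trigonal bipyramidal) are split by the
      relative metal radius against a metal- and geometry-specific cut-off:
      strictly below the cut-off -> lowest spin, otherwise high spin. For
      d4 octahedral and d6 square-planar/trigonal-bipyramidal complexes the
      lowest accessible state is a triplet, not the parity minimum.
  R6  Remaining geometries (tetrahedral, trigonal prismatic, seesaw, the
      planar low-CN shapes) are observed exclusively high spin.

Intermediate-spin states are never emitted: square-pyramidal d6 complexes
that are really triplets would need a second cut-off, a known limitation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .chem_core import SPIN_LABELS, MetalCenter, multiplicity_from_unpaired
from .errors import ConfigError, ValidationError
from .geometry import GeometryAssignment


def high_spin_multiplicity(n_d: int) -> int:
    """Multiplicity with the maximum number of unpaired d electrons."""
    if not 0 <= n_d <= 10:
        raise ValidationError(f"d-count {n_d} outside 0..10")
    unpaired = n_d if n_d <= 5 else 10 - n_d
    return unpaired + 1


def lowest_spin_multiplicity(n_d: int) -> int:
    """Parity-minimal multiplicity: singlet (even N_d) or doublet (odd)."""
    if not 0 <= n_d <= 10:
        raise ValidationError(f"d-count {n_d} outside 0..10")
    return 1 if n_d % 2 == 0 else 2


@dataclass
class CutoffTable:
    """r_rel cut-offs per (metal, geometry) plus lowest-spin overrides."""

    cutoffs: dict[tuple[str, str], float]
    lowest_spin_overrides: dict[tuple[int, str], int] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self):
        for key, value in self.cutoffs.items():
            if value <= 0:
                raise ConfigError(f"cut-off for {key} must be positive, got {value}")
        for (n_d, geom), mult in self.lowest_spin_overrides.items():
            if (mult - 1) % 2 != n_d % 2:
                raise ConfigError(
                    f"override multiplicity {mult} parity-inconsistent with d-count {n_d}"
                )

    def lookup(self, metal_symbol: str, geometry: str) -> Optional[float]:
        return self.cutoffs.get((metal_symbol, geometry))

    def lowest_spin(self, n_d: int, geometry: str) -> int:
        return self.lowest_spin_overrides.get((n_d, geometry),
                                              lowest_spin_multiplicity(n_d))


def load_cutoffs(path: Optional[str] = None) -> CutoffTable:
    """Load the cut-off table from YAML (bundled default if no path)."""
    if path is None:
        text = resources.files("gsspin.data").joinpath("cutoffs.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    try:
        cutoffs = {
            (metal, geom): float(value)
            for metal, table in raw["cutoffs"].items()
            for geom, value in table.items()
        }
        overrides = {
            (int(e["n_d"]), str(e["geometry"])): int(e["multiplicity"])
            for e in raw.get("lowest_spin_overrides", [])
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed cut-off table: {exc}") from exc
    return CutoffTable(cutoffs=cutoffs, lowest_spin_overrides=overrides,
                       version=str(raw.get("version", "unversioned")))


@dataclass
class SpinAssignment:
    multiplicity: int
    rule_trace: list[str]

    @property
    def spin_label(self) -> str:
        return SPIN_LABELS[self.multiplicity]


def assign_spin(
    metal: MetalCenter,
    geometry: GeometryAssignment,
    r_rel: float,
    cutoffs: CutoffTable,
) -> SpinAssignment:
    """Walk the decision tree; returns the multiplicity and the fired rules.

    The trace records every traversed decision so an assignment can be
    audited; identical inputs always give identical traces.
    """
    n_d = metal.d_electron_count
    sym = metal.symbol
    os_ = metal.oxidation_state
    cn = geometry.coordination_number
    trace: list[str] = [f"enter:{sym}(+{os_}) d{n_d} {geometry.geometry} cn{cn}"]

    if n_d in (0, 1, 2, 3, 9, 10):
        trace.append("R1:fixed-by-unpaired-count")
        return SpinAssignment(multiplicity_from_unpaired(n_d), trace)
    trace.append("R1:d4-d8-needs-environment")

    if os_ == 0:
        trace.append("R2:zero-valent-strong-field")
        return SpinAssignment(lowest_spin_multiplicity(n_d), trace)
    if sym == "Mn" and os_ == 1:
        trace.append("R2:mn(i)-strong-field")
        return SpinAssignment(lowest_spin_multiplicity(n_d), trace)
    trace.append("R2:not-low-valent")

    if sym == "Co" and os_ == 3 and geometry.geometry == "octahedral":
        trace.append("R3:co(iii)-octahedral-singlet")
        return SpinAssignment(1, trace)
    if sym == "Ni" and os_ == 3:
        trace.append("R3:ni(iii)-doublet")
        return SpinAssignment(2, trace)
    trace.append("R3:no-constant-spin-exception")

    if cn == 2 or cn > 6:
        trace.append("R4:extreme-cn-high-spin")
        return SpinAssignment(high_spin_multiplicity(n_d), trace)
    trace.append("R4:cn-in-3..6")

    cutoff = cutoffs.lookup(sym, geometry.geometry)
    if cutoff is not None:
        if r_rel < cutoff:
            trace.append(f"R5:r_rel<{cutoff}-lowest-spin")
            return SpinAssignment(cutoffs.lowest_spin(n_d, geometry.geometry), trace)
        trace.append(f"R5:r_rel>={cutoff}-high-spin")
        return SpinAssignment(high_spin_multiplicity(n_d), trace)
    trace.append("R5:no-cutoff-entry")

    trace.append("R6:hs-only-geometry")
    return SpinAssignment(high_spin_multiplicity(n_d), trace)
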