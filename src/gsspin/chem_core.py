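"""Periodic-table facts, d-electron bookkeeping, and the complex data model.

The supported metals are the first-row transition metals Cr, Mn, Fe, Co and
Ni, whose formal d-electron count follows the usual group-minus-oxidation-
state convention (Cr is group 6, ..., Ni is group 10). Covalent radii are
loaded from a small editable YAML table bundled as package data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import MissingRadiusError, UnsupportedElementError, ValidationError

# Atomic numbers for elements that plausibly appear in a coordination sphere
# or as spectators. Extend freely; parity bookkeeping is the only consumer.
ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9,
    "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17,
    "K": 19, "Ca": 20, "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28,
    "Cu": 29, "Zn": 30, "Ge": 32, "As": 33, "Se": 34, "Br": 35,
    "Sb": 51, "Te": 52, "I": 53,
}

#: Periodic group of each supported metal; N_d = group - oxidation state.
METAL_GROUPS = {"Cr": 6, "Mn": 7, "Fe": 8, "Co": 9, "Ni": 10}

SPIN_LABELS = {1: "singlet", 2: "doublet", 3: "triplet",
               4: "quartet", 5: "quintet", 6: "sextet"}


def load_covalent_radii(path: Optional[str] = None) -> dict[str, float]:
    """Load the covalent-radius table (angstrom) from YAML.

    Without ``path`` the bundled crystallographic-analysis values are used.
    """
    if path is None:
        text = resources.files("gsspin.data").joinpath("covalent_radii.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = yaml.safe_load(text)
    out = {str(k): float(v) for k, v in table.items()}
    for sym, r in out.items():
        if r <= 0:
            raise ValidationError(f"covalent radius for {sym} must be positive, got {r}")
    return out


def covalent_radius(symbol: str, radii: Optional[dict[str, float]] = None) -> float:
    radii = radii if radii is not None else load_covalent_radii()
    try:
        return radii[symbol]
    except KeyError:
        raise MissingRadiusError(symbol) from None


@dataclass(frozen=True)
class ElementInfo:
    symbol: str
    atomic_number: int
    covalent_radius: float
    group: Optional[int] = None

    def __post_init__(self):
        if self.covalent_radius <= 0:
            raise ValidationError("covalent_radius must be positive")
        if self.group is not None and not 1 <= self.group <= 18:
            raise ValidationError(f"group {self.group} outside 1..18")
        known = ATOMIC_NUMBERS.get(self.symbol)
        if known is not None and known != self.atomic_number:
            raise ValidationError(
                f"atomic number {self.atomic_number} inconsistent with {self.symbol}"
            )


def element_info(symbol: str, radii: Optional[dict[str, float]] = None) -> ElementInfo:
    if symbol not in ATOMIC_NUMBERS:
        raise UnsupportedElementError(f"unknown element {symbol!r}")
    return ElementInfo(
        symbol=symbol,
        atomic_number=ATOMIC_NUMBERS[symbol],
        covalent_radius=covalent_radius(symbol, radii),
        group=METAL_GROUPS.get(symbol),
    )


def d_electron_count(metal_symbol: str, oxidation_state: int) -> int:
    """Formal d-electron count N_d = group - OS for a supported metal.

    Raises :class:`UnsupportedElementError` for metals outside Cr..Ni and
    :class:`ValidationError` for an oxidation state outside 0..group.
    """
    try:
        group = METAL_GROUPS[metal_symbol]
    except KeyError:
        raise UnsupportedElementError(
            f"{metal_symbol!r} is not a supported first-row metal "
            f"(expected one of {sorted(METAL_GROUPS)})"
        ) from None
    if not 0 <= oxidation_state <= group:
        raise ValidationError(
            f"oxidation state {oxidation_state} outside 0..{group} for {metal_symbol}"
        )
    return group - oxidation_state


def candidate_multiplicities(parity: str) -> tuple[int, int, int]:
    """Accessible multiplicities for an electron-count parity.

    Even electron counts can be singlet/triplet/quintet, odd ones
    doublet/quartet/sextet.
    """
    if parity == "even":
        return (1, 3, 5)
    if parity == "odd":
        return (2, 4, 6)
    raise ValidationError(f"parity must be 'even' or 'odd', got {parity!r}")


def multiplicity_from_unpaired(n_d: int) -> int:
    """Multiplicity fixed by the unpaired-electron count alone.

    Valid only for d-counts 0-3 and 9-10, where high and low spin coincide;
    d4-d8 require the ligand-field decision tree.
    """
    from .errors import OutOfRuleDomainError

    if n_d not in (0, 1, 2, 3, 9, 10):
        raise OutOfRuleDomainError(
            f"d-count {n_d} has spin-state freedom; use the decision tree"
        )
    unpaired = n_d if n_d <= 5 else 10 - n_d
    return unpaired + 1


@dataclass(frozen=True)
class MetalCenter:
    """A supported metal in a formal oxidation state."""

    element: ElementInfo
    oxidation_state: int

    def __post_init__(self):
        # delegates range/identity checks
        d_electron_count(self.element.symbol, self.oxidation_state)

    @property
    def symbol(self) -> str:
        return self.element.symbol

    @property
    def d_electron_count(self) -> int:
        return d_electron_count(self.element.symbol, self.oxidation_state)


def metal_center(symbol: str, oxidation_state: int,
                 radii: Optional[dict[str, float]] = None) -> MetalCenter:
    if symbol not in METAL_GROUPS:
        raise UnsupportedElementError(
            f"{symbol!r} is not a supported first-row metal"
        )
    return MetalCenter(element=element_info(symbol, radii), oxidation_state=oxidation_state)


@dataclass
class ComplexRecord:
    """A mononuclear complex: symbols, Cartesian coordinates (angstrom), metal.

    ``total_charge`` is the charge of the whole complex; when it is unknown
    the electron parity is inferred from the d-count under a closed-shell
    ligand assumption (see :func:`electron_parity`).
    """

    identifier: str
    metal: MetalCenter
    symbols: list[str]
    coords: np.ndarray
    metal_index: int
    total_charge: Optional[int] = None
    comment: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.symbols) < 2:
            raise ValidationError("a complex needs at least 2 atoms")
        if self.coords.shape != (len(self.symbols), 3):
            raise ValidationError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if not 0 <= self.metal_index < len(self.symbols):
            raise ValidationError("metal_index out of range")
        if self.symbols[self.metal_index] != self.metal.symbol:
            raise ValidationError(
                f"atom {self.metal_index} is {self.symbols[self.metal_index]}, "
                f"not the declared metal {self.metal.symbol}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def metal_position(self) -> np.ndarray:
        return self.coords[self.metal_index]


def electron_parity(complex_: ComplexRecord) -> tuple[str, bool]:
    """Electron-count parity of a complex, ``(parity, inferred)``.

    With a known total charge the parity is that of sum(Z) - charge. Without
    one, closed-shell ligands are assumed and the parity is that of the
    metal's d-count; ``inferred`` is True in that case.
    """
    if complex_.total_charge is not None:
        total = 0
        for sym in complex_.symbols:
            try:
                total += ATOMIC_NUMBERS[sym]
            except KeyError:
                raise UnsupportedElementError(f"no atomic number for {sym!r}") from None
        total -= complex_.total_charge
        return ("even" if total % 2 == 0 else "odd", False)
    n_d = complex_.metal.d_electron_count
    return ("even" if n_d % 2 == 0 else "odd", True)
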