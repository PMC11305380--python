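"""Minimal XYZ structure I/O (element + Cartesian angstrom per line)."""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from .chem_core import ComplexRecord, metal_center
from .errors import ValidationError, XYZParseError


def read_xyz(path: Union[str, Path]) -> tuple[list[str], np.ndarray, str]:
    """Read one XYZ frame -> (symbols, coords, comment)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}: first line must be the atom count") from None
    if len(lines) < n + 2:
        raise XYZParseError(f"{path}: expected {n} atom lines, file too short")
    comment = lines[1].rstrip("\n")
    symbols: list[str] = []
    coords = np.empty((n, 3), dtype=float)
    for i, line in enumerate(lines[2:2 + n]):
        tokens = line.split()
        if len(tokens) < 4:
            raise XYZParseError(f"{path}: atom line {i + 3} has {len(tokens)} tokens, need 4")
        symbols.append(tokens[0])
        try:
            coords[i] = [float(t) for t in tokens[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}: non-numeric coordinate on line {i + 3}") from None
    return symbols, coords, comment


def write_xyz(path: Union[str, Path], symbols: list[str], coords: np.ndarray,
              comment: str = "") -> None:
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{len(symbols)}\n{comment}\n")
        for sym, (x, y, z) in zip(symbols, coords):
            fh.write(f"{sym:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def complex_from_xyz(
    path: Union[str, Path],
    metal_symbol: str,
    oxidation_state: int,
    identifier: Optional[str] = None,
    total_charge: Optional[int] = None,
    metal_index: Optional[int] = None,
    radii: Optional[dict[str, float]] = None,
) -> ComplexRecord:
    """Build a ComplexRecord from an XYZ file and the metal identity.

    If ``metal_index`` is omitted the metal must occur exactly once.
    """
    symbols, coords, comment = read_xyz(path)
    if metal_index is None:
        hits = [i for i, s in enumerate(symbols) if s == metal_symbol]
        if not hits:
            raise ValidationError(f"{path}: metal {metal_symbol} not found")
        if len(hits) > 1:
            raise ValidationError(
                f"{path}: {metal_symbol} occurs {len(hits)} times; pass metal_index"
            )
        metal_index = hits[0]
    return ComplexRecord(
        identifier=identifier or Path(path).stem,
        metal=metal_center(metal_symbol, oxidation_state, radii),
        symbols=symbols,
        coords=coords,
        metal_index=metal_index,
        total_charge=total_charge,
        comment=comment,
    )


def complex_to_xyz(path: Union[str, Path], complex_: ComplexRecord) -> None:
    write_xyz(path, complex_.symbols, complex_.coords,
              comment=complex_.comment or complex_.identifier)
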