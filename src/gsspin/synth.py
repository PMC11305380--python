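"""Synthetic complexes and spin-state tables for end-to-end testing.

The generator emulates the structural variety of a curated crystallographic
dataset of mononuclear first-row TM complexes: every supported metal in its
observed oxidation states, 18 coordination geometries spanning CN 2-8, and
donor spheres drawn from the seven most common donor elements. Donors are
placed on the ideal polyhedron vertices at ``elongation * (r_M + r_A)`` from
the metal, rigidly rotated, and jittered with per-component Gaussian noise.
Bond elongation is the spin handle: low-spin complexes are generated at the
covalent-radius sum (elongation 1.0) and high-spin ones 15% longer,
mimicking the antibonding-driven bond lengthening of real HS complexes.

Only the first coordination sphere is modeled (no multi-atom ligand
scaffolds) -- sufficient for every downstream operation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    ComplexRecord,
    MetalCenter,
    load_covalent_radii,
    metal_center,
    multiplicity_from_unpaired,
)
from .descriptors import relative_metal_radius
from .errors import ConfigError
from .geometry import (
    ReferencePolyhedron,
    classify_geometry,
    detect_coordination_sphere,
    load_polyhedra,
)
from .spin_rules import (
    CutoffTable,
    assign_spin,
    high_spin_multiplicity,
    load_cutoffs,
    lowest_spin_multiplicity,
)

#: Oxidation states represented per metal in the emulated dataset.
OBSERVED_OXIDATION_STATES = {
    "Cr": (0, 2, 3),
    "Mn": (1, 2, 3),
    "Fe": (0, 2, 3),
    "Co": (1, 2, 3),
    "Ni": (0, 2, 3),
}

#: The seven most frequent donor elements, most common first.
DONOR_PALETTE = ("N", "O", "C", "S", "P", "Cl", "Br")

#: LS bonds sit at the covalent-radius sum; HS bonds are ~12% longer
#: (about 0.2 angstrom on a typical 2 angstrom metal-donor bond), which
#: keeps even the largest palette donor within the bonding cutoff.
LS_ELONGATION = 1.00
HS_ELONGATION = 1.12


@dataclass
class SynthSpec:
    """Recipe for one synthetic complex."""

    metal: str
    oxidation_state: int
    geometry: str
    bond_elongation: float = LS_ELONGATION
    distortion_amplitude: float = 0.0  # angstrom, per Cartesian component
    donors: Optional[Sequence[str]] = None  # explicit per-vertex elements
    seed: int = 0

    def __post_init__(self):
        if self.bond_elongation <= 0:
            raise ConfigError("bond_elongation must be positive")
        if self.distortion_amplitude < 0:
            raise ConfigError("distortion_amplitude must be >= 0")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _find_reference(name: str, library: Sequence[ReferencePolyhedron]) -> ReferencePolyhedron:
    for ref in library:
        if ref.name == name:
            return ref
    raise ConfigError(f"unknown geometry {name!r}")


def generate_complex(
    spec: SynthSpec,
    radii: Optional[dict[str, float]] = None,
    library: Optional[Sequence[ReferencePolyhedron]] = None,
    identifier: Optional[str] = None,
) -> ComplexRecord:
    """Build one synthetic complex from a spec; deterministic per seed."""
    radii = radii if radii is not None else load_covalent_radii()
    library = library if library is not None else load_polyhedra()
    ref = _find_reference(spec.geometry, library)
    rng = np.random.default_rng(spec.seed)

    if spec.donors is not None:
        donors = list(spec.donors)
        if len(donors) != ref.cn:
            raise ConfigError(
                f"{len(donors)} donor elements for {spec.geometry} (cn {ref.cn})"
            )
    else:
        donors = [DONOR_PALETTE[i] for i in rng.integers(0, len(DONOR_PALETTE), ref.cn)]
    for sym in donors:
        if sym not in radii:
            raise ConfigError(f"no covalent radius for donor {sym!r}")
    if spec.metal not in radii:
        raise ConfigError(f"no covalent radius for metal {spec.metal!r}")

    r_m = radii[spec.metal]
    rot = _random_rotation(rng)
    directions = ref.directions @ rot.T
    dists = spec.bond_elongation * (r_m + np.array([radii[s] for s in donors]))
    positions = directions * dists[:, None]
    if spec.distortion_amplitude > 0:
        positions = positions + rng.normal(0.0, spec.distortion_amplitude,
                                           size=positions.shape)

    symbols = [spec.metal] + donors
    coords = np.vstack([np.zeros(3), positions])
    return ComplexRecord(
        identifier=identifier or f"synth-{spec.metal}{spec.oxidation_state}-{spec.geometry}-{spec.seed}",
        metal=metal_center(spec.metal, spec.oxidation_state, radii),
        symbols=symbols,
        coords=coords,
        metal_index=0,
        comment=f"synthetic {spec.geometry} elongation={spec.bond_elongation}",
    )


def implied_multiplicity(
    metal: MetalCenter,
    geometry: str,
    cn: int,
    regime: str,
    cutoffs: CutoffTable,
) -> int:
    """Ground-truth multiplicity implied by the construction of a complex.

    Fixed-spin situations (d-counts 0-3/9-10, low-valent strong-field
    centers, the constant Co(III)/Ni(III) cases, extreme CN, HS-only
    geometries) ignore the bond-length regime; only geometries with genuine
    spin freedom take their truth from whether the complex was built with
    LS- or HS-regime bonds.
    """
    n_d = metal.d_electron_count
    if n_d in (0, 1, 2, 3, 9, 10):
        return multiplicity_from_unpaired(n_d)
    if metal.oxidation_state == 0 or (metal.symbol == "Mn" and metal.oxidation_state == 1):
        return lowest_spin_multiplicity(n_d)
    if metal.symbol == "Co" and metal.oxidation_state == 3 and geometry == "octahedral":
        return 1
    if metal.symbol == "Ni" and metal.oxidation_state == 3:
        return 2
    if cn == 2 or cn > 6:
        return high_spin_multiplicity(n_d)
    if cutoffs.lookup(metal.symbol, geometry) is not None:
        if regime == "LS":
            return cutoffs.lowest_spin(n_d, geometry)
        return high_spin_multiplicity(n_d)
    return high_spin_multiplicity(n_d)


def generate_labeled_dataset(
    n: int,
    seed: int = 0,
    ls_elongation: float = LS_ELONGATION,
    hs_elongation: float = HS_ELONGATION,
    label_noise: float = 0.0,
    distortion_amplitude: float = 0.02,
    radii: Optional[dict[str, float]] = None,
    library: Optional[Sequence[ReferencePolyhedron]] = None,
    cutoffs: Optional[CutoffTable] = None,
) -> pd.DataFrame:
    """Generate n complexes, run the full structural pipeline, label them.

    Each row carries the F_TM+CE feature slots (Z, OS, N_d, CN, CG, r_rel),
    the classified geometry and shape measure, the generating regime and
    elongation, the construction-implied ``truth`` multiplicity, and the
    decision-tree ``label`` (optionally flipped at ``label_noise`` to a
    different parity-consistent multiplicity). With zero noise the label is
    a deterministic function of the feature slots.
    """
    if not ls_elongation < hs_elongation:
        raise ConfigError("ls_elongation must be smaller than hs_elongation")
    if not 0.0 <= label_noise < 1.0:
        raise ConfigError("label_noise must be in [0, 1)")
    radii = radii if radii is not None else load_covalent_radii()
    library = library if library is not None else load_polyhedra()
    cutoffs = cutoffs if cutoffs is not None else load_cutoffs()
    rng = np.random.default_rng(seed)

    metals = sorted(OBSERVED_OXIDATION_STATES)
    rows = []
    for i in range(n):
        metal_sym = metals[rng.integers(len(metals))]
        os_choices = OBSERVED_OXIDATION_STATES[metal_sym]
        os_ = int(os_choices[rng.integers(len(os_choices))])
        ref = library[rng.integers(len(library))]
        regime = "LS" if rng.random() < 0.5 else "HS"
        elongation = ls_elongation if regime == "LS" else hs_elongation
        # regenerate in the rare case jitter pushes a donor past the cutoff
        for _attempt in range(10):
            spec = SynthSpec(
                metal=metal_sym,
                oxidation_state=os_,
                geometry=ref.name,
                bond_elongation=elongation,
                distortion_amplitude=distortion_amplitude,
                seed=int(rng.integers(2 ** 31)),
            )
            cx = generate_complex(spec, radii=radii, library=library,
                                  identifier=f"SYN-{i:05d}")
            sphere = detect_coordination_sphere(cx, radii)
            if sphere.coordination_number == ref.cn:
                break
        assignment = classify_geometry(sphere, library)
        r_rel = relative_metal_radius(sphere, radii[metal_sym])
        spin = assign_spin(cx.metal, assignment, r_rel.value, cutoffs)
        truth = implied_multiplicity(cx.metal, ref.name, sphere.coordination_number,
                                     regime, cutoffs)

        label = spin.multiplicity
        if label_noise > 0 and rng.random() < label_noise:
            pool = [m for m in ((1, 3, 5) if label % 2 == 1 else (2, 4, 6))
                    if m != label]
            label = int(pool[rng.integers(len(pool))])

        code = next(j for j, r in enumerate(library) if r.name == assignment.geometry)
        rows.append({
            "identifier": cx.identifier,
            "metal": metal_sym,
            "Z": float(cx.metal.element.atomic_number),
            "OS": float(os_),
            "N_d": float(cx.metal.d_electron_count),
            "CN": float(sphere.coordination_number),
            "CG": float(code),
            "r_rel": r_rel.value,
            "geometry": assignment.geometry,
            "cshm": assignment.cshm,
            "regime": regime,
            "elongation": elongation,
            "truth": truth,
            "rule_multiplicity": spin.multiplicity,
            "label": label,
        })
    return pd.DataFrame(rows)


def generate_spin_energy_table(
    n: int,
    seed: int = 0,
    small_gap_fraction: float = 0.0,
    contamination_fraction: float = 0.0,
    all_failed_fraction: float = 0.0,
    gap_range: tuple[float, float] = (6.0, 25.0),
    small_gap_range: tuple[float, float] = (0.5, 4.5),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic per-complex spin-state energy/<S^2> tables with known truth.

    Each complex gets three parity-consistent states; a planted fraction is
    given a ground-to-second gap below 5 kcal/mol, a fraction is given a
    contaminated ground-state <S^2>, and a fraction fails to converge in all
    states. Returns ``(records, truth)``: the records table in the curation
    CSV dialect and a per-complex truth table of what was planted.
    """
    rng = np.random.default_rng(seed)
    rec_rows, truth_rows = [], []
    for i in range(n):
        ident = f"SYN-{i:05d}"
        mults = (1, 3, 5) if rng.random() < 0.5 else (2, 4, 6)
        ground = int(mults[rng.integers(3)])
        small = rng.random() < small_gap_fraction
        contaminated = rng.random() < contamination_fraction
        failed = rng.random() < all_failed_fraction

        base = float(rng.uniform(-100.0, 0.0))
        gap2 = float(rng.uniform(*small_gap_range) if small else rng.uniform(*gap_range))
        gap3 = gap2 + float(rng.uniform(2.0, 20.0))
        others = [m for m in mults if m != ground]
        rng.shuffle(others)
        energies = {ground: base, others[0]: base + gap2, others[1]: base + gap3}

        for mult in mults:
            s = (mult - 1) / 2
            exact = s * (s + 1)
            tol = 0.1 if mult <= 2 else 0.2
            if mult == ground and contaminated:
                # contamination mixes in higher-spin determinants: <S^2> inflates
                s2 = exact + tol + float(rng.uniform(0.05, 0.3))
            else:
                dev = float(rng.uniform(0.0, 0.4 * tol))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                s2 = max(exact + sign * dev, 0.0)
            rec_rows.append({
                "identifier": ident,
                "multiplicity": mult,
                "energy": energies[mult],
                "energy_unit": "kcal/mol",
                "s2": s2,
                "converged": not failed,
            })
        truth_rows.append({
            "identifier": ident,
            "multiplicity": ground,
            "small_gap": small,
            "contaminated": contaminated,
            "all_failed": failed,
        })
    return pd.DataFrame(rec_rows), pd.DataFrame(truth_rows)
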