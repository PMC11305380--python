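"""Dataset curation: ground-state selection, reliability filters, sampling.

Consumes per-complex tables of spin-state electronic energies and <S^2>
expectation values (one row per attempted multiplicity) and reduces them to
a curated set of (complex, ground-state spin) pairs:

  * the ground state is the lowest-energy converged state;
  * complexes whose ground-to-second energy gap is below 5 kcal/mol are
    dropped (below the reliability of DFT spin-state energetics, and the
    regime where spin-crossover behavior lives);
  * complexes whose ground-state <S^2> deviates from S(S+1) by more than
    0.1 (singlet/doublet) or 0.2 (higher multiplicities) are dropped as
    spin-contaminated.

Also provides the stratified sampler used to build a diverse subset in which
every (metal, OS, CN, geometry, donor-composition) group is represented, and
conservative structural flags for non-innocent (nitrosyl) and suspected
haptic ligands.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Hashable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chem_core import ComplexRecord
from .errors import AllStatesFailedError, InfeasibleSamplingError, ValidationError
from .geometry import DEFAULT_BOND_TOLERANCE, detect_coordination_sphere

HARTREE_TO_KCAL = 627.5095


@dataclass(frozen=True)
class SpinStateRecord:
    multiplicity: int
    energy: float  # kcal/mol (absolute or relative; consistent per complex)
    s2_expectation: Optional[float] = None
    converged: bool = True

    @property
    def spin(self) -> float:
        return (self.multiplicity - 1) / 2

    @property
    def s2_exact(self) -> float:
        s = self.spin
        return s * (s + 1)


@dataclass
class CurationConfig:
    gap_threshold: float = 5.0      # kcal/mol
    s2_tol_low: float = 0.1         # singlet/doublet
    s2_tol_high: float = 0.2        # triplet and above
    geometry_threshold: float = 3.0  # CShM units

    def __post_init__(self):
        for name in ("gap_threshold", "s2_tol_low", "s2_tol_high", "geometry_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class GroupKey:
    """Stratification key: what makes two complexes 'the same kind'."""

    metal: str
    oxidation_state: int
    coordination_number: int
    geometry: str
    composition: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "composition", tuple(sorted(self.composition)))


@dataclass
class GroundState:
    multiplicity: int
    gap: Optional[float]       # kcal/mol to the second-lowest state; None if single state
    record: SpinStateRecord
    tie: bool = False


def select_ground_state(records: Sequence[SpinStateRecord]) -> GroundState:
    """Lowest-energy converged state and its gap to the runner-up.

    Exact energy ties are resolved toward the lower multiplicity and flagged.
    """
    converged = [r for r in records if r.converged]
    if not converged:
        raise AllStatesFailedError("no spin state converged for this complex")
    ordered = sorted(converged, key=lambda r: (r.energy, r.multiplicity))
    ground = ordered[0]
    if len(ordered) == 1:
        return GroundState(ground.multiplicity, None, ground)
    gap = ordered[1].energy - ground.energy
    return GroundState(ground.multiplicity, float(gap), ground,
                       tie=(gap == 0.0))


def gap_filter(gap: Optional[float], config: CurationConfig) -> bool:
    """Keep iff the ground-to-second gap is defined and not below threshold.

    'Smaller than' is strict: a gap exactly at the threshold is kept. An
    undefined gap (only one accessible state) cannot certify an unambiguous
    ground state and is dropped.
    """
    if gap is None:
        return False
    return gap >= config.gap_threshold


def spin_contamination_filter(ground: SpinStateRecord,
                              config: CurationConfig) -> tuple[bool, Optional[str]]:
    """Keep iff |<S^2> - S(S+1)| is within tolerance; boundary inclusive.

    Returns ``(keep, warning)``; a missing <S^2> keeps the record but warns.
    """
    if ground.s2_expectation is None:
        return True, "missing <S^2>; contamination not checked"
    tol = config.s2_tol_low if ground.multiplicity <= 2 else config.s2_tol_high
    deviation = abs(ground.s2_expectation - ground.s2_exact)
    # tiny slack so a deviation exactly at the tolerance survives float round-off
    return deviation <= tol + 1e-9, None


def stratified_sample(
    items: Sequence,
    key_fn: Callable[[object], Hashable],
    n_target: int,
    seed: int,
) -> list:
    """Seeded stratified subsample: every nonempty group contributes >= 1.

    Beyond the one-per-group floor, slots are allocated proportionally to
    group size by largest remainder (capped at group size); within a group
    the draw is uniform without replacement. Deterministic for a fixed seed.
    """
    groups: dict[Hashable, list] = defaultdict(list)
    for item in items:
        groups[key_fn(item)].append(item)
    keys = sorted(groups, key=repr)  # canonical order for determinism
    n_groups = len(keys)
    total = len(items)
    if n_target < n_groups:
        raise InfeasibleSamplingError(
            f"target {n_target} smaller than the {n_groups} nonempty groups"
        )
    if n_target > total:
        raise InfeasibleSamplingError(f"target {n_target} exceeds population {total}")

    sizes = np.array([len(groups[k]) for k in keys], dtype=int)
    quota = np.ones(n_groups, dtype=int)
    remaining = n_target - n_groups
    while remaining > 0:
        capacity = sizes - quota
        open_ = capacity > 0
        weights = np.where(open_, sizes, 0).astype(float)
        ideal = remaining * weights / weights.sum()
        add = np.minimum(np.floor(ideal).astype(int), capacity)
        leftover = remaining - int(add.sum())
        if leftover > 0:
            frac = np.where(capacity - add > 0, ideal - np.floor(ideal), -1.0)
            # largest remainders first; index order breaks ties
            for idx in np.argsort(-frac, kind="stable"):
                if leftover == 0:
                    break
                if capacity[idx] - add[idx] > 0:
                    add[idx] += 1
                    leftover -= 1
        if add.sum() == 0:
            raise InfeasibleSamplingError("allocation stalled")  # pragma: no cover
        quota += add
        remaining = n_target - int(quota.sum())

    rng = np.random.default_rng(seed)
    chosen: list = []
    for k, q in zip(keys, quota):
        members = groups[k]
        idx = rng.choice(len(members), size=int(q), replace=False)
        chosen.extend(members[i] for i in sorted(idx))
    return chosen


def _bond_graph(complex_: ComplexRecord, radii: dict[str, float],
                tolerance: float) -> nx.Graph:
    g = nx.Graph()
    n = complex_.n_atoms
    g.add_nodes_from(range(n))
    coords = complex_.coords
    for i in range(n):
        ri = radii.get(complex_.symbols[i])
        if ri is None:
            continue
        for j in range(i + 1, n):
            rj = radii.get(complex_.symbols[j])
            if rj is None:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= ri + rj + tolerance:
                g.add_edge(i, j)
    return g


def ligand_exclusion_flags(
    complex_: ComplexRecord,
    radii: dict[str, float],
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> set[str]:
    """Structural red flags: 'nitrosyl' and 'suspected-haptic'.

    Nitrosyl: an N donor bonded (outside the metal) to exactly one O and
    nothing else. Suspected haptic: two or more mutually bonded carbon
    donors, the signature of a pi-face (e.g. cyclopentadienyl) coordinating
    through adjacent ring atoms. Pure flagging; the caller decides exclusion.
    """
    sphere = detect_coordination_sphere(complex_, radii, tolerance)
    graph = _bond_graph(complex_, radii, tolerance)
    m = complex_.metal_index
    flags: set[str] = set()

    carbon_donors = []
    for donor in sphere.donors:
        i = donor.atom_index
        neighbors = [j for j in graph.neighbors(i) if j != m]
        if donor.element == "N":
            if len(neighbors) == 1 and complex_.symbols[neighbors[0]] == "O":
                flags.add("nitrosyl")
        if donor.element == "C":
            carbon_donors.append(i)
    for a in carbon_donors:
        for b in carbon_donors:
            if a < b and graph.has_edge(a, b):
                flags.add("suspected-haptic")
    return flags


# ---------------------------------------------------------------------------
# Table-level pipeline

REQUIRED_COLUMNS = ("identifier", "multiplicity", "energy", "energy_unit",
                    "s2", "converged")


def records_from_table(df: pd.DataFrame) -> dict[str, list[SpinStateRecord]]:
    """Group a spin-state result table into per-complex record lists.

    Energies are converted to kcal/mol ('hartree' and 'kcal/mol' accepted).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"input table missing columns {missing}")
    out: dict[str, list[SpinStateRecord]] = defaultdict(list)
    for row in df.itertuples(index=False):
        unit = str(row.energy_unit).lower()
        if unit in ("kcal/mol", "kcal_mol", "kcal"):
            energy = float(row.energy)
        elif unit in ("hartree", "au", "a.u."):
            energy = float(row.energy) * HARTREE_TO_KCAL
        else:
            raise ValidationError(f"unknown energy unit {row.energy_unit!r}")
        s2 = None if pd.isna(row.s2) else float(row.s2)
        out[str(row.identifier)].append(
            SpinStateRecord(multiplicity=int(row.multiplicity), energy=energy,
                            s2_expectation=s2, converged=bool(row.converged))
        )
    return dict(out)


def curate_table(df: pd.DataFrame,
                 config: Optional[CurationConfig] = None) -> tuple[pd.DataFrame, dict]:
    """Run ground-state selection and both reliability filters on a table.

    Returns the curated table (identifier, multiplicity, gap, s2) and a
    report with per-filter drop accounting; kept + dropped == input count.
    """
    config = config or CurationConfig()
    by_complex = records_from_table(df)
    kept_rows = []
    dropped: dict[str, str] = {}
    counts = {"input": len(by_complex), "all_failed": 0, "small_gap": 0,
              "contaminated": 0, "kept": 0}
    warnings: dict[str, str] = {}

    for ident in sorted(by_complex):
        try:
            ground = select_ground_state(by_complex[ident])
        except AllStatesFailedError:
            counts["all_failed"] += 1
            dropped[ident] = "no converged spin state"
            continue
        if not gap_filter(ground.gap, config):
            counts["small_gap"] += 1
            dropped[ident] = (
                "single accessible state" if ground.gap is None
                else f"spin-state gap {ground.gap:.2f} kcal/mol below "
                     f"{config.gap_threshold}"
            )
            continue
        keep, warning = spin_contamination_filter(ground.record, config)
        if warning:
            warnings[ident] = warning
        if not keep:
            counts["contaminated"] += 1
            dropped[ident] = "spin contamination beyond tolerance"
            continue
        counts["kept"] += 1
        kept_rows.append({
            "identifier": ident,
            "multiplicity": ground.multiplicity,
            "gap_kcal_mol": ground.gap,
            "s2": ground.record.s2_expectation,
            "tie": ground.tie,
        })

    curated = pd.DataFrame(
        kept_rows, columns=["identifier", "multiplicity", "gap_kcal_mol", "s2", "tie"]
    )
    report = {"counts": counts, "dropped": dropped, "warnings": warnings,
              "config": {"gap_threshold": config.gap_threshold,
                         "s2_tol_low": config.s2_tol_low,
                         "s2_tol_high": config.s2_tol_high}}
    return curated, report
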