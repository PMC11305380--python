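import io

import numpy as np
import pandas as pd
import pytest

from gsspin import (
    ComplexRecord,
    CurationConfig,
    SpinStateRecord,
    curate_table,
    gap_filter,
    generate_spin_energy_table,
    ligand_exclusion_flags,
    metal_center,
    select_ground_state,
    spin_contamination_filter,
    stratified_sample,
)
from gsspin.curation import GroupKey, records_from_table
from gsspin.errors import AllStatesFailedError, InfeasibleSamplingError, ValidationError

CFG = CurationConfig()


def rec(mult, energy, s2=None, converged=True):
    return SpinStateRecord(mult, energy, s2, converged)


class TestGroundState:
    def test_argmin_and_gap(self):
        gs = select_ground_state([rec(1, 0.0), rec(3, -2.0), rec(5, 8.0)])
        assert gs.multiplicity == 3
        assert gs.gap == pytest.approx(2.0)

    def test_single_converged_record(self):
        gs = select_ground_state([rec(3, -5.0), rec(1, 0.0, converged=False)])
        assert gs.multiplicity == 3 and gs.gap is None

    def test_all_failed(self):
        with pytest.raises(AllStatesFailedError):
            select_ground_state([rec(1, 0.0, converged=False)])

    def test_tie_goes_to_lower_multiplicity_and_is_flagged(self):
        gs = select_ground_state([rec(5, -1.0), rec(3, -1.0), rec(1, 4.0)])
        assert gs.multiplicity == 3 and gs.tie

    def test_invariant_under_uniform_energy_shift(self):
        records = [rec(1, 0.0), rec(3, -2.0), rec(5, 8.0)]
        shifted = [rec(r.multiplicity, r.energy + 123.4) for r in records]
        a, b = select_ground_state(records), select_ground_state(shifted)
        assert (a.multiplicity, a.gap) == (b.multiplicity, pytest.approx(b.gap))


class TestFilters:
    @pytest.mark.parametrize("gap,keep", [(3.0, False), (5.0, True), (20.0, True),
                                          (None, False)])
    def test_gap_filter_strict_below(self, gap, keep):
        assert gap_filter(gap, CFG) is keep

    @pytest.mark.parametrize("mult,s2,keep", [
        (1, 0.15, False),   # singlet deviates by 0.15 > 0.1
        (5, 6.05, True),    # quintet S(S+1)=6, deviation 0.05
        (2, 0.75, True),    # exact doublet
        (3, 2.2, True),     # boundary: deviation exactly 0.2 kept
        (3, 2.21, False),
        (2, 0.85, True),    # boundary: deviation exactly 0.1 kept
    ])
    def test_spin_contamination_thresholds(self, mult, s2, keep):
        ok, warning = spin_contamination_filter(rec(mult, 0.0, s2), CFG)
        assert ok is keep and warning is None

    def test_missing_s2_keeps_with_warning(self):
        ok, warning = spin_contamination_filter(rec(3, 0.0, None), CFG)
        assert ok and warning


class TestTablePipeline:
    def _table(self):
        rows = [
            # kept: gap 10, clean s2
            ("A", 1, 0.0, "kcal/mol", 0.0, True),
            ("A", 3, 10.0, "kcal/mol", 2.0, True),
            ("A", 5, 30.0, "kcal/mol", 6.0, True),
            # dropped: gap 2
            ("B", 2, 0.0, "kcal/mol", 0.75, True),
            ("B", 4, 2.0, "kcal/mol", 3.75, True),
            # dropped: contaminated singlet ground
            ("C", 1, 0.0, "kcal/mol", 0.5, True),
            ("C", 3, 20.0, "kcal/mol", 2.0, True),
            # dropped: nothing converged
            ("D", 1, 0.0, "kcal/mol", 0.0, False),
        ]
        return pd.DataFrame(rows, columns=["identifier", "multiplicity", "energy",
                                           "energy_unit", "s2", "converged"])

    def test_counts_conserve_and_reasons_recorded(self):
        curated, report = curate_table(self._table())
        counts = report["counts"]
        assert counts["input"] == 4
        assert counts["kept"] + counts["small_gap"] + counts["contaminated"] \
            + counts["all_failed"] == counts["input"]
        assert list(curated["identifier"]) == ["A"]
        assert set(report["dropped"]) == {"B", "C", "D"}

    def test_hartree_unit_conversion(self):
        df = pd.DataFrame({
            "identifier": ["X", "X"], "multiplicity": [1, 3],
            "energy": [-100.0, -100.0 + 0.01], "energy_unit": ["hartree"] * 2,
            "s2": [0.0, 2.0], "converged": [True, True],
        })
        records = records_from_table(df)["X"]
        gs = select_ground_state(records)
        assert gs.gap == pytest.approx(0.01 * 627.5095)

    def test_rerun_byte_identical(self, tmp_path):
        df = self._table()
        outs = []
        for run in range(2):
            curated, _ = curate_table(df)
            buf = io.StringIO()
            curated.to_csv(buf, index=False)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]


class TestStratifiedSampling:
    def test_minimum_one_per_group(self):
        items = [("a", i) for i in range(5)] + [("b", 0)] + [("c", i) for i in range(10)]
        out = stratified_sample(items, key_fn=lambda x: x[0], n_target=3, seed=0)
        assert len(out) == 3
        assert {k for k, _ in out} == {"a", "b", "c"}

    def test_full_population_identity(self):
        items = list(range(20))
        out = stratified_sample(items, key_fn=lambda x: x % 4, n_target=20, seed=1)
        assert sorted(out) == items

    def test_singleton_group_always_included(self):
        items = [("A", i) for i in range(100)] + [("B", 0)]
        for seed in range(5):
            out = stratified_sample(items, key_fn=lambda x: x[0], n_target=11, seed=seed)
            assert ("B", 0) in out
            assert sum(1 for k, _ in out if k == "A") == 10

    def test_deterministic_for_fixed_seed(self):
        items = [(f"g{i % 7}", i) for i in range(200)]
        a = stratified_sample(items, key_fn=lambda x: x[0], n_target=40, seed=11)
        b = stratified_sample(items, key_fn=lambda x: x[0], n_target=40, seed=11)
        assert a == b

    def test_infeasible_target(self):
        items = [(k, 0) for k in "abcde"]
        with pytest.raises(InfeasibleSamplingError):
            stratified_sample(items, key_fn=lambda x: x[0], n_target=3, seed=0)

    def test_group_key_canonical_composition(self):
        a = GroupKey("Fe", 2, 6, "octahedral", ("N", "O", "N"))
        b = GroupKey("Fe", 2, 6, "octahedral", ("N", "N", "O"))
        assert a == b and hash(a) == hash(b)


class TestLigandFlags:
    def _complex(self, symbols, coords):
        return ComplexRecord("flag", metal_center("Fe", 2), symbols,
                             np.asarray(coords, float), 0)

    def test_linear_nitrosyl_flagged(self, radii):
        cx = self._complex(
            ["Fe", "N", "O", "N", "N"],
            [[0, 0, 0], [1.8, 0, 0], [2.95, 0, 0], [-2.0, 0, 0], [0, 2.0, 0]],
        )
        assert "nitrosyl" in ligand_exclusion_flags(cx, radii)

    def test_amine_sphere_clean(self, radii):
        d = radii["Fe"] + radii["N"]
        dirs = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        coords = [[0, 0, 0]] + [[d * x, d * y, d * z] for x, y, z in dirs]
        cx = self._complex(["Fe"] + ["N"] * 6, coords)
        assert ligand_exclusion_flags(cx, radii) == set()

    def test_adjacent_carbon_donors_flag_haptic(self, radii):
        # two carbons both bonded to Fe and to each other (1.42 A apart)
        cx = self._complex(
            ["Fe", "C", "C"],
            [[0, 0, 0], [2.0, 0.71, 0], [2.0, -0.71, 0]],
        )
        assert "suspected-haptic" in ligand_exclusion_flags(cx, radii)


class TestSyntheticEnergyTables:
    def test_clean_table_fully_kept(self):
        records, truth = generate_spin_energy_table(
            100, seed=5, small_gap_fraction=0.0, contamination_fraction=0.0,
            gap_range=(10.0, 25.0))
        curated, report = curate_table(records)
        assert report["counts"]["kept"] == 100

    def test_planted_fractions_recovered(self):
        n = 1000
        records, truth = generate_spin_energy_table(
            n, seed=9, small_gap_fraction=0.2, contamination_fraction=0.0)
        curated, report = curate_table(records)
        kept = report["counts"]["kept"]
        planted = int((~truth.small_gap).sum())
        assert kept == planted  # filter recovers exactly the planted clean set
        # and the planted fraction itself is binomially near 80%
        assert abs(planted / n - 0.8) < 4 * np.sqrt(0.8 * 0.2 / n)

    def test_ground_truth_recoverable_on_kept_rows(self):
        records, truth = generate_spin_energy_table(
            200, seed=2, small_gap_fraction=0.1, contamination_fraction=0.1)
        curated, _ = curate_table(records)
        merged = curated.merge(truth, on="identifier", suffixes=("_cur", "_true"))
        assert (merged.multiplicity_cur == merged.multiplicity_true).all()
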