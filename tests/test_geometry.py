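import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsspin import (
    classify_geometry,
    detect_coordination_sphere,
    geometry_deviation_filter,
    metal_center,
    shape_measure,
)
from gsspin.chem_core import ComplexRecord
from gsspin.errors import (
    DegenerateGeometryError,
    EmptyCoordinationSphereError,
    ShapeMismatchError,
    UnsupportedCoordinationError,
)

from .conftest import make_sphere
from .oracles import cshm_bruteforce


def _octahedron_complex(radii, extra=None, bond_scale=1.0):
    d = bond_scale * (radii["Fe"] + radii["N"])
    dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
    symbols = ["Fe"] + ["N"] * 6
    coords = np.vstack([np.zeros(3), d * dirs])
    if extra:
        for sym, pos in extra:
            symbols.append(sym)
            coords = np.vstack([coords, pos])
    return ComplexRecord("oct", metal_center("Fe", 2), symbols, coords, 0)


class TestSphereDetection:
    def test_ideal_octahedron_has_cn6(self, radii):
        sphere = detect_coordination_sphere(_octahedron_complex(radii), radii)
        assert sphere.coordination_number == 6
        assert sphere.composition == ("N",) * 6

    def test_spectator_beyond_cutoff_ignored(self, radii):
        far = 2.0 * (radii["Fe"] + radii["C"])
        cx = _octahedron_complex(radii, extra=[("C", np.array([far, 0.0, 0.0]))])
        assert detect_coordination_sphere(cx, radii).coordination_number == 6

    def test_distant_pair_excluded(self, radii):
        """4 donors at the covalent sum, 2 at sum + 2*tolerance -> CN 4."""
        tol = 0.4
        near = radii["Fe"] + radii["N"]
        far = near + 2 * tol
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        coords = np.vstack([np.zeros(3), near * dirs[:4], far * dirs[4:]])
        cx = ComplexRecord("mix", metal_center("Fe", 2), ["Fe"] + ["N"] * 6, coords, 0)
        sphere = detect_coordination_sphere(cx, radii, tolerance=tol)
        assert sphere.coordination_number == 4

    def test_empty_sphere_raises(self, radii):
        cx = ComplexRecord("far", metal_center("Fe", 2), ["Fe", "N"],
                           np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]), 0)
        with pytest.raises(EmptyCoordinationSphereError):
            detect_coordination_sphere(cx, radii)

    def test_donor_ordering_deterministic(self, radii):
        sphere = detect_coordination_sphere(_octahedron_complex(radii), radii)
        keys = [(round(np.linalg.norm(d.position), 8), d.element, d.atom_index)
                for d in sphere.donors]
        assert keys == sorted(keys)


class TestShapeMeasure:
    def test_library_shapes_self_score_zero(self, library):
        for ref in library:
            assert shape_measure(ref.directions, ref) < 1e-9

    def test_rotation_translation_scale_invariance(self, ref_by_name):
        tet = ref_by_name["tetrahedral"]
        rng = np.random.default_rng(42)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = 3.7 * tet.directions @ q.T + np.array([1.0, -2.0, 0.5])
        assert shape_measure(moved, tet) < 1e-9

    def test_square_vs_tetrahedron_matches_bruteforce(self, ref_by_name):
        square = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], float)
        tet = ref_by_name["tetrahedral"]
        value = shape_measure(square, tet)
        assert value == pytest.approx(cshm_bruteforce(square, tet), abs=1e-10)
        assert value == pytest.approx(100.0 / 3.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_vertex_permutation_invariance(self, ref_by_name, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(5, 3))
        ref = ref_by_name["trigonal bipyramidal"]
        base = shape_measure(pts, ref)
        perm = rng.permutation(5)
        assert shape_measure(pts[perm], ref) == pytest.approx(base, abs=1e-10)

    def test_errors(self, ref_by_name):
        oct_ = ref_by_name["octahedral"]
        with pytest.raises(ShapeMismatchError):
            shape_measure(np.zeros((4, 3)), oct_)
        with pytest.raises(DegenerateGeometryError):
            shape_measure(np.ones((6, 3)), oct_)


class TestClassification:
    def test_each_library_shape_classifies_as_itself(self, library, radii):
        for ref in library:
            sphere = make_sphere(["N"] * ref.cn, [2.0] * ref.cn, radii,
                                 directions=ref.directions)
            out = classify_geometry(sphere, library)
            assert out.geometry == ref.name
            assert out.cshm < 1e-9
            # every non-matching same-CN reference scores strictly positive
            for other, value in out.all_measures.items():
                if other != ref.name:
                    assert value > 1e-6

    def test_stretched_octahedron_still_octahedral(self, library, ref_by_name, radii):
        dirs = ref_by_name["octahedral"].directions.copy()
        pts = dirs * 2.0
        pts[0] *= 1.10  # one axial bond stretched 10%
        sphere = make_sphere(["N"] * 6, np.linalg.norm(pts, axis=1), radii,
                             directions=pts / np.linalg.norm(pts, axis=1, keepdims=True))
        out = classify_geometry(sphere, library)
        assert out.geometry == "octahedral"
        assert 0 < out.cshm < min(v for k, v in out.all_measures.items() if k != "octahedral")

    def test_unsupported_cn(self, library, radii):
        sphere = make_sphere(["N"], [2.0], radii)
        with pytest.raises(UnsupportedCoordinationError):
            classify_geometry(sphere, library)


def test_deviation_filter_boundary():
    from gsspin.geometry import GeometryAssignment

    mk = lambda v: GeometryAssignment("octahedral", v, {"octahedral": v}, 6)
    assert geometry_deviation_filter(mk(0.0), threshold=3.0)
    assert geometry_deviation_filter(mk(3.0), threshold=3.0)   # boundary inclusive
    assert not geometry_deviation_filter(mk(3.0 + 1e-9), threshold=3.0)
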