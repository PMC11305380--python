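import numpy as np
import pytest

import gsspin


@pytest.fixture(scope="session")
def radii():
    return gsspin.load_covalent_radii()


@pytest.fixture(scope="session")
def library():
    return gsspin.load_polyhedra()


@pytest.fixture(scope="session")
def cutoffs():
    return gsspin.load_cutoffs()


@pytest.fixture(scope="session")
def ref_by_name(library):
    return {p.name: p for p in library}


@pytest.fixture(scope="session")
def labeled_2000():
    """The study-size synthetic labeled dataset, generated once per session."""
    return gsspin.generate_labeled_dataset(2000, seed=7)


@pytest.fixture(scope="session")
def labeled_small():
    """A small labeled dataset for fast non-acceptance ML checks."""
    return gsspin.generate_labeled_dataset(300, seed=3)


def make_sphere(elements, distances, radii, directions=None):
    """Build a CoordinationSphere by hand (metal at the origin)."""
    from gsspin.geometry import CoordinationSphere, Donor

    n = len(elements)
    if directions is None:
        rng = np.random.default_rng(0)
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    donors = [
        Donor(element=e, position=d * u, covalent_radius=radii[e], atom_index=i + 1)
        for i, (e, d, u) in enumerate(zip(elements, distances, directions))
    ]
    return CoordinationSphere(metal_position=np.zeros(3), donors=donors)
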