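"""Classify a distorted coordination polyhedron by continuous shape measures.

Builds a five-coordinate Co(II) complex halfway between square-pyramidal and
trigonal-bipyramidal and prints the shape measure against every CN-5
reference: the smallest value wins; 0 would be a perfect match and larger
values mean stronger deviation.
"""
import numpy as np

from gsspin import (
    classify_geometry,
    detect_coordination_sphere,
    generate_complex,
    load_covalent_radii,
    load_polyhedra,
    SynthSpec,
)

radii = load_covalent_radii()
library = load_polyhedra()

complex_ = generate_complex(
    SynthSpec("Co", 2, "square pyramidal", donors=["N"] * 5,
              distortion_amplitude=0.15, seed=3),
    radii=radii, library=library)

sphere = detect_coordination_sphere(complex_, radii)
assignment = classify_geometry(sphere, library)

print(f"coordination number: {sphere.coordination_number}")
for name, value in sorted(assignment.all_measures.items(), key=lambda kv: kv[1]):
    marker = "  <-- assigned" if name == assignment.geometry else ""
    print(f"  CShM vs {name:<22s}: {value:7.3f}{marker}")
print()
print("The jittered square pyramid still scores lowest against its own")
print("reference; a CShM above ~3 would flag the shape as unreliable.")
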