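# Relative-metal-radius cut-offs for the decision-tree nodes that separate
# the lowest spin state from high spin, keyed by metal then coordination
# geometry. These defaults were calibrated once against the synthetic
# generator's bond-length regimes (low-spin bonds at the covalent-radius sum,
# high-spin bonds 12% longer): each cut-off is the midpoint elongation 1.06
# mapped through the palette-average donor radius for that metal. Replace
# with values fitted to a real curated dataset for production use; the table
# is versioned configuration, not code.
version: synthetic-calibration-1
cutoffs:
  Cr:
    octahedral: 1.100
    square planar: 1.100
    square pyramidal: 1.100
    trigonal bipyramidal: 1.100
  Mn:
    octahedral: 1.100
    square planar: 1.100
    square pyramidal: 1.100
    trigonal bipyramidal: 1.100
  Fe:
    octahedral: 1.102
    square planar: 1.102
    square pyramidal: 1.102
    trigonal bipyramidal: 1.102
  Co:
    octahedral: 1.104
    square planar: 1.104
    square pyramidal: 1.104
    trigonal bipyramidal: 1.104
  Ni:
    octahedral: 1.105
    square planar: 1.105
    square pyramidal: 1.105
    trigonal bipyramidal: 1.105
# Geometries where the lowest accessible state is not the parity-minimal
# multiplicity: d4 octahedral and d6 square-planar/trigonal-bipyramidal
# complexes bottom out at a triplet.
lowest_spin_overrides:
  - {n_d: 4, geometry: octahedral, multiplicity: 3}
  - {n_d: 6, geometry: square planar, multiplicity: 3}
  - {n_d: 6, geometry: trigonal bipyramidal, multiplicity: 3}
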