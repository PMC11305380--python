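# gsspin

Ground-state spin assignment for mononuclear first-row transition-metal
complexes (Cr, Mn, Fe, Co, Ni) directly from structure — no electronic-
structure calculation required.

## The problem

Crystallographic repositories hold enormous numbers of transition-metal
complexes, but a crystal structure records neither the metal's spin state
nor, directly, anything that lets you start a quantum-chemical calculation
on the molecule: for that you need the spin multiplicity 2S+1. The spin of
a first-row d⁴–d⁸ center depends on the balance between d-orbital splitting
and pairing energy, which in turn is set by the metal, its oxidation state,
and the geometry and tightness of its first coordination sphere. `gsspin`
encodes those regularities so that the most probable ground-state spin can
be read off the structure itself.

## What it computes

* **Coordination sphere and geometry.** Donors are the atoms within
  `r_M + r_A + 0.4 Å` of the metal. The donor polyhedron is classified
  against a library of 18 ideal shapes (CN 2–8) by the continuous shape
  measure

  `S(Q, P) = 100 · min_{σ,R,s,t} Σᵢ |qᵢ − sR p_{σ(i)} − t|² / Σᵢ |qᵢ − q̄|²`,

  minimized exhaustively over vertex matchings σ and in closed form over
  rotation R, scale s and translation t. `S = 0` is a perfect shape; the
  assigned geometry is the argmin over same-CN references.

* **Relative metal radius.** The one-number descriptor of bond tightness,

  `r_rel = (1/CN) Σᵢ (d(M−Aᵢ) − r_{Aᵢ}) / r_M`,

  the metal's mean apparent radius in units of its covalent radius.
  `r_rel = 1` means bonds at the covalent-radius sum; high-spin complexes,
  with populated antibonding orbitals, show systematically larger values.

* **Rule-based assignment.** A decision tree over (N_d, OS, CN, geometry,
  r_rel): d⁰–d³/d⁹–d¹⁰ counts fix the spin outright; zero-valent centers and
  Mn(I) are strong-field singlets/doublets; Co(III) octahedral and Ni(III)
  are constant singlet/doublet; CN = 2 or CN > 6 is high spin; geometries
  with genuine spin freedom are split by r_rel against a per-metal,
  per-geometry cut-off (configuration, YAML).

* **Random-forest models** over interpretable feature vectors — F_TM =
  (Z, OS, N_d), F_CE = (CN, CG, r_rel), and their 6-slot concatenation
  F_TM+CE — with stratified 10-fold cross-validation, per-metal subsets and
  impurity feature importances.

* **Dataset curation** for building spin-labeled datasets from computed
  spin-state tables: lowest-energy ground-state selection, a 5 kcal/mol
  minimum spin-state gap, ⟨Ŝ²⟩ spin-contamination tolerances (0.1 for
  singlet/doublet, 0.2 otherwise), shape-deviation screening, seeded
  stratified sampling, and nitrosyl/haptic structural flags.

* **A synthetic-data generator** producing complexes in all 18 geometries
  with tunable bond elongation and distortion, plus spin-state energy tables
  with planted defects, so the whole pipeline is testable end to end.

## Worked example

```bash
python examples/assign_spin.py
```

```
Fe(II)N6 octahedron, short bonds:
  CShM vs octahedral reference : 0.0000
  relative metal radius r_rel  : 1.0000
  assigned spin                : singlet (multiplicity 1)
  fired rule                   : R5:r_rel<1.102-lowest-spin

Fe(II)N6 octahedron, elongated bonds:
  CShM vs octahedral reference : 0.0000
  relative metal radius r_rel  : 1.1845
  assigned spin                : quintet (multiplicity 5)
  fired rule                   : R5:r_rel>=1.102-high-spin
```

Both complexes are perfect octahedra (CShM 0); the only difference is a 12%
bond elongation. The short-bond complex sits at `r_rel = 1.0`, below the
Fe/octahedral cut-off, and is assigned low spin (singlet for d⁶); the
elongated one crosses the cut-off and comes out high spin (quintet). The
other scripts in `examples/` walk through geometry classification, table
curation and the random-forest models the same way.

A CLI wraps the same pipeline for shell use:

```bash
gsspin assign structure.xyz --metal Fe -q 2          # JSON report with rule trace
gsspin synth --n 500 --seed 1 --manifest data.csv    # synthetic labeled dataset
gsspin cv data.csv --features F_TM+CE --out cv.json  # 10-fold cross-validation
gsspin curate energies.csv --out curated.csv         # curation filters
```

## Configuration

The covalent-radius table, the reference-polyhedron library and the r_rel
cut-off table ship as editable YAML under `src/gsspin/data/` and can be
replaced wholesale (`gsspin --config my.yaml …` or
`gsspin.load_settings(...)`). Every report embeds a SHA-256 fingerprint of
the configuration that produced it. The default cut-offs are calibrated to
the synthetic generator's bond-length regimes and are meant to be replaced
with values fitted to real curated data; see `docs/methods.md`.
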