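# Methods

This note documents the models and procedures implemented in `gsspin`, the
assumptions behind them, the tunable parameters, and what the synthetic
test bed does and does not establish.

## Scope and assumptions

The package targets mononuclear complexes of Cr, Mn, Fe, Co and Ni. The
formal d-electron count is N_d = group − OS (Cr 6 … Ni 10), which assumes
innocent, closed-shell ligands; complexes with radical or non-innocent
ligands (e.g. nitrosyls) are outside the model's domain, and the curation
module flags the common structural signatures (`nitrosyl`,
`suspected-haptic`) rather than silently mis-assigning them. Second- and
third-row metals are excluded: their larger field splittings make them
almost uniformly low spin, so the interesting spin-state freedom — and the
model — lives in the first row with d⁴–d⁸ configurations.

Electron-count parity decides the accessible multiplicities (1/3/5 for even
counts, 2/4/6 for odd). When the total charge of a complex is unknown the
parity is inferred from N_d under the closed-shell-ligand assumption and
the result is flagged as inferred.

## Coordination sphere and geometry

Bond detection uses the covalent-radius criterion d(M−A) ≤ r_M + r_A + t
with t = 0.40 Å by default, the conventional crystallographic bonding
margin; t is configurable. Covalent radii come from the Cordero et al.
(2008) statistical analysis of experimental crystal structures, one value
per element; where that analysis distinguishes spin states (Mn, Fe, Co) the
low-spin value is used so that r_rel reads as elongation relative to a
strong-field bond. The table is YAML package data and can be replaced.

Geometry classification uses the continuous shape measure. For a fixed
vertex matching the optimum over translation is centroid superposition and
the optimum over rotation and scale has the closed form
S = 100·(1 − D²/(|Q|²|P|²)), where D is the proper-rotation trace maximum:
the sum of the singular values of the cross-covariance matrix, with the
smallest sign-flipped when the optimal alignment would otherwise be a
reflection. Vertex matchings are searched exhaustively; coordination
numbers stop at 8, so the worst case is 8! = 40 320 matchings, evaluated as
one vectorized batch. Numerically the batch uses LAPACK singular values up
to CN 6 (small batches, reference-grade precision, verified against an
independent per-permutation brute force to 1e−8) and closed-form 3×3
eigenvalues for the CN 7–8 batches, where the ~1e−6 worst-case error of the
trigonometric eigenvalue formula is negligible against any classification
margin but the speedup is more than an order of magnitude.

The reference library ships 18 ideal shapes (CN 2–8) as YAML: linear,
trigonal planar, T-shaped, tetrahedral, square planar, seesaw, square
pyramidal, trigonal bipyramidal, pentagonal planar, octahedral, trigonal
prismatic, hexagonal planar, pentagonal bipyramidal, capped octahedral,
capped trigonal prismatic, cube, square antiprismatic and (triangular)
dodecahedral. Vertices are metal-centric and unit-norm — all ideal donors
equidistant from the metal. Where a shape has competing conventions the
library uses: square pyramid as vacant octahedron (90° apical angle),
seesaw as cis-divacant octahedron, trigonal prism with square lateral
faces, equal-edge square antiprism, and the Hoard–Silverton dodecahedron
(θ_A = 36.85°, θ_B = 69.46°). The library order is the ordinal geometry
code used in feature vectors, so entries must be appended, never reordered.
Classification ties break by library order. Structures whose best measure
exceeds a threshold (default 3.0, boundary inclusive) are flagged
unreliable; the threshold marks the usual boundary between "clearly this
shape" and ambiguous polyhedra.

## Relative metal radius

r_rel = (1/CN) Σᵢ (d(M−Aᵢ) − r_{Aᵢ})/r_M. Two exact properties anchor the
implementation and its tests: r_rel = 1 when every bond equals the
covalent-radius sum, and a uniform elongation of all bonds by δ shifts
r_rel by exactly δ/r_M. The descriptor is donor-order invariant. Its
increase with coordination number at fixed bond regime is a dataset
property, not a theorem, and is checked only qualitatively on synthetic
populations.

## Decision tree

Rules fire in a fixed order (R1–R6, see `spin_rules`); every traversed
decision is recorded in a trace so assignments are auditable and
reproducible. Boundary convention at the r_rel cut-off: strictly below →
lowest spin; at or above → high spin. The lowest spin is the
parity-minimal multiplicity except for d⁴ octahedral and d⁶
square-planar/trigonal-bipyramidal complexes, where the lowest observed
state is a triplet (an override block in the cut-off YAML). The tree never
emits intermediate spin for square-pyramidal d⁶; that would need a second
cut-off per node and is a known, documented limitation. Whether the
low-valent strong-field rule should cover Mn(I) in addition to zero-valent
centers was an open design point; it is included (as a distinct rule id in
the trace) because Mn(I) complexes bind the same carbonyl/phosphine ligand
class.

### Cut-off table

The per-(metal, geometry) cut-offs are versioned configuration, not code.
The shipped defaults (`synthetic-calibration-1`) were derived once from the
synthetic generator's two bond-length regimes: the midpoint elongation 1.06
mapped through the palette-average donor radius for each metal, giving
1.100 (Cr, Mn), 1.102 (Fe), 1.104 (Co), 1.105 (Ni) for the four geometries
with genuine spin variability (octahedral, square planar, square pyramidal,
trigonal bipyramidal). For production use on real structures the table
should be refitted to a curated experimental dataset and dropped in
verbatim — the pipeline reads whatever the YAML provides and fingerprints
it in every report.

## Curation

Ground state = lowest-energy converged state; exact ties go to the lower
multiplicity and are flagged. The gap filter drops complexes whose
ground-to-second gap is below 5 kcal/mol ("smaller than" is strict, so a
gap of exactly 5 is kept); this both removes cases inside the error bar of
DFT spin-state energetics and eliminates spin-crossover candidates. The
gap is ground-to-second, not pairwise — with three states the ground-to-
second gap is the binding ambiguity. The ⟨Ŝ²⟩ filter drops ground states
deviating from S(S+1) by more than 0.1 (multiplicity ≤ 2) or 0.2
(otherwise), boundary inclusive with a 1e−9 slack so a deviation exactly at
tolerance survives float round-off. Energies are accepted in kcal/mol or
hartree (627.5095 kcal/mol per hartree). All filters are pure per-complex
predicates, so the pipeline outcome is order-independent and the report's
per-filter counts always sum to the input count.

Stratified sampling gives every nonempty (metal, OS, CN, geometry,
donor-composition) group at least one slot and allocates the remainder
proportionally to group size by largest remainder (capped at group size);
within-group draws are uniform under an explicit seed. The allocation rule
beyond the one-per-group floor was an open choice; proportional allocation
preserves the population's composition while guaranteeing coverage of rare
groups.

## Random-forest models

Defaults: 500 trees, Gini impurity, no depth cap, one job —
hyperparameters are deliberately plain and fully exposed. Folding is
stratified by multiplicity so no fold loses a class; accuracy is the
unweighted fraction correct; the fold seed and feature names are recorded
in every CVResult. The geometry enters as a single ordinal code (library
index) rather than one-hot, keeping F_TM+CE at its designed six slots;
trees split ordinal codes without assuming metric structure, so the
encoding costs nothing for forests.

## Synthetic generator

The generator emulates the diversity of a curated crystallographic
population: five metals in their observed oxidation states (Cr 0/II/III,
Mn I/II/III, Fe 0/II/III, Co I/II/III, Ni 0/II/III — d-counts 3–10), all 18
geometries, and donors drawn from the seven most common donor elements
(N, O, C, S, P, Cl, Br). Donors sit on ideal vertices at
elongation·(r_M + r_A), rigidly rotated, with per-component Gaussian jitter
(default σ = 0.02 Å). The low-spin regime uses elongation 1.00 and the
high-spin regime 1.12 — about 0.2 Å on a typical 2 Å metal–donor bond, the
textbook HS lengthening, and small enough that even the largest palette
donor (Br on Cr/Mn) stays inside the 0.4 Å bonding margin. Labels come
from running the full structural pipeline plus the decision tree on each
generated complex, so with zero label noise the labels are a deterministic
function of the F_TM+CE features; optional label-flip noise stays
parity-consistent. Spin-state energy tables plant known fractions of
small-gap, contaminated and unconverged complexes with the ground truth
returned alongside.

What the synthetic bed does not emulate: real ligand scaffolds (only the
first coordination sphere is built), correlated distortions such as
Jahn–Teller axes, genuinely ambiguous borderline r_rel populations near
the cut-offs, intermediate-spin structures, and any discrepancy between the
decision tree and physical reality. Consequently, passing the ML-recovery
tests shows that the models can represent and recover the rule structure
from the designed feature set under realistic geometric noise — not that
the rules themselves achieve any particular accuracy on experimental
structures; that number can only come from a real curated dataset.

## Problem sizes and numerical choices

The reproduction script and acceptance tests use a 2000-complex synthetic
population for the ML comparisons (10-fold CV × three feature sets), 1000
complexes for the curation-fraction checks, and 100 random point sets for
the shape-measure oracle equivalence — sizes at which every reported
quantity is stable to well inside its tolerance. Shape-measure values are
clamped to [0, 100]; degenerate (zero-spread) vertex sets and empty
coordination spheres raise typed errors rather than returning numbers.
Donor ordering is deterministic (distance, then element, then input index),
as are all seeded samplers, so identical inputs and seeds give byte-
identical outputs everywhere.
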