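# Ideal reference polyhedra for coordination-geometry classification.
# Unit-scale Cartesian vertices; centered and norm-scaled at load time,
# so only the shape matters. Library order defines the ordinal geometry
# code used in feature vectors -- append, never reorder.
polyhedra:
- name: linear
  cn: 2
  vertices:
  - [0.0, 0.0, 1.0]
  - [0.0, 0.0, -1.0]
- name: trigonal planar
  cn: 3
  vertices:
  - [1.0, 0.0, 0.0]
  - [-0.5, 0.8660254, 0.0]
  - [-0.5, -0.8660254, 0.0]
- name: T-shaped
  cn: 3
  vertices:
  - [1.0, 0.0, 0.0]
  - [-1.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0]
- name: tetrahedral
  cn: 4
  vertices:
  - [0.57735027, 0.57735027, 0.57735027]
  - [0.57735027, -0.57735027, -0.57735027]
  - [-0.57735027, 0.57735027, -0.57735027]
  - [-0.57735027, -0.57735027, 0.57735027]
- name: square planar
  cn: 4
  vertices:
  - [1.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0]
  - [-1.0, 0.0, 0.0]
  - [-0.0, -1.0, 0.0]
- name: seesaw
  cn: 4
  vertices:
  - [0.0, 0.0, 1.0]
  - [0.0, 0.0, -1.0]
  - [1.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0]
- name: square pyramidal
  cn: 5
  vertices:
  - [0.0, 0.0, 1.0]
  - [1.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0]
  - [-1.0, 0.0, 0.0]
  - [-0.0, -1.0, 0.0]
- name: trigonal bipyramidal
  cn: 5
  vertices:
  - [0.0, 0.0, 1.0]
  - [0.0, 0.0, -1.0]
  - [1.0, 0.0, 0.0]
  - [-0.5, 0.8660254, 0.0]
  - [-0.5, -0.8660254, 0.0]
- name: pentagonal planar
  cn: 5
  vertices:
  - [1.0, 0.0, 0.0]
  - [0.30901699, 0.95105652, 0.0]
  - [-0.80901699, 0.58778525, 0.0]
  - [-0.80901699, -0.58778525, 0.0]
  - [0.30901699, -0.95105652, 0.0]
- name: octahedral
  cn: 6
  vertices:
  - [1.0, 0.0, 0.0]
  - [-1.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0]
  - [0.0, -1.0, 0.0]
  - [0.0, 0.0, 1.0]
  - [0.0, 0.0, -1.0]
- name: trigonal prismatic
  cn: 6
  vertices:
  - [0.75592895, 0.0, 0.65465367]
  - [-0.37796447, 0.65465367, 0.65465367]
  - [-0.37796447, -0.65465367, 0.65465367]
  - [0.75592895, 0.0, -0.65465367]
  - [-0.37796447, 0.65465367, -0.65465367]
  - [-0.37796447, -0.65465367, -0.65465367]
- name: hexagonal planar
  cn: 6
  vertices:
  - [1.0, 0.0, 0.0]
  - [0.5, 0.8660254, 0.0]
  - [-0.5, 0.8660254, 0.0]
  - [-1.0, 0.0, 0.0]
  - [-0.5, -0.8660254, 0.0]
  - [0.5, -0.8660254, 0.0]
- name: pentagonal bipyramidal
  cn: 7
  vertices:
  - [0.0, 0.0, 1.0]
  - [0.0, 0.0, -1.0]
  - [1.0, 0.0, 0.0]
  - [0.30901699, 0.95105652, 0.0]
  - [-0.80901699, 0.58778525, 0.0]
  - [-0.80901699, -0.58778525, 0.0]
  - [0.30901699, -0.95105652, 0.0]
- name: capped octahedral
  cn: 7
  vertices:
  - [1.0, 0.0, 0.0]
  - [-1.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0]
  - [0.0, -1.0, 0.0]
  - [0.0, 0.0, 1.0]
  - [0.0, 0.0, -1.0]
  - [0.57735027, 0.57735027, 0.57735027]
- name: capped trigonal prismatic
  cn: 7
  vertices:
  - [0.75592895, 0.0, 0.65465367]
  - [-0.37796447, 0.65465367, 0.65465367]
  - [-0.37796447, -0.65465367, 0.65465367]
  - [0.75592895, 0.0, -0.65465367]
  - [-0.37796447, 0.65465367, -0.65465367]
  - [-0.37796447, -0.65465367, -0.65465367]
  - [0.5, 0.8660254, 0.0]
- name: cube
  cn: 8
  vertices:
  - [0.57735027, 0.57735027, 0.57735027]
  - [0.57735027, 0.57735027, -0.57735027]
  - [0.57735027, -0.57735027, 0.57735027]
  - [0.57735027, -0.57735027, -0.57735027]
  - [-0.57735027, 0.57735027, 0.57735027]
  - [-0.57735027, 0.57735027, -0.57735027]
  - [-0.57735027, -0.57735027, 0.57735027]
  - [-0.57735027, -0.57735027, -0.57735027]
- name: square antiprismatic
  cn: 8
  vertices:
  - [0.8595325, 0.0, 0.51108108]
  - [0.0, 0.8595325, 0.51108108]
  - [-0.8595325, 0.0, 0.51108108]
  - [-0.0, -0.8595325, 0.51108108]
  - [0.60778126, 0.60778126, -0.51108108]
  - [-0.60778126, 0.60778126, -0.51108108]
  - [-0.60778126, -0.60778126, -0.51108108]
  - [0.60778126, -0.60778126, -0.51108108]
- name: dodecahedral
  cn: 8
  vertices:
  - [0.59972214, 0.0, 0.80020832]
  - [-0.59972214, 0.0, 0.80020832]
  - [0.93642747, 0.0, -0.35086122]
  - [-0.93642747, 0.0, -0.35086122]
  - [0.0, 0.93642747, 0.35086122]
  - [0.0, -0.93642747, 0.35086122]
  - [0.0, 0.59972214, -0.80020832]
  - [0.0, -0.59972214, -0.80020832]
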