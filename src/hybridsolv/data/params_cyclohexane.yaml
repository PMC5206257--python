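# Three-bead coarse-grained cyclohexane: uncharged LJ beads (ring-scaled
# lipid-tail parameters, sigma 4.1 A, epsilon 3.19 kJ/mol) joined into a
# triangle by harmonic bonds E = k (r - r0)^2 with r0 = 4.05 A and
# k = 12.69 kJ/mol/A^2.
sites:
  - {name: CHX, kind: cg_cyclohexane, sigma: 4.1, epsilon: 3.19, mass: 28.053}
  - {name: CHX, kind: cg_cyclohexane, sigma: 4.1, epsilon: 3.19, mass: 28.053}
  - {name: CHX, kind: cg_cyclohexane, sigma: 4.1, epsilon: 3.19, mass: 28.053}
bonds:
  - [0, 1, 4.05, 12.69]
  - [1, 2, 4.05, 12.69]
  - [2, 0, 4.05, 12.69]
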