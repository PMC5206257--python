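# Synthetic constrained diatomic solute (one SHAKE constraint, +/- partial
# charges) used by the test fixtures; not a parameterisation of any real
# compound.
sites:
  - {name: C, kind: atom, sigma: 3.4, epsilon: 0.4, charge: 0.2, mass: 12.011}
  - {name: H, kind: atom, sigma: 2.6, epsilon: 0.1, charge: -0.2, mass: 1.008}
constraints:
  - [0, 1, 1.09]
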