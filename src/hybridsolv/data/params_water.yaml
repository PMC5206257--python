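# Elba-style Stockmayer water bead.  sigma/epsilon/dipole follow the
# published Elba water model (LJ sigma 3.05 A, epsilon 0.55 kcal/mol,
# dipole 2.6 D); the rotational inertia is a bead parameter chosen for
# smooth integration at a 6 fs outer timestep.  Units: A, kJ/mol, e*A,
# g/mol, g/mol*A^2.
sites:
  - {name: W, kind: cg_water, sigma: 3.05, epsilon: 2.3012,
     dipole: 0.54131, mass: 18.01528, rot_inertia: 4.0}
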