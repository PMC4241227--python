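# Two-species / three-reaction lin-log toy (simplified form
# v = a + sum g ln X).  dof = 1.  Synthetic ground truth for in-silico
# recovery benchmarks of the lin-log estimation path, where the inner
# problem is exactly linear in the parameters.
#
# The inflow offset a_v1 is FIXED (known): because lin-log rates are
# affine, shifting every offset along a right-null vector of S (here
# (1,1,1)) leaves dX/dt unchanged, so concentration data alone cannot
# pin absolute offset levels.  Fixing one offset per null direction
# removes the degeneracy and makes the remaining 5 parameters
# identifiable.
name: toy_linlog
species: [X1, X2]
offline: []
initial_conditions: {X1: 1.0, X2: 1.0}
reactions:
  - name: v1
    stoichiometry: {X1: 1}
    law: linlog
    a: {free: false, value: 2.0}
    g:
      X2: {free: true, lower: -5.0, upper: 5.0, true: -0.5}
  - name: v2
    stoichiometry: {X1: -1, X2: 1}
    law: linlog
    a: {free: true, lower: -5.0, upper: 5.0, true: 1.0}
    g:
      X1: {free: true, lower: -5.0, upper: 5.0, true: 1.2}
  - name: v3
    stoichiometry: {X2: -1}
    law: linlog
    a: {free: true, lower: -5.0, upper: 5.0, true: 0.8}
    g:
      X2: {free: true, lower: -5.0, upper: 5.0, true: 0.9}
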