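# Two-species / three-reaction GMA toy: constant inflow, linear chain,
# outflow.  dof = 1; the smallest network on which the nested
# (independent/dependent) estimation is exercised end to end.
# Synthetic ground truth for in-silico recovery benchmarks.
name: toy_gma
species: [X1, X2]
offline: []
initial_conditions: {X1: 0.4, X2: 0.3}
reactions:
  - name: v1
    stoichiometry: {X1: 1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 1.5}
  - name: v2
    stoichiometry: {X1: -1, X2: 1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 2.0}
    g:
      X1: {free: true, lower: 0.0, upper: 2.0, true: 0.8}
  - name: v3
    stoichiometry: {X2: -1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 1.2}
    g:
      X2: {free: true, lower: 0.0, upper: 2.0, true: 0.6}
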