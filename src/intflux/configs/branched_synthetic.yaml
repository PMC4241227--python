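# Generic branched metabolic pathway, GMA (power-law) kinetics.
#
# Structure: an inflow v1 under feedback inhibition by the end product X4,
# a branch point at X1 (v2 -> X2 towards X4; v3 -> X3, a side branch
# drained by v5), and an outflow v6 from X4.  The side-branch metabolite
# X3 cross-inhibits the main-branch step v4.
#
#   v1:  -> X1      v1 = a1 * X4^g14          (g14 < 0: feedback inhibition)
#   v2: X1 -> X2    v2 = a2 * X1^g21
#   v3: X1 -> X3    v3 = a3 * X1^g31
#   v4: X2 -> X4    v4 = a4 * X2^g42 * X3^g43 (g43 < 0: cross inhibition)
#   v5: X3 ->       v5 = a5 * X3^g53
#   v6: X4 ->       v6 = a6 * X4^g64
#
# 4 metabolites, 6 reactions, 13 free parameters, dof = n - rank(S) = 2.
# Independent set {v1, v6} gives a square invertible S_D and the fewest
# independent parameters (4); {v1, v4} is an alternative with 5.
#
# The `true` values below are a SYNTHETIC ground truth chosen for the
# in-silico benchmark (the published values for this pathway are not
# shipped with the package); rate constants are bounded in [0, 25] and
# kinetic orders in [0, 2] (sign-flipped to [-2, 0] for the two
# inhibitory orders).
name: branched
species: [X1, X2, X3, X4]
offline: []
initial_conditions: {X1: 0.6, X2: 0.4, X3: 0.6, X4: 1.2}
reactions:
  - name: v1
    stoichiometry: {X1: 1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 12.0}
    g:
      X4: {free: true, lower: -2.0, upper: 0.0, true: -0.8}
  - name: v2
    stoichiometry: {X1: -1, X2: 1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 4.0}
    g:
      X1: {free: true, lower: 0.0, upper: 2.0, true: 0.5}
  - name: v3
    stoichiometry: {X1: -1, X3: 1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 6.0}
    g:
      X1: {free: true, lower: 0.0, upper: 2.0, true: 0.75}
  - name: v4
    stoichiometry: {X2: -1, X4: 1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 3.0}
    g:
      X2: {free: true, lower: 0.0, upper: 2.0, true: 0.75}
      X3: {free: true, lower: -2.0, upper: 0.0, true: -0.2}
  - name: v5
    stoichiometry: {X3: -1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 5.0}
    g:
      X3: {free: true, lower: 0.0, upper: 2.0, true: 0.5}
  - name: v6
    stoichiometry: {X4: -1}
    law: gma
    a: {free: true, lower: 0.0, upper: 25.0, true: 6.0}
    g:
      X4: {free: true, lower: 0.0, upper: 2.0, true: 0.8}
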