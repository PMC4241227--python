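# Lin-log model of the Lactococcus lactis glycolytic pathway (structure).
#
# Nine metabolites: G6P (X1), FBP (X2), 3-PGA (X3), PEP (X4), pyruvate
# (X5), lactate (X6), external glucose (X7), ATP (X8) and inorganic
# phosphate (X9).  X7-X9 are off-line variables: they modulate the rates
# but carry no mass balance (their trajectories are supplied as smoothed
# data).  Nine fluxes:
#
#   v1: PEP + Glu -> G6P + Pyr   (PTS uptake)
#   v2: G6P -> FBP               (phosphofructokinase step, ATP-dependent)
#   v3: FBP -> 2 3-PGA           (lower glycolysis, Pi-dependent)
#   v4: 3-PGA -> PEP
#   v5: PEP -> Pyr               (pyruvate kinase, FBP-activated)
#   v6: Pyr -> Lactate           (lactate dehydrogenase, FBP-activated)
#   v7: FBP ->                   (branch drain from FBP)
#   v8: Pyr ->                   (branch drain from pyruvate)
#   v9: Lactate ->               (lactate export)
#
# dof over the six balanced species = 9 - 6 = 3; independent set
# {v5, v7, v9} leaves a square invertible S_D and the fewest independent
# parameters.  All parameters are bounded in [-500, 500].  The simplified
# lin-log parameterization (v = a + sum g ln X) carries no reference-state
# values, so the parameters have no direct physical interpretation.
# This structure is a SYNTHETIC reconstruction for in-silico use; no
# ground-truth values are shipped.
name: lactis_linlog
species: [X1, X2, X3, X4, X5, X6, X7, X8, X9]
offline: [X7, X8, X9]
initial_conditions: {X1: 1.0, X2: 1.0, X3: 1.0, X4: 1.0, X5: 1.0, X6: 0.1}
reactions:
  - name: v1
    stoichiometry: {X1: 1, X4: -1, X5: 1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X4: {free: true, lower: -500.0, upper: 500.0}
      X7: {free: true, lower: -500.0, upper: 500.0}
  - name: v2
    stoichiometry: {X1: -1, X2: 1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X1: {free: true, lower: -500.0, upper: 500.0}
      X8: {free: true, lower: -500.0, upper: 500.0}
  - name: v3
    stoichiometry: {X2: -1, X3: 2}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X2: {free: true, lower: -500.0, upper: 500.0}
      X9: {free: true, lower: -500.0, upper: 500.0}
  - name: v4
    stoichiometry: {X3: -1, X4: 1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X3: {free: true, lower: -500.0, upper: 500.0}
  - name: v5
    stoichiometry: {X4: -1, X5: 1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X4: {free: true, lower: -500.0, upper: 500.0}
      X2: {free: true, lower: -500.0, upper: 500.0}
  - name: v6
    stoichiometry: {X5: -1, X6: 1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X5: {free: true, lower: -500.0, upper: 500.0}
      X2: {free: true, lower: -500.0, upper: 500.0}
  - name: v7
    stoichiometry: {X2: -1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X2: {free: true, lower: -500.0, upper: 500.0}
  - name: v8
    stoichiometry: {X5: -1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X5: {free: true, lower: -500.0, upper: 500.0}
      X9: {free: true, lower: -500.0, upper: 500.0}
  - name: v9
    stoichiometry: {X6: -1}
    law: linlog
    a: {free: true, lower: -500.0, upper: 500.0}
    g:
      X6: {free: true, lower: -500.0, upper: 500.0}
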