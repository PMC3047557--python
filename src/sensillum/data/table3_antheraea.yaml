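# Second-messenger and ionic-current parameters of the Antheraea sensillum model
# (40-compartment parameterization).  Maximal conductances G_M* are for the WHOLE
# outer dendrite; per-compartment values are G_M*/N.  The K+ channel sits on the
# inner dendrite / soma membrane.
s_M: 653.0            # maximal second-messenger synthesis rate, 1/s

Ca:                   # IP3-gated Ca2+ current
  E: 140.0            # reversal potential, mV
  G_M: 0.137          # maximal conductance (whole dendrite), nS
  K_m: 3.48           # EC50 for IP3, uM
  n: 1.0              # Hill coefficient for IP3
  i_M: 3.08           # maximal inhibition (dimensionless, >= 1)
  K_i: 0.61           # IC50 for CaCaM, uM
  n_i: 2.51           # Hill coefficient for CaCaM

cat:                  # DAG-gated cationic current
  E: 0.0
  G_M: 0.877
  K_m: 0.0104
  n: 0.776
  i_M: 53.2
  K_i: 0.0377         # IC50 for CaCaM, uM
  n_i: 0.818

Cl:                   # Ca2+-gated chloride current
  E: -11.5
  G_M: 12.1
  K_m: 81.2           # EC50 for Ca2+, uM
  n: 1.443
  i_M: 1.4
  K_i: 0.06           # IC50 for PKC*, uM
  n_i: 1.1

x:                    # Na+/Ca2+ exchanger (Ca2+ extrusion); no antagonist
  E: -25.7
  G_M: 2.21e-3
  K_m: 0.54           # EC50 for Ca2+, uM
  n: 0.605

K:                    # Ca2+- and voltage-gated K+ current (inner dendrite/soma)
  E: -62.0
  G_M: 1.6091
  K_m: 2.803e-4       # EC50 for Ca2+ at the soma, uM
  A: 12.5             # voltage-dependence slope, mV

conversion:           # charge-to-concentration conversion factors, uM/pC
  F: 136.37           # for the NCX extrusion current
  f_Ca: 4.87          # for IP3-gated channels
  f_cat: 2.50         # for DAG-gated channels
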