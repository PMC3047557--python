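# Basic geometrical and passive electrical parameters of the Antheraea polyphemus
# pheromone-sensitive sensillum (trichodeum, cell A, tip-recording conditions:
# cut hair, outer dendrite length 220 um).  Keys follow the standard symbol names.
L_d: 220.0        # outer dendrite length, um
D_i: 0.475        # outer dendrite mean diameter, um
rho_ld: 7500.0    # outer dendrite membrane resistivity, Ohm.cm^2
D_e: 1.8          # hair-lumen mean inside diameter, um
rho_e: 40.0       # sensillar lymph resistivity, Ohm.cm
rho_i: 40.0       # intracellular resistivity, Ohm.cm
S_s: 144.0        # inner dendrite + soma lateral area, um^2
rho_ls: 1000.0    # soma membrane resistivity, Ohm.cm^2
E_ls: -62.0       # soma leak equilibrium potential, mV
C_api: 30.0       # auxiliary-cell apical membrane capacitance, pF
R_api: 300.0      # auxiliary-cell apical membrane resistance, MOhm
rho_bas: 100.0    # auxiliary-cell basolateral membrane resistivity, Ohm.cm^2
R_bas: 25.0       # auxiliary-cell basolateral membrane resistance, MOhm
E_a: -35.0        # auxiliary battery (gives rise to the transepithelial potential), mV
c: 1.0            # specific membrane capacitance, uF/cm^2
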