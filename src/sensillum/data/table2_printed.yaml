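# Published reference values for the derived cable quantities of the Antheraea
# sensillum parameterization, as tabulated in the source literature.  Used only in
# regression tests against derive_cable_parameters(); the formulas are the single
# source of truth.  Two tabulated dimensionless ratios (r_in = 0.900, a = 0.3018)
# are inconsistent with their own defining formulas (they correspond to using the
# apical resistance alone, 300 MOhm, instead of R_a = R_api + R_bas = 325 MOhm) and
# are therefore listed here under `inconsistent:` rather than compared.
S_d: 328.0        # um^2
V_d: 38.0         # um^3 (printed as 38; formula gives 38.98)
E_ld: -97.0       # mV
c_d: 1.49e-10     # F/cm
C_d: 3.28         # pF
r_ld: 50.26       # MOhm.cm
R_ld: 2.28        # GOhm
G_ld: 0.4373      # nS
lam: 455.0        # um
tau: 7.5          # ms
l_d: 0.484        # dimensionless
r_e: 1.69         # GOhm/cm
g_e: 0.592        # nS.cm
R_e: 37.4         # MOhm
G_e: 26.77        # nS
r_i: 22.57        # GOhm/cm
g_i: 0.0443       # nS.cm
R_i: 497.0        # MOhm
G_i: 2.011        # nS
R_ls: 694.0       # MOhm
G_ls: 1.44        # nS
C_s: 1.44         # pF
S_api: 3000.0     # um^2
rho_api: 9000.0   # Ohm.cm^2
S_bas: 400.0      # um^2
C_bas: 4.0        # pF
R_a: 325.0        # MOhm
G_a: 3.1          # nS
C_a: 3.53         # pF
inconsistent:
  r_in: 0.900
  a: 0.3018
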