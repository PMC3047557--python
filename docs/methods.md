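# Methods

## The model

A single pheromone-sensitive ORN and its auxiliary cells are represented as
an electrical network referenced to the hemolymph (0 mV).  The sensory outer
dendrite (length L_d = 220 µm, diameter D_i = 0.475 µm in tip-recording
conditions) is discretized into N identical cylindrical compartments.  Each
compartment spans two nodes — intracellular V_id[j] and sensillar-lymph
V_ed[j] — joined across the membrane by the capacitance C_d/N, the leak
branch (G_ld/N, E_ld) and the pheromone-dependent branches.  Node j sits at
X = j·L_d/N from the sealed hair tip; adjacent intracellular nodes are
coupled by g_ic = N·G_i and adjacent lymph nodes by g_ec = N·G_e (full-segment
links, including the links from compartment N to the soma node and from the
auxiliary apical node to the lymph of compartment N).  The inner dendrite and
soma form one compartment (C_s, leak (G_ls, E_ls), K⁺ branch to hemolymph);
the three auxiliary cells form another (C_a, conductance G_a in series with
the battery E_a, oriented so the lymph rests at the transepithelial potential
−E_a = +35 mV above hemolymph).

Battery consistency E_ld = E_ls + E_a makes the rest state exactly
current-free: V_id = E_ls, V_ed = −E_a, transmembrane potential E_ld = −97 mV
throughout.  RP is the stimulus-induced change of the transmembrane potential
(RP_j along the dendrite, RP_s at the soma); SP is the change of the lymph
potential at the tip, V_ed[1] — opposite in sign to RP.

### Channel gating

Each outer-dendritic current I_y = g_y·((V_id−V_ed) − E_y) (positive outward)
is gated by a cytosolic agonist through the Hill form
g_y = (G_My/N)·Yⁿ/(K_yⁿ+Yⁿ).  Antagonist feedback (CaCaM on the Ca²⁺ and
cationic channels, PKC* on Cl⁻) shifts the effective EC50 by
K_y = K_my·(1 + (i_My−1)·Z^{n_i}/(K_iy^{n_i}+Z^{n_i})) — equal to K_my
without antagonist, saturating at K_my·i_My, with the half-shift at the IC50.
The somatic K⁺ conductance is multiplicative in Ca²⁺ and voltage:
G_K = G_MK·(Ca/(K_mK+Ca))·1/(1+e^{−(V−V_h)/A_K}); only G_MK, K_mK and A_K are
constrained by the parameter tables, so the half-activation voltage V_h is an
exposed parameter defaulting to the resting soma potential (−62 mV).

### State reduction and integration

Only the membrane capacitances store charge.  The ODE states are the N
transmembrane potentials plus V_is and V_a; the 2N node potentials follow at
every instant from Kirchhoff's current law, which reduces to one tridiagonal
linear solve for the lymph potentials.  This eliminates the sub-microsecond
axial relaxation modes (per-compartment capacitance ~0.08 pF against axial
conductances ~80 nS at N = 40) from the differentiated variables, but the
reduced system is still stiff, so:

- the simplified model under piecewise-constant conductance is linear
  time-invariant and is propagated *exactly* segment by segment through the
  eigendecomposition of the (N+2)×(N+2) circuit matrix, sampled on an
  arbitrary output grid;
- time-varying-conductance replays and the complete multichannel model use
  LSODA (stiff-capable, adaptive; rtol 1e-6/1e-8, atol 1e-8/1e-10).  An
  explicit RK45 route remains selectable but is impractical at N ≳ 10.

### Ca²⁺ mass balance and modulator drive

Dendritic Ca²⁺ obeys dCa/dt = −f_Ca·I_Ca − f_cat·I_cat + F·I_x (µM/s, currents
in pA): inward Ca-carrying currents raise Ca²⁺; the NCX extrusion current is
net inward *while* it removes Ca²⁺ (3 Na⁺ in per Ca²⁺ out), hence the opposite
sign.  No buffering or diffusion terms are included.  Ca²⁺ is clamped at ≥ 0.

The upstream biochemistry (receptor, G-protein, effector, second-messenger
synthesis) is replaced by a pluggable drive.  The bundled synthetic generator
produces IP₃ and DAG waveforms (square, exponential or biphasic
fast-transient-plus-sustained shapes) scaled across dose by
U^h/(K^h+U^h); CaCaM, PKC* and somatic Ca²⁺ are low-pass-filtered copies of
dendritic Ca²⁺, preserving the feedback ordering of the cascade.  Drive
defaults (IP₃ 30 µM, DAG 0.15 µM saturating amplitudes; h = 0.35,
K = 0.5 µM/s; CaCaM/PKC* gains 0.005/0.002 with 0.3/1.0 s time constants)
were chosen once so that the simulation satisfies the qualitative screens the
parameterization is subject to — transient cationic kinetics (the early
conductance bump decays before a 2-s stimulus ends), a sustained Cl⁻
conductance, dendritic Ca²⁺ below 200 µM — and produces peak somatic RP in
the 25–28 mV range at the highest uptake with total pheromone-dependent
conductance ~1.1 nS.

What the generator does *not* emulate: the quantitative dose-response of the
upstream cascade (its EC50 chain and the ~170-fold sensitivity gain), the
full 4-nS conductance excursion, and the equality of |SP| and RP_s at the
reference K⁺ conductance.  Those depend on the upstream reaction network,
which is outside this package; with the conversion-factor-only Ca²⁺ balance,
dendritic Ca²⁺ plateaus near 10 µM, which caps the Cl⁻ conductance (EC50
81.2 µM) well below its maximum, and at high uptake the early cationic bump
exceeds the late Cl⁻ wave.  Passing tests therefore certify the electrical
circuit, its analytics and the characteristic-extraction machinery
quantitatively, but the complete-cascade dose-response only qualitatively
(signs, monotonicity, biphasic structure).

### Analytic oracles

At steady state with uniform conductance the dendrite is a two-wire cable.
In dimensionless form (x in space constants, g = r_ld·g_p = G_p/G_ld) with
µ = √(1+g) and D = cosh(µl_d) + µ·r_in·sinh(µl_d):

    RP(x) = g(E_p−E_ld)/(1+g) · (1 − cosh(µx)/D)
    RP_b  = g(E_p−E_ld)/(1+g) · µ r_in sinh(µl_d)/D
    SP    = −a·RP_b − β·(RP(0) − RP_b),   β = r_e/(r_e+r_i)

derived by solving the boundary-value problem with sealed tip and the lumped
load (R_ls + R_a between the two wires) at the base; correctness is certified
by grid refinement of the compartmental circuit (N = 2000 agrees to < 0.05%),
not by transcription.  With E_p = 0 the SP/RP ratio is exactly independent of
every battery; it is dose-independent only to ~1% because the spatial profile
steepens with g.

The transient oracle solves the linearized cable with the conductance step
over [0, l_d] on a cable sealed at both ends.  The base load is represented
by a sealed passive extension: a sealed stub of ℓ space constants has
normalized input conductance coth(ℓ) → 1, and the actual load r_in ≈ 0.92 is
close to matched, so the default tail of 3 space constants (coth 3 = 1.005)
emulates it to better than 1% at DC.  The g·v term is kept — the equation
stays linear — which makes the eigenfunctions piecewise trigonometric with a
transcendental matching condition at l_d; eigenvalues are bracketed by a scan
and refined by bisection, projections use split trapezoid quadrature (the
forcing is discontinuous at l_d), and the series is truncated when three
consecutive terms fall below 1e-8 of the forcing scale.  The residual
deviation from the N = 40 circuit (up to ~12% at the dendrite base for 0.2-nS
steps, smallest at the tip) reflects the lumped-versus-distributed load and
the linearization, and sits inside the documented 16% band.

### Equivalent single conductance

Replacing the four pheromone-dependent currents of compartment j by one
branch with g_pj = (I_Ca+I_cat+I_Cl+I_x)/(V_m − E_p) and E_p = 0 reproduces
the summed current identically (samples with driving force below 1e-6 mV are
flagged and interpolated, never silently zeroed).  Exact reproduction of a
complete-model run through the single-conductance circuit additionally
requires replaying the somatic K⁺ conductance G_K(t) — it is part of the
original circuit — after which the replay agrees to ~0.5 mV on ~47 mV
signals, limited by the 1-ms interpolation of the stored conductances.

### Response characteristics and fitting

Curves are summarized by height (signed extremum, first on ties), half-rise
time (onset to the first half-height crossing, linear interpolation between
samples) and half-fall time (offset to the first half-height crossing after
the extremum; negative when the response decays below half before the
stimulus ends).  EC50s interpolate the first upward 0.5-crossing in log-dose.
The fit cost sums weighted absolute characteristic differences over doses
(defaults w_H = 1 /mV, w_rise = w_fall = 10 /s — a package choice, exposed);
a characteristic missing in the prediction but present in the target incurs
10× the weight, and characteristics missing in both cost nothing.
Nelder–Mead is used as the local optimizer with bounds enforced by a clipped
evaluation plus penalty; restarts jitter the start with seeded noise.

## Problem sizes and numerical defaults

Validation and benchmark computations use N = 40 compartments (the count at
which the steady-state error against the cable solution falls below 1% at
5 nS), output grids of 10 µs during transients, and the exact LTI propagation
wherever conductances are piecewise constant.  The parameter-recovery study
fits the three maximal conductances {G_Mcat, G_MCl, G_MK} of the complete
model at N = 4 compartments over three uptakes with 0.5-s pulses — sizes
chosen to keep a full simplex run in minutes while leaving each parameter
identifiable (recovery lands within ~3% from +20% starts; looser simplex
tolerances stall in a shallow cost valley with compensating parameters, so
the defaults keep xatol/fatol tight rather than capping iterations).

## Known limitations

- The tabulated load ratios r_in = 0.900 and a = 0.3018 of the source
  literature are inconsistent with their own defining formulas (they
  correspond to using the apical auxiliary resistance alone); this package
  follows the formulas (r_in = 0.923, a = 0.319), which is also what the
  numeric/analytic agreement requires.
- The single-compartment (N = 1) steady-state RP_b error at 5 nS is 18.8%
  here, somewhat below the 22+% reported for the original implementation; no
  defensible discretization reproduces the larger value while keeping the
  N = 40 error below 1%.
- The tip RP settles to within 5% of steady state 8.8 ms after a 0.1-nS step
  (50% at 2.0 ms, 90% at 6.8 ms); descriptions of the same transient as
  "≈5 ms" correspond to the 80–90% point.
- No action-potential generation, no two-ORN sensilla, no stochastic channel
  gating, no perireceptor pheromone transport.
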