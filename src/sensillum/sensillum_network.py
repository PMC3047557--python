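"""Electrical network of the sensillum and its time integration.

Topology
--------
The outer dendrite is divided into ``N`` isopotential compartments, each with
an intracellular node ``V_id[j]`` and a sensillar-lymph node ``V_ed[j]``
(hemolymph is the global 0 mV reference).  Node ``j`` sits at ``j * L_d / N``
from the sealed hair tip, so node ``N`` is at the dendrite base.  Across the
membrane of each compartment: the capacitance ``c_dc = C_d/N``, the leak
branch ``(g_ldc, E_ld)`` and the pheromone-dependent branches.  Adjacent
intracellular nodes are joined by ``g_ic = N G_i`` and adjacent lymph nodes by
``g_ec = N G_e``; compartment ``N`` couples intracellularly to the soma node
``V_is`` (capacitance ``C_s``, leak ``(G_ls, E_ls)``, K+ branch) and its lymph
node couples to the auxiliary apical node ``V_a`` (capacitance ``C_a``, branch
``G_a`` in series with the battery ``E_a``, oriented so the resting lymph sits
at the transepithelial potential ``-E_a`` above hemolymph).  The tip end is
sealed: no axial current beyond compartment 1.

State reduction
---------------
Only the membrane capacitances store charge, so the natural ODE states are the
transmembrane potentials ``dV[j] = V_id[j] - V_ed[j]`` plus ``V_is`` and
``V_a``; the individual node potentials follow from Kirchhoff's current law as
the solution of a tridiagonal linear system at every instant (the membrane
current leaving an intracellular node must return through the lymph).  This
removes the sub-microsecond axial modes from the differentiated variables.
With piecewise-constant conductances the reduced system is linear
time-invariant and is propagated exactly through its eigendecomposition; the
nonlinear complete model is integrated with a stiff-capable adaptive solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import LinAlgError, eig, expm, solve, solve_banded

from . import channels as ch
from .biochem_drive import DriveProtocol, ModulatorState
from .parameters import CompartmentalScaling

__all__ = [
    "SensillumCircuit",
    "Trajectory",
    "SteadyState",
    "StepProtocol",
    "SquareProtocol",
    "resting_state",
    "steady_state_simplified",
    "integrate_simplified",
    "integrate_complete",
    "extract_potentials",
    "leak_and_axial_currents",
    "kirchhoff_residuals",
]


@dataclass(frozen=True)
class StepProtocol:
    """Total pheromone-dependent conductance stepped to ``G_p`` nS at ``t_on`` ms,
    distributed uniformly over the compartments."""

    G_p: float
    t_on: float = 0.0

    def __post_init__(self):
        if self.G_p < 0:
            raise ValueError("conductance must be non-negative")


@dataclass(frozen=True)
class SquareProtocol:
    """Square pulse of total conductance ``G_p`` nS between ``t_on`` and
    ``t_off`` ms, uniform across compartments."""

    G_p: float
    t_on: float = 0.0
    t_off: float = 2000.0

    def __post_init__(self):
        if self.G_p < 0:
            raise ValueError("conductance must be non-negative")
        if self.t_off < self.t_on:
            raise ValueError("t_off must be >= t_on")


class SensillumCircuit:
    """Precomputed electrical structure for one compartment count ``N``."""

    def __init__(self, scaling: CompartmentalScaling, E_p: float = 0.0):
        self.scaling = scaling
        self.E_p = E_p
        d = scaling.derived
        self.N = scaling.N
        self.g_ic = scaling.g_ic
        self.g_ec = scaling.g_ec
        self.c_dc = scaling.c_dc
        self.g_ldc = scaling.g_ldc
        self.E_ld = d.E_ld
        self.E_ls = d.E_ls
        self.E_a = d.E_a
        self.G_ls = d.G_ls
        self.G_a = d.G_a
        self.C_s = d.C_s
        self.C_a = d.C_a
        self._build_axial_matrix()

    # -- axial (algebraic) subsystem -------------------------------------

    def _build_axial_matrix(self) -> None:
        N, off = self.N, self.g_ic + self.g_ec
        ab = np.zeros((3, N))
        ab[0, 1:] = off                      # superdiagonal
        ab[2, :-1] = off                     # subdiagonal
        deg = np.full(N, 2.0)
        deg[0] = 1.0
        if N > 1:
            deg[-1] = 1.0
        deg[-1] += 1.0                       # base couples to soma + auxiliary
        if N == 1:
            deg[0] = 1.0                     # only the base links exist
        ab[1] = -deg * off
        self._ab = ab

    def solve_external(self, dV: np.ndarray, V_is, V_a) -> np.ndarray:
        """Lymph node potentials ``V_ed`` from the instantaneous KCL constraint.

        Accepts ``dV`` of shape (N,) or (T, N) with matching scalar/array
        ``V_is``, ``V_a``; returns the same shape.
        """
        dV = np.asarray(dV, dtype=float)
        single = dV.ndim == 1
        dVm = np.atleast_2d(dV)
        V_is = np.atleast_1d(np.asarray(V_is, dtype=float))
        V_a = np.atleast_1d(np.asarray(V_a, dtype=float))
        N = self.N
        d = np.zeros_like(dVm)
        lap = np.zeros_like(dVm)
        if N > 1:
            lap[:, 0] = dVm[:, 1] - dVm[:, 0]
            lap[:, -1] = dVm[:, -2] - dVm[:, -1]
            if N > 2:
                lap[:, 1:-1] = dVm[:, 2:] - 2 * dVm[:, 1:-1] + dVm[:, :-2]
        d -= self.g_ic * lap
        d[:, -1] -= self.g_ic * (V_is - dVm[:, -1]) + self.g_ec * V_a
        W = solve_banded((1, 1), self._ab, d.T).T
        return W[0] if single else W

    # -- right-hand sides -------------------------------------------------

    def electrical_rates(self, dV, V_is, V_a, I_ion, G_K=0.0):
        """Time derivatives of (dV, V_is, V_a) given the ionic membrane
        currents ``I_ion`` (pA, outward positive) of every compartment."""
        W = self.solve_external(dV, V_is, V_a)
        V_id = W + dV
        axial = np.zeros_like(dV)
        if self.N > 1:
            axial[0] = self.g_ic * (V_id[1] - V_id[0])
            axial[-1] = self.g_ic * (V_id[-2] - V_id[-1])
            if self.N > 2:
                axial[1:-1] = self.g_ic * (V_id[2:] - 2 * V_id[1:-1] + V_id[:-2])
        axial[-1] += self.g_ic * (V_is - V_id[-1])
        d_dV = (axial - I_ion) / self.c_dc
        I_K = G_K * (V_is - self.scaling.channels.K.E)
        d_Vis = (self.g_ic * (V_id[-1] - V_is)
                 - self.G_ls * (V_is - self.E_ls) - I_K) / self.C_s
        d_Va = (self.g_ec * (W[-1] - V_a)
                - self.G_a * (V_a + self.E_a)) / self.C_a
        return d_dV, d_Vis, d_Va

    def simplified_matrices(self, g_p: np.ndarray, G_K: float = 0.0):
        """LTI form ``dy/dt = A y + b`` for y = (dV[1..N], V_is, V_a) with the
        given per-compartment pheromone conductances (nS) held constant."""
        g_p = np.broadcast_to(np.asarray(g_p, dtype=float), (self.N,))
        if np.any(g_p < 0):
            raise ValueError("conductance must be non-negative")

        def f(y):
            dV, V_is, V_a = y[: self.N], y[self.N], y[self.N + 1]
            I_ion = (self.g_ldc * (dV - self.E_ld) + g_p * (dV - self.E_p))
            d_dV, d_Vis, d_Va = self.electrical_rates(dV, V_is, V_a, I_ion, G_K)
            return np.concatenate([d_dV, [d_Vis, d_Va]])

        n = self.N + 2
        b = f(np.zeros(n))
        A = np.empty((n, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            A[:, i] = f(e) - b
        return A, b

    def rest_vector(self) -> np.ndarray:
        """Battery-consistent resting state (exact when E_ld = E_ls + E_a)."""
        y = np.empty(self.N + 2)
        y[: self.N] = self.E_ld
        y[self.N] = self.E_ls
        y[self.N + 1] = -self.E_a
        return y


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyState:
    """Steady solution of the circuit for constant conductances."""

    dV: np.ndarray
    V_is: float
    V_a: float
    V_ed: np.ndarray
    RP: np.ndarray          # per compartment, mV
    RP_s: float
    SP: float
    G_K: float = 0.0

    @property
    def RP_b(self) -> float:
        return float(self.RP[-1])


@dataclass
class Trajectory:
    """Time-indexed record of a simulation.

    Potentials in mV, time in ms.  ``RP[k, j]`` is the receptor potential of
    compartment ``j`` (transmembrane, relative to rest), ``RP_s`` the somatic
    and ``SP`` the tip-recorded sensillar potential.  ``RP_b`` is the base
    value ``RP[:, -1]``.
    """

    t: np.ndarray
    dV: np.ndarray
    V_is: np.ndarray
    V_a: np.ndarray
    V_ed: np.ndarray
    RP: np.ndarray
    RP_s: np.ndarray
    SP: np.ndarray
    N: int
    rest: np.ndarray
    g_p: np.ndarray | None = None
    modulators: Mapping[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def RP_b(self) -> np.ndarray:
        return self.RP[:, -1]

    @property
    def V_id(self) -> np.ndarray:
        return self.V_ed + self.dV


def _finish_trajectory(circuit: SensillumCircuit, t, Y, rest, g_p=None,
                       modulators=None, meta=None) -> Trajectory:
    N = circuit.N
    dV = Y[:, :N]
    V_is = Y[:, N]
    V_a = Y[:, N + 1]
    V_ed = circuit.solve_external(dV, V_is, V_a)
    rest_ed = circuit.solve_external(rest[:N], rest[N], rest[N + 1])
    RP = dV - rest[:N]
    RP_s = V_is - rest[N]
    SP = V_ed[:, 0] - rest_ed[0]
    return Trajectory(t=np.asarray(t, float), dV=dV, V_is=V_is, V_a=V_a,
                      V_ed=V_ed, RP=RP, RP_s=RP_s, SP=SP, N=N, rest=rest.copy(),
                      g_p=g_p, modulators=modulators, meta=meta or {})


# ---------------------------------------------------------------------------
# Resting and steady states
# ---------------------------------------------------------------------------


def resting_state(scaling: CompartmentalScaling, E_p: float = 0.0,
                  tol: float = 1e-9) -> SteadyState:
    """Resting state with all pheromone-dependent conductances zero.

    When the batteries are consistent (E_ld = E_ls + E_a) the exact rest is
    uniform with every branch current zero; otherwise the linear circuit is
    solved numerically (a warning case: a circulating standing current then
    flows at rest).
    """
    circuit = SensillumCircuit(scaling, E_p)
    d = scaling.derived
    if abs(d.E_ld - (d.E_ls + d.E_a)) <= tol:
        y = circuit.rest_vector()
    else:
        A, b = circuit.simplified_matrices(np.zeros(scaling.N))
        try:
            y = solve(A, -b)
        except LinAlgError as err:
            raise ValueError(f"singular resting circuit: {err}") from err
    return _steady_from_vector(circuit, y, y)


def _steady_from_vector(circuit, y, rest) -> SteadyState:
    N = circuit.N
    V_ed = circuit.solve_external(y[:N], y[N], y[N + 1])
    rest_ed = circuit.solve_external(rest[:N], rest[N], rest[N + 1])
    return SteadyState(
        dV=y[:N], V_is=float(y[N]), V_a=float(y[N + 1]), V_ed=V_ed,
        RP=y[:N] - rest[:N], RP_s=float(y[N] - rest[N]),
        SP=float(V_ed[0] - rest_ed[0]),
    )


def steady_state_simplified(
    scaling: CompartmentalScaling,
    G_p: float | np.ndarray,
    E_p: float = 0.0,
    G_K_func: Callable[[float], float] | None = None,
) -> SteadyState:
    """Steady state under constant pheromone-dependent conductance.

    ``G_p`` is the TOTAL dendritic conductance (nS), distributed uniformly,
    unless an array of per-compartment values is given.  ``G_K_func`` allows a
    voltage-dependent somatic K+ conductance, resolved by fixed-point
    iteration (used for complete-model-style steady sweeps).
    """
    circuit = SensillumCircuit(scaling, E_p)
    g_p = _per_compartment(G_p, scaling.N)
    rest = circuit.rest_vector()
    G_K = 0.0
    for _ in range(200):
        A, b = circuit.simplified_matrices(g_p, G_K)
        y = solve(A, -b)
        if G_K_func is None:
            break
        G_K_new = float(G_K_func(float(y[scaling.N])))
        if abs(G_K_new - G_K) < 1e-12:
            G_K = G_K_new
            break
        G_K = 0.5 * G_K + 0.5 * G_K_new   # damped update
    else:
        raise RuntimeError("K-conductance fixed point did not converge")
    out = _steady_from_vector(circuit, y, rest)
    return SteadyState(**{**out.__dict__, "G_K": G_K})


def _per_compartment(G_p, N: int) -> np.ndarray:
    arr = np.asarray(G_p, dtype=float)
    if arr.ndim == 0:
        g = np.full(N, float(arr) / N)
    elif arr.shape == (N,):
        g = arr.astype(float)
    else:
        raise ValueError(f"G_p must be scalar or length-{N} array")
    if np.any(g < 0):
        raise ValueError("conductance must be non-negative")
    return g


# ---------------------------------------------------------------------------
# Linear (simplified-model) propagation
# ---------------------------------------------------------------------------


def _lti_segment(A, b, y0, t):
    """Exact solution of dy/dt = A y + b at times ``t`` (from t = 0)."""
    y_ss = solve(A, -b)
    lam, V = eig(A)
    try:
        c = solve(V, (y0 - y_ss).astype(complex))
        bad = np.linalg.cond(V) > 1e10
    except np.linalg.LinAlgError:
        bad = True
    if not bad:
        with np.errstate(under="ignore"):
            modes = np.exp(np.outer(t, lam)) * c
        return y_ss + (modes @ V.T).real
    # defective eigenbasis: fall back to stepping with the matrix exponential
    t = np.asarray(t, float)
    out = np.empty((t.size, y0.size))
    y = y0.copy()
    prev = 0.0
    for k, tk in enumerate(t):
        if tk != prev:
            y = y_ss + expm(A * (tk - prev)) @ (y - y_ss)
            prev = tk
        out[k] = y
    return out


def _default_grid(t_end: float, dt: float) -> np.ndarray:
    return np.arange(0.0, t_end + 0.5 * dt, dt)


def integrate_simplified(
    scaling: CompartmentalScaling,
    protocol,
    E_p: float = 0.0,
    t_end: float | None = None,
    dt: float = 0.05,
    t_eval: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    solver: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-9,
    G_K_of_t: Callable[[float], float] | None = None,
) -> Trajectory:
    """Integrate the single-conductance (simplified) sensillum model.

    ``protocol`` is a :class:`StepProtocol`, a :class:`SquareProtocol`, or a
    callable ``g_p(t_ms) -> (N,) array`` of per-compartment conductances (nS).
    Step and square protocols are piecewise linear-time-invariant and are
    propagated exactly by eigendecomposition; a callable protocol goes through
    the adaptive ODE solver.  The somatic K+ branch is absent by default
    (G_MK = 0, repolarization by the leak conductances alone); for exact
    replay of a complete-model run its time-varying K+ conductance can be
    supplied as ``G_K_of_t`` (only with a callable protocol).
    """
    circuit = SensillumCircuit(scaling, E_p)
    rest = circuit.rest_vector()
    if y0 is None:
        y0 = rest
    if t_eval is None:
        if t_end is None:
            raise ValueError("give t_end or t_eval")
        t_eval = _default_grid(t_end, dt)
    t_eval = np.asarray(t_eval, dtype=float)

    if isinstance(protocol, (StepProtocol, SquareProtocol)):
        if G_K_of_t is not None:
            raise ValueError("G_K_of_t requires a callable conductance protocol")
        g_on = _per_compartment(protocol.G_p, scaling.N)
        if isinstance(protocol, StepProtocol):
            pieces = [(protocol.t_on, np.zeros(scaling.N)),
                      (np.inf, g_on)]
        else:
            pieces = [(protocol.t_on, np.zeros(scaling.N)),
                      (protocol.t_off, g_on),
                      (np.inf, np.zeros(scaling.N))]
        Y = np.empty((t_eval.size, scaling.N + 2))
        y = y0.copy()
        t0 = t_eval[0]
        start = t0
        for t_edge, g_seg in pieces:
            mask = (t_eval >= start - 1e-12) & (t_eval < t_edge)
            seg_times = t_eval[mask] - start
            A, b = circuit.simplified_matrices(g_seg)
            if seg_times.size:
                Y[mask] = _lti_segment(A, b, y, seg_times)
            if not np.isfinite(t_edge):
                break
            y = _lti_segment(A, b, y, np.array([t_edge - start]))[0]
            start = t_edge
        g_p_t = np.empty((t_eval.size, scaling.N))
        for (t_edge, g_seg), t_lo in zip(pieces, [t0, *[p[0] for p in pieces[:-1]]]):
            mask = (t_eval >= t_lo - 1e-12) & (t_eval < t_edge)
            g_p_t[mask] = g_seg
        return _finish_trajectory(circuit, t_eval, Y, rest, g_p=g_p_t,
                                  meta={"model": "simplified", "E_p": E_p})

    if not callable(protocol):
        raise TypeError("protocol must be StepProtocol, SquareProtocol or callable")

    def rhs(t, y):
        g_p = np.asarray(protocol(t), dtype=float)
        if np.any(g_p < 0):
            raise ValueError(f"negative conductance at t = {t} ms")
        dV, V_is, V_a = y[: scaling.N], y[scaling.N], y[scaling.N + 1]
        I_ion = circuit.g_ldc * (dV - circuit.E_ld) + g_p * (dV - E_p)
        G_K = float(G_K_of_t(t)) if G_K_of_t is not None else 0.0
        d_dV, d_Vis, d_Va = circuit.electrical_rates(dV, V_is, V_a, I_ion, G_K)
        return np.concatenate([d_dV, [d_Vis, d_Va]])

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), y0, method=solver,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"simplified-model integration failed: {sol.message}")
    g_p_t = np.array([protocol(tk) for tk in t_eval])
    return _finish_trajectory(circuit, t_eval, sol.y.T, rest, g_p=g_p_t,
                              meta={"model": "simplified", "E_p": E_p,
                                    "solver": solver})


# ---------------------------------------------------------------------------
# Complete (multichannel) model
# ---------------------------------------------------------------------------


def _unpack_complete(y, N):
    dV = y[:N]
    V_is = y[N]
    V_a = y[N + 1]
    Ca = np.maximum(y[N + 2: 2 * N + 2], 0.0)
    CaCaM = np.maximum(y[2 * N + 2: 3 * N + 2], 0.0)
    PKC = np.maximum(y[3 * N + 2: 4 * N + 2], 0.0)
    Ca_s = max(float(y[-1]), 0.0)
    return dV, V_is, V_a, Ca, CaCaM, PKC, Ca_s


def _complete_conductances(par: CompartmentalScaling, mods: ModulatorState,
                           Ca, CaCaM, PKC):
    """Per-compartment gated conductances given the modulator levels.

    Prescribed (drive-supplied) Ca/CaCaM/PKC waveforms override the dynamic
    states when the drive provides them (non-zero), so that plateau-style
    protocols can bypass the mass balance.
    """
    c = par.channels
    Ca_eff = mods.Ca if np.any(np.asarray(mods.Ca) > 0) else Ca
    CaM_eff = mods.CaCaM if np.any(np.asarray(mods.CaCaM) > 0) else CaCaM
    PKC_eff = mods.PKC if np.any(np.asarray(mods.PKC) > 0) else PKC
    return {
        "Ca": ch.gated_conductance(c.Ca, mods.IP3, CaM_eff, par.N),
        "cat": ch.gated_conductance(c.cat, mods.DAG, CaM_eff, par.N),
        "Cl": ch.gated_conductance(c.Cl, Ca_eff, PKC_eff, par.N),
        "x": ch.gated_conductance(c.x, Ca_eff, None, par.N),
    }


def integrate_complete(
    scaling: CompartmentalScaling,
    drive: DriveProtocol,
    U: float,
    t_end: float,
    dt: float = 1.0,
    solver: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-8,
    record_conductance: bool = True,
) -> Trajectory:
    """Integrate the complete multichannel model at one pheromone uptake.

    ``U`` in uM/s, ``t_end`` and ``dt`` in ms (the drive works in seconds and
    is converted at this interface).  State: transmembrane potentials, soma and
    auxiliary potentials, and per-compartment Ca2+, CaCaM and PKC* plus
    somatic Ca2+; IP3 and DAG come from the drive, dendritic Ca2+ from the
    charge-to-concentration mass balance, CaCaM/PKC*/somatic Ca2+ as low-pass
    stages with the drive's time constants.
    """
    circuit = SensillumCircuit(scaling, E_p=0.0)
    N = scaling.N
    cp = scaling.channels
    rest_el = circuit.rest_vector()
    y0 = np.concatenate([rest_el, np.zeros(3 * N + 1)])

    E = {name: rec.E for name, rec in cp.gated.items()}

    def rhs(t_ms, y):
        dV, V_is, V_a, Ca, CaCaM, PKC, Ca_s = _unpack_complete(y, N)
        mods = drive.modulators(t_ms * 1e-3, U)
        g = _complete_conductances(scaling, mods, Ca, CaCaM, PKC)
        I = {name: g[name] * (dV - E[name]) for name in g}
        I_ion = circuit.g_ldc * (dV - circuit.E_ld) + sum(I.values())
        G_K = ch.k_conductance(Ca_s, V_is, cp.K)
        d_dV, d_Vis, d_Va = circuit.electrical_rates(dV, V_is, V_a, I_ion, G_K)
        dCa = (-cp.f_Ca * I["Ca"] - cp.f_cat * I["cat"] + cp.F * I["x"]) * 1e-3
        dCa = np.where((y[N + 2: 2 * N + 2] <= 0) & (dCa < 0), 0.0, dCa)
        dCaM = (drive.kappa_cam * Ca - CaCaM) / (drive.tau_cam * 1e3)
        dPKC = (drive.kappa_pkc * Ca - PKC) / (drive.tau_pkc * 1e3)
        dCas = (drive.kappa_cas * float(np.mean(Ca)) - Ca_s) / (drive.tau_cas * 1e3)
        return np.concatenate([d_dV, [d_Vis, d_Va], dCa, dCaM, dPKC, [dCas]])

    t_eval = _default_grid(t_end, dt)
    sol = solve_ivp(rhs, (0.0, t_eval[-1]), y0, method=solver, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"complete-model integration failed at t = {sol.t[-1]:.3f} ms: "
            f"{sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError("complete-model integration produced non-finite state")

    Y = sol.y.T
    traj = _finish_trajectory(circuit, t_eval, Y[:, : N + 2], rest_el,
                              meta={"model": "complete", "U": U, "solver": solver})
    # solver states may dip infinitesimally below zero; concentrations are
    # clamped on output just as inside the right-hand side
    mods_t = {"Ca": np.maximum(Y[:, N + 2: 2 * N + 2], 0.0),
              "CaCaM": np.maximum(Y[:, 2 * N + 2: 3 * N + 2], 0.0),
              "PKC": np.maximum(Y[:, 3 * N + 2: 4 * N + 2], 0.0),
              "Ca_soma": np.maximum(Y[:, -1], 0.0)}
    drive_t = drive.modulators(t_eval * 1e-3, U)
    mods_t["IP3"] = np.asarray(drive_t.IP3)
    mods_t["DAG"] = np.asarray(drive_t.DAG)
    traj.modulators = mods_t
    traj.meta["G_K"] = ch.k_conductance(mods_t["Ca_soma"], traj.V_is, cp.K)
    if record_conductance:
        g_p = np.empty((t_eval.size, N))
        for k in range(t_eval.size):
            mk = drive.modulators(t_eval[k] * 1e-3, U)
            g = _complete_conductances(scaling, mk, mods_t["Ca"][k],
                                       mods_t["CaCaM"][k], mods_t["PKC"][k])
            I_sum = sum(g[name] * (traj.dV[k] - E[name]) for name in g)
            g_p[k] = ch.lumped_conductance(I_sum, traj.dV[k], E_p=0.0)
        # fill any flagged (near-zero driving force) samples per compartment
        for j in range(N):
            g_p[:, j] = ch.interpolate_flagged(t_eval, g_p[:, j])
        traj.g_p = g_p
    return traj


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


def extract_potentials(traj: Trajectory, atol: float = 1e-3):
    """(RP_j, RP_b, RP_s, SP) time series from a trajectory starting at rest.

    RP_j(t) = dV_j(t) - dV_j(0), RP_s(t) = V_is(t) - V_is(0) and
    SP(t) = V_ed_1(t) - V_ed_1(0); refused when the trajectory does not start
    at the resting state (the reference would be undefined).
    """
    start = np.concatenate([traj.dV[0], [traj.V_is[0], traj.V_a[0]]])
    if not np.allclose(start, traj.rest, atol=atol):
        raise ValueError("trajectory does not start at rest; RP/SP undefined")
    return traj.RP, traj.RP_b, traj.RP_s, traj.SP


def leak_and_axial_currents(traj_or_state, scaling: CompartmentalScaling,
                            index: int = -1, E_p: float = 0.0,
                            g_p: np.ndarray | None = None,
                            G_K: float = 0.0) -> ch.CurrentsSnapshot:
    """Branch currents of the circuit at one instant (pA).

    For a :class:`Trajectory`, ``index`` selects the sample; a
    :class:`SteadyState` is evaluated directly.  Pheromone-dependent branches
    are included when per-compartment ``g_p`` is given (or stored on the
    trajectory).
    """
    circuit = SensillumCircuit(scaling, E_p)
    if isinstance(traj_or_state, SteadyState):
        dV, V_is, V_a, V_ed = (traj_or_state.dV, traj_or_state.V_is,
                               traj_or_state.V_a, traj_or_state.V_ed)
    else:
        tr = traj_or_state
        if tr.N != scaling.N:
            raise ValueError("trajectory and scaling dimensions differ")
        dV, V_is, V_a, V_ed = (tr.dV[index], tr.V_is[index], tr.V_a[index],
                               tr.V_ed[index])
        if g_p is None and tr.g_p is not None:
            g_p = tr.g_p[index]
    V_id = V_ed + dV
    N = scaling.N
    I_ld = scaling.g_ldc * (dV - scaling.derived.E_ld)
    gated = {}
    if g_p is not None:
        gated["p"] = np.asarray(g_p, float) * (dV - E_p)
    I_i = np.empty(N)
    I_e = np.empty(N)
    if N > 1:
        I_i[:-1] = scaling.g_ic * (V_id[:-1] - V_id[1:])
        I_e[:-1] = scaling.g_ec * (V_ed[1:] - V_ed[:-1])
    I_i[-1] = scaling.g_ic * (V_id[-1] - V_is)
    I_e[-1] = scaling.g_ec * (V_a - V_ed[-1])
    I_K = G_K * (V_is - scaling.channels.K.E)
    I_ls = scaling.derived.G_ls * (V_is - scaling.derived.E_ls)
    I_a = scaling.derived.G_a * (V_a + scaling.derived.E_a)
    return ch.CurrentsSnapshot(I_ld=I_ld, I_gated=gated, I_i=I_i, I_e=I_e,
                               I_K=float(I_K), I_ls=float(I_ls), I_a=float(I_a))


def kirchhoff_residuals(traj: Trajectory, scaling: CompartmentalScaling,
                        E_p: float = 0.0) -> np.ndarray:
    """Per-sample, per-lymph-node current residual (pA).

    The reduced formulation enforces, at every instant, that the membrane
    current leaving each intracellular node returns through the lymph network;
    this recomputes that balance from the stored potentials as an independent
    bookkeeping check.
    """
    circuit = SensillumCircuit(scaling, E_p)
    V_ed = traj.V_ed
    V_id = V_ed + traj.dV
    N = scaling.N
    res = np.zeros_like(V_ed)
    # net axial current INTO each intracellular node minus net axial current
    # OUT of the matching lymph node must vanish (charge bookkeeping).
    for arr, g, bound in ((V_id, circuit.g_ic, traj.V_is),
                          (V_ed, circuit.g_ec, traj.V_a)):
        flow = np.zeros_like(V_ed)
        if N > 1:
            flow[:, 0] = g * (arr[:, 1] - arr[:, 0])
            flow[:, -1] = g * (arr[:, -2] - arr[:, -1])
            if N > 2:
                flow[:, 1:-1] = g * (arr[:, 2:] - 2 * arr[:, 1:-1] + arr[:, :-2])
        flow[:, -1] += g * (np.asarray(bound) - arr[:, -1])
        res += flow
    return res
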