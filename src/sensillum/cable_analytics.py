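"""Closed-form cable solutions used as oracles for the compartmental circuit.

Steady state
------------
With a uniform pheromone-dependent conductance the outer dendrite is a
two-wire cable (intracellular core, sensillar-lymph return) with sealed tip
and a lumped load (soma in one wire, auxiliary cells in the other) at the
base.  In dimensionless form — position ``x`` in space constants, conductance
``g = r_ld g_p`` in units of the resting membrane conductance — the
transmembrane potential obeys ``d^2(dV)/dx^2 = (1+g)(dV - E_inf)`` and the
boundary-value problem solves in hyperbolic functions.  With ``mu =
sqrt(1+g)`` and ``D = cosh(mu l_d) + mu r_in sinh(mu l_d)``::

    RP(x)  = g (E_p - E_ld) / (1+g) * (1 - cosh(mu x) / D)
    RP_b   = g (E_p - E_ld) / (1+g) * mu r_in sinh(mu l_d) / D
    SP     = -a RP_b - beta (RP(0) - RP_b),    beta = r_e / (r_e + r_i)

so with ``E_p = 0`` the ratio SP/RP is independent of every battery and
depends only on the resistance ratios and the electrotonic length.

Transient
---------
The step response is obtained on a cable sealed at both ends whose sensory
region ``[0, l_d]`` receives the uniform conductance step at ``t = 0``.  The
base load is represented by a sealed passive extension ("tail"): a sealed
stub of ``l`` space constants has normalized input conductance ``coth(l) -> 1``
for long ``l``, and the actual load ``r_in ~ 0.92`` is close to matched, so a
tail of a few space constants emulates it closely.  The equation stays linear
(the conductance-load term ``g v`` is kept), but with the piecewise-constant
coefficient the eigenfunctions are piecewise trigonometric with a
transcendental matching condition, solved numerically; the response is the
eigenfunction series ``v = sum_k c_k / L_k (1 - exp(-L_k t')) phi_k(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import DerivedCableParams

__all__ = [
    "DimensionlessCable",
    "dimensionless_conductance",
    "steady_rp_base",
    "steady_rp_profile",
    "steady_sp",
    "transient_small_signal",
    "transient_steady_limit",
    "analytic_steady",
    "analytic_transient",
]

DEFAULT_TAIL = 3.0   # sealed extension beyond the dendrite, in space constants


@dataclass(frozen=True)
class DimensionlessCable:
    """Dimensionless groups of the cable problem for one parameter set."""

    g: float          # pheromone conductance in resting-membrane units
    l_d: float        # electrotonic dendrite length
    r_in: float       # normalized base load (soma + auxiliary)
    a: float          # auxiliary fraction of the base load
    beta: float       # extracellular fraction r_e / (r_e + r_i)
    E_ld: float       # dendritic leak battery, mV
    E_p: float        # lumped pheromone battery, mV

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("dimensionless conductance must be >= 0")


def dimensionless_conductance(derived: DerivedCableParams, G_p: float) -> float:
    """Total conductance ``G_p`` (nS) in resting-membrane units, g = G_p/G_ld."""
    return G_p / derived.G_ld


def _D(mu: float, l_d: float, r_in: float) -> float:
    return np.cosh(mu * l_d) + mu * r_in * np.sinh(mu * l_d)


def steady_rp_base(g: float, l_d: float, r_in: float,
                   E_ld: float = -97.0, E_p: float = 0.0) -> float:
    """Steady-state receptor potential at the dendrite base (mV)."""
    if g < 0:
        raise ValueError("g must be >= 0")
    if g == 0:
        return 0.0
    mu = np.sqrt(1.0 + g)
    return float(g * (E_p - E_ld) / (1.0 + g)
                 * mu * r_in * np.sinh(mu * l_d) / _D(mu, l_d, r_in))


def steady_rp_profile(x, g: float, l_d: float, r_in: float,
                      E_ld: float = -97.0, E_p: float = 0.0):
    """Steady-state RP at position(s) ``x`` (space constants from the tip)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > l_d + 1e-12):
        raise ValueError(f"position x must lie in [0, l_d = {l_d}]")
    if g < 0:
        raise ValueError("g must be >= 0")
    mu = np.sqrt(1.0 + g)
    out = (g * (E_p - E_ld) / (1.0 + g)
           * (1.0 - np.cosh(mu * x) / _D(mu, l_d, r_in)))
    return out if out.ndim else float(out)


def steady_sp(g: float, l_d: float, r_in: float, a: float, beta: float,
              E_ld: float = -97.0, E_p: float = 0.0) -> float:
    """Steady-state tip-recorded sensillar potential (mV); negative-going."""
    rp_b = steady_rp_base(g, l_d, r_in, E_ld, E_p)
    rp_0 = float(steady_rp_profile(0.0, g, l_d, r_in, E_ld, E_p))
    return -a * rp_b - beta * (rp_0 - rp_b)


# ---------------------------------------------------------------------------
# Transient eigenfunction series
# ---------------------------------------------------------------------------


def _region1(lam: float, g: float, x):
    """phi and phi' in the sensory region (phi'(0) = 0, phi(0) = 1)."""
    s = lam - 1.0 - g
    x = np.asarray(x, dtype=float)
    if s > 1e-14:
        w = np.sqrt(s)
        return np.cos(w * x), -w * np.sin(w * x)
    if s < -1e-14:
        w = np.sqrt(-s)
        return np.cosh(w * x), w * np.sinh(w * x)
    return np.ones_like(x), np.zeros_like(x)


def _region2(lam: float, Lp: float, x):
    """phi and phi' in the tail (phi'(Lp) = 0, phi = cos-type of (Lp - x))."""
    s = lam - 1.0
    y = Lp - np.asarray(x, dtype=float)
    if s > 1e-14:
        w = np.sqrt(s)
        return np.cos(w * y), w * np.sin(w * y)
    if s < -1e-14:
        w = np.sqrt(-s)
        return np.cosh(w * y), -w * np.sinh(w * y)
    return np.ones_like(y), np.zeros_like(y)


def _secular(lam: float, g: float, l_d: float, Lp: float) -> float:
    c1, d1 = _region1(lam, g, l_d)
    c2, d2 = _region2(lam, Lp, l_d)
    return float(d1 * c2 - c1 * d2)


def _eigenmodes(g: float, l_d: float, Lp: float, n_modes: int):
    """Eigenvalues and piecewise eigenfunction factory for the composite cable."""
    # scan in b = sqrt(lam - 1); mode spacing ~ pi / Lp
    b_max = (n_modes + 2) * np.pi / Lp + np.sqrt(max(g, 1.0))
    bs = np.linspace(1e-9, b_max, int(40 * b_max * Lp / np.pi) + 100)
    lams = 1.0 + bs**2
    vals = np.array([_secular(l, g, l_d, Lp) for l in lams])
    roots = []
    for i in range(len(lams) - 1):
        if vals[i] == 0.0:
            roots.append(lams[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(_secular, lams[i], lams[i + 1],
                                args=(g, l_d, Lp), xtol=1e-13, rtol=1e-14))
        if len(roots) >= n_modes:
            break
    return np.array(roots)


def _eigenfunction(lam: float, g: float, l_d: float, Lp: float, x):
    x = np.asarray(x, dtype=float)
    c1, _ = _region1(lam, g, l_d)
    c2, _ = _region2(lam, Lp, l_d)
    phi = np.empty_like(x)
    left = x <= l_d
    phi[left] = _region1(lam, g, x[left])[0]
    # continuity scaling of the tail branch; near-nodal c2 is handled by
    # scaling from whichever side is better conditioned
    if abs(c2) >= abs(c1) * 1e-12:
        phi[~left] = _region2(lam, Lp, x[~left])[0] * (c1 / c2)
    else:
        phi[~left] = 0.0
    return phi


def transient_small_signal(x, t_prime, g_step: float, l_d: float,
                           tail: float = DEFAULT_TAIL,
                           E_ld: float = -97.0, E_p: float = 0.0,
                           n_modes: int = 500, tol: float = 1e-8):
    """Step response ``v(x, t')`` (mV) of the linearized sealed-sealed cable.

    ``x`` positions (space constants), ``t_prime`` times (membrane time
    constants); ``g_step`` is the dimensionless conductance switched on over
    the sensory region at ``t' = 0``.  Returns an array of shape
    ``(len(t_prime), len(x))``.  Raises if the series has not converged at
    ``n_modes`` terms.
    """
    if g_step < 0:
        raise ValueError("g_step must be >= 0")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.atleast_1d(np.asarray(t_prime, dtype=float))
    if g_step == 0:
        return np.zeros((t.size, x.size))
    Lp = l_d + tail
    E = E_p - E_ld
    lams = _eigenmodes(g_step, l_d, Lp, n_modes)
    if lams.size == 0:
        raise RuntimeError("no eigenmodes found")
    # quadrature grids for projections (independent of any compartmental
    # grid); the forcing jumps at l_d, so the sensory and tail regions are
    # integrated separately to keep the trapezoid rule at O(h^2)
    xq1 = np.linspace(0.0, l_d, 2001)
    xq2 = np.linspace(l_d, Lp, 3001)
    v = np.zeros((t.size, x.size))
    growth = np.exp(np.outer(-t, lams))          # (T, K)
    scale = abs(g_step * E)
    converged = False
    small_run = 0
    for k, lam in enumerate(lams):
        phi_1 = _eigenfunction(lam, g_step, l_d, Lp, xq1)
        phi_2 = _eigenfunction(lam, g_step, l_d, Lp, xq2)
        num = g_step * E * np.trapezoid(phi_1, xq1)
        den = np.trapezoid(phi_1**2, xq1) + np.trapezoid(phi_2**2, xq2)
        c_k = num / den
        phi_x = _eigenfunction(lam, g_step, l_d, Lp, x)
        term = (c_k / lam) * (1.0 - growth[:, k])[:, None] * phi_x[None, :]
        v += term
        # a single small term can be accidental (node of phi at the sample
        # points); require a run of three before truncating
        small_run = small_run + 1 if np.max(np.abs(term)) < tol * max(scale, 1e-30) else 0
        if k > 2 and small_run >= 3:
            converged = True
            break
    if not converged and lams.size >= n_modes:
        raise RuntimeError(
            f"eigenfunction series not converged after {n_modes} modes")
    return v


def transient_steady_limit(x, g_step: float, l_d: float,
                           tail: float = DEFAULT_TAIL,
                           E_ld: float = -97.0, E_p: float = 0.0):
    """Closed-form t -> infinity limit of :func:`transient_small_signal`."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if g_step == 0:
        return np.zeros_like(x)
    E = E_p - E_ld
    mu = np.sqrt(1.0 + g_step)
    u = tail
    plateau = g_step * E / (1.0 + g_step)
    B = plateau / (np.cosh(u) + np.sinh(u) * np.cosh(mu * l_d)
                   / (mu * np.sinh(mu * l_d)))
    A = -B * np.sinh(u) / (mu * np.sinh(mu * l_d))
    out = np.where(x <= l_d, plateau + A * np.cosh(mu * x),
                   B * np.cosh(l_d + u - x))
    return out


# ---------------------------------------------------------------------------
# Dimensional wrappers
# ---------------------------------------------------------------------------


def _groups(derived: DerivedCableParams, G_p: float, E_p: float
            ) -> DimensionlessCable:
    return DimensionlessCable(
        g=dimensionless_conductance(derived, G_p), l_d=derived.l_d,
        r_in=derived.r_in, a=derived.a, beta=derived.beta,
        E_ld=derived.E_ld, E_p=E_p)


def analytic_steady(derived: DerivedCableParams, G_p: float, E_p: float = 0.0,
                    x_um=None):
    """Steady RP_b, SP (mV) — and the RP profile at ``x_um`` if given —
    for a total conductance ``G_p`` in nS."""
    c = _groups(derived, G_p, E_p)
    rp_b = steady_rp_base(c.g, c.l_d, c.r_in, c.E_ld, c.E_p)
    sp = steady_sp(c.g, c.l_d, c.r_in, c.a, c.beta, c.E_ld, c.E_p)
    if x_um is None:
        return rp_b, sp
    x = np.asarray(x_um, dtype=float) / derived.lam
    prof = steady_rp_profile(x, c.g, c.l_d, c.r_in, c.E_ld, c.E_p)
    return rp_b, sp, prof


def analytic_transient(derived: DerivedCableParams, G_p: float, x_um, t_ms,
                       E_p: float = 0.0, tail: float = DEFAULT_TAIL,
                       **kwargs):
    """Step-response RP(x, t) (mV) for positions in um and times in ms."""
    c = _groups(derived, G_p, E_p)
    x = np.asarray(x_um, dtype=float) / derived.lam
    t = np.asarray(t_ms, dtype=float) / derived.tau
    return transient_small_signal(x, t, c.g, c.l_d, tail=tail,
                                  E_ld=c.E_ld, E_p=c.E_p, **kwargs)
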