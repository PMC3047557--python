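"""Gating variables and currents of the sensillum circuit.

Four pheromone-dependent channels sit on the outer-dendritic membrane, each
gated by a cytosolic agonist through a Hill function: the IP3-gated Ca2+
channel, the DAG-gated cationic channel, the Ca2+-gated chloride channel and
the Na+/Ca2+ exchanger.  Feedback inhibition (CaCaM on the Ca2+ and cationic
channels, PKC* on the chloride channel) raises the effective EC50 between
``K_m`` (no antagonist) and ``K_m * i_M`` (saturating antagonist).  A Ca2+-
and voltage-gated K+ channel sits on the inner-dendrite/soma membrane.

Sign convention: transmembrane currents are positive OUTWARD (intracellular to
extracellular), so the depolarizing pheromone-gated currents are negative
during stimulation.  With conductances in nS and potentials in mV, currents
come out in pA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ChannelParamSet, ChannelRecord, KChannelRecord

__all__ = [
    "hill_conductance",
    "inhibited_ec50",
    "gated_conductance",
    "channel_current",
    "k_conductance",
    "lumped_conductance",
    "CurrentsSnapshot",
]


def hill_conductance(g_max, Y, K_y, n_y):
    """Hill activation: ``g_max * Y**n / (K_y**n + Y**n)``.

    ``Y = K_y`` gives half-maximal conductance (the EC50 definition); the value
    is in ``[0, g_max)`` and monotone increasing in the agonist concentration.
    Accepts scalars or arrays.
    """
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("agonist concentration must be non-negative")
    if np.any(np.asarray(K_y) <= 0):
        raise ValueError("EC50 K_y must be positive")
    # Y**n with fractional n is fine for Y >= 0; guard 0/0 at Y = 0.
    Yn = np.power(Y, n_y)
    out = g_max * Yn / (np.power(K_y, n_y) + Yn)
    return out if out.ndim else float(out)


def inhibited_ec50(K_my, Z, K_iy, n_iy, i_My):
    """Effective EC50 shifted by an antagonist.

    Hill interpolation between the two limits: ``K_my`` at ``Z = 0`` and
    ``K_my * i_My`` as ``Z -> inf``, with half-shift at ``Z = K_iy``::

        K_y = K_my * (1 + (i_My - 1) * Z**n_i / (K_iy**n_i + Z**n_i))
    """
    if i_My < 1:
        raise ValueError(f"maximal inhibition i_My must be >= 1, got {i_My}")
    Z = np.asarray(Z, dtype=float)
    if np.any(Z < 0):
        raise ValueError("antagonist concentration must be non-negative")
    Zn = np.power(Z, n_iy)
    out = K_my * (1.0 + (i_My - 1.0) * Zn / (K_iy**n_iy + Zn))
    return out if out.ndim else float(out)


def gated_conductance(rec: ChannelRecord, Y, Z=None, N: int = 1):
    """Per-compartment conductance of one gated channel.

    ``rec.G_M`` is the whole-dendrite maximum; dividing by ``N`` gives the
    per-compartment maximum.  ``Z`` is the antagonist concentration (ignored
    for channels without inhibition).
    """
    if rec.i_M is not None and Z is not None:
        K = inhibited_ec50(rec.K_m, Z, rec.K_i, rec.n_i, rec.i_M)
    else:
        K = rec.K_m
    return hill_conductance(rec.G_M / N, Y, K, rec.n)


def channel_current(g, V_in, V_out, E_y):
    """Ohmic current ``g * ((V_in - V_out) - E_y)``, positive outward (pA)."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("conductance must be non-negative")
    out = g * ((np.asarray(V_in, float) - np.asarray(V_out, float)) - E_y)
    return out if out.ndim else float(out)


def k_conductance(Ca_soma, V, params: ChannelParamSet | KChannelRecord,
                  V_half: float | None = None):
    """Ca2+- and voltage-gated K+ conductance at the soma (nS).

    Multiplicative form: Hill activation in somatic Ca2+ (EC50 ``K_m``) times a
    logistic voltage factor ``1 / (1 + exp(-(V - V_half)/A))``.  Only ``G_M``,
    ``K_m`` and ``A`` are constrained by the parameter tables; the half-
    activation voltage ``V_half`` defaults to the resting soma potential
    (``E_K``, which equals ``E_ls`` in the bundled parameterization) and is
    exposed for sensitivity studies.
    """
    rec = params.K if isinstance(params, ChannelParamSet) else params
    if V_half is None:
        V_half = rec.E
    Ca_soma = np.asarray(Ca_soma, dtype=float)
    if np.any(Ca_soma < 0):
        raise ValueError("somatic Ca2+ must be non-negative")
    ca_factor = Ca_soma / (rec.K_m + Ca_soma)
    v_factor = 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - V_half) / rec.A))
    out = rec.G_M * ca_factor * v_factor
    return out if out.ndim else float(out)


_DRIVING_FORCE_FLOOR = 1e-6  # mV; below this Eq.-style division is unreliable


def lumped_conductance(I_sum, V_m, E_p=0.0, floor: float = _DRIVING_FORCE_FLOOR):
    """Equivalent single conductance reproducing a summed pheromone current.

    ``g_p = (I_Ca + I_cat + I_Cl + I_x) / (V_m - E_p)`` per compartment, where
    ``V_m`` is the transmembrane potential.  Reinserted as
    ``I_p = g_p (V_m - E_p)`` it reproduces the summed current exactly.

    Samples whose driving force ``|V_m - E_p|`` is below ``floor`` are returned
    as NaN (flagged, never silently zero); see
    :func:`interpolate_flagged` to fill them from neighbors in a time series.
    """
    I_sum = np.asarray(I_sum, dtype=float)
    drive = np.asarray(V_m, dtype=float) - E_p
    small = np.abs(drive) < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        g = I_sum / drive
    g = np.where(small, np.nan, g)
    return g if g.ndim else float(g)


def interpolate_flagged(t, g):
    """Fill NaN samples of a lumped-conductance time series by interpolation."""
    t = np.asarray(t, float)
    g = np.asarray(g, float).copy()
    bad = ~np.isfinite(g)
    if bad.all():
        raise ValueError("every sample is flagged; cannot interpolate")
    if bad.any():
        g[bad] = np.interp(t[bad], t[~bad], g[~bad])
    return g


@dataclass(frozen=True)
class CurrentsSnapshot:
    """All branch currents of the circuit at one instant (pA, outward/tipward
    positive).  Axial arrays: ``I_i[j]`` is the intracellular current flowing
    from compartment j to j+1 (j = N-1 flows into the soma); ``I_e[j]`` the
    extracellular current flowing from compartment j+1 (or the auxiliary node)
    to compartment j."""

    I_ld: np.ndarray          # leak, per compartment
    I_gated: dict             # name -> per-compartment array (Ca, cat, Cl, x or p)
    I_i: np.ndarray           # axial intracellular, length N
    I_e: np.ndarray           # axial extracellular, length N
    I_K: float                # somatic K+ current
    I_ls: float               # somatic leak
    I_a: float                # auxiliary-cell leak

    @property
    def I_membrane(self) -> np.ndarray:
        """Total ionic membrane current per dendritic compartment."""
        total = self.I_ld.copy()
        for arr in self.I_gated.values():
            total = total + arr
        return total
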