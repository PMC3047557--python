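"""Per-compartment modulator concentrations driving the transduction channels.

The upstream cascade (receptor activation, G-protein/effector kinetics,
second-messenger synthesis) is not part of this package; it is replaced by a
pluggable drive interface plus synthetic waveform generators.  A drive maps
(time, pheromone uptake) to the concentrations of the channel modulators:
IP3 and DAG (the second messengers), CaCaM and PKC* (the feedback inhibitors)
and, where prescribed rather than integrated, Ca2+.  Dendritic Ca2+ is
normally obtained from a mass balance over the Ca-carrying membrane currents
(:func:`calcium_rate`), with CaCaM, PKC* and somatic Ca2+ as low-pass-filtered
copies of it, preserving the feedback ordering of the cascade.

Times in this module are in SECONDS (the natural scale of the biochemistry and
of stimulus protocols); the electrical network converts at its interface.
Concentrations are in uM, uptake in uM/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ChannelParamSet

__all__ = [
    "ModulatorState",
    "DriveProtocol",
    "UptakeProtocol",
    "ExternalTableDrive",
    "dose_grid",
    "synthetic_modulators",
    "calcium_rate",
    "calcium_balance",
]

MODULATORS = ("IP3", "DAG", "Ca", "CaCaM", "PKC")


@dataclass(frozen=True)
class ModulatorState:
    """Modulator concentrations (uM) in one or more outer-dendritic
    compartments, plus Ca2+ at the inner dendrite / soma."""

    IP3: float | np.ndarray = 0.0
    DAG: float | np.ndarray = 0.0
    Ca: float | np.ndarray = 0.0
    CaCaM: float | np.ndarray = 0.0
    PKC: float | np.ndarray = 0.0
    Ca_soma: float = 0.0

    def __post_init__(self) -> None:
        for name in (*MODULATORS, "Ca_soma"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"concentration {name} must be non-negative")


def dose_grid(min_exp: float, max_exp: float, step: float) -> np.ndarray:
    """Inclusive log-spaced uptake grid, 10**min_exp .. 10**max_exp (uM/s).

    ``dose_grid(-4.75, 1.5, 0.25)`` gives the standard 26-uptake series.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_exp < min_exp:
        raise ValueError("max_exp must be >= min_exp")
    n = int(round((max_exp - min_exp) / step)) + 1
    exps = min_exp + step * np.arange(n)
    if exps[-1] > max_exp + 1e-9:
        exps = exps[exps <= max_exp + 1e-9]
    if exps.size == 0:
        raise ValueError("empty dose grid")
    return 10.0**exps


@dataclass(frozen=True)
class UptakeProtocol:
    """Square pheromone-uptake pulse plus the dose grid it is run over.

    ``U`` is the uptake into the sensillum (uM/s), the natural dose variable of
    a flux detector; the equivalent air concentration is ``L_air = U / k_i``
    with the translocation rate ``k_i ~ 1e4 / s``.
    """

    min_exp: float = -4.75
    max_exp: float = 1.5
    step: float = 0.25
    pulse_duration: float = 2.0       # s
    k_i: float = 1e4                  # 1/s

    @property
    def uptakes(self) -> np.ndarray:
        return dose_grid(self.min_exp, self.max_exp, self.step)

    def l_air(self, U: float) -> float:
        """Air concentration (uM) equivalent to uptake ``U`` (uM/s)."""
        return U / self.k_i


def _dose_amplitude(U: float, h: float, K: float) -> float:
    """Saturating dose-scaling rule: relative amplitude U**h/(K**h + U**h)."""
    Uh = U**h
    return Uh / (K**h + Uh)


@dataclass(frozen=True)
class DriveProtocol:
    """Synthetic modulator waveform generator standing in for the upstream
    cascade.

    kind
        ``"square"`` — smoothed plateau at the configured amplitudes;
        ``"exponential"`` — single-exponential rise to plateau, exponential
        return after offset;
        ``"biphasic"`` — second messengers with a fast transient component
        riding on a slower sustained one, emulating the transient cationic
        drive followed by the long-lasting Ca2+-gated wave.
    amplitudes
        Saturating concentration (uM) per modulator; entries absent or 0 leave
        that modulator to the dynamic mass balance (the default for Ca).
    dose_h, dose_K
        Hill-type dose-scaling rule: amplitudes are multiplied by
        ``U**h / (K**h + U**h)``, giving a log-log slope ``h`` below ``K`` and
        saturation above, matching the near-linear log conductance/log uptake
        growth up to ~1 uM/s.
    """

    kind: str = "biphasic"
    onset: float = 0.0                 # s
    offset: float = 2.0                # s
    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"IP3": 30.0, "DAG": 0.15}
    )
    dose_h: float = 0.35
    dose_K: float = 0.5                # uM/s
    tau_rise: float = 0.05             # s, fast (transient) rise
    tau_decay: float = 0.40            # s, transient decay during the pulse
    tau_slow: float = 0.60             # s, sustained component rise
    tau_off: float = 0.30              # s, return to baseline after offset
    sustained_frac: float = 0.35       # weight of the sustained component
    edge_tau: float = 0.005            # s, smoothing of square edges
    # Low-pass feedback stages (driven from dendritic Ca2+ by the network):
    kappa_cam: float = 0.005           # CaCaM per Ca, dimensionless
    tau_cam: float = 0.30              # s
    kappa_pkc: float = 0.002
    tau_pkc: float = 1.0
    kappa_cas: float = 1e-3            # somatic Ca per mean dendritic Ca
    tau_cas: float = 0.30

    def __post_init__(self) -> None:
        if self.kind not in ("square", "exponential", "biphasic"):
            raise ValueError(f"unknown drive kind {self.kind!r}")
        if self.onset < 0 or self.offset < self.onset:
            raise ValueError("need 0 <= onset <= offset")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be non-negative")

    def modulators(self, t, U: float) -> ModulatorState:
        return synthetic_modulators(self, t, U)


def _shape_square(p: DriveProtocol, t: np.ndarray) -> np.ndarray:
    # Exponential edges keep the waveform continuous for the ODE solver.
    s = np.where(t >= p.onset, 1.0 - np.exp(-(t - p.onset) / p.edge_tau), 0.0)
    after = t >= p.offset
    if np.any(after):
        level = 1.0 - np.exp(-(p.offset - p.onset) / p.edge_tau)
        s = np.where(after, level * np.exp(-(t - p.offset) / p.edge_tau), s)
    return s


def _shape_exponential(p: DriveProtocol, t: np.ndarray) -> np.ndarray:
    s = np.where(t >= p.onset, 1.0 - np.exp(-(t - p.onset) / p.tau_slow), 0.0)
    after = t >= p.offset
    if np.any(after):
        level = 1.0 - np.exp(-(p.offset - p.onset) / p.tau_slow)
        s = np.where(after, level * np.exp(-(t - p.offset) / p.tau_off), s)
    return s


def _shape_biphasic(p: DriveProtocol, t: np.ndarray) -> np.ndarray:
    """Fast transient + slow sustained component, peak-normalized to <= 1."""
    dt = np.maximum(t - p.onset, 0.0)
    on = t >= p.onset
    fast = np.exp(-dt / p.tau_decay) - np.exp(-dt / p.tau_rise)
    # normalize the transient to unit peak
    tp = (p.tau_decay * p.tau_rise / (p.tau_decay - p.tau_rise)
          * np.log(p.tau_decay / p.tau_rise))
    fpk = np.exp(-tp / p.tau_decay) - np.exp(-tp / p.tau_rise)
    slow = 1.0 - np.exp(-dt / p.tau_slow)
    s = np.where(on, (1.0 - p.sustained_frac) * fast / fpk
                 + p.sustained_frac * slow, 0.0)
    after = t >= p.offset
    if np.any(after):
        t_off = p.offset - p.onset
        level = ((1.0 - p.sustained_frac)
                 * (np.exp(-t_off / p.tau_decay) - np.exp(-t_off / p.tau_rise)) / fpk
                 + p.sustained_frac * (1.0 - np.exp(-t_off / p.tau_slow)))
        s = np.where(after, level * np.exp(-(t - p.offset) / p.tau_off), s)
    return s


_SHAPES = {
    "square": _shape_square,
    "exponential": _shape_exponential,
    "biphasic": _shape_biphasic,
}


def synthetic_modulators(protocol: DriveProtocol, t, U: float) -> ModulatorState:
    """Evaluate the synthetic drive at time ``t`` (s) and uptake ``U`` (uM/s).

    Deterministic and continuous; identically zero before onset.  Scalar or
    array ``t`` is accepted.
    """
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    shape = _SHAPES[protocol.kind](protocol, tt)
    rel = _dose_amplitude(U, protocol.dose_h, protocol.dose_K)
    vals = {}
    for name in MODULATORS:
        amp = protocol.amplitudes.get(name, 0.0)
        w = amp * rel * shape
        vals[name] = w if np.ndim(t) else float(w[0])
    return ModulatorState(**vals)


@dataclass(frozen=True)
class ExternalTableDrive:
    """User-supplied modulator trajectories from a delimited text table.

    The table must have a ``time`` column (s) and one column per modulator
    (any of IP3, DAG, Ca, CaCaM, PKC); values are linearly interpolated in
    time and held at the table edges.  The table is taken to describe the
    saturating response; the same dose-scaling rule as the synthetic drive is
    applied on top.
    """

    time: np.ndarray
    series: Mapping[str, np.ndarray]
    dose_h: float = 0.4
    dose_K: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None,
                  dose_h: float = 0.4, dose_K: float = 1.0) -> "ExternalTableDrive":
        df = pd.read_csv(path, sep=sep, engine="python")
        if "time" not in df.columns:
            raise ValueError(f"drive table {path} needs a 'time' column")
        cols = [c for c in df.columns if c in MODULATORS]
        if not cols:
            raise ValueError(f"drive table {path} has no modulator columns")
        t = df["time"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time column must be strictly increasing")
        return cls(time=t, series={c: df[c].to_numpy(float) for c in cols},
                   dose_h=dose_h, dose_K=dose_K)

    def modulators(self, t, U: float) -> ModulatorState:
        rel = _dose_amplitude(U, self.dose_h, self.dose_K)
        vals = {}
        for name in MODULATORS:
            if name in self.series:
                w = rel * np.interp(np.asarray(t, float), self.time,
                                    self.series[name])
                vals[name] = w if np.ndim(t) else float(w)
        return ModulatorState(**vals)


def calcium_rate(I_Ca, I_cat, I_x, factors: ChannelParamSet):
    """Rate of change of dendritic Ca2+ (uM/s) from the Ca-carrying currents.

    Currents are in pA, positive outward.  Inward (negative) Ca2+ and cationic
    currents raise Ca2+ through the conversion factors f_Ca and f_cat; the
    NCX extrusion current is net INWARD while it removes Ca2+ (3 Na+ in per
    Ca2+ out), so its contribution enters with the opposite sign, scaled by F.
    """
    return (-factors.f_Ca * np.asarray(I_Ca, float)
            - factors.f_cat * np.asarray(I_cat, float)
            + factors.F * np.asarray(I_x, float))


def calcium_balance(Ca, I_Ca, I_cat, I_x, factors: ChannelParamSet, dt: float):
    """Advance Ca2+ (uM) by one explicit step of ``dt`` ms, clamped at >= 0."""
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("Ca2+ must be non-negative")
    out = Ca + calcium_rate(I_Ca, I_cat, I_x, factors) * (dt * 1e-3)
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)
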