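"""Reduction of kinetic curves to response characteristics.

Every simulated response (RP or SP kinetics, conductance kinetics) is
summarized by three numbers: the height (signed extremum), the half-rise time
(stimulation onset to half-maximal response) and the half-fall time
(stimulation offset to half-maximal response, negative when the response
decays below half-maximum before the stimulus ends).  Half-maxima are used
because the times of the extrema themselves are poorly determined on slowly
saturating curves.  Dose-response curves collect one characteristic per dose;
the EC50 is read off the relative-height curve by log-domain interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "ResponseCharacteristics",
    "DoseResponseCurve",
    "characterize",
    "ec50",
    "relative_error",
    "amplification_ratios",
    "parameter_sweep",
]


@dataclass(frozen=True)
class ResponseCharacteristics:
    """Height and half-maximum timing of one kinetic curve.

    Times are in the units of the time vector they were computed from; a NaN
    time means the corresponding half-crossing does not exist (reported as
    missing, never silently zero).  ``tau_fall`` may be negative when the
    curve drops below half-maximum before stimulus offset.
    """

    height: float
    tau_rise: float
    tau_fall: float
    label: float | str | None = None

    @property
    def missing_rise(self) -> bool:
        return not math.isfinite(self.tau_rise)

    @property
    def missing_fall(self) -> bool:
        return not math.isfinite(self.tau_fall)


def _cross_time(t, yn, k, level=0.5):
    """Linear interpolation of the crossing between samples k-1 and k."""
    if k == 0 or yn[k - 1] == yn[k]:
        return float(t[k])
    w = (level - yn[k - 1]) / (yn[k] - yn[k - 1])
    return float(t[k - 1] + w * (t[k] - t[k - 1]))


def characterize(t, y, onset: float, offset: float,
                 label=None) -> ResponseCharacteristics:
    """Characterize a curve starting at baseline zero.

    Height is the signed global extremum (first one on ties); the rise time is
    the first crossing of half-height after ``onset`` minus onset; the fall
    time is the first crossing of half-height after the extremum minus
    ``offset``.  Crossings are located by linear interpolation between
    samples, so the result is invariant to refinement of the time grid.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be matching 1-d arrays")
    if offset < onset:
        raise ValueError("offset must be >= onset")
    pk = int(np.argmax(np.abs(y)))
    height = float(y[pk])
    if height == 0.0:
        return ResponseCharacteristics(0.0, float("nan"), float("nan"), label)
    yn = y / height                       # normalized, peak = +1
    sel = t >= onset
    above = sel & (yn >= 0.5)
    if not above.any():
        tau_rise = float("nan")
    else:
        k = int(np.argmax(above))
        tau_rise = _cross_time(t, yn, k) - onset
    below = (np.arange(t.size) > pk) & (yn <= 0.5)
    if not below.any():
        tau_fall = float("nan")
    else:
        k = int(np.argmax(below))
        tau_fall = _cross_time(t, yn, k) - offset
    return ResponseCharacteristics(height, tau_rise, tau_fall, label)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Characteristics per dose (uptake in uM/s or conductance in nS)."""

    doses: np.ndarray
    heights: np.ndarray
    tau_rise: np.ndarray
    tau_fall: np.ndarray
    name: str = ""

    def __post_init__(self):
        n = len(self.doses)
        for arr in (self.heights, self.tau_rise, self.tau_fall):
            if len(arr) != n:
                raise ValueError("all columns must have one entry per dose")

    @property
    def relative_heights(self) -> np.ndarray:
        m = np.nanmax(np.abs(self.heights))
        if m == 0:
            raise ValueError("all heights are zero; cannot normalize")
        return np.abs(self.heights) / m

    @property
    def ec50(self) -> float:
        return ec50(self.doses, self.relative_heights)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose": self.doses, "height": self.heights,
            "relative_height": self.relative_heights,
            "tau_rise": self.tau_rise, "tau_fall": self.tau_fall,
        })


def ec50(doses, relative_heights) -> float:
    """Dose of half-maximal response, interpolated linearly in log-dose.

    Uses the first upward crossing of 0.5 of the relative-height curve;
    returns NaN (missing) when the curve never spans 0.5.
    """
    d = np.asarray(doses, dtype=float)
    h = np.asarray(relative_heights, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be positive for log interpolation")
    for k in range(1, d.size):
        if h[k - 1] < 0.5 <= h[k]:
            w = (0.5 - h[k - 1]) / (h[k] - h[k - 1])
            return float(10 ** (np.log10(d[k - 1])
                                + w * (np.log10(d[k]) - np.log10(d[k - 1]))))
    if h.size and h[0] >= 0.5:
        return float(d[0])
    return float("nan")


def relative_error(numeric: float, analytic: float) -> float:
    """|numeric - analytic| / |analytic| (dimensionless fraction)."""
    if analytic == 0:
        raise ValueError("relative error undefined for analytic value 0")
    return abs(numeric - analytic) / abs(analytic)


def amplification_ratios(G_p, RP_s):
    """Relative amplification f_r = H_r / G_r along a conductance grid.

    ``H_r = RP_s / max(RP_s)`` and ``G_r = G_p / max(G_p)``; f_r = 1 at the
    grid maximum by construction and exceeds 1 wherever the conductance-to-
    voltage conversion compresses strong stimuli (saturation).
    """
    G_p = np.asarray(G_p, dtype=float)
    RP_s = np.asarray(RP_s, dtype=float)
    if np.max(np.abs(RP_s)) == 0 or np.max(G_p) <= 0:
        raise ValueError("grid must contain a non-zero maximum")
    H_r = np.abs(RP_s) / np.max(np.abs(RP_s))
    G_r = G_p / np.max(G_p)
    return H_r / G_r


_MAX_COND_NAMES = {"G_MCa": "Ca", "G_Mcat": "cat", "G_MCl": "Cl",
                   "G_Mx": "x", "G_MK": "K"}


def substitute_parameter(params: ParameterSet, name: str, value: float
                         ) -> ParameterSet:
    """New :class:`ParameterSet` with one named parameter replaced.

    Base (Table-style) names re-derive the whole dependent chain; maximal
    conductances (G_MCa, G_Mcat, G_MCl, G_Mx, G_MK) replace the channel
    record.  Unknown names are rejected.
    """
    from dataclasses import fields
    base_names = {f.name for f in fields(params.base)}
    if name in base_names:
        return params.with_base(**{name: value})
    if name in _MAX_COND_NAMES:
        ch_name = _MAX_COND_NAMES[name]
        rec = dc_replace(getattr(params.channels, ch_name), G_M=value)
        channels = dc_replace(params.channels, **{ch_name: rec})
        return ParameterSet(base=params.base, derived=params.derived,
                            channels=channels)
    raise KeyError(f"unknown parameter id {name!r}")


def parameter_sweep(params: ParameterSet, name: str, values: Sequence[float],
                    metric: Callable[[ParameterSet], float],
                    metric_name: str = "metric") -> pd.DataFrame:
    """Sweep one parameter, re-deriving dependent quantities at each value.

    ``metric`` receives the substituted :class:`ParameterSet` and returns a
    scalar (e.g. a steady-state RP_b from the simplified model).
    """
    rows = []
    for v in values:
        ps = substitute_parameter(params, name, float(v))
        rows.append({name: float(v), metric_name: float(metric(ps))})
    return pd.DataFrame(rows)
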