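"""Model constants and derived cable quantities of the sensillum circuit.

The moth pheromone-sensitive sensillum is described by a small set of measured
geometrical and passive electrical quantities (outer-dendrite geometry, membrane
and medium resistivities, auxiliary-cell membrane data) from which every cable
and circuit parameter of the model follows by elementary formulas: membrane
areas, distributed resistances and capacitances, the space constant ``lambda``,
the time constant ``tau``, the electrotonic length ``l_d`` and the dimensionless
base-load ratios ``r_in`` and ``a``.

Internal unit system
--------------------
mV, nS, pF, pA, ms, uM and um, so that nS * mV = pA and pF * mV / ms = pA.
Distributed (per-unit-length) quantities are kept in the customary CGS-flavored
units of the sensillum literature (Ohm.cm, F/cm, GOhm/cm) because they are only
used to form the dimensionless cable groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "MorphoElectricalBase",
    "DerivedCableParams",
    "ChannelRecord",
    "KChannelRecord",
    "ChannelParamSet",
    "CompartmentalScaling",
    "ParameterSet",
    "derive_cable_parameters",
    "scale_to_compartments",
    "check_battery_consistency",
    "load_base_parameters",
    "load_channel_parameters",
    "load_printed_reference",
]

_BASE_FIELDS = {
    "L_d", "D_i", "rho_ld", "D_e", "rho_e", "rho_i", "S_s", "rho_ls",
    "E_ls", "C_api", "R_api", "rho_bas", "R_bas", "E_a", "c",
}

# Fields that must be strictly positive (potentials E_ls / E_a may take any sign).
_POSITIVE_FIELDS = _BASE_FIELDS - {"E_ls", "E_a"}


@dataclass(frozen=True)
class MorphoElectricalBase:
    """Measured geometrical and passive electrical parameters.

    Units: lengths/diameters um, areas um^2, membrane resistivities Ohm.cm^2,
    medium resistivities Ohm.cm, resistances MOhm, capacitances pF, potentials
    mV, specific capacitance uF/cm^2.
    """

    L_d: float = 220.0
    D_i: float = 0.475
    rho_ld: float = 7500.0
    D_e: float = 1.8
    rho_e: float = 40.0
    rho_i: float = 40.0
    S_s: float = 144.0
    rho_ls: float = 1000.0
    E_ls: float = -62.0
    C_api: float = 30.0
    R_api: float = 300.0
    rho_bas: float = 100.0
    R_bas: float = 25.0
    E_a: float = -35.0
    c: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} is not finite: {v!r}")
            if f.name in _POSITIVE_FIELDS and v <= 0:
                raise ValueError(
                    f"parameter {f.name!r} must be strictly positive, got {v!r}"
                )
        if self.D_e <= self.D_i:
            raise ValueError(
                "hair-lumen diameter D_e must exceed dendrite diameter D_i "
                f"(no lymph annulus: D_e={self.D_e}, D_i={self.D_i})"
            )


@dataclass(frozen=True)
class DerivedCableParams:
    """Cable and circuit quantities derived from :class:`MorphoElectricalBase`.

    Whole-structure values are in the internal unit system (nS, pF, MOhm/GOhm);
    per-unit-length values in F/cm, MOhm.cm and GOhm/cm.
    """

    S_d: float        # outer-dendrite lateral area, um^2
    V_d: float        # outer-dendrite volume, um^3
    E_ld: float       # dendrite leak battery = E_ls + E_a, mV
    c_d: float        # membrane capacitance per unit length, F/cm
    C_d: float        # whole-dendrite capacitance, pF
    r_ld: float       # membrane resistance x length, MOhm.cm
    R_ld: float       # whole-dendrite membrane resistance, GOhm
    G_ld: float       # whole-dendrite leak conductance, nS
    lam: float        # space constant, um
    tau: float        # membrane time constant, ms
    l_d: float        # electrotonic length, dimensionless
    r_e: float        # lymph resistance per unit length, GOhm/cm
    g_e: float        # lymph conductance x length, nS.cm
    R_e: float        # whole-lymph resistance, MOhm
    G_e: float        # whole-lymph conductance, nS
    r_i: float        # intracellular resistance per unit length, GOhm/cm
    g_i: float        # intracellular conductance x length, nS.cm
    R_i: float        # whole intracellular resistance, MOhm
    G_i: float        # whole intracellular conductance, nS
    R_ls: float       # soma membrane resistance, MOhm
    G_ls: float       # soma leak conductance, nS
    C_s: float        # soma capacitance, pF
    r_in: float       # (R_ls + R_a) / (lambda (r_e + r_i)), dimensionless load
    a: float          # R_a / (R_ls + R_a), dimensionless auxiliary fraction
    S_api: float      # auxiliary apical membrane area, um^2
    rho_api: float    # auxiliary apical membrane resistivity, Ohm.cm^2
    S_bas: float      # auxiliary basolateral membrane area, um^2
    C_bas: float      # auxiliary basolateral capacitance, pF
    R_a: float        # auxiliary resistance (apical + basolateral in series), MOhm
    G_a: float        # auxiliary conductance, nS
    C_a: float        # auxiliary capacitance (apical, basolateral in series), pF
    E_ls: float       # soma leak battery (copied through), mV
    E_a: float        # auxiliary battery (copied through), mV

    @property
    def beta(self) -> float:
        """Extracellular fraction of the series resistance, r_e / (r_e + r_i)."""
        return self.r_e / (self.r_e + self.r_i)


def derive_cable_parameters(base: MorphoElectricalBase) -> DerivedCableParams:
    """Compute every derived cable quantity from the base parameters.

    All unit conversions (um <-> cm, Ohm <-> MOhm/GOhm, uF <-> pF) are applied
    here once; downstream code works in the internal unit system.
    """
    b = base
    S_d = math.pi * b.L_d * b.D_i                       # um^2
    V_d = math.pi * b.L_d * b.D_i**2 / 4.0              # um^3
    E_ld = b.E_ls + b.E_a

    c_d = b.c * math.pi * b.D_i * 1e-10                 # F/cm
    C_d = b.c * S_d * 1e-2                              # pF
    r_ld = b.rho_ld / (math.pi * b.D_i) * 1e-2          # MOhm.cm
    R_ld = b.rho_ld / S_d * 1e-1                        # GOhm
    G_ld = 1.0 / R_ld                                   # nS

    r_e = 4.0 * b.rho_e / (math.pi * (b.D_e**2 - b.D_i**2)) * 1e-1   # GOhm/cm
    r_i = 4.0 * b.rho_i / (math.pi * b.D_i**2) * 1e-1                # GOhm/cm
    g_e = 1.0 / r_e                                     # nS.cm
    g_i = 1.0 / r_i

    # lambda^2 = r_ld / (r_e + r_i); r_ld in GOhm.cm to match r_e, r_i.
    lam_cm = math.sqrt((r_ld * 1e-3) / (r_e + r_i))
    lam = lam_cm * 1e4                                  # um
    tau = (r_ld * 1e6) * c_d * 1e3                      # ms
    l_d = b.L_d / lam

    L_cm = b.L_d * 1e-4
    R_e = r_e * L_cm * 1e3                              # MOhm
    G_e = 1e3 / R_e                                     # nS
    R_i = r_i * L_cm * 1e3
    G_i = 1e3 / R_i

    R_ls = b.rho_ls / b.S_s * 1e2                       # MOhm
    G_ls = 1e3 / R_ls
    C_s = b.c * b.S_s * 1e-2                            # pF

    S_api = b.C_api / b.c * 1e2                         # um^2
    rho_api = S_api * 1e-8 * b.R_api * 1e6              # Ohm.cm^2
    S_bas = b.rho_bas / b.R_bas * 1e2                   # um^2
    C_bas = b.c * S_bas * 1e-2                          # pF
    R_a = b.R_api + b.R_bas                             # MOhm
    G_a = 1e3 / R_a
    C_a = b.C_api * C_bas / (b.C_api + C_bas)           # pF, series combination

    # Dimensionless base-load groups; lambda*(r_e+r_i) in MOhm.
    z_c = lam_cm * (r_e + r_i) * 1e3
    r_in = (R_ls + R_a) / z_c
    a = R_a / (R_ls + R_a)

    return DerivedCableParams(
        S_d=S_d, V_d=V_d, E_ld=E_ld, c_d=c_d, C_d=C_d, r_ld=r_ld, R_ld=R_ld,
        G_ld=G_ld, lam=lam, tau=tau, l_d=l_d, r_e=r_e, g_e=g_e, R_e=R_e, G_e=G_e,
        r_i=r_i, g_i=g_i, R_i=R_i, G_i=G_i, R_ls=R_ls, G_ls=G_ls, C_s=C_s,
        r_in=r_in, a=a, S_api=S_api, rho_api=rho_api, S_bas=S_bas, C_bas=C_bas,
        R_a=R_a, G_a=G_a, C_a=C_a, E_ls=b.E_ls, E_a=b.E_a,
    )


def check_battery_consistency(derived: DerivedCableParams, tol: float = 1e-9) -> bool:
    """True iff E_ld = E_ls + E_a within ``tol`` mV.

    When this holds, the circuit has a zero-circulating-current resting state:
    every battery is exactly balanced and all branch currents vanish at rest.
    """
    return abs(derived.E_ld - (derived.E_ls + derived.E_a)) <= tol


@dataclass(frozen=True)
class ChannelRecord:
    """One pheromone-dependent outer-dendritic current (Hill-gated).

    ``E`` mV, ``G_M`` nS (whole dendrite), ``K_m`` uM, ``n`` dimensionless.
    Antagonist fields (``i_M`` >= 1, ``K_i`` uM, ``n_i``) are None for channels
    without feedback inhibition (the NCX extrusion current).
    """

    E: float
    G_M: float
    K_m: float
    n: float
    i_M: float | None = None
    K_i: float | None = None
    n_i: float | None = None

    def __post_init__(self) -> None:
        if self.G_M < 0 or self.K_m <= 0 or self.n <= 0:
            raise ValueError("G_M must be >= 0 and K_m, n > 0")
        if self.i_M is not None:
            if self.i_M < 1:
                raise ValueError(f"maximal inhibition i_M must be >= 1, got {self.i_M}")
            if self.K_i is None or self.K_i <= 0 or self.n_i is None or self.n_i <= 0:
                raise ValueError("inhibited channel needs K_i > 0 and n_i > 0")


@dataclass(frozen=True)
class KChannelRecord:
    """Ca2+- and voltage-gated K+ current at the inner dendrite / soma."""

    E: float
    G_M: float
    K_m: float
    A: float          # voltage-dependence slope, mV

    def __post_init__(self) -> None:
        if self.G_M < 0 or self.K_m <= 0 or self.A <= 0:
            raise ValueError("K channel needs G_M >= 0 and K_m, A > 0")


@dataclass(frozen=True)
class ChannelParamSet:
    """All channel and second-messenger parameters (Hill gates + conversions)."""

    Ca: ChannelRecord
    cat: ChannelRecord
    Cl: ChannelRecord
    x: ChannelRecord
    K: KChannelRecord
    s_M: float                    # maximal second-messenger synthesis rate, 1/s
    F: float                      # NCX charge-to-concentration factor, uM/pC
    f_Ca: float                   # IP3-gated-channel factor, uM/pC
    f_cat: float                  # DAG-gated-channel factor, uM/pC

    @property
    def gated(self) -> dict[str, ChannelRecord]:
        return {"Ca": self.Ca, "cat": self.cat, "Cl": self.Cl, "x": self.x}


@dataclass(frozen=True)
class CompartmentalScaling:
    """Per-compartment circuit quantities for a chosen compartment count N.

    Membrane quantities divide by N (c_dc = C_d/N, g_ldc = G_ld/N, g_My = G_My/N);
    series (axial) conductances multiply by N (g_ec = N G_e, g_ic = N G_i), since
    each axial link spans 1/N of the dendrite length.
    """

    N: int
    c_dc: float                   # pF per compartment
    g_ldc: float                  # nS per compartment
    g_ec: float                   # nS per axial lymph link
    g_ic: float                   # nS per axial intracellular link
    g_M: Mapping[str, float]      # per-compartment maximal conductances, nS
    derived: DerivedCableParams
    channels: ChannelParamSet


def scale_to_compartments(
    derived: DerivedCableParams, channels: ChannelParamSet, N: int
) -> CompartmentalScaling:
    """Distribute whole-dendrite quantities over ``N`` identical compartments."""
    if not isinstance(N, (int,)) or isinstance(N, bool):
        raise TypeError(f"N must be an integer, got {N!r}")
    if N < 1:
        raise ValueError(f"compartment count N must be >= 1, got {N}")
    g_M = {name: rec.G_M / N for name, rec in channels.gated.items()}
    return CompartmentalScaling(
        N=N,
        c_dc=derived.C_d / N,
        g_ldc=derived.G_ld / N,
        g_ec=N * derived.G_e,
        g_ic=N * derived.G_i,
        g_M=g_M,
        derived=derived,
        channels=channels,
    )


# ---------------------------------------------------------------------------
# Loaders for the packaged parameter files
# ---------------------------------------------------------------------------

def _read_yaml(source: str | Path | None, packaged: str) -> dict:
    if source is None:
        text = resources.files("sensillum.data").joinpath(packaged).read_text()
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"parameter file {source or packaged!r} is not a mapping")
    return doc


def load_base_parameters(path: str | Path | None = None) -> MorphoElectricalBase:
    """Load morphological/electrical base parameters (packaged file by default).

    Unknown keys are reported rather than silently ignored, so that a typo in a
    user-supplied file cannot leave a parameter at its default.
    """
    doc = _read_yaml(path, "table1_antheraea.yaml")
    unknown = set(doc) - _BASE_FIELDS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return MorphoElectricalBase(**{k: float(v) for k, v in doc.items()})


def load_channel_parameters(path: str | Path | None = None) -> ChannelParamSet:
    doc = _read_yaml(path, "table3_antheraea.yaml")
    known = {"s_M", "Ca", "cat", "Cl", "x", "K", "conversion"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    conv = doc["conversion"]
    return ChannelParamSet(
        Ca=ChannelRecord(**doc["Ca"]),
        cat=ChannelRecord(**doc["cat"]),
        Cl=ChannelRecord(**doc["Cl"]),
        x=ChannelRecord(**doc["x"]),
        K=KChannelRecord(**doc["K"]),
        s_M=float(doc["s_M"]),
        F=float(conv["F"]),
        f_Ca=float(conv["f_Ca"]),
        f_cat=float(conv["f_cat"]),
    )


def load_printed_reference() -> dict:
    """Published reference values for the derived quantities (regression aid)."""
    return _read_yaml(None, "table2_printed.yaml")


@dataclass(frozen=True)
class ParameterSet:
    """Bundle of base, derived and channel parameters for one sensillum."""

    base: MorphoElectricalBase
    derived: DerivedCableParams
    channels: ChannelParamSet

    @classmethod
    def default(cls) -> "ParameterSet":
        base = load_base_parameters()
        return cls(base=base, derived=derive_cable_parameters(base),
                   channels=load_channel_parameters())

    @classmethod
    def from_files(cls, base_path: str | Path, channel_path: str | Path | None = None
                   ) -> "ParameterSet":
        base = load_base_parameters(base_path)
        return cls(base=base, derived=derive_cable_parameters(base),
                   channels=load_channel_parameters(channel_path))

    def with_base(self, **updates: float) -> "ParameterSet":
        """New set with base parameters replaced and the derived chain recomputed."""
        base = replace(self.base, **updates)
        return ParameterSet(base=base, derived=derive_cable_parameters(base),
                            channels=self.channels)

    def scale(self, N: int) -> CompartmentalScaling:
        return scale_to_compartments(self.derived, self.channels, N)
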