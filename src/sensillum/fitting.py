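"""Cost function over dose-response characteristics and simplex fitting.

The model is judged against a target set of response characteristics — height
``H_i``, half-rise time and half-fall time at each of ``n`` uptakes — through
a weighted sum of absolute differences::

    J(theta) = sum_i  w_H |dH_i| + w_rise |d tau_rise,i| + w_fall |d tau_fall,i|

The characteristics vary on different scales (mV versus s), hence the
weights; they are exposed, defaulting to w_H = 1 /mV and w_rise = w_fall =
10 /s.  Minimization uses the Nelder–Mead simplex (the classical local,
derivative-free choice for this problem); parameter bounds are enforced by a
penalty since the simplex itself is unconstrained, and optional restarts
jitter the starting point with seeded noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .biochem_drive import DriveProtocol
from .parameters import ParameterSet
from .response_metrics import characterize, substitute_parameter

logger = logging.getLogger(__name__)

__all__ = [
    "FitTarget",
    "FitSpec",
    "FitResult",
    "cost",
    "optimize",
    "make_complete_model_runner",
    "qualitative_screens",
]

FAILURE_PENALTY = 1e6


@dataclass(frozen=True)
class FitTarget:
    """Target characteristics per dose, with the cost weights.

    ``heights`` in mV, times in s; NaN entries mark characteristics that are
    missing (no half-crossing) in the target itself.
    """

    doses: np.ndarray
    heights: np.ndarray
    tau_rise: np.ndarray
    tau_fall: np.ndarray
    w_H: float = 1.0          # per mV
    w_rise: float = 10.0      # per s
    w_fall: float = 10.0      # per s
    miss_penalty: float = 10.0  # x weight, per prediction missing a crossing

    def __post_init__(self):
        n = len(self.doses)
        if n < 1:
            raise ValueError("need at least one dose")
        for arr in (self.heights, self.tau_rise, self.tau_fall):
            if len(arr) != n:
                raise ValueError("one characteristic triple per dose required")
        if min(self.w_H, self.w_rise, self.w_fall) < 0:
            raise ValueError("weights must be non-negative")


def _term(w: float, pred, targ, miss_penalty: float) -> float:
    """Weighted |pred - targ| with the missing-value convention."""
    if w == 0:
        return 0.0
    p, q = float(pred), float(targ)
    p_ok, q_ok = np.isfinite(p), np.isfinite(q)
    if p_ok and q_ok:
        return w * abs(p - q)
    if p_ok == q_ok:          # both missing: consistent, no cost
        return 0.0
    return w * miss_penalty


def cost(predictions, target: FitTarget) -> float:
    """Weighted characteristic mismatch; zero iff all weighted entries agree.

    ``predictions`` is a (heights, tau_rise, tau_fall) triple of arrays
    aligned with ``target.doses``.
    """
    H, tr, tf = (np.asarray(a, dtype=float) for a in predictions)
    if H.shape != target.heights.shape:
        raise ValueError("prediction/target dose grids differ")
    J = 0.0
    for i in range(H.size):
        J += _term(target.w_H, H[i], target.heights[i], target.miss_penalty)
        J += _term(target.w_rise, tr[i], target.tau_rise[i], target.miss_penalty)
        J += _term(target.w_fall, tf[i], target.tau_fall[i], target.miss_penalty)
    return float(J)


@dataclass(frozen=True)
class FitSpec:
    """Free parameters, bounds, initial vector and optimizer settings."""

    names: Sequence[str]
    bounds: Mapping[str, tuple[float, float]]
    theta0: Mapping[str, float]
    max_iter: int = 400
    xatol: float = 1e-4
    fatol: float = 1e-6
    restarts: int = 0
    jitter: float = 0.05      # fraction of bound width for restart jitter
    seed: int | None = None

    def __post_init__(self):
        for n in self.names:
            lo, hi = self.bounds[n]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {n!r} must be finite with lo < hi")
            if not (lo <= self.theta0[n] <= hi):
                raise ValueError(
                    f"initial value of {n!r} ({self.theta0[n]}) outside bounds "
                    f"[{lo}, {hi}]")


@dataclass
class FitResult:
    theta: dict
    J: float
    theta0: dict
    J0: float
    n_eval: int
    converged: bool
    trace: list = field(default_factory=list)
    restarts: list = field(default_factory=list)
    message: str = ""


def optimize(spec: FitSpec, target: FitTarget,
             runner: Callable[[Mapping[str, float]], tuple]) -> FitResult:
    """Nelder–Mead minimization of the characteristic cost.

    ``runner(theta)`` returns the (heights, tau_rise, tau_fall) predictions on
    the target's dose grid; a runner exception is converted into a large
    finite penalty (logged) rather than aborting the simplex.  Bounds are
    enforced by evaluating at the clipped point plus a violation penalty.
    Guarantees ``J(theta) <= J(theta0)``.
    """
    names = list(spec.names)
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    x0 = np.array([spec.theta0[n] for n in names], dtype=float)
    trace: list = []
    n_eval = 0

    def J_of(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        xc = np.clip(x, lo, hi)
        violation = np.sum(np.abs(x - xc) / (hi - lo))
        theta = dict(zip(names, xc))
        try:
            pred = runner(theta)
        except Exception as err:  # model failure at some dose
            logger.warning("model run failed at theta=%s: %s", theta, err)
            return FAILURE_PENALTY + 1e3 * violation
        J = cost(pred, target) + 1e3 * violation
        trace.append((theta, J))
        return J

    J0 = J_of(x0)
    rng = np.random.default_rng(spec.seed)
    best_x, best_J, best_msg, best_ok = x0, J0, "initial point", True
    starts = [x0]
    for _ in range(spec.restarts):
        starts.append(np.clip(
            x0 + rng.normal(scale=spec.jitter * (hi - lo), size=x0.size), lo, hi))
    restart_log = []
    for k, xs in enumerate(starts):
        res = minimize(J_of, xs, method="Nelder-Mead",
                       options={"maxiter": spec.max_iter, "xatol": spec.xatol,
                                "fatol": spec.fatol})
        restart_log.append({"start": dict(zip(names, xs)), "J": float(res.fun),
                            "converged": bool(res.success)})
        if res.fun < best_J:
            best_x, best_J = np.clip(res.x, lo, hi), float(res.fun)
            best_msg, best_ok = res.message, bool(res.success)
    return FitResult(theta=dict(zip(names, best_x)), J=best_J,
                     theta0=dict(zip(names, x0)), J0=J0, n_eval=n_eval,
                     converged=best_ok, trace=trace, restarts=restart_log,
                     message=str(best_msg))


def make_complete_model_runner(
    params: ParameterSet,
    doses: np.ndarray,
    N: int = 8,
    drive: DriveProtocol | None = None,
    pulse_s: float = 0.5,
    t_end_s: float = 2.0,
    dt_ms: float = 2.0,
    signal: str = "SP",
):
    """Build a runner mapping maximal conductances to SP/RP characteristics.

    The returned callable accepts ``theta`` entries named like ``G_Mcat``,
    ``G_MCl``, ``G_MK``, substitutes them into the channel set, integrates the
    complete model at every dose and reduces the chosen signal to its
    (height, tau_rise, tau_fall) triple with times in seconds.
    """
    from .sensillum_network import integrate_complete

    if drive is None:
        drive = DriveProtocol(onset=0.0, offset=pulse_s)

    def runner(theta: Mapping[str, float]):
        ps = params
        for name, value in theta.items():
            ps = substitute_parameter(ps, name, float(value))
        scaling = ps.scale(N)
        H = np.empty(len(doses))
        tr = np.empty(len(doses))
        tf = np.empty(len(doses))
        for i, U in enumerate(doses):
            traj = integrate_complete(scaling, drive, float(U),
                                      t_end=t_end_s * 1e3, dt=dt_ms,
                                      record_conductance=False)
            y = traj.SP if signal == "SP" else traj.RP_s
            c = characterize(traj.t * 1e-3, y, drive.onset, drive.offset)
            H[i], tr[i], tf[i] = c.height, c.tau_rise, c.tau_fall
        return H, tr, tf

    return runner


def qualitative_screens(traj, scaling, onset_ms: float, offset_ms: float) -> dict:
    """Post-fit boolean screens on a complete-model trajectory.

    Checks (reported, not folded into the cost): transient kinetics of the
    DAG- and IP3-gated currents (their lumped early conductance decays before
    stimulus offset), a sustained Cl- conductance, and intracellular Ca2+
    staying below 200 uM.
    """
    from . import channels as ch
    from .sensillum_network import _complete_conductances
    from .biochem_drive import ModulatorState

    mods = traj.modulators
    if mods is None:
        raise ValueError("trajectory has no recorded modulators")
    t = traj.t
    in_pulse = (t >= onset_ms) & (t <= offset_ms)
    ca_ok = float(np.max(mods["Ca"])) < 200.0

    # reconstruct per-channel conductance kinetics at the tip compartment
    g_cat = np.empty(t.size)
    g_Cl = np.empty(t.size)
    for k in range(t.size):
        state = ModulatorState(IP3=float(np.atleast_1d(mods["IP3"])[min(k, np.size(mods["IP3"]) - 1)]),
                               DAG=float(np.atleast_1d(mods["DAG"])[min(k, np.size(mods["DAG"]) - 1)]))
        g = _complete_conductances(scaling, state, mods["Ca"][k],
                                   mods["CaCaM"][k], mods["PKC"][k])
        g_cat[k] = g["cat"][0]
        g_Cl[k] = g["Cl"][0]
    k_off = int(np.argmin(np.abs(t - offset_ms)))
    cat_transient = (np.max(g_cat[in_pulse]) > 0
                     and g_cat[k_off] < 0.5 * np.max(g_cat[in_pulse]))
    cl_sustained = (np.max(g_Cl[in_pulse]) > 0
                    and g_Cl[k_off] >= 0.5 * np.max(g_Cl[in_pulse]))
    return {"ca_below_200uM": bool(ca_ok),
            "cationic_transient": bool(cat_transient),
            "chloride_sustained": bool(cl_sustained)}
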