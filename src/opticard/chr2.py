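"""ChR2 photocurrent model and the excitation-threshold-vs-conductance theory.

The light-gated channel is a four-state Markov scheme (closed C1, open O1,
open O2, closed C2) whose activation rates scale with irradiance; retinal
availability enters purely as a scaler of the maximal conductance g_ChR2, so
threshold-versus-conductance curves can be reread as
threshold-versus-supplemental-retinal curves through a dose-to-conductance
mapping (linear, saturating or parabolic).

Two cell models are provided:

- :class:`IdealChargeCell` — a fixed-charge-threshold membrane driven by an
  ideal rectangular light-to-current conversion. Its threshold is analytic
  (E_th = Q/(g d)), giving the exact 1/x reference limit.
- :class:`FastSodiumCell` — a regenerative excitable membrane (Hodgkin-
  Huxley-type fast sodium current plus a linear background/leak current)
  resting near -85 mV. It reproduces the qualitative threshold behaviour of
  a ventricular myocyte: all-or-none upstroke crossing 0 mV, monotone
  threshold in irradiance, and a steep/flat two-region E_th(g) curve.

Any object with ``initial_state()``, ``rhs(t, y, i_inject)`` and
``v_index`` can be plugged in as a heavier cell model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ChR2ModelParams",
    "AtrMapping",
    "IdealChargeCell",
    "FastSodiumCell",
    "load_params",
    "rate_matrix",
    "chr2_photocurrent",
    "steady_state",
    "simulate_excitation",
    "excitation_threshold",
    "eth_vs_g",
    "map_atr_to_g",
    "eth_vs_atr",
]

#: states of the photocycle, in state-vector order
STATES = ("C1", "O1", "O2", "C2")


@dataclass
class ChR2ModelParams:
    """Kinetic and conductance parameters of the four-state ChR2 model.

    ``g_chr2`` (nS/pF) scales the photocurrent linearly; the light-dependent
    activation rates are ``epsilon * flux_per_irradiance * irradiance * p``
    where ``p`` relaxes toward 1 (light on) or 0 (light off) with
    ``tau_activation_ms``. See ``data/chr2_h134r.yaml`` for the constants.
    """

    g_chr2: float
    e_rev_mv: float
    gamma: float
    epsilon1: float
    epsilon2: float
    flux_per_irradiance: float
    tau_activation_ms: float
    gd1: dict
    gd2: float
    gr: dict
    e12: dict
    e21: dict
    rectifier: dict

    def replace(self, **changes) -> "ChR2ModelParams":
        from dataclasses import replace as _replace
        return _replace(self, **changes)


def load_params(path: str | None = None, **overrides) -> ChR2ModelParams:
    """Load kinetic constants from YAML (packaged defaults when path is None)."""
    if path is None:
        text = resources.files("opticard.data").joinpath("chr2_h134r.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    cfg.update(overrides)
    return ChR2ModelParams(**cfg)


def _gd1(p: ChR2ModelParams, v: float) -> float:
    d = p.gd1
    return d["base"] + d["amp"] * math.tanh(-(v - d["v0"]) / d["dv"])


def _gr(p: ChR2ModelParams, v: float) -> float:
    return p.gr["base"] * math.exp(-p.gr["k"] * v)


def _e12(p: ChR2ModelParams, irradiance: float) -> float:
    d = p.e12
    return d["base"] + d["amp"] * math.log1p(irradiance / d["e0"])


def _e21(p: ChR2ModelParams, irradiance: float) -> float:
    d = p.e21
    return d["base"] + d["amp"] * math.log1p(irradiance / d["e0"])


def rate_matrix(
    p: ChR2ModelParams, v: float, irradiance: float, activation: float = 1.0
) -> np.ndarray:
    """Generator matrix Q such that d(state)/dt = Q @ state.

    Columns sum to zero, so occupancy is conserved exactly by any linear
    integrator. ``activation`` is the light-activation variable p in [0, 1].
    """
    k1 = p.epsilon1 * p.flux_per_irradiance * irradiance * activation
    k2 = p.epsilon2 * p.flux_per_irradiance * irradiance * activation
    gd1 = _gd1(p, v)
    e12 = _e12(p, irradiance)
    e21 = _e21(p, irradiance)
    gr = _gr(p, v)
    q = np.zeros((4, 4))
    # C1 -> O1 (k1), O1 -> C1 (gd1)
    q[0, 0] -= k1; q[1, 0] += k1
    q[1, 1] -= gd1; q[0, 1] += gd1
    # O1 <-> O2
    q[1, 1] -= e12; q[2, 1] += e12
    q[2, 2] -= e21; q[1, 2] += e21
    # O2 -> C2 (gd2), C2 -> O2 (k2)
    q[2, 2] -= p.gd2; q[3, 2] += p.gd2
    q[3, 3] -= k2; q[2, 3] += k2
    # C2 -> C1 (gr)
    q[3, 3] -= gr; q[0, 3] += gr
    return q


def photocurrent_density(p: ChR2ModelParams, v: float, state: np.ndarray) -> float:
    """I_ChR2 in pA/pF: g * f(V) * (O1 + gamma*O2), inward negative.

    The voltage dependence uses the empirical inward rectifier
    f(V) = a - b*exp(-V/c) (mV scale), which already contains the driving
    force relative to the ~0 mV reversal: f crosses zero near E_rev and is
    large and negative at diastolic potentials.
    """
    r = p.rectifier
    f = r["a"] - r["b"] * math.exp(-v / r["c"])
    open_frac = state[1] + p.gamma * state[2]
    return p.g_chr2 * f * open_frac


def chr2_photocurrent(
    p: ChR2ModelParams,
    v: float,
    irradiance: float,
    state: np.ndarray,
    dt: float,
    activation: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Advance the photocycle one RK4 step of size ``dt`` ms.

    Returns ``(I_ChR2, next_state)``. The generator matrix has zero column
    sums, and RK4 preserves linear invariants exactly, so the occupancy sum
    stays 1 to rounding error. A step producing negative occupancy raises
    (step size too large for the rates).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (4,) or abs(state.sum() - 1.0) > 1e-6 or (state < -1e-12).any():
        raise ValueError("state must be a length-4 occupancy vector summing to 1")
    q = rate_matrix(p, v, irradiance, activation)
    k1 = q @ state
    k2 = q @ (state + 0.5 * dt * k1)
    k3 = q @ (state + 0.5 * dt * k2)
    k4 = q @ (state + dt * k3)
    nxt = state + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if (nxt < -1e-9).any():
        raise ValueError("negative occupancy after step; reduce the step size")
    return photocurrent_density(p, v, nxt), nxt


def steady_state(p: ChR2ModelParams, v: float, irradiance: float) -> np.ndarray:
    """Occupancies under constant light: the null space of the rate matrix."""
    q = rate_matrix(p, v, irradiance)
    a = np.vstack([q, np.ones(4)])
    b = np.zeros(5)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol


def dark_state() -> np.ndarray:
    """Fully dark-adapted occupancy: everything in C1."""
    return np.array([1.0, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# cell models
# ---------------------------------------------------------------------------


@dataclass
class IdealChargeCell:
    """Fixed-charge-threshold membrane with ideal rectangular photocurrent.

    Excitation occurs iff the injected charge g * E * d reaches
    ``charge_threshold`` (pA/pF * ms); the threshold irradiance is therefore
    exactly Q / (g * d) — the ideal 1/x reference limit.
    """

    charge_threshold: float = 50.0

    def threshold_irradiance(self, g: float, duration: float) -> float:
        if g <= 0 or duration <= 0:
            raise ValueError("conductance and duration must be positive")
        return self.charge_threshold / (g * duration)

    def excited(self, g: float, irradiance: float, duration: float) -> bool:
        return g * irradiance * duration >= self.charge_threshold


@dataclass
class FastSodiumCell:
    """Regenerative excitable membrane: HH-type fast sodium + linear leak.

    State vector ``[V, m, h]``; V in mV, gates dimensionless. Default
    constants give a resting potential of -85 mV, an all-or-none upstroke
    overshooting past 0 mV, and a ~25 mV depolarisation needed to fire —
    qualitatively the threshold behaviour of a paced ventricular myocyte.
    """

    g_na: float = 23.0        # nS/pF
    e_na: float = 54.4        # mV
    g_leak: float = 0.15      # nS/pF
    e_leak: float = -85.0     # mV
    v_index: int = 0

    def initial_state(self) -> np.ndarray:
        v = self.e_leak
        am, bm = self._m_rates(v)
        ah, bh = self._h_rates(v)
        return np.array([v, am / (am + bm), ah / (ah + bh)])

    @staticmethod
    def _m_rates(v: float) -> tuple[float, float]:
        x = v + 47.13
        if abs(x) < 1e-6:
            am = 3.2
        else:
            am = 0.32 * x / (1.0 - math.exp(-0.1 * x))
        bm = 0.08 * math.exp(-v / 11.0)
        return am, bm

    @staticmethod
    def _h_rates(v: float) -> tuple[float, float]:
        if v < -40.0:
            ah = 0.135 * math.exp(-(80.0 + v) / 6.8)
            bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        else:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        return ah, bh

    def rhs(self, t: float, y: np.ndarray, i_inject: float) -> np.ndarray:
        v, m, h = y
        am, bm = self._m_rates(v)
        ah, bh = self._h_rates(v)
        i_na = self.g_na * m**3 * h * (v - self.e_na)
        i_leak = self.g_leak * (v - self.e_leak)
        dv = -(i_na + i_leak + i_inject)
        return np.array([dv, am * (1.0 - m) - bm * m, ah * (1.0 - h) - bh * h])


# ---------------------------------------------------------------------------
# excitation simulation and threshold curves
# ---------------------------------------------------------------------------


def simulate_excitation(
    params: ChR2ModelParams,
    irradiance: float,
    pulse_duration: float,
    cell: FastSodiumCell | None = None,
    t_max: float = 200.0,
    rtol: float = 1e-6,
) -> bool:
    """Integrate membrane + photocycle ODEs; True if V crosses 0 mV.

    The light pulse spans [0, pulse_duration] ms; excitation must occur
    within ``t_max`` ms of pulse onset. C2 occupancy is eliminated as
    1 - C1 - O1 - O2, so conservation is exact by construction.
    """
    if irradiance < 0 or pulse_duration <= 0:
        raise ValueError("irradiance must be >= 0 and pulse_duration positive")
    cell = cell or FastSodiumCell()
    cell_state = cell.initial_state()
    n_cell = cell_state.size

    def rhs(t: float, y: np.ndarray, light: float) -> np.ndarray:
        cell_y = y[:n_cell]
        c1, o1, o2 = y[n_cell:n_cell + 3]
        p_act = y[n_cell + 3]
        v = cell_y[cell.v_index]
        state = np.array([c1, o1, o2, 1.0 - c1 - o1 - o2])
        q = rate_matrix(params, v, light, activation=p_act)
        dstate = q @ state
        i_chr2 = photocurrent_density(params, v, state)
        dcell = cell.rhs(t, cell_y, i_chr2)
        p_target = 1.0 if light > 0 else 0.0
        dp = (p_target - p_act) / params.tau_activation_ms
        return np.concatenate([dcell, dstate[:3], [dp]])

    y0 = np.concatenate([cell_state, dark_state()[:3], [0.0]])

    def crossed(t, y, light):
        return y[cell.v_index]
    crossed.terminal = True
    crossed.direction = 1.0

    sol_on = solve_ivp(
        rhs, (0.0, min(pulse_duration, t_max)), y0, args=(irradiance,),
        method="LSODA", rtol=rtol, atol=1e-9, events=crossed, max_step=5.0,
    )
    if not sol_on.success:
        raise RuntimeError(f"integration failed during pulse: {sol_on.message}")
    if sol_on.t_events[0].size:
        return True
    if pulse_duration >= t_max:
        return False
    sol_off = solve_ivp(
        rhs, (pulse_duration, t_max), sol_on.y[:, -1], args=(0.0,),
        method="LSODA", rtol=rtol, atol=1e-9, events=crossed, max_step=5.0,
    )
    if not sol_off.success:
        raise RuntimeError(f"integration failed after pulse: {sol_off.message}")
    return bool(sol_off.t_events[0].size)


def excitation_threshold(
    params: ChR2ModelParams,
    pulse_duration: float = 10.0,
    g: float | None = None,
    cell: FastSodiumCell | IdealChargeCell | None = None,
    e_lo: float = 1e-4,
    e_hi: float = 1e3,
    rel_precision: float = 0.01,
) -> float:
    """Minimal irradiance triggering an action potential (bisection to 1%).

    Returns ``inf`` when even ``e_hi`` fails to excite. With an
    :class:`IdealChargeCell` the closed-form threshold is returned directly.
    """
    p = params if g is None else params.replace(g_chr2=g)
    if isinstance(cell, IdealChargeCell):
        return cell.threshold_irradiance(p.g_chr2, pulse_duration)
    if not simulate_excitation(p, e_hi, pulse_duration, cell):
        return math.inf
    if simulate_excitation(p, e_lo, pulse_duration, cell):
        return e_lo
    lo, hi = e_lo, e_hi
    while hi / lo > 1.0 + 2.0 * rel_precision:
        mid = math.sqrt(lo * hi)
        if simulate_excitation(p, mid, pulse_duration, cell):
            hi = mid
        else:
            lo = mid
    return hi


def eth_vs_g(
    g_grid: np.ndarray,
    pulse_duration: float = 10.0,
    params: ChR2ModelParams | None = None,
    cell: FastSodiumCell | IdealChargeCell | None = None,
    rel_precision: float = 0.01,
) -> pd.DataFrame:
    """Threshold irradiance across a conductance grid, with region labels.

    Returns columns ``g``, ``e_th``, ``loglog_slope`` and ``region``
    (``"steep"`` where the local log-log slope is <= -1, ``"flat"`` where it
    is > -0.2, ``"transition"`` otherwise). E_th(g) is monotone nonincreasing
    up to the bisection precision.
    """
    params = params or load_params()
    g_grid = np.asarray(g_grid, dtype=float)
    if g_grid.size < 2 or (np.diff(g_grid) <= 0).any() or (g_grid <= 0).any():
        raise ValueError("g_grid must be positive and strictly ascending")
    e = np.array([
        excitation_threshold(params, pulse_duration, g=g, cell=cell,
                             rel_precision=rel_precision)
        for g in g_grid
    ])
    finite = np.isfinite(e)
    slope = np.full(g_grid.size, np.nan)
    if finite.sum() >= 2:
        slope[finite] = np.gradient(np.log(e[finite]), np.log(g_grid[finite]))
    region = np.where(slope <= -1.0, "steep",
                      np.where(slope > -0.2, "flat", "transition"))
    region = np.where(finite, region, "inexcitable")
    return pd.DataFrame({"g": g_grid, "e_th": e, "loglog_slope": slope,
                         "region": region})


# ---------------------------------------------------------------------------
# retinal-dose -> conductance mappings
# ---------------------------------------------------------------------------


@dataclass
class AtrMapping:
    """Supplemental-retinal-dose to ChR2-conductance mapping.

    ``linear``:      g = g0 + slope * a                  (monotone)
    ``saturating``:  g = g0 + g_max * a / (a + a_half)   (monotone, bounded)
    ``parabolic``:   g = max(g_floor, g0 + b*a - c*a^2)  (interior maximum)

    ``g0`` is the baseline endogenous conductance at zero supplement; it is
    strictly positive so unsupplemented samples remain optically excitable.
    """

    form: Literal["linear", "saturating", "parabolic"] = "linear"
    g0: float = 0.4
    slope: float = 2.0          # linear: nS/pF per uM
    g_max: float = 4.0          # saturating: asymptotic added conductance
    a_half: float = 0.5         # saturating: half-saturation dose, uM
    b: float = 4.0              # parabolic: rising coefficient
    c: float = 1.0              # parabolic: falling coefficient
    g_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.g0 <= 0:
            raise ValueError("baseline conductance g0 must be positive")

    @property
    def optimum(self) -> float:
        """Dose of maximal conductance (parabolic form)."""
        return self.b / (2.0 * self.c)

    def __call__(self, atr) -> np.ndarray:
        return map_atr_to_g(self, atr)


def map_atr_to_g(m: AtrMapping, atr) -> np.ndarray | float:
    """Evaluate the mapping; rejects negative doses, guarantees g > 0."""
    a = np.asarray(atr, dtype=float)
    if (a < 0).any():
        raise ValueError("ATR dose must be >= 0")
    if m.form == "linear":
        g = m.g0 + m.slope * a
    elif m.form == "saturating":
        g = m.g0 + m.g_max * a / (a + m.a_half)
    elif m.form == "parabolic":
        g = np.maximum(m.g_floor, m.g0 + m.b * a - m.c * a**2)
    else:
        raise ValueError(f"unknown mapping form {m.form!r}")
    return float(g) if np.isscalar(atr) else g


def eth_vs_atr(
    mapping: AtrMapping,
    atr_grid: np.ndarray,
    pulse_duration: float = 10.0,
    params: ChR2ModelParams | None = None,
    cell: FastSodiumCell | IdealChargeCell | None = None,
    rel_precision: float = 0.01,
) -> pd.DataFrame:
    """Composite curve E_th(a) = E_th(g(a)) on a dose grid.

    Returns columns ``atr``, ``g`` and ``e_th``. With a linear mapping the
    curve is hyperbola-like (two sensitivity regions); with a parabolic
    mapping it is non-monotonic with an interior minimum.
    """
    params = params or load_params()
    atr_grid = np.asarray(atr_grid, dtype=float)
    g = np.asarray(map_atr_to_g(mapping, atr_grid), dtype=float)
    e = np.array([
        excitation_threshold(params, pulse_duration, g=gi, cell=cell,
                             rel_precision=rel_precision)
        for gi in g
    ])
    return pd.DataFrame({"atr": atr_grid, "g": g, "e_th": e})
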