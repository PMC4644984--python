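"""Capture thresholds, strength-duration curves, rheobase/chronaxie fits.

The pacing threshold E_th at a pulse duration is the smallest irradiance at
which at least 10 of 10 consecutive 1-Hz pulses capture the tissue. The
search walks a geometric irradiance grid (ratio 1.25) to bracket the
transition, then bisects to 2% relative precision; every oracle evaluation is
kept as a certificate. Strength-duration data are fitted with the Lapicque
hyperbola E(d) = rheobase * (1 + chronaxie/d) (Weiss linear-charge form
selectable), and threshold-versus-retinal-dose data with the hyperbola
E(a) = k/(a + a0) + E_inf restricted to the monotone-decreasing dose range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from opticard.synthetic import lapicque

__all__ = [
    "ThresholdResult",
    "StrengthDurationCurve",
    "SDFit",
    "HyperbolicFit",
    "find_threshold",
    "build_sd_curve",
    "fit_rheobase_chronaxie",
    "fit_eth_vs_atr",
    "plot_sd_curves",
]

#: number of consecutive captured beats required to accept an irradiance
N_REQUIRED_BEATS = 10

#: geometric grid ratio and relative bisection precision of the search
GRID_RATIO = 1.25
REL_PRECISION = 0.02


@dataclass
class ThresholdResult:
    """Outcome of one threshold search at a fixed pulse duration."""

    duration: float
    e_th: float                       # mW/mm^2; inf when inexcitable
    inexcitable: bool
    certificate: pd.DataFrame         # every (irradiance, captured) evaluation
    bracket: tuple[float, float]      # final (failing, capturing) irradiances


@dataclass
class StrengthDurationCurve:
    """E_th(d) samples for one condition, with replicate statistics."""

    condition: str
    table: pd.DataFrame               # duration_ms, mean, sem, n
    replicates: pd.DataFrame          # duration_ms, replicate, e_th

    @property
    def durations(self) -> np.ndarray:
        return self.table["duration_ms"].to_numpy()

    @property
    def e_th(self) -> np.ndarray:
        return self.table["mean"].to_numpy()


@dataclass
class SDFit:
    """Fitted strength-duration parameters."""

    rheobase: float
    chronaxie: float
    model: str
    residuals: np.ndarray
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class HyperbolicFit:
    """Fit of E(a) = k/(a + a0) + e_inf over the monotone dose range."""

    k: float
    a0: float
    e_inf: float
    r_squared: float
    used_doses: np.ndarray
    excluded_doses: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __call__(self, a):
        return self.k / (np.asarray(a, dtype=float) + self.a0) + self.e_inf


def find_threshold(
    tester: Callable[[float, float, int], int],
    duration: float,
    n_required: int = N_REQUIRED_BEATS,
    n_pulses: int = N_REQUIRED_BEATS,
    floor: float = 1e-3,
    ceiling: float = 50.0,
    grid_ratio: float = GRID_RATIO,
    rel_precision: float = REL_PRECISION,
) -> ThresholdResult:
    """Find the smallest irradiance capturing >= ``n_required`` of ``n_pulses``.

    ``tester(irradiance, duration_ms, n_pulses)`` returns the captured-beat
    count. The certified capturing irradiance (upper end of the final
    bracket) is reported as E_th. ``floor`` defaults to 1 uW/mm^2; if even
    the floor captures, the grid is extended downwards. No capture at
    ``ceiling`` flags the duration as inexcitable.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    evals: list[dict] = []

    def captured(e: float) -> bool:
        n = tester(e, duration, n_pulses)
        evals.append({"irradiance": e, "captured": n, "accepted": n >= n_required})
        return n >= n_required

    # ascending geometric scan for the first capturing grid point
    hi = None
    lo = None
    e = floor
    while e <= ceiling * (1.0 + 1e-12):
        if captured(e):
            hi = e
            break
        lo = e
        e *= grid_ratio
    if hi is None:
        cert = pd.DataFrame(evals)
        return ThresholdResult(duration, math.inf, True, cert, (lo or floor, math.inf))
    if lo is None:
        # the floor already captures: extend downwards to bracket the transition
        e = floor / grid_ratio
        while e > 1e-9:
            if not captured(e):
                lo = e
                break
            hi = e
            e /= grid_ratio
        if lo is None:
            lo = e
    # bisect (in log space) until the bracket is within the relative precision
    while hi / lo > 1.0 + 2.0 * rel_precision:
        mid = math.sqrt(lo * hi)
        if captured(mid):
            hi = mid
        else:
            lo = mid
    return ThresholdResult(duration, hi, False, pd.DataFrame(evals), (lo, hi))


def build_sd_curve(
    thresholds: Mapping[float, Sequence[float]] | Sequence[ThresholdResult],
    condition: str = "",
) -> StrengthDurationCurve:
    """Aggregate per-duration replicate thresholds into mean +/- SEM.

    Accepts either ``{duration: [e_th, ...]}`` or a flat list of
    ``ThresholdResult``. Inexcitable (infinite) thresholds propagate as
    missing points. At least two durations are required.
    """
    if isinstance(thresholds, Mapping):
        items = [(d, list(v)) for d, v in thresholds.items()]
    else:
        grouped: dict[float, list[float]] = {}
        for res in thresholds:
            grouped.setdefault(res.duration, []).append(res.e_th)
        items = sorted(grouped.items())
    rows_rep = []
    rows = []
    for d, vals in sorted(items):
        finite = [v for v in vals if math.isfinite(v)]
        for j, v in enumerate(vals):
            rows_rep.append({"duration_ms": d, "replicate": j, "e_th": v})
        if not finite:
            continue
        sem = (float(np.std(finite, ddof=1) / math.sqrt(len(finite)))
               if len(finite) > 1 else math.nan)
        rows.append({"duration_ms": d, "mean": float(np.mean(finite)),
                     "sem": sem, "n": len(finite)})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("need thresholds at >= 2 durations")
    return StrengthDurationCurve(condition, table, pd.DataFrame(rows_rep))


def fit_rheobase_chronaxie(
    curve: StrengthDurationCurve | tuple[np.ndarray, np.ndarray],
    model: str = "lapicque",
) -> SDFit:
    """Fit rheobase and chronaxie to a strength-duration curve.

    ``model="lapicque"`` (default) does nonlinear least squares of
    E(d) = r * (1 + c/d); ``model="weiss"`` fits the equivalent linear charge
    form Q = E*d = r*d + r*c. Rheobase is the asymptotic threshold at long
    durations; chronaxie is the duration where the fitted E equals twice the
    rheobase. A chronaxie collapsing to the lower boundary is flagged.
    """
    if isinstance(curve, StrengthDurationCurve):
        d = curve.durations.astype(float)
        e = curve.e_th.astype(float)
    else:
        d = np.asarray(curve[0], dtype=float)
        e = np.asarray(curve[1], dtype=float)
    keep = np.isfinite(d) & np.isfinite(e)
    d, e = d[keep], e[keep]
    if d.size < 3 or d.max() / d.min() < 10.0:
        raise ValueError("need >= 3 durations spanning at least one decade")
    flags: list[str] = []
    if model == "weiss":
        # Q = E*d is linear in d: slope = rheobase, intercept = rheobase*chronaxie
        slope, intercept = np.polyfit(d, e * d, 1)
        r, c = float(slope), float(intercept / slope) if slope > 0 else math.nan
        resid = e - lapicque(d, r, c)
        converged = slope > 0 and intercept > 0
        if not converged:
            flags.append("weiss_fit_nonphysical")
    elif model == "lapicque":
        r0 = float(e.min())
        # initial chronaxie: duration where E first drops below 2*rheobase
        below = d[e <= 2.0 * r0]
        c0 = float(below.min()) if below.size else float(np.median(d))
        try:
            popt, _ = curve_fit(
                lapicque, d, e, p0=[max(r0, 1e-12), max(c0, 1e-6)],
                bounds=([1e-15, 1e-9], [np.inf, np.inf]), maxfev=20000,
            )
            r, c = float(popt[0]), float(popt[1])
            converged = True
        except RuntimeError:
            r, c = math.nan, math.nan
            converged = False
            flags.append("fit_failed")
        resid = e - lapicque(d, r, c) if converged else e * math.nan
    else:
        raise ValueError(f"unknown strength-duration model {model!r}")
    if converged and c <= 1e-2 * float(d.min()):
        flags.append("chronaxie_at_zero_boundary")
    return SDFit(rheobase=r, chronaxie=c, model=model,
                 residuals=np.asarray(resid), converged=converged, flags=flags)


def plot_sd_curves(
    curves: Sequence[StrengthDurationCurve],
    fits: Sequence[SDFit] | None = None,
    path: str | None = None,
):
    """Log-log strength-duration plot, optionally with fitted Lapicque curves.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for i, curve in enumerate(curves):
        t = curve.table
        ax.errorbar(t["duration_ms"], t["mean"], yerr=t["sem"].fillna(0.0),
                    marker="o", linestyle="none", capsize=3,
                    label=curve.condition or f"condition {i}")
        if fits is not None and i < len(fits) and fits[i].converged:
            d = np.geomspace(t["duration_ms"].min(), t["duration_ms"].max(), 100)
            ax.plot(d, lapicque(d, fits[i].rheobase, fits[i].chronaxie), "--")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("pulse duration (ms)")
    ax.set_ylabel(r"E$_{th}$ (mW/mm$^2$)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def _hyperbola(a, k, a0, e_inf):
    return k / (a + a0) + e_inf


def fit_eth_vs_atr(
    atr: np.ndarray, e_th: np.ndarray, restrict_monotone: bool = True
) -> HyperbolicFit:
    """Fit E(a) = k/(a + a0) + e_inf to threshold-versus-dose data.

    With ``restrict_monotone`` (default) the fit uses only doses up to the
    observed minimum-threshold dose — beyond it the experimental rebound
    (toxicity-driven) departs from the theory — and records the exclusion.
    All parameters are constrained non-negative. Needs >= 3 usable doses.
    """
    atr = np.asarray(atr, dtype=float)
    e_th = np.asarray(e_th, dtype=float)
    order = np.argsort(atr)
    atr, e_th = atr[order], e_th[order]
    flags: list[str] = []
    if restrict_monotone:
        argmin = int(np.argmin(e_th))
        used = slice(0, argmin + 1)
        excluded = atr[argmin + 1:]
        if excluded.size:
            flags.append("excluded_rebound_doses")
    else:
        used = slice(None)
        excluded = np.empty(0)
    a_fit, e_fit = atr[used], e_th[used]
    if a_fit.size < 3:
        raise ValueError("need at least 3 doses in the monotone range")
    k0 = max((e_fit[0] - e_fit[-1]) * max(a_fit[-1], 1.0), 1e-9)
    p0 = [k0, max(0.1 * (a_fit[-1] - a_fit[0]), 1e-3), max(e_fit[-1], 0.0)]
    popt, _ = curve_fit(
        _hyperbola, a_fit, e_fit, p0=p0,
        bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]), maxfev=50000,
    )
    pred = _hyperbola(a_fit, *popt)
    ss_res = float(np.sum((e_fit - pred) ** 2))
    ss_tot = float(np.sum((e_fit - e_fit.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return HyperbolicFit(k=float(popt[0]), a0=float(popt[1]), e_inf=float(popt[2]),
                         r_squared=r2, used_doses=a_fit, excluded_doses=excluded,
                         flags=flags)
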