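"""Activation maps, isochrones, conduction velocity and phase movies.

Activation time at a pixel is the time of maximum fluorescence rise within a
beat window, refined below the frame interval by parabolic interpolation of
the temporal-derivative peak. Conduction velocity is estimated along straight
paths across the activation map, by default three parallel paths through the
map centroid aligned with the median activation-gradient direction, with CV
taken from the regression of activation time on distance along each path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from opticard.stack import MovieStack

__all__ = [
    "ActivationResult",
    "activation_map",
    "isochrones",
    "conduction_velocity",
    "hilbert_phase",
]

#: default isochrone spacing, ms
ISOCHRONE_INTERVAL_MS = 10.0

#: pixels whose event amplitude falls below this fraction of the field median
#: are treated as unexcited (dead-cell patches cause spurious times otherwise)
AMPLITUDE_GATE_FRACTION = 0.2


@dataclass
class ActivationResult:
    """Per-pixel activation-time map plus derived conduction estimates.

    ``activation_map`` holds wavefront arrival times in ms (NaN where the
    amplitude gate rejected the pixel). ``cv_paths`` is one row per straight
    path with endpoints, per-path CV (cm/s) and a validity flag; ``cv_mean``
    averages the valid paths.
    """

    activation_map: np.ndarray
    frame_interval: float
    pixel_pitch: float
    isochrone_interval: float = ISOCHRONE_INTERVAL_MS
    cv_paths: pd.DataFrame | None = None
    cv_mean: float = math.nan
    meta: dict = field(default_factory=dict)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.activation_map)


def activation_map(
    m: MovieStack,
    beat_window: tuple[float, float] | None = None,
    amplitude_gate: float = AMPLITUDE_GATE_FRACTION,
) -> ActivationResult:
    """Build the activation map for one paced beat.

    ``beat_window`` is (start_ms, stop_ms) isolating a single beat; ``None``
    uses the whole recording (only sensible for a one-beat movie). Raises if
    the window contains no upstroke anywhere (field-median amplitude
    indistinguishable from noise).
    """
    if beat_window is None:
        w0, w1 = 0, m.n_frames
    else:
        w0 = max(0, int(math.floor(beat_window[0] / m.frame_interval)))
        w1 = min(m.n_frames, int(math.ceil(beat_window[1] / m.frame_interval)) + 1)
    if w1 - w0 < 5:
        raise ValueError("beat window too short")
    seg = m.data[w0:w1].astype(float)

    amp = seg.max(axis=0) - seg.min(axis=0)
    med_amp = float(np.median(amp))
    # robust per-pixel noise from frame-to-frame differences
    noise = 1.4826 * np.median(np.abs(np.diff(seg, axis=0)), axis=0) / math.sqrt(2.0)
    if med_amp <= 5.0 * float(np.median(noise)) or med_amp <= 0:
        raise ValueError("beat window contains no upstroke anywhere")

    deriv = np.gradient(seg, axis=0)
    idx = np.argmax(deriv, axis=0)
    # parabolic refinement of the derivative peak
    idx_c = np.clip(idx, 1, seg.shape[0] - 2)
    rows, cols = np.indices(idx.shape)
    d0 = deriv[idx_c - 1, rows, cols]
    d1 = deriv[idx_c, rows, cols]
    d2 = deriv[idx_c + 1, rows, cols]
    denom = d0 - 2.0 * d1 + d2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (d0 - d2) / np.where(denom == 0, 1.0, denom), 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    act = (w0 + idx_c + shift) * m.frame_interval

    gated = amp < amplitude_gate * med_amp
    act = np.where(gated, np.nan, act)
    return ActivationResult(
        activation_map=act,
        frame_interval=m.frame_interval,
        pixel_pitch=m.pixel_pitch,
        meta={"beat_window": (w0 * m.frame_interval, (w1 - 1) * m.frame_interval),
              "n_gated": int(gated.sum()), "amplitude_gate": amplitude_gate},
    )


def isochrones(
    r: ActivationResult, interval: float = ISOCHRONE_INTERVAL_MS
) -> dict[float, list[np.ndarray]]:
    """Level sets of the activation map at multiples of ``interval`` ms.

    Returns ``{level_ms: [polyline, ...]}`` where each polyline is an (N, 2)
    array of (row, col) pixel coordinates. Levels start one interval above
    the earliest activation. Raises on an all-NaN map.
    """
    from skimage import measure

    amap = r.activation_map
    if not np.isfinite(amap).any():
        raise ValueError("activation map has no valid pixels")
    lo = float(np.nanmin(amap))
    hi = float(np.nanmax(amap))
    # NaN pixels must not generate contours: push them far above every level
    filled = np.where(np.isfinite(amap), amap, hi + 100.0 * interval)
    out: dict[float, list[np.ndarray]] = {}
    k = 1
    while lo + k * interval <= hi:
        level = lo + k * interval
        contours = measure.find_contours(filled, level)
        out[level] = [c for c in contours if len(c) >= 2]
        k += 1
    return out


def _auto_paths(
    amap: np.ndarray, n_paths: int = 3, offset_fraction: float = 0.2
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Straight paths through the centroid along the median gradient direction."""
    valid = np.isfinite(amap)
    gy, gx = np.gradient(amap)
    good = valid & np.isfinite(gy) & np.isfinite(gx)
    if good.sum() < 10:
        raise ValueError("too few valid pixels for automatic path selection")
    vy = float(np.median(gy[good]))
    vx = float(np.median(gx[good]))
    norm = math.hypot(vy, vx)
    if norm == 0:
        raise ValueError("activation map has no gradient; cannot orient paths")
    u = np.array([vy, vx]) / norm          # propagation direction
    perp = np.array([-u[1], u[0]])
    rows, cols = np.nonzero(valid)
    centroid = np.array([rows.mean(), cols.mean()])
    h, w = amap.shape
    half_span = 0.5 * math.hypot(h, w)
    extent = offset_fraction * min(h, w)
    offsets = np.linspace(-extent, extent, n_paths) if n_paths > 1 else [0.0]
    paths = []
    for off in offsets:
        c = centroid + off * perp
        paths.append((c - half_span * u, c + half_span * u))
    return paths


def _sample_path(
    amap: np.ndarray, p0: np.ndarray, p1: np.ndarray, step_px: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample activation times along the segment p0->p1, clipped to the map."""
    length = float(np.hypot(*(np.asarray(p1) - np.asarray(p0))))
    n = max(int(length / step_px) + 1, 2)
    frac = np.linspace(0.0, 1.0, n)
    pts = np.asarray(p0)[None, :] + frac[:, None] * (np.asarray(p1) - np.asarray(p0))[None, :]
    inside = ((pts[:, 0] >= 0) & (pts[:, 0] <= amap.shape[0] - 1)
              & (pts[:, 1] >= 0) & (pts[:, 1] <= amap.shape[1] - 1))
    pts = pts[inside]
    if len(pts) < 2:
        return np.empty(0), np.empty(0)
    filled = np.where(np.isfinite(amap), amap, np.nan)
    t = ndimage.map_coordinates(filled, pts.T, order=1, mode="constant", cval=np.nan)
    s = np.hypot(pts[:, 0] - pts[0, 0], pts[:, 1] - pts[0, 1])
    keep = np.isfinite(t)
    return s[keep], t[keep]


def conduction_velocity(
    r: ActivationResult,
    paths: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
    method: str = "regression",
    min_points: int = 10,
    monotone_fraction: float = 0.8,
) -> ActivationResult:
    """Estimate CV along straight paths across the activation map.

    Per path, CV = distance travelled / activation-time difference. With
    ``method="regression"`` (default) the slope of activation time on
    distance along the path is used; ``"endpoints"`` divides path length by
    the endpoint time difference. Paths with non-monotone activation (less
    than ``monotone_fraction`` of increments positive) are flagged and
    excluded from the mean. Updates and returns ``r`` with ``cv_paths`` and
    ``cv_mean``.
    """
    amap = r.activation_map
    if paths is None:
        segments = _auto_paths(amap)
    else:
        segments = [(np.asarray(a, float), np.asarray(b, float)) for a, b in paths]
    rows = []
    for i, (p0, p1) in enumerate(segments):
        s_px, t_ms = _sample_path(amap, p0, p1)
        valid = s_px.size >= min_points
        cv = math.nan
        mono = math.nan
        if valid:
            dt = np.diff(t_ms)
            mono = float(np.mean(dt > 0)) if dt.size else 0.0
            if mono < monotone_fraction:
                valid = False
        if valid:
            s_cm = s_px * r.pixel_pitch / 10.0
            t_s = t_ms / 1000.0
            if method == "regression":
                slope = np.polyfit(s_cm, t_s, 1)[0]
            elif method == "endpoints":
                slope = (t_s[-1] - t_s[0]) / (s_cm[-1] - s_cm[0])
            else:
                raise ValueError(f"unknown CV method {method!r}")
            if slope <= 0:
                valid = False
            else:
                cv = 1.0 / slope
        rows.append({
            "path": i,
            "r0": float(p0[0]), "c0": float(p0[1]),
            "r1": float(p1[0]), "c1": float(p1[1]),
            "n_points": int(s_px.size),
            "monotone_fraction": mono,
            "cv_cm_per_s": cv,
            "valid": valid,
        })
    df = pd.DataFrame(rows)
    good = df.loc[df["valid"], "cv_cm_per_s"]
    r.cv_paths = df
    r.cv_mean = float(good.mean()) if len(good) else math.nan
    r.meta["cv_method"] = method
    return r


def hilbert_phase(m: MovieStack) -> np.ndarray:
    """Instantaneous phase movie via the analytic signal, radians in (-pi, pi].

    Traces are zero-centred per pixel before the Hilbert transform. Constant
    pixels have undefined phase and are set to NaN.
    """
    data = m.data.astype(float)
    centered = data - data.mean(axis=0, keepdims=True)
    span = data.max(axis=0) - data.min(axis=0)
    analytic = signal.hilbert(centered, axis=0)
    phase = np.angle(analytic)
    phase = np.where(span[None, :, :] > 0, phase, np.nan)
    return phase
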