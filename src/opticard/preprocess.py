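"""Movie pre-processing chain for optical-mapping recordings.

The fixed order is: baseline removal -> scaling to full dynamic range ->
3x3 Bartlett spatial filter -> second-order, 7-frame Savitzky-Golay temporal
filter. Each step records itself in the movie's provenance metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal

from opticard.stack import MovieStack

__all__ = [
    "remove_baseline",
    "scale_full_range",
    "bartlett_3x3",
    "savgol_2_7",
    "preprocess",
    "BARTLETT_KERNEL",
]

#: normalised 3x3 triangular (Bartlett) kernel, outer([1,2,1],[1,2,1])/16
BARTLETT_KERNEL = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0


def _polynomial_baseline(
    data: np.ndarray, order: int, window_frames: int, band_fraction: float = 0.05
) -> np.ndarray:
    """Per-pixel polynomial baseline fitted to detected diastolic samples.

    Diastolic (quiescent) frames are those within a small band of the
    per-pixel rolling minimum: the rolling window is longer than one
    transient, so its minimum always touches the diastolic envelope and the
    selected frames are spread uniformly across beats regardless of the
    transient duty cycle. The band is ``band_fraction`` of the per-pixel
    amplitude plus three robust noise sigmas, so noisy diastole is kept
    without admitting transient tails.
    """
    t_frames = data.shape[0]
    flat = data.reshape(t_frames, -1).T  # (P, T)
    t = np.arange(t_frames, dtype=float)
    t_norm = (t - t.mean()) / max(t.std(), 1.0)
    design = np.vander(t_norm, order + 1, increasing=True)  # (T, k)

    rollmin = ndimage.minimum_filter1d(flat, size=window_frames, axis=1, mode="nearest")
    amp = flat.max(axis=1, keepdims=True) - flat.min(axis=1, keepdims=True)
    sigma = 1.4826 * np.median(np.abs(np.diff(flat, axis=1)), axis=1, keepdims=True) / np.sqrt(2.0)
    weights = (flat <= rollmin + band_fraction * amp + 3.0 * sigma).astype(float)

    # weighted normal equations per pixel: (A' W A) c = A' W y
    gram = np.einsum("pt,ti,tj->pij", weights, design, design)
    rhs = np.einsum("pt,ti,pt->pi", weights, design, flat)
    coef = np.linalg.solve(gram, rhs[..., None])[..., 0]  # (P, k)
    baseline = coef @ design.T  # (P, T)
    return baseline.T.reshape(data.shape)


def remove_baseline(
    m: MovieStack,
    method: str = "polynomial",
    order: int = 2,
    window_ms: float = 1100.0,
) -> MovieStack:
    """Subtract the per-pixel slow trend (drift, photobleaching).

    ``method="polynomial"`` (default) fits an order-``order`` polynomial to
    the diastolic samples of each pixel (frames near the rolling minimum
    over a ``window_ms`` window, which must exceed one transient duration);
    ``method="tophat"`` subtracts a temporal morphological opening with the
    same window.
    """
    if m.n_frames < 7:
        raise ValueError("movie too short for baseline removal")
    window_frames = max(3, int(round(window_ms / m.frame_interval)))
    if method == "polynomial":
        if order + 1 >= m.n_frames:
            raise ValueError("polynomial order incompatible with movie length")
        baseline = _polynomial_baseline(m.data.astype(float), order, window_frames)
        out = m.data - baseline
        return m.with_data(out, step="remove_baseline", method=method, order=order,
                           window_ms=window_ms)
    if method == "tophat":
        if window_frames >= m.n_frames:
            raise ValueError("tophat window longer than the recording")
        baseline = ndimage.grey_opening(m.data.astype(float), size=(window_frames, 1, 1))
        out = m.data - baseline
        return m.with_data(out, step="remove_baseline", method=method, window_ms=window_ms)
    raise ValueError(f"unknown baseline method {method!r}")


def scale_full_range(m: MovieStack, mode: str = "per_pixel") -> MovieStack:
    """Affinely scale traces to [0, 1].

    ``per_pixel`` (default) normalises each pixel's trace independently;
    ``global`` uses one min/max for the whole movie. Flat domains (max equals
    min) are set to 0 and counted in the provenance record rather than
    raising.
    """
    data = m.data.astype(float)
    n_flat = 0
    if mode == "per_pixel":
        lo = data.min(axis=0, keepdims=True)
        hi = data.max(axis=0, keepdims=True)
        span = hi - lo
        flat = span <= 0
        n_flat = int(flat.sum())
        span = np.where(flat, 1.0, span)
        out = (data - lo) / span
        out = np.where(flat, 0.0, out)
    elif mode == "global":
        lo, hi = data.min(), data.max()
        if hi <= lo:
            n_flat = data[0].size
            out = np.zeros_like(data)
        else:
            out = (data - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    if n_flat:
        warnings.warn(f"{n_flat} flat pixel(s) set to 0 during scaling", stacklevel=2)
    return m.with_data(out, step="scale_full_range", mode=mode, n_flat=n_flat)


def bartlett_3x3(m: MovieStack) -> MovieStack:
    """Spatially smooth each frame with the normalised 3x3 Bartlett kernel.

    Borders use reflection, so constants and interior affine ramps pass
    through unchanged.
    """
    if m.frame_shape[0] < 3 or m.frame_shape[1] < 3:
        raise ValueError("frames must be at least 3x3 for the Bartlett filter")
    kernel = BARTLETT_KERNEL[None, :, :]
    out = ndimage.convolve(m.data.astype(float), kernel, mode="reflect")
    return m.with_data(out, step="bartlett_3x3", border="reflect")


def savgol_2_7(m: MovieStack) -> MovieStack:
    """Temporally smooth each pixel with an order-2, 7-frame Savitzky-Golay
    filter. Ends are handled by a polynomial edge fit (scipy ``mode="interp"``),
    so quadratic-in-time traces are reproduced exactly everywhere.
    """
    if m.n_frames < 7:
        raise ValueError("need at least 7 frames for the Savitzky-Golay filter")
    out = signal.savgol_filter(m.data.astype(float), window_length=7, polyorder=2,
                               axis=0, mode="interp")
    return m.with_data(out, step="savgol_2_7", ends="polynomial_edge_fit")


def preprocess(
    m: MovieStack,
    baseline_method: str = "polynomial",
    baseline_order: int = 2,
    scale_mode: str = "per_pixel",
    spatial_filter: bool = True,
    temporal_filter: bool = True,
) -> MovieStack:
    """Run the full chain: baseline -> scale -> Bartlett 3x3 -> Savitzky-Golay 2/7."""
    out = remove_baseline(m, method=baseline_method, order=baseline_order)
    out = scale_full_range(out, mode=scale_mode)
    if spatial_filter:
        out = bartlett_3x3(out)
    if temporal_filter:
        out = savgol_2_7(out)
    return out
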