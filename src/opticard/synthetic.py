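"""Ground-truth synthetic data for every input class the pipeline consumes.

The generators emulate the three kinds of raw data produced by an integrated
optical-actuation / optical-mapping experiment on ChR2-expressing cardiac
monolayers:

1. propagating excitation-wave movies (voltage or calcium channel) with
   parameterised transient templates, known conduction velocity, noise and
   optional photobleaching drift;
2. static micrograph pairs — PI/DAPI for viability, eYFP/DAPI for
   expression — with a controlled number of nuclei, dead fraction and
   per-cell expression signal over uniform autofluorescence;
3. a virtual paced monolayer whose capture response to (irradiance,
   pulse-duration) stimuli follows a Lapicque strength-duration law with
   known rheobase and chronaxie.

All generators are deterministic under a fixed seed, and every quantity the
downstream analysis estimates (APD80/CTD80, CV, dead fraction, expression
fold, rheobase/chronaxie) is exact by construction in the returned ground
truth.

Transient templates are piecewise smooth: a half-cosine upstroke of duration
``rise_time`` followed by a stretched-exponential repolarisation
``exp(-((t - rise_time)/tau)**p)``. The decay constant ``tau`` is solved in
closed form so that the time from the 10%-amplitude upstroke crossing to the
80%-recovery point equals ``duration80`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from opticard.stack import MovieStack

__all__ = [
    "WaveGroundTruth",
    "MicrographGroundTruth",
    "OracleParams",
    "transient_template",
    "true_activation_map",
    "gen_voltage_movie",
    "gen_calcium_movie",
    "gen_micrographs",
    "gen_capture_oracle",
]

# template shape constants: voltage APs have a fast upstroke and a plateau
# (high stretching power); calcium transients rise and decay more slowly.
AP_RISE_MS = 5.0
AP_POWER = 3.0
CT_RISE_MS = 30.0
CT_POWER = 1.5

#: fraction of amplitude defining the transient "beginning" on the upstroke
ONSET_FRACTION = 0.1


@dataclass
class WaveGroundTruth:
    """True parameters of a propagating excitation wave.

    cv:
        Conduction velocity in cm/s.
    duration80:
        APD80 (voltage) or CTD80 (calcium) of the underlying template, ms,
        measured from the 10%-amplitude upstroke crossing to 80% recovery.
    pacing_period:
        Beat-to-beat interval in ms (1000 ms = 1 Hz pacing).
    n_beats:
        Number of paced beats in the recording.
    geometry:
        ``"planar"`` (wave travels along columns, left to right) or
        ``"point"`` (radial wave from ``origin``).
    origin:
        (row, col) pixel coordinates of the wave source (point geometry).
    snr:
        Transient amplitude divided by the additive Gaussian noise sigma;
        ``inf`` disables noise.
    seed:
        Seed for the noise stream.
    """

    cv: float
    duration80: float
    pacing_period: float = 1000.0
    n_beats: int = 4
    geometry: Literal["planar", "point"] = "planar"
    origin: tuple[float, float] = (0.0, 0.0)
    snr: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.duration80 <= 0:
            raise ValueError("duration80 must be positive")
        if self.pacing_period < self.duration80 + 50.0:
            raise ValueError(
                "pacing_period must exceed duration80 by >= 50 ms to avoid beat fusion"
            )
        if self.n_beats < 3:
            raise ValueError("n_beats must be >= 3")
        if self.geometry not in ("planar", "point"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (inf for noise-free)")


@dataclass
class MicrographGroundTruth:
    """True parameters of a synthetic micrograph field of view."""

    n_cells: int
    dead_fraction: float = 0.0
    expression_per_cell: float = 150.0
    autofluorescence_level: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.expression_per_cell < 0 or self.autofluorescence_level < 0:
            raise ValueError("intensity fields must be non-negative")


@dataclass
class OracleParams:
    """True strength-duration law of a virtual paced monolayer."""

    rheobase: float
    chronaxie: float
    capture_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rheobase <= 0:
            raise ValueError("rheobase must be positive")
        if self.chronaxie <= 0:
            raise ValueError("chronaxie must be positive")
        if not 0.0 <= self.capture_noise < 0.5:
            raise ValueError("capture_noise must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# transient templates
# ---------------------------------------------------------------------------

#: the repolarisation reaches exactly zero at CUTOFF_FACTOR * duration80
#: past the end of the upstroke, so 1-Hz pacing leaves a clean diastole
CUTOFF_FACTOR = 1.6


def _template_params(
    duration80: float, rise_time: float, power: float
) -> tuple[float, float, float]:
    """Return (t_onset, tau, t_cut) for an exact 80%-recovery duration.

    The 10%-amplitude upstroke crossing is at ``rise_time * acos(0.8)/pi``
    (half-cosine rise). The decay is a stretched exponential renormalised to
    hit zero at ``t_cut = CUTOFF_FACTOR * duration80`` after the upstroke;
    its time constant ``tau`` is root-solved so that the decay passes 20% of
    peak exactly ``duration80`` after the onset crossing.
    """
    t_onset = rise_time * math.acos(1.0 - 2.0 * ONSET_FRACTION) / math.pi
    span = duration80 - (rise_time - t_onset)
    if span <= 0:
        raise ValueError("duration80 too short for the template rise time")
    t_cut = CUTOFF_FACTOR * duration80

    def recovery_level(tau: float) -> float:
        eps = math.exp(-((t_cut / tau) ** power))
        return (math.exp(-((span / tau) ** power)) - eps) / (1.0 - eps) - 0.2

    from scipy.optimize import brentq

    tau = brentq(recovery_level, span / 50.0, span * 200.0, xtol=1e-10)
    return t_onset, tau, t_cut


def transient_template(
    t: np.ndarray,
    duration80: float,
    rise_time: float = AP_RISE_MS,
    power: float = AP_POWER,
) -> np.ndarray:
    """Evaluate the unit-amplitude transient template at times ``t`` (ms).

    ``t`` is measured from template onset (t=0 is the foot of the upstroke).
    The template rises 0 -> 1 over ``rise_time`` with a half-cosine, then
    repolarises monotonically as a renormalised stretched exponential that
    reaches zero at ``CUTOFF_FACTOR * duration80`` past the upstroke. The
    decay constant is root-solved so the time from the 10%-amplitude onset
    crossing to 80% recovery equals ``duration80`` exactly.
    """
    _, tau, t_cut = _template_params(duration80, rise_time, power)
    eps = math.exp(-((t_cut / tau) ** power))
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_time)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / rise_time))
    falling = (t >= rise_time) & (t < rise_time + t_cut)
    rel = (t[falling] - rise_time) / tau
    out[falling] = (np.exp(-(rel**power)) - eps) / (1.0 - eps)
    return out


def template_onset_delay(rise_time: float = AP_RISE_MS) -> float:
    """Delay (ms) from template t=0 to its 10%-amplitude upstroke crossing."""
    return rise_time * math.acos(1.0 - 2.0 * ONSET_FRACTION) / math.pi


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def true_activation_map(
    gt: WaveGroundTruth, frame_shape: tuple[int, int], pixel_pitch: float
) -> np.ndarray:
    """Wavefront arrival time (ms) at each pixel, relative to the source.

    Planar geometry propagates along columns (left to right); point geometry
    radially from ``gt.origin``. ``cv`` in cm/s and ``pixel_pitch`` in mm give
    arrival time ``distance_mm / (10 * cv) * 1000``.
    """
    h, w = frame_shape
    rows, cols = np.mgrid[0:h, 0:w]
    if gt.geometry == "planar":
        dist_px = cols.astype(float)
    else:
        r0, c0 = gt.origin
        dist_px = np.hypot(rows - r0, cols - c0)
    dist_cm = dist_px * pixel_pitch / 10.0
    return dist_cm / gt.cv * 1000.0


def _gen_wave_movie(
    gt: WaveGroundTruth,
    shape: tuple[int, int, int],
    frame_interval: float,
    pixel_pitch: float,
    channel: str,
    rise_time: float,
    power: float,
    first_onset: float,
    baseline_offset: float,
    amplitude: float,
    drift_tau: float | None,
) -> tuple[MovieStack, WaveGroundTruth]:
    t_frames, h, w = shape
    if h < 1 or w < 1 or t_frames < 7:
        raise ValueError("movie shape must be at least 7 x 1 x 1")
    if pixel_pitch <= 0 or frame_interval <= 0:
        raise ValueError("pixel_pitch and frame_interval must be positive")

    act = true_activation_map(gt, (h, w), pixel_pitch)
    record_span = (t_frames - 1) * frame_interval
    # the last beat must fully traverse the field and repolarise on record;
    # the template footprint is rise_time + CUTOFF_FACTOR * duration80
    needed = (first_onset + (gt.n_beats - 1) * gt.pacing_period + act.max()
              + rise_time + CUTOFF_FACTOR * gt.duration80)
    if needed > record_span:
        raise ValueError(
            f"wave cannot traverse the field within the recording: needs "
            f"{needed:.0f} ms, recording spans {record_span:.0f} ms"
        )

    times = np.arange(t_frames) * frame_interval
    signal = np.zeros((t_frames, h, w))
    rel0 = times[:, None, None] - first_onset - act[None, :, :]
    for beat in range(gt.n_beats):
        signal += transient_template(rel0 - beat * gt.pacing_period, gt.duration80, rise_time, power)

    data = baseline_offset + amplitude * signal
    if drift_tau is not None:
        data = data * np.exp(-times / drift_tau)[:, None, None]
    if math.isfinite(gt.snr):
        rng = np.random.default_rng(gt.seed)
        data = data + rng.normal(0.0, amplitude / gt.snr, size=data.shape)

    meta = {
        "synthetic": True,
        "first_onset_ms": first_onset,
        "rise_time_ms": rise_time,
        "template_power": power,
        "baseline_offset": baseline_offset,
        "amplitude": amplitude,
        "drift_tau_ms": drift_tau,
    }
    stack = MovieStack(data, frame_interval, pixel_pitch, channel=channel, meta=meta)
    return stack, gt


def gen_voltage_movie(
    gt: WaveGroundTruth,
    shape: tuple[int, int, int],
    frame_interval: float = 10.0 / 3.0,
    pixel_pitch: float = 0.05,
    first_onset: float = 50.0,
    baseline_offset: float = 100.0,
    amplitude: float = 1000.0,
    drift_tau: float | None = None,
) -> tuple[MovieStack, WaveGroundTruth]:
    """Generate a voltage-channel movie (300 fps default, fast AP upstroke).

    Per-pixel traces are the AP template delayed by the wavefront arrival
    time implied by ``gt.cv`` and the geometry, with additive Gaussian noise
    at ``gt.snr`` and optional multiplicative photobleaching drift
    (``exp(-t/drift_tau)``). Returns the movie and the echoed ground truth.
    """
    return _gen_wave_movie(
        gt, shape, frame_interval, pixel_pitch, "voltage",
        AP_RISE_MS, AP_POWER, first_onset, baseline_offset, amplitude, drift_tau,
    )


def gen_calcium_movie(
    gt: WaveGroundTruth,
    shape: tuple[int, int, int],
    frame_interval: float = 5.0,
    pixel_pitch: float = 0.05,
    first_onset: float = 50.0,
    baseline_offset: float = 100.0,
    amplitude: float = 1000.0,
    drift_tau: float | None = None,
) -> tuple[MovieStack, WaveGroundTruth]:
    """Generate a calcium-channel movie (200 fps default, slow transient)."""
    return _gen_wave_movie(
        gt, shape, frame_interval, pixel_pitch, "calcium",
        CT_RISE_MS, CT_POWER, first_onset, baseline_offset, amplitude, drift_tau,
    )


def n_frames_for(
    gt: WaveGroundTruth,
    frame_shape: tuple[int, int],
    frame_interval: float,
    pixel_pitch: float,
    first_onset: float = 50.0,
    tail_ms: float = 150.0,
) -> int:
    """Smallest frame count that holds all beats, traversal and repolarisation."""
    act_max = true_activation_map(gt, frame_shape, pixel_pitch).max()
    # CT_RISE_MS bounds the rise time of both templates; the repolarisation
    # footprint extends to CUTOFF_FACTOR * duration80 past the upstroke
    span = (first_onset + (gt.n_beats - 1) * gt.pacing_period + act_max
            + CT_RISE_MS + CUTOFF_FACTOR * gt.duration80 + tail_ms)
    return int(math.ceil(span / frame_interval)) + 1


# ---------------------------------------------------------------------------
# micrographs
# ---------------------------------------------------------------------------

def _place_nuclei(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_sep: float,
    margin: float,
    max_attempts_per_cell: int = 400,
) -> np.ndarray:
    """Place n points with pairwise distance >= min_sep via grid-hashed rejection."""
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image too small for the requested nucleus radius")
    cell = max(min_sep, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = max_attempts_per_cell * n
    while placed < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} non-overlapping nuclei in a {h}x{w} image"
            )
        attempts += 1
        p = rng.uniform([margin, margin], [h - margin, w - margin])
        gi, gj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    if np.hypot(*(pts[k] - p)) < min_sep:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault((gi, gj), []).append(placed)
            placed += 1
    return pts


def _render_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radius: float,
    amplitudes: np.ndarray,
    softness: float = 1.0,
) -> np.ndarray:
    """Sum of soft-edged disks: amplitude inside radius, smooth roll-off."""
    img = np.zeros(shape)
    half = int(math.ceil(radius + 3 * softness))
    for (r, c), a in zip(centers, amplitudes):
        r0, c0 = int(round(r)), int(round(c))
        rlo, rhi = max(0, r0 - half), min(shape[0], r0 + half + 1)
        clo, chi = max(0, c0 - half), min(shape[1], c0 + half + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        d = np.hypot(rr - r, cc - c)
        img[rlo:rhi, clo:chi] += a / (1.0 + np.exp((d - radius) / softness))
    return img


def gen_micrographs(
    gt: MicrographGroundTruth,
    kind: Literal["viability", "expression"],
    shape: tuple[int, int] = (512, 512),
    nucleus_radius: float = 5.0,
    cell_radius: float | None = None,
    dapi_amplitude: float = 200.0,
    pi_amplitude: float = 120.0,
    background_offset: float = 10.0,
    noise_sigma: float = 2.0,
) -> dict:
    """Generate a micrograph channel pair with known ground truth.

    ``kind="viability"`` returns ``{"PI", "DAPI"}``: all nuclei appear in the
    DAPI channel and ``round(dead_fraction * n_cells)`` of them are
    PI-positive. ``kind="expression"`` returns ``{"eYFP", "DAPI"}``: every
    cell contributes a soft disk of mean amplitude ``expression_per_cell``
    (10% cell-to-cell spread) over a uniform autofluorescence floor.

    Returns a dict with the channel images, nucleus ``centers`` and, for
    viability, the index array ``dead_idx``.
    """
    if kind not in ("viability", "expression"):
        raise ValueError(f"unknown micrograph kind {kind!r}")
    rng = np.random.default_rng(gt.seed)
    min_sep = 2.0 * nucleus_radius + 2.0
    centers = _place_nuclei(rng, shape, gt.n_cells, min_sep, margin=min_sep)

    dapi_amp = dapi_amplitude * rng.uniform(0.85, 1.15, gt.n_cells)
    dapi = background_offset + _render_disks(shape, centers, nucleus_radius, dapi_amp)
    dapi += rng.normal(0.0, noise_sigma, shape)

    out: dict = {"DAPI": dapi, "centers": centers, "ground_truth": gt}
    if kind == "viability":
        n_dead = int(round(gt.dead_fraction * gt.n_cells))
        dead_idx = rng.choice(gt.n_cells, size=n_dead, replace=False)
        pi = np.full(shape, background_offset, dtype=float)
        if n_dead:
            pi_amp = pi_amplitude * rng.uniform(0.9, 1.1, n_dead)
            pi += _render_disks(shape, centers[dead_idx], nucleus_radius, pi_amp)
        pi += rng.normal(0.0, noise_sigma, shape)
        out["PI"] = pi
        out["dead_idx"] = np.sort(dead_idx)
    else:
        rad = cell_radius if cell_radius is not None else 2.0 * nucleus_radius
        amps = np.clip(
            rng.normal(gt.expression_per_cell, 0.1 * gt.expression_per_cell, gt.n_cells),
            0.0, None,
        ) if gt.expression_per_cell > 0 else np.zeros(gt.n_cells)
        eyfp = gt.autofluorescence_level + _render_disks(shape, centers, rad, amps)
        eyfp += rng.normal(0.0, noise_sigma, shape)
        out["eYFP"] = eyfp
        out["cell_radius"] = rad
    return out


# ---------------------------------------------------------------------------
# capture oracle
# ---------------------------------------------------------------------------

def lapicque(duration: float | np.ndarray, rheobase: float, chronaxie: float):
    """Lapicque strength-duration law: threshold E = rheobase * (1 + chronaxie/d)."""
    return rheobase * (1.0 + chronaxie / np.asarray(duration, dtype=float))


def gen_capture_oracle(p: OracleParams) -> Callable[[float, float, int], int]:
    """Return ``sample(irradiance, duration_ms, n_pulses) -> captured count``.

    A pulse captures iff ``irradiance >= rheobase * (1 + chronaxie/duration)``.
    Within +/-5% of that boundary each would-be capture independently fails
    with probability ``capture_noise``. Replies are deterministic for a fixed
    seed and fixed query, independent of query order (the noise stream is
    keyed on the query values).
    """

    def sample(irradiance: float, duration_ms: float, n_pulses: int = 10) -> int:
        if irradiance <= 0 or duration_ms <= 0:
            raise ValueError("irradiance and duration must be positive")
        if n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        boundary = p.rheobase * (1.0 + p.chronaxie / duration_ms)
        if irradiance < boundary:
            return 0
        if p.capture_noise > 0 and abs(irradiance - boundary) <= 0.05 * boundary:
            key = np.array([irradiance, duration_ms], dtype=np.float64).view(np.uint64)
            rng = np.random.default_rng(
                np.random.SeedSequence([p.seed, int(key[0]), int(key[1])])
            )
            return int(np.sum(rng.random(n_pulses) >= p.capture_noise))
        return n_pulses

    sample.params = p  # type: ignore[attr-defined]
    return sample
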