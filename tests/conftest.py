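"""Shared fixtures and independent brute-force measurement oracles.

The oracles here deliberately avoid the package's analysis code paths: they
scan raw samples for level crossings directly, so generator ground truth can
be checked without trusting the pipeline under test.
"""

import numpy as np
import pytest

from opticard import synthetic


def bruteforce_duration80(trace, frame_interval, onset_fraction=0.1):
    """Direct threshold-crossing measurement of the first transient.

    Baseline is the trace minimum, amplitude the max-min range. The onset is
    the last upward crossing of ``onset_fraction`` of amplitude before the
    peak, the recovery the first downward crossing of 20% after it; both are
    linearly interpolated between raw samples.
    """
    trace = np.asarray(trace, dtype=float)
    base = trace.min()
    amp = trace.max() - base
    pk = int(np.argmax(trace))
    lvl_on = base + onset_fraction * amp
    lvl_off = base + 0.2 * amp
    t_on = None
    for j in range(pk, 0, -1):
        if trace[j - 1] <= lvl_on <= trace[j]:
            frac = (lvl_on - trace[j - 1]) / (trace[j] - trace[j - 1])
            t_on = (j - 1 + frac) * frame_interval
            break
    t_off = None
    for j in range(pk + 1, trace.size):
        if trace[j - 1] >= lvl_off >= trace[j]:
            frac = (lvl_off - trace[j - 1]) / (trace[j] - trace[j - 1])
            t_off = (j - 1 + frac) * frame_interval
            break
    assert t_on is not None and t_off is not None, "no complete transient found"
    return t_off - t_on


def make_voltage_movie(duration80=260.0, cv=19.1, snr=np.inf, seed=0,
                       frame_shape=(24, 36), n_beats=4, **kwargs):
    gt = synthetic.WaveGroundTruth(cv=cv, duration80=duration80, n_beats=n_beats,
                                   snr=snr, seed=seed)
    fi = 10.0 / 3.0
    shape = (synthetic.n_frames_for(gt, frame_shape, fi, 0.05), *frame_shape)
    return synthetic.gen_voltage_movie(gt, shape, **kwargs)


def make_calcium_movie(duration80=552.0, cv=19.1, snr=np.inf, seed=0,
                       frame_shape=(24, 36), n_beats=4, **kwargs):
    gt = synthetic.WaveGroundTruth(cv=cv, duration80=duration80, n_beats=n_beats,
                                   snr=snr, seed=seed)
    shape = (synthetic.n_frames_for(gt, frame_shape, 5.0, 0.05), *frame_shape)
    return synthetic.gen_calcium_movie(gt, shape, **kwargs)


@pytest.fixture(scope="session")
def voltage_movie_clean():
    """Noise-free 4-beat planar voltage movie, APD80 = 260 ms, CV = 19.1 cm/s."""
    movie, _ = make_voltage_movie()
    return movie


@pytest.fixture(scope="session")
def calcium_movie_clean():
    """Noise-free 4-beat planar calcium movie, CTD80 = 552 ms."""
    movie, _ = make_calcium_movie()
    return movie
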