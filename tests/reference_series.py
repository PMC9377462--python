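"""Deterministic generator for the 100 reference time series.

The frozen expected values in ``tests/data/catch22_reference.csv`` were
produced by running the published reference implementation of the 22
canonical time-series characteristics on exactly these series (see
``scripts/make_catch22_reference.py``).  The series are regenerated
programmatically here so no raw data needs to be stored.
"""

from __future__ import annotations

import numpy as np

N_SERIES = 100


def reference_series(i: int) -> np.ndarray:
    """Series ``i`` of the reference suite: length 50-500, continuous-valued."""
    rng = np.random.RandomState(1000 + i)
    n = rng.randint(50, 501)
    kind = i % 4
    if kind == 0:  # white noise at arbitrary scale/offset
        return rng.randn(n) * rng.uniform(0.5, 30) + rng.uniform(-100, 100)
    if kind == 1:  # smooth mean-reverting process
        y = np.empty(n)
        y[0] = rng.randn()
        for t in range(1, n):
            y[t] = 0.9 * y[t - 1] + rng.randn()
        return y * 3 + 70
    if kind == 2:  # oscillation plus noise (heart-rate-like)
        t = np.arange(n)
        period = rng.uniform(10, 40)
        return 70 + 8 * np.sin(2 * np.pi * t / period) + rng.randn(n) * 2
    # spiky positive-skew series
    return rng.exponential(1.0, n) + 60
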