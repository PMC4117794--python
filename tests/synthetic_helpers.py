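"""Shared synthetic-signal builders for the detector tests."""
import numpy as np

from g4pull.trace_synthesis import ExtensionTrace


def make_trace(extension, rate=200.0, force=5.0):
    n = len(extension)
    return ExtensionTrace(
        time=np.arange(n) / rate,
        extension=np.asarray(extension, dtype=float),
        force=np.full(n, force),
        sampling_rate=rate,
    )


def two_state_trace(rng, dwell_lo=2.0, dwell_hi=6.0, total=100.0, step=6.0,
                    sigma=2.0, rate=200.0):
    """Alternating two-level trace with uniform dwell lengths.

    Returns (trace, interior transition times, true folded path).
    """
    t, lev, state = 0.0, [], False
    bounds = [0.0]
    while t < total:
        d = rng.uniform(dwell_lo, dwell_hi)
        t += d
        bounds.append(min(t, total))
        lev.append(state)
        state = not state
    x = np.empty(int(total * rate))
    path = np.empty(len(x), dtype=bool)
    for a, b, s in zip(bounds[:-1], bounds[1:], lev):
        i, j = int(a * rate), int(b * rate)
        x[i:j] = 0.0 if not s else -step
        path[i:j] = s
    x += rng.normal(0, sigma, len(x))
    return make_trace(x, rate), np.array(bounds[1:-1]), path
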