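"""Per-sample inner loops (hold/decay envelope tracker, gain slew limiter).

Compiled with numba when available; a pure-numpy fallback keeps the package
functional (if slower) without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _track_envelope_loop(amps, hold_samples, decay_per_sample):
    n_ch, n = amps.shape
    out = np.empty_like(amps)
    held = np.zeros(n_ch)
    timer = np.zeros(n_ch, dtype=np.int64)
    for j in range(n_ch):
        held[j] = amps[j, 0]
        timer[j] = hold_samples
        out[j, 0] = held[j]
    for i in range(1, n):
        for j in range(n_ch):
            a = amps[j, i]
            if a >= held[j]:
                # a new local maximum restarts the hold; onsets pass instantly
                held[j] = a
                timer[j] = hold_samples
            elif timer[j] > 0:
                timer[j] -= 1
            else:
                d = held[j] * decay_per_sample
                held[j] = d if d > a else a
            out[j, i] = held[j]
    return out


@njit(cache=False)
def _gammatone_cascade_loop(x, poles, coeffs):
    n_ch = poles.size
    n = x.size
    out = np.empty((n_ch, n), dtype=np.complex128)
    for j in range(n_ch):
        p = poles[j]
        c = coeffs[j]
        s1 = 0.0 + 0.0j
        s2 = 0.0 + 0.0j
        s3 = 0.0 + 0.0j
        s4 = 0.0 + 0.0j
        for i in range(n):
            s1 = x[i] + p * s1
            s2 = s1 + p * s2
            s3 = s2 + p * s3
            s4 = s3 + p * s4
            out[j, i] = c * s4
    return out


def gammatone_cascade(x: np.ndarray, poles: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """All channels of the 4-stage one-pole cascade in one pass."""
    x = np.ascontiguousarray(x, dtype=float)
    if _HAVE_NUMBA:
        return _gammatone_cascade_loop(
            x, np.ascontiguousarray(poles), np.ascontiguousarray(coeffs)
        )
    from scipy.signal import lfilter

    out = np.empty((poles.size, x.size), dtype=complex)
    xc = x.astype(complex)
    for j, (p, c) in enumerate(zip(poles, coeffs)):
        den = np.array([1.0, -4 * p, 6 * p * p, -4 * p ** 3, p ** 4], dtype=complex)
        out[j] = c * lfilter(np.array([1.0 + 0j]), den, xc)
    return out


@njit(cache=False)
def _slew_limit_loop(target, max_step):
    n_ch, n = target.shape
    out = np.empty_like(target)
    for j in range(n_ch):
        g = target[j, 0]
        out[j, 0] = g
        s = max_step[j]
        for i in range(1, n):
            d = target[j, i] - g
            if d > s:
                d = s
            elif d < -s:
                d = -s
            g += d
            out[j, i] = g
    return out


def track_envelope_amplitudes(
    amps: np.ndarray, hold_samples: int, decay_per_sample: float
) -> np.ndarray:
    """Run the hold/decay automaton on per-channel instantaneous amplitudes."""
    amps = np.ascontiguousarray(amps, dtype=float)
    return _track_envelope_loop(amps, hold_samples, decay_per_sample)


def slew_limit(target_db: np.ndarray, max_step_db: np.ndarray) -> np.ndarray:
    """Clip per-sample changes of each row of ``target_db`` to ``max_step_db``."""
    target_db = np.ascontiguousarray(target_db, dtype=float)
    max_step_db = np.ascontiguousarray(max_step_db, dtype=float)
    return _slew_limit_loop(target_db, max_step_db)
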