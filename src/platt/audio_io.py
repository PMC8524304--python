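"""Calibrated mono WAV input/output.

Audio is held in memory as float64 in [-1, 1]; the calibration convention is
that a full-scale sine corresponds to ``calibration_dbspl_fs`` (default 120)
dB SPL.  PCM16/24/32 and float32/64 files are read; float32 (default) or
PCM16 are written, preserving the sample rate.
"""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav"]

_INT_SCALE = {
    np.dtype(np.int16): 2.0 ** 15,
    np.dtype(np.int32): 2.0 ** 31,  # scipy loads 24-bit PCM into int32
    np.dtype(np.uint8): 2.0 ** 7,
}


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file as (mono float64 samples in [-1, 1], sample rate)."""
    fs, data = wavfile.read(path)
    x = np.asarray(data)
    if x.ndim == 2:  # average channels down to mono
        x = x.mean(axis=1)
    if x.dtype in _INT_SCALE:
        scale = _INT_SCALE[x.dtype]
        if data.dtype == np.uint8:
            x = x - 128.0
        x = x / scale
    return x.astype(float), int(fs)


def write_wav(path, samples: np.ndarray, sample_rate_hz: int,
              subtype: str = "float32") -> None:
    """Write mono samples; ``subtype`` is ``float32`` or ``pcm16``."""
    x = np.asarray(samples, dtype=float)
    if subtype == "float32":
        wavfile.write(path, int(sample_rate_hz), x.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(x, -1.0, 1.0 - 2.0 ** -15)
        wavfile.write(path, int(sample_rate_hz),
                      np.round(clipped * 2.0 ** 15).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
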