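"""Spectro-temporal representation: hold/decay envelope, dB SPL, threshold floor.

Each channel's instantaneous amplitude (magnitude of the complex band signal)
is tracked by a hold/decay automaton: every new local maximum is held for
15 ms and then decays at 1 dB/ms until overtaken by the current amplitude.
This removes the temporal fine structure while preserving onsets
instantaneously, and guarantees that downsampling to 1 kHz misses no local
maximum.  Levels are expressed in dB SPL via the session calibration (a
full-scale sine is 120 dB SPL by default) and floored at the normal-hearing
threshold, interpolated from the ISO 226:2003 threshold-of-hearing contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import track_envelope_amplitudes
from .filterbank import FilterbankSpec

__all__ = [
    "CALIBRATION_DBSPL_FS",
    "EnvelopeTrack",
    "track_envelope",
    "to_db_spl",
    "normal_hearing_threshold",
    "apply_hearing_floor",
    "downsample_to_1khz",
    "envelope_track",
]

#: Default calibration: a full-scale (amplitude 1.0) sine is 120 dB SPL.
CALIBRATION_DBSPL_FS = 120.0

HOLD_MS = 15.0
DECAY_DB_PER_MS = 1.0
FRAME_RATE_HZ = 1000.0

# ISO 226:2003 threshold of hearing (free field, frontal incidence):
# frequency in Hz -> threshold in dB SPL.
_ISO226_THRESHOLD = np.array([
    (20.0, 78.5), (25.0, 68.7), (31.5, 59.5), (40.0, 51.1), (50.0, 44.0),
    (63.0, 37.5), (80.0, 31.5), (100.0, 26.5), (125.0, 22.1), (160.0, 17.9),
    (200.0, 14.4), (250.0, 11.4), (315.0, 8.6), (400.0, 6.2), (500.0, 4.4),
    (630.0, 3.0), (800.0, 2.2), (1000.0, 2.4), (1250.0, 3.5), (1600.0, 1.7),
    (2000.0, -1.3), (2500.0, -4.2), (3150.0, -6.0), (4000.0, -5.4),
    (5000.0, -1.5), (6300.0, 6.0), (8000.0, 12.6), (10000.0, 13.9),
    (12500.0, 12.3),
])


@dataclass
class EnvelopeTrack:
    """The internal spectro-temporal representation at the 1 kHz update rate."""

    levels_db_spl: np.ndarray      # (n_frames, n_channels)
    channel_freqs_hz: np.ndarray   # (n_channels,)
    frame_rate_hz: float = FRAME_RATE_HZ

    @property
    def n_frames(self) -> int:
        return self.levels_db_spl.shape[0]

    def to_csv(self, path) -> None:
        """Export as CSV with channel center frequencies as the header row."""
        import pandas as pd

        pd.DataFrame(
            self.levels_db_spl,
            columns=[f"{f:.0f}" for f in self.channel_freqs_hz],
        ).to_csv(path, index=False)


def track_envelope(bands: np.ndarray, spec: FilterbankSpec) -> np.ndarray:
    """Hold/decay-track the instantaneous amplitude of each band at audio rate.

    Returns an array shaped like ``bands`` (channels x samples) of tracked
    amplitudes (linear).
    """
    amps = np.abs(np.asarray(bands))
    if amps.size == 0:
        return amps.astype(float)
    fs = spec.sample_rate_hz
    hold_samples = int(round(HOLD_MS * fs / 1000.0))
    decay = 10.0 ** (-(DECAY_DB_PER_MS * 1000.0 / fs) / 20.0)
    return track_envelope_amplitudes(amps, hold_samples, decay)


def to_db_spl(
    amplitudes: np.ndarray, calibration_dbspl_fs: float = CALIBRATION_DBSPL_FS
) -> np.ndarray:
    """Convert linear amplitudes to dB SPL under the sine calibration.

    A tone of amplitude ``a`` reads ``calibration + 20*log10(a)``; zero or
    negative amplitudes map to −inf (they are floored later).
    """
    a = np.asarray(amplitudes, dtype=float)
    with np.errstate(divide="ignore"):
        return calibration_dbspl_fs + 20.0 * np.log10(np.maximum(a, 0.0))


def normal_hearing_threshold(freqs_hz: np.ndarray) -> np.ndarray:
    """ISO 226:2003 hearing threshold interpolated on a log-frequency axis.

    Frequencies outside the tabulated 20 Hz–12.5 kHz range clamp to the
    nearest table entry.
    """
    f = np.clip(np.asarray(freqs_hz, dtype=float),
                _ISO226_THRESHOLD[0, 0], _ISO226_THRESHOLD[-1, 0])
    return np.interp(
        np.log10(f), np.log10(_ISO226_THRESHOLD[:, 0]), _ISO226_THRESHOLD[:, 1]
    )


def apply_hearing_floor(
    levels_db_spl: np.ndarray, channel_freqs_hz: np.ndarray
) -> np.ndarray:
    """Replace values below the normal-hearing threshold by the threshold.

    ``levels_db_spl`` may be (channels x frames) or (frames x channels); the
    axis matching ``channel_freqs_hz`` is floored.
    """
    lv = np.asarray(levels_db_spl, dtype=float)
    thr = normal_hearing_threshold(channel_freqs_hz)
    if lv.ndim == 1 or lv.shape[0] == thr.size:
        return np.maximum(lv, thr[..., None] if lv.ndim == 2 else thr)
    return np.maximum(lv, thr[None, :])


def downsample_to_1khz(
    tracked: np.ndarray, spec: FilterbankSpec
) -> np.ndarray:
    """Decimate audio-rate tracked amplitudes to the 1 kHz frame rate.

    Because every local maximum is held for 15 ms >> 1 ms, plain decimation
    (every ``fs/1000``-th sample) loses no held maximum.  Sample rates that
    are not integer multiples of 1 kHz are handled by nearest-sample picking.
    """
    tracked = np.asarray(tracked)
    fs = spec.sample_rate_hz
    n = tracked.shape[-1]
    step = fs / FRAME_RATE_HZ
    if abs(step - round(step)) < 1e-9:
        idx = np.arange(0, n, int(round(step)))
    else:
        idx = np.round(np.arange(0, n - 0.5, step)).astype(int)
        idx = idx[idx < n]
    return tracked[..., idx]


def envelope_track(
    bands: np.ndarray,
    spec: FilterbankSpec,
    calibration_dbspl_fs: float = CALIBRATION_DBSPL_FS,
) -> EnvelopeTrack:
    """Full representation chain: track, downsample, dB SPL, threshold floor."""
    tracked = track_envelope(bands, spec)
    frames = downsample_to_1khz(tracked, spec)
    levels = to_db_spl(frames, calibration_dbspl_fs)
    levels = apply_hearing_floor(levels, spec.center_freqs_hz)
    return EnvelopeTrack(
        levels_db_spl=levels.T, channel_freqs_hz=spec.center_freqs_hz
    )
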