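"""Log-Mel feature front end and class-A/class-D hearing-loss manipulations.

The recognition harness works on a 36-channel log Mel-spectrogram (25 ms Hann
windows, 10 ms shift, triangular Mel filters spanning 64–16000 Hz) calibrated
so a tone at a channel center reads its dB SPL level.  Impaired hearing is
simulated by removing information from this representation:

* class A (attenuation) — values below an absolute-threshold audiogram are
  replaced by the threshold (compensable by amplification);
* class D (distortion) — an upper frequency limit removes channels, and a
  *level uncertainty* adds i.i.d. Gaussian noise (SD in dB) to every
  time–frequency value.  Both act in the log domain, so linear amplification
  shifts all values equally and cannot undo them.

Listener profiles combine an upper frequency limit (1, 2, 4 or 8 kHz) with a
level uncertainty (1, 7, 14 or 21 dB), named ``P-<flim>-<u>``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .envelope import CALIBRATION_DBSPL_FS

__all__ = [
    "N_MEL_CHANNELS",
    "LogMelSpectrogram",
    "ListenerProfile",
    "mel_center_freqs_hz",
    "log_mel_spectrogram",
    "apply_level_uncertainty",
    "apply_frequency_limit",
    "apply_absolute_threshold",
    "apply_profile",
]

N_MEL_CHANNELS = 36
WINDOW_MS = 25.0
SHIFT_MS = 10.0
MEL_FMIN_HZ = 64.0
MEL_FMAX_HZ = 16000.0


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_band_edges(n_channels: int = N_MEL_CHANNELS) -> np.ndarray:
    """n_channels + 2 edge frequencies, Mel-equidistant over 64–16000 Hz."""
    m = np.linspace(_hz_to_mel(MEL_FMIN_HZ), _hz_to_mel(MEL_FMAX_HZ),
                    n_channels + 2)
    return _mel_to_hz(m)


def mel_center_freqs_hz(n_channels: int = N_MEL_CHANNELS) -> np.ndarray:
    """Center frequencies of the triangular Mel channels."""
    return _mel_band_edges(n_channels)[1:-1]


@dataclass(frozen=True)
class LogMelSpectrogram:
    values_db: np.ndarray         # (n_frames, n_channels)
    channel_freqs_hz: np.ndarray  # (n_channels,)
    window_ms: float = WINDOW_MS
    shift_ms: float = SHIFT_MS

    @property
    def n_frames(self) -> int:
        return self.values_db.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values_db.shape[1]

    def frame_times_s(self) -> np.ndarray:
        """Window-center times of the frames in seconds."""
        return (np.arange(self.n_frames) * self.shift_ms
                + self.window_ms / 2.0) / 1000.0

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.values_db,
            columns=[f"{f:.0f}" for f in self.channel_freqs_hz],
        ).to_csv(path, index=False)


def log_mel_spectrogram(
    audio: np.ndarray,
    sample_rate_hz: float,
    calibration_dbspl_fs: float = CALIBRATION_DBSPL_FS,
) -> LogMelSpectrogram:
    """36-channel log Mel-spectrogram, 25 ms Hann window, 10 ms shift.

    The scale is anchored to the sine calibration: a tone at a channel center
    with level L dB SPL reads approximately L in that channel.  Amplifying
    the audio by G dB shifts all values by exactly G.
    """
    x = np.asarray(audio, dtype=float)
    fs = float(sample_rate_hz)
    win = int(round(WINDOW_MS * fs / 1000.0))
    hop = int(round(SHIFT_MS * fs / 1000.0))
    if x.size < win:
        raise ValueError("signal shorter than one analysis window")
    n_frames = (x.size - win) // hop + 1
    w = np.hanning(win)
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * w[None, :]
    spec = np.fft.rfft(frames, axis=1)
    # mean-square-calibrated power: a sine of amplitude A at a bin center
    # contributes A^2/2, i.e. its mean-square value
    power = 2.0 * np.abs(spec) ** 2 / w.sum() ** 2

    edges = _mel_band_edges()
    fft_freqs = np.fft.rfftfreq(win, 1.0 / fs)
    fb = np.zeros((N_MEL_CHANNELS, fft_freqs.size))
    for i in range(N_MEL_CHANNELS):
        lo, cf, hi = edges[i], edges[i + 1], edges[i + 2]
        rise = (fft_freqs - lo) / (cf - lo)
        fall = (hi - fft_freqs) / (hi - cf)
        fb[i] = np.clip(np.minimum(rise, fall), 0.0, None)
    mel_power = power @ fb.T
    # offset so that mean-square power 0.5 (a full-scale sine) reads the
    # full-scale calibration level
    offset = calibration_dbspl_fs - 10.0 * np.log10(0.5)
    with np.errstate(divide="ignore"):
        values = 10.0 * np.log10(np.maximum(mel_power, 1e-300)) + offset
    return LogMelSpectrogram(
        values_db=values, channel_freqs_hz=mel_center_freqs_hz()
    )


def apply_level_uncertainty(
    lms: LogMelSpectrogram, u_db: float, seed
) -> LogMelSpectrogram:
    """Add i.i.d. Gaussian noise with SD ``u_db`` to every value (class D).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the same seed
    reproduces the same noise.
    """
    if u_db < 0:
        raise ValueError("level uncertainty must be >= 0")
    if u_db == 0:
        return lms
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, u_db, size=lms.values_db.shape)
    return replace(lms, values_db=lms.values_db + noise)


def apply_frequency_limit(
    lms: LogMelSpectrogram, limit_freq_hz: float
) -> LogMelSpectrogram:
    """Remove channels whose center frequency exceeds the limit (class D)."""
    keep = lms.channel_freqs_hz <= limit_freq_hz
    if not np.any(keep):
        raise ValueError(
            f"frequency limit {limit_freq_hz} Hz is below the lowest channel"
        )
    return replace(
        lms,
        values_db=lms.values_db[:, keep],
        channel_freqs_hz=lms.channel_freqs_hz[keep],
    )


def apply_absolute_threshold(
    lms: LogMelSpectrogram, audiogram_db: np.ndarray
) -> LogMelSpectrogram:
    """Floor every value at a per-channel absolute threshold (class A)."""
    thr = np.asarray(audiogram_db, dtype=float)
    return replace(lms, values_db=np.maximum(lms.values_db, thr[None, :]))


@dataclass(frozen=True)
class ListenerProfile:
    """Class-D listener profile ``P-<limit_freq>-<level_uncertainty>``."""

    limit_freq_hz: float = 8000.0
    level_uncertainty_db: float = 1.0
    audiogram_db: np.ndarray | None = None

    @property
    def name(self) -> str:
        return f"P-{self.limit_freq_hz:.0f}-{self.level_uncertainty_db:.0f}"

    @classmethod
    def from_name(cls, name: str) -> "ListenerProfile":
        parts = name.split("-")
        if len(parts) != 3 or parts[0] != "P":
            raise ValueError(f"profile name {name!r} is not of the form P-<f>-<u>")
        return cls(limit_freq_hz=float(parts[1]),
                   level_uncertainty_db=float(parts[2]))


def apply_profile(
    lms: LogMelSpectrogram, profile: ListenerProfile, seed
) -> LogMelSpectrogram:
    """Apply a listener profile: frequency limit, threshold, then uncertainty."""
    out = apply_frequency_limit(lms, profile.limit_freq_hz)
    if profile.audiogram_db is not None:
        keep = lms.channel_freqs_hz <= profile.limit_freq_hz
        out = apply_absolute_threshold(out, np.asarray(profile.audiogram_db)[keep])
    return apply_level_uncertainty(out, profile.level_uncertainty_db, seed)
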