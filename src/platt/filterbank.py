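"""Half-ERB-spaced complex Gammatone filterbank: design, analysis, resynthesis.

The frequency decomposition uses 78 complex fourth-order Gammatone filters
whose center frequencies lie on a Mel-spaced grid covering 123–13943 Hz at
roughly 0.5 ERB spacing.  Each filter is a cascade of four identical
first-order complex one-pole sections followed by a single complex
feed-forward (FIR) coefficient.  The −10 dB bandwidth of a filter equals the
difference of the grid frequencies two positions to the right and left of its
center, the peak gain is normalized to 2, and the FIR phases are chosen so
that neighboring filters agree in phase at the delay where the product of
their temporal envelopes peaks.  Those three choices together give a nearly
flat summed ("joint") frequency response, so that summing the real parts of
all band signals resynthesizes the input almost transparently.

Time-varying per-channel gains can be applied before summation; their rate of
change is limited to 24 dB per period of the channel's center frequency to
limit cross-channel modulation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GRID_FREQS_HZ",
    "GammatoneChannel",
    "FilterbankSpec",
    "JointResponse",
    "frequency_grid",
    "design_filterbank",
    "analyze",
    "slew_limited_gains",
    "resynthesize",
    "joint_response",
]

#: The 78 + 4 grid frequencies in Hz (Mel-equidistant at half the usual MFCC
#: spacing, spanning 64 Hz to 15080 Hz).  The first/last two values only serve
#: the bandwidth rule; channels are built for grid indices 2..79.
GRID_FREQS_HZ: tuple[int, ...] = (
    64, 93, 123, 155, 187, 221, 256, 293, 330, 370, 410, 453, 496, 542, 589,
    638, 689, 742, 797, 854, 914, 975, 1039, 1105, 1174, 1245, 1319, 1396,
    1476, 1559, 1645, 1734, 1827, 1923, 2023, 2127, 2235, 2346, 2462, 2583,
    2708, 2838, 2972, 3112, 3257, 3408, 3565, 3727, 3896, 4071, 4253, 4441,
    4637, 4840, 5051, 5270, 5498, 5734, 5979, 6233, 6497, 6771, 7056, 7352,
    7658, 7977, 8307, 8650, 9006, 9376, 9760, 10158, 10572, 11001, 11447,
    11909, 12390, 12888, 13406, 13943, 14501, 15080,
)

N_CHANNELS = 78
FILTER_ORDER = 4
PEAK_GAIN = 2.0
SLEW_DB_PER_PERIOD = 24.0

# -10 dB amplitude ratio expressed per first-order stage of the 4-stage
# cascade: |H1_edge/H1_peak|^4 = 10^(-10/20)  =>  power ratio per stage.
_Q_EDGE = 10.0 ** 0.25


def frequency_grid() -> list[int]:
    """Return the 82-value center-frequency grid in Hz as printed constants."""
    return list(GRID_FREQS_HZ)


@dataclass(frozen=True)
class GammatoneChannel:
    """One complex fourth-order Gammatone filter.

    The transfer function is ``fir_coeff / (1 - pole * z**-1)**4``: four
    identical complex one-pole stages and one complex feed-forward
    coefficient that sets peak gain (2) and phase.
    """

    center_freq_hz: float
    bandwidth_10db_hz: float
    pole: complex
    fir_coeff: complex
    order: int = FILTER_ORDER

    def impulse_response(self, n_samples: int) -> np.ndarray:
        """Analytic impulse response ``c * C(n+3,3) * p**n`` (complex)."""
        n = np.arange(n_samples)
        binom = (n + 1.0) * (n + 2.0) * (n + 3.0) / 6.0
        return self.fir_coeff * binom * self.pole ** n

    def envelope(self, n_samples: int) -> np.ndarray:
        """Temporal envelope (magnitude) of the impulse response."""
        return np.abs(self.impulse_response(n_samples))


@dataclass(frozen=True)
class FilterbankSpec:
    sample_rate_hz: float
    grid_freqs_hz: tuple[int, ...]
    channels: tuple[GammatoneChannel, ...]
    #: fixed scalar applied after summation so the joint analysis–resynthesis
    #: path has unity gain over its flat region
    resynth_scale: float = 1.0
    # cached coefficient arrays for vectorized processing
    _poles: np.ndarray = field(repr=False, default=None)
    _coeffs: np.ndarray = field(repr=False, default=None)

    @property
    def center_freqs_hz(self) -> np.ndarray:
        return np.array([ch.center_freq_hz for ch in self.channels])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_index(self, freq_hz: float) -> int:
        """Index of the channel whose center frequency is nearest ``freq_hz``."""
        return int(np.argmin(np.abs(self.center_freqs_hz - freq_hz)))


def _edge_offset_rad(r: float) -> float:
    """Angular offset from center where the 4th-order response is −10 dB."""
    cos_d = (1.0 + r * r - _Q_EDGE * (1.0 - r) ** 2) / (2.0 * r)
    return float(np.arccos(np.clip(cos_d, -1.0, 1.0)))


def _measured_bw10_hz(r: float, fs: float) -> float:
    # the one-pole cascade's magnitude is symmetric about the pole angle, so
    # the -10 dB bandwidth is twice the edge offset
    return _edge_offset_rad(r) * fs / np.pi


def pole_magnitude_for_bandwidth(bw_hz: float, sample_rate_hz: float) -> float:
    """Numerically solve the pole radius for a given −10 dB bandwidth.

    The printed closed form for the pole is garbled in the source material;
    the bandwidth condition itself is unambiguous, so the radius is obtained
    by a root solve of ``measured_bw10(r) == bw_hz``.
    """
    return float(
        brentq(
            lambda r: _measured_bw10_hz(r, sample_rate_hz) - bw_hz,
            1e-9,
            1.0 - 1e-12,
            xtol=1e-15,
        )
    )


def design_filterbank(sample_rate_hz: float = 48000.0) -> FilterbankSpec:
    """Design the 78-channel filterbank for a given sample rate.

    Raises
    ------
    ValueError
        If the sample rate cannot represent the top grid frequency
        (requires ``sample_rate_hz >= 2 * 15080``).
    """
    fs = float(sample_rate_hz)
    if fs < 2.0 * GRID_FREQS_HZ[-1]:
        raise ValueError(
            f"sample rate {fs} Hz is below the Nyquist bound "
            f"{2 * GRID_FREQS_HZ[-1]} Hz for the top grid frequency"
        )
    grid = GRID_FREQS_HZ
    centers = np.array(grid[2:2 + N_CHANNELS], dtype=float)
    bws = np.array(
        [grid[i + 2] - grid[i - 2] for i in range(2, 2 + N_CHANNELS)],
        dtype=float,
    )
    radii = np.array([pole_magnitude_for_bandwidth(b, fs) for b in bws])
    phases = 2.0 * np.pi * centers / fs
    poles = radii * np.exp(1j * phases)
    # peak gain of the cascade at the pole angle is 1/(1-r)^4
    coeff_mags = PEAK_GAIN * (1.0 - radii) ** FILTER_ORDER

    # FIR phase: align each neighboring pair at the delay where the product of
    # their temporal envelopes peaks; propagate from the lowest channel (phase
    # 0) upward, which makes the solution unique.
    n_env = int(round(0.100 * fs))
    n = np.arange(n_env)
    binom = (n + 1.0) * (n + 2.0) * (n + 3.0) / 6.0
    envs = coeff_mags[:, None] * binom[None, :] * radii[:, None] ** n[None, :]
    coeff_args = np.zeros(N_CHANNELS)
    for k in range(N_CHANNELS - 1):
        n_star = int(np.argmax(envs[k] * envs[k + 1]))
        coeff_args[k + 1] = coeff_args[k] + n_star * (phases[k] - phases[k + 1])
    coeffs = coeff_mags * np.exp(1j * coeff_args)

    channels = tuple(
        GammatoneChannel(
            center_freq_hz=float(centers[i]),
            bandwidth_10db_hz=float(bws[i]),
            pole=complex(poles[i]),
            fir_coeff=complex(coeffs[i]),
        )
        for i in range(N_CHANNELS)
    )
    # The phase-aligned sum of all channels is spectrally flat but not unity
    # (overlapping peak-gain-2 filters add up); a single scalar restores the
    # calibration of the resynthesized signal.
    irs = coeffs[:, None] * binom[None, :] * poles[:, None] ** n[None, :]
    summed = irs.real.sum(axis=0)
    nfft = 1 << 16
    mag = np.abs(np.fft.rfft(summed, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = (freqs >= 200.0) & (freqs <= 12000.0)
    joint_gain = float(np.exp(np.mean(np.log(mag[band]))))

    return FilterbankSpec(
        sample_rate_hz=fs,
        grid_freqs_hz=grid,
        channels=channels,
        resynth_scale=1.0 / joint_gain,
        _poles=poles,
        _coeffs=coeffs,
    )


def analyze(signal: np.ndarray, spec: FilterbankSpec) -> np.ndarray:
    """Run the analysis filterbank.

    Parameters
    ----------
    signal : real array of samples at ``spec.sample_rate_hz``.
    spec : filterbank design.

    Returns
    -------
    complex array of shape (78, n_samples); the real part of each row is the
    band's contribution to the resynthesized signal.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("analyze expects a mono signal (1-D array)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if x.size == 0:
        return np.empty((spec.n_channels, 0), dtype=complex)
    from ._kernels import gammatone_cascade

    poles = (spec._poles if spec._poles is not None
             else np.array([ch.pole for ch in spec.channels]))
    coeffs = (spec._coeffs if spec._coeffs is not None
              else np.array([ch.fir_coeff for ch in spec.channels]))
    return gammatone_cascade(x, poles, coeffs)


def slew_limited_gains(
    gains_db: np.ndarray, spec: FilterbankSpec, frame_rate_hz: float = 1000.0
) -> np.ndarray:
    """Expand 1 kHz gain trajectories to audio rate with the 24 dB/period slew.

    The frame-rate trajectory is zero-order held to the audio rate, then each
    channel's per-sample change is clipped to ``24 dB * f_c / f_s``, i.e. to
    24 dB per period of the channel's center frequency.  The limiter starts
    from the first commanded value.

    Returns an array of shape (n_channels, n_frames * fs / frame_rate) in dB.
    """
    from ._kernels import slew_limit

    g = np.atleast_2d(np.asarray(gains_db, dtype=float))
    if g.shape[0] != spec.n_channels and g.shape[1] == spec.n_channels:
        g = g.T
    if g.shape[0] != spec.n_channels:
        raise ValueError("gain trajectory channel count does not match spec")
    hop = int(round(spec.sample_rate_hz / frame_rate_hz))
    held = np.repeat(g, hop, axis=1)
    max_step = SLEW_DB_PER_PERIOD * spec.center_freqs_hz / spec.sample_rate_hz
    return slew_limit(held, max_step)


def resynthesize(
    bands: np.ndarray,
    gains_db: np.ndarray | None,
    spec: FilterbankSpec,
    frame_rate_hz: float = 1000.0,
) -> np.ndarray:
    """Sum the real band signals after applying slew-limited gains.

    ``gains_db`` holds one 1 kHz-rate dB trajectory per channel
    (shape (n_channels, n_frames) or (n_frames, n_channels)); ``None`` applies
    0 dB everywhere, which makes analysis + resynthesis an (almost) identity
    within the joint-response ripple.
    """
    bands = np.asarray(bands)
    if bands.shape[0] != spec.n_channels:
        raise ValueError(
            f"expected {spec.n_channels} band rows, got {bands.shape[0]}"
        )
    if gains_db is None:
        return spec.resynth_scale * bands.real.sum(axis=0)
    g = slew_limited_gains(gains_db, spec, frame_rate_hz)
    n = bands.shape[1]
    if g.shape[1] < n:  # pad by holding the final gain
        pad = np.repeat(g[:, -1:], n - g.shape[1], axis=1)
        g = np.concatenate([g, pad], axis=1)
    lin = 10.0 ** (g[:, :n] / 20.0)
    return spec.resynth_scale * (bands.real * lin).sum(axis=0)


@dataclass(frozen=True)
class JointResponse:
    """Magnitude and delay characterization of the summed filterbank."""

    freqs_hz: np.ndarray          # dense frequency axis of magnitude_db
    magnitude_db: np.ndarray      # |H(f)| of the summed real impulse response
    center_freqs_hz: np.ndarray   # 78 channel centers
    delay_ms: np.ndarray          # envelope-peak delay per channel

    def ripple_db(self, f_lo: float = 200.0, f_hi: float = 12000.0) -> float:
        sel = (self.freqs_hz >= f_lo) & (self.freqs_hz <= f_hi)
        m = self.magnitude_db[sel]
        return float(m.max() - m.min())

    def delay_at(self, freq_hz: float) -> float:
        """Envelope-peak delay (ms) of the channel nearest ``freq_hz``."""
        i = int(np.argmin(np.abs(self.center_freqs_hz - freq_hz)))
        return float(self.delay_ms[i])


def joint_response(
    spec: FilterbankSpec, duration_s: float = 0.100, nfft: int = 1 << 18
) -> JointResponse:
    """Characterize the summed analysis–resynthesis path with 0 dB gains.

    The summed real impulse response is a downward frequency sweep; its
    magnitude spectrum quantifies reconstruction flatness, and the
    envelope-peak delay of each channel's impulse response gives the
    frequency-dependent delay of the path.
    """
    fs = spec.sample_rate_hz
    n_ir = int(round(duration_s * fs))
    irs = np.array([ch.impulse_response(n_ir) for ch in spec.channels])
    summed = spec.resynth_scale * irs.real.sum(axis=0)
    mag = np.abs(np.fft.rfft(summed, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    mag_db = 20.0 * np.log10(np.maximum(mag, 1e-300))
    delays = np.abs(irs).argmax(axis=1) / fs * 1000.0
    return JointResponse(
        freqs_hz=freqs,
        magnitude_db=mag_db,
        center_freqs_hz=spec.center_freqs_hz,
        delay_ms=delays,
    )
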