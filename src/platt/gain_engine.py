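"""Adaptive spectral gain: layer decomposition, mapping, expansion, compression.

Each 78-value spectral frame (dB SPL, 1 kHz update rate) is decomposed with
spectral-modulation low-pass filters — Hanning smoothings of widths 8, 16, 32
and 64 channels (FWHM about 2, 4, 8 and 16 ERB at the 0.5 ERB channel
spacing) — into a coarse *base layer* plus four *difference layers* d1..d4
holding successively lower spectral-modulation frequencies.  The base layer
is mapped from the input to the output dynamic range; d1 and d2 (patterns up
to ~4 ERB, the ones assumed most relevant for speech recognition) are added
back unconditionally, d2 optionally expanded by a factor > 1; d3 and then d4
are added conditionally with per-channel factors in [0, 1] chosen so the
output stays inside the output dynamic range, with the strongest compression
propagated to neighboring channels through Hanning tapers (FWHM 6 and 12
channels).  The gain is the difference between the desired output levels and
the input frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import envelope as _env
from . import filterbank as _fb

__all__ = [
    "SMOOTHING_WIDTHS",
    "SpectralFrame",
    "LayerDecomposition",
    "DynamicRangeSpec",
    "ExpansionConfig",
    "smooth_spectrum",
    "decompose_layers",
    "map_base_layer",
    "conditional_factor",
    "propagate_factors",
    "compute_frame_gain",
    "compute_gains",
    "process",
]

SMOOTHING_WIDTHS = (8, 16, 32, 64)
PROPAGATION_FWHM = {3: 6, 4: 12}  # difference index -> taper FWHM in channels


@dataclass(frozen=True)
class SpectralFrame:
    levels_db_spl: np.ndarray  # (78,)
    time_ms: float = 0.0


@dataclass(frozen=True)
class LayerDecomposition:
    """Base layer plus four spectral-modulation difference layers.

    ``base + d4 + d3 + d2 + d1`` reconstructs the input frame exactly (the
    decomposition is telescoping by construction).
    """

    base: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    d4: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.base + self.d4 + self.d3 + self.d2 + self.d1


def _interp_log_freq(freqs_hz, bp_freqs, bp_vals):
    return np.interp(np.log10(freqs_hz), np.log10(bp_freqs), bp_vals)


@dataclass(frozen=True)
class DynamicRangeSpec:
    """Per-channel input and output dynamic-range limits in dB SPL."""

    in_low: np.ndarray
    in_high: np.ndarray
    out_low: np.ndarray
    out_high: np.ndarray

    def __post_init__(self):
        for lo, hi in ((self.in_low, self.in_high),
                       (self.out_low, self.out_high)):
            if not np.all(lo < hi):
                raise ValueError("dynamic-range low limit must be below high")

    @classmethod
    def default_input_range(cls, channel_freqs_hz: np.ndarray):
        """The assumed normal-hearing input range.

        Upper limit: frequency-independent 105 dB SPL (uncomfortable level).
        Lower limit: 25 dB SPL from 500 Hz to 4 kHz, 30 dB SPL below 250 Hz
        and above 8 kHz, interpolated linearly on a log-frequency axis in
        between.
        """
        f = np.asarray(channel_freqs_hz, dtype=float)
        lo = _interp_log_freq(
            f, [20.0, 250.0, 500.0, 4000.0, 8000.0, 20000.0],
            [30.0, 30.0, 25.0, 25.0, 30.0, 30.0],
        )
        return lo, np.full_like(f, 105.0)

    @classmethod
    def transparent(cls, channel_freqs_hz: np.ndarray) -> "DynamicRangeSpec":
        """Output range equal to the input range (minimizes compression)."""
        lo, hi = cls.default_input_range(channel_freqs_hz)
        return cls(in_low=lo, in_high=hi, out_low=lo.copy(), out_high=hi.copy())

    @classmethod
    def with_output_range(
        cls, channel_freqs_hz: np.ndarray, out_low, out_high
    ) -> "DynamicRangeSpec":
        """Default input range with scalar or per-channel output limits."""
        f = np.asarray(channel_freqs_hz, dtype=float)
        lo, hi = cls.default_input_range(f)
        return cls(
            in_low=lo,
            in_high=hi,
            out_low=np.broadcast_to(np.asarray(out_low, float), f.shape).copy(),
            out_high=np.broadcast_to(np.asarray(out_high, float), f.shape).copy(),
        )


@dataclass(frozen=True)
class ExpansionConfig:
    """Expansion factor for difference layer 2 and the base-layer map mode."""

    factor: float = 1.0
    base_map_mode: Literal["linear", "identity"] = "identity"

    def __post_init__(self):
        if self.factor < 1.0:
            raise ValueError("expansion factor must be >= 1")


def _hann_kernel(width: int) -> np.ndarray:
    # symmetric (width+1)-point Hanning, zero at both ends, unit sum;
    # its FWHM is width/2 channels = width/4 ERB at 0.5 ERB spacing
    w = np.hanning(width + 1)
    return w / w.sum()


def smooth_spectrum(frame: np.ndarray, width: int) -> np.ndarray:
    """Convolve a spectral frame with a unit-sum Hanning window.

    Boundaries are handled by symmetric reflection, which avoids spurious
    roll-off of the base layer at the spectrum edges.
    """
    x = np.asarray(frame, dtype=float)
    w = _hann_kernel(width)
    pad = (w.size - 1) // 2
    if x.ndim == 1:
        xp = np.pad(x, pad, mode="reflect")
        return np.convolve(xp, w, mode="valid")
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    from scipy.signal import fftconvolve

    return fftconvolve(xp, w[None, :], mode="valid", axes=1)


def decompose_layers(frame: np.ndarray) -> LayerDecomposition:
    """Split a frame into the base layer and difference layers d1..d4."""
    x = np.asarray(frame, dtype=float)
    s8, s16, s32, s64 = (smooth_spectrum(x, w) for w in SMOOTHING_WIDTHS)
    return LayerDecomposition(
        base=s64, d1=x - s8, d2=s8 - s16, d3=s16 - s32, d4=s32 - s64
    )


def map_base_layer(
    base: np.ndarray, drs: DynamicRangeSpec, mode: str = "linear"
) -> np.ndarray:
    """Map the base layer from the input to the output dynamic range."""
    if mode == "identity":
        return np.asarray(base, dtype=float).copy()
    if mode != "linear":
        raise ValueError(f"unknown base map mode {mode!r}")
    b = np.asarray(base, dtype=float)
    span_in = drs.in_high - drs.in_low
    span_out = drs.out_high - drs.out_low
    return drs.out_low + (b - drs.in_low) / span_in * span_out


def conditional_factor(
    current: np.ndarray, diff: np.ndarray, drs: DynamicRangeSpec
) -> np.ndarray:
    """Largest per-channel factor in [0, 1] keeping ``current + f*diff`` in range.

    A positive difference is limited by the upper output limit, a negative one
    by the lower; zero difference gets factor 1.  A channel already at (or
    beyond) the limit in the difference's direction gets factor 0.
    """
    cur = np.asarray(current, dtype=float)
    d = np.asarray(diff, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_up = np.clip((drs.out_high - cur) / d, 0.0, 1.0)
        f_dn = np.clip((drs.out_low - cur) / d, 0.0, 1.0)
    return np.where(d > 0, f_up, np.where(d < 0, f_dn, 1.0))


def _propagation_taper(fwhm: int) -> np.ndarray:
    # peak-normalized Hanning: w(0)=1, w(+-fwhm/2)=0.5, w(+-fwhm)=0
    d = np.arange(-fwhm, fwhm + 1)
    return 0.5 * (1.0 + np.cos(np.pi * d / fwhm))


def propagate_factors(raw_factors: np.ndarray, fwhm: int) -> np.ndarray:
    """Spread the strongest compression to neighboring channels.

    Every channel's factor is capped by ``raw_k + (1 - w(j - k))`` for all k,
    where w is a peak-normalized Hanning taper of the given FWHM (zero beyond
    ±FWHM channels).  A zero factor therefore caps its neighbors at 0.5 at
    ±FWHM/2 channels and has no effect beyond ±FWHM channels.
    """
    raw = np.asarray(raw_factors, dtype=float)
    w = _propagation_taper(fwhm)
    out = raw.copy()
    n = raw.shape[-1]
    for off, wv in zip(range(-fwhm, fwhm + 1), w):
        if off == 0 or wv <= 0.0:
            continue
        cap = np.empty_like(raw)
        if off > 0:  # cap at j from raw at j-off
            cap[..., off:] = raw[..., :n - off] + (1.0 - wv)
            cap[..., :off] = np.inf
        else:
            cap[..., :n + off] = raw[..., -off:] + (1.0 - wv)
            cap[..., n + off:] = np.inf
        out = np.minimum(out, cap)
    return np.clip(out, 0.0, 1.0)


def compute_frame_gain(
    frame: np.ndarray, drs: DynamicRangeSpec, cfg: ExpansionConfig
) -> np.ndarray:
    """Per-channel gain (dB) for one spectral frame.

    Desired output = mapped base + d1 + factor*d2, then d3 and d4 are added
    conditionally (factors from the remaining output dynamic, compression
    propagated across channels); the gain is desired output minus input.
    """
    x = np.asarray(frame, dtype=float)
    lay = decompose_layers(x)
    out = map_base_layer(lay.base, drs, cfg.base_map_mode)
    out = out + lay.d1 + cfg.factor * lay.d2
    for idx, diff in ((3, lay.d3), (4, lay.d4)):
        f = conditional_factor(out, diff, drs)
        f = propagate_factors(f, PROPAGATION_FWHM[idx])
        out = out + f * diff
    return out - x


def compute_gains(
    track: _env.EnvelopeTrack, drs: DynamicRangeSpec, cfg: ExpansionConfig
) -> np.ndarray:
    """Gain trajectories (n_frames x n_channels) for a whole envelope track."""
    frames = track.levels_db_spl
    lay = decompose_layers(frames)  # smoothing broadcasts over frames
    out = map_base_layer(lay.base, drs, cfg.base_map_mode)
    out = out + lay.d1 + cfg.factor * lay.d2
    for idx, diff in ((3, lay.d3), (4, lay.d4)):
        f = conditional_factor(out, diff, drs)
        f = propagate_factors(f, PROPAGATION_FWHM[idx])
        out = out + f * diff
    return out - frames


def process(
    audio: np.ndarray,
    spec: _fb.FilterbankSpec,
    drs: DynamicRangeSpec | None = None,
    cfg: ExpansionConfig | None = None,
    calibration_dbspl_fs: float = _env.CALIBRATION_DBSPL_FS,
) -> np.ndarray:
    """Full processing chain: analyze, track, per-frame gains, resynthesize.

    With the transparent configuration (identity base map, expansion 1,
    output range equal to the input range) the output equals the plain
    analysis–resynthesis pass-through within the joint-response ripple.
    """
    if drs is None:
        drs = DynamicRangeSpec.transparent(spec.center_freqs_hz)
    if cfg is None:
        cfg = ExpansionConfig()
    bands = _fb.analyze(audio, spec)
    track = _env.envelope_track(bands, spec, calibration_dbspl_fs)
    gains = compute_gains(track, drs, cfg)
    return _fb.resynthesize(bands, gains.T, spec)
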