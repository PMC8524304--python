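"""Seeded generators for calibrated synthetic test signals.

All fixtures used by the evaluation harness are generated here: pure tones,
a stationary speech-shaped noise (standing in for a matrix test's
test-specific masker), a three-band co-modulated fluctuating noise with
pauses capped at 250 ms (standing in for an ICRA-style fluctuating masker),
a synthetic word corpus of formant-glide tokens (standing in for a matrix
test vocabulary), and calibrated SNR mixing.  The maskers emulate the
*properties* that matter for the simulations (long-term speech spectrum;
stationary vs. co-modulated with bounded pauses) — they are synthetic
stand-ins, not reconstructions of the original recordings.

Levels follow the sine calibration of the rest of the package: a full-scale
sine is ``CALIBRATION_DBSPL_FS`` (120) dB SPL, and the level of an arbitrary
signal is ``120 + 20*log10(rms * sqrt(2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import butter, sosfilt

from .envelope import CALIBRATION_DBSPL_FS

__all__ = [
    "MaskerKind",
    "WordCorpus",
    "measure_level_db_spl",
    "set_level_db_spl",
    "pure_tone",
    "speech_shaped_noise",
    "fluctuating_noise",
    "make_masker",
    "synthetic_word_corpus",
    "mix_at_snr",
]

#: Long-term-average-speech-spectrum-like magnitude curve (dB, arbitrary
#: reference): flat plateau 125–500 Hz, −6 dB/octave above 500 Hz, low-cut
#: below 125 Hz.
_LTASS_BREAKPOINTS = (
    (50.0, -8.0), (125.0, 0.0), (500.0, 0.0), (1000.0, -6.0), (2000.0, -12.0),
    (4000.0, -18.0), (8000.0, -24.0), (16000.0, -30.0),
)

_FLUCT_BAND_EDGES_HZ = (800.0, 2400.0)  # three co-modulated bands


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def measure_level_db_spl(x: np.ndarray) -> float:
    """Level of a signal in dB SPL under the full-scale-sine calibration."""
    return CALIBRATION_DBSPL_FS + 20.0 * np.log10(_rms(x) * np.sqrt(2.0))


def set_level_db_spl(x: np.ndarray, level_db_spl: float) -> np.ndarray:
    """Scale a signal to an exact presentation level."""
    target_rms = 10.0 ** ((level_db_spl - CALIBRATION_DBSPL_FS) / 20.0) / np.sqrt(2.0)
    return x * (target_rms / _rms(x))


def pure_tone(
    freq_hz: float,
    level_db_spl: float,
    duration_s: float,
    sample_rate_hz: float = 48000.0,
) -> np.ndarray:
    """Calibrated sine; 120 dB SPL corresponds to amplitude 1.0 by default."""
    if freq_hz >= sample_rate_hz / 2.0:
        raise ValueError("tone frequency must be below the Nyquist frequency")
    n = int(round(duration_s * sample_rate_hz))
    amp = 10.0 ** ((level_db_spl - CALIBRATION_DBSPL_FS) / 20.0)
    return amp * np.sin(2.0 * np.pi * freq_hz * np.arange(n) / sample_rate_hz)


def _shape_noise(white: np.ndarray, fs: float) -> np.ndarray:
    """Spectrally shape white noise with the embedded LTASS-like curve."""
    n = white.size
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    bp = np.array(_LTASS_BREAKPOINTS)
    gain_db = np.interp(
        np.log10(np.maximum(f, 1.0)), np.log10(bp[:, 0]), bp[:, 1]
    )
    gain_db[f > fs * 0.45] = -80.0  # keep the top clean of aliasing energy
    spec *= 10.0 ** (gain_db / 20.0)
    return np.fft.irfft(spec, n)


def speech_shaped_noise(
    level_db_spl: float,
    duration_s: float,
    seed,
    sample_rate_hz: float = 48000.0,
) -> np.ndarray:
    """Stationary Gaussian noise with a speech-like long-term spectrum."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    x = _shape_noise(rng.standard_normal(n), sample_rate_hz)
    return set_level_db_spl(x, level_db_spl)


def _syllabic_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Speech-like on/off envelope; pauses never exceed 250 ms.

    Alternates "syllable" bursts (100–250 ms, random amplitude) and pauses
    (50–200 ms), smoothed with a 20 ms window; the alternation rate puts the
    modulation-spectrum peak in the syllabic 2–8 Hz range.
    """
    env = np.zeros(n)
    i = 0
    on = rng.random() < 0.7
    while i < n:
        if on:
            dur = int(rng.uniform(0.100, 0.250) * fs)
            env[i:i + dur] = rng.uniform(0.4, 1.3)
        else:
            dur = int(rng.uniform(0.050, 0.200) * fs)
        i += dur
        on = not on
    k = np.hanning(max(int(0.020 * fs), 3))
    env = np.convolve(env, k / k.sum(), mode="same")
    return env / np.sqrt(np.mean(env ** 2))  # unit RMS keeps band spectra


def fluctuating_noise(
    level_db_spl: float,
    duration_s: float,
    seed,
    sample_rate_hz: float = 48000.0,
) -> np.ndarray:
    """Speech-shaped noise co-modulated in three independent frequency bands.

    Each band (split at 800 and 2400 Hz) is multiplied by an independent
    syllabic envelope whose pauses are capped below 250 ms.
    """
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    n = int(round(duration_s * fs))
    base = _shape_noise(rng.standard_normal(n), fs)
    lo, hi = _FLUCT_BAND_EDGES_HZ
    sos_lo = butter(4, lo, btype="low", fs=fs, output="sos")
    sos_mid = butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    sos_hi = butter(4, hi, btype="high", fs=fs, output="sos")
    out = np.zeros(n)
    for sos in (sos_lo, sos_mid, sos_hi):
        band = sosfilt(sos, base)
        out += band * _syllabic_envelope(n, fs, rng)
    return set_level_db_spl(out, level_db_spl)


@dataclass(frozen=True)
class MaskerKind:
    """Masker condition: stationary or fluctuating, at a presentation level."""

    kind: Literal["stationary", "fluctuating"] = "stationary"
    level_db_spl: float = 70.0
    seed: int = 0


def make_masker(
    masker: MaskerKind, duration_s: float, sample_rate_hz: float = 48000.0
) -> np.ndarray:
    if masker.kind == "stationary":
        return speech_shaped_noise(
            masker.level_db_spl, duration_s, masker.seed, sample_rate_hz
        )
    if masker.kind == "fluctuating":
        return fluctuating_noise(
            masker.level_db_spl, duration_s, masker.seed, sample_rate_hz
        )
    raise ValueError(f"unknown masker kind {masker.kind!r}")


@dataclass
class WordCorpus:
    """Labeled synthetic word tokens: (word index, audio) pairs."""

    word_labels: list[str]
    tokens: list[tuple[int, np.ndarray]]
    sample_rate_hz: float
    level_db_spl: float

    @property
    def n_words(self) -> int:
        return len(self.word_labels)

    def split(self) -> tuple[list[tuple[int, np.ndarray]], list[tuple[int, np.ndarray]]]:
        """Disjoint train/test token sets (first/second half per word)."""
        per_word: dict[int, list[np.ndarray]] = {}
        for w, a in self.tokens:
            per_word.setdefault(w, []).append(a)
        train, test = [], []
        for w, toks in per_word.items():
            half = len(toks) // 2
            train += [(w, a) for a in toks[:half]]
            test += [(w, a) for a in toks[half:]]
        return train, test


def _word_template(rng: np.random.Generator) -> dict:
    n_glides = int(rng.integers(2, 4))
    return {
        "duration_s": float(rng.uniform(0.3, 0.6)),
        "glides": [
            {
                "f0": float(np.exp(rng.uniform(np.log(300.0), np.log(3500.0)))),
                "f1": float(np.exp(rng.uniform(np.log(300.0), np.log(3500.0)))),
                "amp": float(rng.uniform(0.4, 1.0)),
                "span": sorted(rng.uniform(0.0, 1.0, size=2).tolist()),
            }
            for _ in range(n_glides)
        ],
        "burst": {
            "center": float(np.exp(rng.uniform(np.log(500.0), np.log(6000.0)))),
            "width_oct": float(rng.uniform(0.3, 1.0)),
            "pos": float(rng.uniform(0.0, 0.8)),
            "dur": float(rng.uniform(0.05, 0.12)),
            "amp": float(rng.uniform(0.2, 0.6)),
        },
    }


def _render_token(
    tpl: dict, fs: float, rng: np.random.Generator
) -> np.ndarray:
    time_scale = float(rng.uniform(0.95, 1.05))          # +-5 % duration
    pitch = 2.0 ** (rng.uniform(-1.0, 1.0) / 12.0)       # +-1 semitone
    dur = tpl["duration_s"] * time_scale
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for g in tpl["glides"]:
        a, b = g["span"]
        i0, i1 = int(a * n), max(int(b * n), int(a * n) + int(0.05 * fs))
        i1 = min(i1, n)
        if i1 <= i0:
            continue
        seg = np.arange(i1 - i0)
        f = np.geomspace(g["f0"] * pitch, g["f1"] * pitch, i1 - i0)
        phase = 2.0 * np.pi * np.cumsum(f) / fs
        ramp = np.hanning(max(int(0.02 * fs), 3))
        win = np.ones(i1 - i0)
        h = ramp.size // 2
        win[:h] = ramp[:h]
        win[-h:] = ramp[-h:]
        x[i0:i1] += g["amp"] * win * np.sin(phase + rng.uniform(0, 2 * np.pi))
        del seg
    b = tpl["burst"]
    i0 = int(b["pos"] * n)
    i1 = min(i0 + int(b["dur"] * time_scale * fs), n)
    if i1 > i0 + 8:
        lo = b["center"] * 2.0 ** (-b["width_oct"] / 2.0)
        hi = min(b["center"] * 2.0 ** (b["width_oct"] / 2.0), fs * 0.45)
        sos = butter(2, [lo, hi], btype="band", fs=fs, output="sos")
        burst = sosfilt(sos, rng.standard_normal(i1 - i0))
        burst *= np.hanning(i1 - i0)
        x[i0:i1] += b["amp"] * burst / max(np.max(np.abs(burst)), 1e-12)
    return x


def synthetic_word_corpus(
    n_words: int = 10,
    n_tokens: int = 20,
    seed: int = 0,
    sample_rate_hz: float = 48000.0,
    level_db_spl: float = 65.0,
) -> WordCorpus:
    """Generate ``n_words * n_tokens`` labeled tokens.

    Each word is a distinct formant-like spectro-temporal template (2–3 tone
    glides plus a noise burst, 300–600 ms); tokens are jittered realizations
    (±5 % duration, ±1 semitone).  Deterministic for a given seed.
    """
    if n_words < 2:
        raise ValueError("need at least 2 words")
    fs = sample_rate_hz
    word_labels = [f"w{i:02d}" for i in range(n_words)]
    tokens = []
    for w in range(n_words):
        tpl_rng = np.random.default_rng(np.random.SeedSequence((seed, w)))
        tpl = _word_template(tpl_rng)
        for k in range(n_tokens):
            tok_rng = np.random.default_rng(np.random.SeedSequence((seed, w, k)))
            audio = _render_token(tpl, fs, tok_rng)
            tokens.append((w, set_level_db_spl(audio, level_db_spl)))
    return WordCorpus(
        word_labels=word_labels,
        tokens=tokens,
        sample_rate_hz=fs,
        level_db_spl=level_db_spl,
    )


def mix_at_snr(
    speech: np.ndarray,
    masker: np.ndarray,
    snr_db: float,
    masker_level_db_spl: float,
    seed=0,
) -> np.ndarray:
    """Mix speech with a randomly chosen masker fragment at a given SNR.

    The masker is scaled to its presentation level, the speech to
    ``masker_level + snr``; a seeded random offset selects the masker
    fragment.  ``snr_db = inf`` returns the speech alone (listening in
    quiet is represented by a 0 dB SPL masker level instead).
    """
    if np.isinf(snr_db) and snr_db > 0:
        return np.array(speech, dtype=float, copy=True)
    if masker.size < speech.size:
        raise ValueError("masker must be at least as long as the speech")
    rng = np.random.default_rng(seed)
    off = int(rng.integers(0, masker.size - speech.size + 1))
    m = set_level_db_spl(masker[off:off + speech.size], masker_level_db_spl)
    s = set_level_db_spl(speech, masker_level_db_spl + snr_db)
    out = s + m
    if np.max(np.abs(out)) > 1.0:
        import warnings

        warnings.warn("mixture exceeds full scale (clipping on PCM export)")
    return out
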