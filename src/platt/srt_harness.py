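"""Scaled-down speech-recognition-threshold (SRT) simulation harness.

The harness mirrors the structure of simulation frameworks that predict
speech recognition tests with a re-purposed recognizer: for one listening
condition (masker kind and level, listener profile, optional signal
processing) a *recognition result map* — percent words correct over a
training-SNR × test-SNR grid — is computed, and SRTs are interpolated from
it as the lowest test SNR at which a target recognition rate is reached,
minimized over training SNRs.  Conditions are simulated completely
independently of each other.

The recognizer is deliberately lightweight: a diagonal-Gaussian per-word
template classifier on time-pooled log-Mel statistics (channel means,
standard deviations and delta standard deviations).  It reproduces the
*procedure* (noisy training at each SNR, testing across SNRs, map → SRT
interpolation), not the absolute performance of a full GMM–HMM recognizer,
so only directions and orderings of effects are meaningful at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features_profiles as fp
from . import gain_engine as ge
from . import synth_signals as ss
from .envelope import CALIBRATION_DBSPL_FS
from .filterbank import design_filterbank

__all__ = [
    "RecognitionResultMap",
    "SrtResult",
    "default_snr_grid",
    "make_platt_processor",
    "precompute_condition_features",
    "map_from_features",
    "simulate_recognition_map",
    "srt_from_map",
    "psychometric_segment",
    "plomp_curve_and_benefit",
]

VARIANCE_FLOOR = 1e-3


def _stable_tag(tag: str) -> int:
    """Deterministic small integer from a stage/arm tag (hash() is salted)."""
    import zlib

    return zlib.crc32(tag.encode()) & 0x7FFF
BENEFIT_LEVELS_DB_SPL = (70.0, 80.0, 90.0)


def default_snr_grid() -> np.ndarray:
    """Training/testing SNR grid: −30 … +10 dB in 3 dB steps."""
    return np.arange(-30.0, 10.0 + 1e-9, 3.0)


@dataclass
class RecognitionResultMap:
    train_snrs_db: np.ndarray
    test_snrs_db: np.ndarray
    correct_pct: np.ndarray  # (n_train, n_test)
    metadata: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.correct_pct,
            index=pd.Index(self.train_snrs_db, name="train_snr_db"),
            columns=pd.Index(self.test_snrs_db, name="test_snr_db"),
        )


@dataclass
class SrtResult:
    srt_db: float
    target_pct: float
    train_snr_at_min: float
    censored: str = "none"  # none | left (target met at grid minimum) | unreached

    @property
    def reached(self) -> bool:
        return self.censored != "unreached"


def make_platt_processor(
    sample_rate_hz: float,
    expansion_factor: float,
    base_map_mode: str = "identity",
    out_low_db=None,
    out_high_db=None,
    calibration_dbspl_fs: float = CALIBRATION_DBSPL_FS,
):
    """Build an audio→audio callable applying the dynamic-range manipulation.

    By default the output range equals the input range and the base map is
    the identity, which isolates the expansion of difference layer 2 from
    the compression management.
    """
    spec = design_filterbank(sample_rate_hz)
    if out_low_db is None and out_high_db is None:
        drs = ge.DynamicRangeSpec.transparent(spec.center_freqs_hz)
    else:
        drs = ge.DynamicRangeSpec.with_output_range(
            spec.center_freqs_hz, out_low_db, out_high_db
        )
    cfg = ge.ExpansionConfig(factor=expansion_factor, base_map_mode=base_map_mode)

    def processor(audio: np.ndarray) -> np.ndarray:
        return ge.process(audio, spec, drs, cfg, calibration_dbspl_fs)

    processor.description = f"PLATT-{expansion_factor:g}"  # type: ignore[attr-defined]
    return processor


def _pooled_stats(lms: fp.LogMelSpectrogram, n_segments: int = 3) -> np.ndarray:
    """Time-pooled token statistics: segment means plus spread/delta stats.

    Pooling channel means over a few temporal segments keeps coarse temporal
    structure (onset/nucleus/offset) while averaging the per-bin level
    uncertainty down by sqrt(frames per segment).
    """
    v = lms.values_db
    seg_means = [s.mean(axis=0) for s in np.array_split(v, n_segments, axis=0)
                 if s.size]
    while len(seg_means) < n_segments:  # extremely short tokens
        seg_means.append(seg_means[-1])
    delta = np.diff(v, axis=0) if v.shape[0] > 1 else np.zeros_like(v)
    return np.concatenate(seg_means + [v.std(axis=0), delta.std(axis=0)])


def precompute_condition_features(
    tokens,
    masker: ss.MaskerKind,
    processing,
    snrs_db,
    seed,
    sample_rate_hz: float,
    tag: str = "",
    masker_duration_s: float = 10.0,
):
    """Mix, (optionally) process and feature-extract tokens at each SNR.

    Returns ``{snr: [(word, LogMelSpectrogram), ...]}``.  This profile-free
    stage is the expensive part of a simulation; the same result can be
    reused for several listener profiles.
    """
    fs = sample_rate_hz
    masker_sig = ss.make_masker(masker, masker_duration_s, fs)
    out = {}
    for i_snr, snr in enumerate(snrs_db):
        feats = []
        for i_tok, (word, audio) in enumerate(tokens):
            mix_seed = np.random.SeedSequence(
                (seed, _stable_tag(tag), i_snr, i_tok)
            )
            mixed = ss.mix_at_snr(
                audio, masker_sig, snr, masker.level_db_spl, mix_seed
            )
            if processing is not None:
                mixed = processing(mixed)
            feats.append((word, fp.log_mel_spectrogram(mixed, fs)))
        out[float(snr)] = feats
    return out


def _profile_pooled(feats, profile, seed, stage: str):
    """Apply a listener profile per utterance and pool over time."""
    by_snr = {}
    for snr, lst in feats.items():
        rows, words = [], []
        for i, (word, lms) in enumerate(lst):
            useed = np.random.SeedSequence(
                (seed, _stable_tag(stage), int(round(snr * 10)) & 0xFFFF, i)
            )
            deg = fp.apply_profile(lms, profile, useed)
            rows.append(_pooled_stats(deg))
            words.append(word)
        by_snr[snr] = (np.array(words), np.vstack(rows))
    return by_snr


def map_from_features(
    train_feats,
    test_feats,
    profile: fp.ListenerProfile,
    seed,
    metadata: dict | None = None,
) -> RecognitionResultMap:
    """Train per-word diagonal-Gaussian templates per training SNR, test across SNRs."""
    train = _profile_pooled(train_feats, profile, seed, "train")
    test = _profile_pooled(test_feats, profile, seed, "test")
    train_snrs = np.array(sorted(train))
    test_snrs = np.array(sorted(test))
    pct = np.zeros((train_snrs.size, test_snrs.size))
    for i, tr_snr in enumerate(train_snrs):
        words, X = train[float(tr_snr)]
        labels = np.unique(words)
        mu = np.array([X[words == w].mean(axis=0) for w in labels])
        var = np.array([X[words == w].var(axis=0) for w in labels])
        var = np.maximum(var, VARIANCE_FLOOR)
        log_var_term = np.log(var).sum(axis=1)
        for j, te_snr in enumerate(test_snrs):
            wt, Xt = test[float(te_snr)]
            # log-likelihood of each token under each word template
            ll = -0.5 * (
                ((Xt[:, None, :] - mu[None, :, :]) ** 2 / var[None, :, :]).sum(axis=2)
                + log_var_term[None, :]
            )
            pred = labels[np.argmax(ll, axis=1)]
            pct[i, j] = 100.0 * np.mean(pred == wt)
    return RecognitionResultMap(
        train_snrs_db=train_snrs,
        test_snrs_db=test_snrs,
        correct_pct=pct,
        metadata=metadata or {},
    )


def simulate_recognition_map(
    corpus: ss.WordCorpus,
    masker: ss.MaskerKind,
    profile: fp.ListenerProfile,
    processing,
    train_snrs_db,
    test_snrs_db,
    seed: int,
    masker_duration_s: float = 10.0,
) -> RecognitionResultMap:
    """Simulate one listening condition end to end.

    Training and testing use disjoint token sets of the corpus; the listener
    profile (frequency limit and level uncertainty) is applied independently
    to every feature matrix, training and testing alike.
    """
    if corpus.n_words < 2:
        raise ValueError("corpus must contain at least 2 words")
    train_tokens, test_tokens = corpus.split()
    fs = corpus.sample_rate_hz
    train_feats = precompute_condition_features(
        train_tokens, masker, processing, train_snrs_db, seed, fs,
        tag="train", masker_duration_s=masker_duration_s,
    )
    test_feats = precompute_condition_features(
        test_tokens, masker, processing, test_snrs_db, seed, fs,
        tag="test", masker_duration_s=masker_duration_s,
    )
    meta = {
        "masker": masker.kind,
        "level_db_spl": masker.level_db_spl,
        "profile": profile.name,
        "processing": getattr(processing, "description", "none")
        if processing is not None else "none",
    }
    return map_from_features(train_feats, test_feats, profile, seed, meta)


def _row_crossing(test_snrs, pct_row, target) -> float | None:
    """Lowest test SNR where the row reaches the target (linear interpolation)."""
    above = pct_row >= target
    if not np.any(above):
        return None
    j = int(np.argmax(above))
    if j == 0:
        return float(test_snrs[0])  # left-censored
    x0, x1 = test_snrs[j - 1], test_snrs[j]
    y0, y1 = pct_row[j - 1], pct_row[j]
    return float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))


def srt_from_map(rmap: RecognitionResultMap, target_pct: float = 50.0) -> SrtResult:
    """Interpolate the SRT: lowest crossing per training SNR, minimum over rows."""
    best, best_row = None, None
    for i, row in enumerate(rmap.correct_pct):
        c = _row_crossing(rmap.test_snrs_db, row, target_pct)
        if c is not None and (best is None or c < best):
            best, best_row = c, i
    if best is None:
        return SrtResult(
            srt_db=float("nan"), target_pct=target_pct,
            train_snr_at_min=float("nan"), censored="unreached",
        )
    censored = "left" if best <= rmap.test_snrs_db[0] else "none"
    return SrtResult(
        srt_db=best,
        target_pct=target_pct,
        train_snr_at_min=float(rmap.train_snrs_db[best_row]),
        censored=censored,
    )


def psychometric_segment(
    rmap: RecognitionResultMap, targets=tuple(range(20, 95, 5))
) -> list[SrtResult]:
    """SRTs for target rates 20..90 % in 5 % steps (a psychometric segment)."""
    return [srt_from_map(rmap, float(t)) for t in targets]


def _srt_value(x) -> float:
    return x.srt_db if isinstance(x, SrtResult) else float(x)


def plomp_curve_and_benefit(
    unaided: dict, aided: dict, levels=BENEFIT_LEVELS_DB_SPL
) -> tuple[float, pd.DataFrame]:
    """SRT-vs-masker-level curves and the high-level benefit of the aided arm.

    ``unaided`` and ``aided`` map masker presentation level (dB SPL) to an
    SRT (float or :class:`SrtResult`).  The benefit is the mean over the
    given high presentation levels (at which linear amplification cannot
    improve the SRT) of unaided minus aided SRT; positive means improvement.
    """
    for lv in levels:
        for name, arm in (("unaided", unaided), ("aided", aided)):
            if lv not in arm:
                raise ValueError(f"missing SRT at {lv} dB SPL in the {name} arm")
    all_levels = sorted(set(unaided) | set(aided))
    curve = pd.DataFrame({
        "level_db_spl": all_levels,
        "srt_unaided_db": [_srt_value(unaided[lv]) if lv in unaided else np.nan
                           for lv in all_levels],
        "srt_aided_db": [_srt_value(aided[lv]) if lv in aided else np.nan
                         for lv in all_levels],
    })
    benefit = float(np.mean(
        [_srt_value(unaided[lv]) - _srt_value(aided[lv]) for lv in levels]
    ))
    return benefit, curve
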