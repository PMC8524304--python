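"""Layer decomposition, dynamic-range mapping and adaptive gain rules."""

import numpy as np
import pytest

from platt import filterbank as fb
from platt import gain_engine as ge
from platt.envelope import envelope_track
from platt.synth_signals import pure_tone, set_level_db_spl


@pytest.fixture()
def freqs(spec48):
    return spec48.center_freqs_hz


@pytest.fixture()
def drs(freqs):
    return ge.DynamicRangeSpec.transparent(freqs)


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        x = np.full(78, 42.0)
        for w in ge.SMOOTHING_WIDTHS:
            np.testing.assert_allclose(ge.smooth_spectrum(x, w), 42.0)

    def test_width8_kernel_fwhm_is_4_samples(self):
        """Width-8 smoothing has FWHM 4 channels = 2 ERB at 0.5 ERB spacing."""
        w = ge._hann_kernel(8)
        half = w.max() / 2
        above = np.where(w >= half)[0]
        assert above[-1] - above[0] == 4

    def test_interior_impulse_returns_kernel(self):
        x = np.zeros(78)
        x[40] = 1.0
        out = ge.smooth_spectrum(x, 8)
        ref = np.convolve(x, ge._hann_kernel(8), mode="same")
        np.testing.assert_allclose(out, ref, atol=1e-15)


class TestLayers:
    def test_exact_reconstruction(self, rng):
        frame = rng.uniform(0.0, 100.0, 78)
        lay = ge.decompose_layers(frame)
        np.testing.assert_allclose(lay.reconstruct(), frame, atol=1e-9)

    def test_layers_are_successive_differences(self, rng):
        frame = rng.uniform(0.0, 100.0, 78)
        lay = ge.decompose_layers(frame)
        s8 = ge.smooth_spectrum(frame, 8)
        s16 = ge.smooth_spectrum(frame, 16)
        np.testing.assert_allclose(lay.d1, frame - s8)
        np.testing.assert_allclose(lay.d2, s8 - s16)


class TestBaseMap:
    def test_identity_mode(self, drs, rng):
        base = rng.uniform(20.0, 100.0, 78)
        np.testing.assert_array_equal(
            ge.map_base_layer(base, drs, "identity"), base
        )

    def test_affine_endpoints(self, freqs):
        drs = ge.DynamicRangeSpec.with_output_range(freqs, 50.0, 90.0)
        np.testing.assert_allclose(
            ge.map_base_layer(drs.in_low, drs, "linear"), drs.out_low
        )
        np.testing.assert_allclose(
            ge.map_base_layer(drs.in_high, drs, "linear"), drs.out_high
        )

    def test_hand_computed_midpoint(self, freqs):
        """65 dB mapped from [25, 105] to [50, 90] lands at 70 dB."""
        drs = ge.DynamicRangeSpec(
            in_low=np.full(78, 25.0), in_high=np.full(78, 105.0),
            out_low=np.full(78, 50.0), out_high=np.full(78, 90.0),
        )
        out = ge.map_base_layer(np.full(78, 65.0), drs, "linear")
        np.testing.assert_allclose(out, 70.0)


class TestConditionalFactor:
    def test_printed_one_third_example(self, freqs):
        """80 dB SPL current, +30 dB difference, 90 dB limit → factor 1/3."""
        drs = ge.DynamicRangeSpec.with_output_range(freqs, 50.0, 90.0)
        f = ge.conditional_factor(np.full(78, 80.0), np.full(78, 30.0), drs)
        np.testing.assert_allclose(f, 1.0 / 3.0)

    def test_zero_difference_gives_one(self, drs):
        f = ge.conditional_factor(np.full(78, 80.0), np.zeros(78), drs)
        np.testing.assert_array_equal(f, 1.0)

    def test_downward_mirror_case(self, freqs):
        drs = ge.DynamicRangeSpec.with_output_range(freqs, 50.0, 90.0)
        f = ge.conditional_factor(np.full(78, 60.0), np.full(78, -30.0), drs)
        np.testing.assert_allclose(f, 1.0 / 3.0)

    def test_against_alpha_grid_oracle(self, freqs, rng):
        """Exhaustive alpha scan confirms the closed-form factor."""
        drs = ge.DynamicRangeSpec.with_output_range(freqs, 50.0, 90.0)
        cur = rng.uniform(30.0, 110.0, 78)
        diff = rng.uniform(-40.0, 40.0, 78)
        f = ge.conditional_factor(cur, diff, drs)
        alphas = np.linspace(0.0, 1.0, 2001)
        for j in range(0, 78, 5):
            vals = cur[j] + alphas * diff[j]
            if diff[j] > 0:
                ok = vals <= drs.out_high[j] + 1e-12
            elif diff[j] < 0:
                ok = vals >= drs.out_low[j] - 1e-12
            else:
                ok = np.ones_like(alphas, bool)
            best = alphas[ok][-1] if ok.any() else 0.0
            assert f[j] == pytest.approx(best, abs=1e-3)

    def test_applying_factor_keeps_in_range_channels_in_range(self, freqs, rng):
        drs = ge.DynamicRangeSpec.with_output_range(freqs, 50.0, 90.0)
        cur = rng.uniform(50.0, 90.0, 78)
        diff = rng.uniform(-60.0, 60.0, 78)
        f = ge.conditional_factor(cur, diff, drs)
        out = cur + f * diff
        assert np.all(out <= drs.out_high + 1e-9)
        assert np.all(out >= drs.out_low - 1e-9)


class TestPropagation:
    def test_printed_worked_example(self, freqs):
        """Zero factor at 2708 Hz, FWHM 6: ≤0.5 at 2346/3112 Hz, 1 beyond
        2023/3565 Hz."""
        raw = np.ones(78)
        i2708 = int(np.argmin(np.abs(freqs - 2708)))
        raw[i2708] = 0.0
        out = ge.propagate_factors(raw, 6)
        for f in (2346.0, 3112.0):
            assert out[int(np.argmin(np.abs(freqs - f)))] <= 0.5 + 1e-12
        i2023 = int(np.argmin(np.abs(freqs - 2023)))
        i3565 = int(np.argmin(np.abs(freqs - 3565)))
        assert np.all(out[: i2023 + 1] == 1.0)
        assert np.all(out[i3565:] == 1.0)

    def test_all_ones_unchanged(self):
        np.testing.assert_array_equal(ge.propagate_factors(np.ones(78), 6), 1.0)

    def test_never_exceeds_raw(self, rng):
        raw = rng.uniform(0.0, 1.0, 78)
        out = ge.propagate_factors(raw, 12)
        assert np.all(out <= raw + 1e-12)

    def test_against_quadratic_oracle(self, rng):
        """Exhaustive min over all channel pairs of the cap formula."""
        raw = rng.uniform(0.0, 1.0, 78)
        for fwhm in (6, 12):
            out = ge.propagate_factors(raw, fwhm)
            ref = raw.copy()
            for j in range(78):
                for k in range(78):
                    d = abs(j - k)
                    w = 0.5 * (1 + np.cos(np.pi * d / fwhm)) if d <= fwhm else 0.0
                    ref[j] = min(ref[j], raw[k] + (1.0 - w))
            np.testing.assert_allclose(out, np.clip(ref, 0, 1), atol=1e-12)


class TestFrameGain:
    def test_transparent_configuration_is_zero_gain(self, freqs, drs, rng):
        """Identity map, factor 1, in-range frame → no gain at all."""
        frame = rng.uniform(45.0, 95.0, 78)
        frame = ge.smooth_spectrum(frame, 8)  # keep d3/d4 additions in range
        gain = ge.compute_frame_gain(frame, drs, ge.ExpansionConfig(1.0))
        np.testing.assert_allclose(gain, 0.0, atol=1e-9)

    def test_expansion_is_linear_in_d2(self, freqs, rng):
        """Without range limits, factor E adds exactly (E−1)·d2."""
        wide = ge.DynamicRangeSpec(
            in_low=np.full(78, 25.0), in_high=np.full(78, 105.0),
            out_low=np.full(78, -1e6), out_high=np.full(78, 1e6),
        )
        frame = rng.uniform(30.0, 100.0, 78)
        d2 = ge.decompose_layers(frame).d2
        g1 = ge.compute_frame_gain(frame, wide, ge.ExpansionConfig(1.0))
        g2 = ge.compute_frame_gain(frame, wide, ge.ExpansionConfig(2.0))
        np.testing.assert_allclose(g2 - g1, d2, atol=1e-9)

    def test_low_spectral_dynamic_gets_uniform_gain(self, freqs):
        """A white-noise-like (spectrally flat) frame inside a reduced output
        range is shifted, not compressed: gains nearly equal across channels."""
        drs = ge.DynamicRangeSpec.with_output_range(freqs, 50.0, 90.0)
        frame = np.full(78, 70.0) + 0.5 * np.sin(np.arange(78) / 9.0)
        gain = ge.compute_frame_gain(frame, drs, ge.ExpansionConfig(1.0, "linear"))
        assert gain.max() - gain.min() <= 1.5


class TestProcess:
    def test_transparent_process_matches_passthrough(self, spec48, rng):
        x = set_level_db_spl(rng.standard_normal(24000), 80.0)
        y = ge.process(x, spec48)
        ref = fb.resynthesize(fb.analyze(x, spec48), None, spec48)
        # steady state (after the tracker settles) matches the passthrough
        seg = slice(10000, 24000)
        err = np.sqrt(np.mean((y[seg] - ref[seg]) ** 2) / np.mean(ref[seg] ** 2))
        assert err < 0.05

    def test_expansion_raises_broadband_level(self, spec48, rng):
        """Expanding d2 on speech-like signal in noise raises the RMS level."""
        from platt.synth_signals import mix_at_snr, speech_shaped_noise
        from platt.synth_signals import synthetic_word_corpus

        corpus = synthetic_word_corpus(2, 1, seed=3, sample_rate_hz=48000.0)
        tok = corpus.tokens[0][1]
        noise = speech_shaped_noise(70.0, 1.0, 5, 48000.0)
        x = mix_at_snr(tok, noise, 0.0, 70.0, 7)
        cfg8 = ge.ExpansionConfig(8.0)
        y8 = ge.process(x, spec48, cfg=cfg8)
        y1 = ge.process(x, spec48)
        gain_db = 10 * np.log10(np.mean(y8 ** 2) / np.mean(y1 ** 2))
        assert gain_db > 1.0  # direction only

    def test_d2_span_grows_monotonically_with_factor(self, spec48):
        """Measured on the reprocessed output's own spectral frames.  A
        dense spectrum (speech-shaped noise) is used so the output's d2
        reflects the commanded expansion rather than filter skirts."""
        from platt.synth_signals import speech_shaped_noise

        x = speech_shaped_noise(75.0, 0.6, seed=9)
        spans = []
        for factor in (1.0, 2.0, 4.0, 8.0):
            y = ge.process(x, spec48, cfg=ge.ExpansionConfig(factor))
            track = envelope_track(fb.analyze(y, spec48), spec48)
            frame = track.levels_db_spl[250:500].mean(axis=0)
            lay = ge.decompose_layers(frame)
            spans.append(lay.d2.max() - lay.d2.min())
        assert all(b > a for a, b in zip(spans, spans[1:]))
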