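"""Filter fitting, preprocessing, deconvolution and glottal pressure."""

import numpy as np
import pytest
import scipy.signal as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from tractacoustics.backfilter import (
    IIRFilter,
    deconvolve,
    fit_iir,
    glottal_pressure,
    impulse_response,
    load_filter,
    preprocess_audio,
    save_filter,
)
from tractacoustics.helmholtz import TransferFunction
from tractacoustics.synthetic import AudioSignal, make_glottal_flow, render_microphone

GRID = np.arange(10.0, 10001.0, 10.0)


class TestPreprocess:
    def test_tone_attenuations(self):
        fs, f_o = 44100.0, 300.0
        t = np.arange(int(fs)) / fs

        def gain_db(freq):
            sig = AudioSignal(samples=np.sin(2 * np.pi * freq * t), fs=fs)
            out = preprocess_audio(sig, f_o)
            mid = out.samples[5000:-5000]
            return 20 * np.log10(np.sqrt(2) * np.std(mid))

        assert gain_db(f_o) > -0.2  # passband
        assert gain_db(0.4 * f_o) < -55.0  # deep in the stopband
        # corner: -3 dB per pass, doubled by zero-phase application
        assert gain_db(0.8 * f_o) == pytest.approx(-6.0, abs=0.6)

    def test_resampled_length(self):
        sig = AudioSignal(samples=np.random.default_rng(0).normal(size=44100), fs=44100.0)
        out = preprocess_audio(sig, 200.0)
        assert len(out.samples) == 20000 and out.fs == 20000.0

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            preprocess_audio(AudioSignal(samples=np.zeros(4000), fs=16000.0), 200.0)


class TestFitIIR:
    def test_constant_response_is_identity(self):
        tf = TransferFunction("H_gl", GRID, np.ones(len(GRID), complex))
        filt = fit_iir(tf, n=256)
        assert filt.fit_rms_error < 1e-6
        assert abs(filt.b[0] - 1.0) < 1e-6

    def test_two_pole_two_zero_target_recovered(self):
        b0 = np.array([0.8, -0.3, 0.1])
        a0 = np.array([1.0, -0.6, 0.25])  # poles well inside the unit circle
        w = 2 * np.pi * GRID / 20000.0
        _, H = sps.freqz(b0, a0, worN=w)
        filt = fit_iir(TransferFunction("H_gl", GRID, H), n=256)
        resp = filt.response(GRID)
        assert np.abs(20 * np.log10(np.abs(resp) / np.abs(H))).max() < 0.1
        assert np.rad2deg(np.abs(np.angle(resp / H))).max() < 2.0

    def test_error_monotone_in_filter_length(self, small_tract_tfs):
        errs = [
            fit_iir(small_tract_tfs["h_gl"], n=n).fit_rms_error
            for n in (32, 64, 128, 256)
        ]
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi * (1 + 1e-9) + 1e-12

    def test_emitted_filters_are_stable(self, small_tract_tfs):
        for kind in ("h_gl", "h_gg"):
            for n_poles in (0, 12):
                filt = fit_iir(small_tract_tfs[kind], n=64, n_poles=n_poles)
                assert filt.max_pole_magnitude() < 1.0

    def test_unstable_construction_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            IIRFilter(b=[1.0], a=[1.0, -1.5])

    def test_round_trip_serialization(self, tmp_path, small_tract_tfs):
        filt = fit_iir(small_tract_tfs["h_gl"], n=64)
        save_filter(tmp_path / "f.json", filt)
        back = load_filter(tmp_path / "f.json")
        assert np.allclose(back.b, filt.b) and np.allclose(back.a, filt.a)
        assert back.fit_rms_error == pytest.approx(filt.fit_rms_error)


class TestImpulseResponse:
    def test_identity_filter(self):
        h = impulse_response(IIRFilter(b=[1.0], a=[1.0]), 8)
        assert np.array_equal(h, [1, 0, 0, 0, 0, 0, 0, 0])

    def test_one_pole_geometric(self):
        h = impulse_response(IIRFilter(b=[1.0], a=[1.0, -0.5]), 32)
        assert np.allclose(h, 0.5 ** np.arange(32))

    def test_fitted_filter_decays(self, small_tract_tfs):
        filt = fit_iir(small_tract_tfs["h_gl"], n=200)
        h = impulse_response(filt, 4096)
        tail = np.abs(h[-410:]).max()
        assert tail < 1e-3 * np.abs(h).max()


class TestDeconvolve:
    def test_unit_impulse_identity(self):
        x = np.arange(1.0, 20.0)
        res = deconvolve(x, np.array([1.0]))
        assert res.method == "long-division"
        assert np.array_equal(res.v_g, x)

    def test_exact_inverse_of_convolution(self):
        rng = np.random.default_rng(12)
        v = rng.normal(size=400)
        h = np.r_[1.0, 0.08 * rng.normal(size=31)]
        res = deconvolve(np.convolve(v, h), h)
        assert res.method == "long-division"
        assert np.abs(res.v_g - v).max() <= 1e-8 * np.abs(v).max()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_roundtrip_property(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=rng.integers(50, 300))
        h = np.r_[rng.uniform(0.5, 2.0), 0.05 * rng.normal(size=rng.integers(4, 40))]
        res = deconvolve(np.convolve(v, h), h)
        assert len(res.v_g) == len(v)
        assert np.abs(res.v_g - v).max() <= 1e-8 * np.abs(v).max()

    def test_ill_conditioned_falls_back_to_frequency_domain(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=256)
        h = np.r_[1e-9, 1.0, 0.3]  # tiny leading sample
        res = deconvolve(np.convolve(v, h), h)
        assert res.method == "frequency-domain"

    def test_end_to_end_source_recovery(self, small_tract_tfs):
        """render -> deconvolve recovers harmonic magnitudes within 1 dB."""
        filt = fit_iir(small_tract_tfs["h_gl"], n=200)
        ir = impulse_response(filt, 2048)
        flow = make_glottal_flow(208.0, 1.0, 20000.0, -12.0, seed=9)
        mic = render_microphone(flow, ir)
        res = deconvolve(mic, ir)
        v = res.v_g
        spec_in = np.fft.rfft(flow.samples)
        spec_out = np.fft.rfft(v, len(flow.samples))
        freqs = np.fft.rfftfreq(len(flow.samples), 1 / 20000.0)
        for k in range(1, int(8000 / 208)):
            i = np.argmin(np.abs(freqs - k * 208.0))
            if freqs[i] < 100.0:
                continue
            diff = 20 * np.log10(np.abs(spec_out[i]) / np.abs(spec_in[i]))
            assert abs(diff) < 1.0


class TestGlottalPressure:
    def test_identity_and_gain(self):
        v = np.arange(16.0)
        assert np.array_equal(glottal_pressure(v, IIRFilter(b=[1.0], a=[1.0])), v)
        assert np.allclose(glottal_pressure(v, IIRFilter(b=[3.0], a=[1.0])), 3 * v)

    def test_steady_state_sinusoid_gain(self):
        filt = IIRFilter(b=[0.5, 0.2], a=[1.0, -0.4])
        fs, f0 = 20000.0, 500.0
        t = np.arange(int(fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = glottal_pressure(x, filt)
        expected = np.abs(filt.response(np.array([f0]))[0])
        measured = np.sqrt(2) * np.std(y[2000:])
        assert measured == pytest.approx(expected, rel=0.01)
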