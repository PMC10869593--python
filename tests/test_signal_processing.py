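"""Causal chain: FIR filter, frequency estimate, measuring devices,
delay compensation."""

import numpy as np
import pytest

from phasegate.signal_processing import (FirSpec, FirFilter, DeviceParams,
                                         LinearDevice,
                                         PhaseAmplitudeEstimator,
                                         design_bandpass_fir,
                                         estimate_mean_frequency,
                                         compensate_delay,
                                         invert_resonance)

DELTA = 0.1
F0 = 0.032  # a collective-rhythm-like frequency, cycles per time unit


def make_chain(M=350, f0=F0, nu_factor=1.0):
    fir = design_bandpass_fir(M, DELTA, 0.8 * f0, 1.2 * f0)
    omega = 2 * np.pi * f0 * nu_factor
    dev = DeviceParams.from_signal_frequency(omega)
    return PhaseAmplitudeEstimator(fir, dev, omega)


class TestFirDesign:
    def test_taps_are_exactly_symmetric(self):
        spec = design_bandpass_fir(123, DELTA, 0.02, 0.05)
        assert np.array_equal(spec.taps, spec.taps[::-1])

    def test_unit_gain_at_band_centre(self):
        spec = design_bandpass_fir(350, DELTA, 0.02, 0.05)
        assert abs(spec.gain_at(np.sqrt(0.02 * 0.05)) - 1.0) < 0.05

    def test_stopband_attenuation_at_three_times_centre(self):
        spec = design_bandpass_fir(350, DELTA, 0.02, 0.05)
        fc = np.sqrt(0.02 * 0.05)
        assert spec.gain_at(3 * fc) < 10 ** (-20 / 20)

    def test_dc_rejection(self):
        spec = design_bandpass_fir(350, DELTA, 0.02, 0.05)
        f = FirFilter(spec)
        out = f.process(np.ones(2 * 350 + 2))
        assert abs(out[-1]) < 0.01

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_bandpass_fir(100, DELTA, 0.02, 6.0)

    def test_taps_roundtrip_through_text_file(self, tmp_path):
        spec = design_bandpass_fir(40, DELTA, 0.02, 0.05)
        spec.save_taps(tmp_path / "taps.txt")
        back = FirSpec.load_taps(tmp_path / "taps.txt", DELTA, 0.02, 0.05)
        assert back.M == 40
        assert np.allclose(back.taps, spec.taps)


class TestFirStreaming:
    def test_impulse_response_replays_taps(self):
        spec = design_bandpass_fir(25, DELTA, 0.02, 0.05)
        f = FirFilter(spec)
        x = np.zeros(2 * 25 + 1)
        x[0] = 1.0
        assert np.allclose(f.process(x), spec.taps)

    def test_inband_sinusoid_delayed_exactly_M_samples(self):
        M = 350
        spec = design_bandpass_fir(M, DELTA, 0.8 * F0, 1.2 * F0)
        n = np.arange(6 * (2 * M + 1))
        x = np.sin(2 * np.pi * F0 * DELTA * n)
        f = FirFilter(spec)
        y = f.process(x)
        sl = slice(3 * (2 * M + 1), None)
        # group delay via cross-correlation peak
        lags = np.arange(M - 5, M + 6)
        cc = [np.dot(y[sl], x[np.asarray(sl.start + np.arange(y[sl].size))
                              - lag]) for lag in lags]
        assert lags[int(np.argmax(cc))] == M
        assert abs(y[sl].std() / x[sl].std() - 1.0) < 0.05


class TestMeanFrequency:
    def test_pure_sinusoid_within_one_percent(self):
        nu = 2 * np.pi * F0
        t = np.arange(0, 10 / F0, DELTA)
        omega = estimate_mean_frequency(np.sin(nu * t), DELTA)
        assert abs(omega - nu) / nu < 0.01

    def test_filtered_rippled_sinusoid_within_two_percent(self):
        nu = 2 * np.pi * F0
        t = np.arange(0, 60 / F0, DELTA)
        x = np.sin(nu * t) + 0.05 * np.sin(10 * nu * t)
        spec = design_bandpass_fir(350, DELTA, 0.5 * F0, 1.5 * F0)
        y = FirFilter(spec).process(x)
        omega = estimate_mean_frequency(y[2 * 701:], DELTA)
        assert abs(omega - nu) / nu < 0.02

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError):
            estimate_mean_frequency(np.ones(1000), DELTA)


class TestDevice:
    def test_free_decay(self):
        d = LinearDevice(omega=1.6, gamma=1.6, delta=DELTA)
        d.u = 1.0
        amp0 = 1.0
        for _ in range(int(10 / 1.6 / DELTA)):
            d.push(0.0)
        assert np.hypot(d.u, d.v / 1.6) < 1e-3 * amp0

    def test_static_gain(self):
        d = LinearDevice(omega=1.6, gamma=1.6, delta=DELTA)
        for _ in range(5000):
            d.push(2.0)
        assert abs(d.u - 2.0 / 1.6 ** 2) < 1e-6

    def test_driven_amplitude_matches_resonance_curve(self):
        w, g, nu, E = 1.6, 0.16, 0.2, 1.0
        d = LinearDevice(omega=w, gamma=g, delta=DELTA)
        us = []
        for i in range(60_000):
            d.push(E * np.cos(nu * i * DELTA))
            if i > 40_000:
                us.append(np.hypot(d.u, d.v / nu))
        pred = E / np.sqrt((w ** 2 - nu ** 2) ** 2 + 4 * g ** 2 * nu ** 2)
        assert abs(np.mean(us) - pred) / pred < 0.01

    def test_params_require_nonresonant_ordering(self):
        with pytest.raises(ValueError):
            DeviceParams(omega_dev=0.1, gamma_amp=1.0, gamma_phase=0.1,
                         nu=0.2)
        with pytest.raises(ValueError):
            DeviceParams(omega_dev=1.6, gamma_amp=0.1, gamma_phase=1.0,
                         nu=0.2)


class TestInversion:
    def test_harmonic_amplitude_and_phase_recovered(self):
        nu = 2 * np.pi * F0
        dev = DeviceParams.from_signal_frequency(nu)
        da = LinearDevice(dev.omega_dev, dev.gamma_amp, DELTA)
        dp = LinearDevice(dev.omega_dev, dev.gamma_phase, DELTA)
        E, phi0 = 1.5, 0.9
        for i in range(40_000):
            s = E * np.cos(nu * i * DELTA + phi0)
            da.push(s)
            dp.push(s)
        theta, a = invert_resonance(da, dp, dev)
        true_phase = (nu * 39_999 * DELTA + phi0) % (2 * np.pi)
        err = abs((theta - true_phase + np.pi) % (2 * np.pi) - np.pi)
        assert abs(a - E) / E < 0.02
        assert err < 0.05

    def test_slow_amplitude_ramp_is_tracked(self):
        nu = 2 * np.pi * F0
        dev = DeviceParams.from_signal_frequency(nu)
        da = LinearDevice(dev.omega_dev, dev.gamma_amp, DELTA)
        dp = LinearDevice(dev.omega_dev, dev.gamma_phase, DELTA)
        period = 2 * np.pi / nu
        rate = 0.01 / period  # 1% per period
        errs = []
        for i in range(60_000):
            t = i * DELTA
            E = 1.0 + rate * t
            da.push(E * np.cos(nu * t))
            dp.push(E * np.cos(nu * t))
            if i > 30_000:
                _, a = invert_resonance(da, dp, dev)
                errs.append((a - E) / E)
        assert abs(np.mean(errs)) < 0.05

    def test_zero_input_amplitude_decays_to_zero(self):
        nu = 2 * np.pi * F0
        dev = DeviceParams.from_signal_frequency(nu)
        da = LinearDevice(dev.omega_dev, dev.gamma_amp, DELTA)
        dp = LinearDevice(dev.omega_dev, dev.gamma_phase, DELTA)
        da.u = 1.0
        for _ in range(20_000):
            da.push(0.0)
            dp.push(0.0)
        _, a = invert_resonance(da, dp, dev)
        assert a < 1e-6


class TestCompensation:
    def test_zero_length_filter_is_identity(self):
        assert compensate_delay(1.0, 0.2, 0, DELTA) == 1.0

    def test_wrap_arithmetic(self):
        out = compensate_delay(1.0, 0.17, 350, DELTA)
        assert out == pytest.approx(1.0 + 0.17 * 35 - 2 * np.pi,
                                    abs=1e-4)  # ~ 0.6668

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            compensate_delay(1.0, 0.0, 10, DELTA)

    def test_noiseless_chain_recovers_current_phase(self):
        est = make_chain()
        nu = 2 * np.pi * F0
        errs = []
        for i in range(30_000):
            t = i * DELTA
            r = est.update(np.cos(nu * t))
            if i > est.startup_samples * 2:
                true = (nu * t) % (2 * np.pi)
                errs.append((r.theta_hat - true + np.pi) % (2 * np.pi)
                            - np.pi)
        assert abs(np.mean(errs)) < 0.05


class TestEndToEnd:
    def test_phase_and_amplitude_under_strong_noise(self):
        """Harmonic of unit amplitude buried in sigma = 3 white noise."""
        est = make_chain()
        nu = 2 * np.pi * F0
        g = np.random.default_rng(42)
        n = 60_000
        t = np.arange(n) * DELTA
        x = np.cos(nu * t) + 3.0 * g.standard_normal(n)
        out = est.process(x)
        sl = slice(2 * est.startup_samples, None)
        true = (nu * t[sl]) % (2 * np.pi)
        d = np.angle(np.exp(1j * (out["theta_hat"][sl] - true)))
        rms = np.sqrt(np.mean(d ** 2))
        assert rms < 0.3
        assert abs(np.mean(out["a"][sl]) - 1.0) < 0.10

    def test_amplitude_invariant_to_out_of_band_contaminant(self):
        nu = 2 * np.pi * F0
        n = 50_000
        t = np.arange(n) * DELTA
        base = np.cos(nu * t)
        contam = base + 3.0 * np.cos(8 * nu * t)
        a_clean = make_chain().process(base)["a"]
        a_dirty = make_chain().process(contam)["a"]
        sl = slice(2 * 2 * (2 * 350 + 1), None)
        rel = abs(np.mean(a_dirty[sl]) - np.mean(a_clean[sl]))
        assert rel / np.mean(a_clean[sl]) < 0.10
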