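"""Level-crossing converter: analytics, event simulation, reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcecg import (DenseSignal, LCConfig, LCEventStream, TimerOverflowError,
                   gen_sinusoid, ideal_snr_adc, ideal_snr_lcadc, lc_sample,
                   max_rate, measure_snr, quantum, reconstruct, upsample)


class TestAnalytics:
    def test_quantum(self):
        assert quantum(LCConfig(delta_v=31, m_bits=5)) == pytest.approx(1.0)
        assert quantum(LCConfig(delta_v=1, m_bits=2)) == pytest.approx(1 / 3)

    @given(dv=st.floats(0.1, 100), m=st.integers(2, 12))
    @settings(deadline=None, derandomize=True)
    def test_quantum_round_trip(self, dv, m):
        cfg = LCConfig(delta_v=dv, m_bits=m)
        assert cfg.q * (2**m - 1) == pytest.approx(dv)

    def test_max_rate_full_scale(self):
        cfg = LCConfig(delta_v=1.0, m_bits=5)
        assert max_rate(60, cfg, 1.0) == pytest.approx(3600.0)

    def test_max_rate_linearity_and_low_resolution(self):
        cfg = LCConfig(delta_v=2.0, m_bits=5)
        assert max_rate(60, cfg, 1.0) == pytest.approx(0.5 * max_rate(60, cfg, 2.0))
        cfg2 = LCConfig(delta_v=1.0, m_bits=2)
        assert max_rate(10, cfg2, 0.5) == pytest.approx(2 * 10 * 2 * 0.5)

    def test_max_rate_rejects_overrange(self):
        with pytest.raises(ValueError):
            max_rate(60, LCConfig(delta_v=1.0, m_bits=5), 1.5)

    def test_lcadc_snr_values(self):
        assert ideal_snr_lcadc(60, 1e-6) == pytest.approx(73.25, abs=0.005)
        gain = ideal_snr_lcadc(60, 0.5e-6) - ideal_snr_lcadc(60, 1e-6)
        assert gain == pytest.approx(6.02, abs=0.005)
        drop = ideal_snr_lcadc(120, 1e-6) - ideal_snr_lcadc(60, 1e-6)
        assert drop == pytest.approx(-6.02, abs=0.005)

    def test_adc_snr_and_equivalence(self):
        assert ideal_snr_adc(1) == pytest.approx(7.78)
        # the LCADC figure matches a ~11.9-bit classical converter
        assert abs(ideal_snr_adc(11.9) - 73.25) < 0.2
        assert round((73.25 - 1.76) / 6.02, 1) == 11.9


class TestUpsample:
    def test_identity(self):
        y = DenseSignal(np.arange(10.0), 10.0)
        out = upsample(y, 1)
        np.testing.assert_array_equal(out.samples, y.samples)

    def test_constant(self):
        y = DenseSignal(np.full(50, 3.7), 100.0)
        out = upsample(y, 400)
        assert np.allclose(out.samples, 3.7, atol=1e-9)
        assert out.fs_dense == pytest.approx(40_000.0)

    def test_sinusoid_against_closed_form(self):
        fs, u = 360.0, 400
        t = np.arange(int(fs)) / fs
        y = DenseSignal(np.sin(2 * np.pi * 5 * t), fs)
        out = upsample(y, u)
        ref = np.sin(2 * np.pi * 5 * out.times)
        interior = slice(10 * u, -10 * u)  # spline ends are extrapolation-adjacent
        assert np.max(np.abs(out.samples[interior] - ref[interior])) < 1e-3

    def test_passes_through_inputs(self):
        rng = np.random.default_rng(0)
        y = DenseSignal(rng.normal(size=30), 30.0)
        out = upsample(y, 7)
        np.testing.assert_allclose(out.samples[::7], y.samples, atol=1e-12)

    def test_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            upsample(DenseSignal(np.arange(5.0), 5.0), 0)


def _smooth_signal(seed, fs=4000.0, duration=1.0):
    """Random band-limited test signal (few low-frequency components)."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(fs * duration)) / fs
    x = np.zeros_like(t)
    for _ in range(4):
        f = rng.uniform(0.5, 40)
        x += rng.uniform(0.2, 1) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return DenseSignal(x, fs)


class TestLCSample:
    def test_constant_signal_no_events(self):
        cfg = LCConfig(delta_v=1.0, m_bits=5)
        s = DenseSignal(np.full(1000, 0.4), 1000.0)
        assert len(lc_sample(s, cfg, origin=0.0)) == 0

    @pytest.mark.parametrize("m", [3, 5, 8])
    def test_ramp_full_grid(self, m):
        cfg = LCConfig(delta_v=1.0, m_bits=m)
        s = DenseSignal(np.linspace(0, 1, 20_000), 20_000.0)
        ev = lc_sample(s, cfg, origin=0.0)
        assert len(ev) == 2**m - 1
        np.testing.assert_allclose(ev.amplitudes, cfg.q * np.arange(1, 2**m), atol=1e-12)

    @given(seed=st.integers(0, 200))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_hysteresis_and_grid_invariants(self, seed):
        s = _smooth_signal(seed)
        cfg = LCConfig(delta_v=float(np.ptp(s.samples)), m_bits=5)
        ev = lc_sample(s, cfg, origin=float(s.samples.min()))
        ev.validate()  # step == q, on-grid amplitudes, strictly increasing ticks

    def test_event_count_monotone_in_resolution(self):
        s = _smooth_signal(3)
        counts = []
        for m in range(3, 9):
            cfg = LCConfig(delta_v=float(np.ptp(s.samples)), m_bits=m)
            counts.append(len(lc_sample(s, cfg, origin=float(s.samples.min()))))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_mean_rate_below_max_rate(self):
        # near-full-scale sinusoid at an incommensurate frequency
        f = 13.7
        sig = gen_sinusoid(f, amplitude=0.999, duration=1.0, fs_dense=100_000.0)
        cfg = LCConfig(delta_v=2.0, m_bits=5, f_timer=1e6)
        ev = lc_sample(sig, cfg, origin=-1.0)
        span = (ev.ticks[-1] - ev.ticks[0]) / cfg.f_timer
        assert len(ev) / span <= max_rate(f, cfg, a_in=2.0)

    def test_crossing_times_match_closed_form(self):
        """Piecewise-linear input: simulator ticks vs exact crossing times."""
        cfg = LCConfig(delta_v=8.0, m_bits=4, f_timer=1e4)
        knots_t = np.array([0.0, 0.3, 0.5, 0.8, 1.0])
        knots_y = np.array([0.1, 6.9, 2.2, 7.4, 0.6])
        fs = 1e6
        t = np.arange(int(fs)) / fs
        sig = DenseSignal(np.interp(t, knots_t, knots_y), fs)
        ev = lc_sample(sig, cfg, origin=0.0)
        ev.validate()

        # independent closed-form hysteresis walk over the exact line segments
        q = cfg.q
        u = knots_y / q
        last = math.floor(u[0])
        exact = []
        for k in range(len(u) - 1):
            u0, u1 = u[k], u[k + 1]
            t0, t1 = knots_t[k], knots_t[k + 1]
            step = 1 if u1 > u0 else -1
            v = last + step
            while (v <= u1) if step > 0 else (v >= u1):
                exact.append((v * q, t0 + (v - u0) / (u1 - u0) * (t1 - t0)))
                last = v
                v += step
        assert len(exact) == len(ev)
        np.testing.assert_allclose(ev.amplitudes, [a for a, _ in exact], atol=1e-12)
        exact_ticks = np.floor(np.array([tt for _, tt in exact]) * cfg.f_timer)
        assert np.max(np.abs(ev.ticks - exact_ticks)) <= 1

    def test_overrange_clips_with_warning(self):
        cfg = LCConfig(delta_v=1.0, m_bits=4)
        s = DenseSignal(np.linspace(-0.5, 1.5, 5000), 5000.0)
        with pytest.warns(RuntimeWarning, match="clipping"):
            ev = lc_sample(s, cfg, origin=0.0)
        assert ev.amplitudes.max() <= 1.0 + 1e-12

    def test_timer_overflow_raises(self):
        cfg = LCConfig(delta_v=1.0, m_bits=3, f_timer=1e6, timer_bits=8)
        s = DenseSignal(np.concatenate([np.linspace(0, 1, 100),
                                        np.full(5000, 1.0),
                                        np.linspace(1, 0, 100)]), 1000.0)
        with pytest.raises(TimerOverflowError):
            lc_sample(s, cfg, origin=0.0)


class TestReconstruct:
    def test_ramp_within_half_quantum(self):
        cfg = LCConfig(delta_v=1.0, m_bits=6)
        s = DenseSignal(np.linspace(0, 1, 50_000), 50_000.0)
        ev = lc_sample(s, cfg, origin=0.0)
        rec = reconstruct(ev, fs_out=s.fs_dense)
        truth = rec.times  # the ramp is the identity map on [0, 1] seconds
        assert np.max(np.abs(rec.samples - truth)) <= cfg.q / 2 + 1e-6

    def test_two_events_straight_line(self):
        cfg = LCConfig(delta_v=1.0, m_bits=4, f_timer=1e6)
        ev = LCEventStream(np.array([0.2, 0.2 + cfg.q]),
                           np.array([0, 1_000_000]), cfg, origin=0.2)
        rec = reconstruct(ev, fs_out=10.0)
        np.testing.assert_allclose(np.diff(rec.samples),
                                   np.full(len(rec) - 1, cfg.q / 10), atol=1e-12)

    def test_too_few_events(self):
        cfg = LCConfig(delta_v=1.0, m_bits=4)
        ev = LCEventStream(np.array([0.5]), np.array([3]), cfg)
        with pytest.raises(ValueError):
            reconstruct(ev, 100.0)


class TestMeasureSNR:
    def test_identical_signals_capped(self):
        s = DenseSignal(np.sin(np.linspace(0, 10, 1000)), 100.0)
        assert measure_snr(s, s) > 300

    def test_known_noise_matches_analytic(self, rng):
        n = 100_000
        x = np.sqrt(2) * np.sin(2 * np.pi * 5 * np.arange(n) / 1000)  # unit power
        sd = 0.01
        noisy = x + rng.normal(0, sd, n)
        got = measure_snr(DenseSignal(x, 1000.0), DenseSignal(noisy, 1000.0))
        assert got == pytest.approx(10 * math.log10(1 / sd**2), abs=0.5)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=1000)
        y = x + rng.normal(0, 0.1, 1000)
        a = measure_snr(DenseSignal(x, 1.0), DenseSignal(y, 1.0))
        b = measure_snr(DenseSignal(5 * x, 1.0), DenseSignal(5 * y, 1.0))
        assert a == pytest.approx(b, abs=1e-9)

    def test_mismatched_grids(self):
        a = DenseSignal(np.zeros(10), 10.0)
        with pytest.raises(ValueError):
            measure_snr(a, DenseSignal(np.zeros(11), 10.0))
        with pytest.raises(ValueError):
            measure_snr(a, DenseSignal(np.zeros(10), 20.0))
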