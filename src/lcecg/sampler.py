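"""Level-crossing ADC simulator with hysteresis and timer-tick timestamping.

A level-crossing converter (LCADC) emits a sample only when the quasi-analog
input crosses the amplitude grid level one quantum ``q = dV/(2^M - 1)``
above or below the last emitted level (hysteresis rule ``x_n = x_{n-1} +/- q``).
Amplitudes are exact grid values; event times are quantized by a timer
running at ``f_timer`` with a ``timer_bits``-wide counter.

Analytic figures of merit:

* ideal LCADC SNR, a function of the test-sinusoid frequency and the timer
  period only: ``SNR_dB = -11.19 - 20 log10(fsig * T_timer)``;
* ideal classical-ADC SNR ``6.02 M + 1.76`` dB for an M-bit converter;
* maximum event rate for a full-band input,
  ``Fs_max = 2 fmax (2^M - 2) A_in / dV``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .synthetic import DenseSignal

__all__ = [
    "LCConfig",
    "LCEventStream",
    "TimerOverflowError",
    "upsample",
    "quantum",
    "max_rate",
    "ideal_snr_lcadc",
    "ideal_snr_adc",
    "lc_sample",
    "reconstruct",
    "measure_snr",
    "SNR_CAP_DB",
]

#: Sentinel SNR (dB) reported when the error power is exactly zero.
SNR_CAP_DB = 400.0


@dataclass(frozen=True)
class LCConfig:
    """Level-crossing converter parameters.

    delta_v : amplitude dynamic (full-scale range, signal units)
    m_bits  : resolution; the grid has 2^M levels spaced by q = dV/(2^M - 1)
    f_timer : timestamp clock frequency, Hz
    timer_bits : width of the inter-event timer counter
    """

    delta_v: float
    m_bits: int = 5
    f_timer: float = 1e6
    timer_bits: int = 21

    def __post_init__(self) -> None:
        if self.m_bits < 2:
            raise ValueError("m_bits must be >= 2")
        if self.delta_v <= 0:
            raise ValueError("delta_v must be positive")
        if self.f_timer <= 0:
            raise ValueError("f_timer must be positive")
        if self.timer_bits < 1:
            raise ValueError("timer_bits must be >= 1")

    @property
    def q(self) -> float:
        """Quantum q = dV / (2^M - 1)."""
        return self.delta_v / (2**self.m_bits - 1)

    @property
    def n_levels(self) -> int:
        return 2**self.m_bits


class TimerOverflowError(RuntimeError):
    """Raised when an inter-event gap exceeds the timer counter capacity."""


@dataclass
class LCEventStream:
    """Non-uniform level-crossing samples.

    ``amplitudes`` are exact grid values ``origin + k*q``; ``ticks`` are
    integer timer counts (strictly increasing).
    """

    amplitudes: np.ndarray
    ticks: np.ndarray
    config: LCConfig
    origin: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.ticks = np.asarray(self.ticks, dtype=np.int64)
        if self.amplitudes.shape != self.ticks.shape:
            raise ValueError("amplitudes and ticks must have equal length")

    def __len__(self) -> int:
        return self.amplitudes.size

    @property
    def times(self) -> np.ndarray:
        """Event times in seconds (ticks / f_timer)."""
        return self.ticks / self.config.f_timer

    def validate(self) -> None:
        """Assert the hysteresis, grid and timer invariants."""
        q = self.config.q
        if len(self) == 0:
            return
        k = (self.amplitudes - self.origin) / q
        if not np.allclose(k, np.round(k), atol=1e-9):
            raise AssertionError("amplitudes off the q-grid")
        if len(self) > 1:
            steps = np.diff(self.amplitudes)
            if not np.allclose(np.abs(steps), q, rtol=1e-9, atol=1e-12):
                raise AssertionError("hysteresis step != q between consecutive events")
            dticks = np.diff(self.ticks)
            if np.any(dticks <= 0):
                raise AssertionError("ticks not strictly increasing")
            if np.any(dticks >= 2**self.config.timer_bits):
                raise TimerOverflowError("inter-event gap exceeds timer capacity")

    def slice(self, start: int, stop: int) -> "LCEventStream":
        """Contiguous sub-stream [start, stop)."""
        return LCEventStream(
            self.amplitudes[start:stop], self.ticks[start:stop], self.config, self.origin
        )


def upsample(y: DenseSignal, u: int) -> DenseSignal:
    """Cubic-spline upsampling by an integer factor ``u``.

    Reconstructs the quasi-analog signal from a uniformly sampled record;
    the output passes through the input samples at the original instants.
    """
    if u < 1:
        raise ValueError("upsampling factor must be >= 1")
    if u == 1:
        return DenseSignal(y.samples.copy(), y.fs_dense, y.t0)
    t_in = y.times
    spline = CubicSpline(t_in, y.samples)
    fs_out = y.fs_dense * u
    n_out = (len(y) - 1) * u + 1
    t_out = y.t0 + np.arange(n_out) / fs_out
    return DenseSignal(spline(t_out), fs_out, y.t0)


def quantum(config: LCConfig) -> float:
    """Amplitude quantum q = dV / (2^M - 1)."""
    return config.q


def max_rate(fmax: float, config: LCConfig, a_in: float | None = None) -> float:
    """Maximum LCADC event rate for a sinusoid of amplitude ``a_in``.

    ``Fs_max = 2 * fmax * (2^M - 2) * a_in / delta_v``; full-scale input
    (``a_in = delta_v``) by default.
    """
    if fmax <= 0:
        raise ValueError("fmax must be positive")
    if a_in is None:
        a_in = config.delta_v
    if not 0 < a_in <= config.delta_v:
        raise ValueError("a_in must lie in (0, delta_v]")
    return 2.0 * fmax * (2**config.m_bits - 2) * (a_in / config.delta_v)


def ideal_snr_lcadc(fsig: float, t_timer: float) -> float:
    """Ideal LCADC SNR in dB: -11.19 - 20*log10(fsig * T_timer)."""
    if fsig <= 0 or t_timer <= 0:
        raise ValueError("fsig and t_timer must be positive")
    return -11.19 - 20.0 * math.log10(fsig * t_timer)


def ideal_snr_adc(m_bits: float) -> float:
    """Ideal classical-ADC SNR in dB: 6.02*M + 1.76."""
    if m_bits <= 0:
        raise ValueError("m_bits must be positive")
    return 6.02 * m_bits + 1.76


def lc_sample(x: DenseSignal, config: LCConfig, origin: float | None = None) -> LCEventStream:
    """Simulate level-crossing sampling with hysteresis.

    The dense input is treated as piecewise-linear between samples; an
    event is emitted exactly when it crosses the grid level one quantum
    above or below the last emitted amplitude.  Crossing times are located
    by linear interpolation and quantized to timer ticks (floor); colliding
    ticks are bumped to keep the counter strictly increasing.

    Input outside ``[origin, origin + delta_v]`` is clipped with a warning.
    """
    s = np.asarray(x.samples, dtype=float)
    if origin is None:
        origin = float(s.min()) if s.size else 0.0
    top = origin + config.delta_v
    if s.size and (s.min() < origin - 1e-12 or s.max() > top + 1e-12):
        warnings.warn("input exceeds the converter dynamic; clipping", RuntimeWarning)
        s = np.clip(s, origin, top)
    if s.size < 2:
        return LCEventStream(np.empty(0), np.empty(0, dtype=np.int64), config, origin)

    q = config.q
    u = (s - origin) / q  # continuous level index in [0, 2^M - 1]
    f = np.floor(u).astype(np.int64)
    candidates = np.nonzero(f[1:] != f[:-1])[0]

    last = int(min(max(f[0], 0), config.n_levels - 1))
    dt = 1.0 / x.fs_dense
    f_timer = config.f_timer
    amps: list[float] = []
    ticks: list[int] = []
    last_tick: int | None = None

    def emit(level: int, t: float) -> None:
        nonlocal last_tick
        tick = math.floor(t * f_timer)
        if last_tick is not None and tick <= last_tick:
            tick = last_tick + 1
        last_tick = tick
        amps.append(origin + level * q)
        ticks.append(tick)

    for i in candidates:
        u0 = u[i]
        u1 = u[i + 1]
        if u1 > u0:
            v = last + 1
            while v <= u1:
                frac = (v - u0) / (u1 - u0)
                emit(v, x.t0 + (i + frac) * dt)
                last = v
                v += 1
        else:
            v = last - 1
            while v >= u1:
                frac = (v - u0) / (u1 - u0)
                emit(v, x.t0 + (i + frac) * dt)
                last = v
                v -= 1

    stream = LCEventStream(np.array(amps), np.array(ticks, dtype=np.int64), config, origin)
    if len(stream) > 1 and np.any(np.diff(stream.ticks) >= 2**config.timer_bits):
        raise TimerOverflowError("inter-event gap exceeds timer capacity")
    return stream


def reconstruct(events: LCEventStream, fs_out: float) -> DenseSignal:
    """Linear-interpolation reconstruction of an event stream on a uniform grid."""
    if len(events) < 2:
        raise ValueError("reconstruction needs at least 2 events")
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    t = events.times
    n = int(math.floor((t[-1] - t[0]) * fs_out)) + 1
    grid = t[0] + np.arange(n) / fs_out
    return DenseSignal(np.interp(grid, t, events.amplitudes), fs_out, t0=float(t[0]))


def measure_snr(reference: DenseSignal, test: DenseSignal) -> float:
    """Empirical SNR in dB: 10*log10(signal power / error power).

    Both signals must share length and rate.  A zero-error comparison
    returns the :data:`SNR_CAP_DB` sentinel (reported as > 300 dB).
    """
    if len(reference) != len(test):
        raise ValueError("signals must have equal length")
    if not math.isclose(reference.fs_dense, test.fs_dense, rel_tol=1e-9):
        raise ValueError("signals must share the sampling rate")
    ref = reference.samples
    err = ref - test.samples
    p_sig = float(np.mean(ref**2))
    p_err = float(np.mean(err**2))
    if p_err == 0.0:
        return SNR_CAP_DB
    return min(10.0 * math.log10(p_sig / p_err), SNR_CAP_DB)
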